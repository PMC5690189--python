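# Generator calibration constants for modality-characteristic DVH shapes.
# These are properties of the synthetic-cohort generator, not published
# model parameters.  Fractions are of organ volume; scales/spreads in Gy.
#
# Qualitative targets encoded here: the rotational-IMRT profile trades
# high-dose volume for a much larger low-dose bath; the proton profile
# reduces both; conformal photon therapy sits between.

["3DCRT"]
rbe_factor = 1.0

["3DCRT".heart]
in_field_fraction = 0.12
bath_fraction = 0.30
bath_scale_gy = 3.0
penumbra_gy = 1.2
jitter = 0.25

["3DCRT".lung]
in_field_fraction = 0.25
bath_fraction = 0.30
bath_scale_gy = 3.0
penumbra_gy = 1.5
jitter = 0.10

["3DCRT".breast]
in_field_fraction = 0.04
bath_fraction = 0.25
bath_scale_gy = 2.5
penumbra_gy = 1.5
jitter = 0.12

[HT]
rbe_factor = 1.0

[HT.heart]
in_field_fraction = 0.10
bath_fraction = 0.60
bath_scale_gy = 4.0
penumbra_gy = 1.0
jitter = 0.25

[HT.lung]
in_field_fraction = 0.22
bath_fraction = 0.72
bath_scale_gy = 6.0
penumbra_gy = 1.2
jitter = 0.10

[HT.breast]
in_field_fraction = 0.03
bath_fraction = 0.85
bath_scale_gy = 4.5
penumbra_gy = 1.2
jitter = 0.12

[IMPT]
rbe_factor = 1.1

[IMPT.heart]
in_field_fraction = 0.09
bath_fraction = 0.15
bath_scale_gy = 2.0
penumbra_gy = 1.0
jitter = 0.25

[IMPT.lung]
in_field_fraction = 0.15
bath_fraction = 0.18
bath_scale_gy = 2.5
penumbra_gy = 1.0
jitter = 0.10

[IMPT.breast]
in_field_fraction = 0.03
bath_fraction = 0.06
bath_scale_gy = 1.5
penumbra_gy = 1.0
jitter = 0.12
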