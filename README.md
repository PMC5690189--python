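# dvhrisk

Late-toxicity risk modelling for thoracic radiotherapy from organ-at-risk
dose-volume histograms (DVHs):

* **Cardiac mortality** — relative seriality (Poisson) NTCP model on the
  heart DVH.
* **Secondary lung / breast cancer** — modified linear-quadratic
  cancer-induction model (organ-equivalent dose), reported as excess
  absolute risk (EAR) in cases per 10,000 person-years.
* **Cohort comparison** — per-patient risk tables across treatment
  modalities (3D CRT, helical tomotherapy, intensity-modulated proton
  therapy), modality-vs-reference risk ratios, paired t-tests, and
  dose-uncertainty / neutron-bath sensitivity analyses.
* **Synthetic cohort generator** — seeded, modality-characteristic DVH
  cohorts (truncated-normal in-field component + exponential low-dose bath
  + unirradiated remainder) so the full pipeline is testable without
  clinical data.

## Layout

| module | contents |
| --- | --- |
| `dvhrisk.dvh` | DVH types, CSV I/O, differential/cumulative conversion, rebinning, Vx / mean dose / dose scaling |
| `dvhrisk.params` | parameter sets + TOML config loading (defaults shipped in `dvhrisk/data/default_params.toml`) |
| `dvhrisk.seriality` | subvolume response, whole-organ NTCP, voxelwise reference route, optional EQD2 transform |
| `dvhrisk.schneider` | EAR density, whole-organ EAR, organ-equivalent dose |
| `dvhrisk.synth` | patient specs, modality profiles, seeded DVH/cohort generation, cohort I/O |
| `dvhrisk.stats` | cohort risk tables, risk ratios, paired t-test, sensitivity sweeps |
| `dvhrisk.cli` | `dvhrisk` command-line interface |

## CLI

```sh
# generate a 20-patient synthetic cohort (3 plans per patient)
dvhrisk generate --n 20 --seed 1 --out cohort_dir

# score a differential DVH CSV
dvhrisk risk --dvh dvhs.csv --out risks.csv

# analyze an existing cohort directory (risk table, ratios, t-tests)
dvhrisk analyze --cohort cohort_dir --out report_dir \
    --dose-uncertainty 0.1 --neutron-bath 50

# end to end: generate -> risks -> stats -> CSVs + figures
dvhrisk run --n 20 --seed 1 --out report_dir
```

DVH CSV dialects (UTF-8, header required):

* differential: `patient_id, modality, organ, bin_lo_gy, bin_hi_gy, frac_volume`
* cumulative: `patient_id, modality, organ, dose_gy, frac_volume_ge`

Fractional volumes of a differential DVH must sum to 1 per organ
(unirradiated volume goes in a zero-dose bin).

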