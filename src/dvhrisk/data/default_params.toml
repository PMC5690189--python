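# Default risk-model parameter sets.

[cardiac_mortality]
# relative seriality model, whole heart
d50 = 70.3      # Gy at 50% complication probability
gamma = 0.96    # maximum normalized dose-response slope
s = 1.0         # relative seriality
horizon_years = 15

[lung_cancer]
# modified linear-quadratic cancer induction, whole paired lung
rf = 0.84       # repopulation/repair fraction
alpha = 0.061   # per Gy
mu = 2.7        # cases per 10,000 person-years per Gy
horizon_years = 30

[breast_cancer]
rf = 0.62
alpha = 0.067
mu = 4.8
horizon_years = 30
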