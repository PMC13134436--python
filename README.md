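# ammoflow

Myocardial blood flow (MBF) and flow reserve (MFR) quantitation from
dynamic ¹³N-ammonia PET time–activity curves (TACs), for researchers who
study how kinetic-model choice affects clinically reported perfusion
values.

Clinical software quantifies MBF by fitting a compartment model to the
first 2–3 minutes of dynamic data, but different packages implement
different models. `ammoflow` implements the three in common use and makes
their disagreement measurable on fully synthetic data with known ground
truth:

- **1TCM** — one-tissue model, dC_myo/dt = K1·C_P − k2·C_myo, linear
  metabolite correction, 4 free parameters (K1, k2, V_LV, V_RV), 0–3 min
  window;
- **Hutchins** — two-tissue model with irreversible trapping
  (dC1/dt = K1·C_P − (k2+k3)·C1, dC2/dt = k3·C1), delayed-exponential
  metabolite correction (t0 = 0.48 min, T½ = 6.69 min), 5 parameters,
  0–2 min window;
- **UCLA** — constrained two-tissue model with k2 = K1/V_ND
  (V_ND = 0.8 mL/g) and k3 = K1/(1.65·e^(1.25/K1) − 1), 3 parameters
  (K1, V_LV, V_RV), 0–2 min window.

All models include dual spillover from the LV and RV blood pools:
C_model = (1 − V_LV − V_RV)·C_tissue + V_LV·C_LV + V_RV·C_RV. Parameters
are estimated per AHA segment by weighted nonlinear least squares; MBF is
the fitted K1 (standard for ¹³N-ammonia), MFR = stress MBF / rest MBF, and
results aggregate to LAD/LCX/RCA territories and a global value. A seeded
simulator generates bolus input functions, tissue responses, count-limited
noise, stress/rest carryover and whole cohorts; the statistics harness
computes Pearson ρ, Bland–Altman bias with 95% limits of agreement, and
one-way ANOVA with Tukey post hoc tests across models.

## Worked example

Simulate one noiseless subject with known kinetics and fit it with two
models:

```python
import numpy as np
import ammoflow as af

truth = af.SubjectTruth(
    k1_stress=np.full(17, 2.4),   # true stress MBF, mL/g/min
    k1_rest=np.full(17, 0.9),     # true rest MBF
    v_lv=0.30, v_rv=0.10,         # spillover fractions
    model_kind=af.ModelKind.ONE_TCM,
    noise_level=0.0, seed=11,
)
stress, rest = af.simulate_subject(truth)

for kind in ("1tcm", "ucla"):
    spec = af.ModelSpec.for_model(kind)
    res = af.fit_study(spec, stress, rest)
    s = res.summary()
    print(f"{kind:8s} global stress MBF {s['stress_mbf']['GLOBAL']:.3f}"
          f"  rest {s['rest_mbf']['GLOBAL']:.3f}"
          f"  MFR {s['mfr']['GLOBAL']:.3f}")
```

prints

```
1tcm     global stress MBF 2.403  rest 0.900  MFR 2.669
ucla     global stress MBF 4.106  rest 1.759  MFR 2.334
```

Fitting the generative model recovers the truth (2.4 / 0.9 / 2.67 —
stress K1 within 0.2%); fitting the UCLA model to the *same* curves
reports a much higher MBF, because its constraint layer assumes most of
the uptake washes back (k2 = K1/0.8) and compensates with a larger K1
when the data plateau. That systematic, rank-preserving divergence —
highest MBF under UCLA, near-perfect UCLA–1TCM correlation — is the
model-dependence mechanism the package quantifies at cohort scale.

The same pipeline is scriptable from the shell:

```
ammoflow simulate --n 20 --seed 7 --out cohort/
ammoflow fit cohort/ --model hutchins --out fits/
ammoflow compare cohort/ --model 1tcm --model hutchins --model ucla --out report/
```

`compare` writes `summary.tsv` (mean ± SD per index per model with
ANOVA/Tukey p), `correlations.tsv` (pairwise Pearson ρ at global and
territory levels) and `bland_altman.tsv` (pairwise bias and 95% limits of
agreement).

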