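# Methods

## Problem and scope

Dynamic ¹³N-ammonia PET estimates absolute myocardial blood flow (MBF,
mL/g/min) by fitting a compartmental model to the first minutes of
myocardial time–activity curves (TACs), using the LV blood-pool TAC as the
input function. Myocardial flow reserve (MFR) is the ratio of stress to
rest MBF. Different clinical software packages implement different kinetic
models, and the choice of model shifts the reported numbers. `ammoflow`
implements the three models in common clinical use, a per-segment fitting
pipeline (TACs in, segmental / territorial / global MBF and MFR out), a
synthetic-cohort simulator with exact ground truth, and the agreement
statistics used in method-comparison studies, so the model dependence of
MBF/MFR can be exercised end to end without patient data.

The pipeline begins at the TAC level. Image reconstruction, myocardial
contouring, VOI placement and motion correction are out of scope, as are
partial-volume recovery and ¹³N physical-decay modelling (all TACs are
assumed decay-corrected, as is standard for reconstructed dynamic PET).

## Kinetic models

All three models share the dual-spillover measurement equation

    C_model(t) = (1 − V_LV − V_RV)·C_tissue(t) + V_LV·C_LV(t) + V_RV·C_RV(t)

where V_LV, V_RV are blood-pool spillover fractions and C_LV, C_RV the LV
and RV cavity TACs. They differ in the tissue model and in how the plasma
input C_P is obtained from C_LV:

**One-tissue model (1TCM).** dC_myo/dt = K1·C_P − k2·C_myo, with linear
metabolite correction C_P(t) = (1 − m_corr·t)·C_LV(t). Free parameters:
K1, k2, V_LV, V_RV (4). Default fitting window 0–3 min. The linear factor
is clamped at zero — the raw expression goes negative for t > 1/m_corr and
a negative plasma concentration is unphysical. The slope m_corr defaults to
0 (correction disabled): no standard value exists that we are willing to
bake in as ground truth, so a nonzero slope must be supplied explicitly.

**Hutchins two-tissue model.** dC1/dt = K1·C_P − (k2+k3)·C1,
dC2/dt = k3·C1 (irreversible trapping, glutamine synthesis), with the
delayed-exponential metabolite correction: C_P = C_LV for t ≤ t0 and
C_P = exp(−ln2·(t−t0)/T½)·C_LV after, with t0 = 0.48 min and
T½ = 6.69 min. Free parameters: K1, k2, k3, V_LV, V_RV (5). Window
0–2 min.

**UCLA constrained two-tissue model.** Same state equations, but k2 and k3
are functions of K1: k2 = K1/V_ND with fixed distribution volume
V_ND = 0.8 mL/g, and k3 = K1/(1.65·e^(1.25/K1) − 1). Free parameters: K1,
V_LV, V_RV (3). Window 0–2 min, no metabolite correction (the short window
itself limits metabolite influence). The k3 expression is monotone
increasing in K1 with k3 → 0 as K1 → 0⁺, which the implementation returns
exactly at K1 = 0; this parse was adopted for dimensional consistency and
sensible limits.

MBF is reported as the fitted K1 for all three models: first-pass
extraction of ammonia is near unity and none of the clinical
implementations documents a separate flow–extraction conversion. k2/k3
estimates are retained as diagnostics, not clinical outputs.

## Numerics

Time inside the kinetics layer is in minutes (the constants above are in
minutes); frame schedules are stored in seconds and converted at the
boundary. Continuous curves live on a uniform fine grid of 1/240 min
(0.25 s), chosen so the 5-s clinical frames contain an integer number of
grid steps; inputs are treated as piecewise-linear between nodes.

The compartment solutions are computed by *exact* convolution against the
piecewise-linear input — closed form per linear segment, accumulated with
an exponentially rescaled cumulative sum (with a sequential fallback when
λ·t would overflow the rescaling) — not by generic ODE stepping. The
trapped compartment is also exact: for λ = k2 + k3 > 0,
C2 = (k3/λ)·(K1·∫C_P − C1), where the cumulative integral of a
piecewise-linear curve is itself exact. Against an independent stiff ODE
integrator (LSODA at rtol 1e−10) the curves agree to ~1e−8 relative — the
forward model contributes no discretisation error at fitting precision.

Frame averaging is the exact time-average of the piecewise-linear curve
over each frame, assembled once per (grid, schedule) as a weight matrix.

## Fitting

Weighted nonlinear least squares per segment. Residuals are weighted by
frame duration (longer frames have lower count noise); uniform weights are
available. Frames enter the fit if their midpoint lies in the model's
window. Bounds: K1 ∈ (0, 10] mL/g/min, k2, k3 ∈ [0, 10] /min,
V_LV, V_RV ∈ [0, 0.9]; the physical constraint V_LV + V_RV < 1 is enforced
by a smooth penalty residual, 50·max(0, V_LV+V_RV − 0.97), which keeps the
squared cost C¹-smooth. The optimiser is SciPy's trust-region-reflective
least-squares solver with tight tolerances (1e−12): the classic
Levenberg–Marquardt iteration solves the same weighted-SSQ problem but
supports no bounds in SciPy, and the trust-region variant is its bounded
counterpart. Fits are single-start (K1 = 1.0, k2 = 0.5, k3 = 0.1,
V_LV = 0.3, V_RV = 0.1) and deterministic; two alternative starts are
tried only if the first fails to converge, and non-convergence is flagged
in the result rather than silently accepted.

**Input reconstruction.** Measured blood-pool TACs are frame *averages* of
the continuous concentration. Fitting reconstructs a continuous input by
monotone-cubic (PCHIP) interpolation of the cumulative integral at frame
boundaries and differentiation of the interpolant. This reconstruction
reproduces every measured frame average exactly and is smooth and
non-negative for non-negative TACs; it is what lets noiseless
simulate-then-fit recover K1 to ≪0.5% even though the simulator and the
fitter never share a continuous curve (no inverse crime).

**Carryover.** Rest studies acquired shortly after stress retain residual
activity. The first-frame-subtraction correction subtracts each TAC's
first-frame value (acquired before the rest bolus arrives) from all its
frames, clamping at zero.

## Geometry

Segmental values follow the AHA 17-segment numbering. Two territory
schemes are provided. The standard mapping assigns LAD = {1,2,7,8,13,14,17},
LCX = {5,6,11,12,16}, RCA = {3,4,9,10,15}. The geometric-sector scheme
partitions the polar map into a 150° LAD sector centred on the anterior
wall, then clockwise 105° LCX and 105° RCA sectors; each segment is
assigned by its centroid angle and the apex (segment 17) is always LAD.
The angular origin is a package choice (anterior wall = 0°, clockwise on
the standard polar display, so lateral = 90°); under AHA centroid angles
this yields territory sizes 8/3/6 rather than the standard 7/5/5 — an
honest consequence of sector geometry, since the 150° anterior sector
captures both ±60° centroid columns. Territory and global values are
unweighted means of member segments (no area weighting); the global mean
is therefore scheme-invariant.

## Synthetic data

The simulator defines the study conditions under which the pipeline is
validated.

**Input function.** A peak-normalised gamma-variate,
A·((t−ta)/(αβ))^α·e^(α−(t−ta)/β), zero before arrival ta, peaking at
ta + αβ with value A, plus a recirculation plateau equal to a fraction of
the running peak, low-pass filtered (single pole, τ = 0.3 min). Defaults:
ta = 0.15 min, α = 3, β = 0.08 min, A = 100 kBq/mL, recirculation 0.15 —
a bolus whose ~0.2-min peak the 5-s frames resolve. The RV curve leads the
LV curve by 0.05 min at 1.2× amplitude (the right heart sees the less
dispersed bolus first).

**Tissue truth.** Because ammonia is metabolically trapped, clinical
myocardial TACs plateau rather than wash out; the one-tissue generator
therefore uses a small fixed apparent washout k2 = 0.2 /min, and the
Hutchins generator mid-range literature rates k2 = 0.6, k3 = 0.15 /min.
The UCLA generator derives both rates from K1 via its constraint layer.
Spillover truth defaults to V_LV = 0.30, V_RV = 0.10.

**Noise.** Additive Gaussian with σᵢ = level·sqrt(max(valueᵢ, 1)/durationᵢ[s])
— variance proportional to activity and inversely to frame duration,
emulating reconstructed count statistics without full Poisson modelling.
Default level 1.0 gives roughly 10–15% relative noise on mid-uptake 5-s
frames; blood-pool TACs use 0.5× that level, reflecting the larger
averaging volume of cavity VOIs. Noise is applied after frame averaging
(and after the optional constant rest-carryover residual), seeded and
reproducible.

**Cohorts.** Per-subject global rest and stress MBF are drawn from
truncated normals (rest 0.93 ± 0.20, stress 2.42 ± 0.80 mL/g/min, floor
0.2 — typical referral-population values), with shared per-segment
multipliers (CV 10%, floored at 0.3) applied to both conditions.
Disease composition defaults to 60/20/10/10 percent normal / single- /
two- / three-vessel; affected territories (standard mapping) have stress
K1 scaled by 0.5. The lesion-territory draw consumes its own child RNG so
the K1 stream is identical across disease compositions, enabling paired
comparisons. Everything is reproducible from (parameters, seed).

**What the simulator does not emulate.** Image-space effects (contouring
error, motion, liver/stomach spillover into the inferior wall),
Poisson-deviating reconstruction noise correlations, inter-injection input
variability, and metabolite build-up in blood (the simulated LV curve *is*
the plasma input for the generating model). Passing recovery tests
therefore demonstrate estimator correctness under the stated generative
model, not clinical accuracy; conversely, the cross-model divergence the
pipeline demonstrates is a property of the model family itself and carries
over qualitatively to real data.

## Agreement statistics

Pearson product-moment correlation (undefined for constant input — raised
as an error, not returned as NaN); Bland–Altman bias with 95% limits of
agreement bias ± 1.96·SD (n−1 denominator; the z-multiplier, not the exact
t-quantile, matching common practice); one-way ANOVA with Tukey HSD post
hoc on the studentized-range distribution, two-sided α = 0.05 convention.
Normality is not re-tested by default, keeping the harness deterministic.
The cohort report emits mean ± SD with ANOVA/Tukey p per index (stress
MBF, rest MBF, MFR), pairwise Pearson ρ and Bland–Altman summaries at the
global and three territory levels, as delimited text tables.

## Validation problem sizes

Forward-model exactness is checked on 100 random parameter sets against an
LSODA oracle; noiseless recovery on 51 segments per model (3 subjects ×
17 segments spanning K1 0.5–3.5); noise bias on 200 replicates at the
default noise level; the model-dependence mechanism on a 100-subject
cohort in the test suite and a 60-subject cohort in the acceptance script.
These sizes give stable medians and Monte-Carlo CIs while keeping the full
validation run in the minutes range on a single core.

## Known limitations

- MBF = K1 is a convention; no extraction-fraction correction is applied.
- The geometric-sector territory sizes depend on the chosen angular origin;
  only the sector widths and ordering are fixed by the scheme definition.
- The penalty constant and cap for the spillover-sum constraint are
  heuristic; estimates with V_LV + V_RV near 1 indicate a degenerate fit
  regardless of the exact cap.
- No claim is made about which model is closest to true MBF; the package
  quantifies model dependence, not model correctness.
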