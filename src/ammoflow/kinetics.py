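"""Forward kinetic machinery for ¹³N-ammonia myocardial perfusion models.

This module holds the compartmental building blocks shared by fitting and
simulation: the dynamic frame schedule, continuous-curve plumbing, the
metabolite corrections that convert LV whole-blood activity to a plasma
input, the one- and two-tissue compartment solutions, dual LV/RV spillover
composition, and frame averaging.

Units
-----
Rate constants and continuous time are in minutes (K1 in mL/g/min; k2, k3
in 1/min), matching the conventional reporting of MBF.  Frame schedules are
stored in seconds, as acquisition protocols specify them, and converted at
the boundary.  Activity concentrations are kBq/mL throughout.  All curves
are assumed decay-corrected, as is standard for reconstructed dynamic PET.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SEC_PER_MIN",
    "FrameSchedule",
    "TimeActivityCurve",
    "ContinuousCurve",
    "KineticParams",
    "ModelKind",
    "MetaboliteCorrection",
    "ModelSpec",
    "TissueSolution",
    "default_frame_schedule",
    "uniform_grid",
    "metabolite_correct_linear",
    "metabolite_correct_delayed_exp",
    "plasma_input",
    "ucla_rate_constraints",
    "solve_tissue",
    "compose_model_tac",
    "frame_average",
    "frame_average_matrix",
]

SEC_PER_MIN = 60.0

#: Default fine-grid spacing in minutes.  1/240 min (0.25 s) divides the 5 s
#: clinical frame length exactly, so frame boundaries fall on grid nodes.
DEFAULT_GRID_DT = 1.0 / 240.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frames (seconds)."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(durations <= 0):
            raise ValueError("all frame durations must be positive")
        if starts[0] < 0:
            raise ValueError("schedule must not start before t = 0")
        expected = starts[:-1] + durations[:-1]
        if not np.allclose(starts[1:], expected, rtol=0, atol=1e-9):
            bad = int(np.argmax(~np.isclose(starts[1:], expected, rtol=0, atol=1e-9)))
            raise ValueError(
                f"frames must be contiguous: frame {bad + 1} starts at "
                f"{starts[bad + 1]} s but frame {bad} ends at {expected[bad]} s"
            )

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def end_time(self) -> float:
        """End of the last frame, seconds."""
        return float(self.ends[-1])

    @property
    def mid_minutes(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return (self.starts + 0.5 * self.durations) / SEC_PER_MIN

    @property
    def duration_minutes(self) -> np.ndarray:
        return self.durations / SEC_PER_MIN


@dataclass(frozen=True)
class TimeActivityCurve:
    """Measured (or simulated) activity concentration per frame, kBq/mL."""

    schedule: FrameSchedule
    values: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.schedule.n_frames:
            raise ValueError(
                f"expected {self.schedule.n_frames} frame values, got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("TAC values must be finite")

    def with_values(self, values: np.ndarray) -> "TimeActivityCurve":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class ContinuousCurve:
    """Piecewise-linear curve on a fine time grid (minutes, kBq/mL)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if times.size < 2:
            raise ValueError("curve needs at least two samples")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("curve values must be finite")

    def __call__(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.values)

    def with_values(self, values: np.ndarray) -> "ContinuousCurve":
        return replace(self, values=np.asarray(values, dtype=float))

    def same_grid(self, other: "ContinuousCurve") -> bool:
        return self.times.shape == other.times.shape and np.array_equal(
            self.times, other.times
        )


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameter set; the single home of every model symbol.

    K1 : uptake rate, mL/g/min (reported as MBF)
    k2 : washout rate of the exchangeable compartment, 1/min
    k3 : trapping rate (glutamine synthesis), 1/min
    v_lv, v_rv : LV / RV blood-pool spillover fractions (dimensionless)
    m_corr : linear metabolite-correction slope, 1/min
    v_nd : distribution volume of free tracer, mL/g
    """

    k1: float
    k2: float = 0.0
    k3: float = 0.0
    v_lv: float = 0.0
    v_rv: float = 0.0
    m_corr: float = 0.0
    v_nd: float = 0.8

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("K1 must be >= 0")
        if self.k2 < 0 or self.k3 < 0:
            raise ValueError("k2 and k3 must be >= 0")
        if self.v_lv < 0 or self.v_rv < 0:
            raise ValueError("spillover fractions must be >= 0")
        if self.v_lv + self.v_rv >= 1:
            raise ValueError("V_LV + V_RV must be < 1")
        if self.v_nd <= 0:
            raise ValueError("V_ND must be > 0")
        if self.m_corr < 0:
            raise ValueError("m_corr must be >= 0")


class ModelKind(str, enum.Enum):
    ONE_TCM = "1tcm"
    HUTCHINS = "hutchins"
    UCLA = "ucla"


class MetaboliteCorrection(str, enum.Enum):
    LINEAR = "linear"
    DELAYED_EXP = "delayed_exp"
    NONE = "none"


#: Free parameters estimated per model; all models add dual spillover.
FREE_PARAMS: dict[ModelKind, tuple[str, ...]] = {
    ModelKind.ONE_TCM: ("k1", "k2", "v_lv", "v_rv"),
    ModelKind.HUTCHINS: ("k1", "k2", "k3", "v_lv", "v_rv"),
    ModelKind.UCLA: ("k1", "v_lv", "v_rv"),
}

_DEFAULT_WINDOWS = {
    ModelKind.ONE_TCM: (0.0, 3.0),
    ModelKind.HUTCHINS: (0.0, 2.0),
    ModelKind.UCLA: (0.0, 2.0),
}

_DEFAULT_CORRECTION = {
    ModelKind.ONE_TCM: MetaboliteCorrection.LINEAR,
    ModelKind.HUTCHINS: MetaboliteCorrection.DELAYED_EXP,
    ModelKind.UCLA: MetaboliteCorrection.NONE,
}


@dataclass(frozen=True)
class ModelSpec:
    """A kinetic model choice plus its fitting window and fixed constants.

    Defaults per model: the one-tissue model fits (K1, k2, V_LV, V_RV) on
    0–3 min with linear metabolite correction; the Hutchins two-tissue model
    fits (K1, k2, k3, V_LV, V_RV) on 0–2 min with the delayed-exponential
    correction (t0 = 0.48 min, T1/2 = 6.69 min); the UCLA constrained
    two-tissue model fits (K1, V_LV, V_RV) on 0–2 min with k2 and k3 tied to
    K1 through V_ND = 0.8 mL/g and no metabolite correction.
    """

    kind: ModelKind
    window: tuple[float, float]
    metabolite: MetaboliteCorrection
    constants: dict = field(default_factory=dict)

    @property
    def free_params(self) -> tuple[str, ...]:
        return FREE_PARAMS[self.kind]

    @classmethod
    def for_model(
        cls,
        kind: ModelKind | str,
        window: tuple[float, float] | None = None,
        metabolite: MetaboliteCorrection | str | None = None,
        **constants,
    ) -> "ModelSpec":
        kind = ModelKind(kind)
        base = {"t0": 0.48, "half_life": 6.69, "v_nd": 0.8, "m_corr": 0.0}
        base.update(constants)
        corr = (
            _DEFAULT_CORRECTION[kind]
            if metabolite is None
            else MetaboliteCorrection(metabolite)
        )
        win = _DEFAULT_WINDOWS[kind] if window is None else tuple(window)
        if not win[1] > win[0] >= 0:
            raise ValueError("fit window must satisfy 0 <= start < end")
        return cls(kind=kind, window=win, metabolite=corr, constants=base)


# ---------------------------------------------------------------------------
# Schedules and grids
# ---------------------------------------------------------------------------

def default_frame_schedule() -> FrameSchedule:
    """The clinical 21-frame dynamic schedule: 15 × 5 s, 5 × 15 s, 1 × 30 s.

    Covers the first 180 s of the acquisition, contiguous from t = 0.
    """
    durations = np.concatenate([np.full(15, 5.0), np.full(5, 15.0), [30.0]])
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts=starts, durations=durations)


def uniform_grid(t_end_min: float, dt: float = DEFAULT_GRID_DT) -> np.ndarray:
    """Uniform time grid (minutes) on [0, t_end_min] with spacing <= dt."""
    if t_end_min <= 0:
        raise ValueError("t_end_min must be positive")
    n = int(np.ceil(t_end_min / dt))
    return np.linspace(0.0, n * dt, n + 1)


# ---------------------------------------------------------------------------
# Metabolite corrections (whole-blood LV activity -> plasma input)
# ---------------------------------------------------------------------------

def linear_metabolite_factor(t_min: np.ndarray, m_corr: float) -> np.ndarray:
    if m_corr < 0:
        raise ValueError("m_corr must be >= 0")
    return np.maximum(0.0, 1.0 - m_corr * np.asarray(t_min, dtype=float))


def delayed_exp_metabolite_factor(
    t_min: np.ndarray, t0: float, half_life: float
) -> np.ndarray:
    if t0 < 0:
        raise ValueError("t0 must be >= 0")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(t_min, dtype=float)
    return np.where(t <= t0, 1.0, np.exp(-np.log(2.0) * (t - t0) / half_life))


def metabolite_correct_linear(clv: ContinuousCurve, m_corr: float) -> ContinuousCurve:
    """Plasma input with linear metabolite correction.

    C_P(t) = max(0, 1 − m_corr·t) · C_LV(t).  The factor is clamped at zero:
    the raw linear expression turns negative for t > 1/m_corr and a negative
    plasma concentration is unphysical.
    """
    return clv.with_values(clv.values * linear_metabolite_factor(clv.times, m_corr))


def metabolite_correct_delayed_exp(
    clv: ContinuousCurve, t0: float = 0.48, half_life: float = 6.69
) -> ContinuousCurve:
    """Plasma input with the delayed-exponential metabolite correction.

    C_P(t) = C_LV(t) for t ≤ t0, then decays with effective half-life T1/2;
    continuous at t0.  Defaults t0 = 0.48 min, T1/2 = 6.69 min.
    """
    return clv.with_values(
        clv.values * delayed_exp_metabolite_factor(clv.times, t0, half_life)
    )


def plasma_input(spec: ModelSpec, clv: ContinuousCurve) -> ContinuousCurve:
    """Apply the spec's metabolite correction to the LV blood curve."""
    if spec.metabolite is MetaboliteCorrection.LINEAR:
        return metabolite_correct_linear(clv, spec.constants["m_corr"])
    if spec.metabolite is MetaboliteCorrection.DELAYED_EXP:
        return metabolite_correct_delayed_exp(
            clv, spec.constants["t0"], spec.constants["half_life"]
        )
    return clv


# ---------------------------------------------------------------------------
# UCLA rate constraints
# ---------------------------------------------------------------------------

def ucla_rate_constraints(k1: float, v_nd: float = 0.8) -> tuple[float, float]:
    """Washout and trapping rates tied to K1 in the constrained 2-tissue model.

    k2 = K1 / V_ND and k3 = K1 / (1.65·e^(1.25/K1) − 1).  As K1 → 0⁺ the
    trapping rate vanishes (the exponential dominates), so k3(0) = 0 exactly;
    k3 is monotone increasing in K1.
    """
    if k1 < 0:
        raise ValueError("K1 must be >= 0")
    if v_nd <= 0:
        raise ValueError("V_ND must be > 0")
    k2 = k1 / v_nd
    if k1 == 0.0:
        return k2, 0.0
    with np.errstate(over="ignore"):
        denom = 1.65 * np.exp(1.25 / k1) - 1.0
    if not np.isfinite(denom):  # K1 tiny: exp overflows, limit is 0
        return k2, 0.0
    return k2, float(k1 / denom)


# ---------------------------------------------------------------------------
# Compartment solutions (exact convolution against piecewise-linear input)
# ---------------------------------------------------------------------------

def _conv_exp(t: np.ndarray, f: np.ndarray, lam: float) -> np.ndarray:
    """y(t_n) = ∫₀^{t_n} f(s)·exp(−lam·(t_n − s)) ds, exact for piecewise-
    linear f on the (possibly non-uniform) grid t.  y(t_0) = 0."""
    dt = np.diff(t)
    a = f[:-1]
    b = f[1:]
    if lam == 0.0:
        seg = 0.5 * dt * (a + b)
        return np.concatenate([[0.0], np.cumsum(seg)])
    x = lam * dt
    em = np.exp(-x)
    # ∫₀^h (a + (b−a)u/h) e^{−lam(h−u)} du, closed form per segment
    seg = a * (1.0 - em) / lam + (b - a) * (x - (1.0 - em)) / (dt * lam * lam)
    if lam * (t[-1] - t[0]) < 500.0:
        # vectorised recursion via exponential rescaling; safe while
        # exp(lam·t_end) stays in range
        w = np.exp(lam * t[1:])
        return np.concatenate([[0.0], np.exp(-lam * t[1:]) * np.cumsum(seg * w)])
    # extreme lam·t: sequential recursion avoids overflow of exp(lam·t)
    y = np.zeros_like(f)
    for i in range(dt.size):
        y[i + 1] = y[i] * em[i] + seg[i]
    return y


def _cumint(t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exact cumulative integral of a piecewise-linear curve."""
    seg = 0.5 * np.diff(t) * (f[:-1] + f[1:])
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class TissueSolution:
    """Tissue compartment curves; c2 is None for the one-tissue model."""

    c1: ContinuousCurve
    c2: ContinuousCurve | None = None

    @property
    def total(self) -> ContinuousCurve:
        if self.c2 is None:
            return self.c1
        return self.c1.with_values(self.c1.values + self.c2.values)


def _tissue_values(
    kind: ModelKind, k1: float, k2: float, k3: float, t: np.ndarray, cp: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None]:
    """Array-level compartment solution shared by the public API and the
    fitting engine."""
    if kind is ModelKind.ONE_TCM:
        return k1 * _conv_exp(t, cp, k2), None
    lam = k2 + k3
    c1 = k1 * _conv_exp(t, cp, lam)
    if k3 == 0.0:
        return c1, np.zeros_like(c1)
    # dC2/dt = k3·C1 with C1 = K1·(Cp ⊛ e^{−lam s}) integrates exactly to
    # C2 = (k3/lam)·(K1·∫Cp − C1); lam > 0 is guaranteed here since k3 > 0.
    c2 = (k3 / lam) * (k1 * _cumint(t, cp) - c1)
    return c1, c2


def solve_tissue(
    kind: ModelKind | str, params: KineticParams, cp: ContinuousCurve
) -> TissueSolution:
    """Solve the tissue compartment(s) driven by the plasma input.

    One-tissue: C_myo(t) = K1·∫₀ᵗ C_P(s)·e^(−k2(t−s)) ds.
    Two-tissue (Hutchins, UCLA): C_1 with rate k2+k3, plus the irreversible
    trap C_2(t) = k3·∫₀ᵗ C_1(s) ds.  For UCLA, k2 and k3 are first derived
    from K1 via :func:`ucla_rate_constraints`.  The convolution is exact for
    the piecewise-linear input (closed form per linear segment), not generic
    ODE stepping.
    """
    kind = ModelKind(kind)
    if not np.all(np.isfinite(cp.values)):
        raise ValueError("plasma input contains non-finite values")
    k1, k2, k3 = params.k1, params.k2, params.k3
    if kind is ModelKind.UCLA:
        k2, k3 = ucla_rate_constraints(k1, params.v_nd)
    c1_vals, c2_vals = _tissue_values(kind, k1, k2, k3, cp.times, cp.values)
    c1 = cp.with_values(c1_vals)
    c2 = None if c2_vals is None else cp.with_values(c2_vals)
    return TissueSolution(c1=c1, c2=c2)


def compose_model_tac(
    tissue_total: ContinuousCurve,
    clv: ContinuousCurve,
    crv: ContinuousCurve,
    v_lv: float,
    v_rv: float,
) -> ContinuousCurve:
    """Dual blood-pool spillover composition.

    C_model(t) = (1 − V_LV − V_RV)·C_tissue(t) + V_LV·C_LV(t) + V_RV·C_RV(t).
    """
    if v_lv < 0 or v_rv < 0:
        raise ValueError("spillover fractions must be >= 0")
    if v_lv + v_rv >= 1:
        raise ValueError("V_LV + V_RV must be < 1")
    if not (tissue_total.same_grid(clv) and tissue_total.same_grid(crv)):
        raise ValueError("curves must share one time grid")
    vals = (
        (1.0 - v_lv - v_rv) * tissue_total.values
        + v_lv * clv.values
        + v_rv * crv.values
    )
    return tissue_total.with_values(vals)


# ---------------------------------------------------------------------------
# Frame averaging
# ---------------------------------------------------------------------------

def frame_average_matrix(times_min: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Matrix W with (W @ values) = per-frame time averages of the
    piecewise-linear curve defined on ``times_min``.

    Exact for piecewise-linear curves regardless of whether frame boundaries
    coincide with grid nodes.
    """
    t = np.asarray(times_min, dtype=float)
    starts = schedule.starts / SEC_PER_MIN
    ends = schedule.ends / SEC_PER_MIN
    if starts[0] < t[0] - 1e-12 or ends[-1] > t[-1] + 1e-12:
        raise ValueError("schedule extends beyond curve support")
    n_frames, n = schedule.n_frames, t.size
    W = np.zeros((n_frames, n))
    seg_lo, seg_hi = t[:-1], t[1:]
    for fi in range(n_frames):
        a, b = starts[fi], min(ends[fi], t[-1])
        lo = np.maximum(seg_lo, a)
        hi = np.minimum(seg_hi, b)
        mask = hi > lo
        idx = np.nonzero(mask)[0]
        for i in idx:
            h = t[i + 1] - t[i]
            # linear interp weights of v_i, v_{i+1} at lo/hi
            wl = (t[i + 1] - lo[i]) / h
            wh = (t[i + 1] - hi[i]) / h
            width = hi[i] - lo[i]
            # trapezoid of the linear piece over [lo, hi]
            W[fi, i] += 0.5 * width * (wl + wh)
            W[fi, i + 1] += 0.5 * width * ((1 - wl) + (1 - wh))
        W[fi] /= b - a
    return W


def frame_average(curve: ContinuousCurve, schedule: FrameSchedule) -> TimeActivityCurve:
    """Average the continuous curve over each acquisition frame."""
    W = frame_average_matrix(curve.times, schedule)
    return TimeActivityCurve(schedule=schedule, values=W @ curve.values)
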