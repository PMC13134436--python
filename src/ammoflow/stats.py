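"""Agreement statistics for method comparison.

Pairwise Pearson correlation, Bland–Altman bias with 95% limits of
agreement, and one-way ANOVA with Tukey HSD post hoc tests — applied to
per-subject perfusion indices (stress MBF, rest MBF, MFR) at the global and
coronary-territory levels, producing machine-readable analogues of the usual
method-comparison report tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import PerfusionResult

__all__ = [
    "AgreementResult",
    "GroupComparison",
    "pearson_rho",
    "bland_altman",
    "anova_tukey",
    "comparison_report",
]

INDICES = ("stress_mbf", "rest_mbf", "mfr")
LEVELS = ("GLOBAL", "LAD", "LCX", "RCA")

#: Two-sided normal quantile used for the 95% limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    loa_lower: float
    loa_upper: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the bias")


@dataclass(frozen=True)
class GroupComparison:
    means: tuple[float, ...]
    sds: tuple[float, ...]
    f_stat: float
    p_value: float
    tukey_p: dict[tuple[int, int], float]


def pearson_rho(x, y) -> float:
    """Product-moment correlation of paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(x, y) -> AgreementResult:
    """Mean bias and 95% limits of agreement of paired differences x − y.

    Limits are bias ± 1.96·SD of the differences, with the sample (n − 1)
    standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        bias=bias,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        n=x.size,
    )


def anova_tukey(groups: list) -> GroupComparison:
    """One-way ANOVA across groups followed by all-pairs Tukey HSD.

    Two-sided, with the conventional α = 0.05 read-off left to the caller.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise ValueError("F undefined: all values identical across groups")
    f_stat, p_value = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    tukey_p = {
        (i, j): float(tukey.pvalue[i, j])
        for i, j in itertools.combinations(range(len(arrays)), 2)
    }
    return GroupComparison(
        means=tuple(float(np.mean(a)) for a in arrays),
        sds=tuple(float(np.std(a, ddof=1)) for a in arrays),
        f_stat=float(f_stat),
        p_value=float(p_value),
        tukey_p=tukey_p,
    )


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

def _index_matrix(results: list[PerfusionResult]) -> dict[str, dict[str, np.ndarray]]:
    """index -> level -> per-subject values."""
    out: dict[str, dict[str, list[float]]] = {
        idx: {lv: [] for lv in LEVELS} for idx in INDICES
    }
    for res in results:
        summ = res.summary()
        for idx in INDICES:
            for lv in LEVELS:
                out[idx][lv].append(summ[idx][lv])
    return {
        idx: {lv: np.asarray(v) for lv, v in by_level.items()}
        for idx, by_level in out.items()
    }


def comparison_report(
    results_by_model: dict[str, list[PerfusionResult]],
) -> dict[str, pd.DataFrame]:
    """Method-comparison tables across ≥ 2 models fitted to the same subjects.

    Returns three tables:

    ``summary``       mean ± SD per index per model with the one-way ANOVA p
                      (ANOVA flagged NaN when only one model is supplied —
                      the function itself requires at least two);
    ``correlations``  pairwise Pearson ρ per index at global and territory
                      levels;
    ``bland_altman``  pairwise bias and 95% limits of agreement per index
                      and level.
    """
    models = list(results_by_model)
    if len(models) < 2:
        raise ValueError("comparison requires results from at least 2 models")
    n_subjects = {m: len(v) for m, v in results_by_model.items()}
    if len(set(n_subjects.values())) != 1 or min(n_subjects.values()) == 0:
        raise ValueError(f"subject counts differ across models: {n_subjects}")

    matrices = {m: _index_matrix(results_by_model[m]) for m in models}

    summary_rows = []
    for idx in INDICES:
        groups = [matrices[m][idx]["GLOBAL"] for m in models]
        comp = anova_tukey(groups) if len(groups[0]) >= 2 else None
        for mi, m in enumerate(models):
            summary_rows.append(
                {
                    "index": idx,
                    "model": m,
                    "mean": float(np.mean(groups[mi])),
                    "sd": float(np.std(groups[mi], ddof=1)) if len(groups[mi]) > 1 else np.nan,
                    "anova_p": comp.p_value if comp else np.nan,
                }
            )
        if comp:
            for (i, j), p in comp.tukey_p.items():
                summary_rows.append(
                    {
                        "index": idx,
                        "model": f"{models[i]} vs {models[j]} (Tukey)",
                        "mean": np.nan,
                        "sd": np.nan,
                        "anova_p": p,
                    }
                )

    corr_rows = []
    ba_rows = []
    for idx in INDICES:
        for lv in LEVELS:
            for a, b in itertools.combinations(models, 2):
                xa = matrices[a][idx][lv]
                xb = matrices[b][idx][lv]
                corr_rows.append(
                    {
                        "index": idx,
                        "level": lv,
                        "pair": f"{a}-{b}",
                        "rho": pearson_rho(xa, xb),
                    }
                )
                ba = bland_altman(xa, xb)
                ba_rows.append(
                    {
                        "index": idx,
                        "level": lv,
                        "pair": f"{a}-{b}",
                        "bias": ba.bias,
                        "loa_lower": ba.loa_lower,
                        "loa_upper": ba.loa_upper,
                        "n": ba.n,
                    }
                )

    return {
        "summary": pd.DataFrame(summary_rows),
        "correlations": pd.DataFrame(corr_rows),
        "bland_altman": pd.DataFrame(ba_rows),
    }
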