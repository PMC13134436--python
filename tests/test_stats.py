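"""Agreement harness: correlation, Bland–Altman, ANOVA + Tukey, reports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ammoflow as af
from ammoflow.geometry import TerritoryScheme
from ammoflow.fitting import PerfusionResult
from ammoflow.kinetics import ModelKind


class TestPearson:
    def test_perfect_affine(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert af.pearson_rho(x, 2 * x + 1) == pytest.approx(1.0)
        assert af.pearson_rho(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert af.pearson_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            af.pearson_rho([1, 1, 1], [1, 2, 3])

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        c=st.floats(0.1, 10), d=st.floats(-5, 5),
        seed=st.integers(0, 50),
    )
    def test_invariant_under_positive_affine_transforms(self, a, b, c, d, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20) + 0.5 * x
        base = af.pearson_rho(x, y)
        assert af.pearson_rho(a * x + b, c * y + d) == pytest.approx(base, abs=1e-12)


class TestBlandAltman:
    def test_identical_series(self):
        res = af.bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0 and res.loa_lower == 0 and res.loa_upper == 0

    def test_constant_offset(self):
        res = af.bland_altman([1.3, 2.3], [1.0, 2.0])
        assert res.bias == pytest.approx(0.3)
        assert res.loa_lower == pytest.approx(0.3)
        assert res.loa_upper == pytest.approx(0.3)

    def test_hand_computed_limits(self):
        # d = (-1, 1): bias 0, SD = sqrt(2), LoA = ±1.96·sqrt(2)
        res = af.bland_altman([0.0, 2.0], [1.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_upper == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert res.loa_lower == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            af.bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(seed=st.integers(0, 200))
    def test_bias_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 15))
        assert af.bland_altman(x, y).bias == -af.bland_altman(y, x).bias


class TestAnovaTukey:
    def test_identical_means_give_null_result(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 1.0, 3.0], [3.0, 2.0, 1.0]]
        res = af.anova_tukey(groups)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert all(p > 0.999 for p in res.tukey_p.values())

    def test_distant_group_detected_by_tukey(self):
        res = af.anova_tukey([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]])
        assert res.p_value < 0.05
        assert res.tukey_p[(0, 2)] < 0.05
        assert res.tukey_p[(1, 2)] < 0.05
        assert res.tukey_p[(0, 1)] > 0.05

    def test_scale_equivariance_of_f(self):
        groups = [[1.0, 2.0, 4.0], [2.0, 5.0, 3.0], [4.0, 6.0, 8.0]]
        f1 = af.anova_tukey(groups).f_stat
        f2 = af.anova_tukey([[2 * v for v in g] for g in groups]).f_stat
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            af.anova_tukey([[2.0, 2.0], [2.0, 2.0]])

    def test_p_matches_permutation_estimate(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 8), rng.normal(0.9, 1, 8), rng.normal(0.4, 1, 8)]
        res = af.anova_tukey(groups)
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        count = 0
        n_perm = 4000
        from scipy.stats import f_oneway
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if f_oneway(*parts).statistic >= res.f_stat:
                count += 1
        p_perm = count / n_perm
        mc_err = 3 * np.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(p_perm - res.p_value) < mc_err + 0.01


def _fake_result(rng, offset=0.0, scale=1.0, kind=ModelKind.ONE_TCM):
    stress = scale * rng.uniform(1.5, 3.5, 17) + offset
    rest = rng.uniform(0.6, 1.2, 17)
    return PerfusionResult(
        model_kind=kind,
        scheme=TerritoryScheme.aha(),
        stress_mbf=stress,
        rest_mbf=rest,
    )


class TestComparisonReport:
    def _cohorts(self, n=12, identical=False):
        rng = np.random.default_rng(21)
        a = [_fake_result(rng) for _ in range(n)]
        if identical:
            b = [PerfusionResult(ModelKind.UCLA, r.scheme, r.stress_mbf, r.rest_mbf)
                 for r in a]
        else:
            rng2 = np.random.default_rng(22)
            b = [_fake_result(rng2, offset=0.4, kind=ModelKind.UCLA) for _ in range(n)]
        return {"1tcm": a, "ucla": b}

    def test_identical_sets_give_unit_rho_and_zero_bias(self):
        tables = af.comparison_report(self._cohorts(identical=True))
        assert np.allclose(tables["correlations"]["rho"], 1.0)
        assert np.allclose(tables["bland_altman"]["bias"], 0.0)

    def test_report_shape(self):
        rng = np.random.default_rng(30)
        cohorts = {
            m: [_fake_result(rng, offset=o) for _ in range(10)]
            for m, o in (("1tcm", 0.0), ("hutchins", 0.2), ("ucla", 0.6))
        }
        tables = af.comparison_report(cohorts)
        # 3 indices × 4 levels × 3 pairwise panels
        assert len(tables["correlations"]) == 3 * 4 * 3
        assert len(tables["bland_altman"]) == 3 * 4 * 3
        assert set(tables["summary"]["index"]) == {"stress_mbf", "rest_mbf", "mfr"}

    def test_single_model_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="at least 2"):
            af.comparison_report({"1tcm": [_fake_result(rng) for _ in range(5)]})
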