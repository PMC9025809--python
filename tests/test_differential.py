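"""NB differential engine: normalisation, testing, FDR and calling rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoforge.differential import (
    CountMatrix,
    DifferentialResult,
    bh_adjust,
    call_deis,
    call_differential_peaks,
    differential_analysis,
    nb_test,
    size_factors,
)


def matrix(counts, groups=("A", "A", "B", "B")):
    counts = np.asarray(counts)
    return CountMatrix(
        feature_ids=[f"f{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        group_labels=list(groups),
    )


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = matrix([[10, 10, 10, 10], [5, 5, 5, 5], [100, 100, 100, 100]])
        assert size_factors(m) == pytest.approx([1, 1, 1, 1])

    def test_doubled_column_gets_double_factor(self):
        base = np.array([[10], [20], [40], [80], [7]])
        counts = np.hstack([base, base, 2 * base, base])
        f = size_factors(matrix(counts))
        assert f[2] == pytest.approx(2 * f[0])

    def test_worked_median_of_ratios(self):
        counts = np.array(
            [
                [10, 20, 30, 40],
                [5, 5, 5, 5],
                [100, 50, 100, 200],
                [0, 8, 8, 8],  # excluded: contains a zero
                [16, 16, 32, 16],
            ]
        )
        # direct formula: geometric means over rows without zeros
        included = counts[[0, 1, 2, 4]].astype(float)
        geo = np.exp(np.mean(np.log(included), axis=1))
        expected = np.median(included / geo[:, None], axis=0)
        assert size_factors(matrix(counts)) == pytest.approx(expected)

    def test_error_when_no_common_nonzero_feature(self):
        m = matrix([[0, 1, 1, 1], [1, 0, 1, 1]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(m)
        assert np.all(size_factors(m, pseudo_reference=True) > 0)

    def test_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=(40, 4)) + 1
        f1 = size_factors(matrix(counts))
        f2 = size_factors(matrix(counts[rng.permutation(40)]))
        assert f1 == pytest.approx(f2)


class TestNbTest:
    def test_flat_feature_is_null(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(50, 6))
        counts[0] = 80
        m = matrix(counts, groups=["A"] * 3 + ["B"] * 3)
        res = nb_test(m, np.ones(6))
        assert res[0].log2_fold_change == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0, abs=0.05)

    def test_fold_change_tracks_mean_ratio(self):
        counts = np.array([[10, 10, 10, 40, 40, 40]] * 30)
        m = matrix(counts, groups=["A"] * 3 + ["B"] * 3)
        res = nb_test(m, np.ones(6))
        # log2((40+.5)/(10+.5)) — the +0.5 pseudo-count distorts slightly
        assert res[0].log2_fold_change == pytest.approx(
            np.log2(40.5 / 10.5)
        )
        assert abs(res[0].log2_fold_change - 2.0) < 0.1

    def test_all_zero_feature(self):
        counts = np.vstack([[0, 0, 0, 0, 0, 0], np.full((20, 6), 30)])
        m = matrix(counts, groups=["A"] * 3 + ["B"] * 3)
        res = nb_test(m, np.ones(6))
        assert res[0].p_value == 1.0 and res[0].log2_fold_change == 0.0

    def test_requires_two_samples_per_group(self):
        m = matrix([[1, 2, 3]], groups=["A", "B", "B"])
        with pytest.raises(ValueError):
            nb_test(m, np.ones(3))

    def test_null_calibration(self):
        """Planted null (no group effect, NB dispersion 0.1, 3 vs 3,
        2000 features, three replicate simulations): the Wald test's
        type-I error at 0.05 stays near nominal."""
        from isoforge.simulate import SimulationConfig, simulate_counts

        hits = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(seed=seed, de_fraction=0.0)
            m, _ = simulate_counts([f"f{i}" for i in range(2000)], cfg)
            res = nb_test(m, size_factors(m))
            hits.extend(r.p_value < 0.05 for r in res)
        assert 0.03 <= np.mean(hits) <= 0.07

    def test_agrees_with_statsmodels_glm(self):
        """Independent cross-check: per-feature statsmodels NB GLM with the
        same fixed dispersion reproduces the Wald coefficient and SE."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        counts = rng.poisson([40, 44, 36, 90, 110, 100], size=(5, 6))
        m = matrix(counts, groups=["A"] * 3 + ["B"] * 3)
        factors = np.ones(6)
        from isoforge.differential import (
            _mom_dispersion,
            _nb_wald_vectorized,
            _shrink_dispersion,
        )

        norm = counts.astype(float)
        mask1 = np.array([True] * 3 + [False] * 3)
        m1 = norm[:, mask1].mean(axis=1)
        m2 = norm[:, ~mask1].mean(axis=1)
        alpha = _shrink_dispersion(
            _mom_dispersion(norm, m1, m2, mask1, ~mask1), norm.mean(axis=1)
        )
        b1, se = _nb_wald_vectorized(
            counts.astype(float), factors, (~mask1).astype(float), alpha
        )
        X = sm.add_constant((~mask1).astype(float))
        for i in range(5):
            fit = sm.GLM(
                counts[i],
                X,
                family=sm.families.NegativeBinomial(alpha=alpha[i]),
            ).fit()
            assert b1[i] == pytest.approx(fit.params[1], abs=1e-5)
            assert se[i] == pytest.approx(fit.bse[1], rel=1e-4)


def brute_force_bh(p):
    """Step-up enumeration: find the largest k with p_(k) <= k/m * q."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.031]) == pytest.approx([0.031])

    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_all_ones(self):
        assert bh_adjust([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)


def result(fid, lfc, fdr):
    return DifferentialResult(fid, 10.0, lfc, 0.01, fdr=fdr)


class TestCallingRules:
    def test_dei_thresholds(self):
        results = [
            result("up", 1.5, 0.01),  # |FC| > 2, FDR < .05 -> DEI
            result("weak", 0.5, 0.001),  # fails FC
            result("down", -2.0, 0.04),  # down-regulated DEI
            result("ns", 3.0, 0.20),  # fails FDR
        ]
        deis = call_deis(results)
        assert [r.feature_id for r in deis] == ["up", "down"]

    def test_dei_min_fc_validated(self):
        with pytest.raises(ValueError):
            call_deis([result("x", 1.0, 0.01)], min_fc=1.0)

    def test_differential_peak_rule(self):
        results = [
            result("up", 0.8, 0.04),  # differential, up
            result("ns", 3.0, 0.20),  # fails FDR
            result("zero", 0.0, 0.01),  # Fold not > 0
            result("down", -1.2, 0.02),  # differential, down
        ]
        up, down = call_differential_peaks(results)
        assert [r.feature_id for r in up] == ["up"]
        assert [r.feature_id for r in down] == ["down"]

    def test_fdr_must_be_populated(self):
        bare = DifferentialResult("x", 1.0, 2.0, 0.01)
        with pytest.raises(ValueError):
            call_deis([bare])


class TestPlantedRecovery:
    def test_planted_fold_changes_recovered(self):
        """10% of features planted at |log2FC| = 2: the called DEI set is
        mostly true and the effect estimates are close to truth."""
        from isoforge.simulate import SimulationConfig, simulate_counts

        cfg = SimulationConfig(seed=17)
        m, truth = simulate_counts([f"iso{i}" for i in range(2000)], cfg)
        res = differential_analysis(m)
        deis = call_deis(res)
        called = {r.feature_id for r in deis}
        true_de = set(truth.loc[truth.is_de, "feature_id"])
        fdr = len(called - true_de) / max(1, len(called))
        sensitivity = len(called & true_de) / len(true_de)
        assert fdr <= 0.10
        assert sensitivity >= 0.5
        planted_lfc = [
            abs(r.log2_fold_change)
            for r in res
            if r.feature_id in true_de
        ]
        assert abs(np.median(planted_lfc) - 2.0) <= 0.3
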