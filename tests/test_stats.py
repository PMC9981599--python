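"""Surrogate nulls, cluster permutation, ANOVA, Bayes factors, power."""

import numpy as np
import pytest
from scipy import stats as sps

from gazesync.stats import (
    cluster_test_paired,
    cluster_test_vs_null,
    jzs_bayes_factor_paired,
    power_from_r2,
    random_derangement,
    rm_anova_2x2,
    surrogate_dyad_null,
    surrogate_event_null,
    tukey_kramer_pairwise,
    valid_onset_samples,
    zscore_pvalue,
)


class TestZscorePvalue:
    # null crafted with exact mean 0 and SD 1 (ddof=1)
    NULL = np.array([-1.0, 1.0]) / np.sqrt(2)

    def test_centre_gives_half(self):
        p, z = zscore_pvalue(0.0, self.NULL)
        assert p == pytest.approx(0.5)

    def test_gaussian_upper_tail_quantile(self):
        p, z = zscore_pvalue(1.6448536269514722, self.NULL)
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_negative_z(self):
        p, z = zscore_pvalue(-1.0, self.NULL)
        assert p == pytest.approx(sps.norm.cdf(1.0), abs=1e-9)

    def test_monotone_in_observed(self):
        ps = [zscore_pvalue(v, self.NULL)[0] for v in np.linspace(-2, 2, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bonferroni_multiplies_and_clips(self):
        p1, _ = zscore_pvalue(1.6448536269514722, self.NULL, bonferroni=4)
        assert p1 == pytest.approx(0.2, abs=1e-9)
        p2, _ = zscore_pvalue(-3.0, self.NULL, bonferroni=4)
        assert p2 == 1.0

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            zscore_pvalue(0.0, np.zeros(10))


class TestDyadSurrogate:
    def test_derangement_has_no_fixed_points(self, rng):
        for n in (2, 3, 5, 20):
            for _ in range(20):
                perm = random_derangement(n, rng)
                assert not np.any(perm == np.arange(n))
                assert sorted(perm) == list(range(n))

    def test_exchangeable_null_centres_on_observed(self, rng):
        # metric depends only on marginals -> re-pairing changes nothing
        infants = rng.standard_normal((10, 50))
        adults = rng.standard_normal((10, 50))
        metric = lambda i, a: i.mean() + a.mean()
        null = surrogate_dyad_null(infants, adults, metric, n_perm=300, rng=rng)
        assert null.mean == pytest.approx(null.observed, abs=1e-9)

    def test_coupled_dyads_exceed_null(self, rng):
        shared = rng.standard_normal((12, 400))
        infants = shared + 0.8 * rng.standard_normal((12, 400))
        adults = shared + 0.8 * rng.standard_normal((12, 400))
        metric = lambda i, a: float(np.corrcoef(i, a)[0, 1])
        null = surrogate_dyad_null(infants, adults, metric, n_perm=300, rng=rng)
        assert null.observed > null.percentile(95)

    def test_single_dyad_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_dyad_null([1], [1], lambda i, a: 0.0, rng=rng)

    def test_seeded_null_is_reproducible(self):
        infants = np.arange(8, dtype=float).reshape(8, 1)
        adults = np.arange(8, dtype=float).reshape(8, 1)
        metric = lambda i, a: float(i[0] * a[0])
        a = surrogate_dyad_null(infants, adults, metric, 100, np.random.default_rng(5))
        b = surrogate_dyad_null(infants, adults, metric, 100, np.random.default_rng(5))
        np.testing.assert_array_equal(a.null, b.null)


class TestEventSurrogate:
    def test_onsets_respect_edges_and_mask(self, rng):
        fs, n = 100.0, 10_000
        mask = np.ones(n, bool)
        mask[4000:4500] = False
        seen = []
        surrogate_event_null(
            n, fs, 5, lambda on: seen.append(on) or 0.0,
            window=(-1.0, 1.0), n_perm=50, rng=rng, mask=mask,
        )
        onsets = np.concatenate(seen)
        s = np.round(onsets * fs).astype(int)
        assert s.min() >= 100 and s.max() < n - 100
        # no epoch may overlap the masked span
        assert not np.any((s + 100 > 4000) & (s - 100 < 4500))

    def test_insufficient_span_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_event_null(100, 100.0, 5, lambda on: 0.0, window=(-1, 1), rng=rng)

    def test_valid_onset_helper_counts(self):
        cand = valid_onset_samples(1000, 100.0, (-1.0, 1.0))
        assert cand[0] == 100 and cand[-1] == 899


class TestClusterPermutation:
    def _null_maps(self, rng, n_perm=250, shape=(6, 20)):
        return rng.standard_normal((n_perm,) + shape)

    def test_degenerate_exchangeable_case(self, rng):
        nulls = self._null_maps(rng)
        res = cluster_test_vs_null(nulls[0], nulls, forming_alpha=0.05)
        assert all(c["p"] > 0.05 for c in res.clusters)

    def test_injected_contiguous_effect_detected(self, rng):
        nulls = self._null_maps(rng)
        obs = rng.standard_normal((6, 20))
        obs[2:4, 5:10] += 8.0  # 10-point block, large amplitude
        res = cluster_test_vs_null(obs, nulls, forming_alpha=0.05)
        assert res.any_significant and res.min_p < 0.01
        top = res.clusters[0]
        assert len(top["indices"]) >= 10

    def test_paired_contrast_detects_block_difference(self, rng):
        a = rng.standard_normal((12, 6, 20))
        b = rng.standard_normal((12, 6, 20))
        a[:, 1:3, 4:9] += 2.0
        res = cluster_test_paired(a, b, n_perm=300, rng=rng)
        assert res.min_p < 0.01
        assert res.clusters[0]["sign"] == 1

    def test_paired_null_is_well_behaved(self, rng):
        a = rng.standard_normal((10, 6, 20))
        b = rng.standard_normal((10, 6, 20))
        res = cluster_test_paired(a, b, n_perm=300, rng=rng)
        assert res.min_p > 0.01

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_test_vs_null(np.zeros((4, 4)), np.zeros((50, 4, 4)))


class TestRmAnova:
    def test_identical_conditions_give_null_gaze_effect(self, rng):
        band = rng.standard_normal(20)
        cells = np.stack([np.stack([band, band + 1], 1)] * 2, 1)  # gaze x band
        res = rm_anova_2x2(cells)
        assert res["gaze_type"]["F"] == pytest.approx(0.0, abs=1e-18)
        assert res["gaze_type"]["p"] == pytest.approx(1.0)
        assert res["frequency"]["p"] < 1e-6

    def test_f_equals_squared_paired_t(self, rng):
        x = rng.standard_normal((15, 2, 2)) + [[0.3, 0.0], [0.0, 0.0]]
        res = rm_anova_2x2(x)
        c = x[:, 0, :].mean(1) - x[:, 1, :].mean(1)
        t = sps.ttest_1samp(c, 0.0)
        assert res["gaze_type"]["F"] == pytest.approx(t.statistic**2, rel=1e-10)
        assert res["gaze_type"]["p"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.standard_normal((12, 2, 2))
        rows = [
            {"subj": s, "gaze": g, "band": b, "y": x[s, gi, bi]}
            for s in range(12)
            for gi, g in enumerate(["mut", "non"])
            for bi, b in enumerate(["theta", "alpha"])
        ]
        ref = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["gaze", "band"], subject="subj"
        )
        res = rm_anova_2x2(x)
        assert res["gaze_type"]["F"] == pytest.approx(
            float(ref.loc[ref.Source == "gaze", "F"].iloc[0]), rel=1e-6
        )
        assert res["frequency"]["F"] == pytest.approx(
            float(ref.loc[ref.Source == "band", "F"].iloc[0]), rel=1e-6
        )
        assert res["gaze_type*frequency"]["F"] == pytest.approx(
            float(ref.loc[ref.Source == "gaze * band", "F"].iloc[0]), rel=1e-6
        )

    def test_band_effect_power_at_n_55(self):
        rng = np.random.default_rng(3)
        n = 55
        theta = 0.12 + 0.02 * rng.standard_normal((n, 2))
        alpha = 0.10 + 0.02 * rng.standard_normal((n, 2))
        cells = np.stack([theta, alpha], axis=2)  # (n, gaze, band)
        res = rm_anova_2x2(cells)
        assert res["frequency"]["p"] < 0.05
        assert res["gaze_type"]["p"] > 0.05

    def test_missing_cells_rejected(self):
        x = np.zeros((5, 2, 2))
        x[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(x)

    def test_tukey_orders_by_separation(self, rng):
        cells = rng.standard_normal((20, 4)) * 0.1
        cells[:, 0] += 2.0
        out = tukey_kramer_pairwise(cells)
        pairs = {tuple(c["cells"]): c["p_adj"] for c in out}
        assert pairs[(0, 1)] < 0.01
        assert pairs[(2, 3)] > 0.2


class TestBayesFactor:
    def test_t_zero_favours_null(self, rng):
        x = rng.standard_normal(30)
        x = x - x.mean()  # force t = 0
        res = jzs_bayes_factor_paired(x)
        assert res["BF10"] < 1.0
        assert res["BF01"] == pytest.approx(1.0 / res["BF10"])

    def test_monotone_in_t(self):
        n = 25
        base = np.concatenate([np.linspace(-1, 1, n)])
        bfs = []
        for shift in (0.0, 0.2, 0.5, 1.0, 2.0):
            bfs.append(jzs_bayes_factor_paired(base + shift)["BF10"])
        assert all(a < b for a, b in zip(bfs, bfs[1:]))

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        d = rng.standard_normal(24) + 0.4
        ours = jzs_bayes_factor_paired(d)
        ref = float(pg.bayesfactor_ttest(ours["t"], nx=24, paired=True, r=np.sqrt(2) / 2))
        assert ours["BF10"] == pytest.approx(ref, rel=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            jzs_bayes_factor_paired(np.ones(10), np.zeros(10) + 1.0)


class TestPower:
    def test_reported_design_exceeds_99pct(self):
        assert power_from_r2(0.332, 55, 0.05) > 0.99

    def test_null_limit_is_alpha(self):
        assert power_from_r2(1e-12, 55, 0.05) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_n(self):
        powers = [power_from_r2(0.05, n, 0.05) for n in (5, 10, 20, 40, 80)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            power_from_r2(1.5, 10)
        with pytest.raises(ValueError):
            power_from_r2(0.3, 1)
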