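"""One-sample tests, BH-FDR, the random-intercept age model, ROI tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainmorph import (
    LabelAtlas,
    ScalarMap,
    SyntheticCohortSpec,
    bh_fdr,
    classify_growth,
    default_grid,
    fit_lme,
    make_phantom_atlas,
    one_sample_t_map,
    roi_summarize,
    simulate_cohort,
    simulate_scalar_cohort,
    voxelwise_lme,
)


def _maps(grid, arrays, mask=None):
    return [ScalarMap(grid, a, None if mask is None else mask.copy()) for a in arrays]


class TestOneSampleT:
    def test_all_at_null_gives_t0_p1(self, grid8):
        maps = _maps(grid8, [np.ones(grid8.shape)] * 4)
        res = one_sample_t_map(maps, null_value=1.0)
        assert np.all(res.t.values == 0.0)
        assert np.all(res.p.values == 1.0)
        assert not res.significant.any()
        assert res.n_zero_variance_flagged == 0

    def test_hand_computed_t_and_p(self, grid8):
        # values {1.1, 1.2, 1.3} against null 1: mean 1.2, sd 0.1,
        # t = 0.2/(0.1/sqrt(3)) = 2*sqrt(3), df 2; the two-sided p has the
        # closed form 1 - t/sqrt(2 + t^2) for 2 df: 1 - sqrt(12/14)
        maps = _maps(grid8, [np.full(grid8.shape, v) for v in (1.1, 1.2, 1.3)])
        res = one_sample_t_map(maps, null_value=1.0)
        assert res.df == 2
        assert np.allclose(res.t.values, 2 * np.sqrt(3.0), atol=1e-9)
        assert np.allclose(res.p.values, 1 - np.sqrt(12.0 / 14.0), atol=1e-9)

    def test_antisymmetric_sample_gives_t0(self, grid8):
        d = 0.3
        maps = _maps(
            grid8,
            [np.full(grid8.shape, 1 - d), np.full(grid8.shape, 1 + d)] * 2,
        )
        res = one_sample_t_map(maps, null_value=1.0)
        assert np.allclose(res.t.values, 0.0)

    def test_zero_variance_off_null_flagged(self, grid8):
        maps = _maps(grid8, [np.full(grid8.shape, 1.5)] * 3)
        res = one_sample_t_map(maps, null_value=1.0)
        assert res.n_zero_variance_flagged == grid8.n_voxels
        assert np.all(res.p.values == 0.0)

    def test_fewer_than_three_subjects_rejected(self, grid8):
        with pytest.raises(ValueError, match="at least 3"):
            one_sample_t_map(_maps(grid8, [np.ones(grid8.shape)] * 2), 1.0)

    def test_adjusted_p_at_least_raw_p(self, grid8, rng):
        maps = _maps(grid8, [rng.normal(1, 0.1, grid8.shape) for _ in range(6)])
        res = one_sample_t_map(maps, null_value=1.0)
        assert np.all(res.p_adj.values[res.p.mask] >= res.p.values[res.p.mask])
        assert np.array_equal(
            res.significant[res.p.mask], res.p_adj.values[res.p.mask] < 0.05
        )

    def test_null_rejection_rate_near_alpha(self, rng):
        # simulated global null: raw-p rejections at alpha=0.05 within
        # binomial noise of 0.05
        n_vox, n_sub = 4000, 33
        grid = default_grid(1)
        data = rng.normal(1.0, 0.05, size=(n_sub, n_vox))
        from scipy import stats as sps

        t = (data.mean(0) - 1.0) / (data.std(0, ddof=1) / np.sqrt(n_sub))
        p = 2 * sps.t.sf(np.abs(t), n_sub - 1)
        rate = (p < 0.05).mean()
        bound = 3 * np.sqrt(0.05 * 0.95 / n_vox)
        assert abs(rate - 0.05) < bound


def _brute_force_bh(p, q):
    """Independent oracle: try every rejection count k, keep the largest
    k whose k-th smallest p-value satisfies p <= k*q/m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="stable")
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            best_k = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:best_k]] = True
    return reject


class TestBhFdr:
    def test_step_up_worked_example(self):
        p = np.array([0.005, 0.011, 0.02, 0.04, 0.13])
        _, reject = bh_fdr(p, q=0.05)
        # p(4) = 0.04 <= 4*0.05/5 = 0.04, so the first four are rejected
        assert reject.tolist() == [True, True, True, True, False]

    def test_all_ones_no_rejections(self):
        p_adj, reject = bh_fdr(np.ones(7))
        assert not reject.any()
        assert np.all(p_adj == 1.0)

    def test_single_p_value_unchanged(self):
        p_adj, reject = bh_fdr(np.array([0.03]))
        assert p_adj[0] == 0.03
        assert reject[0]

    def test_empty_input(self):
        p_adj, reject = bh_fdr(np.array([]))
        assert p_adj.size == 0 and reject.size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        q=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_threshold_search(self, p, q):
        p = np.array(p)
        _, reject = bh_fdr(p, q=q)
        assert np.array_equal(reject, _brute_force_bh(p, q))

    @given(p=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_p_matches_statsmodels(self, p):
        sm_mt = pytest.importorskip("statsmodels.stats.multitest")
        p = np.array(p)
        p_adj, _ = bh_fdr(p)
        _, p_adj_sm, _, _ = sm_mt.multipletests(p, method="fdr_bh")
        assert np.allclose(p_adj, p_adj_sm, atol=1e-12)


class TestFitLme:
    def test_balanced_design_reduces_to_pooled_ols(self, rng):
        # independent errors, balanced schedule: fixed effects equal OLS
        spec = SyntheticCohortSpec(n_subjects=12, sigma_b=0.0, sigma_e=0.1, seed=5)
        df = simulate_scalar_cohort(spec)
        fit = fit_lme(df)
        X = np.column_stack([np.ones(len(df)), df["midpoint_age_days"]])
        beta_ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert np.allclose(fit.beta, beta_ols, atol=1e-6)

    def test_two_subject_toy_recovers_common_within_slope(self):
        # identical within-subject slopes: the random intercept absorbs the
        # subject offset and beta1 = 0.1 exactly
        df = pd.DataFrame(
            {
                "subject_id": ["A", "A", "B", "B"],
                "midpoint_age_days": [10.0, 20.0, 10.0, 20.0],
                "y": [1.0, 2.0, 2.0, 3.0],
            }
        )
        fit = fit_lme(df)
        assert np.isclose(fit.slope, 0.1, atol=1e-10)

    def test_constant_age_rejected(self):
        df = pd.DataFrame(
            {
                "subject_id": ["A", "A", "B", "B"],
                "midpoint_age_days": [10.0] * 4,
                "y": [1.0, 2.0, 2.0, 3.0],
            }
        )
        with pytest.raises(ValueError, match="age does not vary"):
            fit_lme(df)

    def test_variance_components_nonnegative(self, rng):
        df = simulate_scalar_cohort(SyntheticCohortSpec(seed=11))
        fit = fit_lme(df)
        assert fit.sigma2_b >= 0
        assert fit.sigma2_e > 0
        assert fit.n_subjects == 33
        assert fit.n_obs == 132

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_with_statsmodels(self, seed):
        # 20 random small datasets: REML estimates match the reference
        # mixed-model implementation within 1e-4 relative
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(1000 + seed)
        n_sub, n_per = 8, 4
        ages = np.tile(np.array([20.0, 40.0, 70.0, 100.0]), n_sub)
        subj = np.repeat([f"s{i}" for i in range(n_sub)], n_per)
        b = rng.normal(0, 0.5, n_sub)
        y = 2.0 - 0.01 * ages + np.repeat(b, n_per) + rng.normal(0, 0.3, n_sub * n_per)
        df = pd.DataFrame(
            {"subject_id": subj, "midpoint_age_days": ages, "y": y}
        )
        fit = fit_lme(df)
        ref = smf.mixedlm(
            "y ~ midpoint_age_days", df, groups=df["subject_id"]
        ).fit(reml=True)
        assert np.allclose(fit.beta, ref.params.values[:2], rtol=1e-4)
        assert np.isclose(fit.sigma2_e, ref.scale, rtol=1e-4)
        assert np.isclose(
            fit.sigma2_b, ref.cov_re.values[0, 0], rtol=1e-4, atol=1e-8
        )

    def test_parameter_recovery_small_monte_carlo(self):
        # reduced-size sanity check at 3 Monte-Carlo SEs; the full
        # 200-replicate study at 2 SEs runs in the acceptance suite
        spec = SyntheticCohortSpec()
        master = np.random.default_rng(42)
        est = []
        for _ in range(100):
            df = simulate_scalar_cohort(spec, rng=master)
            est.append(fit_lme(df).slope)
        est = np.array(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - spec.beta1) < 3 * mc_se


class TestVoxelwiseLme:
    def test_constant_in_age_gives_zero_slope_no_hits(self, rng):
        grid = default_grid(4)
        spec = SyntheticCohortSpec(n_subjects=8, beta1=0.0, sigma_e=0.0, sigma_b=0.05, seed=2)
        maps, cohort = simulate_cohort(spec, grid, blob=np.zeros(grid.shape, bool))
        res = voxelwise_lme(maps, cohort)
        assert np.allclose(res.slope.values, 0.0, atol=1e-8)
        assert not res.significant.any()

    def test_blob_effect_detected_with_fdr_control(self):
        # negative age slope confined to a known blob: high in-blob
        # sensitivity, out-of-blob false positive fraction below q
        grid = default_grid(8)
        blob = np.zeros(grid.shape, dtype=bool)
        blob[2:5, 2:5, 2:5] = True
        spec = SyntheticCohortSpec(beta1=-0.003, sigma_e=0.01, sigma_b=0.05, seed=9)
        maps, cohort = simulate_cohort(spec, grid, blob=blob)
        res = voxelwise_lme(maps, cohort, q=0.05)
        sens = res.significant[blob].mean()
        fpr = res.significant[~blob].mean()
        assert sens >= 0.8
        assert fpr <= 0.05
        assert np.all(res.slope.values[res.significant & blob] < 0)

    def test_row_count_mismatch_rejected(self, rng):
        grid = default_grid(4)
        spec = SyntheticCohortSpec(n_subjects=4, seed=1)
        maps, cohort = simulate_cohort(spec, grid, blob=np.zeros(grid.shape, bool))
        with pytest.raises(ValueError, match="one map per row"):
            voxelwise_lme(maps[:-1], cohort)


class TestRoiTables:
    def test_direct_threshold_classification(self, grid8):
        # 11 masked voxels: 3 at 2.0 (ROI A), 8 at 1.0 (ROI B); the 75th
        # percentile interpolates between sorted values 1.0 and 2.0 to
        # exactly 1.5, so ROI A (mean 2.0 > 1.5) is fast
        labels = np.zeros(grid8.shape, dtype=np.int32)
        flat = labels.ravel()
        flat[:3] = 1
        flat[3:11] = 2
        mask = labels > 0
        atlas = LabelAtlas(grid8, labels, {1: "A", 2: "B"})
        vals = np.where(labels == 1, 2.0, 1.0)
        table = classify_growth(ScalarMap(grid8, vals, mask), atlas).set_index("name")
        assert table.loc["A", "whole_brain_p75"] == 1.5
        assert table.loc["A", "classification"] == "fast"
        assert table.loc["B", "classification"] == "neither"  # mean 1.0 = p25

    def test_uniform_map_classifies_nothing(self, grid8):
        labels = np.ones(grid8.shape, dtype=np.int32)
        labels[4:] = 2
        atlas = LabelAtlas(grid8, labels, {1: "A", 2: "B"})
        table = classify_growth(ScalarMap(grid8, np.full(grid8.shape, 1.3)), atlas)
        assert (table["classification"] == "neither").all()

    def test_three_roi_phantom_quartile_construction(self):
        # phantom built so whole-brain voxel quartiles are exactly
        # (1.2, 1.8) and ROI means are (1.9, 1.5, 1.1)
        grid = default_grid(16)
        atlas, mask, m = _quartile_phantom(grid)
        vox = m.masked()
        assert np.percentile(vox, 25) == 1.2
        assert np.percentile(vox, 75) == 1.8
        table = classify_growth(m, atlas).set_index("label")
        assert np.allclose(table["mean"], [1.9, 1.5, 1.1])
        assert table["classification"].tolist() == ["fast", "neither", "slow"]

    def test_fast_and_slow_mutually_exclusive(self, grid8, rng):
        labels = (rng.integers(1, 4, size=grid8.shape)).astype(np.int32)
        atlas = LabelAtlas(grid8, labels, {1: "A", 2: "B", 3: "C"})
        table = classify_growth(ScalarMap(grid8, rng.normal(size=grid8.shape)), atlas)
        assert set(table["classification"]) <= {"fast", "slow", "neither"}

    def test_empty_roi_excluded_with_warning(self, grid8):
        labels = np.ones(grid8.shape, dtype=np.int32)
        labels[4:] = 2
        atlas = LabelAtlas(grid8, labels, {1: "A", 2: "B"})
        mask = labels == 1  # ROI B has no masked voxels
        with pytest.warns(UserWarning, match="ROI 2"):
            table = roi_summarize(ScalarMap(grid8, np.ones(grid8.shape), mask), atlas)
        assert table["label"].tolist() == [1]

    def test_percentiles_permutation_invariant(self, grid8, rng):
        vals = rng.normal(size=grid8.shape)
        labels = np.ones(grid8.shape, dtype=np.int32)
        atlas = LabelAtlas(grid8, labels, {1: "A"})
        t1 = classify_growth(ScalarMap(grid8, vals), atlas)
        perm = rng.permutation(vals.ravel()).reshape(vals.shape)
        t2 = classify_growth(ScalarMap(grid8, perm), atlas)
        assert t1["whole_brain_p25"].iloc[0] == t2["whole_brain_p25"].iloc[0]
        assert t1["whole_brain_p75"].iloc[0] == t2["whole_brain_p75"].iloc[0]


def _quartile_phantom(grid):
    """3-ROI phantom with whole-brain quartiles exactly (1.2, 1.8) and ROI
    means (1.9, 1.5, 1.1).

    ROI 1 mixes values {1.8, 2.0} (mean 1.9), ROI 2 is constant 1.5, ROI 3
    mixes {1.0, 1.2} (mean 1.1); the equal-count mixtures put long runs of
    1.2 and 1.8 across the 25th/75th percentile positions so linear
    interpolation lands on them exactly.
    """
    from strainmorph import make_phantom_atlas

    atlas, mask = make_phantom_atlas(grid, 3)
    vals = np.zeros(grid.shape)
    rois = [
        (1, 1.8, 2.0, 1.9),
        (2, 1.5, 1.5, 1.5),
        (3, 1.0, 1.2, 1.1),
    ]
    for label, lo, hi, mean in rois:
        sel = np.flatnonzero((atlas.labels == label).ravel())
        n = sel.size
        half = n // 2
        flat = vals.ravel()
        flat[sel[:half]] = lo
        flat[sel[half : 2 * half]] = hi
        if n % 2:
            flat[sel[-1]] = mean
    return atlas, mask, ScalarMap(grid, vals, mask)
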