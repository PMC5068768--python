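"""Statistical core: clustering, effects, smoothing, null, regions, scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methbump import (
    BumpHunterConfig,
    NullDistribution,
    ValidationError,
    bootstrap_null,
    build_design,
    cluster_probes,
    find_candidate_regions,
    fit_probe_effects,
    pick_cutoff,
    run_bumphunter,
    score_regions,
    smooth_effects,
    simulate_study,
    SimConfig,
)
from methbump.bumphunt import EffectProfile, running_median, _find_runs

from conftest import make_m_matrix, make_manifest, make_sheet


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterProbes:
    def test_gap_rule(self):
        man = make_manifest([100, 550, 1200])
        assert cluster_probes(man, 500).tolist() == [0, 0, 1]     # gaps 450, 650
        assert cluster_probes(man, 1000).tolist() == [0, 0, 0]    # sensitivity maxgap

    def test_chromosome_boundary_always_splits(self):
        man = make_manifest([100, 101], chrom=["chr1", "chr2"])
        assert cluster_probes(man, 500).tolist() == [0, 1]

    def test_unsorted_manifest_rejected(self):
        man = make_manifest([100, 550])
        unsorted = type(man)(man.df.iloc[::-1].copy())
        with pytest.raises(ValidationError):
            cluster_probes(unsorted, 500)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(min_value=1, max_value=2000), min_size=2,
                    max_size=30, unique=True))
    def test_coarsening_maxgap_never_splits_clusters(self, positions):
        """Clusters at maxgap=500 refine clusters at maxgap=1000."""
        man = make_manifest(sorted(positions))
        fine = cluster_probes(man, 500)
        coarse = cluster_probes(man, 1000)
        # same fine cluster -> same coarse cluster
        for cid in np.unique(fine):
            assert len(np.unique(coarse[fine == cid])) == 1


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

class TestBuildDesign:
    def test_full_covariates_give_five_columns(self):
        design = build_design(make_sheet(3, 3))
        assert design.columns == ["intercept", "group", "sex", "age", "pmi"]

    def test_missing_pmi_dropped_with_warning(self):
        pmi = [10.0, 12.0, np.nan, 15.0, 20.0, 25.0]
        design = build_design(make_sheet(3, 3, pmi=pmi))
        assert "pmi" not in design.columns and "pmi" in design.dropped
        assert len(design.columns) == 4

    def test_group_confounded_with_sex_raises(self):
        sheet = make_sheet(3, 3, sex=["M"] * 3 + ["F"] * 3)
        with pytest.raises(ValidationError, match="sex"):
            build_design(sheet)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValidationError):
            build_design(make_sheet(1, 5))


# ---------------------------------------------------------------------------
# per-probe effects
# ---------------------------------------------------------------------------

def _no_covariate_sheet(n_case, n_control):
    return make_sheet(n_case, n_control,
                      sex=[None] * (n_case + n_control),
                      age=[np.nan] * (n_case + n_control),
                      pmi=[np.nan] * (n_case + n_control))


class TestFitProbeEffects:
    def test_reduces_to_group_mean_difference(self):
        mat = make_m_matrix([[2.0, 2.0, 0.0, 0.0]])
        design = build_design(_no_covariate_sheet(2, 2))
        profile = fit_probe_effects(mat, design)
        assert profile.raw[0] == pytest.approx(2.0, abs=1e-12)

    def test_group_mean_identity_on_random_matrix(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(10, 6))
        mat = make_m_matrix(Y)
        design = build_design(_no_covariate_sheet(3, 3))
        profile = fit_probe_effects(mat, design)
        expected = Y[:, :3].mean(axis=1) - Y[:, 3:].mean(axis=1)
        np.testing.assert_allclose(profile.raw, expected, atol=1e-10)

    def test_orthogonal_covariate_leaves_effect_unchanged(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(5, 6))
        # age orthogonal to the centred group indicator and to the intercept
        age = np.array([1.0, -1.0, 0.0, 1.0, -1.0, 0.0]) + 60
        no_cov = fit_probe_effects(
            make_m_matrix(Y), build_design(_no_covariate_sheet(3, 3)))
        with_cov = fit_probe_effects(
            make_m_matrix(Y),
            build_design(make_sheet(3, 3, sex=[None] * 6, age=age, pmi=[np.nan] * 6)))
        np.testing.assert_allclose(with_cov.raw, no_cov.raw, atol=1e-10)

    def test_recovers_known_coefficients_noiselessly(self):
        """Y built from known group (1.5) and age (0.02) coefficients; the
        fitted group coefficient must match the generating value."""
        age = np.array([40.0, 55.0, 62.0, 47.0, 70.0, 58.0])
        group = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        Y = (0.3 + 1.5 * group + 0.02 * age)[None, :]
        # independent check via generic least squares on the same design
        X = np.column_stack([np.ones(6), group, age - age.mean()])
        oracle = np.linalg.lstsq(X, Y[0], rcond=None)[0][1]
        sheet = make_sheet(3, 3, sex=[None] * 6, age=age, pmi=[np.nan] * 6)
        profile = fit_probe_effects(make_m_matrix(Y), build_design(sheet))
        assert profile.raw[0] == pytest.approx(1.5, abs=1e-9)
        assert profile.raw[0] == pytest.approx(oracle, abs=1e-9)

    def test_underdetermined_design_rejected(self):
        from methbump.bumphunt import Design
        mat = make_m_matrix(np.zeros((2, 2)))
        design = Design(np.array([[1.0, 1.0, 2.0], [1.0, 0.0, 5.0]]),
                        ["intercept", "group", "age"], mat.sample_ids)
        with pytest.raises(ValidationError):
            fit_probe_effects(mat, design)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def _profile(values):
    values = np.asarray(values, float)
    return EffectProfile(pd.Index([f"p{i}" for i in range(len(values))]), values)


def brute_force_runmed(v, k):
    """Window-enumeration oracle for the truncated running median."""
    m = len(v)
    if m < k:
        return np.asarray(v, float).copy()
    half = (k - 1) // 2
    return np.array([
        np.median(v[max(0, i - half):min(m, i + half + 1)]) for i in range(m)
    ])


class TestSmoothing:
    def test_truncated_window_example(self):
        out = smooth_effects(_profile([0, 5, 0, 0]), np.zeros(4, int), 3)
        np.testing.assert_allclose(out.smoothed, [2.5, 0, 0, 0])

    def test_constant_cluster_unchanged(self):
        out = smooth_effects(_profile([3.0] * 5), np.zeros(5, int), 3)
        np.testing.assert_allclose(out.smoothed, 3.0)

    def test_below_window_cluster_keeps_raw(self):
        out = smooth_effects(_profile([1.0, -2.0]), np.zeros(2, int), 5)
        np.testing.assert_allclose(out.smoothed, [1.0, -2.0])

    def test_smoothing_respects_cluster_boundaries(self):
        values = [0.0, 0.0, 0.0, 9.0, 9.0, 9.0]
        clusters = np.array([0, 0, 0, 1, 1, 1])
        out = smooth_effects(_profile(values), clusters, 3)
        np.testing.assert_allclose(out.smoothed, values)

    def test_matches_window_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = int(rng.integers(1, 40))
            k = int(rng.choice([1, 3, 5, 7]))
            v = rng.normal(size=m)
            got = running_median(v[None, :], k)[0]
            np.testing.assert_allclose(got, brute_force_runmed(v, k), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=5, max_size=25),
           st.sampled_from([3, 5, 7]))
    def test_output_within_window_bounds(self, values, k):
        v = np.array(values)
        out = smooth_effects(_profile(v), np.zeros(len(v), int), k).smoothed
        half = (k - 1) // 2
        for i, x in enumerate(out):
            window = v[max(0, i - half):i + half + 1] if len(v) >= k else v[i:i + 1]
            assert window.min() - 1e-12 <= x <= window.max() + 1e-12


# ---------------------------------------------------------------------------
# bootstrap null and cutoff
# ---------------------------------------------------------------------------

class TestBootstrapNull:
    def test_zero_residuals_give_degenerate_null(self):
        """Data exactly equal to the null fit: every null statistic is 0."""
        sheet = _no_covariate_sheet(3, 3)
        design = build_design(sheet)
        Y = np.tile(np.array([1.0, -2.0, 0.5]), (6, 1)).T  # constant per probe
        mat = make_m_matrix(Y)
        cfg = BumpHunterConfig(n_boot=20, seed=1)
        null = bootstrap_null(mat, design, np.zeros(3, int), cfg)
        np.testing.assert_allclose(null.smoothed, 0.0, atol=1e-10)
        null.scan_regions(0.1, np.zeros(3, int))
        assert null.pooled_areas.size == 0

    def test_same_seed_reproduces_null(self):
        rng = np.random.default_rng(2)
        mat = make_m_matrix(rng.normal(size=(20, 8)))
        design = build_design(_no_covariate_sheet(4, 4))
        clusters = np.repeat([0, 1], 10)
        cfg = BumpHunterConfig(n_boot=30, seed=42)
        a = bootstrap_null(mat, design, clusters, cfg)
        b = bootstrap_null(mat, design, clusters, cfg)
        np.testing.assert_array_equal(a.smoothed, b.smoothed)

    def test_matches_explicit_refit_oracle(self):
        """The batched linear-estimator bootstrap equals literally re-fitting
        the full design on M* = F + R[:, idx] for every bootstrap."""
        rng = np.random.default_rng(3)
        P, n, B = 12, 8, 10
        mat = make_m_matrix(rng.normal(size=(P, n)))
        sheet = make_sheet(4, 4)
        design = build_design(sheet)
        clusters = np.zeros(P, int)
        cfg = BumpHunterConfig(n_boot=B, seed=9, smooth_k=1)
        null = bootstrap_null(mat, design, clusters, cfg)

        X = design.matrix
        g = design.group_index
        X0 = np.delete(X, g, axis=1)
        Y = mat.values.to_numpy()
        F = (X0 @ (np.linalg.pinv(X0) @ Y.T)).T
        R = (Y - F) * np.sqrt(n / (n - X0.shape[1]))
        idx = np.random.default_rng(9).integers(0, n, size=(B, n))
        for b in range(B):
            Mstar = F + R[:, idx[b]]
            refit = (Mstar @ np.linalg.pinv(X).T)[:, g]
            np.testing.assert_allclose(null.smoothed[b], refit, atol=1e-10)

    def test_null_exceedance_matches_quantile_by_construction(self):
        """Fraction of pooled null statistics beyond the 95% cutoff is 5%."""
        cfg = SimConfig(n_cohorts=1, cohort_sizes=((8, 8),), n_clusters=25,
                        n_shared_hyper=0, n_shared_hypo=0, n_private_per_cohort=0)
        study = simulate_study(cfg, seed=3)
        cohort = study.cohorts[0]
        bcfg = BumpHunterConfig(n_boot=100, seed=3)
        res = run_bumphunter(cohort.betas, cohort.detp, study.manifest,
                             cohort.sheet, bcfg)
        frac = float((np.abs(res.null.smoothed) > res.cutoff).mean())
        assert frac == pytest.approx(0.05, abs=0.01)
        # and the observed (data) profile exceeds it at a similar rate
        obs = float((np.abs(res.profile.smoothed) > res.cutoff).mean())
        assert obs == pytest.approx(0.05, abs=0.05)


class TestPickCutoff:
    def test_q1_gives_maximum(self):
        null = NullDistribution(np.arange(0.1, 1.05, 0.1)[None, :], B=1, seed=0)
        assert pick_cutoff(null, 1.0) == pytest.approx(1.0)

    def test_constant_pool(self):
        null = NullDistribution(np.full((2, 5), 0.3), B=2, seed=0)
        for q in (0.1, 0.5, 0.95):
            assert pick_cutoff(null, q) == pytest.approx(0.3)

    def test_interpolated_quantile_value(self):
        vals = np.arange(1, 101) * 0.01
        null = NullDistribution(vals[None, :], B=1, seed=0)
        assert pick_cutoff(null, 0.95) == pytest.approx(0.9505)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(0)
        null = NullDistribution(rng.normal(size=(5, 50)), B=5, seed=0)
        qs = np.linspace(0.05, 0.99, 20)
        cuts = [pick_cutoff(null, q) for q in qs]
        assert all(a <= b + 1e-15 for a, b in zip(cuts, cuts[1:]))


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------

def brute_force_regions(smoothed, clusters, cutoff, min_probes=1):
    """Enumerate every run directly: for each maximal index interval, check
    membership of each probe and consistency of sign."""
    runs = []
    i = 0
    n = len(smoothed)
    while i < n:
        if smoothed[i] > cutoff:
            sign = 1
        elif smoothed[i] < -cutoff:
            sign = -1
        else:
            i += 1
            continue
        j = i
        while (j + 1 < n and clusters[j + 1] == clusters[i]
               and ((smoothed[j + 1] > cutoff) if sign > 0 else (smoothed[j + 1] < -cutoff))):
            j += 1
        if j - i + 1 >= min_probes:
            runs.append((i, j, sign))
        i = j + 1
    return runs


class TestFindCandidateRegions:
    def test_direct_rule_application(self):
        man = make_manifest([100, 200, 900])
        prof = EffectProfile(man.probe_ids, np.zeros(3),
                             np.array([0.3, 0.3, 0.1]))
        regions = find_candidate_regions(prof, np.zeros(3, int), man, 0.2)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.n_probes, r.direction) == (100, 200, 2, "hyper")
        assert r.avg_delta_m == pytest.approx(0.3)
        assert r.area == pytest.approx(0.6)

    def test_sign_change_splits_runs(self):
        man = make_manifest([100, 150])
        prof = EffectProfile(man.probe_ids, np.zeros(2), np.array([-0.3, 0.3]))
        regions = find_candidate_regions(prof, np.zeros(2, int), man, 0.2)
        assert [r.direction for r in regions] == ["hypo", "hyper"]
        assert all(r.n_probes == 1 for r in regions)

    def test_cluster_boundary_splits_runs(self):
        man = make_manifest([100, 150, 5000, 5050])
        prof = EffectProfile(man.probe_ids, np.zeros(4), np.full(4, 0.5))
        regions = find_candidate_regions(prof, np.array([0, 0, 1, 1]), man, 0.2)
        assert len(regions) == 2
        assert [r.cluster_id for r in regions] == [0, 1]

    def test_exact_cutoff_ties_excluded(self):
        man = make_manifest([100, 150])
        prof = EffectProfile(man.probe_ids, np.zeros(2), np.array([0.2, 0.3]))
        regions = find_candidate_regions(prof, np.zeros(2, int), man, 0.2)
        assert len(regions) == 1 and regions[0].n_probes == 1

    def test_area_equals_avg_times_n(self):
        rng = np.random.default_rng(4)
        man = make_manifest(sorted(rng.choice(10_000, 30, replace=False)))
        sm = rng.normal(scale=0.5, size=30)
        prof = EffectProfile(man.probe_ids, np.zeros(30), sm)
        clusters = cluster_probes(man, 500)
        for r in find_candidate_regions(prof, clusters, man, 0.3):
            assert r.area == pytest.approx(abs(r.avg_delta_m) * r.n_probes, abs=1e-10)

    def test_matches_brute_force_enumeration(self):
        """On small instances the region calls equal exhaustive run enumeration."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            sm = rng.normal(scale=0.4, size=n)
            clusters = np.sort(rng.integers(0, 3, size=n))
            cutoff = float(rng.uniform(0.05, 0.6))
            got = _find_runs(sm, clusters, cutoff)
            assert got == brute_force_regions(sm, clusters, cutoff)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _null_with(areas_by_boot):
    null = NullDistribution(np.zeros((len(areas_by_boot), 1)), B=len(areas_by_boot), seed=0)
    null.null_areas = [np.asarray(a, float) for a in areas_by_boot]
    null.boot_max = np.array([max(a) if len(a) else 0.0 for a in areas_by_boot])
    return null


def _region(area, p=np.nan):
    from methbump import CandidateRegion
    return CandidateRegion(chrom="chr1", start=1, end=2, probe_ids=["a"],
                           cluster_id=0, n_probes=1, avg_delta_m=area, area=area,
                           direction="hyper", p_value=p)


class TestScoreRegions:
    def test_pooled_null_proportion(self):
        null = _null_with([[1.0, 2.0], [3.0, 4.0]])
        (r,) = score_regions([_region(2.5)], null)
        assert r.p_value == pytest.approx(0.5)  # 2 of 4 null areas >= 2.5

    def test_fwer_from_bootstrap_maxima(self):
        null = _null_with([[3.0], [4.0]])
        (r,) = score_regions([_region(3.5)], null)
        assert r.fwer == pytest.approx(0.5)  # 1 of 2 maxima >= 3.5

    def test_bh_adjustment_hand_example(self):
        # pool of 100 areas 1..100; regions at 100, 99, 98 give p = .01/.02/.03,
        # and the BH step-up rule by hand gives (.03, .03, .03)
        null = _null_with([list(range(1, 101))])
        regions = [_region(a) for a in (100.0, 99.0, 98.0)]
        scored = score_regions(regions, null)
        np.testing.assert_allclose([r.p_value for r in scored], [0.01, 0.02, 0.03])
        np.testing.assert_allclose([r.fdr for r in scored], [0.03, 0.03, 0.03])

    def test_empty_pool_gives_zero_p(self):
        null = _null_with([[], []])
        (r,) = score_regions([_region(1.0)], null)
        assert r.p_value == 0.0 and r.fwer == 0.0

    def test_p_and_fwer_monotone_in_area(self):
        rng = np.random.default_rng(6)
        null = _null_with([rng.exponential(size=5) for _ in range(20)])
        areas = np.sort(rng.exponential(size=10))
        scored = score_regions([_region(a) for a in areas], null)
        ps = [r.p_value for r in scored]
        fs = [r.fwer for r in scored]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(a >= b for a, b in zip(fs, fs[1:]))


# ---------------------------------------------------------------------------
# full single-cohort pipeline
# ---------------------------------------------------------------------------

class TestRunBumphunter:
    def test_probe_order_invariance(self, small_study):
        cohort = small_study.cohorts[0]
        cfg = BumpHunterConfig(n_boot=30, seed=5)
        base = run_bumphunter(cohort.betas, None, small_study.manifest,
                              cohort.sheet, cfg)
        perm = np.random.default_rng(0).permutation(len(cohort.betas.probe_ids))
        shuffled = type(cohort.betas)(cohort.betas.values.iloc[perm].copy(), "beta")
        shuffled_man = type(small_study.manifest)(
            small_study.manifest.df.iloc[perm].copy())
        again = run_bumphunter(shuffled, None, shuffled_man, cohort.sheet, cfg)
        assert [(r.chrom, r.start, r.end, r.direction) for r in base.regions] == \
               [(r.chrom, r.start, r.end, r.direction) for r in again.regions]

    def test_deterministic_under_seed(self, small_study):
        cohort = small_study.cohorts[0]
        cfg = BumpHunterConfig(n_boot=30, seed=5)
        a = run_bumphunter(cohort.betas, cohort.detp, small_study.manifest,
                           cohort.sheet, cfg)
        b = run_bumphunter(cohort.betas, cohort.detp, small_study.manifest,
                           cohort.sheet, cfg)
        assert a.cutoff == b.cutoff
        assert [(r.start, r.p_value, r.fwer) for r in a.regions] == \
               [(r.start, r.p_value, r.fwer) for r in b.regions]

    def test_recovers_single_planted_dmr(self):
        """A planted 8-probe dM=1.0 DMR is the top-area region with low FWER
        in at least 90% of seeds."""
        hits = 0
        for seed in range(20):
            cfg = SimConfig(n_cohorts=1, cohort_sizes=((12, 12),), n_clusters=50,
                            n_shared_hyper=1, n_shared_hypo=0,
                            n_private_per_cohort=0, effect_size=1.0,
                            dmr_probes=(8, 8))
            study = simulate_study(cfg, seed=seed)
            cohort = study.cohorts[0]
            res = run_bumphunter(cohort.betas, cohort.detp, study.manifest,
                                 cohort.sheet, BumpHunterConfig(n_boot=100, seed=seed))
            if not res.regions:
                continue
            top = max(res.regions, key=lambda r: r.area)
            d = study.truth.shared_dmrs[0]
            overlaps = top.chrom == d.chrom and top.start <= d.end and top.end >= d.start
            if overlaps and top.fwer < 0.05:
                hits += 1
        assert hits >= 18

    def test_candidate_regions_exceed_cutoff_with_consistent_sign(self, small_study):
        cohort = small_study.cohorts[0]
        res = run_bumphunter(cohort.betas, None, small_study.manifest,
                             cohort.sheet, BumpHunterConfig(n_boot=30, seed=5))
        sm = pd.Series(res.profile.smoothed, index=res.manifest.probe_ids)
        covered = set()
        for r in res.regions:
            vals = sm.loc[r.probe_ids]
            if r.direction == "hyper":
                assert (vals > res.cutoff).all()
            else:
                assert (vals < -res.cutoff).all()
            assert not covered & set(r.probe_ids)  # pairwise disjoint
            covered |= set(r.probe_ids)
        outside = sm.drop(list(covered))
        assert (outside.abs() <= res.cutoff).all()
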