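import numpy as np
import pandas as pd
import pytest

from surfhomog import (
    CohortDesign,
    adjust_reho,
    cluster_correct,
    compute_reho,
    find_clusters,
    fit_group_glm,
    ring_neighbors,
    signed_log_p,
    simulate_cohort,
)
from surfhomog.group_stats import build_group_design


def _pheno(n, n_sites=2, seed=0):
    rng = np.random.default_rng(seed)
    sites = [f"S{(i % n_sites) + 1}" for i in range(n)]
    return pd.DataFrame({
        "SUB_ID": [f"s{i}" for i in range(n)],
        "SITE_ID": sites,
        "DX_GROUP": [1 if (i // n_sites) % 2 == 0 else 2 for i in range(n)],
        "AGE_AT_SCAN": rng.uniform(8, 30, n),
        "FIQ": rng.normal(108, 10, n),
        "MEAN_FD": rng.uniform(0.05, 0.3, n),
        "MC_BBR": rng.uniform(0.3, 0.6, n),
    })


class TestAdjustReho:
    def test_identical_nuisances_leave_maps_unchanged(self, rng):
        n, v = 20, 50
        y = rng.random((n, v))
        y = y - y.mean(axis=1, keepdims=True) + 0.5  # equalize gm across subjects
        pheno = _pheno(n)
        pheno["MEAN_FD"] = 0.2
        pheno["MC_BBR"] = 0.5
        jac = np.tile(rng.random(v), (n, 1))  # same map for everyone
        with pytest.warns(RuntimeWarning):
            yadj = adjust_reho(y, pheno, jac)
        np.testing.assert_allclose(yadj, y, atol=1e-10)

    def test_gm_effect_removed(self, rng):
        n, v = 100, 60
        gm_driver = rng.standard_normal(n)
        y = 0.5 + 2.0 * gm_driver[:, None] + 0.1 * rng.standard_normal((n, v))
        pheno = _pheno(n)
        jac = 1 + 0.05 * rng.standard_normal((n, v))
        yadj = adjust_reho(y, pheno, jac)
        gm = y.mean(axis=1)
        corr = np.array([np.corrcoef(yadj[:, j], gm)[0, 1] for j in range(v)])
        assert np.abs(corr).mean() < 0.05

    def test_orthogonal_group_difference_preserved(self, rng):
        """A focal, zero-global-mean group difference survives adjustment
        (it is orthogonal to gm and the other nuisances by construction)."""
        n, v = 200, 40
        pheno = _pheno(n)
        group = np.where(pheno["DX_GROUP"] == 1, 1.0, -1.0)
        pattern = np.concatenate([np.full(v // 2, 0.05), np.full(v // 2, -0.05)])
        y = 0.5 + group[:, None] * pattern + 0.01 * rng.standard_normal((n, v))
        jac = 1 + 0.05 * rng.standard_normal((n, v))
        yadj = adjust_reho(y, pheno, jac)
        diff_before = y[group > 0].mean(0) - y[group < 0].mean(0)
        diff_after = yadj[group > 0].mean(0) - yadj[group < 0].mean(0)
        np.testing.assert_allclose(diff_after, diff_before, rtol=0.05, atol=0.003)

    def test_grand_mean_preserved(self, rng):
        n, v = 30, 25
        y = rng.random((n, v))
        pheno = _pheno(n)
        jac = 1 + 0.1 * rng.standard_normal((n, v))
        yadj = adjust_reho(y, pheno, jac)
        assert yadj.mean() == pytest.approx(y.mean(), abs=1e-10)

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            adjust_reho(rng.random((6, 10)), _pheno(6), np.ones((6, 10)))


class TestGroupGLM:
    def test_matches_statsmodels_per_vertex(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n, v = 40, 5
        pheno = _pheno(n, n_sites=3)
        y = rng.standard_normal((n, v))
        fit = fit_group_glm(y, pheno)
        x, meta = build_group_design(pheno)
        for j in range(v):
            ref = sm.OLS(y[:, j], x).fit()
            assert fit.beta["group"][j] == pytest.approx(ref.params[meta["group_col"]])
            assert fit.stat["group"][j] == pytest.approx(ref.tvalues[meta["group_col"]])
            assert fit.p["group"][j] == pytest.approx(ref.pvalues[meta["group_col"]])
            assert fit.stat["group_x_age"][j] == pytest.approx(
                ref.tvalues[meta["interaction_col"]])
            # site block F test against statsmodels' f_test
            contrast = np.zeros((len(meta["site_cols"]), x.shape[1]))
            for row, col in enumerate(meta["site_cols"]):
                contrast[row, col] = 1.0
            ftest = ref.f_test(contrast)
            assert fit.stat["site"][j] == pytest.approx(float(ftest.fvalue))
            assert fit.p["site"][j] == pytest.approx(float(ftest.pvalue))

    def test_group_label_swap_negates_t_map(self, rng):
        n, v = 30, 20
        pheno = _pheno(n)
        y = rng.standard_normal((n, v))
        t_orig = fit_group_glm(y, pheno).stat["group"]
        flipped = pheno.copy()
        flipped["DX_GROUP"] = np.where(pheno["DX_GROUP"] == 1, 2, 1)
        t_flip = fit_group_glm(y, flipped).stat["group"]
        np.testing.assert_allclose(t_flip, -t_orig, atol=1e-10)

    def test_single_site_rejected(self, rng):
        pheno = _pheno(10, n_sites=1)
        with pytest.raises(ValueError):
            fit_group_glm(rng.standard_normal((10, 5)), pheno)

    def test_single_group_site_warns(self, rng):
        pheno = _pheno(20, n_sites=2)
        pheno.loc[pheno["SITE_ID"] == "S2", "DX_GROUP"] = 2
        with pytest.warns(RuntimeWarning, match="single diagnostic group"):
            fit_group_glm(rng.standard_normal((20, 5)), pheno)

    def test_two_stage_close_to_joint_model(self, mesh3, table3_ring1):
        """Adjust-then-fit group t values track a single joint GLM that
        carries the nuisances alongside the terms of interest (|Δt| < 0.2).

        The agreement is asymptotic — stage 1 estimates nuisance betas
        without controlling the design terms, so finite-sample correlations
        between nuisances and group widen the gap — hence a cohort large
        enough for sampling correlations to be small.
        """
        design = CohortDesign(n_sites=3, subjects_per_site_per_group=30, seed=13)
        cohort = simulate_cohort(mesh3, design)
        maps = np.array([compute_reho(s.bold, table3_ring1).values
                         for s in cohort.subjects])
        jac = np.array([s.jacobian for s in cohort.subjects])
        pheno = cohort.phenotypes
        t_two_stage = fit_group_glm(adjust_reho(maps, pheno, jac), pheno).stat["group"]

        x, meta = build_group_design(pheno)
        gm = maps.mean(axis=1)
        nuis = np.column_stack([gm, pheno["MEAN_FD"], pheno["MC_BBR"]])
        nuis = nuis - nuis.mean(axis=0)
        col = meta["group_col"]
        t_joint = np.empty(maps.shape[1])
        for j in range(maps.shape[1]):
            xj = np.column_stack([x, nuis, jac[:, j] - jac[:, j].mean()])
            beta, _, _, _ = np.linalg.lstsq(xj, maps[:, j], rcond=None)
            resid = maps[:, j] - xj @ beta
            dof = xj.shape[0] - xj.shape[1]
            sigma2 = resid @ resid / dof
            cov = sigma2 * np.linalg.inv(xj.T @ xj)
            t_joint[j] = beta[col] / np.sqrt(cov[col, col])
        assert np.abs(t_two_stage - t_joint).max() < 0.2


class TestSignedLogP:
    @pytest.mark.parametrize("t,p,expected", [
        (2.0, 0.01, 2.0),
        (-2.0, 0.001, -3.0),
        (0.0, 1.0, 0.0),
    ])
    def test_examples(self, t, p, expected):
        got = signed_log_p(np.array([t]), np.array([p]))
        assert got[0] == pytest.approx(expected)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            out = signed_log_p(np.array([5.0]), np.array([0.0]))
        assert np.isfinite(out[0]) and out[0] > 300

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            signed_log_p(np.array([1.0]), np.array([1.5]))


class TestFindClusters:
    def test_single_isolated_vertex(self, mesh2):
        slp = np.zeros(mesh2.n_vertices)
        slp[40] = 3.0
        clusters = find_clusters(slp, mesh2)
        assert len(clusters) == 1
        assert clusters[0].vertex_count == 1
        assert clusters[0].peak_vertex == 40

    def test_disjoint_patches_are_separate(self, mesh2):
        a = ring_neighbors(mesh2, 10, 1, include_center=True)
        b = ring_neighbors(mesh2, 150, 1, include_center=True)
        slp = np.zeros(mesh2.n_vertices)
        slp[a] = 4.0
        slp[b] = 4.0
        clusters = find_clusters(slp, mesh2)
        assert sorted(c.vertex_count for c in clusters) == [len(a), len(b)]

    def test_opposite_signs_cluster_separately(self, mesh2):
        a = ring_neighbors(mesh2, 10, 1, include_center=True)
        b = ring_neighbors(mesh2, 11, 1, include_center=True)  # adjacent patch
        slp = np.zeros(mesh2.n_vertices)
        slp[a] = 4.0
        slp[b] = -4.0
        signs = sorted(c.sign for c in find_clusters(slp, mesh2))
        assert signs == [-1, 1]

    def test_full_mesh_single_cluster(self, mesh2):
        clusters = find_clusters(np.full(mesh2.n_vertices, 5.0), mesh2)
        assert len(clusters) == 1
        assert clusters[0].vertex_count == mesh2.n_vertices

    def test_extent_invariant_to_threshold_preserving_transform(self, mesh2, rng):
        slp = 3.0 * rng.standard_normal(mesh2.n_vertices)
        a = find_clusters(slp, mesh2)
        transformed = np.sign(slp) * np.expm1(np.abs(slp))  # monotone in |slp|
        # same threshold set: |x|>2 iff |expm1(|x|)|>expm1(2); rescale to match
        b = find_clusters(transformed * (2.0 / np.expm1(2.0)), mesh2)
        assert sorted(c.vertex_count for c in a) == sorted(c.vertex_count for c in b)


@pytest.fixture(scope="module")
def effect_cohort(mesh3, table3_ring1):
    """Cohort with a strong seeded patient > control region (order-3 mesh,
    so the focal region barely contaminates the global-mean nuisance)."""
    region = ring_neighbors(mesh3, 200, 2, include_center=True)
    design = CohortDesign(n_sites=3, subjects_per_site_per_group=8,
                          effect_region=region, effect_size_delta=0.15,
                          seed=31)
    cohort = simulate_cohort(mesh3, design)
    maps = np.array([compute_reho(s.bold, table3_ring1).values
                     for s in cohort.subjects])
    jac = np.array([s.jacobian for s in cohort.subjects])
    yadj = adjust_reho(maps, cohort.phenotypes, jac)
    return cohort, yadj, region


class TestClusterCorrect:
    def test_strong_effect_hits_permutation_floor(self, mesh3, effect_cohort):
        cohort, yadj, region = effect_cohort
        fit = fit_group_glm(yadj, cohort.phenotypes)
        clusters = find_clusters(fit.signed_log_p_maps["group"], mesh3)
        assert clusters  # the seeded region is detected at the defining threshold
        res = cluster_correct(clusters, yadj, cohort.phenotypes, mesh3,
                              n_permutations=200, seed=2)
        floor = 1.0 / (res.n_permutations + 1)
        assert min(c.corrected_p for c in res.clusters) == pytest.approx(floor)
        # every corrected p respects the permutation lower bound
        assert all(c.corrected_p >= floor for c in res.clusters)

    def test_deterministic_per_seed(self, mesh3, effect_cohort):
        cohort, yadj, _ = effect_cohort
        fit = fit_group_glm(yadj, cohort.phenotypes)
        clusters = find_clusters(fit.signed_log_p_maps["group"], mesh3)
        r1 = cluster_correct(clusters, yadj, cohort.phenotypes, mesh3,
                             n_permutations=120, seed=9)
        r2 = cluster_correct(clusters, yadj, cohort.phenotypes, mesh3,
                             n_permutations=120, seed=9)
        assert [c.corrected_p for c in r1.clusters] == [c.corrected_p for c in r2.clusters]
        np.testing.assert_array_equal(r1.null_max_extents, r2.null_max_extents)

    def test_exhausted_permutations_noted(self, mesh2, rng):
        """A cohort with few distinct within-site relabelings runs fewer
        permutations and says so."""
        pheno = _pheno(8, n_sites=2, seed=4)  # 2 sites × C(4,2) = 36 < 100
        y = rng.standard_normal((8, mesh2.n_vertices)) * 0.1 + 0.5
        y[:, :12] += np.where(pheno["DX_GROUP"] == 1, 0.5, 0.0)[:, None]
        fit = fit_group_glm(y, pheno)
        clusters = find_clusters(fit.signed_log_p_maps["group"], mesh2)
        res = cluster_correct(clusters, y, pheno, mesh2, n_permutations=100, seed=0)
        assert res.n_permutations == 36
        assert res.notes

    def test_too_few_permutations_rejected(self, mesh3, effect_cohort):
        cohort, yadj, _ = effect_cohort
        with pytest.raises(ValueError):
            cluster_correct([], yadj, cohort.phenotypes, mesh3, n_permutations=50)
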