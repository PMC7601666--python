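"""Cluster-based permutation inference: rank-correlation core, clustering
on the montage graph, and agreement with exhaustive enumeration."""

from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comareact import cluster_perm as cp
from comareact.montage import ELECTRODES


class TestAdjacency:
    def test_graph_is_symmetric_connected_and_simple(self, adjacency):
        assert set(adjacency.nodes) == set(ELECTRODES)
        assert nx.is_connected(adjacency)
        assert all(a != b for a, b in adjacency.edges)

    def test_central_electrode_neighbours(self, adjacency):
        assert set(adjacency.neighbors("C3")) == {"F3", "T3", "Cz", "P3"}


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert cp.spearman_rho(x, 2 * x + 1) == pytest.approx(1.0)
        assert cp.spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_pearson(self, rng):
        x = rng.integers(0, 4, 20).astype(float)
        y = rng.integers(0, 4, 20).astype(float)
        got = cp.spearman_rho(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        brute = (np.mean(rx * ry) - rx.mean() * ry.mean()) / (
            np.std(rx) * np.std(ry))
        assert got == pytest.approx(brute, rel=1e-12)
        assert got == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            cp.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])


class TestRhoToT:
    def test_zero_and_closed_form(self):
        assert cp.rho_to_t(0.0, 10) == 0.0
        assert cp.rho_to_t(0.8, 10) == pytest.approx(0.8 * np.sqrt(8 / 0.36))

    def test_strictly_increasing_in_rho(self):
        rhos = np.linspace(-0.95, 0.95, 41)
        ts = [cp.rho_to_t(r, 12) for r in rhos]
        assert np.all(np.diff(ts) > 0)

    def test_perfect_correlation_flagged_as_capped_infinity(self):
        assert cp.rho_to_t(1.0, 10) == cp.T_CAP
        assert cp.rho_to_t(-1.0, 10) == -cp.T_CAP


class TestThresholdMap:
    def test_zero_map_with_symmetric_null_has_no_candidates(self, rng):
        t_map = pd.Series(0.0, index=list(ELECTRODES))
        null = np.concatenate([rng.normal(size=500), -rng.normal(size=500)])
        pos, neg, _ = cp.threshold_map(t_map, null)
        assert pos == [] and neg == []

    def test_single_extreme_electrode_is_singleton_candidate(self, rng):
        t_map = pd.Series(0.0, index=list(ELECTRODES))
        t_map["Cz"] = 99.0
        pos, neg, _ = cp.threshold_map(t_map, rng.normal(size=1000))
        assert pos == ["Cz"] and neg == []

    def test_thresholds_match_sorted_array_quantiles(self, rng):
        null = rng.normal(size=2000)
        t_map = pd.Series(0.0, index=list(ELECTRODES))
        _, _, (lo, hi) = cp.threshold_map(t_map, null)
        assert lo == pytest.approx(np.quantile(null, 0.025))
        assert hi == pytest.approx(np.quantile(null, 0.975))

    def test_degenerate_null_is_an_error(self):
        t_map = pd.Series(0.0, index=list(ELECTRODES))
        with pytest.raises(ValueError, match="degenerate"):
            cp.threshold_map(t_map, np.ones(100))


class TestFormClusters:
    def test_singleton_cluster_mass(self, adjacency):
        t_map = pd.Series(0.0, index=list(ELECTRODES))
        t_map["Fz"] = 3.1
        clusters = cp.form_clusters(["Fz"], t_map, adjacency)
        assert clusters == [(("Fz",), pytest.approx(3.1))]

    def test_adjacent_pair_merges_with_summed_mass(self, adjacency):
        t_map = pd.Series(0.0, index=list(ELECTRODES))
        t_map["C3"], t_map["Cz"] = 2.0, 2.5
        clusters = cp.form_clusters(["C3", "Cz"], t_map, adjacency)
        assert len(clusters) == 1
        assert clusters[0][0] == ("C3", "Cz")
        assert clusters[0][1] == pytest.approx(4.5)

    def test_non_adjacent_electrodes_stay_separate(self, adjacency):
        t_map = pd.Series(1.0, index=list(ELECTRODES))
        clusters = cp.form_clusters(["Fp1", "O2"], t_map, adjacency)
        assert sorted(c[0] for c in clusters) == [("Fp1",), ("O2",)]

    def test_min_size_filters_small_components(self, adjacency):
        t_map = pd.Series(1.0, index=list(ELECTRODES))
        clusters = cp.form_clusters(["Fp1", "C3", "Cz"], t_map, adjacency,
                                    min_size=2)
        assert clusters == [(("C3", "Cz"), pytest.approx(2.0))]


def _coupled_contrasts(rng, n=8, noise=0.3):
    base = rng.normal(size=n)
    contrasts = pd.DataFrame(
        base[:, None] + noise * rng.normal(size=(n, 19)),
        index=[f"P{i:02d}" for i in range(n)], columns=list(ELECTRODES))
    covariate = pd.Series(base + noise * rng.normal(size=n),
                          index=contrasts.index)
    return contrasts, covariate


class TestPermutationTest:
    def test_same_seed_gives_identical_results(self, rng):
        contrasts, cov = _coupled_contrasts(rng)
        cfg = cp.PermConfig(n_permutations=200, seed=5)
        r1 = cp.permutation_test(contrasts, cov, cfg)
        r2 = cp.permutation_test(contrasts, cov, cfg)
        assert [(c.electrodes, c.mass, c.p) for c in r1.clusters] == \
            [(c.electrodes, c.mass, c.p) for c in r2.clusters]

    def test_rank_core_invariant_under_monotone_covariate_transform(self, rng):
        contrasts, cov = _coupled_contrasts(rng)
        cfg = cp.PermConfig(n_permutations=200, seed=5)
        r1 = cp.permutation_test(contrasts, cov, cfg)
        r2 = cp.permutation_test(contrasts, np.exp(cov), cfg)
        assert [(c.electrodes, c.p) for c in r1.clusters] == \
            [(c.electrodes, c.p) for c in r2.clusters]
        np.testing.assert_allclose(r1.rho, r2.rho)

    def test_constant_covariate_rejected(self, rng):
        contrasts, cov = _coupled_contrasts(rng)
        with pytest.raises(ValueError, match="constant"):
            cp.permutation_test(contrasts, cov * 0 + 1.0,
                                cp.PermConfig(seed=1))

    def test_missing_covariate_subjects_dropped_with_warning(self, rng):
        contrasts, cov = _coupled_contrasts(rng, n=8)
        cov.iloc[0] = np.nan
        with pytest.warns(UserWarning, match="missing"):
            res = cp.permutation_test(contrasts, cov, cp.PermConfig(seed=1))
        assert res.n_subjects == 7

    def test_too_few_subjects_rejected(self, rng):
        contrasts, cov = _coupled_contrasts(rng, n=4)
        with pytest.raises(ValueError, match=">= 5"):
            cp.permutation_test(contrasts, cov, cp.PermConfig(seed=1))

    def test_matches_exhaustive_enumeration_at_n5(self, rng, adjacency):
        # 5 subjects: the covariate has 120 permutations, so the exact
        # cluster p is enumerable; the sampled p must sit within
        # Monte-Carlo error of it (parametric threshold on both routes)
        contrasts, cov = _coupled_contrasts(rng, n=5, noise=0.5)
        cfg = cp.PermConfig(n_permutations=500, seed=11,
                            threshold_mode="parametric",
                            bonferroni_covariates=False)
        res = cp.permutation_test(contrasts, cov, cfg)
        assert res.clusters, "expected at least one observed cluster"
        top = res.clusters[0]

        hi = stats.t.ppf(0.975, 3)
        x = contrasts.to_numpy()
        null_max = []
        for perm in permutations(cov.to_numpy()):
            ts = np.array([cp.rho_to_t(cp.spearman_rho(x[:, e], perm), 5)
                           for e in range(19)])
            t_map = pd.Series(ts, index=list(ELECTRODES))
            sup_pos = [e for e in ELECTRODES if t_map[e] > hi]
            sup_neg = [e for e in ELECTRODES if t_map[e] < -hi]
            masses = [abs(m) for _, m in
                      cp.form_clusters(sup_pos, t_map, adjacency)]
            masses += [abs(m) for _, m in
                       cp.form_clusters(sup_neg, t_map, adjacency)]
            null_max.append(max(masses) if masses else 0.0)
        null_max = np.array(null_max)
        p_exact = np.mean(null_max >= abs(top.mass))
        se = np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / 500)
        assert abs(top.p - p_exact) <= 3 * se + 2.0 / 500


class TestCovariateBattery:
    def test_recovers_generator_coupling_signs(
            self, patient_theta_contrast, recovery_cohort):
        cfg = cp.PermConfig(n_permutations=500, seed=21)
        results = cp.run_covariate_battery(
            patient_theta_contrast, recovery_cohort.morphometry,
            recovery_cohort.clinical, cfg,
            covariates=("total_gray_volume", "surface_holes", "gose"))
        by_name = {r.covariate: r for r in results}
        # positive association for the volume covariate, negative for the
        # damage proxy and (theta decrease <-> better outcome) for GOSe
        assert by_name["total_gray_volume"].rho.mean() > 0
        assert by_name["surface_holes"].rho.mean() < 0
        assert by_name["gose"].rho.mean() < 0
        sig = [c for r in results for c in r.significant_clusters()]
        assert sig, "strong coupling should produce significant clusters"
        for r in results:
            for c in r.clusters:
                assert np.sign(c.mass) == c.sign
                sub = r.t[list(c.electrodes)]
                assert (np.sign(sub) == c.sign).all()

    def test_same_seed_reproduces_battery(self, patient_theta_contrast,
                                          recovery_cohort):
        cfg = cp.PermConfig(n_permutations=120, seed=9)
        args = (patient_theta_contrast, recovery_cohort.morphometry,
                recovery_cohort.clinical, cfg)
        t1 = cp.cluster_table(cp.run_covariate_battery(
            *args, covariates=("gose", "right_putamen")))
        t2 = cp.cluster_table(cp.run_covariate_battery(
            *args, covariates=("gose", "right_putamen")))
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_covariate_lists_available_names(
            self, patient_theta_contrast, recovery_cohort):
        with pytest.raises(KeyError, match="available"):
            cp.run_covariate_battery(
                patient_theta_contrast, recovery_cohort.morphometry,
                recovery_cohort.clinical, cp.PermConfig(seed=1),
                covariates=("left_amygdala",))

    def test_cluster_p_floor_and_invariants(self, patient_theta_contrast,
                                            recovery_cohort):
        cfg = cp.PermConfig(n_permutations=500, seed=2)
        results = cp.run_covariate_battery(
            patient_theta_contrast, recovery_cohort.morphometry,
            recovery_cohort.clinical, cfg, covariates=("total_gray_volume",))
        for r in results:
            for c in r.clusters:
                assert 1.0 / (r.n_permutations + 1) <= c.p <= 1.0
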