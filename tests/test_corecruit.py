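"""Recruitment profiles, bootstrap Pearson, clustering and the network."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import corecnet as cn
from corecnet.corecruit import (CorrelationMatrix, bootstrap_pearson,
                                pearson_with_p, suggest_k)

from conftest import make_design, make_normalized, small_config


@pytest.fixture(scope="module")
def noiseless_pipeline():
    """Noise-free simulated experiment carried through to profiles."""
    c = small_config(noise_sd_log=0.0, protein_noise_sd_log=0.0,
                     module_kinetic_sd_log=0.0, missing_rate=0.0,
                     detection_floor=0.0, seed=31)
    table, design, truth = cn.simulate_experiment(c)
    norm = cn.preprocess_table(table, design, seed=2)
    bnorm = cn.bait_normalize(norm, design)
    interactors = sorted(truth.specific_ids)
    profiles = cn.build_profiles(bnorm, design, interactors)
    return c, design, truth, bnorm, profiles


@pytest.fixture(scope="module")
def noisy_matrix():
    """Default-noise experiment carried through to the correlation matrix."""
    c = small_config(n_specific=12, n_background_proteins=40,
                     modules=(("M1", 6, "early-peak"), ("M2", 6, "late-peak")),
                     seed=37)
    table, design, truth = cn.simulate_experiment(c)
    norm = cn.preprocess_table(table, design, seed=2)
    res = cn.bootstrap_detection(norm, design,
                                 cn.DetectionConfig(n_boot=60, seed=3))
    interactors = res.interactors()
    bnorm = cn.bait_normalize(norm, design)
    profiles = cn.build_profiles(bnorm, design, interactors)
    matrix = cn.correlation_matrix(profiles, n_boot=300, seed=7)
    return truth, interactors, matrix


class TestBaitNormalize:
    def test_constant_bait_is_identity(self, noiseless_pipeline):
        c, design, _, bnorm, _ = noiseless_pipeline
        again = cn.bait_normalize(bnorm, design)
        pd.testing.assert_frame_equal(again.log_data, bnorm.log_data)

    def test_bait_row_has_zero_variance_after_op(self, noiseless_pipeline):
        c, design, _, bnorm, _ = noiseless_pipeline
        bait_runs = design.runs(background="bait")
        row = bnorm.log_data.loc[c.bait_name, bait_runs]
        assert row.std() == pytest.approx(0.0, abs=1e-12)

    def test_doubled_bait_run_is_halved(self):
        runs = ["b1", "b2", "c1", "c2"]
        vals = np.log10(np.array([[100.0, 200.0, 1.0, 1.0],
                                  [40.0, 40.0, 1.0, 1.0]]))
        norm = make_normalized(vals, runs=runs, proteins=["BAIT1", "P1"])
        design = make_design([("b1", "bait", 0.0, 1, 1),
                              ("b2", "bait", 0.0, 1, 2),
                              ("c1", "control", 0.0, 1, 1),
                              ("c2", "control", 0.0, 1, 2)])
        out = cn.bait_normalize(norm, design, bait="BAIT1")
        ratio = 10 ** (out.log_data.at["P1", "b2"]
                       - out.log_data.at["P1", "b1"])
        assert ratio == pytest.approx(0.5)

    def test_missing_bait_value_names_the_run(self):
        runs = ["b1", "b2", "c1", "c2"]
        vals = np.array([[2.0, np.nan, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]])
        df = pd.DataFrame(vals, index=["BAIT1", "P1"], columns=runs)
        norm = cn.NormalizedTable(df, pd.DataFrame(False, index=df.index,
                                                   columns=df.columns))
        design = make_design([("b1", "bait", 0.0, 1, 1),
                              ("b2", "bait", 0.0, 1, 2),
                              ("c1", "control", 0.0, 1, 1),
                              ("c2", "control", 0.0, 1, 2)])
        with pytest.raises(ValueError, match="b2"):
            cn.bait_normalize(norm, design, bait="BAIT1")


class TestBuildProfiles:
    def _tiny(self, series):
        """One protein, one bio rep, one tech rep, len(series) times."""
        runs = [f"b{t}" for t in range(len(series))]
        vals = np.log10(np.array([series], dtype=float))
        norm = make_normalized(vals, runs=runs, proteins=["P1"])
        design = make_design([(f"b{t}", "bait", float(t), 1, 1)
                              for t in range(len(series))])
        return cn.build_profiles(norm, design, ["P1"])

    def test_monotone_series_max_normalized(self):
        prof = self._tiny([1.0, 2.0, 4.0])
        np.testing.assert_allclose(prof.tech_mean.loc[("P1", 1)].to_numpy(),
                                   [0.25, 0.5, 1.0], rtol=1e-12)

    def test_constant_series_is_all_ones(self):
        prof = self._tiny([3.0, 3.0, 3.0])
        np.testing.assert_allclose(prof.tech_mean.loc[("P1", 1)].to_numpy(),
                                   [1.0, 1.0, 1.0])

    def test_noiseless_profiles_recover_planted_kinetics(self, noiseless_pipeline):
        _, _, truth, _, profiles = noiseless_pipeline
        for prey in sorted(truth.specific_ids)[:5]:
            planted = truth.profile_of[prey]
            for bio in (1, 2, 3):
                got = profiles.tech_mean.loc[(prey, bio)].to_numpy()
                np.testing.assert_allclose(got, planted / planted.max(),
                                           rtol=1e-9)

    def test_bio_rep_scaling_leaves_profiles_unchanged(self, noiseless_pipeline):
        c, design, truth, bnorm, profiles = noiseless_pipeline
        scaled = bnorm.copy()
        bio1 = design.runs(background="bait", bio_rep=1)
        scaled.log_data[bio1] = scaled.log_data[bio1] + 0.7
        prof2 = cn.build_profiles(scaled, design, sorted(truth.specific_ids))
        pd.testing.assert_frame_equal(profiles.obs, prof2.obs)


class TestPearson:
    def test_closed_form_matches_scipy_to_12_decimals(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.normal(size=15)
            y = 0.5 * x + rng.normal(size=15)
            r, p = pearson_with_p(x, y)
            oracle = stats.pearsonr(x, y)
            assert r == pytest.approx(oracle.statistic, abs=1e-12)
            assert p == pytest.approx(oracle.pvalue, abs=1e-12)

    def test_self_correlation_is_one_with_minimal_p(self):
        x = np.arange(10, dtype=float)
        r, p = bootstrap_pearson(x, x, n_boot=100, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= np.finfo(float).tiny

    def test_perfect_anticorrelation(self):
        x = np.arange(10, dtype=float)
        r, p = bootstrap_pearson(x, -x, n_boot=100, seed=0)
        assert r == pytest.approx(-1.0)

    def test_bootstrap_mean_within_monte_carlo_band_of_oracle(self):
        """Bootstrap means agree with an independent large-sample resampling
        oracle within its 3-SE Monte-Carlo band."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=15)
        y = 0.8 * x + 0.4 * rng.normal(size=15)
        r, p = bootstrap_pearson(x, y, n_boot=4000, seed=1)
        # independent oracle: explicit loop, separate stream, 20k samples
        orng = np.random.default_rng(10_007)
        rs, ps = [], []
        for _ in range(20000):
            idx = orng.integers(0, 15, 15)
            xr, yr = x[idx], y[idx]
            if xr.std() == 0 or yr.std() == 0:
                continue
            res = stats.pearsonr(xr, yr)
            rs.append(res.statistic)
            ps.append(res.pvalue)
        se_r = np.std(rs) / np.sqrt(len(rs)) + np.std(rs) / np.sqrt(4000)
        se_p = np.std(ps) / np.sqrt(len(ps)) + np.std(ps) / np.sqrt(4000)
        assert abs(r - np.mean(rs)) < 3 * se_r
        assert abs(p - np.mean(ps)) < 3 * se_p

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            bootstrap_pearson(np.ones(2), np.ones(2))


class TestCorrelationMatrix:
    def test_two_protein_matrix_equals_single_pair_call(self):
        obs = pd.DataFrame(
            np.random.default_rng(3).uniform(0, 1, (2, 15)),
            index=["A", "B"],
            columns=pd.MultiIndex.from_product(
                [[1, 2, 3], [0.0, 30.0, 120.0, 300.0, 600.0]],
                names=["bio_rep", "time_s"]))
        profiles = cn.corecruit.RecruitmentProfiles(
            obs=obs, tech_mean=pd.DataFrame(), points="tech-mean")
        mat = cn.correlation_matrix(profiles, n_boot=200, seed=9)
        ss = np.random.SeedSequence(9).spawn(1)[0]
        r, p = bootstrap_pearson(obs.loc["A"].to_numpy(),
                                 obs.loc["B"].to_numpy(), n_boot=200,
                                 rng=np.random.default_rng(ss))
        assert mat.R.at["A", "B"] == pytest.approx(r, rel=1e-12)
        assert mat.P.at["A", "B"] == pytest.approx(p, rel=1e-12)

    def test_symmetry_and_unit_diagonal(self, noisy_matrix):
        _, _, matrix = noisy_matrix
        np.testing.assert_array_equal(matrix.R.to_numpy(),
                                      matrix.R.to_numpy().T)
        np.testing.assert_allclose(np.diag(matrix.R.to_numpy()), 1.0)
        assert (matrix.P.to_numpy() <= 1.0).all()

    def test_within_module_correlation_exceeds_between(self, noisy_matrix):
        truth, interactors, matrix = noisy_matrix
        within, between = [], []
        prots = matrix.proteins
        for i, a in enumerate(prots):
            for b in prots[i + 1:]:
                r = matrix.R.at[a, b]
                if truth.module_of.get(a) == truth.module_of.get(b):
                    within.append(r)
                else:
                    between.append(r)
        assert np.mean(within) > np.mean(between)

    def test_node_order_invariance(self):
        rng = np.random.default_rng(13)
        obs = pd.DataFrame(
            rng.uniform(0, 1, (4, 15)), index=["D", "B", "A", "C"],
            columns=pd.MultiIndex.from_product(
                [[1, 2, 3], [0.0, 30.0, 120.0, 300.0, 600.0]],
                names=["bio_rep", "time_s"]))
        profiles1 = cn.corecruit.RecruitmentProfiles(
            obs=obs, tech_mean=pd.DataFrame(), points="tech-mean")
        profiles2 = cn.corecruit.RecruitmentProfiles(
            obs=obs.loc[["A", "B", "C", "D"]], tech_mean=pd.DataFrame(),
            points="tech-mean")
        m1 = cn.correlation_matrix(profiles1, n_boot=100, seed=3)
        m2 = cn.correlation_matrix(profiles2, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(m1.R, m2.R)


class TestKMeans:
    def _block_matrix(self, sizes, rho_in=0.95, rho_out=0.0):
        labels = []
        for m, size in enumerate(sizes):
            labels += [m] * size
        n = len(labels)
        r = np.full((n, n), rho_out)
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    r[i, j] = rho_in
        np.fill_diagonal(r, 1.0)
        prots = [f"P{i}" for i in range(n)]
        df = pd.DataFrame(r, index=prots, columns=prots)
        return CorrelationMatrix(R=df, P=df * 0 + 1e-12, n_boot=1, seed=0), labels

    def test_separable_modules_recovered_exactly(self):
        matrix, labels = self._block_matrix([5, 5])
        got = cn.kmeans_partition(matrix, 2, seed=1)
        assert adjusted_rand_score(labels, got.to_numpy()) == 1.0

    def test_k_equals_n_gives_singletons(self):
        matrix, _ = self._block_matrix([2, 2])
        got = cn.kmeans_partition(matrix, 4, seed=1)
        assert len(set(got)) == 4

    def test_k_larger_than_n_rejected(self):
        matrix, _ = self._block_matrix([2, 2])
        with pytest.raises(ValueError, match="exceeds"):
            cn.kmeans_partition(matrix, 5)

    def test_planted_modules_recovered_from_noisy_matrix(self, noisy_matrix):
        truth, _, matrix = noisy_matrix
        got = cn.kmeans_partition(matrix, 2, seed=4)
        want = [truth.module_of[p] for p in matrix.proteins]
        assert adjusted_rand_score(want, got.to_numpy()) >= 0.8

    def test_silhouette_helper_prefers_true_k(self):
        matrix, _ = self._block_matrix([6, 6, 6])
        scores = suggest_k(matrix, k_min=2, k_max=6, seed=0)
        assert scores.idxmax() == 3


class TestNetwork:
    def test_bonferroni_reproduces_printed_thresholds(self):
        assert cn.bonferroni_threshold(5e-5, 98) == pytest.approx(1.05e-8,
                                                                  rel=5e-3)
        assert cn.bonferroni_threshold(5e-5, 44) == pytest.approx(5.29e-8,
                                                                  rel=5e-3)
        assert cn.bonferroni_threshold(0.01, 2) == pytest.approx(0.01)

    def test_all_p_one_gives_empty_network(self):
        prots = ["A", "B", "C"]
        r = pd.DataFrame(np.eye(3), index=prots, columns=prots)
        p = pd.DataFrame(np.ones((3, 3)), index=prots, columns=prots)
        matrix = CorrelationMatrix(R=r, P=p, n_boot=1, seed=0)
        net = cn.build_network(matrix, alpha=5e-5)
        assert len(net.edges) == 0

    def test_identical_noiseless_profiles_linked_with_r_one(self, noiseless_pipeline):
        _, design, truth, bnorm, profiles = noiseless_pipeline
        matrix = cn.correlation_matrix(profiles, n_boot=50, seed=5)
        net = cn.build_network(matrix, alpha=5e-5)
        members = sorted(p for p, m in truth.module_of.items() if m == "M1")
        a, b = members[:2]
        assert (a, b) in set(net.edges)
        assert net.graph[a][b]["R"] == pytest.approx(1.0)

    def test_alpha_monotonicity(self, noisy_matrix):
        _, _, matrix = noisy_matrix
        e_small = set(cn.build_network(matrix, alpha=1e-8).edges)
        e_large = set(cn.build_network(matrix, alpha=1e-3).edges)
        assert e_small <= e_large

    def test_high_confidence_subset_of_full(self, noisy_matrix):
        _, _, matrix = noisy_matrix
        net = cn.build_network(matrix, alpha=5e-5)
        hc = net.high_confidence_subnetwork()
        assert set(hc.edges) <= set(net.edges)
        for a, b in hc.edges:
            assert hc.graph[a][b]["R"] > 0.8

    def test_planted_edges_recovered(self, noisy_matrix):
        truth, interactors, matrix = noisy_matrix
        net = cn.build_network(matrix, alpha=5e-5)
        detected = set(matrix.proteins)
        true_among = {e for e in truth.true_edges
                      if e[0] in detected and e[1] in detected}
        got = set(net.edges) & true_among
        assert len(got) / len(true_among) >= 0.8
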