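"""Network stage: bicor, adjacency, TOM, tree cut, eigenproteins, traits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prmnet import network as net
from prmnet.errors import ConfigurationError, ValidationError
from .conftest import analysis_matrix


def bicor_oracle(x, y):
    """Textbook biweight midcorrelation, coded independently."""

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9.0 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return (v - med) * w

    a, b = transform(np.asarray(x, float)), transform(np.asarray(y, float))
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))


class TestBicor:
    def test_perfect_linear_relation(self):
        x = np.arange(20, dtype=float)
        assert net.bicor(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)
        assert net.bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=20)
            y = 0.5 * x + rng.normal(size=20)
            assert net.bicor(x, y) == pytest.approx(bicor_oracle(x, y), abs=1e-12)

    def test_close_to_pearson_without_outliers(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        assert abs(net.bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05

    def test_robust_to_a_single_outlier(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.9 * x + 0.1 * rng.normal(size=50)
        y_out = y.copy()
        y_out[0] = 100.0
        assert net.bicor(x, y_out) > np.corrcoef(x, y_out)[0, 1]

    def test_constant_vector_flagged_missing(self):
        assert np.isnan(net.bicor(np.ones(10), np.arange(10.0)))

    def test_zero_mad_falls_back_to_pearson(self):
        # a majority at one value makes MAD zero without being constant;
        # both vectors then use the Pearson transform
        x = np.array([5.0] * 8 + [1.0, 9.0])
        y = np.array([2.0] * 8 + [0.0, 7.0])
        r_pearson = np.corrcoef(x, y)[0, 1]
        assert net.bicor(x, y) == pytest.approx(r_pearson, abs=1e-12)

    def test_correlation_p_matches_t_distribution(self):
        rho, n = 0.5, 30
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
        assert net.correlation_p(rho, n) == pytest.approx(
            2 * stats.t.sf(t, n - 2), abs=1e-12
        )


class TestAdjacencyAndTom:
    def test_signed_transform_bounds(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert net.signed_adjacency(R, 23)[0, 1] == 1.0
        R = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert net.signed_adjacency(R, 23)[0, 1] == 0.0
        R = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert net.signed_adjacency(R, 23)[0, 1] == pytest.approx(0.5**23)

    def test_beta_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            net.signed_adjacency(np.eye(2), 0.5)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValidationError):
            net.signed_adjacency(bad, 2)
        with pytest.raises(ValidationError):
            net.tom_similarity(bad)

    def test_three_node_hand_computation(self):
        a, b, c = 0.6, 0.3, 0.2  # a_01, a_02, a_12
        A = np.array([[1.0, a, b], [a, 1.0, c], [b, c, 1.0]])
        tom = net.tom_similarity(A, denominator="mean")
        k = np.array([a + b, a + c, b + c])
        # TOM_01: shared neighbor 2 contributes a_02 * a_12
        expect01 = (b * c + a) / ((k[0] + k[1]) / 2 - a + 1)
        expect02 = (a * c + b) / ((k[0] + k[2]) / 2 - b + 1)
        assert tom[0, 1] == pytest.approx(expect01, abs=1e-12)
        assert tom[0, 2] == pytest.approx(expect02, abs=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(4)
        n = 12
        A = rng.uniform(0, 1, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = net.tom_similarity(A, denominator="mean")
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(A[i, u] for u in range(n) if u != i)
                k_j = sum(A[j, u] for u in range(n) if u != j)
                expect = (l_ij + A[i, j]) / ((k_i + k_j) / 2 - A[i, j] + 1)
                assert tom[i, j] == pytest.approx(expect, abs=1e-12)

    def test_no_edges_gives_zero_overlap(self):
        tom = net.tom_similarity(np.eye(5))
        assert np.allclose(tom - np.eye(5), 0.0)

    def test_tom_is_symmetric_in_unit_interval(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(0, 1, (30, 30))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        tom = net.tom_similarity(A)
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1
        d = 1 - tom
        assert np.allclose(np.diag(d), 0)


class TestPowerSelection:
    def test_lowest_power_reaching_target(self):
        diag = pd.DataFrame({"power": [6, 12, 23], "r_squared": [0.5, 0.85, 0.9]})
        assert net.select_power_from_curve(diag) == 12

    def test_plateau_rule_when_target_unreached(self):
        diag = pd.DataFrame(
            {"power": [4, 8, 12, 16, 20],
             "r_squared": [0.2, 0.45, 0.6, 0.65, 0.652]}
        )
        # R^2 gain from 12 to 16 drops below 0.01? no: 0.05; from 16 to 20: 0.002
        assert net.select_power_from_curve(diag) == 20
        diag2 = pd.DataFrame(
            {"power": [4, 8, 12, 16, 20],
             "r_squared": [0.2, 0.45, 0.6, 0.605, 0.61]}
        )
        assert net.select_power_from_curve(diag2) == 16

    def test_scale_free_graph_fits_well(self):
        import networkx as nx

        g = nx.barabasi_albert_graph(600, 2, seed=7)
        A = nx.to_numpy_array(g)
        r2, slope = net.scale_free_fit(A)
        assert r2 >= 0.80
        assert slope < 0

    def test_runs_on_planted_matrix(self, default_cfg):
        m, _, _, _ = analysis_matrix(default_cfg)
        beta, diag = net.pick_soft_power(m.values, candidate_powers=(2, 6, 12, 23))
        assert beta in (2.0, 6.0, 12.0, 23.0)
        assert set(diag.columns) == {"power", "r_squared", "slope"}

    def test_too_few_candidates_rejected(self, default_cfg):
        m, _, _, _ = analysis_matrix(default_cfg)
        with pytest.raises(ConfigurationError):
            net.pick_soft_power(m.values, candidate_powers=(6,))


class TestCutModules:
    def _block_dissimilarity(self, sizes, within=0.1, between=0.9):
        n = sum(sizes)
        D = np.full((n, n), between)
        start = 0
        for s in sizes:
            D[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_planted_blocks_recovered_exactly(self):
        D = self._block_dissimilarity([10, 10])
        part = net.cut_modules(D)
        labels = part.labels([f"P{i}" for i in range(20)])
        assert part.n_modules == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_tied_dissimilarity_gives_single_module(self):
        D = np.full((12, 12), 0.5)
        np.fill_diagonal(D, 0.0)
        part = net.cut_modules(D)
        assert part.n_modules == 1

    def test_fewer_entities_than_min_size_all_unassigned(self):
        D = self._block_dissimilarity([3])
        part = net.cut_modules(D)
        assert part.n_modules == 0
        assert all(m == "M0" for m in part.assignment.values())

    def test_small_blocks_go_unassigned(self):
        D = self._block_dissimilarity([8, 3])
        part = net.cut_modules(D, net.NetworkConfig(pam_stage=False))
        labels = part.labels([f"P{i}" for i in range(11)])
        assert part.n_modules == 1
        assert set(labels[8:]) == {"M0"}


class TestEigenprotein:
    def test_identical_profiles(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        m = pd.DataFrame([profile, profile, profile],
                         index=list("abc"), columns=list("WXYZ"))
        v, ve = net.module_eigenprotein(m, list("abc"))
        assert ve == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(v, z / np.linalg.norm(z), atol=1e-12)

    def test_correlated_pair_closed_form(self):
        # 2 members with correlation r: Gram eigenvalues 1 +- |r|,
        # so variance explained is (1 + |r|) / 2
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = -0.8 * x + 0.3 * rng.normal(size=40)
        m = pd.DataFrame([x, y], index=["a", "b"], columns=range(40))
        r = np.corrcoef(x, y)[0, 1]
        _, ve = net.module_eigenprotein(m, ["a", "b"])
        assert ve == pytest.approx((1 + abs(r)) / 2, abs=1e-10)

    def test_sign_aligned_with_mean_profile(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=30)
        rows = [base + 0.1 * rng.normal(size=30) for _ in range(5)]
        m = pd.DataFrame(rows, columns=range(30))
        v, _ = net.module_eigenprotein(m, list(m.index))
        mean_profile = ((m.T - m.mean(axis=1)) / m.std(axis=1, ddof=1)).T.mean()
        assert np.dot(v, mean_profile) > 0

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.normal(size=(6, 25)), columns=range(25))
        v, ve = net.module_eigenprotein(m, list(m.index))
        Z = ((m.T - m.mean(axis=1)) / m.std(axis=1, ddof=1)).T.to_numpy()
        G = Z.T @ Z
        w = rng.normal(size=25)
        for _ in range(3000):
            w = G @ w
            w /= np.linalg.norm(w)
        if np.dot(w, v) < 0:
            w = -w
        np.testing.assert_allclose(np.abs(v), np.abs(w), atol=1e-8)
        assert ve == pytest.approx((w @ G @ w) / np.trace(G), abs=1e-8)

    def test_single_member_returns_standardized_profile(self):
        m = pd.DataFrame([[1.0, 2.0, 4.0]], index=["a"], columns=list("XYZ"))
        v, ve = net.module_eigenprotein(m, ["a"])
        assert ve == 1.0
        assert np.linalg.norm(v) == pytest.approx(1.0)


class TestMergeAndClean:
    def test_near_identical_modules_merged(self):
        rng = np.random.default_rng(9)
        base = rng.normal(size=30)
        rows = [base + 0.05 * rng.normal(size=30) for _ in range(12)]
        m = pd.DataFrame(rows, index=[f"p{i}" for i in range(12)], columns=range(30))
        part = net.ModulePartition(
            assignment={f"p{i}": ("M1" if i < 6 else "M2") for i in range(12)}
        )
        out = net.merge_and_clean(part, m)
        assert out.n_modules == 1

    def test_low_kme_member_moved_to_unassigned(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=40)
        rows = [base + 0.1 * rng.normal(size=40) for _ in range(7)]
        rows.append(rng.normal(size=40))  # unrelated member
        m = pd.DataFrame(rows, index=[f"p{i}" for i in range(8)], columns=range(40))
        part = net.ModulePartition(assignment={f"p{i}": "M1" for i in range(8)})
        out = net.merge_and_clean(part, m)
        assert out.assignment["p7"] == "M0"
        assert all(out.assignment[f"p{i}"] == "M1" for i in range(7))

    def test_artificially_split_module_restored(self):
        rng = np.random.default_rng(11)
        base = rng.normal(size=30)
        rows = [base + 0.2 * rng.normal(size=30) for _ in range(20)]
        m = pd.DataFrame(rows, index=[f"p{i}" for i in range(20)], columns=range(30))
        part = net.ModulePartition(
            assignment={f"p{i}": ("M1" if i < 10 else "M2") for i in range(20)}
        )
        out = net.merge_and_clean(part, m)
        assert out.n_modules == 1
        assert len(out.modules["M1"]) == 20

    def test_labels_ordered_by_size(self, default_cfg):
        m, _, _, _ = analysis_matrix(default_cfg)
        part = net.build_network(m.values)
        sizes = [len(v) for v in part.modules.values()]
        assert sizes == sorted(sizes, reverse=True)
        assert list(part.modules) == [f"M{i+1}" for i in range(part.n_modules)]


class TestTraitsAndPathology:
    def test_eigenprotein_equal_to_trait_gives_rho_one(self, default_cohort):
        cerad = default_cohort["cerad"].to_numpy(float)
        part = net.ModulePartition(
            assignment={},
            eigenproteins=pd.DataFrame(
                [cerad], index=["M1"], columns=default_cohort["case_id"]
            ),
        )
        table = net.module_trait_correlations(part, default_cohort)
        row = table.set_index(["module", "trait"]).loc[("M1", "cerad")]
        assert row["rho"] == pytest.approx(1.0, abs=1e-12)

    def test_planted_ad_module_correlates_with_ad_status(self, default_cfg):
        m, cohort, truth, _ = analysis_matrix(default_cfg)
        part = net.build_network(m.values)
        table = net.module_trait_correlations(part, cohort).set_index(
            ["module", "trait"]
        )
        # the module holding MAPT tracks AD diagnosis
        mod = part.assignment["MAPT"]
        row = table.loc[(mod, "AD")]
        assert row["rho"] > 0.3
        assert row["p"] < 0.05

    def test_toy_case_matches_bicor_and_t_oracle(self):
        rng = np.random.default_rng(12)
        e = rng.normal(size=10)
        trait = 0.8 * e + 0.3 * rng.normal(size=10)
        meta = pd.DataFrame(
            {"case_id": [f"S{i}" for i in range(10)],
             "group": ["CTL"] * 5 + ["AD"] * 5,
             "cerad": trait, "braak": trait}
        )
        part = net.ModulePartition(
            assignment={},
            eigenproteins=pd.DataFrame([e], index=["M1"], columns=meta["case_id"]),
        )
        table = net.module_trait_correlations(part, meta).set_index(
            ["module", "trait"]
        )
        rho = bicor_oracle(e, trait)
        t = rho * np.sqrt(8 / (1 - rho**2))
        p = 2 * stats.t.sf(abs(t), 8)
        assert table.loc[("M1", "cerad"), "rho"] == pytest.approx(rho, abs=1e-10)
        assert table.loc[("M1", "cerad"), "p"] == pytest.approx(p, abs=1e-10)

    def test_constant_trait_flagged_missing(self):
        meta = pd.DataFrame(
            {"case_id": ["S0", "S1", "S2", "S3"], "group": ["CTL"] * 4,
             "cerad": [1.0, 1.0, 1.0, 1.0], "braak": [0, 1, 2, 3]}
        )
        part = net.ModulePartition(
            assignment={},
            eigenproteins=pd.DataFrame(
                [[0.1, 0.4, 0.2, 0.3]], index=["M1"], columns=meta["case_id"]
            ),
        )
        table = net.module_trait_correlations(
            part, meta, diagnosis_indicators=False
        ).set_index(["module", "trait"])
        assert np.isnan(table.loc[("M1", "cerad"), "rho"])
        assert not np.isnan(table.loc[("M1", "braak"), "rho"])

    def test_pathology_ranking_recovers_planted_structure(self, default_cfg):
        m, cohort, truth, _ = analysis_matrix(default_cfg)
        ranking = net.pathology_ranking(m.values).set_index("entity")
        assert ranking.at["MAPT", "bicor_tau"] == pytest.approx(1.0, abs=1e-12)
        members = [e for e, mm in truth["assignment"].items()
                   if mm == 1 and e not in ("MAPT", "Abeta")]
        background = [e for e, mm in truth["assignment"].items() if mm == 0]
        assert ranking.loc[members, "bicor_tau"].median() > \
            ranking.loc[background, "bicor_tau"].median() + 0.3
        # the AD-depleted module anti-tracks tau
        anti = [e for e, mm in truth["assignment"].items() if mm == 3]
        assert ranking.loc[anti, "bicor_tau"].median() < -0.05

    def test_missing_anchor_is_configuration_error(self):
        m = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        with pytest.raises(ConfigurationError):
            net.pathology_ranking(m)


class TestDeterminism:
    def test_build_network_is_deterministic(self, default_cfg):
        m, _, _, _ = analysis_matrix(default_cfg)
        p1 = net.build_network(m.values)
        p2 = net.build_network(m.values)
        assert p1.assignment == p2.assignment
        pd.testing.assert_frame_equal(p1.eigenproteins, p2.eigenproteins)
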