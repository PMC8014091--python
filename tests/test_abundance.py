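"""Roll-up, half-minimum imputation, log2 and covariate residualization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import prmnet
from prmnet import abundance as ab
from prmnet.errors import MappingError, OrderingError


def peptide_matrix(values, peptides, samples, mapping):
    df = pd.DataFrame(values, index=peptides, columns=samples)
    return ab.AbundanceMatrix(values=df, level="peptide", stages=("corrected",)), mapping


def target_frame(mapping):
    return pd.DataFrame(
        {
            "protein": list(mapping.values()),
            "entity": list(mapping.values()),
            "peptide": list(mapping.keys()),
            "charge": 2,
            "precursor_mz": 500.0,
            "is_reference": False,
            "reference_level": 0,
        }
    )


class TestRollup:
    def test_hand_sum(self):
        m, mapping = peptide_matrix([[3.0], [7.0]], ["a", "b"], ["S1"], {"a": "P", "b": "P"})
        out = ab.rollup_proteins(m, target_frame(mapping))
        assert out.values.at["P", "S1"] == 10.0
        assert out.level == "protein"

    def test_matches_grouped_sum_oracle(self):
        rng = np.random.default_rng(2)
        peptides = [f"pep{i}" for i in range(12)]
        mapping = {p: f"E{i % 4}" for i, p in enumerate(peptides)}
        values = rng.uniform(0, 100, (12, 5))
        samples = [f"S{j}" for j in range(5)]
        m, _ = peptide_matrix(values, peptides, samples, mapping)
        out = ab.rollup_proteins(m, target_frame(mapping))
        for e in sorted(set(mapping.values())):
            rows = [i for i, p in enumerate(peptides) if mapping[p] == e]
            np.testing.assert_allclose(
                out.values.loc[e].to_numpy(), values[rows].sum(axis=0)
            )

    def test_unmapped_peptide_is_error(self):
        m, mapping = peptide_matrix([[1.0], [2.0]], ["a", "zz"], ["S1"], {"a": "P"})
        with pytest.raises(MappingError):
            ab.rollup_proteins(m, target_frame(mapping))

    def test_default_synthetic_matrix_is_390_by_44(self, full_protein_pipeline):
        protein = full_protein_pipeline["protein"]
        assert protein.values.shape == (390, 44)

    def test_rollup_commutes_with_sample_reordering(self):
        rng = np.random.default_rng(4)
        peptides = [f"p{i}" for i in range(6)]
        mapping = {p: f"E{i % 2}" for i, p in enumerate(peptides)}
        samples = [f"S{j}" for j in range(4)]
        values = rng.uniform(0, 10, (6, 4))
        m, _ = peptide_matrix(values, peptides, samples, mapping)
        out1 = ab.rollup_proteins(m, target_frame(mapping))
        perm = ["S2", "S0", "S3", "S1"]
        m2 = dataclasses.replace(m, values=m.values[perm])
        out2 = ab.rollup_proteins(m2, target_frame(mapping))
        pd.testing.assert_frame_equal(out1.values[perm], out2.values)


class TestImpute:
    def _pm(self, rows, index=None):
        df = pd.DataFrame(rows, index=index or [f"e{i}" for i in range(len(rows))])
        return ab.AbundanceMatrix(values=df, stages=("corrected",))

    def test_half_minimum_rule(self):
        out, report = ab.impute_half_min(self._pm([[4.0, 0.0, 8.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[4, 2, 8]])
        assert report["n_imputed"] == 1
        assert report["imputed_fraction"] == pytest.approx(1 / 3)
        assert out.imputed_mask.to_numpy().tolist() == [[False, True, False]]

    def test_row_without_zeros_unchanged(self):
        out, report = ab.impute_half_min(self._pm([[4.0, 2.0, 8.0]]))
        np.testing.assert_allclose(out.values.to_numpy(), [[4, 2, 8]])
        assert report["n_imputed"] == 0

    def test_all_zero_row_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out, report = ab.impute_half_min(
                self._pm([[0.0, 0.0], [1.0, 2.0]], index=["dead", "ok"])
            )
        assert list(out.values.index) == ["ok"]
        assert report["dropped_rows"] == ["dead"]
        assert "dead" in caplog.text

    def test_synthetic_missingness_fraction(self, full_protein_pipeline):
        _, report = ab.impute_half_min(full_protein_pipeline["protein"])
        n = 390 * 44
        sd = np.sqrt(0.0073 * (1 - 0.0073) / n)
        assert report["n_values"] == n
        assert report["imputed_fraction"] == pytest.approx(0.0073, abs=4 * sd)


class TestLog2AndOrdering:
    def test_log2_values(self):
        m = ab.AbundanceMatrix(
            values=pd.DataFrame([[8.0, 1.0]]), stages=("corrected", "imputed")
        )
        out = ab.log2_transform(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[3.0, 0.0]])

    def test_log2_requires_positive_values(self):
        m = ab.AbundanceMatrix(values=pd.DataFrame([[4.0, 0.0]]))
        with pytest.raises(OrderingError):
            ab.log2_transform(m)

    def test_stages_cannot_run_backwards(self):
        m = ab.AbundanceMatrix(values=pd.DataFrame([[2.0]]),
                               stages=("corrected", "imputed", "log2"))
        with pytest.raises(OrderingError):
            m.advance("imputed")
        with pytest.raises(OrderingError):
            m.advance("corrected")

    def test_residualize_requires_log2(self):
        m = ab.AbundanceMatrix(values=pd.DataFrame([[2.0]], columns=["S1"]))
        meta = pd.DataFrame({"case_id": ["S1"], "age_death": [70], "sex": ["M"],
                             "pmi": [5.0]})
        with pytest.raises(OrderingError):
            ab.residualize_covariates(m, meta)


class TestResidualize:
    def _meta(self, n, rng):
        return pd.DataFrame(
            {
                "case_id": [f"S{i}" for i in range(n)],
                "age_death": rng.uniform(60, 90, n),
                "sex": rng.choice(["M", "F"], n),
                "pmi": rng.uniform(2, 20, n),
            }
        )

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        meta = self._meta(5, rng)
        meta["sex"] = ["M", "F", "M", "F", "M"]
        y = rng.normal(20, 1, (1, 5))
        m = ab.AbundanceMatrix(
            values=pd.DataFrame(y, index=["P"], columns=meta["case_id"]),
            stages=("corrected", "imputed", "log2"),
        )
        out, coefs = ab.residualize_covariates(m, meta)
        X = np.column_stack(
            [np.ones(5), meta["age_death"],
             meta["sex"].map({"M": 0, "F": 1}), meta["pmi"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y[0])
        expected = y[0] - X @ beta + y[0].mean()
        np.testing.assert_allclose(out.values.loc["P"].to_numpy(), expected,
                                   atol=1e-10)
        np.testing.assert_allclose(
            coefs.loc["P"].to_numpy(), beta[1:], atol=1e-10
        )

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(11)
        meta = self._meta(30, rng)
        y = rng.normal(18, 2, (20, 30))
        m = ab.AbundanceMatrix(
            values=pd.DataFrame(y, columns=meta["case_id"]),
            stages=("corrected", "imputed", "log2"),
        )
        out, _ = ab.residualize_covariates(m, meta)
        resid = out.values.to_numpy() - out.values.to_numpy().mean(axis=1, keepdims=True)
        for cov in ("age_death", "pmi"):
            c = meta[cov].to_numpy() - meta[cov].mean()
            assert np.abs(resid @ c).max() < 1e-8

    def test_constant_covariate_dropped_leaves_matrix_unchanged(self, caplog):
        rng = np.random.default_rng(13)
        meta = self._meta(8, rng)
        meta["age_death"] = 75.0
        meta["pmi"] = 10.0
        meta["sex"] = "M"
        y = rng.normal(20, 1, (3, 8))
        m = ab.AbundanceMatrix(
            values=pd.DataFrame(y, columns=meta["case_id"]),
            stages=("corrected", "imputed", "log2"),
        )
        with caplog.at_level("WARNING"):
            out, coefs = ab.residualize_covariates(m, meta)
        np.testing.assert_allclose(out.values.to_numpy(), y, atol=1e-12)
        assert coefs.empty or coefs.shape[1] == 0
        assert "constant" in caplog.text

    def test_planted_age_slope_recovered(self, default_cfg):
        cfg = dataclasses.replace(default_cfg, age_slope=0.05, effect_table=(),
                                  within_module_cor=0.0, noise_cv=0.05)
        estimates = []
        for seed in range(30, 35):
            cfg_s = dataclasses.replace(cfg, seed=seed)
            cohort = prmnet.generate_cohort(cfg_s)
            raw, _ = prmnet.generate_protein_matrix(cohort, cfg_s)
            m = ab.AbundanceMatrix(values=raw).advance("corrected")
            m, _ = ab.impute_half_min(m)
            m = ab.log2_transform(m)
            _, coefs = ab.residualize_covariates(m, cohort)
            estimates.append(coefs["age_death"].mean())
        assert np.mean(estimates) == pytest.approx(0.05, abs=0.01)
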