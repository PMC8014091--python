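"""Shared fixtures: study-scale and desk-scale synthetic configurations."""

import dataclasses

import pytest

import prmnet
from prmnet import abundance as ab
from prmnet import quant


@pytest.fixture(scope="session")
def default_cfg():
    """The full study design: 44 cases, 870 peptides, 390 entities."""
    return prmnet.SimulationConfig()


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced design for fast structural tests."""
    return prmnet.SimulationConfig(
        group_sizes=(("CTL", 4), ("AsymAD", 3), ("AD", 4), ("PD", 4)),
        n_proteins=24,
        n_peptides=70,
        n_modules_planted=3,
        module_size_range=(3, 6),
        mapt_peptides=5,
        app_peptides=4,
        abeta_peptides=2,
        n_pooled_injections=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def default_cohort(default_cfg):
    return prmnet.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def default_targets(default_cfg):
    return prmnet.generate_target_list(default_cfg)


@pytest.fixture(scope="session")
def small_run(small_cfg):
    """Transition table, reference areas and truth at desk scale."""
    cohort = prmnet.generate_cohort(small_cfg)
    targets = prmnet.generate_target_list(small_cfg)
    table, ref_areas, truth = prmnet.generate_transitions(cohort, targets, small_cfg)
    return dict(cohort=cohort, targets=targets, table=table,
                ref_areas=ref_areas, truth=truth)


@pytest.fixture(scope="session")
def full_protein_pipeline(default_cfg, default_cohort, default_targets):
    """The complete transition-level path to a corrected protein matrix."""
    from prmnet import normalize

    table, ref_areas, truth = prmnet.generate_transitions(
        default_cohort, default_targets, default_cfg
    )
    peptides = quant.quantify_peptides(table)
    panel = normalize.build_reference_panel(peptides, default_targets)
    normalize.select_reference_peptides(panel)
    cf = normalize.compute_correction_factors(panel)
    corrected = normalize.apply_correction(peptides, cf)
    protein = ab.rollup_proteins(corrected, default_targets)
    cases = [c for c in protein.values.columns if not c.startswith("GPS")]
    protein = dataclasses.replace(protein, values=protein.values[cases])
    return dict(table=table, peptides=peptides, panel=panel, cf=cf,
                corrected=corrected, protein=protein, truth=truth)


def analysis_matrix(cfg, seed=None, residualize=True):
    """Matrix-path helper: generator -> impute -> log2 (-> residualize)."""
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    cohort = prmnet.generate_cohort(cfg)
    raw, truth = prmnet.generate_protein_matrix(cohort, cfg)
    m = ab.AbundanceMatrix(values=raw).advance("corrected")
    m, report = ab.impute_half_min(m)
    m = ab.log2_transform(m)
    if residualize:
        m, _ = ab.residualize_covariates(m, cohort)
    return m, cohort, truth, report
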