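"""Abundance matrices and the roll-up / impute / log2 / residualize chain.

The analysis-ready protein matrix is produced in a fixed order: peptide
quantities are drift-corrected, summed into proteins, zeros are imputed at
half the row-wise minimum non-zero value, the matrix is log2-transformed,
and finally each protein is regressed on age, sex and post-mortem interval
so group comparisons are not confounded by those covariates. The stage
flags on :class:`AbundanceMatrix` enforce that ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import MappingError, OrderingError

logger = logging.getLogger(__name__)

STAGE_ORDER = ("corrected", "imputed", "log2", "residualized")


@dataclass
class AbundanceMatrix:
    """Entities x samples abundance grid with bookkeeping.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows are entities (peptides or proteins), columns are sample ids.
    level : str
        ``"peptide"`` or ``"protein"``.
    stages : tuple of str
        Processing flags already applied, a prefix-ordered subset of
        :data:`STAGE_ORDER`.
    imputed_mask : pandas.DataFrame or None
        Boolean grid marking values that were imputed from zeros.
    sample_injections : dict or None
        sample id -> 1-based injection index.
    entity_map : dict or None
        peptide -> roll-up entity (peptide level only).
    """

    values: pd.DataFrame
    level: str = "protein"
    stages: tuple = ()
    imputed_mask: pd.DataFrame | None = None
    sample_injections: dict | None = None
    entity_map: dict | None = None

    def has_stage(self, stage: str) -> bool:
        return stage in self.stages

    def advance(self, stage: str, **changes) -> "AbundanceMatrix":
        """Return a copy with ``stage`` appended, enforcing stage order."""
        if stage not in STAGE_ORDER:
            raise OrderingError(f"unknown stage {stage!r}")
        if stage in self.stages:
            raise OrderingError(f"stage {stage!r} already applied")
        later = STAGE_ORDER[STAGE_ORDER.index(stage) + 1 :]
        if any(s in self.stages for s in later):
            raise OrderingError(
                f"cannot apply {stage!r} after {self.stages}: stages advance "
                f"in the order {STAGE_ORDER}"
            )
        return replace(self, stages=self.stages + (stage,), **changes)


def rollup_proteins(peptide_matrix: AbundanceMatrix, target_list: pd.DataFrame) -> AbundanceMatrix:
    """Sum corrected peptide quantities into roll-up entities.

    Every peptide must map to exactly one entity via the target list
    (column ``entity``); reference spike-in peptides are excluded from the
    roll-up. The output has one row per non-reference entity.
    """
    mapping = (
        target_list.loc[~target_list["is_reference"]]
        .set_index("peptide")["entity"]
        .to_dict()
    )
    ref_peps = set(target_list.loc[target_list["is_reference"], "peptide"])
    values = peptide_matrix.values
    rows = [p for p in values.index if p not in ref_peps]
    unmapped = [p for p in rows if p not in mapping]
    if unmapped:
        raise MappingError(f"{len(unmapped)} peptides not in target list, e.g. {unmapped[:3]}")
    sub = values.loc[rows]
    entities = pd.Index([mapping[p] for p in rows], name="entity")
    protein = sub.groupby(entities).sum()
    # preserve target-list entity order
    order = list(dict.fromkeys(target_list.loc[~target_list["is_reference"], "entity"]))
    protein = protein.loc[[e for e in order if e in protein.index]]
    return AbundanceMatrix(
        values=protein,
        level="protein",
        stages=peptide_matrix.stages,
        sample_injections=peptide_matrix.sample_injections,
    )


def impute_half_min(matrix: AbundanceMatrix) -> tuple[AbundanceMatrix, dict]:
    """Replace zeros by half the row-wise minimum non-zero abundance.

    Rows that are entirely zero cannot define a half-minimum and are
    dropped with a warning. Returns the imputed matrix plus a report with
    the imputed count and fraction of all values.
    """
    values = matrix.values
    all_zero = (values <= 0).all(axis=1)
    if all_zero.any():
        dropped = list(values.index[all_zero])
        logger.warning("dropping %d all-zero rows: %s", len(dropped), dropped[:5])
        values = values.loc[~all_zero]
    else:
        dropped = []
    arr = values.to_numpy(dtype=float)
    zero = arr == 0
    row_min = np.where(zero, np.inf, arr).min(axis=1)
    filled = np.where(zero, 0.5 * row_min[:, None], arr)
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    mask = pd.DataFrame(zero, index=values.index, columns=values.columns)
    report = {
        "n_imputed": int(zero.sum()),
        "n_values": int(arr.size),
        "imputed_fraction": float(zero.sum() / arr.size) if arr.size else 0.0,
        "dropped_rows": dropped,
    }
    return matrix.advance("imputed", values=out, imputed_mask=mask), report


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2; requires strictly positive values (impute first)."""
    arr = matrix.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise OrderingError("non-positive values present; impute before log2")
    return matrix.advance("log2", values=np.log2(matrix.values))


def residualize_covariates(
    matrix: AbundanceMatrix,
    metadata: pd.DataFrame,
    covariates: tuple = ("age_death", "sex", "pmi"),
) -> tuple[AbundanceMatrix, pd.DataFrame]:
    """Regress out covariates per entity, keeping the grand mean.

    For each entity an ordinary least-squares fit on the (intercept +
    covariates) design is computed across samples; the output is the
    residual plus the entity's grand mean, so downstream group means stay
    on the original log2 scale. Sex is coded 0/1 (M=0, F=1) if given as
    strings. Constant covariates are dropped with a warning.

    Returns the residualized matrix and a per-entity coefficient table.
    """
    if not matrix.has_stage("log2"):
        raise OrderingError("residualization expects a log2 matrix")
    samples = list(matrix.values.columns)
    meta = metadata.set_index("case_id").loc[samples]
    cols = []
    names = []
    for cov in covariates:
        v = meta[cov]
        if v.dtype == object:
            v = v.map({"M": 0.0, "F": 1.0})
        v = v.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.warning("covariate %s is constant across samples; dropped", cov)
            continue
        cols.append(v)
        names.append(cov)
    Y = matrix.values.to_numpy(dtype=float)  # entities x samples
    if not cols:
        coefs = pd.DataFrame(index=matrix.values.index)
        return matrix.advance("residualized"), coefs
    X = np.column_stack([np.ones(len(samples))] + cols)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (1+p) x entities
    fitted = X @ beta
    resid = Y.T - fitted
    out = resid.T + Y.mean(axis=1, keepdims=True)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    coefs = pd.DataFrame(
        beta[1:].T, index=matrix.values.index, columns=list(names)
    )
    return matrix.advance("residualized", values=values), coefs
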