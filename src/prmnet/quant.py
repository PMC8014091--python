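"""Transition-report I/O and peptide-level quantification.

A transition report is a long-format table of product-ion (fragment)
chromatographic peak areas, one row per (injection, peptide, charge,
fragment), as exported by targeted-proteomics software. Peptides are
quantified by summing the areas of their strongest product ions
(the quantifier ions), and peptides map to roll-up entities (usually a
protein; the amyloid-beta region of APP is treated as its own entity).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from pyteomics import mass as _pt_mass

from .abundance import AbundanceMatrix
from .errors import (
    ConfigurationError,
    FormatError,
    InsufficientDataError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Required columns of a transition report, in canonical order.
TRANSITION_COLUMNS = (
    "injection_index",
    "sample_id",
    "protein",
    "entity",
    "peptide",
    "charge",
    "fragment_ion",
    "area",
)

#: Monoisotopic mass of the carbamidomethyl fixed modification on Cys.
CARBAMIDOMETHYL_DA = 57.0215
PROTON_DA = 1.00728


def read_transition_report(path) -> pd.DataFrame:
    """Read and validate a transition-report CSV.

    Parameters
    ----------
    path : str or pathlib.Path
        RFC-4180 CSV with the columns in :data:`TRANSITION_COLUMNS`.

    Returns
    -------
    pandas.DataFrame
        Typed transition table.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        If a row carries a negative area or a non-numeric field; the
        message names the offending line number (1-based, header = line 1).
    """
    df = pd.read_csv(path, dtype={"peptide": str, "protein": str})
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"transition report {path} missing columns: {missing}")
    df = df.loc[:, list(TRANSITION_COLUMNS)]
    for col, kind in (("injection_index", int), ("charge", int), ("area", float)):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValidationError(f"non-numeric {col} on line {line}")
        df[col] = coerced.astype(kind)
    neg = df["area"] < 0
    if neg.any():
        line = int(df.index[neg][0]) + 2
        raise ValidationError(f"negative area on line {line}")
    dup = df.duplicated(subset=["injection_index", "peptide", "charge", "fragment_ion"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValidationError(f"duplicate transition on line {line}")
    return df


def write_transition_report(table: pd.DataFrame, path) -> None:
    """Write a transition table as RFC-4180 CSV (UTF-8, '.' decimals)."""
    table.loc[:, list(TRANSITION_COLUMNS)].to_csv(path, index=False)


def select_quantifier_ions(table: pd.DataFrame, peptide: str, k: int = 5) -> list[str]:
    """Pick the *k* strongest product ions of a peptide as quantifiers.

    Strength is the mean area across all injections of the experiment, so
    the quantifier set is a single stable choice per peptide. Ties at the
    rank-k boundary are broken toward the lexicographically smaller
    fragment label.

    Parameters
    ----------
    table : pandas.DataFrame
        Transition table.
    peptide : str
        Peptide to rank fragments for.
    k : int
        Number of quantifier ions, clipped to the 3..6 band used for
        targeted acquisition; defaults to the top five y-ions convention.
    """
    if not 3 <= k <= 6:
        raise ConfigurationError(f"k={k} outside the supported 3..6 band")
    rows = table.loc[table["peptide"] == peptide]
    if rows.empty:
        raise InsufficientDataError(f"peptide {peptide!r} absent from table")
    means = rows.groupby("fragment_ion")["area"].mean()
    if len(means) < 3:
        raise InsufficientDataError(
            f"peptide {peptide!r} has only {len(means)} fragments (< 3)"
        )
    # primary key: descending mean area; secondary: fragment label
    ranked = means.iloc[np.lexsort((means.index, -means.to_numpy()))]
    return list(ranked.index[: min(k, len(ranked))])


def quantify_peptides(
    table: pd.DataFrame,
    k: int = 5,
    min_fragments: int = 3,
) -> AbundanceMatrix:
    """Quantify every peptide per injection from its quantifier-ion areas.

    The peptide quantity is the sum of its quantifier-ion areas in that
    injection. Peptides observed with fewer than ``min_fragments`` nonzero
    quantifier ions in an injection are recorded as 0 (missing) there.

    Returns a peptide-level :class:`AbundanceMatrix` whose columns are
    sample ids ordered by injection index, with the sample->injection map
    attached.
    """
    if not 3 <= k <= 6:
        raise ConfigurationError(f"k={k} outside the supported 3..6 band")
    means = (
        table.groupby(["peptide", "fragment_ion"], sort=False)["area"]
        .mean()
        .reset_index()
    )
    n_frag = means.groupby("peptide")["area"].size()
    short = n_frag[n_frag < 3]
    if len(short):
        raise InsufficientDataError(
            f"{len(short)} peptides have < 3 fragments, e.g. {list(short.index[:3])}"
        )
    means = means.sort_values(
        ["peptide", "area", "fragment_ion"], ascending=[True, False, True],
        kind="mergesort",
    )
    means["rank"] = means.groupby("peptide").cumcount()
    quantifier = set(
        zip(means.loc[means["rank"] < k, "peptide"],
            means.loc[means["rank"] < k, "fragment_ion"])
    )
    sel = [
        (p, f) in quantifier
        for p, f in zip(table["peptide"], table["fragment_ion"])
    ]
    sub = table.loc[sel]

    inj_to_sample = (
        table.drop_duplicates("injection_index")
        .set_index("injection_index")["sample_id"]
        .to_dict()
    )
    quantity = sub.pivot_table(
        index="peptide", columns="injection_index", values="area", aggfunc="sum"
    ).fillna(0.0)
    nonzero = sub.assign(nz=sub["area"] > 0).pivot_table(
        index="peptide", columns="injection_index", values="nz", aggfunc="sum"
    ).fillna(0)
    quantity = quantity.where(nonzero >= min_fragments, 0.0)
    quantity = quantity.reindex(sorted(quantity.columns), axis=1)
    quantity = quantity.loc[list(dict.fromkeys(table["peptide"]))]

    sample_injections = {inj_to_sample[j]: int(j) for j in quantity.columns}
    quantity.columns = [inj_to_sample[j] for j in quantity.columns]
    entity_map = (
        table.drop_duplicates("peptide").set_index("peptide")["entity"].to_dict()
    )
    return AbundanceMatrix(
        values=quantity,
        level="peptide",
        sample_injections=sample_injections,
        entity_map=entity_map,
    )


def compute_precursor_mz(peptide: str, charge: int, carbamidomethyl: bool = True) -> float:
    """Monoisotopic (M + z*H+)/z of a peptide precursor, in Th.

    Cysteines carry the fixed carbamidomethyl modification (+57.0215 Da)
    unless disabled.
    """
    if charge < 1:
        raise ValidationError(f"charge must be >= 1, got {charge}")
    if not peptide or any(r not in _pt_mass.std_aa_mass for r in peptide):
        bad = [r for r in peptide] if not peptide else [
            r for r in peptide if r not in _pt_mass.std_aa_mass
        ]
        raise ValidationError(f"unknown residues in {peptide!r}: {bad}")
    m = _pt_mass.calculate_mass(sequence=peptide)
    if carbamidomethyl:
        m += CARBAMIDOMETHYL_DA * peptide.count("C")
    return (m + charge * PROTON_DA) / charge


def build_target_list(
    identified_proteins,
    annotation_sets: dict,
    interactome,
    shared_peptide_proteins=(),
) -> list[str]:
    """Select quantifiable target proteins by ontology membership.

    The target set is the union of gene symbols belonging to any supplied
    annotation set (e.g. spliceosome, ribonucleoprotein, mRNA processing,
    RNA binding, snRNP/Sm) or to the interactome list, intersected with
    the identified proteins. Proteins without a unique (unshared) peptide
    are removed, since they cannot be quantified unambiguously.
    """
    if not annotation_sets:
        raise ConfigurationError("annotation_sets is empty")
    eligible = set(interactome)
    for genes in annotation_sets.values():
        eligible |= set(genes)
    selected = sorted((set(identified_proteins) & eligible) - set(shared_peptide_proteins))
    return selected
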