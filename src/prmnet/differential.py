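"""Groupwise differential-insolubility statistics.

Volcano tables compare each disease group with controls on the
residualized log2 matrix: the effect is the difference of groupwise mean
log2 abundances (a log2 fold change) and significance is a two-tailed
equal-variance Student t test. A protein is flagged up/down when its
linear fold change passes +-1.5-fold with p < 0.05; p-values are not
FDR-adjusted, matching the small-cohort design. Omnibus one-way ANOVA
and Kruskal-Wallis tests cover all four groups, and per-module summaries
count the fraction of members reaching p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceMatrix
from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

COMPARISONS = ("AsymAD/CTL", "AD/CTL", "PD/CTL")
FOLD_CHANGE_THRESHOLD = 1.5
P_THRESHOLD = 0.05
P_FLOOR = 1e-300


def _group_values(matrix: AbundanceMatrix, metadata: pd.DataFrame, group: str) -> np.ndarray:
    meta = metadata.set_index("case_id")
    cols = [c for c in matrix.values.columns if c in meta.index and meta.at[c, "group"] == group]
    return matrix.values[cols].to_numpy(float)


def classify(log2fc: float, p: float) -> str:
    """Flag from the |FC| > 1.5 (linear) and p < 0.05 rule."""
    if p < P_THRESHOLD and log2fc > np.log2(FOLD_CHANGE_THRESHOLD):
        return "up"
    if p < P_THRESHOLD and log2fc < -np.log2(FOLD_CHANGE_THRESHOLD):
        return "down"
    return "unchanged"


def volcano(matrix: AbundanceMatrix, metadata: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Per-entity log2 fold change and Student t p for one comparison.

    ``comparison`` is "<disease>/<control>", e.g. ``"AD/CTL"``. Both
    groups need at least two samples. Returns a table with columns
    entity, comparison, log2fc, p_t, neg_log10_p, flag.
    """
    disease, control = comparison.split("/")
    a = _group_values(matrix, metadata, disease)
    b = _group_values(matrix, metadata, control)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise InsufficientDataError(
            f"comparison {comparison}: groups have {a.shape[1]} and "
            f"{b.shape[1]} samples; need >= 2 each"
        )
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.clip(np.nan_to_num(p, nan=1.0), P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "entity": matrix.values.index,
            "comparison": comparison,
            "log2fc": log2fc,
            "t": t,
            "p_t": p,
            "neg_log10_p": -np.log10(p),
        }
    )
    out["flag"] = [classify(fc, pv) for fc, pv in zip(out["log2fc"], out["p_t"])]
    return out


def volcano_all(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Volcano tables for all three disease-vs-control comparisons."""
    return pd.concat(
        [volcano(matrix, metadata, c) for c in COMPARISONS], ignore_index=True
    )


def significance_stars(p: float) -> str:
    """Star bins at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def omnibus_tests(matrix: AbundanceMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """One-way ANOVA F and Kruskal-Wallis H p-values across all groups.

    Entities whose values are tied within every group are degenerate for
    both tests and reported with p = 1 and a warning.
    """
    meta = metadata.set_index("case_id")
    groups = {}
    for g in meta["group"].unique():
        cols = [c for c in matrix.values.columns if c in meta.index and meta.at[c, "group"] == g]
        if len(cols) >= 2:
            groups[g] = matrix.values[cols].to_numpy(float)
    if len(groups) < 2:
        raise InsufficientDataError("omnibus tests need >= 2 groups with >= 2 samples")
    rows = []
    for i, entity in enumerate(matrix.values.index):
        samples = [v[i] for v in groups.values()]
        if all(np.ptp(s) == 0 for s in samples) and np.ptp(np.concatenate(samples)) == 0:
            logger.warning("entity %s constant in every group; p set to 1", entity)
            p_a = p_k = 1.0
        else:
            p_a = float(stats.f_oneway(*samples).pvalue)
            try:
                p_k = float(stats.kruskal(*samples).pvalue)
            except ValueError:  # all values identical
                p_k = 1.0
        p_a = min(max(np.nan_to_num(p_a, nan=1.0), P_FLOOR), 1.0)
        p_k = min(max(np.nan_to_num(p_k, nan=1.0), P_FLOOR), 1.0)
        rows.append((entity, p_a, p_k, significance_stars(p_k)))
    return pd.DataFrame(rows, columns=["entity", "p_anova", "p_kw", "stars_kw"])


def module_significance_fraction(
    results: pd.DataFrame, assignment: dict
) -> pd.DataFrame:
    """Per module x comparison: fraction significant and mean log2fc.

    ``assignment`` maps entity -> module label. For each module and
    comparison, reports the fraction of members with p_t < 0.05 and the
    mean log2 fold change of those significant members (the heat color
    value of the stacked-bar figure); modules with no significant member
    get mean_log2fc_significant = NaN.
    """
    rows = []
    modules = sorted(set(assignment.values()), key=str)
    known = set(results["entity"])
    for mod in modules:
        members = [e for e, m in assignment.items() if m == mod]
        present = [e for e in members if e in known]
        if not present:
            logger.warning("module %s absent from results; skipped", mod)
            continue
        for comp, sub in results.groupby("comparison"):
            sub = sub.set_index("entity").loc[present]
            sig = sub["p_t"] < P_THRESHOLD
            rows.append(
                (
                    mod,
                    comp,
                    len(present),
                    float(sig.mean()),
                    float(sub.loc[sig, "log2fc"].mean()) if sig.any() else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["module", "comparison", "n_members", "fraction_significant",
                 "mean_log2fc_significant"],
    )
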