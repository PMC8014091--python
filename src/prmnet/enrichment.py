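"""Fisher-exact ontology over-representation and module co-clustering.

For every (module, term) pair a two-tailed Fisher exact test on the 2x2
overlap table against a background universe gives a p-value, converted to
a signed Z-score equivalent (positive for over-representation). A term is
flagged significant for a module when Z > 1.96 and at least 3 gene
symbols overlap. The module x term Z matrix is co-clustered with
Manhattan distance and Ward linkage into macro-clusters of modules that
share enrichment profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.96
MIN_OVERLAP = 3


def fisher_overrep(module_genes, term_genes, background) -> tuple[float, int]:
    """Two-tailed Fisher exact p of the module/term overlap.

    The 2x2 table counts (in module & in term, in module only, in term
    only, in neither) over the background universe. Returns (p, overlap).
    """
    bg = set(background)
    if not bg:
        raise ConfigurationError("background universe is empty")
    mod = set(module_genes) & bg
    term = set(term_genes) & bg
    a = len(mod & term)
    b = len(mod - term)
    c = len(term - mod)
    d = len(bg) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p), a


def expected_overlap(module_genes, term_genes, background) -> float:
    """Expected overlap under independence: |module| * |term| / |background|."""
    bg = set(background)
    mod = set(module_genes) & bg
    term = set(term_genes) & bg
    return len(mod) * len(term) / len(bg)


def p_to_z(p: float, over_represented: bool = True) -> float:
    """Z-score equivalent of a two-tailed p, signed by direction.

    Z = Phi^-1 survival of p/2; positive when the observed overlap
    exceeds its expectation, negative otherwise.
    """
    if not 0 < p <= 1:
        raise ValidationError(f"p must be in (0, 1], got {p}")
    z = float(stats.norm.isf(p / 2.0))
    return z if over_represented else -z


def z_to_p(z: float) -> float:
    """Inverse of :func:`p_to_z` (two-tailed p of |Z|)."""
    return float(2.0 * stats.norm.sf(abs(z)))


def enrichment_table(
    module_genes: dict,
    term_genes: dict,
    background,
) -> pd.DataFrame:
    """Fisher p / signed Z for every module x term pair.

    ``module_genes`` and ``term_genes`` map labels to gene-symbol
    collections; only positive-signed (over-represented) rows with
    overlap >= 3 and Z > 1.96 are flagged significant.
    """
    rows = []
    for mod, genes in module_genes.items():
        for term, tg in term_genes.items():
            p, overlap = fisher_overrep(genes, tg, background)
            over = overlap > expected_overlap(genes, tg, background)
            z = p_to_z(max(p, 1e-300), over)
            rows.append(
                (mod, term, overlap, p, z,
                 bool(z > Z_THRESHOLD and overlap >= MIN_OVERLAP))
            )
    return pd.DataFrame(
        rows, columns=["module", "term", "overlap", "fisher_p", "z", "significant"]
    )


def z_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot an enrichment table into a module x term Z matrix."""
    return table.pivot(index="module", columns="term", values="z").fillna(0.0)


def cocluster_z_matrix(
    z: pd.DataFrame, n_clusters: int = 6
) -> tuple[pd.Series, list, list]:
    """Co-cluster the module x term Z matrix into macro-clusters.

    Rows (modules) and columns (terms) are clustered hierarchically with
    Manhattan (L1) distance and Ward linkage; modules are cut into
    ``n_clusters`` macro-clusters. Returns (module macro-cluster labels,
    module leaf order, term leaf order).
    """
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValidationError("co-clustering needs >= 2 modules and >= 2 terms")
    if not np.any(z.to_numpy()):
        logger.warning("all-zero Z matrix; single macro-cluster")
        return (
            pd.Series(1, index=z.index, name="macro_cluster"),
            list(z.index),
            list(z.columns),
        )
    n_clusters = min(n_clusters, z.shape[0])
    row_link = hierarchy.linkage(pdist(z.to_numpy(), metric="cityblock"), method="ward")
    col_link = hierarchy.linkage(pdist(z.to_numpy().T, metric="cityblock"), method="ward")
    labels = hierarchy.fcluster(row_link, t=n_clusters, criterion="maxclust")
    row_order = [z.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [z.columns[i] for i in hierarchy.leaves_list(col_link)]
    return pd.Series(labels, index=z.index, name="macro_cluster"), row_order, col_order


def read_gene_sets(path) -> dict:
    """Read gene sets from GMT or two-column (term, gene) TSV."""
    sets: dict = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if "\t" in first and len(first.rstrip("\n").split("\t")) > 2:
            for line in fh:  # GMT: term, description, genes...
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 3:
                    sets[parts[0]] = set(g for g in parts[2:] if g)
        else:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0]:
                    sets.setdefault(parts[0], set()).add(parts[1])
    if not sets:
        raise ConfigurationError(f"no gene sets parsed from {path}")
    return sets
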