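"""Pathway enrichment by a one-sided Wilcoxon rank-sum test on gene ranks.

Genes are ranked by their differential-expression p-value (rank 1 = most
significant, probes collapsed to genes by the best probe's p, ties averaged).
For each KEGG pathway the ranks of member genes are compared with the ranks
of all other genes; the one-sided alternative is that pathway genes occupy
lower (more significant) ranks.  Small instances are tested by exact
enumeration of the rank-sum null distribution, larger ones by the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGeneSet",
    "EnrichmentResult",
    "read_pathways_tsv",
    "rank_genes",
    "wilcoxon_geneset_test",
    "enrich_all",
]

# exact-enumeration limits: the smaller side and the total universe
EXACT_MIN_SIDE = 10
EXACT_MAX_TOTAL = 25


@dataclass(frozen=True)
class PathwayGeneSet:
    pathway_id: str  # e.g. hsa04310
    name: str
    gene_symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"{self.pathway_id}: empty gene set")


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    name: str
    n_in_matrix: int
    p: float | None
    testable: bool


def read_pathways_tsv(path) -> list[PathwayGeneSet]:
    """Read pathway membership (columns pathway_id, name, gene_symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"pathway_id", "name", "gene_symbol"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    sets = []
    for (pid, name), grp in df.groupby(["pathway_id", "name"], sort=True):
        sets.append(PathwayGeneSet(pid, name, frozenset(grp["gene_symbol"])))
    ids = [s.pathway_id for s in sets]
    if len(ids) != len(set(ids)):
        raise ValueError(f"{path}: pathway_id repeated with differing names")
    return sets


def rank_genes(de: pd.DataFrame, annotation: pd.Series | None = None) -> pd.Series:
    """Gene -> rank by differential-expression p (1 = most significant).

    *de* is a moderated-DE table indexed by probe with a ``p`` column (and a
    ``gene_symbol`` column, unless *annotation* supplies the probe -> gene
    map).  Probes collapse to genes by the minimum p; tied p-values receive
    average ranks.
    """
    if de.empty:
        raise ValueError("empty differential-expression table")
    if annotation is not None:
        genes = annotation.reindex(de.index).fillna("")
    elif "gene_symbol" in de.columns:
        genes = de["gene_symbol"].fillna("")
    else:
        raise ValueError("need an annotation or a gene_symbol column")
    keep = genes != ""
    if not keep.any():
        raise ValueError("no annotated genes in the table")
    best_p = de.loc[keep, "p"].groupby(genes[keep]).min()
    return best_p.rank(method="average", ascending=True)


def wilcoxon_geneset_test(
    ranks: pd.Series, gene_set: PathwayGeneSet
) -> EnrichmentResult:
    """One-sided rank-sum test: do pathway genes rank better than the rest?

    Untestable (flagged, p = None) when the pathway covers none or all of the
    ranked universe.
    """
    in_set = ranks.index.isin(gene_set.gene_symbols)
    n_in = int(in_set.sum())
    n_out = int((~in_set).sum())
    n_unmatched = len(gene_set.gene_symbols) - n_in
    if n_unmatched:
        logger.info(
            "%s: %d pathway genes not in the ranked universe",
            gene_set.pathway_id, n_unmatched,
        )
    if n_in == 0 or n_out == 0:
        return EnrichmentResult(gene_set.pathway_id, gene_set.name, n_in, None, False)
    set_ranks = ranks[in_set].to_numpy()
    other_ranks = ranks[~in_set].to_numpy()
    has_ties = len(np.unique(ranks.to_numpy())) < len(ranks)
    exact = (
        min(n_in, n_out) <= EXACT_MIN_SIDE
        and (n_in + n_out) <= EXACT_MAX_TOTAL
        and not has_ties
    )
    res = stats.mannwhitneyu(
        set_ranks,
        other_ranks,
        alternative="less",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return EnrichmentResult(
        gene_set.pathway_id, gene_set.name, n_in, float(res.pvalue), True
    )


def enrich_all(
    ranks: pd.Series, pathways: list[PathwayGeneSet]
) -> pd.DataFrame:
    """Run the rank-sum test over a pathway collection; Table-2-style output."""
    rows = [wilcoxon_geneset_test(ranks, ps) for ps in pathways]
    return pd.DataFrame(
        [(r.name, r.pathway_id, r.n_in_matrix, r.p, r.testable) for r in rows],
        columns=["name", "pathway_id", "n_in_matrix", "p", "testable"],
    )
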