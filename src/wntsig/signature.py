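"""Anchor-correlated gene signatures.

A signature is derived by correlating every probe of a WNT-target panel with
the probes of one or two anchor genes (LEF1/TCF4 pooled, or AXIN2) across the
samples of a brain-metastasis expression matrix.  A panel probe enters the
signature when its mean Pearson correlation over the anchor probes reaches
``+threshold`` (positive arm) or ``-threshold`` (negative arm); the default
threshold is r = 0.4.  Gene and probe counts are reported separately because
several probes may map to one gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PearsonResult",
    "pearson_r",
    "AnchorSet",
    "TargetPanel",
    "SignatureEntry",
    "SignatureResult",
    "derive_signature",
]


@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    ci95: tuple[float, float]


def pearson_r(x, y) -> PearsonResult:
    """Sample Pearson correlation with two-sided t-test p and Fisher-z 95% CI.

    Requires equal-length vectors of at least 3 non-constant observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)  # Fisher z-transform interval
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue),
                         ci95=(float(ci.low), float(ci.high)))


@dataclass
class AnchorSet:
    """Named anchor genes with their probe ids resolved in a matrix."""

    name: str
    anchor_genes: list[str]
    anchor_probes: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def resolve(cls, name: str, anchor_genes: list[str],
                annotation: pd.Series, matrix) -> "AnchorSet":
        """Resolve each anchor gene to its probes present in *matrix*.

        *annotation* maps probe_id -> gene_symbol.  Every anchor gene must
        resolve to at least one probe.
        """
        if not anchor_genes:
            raise ValueError("anchor set needs at least one gene")
        present = annotation[annotation.index.isin(matrix.probe_ids)]
        probes: dict[str, list[str]] = {}
        for gene in anchor_genes:
            hits = list(present.index[present == gene])
            if not hits:
                raise ValueError(
                    f"anchor gene {gene!r} has no probe in the matrix"
                )
            probes[gene] = hits
        return cls(name=name, anchor_genes=list(anchor_genes), anchor_probes=probes)

    @property
    def all_probes(self) -> list[str]:
        return [p for g in self.anchor_genes for p in self.anchor_probes[g]]


@dataclass
class TargetPanel:
    """WNT-target panel: gene symbols with their probe ids."""

    probes_by_gene: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.probes_by_gene:
            raise ValueError("empty target panel")

    @classmethod
    def from_tsv(cls, path) -> "TargetPanel":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if not {"gene_symbol", "probe_id"} <= set(df.columns):
            raise ValueError(f"{path}: expected columns gene_symbol, probe_id")
        probes: dict[str, list[str]] = {}
        for gene, probe in zip(df["gene_symbol"], df["probe_id"]):
            probes.setdefault(gene, []).append(probe)
        return cls(probes)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.probes_by_gene)


@dataclass(frozen=True)
class SignatureEntry:
    gene_symbol: str
    probe_id: str
    mean_r: float
    sign: str  # "positive" | "negative"


@dataclass
class SignatureResult:
    anchor_name: str
    entries: list[SignatureEntry]

    @property
    def n_probes(self) -> int:
        return len(self.entries)

    @property
    def n_genes(self) -> int:
        return len({e.gene_symbol for e in self.entries})

    @property
    def probe_ids(self) -> list[str]:
        return [e.probe_id for e in self.entries]

    @property
    def positive_probes(self) -> list[str]:
        return [e.probe_id for e in self.entries if e.sign == "positive"]

    def genes(self) -> list[str]:
        return sorted({e.gene_symbol for e in self.entries})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_symbol, e.probe_id, e.mean_r, e.sign) for e in self.entries],
            columns=["gene_symbol", "probe_id", "mean_r", "sign"],
        )


def derive_signature(
    matrix,
    anchors: AnchorSet,
    panel: TargetPanel,
    threshold: float = 0.4,
    mean_over: str = "probes",
) -> SignatureResult:
    """Correlation-threshold signature derivation.

    For each panel probe present in *matrix*, compute the Pearson r against
    every anchor probe.  ``mean_over='probes'`` (default) averages r over all
    anchor probes pooled; ``mean_over='genes'`` first averages within each
    anchor gene, then across anchor genes.  The probe enters the signature iff
    ``mean_r >= threshold`` or ``mean_r <= -threshold``.  Panel genes that are
    themselves anchors are excluded.
    """
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if mean_over not in ("probes", "genes"):
        raise ValueError(f"mean_over must be 'probes' or 'genes', got {mean_over!r}")

    anchor_rows = {
        gene: [matrix.data.loc[p].to_numpy() for p in anchors.anchor_probes[gene]]
        for gene in anchors.anchor_genes
    }

    entries: list[SignatureEntry] = []
    n_panel_probes_present = 0
    for gene in panel.gene_symbols:
        if gene in anchors.anchor_genes:
            continue
        for probe in panel.probes_by_gene[gene]:
            if probe not in matrix.data.index:
                continue
            n_panel_probes_present += 1
            row = matrix.data.loc[probe].to_numpy()
            if np.ptp(row) == 0:
                logger.info("derive_signature: constant probe %s skipped", probe)
                continue
            per_gene_means = []
            pooled = []
            for agene in anchors.anchor_genes:
                rs = [pearson_r(row, arow).r for arow in anchor_rows[agene]]
                per_gene_means.append(float(np.mean(rs)))
                pooled.extend(rs)
            mean_r = (
                float(np.mean(pooled)) if mean_over == "probes"
                else float(np.mean(per_gene_means))
            )
            if mean_r >= threshold:
                entries.append(SignatureEntry(gene, probe, mean_r, "positive"))
            elif mean_r <= -threshold:
                entries.append(SignatureEntry(gene, probe, mean_r, "negative"))
    if n_panel_probes_present == 0:
        raise ValueError("no panel probe present in the matrix")
    return SignatureResult(anchor_name=anchors.name, entries=entries)
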