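"""End-to-end orchestration of the signature -> cluster -> survival workflow.

``run_full`` executes the complete analysis path: derive the LEF1/TCF4 and
AXIN2 signatures on the metastasis matrix, stratify the primary cohort by
complete-linkage clustering on the chosen signature's probes, quantify the
prognostic split (Cox hazard ratio for cluster 2 vs cluster 1, log-rank,
Kaplan-Meier curves), run moderated-t differential expression between the
clusters, and test pathway enrichment on the resulting gene ranks.  Every
intermediate is written as TSV next to a JSON run report recording config,
seeds, library versions, stage counts and input hashes, so a run can be
reproduced exactly from its report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import hierarchical_cluster
from .diffexpr import moderated_de
from .enrichment import enrich_all, rank_genes, read_pathways_tsv
from .expression import (
    ExpressionMatrix,
    read_annotation_tsv,
    read_matrix_tsv,
    read_series_matrix,
)
from .signature import AnchorSet, TargetPanel, derive_signature
from .survival import (
    SurvivalRecord,
    cox_fit,
    kaplan_meier,
    logrank_test,
    records_from_frame,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and knobs for a full run.  All paths must exist at run start."""

    metastasis_matrix: str
    primary_matrix: str
    panel: str
    annotation: str
    survival: str
    out_dir: str
    pathways: str | None = None
    threshold: float = 0.4
    k: int = 2
    alpha: float = 0.05
    ties: str = "efron"
    mean_over: str = "probes"
    cluster_signature: str = "LEF1/TCF4"
    lef1_tcf4_anchors: list[str] = field(default_factory=lambda: ["LEF1", "TCF4"])
    axin2_anchors: list[str] = field(default_factory=lambda: ["AXIN2"])
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0,1)")
        for name in ("metastasis_matrix", "primary_matrix", "panel",
                     "annotation", "survival"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name} does not exist: {p}")
        if self.pathways is not None and not Path(self.pathways).exists():
            raise FileNotFoundError(f"pathways file not found: {self.pathways}")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_matrix(path) -> ExpressionMatrix:
    with open(path) as fh:
        head = fh.read(4096)
    if "!series_matrix_table_begin" in head or head.startswith("!"):
        return read_series_matrix(path)
    return read_matrix_tsv(path)


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False),
              float_format="%.12g", **kw)


def run_full(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "wntsig_version": __version__,
        "config": asdict(config),
        "input_sha256": {
            name: _sha256(getattr(config, name))
            for name in ("metastasis_matrix", "primary_matrix", "panel",
                         "annotation", "survival")
        },
        "stages": {},
    }
    stage = "load"
    try:
        meta = _read_matrix(config.metastasis_matrix)
        primary = _read_matrix(config.primary_matrix)
        panel = TargetPanel.from_tsv(config.panel)
        annotation = read_annotation_tsv(config.annotation)
        surv_frame = pd.read_csv(config.survival, sep="\t")
        records = records_from_frame(surv_frame)

        stage = "signature"
        signatures = {}
        for name, genes in (
            ("LEF1/TCF4", config.lef1_tcf4_anchors),
            ("AXIN2", config.axin2_anchors),
        ):
            anchors = AnchorSet.resolve(name, genes, annotation, meta)
            sig = derive_signature(
                meta, anchors, panel,
                threshold=config.threshold, mean_over=config.mean_over,
            )
            signatures[name] = sig
            tag = name.replace("/", "_")
            _write_tsv(sig.to_frame(), out / f"signature_{tag}.tsv")
            report["stages"][f"signature_{tag}"] = {
                "n_genes": sig.n_genes, "n_probes": sig.n_probes,
            }

        stage = "cluster"
        cluster_results = {}
        for name, sig in signatures.items():
            tag = name.replace("/", "_")
            probes = [p for p in sig.probe_ids if p in primary.data.index]
            if len(probes) < 3:
                report["stages"][f"cluster_{tag}"] = {
                    "skipped": f"only {len(probes)} signature probes in cohort"
                }
                continue
            assign = hierarchical_cluster(
                primary, probes, k=config.k,
                positive_probes=sig.positive_probes,
            )
            cluster_results[name] = assign
            _write_tsv(assign.to_frame(), out / f"clusters_{tag}.tsv")
            report["stages"][f"cluster_{tag}"] = {
                "sizes": {str(c): len(assign.group(c))
                          for c in sorted(set(assign.labels.values()))}
            }

        chosen = config.cluster_signature
        if chosen not in cluster_results:
            raise PipelineError(
                f"cluster: chosen signature {chosen!r} produced no clustering"
            )
        assign = cluster_results[chosen]

        stage = "survival"
        by_id = {r.sample_id: r for r in records}
        common = [s for s in assign.labels if s in by_id]
        if not common:
            raise PipelineError("survival: no overlap of samples with annotation")
        groups = {1: [], 2: []}
        for s in common:
            groups[assign.labels[s]].append(by_id[s])
        # HR reported for cluster 2 vs cluster 1 (good vs poor prognosis)
        recs = [
            SurvivalRecord(r.sample_id, r.time, r.event,
                           {"cluster2": 1.0 if assign.labels[r.sample_id] == 2
                            else 0.0})
            for r in (by_id[s] for s in common)
        ]
        fit = cox_fit(recs, ["cluster2"], ties=config.ties)
        chi2, logrank_p = logrank_test([groups[1], groups[2]])
        km_frames = []
        for c in (1, 2):
            km = kaplan_meier(groups[c])
            km.insert(0, "cluster", c)
            km_frames.append(km)
        _write_tsv(pd.concat(km_frames), out / "kaplan_meier.tsv")
        est = fit["cluster2"]
        report["stages"]["survival"] = {
            "hr_cluster2_vs_1": est["hr"],
            "ci95": [est["ci_low"], est["ci_high"]],
            "wald_p": est["wald_p"],
            "logrank_chi2": chi2,
            "logrank_p": logrank_p,
            "n": fit.n, "n_events": fit.n_events,
        }

        stage = "diffexpr"
        labels = {s: assign.labels[s] for s in primary.sample_ids}
        de = moderated_de(primary, labels, annotation=annotation)
        _write_tsv(de.reset_index(names="probe_id"), out / "diffexpr.tsv")
        n_sig = int((de["fdr"] < config.alpha).sum())
        sig_genes = sorted(
            set(de.loc[de["fdr"] < config.alpha, "gene_symbol"]) - {""}
        ) if "gene_symbol" in de.columns else []
        report["stages"]["diffexpr"] = {
            "n_probes_tested": int(len(de)),
            "n_significant_probes": n_sig,
            "n_significant_genes": len(sig_genes),
            "significant_genes": sig_genes,
        }

        if config.pathways is not None:
            stage = "enrichment"
            pathways = read_pathways_tsv(config.pathways)
            ranks = rank_genes(de)
            enr = enrich_all(ranks, pathways)
            _write_tsv(enr, out / "enrichment.tsv")
            report["stages"]["enrichment"] = {
                "n_pathways": len(pathways),
                "significant": sorted(
                    enr.loc[enr["testable"] & (enr["p"] < config.alpha),
                            "pathway_id"]
                ),
            }
    except PipelineError:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise PipelineError(f"{stage}: {exc}") from exc

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
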