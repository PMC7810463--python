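"""End-to-end orchestration: expression -> peaks -> sharing -> enhancers -> motifs.

Each stage consumes only files and writes its outputs back to disk, so stages
are independently re-runnable; :func:`run_pipeline` wires them together from a
single :class:`PipelineConfig` and emits a machine-readable JSON summary with
every headline count and fraction. Reruns with the same config reproduce the
summary bit-exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enhancers, expression, motifs, peaks, sharing
from .intervals import read_bed, write_bed

log = logging.getLogger("bifate")


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; mirrors the on-disk YAML layout."""

    # inputs
    genes: str = "genes.tsv"
    chrom_sizes: str = "chrom_sizes.tsv"
    expr_counts: str = "expression_counts.tsv"
    expr_meta: str = "expression_samples.tsv"
    replicate_beds: list = field(default_factory=list)
    atac_counts: str = "atac_counts.tsv"
    atac_tissues: str = "atac_samples.tsv"
    peak_coords: str = "source_peaks.bed"
    blacklist: str | None = "blacklist.bed"
    tracks_manifest: str | None = "tracks_manifest.tsv"
    sequences: str | None = "peak_sequences.fasta"
    motifs_table: str | None = "motifs.tsv"
    # parameters (defaults are the published selection rules)
    alpha: float = 0.05
    min_fc: float = 2.0
    attachment_expr_threshold: float = 10.0
    min_peak_length: int = 500
    vote_threshold: float = 30.0
    min_fraction: float = 0.5
    avg_threshold: float = 30.0
    max_link_distance: int = 1_000_000
    criteria_weights: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "bifate_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        base = Path(path).parent
        cfg = cls(**data)
        # resolve input paths relative to the config file
        for attr in ("genes", "chrom_sizes", "expr_counts", "expr_meta",
                     "atac_counts", "atac_tissues", "peak_coords", "blacklist",
                     "tracks_manifest", "sequences", "motifs_table"):
            val = getattr(cfg, attr)
            if val is not None:
                setattr(cfg, attr, str(base / val) if not Path(val).is_absolute() else val)
        cfg.replicate_beds = [
            str(base / b) if not Path(b).is_absolute() else b for b in cfg.replicate_beds
        ]
        return cfg


def _require(path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


def read_expression(counts_path, meta_path) -> expression.ExpressionMatrix:
    counts = pd.read_csv(_require(counts_path, "counts file"), sep="\t", index_col=0)
    meta = pd.read_csv(_require(meta_path, "sample metadata"), sep="\t")
    return expression.ExpressionMatrix(counts=counts, sample_meta=meta)


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_motifs_table(path) -> list[motifs.Motif]:
    df = pd.read_csv(_require(path, "motif table"), sep="\t")
    out = []
    for _, r in df.iterrows():
        if r["type"] == "consensus":
            out.append(motifs.Motif(id=r["id"], consensus=r["definition"],
                                    score_threshold=float(r.get("threshold", 0.8))))
        else:
            raise ValueError(f"unsupported motif type {r['type']!r} in table "
                             "(PWMs are supplied programmatically)")
    return out


def read_tracks(manifest_path) -> list[enhancers.EvidenceTrack]:
    mdf = pd.read_csv(_require(manifest_path, "tracks manifest"), sep="\t")
    base = Path(manifest_path).parent
    return [
        enhancers.EvidenceTrack(
            name=r["name"], role=r["role"], intervals=read_bed(base / r["path"])
        )
        for _, r in mdf.iterrows()
    ]


def stage_expression(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = read_expression(cfg.expr_counts, cfg.expr_meta)
    labels = expression.classify_genes(
        matrix, cfg.alpha, cfg.min_fc, cfg.attachment_expr_threshold
    )
    de = labels.attrs["de_table"]
    normalized = labels.attrs["normalized"]
    de_genes = de.loc[de["significant"], "gene"].tolist()
    sim = None
    if len(de_genes) >= 3:
        sim = expression.compartment_similarity(normalized, matrix, de_genes)
        sim.pca_coordinates.to_csv(outdir / "pca_coordinates.tsv", sep="\t")
    de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    labels.to_csv(outdir / "gene_labels.tsv", sep="\t", index=False)
    sizes = expression.class_size_summary(labels.set_index("gene")["label"])
    return {
        "labels": labels,
        "summary": {
            "n_genes": int(len(labels)),
            "n_de_genes": int(len(de_genes)),
            "class_sizes": {c: sizes[c] for c in expression.GENE_CLASSES},
            "mixed_set_size": sizes["mixed_set_size"],
            "similarity": None if sim is None else {
                "distance_to_tenocyte": sim.distance_to_tenocyte,
                "distance_to_chondrocyte": sim.distance_to_chondrocyte,
                "closer_to": sim.closer_to,
            },
        },
    }


def stage_peaks(cfg: PipelineConfig, outdir: Path) -> dict:
    beds = [read_bed(_require(b, "replicate BED")) for b in cfg.replicate_beds]
    counts = pd.read_csv(_require(cfg.atac_counts, "ATAC counts"), sep="\t", index_col=0)
    coords = read_bed(_require(cfg.peak_coords, "source peak coordinates"))
    coords = coords.set_index("name", drop=False)
    coords.index.name = None
    tissue_map = pd.read_csv(
        _require(cfg.atac_tissues, "tissue map"), sep="\t", index_col=0
    )["tissue"]
    chrom_sizes = pd.read_csv(
        _require(cfg.chrom_sizes, "chrom sizes"), sep="\t", index_col=0
    )["size"].to_dict()
    blacklist = read_bed(cfg.blacklist) if cfg.blacklist and Path(cfg.blacklist).exists() else None
    result = peaks.run_peak_pipeline(
        beds, counts, coords, tissue_map, chrom_sizes, blacklist,
        cfg.min_peak_length, cfg.vote_threshold, cfg.min_fraction, cfg.avg_threshold,
    )
    out = result.peaks.copy()
    out["score"] = result.tissue_means.max(axis=1).round(2).to_numpy()
    write_bed(out, outdir / "consensus_peaks.bed", ["chrom", "start", "end", "name", "score"])
    result.flags.to_csv(outdir / "accessibility_flags.tsv", sep="\t")
    (outdir / "filter_report.json").write_text(
        json.dumps(result.report.as_dict(), indent=1)
    )
    # retained consensus -> contributing source peaks, for sequence lookup
    mapping = peaks.map_source_peaks(result.peaks, coords)
    mapping.rename("consensus").rename_axis("source").to_csv(
        outdir / "peak_mapping.tsv", sep="\t"
    )
    return {"result": result, "mapping": mapping, "summary": result.report.as_dict()}


def stage_sharing(cfg: PipelineConfig, outdir: Path, peak_result, de_genes=None) -> dict:
    gene_table = pd.read_csv(_require(cfg.genes, "gene table"), sep="\t")
    annotated = sharing.annotate_peaks(
        peak_result.peaks, peak_result.flags, gene_table, cfg.max_link_distance
    )
    annotated.to_csv(outdir / "annotated_peaks.tsv", sep="\t", index=False)
    report = sharing.summarize_sharing(annotated)
    if de_genes:
        report_de = sharing.summarize_sharing(annotated, gene_filter=set(de_genes))
        report["de_linked"] = report_de
    (outdir / "sharing_report.json").write_text(json.dumps(report, indent=1))
    return {"annotated": annotated, "summary": report}


def stage_motifs(cfg: PipelineConfig, outdir: Path, annotated, mapping, labels) -> dict:
    if not (cfg.sequences and cfg.motifs_table):
        return {"summary": None, "hit_peaks": set()}
    sequences = read_fasta(_require(cfg.sequences, "peak sequences"))
    motif_list = read_motifs_table(cfg.motifs_table)
    retained = set(annotated["peak"])
    hit_peaks: set = set()
    for motif in motif_list:
        for source, consensus_id in mapping.items():
            if consensus_id in retained and source in sequences:
                if len(motifs.scan_motif(sequences[source], motif)) > 0:
                    hit_peaks.add(consensus_id)
    universe = labels["gene"].tolist()
    site_table = motifs.gene_site_table(annotated, hit_peaks, retained, universe)
    site_table.rename("has_site").to_csv(outdir / "gene_sites.tsv", sep="\t")
    mixed = set(
        labels.loc[labels["label"].isin(["tenogenic_mixed", "chondrogenic_mixed"]), "gene"]
    )
    summary = None
    if mixed and len(mixed) < len(universe):
        enr = motifs.set_enrichment(mixed, set(universe), site_table)
        summary = {
            "foreground_fraction": enr.foreground_fraction,
            "background_fraction": enr.background_fraction,
            "foreground_with_site": enr.foreground_with_site,
            "foreground_total": enr.foreground_total,
            "background_with_site": enr.background_with_site,
            "background_total": enr.background_total,
            "statistic": enr.statistic,
            "p_value": enr.p_value,
        }
        (outdir / "enrichment.json").write_text(json.dumps(summary, indent=1))
    return {"summary": summary, "hit_peaks": hit_peaks, "site_table": site_table}


def stage_enhancers(cfg: PipelineConfig, outdir: Path, annotated, labels, hit_peaks) -> dict:
    tracks = read_tracks(cfg.tracks_manifest) if cfg.tracks_manifest else []
    consensus = pd.read_csv(
        outdir / "consensus_peaks.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score"],
    )
    evidence = enhancers.overlap_evidence(consensus, tracks)
    gene_labels_series = labels.set_index("gene")["label"]
    ranked = enhancers.score_and_rank(
        annotated, evidence, gene_labels_series, hit_peaks, cfg.criteria_weights or None
    )
    ranked.to_csv(outdir / "candidate_enhancers.tsv", sep="\t", index=False)
    return {
        "ranked": ranked,
        "evidence": evidence,
        "summary": {
            "n_candidates": int(len(ranked)),
            "top_score": int(ranked["score"].iloc[0]) if len(ranked) else None,
        },
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the summary report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": {
        "alpha": cfg.alpha, "min_fc": cfg.min_fc,
        "attachment_expr_threshold": cfg.attachment_expr_threshold,
        "min_peak_length": cfg.min_peak_length,
        "vote_threshold": cfg.vote_threshold, "min_fraction": cfg.min_fraction,
        "avg_threshold": cfg.avg_threshold,
        "max_link_distance": cfg.max_link_distance, "seed": cfg.seed,
    }}
    stage = "expression"
    try:
        log.info("stage: expression")
        expr = stage_expression(cfg, outdir)
        summary["expression"] = expr["summary"]

        stage = "peaks"
        log.info("stage: peaks")
        pk = stage_peaks(cfg, outdir)
        summary["peaks"] = pk["summary"]

        stage = "sharing"
        log.info("stage: sharing")
        labels = expr["labels"]
        de = labels.attrs["de_table"]
        de_genes = de.loc[de["significant"], "gene"].tolist()
        sh = stage_sharing(cfg, outdir, pk["result"], de_genes)
        summary["sharing"] = sh["summary"]

        stage = "motifs"
        log.info("stage: motifs")
        mo = stage_motifs(cfg, outdir, sh["annotated"], pk["mapping"], labels)
        summary["motif_enrichment"] = mo["summary"]

        stage = "enhancers"
        log.info("stage: enhancers")
        en = stage_enhancers(cfg, outdir, sh["annotated"], labels, mo["hit_peaks"])
        summary["enhancers"] = en["summary"]
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
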