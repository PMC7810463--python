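"""Synthetic five-compartment expression + three-tissue ATAC data with ground truth.

The generator emulates the statistical structure of a tendon-to-bone
attachment-site study so every downstream stage is testable without external
data:

* a gene table on a small multi-chromosome genome, genes laid out on a
  regular tile grid so planted peaks never collide;
* a negative-binomial bulk count matrix over the five compartments
  (remote/adjacent tenocyte, attachment, adjacent/remote chondrocyte) with
  planted tenogenic, chondrogenic, attachment-up and attachment-down effects
  — tenogenic genes are high in tenocytes and intermediate in attachment
  (the transitional-tissue gradient), mirrored for chondrogenic;
* per-replicate ATAC peak BEDs and a peak x sample count matrix with planted
  sharing classes: all-shared promoter peaks (TAC), pairwise-shared distal
  peaks congruent with the linked gene's class (TA for tenogenic, AC for
  chondrogenic, A-only for attachment-up, TC for attachment-down), and
  unlinked background peaks with random classes;
* evidence tracks (enhancer/promoter marks, conservation, interaction
  anchors) covering planted elements, a blacklist, and peak sequences with a
  CACCC-box-like consensus planted more often in attachment-linked peaks.

Default sizes mirror the study's headline proportions: out of 2000 genes,
320 tenogenic-mixed, 54 chondrogenic-mixed, 23 attachment-up, 24
attachment-down, plus 361 cell-type-specific differential genes silent in
attachment (so the full differential set is ~735 genes of which 374 are
attachment-expressed); motif planting probability 0.72 in attachment-linked
peaks against a background rate of 0.53.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .enhancers import EvidenceTrack
from .expression import COMPARTMENTS, ExpressionMatrix
from .motifs import Motif, validate_iupac
from .peaks import TISSUES, DEFAULT_VOTE_THRESHOLD

DEFAULT_CLASS_FRACTIONS = {
    "tenogenic_mixed": 320 / 2000,
    "chondrogenic_mixed": 54 / 2000,
    "attachment_up": 23 / 2000,
    "attachment_down": 24 / 2000,
    # differential between the two cell types but NOT expressed in attachment;
    # together with the mixed classes this reproduces the ~735 two-cluster DE
    # genes of which 374 are attachment-expressed
    "tenogenic_nonmixed": 180 / 2000,
    "chondrogenic_nonmixed": 181 / 2000,
}

# downstream label the classifier is expected to assign to each planted class
EXPECTED_DOWNSTREAM_LABEL = {
    "tenogenic_mixed": "tenogenic_mixed",
    "chondrogenic_mixed": "chondrogenic_mixed",
    "attachment_up": "attachment_up",
    "attachment_down": "attachment_down",
    "tenogenic_nonmixed": "unclassified",
    "chondrogenic_nonmixed": "unclassified",
    "unclassified": "unclassified",
}

# sharing class planted on the distal peak of each labelled gene
_DISTAL_CLASS = {
    "tenogenic_mixed": "TA",
    "chondrogenic_mixed": "AC",
    "attachment_up": "A",
    "attachment_down": "TC",
    "tenogenic_nonmixed": "T",
    "chondrogenic_nonmixed": "C",
}

_LETTER_TISSUE = {"T": "tenocyte", "A": "attachment", "C": "chondrocyte"}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 2000
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    n_replicates_expr: int = 5
    n_replicates_atac: int = 3
    nb_dispersion: float = 0.1
    baseline_mean: float = 100.0
    planted_log2fc: float = 2.0
    peak_width_range: tuple = (200, 400)
    background_peak_count: int = 500
    motif_consensus: str = "CACCCAC"
    motif_enrichment_ratio: float = 0.72 / 0.53
    motif_p_fg: float = 0.72
    # ATAC accessibility model: open peaks at atac_open_mean, closed peaks at
    # one third of the voting threshold so voting fails with high probability
    atac_open_mean: float = 120.0
    atac_closed_mean: float = DEFAULT_VOTE_THRESHOLD / 3.0
    atac_dispersion: float = 0.15
    evidence_p_enhancer: float = 0.95
    evidence_p_conservation: float = 0.8
    evidence_p_interaction: float = 0.5
    evidence_p_promoter_mark: float = 0.9
    blacklist_fraction: float = 0.05  # fraction of background peaks blacklisted

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_chroms <= 0 or self.chrom_length <= 0:
            raise ValueError("n_genes must be >= 0, n_chroms and chrom_length positive")
        if self.nb_dispersion < 0 or self.atac_dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.planted_log2fc < 0:
            raise ValueError("planted_log2fc must be non-negative")
        if sum(self.class_fractions.values()) > 1 + 1e-9:
            raise ValueError("class_fractions must sum to <= 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class fractions must be non-negative")
        if self.motif_enrichment_ratio < 1:
            raise ValueError("motif_enrichment_ratio must be >= 1")
        if not (0 < self.motif_p_fg <= 1):
            raise ValueError("motif_p_fg must be in (0, 1]")
        lo, hi = self.peak_width_range
        if lo <= 0 or hi < lo or hi > self.chrom_length:
            raise ValueError("invalid peak_width_range")
        validate_iupac(self.motif_consensus)


@dataclass
class GroundTruth:
    gene_labels: dict
    peak_sharing: dict
    peak_gene_link: dict  # distal/promoter peak -> gene id ('' for background)
    motif_bearing_peaks: set = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "gene_labels": self.gene_labels,
            "peak_sharing": self.peak_sharing,
            "peak_gene_link": self.peak_gene_link,
            "motif_bearing_peaks": sorted(self.motif_bearing_peaks),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_labels=d["gene_labels"],
            peak_sharing=d["peak_sharing"],
            peak_gene_link=d["peak_gene_link"],
            motif_bearing_peaks=set(d["motif_bearing_peaks"]),
        )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_genome(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Gene table (chrom, tss, strand, gene) on a tile grid, plus chrom sizes.

    Genes are distributed evenly across chromosomes; each gene owns one tile
    and its TSS sits ~30% into it with a small jitter, which guarantees
    neighbouring genes' planted peaks cannot merge.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    if config.n_genes == 0:
        return pd.DataFrame(columns=["chrom", "tss", "strand", "gene"]), chrom_sizes
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    rows = []
    gid = 0
    for ci, chrom in enumerate(chrom_sizes):
        n = per_chrom[ci]
        if n == 0:
            continue
        tile = config.chrom_length // n
        for t in range(n):
            jitter = int(rng.integers(0, max(1, tile // 20)))
            tss = t * tile + int(0.3 * tile) + jitter
            tss = min(tss, config.chrom_length - 1)
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, tss, strand, f"g{gid:05d}"))
            gid += 1
    return pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene"]), chrom_sizes


def assign_gene_labels(config: SimulationConfig, gene_table: pd.DataFrame) -> dict:
    """Deterministic label assignment honouring class_fractions (rounded down)."""
    rng = np.random.default_rng(config.seed + 1)
    genes = gene_table["gene"].tolist()
    order = rng.permutation(len(genes))
    labels = {g: "unclassified" for g in genes}
    pos = 0
    for label, frac in config.class_fractions.items():
        n = int(round(frac * len(genes)))
        for idx in order[pos : pos + n]:
            labels[genes[idx]] = label
        pos += n
    return labels


_EXPR_PROFILE = {
    # per class: multiplier exponents (units of planted_log2fc) per compartment group
    # (tenocyte compartments, attachment, chondrocyte compartments); attachment
    # sits halfway up for mixed genes (the transitional gradient) and well below
    # the expression-call threshold for non-mixed differential genes
    "tenogenic_mixed": (1.0, 0.5, 0.0),
    "chondrogenic_mixed": (0.0, 0.5, 1.0),
    "attachment_up": (0.0, 1.0, 0.0),
    "attachment_down": (0.0, -1.0, 0.0),
    # non-mixed cell-type markers are silent both in attachment and in the
    # opposite cell type, so attachment is not "down vs both"
    "tenogenic_nonmixed": (1.0, -2.0, -2.0),
    "chondrogenic_nonmixed": (-2.0, -2.0, 1.0),
    "unclassified": (0.0, 0.0, 0.0),
}


def simulate_expression(config: SimulationConfig, gene_labels: dict) -> ExpressionMatrix:
    """Negative-binomial counts over 5 compartments x replicates.

    Tenogenic genes: baseline x 2^planted_log2fc in both tenocyte
    compartments and x 2^(planted_log2fc/2) in attachment (a gradient);
    chondrogenic mirrored; attachment-up/down shifted only in attachment;
    unclassified flat. Per-sample library size factors in [0.7, 1.4] are
    applied on top.
    """
    config.validate()
    unknown = set(gene_labels.values()) - set(_EXPR_PROFILE)
    if unknown:
        raise ValueError(f"unknown gene labels: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed + 2)
    genes = list(gene_labels)
    samples, compart = [], []
    for comp in COMPARTMENTS:
        for rep in range(1, config.n_replicates_expr + 1):
            samples.append(f"{comp}_rep{rep}")
            compart.append(comp)
    group_of = {
        "remote_tenocyte": 0, "adjacent_tenocyte": 0, "attachment": 1,
        "adjacent_chondrocyte": 2, "remote_chondrocyte": 2,
    }
    exponents = np.array([_EXPR_PROFILE[gene_labels[g]] for g in genes])
    col_group = np.array([group_of[c] for c in compart])
    means = config.baseline_mean * 2.0 ** (
        config.planted_log2fc * exponents[:, col_group]
    )
    size_factors = rng.uniform(0.7, 1.4, size=len(samples))
    counts = _nb_counts(rng, means * size_factors[None, :], config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    meta = pd.DataFrame(
        {"sample": samples, "compartment": compart,
         "replicate": [int(s.rsplit("rep", 1)[1]) for s in samples]}
    )
    return ExpressionMatrix(counts=counts_df, sample_meta=meta)


def _background_classes(rng: np.random.Generator, n: int) -> list[str]:
    # background (unlinked) peaks take any non-empty sharing class; singles and
    # the tenocyte/chondrocyte pair are the most common in real data
    classes = ["T", "A", "C", "TA", "TC", "AC", "TAC"]
    probs = np.array([0.22, 0.08, 0.22, 0.08, 0.2, 0.08, 0.12])
    return [classes[i] for i in rng.choice(len(classes), size=n, p=probs / probs.sum())]


@dataclass
class AtacDataset:
    peak_coords: pd.DataFrame  # chrom, start, end, name (source peaks)
    counts: pd.DataFrame  # source peak x sample raw counts
    tissue_map: pd.Series  # sample -> tissue
    replicate_beds: dict  # "{tissue}_rep{i}" -> DataFrame
    ground_truth: GroundTruth
    blacklist: pd.DataFrame
    evidence_tracks: list


def simulate_atac(
    config: SimulationConfig, gene_labels: dict, gene_table: pd.DataFrame
) -> AtacDataset:
    """Planted peak sets, replicate BEDs and a raw count matrix.

    One promoter peak per gene (all-shared, spanning the TSS), one distal
    peak per labelled gene 5-8 kb downstream of the TSS carrying the class's
    sharing pattern, and unlinked background peaks placed in unclassified
    genes' tiles, well away from any planted peak. A peak appears in a
    replicate BED iff its tissue is open in the planted class; counts are NB
    around open/closed means with per-sample library factors.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    wlo, whi = config.peak_width_range
    if whi >= config.chrom_length:
        raise ValueError("peak widths exceed chromosome length")
    gt_link, gt_share = {}, {}
    rows = []

    def width() -> int:
        return int(rng.integers(wlo, whi + 1))

    for _, g in gene_table.iterrows():
        w = width()
        start = max(0, int(g["tss"]) - w // 2)
        name = f"prom_{g['gene']}"
        rows.append((g["chrom"], start, start + w, name))
        gt_link[name] = g["gene"]
        gt_share[name] = "TAC"
        label = gene_labels[g["gene"]]
        if label != "unclassified":
            w = width()
            start = int(g["tss"]) + int(rng.integers(5000, 8001))
            start = min(start, config.chrom_length - w)
            name = f"dist_{g['gene']}"
            rows.append((g["chrom"], start, start + w, name))
            gt_link[name] = g["gene"]
            gt_share[name] = _DISTAL_CLASS[label]

    unclass = gene_table[[gene_labels[g] == "unclassified" for g in gene_table["gene"]]]
    n_bg = min(config.background_peak_count, len(unclass))
    bg_tiles = unclass.iloc[
        rng.choice(len(unclass), size=n_bg, replace=False)
    ] if n_bg else unclass.iloc[:0]
    bg_classes = _background_classes(rng, n_bg)
    for i, ((_, g), cls) in enumerate(zip(bg_tiles.iterrows(), bg_classes)):
        w = width()
        start = int(g["tss"]) + int(rng.integers(12000, 15001))
        start = min(start, config.chrom_length - w)
        name = f"bg_{i:04d}"
        rows.append((g["chrom"], start, start + w, name))
        gt_link[name] = ""
        gt_share[name] = cls

    peak_coords = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    peak_coords = peak_coords.set_index("name", drop=False)
    peak_coords.index.name = None

    samples, tissues = [], []
    for tissue in TISSUES:
        for rep in range(1, config.n_replicates_atac + 1):
            samples.append(f"{tissue}_rep{rep}")
            tissues.append(tissue)
    tissue_map = pd.Series(tissues, index=samples)

    open_mask = np.array(
        [
            [t in {_LETTER_TISSUE[l] for l in gt_share[name]} for t in tissues]
            for name in peak_coords["name"]
        ]
    )
    means = np.where(open_mask, config.atac_open_mean, config.atac_closed_mean)
    size_factors = rng.uniform(0.7, 1.4, size=len(samples))
    counts = _nb_counts(rng, means * size_factors[None, :], config.atac_dispersion)
    counts_df = pd.DataFrame(counts, index=peak_coords["name"], columns=samples)
    counts_df.index.name = "peak"

    replicate_beds = {}
    for s, t in zip(samples, tissues):
        open_here = [
            name for name in peak_coords["name"]
            if t in {_LETTER_TISSUE[l] for l in gt_share[name]}
        ]
        replicate_beds[s] = peak_coords.loc[open_here, ["chrom", "start", "end", "name"]].reset_index(drop=True)

    # blacklist: intervals over a deterministic subset of background peaks,
    # plus a few intervals in empty space
    n_black = int(round(config.blacklist_fraction * n_bg))
    black_rows = []
    bg_names = [f"bg_{i:04d}" for i in range(n_bg)]
    for name in bg_names[:n_black]:
        r = peak_coords.loc[name]
        black_rows.append((r["chrom"], max(0, int(r["start"]) - 50), int(r["end"]) + 50))
    blacklist = pd.DataFrame(black_rows, columns=["chrom", "start", "end"])

    evidence_tracks = _plant_evidence(config, rng, peak_coords, gt_link, gt_share, gene_labels)

    gt = GroundTruth(gene_labels=dict(gene_labels), peak_sharing=gt_share,
                     peak_gene_link=gt_link)
    return AtacDataset(
        peak_coords=peak_coords.reset_index(drop=True),
        counts=counts_df,
        tissue_map=tissue_map,
        replicate_beds=replicate_beds,
        ground_truth=gt,
        blacklist=blacklist,
        evidence_tracks=evidence_tracks,
    )


def _plant_evidence(config, rng, peak_coords, gt_link, gt_share, gene_labels):
    """Evidence tracks covering planted elements with the configured probabilities."""
    enh, cons, inter, promk = [], [], [], []
    coords = peak_coords.set_index("name") if "name" in peak_coords.columns else peak_coords
    for name in coords.index:
        r = coords.loc[name]
        iv = (r["chrom"], max(0, int(r["start"]) - 20), int(r["end"]) + 20)
        if name.startswith("dist_"):
            if rng.random() < config.evidence_p_enhancer:
                enh.append(iv)
            if rng.random() < config.evidence_p_conservation:
                cons.append((r["chrom"], int(r["start"]) + 10, int(r["start"]) + 60))
            if rng.random() < config.evidence_p_interaction:
                inter.append(iv)
        elif name.startswith("prom_"):
            if rng.random() < config.evidence_p_promoter_mark:
                promk.append(iv)
    def track(name, role, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return EvidenceTrack(name=name, role=role, intervals=df)
    return [
        track("H3K27ac_like", "enhancer_mark", enh),
        track("H3K4me3_like", "promoter_mark", promk),
        track("phastCons_like", "conservation", cons),
        track("hic_anchors", "interaction", inter),
    ]


_BASES = np.array(list("ACGT"))


def plant_motifs(
    peak_coords: pd.DataFrame,
    ground_truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[dict, Motif]:
    """Random peak sequences with the consensus planted in a biased subset.

    Attachment-linked peaks (linked gene in the mixed or attachment-up sets)
    receive >= 1 planted occurrence with probability ``motif_p_fg``; every
    other peak with probability ``motif_p_fg / motif_enrichment_ratio``.
    Planted peak ids are recorded in ``ground_truth.motif_bearing_peaks``.
    Chance occurrences in the random background sequence are possible, as in
    real data. Returns (peak id -> sequence, motif).
    """
    config.validate()
    motif = Motif(id="klf_like", consensus=config.motif_consensus)
    rng = np.random.default_rng(config.seed + 4)
    p_bg = config.motif_p_fg / config.motif_enrichment_ratio
    fg_labels = {"tenogenic_mixed", "chondrogenic_mixed", "attachment_up"}
    sequences = {}
    # IUPAC consensus realised as a concrete instance per planting
    choices = [list(set(c for c in _iupac_class(ch))) for ch in config.motif_consensus]
    coords = peak_coords.set_index("name") if "name" in peak_coords.columns else peak_coords
    for name in coords.index:
        r = coords.loc[name]
        length = int(r["end"]) - int(r["start"])
        seq = "".join(rng.choice(_BASES, size=length))
        gene = ground_truth.peak_gene_link.get(name, "")
        label = ground_truth.gene_labels.get(gene, "unclassified") if gene else "unclassified"
        p = config.motif_p_fg if label in fg_labels else p_bg
        if length >= len(config.motif_consensus) and rng.random() < p:
            instance = "".join(rng.choice(c) for c in choices)
            off = int(rng.integers(0, length - len(instance) + 1))
            seq = seq[:off] + instance + seq[off + len(instance):]
            ground_truth.motif_bearing_peaks.add(name)
        sequences[name] = seq
    return sequences, motif


def _iupac_class(ch: str) -> str:
    from .motifs import IUPAC

    return IUPAC[ch.upper()]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    gene_table: pd.DataFrame
    chrom_sizes: dict
    expression: ExpressionMatrix
    atac: AtacDataset
    sequences: dict
    motif: Motif

    @property
    def ground_truth(self) -> GroundTruth:
        return self.atac.ground_truth


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """End-to-end generation of one coherent dataset from a single seed."""
    config = config or SimulationConfig()
    gene_table, chrom_sizes = simulate_genome(config)
    labels = assign_gene_labels(config, gene_table)
    expression = simulate_expression(config, labels)
    atac = simulate_atac(config, labels, gene_table)
    sequences, motif = plant_motifs(atac.peak_coords, atac.ground_truth, config)
    return SyntheticDataset(
        config=config, gene_table=gene_table, chrom_sizes=chrom_sizes,
        expression=expression, atac=atac, sequences=sequences, motif=motif,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write the dataset as plain-text files; returns the path manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["genes"] = out / "genes.tsv"
    ds.gene_table.to_csv(paths["genes"], sep="\t", index=False)
    paths["chrom_sizes"] = out / "chrom_sizes.tsv"
    pd.Series(ds.chrom_sizes, name="size").rename_axis("chrom").to_csv(
        paths["chrom_sizes"], sep="\t"
    )
    paths["expr_counts"] = out / "expression_counts.tsv"
    ds.expression.counts.to_csv(paths["expr_counts"], sep="\t")
    paths["expr_meta"] = out / "expression_samples.tsv"
    ds.expression.sample_meta.to_csv(paths["expr_meta"], sep="\t", index=False)

    for name, bed in ds.atac.replicate_beds.items():
        p = out / f"{name}.bed"
        bed.to_csv(p, sep="\t", header=False, index=False)
        paths[f"bed:{name}"] = p
    paths["atac_counts"] = out / "atac_counts.tsv"
    ds.atac.counts.to_csv(paths["atac_counts"], sep="\t")
    paths["atac_tissues"] = out / "atac_samples.tsv"
    ds.atac.tissue_map.rename("tissue").rename_axis("sample").to_csv(
        paths["atac_tissues"], sep="\t"
    )
    paths["peak_coords"] = out / "source_peaks.bed"
    ds.atac.peak_coords[["chrom", "start", "end", "name"]].to_csv(
        paths["peak_coords"], sep="\t", header=False, index=False
    )
    paths["blacklist"] = out / "blacklist.bed"
    ds.atac.blacklist.to_csv(paths["blacklist"], sep="\t", header=False, index=False)

    manifest_rows = []
    for tr in ds.atac.evidence_tracks:
        p = out / f"track_{tr.name}.bed"
        tr.intervals.to_csv(p, sep="\t", header=False, index=False)
        manifest_rows.append({"name": tr.name, "role": tr.role, "path": p.name})
        paths[f"track:{tr.name}"] = p
    paths["tracks_manifest"] = out / "tracks_manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(paths["tracks_manifest"], sep="\t", index=False)

    paths["sequences"] = out / "peak_sequences.fasta"
    with open(paths["sequences"], "w") as fh:
        for name, seq in ds.sequences.items():
            fh.write(f">{name}\n{seq}\n")
    paths["motifs"] = out / "motifs.tsv"
    pd.DataFrame(
        [{"id": ds.motif.id, "type": "consensus",
          "definition": ds.motif.consensus, "threshold": ds.motif.score_threshold}]
    ).to_csv(paths["motifs"], sep="\t", index=False)

    paths["ground_truth"] = out / "ground_truth.json"
    ds.ground_truth.to_json(paths["ground_truth"])
    return {k: str(v) for k, v in paths.items()}
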