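# bifate

Integrative transcriptome + chromatin-accessibility analysis of **bi-fated
tendon-to-bone attachment cells**.

Tendon attaches to bone through a transitional tissue (the enthesis) whose
cells simultaneously express parts of the tenocyte (tendon fibroblast) and
chondrocyte (cartilage) transcriptional programs. `bifate` implements, as a
tested and reusable pipeline, the computational analysis that supports this
picture from bulk RNA-seq and ATAC-seq data:

1. **Mixed-transcriptome classifier** (`bifate.expression`) — median-of-ratios
   normalization of a five-compartment count matrix (remote/adjacent tenocyte,
   attachment, adjacent/remote chondrocyte), differential expression between
   the tenocyte and chondrocyte compartments (Welch test on log2(norm+1),
   Benjamini–Hochberg adjustment, selection rule *p*adj ≤ 0.05 and fold
   change ≥ 2), and per-gene labels: `tenogenic_mixed` / `chondrogenic_mixed`
   (differential *and* expressed in attachment cells), `attachment_up` /
   `attachment_down` (shifted in attachment vs both neighbours), else
   `unclassified`. Also reports correlation distance and PCA positioning of
   the attachment samples between the two cell types.
2. **Consensus ATAC peak pipeline** (`bifate.peaks`) — per-replicate peak
   BEDs are combined, merged (book-ended intervals fuse), extended to a
   minimum length of 500 bp, counts are normalized with the same
   median-of-ratios estimator, and a peak is called accessible in a tissue
   by **replicate voting**: normalized count ≥ 30 in at least 50% of that
   tissue's replicates. Peaks reproducible in no tissue, blacklisted peaks,
   and peaks below an average normalized count of 30 in every tissue are
   removed, in that order.
3. **Sharing classifier** (`bifate.sharing`) — each retained peak gets a
   sharing class, the non-empty subset of {T, A, C} where it is accessible
   (7 Venn cells), a promoter/distal call against the strand-aware window
   [TSS − 2 kb, TSS + 0.5 kb], links to its two nearest genes (≤ 1 Mb), and
   the 2×2 promoter-vs-distal × shared-vs-differential chi-square (with
   optional Yates correction).
4. **Enhancer prioritizer** (`bifate.enhancers`) — distal peaks whose sharing
   class is *congruent* with their linked gene (chondrogenic gene + AC peak,
   tenogenic gene + TA peak) are scored against evidence tracks (enhancer /
   promoter histone marks, conservation, chromatin interaction anchors,
   motif sites) and ranked.
5. **Motif enrichment** (`bifate.motifs`) — IUPAC-consensus and PWM scanning
   on both strands, per-gene site tables over linked peaks, and chi-square
   enrichment of a foreground gene set (e.g. the mixed set) against the gene
   universe, as used for KLF/CACCC-box sites.

Everything is exercisable without external data through the bundled
synthetic-data generator (`bifate.synthetic`), which plants known gene
classes, peak sharing classes, evidence tracks and motif occurrences, and
ships the ground truth alongside the files.

## Worked example

```python
from bifate.synthetic import SimulationConfig, simulate_dataset, write_dataset
from bifate.pipeline import PipelineConfig, run_pipeline

ds = simulate_dataset(SimulationConfig(seed=1))
paths = write_dataset(ds, "data")
cfg = PipelineConfig(
    genes=paths["genes"], chrom_sizes=paths["chrom_sizes"],
    expr_counts=paths["expr_counts"], expr_meta=paths["expr_meta"],
    replicate_beds=[v for k, v in paths.items() if k.startswith("bed:")],
    atac_counts=paths["atac_counts"], atac_tissues=paths["atac_tissues"],
    peak_coords=paths["peak_coords"], blacklist=paths["blacklist"],
    tracks_manifest=paths["tracks_manifest"], sequences=paths["sequences"],
    motifs_table=paths["motifs"], outdir="out", seed=1,
)
summary = run_pipeline(cfg)
print(summary["expression"]["mixed_set_size"],
      summary["expression"]["similarity"]["closer_to"],
      summary["sharing"]["by_location"]["promoter"]["shared_pct"])
```

prints

```
383 tenocyte 100
```

meaning: of the 2000 simulated genes, 383 are called mixed-transcriptome
(the generator planted 374 — 320 tenogenic and 54 chondrogenic — so the call
includes a small number of borderline false positives); the attachment
expression profile is closer to tenocytes, as expected under the 320:54
planted imbalance; and 100% of promoter peaks are accessible in all three
cell types (the generator plants every promoter as all-shared, while distal
elements carry the differential accessibility). The same run is available
from the shell:

```bash
bifate simulate --outdir data --seed 1
bifate run --config pipeline.yaml
```

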