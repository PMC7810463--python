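"""Bulk expression analysis for the five-compartment attachment-site design.

The samples come from five micro-dissected compartments spanning the
tendon-to-bone attachment unit: remote tenocytes, adjacent tenocytes,
attachment cells, adjacent chondrocytes and remote chondrocytes. The
analysis normalizes counts by median-of-ratios size factors, calls
differential expression between the tenocyte and chondrocyte compartments,
and classifies genes into:

* ``tenogenic_mixed`` / ``chondrogenic_mixed`` — differential between
  tenocytes and chondrocytes AND expressed by attachment cells (the
  "mixed transcriptome" set);
* ``attachment_up`` / ``attachment_down`` — shifted in attachment cells
  relative to BOTH flanking cell types;
* ``unclassified`` — everything else.

The differential test is a Welch two-sample t-test on log2(normalized + 1);
the selection rule (BH-adjusted p <= alpha and fold change >= min_fc) is what
defines the sets, and the test statistic is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

COMPARTMENTS = [
    "remote_tenocyte",
    "adjacent_tenocyte",
    "attachment",
    "adjacent_chondrocyte",
    "remote_chondrocyte",
]
TENOCYTE_COMPARTMENTS = ["remote_tenocyte", "adjacent_tenocyte"]
CHONDROCYTE_COMPARTMENTS = ["remote_chondrocyte", "adjacent_chondrocyte"]

GENE_CLASSES = [
    "tenogenic_mixed",
    "chondrogenic_mixed",
    "attachment_up",
    "attachment_down",
    "unclassified",
]


@dataclass
class ExpressionMatrix:
    """Integer count matrix (genes x samples) with per-sample compartment labels."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame  # columns: sample, compartment, replicate

    def __post_init__(self):
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        missing = set(self.counts.columns) - set(self.sample_meta["sample"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def samples_of(self, compartments: list[str]) -> list[str]:
        sel = self.sample_meta[self.sample_meta["compartment"].isin(compartments)]
        return [s for s in self.counts.columns if s in set(sel["sample"])]


def normalize_median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """DESeq2-style size factors: median ratio to the geometric-mean reference.

    Only genes with strictly positive counts in every sample contribute to the
    reference. Returns ``(size_factors, normalized)`` with
    ``normalized = counts / size_factor``.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalize")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in all samples; "
            "median-of-ratios reference is undefined (pseudo-reference fallback is off)"
        )
    ref = counts.loc[positive]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geo_mean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    return size_factors, counts.div(size_factors, axis=1)


def _welch_log2(a: np.ndarray, b: np.ndarray) -> float:
    """Welch t-test p-value on log2(x+1); zero-variance rows get p=1."""
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
        return 1.0
    p = stats.ttest_ind(la, lb, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(pvalues, method="fdr_bh")[1]


def differential_expression(
    normalized: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    min_fc: float = 2.0,
    contrast: str = "A_vs_B",
    test=_welch_log2,
) -> pd.DataFrame:
    """Per-gene DE table for group A vs group B on normalized counts.

    log2 fold change is computed on group means with pseudocount 1
    (positive = higher in group A). ``significant`` requires BH-adjusted
    p <= alpha AND |log2FC| >= log2(min_fc). Rows are ordered by gene id
    for determinism.
    """
    for name, grp in (("A", group_a), ("B", group_b)):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 replicates, got {len(grp)}")
        absent = set(grp) - set(normalized.columns)
        if absent:
            raise ValueError(f"group {name} samples missing from matrix: {sorted(absent)}")
    sub_a = normalized[group_a].to_numpy()
    sub_b = normalized[group_b].to_numpy()
    pvals = np.array([test(sub_a[i], sub_b[i]) for i in range(len(normalized))])
    mean_a = sub_a.mean(axis=1)
    mean_b = sub_b.mean(axis=1)
    log2fc = np.log2(mean_a + 1.0) - np.log2(mean_b + 1.0)
    res = pd.DataFrame(
        {
            "gene": normalized.index,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "contrast": contrast,
        }
    ).sort_values("gene", kind="stable").reset_index(drop=True)
    res["p_adjusted"] = benjamini_hochberg(res["p_value"].to_numpy())
    res["significant"] = (res["p_adjusted"] <= alpha) & (
        res["log2_fold_change"].abs() >= np.log2(min_fc)
    )
    return res[
        ["gene", "log2_fold_change", "p_value", "p_adjusted", "significant", "contrast"]
    ]


def classify_mixed_genes(
    de_t_vs_c: pd.DataFrame,
    normalized: pd.DataFrame,
    matrix: ExpressionMatrix,
    attachment_expr_threshold: float = 10.0,
) -> pd.Series:
    """Mixed-transcriptome labels from the tenocyte-vs-chondrocyte contrast.

    tenogenic_mixed: significant with tenocyte-high fold change and mean
    normalized attachment expression >= threshold; chondrogenic_mixed is the
    mirror image. Everything else is unclassified at this stage.
    """
    if attachment_expr_threshold < 0:
        raise ValueError("attachment expression threshold must be >= 0")
    att_samples = matrix.samples_of(["attachment"])
    att_mean = normalized[att_samples].mean(axis=1)
    labels = pd.Series("unclassified", index=normalized.index, name="label")
    de = de_t_vs_c.set_index("gene")
    expressed = att_mean.reindex(de.index) >= attachment_expr_threshold
    teno = de["significant"] & (de["log2_fold_change"] > 0) & expressed
    chondro = de["significant"] & (de["log2_fold_change"] < 0) & expressed
    labels.loc[teno[teno].index] = "tenogenic_mixed"
    labels.loc[chondro[chondro].index] = "chondrogenic_mixed"
    return labels


def detect_attachment_unique(
    normalized: pd.DataFrame,
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    min_fc: float = 2.0,
) -> tuple[set, set]:
    """Genes shifted in attachment cells vs BOTH tenocytes and chondrocytes.

    attachment_up requires significance with positive fold change in the
    attachment-vs-tenocyte AND attachment-vs-chondrocyte contrasts;
    attachment_down is mirrored.
    """
    att = matrix.samples_of(["attachment"])
    teno = matrix.samples_of(TENOCYTE_COMPARTMENTS)
    chon = matrix.samples_of(CHONDROCYTE_COMPARTMENTS)
    de_t = differential_expression(normalized, att, teno, alpha, min_fc, "att_vs_teno")
    de_c = differential_expression(normalized, att, chon, alpha, min_fc, "att_vs_chondro")
    de_t = de_t.set_index("gene")
    de_c = de_c.set_index("gene")
    up = set(
        de_t.index[
            de_t["significant"] & (de_t["log2_fold_change"] > 0)
            & de_c["significant"] & (de_c["log2_fold_change"] > 0)
        ]
    )
    down = set(
        de_t.index[
            de_t["significant"] & (de_t["log2_fold_change"] < 0)
            & de_c["significant"] & (de_c["log2_fold_change"] < 0)
        ]
    )
    return up, down


def classify_genes(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    min_fc: float = 2.0,
    attachment_expr_threshold: float = 10.0,
) -> pd.DataFrame:
    """Full gene classification: one label per gene plus the DE table.

    Attachment-unique labels take precedence over mixed labels so the
    partition is exclusive (a gene up in attachment vs both cell types is
    reported as attachment-specific, not mixed).
    """
    _, normalized = normalize_median_of_ratios(matrix.counts)
    teno = matrix.samples_of(TENOCYTE_COMPARTMENTS)
    chon = matrix.samples_of(CHONDROCYTE_COMPARTMENTS)
    de = differential_expression(
        normalized, teno, chon, alpha, min_fc, "teno_vs_chondro"
    )
    labels = classify_mixed_genes(de, normalized, matrix, attachment_expr_threshold)
    up, down = detect_attachment_unique(normalized, matrix, alpha, min_fc)
    labels.loc[labels.index.isin(up)] = "attachment_up"
    labels.loc[labels.index.isin(down)] = "attachment_down"
    out = pd.DataFrame({"gene": labels.index, "label": labels.to_numpy()})
    out.attrs["de_table"] = de
    out.attrs["normalized"] = normalized
    return out


def class_size_summary(labels: pd.Series) -> dict:
    """Per-class gene counts plus the mixed-transcriptome set size.

    The mixed set is the union of the tenogenic and chondrogenic mixed
    classes (differential between the two cell types AND expressed in
    attachment cells).
    """
    sizes = labels.value_counts().to_dict()
    out = {c: int(sizes.get(c, 0)) for c in GENE_CLASSES}
    out["mixed_set_size"] = out["tenogenic_mixed"] + out["chondrogenic_mixed"]
    return out


@dataclass
class SimilarityReport:
    distance_to_tenocyte: float
    distance_to_chondrocyte: float
    closer_to: str
    pca_coordinates: pd.DataFrame = field(repr=False)


def compartment_similarity(
    normalized: pd.DataFrame, matrix: ExpressionMatrix, gene_set: list[str]
) -> SimilarityReport:
    """Position attachment cells between the two flanking cell types.

    Correlation distance (1 - Pearson r) between mean log2 profiles over
    ``gene_set``; PCA on the full log2-normalized matrix gives per-sample
    coordinates (samples as observations).
    """
    genes = [g for g in gene_set if g in normalized.index]
    if len(genes) < 3:
        raise ValueError("need >= 3 genes for similarity")
    log = np.log2(normalized + 1.0)
    prof = {
        "tenocyte": log.loc[genes, matrix.samples_of(TENOCYTE_COMPARTMENTS)].mean(axis=1),
        "chondrocyte": log.loc[genes, matrix.samples_of(CHONDROCYTE_COMPARTMENTS)].mean(axis=1),
        "attachment": log.loc[genes, matrix.samples_of(["attachment"])].mean(axis=1),
    }
    d_t = 1.0 - np.corrcoef(prof["attachment"], prof["tenocyte"])[0, 1]
    d_c = 1.0 - np.corrcoef(prof["attachment"], prof["chondrocyte"])[0, 1]
    pca = PCA(n_components=min(5, log.shape[1], log.shape[0]))
    coords = pca.fit_transform(log.T.to_numpy())
    coord_df = pd.DataFrame(
        coords,
        index=log.columns,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    coord_df["compartment"] = (
        matrix.sample_meta.set_index("sample")["compartment"].reindex(coord_df.index)
    )
    return SimilarityReport(
        distance_to_tenocyte=float(d_t),
        distance_to_chondrocyte=float(d_c),
        closer_to="tenocyte" if d_t <= d_c else "chondrocyte",
        pca_coordinates=coord_df,
    )
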