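"""Cross-tissue accessibility sharing classes and promoter/distal annotation.

Each retained peak's sharing class is the non-empty subset of
{tenocyte (T), attachment (A), chondrocyte (C)} in which it is accessible —
one of T, A, C, TA, TC, AC, TAC. Peaks are annotated as promoter when they
overlap the strand-aware window from 2 kb upstream to 0.5 kb downstream of a
linked gene's TSS, otherwise distal, and linked to their two nearest genes by
TSS distance. The contingency machinery contrasts promoter vs distal peaks on
shared (accessible in all three cell types) vs differential accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SHARING_CLASSES = ["T", "A", "C", "TA", "TC", "AC", "TAC"]
_TISSUE_LETTER = {"tenocyte": "T", "attachment": "A", "chondrocyte": "C"}
_LETTER_ORDER = "TAC"

PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500
DEFAULT_MAX_LINK_DISTANCE = 1_000_000


def venn_partition(flags: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Sharing class per peak plus the 7-cell count table.

    ``flags`` has tissue-named boolean columns. All-false rows are an error:
    they should have been removed by the voting filter.
    """
    flags = flags.astype(bool)
    letters = {c: _TISSUE_LETTER.get(c, c[0].upper()) for c in flags.columns}
    if (~flags).all(axis=1).any():
        raise ValueError("peak with all-false accessibility flags reached venn_partition")
    cols_by_letter = {letters[c]: c for c in flags.columns}
    classes = pd.Series(
        [
            "".join(l for l in _LETTER_ORDER if flags.at[idx, cols_by_letter[l]])
            for idx in flags.index
        ],
        index=flags.index,
        name="sharing_class",
    )
    counts = classes.value_counts().reindex(SHARING_CLASSES, fill_value=0)
    return classes, counts


def link_genes(
    peaks: pd.DataFrame,
    gene_table: pd.DataFrame,
    max_distance: int = DEFAULT_MAX_LINK_DISTANCE,
) -> pd.DataFrame:
    """Up to two nearest genes per peak by |peak midpoint - TSS|.

    Distances are signed and strand-aware: negative means the peak midpoint
    lies upstream of the TSS in the gene's transcription orientation. Ties in
    absolute distance break lexicographically by gene id. Rows: peak, gene1,
    dist1, gene2, dist2 (NaN-padded when fewer than two genes are in range).
    """
    rows = []
    genes_by_chrom = {
        c: g.sort_values(["tss", "gene"]).reset_index(drop=True)
        for c, g in gene_table.groupby("chrom")
    }
    for _, pk in peaks.iterrows():
        mid = (pk["start"] + pk["end"]) // 2
        g = genes_by_chrom.get(pk["chrom"])
        entry = {"peak": pk["name"], "gene1": None, "dist1": np.nan,
                 "gene2": None, "dist2": np.nan}
        if g is not None:
            absd = (g["tss"] - mid).abs()
            cand = g.assign(absd=absd)
            cand = cand[cand["absd"] <= max_distance]
            cand = cand.sort_values(["absd", "gene"], kind="stable").head(2)
            for slot, (_, row) in enumerate(cand.iterrows(), start=1):
                signed = mid - row["tss"]
                if row["strand"] == "-":
                    signed = -signed
                entry[f"gene{slot}"] = row["gene"]
                entry[f"dist{slot}"] = int(signed)
        rows.append(entry)
    return pd.DataFrame(rows)


def promoter_window(tss: int, strand: str) -> tuple[int, int]:
    """Genomic half-open interval of the strand-aware promoter window."""
    if strand == "+":
        return tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM + 1
    return tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM + 1


def annotate_location(
    peaks: pd.DataFrame, links: pd.DataFrame, gene_table: pd.DataFrame
) -> pd.Series:
    """promoter | distal per peak.

    Promoter iff the peak overlaps (>= 1 bp) the promoter window of ANY of
    its linked genes; the window covers positions TSS-2000..TSS+500 inclusive
    in transcription coordinates, reflected for minus-strand genes.
    """
    ginfo = gene_table.set_index("gene")
    out = []
    pk = peaks.set_index("name")
    for _, ln in links.iterrows():
        start, end = pk.at[ln["peak"], "start"], pk.at[ln["peak"], "end"]
        loc = "distal"
        for slot in ("gene1", "gene2"):
            gid = ln[slot]
            if gid is None or (isinstance(gid, float) and np.isnan(gid)):
                continue
            w0, w1 = promoter_window(int(ginfo.at[gid, "tss"]), ginfo.at[gid, "strand"])
            if start < w1 and end > w0:
                loc = "promoter"
                break
        out.append(loc)
    return pd.Series(out, index=links["peak"].to_numpy(), name="location")


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic: float
    p_value: float
    dof: int = 1
    yates_corrected: bool = False


def contingency_chi_square(table, yates: bool = False) -> ContingencyResult:
    """2x2 chi-square from the closed form sum((|O-E|-c)^2 / E), c = 0.5 if Yates.

    Expected counts come from the product of margins; any zero margin is an
    error (the statistic is undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(row, col) / obs.sum()
    c = 0.5 if yates else 0.0
    dev = np.abs(obs - expected) - c
    dev = np.clip(dev, 0.0, None)
    statistic = float((dev**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ContingencyResult(
        table=obs.astype(int), statistic=statistic, p_value=max(p, 0.0),
        yates_corrected=yates,
    )


def _pct(count: int, total: int) -> int:
    """Percentage rounded half-up to the nearest integer."""
    if total == 0:
        return 0
    return int(np.floor(100.0 * count / total + 0.5))


def annotate_peaks(
    peaks: pd.DataFrame,
    flags: pd.DataFrame,
    gene_table: pd.DataFrame,
    max_distance: int = DEFAULT_MAX_LINK_DISTANCE,
) -> pd.DataFrame:
    """Full annotation table: sharing class, location, two linked genes."""
    classes, _ = venn_partition(flags)
    links = link_genes(peaks, gene_table, max_distance)
    location = annotate_location(peaks, links, gene_table)
    out = links.copy()
    out["sharing_class"] = classes.loc[out["peak"]].to_numpy()
    out["location"] = location.loc[out["peak"]].to_numpy()
    return out[["peak", "sharing_class", "location", "gene1", "dist1", "gene2", "dist2"]]


def summarize_sharing(
    annotated: pd.DataFrame, gene_filter: set | None = None, yates: bool = False
) -> dict:
    """Headline sharing report over (optionally gene-filtered) annotated peaks.

    Per location (promoter / distal): counts of common (TAC) vs differential
    peaks with integer percentages and raw fractions. The attachment-accessible
    distal decomposition splits differential distal peaks containing A into
    shared-with-one-cell-type (TA + AC) and attachment-only (A). A 2x2
    location x (shared vs differential) chi-square is included.
    """
    df = annotated
    if gene_filter is not None:
        keep = df["gene1"].isin(gene_filter) | df["gene2"].isin(gene_filter)
        df = df[keep]
    report: dict = {"n_peaks": int(len(df)), "by_location": {}}
    cells = {}
    for loc in ("promoter", "distal"):
        sub = df[df["location"] == loc]
        shared = int((sub["sharing_class"] == "TAC").sum())
        diff = int(len(sub) - shared)
        cells[loc] = (shared, diff)
        report["by_location"][loc] = {
            "total": int(len(sub)),
            "shared": shared,
            "differential": diff,
            "shared_pct": _pct(shared, len(sub)),
            "differential_pct": _pct(diff, len(sub)),
            "shared_fraction": shared / len(sub) if len(sub) else float("nan"),
        }
    distal_diff = df[(df["location"] == "distal") & (df["sharing_class"] != "TAC")]
    shared_one = int(distal_diff["sharing_class"].isin(["TA", "AC"]).sum())
    att_only = int((distal_diff["sharing_class"] == "A").sum())
    report["attachment_distal"] = {
        "attachment_accessible": shared_one + att_only,
        "shared_with_one": shared_one,
        "attachment_only": att_only,
    }
    table = np.array([cells["promoter"], cells["distal"]])
    if (table.sum(axis=1) > 0).all() and (table.sum(axis=0) > 0).all():
        ct = contingency_chi_square(table, yates=yates)
        report["contingency"] = {
            "table": table.tolist(),
            "statistic": ct.statistic,
            "p_value": ct.p_value,
            "yates": yates,
        }
    venn = df["sharing_class"].value_counts().reindex(SHARING_CLASSES, fill_value=0)
    report["venn"] = {k: int(v) for k, v in venn.items()}
    return report
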