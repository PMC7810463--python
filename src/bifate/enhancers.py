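"""Shared-enhancer candidate prioritization.

Distal peaks whose sharing class is congruent with their linked gene's
expression class (chondrogenic gene + chondrocyte/attachment-shared peak, or
tenogenic gene + tenocyte/attachment-shared peak) are scored against evidence
tracks — enhancer histone marks (H3K27ac/H3K4me1-like), promoter marks,
sequence conservation, chromatin-interaction anchors and motif sites — and
ranked. The additive weights formalize a manual multi-evidence selection; the
required gates (distal, congruent, mixed-set gene) are the grounded part, the
weights are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import overlaps_any

EVIDENCE_ROLES = [
    "enhancer_mark",
    "promoter_mark",
    "repressive_mark",
    "conservation",
    "interaction",
]

DEFAULT_WEIGHTS = {
    "enhancer_mark": 2,
    "conservation": 1,
    "interaction": 1,
    "motif_site": 1,
    "promoter_mark": -1,
    "repressive_mark": 0,
}


@dataclass
class EvidenceTrack:
    name: str
    role: str
    intervals: pd.DataFrame

    def __post_init__(self):
        if self.role not in EVIDENCE_ROLES:
            raise ValueError(
                f"unknown evidence role {self.role!r}; expected one of {EVIDENCE_ROLES}"
            )


def overlap_evidence(peaks: pd.DataFrame, tracks: list[EvidenceTrack]) -> pd.DataFrame:
    """Boolean flag per (peak, role): any track of that role overlaps >= 1 bp."""
    flags = pd.DataFrame(
        False, index=peaks["name"].to_numpy(), columns=EVIDENCE_ROLES
    )
    for track in tracks:
        hit = overlaps_any(peaks, track.intervals)
        flags[track.role] |= pd.Series(hit, index=flags.index)
    flags.index.name = "peak"
    return flags


def congruence(sharing_class: str, gene_label: str) -> bool:
    """Does the peak's accessibility pattern match its gene's expression class?

    Congruent: chondrogenic gene with an AC peak, or tenogenic gene with a TA
    peak — the sharing pattern that can explain the mixed transcriptome.
    """
    return (gene_label == "chondrogenic_mixed" and sharing_class == "AC") or (
        gene_label == "tenogenic_mixed" and sharing_class == "TA"
    )


def attachment_specific_pair(sharing_class: str, gene_label: str) -> bool:
    """Attachment-only peak near an attachment-upregulated gene (reported separately)."""
    return gene_label == "attachment_up" and sharing_class == "A"


def _gene_label(links_row: pd.Series, gene_labels: pd.Series) -> tuple[str | None, str | None]:
    """First linked gene carrying a mixed label, else first linked gene."""
    best = (None, None)
    for slot in ("gene1", "gene2"):
        gid = links_row[slot]
        if gid is None or (isinstance(gid, float) and np.isnan(gid)):
            continue
        lbl = gene_labels.get(gid, "unclassified")
        if lbl in ("tenogenic_mixed", "chondrogenic_mixed"):
            return gid, lbl
        if best[0] is None:
            best = (gid, lbl)
    return best


def score_and_rank(
    annotated: pd.DataFrame,
    evidence: pd.DataFrame,
    gene_labels: pd.Series,
    motif_peaks: set | None = None,
    weights: dict | None = None,
    require_gates: bool = True,
) -> pd.DataFrame:
    """Gate, score and rank distal congruent peaks as candidate enhancers.

    Gates (all required): distal location; linked gene in the mixed set;
    sharing class congruent with that gene's class. Score is the weighted sum
    of evidence flags plus the motif-site flag; ties break by |distance to
    TSS| ascending, then peak id. An empty candidate set is a valid result.
    With ``require_gates=False`` every distal peak with a linked gene is
    scored (the ``congruent`` column still records the gate outcome), which
    is useful for diagnostics and ranking audits.
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    motif_peaks = motif_peaks or set()
    rows = []
    for _, ln in annotated.iterrows():
        if ln["location"] != "distal":
            continue
        gid, lbl = _gene_label(ln, gene_labels)
        if gid is None:
            continue
        congruent = congruence(ln["sharing_class"], lbl)
        if require_gates and (
            lbl not in ("tenogenic_mixed", "chondrogenic_mixed") or not congruent
        ):
            continue
        ev = evidence.loc[ln["peak"]]
        has_motif = ln["peak"] in motif_peaks
        score = sum(w[r] * bool(ev[r]) for r in EVIDENCE_ROLES if r in w)
        score += w.get("motif_site", 0) * has_motif
        dist = ln["dist1"] if ln["gene1"] == gid else ln["dist2"]
        rows.append(
            {
                "peak": ln["peak"],
                "gene": gid,
                "gene_label": lbl,
                "sharing_class": ln["sharing_class"],
                "congruent": congruent,
                "distance_to_tss": int(dist),
                **{r: bool(ev[r]) for r in EVIDENCE_ROLES},
                "motif_site": has_motif,
                "score": int(score),
            }
        )
    cols = [
        "peak", "gene", "gene_label", "sharing_class", "congruent",
        "distance_to_tss", *EVIDENCE_ROLES, "motif_site", "score",
    ]
    if not rows:
        return pd.DataFrame(columns=cols + ["rank"])
    out = pd.DataFrame(rows)[cols]
    out["abs_dist"] = out["distance_to_tss"].abs()
    out = out.sort_values(
        ["score", "abs_dist", "peak"], ascending=[False, True, True], kind="stable"
    ).drop(columns="abs_dist").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
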