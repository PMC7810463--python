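"""Ground-truth diagnostics for synthetic runs.

These helpers compare pipeline outputs with the generator's planted truth:
per-class gene-label recovery, per-peak accessibility-flag agreement, and
the ranking separation between planted congruent enhancers and background
peaks. They are meaningful only for synthetic datasets, where the truth is
known.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import EXPECTED_DOWNSTREAM_LABEL, GroundTruth

_TISSUE_OF = {"T": "tenocyte", "A": "attachment", "C": "chondrocyte"}


def gene_label_recovery(labels: pd.Series, truth: GroundTruth) -> dict:
    """Fraction of genes per planted class receiving the expected label."""
    out = {}
    by_class: dict[str, list] = {}
    for gene, cls in truth.gene_labels.items():
        by_class.setdefault(cls, []).append(gene)
    for cls, genes in by_class.items():
        expected = EXPECTED_DOWNSTREAM_LABEL[cls]
        hit = sum(labels.get(g) == expected for g in genes)
        out[cls] = hit / len(genes)
    return out


def flag_accuracy(
    flags: pd.DataFrame, mapping: pd.Series, truth: GroundTruth
) -> float:
    """Fraction of planted (gene-linked) peaks whose called sharing class
    equals the planted one. Peaks lost upstream (e.g. blacklisted) count as
    misses."""
    ok = total = 0
    for source, cls in truth.peak_sharing.items():
        if not truth.peak_gene_link.get(source):
            continue  # background peaks carry no planted linkage contract
        total += 1
        consensus = mapping.get(source)
        if consensus is None or consensus not in flags.index:
            continue
        row = flags.loc[consensus]
        called = "".join(l for l in "TAC" if row[_TISSUE_OF[l]])
        ok += called == cls
    return ok / total if total else float("nan")


def enhancer_ranking_separation(
    ranked: pd.DataFrame, mapping: pd.Series, truth: GroundTruth
) -> float:
    """Fraction of planted congruent enhancers ranked above every background peak.

    ``ranked`` must be an ungated ranking (all distal peaks scored) so that
    background peaks appear in it; planted congruent enhancers are the distal
    peaks of mixed-class genes whose planted sharing matches the class.
    """
    consensus_of = dict(mapping)
    planted, background = set(), set()
    for source, cls in truth.peak_sharing.items():
        cons = consensus_of.get(source)
        if cons is None:
            continue
        gene = truth.peak_gene_link.get(source)
        if not gene:
            background.add(cons)
            continue
        label = truth.gene_labels[gene]
        if (label == "tenogenic_mixed" and cls == "TA") or (
            label == "chondrogenic_mixed" and cls == "AC"
        ):
            planted.add(cons)
    pos = ranked.set_index("peak")["rank"]
    bg_ranks = pos.reindex([p for p in background if p in pos.index]).dropna()
    if bg_ranks.empty:
        return 1.0
    best_bg = bg_ranks.min()
    planted_ranks = pos.reindex([p for p in planted if p in pos.index]).dropna()
    n_above = int((planted_ranks < best_bg).sum())
    return n_above / len(planted) if planted else float("nan")
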