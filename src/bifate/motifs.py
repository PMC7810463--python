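"""Transcription-factor binding-site scanning and gene-set enrichment.

Motifs are given either as an IUPAC consensus (e.g. a KLF-type CACCC box) or
as a position-weight matrix; sequences are scanned on both strands. A gene
carries a site when any of its linked, retained peaks contains >= 1 hit, and
enrichment of a foreground gene set against a gene universe is tested with a
2x2 chi-square on site carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sharing import contingency_chi_square

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def validate_iupac(consensus: str) -> None:
    bad = set(consensus.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters: {sorted(bad)}")


@dataclass
class Motif:
    """Consensus or PWM motif.

    ``pwm`` is 4 x L (rows A, C, G, T) of column-stochastic probabilities;
    ``score_threshold`` is the fraction of the maximum achievable log-odds
    (uniform background) a window must reach to count as a hit.
    """

    id: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    score_threshold: float = 0.8

    def __post_init__(self):
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("give exactly one of consensus or pwm")
        if self.consensus is not None:
            validate_iupac(self.consensus)
            self.consensus = self.consensus.upper()
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must be 4 x L (rows A,C,G,T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("PWM columns must sum to 1")
        if not (0 < self.score_threshold <= 1):
            raise ValueError("score_threshold must be in (0, 1]")

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[1]


def _consensus_matches(seq: str, consensus: str) -> list[int]:
    """Offsets where every position of ``seq`` is in the IUPAC class.

    N in the sequence never matches (unknown base, no credit).
    """
    L = len(consensus)
    hits = []
    classes = [IUPAC[c] for c in consensus]
    for i in range(len(seq) - L + 1):
        window = seq[i : i + L]
        if all(b in cls for b, cls in zip(window, classes)):
            hits.append(i)
    return hits


def _pwm_scores(seq: str, pwm: np.ndarray) -> np.ndarray:
    """Log-odds score (uniform 0.25 background) at each window; N scores -inf."""
    L = pwm.shape[1]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    logodds = np.log2(np.clip(pwm, 1e-12, None) / 0.25)
    idx = np.array([_BASE_INDEX.get(b, -1) for b in seq])
    scores = np.full(n, -np.inf)
    for i in range(n):
        window = idx[i : i + L]
        if (window >= 0).all():
            scores[i] = logodds[window, np.arange(L)].sum()
    return scores


def scan_motif(sequence: str, motif: Motif) -> pd.DataFrame:
    """All motif hits on both strands: columns offset, strand, score.

    Offsets are 0-based positions of the hit window start on the FORWARD
    sequence regardless of strand. Sequences shorter than the motif yield an
    empty table; letters outside {A,C,G,T,N} are an error.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid bases in sequence: {sorted(bad)}")
    L = motif.length
    rows = []
    if len(seq) >= L:
        if motif.consensus is not None:
            for off in _consensus_matches(seq, motif.consensus):
                rows.append((off, "+", float(L)))
            rc = motif.consensus
            for off in _consensus_matches(seq, reverse_complement(rc)):
                rows.append((off, "-", float(L)))
        else:
            logodds = np.log2(np.clip(motif.pwm, 1e-12, None) / 0.25)
            max_score = logodds.max(axis=0).sum()
            cutoff = motif.score_threshold * max_score
            fwd = _pwm_scores(seq, motif.pwm)
            rev = _pwm_scores(reverse_complement(seq), motif.pwm)
            for off in np.flatnonzero(fwd >= cutoff):
                rows.append((int(off), "+", float(fwd[off])))
            for off in np.flatnonzero(rev >= cutoff):
                # reflect the reverse-strand offset back to forward coordinates
                rows.append((len(seq) - L - int(off), "-", float(rev[off])))
    out = pd.DataFrame(rows, columns=["offset", "strand", "score"])
    return out.sort_values(["offset", "strand"], kind="stable").reset_index(drop=True)


def peak_hits(sequences: dict[str, str], motif: Motif) -> dict[str, pd.DataFrame]:
    """Scan every peak sequence; returns {peak id: hit table}."""
    return {pid: scan_motif(seq, motif) for pid, seq in sequences.items()}


def gene_site_table(
    links: pd.DataFrame, hit_peaks: set, retained_peaks: set, genes: list[str]
) -> pd.Series:
    """Per-gene boolean: >= 1 site in any linked, retained peak.

    ``links`` is the annotation table (peak, gene1, gene2); hits in peaks that
    were filtered out of the consensus set are ignored.
    """
    has_site = pd.Series(False, index=pd.Index(genes, name="gene"))
    live_hits = hit_peaks & retained_peaks
    for _, ln in links.iterrows():
        if ln["peak"] not in live_hits:
            continue
        for slot in ("gene1", "gene2"):
            gid = ln[slot]
            if gid is not None and not (isinstance(gid, float) and np.isnan(gid)):
                if gid in has_site.index:
                    has_site.loc[gid] = True
    return has_site


@dataclass
class EnrichmentResult:
    foreground_with_site: int
    foreground_total: int
    background_with_site: int
    background_total: int
    statistic: float
    p_value: float
    yates: bool = False

    @property
    def foreground_fraction(self) -> float:
        return self.foreground_with_site / self.foreground_total

    @property
    def background_fraction(self) -> float:
        return self.background_with_site / self.background_total

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.foreground_with_site, self.foreground_total - self.foreground_with_site],
                [self.background_with_site, self.background_total - self.background_with_site],
            ]
        )


def set_enrichment(
    foreground: set, universe: set, site_table: pd.Series, yates: bool = False
) -> EnrichmentResult:
    """Chi-square enrichment of site carriers in foreground vs rest of universe.

    ``site_table`` maps gene id -> has-site boolean. The background row of the
    2x2 table is the universe minus the foreground, so foreground == universe
    is a degenerate contrast and raises.
    """
    if not foreground or not universe:
        raise ValueError("foreground and universe must be non-empty")
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    rest = universe - foreground
    if not rest:
        raise ValueError("foreground equals universe: no background to contrast")
    fg_with = sum(bool(site_table.get(g, False)) for g in foreground)
    bg_with = sum(bool(site_table.get(g, False)) for g in rest)
    table = [
        [fg_with, len(foreground) - fg_with],
        [bg_with, len(rest) - bg_with],
    ]
    ct = contingency_chi_square(table, yates=yates)
    return EnrichmentResult(
        foreground_with_site=fg_with,
        foreground_total=len(foreground),
        background_with_site=bg_with,
        background_total=len(rest),
        statistic=ct.statistic,
        p_value=ct.p_value,
        yates=yates,
    )
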