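"""Consensus ATAC peak set via the merge-extend-normalize-vote procedure.

Per-replicate peak interval sets (one BED per replicate, any of the three
tissues: tenocyte, attachment, chondrocyte) are combined, merged, and
extended to a minimum length of 500 bp. Per-peak counts are normalized with
the same median-of-ratios size factors used for expression, and a peak is
called accessible in a tissue when a normalized count >= 30 is seen in at
least 50% of that tissue's replicates ("voting"). Peaks reproducible in no
tissue, peaks in blacklist regions, and peaks whose mean normalized count
stays below 30 in every tissue are removed, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import normalize_median_of_ratios
from .intervals import extend_intervals, merge_intervals, overlaps_any

TISSUES = ["tenocyte", "attachment", "chondrocyte"]

DEFAULT_VOTE_THRESHOLD = 30.0
DEFAULT_MIN_FRACTION = 0.5
DEFAULT_MIN_PEAK_LENGTH = 500
DEFAULT_AVG_THRESHOLD = 30.0


def build_consensus(
    replicate_beds: list[pd.DataFrame],
    chrom_sizes: dict[str, int],
    min_length: int = DEFAULT_MIN_PEAK_LENGTH,
) -> pd.DataFrame:
    """Combine replicate peak sets, merge, and extend to ``min_length``.

    Returns consensus peaks with stable ids ``peak_<n>`` assigned in
    (chrom, start) order.
    """
    combined = pd.concat(
        [b[["chrom", "start", "end"]] for b in replicate_beds], ignore_index=True
    )
    merged = merge_intervals(combined)
    extended = extend_intervals(merged, min_length, chrom_sizes)
    extended = extended.sort_values(["chrom", "start"]).reset_index(drop=True)
    extended["name"] = [f"peak_{i}" for i in range(len(extended))]
    return extended


def map_source_peaks(consensus: pd.DataFrame, peak_coords: pd.DataFrame) -> pd.Series:
    """Map each source peak (by name) to the consensus peak containing its midpoint.

    Source peaks whose midpoint falls outside every consensus interval are
    dropped from the result.
    """
    coords = peak_coords.set_index("name") if "name" in peak_coords.columns else peak_coords
    mid = (coords["start"] + coords["end"]) // 2
    assigned = pd.Series(index=coords.index, dtype=object)
    by_chrom = {c: g.sort_values("start") for c, g in consensus.groupby("chrom")}
    for chrom, grp in coords.groupby("chrom"):
        cons = by_chrom.get(chrom)
        if cons is None:
            continue
        starts = cons["start"].to_numpy()
        ends = cons["end"].to_numpy()
        names = cons["name"].to_numpy()
        m = mid.loc[grp.index].to_numpy()
        idx = np.searchsorted(starts, m, side="right") - 1
        ok = (idx >= 0) & (m < ends[np.clip(idx, 0, None)])
        assigned.loc[grp.index[ok]] = names[idx[ok]]
    return assigned.dropna()


def assign_counts(
    consensus: pd.DataFrame, counts: pd.DataFrame, peak_coords: pd.DataFrame
) -> pd.DataFrame:
    """Re-key a (source-peak x sample) count matrix onto consensus peaks.

    Each source peak (rows of ``counts``, coordinates in ``peak_coords``)
    contributes its counts to the consensus peak containing its midpoint;
    source peaks fused into one consensus interval are summed.
    """
    mapping = map_source_peaks(consensus, peak_coords)
    keep = mapping[mapping.index.isin(counts.index)]
    out = counts.loc[keep.index].groupby(keep).sum()
    out.index.name = "peak"
    return out.reindex(consensus["name"]).fillna(0)


def vote_accessibility(
    normalized: pd.DataFrame,
    tissue_map: pd.Series,
    threshold: float = DEFAULT_VOTE_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> pd.DataFrame:
    """Per-tissue accessibility flags by replicate voting.

    ``flag(tissue) = (#replicates with normalized count >= threshold) /
    (#replicates) >= min_fraction``. Both comparisons are inclusive.
    """
    unmapped = set(normalized.columns) - set(tissue_map.index)
    if unmapped:
        raise ValueError(f"samples without tissue assignment: {sorted(unmapped)}")
    flags = {}
    for tissue in sorted(tissue_map.unique()):
        reps = [s for s in normalized.columns if tissue_map[s] == tissue]
        if not reps:
            raise ValueError(f"tissue {tissue!r} has no replicates")
        passing = (normalized[reps] >= threshold).sum(axis=1)
        flags[tissue] = passing / len(reps) >= min_fraction
    return pd.DataFrame(flags, index=normalized.index)


@dataclass
class FilterReport:
    input_peaks: int
    removed_voting: int
    removed_blacklist: int
    removed_average: int
    retained: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_peaks(
    peaks: pd.DataFrame,
    flags: pd.DataFrame,
    normalized: pd.DataFrame,
    tissue_map: pd.Series,
    blacklist: pd.DataFrame | None = None,
    avg_threshold: float = DEFAULT_AVG_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Apply the three removal rules in order: voting -> blacklist -> average.

    Returns (retained peaks, retained flags, report). A peak survives iff it
    is accessible in >= 1 tissue, overlaps no blacklist interval by >= 1 bp,
    and has mean normalized count >= ``avg_threshold`` in >= 1 tissue.
    """
    flags = flags.loc[peaks["name"]]
    voted = flags.any(axis=1)
    n_voting = int((~voted).sum())
    peaks1 = peaks[voted.to_numpy()].reset_index(drop=True)

    if blacklist is not None and len(blacklist) > 0:
        in_black = overlaps_any(peaks1, blacklist)
    else:
        in_black = np.zeros(len(peaks1), dtype=bool)
    n_black = int(in_black.sum())
    peaks2 = peaks1[~in_black].reset_index(drop=True)

    tissue_means = pd.DataFrame(
        {
            tissue: normalized[[s for s in normalized.columns if tissue_map[s] == tissue]].mean(axis=1)
            for tissue in sorted(tissue_map.unique())
        }
    )
    ok_avg = (tissue_means.loc[peaks2["name"]] >= avg_threshold).any(axis=1)
    n_avg = int((~ok_avg).sum())
    retained = peaks2[ok_avg.to_numpy()].reset_index(drop=True)

    report = FilterReport(
        input_peaks=len(peaks),
        removed_voting=n_voting,
        removed_blacklist=n_black,
        removed_average=n_avg,
        retained=len(retained),
    )
    return retained, flags.loc[retained["name"]], report


@dataclass
class ConsensusResult:
    """Output bundle of the peak pipeline."""

    peaks: pd.DataFrame  # chrom, start, end, name (retained)
    flags: pd.DataFrame  # peaks x tissues booleans
    normalized: pd.DataFrame  # peaks x samples
    size_factors: pd.Series
    report: FilterReport
    tissue_means: pd.DataFrame = field(default=None)


def run_peak_pipeline(
    replicate_beds: list[pd.DataFrame],
    counts: pd.DataFrame,
    peak_coords: pd.DataFrame,
    tissue_map: pd.Series,
    chrom_sizes: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    min_length: int = DEFAULT_MIN_PEAK_LENGTH,
    vote_threshold: float = DEFAULT_VOTE_THRESHOLD,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    avg_threshold: float = DEFAULT_AVG_THRESHOLD,
) -> ConsensusResult:
    """combine -> merge -> extend -> normalize -> vote -> filter."""
    consensus = build_consensus(replicate_beds, chrom_sizes, min_length)
    peak_counts = assign_counts(consensus, counts, peak_coords)
    size_factors, normalized = normalize_median_of_ratios(peak_counts)
    flags = vote_accessibility(normalized, tissue_map, vote_threshold, min_fraction)
    retained, flags_kept, report = filter_peaks(
        consensus, flags, normalized, tissue_map, blacklist, avg_threshold
    )
    tissue_means = pd.DataFrame(
        {
            tissue: normalized[[s for s in normalized.columns if tissue_map[s] == tissue]].mean(axis=1)
            for tissue in sorted(tissue_map.unique())
        }
    )
    return ConsensusResult(
        peaks=retained,
        flags=flags_kept,
        normalized=normalized.loc[retained["name"]],
        size_factors=size_factors,
        report=report,
        tissue_means=tissue_means.loc[retained["name"]],
    )
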