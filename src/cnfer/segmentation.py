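"""Reference-derived copy-number segments and their projection onto queries.

Segments are runs of consecutive bins sharing a copy-number level. They are
detected on the high-tumor-fraction reference sample, per chromosome, by
penalized least-squares changepoint detection (PELT with an l2
piecewise-constant cost and a linear penalty), and then projected unchanged
onto every query: the query's value for a segment is the median query
deviation over the same member bins. Ranking segments by reference copy
number orders the downstream pairwise-comparison matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bin_grid import BinGrid
from .coverage import CoverageProfile

logger = logging.getLogger("cnfer")

DEFAULT_PENALTY_SCALE = 5.0
DEFAULT_MIN_SEG_BINS = 5

SEGMENT_COLUMNS = ["chrom", "start", "end", "first_bin", "last_bin",
                   "n_bins", "ref_value", "qry_value", "rank", "weight"]


class SegmentationError(ValueError):
    pass


def pelt_changepoints(y: np.ndarray, penalty: float, min_size: int = 1
                      ) -> list[int]:
    """Changepoints minimizing sum of within-segment squared error + penalty.

    Exact dynamic program (optimal partitioning) with the PELT pruning rule;
    the l2 cost of segment [s, e) is computed from prefix sums. Returns the
    sorted interior changepoint positions (segment boundaries), excluding 0
    and n.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_size:
        return []
    cs = np.concatenate([[0.0], np.cumsum(y)])
    cs2 = np.concatenate([[0.0], np.cumsum(y * y)])

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    prev = np.zeros(n + 1, dtype=np.int64)
    candidates = np.array([0], dtype=np.int64)
    deadlines = np.array([np.inf])  # time from which a candidate is dropped
    for t in range(min_size, n + 1):
        keep = deadlines > t
        candidates, deadlines = candidates[keep], deadlines[keep]
        new = t - min_size
        if new > 0 and np.isfinite(F[new]):
            candidates = np.append(candidates, new)
            deadlines = np.append(deadlines, np.inf)
        cand = candidates
        seg_len = (t - cand).astype(float)
        seg_sum = cs[t] - cs[cand]
        cost = (cs2[t] - cs2[cand]) - seg_sum * seg_sum / seg_len
        total = F[cand] + cost + penalty
        best = int(np.argmin(total))
        F[t] = total[best]
        prev[t] = cand[best]
        # PELT pruning. A dominated candidate may still be the only
        # admissible predecessor for the next min_size - 1 positions (the
        # dominating candidate t cannot start a segment shorter than
        # min_size), so removal is delayed accordingly; this keeps the
        # program exact for min_size > 1.
        dominated = F[cand] + cost > F[t]
        deadlines = np.where(dominated,
                             np.minimum(deadlines, t + min_size), deadlines)

    cps = []
    t = n
    while t > 0:
        s = int(prev[t])
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def _robust_noise_scale(y: np.ndarray) -> float:
    """MAD-based noise sigma estimated from first differences."""
    d = np.diff(y)
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


@dataclass
class SegmentSet:
    """Ordered reference segments with projected query values.

    ``segments`` holds one row per segment (chrom, bp extent, member-bin
    index range into the grid, median reference/query deviations, rank by
    reference value, similarity weight). Segments partition the retained
    bins of each chromosome and never span a chromosome boundary.
    """

    segments: pd.DataFrame
    n_bins_total: int
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS
    penalty_scale: float = DEFAULT_PENALTY_SCALE
    reference_id: str = ""

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def member_bins(self, seg_idx: int) -> np.ndarray:
        row = self.segments.iloc[seg_idx]
        return np.arange(int(row["first_bin"]), int(row["last_bin"]) + 1)

    def chromosome_segment_count(self) -> pd.Series:
        return self.segments.groupby("chrom", sort=False).size()

    def to_tsv(self, path) -> None:
        self.segments.to_csv(path, sep="\t", index=False, float_format="%.9g")

    @classmethod
    def from_tsv(cls, path, n_bins_total: int) -> "SegmentSet":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(segments=df, n_bins_total=n_bins_total)


def segment_reference(reference: CoverageProfile, grid: BinGrid,
                      penalty_scale: float = DEFAULT_PENALTY_SCALE,
                      min_seg_bins: int = DEFAULT_MIN_SEG_BINS) -> SegmentSet:
    """Detect copy-number segments on the reference deviation profile.

    Per chromosome, PELT with penalty beta = penalty_scale * sigma^2 * ln(n)
    where sigma is the MAD-based noise scale of first differences; segment
    value = median deviation of member bins. A chromosome with fewer than
    ``min_seg_bins`` bins is emitted as a single segment with a warning.
    """
    if reference.deviation is None:
        raise SegmentationError("reference profile must be at deviation stage")
    if reference.n_bins != grid.k:
        raise SegmentationError("profile and grid bin counts differ")

    dev = reference.deviation
    rows = []
    for chrom in grid.chromosomes:
        idx = grid.chrom_index(chrom)
        y = dev[idx]
        n = len(y)
        if n < min_seg_bins:
            logger.warning("segment_reference: %s has %d bins (< %d); "
                           "emitted as a single segment", chrom, n,
                           min_seg_bins)
            bounds = [0, n]
        else:
            sigma = max(_robust_noise_scale(y), 1e-8)
            beta = penalty_scale * sigma**2 * np.log(n)
            cps = pelt_changepoints(y, beta, min_size=min(min_seg_bins, n))
            bounds = [0] + cps + [n]
        for s, e in zip(bounds[:-1], bounds[1:]):
            first, last = int(idx[s]), int(idx[e - 1])
            rows.append({
                "chrom": chrom,
                "start": int(grid.bins["start"].iloc[first]),
                "end": int(grid.bins["end"].iloc[last]),
                "first_bin": first,
                "last_bin": last,
                "n_bins": e - s,
                "ref_value": float(np.median(y[s:e])),
                "qry_value": np.nan,
                "rank": 0,
                "weight": 1.0,
            })
    segments = pd.DataFrame(rows)
    return SegmentSet(segments=segments, n_bins_total=grid.k,
                      min_seg_bins=min_seg_bins, penalty_scale=penalty_scale,
                      reference_id=reference.sample_id)


def project_segments(segset: SegmentSet, query: CoverageProfile) -> SegmentSet:
    """Fill qry_value with the median query deviation over each segment."""
    if query.deviation is None:
        raise SegmentationError("query profile must be at deviation stage")
    if query.n_bins != segset.n_bins_total:
        raise SegmentationError(
            f"grid mismatch: query has {query.n_bins} bins, segments were "
            f"built on {segset.n_bins_total}")
    seg = segset.segments.copy()
    dev = query.deviation
    seg["qry_value"] = [
        float(np.median(dev[int(f):int(l) + 1]))
        for f, l in zip(seg["first_bin"], seg["last_bin"])
    ]
    return SegmentSet(segments=seg, n_bins_total=segset.n_bins_total,
                      min_seg_bins=segset.min_seg_bins,
                      penalty_scale=segset.penalty_scale,
                      reference_id=segset.reference_id)


def rank_segments(segset: SegmentSet) -> SegmentSet:
    """Rank segments 1..S ascending by reference value.

    Ties are broken by genomic position (chromosome order, then start) for
    determinism. The lower half (ranks 1..floor(S/2)) versus the rest is the
    sectioning used by the significance analysis; with odd S the middle
    segment joins the upper half.
    """
    seg = segset.segments.copy()
    order = np.lexsort((seg["start"].to_numpy(),
                        np.arange(len(seg)),  # original order encodes chrom
                        seg["ref_value"].to_numpy()))
    rank = np.empty(len(seg), dtype=np.int64)
    rank[order] = np.arange(1, len(seg) + 1)
    seg["rank"] = rank
    return SegmentSet(segments=seg, n_bins_total=segset.n_bins_total,
                      min_seg_bins=segset.min_seg_bins,
                      penalty_scale=segset.penalty_scale,
                      reference_id=segset.reference_id)


def lower_half_ranks(n_segments: int) -> set[int]:
    """Ranks belonging to the lower copy-number half (1..floor(S/2))."""
    return set(range(1, n_segments // 2 + 1))
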