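"""Per-sample coverage profiles: raw bin counts to centered deviations.

A sample moves through three stages:

1. raw counts -- reads with MAPQ >= 30 counted into every bin they overlap
   (overlapping windows mean one read lands in up to bin_width/step bins);
2. corrected log2 ratios -- log2(count + 1) with sequential robust-spline
   trends in GC, mappability and replication timing removed;
3. deviations -- linear copy-ratio minus 1, centered so the genome-wide
   median is copy-neutral zero. On this scale a segment of absolute tumor
   copy number c in a sample of tumor fraction t sits at t*(c-2)/2, which is
   the linearity the similarity fit relies on.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .bin_grid import BinGrid

logger = logging.getLogger("cnfer")

MIN_BINS_FOR_CORRECTION = 500
DEFAULT_MAPQ_MIN = 30


class CoverageError(ValueError):
    """Raised for unusable alignment input or degenerate profiles."""


@dataclass
class CoverageProfile:
    """Binned coverage of one sample on a shared :class:`BinGrid`."""

    sample_id: str
    raw_counts: np.ndarray
    log2_ratio: np.ndarray | None = None
    deviation: np.ndarray | None = None
    mean_depth: float = float("nan")
    size_selected: bool = False
    fragment_cutoff: int | None = None
    grid_ref: str = ""

    def __post_init__(self):
        self.raw_counts = np.asarray(self.raw_counts, dtype=np.int64)
        if (self.raw_counts < 0).any():
            raise CoverageError("raw counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.raw_counts)

    @property
    def stage(self) -> str:
        if self.deviation is not None:
            return "deviation"
        if self.log2_ratio is not None:
            return "corrected"
        return "raw"

    def to_frame(self, grid: BinGrid) -> pd.DataFrame:
        df = grid.bins[["chrom", "start", "end"]].copy()
        df["raw_count"] = self.raw_counts
        df["log2_ratio"] = (self.log2_ratio if self.log2_ratio is not None
                            else np.nan)
        df["deviation"] = (self.deviation if self.deviation is not None
                           else np.nan)
        return df

    def to_tsv(self, path: str | Path, grid: BinGrid) -> None:
        self.to_frame(grid).to_csv(path, sep="\t", index=False,
                                   float_format="%.12g")
        sidecar = Path(str(path) + ".json")
        sidecar.write_text(json.dumps({
            "sample_id": self.sample_id,
            "mean_depth": None if np.isnan(self.mean_depth) else self.mean_depth,
            "size_selected": self.size_selected,
            "fragment_cutoff": self.fragment_cutoff,
        }, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path, sample_id: str | None = None
                 ) -> "CoverageProfile":
        df = pd.read_csv(path, sep="\t")
        meta = {}
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        dev = df["deviation"].to_numpy(dtype=float)
        l2r = df["log2_ratio"].to_numpy(dtype=float)
        return cls(
            sample_id=sample_id or meta.get("sample_id", Path(path).stem),
            raw_counts=df["raw_count"].to_numpy(dtype=np.int64),
            log2_ratio=None if np.isnan(l2r).all() else l2r,
            deviation=None if np.isnan(dev).all() else dev,
            mean_depth=meta.get("mean_depth") or float("nan"),
            size_selected=bool(meta.get("size_selected", False)),
            fragment_cutoff=meta.get("fragment_cutoff"),
        )


def count_reads(
    alignments: str | Path,
    grid: BinGrid,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    fragment_max: int | None = None,
    sample_id: str | None = None,
) -> CoverageProfile:
    """Count aligned reads into every bin they overlap.

    Secondary, supplementary, duplicate and unmapped records are excluded;
    reads below ``mapq_min`` are excluded. When ``fragment_max`` is set (in
    silico size selection) only read 1 of proper pairs with
    ``0 < |TLEN| < fragment_max`` is counted, so each short fragment
    contributes once.
    """
    import pysam

    bam = pysam.AlignmentFile(str(alignments), "rb")
    try:
        if not bam.has_index():
            raise CoverageError(f"{alignments}: BAM is not indexed")
        counts = np.zeros(grid.k, dtype=np.int64)
        usable = 0
        base_sum = 0
        chrom_set = set(bam.references)
        width = grid.bin_width
        for chrom in grid.chromosomes:
            if chrom not in chrom_set:
                continue
            idx = grid.chrom_index(chrom)
            starts = grid.bins["start"].to_numpy()[idx]
            for read in bam.fetch(chrom):
                if (read.is_unmapped or read.is_secondary
                        or read.is_supplementary or read.is_duplicate):
                    continue
                if read.mapping_quality < mapq_min:
                    continue
                if fragment_max is not None:
                    if not (read.is_proper_pair and read.is_read1):
                        continue
                    tlen = abs(read.template_length)
                    if tlen == 0 or tlen >= fragment_max:
                        continue
                r_start = read.reference_start
                r_end = read.reference_end or (r_start + 1)
                lo = np.searchsorted(starts, r_start - width, side="right")
                hi = np.searchsorted(starts, r_end, side="left")
                if hi > lo:
                    counts[idx[lo]:idx[lo] + (hi - lo)] += 1
                usable += 1
                base_sum += read.query_length or 0
    finally:
        bam.close()

    if usable == 0:
        raise CoverageError(
            f"{alignments}: zero usable reads after filters "
            f"(MAPQ >= {mapq_min}, no duplicates/secondary/supplementary"
            + (f", proper pairs with |TLEN| < {fragment_max}"
               if fragment_max is not None else "") + ")")

    span = sum(grid.chrom_sizes.values()) or grid.k * grid.step
    return CoverageProfile(
        sample_id=sample_id or Path(alignments).stem,
        raw_counts=counts,
        mean_depth=base_sum / span if span else float("nan"),
        size_selected=fragment_max is not None,
        fragment_cutoff=fragment_max,
    )


def _robust_spline_trend(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                         n_knots: int = 5, reweight_passes: int = 2,
                         n_strata: int = 100) -> np.ndarray:
    """Robust cubic spline trend of y on x, evaluated at ``x_eval``.

    The covariate is cut into quantile strata and the trend is a cubic
    B-spline (knots at covariate quantiles) fitted to the per-stratum
    MEDIANS of y with Tukey-biweight iterative reweighting. Stratum medians
    make the fit insensitive to outlying bins -- within any covariate
    stratum the copy-neutral majority sets the median -- so the bias trend
    is estimated without absorbing CNA signal.
    """
    lo, hi = float(x.min()), float(x.max())
    if hi - lo <= 0:
        return np.full_like(x_eval, float(np.median(y)))

    n_strata = max(min(n_strata, len(y) // 10), 4)
    edges = np.quantile(x, np.linspace(0, 1, n_strata + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return np.full_like(x_eval, float(np.median(y)))
    stratum = np.clip(np.searchsorted(edges, x, side="right") - 1, 0,
                      len(edges) - 2)
    xs, ys = [], []
    for s in range(len(edges) - 1):
        mask = stratum == s
        if mask.sum() >= 3:
            xs.append(float(np.median(x[mask])))
            ys.append(float(np.median(y[mask])))
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    order = np.argsort(xs)
    xs, ys = xs[order], ys[order]
    if len(xs) < 5:
        return np.full_like(x_eval, float(np.median(y)))
    # outlier strata: a stratum whose median is hijacked by a large
    # copy-number event (possible where the event territory dominates one
    # covariate stratum, especially at a boundary where the spline has full
    # leverage) is replaced by the running median of its neighbors; strata
    # consistent with their neighborhood -- including genuinely steep trend
    # regions -- are left untouched
    runmed = np.array([np.median(ys[max(0, i - 2):i + 3])
                       for i in range(len(ys))])
    delta = ys - runmed
    mad = 1.4826 * np.median(np.abs(delta))
    hijacked = np.abs(delta) > 5.0 * max(mad, 1e-12)
    ys = np.where(hijacked, runmed, ys)

    k = 3
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    interior = np.unique(np.quantile(xs, qs))
    eps = 1e-9 * (xs[-1] - xs[0]) + 1e-12
    interior = interior[(interior > xs[0] + eps) & (interior < xs[-1] - eps)]
    t = np.concatenate([[xs[0]] * (k + 1), interior, [xs[-1] + eps] * (k + 1)])
    X = BSpline.design_matrix(xs, t, k).toarray()

    w = np.ones(len(ys))
    beta = np.zeros(X.shape[1])
    for _ in range(reweight_passes + 1):
        Xw = X * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ ys, rcond=None)
        resid = ys - X @ beta
        s = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        if s <= 0:
            break
        u = resid / (4.685 * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            w = np.ones(len(ys))
    spl = BSpline(t, beta, k, extrapolate=False)
    dspl = spl.derivative()
    trend = spl(np.clip(x_eval, xs[0], xs[-1]))
    # linear extension beyond the outermost stratum medians (cubic
    # extrapolation is unstable; constant extension under-corrects steep
    # tails)
    below = x_eval < xs[0]
    above = x_eval > xs[-1]
    if below.any():
        trend[below] = spl(xs[0]) + dspl(xs[0]) * (x_eval[below] - xs[0])
    if above.any():
        trend[above] = spl(xs[-1]) + dspl(xs[-1]) * (x_eval[above] - xs[-1])
    # a bias trend cannot stray far outside the range of the stratum medians
    # it was fitted to; clamping suppresses overshoot at sparse boundaries
    span = float(ys.max() - ys.min())
    return np.clip(trend, ys.min() - 0.5 * span, ys.max() + 0.5 * span)


def correct_bias(profile: CoverageProfile, grid: BinGrid,
                 n_knots: int = 5, reweight_passes: int = 2
                 ) -> CoverageProfile:
    """Remove GC, mappability and replication-timing trends from coverage.

    ``log2(count + 1)`` is detrended sequentially against each covariate with
    a robust smoothing spline; each fitted trend is subtracted (re-centered
    so the overall level is preserved). Each step fits twice: a first pass
    over all bins yields trend residuals, bins beyond 2.5 robust SD of the
    residual distribution (copy-number-altered territory) are masked, and
    the trend is refitted on the copy-neutral remainder so aberrations do
    not leak into the bias model; the trend is then removed from every bin.
    A
    covariate that is constant across bins, or missing, skips its step with
    a log message.
    """
    if profile.n_bins != grid.k:
        raise CoverageError("profile and grid bin counts differ")
    if profile.n_bins < MIN_BINS_FOR_CORRECTION:
        logger.warning("correct_bias: only %d bins (< %d); correction may be "
                       "unstable", profile.n_bins, MIN_BINS_FOR_CORRECTION)
    y = np.log2(profile.raw_counts.astype(float) + 1.0)
    for name in ("gc", "mappability", "reptiming"):
        if name not in grid.bins.columns:
            logger.info("correct_bias: no %s annotation; step skipped", name)
            continue
        x = grid.bins[name].to_numpy(dtype=float)
        if np.isnan(x).any():
            logger.info("correct_bias: %s has missing values; step skipped",
                        name)
            continue
        if np.ptp(x) <= 1e-12:
            logger.info("correct_bias: %s constant across bins; step skipped",
                        name)
            continue
        trend0 = _robust_spline_trend(x, y, x, n_knots=n_knots,
                                      reweight_passes=reweight_passes)
        resid = y - trend0
        resid = resid - np.median(resid)
        scale = 1.4826 * np.median(np.abs(resid))
        neutral = np.abs(resid) <= 2.5 * scale
        if neutral.sum() < max(50, len(y) // 10):
            neutral = np.ones(len(y), dtype=bool)
        trend = _robust_spline_trend(x[neutral], y[neutral], x,
                                     n_knots=n_knots,
                                     reweight_passes=reweight_passes)
        y = y - (trend - np.median(trend))
    return replace(profile, log2_ratio=y)


def center_to_deviation(profile: CoverageProfile) -> CoverageProfile:
    """Center corrected coverage to copy-neutral-zero linear deviations.

    deviation_i = ratio_i / median(ratio) - 1 with ratio = 2**log2_ratio;
    the genome-wide median deviation is zero by construction. Assumes most
    of the genome is copy-neutral (true for cfDNA, which is dominated by
    DNA of hematopoietic origin).
    """
    if profile.log2_ratio is None:
        raise CoverageError("profile has not been corrected yet")
    ratio = np.power(2.0, profile.log2_ratio)
    med = np.median(ratio)
    if med <= 0 or not np.isfinite(med):
        raise CoverageError("median coverage ratio is not positive")
    dev = ratio / med - 1.0
    if not np.isfinite(dev).all():
        raise CoverageError("non-finite deviations after centering")
    return replace(profile, deviation=dev)


def profile_from_counts(counts: np.ndarray, grid: BinGrid,
                        sample_id: str = "sample", correct: bool = True,
                        **meta) -> CoverageProfile:
    """Convenience: raw counts -> corrected -> deviation in one call."""
    prof = CoverageProfile(sample_id=sample_id, raw_counts=counts, **meta)
    if correct:
        prof = correct_bias(prof, grid)
    else:
        prof = replace(prof,
                       log2_ratio=np.log2(prof.raw_counts.astype(float) + 1.0))
    return center_to_deviation(prof)
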