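"""Genome bin tiling shared by all samples.

The genome is tiled with fixed-width windows (default 100 kb) advanced in
fixed steps (default 10 kb, i.e. overlapping windows). Low-mappability
territory -- centromeres, telomeres and other repeat-rich regions -- is
masked by a mappability-score cutoff, and only windows lying entirely inside
the remaining high-mappability territory are retained. Each retained bin
carries three covariates used downstream for coverage-bias correction: GC
fraction, mean mappability and replication timing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("cnfer")

GRID_COLUMNS = ["chrom", "start", "end", "gc", "mappability", "reptiming"]

DEFAULT_BIN_WIDTH = 100_000
DEFAULT_STEP = 10_000
DEFAULT_MAPPABILITY_CUTOFF = 0.2


class GridError(ValueError):
    """Raised for invalid grid construction inputs."""


def _chrom_sort_key(name: str) -> tuple[int, float, str]:
    """Karyotype ordering: chr1..chr22 numerically, then everything else."""
    stripped = re.sub(r"^chr", "", name, flags=re.IGNORECASE)
    if stripped.isdigit():
        return (0, int(stripped), "")
    return (1, np.inf, stripped)


def _is_autosome(name: str) -> bool:
    stripped = re.sub(r"^chr", "", name, flags=re.IGNORECASE)
    return stripped.isdigit()


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom.sizes`` TSV into a name -> length map."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                     names=["chrom", "length"], dtype={0: str, 1: np.int64})
    return dict(zip(df["chrom"], df["length"]))


def read_track(source) -> pd.DataFrame:
    """Read a genomic value track into a (chrom, start, end, score) frame.

    Accepts a ready-made DataFrame, a 4-column bedGraph path, or a bigWig
    path (``.bw``/``.bigwig``, read through pyBigWig).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
        df.columns = ["chrom", "start", "end", "score"]
    else:
        path = Path(source)
        if path.suffix.lower() in {".bw", ".bigwig"}:
            import pyBigWig

            rows = []
            with pyBigWig.open(str(path)) as bw:
                for chrom in bw.chroms():
                    for start, end, score in bw.intervals(chrom) or []:
                        rows.append((chrom, start, end, score))
            df = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
        else:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             names=["chrom", "start", "end", "score"],
                             dtype={0: str})
    df["chrom"] = df["chrom"].astype(str)
    df[["start", "end"]] = df[["start", "end"]].astype(np.int64)
    df["score"] = df["score"].astype(float)
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


@dataclass
class BinGrid:
    """Ordered genome tiling with per-bin annotations.

    ``bins`` uses 0-based half-open coordinates (BED convention on disk) and
    is sorted by karyotype chromosome order, then start. ``k`` (total bin
    count) is the summation length of the similarity objective.
    """

    bins: pd.DataFrame
    bin_width: int = DEFAULT_BIN_WIDTH
    step: int = DEFAULT_STEP
    mappability_cutoff: float = DEFAULT_MAPPABILITY_CUTOFF
    autosomes_only: bool = True
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.bins)

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.bins["chrom"]))

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.bins["chrom"].to_numpy() == chrom)

    def to_tsv(self, path: str | Path) -> None:
        self.bins.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, bin_width: int | None = None,
                 step: int | None = None) -> "BinGrid":
        bins = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        if bin_width is None:
            bin_width = int((bins["end"] - bins["start"]).iloc[0])
        if step is None:
            starts = bins["start"].to_numpy()
            diffs = np.diff(starts)
            diffs = diffs[diffs > 0]
            step = int(diffs.min()) if diffs.size else bin_width
        return cls(bins=bins, bin_width=bin_width, step=step)

    def same_grid(self, other: "BinGrid") -> bool:
        if self.k != other.k:
            return False
        return bool(
            (self.bins["chrom"].to_numpy() == other.bins["chrom"].to_numpy()).all()
            and (self.bins["start"].to_numpy() == other.bins["start"].to_numpy()).all()
        )


def _interval_arrays(track: pd.DataFrame, chrom: str):
    sub = track[track["chrom"] == chrom]
    return (sub["start"].to_numpy(), sub["end"].to_numpy(),
            sub["score"].to_numpy())


def _mean_over_bins(starts, ends, scores, bin_starts, width):
    """Mean track value over each bin via a prefix integral.

    Bases not covered by any interval contribute score 0.
    """
    # integral of the score from 0 to each interval boundary
    cum = np.concatenate([[0.0], np.cumsum(scores * (ends - starts))])

    def integral(x):
        # position of x relative to interval starts
        i = np.searchsorted(starts, x, side="right") - 1
        base = cum[np.maximum(i + 1, 0)]
        inside = (i >= 0) & (x < ends[np.maximum(i, 0)])
        # subtract the part of interval i beyond x
        corr = np.where(inside, scores[np.maximum(i, 0)]
                        * (ends[np.maximum(i, 0)] - x), 0.0)
        return base - corr

    lo = integral(bin_starts.astype(float))
    hi = integral((bin_starts + width).astype(float))
    return (hi - lo) / width


def build_bin_grid(
    mappability_track,
    chrom_sizes: Mapping[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
    step: int = DEFAULT_STEP,
    mappability_cutoff: float = DEFAULT_MAPPABILITY_CUTOFF,
    autosomes_only: bool = True,
) -> BinGrid:
    """Tile the mappable genome with fixed-width stepped windows.

    Bases whose mappability score falls below ``mappability_cutoff`` are
    masked (this removes centromeres, telomeres and other low-mappability
    regions); a bin is retained only when its full extent lies in unmasked
    territory, so every retained bin's mean mappability is >= the cutoff.
    Bins truncated at chromosome ends are dropped.
    """
    if not chrom_sizes:
        raise GridError("chrom_sizes is empty")
    if bin_width % step != 0:
        raise GridError(
            f"bin_width ({bin_width}) must be a multiple of step ({step})")
    track = read_track(mappability_track)
    unknown = set(track["chrom"]) - set(chrom_sizes)
    if unknown:
        raise GridError(f"track contains chromosomes not in chrom_sizes: "
                        f"{sorted(unknown)}")

    chroms = [c for c in chrom_sizes if not autosomes_only or _is_autosome(c)]
    chroms.sort(key=_chrom_sort_key)

    frames = []
    for chrom in chroms:
        length = int(chrom_sizes[chrom])
        if length < bin_width:
            continue
        n = (length - bin_width) // step + 1
        bin_starts = np.arange(n, dtype=np.int64) * step
        starts, ends, scores = _interval_arrays(track, chrom)
        if starts.size == 0:
            continue  # no mappability information: nothing retained
        mean_map = _mean_over_bins(starts, ends, scores, bin_starts, bin_width)

        # masked territory: intervals below the cutoff plus uncovered gaps
        bad = [(s, e) for s, e, v in zip(starts, ends, scores)
               if v < mappability_cutoff]
        gap_starts = np.concatenate([[0], ends])
        gap_ends = np.concatenate([starts, [length]])
        bad.extend((int(s), int(e)) for s, e in zip(gap_starts, gap_ends)
                   if e > s)
        keep = np.ones(n, dtype=bool)
        for s, e in bad:
            # bins overlapping the masked interval [s, e)
            lo = np.searchsorted(bin_starts, s - bin_width, side="right")
            hi = np.searchsorted(bin_starts, e, side="left")
            keep[lo:hi] = False
        keep &= mean_map >= mappability_cutoff

        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": bin_starts[keep],
            "end": bin_starts[keep] + bin_width,
            "gc": np.nan,
            "mappability": mean_map[keep],
            "reptiming": np.nan,
        }))

    bins = (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=GRID_COLUMNS))
    return BinGrid(bins=bins, bin_width=bin_width, step=step,
                   mappability_cutoff=mappability_cutoff,
                   autosomes_only=autosomes_only,
                   chrom_sizes={c: int(chrom_sizes[c]) for c in chroms})


def _gc_from_fasta(fasta_path: str | Path, bins: pd.DataFrame) -> np.ndarray:
    import pysam

    gc = np.full(len(bins), np.nan)
    with pysam.FastaFile(str(fasta_path)) as fa:
        for chrom, sub in bins.groupby("chrom", sort=False):
            for idx, start, end in zip(sub.index, sub["start"], sub["end"]):
                seq = fa.fetch(chrom, int(start), int(end)).upper()
                acgt = sum(seq.count(b) for b in "ACGT")
                if acgt == 0:
                    continue  # all-N bin: GC undefined
                gc[idx] = (seq.count("G") + seq.count("C")) / acgt
    return gc


def annotate_bins(grid: BinGrid, gc_source=None, reptiming_track=None) -> BinGrid:
    """Attach GC fraction and replication timing to every retained bin.

    ``gc_source`` is a FASTA path (GC computed over each bin, all-N bins are
    dropped with a logged count) or a per-bin value table / track.
    Replication-timing values missing for a bin are imputed as the chromosome
    median and flagged in a ``reptiming_imputed`` column.
    """
    bins = grid.bins.reset_index(drop=True).copy()

    if gc_source is not None:
        if isinstance(gc_source, (str, Path)) and Path(gc_source).suffix.lower() in {
                ".fa", ".fasta", ".fna"}:
            gc = _gc_from_fasta(gc_source, bins)
        else:
            track = read_track(gc_source)
            gc = np.full(len(bins), np.nan)
            for chrom, sub in bins.groupby("chrom", sort=False):
                s, e, v = _interval_arrays(track, chrom)
                if s.size:
                    gc[sub.index] = _mean_over_bins(
                        s, e, v, sub["start"].to_numpy(), grid.bin_width)
        n_drop = int(np.isnan(gc).sum())
        if n_drop:
            logger.info("annotate_bins: dropping %d bins with undefined GC",
                        n_drop)
        bins["gc"] = gc
        bins = bins[~bins["gc"].isna()].reset_index(drop=True)

    if reptiming_track is not None:
        track = read_track(reptiming_track)
        rt = np.full(len(bins), np.nan)
        for chrom, sub in bins.groupby("chrom", sort=False):
            s, e, v = _interval_arrays(track, chrom)
            if s.size:
                cover = _mean_over_bins(s, e, np.ones_like(v),
                                        sub["start"].to_numpy(), grid.bin_width)
                vals = _mean_over_bins(s, e, v, sub["start"].to_numpy(),
                                       grid.bin_width)
                with np.errstate(invalid="ignore", divide="ignore"):
                    vals = np.where(cover > 0, vals / cover, np.nan)
                rt[sub.index] = vals
        imputed = np.isnan(rt)
        if imputed.any():
            for chrom, sub in bins.groupby("chrom", sort=False):
                miss = imputed[sub.index]
                if miss.any():
                    med = np.nanmedian(rt[sub.index])
                    if np.isnan(med):
                        med = 0.0
                    rt[sub.index[miss]] = med
            logger.info("annotate_bins: imputed replication timing for %d bins",
                        int(imputed.sum()))
        bins["reptiming"] = rt
        bins["reptiming_imputed"] = imputed

    return replace(grid, bins=bins)
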