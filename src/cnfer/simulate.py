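"""Synthetic data generation: truth profiles, admixtures, dilution ladders.

The simulator emulates binned read counts of tumor/normal admixtures at the
bin level: a piecewise-constant absolute copy-number truth profile (diploid
background, aberrant segments in states {0, 1, 3, 4, 6}) is diluted into a
flat diploid background at a chosen tumor fraction t, giving per-bin expected
counts

    mu_i = reads_per_bin * [(1 - t) + t * c_i / 2] * gc_bias_i

drawn from a negative binomial with variance (1 + dispersion) * mu (mild
overdispersion over Poisson, matching shallow-WGS 100 kb bins after bias
correction). The default synthetic genome is 22 autosomes with
hg38-proportional lengths scaled to ~1 Gb, tiled with NON-overlapping 100 kb
bins (~10,000 bins): counts in overlapping stepped windows share reads and
are not independent, so independent draws on a non-overlapping tiling are
the faithful bin-level emulation. A 1x depth equivalent corresponds to
bin_width / read_length = 1000 expected reads per 100 kb bin (100 bp reads).

Small read-level BAM fixtures (with MAPQ, pairing flags, template lengths
and a shorter tumor fragment-length distribution) exercise the alignment
I/O and size-selection paths end to end.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bin_grid import BinGrid
from .coverage import CoverageProfile, profile_from_counts

# hg38 autosome lengths (bp), chr1..chr22
HG38_AUTOSOME_LENGTHS = {
    "chr1": 248_956_422, "chr2": 242_193_529, "chr3": 198_295_559,
    "chr4": 190_214_555, "chr5": 181_538_259, "chr6": 170_805_979,
    "chr7": 159_345_973, "chr8": 145_138_636, "chr9": 138_394_717,
    "chr10": 133_797_422, "chr11": 135_086_622, "chr12": 133_275_309,
    "chr13": 114_364_328, "chr14": 107_043_718, "chr15": 101_991_189,
    "chr16": 90_338_345, "chr17": 83_257_441, "chr18": 80_373_285,
    "chr19": 58_617_616, "chr20": 64_444_167, "chr21": 46_709_983,
    "chr22": 50_818_468,
}

DEFAULT_GENOME_SCALE = 0.35  # ~1 Gb, ~10,000 non-overlapping 100 kb bins
DEFAULT_STATES = {0: 0.10, 1: 0.35, 3: 0.30, 4: 0.15, 6: 0.10}
DEFAULT_DISPERSION = 0.1
DEFAULT_READ_LENGTH = 100


class SimulationError(ValueError):
    pass


def synthetic_chrom_sizes(scale: float = DEFAULT_GENOME_SCALE) -> dict[str, int]:
    """22 autosomes with hg38-proportional lengths, scaled."""
    return {c: int(v * scale) for c, v in HG38_AUTOSOME_LENGTHS.items()}


def make_synthetic_grid(chrom_sizes: dict[str, int] | None = None,
                        bin_width: int = 100_000, step: int | None = None,
                        seed: int = 0) -> BinGrid:
    """Fully mappable annotated grid for bin-level simulation.

    Mappability is 1 everywhere; GC varies smoothly in [0.35, 0.65] and
    replication timing follows a smooth random walk, so the bias-correction
    code paths run on simulated data exactly as on real data.
    """
    chrom_sizes = chrom_sizes or synthetic_chrom_sizes()
    step = step or bin_width
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, length in chrom_sizes.items():
        if length < bin_width:
            continue
        n = (length - bin_width) // step + 1
        starts = np.arange(n, dtype=np.int64) * step
        pos = starts / max(length, 1)
        gc = 0.5 + 0.1 * np.sin(2 * np.pi * (pos * rng.uniform(2, 5)
                                             + rng.uniform()))
        gc += rng.normal(0, 0.01, n)
        rt = np.cumsum(rng.normal(0, 0.05, n))
        rt -= rt.mean()
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + bin_width,
            "gc": np.clip(gc, 0.3, 0.7), "mappability": 1.0, "reptiming": rt,
        }))
    bins = pd.concat(frames, ignore_index=True)
    return BinGrid(bins=bins, bin_width=bin_width, step=step,
                   chrom_sizes=dict(chrom_sizes))


@dataclass
class TruthProfile:
    """Per-bin absolute tumor copy number, piecewise constant over segments."""

    copy_number: np.ndarray
    gi_level: float
    seed: int
    events: list[tuple[str, int, int, int]] = field(default_factory=list)
    # events: (chrom, first_bin, last_bin, state)

    @property
    def altered_fraction(self) -> float:
        return float(np.mean(self.copy_number != 2))


def make_truth_profile(grid: BinGrid, gi_level: float, n_events: int = 30,
                       state_distribution: dict[int, float] | None = None,
                       seed: int = 0) -> TruthProfile:
    """Random non-overlapping aberrant segments up to the target GI level.

    Segments receive states from ``state_distribution`` (copy numbers other
    than 2); at least one focal event (< 30 bins) is placed when n_events
    permits; the last segment is truncated so the altered fraction lands
    within one segment's length of ``gi_level``.
    """
    if not 0 <= gi_level <= 0.8:
        raise SimulationError("gi_level must be in [0, 0.8]")
    states = state_distribution or DEFAULT_STATES
    state_vals = np.array(list(states.keys()))
    state_p = np.array(list(states.values()), dtype=float)
    state_p = state_p / state_p.sum()

    rng = np.random.default_rng(seed)
    c = np.full(grid.k, 2, dtype=np.int64)
    k = grid.k
    target = int(round(gi_level * k))
    if target == 0:
        return TruthProfile(copy_number=c, gi_level=gi_level, seed=seed)

    chrom_idx = {ch: grid.chrom_index(ch) for ch in grid.chromosomes}
    chroms = list(chrom_idx)
    chrom_p = np.array([len(chrom_idx[ch]) for ch in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    altered = np.zeros(k, dtype=bool)
    events: list[tuple[str, int, int, int]] = []

    placed = 0
    total = 0
    while total < target and placed < n_events:
        remaining = target - total
        if placed == 0 and n_events > 1 and remaining > 30:
            length = int(rng.integers(5, 30))  # guaranteed focal event
        else:
            base = max(5, int(np.ceil(remaining / max(n_events - placed, 1))))
            length = int(np.clip(round(base * rng.uniform(0.6, 1.5)), 5,
                                 max(remaining, 5)))
        ok = False
        for _ in range(200):
            ch = chroms[rng.choice(len(chroms), p=chrom_p)]
            idx = chrom_idx[ch]
            if len(idx) <= length:
                continue
            s = int(rng.integers(0, len(idx) - length))
            span = idx[s:s + length]
            if altered[span].any():
                continue
            state = int(rng.choice(state_vals, p=state_p))
            c[span] = state
            altered[span] = True
            events.append((ch, int(span[0]), int(span[-1]), state))
            total += length
            placed += 1
            ok = True
            break
        if not ok:
            break

    if total < target - max(target // max(n_events, 1), 30):
        raise SimulationError(
            f"gi_level {gi_level} unreachable with n_events={n_events} "
            f"(placed {total}/{target} altered bins)")
    return TruthProfile(copy_number=c, gi_level=gi_level, seed=seed,
                        events=events)


@dataclass
class AdmixtureSpec:
    """Conditions of one simulated tumor/normal admixture."""

    tumor_fraction: float
    depth_equivalent: float = 1.0
    dispersion: float = DEFAULT_DISPERSION
    gc_bias: np.ndarray | None = None  # poly coeffs in (gc - 0.5)
    n_replicates: int = 1
    seed: int = 0
    read_length: int = DEFAULT_READ_LENGTH

    def __post_init__(self):
        if not 0 <= self.tumor_fraction <= 1:
            raise SimulationError("tumor_fraction must be in [0, 1]")
        if self.depth_equivalent <= 0:
            raise SimulationError("depth_equivalent must be > 0")

    def reads_per_bin(self, bin_width: int) -> float:
        return self.depth_equivalent * bin_width / self.read_length


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts with variance (1 + dispersion) * mean."""
    mean = np.asarray(mean, dtype=float)
    counts = np.zeros(len(mean), dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        counts[pos] = rng.poisson(mean[pos])
        return counts
    r = mean[pos] / dispersion
    p = 1.0 / (1.0 + dispersion)
    counts[pos] = rng.negative_binomial(r, p)
    return counts


def expected_bin_means(truth: TruthProfile, spec: AdmixtureSpec,
                       grid: BinGrid) -> np.ndarray:
    t = spec.tumor_fraction
    mu = spec.reads_per_bin(grid.bin_width) * (
        (1.0 - t) + t * truth.copy_number / 2.0)
    if spec.gc_bias is not None:
        gc = grid.bins["gc"].to_numpy(dtype=float)
        mult = np.polyval(spec.gc_bias, gc - 0.5)
        mu = mu * np.clip(mult, 0.1, None)
    return mu


def simulate_bin_counts(truth: TruthProfile, spec: AdmixtureSpec,
                        grid: BinGrid, rng: np.random.Generator | None = None,
                        sample_id: str = "sim") -> CoverageProfile:
    """Raw-stage coverage profile of one admixture replicate."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    mu = expected_bin_means(truth, spec, grid)
    counts = _nb_counts(mu, spec.dispersion, rng)
    return CoverageProfile(
        sample_id=sample_id, raw_counts=counts,
        mean_depth=spec.depth_equivalent)


def downsample_counts(counts: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Binomial thinning of per-bin counts (in silico down-sampling).

    Emulates random read down-sampling of one sequencing run: each read is
    kept independently with probability ``fraction``, so the thinned sample
    shares the original's sampling noise, exactly as when a BAM is
    down-sampled to a lower depth equivalent.
    """
    if not 0 < fraction <= 1:
        raise SimulationError("fraction must be in (0, 1]")
    counts = np.asarray(counts, dtype=np.int64)
    if fraction == 1.0:
        return counts.copy()
    return rng.binomial(counts, fraction)


def null_deviation_sampler(grid: BinGrid, reads_per_bin: float,
                           dispersion: float = DEFAULT_DISPERSION):
    """Sampler of flat-noise deviation vectors for lambda calibration."""
    mu = np.full(grid.k, reads_per_bin)

    def sample(rng: np.random.Generator) -> np.ndarray:
        counts = _nb_counts(mu, dispersion, rng).astype(float)
        med = np.median(counts)
        return counts / med - 1.0

    return sample


def simulate_dilution_series(truth: TruthProfile, tf_grid: list[float],
                             spec: AdmixtureSpec, grid: BinGrid,
                             reference_tf: float = 1.0, correct: bool = True
                             ) -> tuple[dict[str, CoverageProfile], pd.DataFrame]:
    """Reference profile plus replicate query admixtures over a TF ladder.

    Returns deviation-stage profiles keyed by sample id, and a manifest of
    (sample_id, role, true_tf, replicate, seed). Matched tumor-free controls
    are appended when 0 is not already on the grid. Replicate seeds are
    spawned deterministically from the master seed.
    """
    if not tf_grid:
        raise SimulationError("tf_grid is empty")
    tfs = list(tf_grid)
    if 0.0 not in tfs:
        tfs.append(0.0)

    ss = np.random.SeedSequence(spec.seed)
    n_children = 1 + len(tfs) * spec.n_replicates
    children = ss.spawn(n_children)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    profiles: dict[str, CoverageProfile] = {}
    rows = []

    ref_spec = AdmixtureSpec(
        tumor_fraction=reference_tf, depth_equivalent=spec.depth_equivalent,
        dispersion=spec.dispersion, gc_bias=spec.gc_bias,
        read_length=spec.read_length)
    ref_raw = simulate_bin_counts(
        truth, ref_spec, grid, rng=np.random.default_rng(children[0]),
        sample_id="reference")
    profiles["reference"] = profile_from_counts(
        ref_raw.raw_counts, grid, sample_id="reference", correct=correct,
        mean_depth=spec.depth_equivalent)
    rows.append({"sample_id": "reference", "role": "reference",
                 "true_tf": reference_tf, "replicate": 0,
                 "seed": child_seeds[0]})

    pos = 1
    for tf in tfs:
        for rep in range(spec.n_replicates):
            sid = f"tf{tf:g}_rep{rep}"
            q_spec = AdmixtureSpec(
                tumor_fraction=tf, depth_equivalent=spec.depth_equivalent,
                dispersion=spec.dispersion, gc_bias=spec.gc_bias,
                read_length=spec.read_length)
            raw = simulate_bin_counts(
                truth, q_spec, grid, rng=np.random.default_rng(children[pos]),
                sample_id=sid)
            profiles[sid] = profile_from_counts(
                raw.raw_counts, grid, sample_id=sid, correct=correct,
                mean_depth=spec.depth_equivalent)
            rows.append({"sample_id": sid, "role": "query", "true_tf": tf,
                         "replicate": rep, "seed": child_seeds[pos]})
            pos += 1

    return profiles, pd.DataFrame(rows)


def make_fixture_bam(path: str | Path, grid: BinGrid, truth: TruthProfile,
                     t: float, n_reads: int,
                     fragment_model: tuple[float, float] = (145.0, 166.0),
                     seed: int = 0, mapq: int = 60, read_length: int = 60
                     ) -> Path:
    """Small single-chromosome paired-end BAM (+ index) for I/O tests.

    ``n_reads`` fragments (two records each) are placed with per-bin density
    proportional to (1 - t) + t * c_i / 2; tumor-origin fragments draw their
    template length from the first (shorter) component of ``fragment_model``.
    """
    import pysam

    if n_reads > 1_000_000:
        raise SimulationError("keep fixture BAMs small (n_reads <= 1e6)")
    rng = np.random.default_rng(seed)
    chrom = grid.chromosomes[0]
    idx = grid.chrom_index(chrom)
    starts = grid.bins["start"].to_numpy()[idx]
    length = int(grid.chrom_sizes.get(chrom, starts[-1] + grid.bin_width))
    c = truth.copy_number[idx]

    w_total = (1.0 - t) + t * c / 2.0
    w_tumor = t * c / 2.0
    p_bin = w_total / w_total.sum()
    bins = rng.choice(len(starts), size=n_reads, p=p_bin)
    frac_tumor = np.divide(w_tumor[bins], w_total[bins],
                           out=np.zeros(n_reads), where=w_total[bins] > 0)
    is_tumor = rng.random(n_reads) < frac_tumor
    mean_len = np.where(is_tumor, fragment_model[0], fragment_model[1])
    frag_len = np.clip(rng.normal(mean_len, 12.0), 2 * read_length + 1,
                       500).astype(int)
    offset = rng.integers(0, grid.bin_width, size=n_reads)
    pos = np.minimum(starts[bins] + offset, length - frag_len - 1)

    order = np.argsort(pos, kind="stable")
    path = Path(path)
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        records = []
        for i in order:
            p1 = int(pos[i])
            fl = int(frag_len[i])
            p2 = p1 + fl - read_length
            for which, (ps, pn, tl) in enumerate(
                    [(p1, p2, fl), (p2, p1, -fl)]):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"frag{i}"
                a.query_sequence = "A" * read_length
                a.query_qualities = pysam.qualitystring_to_array(
                    "I" * read_length)
                a.reference_id = 0
                a.reference_start = ps
                a.cigarstring = f"{read_length}M"
                a.mapping_quality = mapq
                a.flag = (0x1 | 0x2 | (0x40 if which == 0 else 0x80)
                          | (0x20 if which == 0 else 0x10))
                a.next_reference_id = 0
                a.next_reference_start = pn
                a.template_length = tl
                records.append(a)
        records.sort(key=lambda r: r.reference_start)
        for r in records:
            out.write(r)
    pysam.index(str(path))
    return path


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "score"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(sizes.items()).to_csv(path, sep="\t", header=False,
                                       index=False)
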