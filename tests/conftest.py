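"""Shared fixtures: synthetic genome, truth profile, reference, classifier.

Heavy objects are session-scoped so the dilution-ladder and specificity
tests reuse one simulated study. All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cnfer as cf
from cnfer.coverage import CoverageProfile
from cnfer.segmentation import SegmentSet


GRID_SEED = 1
TRUTH_SEED = 2


@pytest.fixture(scope="session")
def sim_grid():
    """Default synthetic genome: 22 autosomes, ~10,000 100 kb bins."""
    return cf.make_synthetic_grid(seed=GRID_SEED)


@pytest.fixture(scope="session")
def truth(sim_grid):
    """High genomic-instability truth profile (40% of bins altered)."""
    return cf.make_truth_profile(sim_grid, gi_level=0.4, seed=TRUTH_SEED)


def make_profile(truth, grid, tf, depth=1.0, seed=0, correct=True):
    raw = cf.simulate_bin_counts(
        truth, cf.AdmixtureSpec(tumor_fraction=tf, depth_equivalent=depth),
        grid, rng=np.random.default_rng(seed))
    return cf.profile_from_counts(raw.raw_counts, grid,
                                  sample_id=f"tf{tf}_d{depth}_s{seed}",
                                  correct=correct, mean_depth=depth)


@pytest.fixture(scope="session")
def reference_full(truth, sim_grid):
    """Pure-tumor reference at 1x-equivalent depth (deviation stage)."""
    return make_profile(truth, sim_grid, tf=1.0, depth=1.0, seed=3)


@pytest.fixture(scope="session")
def reference_segments(reference_full, sim_grid):
    return cf.segment_reference(reference_full, sim_grid)


@pytest.fixture(scope="session")
def default_model(sim_grid, truth):
    """Significance classifier trained on the simulated dilution corpus."""
    return cf.train_default_classifier(grid=sim_grid, truth=truth, seed=5,
                                       n_replicates=100)


def uniform_track(chrom, length, score):
    return pd.DataFrame({"chrom": [chrom], "start": [0], "end": [length],
                         "score": [score]})


def segset_from_values(ref_values, qry_values, chroms=None, n_bins=10):
    """Hand-built SegmentSet for unit tests of weights/correlation."""
    S = len(ref_values)
    chroms = chroms or ["chr1"] * S
    rows = []
    first = 0
    for i in range(S):
        rows.append({
            "chrom": chroms[i], "start": first * 1000,
            "end": (first + n_bins) * 1000, "first_bin": first,
            "last_bin": first + n_bins - 1, "n_bins": n_bins,
            "ref_value": ref_values[i],
            "qry_value": qry_values[i] if qry_values is not None else np.nan,
            "rank": 0, "weight": 1.0,
        })
        first += n_bins
    segs = SegmentSet(segments=pd.DataFrame(rows), n_bins_total=first)
    return cf.rank_segments(segs)


def profile_from_deviation(dev):
    """Deviation-stage profile wrapping a given per-bin deviation vector."""
    dev = np.asarray(dev, dtype=float)
    return CoverageProfile(sample_id="manual",
                           raw_counts=np.zeros(len(dev), dtype=np.int64),
                           log2_ratio=np.log2(1.0 + dev + 1e-12),
                           deviation=dev)


def write_read_bam(path, chrom, length, reads):
    """Tiny BAM from explicit read tuples.

    ``reads``: (pos, mapq, flag, tlen, mate_pos) with 100 bp aligned reads.
    """
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": length}]}
    read_len = 100
    records = []
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for pos, mapq, flag, tlen, mate_pos in sorted(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"r{len(records)}"
            a.query_sequence = "A" * read_len
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = f"{read_len}M"
            a.mapping_quality = mapq
            a.flag = flag
            a.next_reference_id = 0 if mate_pos is not None else -1
            a.next_reference_start = mate_pos if mate_pos is not None else -1
            a.template_length = tlen
            records.append(a)
            out.write(a)
    pysam.index(str(path))
    return path
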