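"""Copy-number similarity: the score x and the query tumor-fraction estimate.

The query deviation profile b is modeled as a scalar multiple x >= 0 of the
reference deviation profile a, fitted by weighted least squares with an l1
shrinkage penalty:

    min_{x >= 0}  sum_i w_i (a_i x - b_i)^2 + lambda * |x|

Because x is a one-dimensional nonnegative scalar the minimizer has the
closed form of a soft-thresholded projection,

    x* = max(0, (sum_i w_i a_i b_i - lambda/2) / sum_i w_i a_i^2),

which is used directly (a numerical solver is kept as an independent
cross-check in the test suite). The query tumor fraction is then
x* times the user-supplied reference tumor fraction; scores above 1 simply
mean the query carries more tumor DNA than the reference.

Weights emphasize focal, high-amplitude aberrations that would otherwise be
underrepresented because they cover few bins: within each multi-segment
chromosome, w = 1 + CN_ref * SD_qry / SD_ref, where CN_ref is the segment's
absolute reference copy number and SD_ref / SD_qry are the standard
deviations of segment copy-number values within that chromosome. Chromosomes
with a single segment carry weight 1. Every bin inherits the weight of its
segment.

The shrinkage penalty lambda is calibrated, not fixed: it is set to the 95th
percentile of |2 * sum_i w_i a_i b_i| over simulated flat-noise queries
matched to the query's depth, so that a tumor-free query shrinks to x = 0
with roughly 95% probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .segmentation import SegmentSet

DEFAULT_WEIGHT_CAP = 10.0
DEFAULT_CN_CAP = 20.0
RECOMMENDED_MIN_BINS = 100


class SimilarityError(ValueError):
    pass


@dataclass
class SimilarityConfig:
    lambda_penalty: float | None = None  # None -> calibrate against nulls
    weight_cap: float = DEFAULT_WEIGHT_CAP
    cn_cap: float = DEFAULT_CN_CAP
    nonneg: bool = True

    def __post_init__(self):
        if self.lambda_penalty is not None and self.lambda_penalty < 0:
            raise SimilarityError("lambda_penalty must be >= 0")
        if self.weight_cap <= 1 or self.cn_cap <= 1:
            raise SimilarityError("weight_cap and cn_cap must be > 1")


@dataclass
class SegmentWeights:
    """Per-segment weights with the quantities they were derived from."""

    table: pd.DataFrame  # columns: chrom, cn_ref, sd_ref, sd_qry, weight

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


@dataclass
class SimilarityResult:
    score: float
    lambda_penalty: float
    k: int
    tf_reference: float | None = None
    tf_estimate: float | None = None
    reference_id: str = ""
    query_id: str = ""

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "lambda": self.lambda_penalty,
            "k": self.k,
            "tf_reference": self.tf_reference,
            "tf_estimate": self.tf_estimate,
            "reference_id": self.reference_id,
            "query_id": self.query_id,
        }


def compute_weights(segset: SegmentSet, tf_reference: float,
                    config: SimilarityConfig | None = None) -> SegmentWeights:
    """Per-segment weights emphasizing focal high-copy aberrations.

    CN_ref is recovered from the reference deviation d and reference tumor
    fraction as CN = 2 + 2 d / TF_ref (diploid background), clipped to
    [0, cn_cap]. SD_ref / SD_qry are the standard deviations of the segment
    median values within the segment's chromosome. Single-segment
    chromosomes, and multi-segment chromosomes whose reference values are
    constant, get weight 1. Weights are capped at weight_cap.
    """
    config = config or SimilarityConfig()
    if not 0 < tf_reference <= 1:
        raise SimilarityError(f"tf_reference must be in (0, 1], got "
                              f"{tf_reference}")
    seg = segset.segments
    if seg["qry_value"].isna().any():
        raise SimilarityError("segments must be projected onto the query "
                              "before weights are computed")
    cn_ref = np.clip(2.0 + 2.0 * seg["ref_value"].to_numpy() / tf_reference,
                     0.0, config.cn_cap)
    weight = np.ones(len(seg))
    sd_ref_col = np.zeros(len(seg))
    sd_qry_col = np.zeros(len(seg))
    for chrom, sub in seg.groupby("chrom", sort=False):
        if len(sub) < 2:
            continue
        sd_ref = float(np.std(sub["ref_value"], ddof=1))
        sd_qry = float(np.std(sub["qry_value"], ddof=1))
        sd_ref_col[sub.index] = sd_ref
        sd_qry_col[sub.index] = sd_qry
        if sd_ref <= 0:
            continue  # degenerate chromosome: no extra weight
        w = 1.0 + cn_ref[sub.index] * sd_qry / sd_ref
        weight[sub.index] = np.minimum(w, config.weight_cap)
    table = pd.DataFrame({
        "chrom": seg["chrom"].to_numpy(),
        "cn_ref": cn_ref,
        "sd_ref": sd_ref_col,
        "sd_qry": sd_qry_col,
        "weight": weight,
    })
    return SegmentWeights(table=table)


def bin_weights(segset: SegmentSet, seg_weights: SegmentWeights) -> np.ndarray:
    """Expand segment weights to per-bin weights (bins inherit their segment)."""
    w = np.ones(segset.n_bins_total)
    for (f, l), wi in zip(
            zip(segset.segments["first_bin"], segset.segments["last_bin"]),
            seg_weights.weights):
        w[int(f):int(l) + 1] = wi
    return w


def solve_similarity(a: np.ndarray, b: np.ndarray, w: np.ndarray | None = None,
                     lambda_penalty: float = 0.0,
                     reference_id: str = "", query_id: str = ""
                     ) -> SimilarityResult:
    """Closed-form minimizer of the weighted, l1-penalized scalar fit."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if w is None:
        w = np.ones_like(a)
    w = np.asarray(w, dtype=float)
    if not (len(a) == len(b) == len(w)):
        raise SimilarityError("a, b and w must have equal length")
    if (w <= 0).any():
        raise SimilarityError("weights must be positive")
    if lambda_penalty < 0:
        raise SimilarityError("lambda_penalty must be >= 0")
    denom = float(np.sum(w * a * a))
    if denom <= 0:
        raise SimilarityError(
            "reference profile flat -- not usable as reference")
    num = float(np.sum(w * a * b))
    x = max(0.0, (num - lambda_penalty / 2.0) / denom)
    return SimilarityResult(score=x, lambda_penalty=lambda_penalty, k=len(a),
                            reference_id=reference_id, query_id=query_id)


def estimate_tf(result: SimilarityResult, tf_reference: float
                ) -> SimilarityResult:
    """Query TF = score x reference TF (unbounded above; x > 1 allowed)."""
    if not 0 < tf_reference <= 1:
        raise SimilarityError(f"tf_reference must be in (0, 1], got "
                              f"{tf_reference}")
    result.tf_reference = tf_reference
    result.tf_estimate = result.score * tf_reference
    return result


def calibrate_lambda(a: np.ndarray, w: np.ndarray,
                     null_sampler: Callable[[np.random.Generator], np.ndarray],
                     n_sims: int = 200, quantile: float = 0.95,
                     seed: int = 0) -> float:
    """Shrinkage penalty from the null distribution of the fit numerator.

    ``null_sampler(rng)`` must return one flat-noise deviation vector matched
    to the query's depth. lambda is the ``quantile`` of |2 sum w a b_null|,
    so tumor-free queries are shrunk to zero at that specificity.
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    stats = np.empty(n_sims)
    for i in range(n_sims):
        b0 = null_sampler(rng)
        stats[i] = abs(2.0 * float(np.sum(w * a * b0)))
    return float(np.quantile(stats, quantile))
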