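"""Copy-number significance analysis: ctDNA detection without a reference TF.

Two complementary analyses feed an SVM classifier:

* segment correlation -- Kendall's rank correlation (tau-b) between the
  reference and query segment values. ctDNA in the query perturbs coverage
  in the direction of the reference aberrations, so a positive correlation
  indicates shared tumor signal above the flat hematopoietic background.

* segment comparison -- Dunn's post-hoc test between every pair of segments
  using the query bin deviations within those segments (joint ranking,
  tie-corrected rank-sum z statistics, two-sided p, Sidak adjustment over
  all S(S-1)/2 pairs). With ctDNA present, comparisons between low- and
  high-copy segments become more significant than comparisons within either
  group.

The adjusted p-value matrix, ordered by reference segment rank, is divided
into three sections: an "upper sub-triangle" (both segments in the lower
copy-number half), a "lower sub-triangle" (both in the upper half) and a
nearly "square" section (one from each half). Eight features -- tau, its
p-value, the three section medians, and three Mann-Whitney comparisons of
sections -- feed a fixed-seed RBF-kernel SVM whose binary output, combined
with the similarity TF estimate, yields the final ctDNA call:
positive iff TF >= 0.2% AND the SVM predicts True.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import CoverageProfile
from .segmentation import SegmentSet, lower_half_ranks

logger = logging.getLogger("cnfer")

FEATURE_NAMES = [
    "tau",
    "tau_p",
    "med_p_upper",
    "med_p_lower",
    "med_p_square",
    "p_upper_vs_square",
    "p_lower_vs_square",
    "p_upper_vs_lower",
]

DEFAULT_LLOD_THRESHOLD = 0.002
MIN_SEGMENTS = 4


class SignificanceError(ValueError):
    pass


@dataclass
class SignificanceFeatures:
    tau: float
    tau_p: float
    med_p_upper: float
    med_p_lower: float
    med_p_square: float
    p_upper_vs_square: float
    p_lower_vs_square: float
    p_upper_vs_lower: float

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}


@dataclass
class PValueMatrix:
    """Lower-triangular Sidak-adjusted Dunn p-values in segment-rank order.

    ``p_adj[i, j]`` (i > j) compares the segments of rank j+1 and i+1; the
    diagonal and upper triangle are NaN. ``order`` maps rank position to the
    original segment row, ``sections`` labels each stored cell.
    """

    p_adj: np.ndarray
    p_raw: np.ndarray
    order: np.ndarray
    ranks: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.p_adj.shape[0]

    def section_of(self, i: int, j: int) -> str:
        low = lower_half_ranks(self.n_segments)
        a, b = i + 1, j + 1
        if a in low and b in low:
            return "upper_subtriangle"
        if a not in low and b not in low:
            return "lower_subtriangle"
        return "square"

    def section_values(self) -> dict[str, np.ndarray]:
        S = self.n_segments
        low = np.arange(1, S + 1) <= S // 2
        ii, jj = np.tril_indices(S, k=-1)
        vals = self.p_adj[ii, jj]
        both_low = low[ii] & low[jj]
        both_high = ~low[ii] & ~low[jj]
        return {
            "upper_subtriangle": vals[both_low],
            "lower_subtriangle": vals[both_high],
            "square": vals[~both_low & ~both_high],
        }

    def to_frame(self) -> pd.DataFrame:
        S = self.n_segments
        rows = []
        for i in range(S):
            for j in range(i):
                rows.append({"rank_i": i + 1, "rank_j": j + 1,
                             "p_raw": self.p_raw[i, j],
                             "p_adj": self.p_adj[i, j],
                             "section": self.section_of(i, j)})
        return pd.DataFrame(rows)


def kendall_segments(segset: SegmentSet) -> tuple[float, float]:
    """Kendall tau-b (with tie correction) between ref and query segment values."""
    seg = segset.segments
    if len(seg) < MIN_SEGMENTS:
        raise SignificanceError("too few segments for correlation "
                                f"({len(seg)} < {MIN_SEGMENTS})")
    if seg["qry_value"].isna().any():
        raise SignificanceError("segments not projected onto the query")
    res = stats.kendalltau(seg["ref_value"].to_numpy(),
                           seg["qry_value"].to_numpy())
    return float(res.statistic), float(res.pvalue)


def sidak_adjust(p: np.ndarray, m: int) -> np.ndarray:
    """Sidak multiple-testing adjustment p_adj = 1 - (1 - p)^m.

    Evaluated as -expm1(m * log1p(-p)) so that very small raw p-values map
    to ~m*p instead of underflowing to zero; the result is clamped to
    [p, 1] (the adjustment can never decrease a p-value).
    """
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = -np.expm1(m * np.log1p(-p))
    adj = np.where(p >= 1.0, 1.0, adj)
    return np.clip(adj, p, 1.0)


def dunn_pvalue_matrix(query: CoverageProfile, segset: SegmentSet
                       ) -> PValueMatrix:
    """Dunn's test between every pair of segments in the query sample.

    All query bin deviations are ranked jointly across segments; for a pair
    (i, j), z = (mean rank_i - mean rank_j) / sqrt(Var) with the tie-corrected
    variance Var = (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j); two-sided
    normal p-values are Sidak-adjusted with m = S(S-1)/2. The matrix rows and
    columns follow reference segment rank (ascending copy number).
    """
    if query.deviation is None:
        raise SignificanceError("query profile must be at deviation stage")
    seg = segset.segments
    if (seg["rank"] <= 0).any():
        raise SignificanceError("segments must be ranked first")
    S = len(seg)
    order = np.argsort(seg["rank"].to_numpy(), kind="stable")

    values = []
    labels = []
    for pos, row_idx in enumerate(order):
        bins = segset.member_bins(int(row_idx))
        values.append(query.deviation[bins])
        labels.append(np.full(len(bins), pos))
    all_vals = np.concatenate(values)
    all_labels = np.concatenate(labels)
    N = len(all_vals)
    ranks = stats.rankdata(all_vals)

    n = np.bincount(all_labels, minlength=S).astype(float)
    rank_sum = np.bincount(all_labels, weights=ranks, minlength=S)
    mean_rank = rank_sum / n

    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = float(np.sum(tie_counts.astype(float)**3 - tie_counts))
    base_var = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    m = S * (S - 1) // 2
    var = base_var * (1.0 / n[:, None] + 1.0 / n[None, :])
    diff = mean_rank[:, None] - mean_rank[None, :]
    degenerate = var <= 0
    if degenerate.any():
        logger.warning("dunn_pvalue_matrix: %d degenerate pairs; p set to 1",
                       int(np.tril(degenerate, -1).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, diff / np.sqrt(np.where(degenerate, 1.0,
                                                              var)))
    p_raw = np.where(degenerate, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p_raw[np.triu_indices(S)] = np.nan
    p_adj = np.where(np.isnan(p_raw), np.nan, sidak_adjust(p_raw, m))
    return PValueMatrix(p_adj=p_adj, p_raw=p_raw, order=order,
                        ranks=np.arange(1, S + 1))


def section_features(matrix: PValueMatrix, segset: SegmentSet,
                     tau: float | None = None, tau_p: float | None = None
                     ) -> SignificanceFeatures:
    """Section the p-value matrix and assemble the 8-feature vector.

    The one-sided Mann-Whitney tests take the alternative that within-half
    (sub-triangle) p-values are stochastically GREATER than cross-half
    (square) p-values: with ctDNA present the low-vs-high comparisons are
    the most significant ones.
    """
    if matrix.n_segments < MIN_SEGMENTS:
        raise SignificanceError("too few segments to section the matrix")
    sections = matrix.section_values()
    upper = sections["upper_subtriangle"]
    lower = sections["lower_subtriangle"]
    square = sections["square"]
    if min(len(upper), len(lower), len(square)) == 0:
        raise SignificanceError("empty matrix section")

    if tau is None or tau_p is None:
        tau, tau_p = kendall_segments(segset)

    p_u = float(stats.mannwhitneyu(upper, square,
                                   alternative="greater").pvalue)
    p_l = float(stats.mannwhitneyu(lower, square,
                                   alternative="greater").pvalue)
    p_ul = float(stats.mannwhitneyu(upper, lower,
                                    alternative="two-sided").pvalue)
    return SignificanceFeatures(
        tau=tau, tau_p=tau_p,
        med_p_upper=float(np.median(upper)),
        med_p_lower=float(np.median(lower)),
        med_p_square=float(np.median(square)),
        p_upper_vs_square=p_u,
        p_lower_vs_square=p_l,
        p_upper_vs_lower=p_ul,
    )


def extract_features(query: CoverageProfile, segset: SegmentSet
                     ) -> SignificanceFeatures:
    """Kendall correlation + Dunn matrix sectioning in one call."""
    tau, tau_p = kendall_segments(segset)
    matrix = dunn_pvalue_matrix(query, segset)
    return section_features(matrix, segset, tau=tau, tau_p=tau_p)


# ---------------------------------------------------------------------------
# SVM classifier


def train_classifier(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                     cv_folds: int = 5):
    """Fit the fixed-seed RBF SVM on standardized 8-feature vectors.

    Returns a dict with the fitted pipeline, the feature order, the seed and
    the cross-validated AUC (NaN when a class is too small for CV).
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise SignificanceError("training data contains a single class")
    if counts.min() < 50:
        logger.warning("train_classifier: smallest class has %d examples "
                       "(< 50); model may be unstable", counts.min())

    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=1.0, class_weight="balanced",
                    random_state=seed)),
    ])

    cv_auc = float("nan")
    if counts.min() >= cv_folds:
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                             random_state=seed)
        cv_auc = float(np.mean(cross_val_score(
            model, features, labels, cv=cv, scoring="roc_auc")))
    model.fit(features, labels)
    return {
        "model": model,
        "feature_names": list(FEATURE_NAMES),
        "seed": seed,
        "cv_auc": cv_auc,
    }


def save_classifier(bundle: dict, path) -> None:
    import sklearn
    import joblib

    bundle = dict(bundle)
    bundle["sklearn_version"] = sklearn.__version__
    joblib.dump(bundle, path)


def load_classifier(path) -> dict:
    import joblib

    return joblib.load(path)


def classify_query(features: SignificanceFeatures, bundle: dict
                   ) -> tuple[bool, float]:
    """Deterministic SVM prediction plus the decision value for diagnostics."""
    vec = features.to_vector()
    if np.isnan(vec).any():
        bad = [n for n, v in zip(FEATURE_NAMES, vec) if np.isnan(v)]
        raise SignificanceError(f"feature(s) {bad} are NaN")
    if bundle["feature_names"] != list(FEATURE_NAMES):
        raise SignificanceError("model was trained with a different feature "
                                "order")
    model = bundle["model"]
    pred = bool(model.predict(vec[None, :])[0])
    decision = float(model.decision_function(vec[None, :])[0])
    return pred, decision


# ---------------------------------------------------------------------------
# Final ctDNA call


@dataclass
class CtDNACall:
    tf_estimate: float
    svm_prediction: bool
    positive: bool
    llod_threshold: float = DEFAULT_LLOD_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "tf_estimate": self.tf_estimate,
            "svm_prediction": self.svm_prediction,
            "positive": self.positive,
            "llod_threshold": self.llod_threshold,
        }


def call_ctdna(tf_estimate: float, svm_prediction: bool,
               threshold: float = DEFAULT_LLOD_THRESHOLD) -> CtDNACall:
    """ctDNA positive iff TF estimate >= threshold AND the SVM predicts True."""
    if tf_estimate < 0:
        raise SignificanceError("tf_estimate must be >= 0")
    return CtDNACall(tf_estimate=tf_estimate,
                     svm_prediction=bool(svm_prediction),
                     positive=bool(tf_estimate >= threshold and svm_prediction),
                     llod_threshold=threshold)


def call_recurrence(calls: Sequence[CtDNACall],
                    times: Sequence[float] | None = None) -> int | None:
    """First follow-up index (0-based) flagged as molecular recurrence.

    Recurrence = the first time point (index >= 1) that is ctDNA positive
    AND has a TF estimate strictly greater than the preceding time point.
    Returns None when no time point qualifies.
    """
    if len(calls) < 2:
        raise SignificanceError("need at least two time points")
    if times is not None:
        t = np.asarray(times, dtype=float)
        if len(t) != len(calls) or (np.diff(t) <= 0).any():
            raise SignificanceError("timestamps must be strictly increasing "
                                    "and match the calls")
    for i in range(1, len(calls)):
        if calls[i].positive and calls[i].tf_estimate > calls[i - 1].tf_estimate:
            return i
    return None
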