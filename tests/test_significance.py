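"""Rank statistics, the p-value matrix, the SVM and the combined call."""

import numpy as np
import pytest

import cnfer as cf
from cnfer import CtDNACall, SignificanceError
from cnfer.significance import FEATURE_NAMES
from conftest import profile_from_deviation, segset_from_values


def make_query_and_segments(seg_values, bins_per_seg, sigma, seed,
                            ref_values=None):
    """Deviation profile with per-segment levels plus Gaussian bin noise."""
    rng = np.random.default_rng(seed)
    dev = np.concatenate([
        rng.normal(level, sigma, bins_per_seg) for level in seg_values])
    segs = segset_from_values(
        ref_values if ref_values is not None else list(seg_values),
        list(seg_values), n_bins=bins_per_seg)
    return profile_from_deviation(dev), segs


class TestKendall:
    def test_perfect_and_inverted_correlation(self):
        segs = segset_from_values([-0.2, 0.0, 0.1, 0.4], [-0.2, 0.0, 0.1, 0.4])
        tau, p = cf.kendall_segments(segs)
        assert tau == pytest.approx(1.0)
        anti = segset_from_values([-0.2, 0.0, 0.1, 0.4],
                                  [0.2, 0.0, -0.1, -0.4])
        tau, _ = cf.kendall_segments(anti)
        assert tau == pytest.approx(-1.0)

    def test_brute_force_pair_count_value(self):
        # query order (1,3,2,4) against ref ranks (1,2,3,4):
        # 5 concordant, 1 discordant pair -> tau = 4/6
        segs = segset_from_values([0.1, 0.2, 0.3, 0.4], [1.0, 3.0, 2.0, 4.0])
        tau, _ = cf.kendall_segments(segs)
        assert tau == pytest.approx(2.0 / 3.0)

    def test_matches_brute_force_on_small_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            S = int(rng.integers(4, 9))
            ref, qry = rng.normal(0, 1, S), rng.normal(0, 1, S)
            segs = segset_from_values(list(ref), list(qry))
            tau, _ = cf.kendall_segments(segs)
            conc = disc = 0
            for i in range(S):
                for j in range(i):
                    s = np.sign(ref[i] - ref[j]) * np.sign(qry[i] - qry[j])
                    conc += s > 0
                    disc += s < 0
            assert tau == pytest.approx((conc - disc) / (S * (S - 1) / 2))

    def test_too_few_segments_error(self):
        segs = segset_from_values([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        with pytest.raises(SignificanceError, match="too few"):
            cf.kendall_segments(segs)


class TestDunnMatrix:
    def test_sidak_identity_and_bounds(self):
        query, segs = make_query_and_segments([0.0, 0.1, -0.1, 0.3], 50,
                                              0.05, seed=1)
        mat = cf.dunn_pvalue_matrix(query, segs)
        ii, jj = np.tril_indices(4, k=-1)
        m = 4 * 3 // 2
        assert np.allclose(mat.p_adj[ii, jj],
                           1 - (1 - mat.p_raw[ii, jj]) ** m)
        assert (mat.p_adj[ii, jj] >= mat.p_raw[ii, jj]).all()
        assert (mat.p_adj[ii, jj] > 0).all() and (mat.p_adj[ii, jj] <= 1).all()
        assert np.isnan(np.diag(mat.p_adj)).all()

    def test_identical_segments_give_p_one(self):
        dev = np.tile(np.linspace(-1, 1, 30), 4)
        segs = segset_from_values([0.0, 0.1, 0.2, 0.3], [0.0] * 4, n_bins=30)
        mat = cf.dunn_pvalue_matrix(profile_from_deviation(dev), segs)
        ii, jj = np.tril_indices(4, k=-1)
        assert np.allclose(mat.p_adj[ii, jj], 1.0)

    def test_separated_segments_highly_significant(self):
        query, segs = make_query_and_segments([0.0, 0.3, 0.0, 0.3], 100,
                                              0.05, seed=2,
                                              ref_values=[0.0, 0.1, 0.2, 0.3])
        mat = cf.dunn_pvalue_matrix(query, segs)
        assert mat.p_adj[1, 0] < 1e-6
        # permutation oracle agrees that the difference is significant
        rng = np.random.default_rng(3)
        a = query.deviation[:100]
        b = query.deviation[100:200]
        observed = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        perm = sum(
            abs((p := rng.permutation(pooled))[:100].mean()
                - p[100:].mean()) >= observed
            for _ in range(1000))
        assert perm / 1000 < 0.01

    def test_null_false_positive_rate_controlled(self):
        rng = np.random.default_rng(4)
        hits = 0
        n_sims = 500
        segs = segset_from_values([0.0, 0.1], [0.0, 0.0], n_bins=200)
        for _ in range(n_sims):
            dev = rng.normal(0, 0.05, 400)   # both segments from one dist.
            mat = cf.dunn_pvalue_matrix(profile_from_deviation(dev), segs)
            hits += mat.p_adj[1, 0] < 0.05
        # nominal level plus three binomial standard errors of Monte Carlo
        assert hits / n_sims <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_sims)

    def test_matrix_invariant_to_segment_input_order(self):
        query, segs = make_query_and_segments([0.2, -0.1, 0.0, 0.4], 40,
                                              0.05, seed=5)
        mat1 = cf.dunn_pvalue_matrix(query, segs)
        shuffled = cf.rank_segments(cf.SegmentSet(
            segments=segs.segments.iloc[[2, 0, 3, 1]].reset_index(drop=True),
            n_bins_total=segs.n_bins_total))
        mat2 = cf.dunn_pvalue_matrix(query, shuffled)
        assert np.allclose(mat1.p_adj[np.tril_indices(4, -1)],
                           mat2.p_adj[np.tril_indices(4, -1)])


class TestSections:
    def test_section_sizes_for_four_segments(self):
        query, segs = make_query_and_segments([0.0, 0.1, 0.2, 0.3], 30,
                                              0.05, seed=6)
        mat = cf.dunn_pvalue_matrix(query, segs)
        sections = mat.section_values()
        assert len(sections["upper_subtriangle"]) == 1
        assert len(sections["lower_subtriangle"]) == 1
        assert len(sections["square"]) == 4

    def test_all_equal_entries_no_separation(self):
        dev = np.tile(np.linspace(-1, 1, 30), 4)
        segs = segset_from_values([0.0, 0.1, 0.2, 0.3], [0.0] * 4, n_bins=30)
        feats = cf.extract_features(profile_from_deviation(dev), segs)
        assert feats.med_p_upper == feats.med_p_lower == feats.med_p_square
        assert feats.p_upper_vs_lower == pytest.approx(1.0)

    def test_ctdna_positive_pattern_in_sections(self, sim_grid, truth):
        from conftest import make_profile
        ref = make_profile(truth, sim_grid, tf=1.0, depth=1.0, seed=50)
        segs = cf.segment_reference(ref, sim_grid)
        qry = make_profile(truth, sim_grid, tf=0.05, depth=1.0, seed=51)
        segs = cf.rank_segments(cf.project_segments(segs, qry))
        feats = cf.extract_features(qry, segs)
        # cross-half (low vs high copy) comparisons are the significant ones
        assert feats.med_p_square <= feats.med_p_upper
        assert feats.p_upper_vs_square < 1e-6
        assert feats.tau > 0.2 and feats.tau_p < 1e-6

    def test_feature_extraction_is_bit_stable(self):
        query, segs = make_query_and_segments([0.0, 0.1, -0.2, 0.3, 0.05],
                                              60, 0.05, seed=7)
        f1 = cf.extract_features(query, segs).to_vector()
        f2 = cf.extract_features(query, segs).to_vector()
        assert (f1 == f2).all()


class TestClassifier:
    @staticmethod
    def _toy_features(n, separation, seed):
        rng = np.random.default_rng(seed)
        X0 = rng.normal(0, 1, (n, len(FEATURE_NAMES)))
        X1 = rng.normal(separation, 1, (n, len(FEATURE_NAMES)))
        X = np.vstack([X0, X1])
        y = np.concatenate([np.zeros(n), np.ones(n)])
        return X, y

    def test_separable_classes_high_cv_auc(self):
        X, y = self._toy_features(100, 2.0, seed=0)
        bundle = cf.train_classifier(X, y, seed=0)
        assert bundle["cv_auc"] > 0.95

    def test_shuffled_labels_chance_auc(self):
        X, y = self._toy_features(250, 2.0, seed=1)
        rng = np.random.default_rng(2)
        bundle = cf.train_classifier(X, rng.permutation(y), seed=0)
        assert bundle["cv_auc"] == pytest.approx(0.5, abs=0.1)

    def test_duplicated_pair_trains_and_separates(self):
        X = np.vstack([np.tile([0.0] * 8, (100, 1)),
                       np.tile([1.0] * 8, (100, 1))])
        y = np.concatenate([np.zeros(100), np.ones(100)])
        bundle = cf.train_classifier(X, y, seed=0)
        assert (bundle["model"].predict(X) == y).all()

    def test_single_class_is_an_error(self):
        X = np.zeros((100, 8))
        with pytest.raises(SignificanceError, match="single class"):
            cf.train_classifier(X, np.ones(100), seed=0)

    def test_classify_deterministic_and_nan_guard(self):
        X, y = self._toy_features(100, 2.0, seed=3)
        bundle = cf.train_classifier(X, y, seed=0)
        feats = cf.SignificanceFeatures(*X[5])
        assert cf.classify_query(feats, bundle) == \
            cf.classify_query(feats, bundle)
        bad = cf.SignificanceFeatures(*([0.1] * 7 + [np.nan]))
        with pytest.raises(SignificanceError, match="p_upper_vs_lower"):
            cf.classify_query(bad, bundle)

    def test_model_round_trip(self, tmp_path):
        X, y = self._toy_features(60, 2.0, seed=4)
        bundle = cf.train_classifier(X, y, seed=0)
        cf.save_classifier(bundle, tmp_path / "model.joblib")
        loaded = cf.load_classifier(tmp_path / "model.joblib")
        feats = cf.SignificanceFeatures(*X[3])
        assert cf.classify_query(feats, loaded) == \
            cf.classify_query(feats, bundle)


class TestCalls:
    @pytest.mark.parametrize("tf,svm,positive", [
        (0.0025, True, True),
        (0.005, False, False),
        (0.0019, True, False),
        (0.002, True, True),     # threshold is inclusive
    ])
    def test_combined_positivity_rule(self, tf, svm, positive):
        call = cf.call_ctdna(tf, svm)
        assert call.positive is positive
        assert call.positive == (call.tf_estimate >= call.llod_threshold
                                 and call.svm_prediction)

    def test_recurrence_first_rising_positive(self):
        neg = lambda tf: CtDNACall(tf, False, False)
        pos = lambda tf: CtDNACall(tf, True, True)
        assert cf.call_recurrence([neg(0.0), pos(0.004), pos(0.01)]) == 1
        assert cf.call_recurrence([neg(0.0), neg(0.0), neg(0.0)]) is None
        # positive throughout: the first INCREASE after a preceding point
        assert cf.call_recurrence([pos(0.01), pos(0.005), pos(0.02)]) == 2

    def test_recurrence_input_validation(self):
        pos = CtDNACall(0.01, True, True)
        with pytest.raises(SignificanceError):
            cf.call_recurrence([pos])
        with pytest.raises(SignificanceError, match="increasing"):
            cf.call_recurrence([pos, pos], times=[2.0, 1.0])
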