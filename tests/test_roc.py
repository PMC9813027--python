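"""Empirical ROC/AUC: scores, operating points, tie handling, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mrmcroc as m
from mrmcroc.roc import ScoreVector, empirical_roc, pom_score, birads_score

from conftest import brute_force_auc, make_rating


def sv(scores, labels, **kw):
    return ScoreVector(case_ids=[f"c{i}" for i in range(len(scores))],
                       scores=np.asarray(scores, float),
                       labels=np.asarray(labels, int), **kw)


class TestScores:
    def test_pom_passthrough_for_suspicious_scores(self):
        assert pom_score(make_rating("c", "r", "DM", 4, pom=65)) == 65.0

    def test_negative_categories_rank_below_any_pom(self):
        s1 = pom_score(make_rating("c", "r", "DM", 1))
        s2 = pom_score(make_rating("c", "r", "DM", 2))
        s3 = pom_score(make_rating("c", "r", "DM", 3, pom=0))
        assert s1 == -2.0 and s2 == -1.0
        assert s1 < s2 < s3 == 0.0

    def test_pooled_variant_collapses_birads_1_and_2(self):
        s1 = pom_score(make_rating("c", "r", "DM", 1), distinguish_birads12=False)
        s2 = pom_score(make_rating("c", "r", "DM", 2), distinguish_birads12=False)
        assert s1 == s2

    def test_birads_score_is_the_ordinal_category(self):
        assert birads_score(make_rating("c", "r", "DM", 5, pom=90)) == 5.0
        assert birads_score(make_rating("c", "r", "DM", 1)) == 1.0

    def test_five_level_scale_gives_at_most_four_interior_points(self):
        scores = [1, 2, 3, 4, 5, 5, 3, 1, 2, 4]
        labels = [0, 0, 0, 1, 1, 1, 1, 0, 0, 1]
        roc = empirical_roc(sv(scores, labels, score_type="birads"))
        interior = [(f, t) for f, t in roc.operating_points
                    if (f, t) not in ((0.0, 0.0), (1.0, 1.0))]
        assert len(interior) <= 4


class TestEmpiricalRoc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.7, 0.3], [1, 1, 0, 0], 1.0),   # perfect separation
        ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),   # all tied
        ([0.9, 0.7, 0.8, 0.3], [1, 1, 0, 0], 0.75),  # 3 wins of 4 pairs
    ])
    def test_reference_values(self, scores, labels, expected):
        assert empirical_roc(sv(scores, labels)).auc == pytest.approx(expected)

    def test_single_class_input_raises(self):
        with pytest.raises(ValueError):
            empirical_roc(sv([1.0, 2.0], [1, 1]))

    def test_curve_is_monotone_and_anchored(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 6, size=40).astype(float)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        roc = empirical_roc(sv(scores, labels))
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert roc.operating_points[0] == (0.0, 0.0)
        assert roc.operating_points[-1] == (1.0, 1.0)

    def test_trapezoid_equals_pair_statistic_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(3, 25)
            scores = rng.integers(0, 5, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert empirical_roc(sv(scores, labels)).auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)


@st.composite
def score_instances(draw):
    n = draw(st.integers(min_value=2, max_value=30))
    scores = draw(st.lists(st.integers(min_value=-3, max_value=3),
                           min_size=n, max_size=n))
    n_pos = draw(st.integers(min_value=1, max_value=n - 1))
    labels = [1] * n_pos + [0] * (n - n_pos)
    return np.array(scores, float), np.array(labels)


class TestInvariances:
    @given(score_instances())
    def test_auc_invariant_under_strictly_increasing_transform(self, inst):
        scores, labels = inst
        base = empirical_roc(sv(scores, labels)).auc
        for f in (lambda x: 3 * x + 7, np.exp, lambda x: x ** 3):
            assert empirical_roc(sv(f(scores), labels)).auc == pytest.approx(
                base, abs=1e-12)

    @given(score_instances())
    def test_label_reversal_maps_auc_to_complement(self, inst):
        scores, labels = inst
        a = empirical_roc(sv(scores, labels)).auc
        b = empirical_roc(sv(scores, 1 - labels)).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    @given(score_instances(), st.integers(min_value=-3, max_value=3))
    def test_appended_tied_pair_receives_exactly_half_credit(self, inst, t):
        # one positive and one negative at the same score t contribute 0.5
        # to the pair count; cross-pairs with existing cases count as usual
        scores, labels = inst
        pos, neg = scores[labels == 1], scores[labels == 0]
        num_old = brute_force_auc(scores, labels) * len(pos) * len(neg)
        cross = (np.sum(t > neg) + 0.5 * np.sum(t == neg)
                 + np.sum(pos > t) + 0.5 * np.sum(pos == t))
        expected = (num_old + cross + 0.5) / ((len(pos) + 1) * (len(neg) + 1))
        scores2 = np.concatenate([scores, [t, t]]).astype(float)
        labels2 = np.concatenate([labels, [1, 0]])
        roc = empirical_roc(sv(scores2, labels2))
        assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_pure_tie_instance_moves_statistic_toward_half(self):
        # appending the tied pair at the common score is a convex pull to 0.5
        scores = np.array([2.0, 2.0, 2.0, 2.0])
        labels = np.array([1, 1, 0, 0])
        grown_s, grown_l = scores, labels
        prev = brute_force_auc(grown_s, grown_l)
        for _ in range(3):
            grown_s = np.concatenate([grown_s, [2.0, 2.0]])
            grown_l = np.concatenate([grown_l, [1, 0]])
            cur = brute_force_auc(grown_s, grown_l)
            assert abs(cur - 0.5) <= abs(prev - 0.5) + 1e-12
            prev = cur


class TestReaderAucTable:
    def test_mean_is_unweighted_average(self, tiny_dataset):
        aucs, mean = m.reader_auc_table(tiny_dataset, "DM", "pom")
        assert set(aucs) == {"R1", "R2"}
        assert mean == pytest.approx(np.mean(list(aucs.values())))

    def test_perfect_readers_reach_auc_one(self):
        cfg = m.SimConfig.with_composition(
            4, 4, 12, n_patients=10, modes=("DM",),
            mu_override={"DM": 60.0}, var_reader=0.0, var_case=0.0,
            var_interaction=0.0, var_resid=1e-8, benign_shift=0.0, seed=3)
        ds = m.generate_study(cfg)
        aucs, mean = m.reader_auc_table(ds, "DM", "pom")
        assert mean == 1.0 and all(a == 1.0 for a in aucs.values())

    def test_roc_points_frame_has_threshold_column(self, tiny_dataset):
        wide, labels = m.roc.mode_score_frame(tiny_dataset, "DM", "pom")
        roc = empirical_roc(sv(wide.iloc[0].to_numpy(), labels))
        frame = m.roc_points_frame(roc)
        assert list(frame.columns) == ["fpr", "tpr", "threshold"]
        assert len(frame) == len(roc.fpr)
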