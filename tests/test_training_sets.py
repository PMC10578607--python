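"""Curation rules, response entropy, confidence selection, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import glyphcurate as gc
from glyphcurate.rt_analysis import InstanceScore
from glyphcurate.training_sets import (
    VARIANTS_PER_IMAGE,
    CurationError,
    ResponseDistribution,
    ValidationError,
    augment,
)


def _score(iid, cls, p, direction, n_zero=0, n_part=30, mean_rank=10.0):
    return InstanceScore(instance_id=iid, class_label=cls, mean_rank=mean_rank,
                         t_stat=-1.0 if direction == "easy" else 1.0,
                         p_value=p, direction=direction, mean_correct=1.5,
                         n_zero_correct=n_zero, n_participants=n_part)


class TestCurateExtreme:
    def test_sizes(self, instance_scores):
        good = gc.curate_extreme(instance_scores, 5, "good")
        bad = gc.curate_extreme(instance_scores, 5, "bad")
        assert len(good) == 20 and len(bad) == 20
        for s in (good, bad):
            assert all(len(m) == 5 for m in s.members.values())
        assert not set(good.all_ids()) & set(bad.all_ids())

    def test_never_correct_candidate_excluded(self):
        scores = ([_score(f"e{k}", 0, 0.001 * (k + 1), "easy") for k in range(6)]
                  + [_score("never", 0, 1e-9, "easy", n_zero=30)])
        good = gc.curate_extreme(scores, 5, "good")
        assert "never" not in good.all_ids()
        assert len(good.members[0]) == 5

    def test_argmin_p_per_class(self):
        scores = []
        for cls in range(4):
            scores.append(_score(f"best{cls}", cls, 1e-6, "easy"))
            scores.extend(_score(f"c{cls}_{k}", cls, 0.2 + 0.1 * k, "easy")
                          for k in range(3))
        good = gc.curate_extreme(scores, 1, "good")
        assert good.all_ids() == [f"best{c}" for c in range(4)]

    def test_insufficient_candidates_raises(self):
        scores = [_score("a", 0, 0.01, "easy")]
        with pytest.raises(CurationError, match="class 0"):
            gc.curate_extreme(scores, 5, "good")

    def test_good_set_more_typical_than_bad(self, instance_scores, instance_map):
        good = gc.curate_extreme(instance_scores, 5, "good")
        bad = gc.curate_extreme(instance_scores, 5, "bad")
        gt = np.mean([instance_map[i].typicality for i in good.all_ids()])
        bt = np.mean([instance_map[i].typicality for i in bad.all_ids()])
        assert gt > bt


class TestCurateRandom:
    def test_sizes_and_determinism(self, instances):
        a = gc.curate_random(instances, 5, seed=9)
        b = gc.curate_random(instances, 5, seed=9)
        assert len(a) == 20
        assert a.members == b.members

    def test_k_equal_to_class_size(self, instances):
        s = gc.curate_random(instances, 20, seed=1)
        by_class = {}
        for i in instances:
            by_class.setdefault(i.class_label, set()).add(i.instance_id)
        for cls, members in s.members.items():
            assert set(members) == by_class[cls]

    def test_k_too_large(self, instances):
        with pytest.raises(CurationError):
            gc.curate_random(instances, 21, seed=1)


class TestResponseEntropy:
    @pytest.mark.parametrize("counts, expected", [
        ((12, 0, 0, 0), 0.0),
        ((3, 3, 3, 3), np.log(4)),
    ])
    def test_known_values(self, counts, expected):
        assert gc.response_entropy(counts) == pytest.approx(expected)

    def test_matches_direct_evaluation(self):
        counts = (6, 2, 1, 1)
        p = np.array(counts) / 10
        expected = -sum(pi * np.log(pi) for pi in p if pi > 0)
        assert gc.response_entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            gc.response_entropy((3, -1, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=2, max_size=10).filter(sum))
    def test_entropy_bounds(self, counts):
        h = gc.response_entropy(counts)
        assert 0.0 <= h <= np.log(len(counts)) + 1e-12


class TestSelectByConfidence:
    def _dists(self, rng, n_per_class=6, k_classes=4):
        dists, labels = [], {}
        for cls in range(k_classes):
            for k in range(n_per_class):
                iid = f"c{cls}_{k}"
                counts = tuple(int(x) for x in rng.integers(0, 10, 4))
                if sum(counts) == 0:
                    counts = (1, 0, 0, 0)
                dists.append(ResponseDistribution(item_id=iid, counts=counts))
                labels[iid] = cls
        return dists, labels

    def test_zero_entropy_selected_first(self):
        dists = [ResponseDistribution("sure", (9, 0, 0, 0)),
                 ResponseDistribution("unsure", (3, 3, 2, 1)),
                 ResponseDistribution("also", (2, 2, 2, 3))]
        labels = {d.item_id: 0 for d in dists}
        sel = gc.select_by_confidence(dists, labels, 1, "high")
        assert sel.all_ids() == ["sure"]

    def test_large_selection_count(self):
        rng = np.random.default_rng(4)
        dists, labels = [], {}
        for cls in range(10):
            for k in range(150):
                iid = f"c{cls}_{k:03d}"
                dists.append(ResponseDistribution(
                    item_id=iid, counts=tuple(int(x) for x in
                                              rng.integers(1, 9, 10))))
                labels[iid] = cls
        sel = gc.select_by_confidence(dists, labels, 100, "high")
        assert len(sel) == 1000

    def test_matches_full_sort(self):
        rng = np.random.default_rng(11)
        dists, labels = self._dists(rng)
        for which, sign in (("high", 1), ("low", -1)):
            sel = gc.select_by_confidence(dists, labels, 3, which)
            for cls in range(4):
                pool = [d for d in dists if labels[d.item_id] == cls]
                pool.sort(key=lambda d: (sign * d.entropy, d.item_id))
                assert sel.members[cls] == [d.item_id for d in pool[:3]]


class TestAugment:
    @pytest.mark.parametrize("n_source, expected", [(20, 540), (320, 8640)])
    def test_counts(self, prototypes, n_source, expected):
        per_class = -(-n_source // 4)
        inst = gc.generate_instances(prototypes, per_class, 11.0,
                                     seed=1)[:n_source]
        aug = augment([(i.instance_id, i.class_label, i.pixels) for i in inst])
        assert len(aug) == expected
        assert len(aug) == VARIANTS_PER_IMAGE * n_source

    def test_identity_variant_present(self, instances):
        aug = augment([(i.instance_id, i.class_label, i.pixels)
                       for i in instances[:3]])
        for src in instances[:3]:
            ident = [it for it in aug.items
                     if it.parent_id == src.instance_id
                     and it.shift == (0, 0) and it.rotation == 0.0]
            assert len(ident) == 1
            assert np.array_equal(ident[0].pixels, src.pixels)

    def test_empty_image_invariant(self):
        aug = augment([("blank", 0, np.zeros((28, 28)))])
        assert len(aug) == 27
        for it in aug.items:
            assert not it.pixels.any()

    def test_shift_semantics(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        aug = augment([("dot", 0, img)])
        by_key = {(it.shift, it.rotation): it.pixels for it in aug.items}
        right = by_key[((1, 0), 0.0)]
        assert right[2, 3] == 1.0 and right.sum() == 1
        down = by_key[((0, 1), 0.0)]
        assert down[3, 2] == 1.0 and down.sum() == 1

    def test_border_content_dropped(self):
        img = np.zeros((4, 4))
        img[0, :] = 1.0
        aug = augment([("edge", 0, img)])
        up = {(it.shift, it.rotation): it.pixels
              for it in aug.items}[((0, -1), 0.0)]
        assert up.sum() == 0

    def test_nonbinary_rejected_when_binarize_off(self):
        img = np.full((4, 4), 0.4)
        with pytest.raises(Exception, match="non-binary"):
            augment([("gray", 0, img)], binarize=False)
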