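"""Representation pipeline: ranking, importance weights, feature maps,
sorted flattening, and the aggregated slide matrix."""

import numpy as np
import pytest

from hipomap.cohort import Patch, Slide
from hipomap.core import (build_hipomap, class_feature_map, compute_importance,
                          patch_representation, rank_top_k, slide_to_hipomap,
                          load_hipomap, save_hipomap)
from hipomap.scoring import ActivationBundle, PatchScore


def _scores(probs, acts=None):
    acts = acts if acts is not None else [0.0] * len(probs)
    return [PatchScore(i, p, a) for i, (p, a) in enumerate(zip(probs, acts))]


class TestRankTopK:
    def test_selects_highest_probabilities(self):
        assert rank_top_k(_scores([0.9, 0.1, 0.5]), 2) == [0, 2]

    def test_probability_ties_break_on_mean_activation(self):
        assert rank_top_k(_scores([0.5, 0.5], acts=[1.0, 2.0]), 1) == [1]

    def test_full_ties_break_on_patch_index(self):
        assert rank_top_k(_scores([0.5, 0.5], acts=[1.0, 1.0]), 2) == [0, 1]

    def test_k_of_at_least_n_orders_everything(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 12))
            probs = rng.choice([0.1, 0.5, 0.9], size=n)  # force ties
            acts = rng.choice([0.0, 1.0], size=n)
            scores = _scores(probs, acts)
            expected = [s.patch_index for s in
                        sorted(scores, key=lambda s: (-s.prob, -s.mean_activation,
                                                      s.patch_index))]
            assert rank_top_k(scores, n + 5) == expected
            assert rank_top_k(scores, 3) == expected[:3]

    def test_invalid_k(self):
        with pytest.raises(ValueError, match="K"):
            rank_top_k(_scores([0.5]), 0)


def _bundle(grads, acts=None):
    grads = np.asarray(grads, dtype=float)
    acts = np.asarray(acts, dtype=float) if acts is not None \
        else np.zeros_like(grads)
    return ActivationBundle(acts, grads, class_index=1)


class TestImportance:
    def test_sums_gradients_then_rectifies(self):
        alpha = compute_importance(_bundle(np.full((1, 2, 2), 0.5)))
        assert np.allclose(alpha.alpha, [2.0])

    def test_negative_map_sum_clamped_to_zero(self):
        grads = np.stack([np.full((2, 2), 0.25), np.full((2, 2), -0.75)])
        alpha = compute_importance(_bundle(grads))
        assert np.allclose(alpha.alpha, [1.0, 0.0])

    def test_average_variant_divides_by_map_area(self):
        alpha = compute_importance(_bundle(np.full((1, 2, 2), 0.5)), average=True)
        assert np.allclose(alpha.alpha, [0.5])


class TestClassFeatureMap:
    def test_alpha_selects_maps(self):
        bundle = _bundle(np.zeros((2, 2, 2)),
                         acts=np.stack([np.ones((2, 2)), np.eye(2)]))
        fmap = class_feature_map(compute_importance(_bundle(
            np.stack([np.full((2, 2), 0.25), np.full((2, 2), -1.0)]))), bundle)
        assert np.allclose(fmap.T, np.ones((2, 2)))

    def test_linear_combination(self):
        from hipomap.core import ImportanceVector
        acts = np.stack([np.eye(2), np.eye(2)])
        fmap = class_feature_map(ImportanceVector(np.array([2.0, 3.0])),
                                 _bundle(np.zeros((2, 2, 2)), acts))
        assert np.allclose(fmap.T, 5.0 * np.eye(2))

    def test_matches_explicit_double_loop(self):
        rng = np.random.default_rng(1)
        acts = rng.random((3, 4, 4))
        alpha = rng.random(3)
        from hipomap.core import ImportanceVector
        fmap = class_feature_map(ImportanceVector(alpha),
                                 _bundle(np.zeros((3, 4, 4)), acts))
        expected = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                for m in range(3):
                    expected[i, j] += alpha[m] * acts[m, i, j]
        assert np.allclose(fmap.T, expected)

    def test_length_mismatch_rejected(self):
        from hipomap.core import ImportanceVector
        with pytest.raises(ValueError, match="activation maps"):
            class_feature_map(ImportanceVector(np.ones(2)),
                              _bundle(np.zeros((3, 2, 2))))


class TestPatchRepresentation:
    def test_flatten_and_sort_descending(self):
        from hipomap.core import ClassFeatureMap
        rep = patch_representation(ClassFeatureMap(np.array([[3., 1.], [2., 4.]])))
        assert np.allclose(rep.F, [4, 3, 2, 1])

    def test_constant_map(self):
        from hipomap.core import ClassFeatureMap
        rep = patch_representation(ClassFeatureMap(np.full((3, 3), 2.5)))
        assert np.allclose(rep.F, 2.5)

    def test_preserves_value_multiset(self):
        from hipomap.core import ClassFeatureMap
        rng = np.random.default_rng(2)
        T = rng.random((5, 7))
        rep = patch_representation(ClassFeatureMap(T))
        assert np.all(np.diff(rep.F) <= 0)
        assert np.allclose(np.sort(rep.F), np.sort(T.reshape(-1)))


def _rep(values):
    from hipomap.core import PatchRepresentation
    return PatchRepresentation(np.sort(np.asarray(values, float))[::-1])


class TestBuildHipoMap:
    def test_rows_sorted_by_descending_sum(self):
        hm = build_hipomap([_rep([1, 0]), _rep([5, 0]), _rep([3, 0])], 3)
        assert hm.row_patch_indices == [1, 2, 0]
        assert np.allclose(hm.X.sum(axis=1), [5, 3, 1])

    def test_zero_padding_below_data_rows(self):
        hm = build_hipomap([_rep([1, 1]), _rep([2, 2])], 4)
        assert hm.pad_count == 2
        assert hm.X.shape == (4, 2)
        assert np.allclose(hm.X[2:], 0)
        assert hm.row_patch_indices[2:] == [-1, -1]

    def test_row_sum_ties_keep_presort_order(self):
        hm = build_hipomap([_rep([2, 0]), _rep([1, 1])], 2,
                           patch_indices=[7, 3])
        assert hm.row_patch_indices == [7, 3]

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            build_hipomap([_rep([1, 0]), _rep([1, 0, 0])], 3)

    def test_too_many_representations_rejected(self):
        with pytest.raises(ValueError, match="K=1"):
            build_hipomap([_rep([1]), _rep([2])], 1)


class TestSlideToHipoMap:
    def test_single_patch_slide_pads_to_k(self, tiny_model):
        img = np.random.default_rng(3).random((32, 32, 3)).astype(np.float32)
        hm = slide_to_hipomap(Slide("one", [Patch(img, 0, 0)]), tiny_model, k=50)
        assert hm.X.shape == (50, 16)  # 32-px patches expose 4x4 maps
        assert hm.pad_count == 49

    def test_fixed_shape_and_nonnegative_for_any_slide(self, tiny_cohort,
                                                       tiny_model):
        _, slides = tiny_cohort
        for s in slides[:4]:
            hm = slide_to_hipomap(s, tiny_model, k=8)
            assert hm.X.shape == (8, 16)
            assert (hm.X >= 0).all()
            assert np.all(np.diff(hm.X.sum(axis=1)) <= 1e-6)
            data = hm.X[: 8 - hm.pad_count]
            assert np.all(np.diff(data, axis=1) <= 1e-6)

    def test_invariant_to_patch_order(self, tiny_cohort, tiny_model):
        _, slides = tiny_cohort
        s = slides[0]
        hm1 = slide_to_hipomap(s, tiny_model, k=6)
        perm = np.random.default_rng(4).permutation(s.n_patches)
        shuffled = Slide(s.slide_id,
                         [Patch(s.patches[i].image, s.patches[i].grid_row,
                                s.patches[i].grid_col) for i in perm],
                         label=s.label,
                         patch_truth=[s.patch_truth[i] for i in perm])
        hm2 = slide_to_hipomap(shuffled, tiny_model, k=6)
        assert np.allclose(hm1.X, hm2.X, atol=1e-5)

    def test_matches_stagewise_composition(self, tiny_cohort, tiny_model):
        """End-to-end result equals explicitly chaining the four stages."""
        from hipomap.scoring import activation_bundles, score_patches
        _, slides = tiny_cohort
        s = slides[1]
        k = 5
        hm = slide_to_hipomap(s, tiny_model, k=k)
        scores = score_patches(tiny_model, s, 1)
        selected = rank_top_k(scores, k)
        reps = []
        for idx in selected:
            bundle = activation_bundles(
                tiny_model, s.patch_array()[[idx]], 1)[0]
            alpha = compute_importance(bundle)
            reps.append(patch_representation(class_feature_map(alpha, bundle)))
        manual = build_hipomap(reps, k, patch_indices=selected)
        assert np.allclose(hm.X, manual.X, atol=1e-5)


def test_persistence_round_trip(tiny_cohort, tiny_model, tmp_path):
    _, slides = tiny_cohort
    hm = slide_to_hipomap(slides[0], tiny_model, k=8)
    save_hipomap(hm, tmp_path / "m1")
    back = load_hipomap(tmp_path / "m1")
    assert np.allclose(back.X, hm.X)
    assert back.pad_count == hm.pad_count
    assert back.row_patch_indices == hm.row_patch_indices
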