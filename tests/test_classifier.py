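"""Tests for the offline/online classification protocols."""

import numpy as np
import pytest

import spraymsm as sm
from spraymsm.exceptions import InvalidInputError, InvalidParameterError


class TestSplitFirstLastHalf:
    def test_even_split(self):
        tr, te = sm.split_first_last_half(np.arange(198))
        assert len(tr) == 99 and len(te) == 99

    def test_odd_split_floor_default_and_ceil_option(self):
        tr, te = sm.split_first_last_half(np.arange(107))
        assert (len(tr), len(te)) == (53, 54)
        tr, te = sm.split_first_last_half(np.arange(107), first="ceil")
        assert (len(tr), len(te)) == (54, 53)

    def test_two_item_boundary(self):
        tr, te = sm.split_first_last_half([1, 2])
        assert (list(tr), list(te)) == ([1], [2])

    def test_framestream_split_preserves_metadata(self):
        frames = [np.zeros((2, 2, 3), dtype=np.uint8)] * 5
        stream = sm.FrameStream.from_arrays(frames, label="spray")
        tr, te = sm.split_first_last_half(stream)
        assert (len(tr), len(te)) == (2, 3)
        assert tr.label == te.label == "spray"
        assert te.indices == (2, 3, 4)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            sm.split_first_last_half([1])


class TestTrainClassifier:
    def test_records_config_and_counts(self, separable_vectors):
        model = sm.train_classifier(separable_vectors, contribution=0.9)
        assert model.classes == ("spray", "non_spray")
        assert model.preprocessing["contribution"] == 0.9
        assert model.provenance["training_counts"] == {"spray": 200, "non_spray": 200}

    def test_undersized_category_names_the_culprit(self):
        good = np.random.default_rng(0).standard_normal((5, 8))
        with pytest.raises(InvalidInputError, match="bad_class"):
            sm.train_classifier({"ok": good, "bad_class": good[:1]})

    def test_duplicate_categories_have_unit_cosines(self, separable_vectors):
        x = separable_vectors["spray"]
        model = sm.train_classifier({"a": x, "b": x.copy()})
        cas = sm.canonical_cosines(model.subspace("a"), model.subspace("b"))
        np.testing.assert_allclose(cas.cosines, 1.0, atol=1e-10)

    def test_separable_classes_discriminate(self, separable_vectors):
        model = sm.train_classifier(separable_vectors)
        within = sm.msm_similarity(model.subspace("spray"), model.subspace("spray"))
        across = sm.msm_similarity(model.subspace("spray"), model.subspace("non_spray"))
        assert across < within

    def test_training_is_reproducible(self, separable_vectors, tmp_path):
        m1 = sm.train_classifier(separable_vectors)
        m2 = sm.train_classifier({k: v.copy() for k, v in separable_vectors.items()})
        sm.save_model(m1, tmp_path / "m1")
        sm.save_model(m2, tmp_path / "m2")
        assert (tmp_path / "m1.json").read_text() == (tmp_path / "m2.json").read_text()
        with np.load(tmp_path / "m1.npz") as a1, np.load(tmp_path / "m2.npz") as a2:
            for key in a1.files:
                np.testing.assert_array_equal(a1[key], a2[key])


@pytest.fixture(scope="module")
def model(separable_vectors):
    """Model trained on the first 100 frames of each separable category."""
    train = {k: v[:100] for k, v in separable_vectors.items()}
    return sm.train_classifier(train)


class TestClassifySet:
    def test_held_out_set_predicted_correctly(self, model, separable_vectors):
        res = sm.classify_set(separable_vectors["spray"][100:120], model)
        assert res.predicted == "spray"
        assert res.similarities["spray"] > res.similarities["non_spray"]

    def test_training_set_is_self_consistent(self, model, separable_vectors):
        res = sm.classify_set(separable_vectors["non_spray"][:100], model)
        assert res.similarities["non_spray"] >= res.similarities["spray"]

    def test_argmax_consistency(self, model, separable_vectors):
        res = sm.classify_set(separable_vectors["spray"][120:140], model)
        assert res.predicted == max(res.similarities, key=res.similarities.get)

    def test_single_vector_falls_back_to_pattern_angle(self, model, separable_vectors, caplog):
        import logging

        v = separable_vectors["spray"][150]
        with caplog.at_level(logging.INFO, logger="spraymsm.classifier"):
            res = sm.classify_set(v, model)
        assert res.predicted == "spray"
        assert any("single test vector" in r.message for r in caplog.records)
        # and it matches the pattern-angle similarity directly
        assert res.similarities["spray"] == pytest.approx(
            sm.sm_similarity(v, model.subspace("spray"))
        )

    def test_single_class_model_always_predicts_it(self, separable_vectors):
        model = sm.train_classifier({"spray": separable_vectors["spray"]})
        res = sm.classify_set(separable_vectors["non_spray"][:10], model)
        assert res.predicted == "spray"
        assert 0.0 <= res.similarities["spray"] <= 1.0

    def test_class_order_permutation_preserves_predictions(self, separable_vectors):
        train = {k: v[:100] for k, v in separable_vectors.items()}
        m_ab = sm.train_classifier(train)
        m_ba = sm.train_classifier(dict(reversed(list(train.items()))))
        for chunk in (separable_vectors["spray"][100:110], separable_vectors["non_spray"][100:110]):
            assert sm.classify_set(chunk, m_ab).predicted == sm.classify_set(chunk, m_ba).predicted

    def test_tie_broken_by_model_order(self, separable_vectors, caplog):
        import logging

        x = separable_vectors["spray"][:50]
        model = sm.train_classifier({"b_first": x, "a_second": x.copy()})
        with caplog.at_level(logging.INFO, logger="spraymsm.classifier"):
            res = sm.classify_set(x[:10], model)
        assert res.predicted == "b_first"
        assert any("tie" in r.message for r in caplog.records)

    def test_empty_input_rejected(self, model):
        with pytest.raises(InvalidInputError):
            sm.classify_set(np.empty((0, 64)), model)


class TestSlidingWindows:
    def test_window_arithmetic(self, rng):
        x = rng.standard_normal((10, 64))
        wins = sm.sliding_windows(x, w=4, stride=1)
        assert [w.start_index for w in wins] == list(range(7))
        assert all(w.vectors.shape == (4, 64) for w in wins)

    def test_exact_fit_single_window(self, rng):
        wins = sm.sliding_windows(rng.standard_normal((4, 64)), w=4)
        assert len(wins) == 1 and wins[0].start_index == 0

    def test_stride_two(self, rng):
        wins = sm.sliding_windows(rng.standard_normal((9, 64)), w=4, stride=2)
        assert [w.start_index for w in wins] == [0, 2, 4]

    def test_short_stream_yields_no_windows(self, rng):
        assert sm.sliding_windows(rng.standard_normal((3, 64)), w=4) == []

    def test_invalid_parameters(self, rng):
        with pytest.raises(InvalidParameterError):
            sm.sliding_windows(rng.standard_normal((5, 64)), w=0)


class TestOnlineClassify:
    def test_homogeneous_stream_all_one_label(self, model, separable_vectors):
        results, trace = sm.online_classify(separable_vectors["spray"][100:140], model)
        assert len(results) == 37
        assert all(r.predicted == "spray" for r in results)
        assert set(trace.columns) == {"window_start", "predicted", "spray", "non_spray"}

    def test_label_switch_near_segment_boundary(self, model, separable_vectors):
        a = separable_vectors["spray"][100:130]
        b = separable_vectors["non_spray"][100:130]
        results, _ = sm.online_classify(np.vstack([a, b]), model, w=4)
        for r in results:
            if r.window_start + 4 <= 30:
                assert r.predicted == "spray"
            elif r.window_start >= 30:
                assert r.predicted == "non_spray"
            # windows straddling the boundary are unconstrained

    def test_identical_frames_rank_one_window_is_handled(self, model):
        v = sm.crop_rows_template() * 255.0
        results, _ = sm.online_classify(np.tile(v, (4, 1)), model, w=4)
        assert len(results) == 1
        assert results[0].predicted == "spray"

    def test_agrees_with_classify_set(self, model, separable_vectors):
        chunk = separable_vectors["non_spray"][110:114]
        results, _ = sm.online_classify(chunk, model, w=4)
        direct = sm.classify_set(chunk, model)
        assert results[0].predicted == direct.predicted
        for c in model.classes:
            assert results[0].similarities[c] == pytest.approx(direct.similarities[c], abs=1e-12)

    def test_short_stream_is_empty_result(self, model, separable_vectors):
        results, trace = sm.online_classify(separable_vectors["spray"][:2], model)
        assert results == [] and trace.empty


class TestModelPersistence:
    def test_roundtrip(self, separable_vectors, tmp_path):
        model = sm.train_classifier(separable_vectors, contribution=0.9)
        sm.save_model(model, tmp_path / "model")
        loaded = sm.load_model(tmp_path / "model")
        assert loaded.classes == model.classes
        assert loaded.preprocessing == model.preprocessing
        for a, b in zip(loaded.subspaces, model.subspaces):
            np.testing.assert_array_equal(a.basis, b.basis)
            np.testing.assert_array_equal(a.eigenvalues, b.eigenvalues)
        # loaded model classifies identically
        chunk = separable_vectors["spray"][50:60]
        assert (
            sm.classify_set(chunk, loaded).similarities
            == sm.classify_set(chunk, model).similarities
        )


class TestOfflineProtocol:
    def test_noise_filtered_transition_stream_end_to_end(self):
        # full path: synthetic flight -> preprocessing -> noise removal -> online
        a, b = sm.default_two_class_params(seed=3, n_frames=40)
        train = {
            "spray": sm.vectorize_stream(sm.generate_scene_sequence(a)),
            "non_spray": sm.vectorize_stream(sm.generate_scene_sequence(b)),
        }
        model = sm.train_classifier(train)
        spec = sm.TransitionSpec(segments=((a, 20), (sm.NOISE, 6), (b, 20)), seed=8)
        stream, labels = sm.flight_transition_stream(spec)
        clean = sm.remove_noise_frames(stream, [lab == sm.NOISE for lab in labels])
        assert len(clean) == 40
        x = sm.vectorize_stream(clean)
        results, _ = sm.online_classify(x, model)
        kept_labels = [lab for lab in labels if lab != sm.NOISE]
        correct = total = 0
        for r in results:
            window_labels = set(kept_labels[r.window_start : r.window_start + 4])
            if len(window_labels) > 1:
                continue  # boundary window
            total += 1
            correct += r.predicted == window_labels.pop()
        assert total > 0 and correct / total >= 0.99

    def test_set_size_grouping_matches_per_image_on_separable_data(self, separable_vectors):
        _, per_image = sm.offline_protocol(separable_vectors)
        _, per_set = sm.offline_protocol(separable_vectors, set_size=4)
        assert len(per_image) == len(per_set) == 200
        acc_img = sm.accuracy(sm.confusion_from_results(per_image, "spray"))
        acc_set = sm.accuracy(sm.confusion_from_results(per_set, "spray"))
        assert acc_img == 100.0 and acc_set == 100.0
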