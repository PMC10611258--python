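"""Tile classifier: weak labelling, training contracts, inference."""

import numpy as np
import pytest

from somaxon.classifier import (TrainConfig, TrainedTileModel,
                                build_training_set, predict_tiles,
                                preprocess_tiles, tiles_for_image, train)
from somaxon.errors import ConfigurationError, TrainingError, UsageError
from somaxon.images import AreaImage
from somaxon.phenotypes import PhenotypeParams
from somaxon.simulate import generate_axon_image, generate_soma_image

from conftest import DAMAGED_PARAMS, HEALTHY_PARAMS, make_soma_images


def _blank_image(side, kind, compound="DMSO", split="train", image_id="blank"):
    return AreaImage(pixels=np.zeros((side, side), np.uint16), area_kind=kind,
                     compound=compound, split=split, image_id=image_id)


class TestBuildTrainingSet:
    def test_weak_labels_inherited_from_compound(self, label_map):
        imgs = (make_soma_images(HEALTHY_PARAMS, 1, 10, compound="DMSO") +
                make_soma_images(DAMAGED_PARAMS, 1, 20, compound="oxaliplatin"))
        ds = build_training_set(imgs, "soma", label_map)
        # 576^2 soma image -> 4 segments x 36 tiles = 144 tiles each
        assert len(ds) == 288
        assert ds.class_counts == {"negative": 144, "positive": 144}
        assert ds.manifest == [("DMSO", "", 1), ("oxaliplatin", "", 1)]

    def test_full_scale_axon_image_yields_16_tiles(self, label_map):
        img = _blank_image(2304, "axon")
        ds = build_training_set([img], "axon", label_map)
        assert len(ds) == 16
        assert ds.tile_side == 576

    def test_empty_collection_warns(self, label_map):
        with pytest.warns(UserWarning):
            ds = build_training_set([], "soma", label_map)
        assert len(ds) == 0

    def test_unknown_compound_rejected(self, label_map):
        img = _blank_image(576, "soma", compound="mystery")
        with pytest.raises(ConfigurationError):
            build_training_set([img], "soma", label_map)

    def test_wrong_split_rejected(self, label_map):
        img = _blank_image(576, "soma", split="test")
        with pytest.raises(UsageError):
            build_training_set([img], "soma", label_map)


class TestTraining:
    def test_single_class_rejected(self, label_map):
        imgs = make_soma_images(HEALTHY_PARAMS, 2, 50, compound="DMSO")
        ds = build_training_set(imgs, "soma", label_map)
        with pytest.raises(TrainingError):
            train(ds, seed=0)

    def test_separable_tiles_reach_high_heldout_accuracy(
            self, separable_dataset, separable_soma_model):
        """Damaged vs healthy tiles are classified almost perfectly.

        Separability is first established by an independent oracle: a
        logistic regression on tile mean intensity alone.
        """
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        ds = separable_dataset
        # oracle on the healthy vs damaged tile blocks (tiles appear in
        # image order: 6 healthy, 2 cell-free, 6 damaged images x 144 tiles)
        idx = np.r_[0:864, 1152:2016]
        X = ds.tiles[idx].reshape(len(idx), -1).mean(axis=1, keepdims=True)
        Xtr, Xte, ytr, yte = train_test_split(
            X, ds.labels[idx], test_size=0.2, random_state=0)
        oracle_acc = LogisticRegression().fit(Xtr, ytr).score(Xte, yte)
        assert oracle_acc >= 0.85  # mean intensity alone nearly separates

        assert separable_soma_model.val_accuracy >= 0.95

    def test_shuffled_labels_give_chance_accuracy(self, separable_dataset):
        """Permuting labels destroys the signal: held-out accuracy ~ 0.5."""
        ds = separable_dataset
        shuffled = type(ds)(tiles=ds.tiles,
                            labels=np.random.default_rng(0).permutation(ds.labels),
                            area_kind=ds.area_kind, tile_side=ds.tile_side,
                            manifest=ds.manifest)
        model = train(shuffled, seed=3, config=TrainConfig(epochs=3))
        assert model.val_accuracy == pytest.approx(0.5, abs=0.1)

    def test_training_is_seed_deterministic(self, label_map):
        imgs = (make_soma_images(HEALTHY_PARAMS, 1, 70, compound="DMSO") +
                make_soma_images(DAMAGED_PARAMS, 1, 80, compound="oxaliplatin"))
        ds = build_training_set(imgs, "soma", label_map)
        cfg = TrainConfig(epochs=2)
        m1 = train(ds, seed=11, config=cfg)
        m2 = train(ds, seed=11, config=cfg)
        s1, s2 = m1.net.state_dict(), m2.net.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)
        m3 = train(ds, seed=12, config=cfg)
        assert not all(np.array_equal(s1[k], m3.net.state_dict()[k]) for k in s1)


class TestInference:
    def test_one_prediction_per_tile_row_major(self, separable_soma_model):
        img = make_soma_images(DAMAGED_PARAMS, 1, 900)[0]
        seg = AreaImage(pixels=img.pixels[:288, :288], area_kind="soma",
                        image_id="seg")
        preds = predict_tiles(separable_soma_model, seg)
        assert len(preds) == 36
        assert (preds[0].origin_x, preds[0].origin_y) == (0, 0)
        assert (preds[1].origin_x, preds[1].origin_y) == (48, 0)
        for p in preds:
            assert p.positive_call == (
                p.positive_probability >= separable_soma_model.decision_threshold)

    def test_area_kind_mismatch_rejected(self, separable_soma_model):
        img = generate_axon_image(PhenotypeParams.from_severity(0, 0), 576, 576, 0)
        with pytest.raises(UsageError):
            predict_tiles(separable_soma_model, img)

    def test_background_image_scores_all_negative(self, separable_soma_model):
        """A cell-free field must not trigger positive tile calls."""
        img = generate_soma_image(HEALTHY_PARAMS, 576, 576, 5, n_somata=0)
        img.image_id = "background"
        preds = predict_tiles(separable_soma_model, img)
        assert all(p.positive_probability <
                   separable_soma_model.decision_threshold for p in preds)

    def test_inference_is_deterministic(self, separable_soma_model):
        img = make_soma_images(DAMAGED_PARAMS, 1, 901)[0]
        p1 = predict_tiles(separable_soma_model, img)
        p2 = predict_tiles(separable_soma_model, img)
        assert [p.positive_probability for p in p1] == \
               [p.positive_probability for p in p2]

    def test_serialization_round_trip(self, separable_soma_model, tmp_path):
        path = separable_soma_model.save(tmp_path / "model.npz")
        loaded = TrainedTileModel.load(path)
        assert loaded.area_kind == separable_soma_model.area_kind
        assert loaded.tile_side == separable_soma_model.tile_side
        assert loaded.training_manifest == separable_soma_model.training_manifest
        img = make_soma_images(HEALTHY_PARAMS, 1, 902)[0]
        seg = AreaImage(pixels=img.pixels[288:, 288:], area_kind="soma",
                        image_id="seg2")
        a = [p.positive_probability for p in predict_tiles(
            separable_soma_model, seg)]
        b = [p.positive_probability for p in predict_tiles(loaded, seg)]
        assert a == b


def test_large_severity_gap_separates_images_with_zero_overlap(
        separable_soma_model):
    """Image-level toxicity probabilities of healthy vs severity-1 fields
    do not overlap over 20 fresh test images per class."""
    from somaxon.scoring import score_image

    healthy = make_soma_images(HEALTHY_PARAMS, 20, 700, split="test")
    damaged = make_soma_images(DAMAGED_PARAMS, 20, 800, split="test",
                               compound="oxaliplatin")

    def image_percent(img):
        samples = score_image(separable_soma_model, img)
        return np.mean([s.percent_positive for s in samples])

    healthy_scores = [image_percent(i) for i in healthy]
    damaged_scores = [image_percent(i) for i in damaged]
    assert max(healthy_scores) < min(damaged_scores)


def test_preprocess_rejects_incompatible_tile_side():
    with pytest.raises(UsageError):
        preprocess_tiles(np.zeros((2, 50, 50), np.uint16), 48)


def test_tiles_for_image_soma_scheme_counts():
    img = _blank_image(576, "soma")
    assert len(tiles_for_image(img)) == 144  # 4 segments x 36
    img = _blank_image(576, "axon")
    assert len(tiles_for_image(img)) == 16
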