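import dataclasses

import numpy as np
import pytest

from octga import trainer as tr
from octga._nn import RMSprop, UNet, bce_with_logits

TINY = tr.TrainConfig(
    input_size=16,
    depth=2,
    base_filters=2,
    batch_size=8,
    samples_per_epoch=16,
    learning_rate=1e-2,
    early_stop_patience=3,
    max_epochs=4,
    seed=0,
)


def _tiny_items(n, rng, size=16):
    """Trivially learnable data: target is a bright square on dark background."""
    items = []
    for i in range(n):
        t = np.zeros((size, size))
        r, c = rng.integers(2, size - 6, 2)
        t[r : r + 4, c : c + 4] = 1.0
        img = 0.2 + 0.6 * t + rng.normal(0, 0.02, t.shape)
        items.append(tr.TrainItem(img.astype(np.float32), t, f"p{i:03d}"))
    return items


class TestPatientSplit:
    def test_ten_patients_eight_one_one(self):
        a = tr.patient_split([f"p{i}" for i in range(10)], seed=0)
        counts = {s: len(a.patients(s)) for s in ("train", "val", "test")}
        assert counts == {"train": 8, "val": 1, "test": 1}

    def test_timepoints_inherit_split(self):
        patients = [("p0", ["t0", "t1", "t2", "t3", "t4"]), ("p1", ["t0"]), ("p2", ["t0"])]
        a = tr.patient_split(patients, fractions=(0.4, 0.3, 0.3), seed=1)
        # a patient id maps to exactly one split; timepoints have no entry of their own
        assert set(a.assignment) == {"p0", "p1", "p2"}
        assert all(v in ("train", "val", "test") for v in a.assignment.values())

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(23)]
        assert tr.patient_split(ids, seed=9).assignment == tr.patient_split(ids, seed=9).assignment

    def test_grouping_and_fraction_invariants(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 80))
            ids = [f"p{i}" for i in range(n)]
            a = tr.patient_split(ids, seed=int(rng.integers(2**31)))
            assert sorted(a.assignment) == sorted(ids)  # every patient in exactly one split
            for frac, split in zip((0.8, 0.1, 0.1), ("train", "val", "test")):
                assert abs(len(a.patients(split)) - frac * n) <= 1

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            tr.patient_split(["p0", "p1"])


class TestBuildModel:
    def test_desk_output_shape_and_range(self):
        model = tr.build_model(TINY)
        x = np.random.default_rng(0).random((2, 16, 16, 1)).astype(np.float32)
        out = model.predict_proba(x)
        assert out.shape == (2, 16, 16, 1)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_paper_scale_parameter_count(self):
        model = tr.build_model(tr.PAPER_CONFIG)
        assert 1e7 <= model.n_params <= 3e7

    def test_first_step_deterministic(self):
        rng = np.random.default_rng(3)
        x = rng.random((4, 16, 16, 1)).astype(np.float32)
        y = (rng.random((4, 16, 16, 1)) > 0.5).astype(np.float32)
        losses = []
        for _ in range(2):
            m = tr.build_model(TINY)
            losses.append(m.train_step(x, y, RMSprop(1e-3)))
        assert losses[0] == losses[1]

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            UNet(input_size=20, depth=3, base=2, k=3)


class TestEarlyStopping:
    def test_strictly_decreasing_runs_to_max(self):
        losses = list(np.linspace(1.0, 0.1, 20))
        assert not any(tr.should_stop(losses[: i + 1], 7) for i in range(20))

    def test_flat_after_epoch_3_stops_at_10(self):
        losses = [1.0, 0.8, 0.5] + [0.5] * 20
        stop_at = next(i + 1 for i in range(len(losses)) if tr.should_stop(losses[: i + 1], 7))
        assert stop_at == 10

    def test_loop_obeys_rule_and_restores_best(self, rng):
        items = _tiny_items(12, rng)
        model = tr.build_model(TINY)
        cfg = dataclasses.replace(TINY, max_epochs=6, early_stop_patience=2)
        model, hist = tr.train(model, items[:8], items[8:], cfg, seed=1)
        assert hist.stopped_epoch <= 6
        assert hist.best_epoch <= hist.stopped_epoch
        # restored weights reproduce the best validation loss
        xv, yv = tr._prepare(items[8:], cfg.input_size)
        vl = tr._val_loss(model, xv, yv, cfg.batch_size)
        assert vl == pytest.approx(min(hist.val_loss), abs=1e-6)

    def test_training_reduces_loss_on_learnable_task(self, rng):
        items = _tiny_items(16, rng)
        model = tr.build_model(TINY)
        cfg = dataclasses.replace(TINY, max_epochs=8, samples_per_epoch=32)
        model, hist = tr.train(model, items[:12], items[12:], cfg, seed=2)
        assert min(hist.val_loss) < hist.val_loss[0]

    def test_empty_validation_rejected(self, rng):
        with pytest.raises(ValueError):
            tr.train(tr.build_model(TINY), _tiny_items(4, rng), [], TINY)

    def test_non_binary_target_rejected(self, rng):
        items = _tiny_items(4, rng)
        items[0] = tr.TrainItem(items[0].image, items[0].target * 0.5, "bad")
        with pytest.raises(ValueError):
            tr.train(tr.build_model(TINY), items[:3], items[3:], TINY)


class TestHardExampleMining:
    def test_all_ties_no_duplicates(self):
        items = list(range(10))
        f = np.full(10, 0.7)
        aug, thr = tr.augment_by_f_scores(items, f, np.arange(10), percentile=30)
        assert thr == pytest.approx(0.7)
        assert aug == items

    def test_ladder_matches_percentile_oracle(self):
        f = np.arange(100) / 100.0  # 0.00 .. 0.99
        items = list(range(100))
        aug, thr = tr.augment_by_f_scores(items, f, np.arange(100), percentile=30)
        expected_thr = np.percentile(f, 30)
        assert thr == pytest.approx(expected_thr)
        expected_dups = [i for i in items if f[i] < expected_thr]
        assert aug[:100] == items and aug[100:] == expected_dups

    def test_random_configs_counting_identity(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 60))
            f = np.round(rng.random(n), 2)
            k = int(rng.integers(1, n + 1))
            sample = rng.choice(n, size=k, replace=False)
            items = list(range(n))
            aug, thr = tr.augment_by_f_scores(items, f, sample, percentile=30)
            assert len(aug) == n + int(np.sum(f < thr))
            assert len(aug) <= 2 * n  # never removes, at most doubles
            assert aug[:n] == items  # originals retained, order stable

    def test_mining_with_model_counts_consistently(self, rng):
        items = _tiny_items(10, rng)
        model = tr.build_model(TINY)  # untrained is fine: any F profile works
        aug, thr = tr.mine_hard_examples(model, items, sample_n=10, seed=0)
        f = [
            tr.pixel_f_score(
                tr.binarize(tr.predict(model, it.image)), it.target.astype(bool)
            )
            for it in items
        ]
        assert len(aug) - len(items) == sum(v < thr for v in f)


class TestRetrain:
    def test_duplicates_sampled_twice_as_often(self, rng):
        # the epoch sampler draws uniformly over the item list, so a
        # duplicated item appears ~2x as often in expectation
        n = 20
        dup_ids = set(range(5))
        listing = list(range(n)) + [i for i in dup_ids]
        counts = np.zeros(n)
        g = np.random.default_rng(0)
        draws = 200 * 100
        idx = g.integers(0, len(listing), size=draws)
        for i in idx:
            counts[listing[i]] += 1
        base = draws / len(listing)
        assert np.allclose(counts[list(dup_ids)] / base, 2.0, rtol=0.1)
        assert np.allclose(counts[5:] / base, 1.0, rtol=0.15)

    def test_retrain_continues_from_given_weights(self, rng):
        items = _tiny_items(10, rng)
        model = tr.build_model(TINY)
        model, _ = tr.train(model, items[:7], items[7:], TINY, seed=3)
        w_before = model.get_weights()
        model2, _ = tr.retrain(model, items[:7], items[7:], dataclasses.replace(TINY, max_epochs=1), seed=4)
        assert any(not np.array_equal(a, b) for a, b in zip(w_before, model2.get_weights()))


class TestPredictAndBinarize:
    def test_binarize_threshold_semantics(self):
        conf = np.full((4, 4), 0.3)
        assert not tr.binarize(conf, 0.5).any()
        assert tr.binarize(conf, 0.2).all()

    def test_binarize_monotone_in_threshold(self, rng):
        conf = rng.random((8, 8))
        low = tr.binarize(conf, 0.3)
        high = tr.binarize(conf, 0.7)
        assert np.all(low[high])  # high-threshold positives subset of low's

    def test_predict_resizes_back_to_native_shape(self, rng):
        model = tr.build_model(TINY)
        img = rng.random((24, 24)).astype(np.float32)
        conf = tr.predict(model, img)
        assert conf.shape == (24, 24)
        assert conf.min() >= 0 and conf.max() <= 1

    def test_save_load_round_trip(self, rng, tmp_path):
        model = tr.build_model(TINY)
        path = tmp_path / "model.npz"
        tr.save_model(model, TINY, path)
        loaded, cfg = tr.load_model(path)
        x = rng.random((1, 16, 16, 1)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), loaded.predict_proba(x))


class TestDatasets:
    def test_enface_dataset_shapes_and_determinism(self):
        g = tr.DeviceGeometry(16, 16, 24)
        a = tr.make_enface_dataset(3, g, seed=5)
        b = tr.make_enface_dataset(3, g, seed=5)
        assert len(a) == 3
        for x, y in zip(a, b):
            assert x.image.shape == (16, 16) and x.target.shape == (16, 16)
            np.testing.assert_array_equal(x.image, y.image)
            np.testing.assert_array_equal(x.target, y.target)

    def test_bscan_dataset_pairs_bscans_with_masks(self):
        g = tr.DeviceGeometry(16, 16, 24)
        items = tr.make_bscan_dataset(1, g, seed=6)
        assert len(items) == 16
        for it in items:
            assert it.image.shape == (24, 16) and it.target.shape == (24, 16)
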