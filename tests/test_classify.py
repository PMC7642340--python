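import numpy as np
import pytest

from molbit.align import reverse_complement
from molbit.classify import (
    UNCLASSIFIED,
    ClassifierConfig,
    build_training_dataset,
    classify_signal,
    evaluate_classifier,
    label_fraction_in_set,
    label_read_by_alignment,
    load_classifier,
    save_classifier,
    train_classifier,
)
from molbit.squiggle import PreprocessConfig, Squiggle, simulate_squiggle

# a small, fast architecture for unit tests; the full-size default is
# exercised by the end-to-end acceptance suite
TINY = ClassifierConfig(
    n_classes=4,
    input_length=400,
    conv_blocks=((8, 7, 2), (16, 7, 2), (16, 7, 2), (32, 7, 2), (32, 7, 2)),
    fc_sizes=(64, 32),
    epochs=6,
    batch_size=16,
    seed=0,
)


@pytest.fixture(scope="module")
def tiny_dataset(pore_model):
    rng = np.random.default_rng(42)
    state_seqs = []
    from molbit.design import DesignConfig, init_barcodes

    state = init_barcodes(DesignConfig(n_barcodes=4), pore_model, "random", rng=17)
    reads = []
    for label, bc in enumerate(state.sequences):
        for _ in range(60):
            # fixed dwell keeps this fixture easy and fast; the harder
            # geometric-dwell task is covered by the end-to-end suite
            sq = simulate_squiggle(
                bc, pore_model, "noisy", "fixed", seed=int(rng.integers(2**31))
            )
            reads.append((sq.samples, label))
    return build_training_dataset(
        reads, TINY, preprocess=PreprocessConfig(truncate_to=400, fixed_skip=0), seed=0
    )


@pytest.fixture(scope="module")
def tiny_model(tiny_dataset):
    return train_classifier(tiny_dataset, TINY)


@pytest.fixture(scope="module")
def barcodes(barcode_state_8):
    return barcode_state_8.sequences


class TestLabeling:
    def test_embedded_barcode_is_found(self, barcodes):
        read = "TTAGGA" + barcodes[3] + "CCTTAA" * 30
        assert label_read_by_alignment(read, barcodes) == 3

    def test_reverse_oriented_read_is_found(self, barcodes):
        read = "TTAGGA" + reverse_complement(barcodes[5]) + "CCTTAA" * 30
        assert label_read_by_alignment(read, barcodes) == 5

    def test_random_read_unlabeled(self, barcodes, rng):
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 500))
        from molbit.align import sw_score

        scores = [
            max(
                sw_score(bc, read, (1, -1, -8), "semilocal"),
                sw_score(reverse_complement(bc), read, (1, -1, -8), "semilocal"),
            )
            for bc in barcodes
        ]
        assert max(scores) < 15  # fixture sanity, checked against the DP
        assert label_read_by_alignment(read, barcodes) is None

    def test_exact_tie_returns_none(self, barcodes):
        read = barcodes[0] + "TTTT" + barcodes[1]
        assert label_read_by_alignment(read, barcodes) is None

    def test_empty_barcode_set_rejected(self):
        with pytest.raises(ValueError):
            label_read_by_alignment("ACGT", [])

    def test_label_fraction_qc(self):
        labels = [0, 1, 2, None, 7, None]
        assert label_fraction_in_set(labels, {0, 1, 2, 3}) == pytest.approx(3 / 4)


class TestDatasetBuild:
    def test_per_class_cap_enforced(self, rng):
        sig = [Squiggle(rng.normal(0, 1, 50), normalized=True) for _ in range(120)]
        reads = [(s, 0) for s in sig] + [(s, 1) for s in sig[:40]]
        cfg = ClassifierConfig(n_classes=2, input_length=50)
        ds = build_training_dataset(reads, cfg, per_class_cap=50, seed=0)
        counts = np.bincount(np.concatenate([ds.y_train, ds.y_val]))
        assert counts[0] == 50 and counts[1] == 40

    def test_split_sizes_85_15(self, rng):
        reads = [
            (Squiggle(rng.normal(0, 1, 50), normalized=True), 0) for _ in range(100)
        ] + [(Squiggle(rng.normal(0, 1, 50), normalized=True), 1) for _ in range(100)]
        cfg = ClassifierConfig(n_classes=2, input_length=50)
        ds = build_training_dataset(reads, cfg, seed=0)
        assert len(ds.y_train) == 170 and len(ds.y_val) == 30

    def test_split_disjointness(self, rng):
        # fingerprint each read by a unique constant so rows are traceable
        reads = []
        for i in range(40):
            x = np.zeros(20)
            x[0] = i
            reads.append((Squiggle(x, normalized=True), i % 2))
        cfg = ClassifierConfig(n_classes=2, input_length=20)
        ds = build_training_dataset(reads, cfg, seed=0)
        train_ids = set(ds.X_train[:, 0].tolist())
        val_ids = set(ds.X_val[:, 0].tolist())
        assert train_ids.isdisjoint(val_ids)
        assert len(train_ids) + len(val_ids) == 40

    def test_zero_padding_to_input_length(self, rng):
        reads = [(Squiggle(rng.normal(0, 1, 30), normalized=True), 0),
                 (Squiggle(rng.normal(0, 1, 30), normalized=True), 1)]
        cfg = ClassifierConfig(n_classes=2, input_length=50)
        ds = build_training_dataset(reads, cfg, seed=0)
        X = np.concatenate([ds.X_train, ds.X_val])
        assert X.shape[1] == 50
        np.testing.assert_array_equal(X[:, 30:], 0)


class TestTraining:
    def test_validation_accuracy_on_synthetic_squiggles(self, tiny_model):
        assert tiny_model.history[-1]["val_acc"] >= 0.9

    def test_loss_decreases_over_first_epochs(self, tiny_model):
        losses = [h["train_loss"] for h in tiny_model.history[:3]]
        assert losses[2] < losses[0]

    def test_single_class_rejected(self, rng):
        reads = [(Squiggle(rng.normal(0, 1, 50), normalized=True), 0) for _ in range(20)]
        cfg = ClassifierConfig(n_classes=2, input_length=50)
        ds = build_training_dataset(reads, cfg, seed=0)
        with pytest.raises(ValueError):
            train_classifier(ds, cfg)

    def test_determinism_of_predictions(self, tiny_dataset):
        cfg = ClassifierConfig(**{**TINY.__dict__, "epochs": 1})
        a = train_classifier(tiny_dataset, cfg)
        b = train_classifier(tiny_dataset, cfg)
        np.testing.assert_array_equal(
            a.predict_proba(tiny_dataset.X_val), b.predict_proba(tiny_dataset.X_val)
        )


class TestClassifySignal:
    def test_probabilities_sum_to_one(self, tiny_model, tiny_dataset):
        res = classify_signal(tiny_model, tiny_dataset.X_val[0])
        assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_below_threshold_is_unclassified(self, tiny_model):
        # an all-zero signal carries no class evidence
        res = classify_signal(tiny_model, np.zeros(400))
        if res.confidence < tiny_model.config.confidence_threshold:
            assert res.molbit_id == UNCLASSIFIED
        strict = ClassifierConfig(**{**TINY.__dict__, "confidence_threshold": 1.0})
        res2 = classify_signal(tiny_model, np.zeros(400), strict)
        if res2.confidence < 1.0:
            assert res2.molbit_id == UNCLASSIFIED

    def test_training_example_classified_to_its_class(self, tiny_model, tiny_dataset):
        x = tiny_dataset.X_train[0]
        res = classify_signal(tiny_model, x)
        assert res.probabilities.argmax() == tiny_dataset.y_train[0]

    def test_empty_signal_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            classify_signal(tiny_model, np.array([]))

    def test_classified_fraction_monotone_in_threshold(self, tiny_model, tiny_dataset):
        probs = tiny_model.predict_proba(tiny_dataset.X_val)
        conf = probs.max(axis=1)
        fractions = [(conf >= t).mean() for t in (0.5, 0.9, 0.99)]
        assert fractions == sorted(fractions, reverse=True)


class TestEvaluate:
    def test_perfect_predictions(self, tiny_model, tiny_dataset):
        acc, confusion = evaluate_classifier(
            tiny_model, tiny_dataset.X_train[:40], tiny_model.predict_proba(
                tiny_dataset.X_train[:40]).argmax(axis=1))
        assert acc == 1.0
        assert np.all(confusion == np.diag(np.diag(confusion)))

    def test_row_sums_equal_class_counts(self, tiny_model, tiny_dataset):
        acc, confusion = evaluate_classifier(
            tiny_model, tiny_dataset.X_val, tiny_dataset.y_val
        )
        np.testing.assert_array_equal(
            confusion.sum(axis=1), np.bincount(tiny_dataset.y_val, minlength=4)
        )

    def test_accuracy_matches_recount_oracle(self, tiny_model, tiny_dataset):
        acc, _ = evaluate_classifier(tiny_model, tiny_dataset.X_val, tiny_dataset.y_val)
        pred = tiny_model.predict_proba(tiny_dataset.X_val).argmax(axis=1)
        recount = sum(int(p == t) for p, t in zip(pred, tiny_dataset.y_val))
        assert acc == pytest.approx(recount / len(pred))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tiny_model, tiny_dataset, tmp_path):
        save_classifier(tiny_model, tmp_path / "model")
        loaded = load_classifier(tmp_path / "model")
        np.testing.assert_array_equal(
            tiny_model.predict_proba(tiny_dataset.X_val),
            loaded.predict_proba(tiny_dataset.X_val),
        )
        assert loaded.class_ids == tiny_model.class_ids
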