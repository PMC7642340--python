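"""Raw-signal molbit classification.

Identifies which barcode generated a nanopore read directly from the
preprocessed current trace, skipping basecalling entirely: with a fixed
barcode vocabulary the problem is n-way signal classification, far easier
than sequence decoding. The model is a 5-block 1-D CNN (convolution ->
ReLU -> average pooling -> batch normalization), two fully connected
layers with 50% dropout, and a softmax output. A read is called only when
the softmax maximum reaches a confidence threshold (default 0.9);
everything below is left unclassified rather than guessed.

Supervised labels for real reads come from sequence space:
``label_read_by_alignment`` aligns every barcode (both orientations)
semilocally against a basecalled read and accepts the best scorer at or
above a score threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import reverse_complement, sw_score
from .nn import (
    Adam,
    AvgPool1D,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    ReLU,
    Sequential,
    cross_entropy,
    softmax,
)
from .squiggle import PreprocessConfig, Squiggle, preprocess_signal

UNCLASSIFIED = -1


@dataclass(frozen=True)
class ClassifierConfig:
    n_classes: int = 96
    input_length: int = 3000
    conv_blocks: tuple[tuple[int, int, int], ...] = (
        (16, 9, 3),
        (32, 9, 3),
        (64, 9, 3),
        (128, 9, 3),
        (256, 9, 3),
    )  # (channels, kernel, pool) per block
    fc_sizes: tuple[int, int] = (512, 256)
    dropout: float = 0.5
    confidence_threshold: float = 0.9
    epochs: int = 5
    batch_size: int = 32
    learning_rate: float = 2e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dropout < 1:
            raise ValueError("dropout must be in (0, 1)")
        if not 0 < self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in (0, 1]")


@dataclass
class ClassificationResult:
    molbit_id: int  # UNCLASSIFIED when below the confidence threshold
    confidence: float
    probabilities: np.ndarray


@dataclass
class TrainingDataset:
    X_train: np.ndarray  # (n, input_length) float32, zero-padded
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    class_ids: list[int]  # model index -> molbit id
    class_mask: np.ndarray  # True where the class had any reads
    per_class_cap: int = 6000
    provenance: tuple[str, ...] = ()


def label_read_by_alignment(
    basecall: str,
    barcodes: list[str],
    threshold: int = 15,
    params: tuple[int, int, int] = (1, -1, -8),
) -> int | None:
    """Label a basecalled read by semilocal alignment against all barcodes.

    Each barcode and its reverse complement is aligned end-to-end within
    the read with free end gaps. Returns the index of the unique best
    barcode with score >= threshold, or None (no hit, or an exact tie
    between distinct barcodes).
    """
    if not barcodes:
        raise ValueError("empty barcode set")
    if not basecall:
        raise ValueError("empty read sequence")
    scores = np.array(
        [
            max(
                sw_score(bc, basecall, params, "semilocal"),
                sw_score(reverse_complement(bc), basecall, params, "semilocal"),
            )
            for bc in barcodes
        ]
    )
    best = int(scores.max())
    if best < threshold:
        return None
    winners = np.flatnonzero(scores == best)
    if len(winners) > 1:
        return None
    return int(winners[0])


def label_fraction_in_set(labels: list[int | None], expected: set[int]) -> float:
    """QC metric: fraction of labeled reads whose label is in ``expected``."""
    hit = [lab for lab in labels if lab is not None]
    if not hit:
        return float("nan")
    return sum(lab in expected for lab in hit) / len(hit)


def _to_fixed_length(samples: np.ndarray, length: int) -> np.ndarray:
    out = np.zeros(length, dtype=np.float32)
    x = np.asarray(samples, dtype=np.float32)[:length]
    out[: len(x)] = x
    return out


def build_training_dataset(
    reads: list[tuple],
    config: ClassifierConfig,
    preprocess: PreprocessConfig | None = None,
    split_fraction: tuple[float, float] = (0.85, 0.15),
    per_class_cap: int = 6000,
    seed: int = 0,
) -> TrainingDataset:
    """Preprocess, balance and split labeled reads.

    ``reads`` is a list of (signal, label) where signal is a raw sample
    vector or a Squiggle (already-normalized Squiggles are used as-is).
    Each class is capped at ``per_class_cap`` reads (seeded downsample)
    and the result split stratified 85/15 into train/validation.
    """
    preprocess = preprocess or PreprocessConfig(truncate_to=config.input_length)
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[np.ndarray]] = {}
    for signal, label in reads:
        if isinstance(signal, Squiggle) and signal.normalized:
            x = signal.samples
        else:
            raw = signal.samples if isinstance(signal, Squiggle) else signal
            x = preprocess_signal(raw, preprocess).samples
        by_class.setdefault(int(label), []).append(
            _to_fixed_length(x, config.input_length)
        )
    class_ids = sorted(by_class)
    class_mask = np.array([len(by_class[c]) > 0 for c in class_ids])
    X_tr, y_tr, X_va, y_va = [], [], [], []
    for idx, cid in enumerate(class_ids):
        xs = by_class[cid]
        if len(xs) > per_class_cap:
            keep = rng.choice(len(xs), size=per_class_cap, replace=False)
            xs = [xs[i] for i in keep]
        order = rng.permutation(len(xs))
        n_val = int(round(split_fraction[1] * len(xs)))
        val_idx = set(order[:n_val].tolist())
        for i, x in enumerate(xs):
            if i in val_idx:
                X_va.append(x)
                y_va.append(idx)
            else:
                X_tr.append(x)
                y_tr.append(idx)
    return TrainingDataset(
        X_train=np.stack(X_tr) if X_tr else np.empty((0, config.input_length), np.float32),
        y_train=np.array(y_tr, dtype=np.int64),
        X_val=np.stack(X_va) if X_va else np.empty((0, config.input_length), np.float32),
        y_val=np.array(y_va, dtype=np.int64),
        class_ids=class_ids,
        class_mask=class_mask,
        per_class_cap=per_class_cap,
    )


def _build_net(config: ClassifierConfig, rng: np.random.Generator) -> Sequential:
    layers: list = []
    in_ch = 1
    length = config.input_length
    for channels, kernel, pool in config.conv_blocks:
        layers += [
            Conv1D(in_ch, channels, kernel, rng),
            ReLU(),
            AvgPool1D(pool),
            BatchNorm1D(channels),
        ]
        in_ch = channels
        length //= pool
    layers.append(Flatten())
    n_in = in_ch * length
    for size in config.fc_sizes:
        layers += [Dense(n_in, size, rng), ReLU(), Dropout(config.dropout, rng)]
        n_in = size
    layers.append(Dense(n_in, config.n_classes, rng))
    return Sequential(layers)


@dataclass
class TrainedClassifier:
    net: Sequential
    config: ClassifierConfig
    class_ids: list[int]
    history: list[dict] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        out = []
        for start in range(0, len(X), batch_size):
            batch = X[start : start + batch_size][:, None, :]
            out.append(softmax(self.net.forward(batch, train=False)))
        return np.concatenate(out, axis=0)


def train_classifier(
    dataset: TrainingDataset, config: ClassifierConfig
) -> TrainedClassifier:
    """Train the CNN; deterministic for a fixed config seed."""
    if len(dataset.X_train) == 0:
        raise ValueError("empty training dataset")
    if len(np.unique(dataset.y_train)) < 2:
        raise ValueError("training requires at least 2 classes")
    rng = np.random.default_rng(config.seed)
    net = _build_net(config, rng)
    opt = Adam(net.params, lr=config.learning_rate)
    clf = TrainedClassifier(net=net, config=config, class_ids=dataset.class_ids)
    n = len(dataset.X_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = dataset.X_train[idx][:, None, :]
            yb = dataset.y_train[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits = cross_entropy(logits, yb)
            net.backward(dlogits)
            opt.step(net.grads)
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        train_acc = correct / n
        val_acc = float("nan")
        if len(dataset.X_val):
            val_pred = clf.predict_proba(dataset.X_val).argmax(axis=1)
            val_acc = float((val_pred == dataset.y_val).mean())
        clf.history.append(
            {
                "epoch": epoch,
                "train_loss": total_loss / n,
                "train_acc": train_acc,
                "val_acc": val_acc,
            }
        )
    return clf


def classify_signal(
    model: TrainedClassifier,
    squiggle: Squiggle | np.ndarray,
    config: ClassifierConfig | None = None,
) -> ClassificationResult:
    """Classify one preprocessed squiggle; below-threshold calls are
    returned as UNCLASSIFIED."""
    config = config or model.config
    x = squiggle.samples if isinstance(squiggle, Squiggle) else np.asarray(squiggle)
    if x.size == 0:
        raise ValueError("empty signal")
    probs = model.predict_proba(_to_fixed_length(x, config.input_length))[0]
    conf = float(probs.max())
    if conf < config.confidence_threshold:
        mid = UNCLASSIFIED
    else:
        mid = model.class_ids[int(probs.argmax())]
    return ClassificationResult(molbit_id=mid, confidence=conf, probabilities=probs)


def evaluate_classifier(
    model: TrainedClassifier, X: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Accuracy and confusion matrix (rows: true class, cols: predicted)."""
    pred = model.predict_proba(X).argmax(axis=1)
    k = len(model.class_ids)
    confusion = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(y, pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion)) / max(len(y), 1)
    return accuracy, confusion


# ---------------------------------------------------------------------------
# checkpointing

def save_classifier(model: TrainedClassifier, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, p in enumerate(model.net.params):
        arrays[f"param_{i}"] = p
    bn = [lay for lay in model.net.layers if isinstance(lay, BatchNorm1D)]
    for i, lay in enumerate(bn):
        arrays[f"bn_{i}_mean"] = lay.running_mean
        arrays[f"bn_{i}_var"] = lay.running_var
    np.savez(directory / "weights.npz", **arrays)
    cfg = model.config.__dict__.copy()
    cfg["conv_blocks"] = [list(b) for b in model.config.conv_blocks]
    cfg["fc_sizes"] = list(model.config.fc_sizes)
    sidecar = {
        "config": cfg,
        "class_ids": model.class_ids,
        "history": model.history,
    }
    (directory / "classifier.json").write_text(json.dumps(sidecar, indent=1))


def load_classifier(directory) -> TrainedClassifier:
    directory = Path(directory)
    sidecar = json.loads((directory / "classifier.json").read_text())
    cfg = sidecar["config"]
    cfg["conv_blocks"] = tuple(tuple(b) for b in cfg["conv_blocks"])
    cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
    config = ClassifierConfig(**cfg)
    rng = np.random.default_rng(config.seed)
    net = _build_net(config, rng)
    with np.load(directory / "weights.npz") as data:
        for i, p in enumerate(net.params):
            p[...] = data[f"param_{i}"]
        bn = [lay for lay in net.layers if isinstance(lay, BatchNorm1D)]
        for i, lay in enumerate(bn):
            lay.running_mean[...] = data[f"bn_{i}_mean"]
            lay.running_var[...] = data[f"bn_{i}_var"]
    return TrainedClassifier(
        net=net,
        config=config,
        class_ids=list(sidecar["class_ids"]),
        history=list(sidecar["history"]),
    )
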