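"""Compact 1D-convolutional peptide classifiers.

Each classifier is a small fully seeded NumPy network:

    token embedding -> IntDropout -> Conv1D + ReLU -> Conv1D + ReLU
        -> global max pooling -> dropout -> dense softmax

trained with Adam on the sparse categorical cross-entropy, exactly the
regime used for the cascade's stages: the housekeeping (toxin vs non-toxin)
and four-class toxin models train for 24 epochs at batch size 32, the
insect–mammal functional models for 8 epochs at batch size 8, all with
learning rate 0.001 and dropout 0.35 on every dropout layer including
IntDropout.  Default layer sizes keep the trainable parameter count below
50,000 — the whole point of the approach is that networks this small
suffice for cysteine-scaffold classes.

Training is deterministic given the seed (single numeric backend assumed):
initialization, batch shuffling and both dropouts draw from one
``numpy.random.Generator``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import LabeledDataset
from .encoding import EncoderSpec, int_dropout, tokenize_batch
from .seq_io import SequenceRecord


@dataclass(frozen=True)
class TrainingSpec:
    """All numeric training hyperparameters in one auditable place."""

    learning_rate: float = 0.001
    dropout_rate: float = 0.35
    epochs: int = 24
    batch_size: int = 32
    seed: int = 0
    embed_dim: int = 16
    conv_filters: tuple[int, int] = (32, 32)
    kernel_size: int = 5
    use_int_dropout: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "dropout_rate": self.dropout_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
            "embed_dim": self.embed_dim,
            "conv_filters": list(self.conv_filters),
            "kernel_size": self.kernel_size,
            "use_int_dropout": self.use_int_dropout,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingSpec":
        d = dict(d)
        d["conv_filters"] = tuple(d["conv_filters"])
        return cls(**d)


#: Regime used for the three functional (insect/mammal) ensemble members.
FUNCTIONAL_TRAINING = TrainingSpec(epochs=8, batch_size=8)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int):
    """Valid 1D convolution. x: (B, L, Cin); w: (k*Cin, F); returns
    (y, windows) with y: (B, L-k+1, F)."""
    B, L, Cin = x.shape
    Lo = L - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B,Lo,Cin,k)
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, Lo, k * Cin)
    return win @ w + b, win


def _conv_backward(dy: np.ndarray, win: np.ndarray, w: np.ndarray,
                   x_shape: tuple, k: int):
    """Gradients of a valid 1D convolution."""
    B, L, Cin = x_shape
    Lo = L - k + 1
    F = w.shape[1]
    dw = win.reshape(-1, k * Cin).T @ dy.reshape(-1, F)
    db = dy.sum(axis=(0, 1))
    dwin = (dy @ w.T).reshape(B, Lo, k, Cin)
    dx = np.zeros(x_shape)
    for j in range(k):
        dx[:, j : j + Lo, :] += dwin[:, :, j, :]
    return dx, dw, db


class TrainedClassifier:
    """A (possibly still untrained) convolutional sequence classifier.

    Emits per-class probabilities over ``class_labels``; ``history`` records
    per-epoch training loss and validation accuracy once :func:`train` has
    run.
    """

    def __init__(
        self,
        encoder_spec: EncoderSpec,
        class_labels: Sequence[str],
        train_spec: TrainingSpec,
    ):
        if len(class_labels) < 2:
            raise ValueError("need at least 2 classes")
        min_len = 2 * (train_spec.kernel_size - 1) + 1
        if encoder_spec.fixed_length < min_len:
            raise ValueError(
                f"fixed_length {encoder_spec.fixed_length} too short for two "
                f"kernel-{train_spec.kernel_size} convolutions (min {min_len})"
            )
        self.encoder_spec = encoder_spec
        self.class_labels = list(class_labels)
        self.train_spec = train_spec
        self.history: list[dict] = []
        self.is_trained = False
        self._init_params(np.random.default_rng(train_spec.seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        V = self.encoder_spec.vocab_size
        d = self.train_spec.embed_dim
        F1, F2 = self.train_spec.conv_filters
        k = self.train_spec.kernel_size
        C = len(self.class_labels)

        def glorot(fan_in, fan_out, shape):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-limit, limit, size=shape)

        self.params = {
            "emb": rng.normal(0.0, 0.05, size=(V, d)),
            "w1": glorot(k * d, F1, (k * d, F1)),
            "b1": np.zeros(F1),
            "w2": glorot(k * F1, F2, (k * F1, F2)),
            "b2": np.zeros(F2),
            "wd": glorot(F2, C, (F2, C)),
            "bd": np.zeros(C),
        }

    @property
    def n_parameters(self) -> int:
        """Total trainable parameter count (contract: small, under 50k)."""
        return int(sum(p.size for p in self.params.values()))

    # ---------------------------------------------------------------- forward

    def _forward(self, tokens: np.ndarray, training: bool,
                 rng: np.random.Generator | None = None):
        spec = self.train_spec
        k = spec.kernel_size
        pad = self.encoder_spec.pad_index
        if training and spec.use_int_dropout:
            tokens = int_dropout(tokens, spec.dropout_rate, True, rng, pad)
        x = self.params["emb"][tokens]  # (B, L, d)
        z1, win1 = _conv_forward(x, self.params["w1"], self.params["b1"], k)
        h1 = np.maximum(z1, 0.0)
        z2, win2 = _conv_forward(h1, self.params["w2"], self.params["b2"], k)
        h2 = np.maximum(z2, 0.0)
        amax = h2.argmax(axis=1)  # (B, F2)
        pooled = np.take_along_axis(h2, amax[:, None, :], axis=1)[:, 0, :]
        drop_mask = None
        if training and spec.dropout_rate > 0:
            keep = 1.0 - spec.dropout_rate
            drop_mask = (rng.random(pooled.shape) < keep) / keep
            pooled = pooled * drop_mask
        logits = pooled @ self.params["wd"] + self.params["bd"]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = dict(tokens=tokens, x=x, win1=win1, z1=z1, h1=h1, win2=win2,
                     z2=z2, amax=amax, pooled=pooled, drop_mask=drop_mask)
        return probs, cache

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        spec = self.train_spec
        k = spec.kernel_size
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = {}
        grads["wd"] = cache["pooled"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dpooled = dlogits @ self.params["wd"].T
        if cache["drop_mask"] is not None:
            dpooled = dpooled * cache["drop_mask"]
        # un-pool: route gradient to the argmax position per filter
        dh2 = np.zeros_like(cache["z2"])
        np.put_along_axis(dh2, cache["amax"][:, None, :], dpooled[:, None, :], axis=1)
        dz2 = dh2 * (cache["z2"] > 0)
        dh1, grads["w2"], grads["b2"] = _conv_backward(
            dz2, cache["win2"], self.params["w2"], cache["h1"].shape, k
        )
        dz1 = dh1 * (cache["z1"] > 0)
        dx, grads["w1"], grads["b1"] = _conv_backward(
            dz1, cache["win1"], self.params["w1"], cache["x"].shape, k
        )
        demb = np.zeros_like(self.params["emb"])
        np.add.at(demb, cache["tokens"].reshape(-1),
                  dx.reshape(-1, dx.shape[-1]))
        grads["emb"] = demb
        return grads

    # ----------------------------------------------------------------- train

    def fit(self, train_set: LabeledDataset, val_set: LabeledDataset) -> "TrainedClassifier":
        """Train in place with Adam; returns self.

        Per epoch, records mean training loss and validation accuracy.
        Deterministic for a fixed ``train_spec.seed``.
        """
        if len(train_set) == 0:
            raise ValueError("empty training set")
        for ds in (train_set, val_set):
            extra = set(ds.labels) - set(self.class_labels)
            if extra:
                raise ValueError(f"labels outside classifier vocabulary: {sorted(extra)}")
        spec = self.train_spec
        rng = np.random.default_rng(spec.seed + 1)
        label_to_idx = {c: i for i, c in enumerate(self.class_labels)}
        Xtr = tokenize_batch([r.residues for r in train_set.records], self.encoder_spec)
        ytr = np.array([label_to_idx[l] for l in train_set.labels])
        Xva = tokenize_batch([r.residues for r in val_set.records], self.encoder_spec)
        yva = np.array([label_to_idx[l] for l in val_set.labels])

        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        step = 0
        n = len(ytr)
        self.history = []
        for epoch in range(spec.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                probs, cache = self._forward(Xtr[idx], training=True, rng=rng)
                loss = -np.mean(
                    np.log(probs[np.arange(len(idx)), ytr[idx]] + 1e-12)
                )
                losses.append(loss)
                grads = self._backward(probs, ytr[idx], cache)
                step += 1
                for key, g in grads.items():
                    m[key] = beta1 * m[key] + (1 - beta1) * g
                    v[key] = beta2 * v[key] + (1 - beta2) * g * g
                    mhat = m[key] / (1 - beta1**step)
                    vhat = v[key] / (1 - beta2**step)
                    self.params[key] -= spec.learning_rate * mhat / (
                        np.sqrt(vhat) + eps
                    )
            val_acc = float(np.mean(self._predict_tokens(Xva) == yva)) if len(yva) else float("nan")
            self.history.append(
                {"epoch": epoch + 1, "train_loss": float(np.mean(losses)),
                 "val_accuracy": val_acc}
            )
        self.is_trained = True
        return self

    # --------------------------------------------------------------- predict

    def _predict_tokens(self, tokens: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(tokens, training=False)
        return probs.argmax(axis=1)

    def predict_proba(self, records: Sequence[SequenceRecord]) -> np.ndarray:
        """Per-record probability vectors over ``class_labels`` (rows sum to 1)."""
        if not self.is_trained:
            raise RuntimeError("classifier has not been trained")
        if len(records) == 0:
            return np.zeros((0, len(self.class_labels)))
        tokens = tokenize_batch([r.residues for r in records], self.encoder_spec)
        out = []
        for start in range(0, len(tokens), 512):
            probs, _ = self._forward(tokens[start : start + 512], training=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def predict(self, records: Sequence[SequenceRecord]) -> list[str]:
        """Argmax class labels; probability ties break to the lowest class
        index."""
        probs = self.predict_proba(records)
        return [self.class_labels[i] for i in probs.argmax(axis=1)]

    # ------------------------------------------------------------------- I/O

    def save(self, path: str | Path) -> None:
        """Save weights (.npz) with a JSON sidecar (.json) holding the class
        labels, encoder spec, training spec and history, so predictions are
        reproducible from disk."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "class_labels": self.class_labels,
            "encoder_spec": self.encoder_spec.to_dict(),
            "train_spec": self.train_spec.to_dict(),
            "history": self.history,
            "is_trained": self.is_trained,
            "n_parameters": self.n_parameters,
        }
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            sidecar = json.load(fh)
        clf = cls(
            EncoderSpec.from_dict(sidecar["encoder_spec"]),
            sidecar["class_labels"],
            TrainingSpec.from_dict(sidecar["train_spec"]),
        )
        with np.load(path.with_suffix(".npz")) as npz:
            clf.params = {k: npz[k] for k in npz.files}
        clf.history = sidecar["history"]
        clf.is_trained = sidecar["is_trained"]
        return clf


def build_classifier(
    encoder_spec: EncoderSpec, n_classes_or_labels, train_spec: TrainingSpec
) -> TrainedClassifier:
    """Construct an untrained classifier.

    ``n_classes_or_labels`` may be an integer (labels become ``class_0`` ...)
    or an explicit ordered label list.
    """
    if isinstance(n_classes_or_labels, int):
        labels = [f"class_{i}" for i in range(n_classes_or_labels)]
    else:
        labels = list(n_classes_or_labels)
    return TrainedClassifier(encoder_spec, labels, train_spec)


def train(
    classifier: TrainedClassifier,
    train_set: LabeledDataset,
    val_set: LabeledDataset,
    spec: TrainingSpec | None = None,
) -> TrainedClassifier:
    """Train ``classifier``; a ``spec`` differing from the one it was built
    with rebuilds the network first (fresh seeded initialization)."""
    if spec is not None and spec != classifier.train_spec:
        classifier = TrainedClassifier(
            classifier.encoder_spec, classifier.class_labels, spec
        )
    return classifier.fit(train_set, val_set)
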