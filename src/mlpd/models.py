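"""Sequence encoding, affinity models, training, and evaluation metrics.

Three output formulations over one shared architecture family:

* **Counts** — regress the normalized sequencing fraction in every pool,
  optionally through a latent-affinity head (hidden layers -> one affinity
  scalar -> one trained multiplier per pool output); affinity score is the
  sum of the designated high-stringency round-2 positive-pool outputs.
* **Binned** — one output per stringency level with ternary labels
  (ambiguous entries are masked out of the loss).
* **SuperBin** — a single 0..6 affinity-level regression target.

All models train with mini-batch squared-error regression (SGD with momentum
or Adam), with positive examples upsampled to a floor fraction of each batch.
The network is a compact explicit-backprop implementation on numpy: optional
1-D convolutions over the one-hot block (the k-mer block joins at the first
dense layer), dense hidden layers with ReLU and dropout, and one of the two
output heads.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import BASES, check_sequence, derive_rng
from .seqdata import (
    AMBIGUOUS,
    POSITIVE,
    CountTable,
    StringencyLabels,
    normalize_counts,
)

SEQ_LENGTH = 40
ONE_HOT_DIM = 4 * SEQ_LENGTH  # 160
KMER_K_MAX = 4
KMER_DIM = sum(4**k for k in range(1, KMER_K_MAX + 1))  # 340
ENCODING_DIM = ONE_HOT_DIM + KMER_DIM  # 500

_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i

_KMER_OFFSETS = {k: sum(4**j for j in range(1, k)) for k in range(1, KMER_K_MAX + 1)}


def kmer_index(kmer: str) -> int:
    """Position of a k-mer (k <= 4) in the fixed lexicographic feature order."""
    code = 0
    for c in kmer:
        code = 4 * code + BASES.index(c)
    return _KMER_OFFSETS[len(kmer)] + code


def _seq_array(sequences: Sequence[str], length: int | None) -> np.ndarray:
    rows = []
    for s in sequences:
        check_sequence(s)
        if length is not None and len(s) != length:
            raise ValueError(f"expected length-{length} sequence, got {len(s)}")
        row = _BASE_LUT[np.frombuffer(s.encode(), dtype=np.uint8)]
        rows.append(row)
    return np.array(rows, dtype=np.int64)


def one_hot_batch(sequences: Sequence[str], length: int = SEQ_LENGTH) -> np.ndarray:
    arr = _seq_array(sequences, length)
    n = arr.shape[0]
    out = np.zeros((n, length * 4))
    flat = np.arange(length) * 4 + arr
    out[np.arange(n)[:, None], flat] = 1.0
    return out


def one_hot(sequence: str, length: int = SEQ_LENGTH) -> np.ndarray:
    """One-hot encoding: 4 binary values per position, base order A,C,G,T."""
    return one_hot_batch([sequence], length)[0]


def kmer_count_batch(sequences: Sequence[str], k_max: int = KMER_K_MAX) -> np.ndarray:
    arr = _seq_array(sequences, None)
    n, L = arr.shape
    dim = sum(4**k for k in range(1, k_max + 1))
    out = np.zeros((n, dim))
    offset = 0
    for k in range(1, k_max + 1):
        codes = np.zeros((n, L - k + 1), dtype=np.int64)
        for j in range(k):
            codes = codes * 4 + arr[:, j : L - k + 1 + j]
        flat = np.arange(n)[:, None] * 4**k + codes
        counts = np.bincount(flat.ravel(), minlength=n * 4**k).reshape(n, 4**k)
        out[:, offset : offset + 4**k] = counts
        offset += 4**k
    return out


def kmer_count_features(sequence: str, k_max: int = KMER_K_MAX) -> np.ndarray:
    """Overlapping occurrence counts of all k-mers up to *k_max*, lexicographic."""
    return kmer_count_batch([sequence], k_max)[0]


def encode_batch(sequences: Sequence[str]) -> np.ndarray:
    return np.hstack([one_hot_batch(sequences), kmer_count_batch(sequences)])


def encode(sequence: str) -> np.ndarray:
    """Combined one-hot (160) + k-mer count (340) feature vector, length 500."""
    return encode_batch([sequence])[0]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Architecture + optimizer settings for one affinity model."""

    conv_layers: int = 0  # 0..3 one-dimensional convolutions over the one-hot block
    conv_filters: int = 16
    conv_width: int = 7
    hidden_sizes: tuple[int, ...] = (64,)
    activation: str = "relu"
    dropout: float = 0.0
    head: str = "fully_connected"  # or "latent_affinity"
    optimizer: str = "sgd"  # momentum-SGD; "adam" selectable
    learning_rate: float = 0.003
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 30
    upsample_floor: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.conv_layers <= 3:
            raise ValueError("conv_layers must be 0..3")
        if not 0 <= len(self.hidden_sizes) <= 4:
            raise ValueError("hidden_sizes supports 0..4 fully connected layers")
        if self.head not in ("fully_connected", "latent_affinity"):
            raise ValueError(f"unknown head {self.head!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


#: Selected per-formulation presets (batch 64, squared error throughout).
PRESETS: dict[str, ModelSpec] = {
    "counts": ModelSpec(
        head="latent_affinity", batch_size=64, learning_rate=0.00138, momentum=0.903
    ),
    "binned": ModelSpec(
        head="fully_connected", batch_size=64, learning_rate=0.00388, momentum=0.737
    ),
    "superbin": ModelSpec(
        head="fully_connected", batch_size=64, learning_rate=0.00203, momentum=0.498
    ),
}

#: Alternative optimizer configuration selectable for the binned/superbin models.
ADAM_ALTERNATIVE = {"optimizer": "adam", "learning_rate": 0.001}


# ---------------------------------------------------------------------------
# Layers (explicit backprop)
# ---------------------------------------------------------------------------


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    def params(self):
        return []


class _Dropout:
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def params(self):
        return []


class _Conv1D:
    """Valid 1-D convolution over (batch, length, channels) input."""

    def __init__(self, width: int, c_in: int, c_out: int, rng: np.random.Generator):
        self.width, self.c_in, self.c_out = width, c_in, c_out
        self.W = rng.normal(0.0, math.sqrt(2.0 / (width * c_in)), size=(width * c_in, c_out))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        Lo = L - self.width + 1
        cols = np.concatenate(
            [x[:, i : i + Lo, :] for i in range(self.width)], axis=2
        )  # (B, Lo, width*C)
        self._cols, self._in_shape = cols, (B, L, C)
        return cols @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C = self._in_shape
        Lo = L - self.width + 1
        self.dW = self._cols.reshape(-1, self.width * C).T @ dy.reshape(-1, self.c_out)
        self.db = dy.sum(axis=(0, 1))
        dcols = dy @ self.W.T
        dx = np.zeros(self._in_shape)
        for i in range(self.width):
            dx[:, i : i + Lo, :] += dcols[:, :, i * C : (i + 1) * C]
        return dx

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class _LatentAffinityHead:
    """Hidden layers -> one latent affinity scalar -> per-output multipliers."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.dense = _Dense(n_in, 1, rng)
        self.multipliers = np.ones(n_out)

    def forward(self, x, train):
        self._a = self.dense.forward(x, train)  # (B, 1)
        return self._a * self.multipliers

    def backward(self, dy):
        self.dm = (self._a * dy).sum(axis=0)
        da = dy @ self.multipliers[:, None]
        return self.dense.backward(da)

    def latent(self) -> np.ndarray:
        return self._a[:, 0]

    def params(self):
        return self.dense.params() + [("m", self.multipliers, self.dm)]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass
class TargetSchema:
    """What the output columns mean, and how they reduce to one affinity score."""

    formulation: str  # counts | binned | superbin
    targets: list[str]
    score_targets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.formulation not in ("counts", "binned", "superbin"):
            raise ValueError(f"unknown formulation {self.formulation!r}")


class AffinityNetwork:
    """Feed-forward network over the 500-dim encoding (see module docstring)."""

    def __init__(self, spec: ModelSpec, schema: TargetSchema, seed: int = 0):
        if spec.head == "latent_affinity" and schema.formulation == "superbin":
            raise ValueError(
                "latent_affinity head is meaningless for the scalar SuperBin target"
            )
        self.spec = spec
        self.schema = schema
        rng = derive_rng(seed, "init")
        self._dropout_rng = derive_rng(seed, "dropout")
        n_targets = len(schema.targets)

        self.conv_stack: list = []
        length, channels = SEQ_LENGTH, 4
        for _ in range(spec.conv_layers):
            self.conv_stack.append(_Conv1D(spec.conv_width, channels, spec.conv_filters, rng))
            self.conv_stack.append(_ReLU())
            length, channels = length - spec.conv_width + 1, spec.conv_filters
        conv_out = length * channels if spec.conv_layers else ONE_HOT_DIM

        self.dense_stack: list = []
        n_in = conv_out + KMER_DIM
        for h in spec.hidden_sizes:
            self.dense_stack.append(_Dense(n_in, h, rng))
            self.dense_stack.append(_ReLU())
            if spec.dropout > 0:
                self.dense_stack.append(_Dropout(spec.dropout, self._dropout_rng))
            n_in = h
        if spec.head == "latent_affinity":
            self.head = _LatentAffinityHead(n_in, n_targets, rng)
        else:
            self.head = _Dense(n_in, n_targets, rng)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        oh, km = X[:, :ONE_HOT_DIM], X[:, ONE_HOT_DIM:]
        if self.conv_stack:
            h = oh.reshape(len(X), SEQ_LENGTH, 4)
            for layer in self.conv_stack:
                h = layer.forward(h, train)
            h = h.reshape(len(X), -1)
        else:
            h = oh
        h = np.hstack([h, km])
        self._split = h.shape[1] - km.shape[1]
        for layer in self.dense_stack:
            h = layer.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dy: np.ndarray) -> None:
        d = self.head.backward(dy)
        for layer in reversed(self.dense_stack):
            d = layer.backward(d)
        if self.conv_stack:
            d = d[:, : self._split].reshape(d.shape[0], -1, self.conv_stack[-2].c_out)
            for layer in reversed(self.conv_stack):
                d = layer.backward(d)

    def params(self):
        out = []
        for layer in self.conv_stack + self.dense_stack + [self.head]:
            out.extend(layer.params())
        return out


def build_model(spec: ModelSpec, schema: TargetSchema, seed: int = 0) -> AffinityNetwork:
    """Instantiate an untrained network for a target schema."""
    return AffinityNetwork(spec, schema, seed)


class _SGDMomentum:
    def __init__(self, lr: float, momentum: float):
        self.lr, self.mu = lr, momentum
        self.v: dict[int, np.ndarray] = {}

    def step(self, params):
        for i, (_, value, grad) in enumerate(params):
            v = self.v.setdefault(i, np.zeros_like(value))
            v *= self.mu
            v -= self.lr * grad
            value += v


class _Adam:
    def __init__(self, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: dict[int, np.ndarray] = {}
        self.s: dict[int, np.ndarray] = {}
        self.t = 0

    def step(self, params):
        self.t += 1
        for i, (_, value, grad) in enumerate(params):
            m = self.m.setdefault(i, np.zeros_like(value))
            s = self.s.setdefault(i, np.zeros_like(value))
            m += (1 - self.b1) * (grad - m)
            s += (1 - self.b2) * (grad**2 - s)
            mhat = m / (1 - self.b1**self.t)
            shat = s / (1 - self.b2**self.t)
            value -= self.lr * mhat / (np.sqrt(shat) + self.eps)


# ---------------------------------------------------------------------------
# Training targets
# ---------------------------------------------------------------------------


@dataclass
class TrainingData:
    """Encoded sequences with regression targets, loss mask, and positive flags."""

    sequences: list[str]
    X: np.ndarray
    Y: np.ndarray
    mask: np.ndarray  # bool, same shape as Y; False entries excluded from loss
    positive: np.ndarray  # bool per sequence, drives batch upsampling
    schema: TargetSchema

    def subset(self, sequences: Sequence[str]) -> "TrainingData":
        index = {s: i for i, s in enumerate(self.sequences)}
        idx = [index[s] for s in sequences if s in index]
        return TrainingData(
            [self.sequences[i] for i in idx],
            self.X[idx],
            self.Y[idx],
            self.mask[idx],
            self.positive[idx],
            self.schema,
        )


def _counts_score_pools(table: CountTable) -> list[str]:
    """Default Counts affinity reduction: the two highest-stringency positive
    pools of the final round."""
    last = max(info.round for info in table.pools.values())
    pos = [i for i in table.pools.values() if i.round == last and i.polarity == "pos"]
    pos.sort(key=lambda i: i.concentration)  # lowest [T] = highest stringency first
    return [i.name for i in pos[:2]]


def make_training_targets(
    formulation: str,
    table: CountTable | None = None,
    labels: StringencyLabels | None = None,
    levels: pd.Series | None = None,
    positive_count_threshold: float | None = None,
    aux_provider: Callable[[str], float] | None = None,
) -> TrainingData:
    """Assemble regression targets for one of the three formulations.

    counts: needs *table*; targets are per-pool normalized sequencing
    fractions, positives are sequences whose summed raw count reaches the
    threshold (default: four bead-complements of reads, a depth-scaled
    analogue of an absolute-count cutoff). binned: needs *labels*; ambiguous
    entries are masked from the loss. superbin: needs *levels*; excluded
    sequences are simply absent. *aux_provider* optionally appends one extra
    auxiliary regression column (counts only), e.g. a fold-energy scorer.
    """
    if formulation == "counts":
        if table is None:
            raise ValueError("counts formulation requires a CountTable")
        fractions = normalize_counts(table)
        seqs = list(fractions.index)
        Y = fractions.values.astype(float)
        names = list(fractions.columns)
        if positive_count_threshold is None:
            cov = np.mean([i.expected_coverage for i in table.pools.values()])
            positive_count_threshold = 4.0 * cov
        positive = table.total_counts().values >= positive_count_threshold
        score_targets = _counts_score_pools(table)
        if aux_provider is not None:
            aux = np.array([aux_provider(s) for s in seqs])[:, None]
            Y = np.hstack([Y, aux])
            names = names + ["aux"]
        schema = TargetSchema("counts", names, score_targets)
        return TrainingData(seqs, encode_batch(seqs), Y, np.ones_like(Y, bool), positive, schema)
    if formulation == "binned":
        if labels is None:
            raise ValueError("binned formulation requires StringencyLabels")
        seqs = list(labels.df.index)
        vals = labels.df.values
        Y = (vals == POSITIVE).astype(float)
        mask = vals != AMBIGUOUS
        positive = (vals == POSITIVE).any(axis=1)
        schema = TargetSchema(
            "binned",
            [f"{c:g}nM" for c in labels.concentrations],
            [f"{c:g}nM" for c in labels.concentrations],
        )
        return TrainingData(seqs, encode_batch(seqs), Y, mask, positive, schema)
    if formulation == "superbin":
        if levels is None:
            raise ValueError("superbin formulation requires a level Series")
        seqs = list(levels.index)
        Y = levels.values.astype(float)[:, None]
        positive = levels.values >= 2  # passed at least the weakest level cleanly
        schema = TargetSchema("superbin", ["level"], ["level"])
        return TrainingData(seqs, encode_batch(seqs), Y, np.ones_like(Y, bool), positive, schema)
    raise ValueError(f"unknown formulation {formulation!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedAffinityModel:
    """A trained network plus the feature normalizer and score-reduction rule."""

    network: AffinityNetwork
    spec: ModelSpec
    schema: TargetSchema
    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: np.ndarray
    target_std: np.ndarray
    history: list[float] = field(default_factory=list)

    def _predict_X(self, X: np.ndarray) -> np.ndarray:
        Xn = (X - self.feature_mean) / self.feature_std
        chunks = [
            self.network.forward(Xn[i : i + 4096], train=False)
            for i in range(0, len(Xn), 4096)
        ]
        out = np.vstack(chunks) if chunks else np.zeros((0, len(self.schema.targets)))
        return out * self.target_std + self.target_mean

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        """Raw model outputs, one column per target."""
        return self._predict_X(encode_batch(list(sequences)))

    def affinity_score(self, sequences: Sequence[str]) -> np.ndarray:
        """Reduce model outputs to one affinity score per sequence.

        counts: sum of the designated round-2 high-stringency positive-pool
        outputs; binned: stringency-rank weighted sum (strongest level gets
        the largest weight); superbin: the scalar output itself.
        """
        out = self.predict(sequences)
        return self.reduce_outputs(out)

    def reduce_outputs(self, outputs: np.ndarray) -> np.ndarray:
        cols = [self.schema.targets.index(t) for t in self.schema.score_targets]
        if self.schema.formulation == "counts":
            return outputs[:, cols].sum(axis=1)
        if self.schema.formulation == "binned":
            weights = np.arange(1, len(cols) + 1, dtype=float)  # weakest -> strongest
            return outputs[:, cols] @ weights
        return outputs[:, cols[0]]

    def level_score(self, sequences: Sequence[str], level: int) -> np.ndarray:
        """Score for ranking at one stringency level (0 = weakest).

        The binned formulation has a dedicated output per level, so
        per-threshold evaluation uses that output directly; the other
        formulations rank every level with their scalar affinity score.
        """
        out = self.predict(sequences)
        if self.schema.formulation == "binned":
            return out[:, level]
        return self.reduce_outputs(out)

    def __call__(self, sequences: Sequence[str]) -> np.ndarray:
        return self.affinity_score(sequences)

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": value for i, (_, value, _) in enumerate(_named_params(self.network))}
        meta = {
            "spec": asdict(self.spec),
            "schema": asdict(self.schema),
            "history": self.history,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            feature_mean=self.feature_mean,
            feature_std=self.feature_std,
            target_mean=self.target_mean,
            target_std=self.target_std,
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedAffinityModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            spec = ModelSpec(**{**meta["spec"], "hidden_sizes": tuple(meta["spec"]["hidden_sizes"])})
            schema = TargetSchema(**meta["schema"])
            net = AffinityNetwork(spec, schema)
            for i, (_, value, _) in enumerate(_named_params(net)):
                value[...] = data[f"p{i}"]
            return cls(
                network=net,
                spec=spec,
                schema=schema,
                feature_mean=data["feature_mean"],
                feature_std=data["feature_std"],
                target_mean=data["target_mean"],
                target_std=data["target_std"],
                history=list(meta["history"]),
            )


def _named_params(net: AffinityNetwork):
    out = []
    for layer in net.conv_stack + net.dense_stack + [net.head]:
        if isinstance(layer, _LatentAffinityHead):
            out.append(("W", layer.dense.W, None))
            out.append(("b", layer.dense.b, None))
            out.append(("m", layer.multipliers, None))
        elif isinstance(layer, (_Dense, _Conv1D)):
            out.append(("W", layer.W, None))
            out.append(("b", layer.b, None))
    return out


def _masked_mse(pred: np.ndarray, Y: np.ndarray, mask: np.ndarray) -> tuple[float, np.ndarray]:
    diff = (pred - Y) * mask
    n = max(int(mask.sum()), 1)
    return float((diff**2).sum() / n), 2.0 * diff / n


def train(
    network: AffinityNetwork,
    data: TrainingData,
    seed: int = 0,
) -> TrainedAffinityModel:
    """Mini-batch squared-error training with positive upsampling.

    When positive examples exist, each batch is patched so that at least
    ``spec.upsample_floor`` of its members are positive. Feature and target
    standardization (per-column mean/std of the training set; for
    convolutional models the one-hot block is left raw) is computed here and
    stored with the model; predictions are de-standardized, so the loss is
    optimized on a unit scale but outputs stay in target units. Fully
    deterministic given the seed.
    """
    spec = network.spec
    X, Y, mask = data.X.astype(float), data.Y.astype(float), data.mask
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std < 1e-8] = 1.0
    if spec.conv_layers:
        mean[:ONE_HOT_DIM] = 0.0
        std[:ONE_HOT_DIM] = 1.0
    Xn = (X - mean) / std
    # per-target standardization over unmasked entries
    t_mean = np.zeros(Y.shape[1])
    t_std = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        col = Y[mask[:, j], j]
        if len(col):
            t_mean[j] = col.mean()
            s = col.std()
            t_std[j] = s if s > 1e-12 else 1.0
    Yn = (Y - t_mean) / t_std

    pos_idx = np.flatnonzero(data.positive)
    if len(pos_idx) == 0:
        warnings.warn("no positive sequences; training proceeds without upsampling")
    opt = (
        _SGDMomentum(spec.learning_rate, spec.momentum)
        if spec.optimizer == "sgd"
        else _Adam(spec.learning_rate)
    )
    rng = derive_rng(seed, "train")
    B = spec.batch_size
    history = []
    for _ in range(spec.epochs):
        perm = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, B):
            idx = perm[start : start + B].copy()
            if len(pos_idx):
                need = math.ceil(spec.upsample_floor * len(idx))
                have = int(data.positive[idx].sum())
                if have < need:
                    neg_slots = np.flatnonzero(~data.positive[idx])
                    patch = rng.choice(neg_slots, size=need - have, replace=False)
                    idx[patch] = rng.choice(pos_idx, size=need - have, replace=True)
            pred = network.forward(Xn[idx], train=True)
            loss, dpred = _masked_mse(pred, Yn[idx], mask[idx])
            network.backward(dpred)
            opt.step(network.params())
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / max(n_batches, 1))
    return TrainedAffinityModel(
        network, spec, data.schema, mean, std, t_mean, t_std, history
    )


def train_formulation(
    formulation: str,
    data: TrainingData,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> TrainedAffinityModel:
    """Convenience: build the preset (or given) spec and train on *data*."""
    spec = spec if spec is not None else PRESETS[formulation]
    net = build_model(spec, data.schema, seed)
    return train(net, data, seed)


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def _rank_auc(scores: np.ndarray, relevant: np.ndarray) -> float:
    """Mann-Whitney AUC with ties averaged."""
    relevant = np.asarray(relevant, dtype=bool)
    n_pos = int(relevant.sum())
    n_neg = len(relevant) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined without both relevant and irrelevant items")
    ranks = rankdata(scores)
    return float((ranks[relevant].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_top_fraction(
    scores: np.ndarray, reference: np.ndarray, top_fraction: float = 0.01
) -> float:
    """AUC for retrieving the top fraction of non-zero reference values.

    Relevance = membership in the top ``ceil(top_fraction * n_nonzero)`` of
    the non-zero reference values; the AUC ranks *scores* against that binary
    relevance over the whole set.
    """
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference, dtype=float)
    nonzero = np.flatnonzero(reference)
    if len(nonzero) == 0:
        raise ValueError("no non-zero reference values")
    k = math.ceil(top_fraction * len(nonzero))
    order = nonzero[np.argsort(-reference[nonzero], kind="stable")]
    relevant = np.zeros(len(reference), dtype=bool)
    relevant[order[:k]] = True
    return _rank_auc(scores, relevant)


def stringency_auc(
    scores: np.ndarray, labels: StringencyLabels, level: int
) -> float:
    """AUC against the concordant positive set at one stringency level.

    Positives are sequences positive at *level* (0 = weakest) and at every
    weaker level; negatives are the rest of the set.
    """
    vals = labels.df.values
    pos = (vals[:, : level + 1] == POSITIVE).all(axis=1)
    if not pos.any():
        raise ValueError(f"no concordant positives at level {level}")
    return _rank_auc(np.asarray(scores, dtype=float), pos)


# ---------------------------------------------------------------------------
# Hyperparameter random search (in-repo stand-in for an external tuner)
# ---------------------------------------------------------------------------


def random_search(
    train_data: TrainingData,
    test_data: TrainingData,
    reference: np.ndarray,
    n_configs: int = 10,
    seed: int = 0,
    top_fraction: float = 0.01,
    base_spec: ModelSpec | None = None,
) -> list[tuple[ModelSpec, float]]:
    """Seeded random hyperparameter search ranked by :func:`auc_top_fraction`."""
    rng = derive_rng(seed, "random_search")
    base = base_spec if base_spec is not None else PRESETS[train_data.schema.formulation]
    results = []
    for i in range(n_configs):
        spec = ModelSpec(
            **{
                **asdict(base),
                "learning_rate": float(10 ** rng.uniform(-3.5, -2.0)),
                "momentum": float(rng.uniform(0.3, 0.95)),
                "hidden_sizes": tuple([int(rng.choice([32, 64, 128]))]),
                "dropout": float(rng.choice([0.0, 0.1, 0.3])),
            }
        )
        model = train_formulation(train_data.schema.formulation, train_data, spec, seed=seed + i)
        scores = model._predict_X(test_data.X)
        auc = auc_top_fraction(model.reduce_outputs(scores), reference, top_fraction)
        results.append((spec, auc))
    results.sort(key=lambda r: -r[1])
    return results
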