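"""Classifier-facing API: one-hot encoding, model construction, training
and evaluation for the multi-label enhancer sequence task.

The output head is sigmoid + binary cross-entropy for every scenario.  The
multi-class task uses one-hot targets with all-zero rows for negatives, so
a trained model scores "not a regulatory sequence" as low probability on
every output.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import nnet
from .grammar_sim import AnnotatedSequence, Dataset

#: one-hot column order, A G C T
ONEHOT_ORDER = "AGCT"
_COL = {b: i for i, b in enumerate(ONEHOT_ORDER)}


def one_hot(seq: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 matrix with columns A, G, C, T.

    N rows are all-zero; any other character raises ValueError.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros((len(seq), 4), dtype=np.float32)
    mask_any = np.zeros(len(seq), dtype=bool)
    for base, col in _COL.items():
        m = arr == ord(base)
        out[m, col] = 1.0
        mask_any |= m
    mask_any |= arr == ord("N")
    if not mask_any.all():
        pos = int(np.nonzero(~mask_any)[0][0])
        raise ValueError(f"invalid character {seq[pos]!r} at position {pos}")
    return out


def encode_sequences(seqs: list[str]) -> np.ndarray:
    return np.stack([one_hot(s) for s in seqs])


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The default matches the simulation-scale network (4 residual blocks of
    two conv layers each, 32 filters, dense 32); ``genome_preset`` returns
    the larger variant used for peak-derived data.
    """

    n_outputs: int
    n_residual_blocks: int = 4
    filters_per_block: tuple[int, ...] = (32, 32, 32, 32)
    kernel_width: int = 11
    pool_width: int = 2
    pool_mode: str = "max"
    dense_units: int = 32
    dropout: float = 0.25

    def __post_init__(self) -> None:
        if isinstance(self.filters_per_block, int):
            self.filters_per_block = (self.filters_per_block,) * self.n_residual_blocks
        self.filters_per_block = tuple(self.filters_per_block)
        if len(self.filters_per_block) != self.n_residual_blocks:
            raise nnet.ConfigError("filters_per_block length must equal n_residual_blocks")
        for v in (*self.filters_per_block, self.kernel_width, self.pool_width,
                  self.dense_units, self.n_outputs, self.n_residual_blocks):
            if int(v) < 1:
                raise nnet.ConfigError("all architecture sizes must be positive")

    @classmethod
    def genome_preset(cls, n_outputs: int) -> "ModelConfig":
        return cls(
            n_outputs=n_outputs,
            n_residual_blocks=5,
            filters_per_block=(128, 256, 256, 512, 512),
            dense_units=1024,
        )


@dataclass
class TrainConfig:
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 5
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.split), 1.0):
            raise ValueError("split fractions must sum to 1")
        if min(self.split) < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")


@dataclass
class EvalResult:
    auroc: dict[str, float]
    aupr: dict[str, float]
    macro_auroc: float
    macro_aupr: float


def build_model(cfg: ModelConfig, input_length: int, seed: int = 0) -> nnet.ResNet1D:
    """Instantiate the residual network for a given input length."""
    return nnet.ResNet1D(
        input_length=input_length,
        n_outputs=cfg.n_outputs,
        filters=cfg.filters_per_block,
        kernel_width=cfg.kernel_width,
        pool_width=cfg.pool_width,
        pool_mode=cfg.pool_mode,
        dense_units=cfg.dense_units,
        dropout=cfg.dropout,
        seed=seed,
    )


def stratified_split(
    labels: np.ndarray, fractions: tuple[float, float, float], seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split indices into train/val/test stratified by full label pattern."""
    rng = np.random.default_rng(seed)
    keys = [tuple(row) for row in labels]
    groups: dict[tuple, list[int]] = {}
    for i, kk in enumerate(keys):
        groups.setdefault(kk, []).append(i)
    tr, va, te = [], [], []
    for idx in groups.values():
        idx = np.array(idx)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr : n_tr + n_va])
        te.extend(idx[n_tr + n_va :])
    return np.sort(tr), np.sort(va), np.sort(te)


def train(
    model: nnet.ResNet1D,
    x: np.ndarray,
    y: np.ndarray,
    tcfg: TrainConfig,
    verbose: bool = False,
) -> dict:
    """Train on a pre-encoded (N, L, 4) array with binary label matrix y.

    Splits off a validation set internally (train and val fractions of the
    configured split, renormalized); early stopping restores the weights
    with the best validation loss.
    """
    y = np.asarray(y, dtype=np.float32)
    if y.ndim != 2:
        raise ValueError("labels must be a binary matrix")
    for c in range(y.shape[1]):
        col = y[:, c]
        if col.min() == col.max():
            warnings.warn(f"output {c} has a single label value in training data")
    f_tr, f_va, _ = self_normalized_split(tcfg.split)
    tr, va, _ = stratified_split(y, (f_tr, f_va, 0.0), tcfg.seed)
    return nnet.fit(
        model,
        x[tr], y[tr], x[va], y[va],
        epochs=tcfg.epochs,
        batch_size=tcfg.batch_size,
        lr=tcfg.learning_rate,
        patience=tcfg.patience,
        weight_decay=tcfg.weight_decay,
        seed=tcfg.seed,
        verbose=verbose,
    )


def self_normalized_split(split: tuple[float, float, float]) -> tuple[float, float, float]:
    tot = split[0] + split[1]
    return split[0] / tot, split[1] / tot, 0.0


def evaluate(scores: np.ndarray, labels: np.ndarray, names: list[str] | None = None) -> EvalResult:
    """Per-class auROC (rank-sum formulation) and auPR (step-wise area).

    Classes lacking both label values are reported as NaN, excluded from
    the macro averages, and flagged with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim == 1:
        scores = scores[:, None]
        labels = labels[:, None]
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    C = scores.shape[1]
    names = names or [f"class_{i}" for i in range(C)]
    auroc: dict[str, float] = {}
    aupr: dict[str, float] = {}
    for c in range(C):
        y = labels[:, c]
        if y.min() == y.max():
            warnings.warn(f"{names[c]}: only one label value present; metrics undefined")
            auroc[names[c]] = float("nan")
            aupr[names[c]] = float("nan")
            continue
        auroc[names[c]] = float(roc_auc_score(y, scores[:, c]))
        aupr[names[c]] = float(average_precision_score(y, scores[:, c]))
    rocs = [v for v in auroc.values() if np.isfinite(v)]
    prs = [v for v in aupr.values() if np.isfinite(v)]
    return EvalResult(auroc, aupr, float(np.mean(rocs)), float(np.mean(prs)))


# ---------------------------------------------------------------------------
# dataset plumbing


def dataset_to_arrays(*datasets: Dataset) -> tuple[np.ndarray, np.ndarray, list[AnnotatedSequence]]:
    """Concatenate datasets into (X, Y, sequences)."""
    seqs: list[AnnotatedSequence] = []
    for d in datasets:
        seqs.extend(d.sequences)
    x = encode_sequences([s.seq for s in seqs])
    y = np.stack([s.label_vector for s in seqs]).astype(np.float32)
    return x, y, seqs


def save_model(model: nnet.ResNet1D, out_dir) -> None:
    """Native checkpoint: npz weights plus a JSON architecture descriptor."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "architecture.json"), "w") as fh:
        json.dump(model.architecture(), fh, indent=1)
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    bn_state = {}
    for i, bn in enumerate(model.bns):
        bn_state[f"bn{i}_mean"] = bn.running_mean
        bn_state[f"bn{i}_var"] = bn.running_var
    np.savez(os.path.join(out_dir, "weights.npz"), **arrays, **bn_state)


def load_model(in_dir) -> nnet.ResNet1D:
    with open(os.path.join(in_dir, "architecture.json")) as fh:
        arch = json.load(fh)
    model = nnet.ResNet1D(
        input_length=arch["input_length"],
        n_outputs=arch["n_outputs"],
        filters=tuple(arch["filters"]),
        kernel_width=arch["kernel_width"],
        pool_width=arch["pool_width"],
        pool_mode=arch.get("pool_mode", "max"),
        dense_units=arch["dense_units"],
        dropout=arch.get("dropout", 0.0),
    )
    data = np.load(os.path.join(in_dir, "weights.npz"))
    model.set_weights([data[f"w{i}"] for i in range(len(model.get_weights()))])
    for i, bn in enumerate(model.bns):
        bn.running_mean = data[f"bn{i}_mean"]
        bn.running_var = data[f"bn{i}_var"]
    return model
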