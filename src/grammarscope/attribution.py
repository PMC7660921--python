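"""Per-nucleotide importance of any neuron in any layer, and per-TFBS
saliency summaries.

Two attribution rules are provided:

* ``grad_input`` — guided backpropagation (negative gradients zeroed at
  every ReLU on the backward pass) of the target neuron's activation with
  respect to the one-hot input, elementwise-multiplied by the input;
* ``ref_contrib`` — reference-based contribution scores following the
  DeepLIFT rescale rule: multipliers are propagated from the neuron to the
  input, each ReLU contributing the finite-difference slope
  (f(x) - f(r)) / (x - r); contributions m * (x - r) are averaged over a
  reference set.  Contributions satisfy summation-to-delta: they add up to
  the activation difference between the input and each reference.

Intermediate-layer neurons are attributed by treating the truncated network
up to that neuron as the model output.  For convolutional layers the neuron
target is a channel, its scalar activation the sum over positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import nnet
from .grammar_sim import AnnotatedSequence, TFBSAnnotation, kmer_shuffle, tf_shuffle
from .resnet_model import encode_sequences, one_hot

_RESCALE_TOL = 1e-9


@dataclass
class AttributionConfig:
    """How to attribute: method, layer, and reference handling."""

    method: str = "ref_contrib"  # or "grad_input"
    layer: str = "penultimate"
    n_references: int = 20
    reference_mode: str = "tfshuffle"  # or "kmer"
    reference_k: int = 8
    window_bp: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("ref_contrib", "grad_input"):
            raise ValueError(f"unknown attribution method {self.method!r}")
        if self.method == "ref_contrib" and self.n_references < 1:
            raise ValueError("ref_contrib requires a non-empty reference set")


@dataclass
class SaliencyProfile:
    """Per-TFBS saliency across all neurons of one layer.

    ``values`` has one row per annotated binding site and one column per
    neuron; ``meta`` carries the row metadata (sequence name, motif id,
    true grammar id, coordinates).
    """

    values: np.ndarray
    meta: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta row counts differ")
        if not np.isfinite(self.values).all():
            raise ValueError("saliency profile contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"neuron_{i}" for i in range(self.values.shape[1])]
        return pd.concat(
            [self.meta.reset_index(drop=True), pd.DataFrame(self.values, columns=cols)], axis=1
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# backward propagation over the inference tape


def _op_input_grad(op: dict, dy: np.ndarray, vals_x: dict, vals_r: dict | None, mode: str):
    """Backward one primitive; returns list of (input_name, grad)."""
    kind = op["kind"]
    name_in = op["inputs"][0]
    if kind == "conv":
        return [(name_in, nnet.conv1d_input_grad(dy, op["W"]))]
    if kind == "dense":
        return [(name_in, dy @ op["W"].T)]
    if kind == "affine":
        return [(name_in, dy * op["scale"])]
    if kind == "pool":
        if op.get("mode") == "max":
            return [(name_in, nnet.maxpool_input_grad(dy, op["arg"], op["p"], op["L"]))]
        return [(name_in, nnet.avgpool_input_grad(dy, op["p"], op["L"]))]
    if kind == "flatten":
        shape = op["shape"]
        return [(name_in, dy.reshape(*dy.shape[:-1], *shape[1:]))]
    if kind == "add":
        return [(op["inputs"][0], dy), (op["inputs"][1], dy)]
    if kind == "relu":
        x_in = vals_x[name_in]
        if mode == "grad":
            return [(name_in, dy * (x_in > 0))]
        if mode == "guided":
            return [(name_in, dy * (x_in > 0) * (dy > 0))]
        # rescale: finite-difference slope against the reference activations
        r_in = vals_r[name_in]
        delta = x_in - r_in
        slope = np.where(
            np.abs(delta) > _RESCALE_TOL,
            (np.maximum(x_in, 0) - np.maximum(r_in, 0)) / np.where(delta == 0, 1.0, delta),
            (x_in > 0).astype(x_in.dtype),
        )
        return [(name_in, dy * slope)]
    raise ValueError(f"unknown op kind {kind!r}")


def _backward(
    tape_x: dict,
    target: str,
    seed_grad: np.ndarray,
    mode: str,
    tape_r: dict | None = None,
) -> np.ndarray:
    """Propagate ``seed_grad`` at node ``target`` back to the input node.

    ``seed_grad`` may carry a leading axis of independent seeds (e.g. one
    per neuron); the returned array has shape (seeds..., N, L, 4).
    """
    ops = tape_x["ops"]
    vals_x = tape_x["values"]
    vals_r = tape_r["values"] if tape_r is not None else None
    idx = next(i for i, op in enumerate(ops) if op["output"] == target)
    grads: dict[str, np.ndarray] = {target: seed_grad}
    for op in reversed(ops[: idx + 1]):
        out = op["output"]
        if out not in grads:
            continue
        dy = grads.pop(out)
        for name, g in _op_input_grad(op, dy, vals_x, vals_r, mode):
            if name in grads:
                grads[name] = grads[name] + g
            else:
                grads[name] = g
    return grads["input"]


def _neuron_seed(model: nnet.ResNet1D, tape: dict, layer: str, neurons: np.ndarray) -> np.ndarray:
    """Seed gradient selecting the given neurons' scalar activations.

    Shape (S, N, ...) matching the target node; conv-layer neurons are
    channels whose activation is summed over positions.
    """
    out = tape["values"][layer]
    S = len(neurons)
    if out.ndim == 2:  # dense-style node (N, units)
        seed = np.zeros((S, *out.shape))
        for s, j in enumerate(neurons):
            seed[s, :, j] = 1.0
    else:  # conv-style node (N, L, C): sum activation over positions
        seed = np.zeros((S, *out.shape))
        for s, j in enumerate(neurons):
            seed[s, :, :, j] = 1.0
    return seed


def _resolve_neurons(model: nnet.ResNet1D, layer: str, neuron) -> np.ndarray:
    width = model.layer_width(layer)
    if neuron == "all" or neuron is None:
        return np.arange(width)
    arr = np.atleast_1d(np.asarray(neuron, dtype=int))
    if (arr < 0).any() or (arr >= width).any():
        raise IndexError(f"neuron index out of range for layer {layer} (width {width})")
    return arr


def make_references(annseq: AnnotatedSequence, cfg: AttributionConfig, rng: np.random.Generator) -> list[str]:
    """Generate reference sequences for one input."""
    if cfg.reference_mode == "tfshuffle":
        return [tf_shuffle(annseq, rng).seq for _ in range(cfg.n_references)]
    if cfg.reference_mode == "kmer":
        return [kmer_shuffle(annseq.seq, cfg.reference_k, rng) for _ in range(cfg.n_references)]
    raise ValueError(f"unknown reference mode {cfg.reference_mode!r}")


# ---------------------------------------------------------------------------
# public attribution API


def neuron_contributions(
    model: nnet.ResNet1D,
    seq: str,
    layer: str,
    neuron,
    references: Sequence[str],
) -> np.ndarray:
    """Rescale-rule contribution scores, shape (n_neurons, L, 4).

    For each reference, multipliers are propagated from the neuron to the
    input and multiplied by (input - reference); the result is the average
    over references.  Summing a single-reference contribution map over all
    positions and channels recovers activation(input) - activation(reference).
    """
    neurons = _resolve_neurons(model, layer, neuron)
    x = one_hot(seq)[None]
    tape_x = model.forward_tape(x)
    total = np.zeros((len(neurons), *x.shape[1:]))
    for ref in references:
        r = one_hot(ref)[None]
        tape_r = model.forward_tape(r)
        seed = _neuron_seed(model, tape_x, layer, neurons)
        mult = _backward(tape_x, layer, seed, "rescale", tape_r)
        total += (mult * (x - r))[:, 0]
    return total / len(references)


def neuron_attribution(
    model: nnet.ResNet1D,
    seq: str,
    layer: str,
    neuron,
    cfg: AttributionConfig,
    references: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-position saliency map(s) for one sequence.

    Returns shape (n_neurons, L) — attribution multiplied elementwise by
    the one-hot input and collapsed over channels, so each position carries
    the score of its observed base.
    """
    neurons = _resolve_neurons(model, layer, neuron)
    x = one_hot(seq)[None]
    if cfg.method == "grad_input":
        tape_x = model.forward_tape(x)
        seed = _neuron_seed(model, tape_x, layer, neurons)
        grad = _backward(tape_x, layer, seed, "guided")
        return (grad * x).sum(axis=-1)[:, 0]
    if references is None:
        raise ValueError("ref_contrib requires references")
    contrib = neuron_contributions(model, seq, layer, neurons, references)
    return (contrib * x[0]).sum(axis=-1)


def tfbs_score(saliency_map: np.ndarray, ann: TFBSAnnotation, window_bp: int = 10) -> float:
    """Mean saliency over a fixed window from the site start.

    The window is ``window_bp`` positions regardless of motif length and is
    truncated at the sequence end.
    """
    sl = saliency_map[ann.start : ann.start + window_bp]
    return float(np.mean(sl))


def _batched_maps(
    model: nnet.ResNet1D,
    seqs: list[AnnotatedSequence],
    layer: str,
    cfg: AttributionConfig,
    rng: np.random.Generator,
    chunk: int = 8,
) -> np.ndarray:
    """Saliency maps for all neurons of a layer over many sequences.

    Returns (n_seqs, n_neurons, L).  ref_contrib draws a fresh reference
    set per sequence (shared across that sequence's neurons).
    """
    neurons = _resolve_neurons(model, layer, "all")
    L = len(seqs[0].seq)
    out = np.zeros((len(seqs), len(neurons), L))
    for lo in range(0, len(seqs), chunk):
        batch = seqs[lo : lo + chunk]
        x = encode_sequences([s.seq for s in batch]).astype(np.float32)
        tape_x = model.forward_tape(x, dtype=np.float32)
        seed = _neuron_seed(model, tape_x, layer, neurons).astype(np.float32)
        if cfg.method == "grad_input":
            grad = _backward(tape_x, layer, seed, "guided")
            sal = (grad * x).sum(axis=-1)  # (S, N, L)
        else:
            refs_per_seq = [make_references(s, cfg, rng) for s in batch]
            acc = np.zeros((len(neurons), len(batch), L, 4), dtype=np.float32)
            for j in range(cfg.n_references):
                r = encode_sequences([refs[j] for refs in refs_per_seq]).astype(np.float32)
                tape_r = model.forward_tape(r, dtype=np.float32)
                mult = _backward(tape_x, layer, seed, "rescale", tape_r)
                acc += mult * (x - r)
            acc /= cfg.n_references
            sal = (acc * x).sum(axis=-1)
        out[lo : lo + len(batch)] = sal.transpose(1, 0, 2)
    return out


def profile_matrix(
    model: nnet.ResNet1D,
    sequences: list[AnnotatedSequence],
    layer: str = "penultimate",
    cfg: AttributionConfig | None = None,
) -> SaliencyProfile:
    """Build the TFBS-by-neuron saliency profile for a set of sequences.

    One row per ground-truth TFBS annotation, one column per neuron of the
    chosen layer; the entry is the windowed mean saliency of that site in
    that neuron's map.
    """
    cfg = cfg or AttributionConfig()
    if not sequences or all(not s.annotations for s in sequences):
        raise ValueError("profile_matrix needs annotated sequences")
    rng = np.random.default_rng(cfg.seed)
    maps = _batched_maps(model, sequences, layer, cfg, rng)
    rows = []
    meta_rows = []
    for i, s in enumerate(sequences):
        for a in s.annotations:
            w = maps[i, :, a.start : a.start + cfg.window_bp]
            rows.append(w.mean(axis=1))
            meta_rows.append(
                {
                    "sequence": s.name,
                    "motif_id": a.motif_id,
                    "grammar_id": a.grammar_id if a.grammar_id is not None else "none",
                    "start": a.start,
                    "end": a.end,
                    "class_id": s.class_id,
                }
            )
    return SaliencyProfile(np.stack(rows), pd.DataFrame(meta_rows), layer)


def saliency_bedgraph(saliency_map: np.ndarray, seq_name: str, path) -> None:
    """Export a per-position saliency map as bedGraph."""
    with open(path, "w") as fh:
        for i, v in enumerate(saliency_map):
            fh.write(f"{seq_name}\t{i}\t{i + 1}\t{v:.6g}\n")
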