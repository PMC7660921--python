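"""A compact NumPy engine for 1-D residual convolutional networks.

Implements exactly the pieces the classifier needs: same-padded 1-D
convolutions, ReLU, batch normalization, average pooling, dense layers,
residual blocks with identity (or 1x1-projection) shortcuts, a sigmoid /
binary-cross-entropy head, and the Adam optimizer.  Everything is plain
``float32`` NumPy, so training is bit-reproducible for a fixed seed.

Besides training, the engine exposes an inference *tape*: an explicit list
of primitive operations with their cached inputs/outputs, which the
attribution module replays backwards under different propagation rules
(plain gradient, guided backprop, reference-based rescale multipliers).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# functional primitives (shared by training layers and the inference tape)


def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padded 1-D convolution.  x: (N, L, Cin), W: (k, Cin, F).

    Computed as a sum of k shifted matmuls, which avoids materializing the
    full im2col matrix; the returned second element is the zero-padded input
    (cached for the weight gradient).
    """
    k, Cin, F = W.shape
    N, L, _ = x.shape
    pl = (k - 1) // 2
    pr = k - 1 - pl
    xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
    Lp = L + pl + pr
    y = np.empty((N, L, F), dtype=np.result_type(x, W))
    np.copyto(y, b)
    flat = xp.reshape(N * Lp, Cin)
    for i in range(k):
        yi = (flat @ W[i]).reshape(N, Lp, F)
        y += yi[:, i : i + L, :]
    return y, xp


def conv1d_input_grad(dy: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Gradient of a same-padded conv w.r.t. its input.

    ``dy`` may carry arbitrary leading axes before (L, F); the result has
    the same leading axes before (L, Cin).
    """
    k, Cin, F = W.shape
    lead = dy.shape[:-2]
    L = dy.shape[-2]
    dyflat = np.ascontiguousarray(dy).reshape(-1, F)
    pl = (k - 1) // 2
    pr = k - 1 - pl
    dxp = np.zeros((*lead, L + pl + pr, Cin), dtype=dy.dtype)
    for i in range(k):
        di = (dyflat @ W[i].T).reshape(*lead, L, Cin)
        dxp[..., i : i + L, :] += di
    return dxp[..., pl : pl + L, :]


def avgpool_forward(x: np.ndarray, p: int) -> np.ndarray:
    """Non-overlapping average pooling with floor truncation; x: (..., L, C)."""
    L = x.shape[-2]
    Lp = L // p
    lead = x.shape[:-2]
    C = x.shape[-1]
    return x[..., : Lp * p, :].reshape(*lead, Lp, p, C).mean(axis=-2)


def avgpool_input_grad(dy: np.ndarray, p: int, L: int) -> np.ndarray:
    lead = dy.shape[:-2]
    Lp, C = dy.shape[-2], dy.shape[-1]
    dx = np.zeros((*lead, L, C), dtype=dy.dtype)
    dx[..., : Lp * p, :] = np.repeat(dy / p, p, axis=-2)
    return dx


def maxpool_forward(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling; returns (pooled, argmax-within-window)."""
    L = x.shape[-2]
    Lp = L // p
    lead = x.shape[:-2]
    C = x.shape[-1]
    win = x[..., : Lp * p, :].reshape(*lead, Lp, p, C)
    if p == 2:  # comparison beats argmax for the common width
        a, b = win[..., 0, :], win[..., 1, :]
        arg = (b > a).astype(np.int8)
        return np.where(arg, b, a), arg
    arg = win.argmax(axis=-2)
    return np.take_along_axis(win, arg[..., None, :], axis=-2).squeeze(-2), arg


def maxpool_input_grad(dy: np.ndarray, arg: np.ndarray, p: int, L: int) -> np.ndarray:
    """Route pooled gradients to the window positions that held the maxima.

    ``arg`` may have fewer leading axes than ``dy`` (shared argmax across
    independent seed axes); it is broadcast accordingly.
    """
    lead = dy.shape[:-2]
    Lp, C = dy.shape[-2], dy.shape[-1]
    dx = np.zeros((*lead, L, C), dtype=dy.dtype)
    dwin = dx[..., : Lp * p, :].reshape(*lead, Lp, p, C)
    if p == 2:
        sel = np.broadcast_to(arg.astype(bool), (*lead, Lp, C))
        dwin[..., 1, :] = np.where(sel, dy, 0)
        dwin[..., 0, :] = np.where(sel, 0, dy)
    else:
        arg_b = np.broadcast_to(arg, (*lead, Lp, C))
        np.put_along_axis(dwin, arg_b[..., None, :], dy[..., None, :], axis=-2)
    return dx


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all elements; returns (loss, dL/dz)."""
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / z.size
    return float(loss.mean()), dz.astype(z.dtype)


# ---------------------------------------------------------------------------
# layers (training path)


class Conv1D:
    def __init__(self, k: int, cin: int, f: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * cin))
        self.W = (rng.standard_normal((k, cin, f)) * scale).astype(np.float32)
        self.b = np.zeros(f, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, xp = conv1d_forward(x, self.W, self.b)
        self._xp = xp
        self._shape = x.shape
        return y

    def backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        k, cin, f = self.W.shape
        N, L, _ = self._shape
        dy2 = np.ascontiguousarray(dy).reshape(N * L, f)
        for i in range(k):
            xi = np.ascontiguousarray(self._xp[:, i : i + L, :]).reshape(N * L, cin)
            self.dW[i] += xi.T @ dy2
        self.db += dy2.sum(axis=0)
        if not need_input_grad:
            return None
        return conv1d_input_grad(dy, self.W)

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = (rng.standard_normal((cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm:
    """Per-channel batch normalization over (batch, position)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            axes = tuple(range(x.ndim - 1))
            M = x.size // x.shape[-1]
            x2 = x.reshape(-1, x.shape[-1])
            s1 = x2.sum(axis=0)
            s2 = np.einsum("nc,nc->c", x2, x2)
            mean = s1 / M
            var = np.maximum(s2 / M - mean * mean, 0.0)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._cache = (xhat, inv, x.size // x.shape[-1])
            return (self.gamma * xhat + self.beta).astype(x.dtype)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return ((x - self.running_mean) * inv * self.gamma + self.beta).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, M = self._cache
        axes = tuple(range(dy.ndim - 1))
        self.dgamma += (dy * xhat).sum(axis=axes)
        self.dbeta += dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = inv / M * (M * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        return dx.astype(dy.dtype)

    def eval_scale_shift(self) -> tuple[np.ndarray, np.ndarray]:
        """The affine map the layer applies at inference time."""
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        shift = self.beta - self.running_mean * scale
        return scale, shift

    @property
    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


@dataclass
class ResidualBlock:
    """Two same-padded conv layers with ReLUs plus a shortcut connection.

    The shortcut is the identity when channel counts match, otherwise a 1x1
    convolution projection.
    """

    conv1: Conv1D
    conv2: Conv1D
    proj: Conv1D | None
    _cache: tuple = field(default=(), repr=False)

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.conv1.forward(x)
        r1 = np.maximum(a, 0)
        b = self.conv2.forward(r1)
        r2 = np.maximum(b, 0)
        short = self.proj.forward(x) if self.proj is not None else x
        self._cache = (a, b)
        return r2 + short

    def backward(self, dy: np.ndarray, need_input_grad: bool = True) -> np.ndarray | None:
        a, b = self._cache
        dr2 = dy * (b > 0)
        dr1 = self.conv2.backward(dr2) * (a > 0)
        dx = self.conv1.backward(dr1, need_input_grad)
        if self.proj is not None:
            dp = self.proj.backward(dy, need_input_grad)
            if need_input_grad:
                dx = dx + dp
        elif need_input_grad:
            dx = dx + dy
        return dx

    @property
    def params(self):
        out = self.conv1.params + self.conv2.params
        if self.proj is not None:
            out += self.proj.params
        return out


# ---------------------------------------------------------------------------
# the network


class ResNet1D:
    """input -> [residual block -> batch norm -> avg pool] * B -> flatten
    -> dense (ReLU, the "penultimate" layer) -> dense -> sigmoid."""

    def __init__(
        self,
        input_length: int,
        n_outputs: int,
        filters: tuple[int, ...] = (32, 32, 32, 32),
        kernel_width: int = 11,
        pool_width: int = 2,
        dense_units: int = 32,
        pool_mode: str = "max",
        dropout: float = 0.25,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.input_length = input_length
        self.n_outputs = n_outputs
        self.filters = tuple(filters)
        self.kernel_width = kernel_width
        self.pool_width = pool_width
        self.dense_units = dense_units
        if pool_mode not in ("max", "avg"):
            raise ConfigError(f"pool_mode must be 'max' or 'avg', got {pool_mode!r}")
        self.pool_mode = pool_mode
        if not (0 <= dropout < 1):
            raise ConfigError("dropout must be in [0, 1)")
        self.dropout = dropout

        self.blocks: list[ResidualBlock] = []
        self.bns: list[BatchNorm] = []
        cin = 4
        L = input_length
        for f in self.filters:
            proj = Conv1D(1, cin, f, rng) if cin != f else None
            self.blocks.append(
                ResidualBlock(Conv1D(kernel_width, cin, f, rng), Conv1D(kernel_width, f, f, rng), proj)
            )
            self.bns.append(BatchNorm(f))
            L = L // pool_width
            if L < 1:
                raise ConfigError("pooled length fell below 1; reduce blocks or pool width")
            cin = f
        self.flat_dim = L * cin
        self.final_length = L
        self.dense1 = Dense(self.flat_dim, dense_units, rng)
        self.dense_out = Dense(dense_units, n_outputs, rng)
        self._cache = None

    # -- training path ------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Return output logits; apply :func:`sigmoid` for probabilities.

        With ``training=True`` batch statistics are used for normalization
        and inverted dropout is applied to the flattened features and the
        penultimate activations (``rng`` supplies the masks; no masks are
        drawn when it is None, making inference deterministic).
        """
        h = x.astype(np.float32)
        pre_pool_lengths = []
        pool_args = []
        for blk, bn in zip(self.blocks, self.bns):
            h = blk.forward(h)
            h = bn.forward(h, training)
            pre_pool_lengths.append(h.shape[1])
            if self.pool_mode == "max":
                h, arg = maxpool_forward(h, self.pool_width)
                pool_args.append(arg)
            else:
                h = avgpool_forward(h, self.pool_width)
                pool_args.append(None)
        N = h.shape[0]
        flat = h.reshape(N, self.flat_dim)
        drop = training and rng is not None and self.dropout > 0
        if drop:
            m1 = (rng.random(flat.shape) >= self.dropout) / (1 - self.dropout)
            flat = flat * m1.astype(np.float32)
        d1 = self.dense1.forward(flat)
        hidden = np.maximum(d1, 0)
        if drop:
            m2 = (rng.random(hidden.shape) >= self.dropout) / (1 - self.dropout)
            hidden = hidden * m2.astype(np.float32)
        else:
            m1 = m2 = None
        logits = self.dense_out.forward(hidden)
        self._cache = (d1, pre_pool_lengths, pool_args, h.shape, m1, m2)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        d1, pre_pool_lengths, pool_args, pooled_shape, m1, m2 = self._cache
        dh = self.dense_out.backward(dlogits)
        if m2 is not None:
            dh = dh * m2
        dd1 = dh * (d1 > 0)
        dflat = self.dense1.backward(dd1)
        if m1 is not None:
            dflat = dflat * m1
        dy = dflat.reshape(pooled_shape).astype(np.float32)
        n_blocks = len(self.blocks)
        for bi, (blk, bn, L, arg) in enumerate(zip(
            reversed(self.blocks), reversed(self.bns),
            reversed(pre_pool_lengths), reversed(pool_args),
        )):
            if self.pool_mode == "max":
                dy = maxpool_input_grad(dy, arg, self.pool_width, L)
            else:
                dy = avgpool_input_grad(dy, self.pool_width, L)
            dy = bn.backward(dy)
            # the first block's input gradient is never used
            dy = blk.backward(dy, need_input_grad=bi < n_blocks - 1)

    def zero_grads(self) -> None:
        for p, g in self.params:
            g[...] = 0

    @property
    def params(self):
        out = []
        for blk, bn in zip(self.blocks, self.bns):
            out += blk.params + bn.params
        out += self.dense1.params + self.dense_out.params
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.params, weights):
            p[...] = w

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(sigmoid(self.forward(x[i : i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    @property
    def n_conv_layers_in_blocks(self) -> int:
        return 2 * len(self.blocks)

    def layer_names(self) -> list[str]:
        """Addressable attribution targets, shallow to deep."""
        return [f"block{i + 1}" for i in range(len(self.blocks))] + ["penultimate", "output"]

    def layer_width(self, layer: str) -> int:
        if layer == "penultimate":
            return self.dense_units
        if layer == "output":
            return self.n_outputs
        if layer.startswith("block"):
            return self.filters[int(layer[5:]) - 1]
        raise KeyError(f"unknown layer {layer!r}; choose from {self.layer_names()}")

    # -- inference tape (used by the attribution module) -----------------

    def forward_tape(self, x: np.ndarray, dtype=np.float64) -> dict:
        """Eval-mode forward pass recording every primitive operation.

        Returns ``{"ops": [...], "values": {name: array}}`` where each op is
        a dict with kind, input node names, output node name, and parameter
        references.  float64 by default so reference-based contributions
        satisfy summation-to-delta tightly; float32 for bulk profiling.
        """
        ops: list[dict] = []
        vals: dict[str, np.ndarray] = {"input": x.astype(dtype)}

        def emit(kind: str, inputs: list[str], output: str, **kw) -> None:
            ops.append({"kind": kind, "inputs": inputs, "output": output, **kw})

        def W_(layer):
            return layer.W.astype(dtype)

        cur = "input"
        for i, (blk, bn) in enumerate(zip(self.blocks, self.bns)):
            pre = cur
            a = f"b{i}_conv1"
            vals[a], _ = conv1d_forward(vals[cur], W_(blk.conv1), blk.conv1.b.astype(dtype))
            emit("conv", [cur], a, W=W_(blk.conv1))
            r1 = f"b{i}_relu1"
            vals[r1] = np.maximum(vals[a], 0)
            emit("relu", [a], r1)
            c2 = f"b{i}_conv2"
            vals[c2], _ = conv1d_forward(vals[r1], W_(blk.conv2), blk.conv2.b.astype(dtype))
            emit("conv", [r1], c2, W=W_(blk.conv2))
            r2 = f"b{i}_relu2"
            vals[r2] = np.maximum(vals[c2], 0)
            emit("relu", [c2], r2)
            if blk.proj is not None:
                sh = f"b{i}_proj"
                vals[sh], _ = conv1d_forward(vals[pre], W_(blk.proj), blk.proj.b.astype(dtype))
                emit("conv", [pre], sh, W=W_(blk.proj))
            else:
                sh = pre
            add = f"b{i}_add"
            vals[add] = vals[r2] + vals[sh]
            emit("add", [r2, sh], add)
            bnn = f"b{i}_bn"
            scale, shift = bn.eval_scale_shift()
            vals[bnn] = (vals[add] * scale + shift).astype(dtype)
            emit("affine", [add], bnn, scale=scale.astype(dtype))
            pool = f"block{i + 1}"
            if self.pool_mode == "max":
                vals[pool], parg = maxpool_forward(vals[bnn], self.pool_width)
            else:
                vals[pool] = avgpool_forward(vals[bnn], self.pool_width)
                parg = None
            emit("pool", [bnn], pool, p=self.pool_width, L=vals[bnn].shape[-2],
                 mode=self.pool_mode, arg=parg)
            cur = pool
        flat = "flat"
        N = x.shape[0]
        vals[flat] = vals[cur].reshape(N, self.flat_dim)
        emit("flatten", [cur], flat, shape=vals[cur].shape)
        d1 = "dense1"
        vals[d1] = vals[flat] @ self.dense1.W.astype(dtype) + self.dense1.b
        emit("dense", [flat], d1, W=self.dense1.W.astype(dtype))
        pen = "penultimate"
        vals[pen] = np.maximum(vals[d1], 0)
        emit("relu", [d1], pen)
        out = "output"
        vals[out] = vals[pen] @ self.dense_out.W.astype(dtype) + self.dense_out.b
        emit("dense", [pen], out, W=self.dense_out.W.astype(dtype))
        return {"ops": ops, "values": vals}

    # -- persistence -----------------------------------------------------

    def architecture(self) -> dict:
        return {
            "input_length": self.input_length,
            "n_outputs": self.n_outputs,
            "filters": list(self.filters),
            "kernel_width": self.kernel_width,
            "pool_width": self.pool_width,
            "pool_mode": self.pool_mode,
            "dropout": self.dropout,
            "dense_units": self.dense_units,
        }


# ---------------------------------------------------------------------------
# optimizer and training loop


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.weight_decay and p.ndim > 1:  # decoupled decay, weights only
                p -= self.lr * self.weight_decay * p


def fit(
    model: ResNet1D,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    epochs: int = 60,
    batch_size: int = 64,
    lr: float = 1e-3,
    patience: int = 5,
    weight_decay: float = 0.0,
    lr_schedule: str = "cosine",
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Minimize mean binary cross-entropy with Adam and early stopping.

    Restores the best-validation-loss weights before returning.  Raises on
    NaN loss.  Returns a history dict with per-epoch train/val losses.
    ``lr_schedule``: "cosine" anneals the learning rate from ``lr`` to
    ``lr/20`` over the epoch budget; "constant" keeps it fixed.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr, weight_decay=weight_decay)
    n = len(x_train)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_weights = model.get_weights()
    bad_epochs = 0
    for epoch in range(epochs):
        if lr_schedule == "cosine":
            frac = epoch / max(epochs - 1, 1)
            opt.lr = lr / 20 + (lr - lr / 20) * 0.5 * (1 + np.cos(np.pi * frac))
        order = rng.permutation(n)
        tot = 0.0
        nb = 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, training=True, rng=rng)
            loss, dz = bce_with_logits(logits, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(f"NaN/inf training loss at epoch {epoch + 1}")
            model.zero_grads()
            model.backward(dz)
            opt.step()
            tot += loss
            nb += 1
        vl = evaluate_loss(model, x_val, y_val, batch_size)
        history["train_loss"].append(tot / max(nb, 1))
        history["val_loss"].append(vl)
        if verbose:
            print(f"epoch {epoch + 1}: train {tot / max(nb, 1):.4f} val {vl:.4f}")
        if vl < best_loss - 1e-6:
            best_loss = vl
            best_weights = model.get_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break
    model.set_weights(best_weights)
    return history


def evaluate_loss(model: ResNet1D, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
    tot, cnt = 0.0, 0
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], training=False)
        loss, _ = bce_with_logits(logits, y[i : i + batch_size])
        tot += loss * logits.size
        cnt += logits.size
    return tot / max(cnt, 1)
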