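"""Transformer-based disease diagnosis from selected CpG-site beta vectors.

The classifier consumes a length-d vector of beta values (d = number of
selected sites, default 400) and produces a two-class probability:

1. the vector is laid out as a token sequence and passed through a
   multi-head self-attention Transformer encoder, giving features H;
2. a *dynamic residual* (highway-style) layer mixes an affine transform
   T = H·W_fc + b_fc with the identity path through a sigmoid gate
   G = sigma(H·W_gate + b_gate):   O = G⊙T + (1−G)⊙H;
3. a linear head with softmax yields P(healthy), P(disease).

Two token layouts exist.  The default ``"single"`` treats the whole vector as
one token of width d — under which self-attention over positions is
degenerate (softmax over one position) and the encoder acts as a stack of
per-token maps; it is kept as the default for fidelity to the model's
published formulation.  ``"per-site"`` gives each site its own token,
embedded to ``embed_dim`` with a learned positional embedding and mean-pooled
after the encoder, which is the layout under which cross-site attention is
meaningful.  In per-site mode the residual/classifier dimension is
``embed_dim``.

Everything runs in float64 on the in-repo autodiff engine; training uses
Adam with minibatches, optional early stopping, and is bit-deterministic for
a fixed seed on one platform.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .autograd import Tensor, softmax, softmax_cross_entropy
from .io import ValidationError

__all__ = [
    "TrainConfig",
    "DynamicResidualParams",
    "DiagnosisModel",
    "init_model",
    "dynamic_residual_forward",
    "model_forward",
    "train_model",
    "predict",
    "predict_matrix",
]


@dataclass
class TrainConfig:
    """Optimization settings (the published model states none; these are ours)."""

    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 3e-4
    optimizer: str = "adam"
    weight_decay: float = 0.0
    dropout: float = 0.1
    patience: int = 20
    min_delta: float = 1e-4
    val_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValidationError(f"unknown optimizer {self.optimizer!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must be in [0, 1)")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValidationError("val_fraction must be in [0, 1)")


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-free sigmoid; saturates to exactly 0/1 at extreme inputs."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class DynamicResidualParams:
    """Weights of the gated residual layer (all shapes d x d or d)."""

    W_fc: np.ndarray
    b_fc: np.ndarray
    W_gate: np.ndarray
    b_gate: np.ndarray

    def validate(self) -> None:
        d = self.W_fc.shape[0]
        if self.W_fc.shape != (d, d) or self.W_gate.shape != (d, d):
            raise ValidationError("residual weight matrices must be d x d")
        if self.b_fc.shape != (d,) or self.b_gate.shape != (d,):
            raise ValidationError("residual biases must be length d")


def dynamic_residual_forward(
    H: np.ndarray, params: DynamicResidualParams
) -> np.ndarray:
    """Gated residual mixing O = G⊙T + (1−G)⊙H (pure numpy, float64).

    T = H·W_fc + b_fc is the transform path, G = sigma(H·W_gate + b_gate)
    the per-feature gate.  With the gate saturated closed the output is H
    exactly; saturated open it is T exactly.
    """
    H = np.asarray(H, dtype=float)
    params.validate()
    d = params.W_fc.shape[0]
    if H.shape[-1] != d:
        raise ValidationError(
            f"feature vector has width {H.shape[-1]}, residual layer expects {d}"
        )
    T = H @ params.W_fc + params.b_fc
    G = _stable_sigmoid(H @ params.W_gate + params.b_gate)
    return G * T + (1.0 - G) * H


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, (fan_in, fan_out))


class DiagnosisModel:
    """Encoder + dynamic residual + softmax classifier over numpy autodiff.

    Parameters
    ----------
    d : int
        Input width = number of selected CpG sites.
    layers, heads : int
        Encoder depth and attention head count; the working width
        (d in ``"single"`` layout, ``embed_dim`` in ``"per-site"``) must be
        divisible by ``heads``.
    use_dynamic_residual : bool
        False gives the ablation baseline: encoder output feeds the
        classifier directly.
    """

    def __init__(
        self,
        d: int,
        layers: int = 2,
        heads: int = 4,
        use_dynamic_residual: bool = True,
        token_layout: str = "single",
        embed_dim: int = 32,
        ff_mult: int = 2,
        dropout: float = 0.1,
        seed: int = 0,
        site_ids: Sequence[str] | None = None,
    ):
        if token_layout not in ("single", "per-site"):
            raise ValidationError(f"unknown token layout {token_layout!r}")
        width = d if token_layout == "single" else embed_dim
        if width % heads != 0:
            raise ValidationError(
                f"model width {width} not divisible by heads {heads}"
            )
        if layers < 1:
            raise ValidationError("need at least one encoder layer")
        self.d = int(d)
        self.layers = int(layers)
        self.heads = int(heads)
        self.use_dynamic_residual = bool(use_dynamic_residual)
        self.token_layout = token_layout
        self.embed_dim = int(embed_dim)
        self.ff_mult = int(ff_mult)
        self.dropout = float(dropout)
        self.seed = int(seed)
        self.site_ids = list(site_ids) if site_ids is not None else None
        self._build(np.random.default_rng(seed))

    # -- parameters -----------------------------------------------------
    @property
    def width(self) -> int:
        return self.d if self.token_layout == "single" else self.embed_dim

    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def _build(self, rng: np.random.Generator) -> None:
        self._params: dict[str, Tensor] = {}
        E, F = self.width, self.width * self.ff_mult
        if self.token_layout == "per-site":
            self._param("embed_w", _xavier(rng, 1, E))
            self._param("embed_b", np.zeros(E))
            self._param("pos", 0.02 * rng.standard_normal((self.d, E)))
        for l in range(self.layers):
            for nm in ("q", "k", "v", "o"):
                self._param(f"enc{l}_W{nm}", _xavier(rng, E, E))
                self._param(f"enc{l}_b{nm}", np.zeros(E))
            self._param(f"enc{l}_ln1_g", np.ones(E))
            self._param(f"enc{l}_ln1_b", np.zeros(E))
            self._param(f"enc{l}_W1", _xavier(rng, E, F))
            self._param(f"enc{l}_b1", np.zeros(F))
            self._param(f"enc{l}_W2", _xavier(rng, F, E))
            self._param(f"enc{l}_b2", np.zeros(E))
            self._param(f"enc{l}_ln2_g", np.ones(E))
            self._param(f"enc{l}_ln2_b", np.zeros(E))
        if self.use_dynamic_residual:
            self._param("res_W_fc", _xavier(rng, E, E))
            self._param("res_b_fc", np.zeros(E))
            self._param("res_W_gate", _xavier(rng, E, E))
            self._param("res_b_gate", np.zeros(E))
        self._param("W_class", _xavier(rng, E, 2))
        self._param("b_class", np.zeros(2))

    def parameters(self) -> dict[str, Tensor]:
        return self._params

    @property
    def residual_params(self) -> DynamicResidualParams:
        if not self.use_dynamic_residual:
            raise ValidationError("baseline model has no dynamic residual layer")
        p = self._params
        return DynamicResidualParams(
            W_fc=p["res_W_fc"].data,
            b_fc=p["res_b_fc"].data,
            W_gate=p["res_W_gate"].data,
            b_gate=p["res_b_gate"].data,
        )

    # -- forward --------------------------------------------------------
    def _attention(self, x: Tensor, l: int, rng) -> Tensor:
        n, S, E = x.shape
        h, hd = self.heads, E // self.heads
        p = self._params

        def split(t: Tensor) -> Tensor:
            return t.reshape(n, S, h, hd).transpose(0, 2, 1, 3)

        q = split(x @ p[f"enc{l}_Wq"] + p[f"enc{l}_bq"])
        k = split(x @ p[f"enc{l}_Wk"] + p[f"enc{l}_bk"])
        v = split(x @ p[f"enc{l}_Wv"] + p[f"enc{l}_bv"])
        scores = (q @ k.transpose(0, 1, 3, 2)) / np.sqrt(hd)
        attn = scores.softmax_last().dropout(self.dropout, rng)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, S, E)
        return out @ p[f"enc{l}_Wo"] + p[f"enc{l}_bo"]

    def _encoder(self, x: Tensor, rng) -> Tensor:
        p = self._params
        for l in range(self.layers):
            a = self._attention(x, l, rng).dropout(self.dropout, rng)
            x = (x + a).layer_norm(p[f"enc{l}_ln1_g"], p[f"enc{l}_ln1_b"])
            f = ((x @ p[f"enc{l}_W1"] + p[f"enc{l}_b1"]).relu()
                 @ p[f"enc{l}_W2"] + p[f"enc{l}_b2"]).dropout(self.dropout, rng)
            x = (x + f).layer_norm(p[f"enc{l}_ln2_g"], p[f"enc{l}_ln2_b"])
        return x

    def forward(self, X: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        """Logits (n, 2); pass a generator to enable dropout (training mode)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = X.shape[0]
        if X.shape[1] != self.d:
            raise ValidationError(
                f"input has {X.shape[1]} sites, model expects {self.d}"
            )
        p = self._params
        if self.token_layout == "single":
            x = Tensor(X).reshape(n, 1, self.d)
        else:
            tokens = Tensor(X).reshape(n, self.d, 1)
            x = tokens @ p["embed_w"] + p["embed_b"] + p["pos"]
        hfeat = self._encoder(x, rng)
        if self.token_layout == "single":
            H = hfeat.reshape(n, self.width)
        else:
            H = hfeat.mean_axis(1)
        if self.use_dynamic_residual:
            T = H @ p["res_W_fc"] + p["res_b_fc"]
            G = (H @ p["res_W_gate"] + p["res_b_gate"]).sigmoid()
            O = G * T + (1.0 - G) * H
        else:
            O = H
        return O @ p["W_class"] + p["b_class"]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-sample class probabilities (evaluation mode, deterministic)."""
        return softmax(self.forward(X, rng=None).data)

    # -- persistence ----------------------------------------------------
    def save(self, directory: str | os.PathLike) -> None:
        """Write architecture + site order (JSON) and weights (npz)."""
        path = Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        config = {
            "d": self.d,
            "layers": self.layers,
            "heads": self.heads,
            "use_dynamic_residual": self.use_dynamic_residual,
            "token_layout": self.token_layout,
            "embed_dim": self.embed_dim,
            "ff_mult": self.ff_mult,
            "dropout": self.dropout,
            "seed": self.seed,
            "site_ids": self.site_ids,
        }
        (path / "config.json").write_text(json.dumps(config, indent=2))
        np.savez(path / "weights.npz", **{k: t.data for k, t in self._params.items()})

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "DiagnosisModel":
        path = Path(directory)
        config = json.loads((path / "config.json").read_text())
        model = cls(**config)
        with np.load(path / "weights.npz") as weights:
            for k, t in model._params.items():
                t.data = np.asarray(weights[k], dtype=float)
        return model


def compatible_heads(d: int, requested: int = 4) -> int:
    """Largest head count <= requested dividing the model width ``d``."""
    for h in range(min(requested, d), 0, -1):
        if d % h == 0:
            return h
    return 1


def init_model(
    d: int,
    layers: int = 2,
    heads: int = 4,
    use_dynamic_residual: bool = True,
    seed: int = 0,
    **kwargs,
) -> DiagnosisModel:
    """Deterministically initialize a diagnosis model (same seed, same weights)."""
    return DiagnosisModel(
        d=d,
        layers=layers,
        heads=heads,
        use_dynamic_residual=use_dynamic_residual,
        seed=seed,
        **kwargs,
    )


def model_forward(C: np.ndarray, model: DiagnosisModel) -> np.ndarray:
    """Probability pair for a single length-d beta vector (evaluation mode)."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 1 or C.size != model.d:
        raise ValidationError(f"expected a length-{model.d} vector, got shape {C.shape}")
    return model.predict_proba(C[None, :])[0]


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SGD:
    def __init__(self, params: dict[str, Tensor], lr: float, weight_decay: float):
        self.params, self.lr, self.wd = params, lr, weight_decay

    def step(self) -> None:
        for p in self.params.values():
            if p.grad is not None:
                p.data = p.data - self.lr * (p.grad + self.wd * p.data)


def _stratified_holdout(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/validation index split."""
    train, val = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        n_val = max(1, int(round(fraction * idx.size))) if fraction > 0 else 0
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train, dtype=int)), np.sort(np.array(val, dtype=int))


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    model: DiagnosisModel | None = None,
    **model_args,
) -> tuple[DiagnosisModel, dict]:
    """Train by minibatch cross-entropy; returns the model and its history.

    ``history`` maps "train_loss" (and "val_loss" when a validation fraction
    is configured) to per-epoch values.  Early stopping restores the best
    validation-loss weights after ``patience`` non-improving epochs.
    Identical data + config + seed give identical final weights.
    """
    config = config or TrainConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X must be (n_samples, d) aligned with labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("training labels contain a single class")
    if counts.min() < 2:
        raise ValidationError("need at least two samples per class")
    if model is None:
        model = DiagnosisModel(d=X.shape[1], seed=config.seed,
                               dropout=config.dropout, **model_args)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    if config.val_fraction > 0:
        tr_idx, val_idx = _stratified_holdout(y, config.val_fraction, rng)
        X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    else:
        X_tr, y_tr, X_val, y_val = X, y, None, None

    optim_cls = _Adam if config.optimizer == "adam" else _SGD
    optim = optim_cls(model.parameters(), config.learning_rate, config.weight_decay)
    history: dict[str, list[float]] = {"train_loss": []}
    if X_val is not None:
        history["val_loss"] = []
    best_val = np.inf
    best_weights: dict[str, np.ndarray] | None = None
    stale = 0
    n = X_tr.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            for t in model.parameters().values():
                t.zero_grad()
            logits = model.forward(X_tr[batch], rng=rng)
            loss = softmax_cross_entropy(logits, y_tr[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            loss.backward()
            optim.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))
        if X_val is not None:
            val_logits = model.forward(X_val, rng=None)
            val_loss = float(softmax_cross_entropy(val_logits, y_val).data)
            history["val_loss"].append(val_loss)
            if val_loss < best_val - config.min_delta:
                best_val = val_loss
                best_weights = {k: t.data.copy() for k, t in model.parameters().items()}
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_weights is not None:
        for k, t in model.parameters().items():
            t.data = best_weights[k]
    return model, history


def predict(model: DiagnosisModel, X: np.ndarray) -> np.ndarray:
    """Per-sample (P(healthy), P(disease)) pairs; rows follow input order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return model.predict_proba(X)


def predict_matrix(model: DiagnosisModel, matrix) -> np.ndarray:
    """Predict from a MethylationMatrix, enforcing the training site order."""
    if model.site_ids is not None:
        if list(matrix.site_ids) != list(model.site_ids):
            for got, want in zip(matrix.site_ids, model.site_ids):
                if got != want:
                    raise ValidationError(
                        f"site order mismatch: matrix has {got!r} where the "
                        f"model expects {want!r}"
                    )
            raise ValidationError(
                "matrix site list length differs from the model's site order"
            )
    return predict(model, matrix.betas)
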