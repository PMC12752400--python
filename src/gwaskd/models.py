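"""Wide-Deep teacher/student networks with multi-head self-attention.

The architecture combines

* a **wide** path — a linear map over raw SNP dosages and configured
  cross-product features ``phi(x) = (x_a * x_b)`` capturing memorised
  low-order interactions:  ``y_wide = W_wide^T [x, phi(x)] + b``;
* a **deep** path — each SNP's scalar dosage is embedded into a learned
  per-position token, optionally transformed by multi-head scaled
  dot-product self-attention
  (``softmax(Q K^T / sqrt(d_k)) V`` per head, heads concatenated and
  projected by ``W_O``), globally average-pooled over SNP tokens, then
  passed through dense layers ``a^(l+1) = f(W^(l) a^(l) + b^(l))``;
* a **fusion** output — the classification probability is
  ``sigmoid(w_out^T a^(L) + y_wide + b_out)``.

For distillation the scalar fused logit ``z`` is presented as the class
logit pair ``(z_0, z_1) = (0, z)`` so that the two-class softmax at
temperature 1 coincides exactly with the sigmoid probability.

Everything is plain numpy with hand-derived backpropagation; training uses
Adam with optional early stopping, deterministic given its seed. The MHA
block follows the scaled dot-product equations exactly: no residual
connection, layer norm, or projection biases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit, ndtr

__all__ = [
    "WideConfig",
    "DeepConfig",
    "AttentionConfig",
    "TeacherModel",
    "StudentModel",
    "wide_forward",
    "multi_head_attention",
    "teacher_forward",
    "extract_features",
    "build_student",
    "train_teacher",
    "default_teacher_configs",
    "default_student_reduction",
]


# --------------------------------------------------------------------------
# configs


@dataclass
class WideConfig:
    """Wide-path layout: raw dosages plus dosage cross-products."""

    cross_product_pairs: list[tuple[int, int]] = field(default_factory=list)
    include_raw: bool = True

    def __post_init__(self) -> None:
        for a, b in self.cross_product_pairs:
            if a == b:
                raise ValueError("cross-product pair indices must differ")
            if a < 0 or b < 0:
                raise ValueError("negative SNP index in cross-product pair")


@dataclass
class DeepConfig:
    """Deep-path layout: per-SNP embedding width and dense stack."""

    embedding_dim: int = 16
    hidden_layer_sizes: Sequence[int] = (128, 64)
    activation: str = "relu"
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be positive")
        if len(self.hidden_layer_sizes) < 1:
            raise ValueError("need at least one hidden layer")
        if any(h < 1 for h in self.hidden_layer_sizes):
            raise ValueError("hidden layer sizes must be positive")
        if self.activation not in ("relu", "gelu"):
            raise ValueError("activation must be 'relu' or 'gelu'")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class AttentionConfig:
    """Multi-head self-attention layout over SNP tokens."""

    n_heads: int = 4
    key_dim: int = 8

    def __post_init__(self) -> None:
        if self.n_heads < 1 or self.key_dim < 1:
            raise ValueError("n_heads and key_dim must be positive")


# --------------------------------------------------------------------------
# activations


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    # exact GELU: z * Phi(z)
    return z * ndtr(z)


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    phi = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    return ndtr(z) + z * phi


def _softmax_lastaxis(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# the network


class WideDeepNet:
    """Parameter container + forward/backward for the fused architecture."""

    def __init__(
        self,
        n_snps: int,
        wide: WideConfig,
        deep: DeepConfig,
        attention: AttentionConfig | None,
        seed: int = 0,
    ) -> None:
        for a, b in wide.cross_product_pairs:
            if a >= n_snps or b >= n_snps:
                raise ValueError(
                    f"cross-product index out of range for {n_snps} SNPs"
                )
        self.n_snps = n_snps
        self.wide = wide
        self.deep = deep
        self.attention = attention
        self.seed = seed
        rng = np.random.default_rng(seed)
        p, d = n_snps, deep.embedding_dim

        def glorot(*shape: int) -> np.ndarray:
            fan_in, fan_out = shape[-2], shape[-1]
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.params: dict[str, np.ndarray] = {}
        n_wide = (p if wide.include_raw else 0) + len(wide.cross_product_pairs)
        self.n_wide = n_wide
        if n_wide:
            self.params["w_wide"] = rng.normal(0.0, 0.01, size=n_wide)
        self.params["embed_W"] = rng.normal(0.0, 0.5, size=(p, d))
        self.params["embed_b"] = np.zeros((p, d))
        if attention is not None:
            h, dk = attention.n_heads, attention.key_dim
            self.params["att_Wq"] = glorot(h, d, dk)
            self.params["att_Wk"] = glorot(h, d, dk)
            self.params["att_Wv"] = glorot(h, d, dk)
            self.params["att_Wo"] = glorot(h * dk, d)
        sizes = [d, *deep.hidden_layer_sizes]
        for i in range(len(deep.hidden_layer_sizes)):
            self.params[f"dense{i}_W"] = glorot(sizes[i], sizes[i + 1])
            self.params[f"dense{i}_b"] = np.zeros(sizes[i + 1])
        self.params["out_w"] = glorot(sizes[-1], 1)[:, 0]
        self.params["out_b"] = np.zeros(())

    # -- helpers ------------------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def wide_features(self, X: np.ndarray) -> np.ndarray:
        cols = []
        if self.wide.include_raw:
            cols.append(X)
        for a, b in self.wide.cross_product_pairs:
            cols.append((X[:, a] * X[:, b])[:, None])
        if not cols:
            return np.zeros((X.shape[0], 0))
        return np.concatenate(cols, axis=1)

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, dict]:
        """Return the fused scalar logit per sample and a backprop cache."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_snps:
            raise ValueError(
                f"expected {self.n_snps} SNP columns, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        P = self.params
        cache: dict = {"X": X}

        wf = self.wide_features(X)
        cache["wide_feats"] = wf
        y_wide = wf @ P["w_wide"] if self.n_wide else np.zeros(X.shape[0])

        tokens = X[:, :, None] * P["embed_W"][None] + P["embed_b"][None]
        cache["tokens"] = tokens
        t_in = tokens
        if self.attention is not None:
            att_cache, t_in = self._mha_forward(tokens)
            cache["att"] = att_cache
        cache["att_out"] = t_in
        pooled = t_in.mean(axis=1)
        cache["pooled"] = pooled

        a = pooled
        acts = []
        for i in range(len(self.deep.hidden_layer_sizes)):
            z = a @ P[f"dense{i}_W"] + P[f"dense{i}_b"]
            a = _act(self.deep.activation, z)
            drop = None
            if train and self.deep.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training forward needs an rng for dropout")
                keep = 1.0 - self.deep.dropout_rate
                drop = (rng.uniform(size=a.shape) < keep) / keep
                a = a * drop
            acts.append({"z": z, "a": a, "drop": drop})
        cache["acts"] = acts

        logit = a @ P["out_w"] + y_wide + P["out_b"]
        cache["a_last"] = a
        return logit, cache

    def _mha_forward(self, T: np.ndarray) -> tuple[dict, np.ndarray]:
        P = self.params
        h = self.attention.n_heads
        dk = self.attention.key_dim
        heads, per_head = [], []
        for i in range(h):
            Q = T @ P["att_Wq"][i]
            K = T @ P["att_Wk"][i]
            V = T @ P["att_Wv"][i]
            S = Q @ K.transpose(0, 2, 1) / np.sqrt(dk)
            A = _softmax_lastaxis(S)
            H = A @ V
            heads.append(H)
            per_head.append({"Q": Q, "K": K, "V": V, "A": A})
        cat = np.concatenate(heads, axis=-1)
        out = cat @ P["att_Wo"]
        return {"per_head": per_head, "cat": cat, "weights": [c["A"] for c in per_head]}, out

    # -- backward -----------------------------------------------------------

    def backward(self, dlogit: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss wrt every parameter, given dL/dlogit."""
        P = self.params
        grads: dict[str, np.ndarray] = {}
        X = cache["X"]

        if self.n_wide:
            grads["w_wide"] = cache["wide_feats"].T @ dlogit
        grads["out_w"] = cache["a_last"].T @ dlogit
        grads["out_b"] = np.asarray(dlogit.sum())

        da = dlogit[:, None] * P["out_w"][None, :]
        acts = cache["acts"]
        for i in range(len(acts) - 1, -1, -1):
            layer = acts[i]
            if layer["drop"] is not None:
                da = da * layer["drop"]
            dz = da * _act_grad(self.deep.activation, layer["z"])
            a_prev = cache["pooled"] if i == 0 else acts[i - 1]["a"]
            grads[f"dense{i}_W"] = a_prev.T @ dz
            grads[f"dense{i}_b"] = dz.sum(axis=0)
            da = dz @ P[f"dense{i}_W"].T

        # pooled = mean over p tokens
        p = self.n_snps
        dtin = np.repeat(da[:, None, :] / p, p, axis=1)

        if self.attention is not None:
            dtokens = self._mha_backward(dtin, cache, grads)
        else:
            dtokens = dtin

        grads["embed_W"] = np.einsum("np,npd->pd", X, dtokens)
        grads["embed_b"] = dtokens.sum(axis=0)
        return grads

    def _mha_backward(
        self, dout: np.ndarray, cache: dict, grads: dict
    ) -> np.ndarray:
        P = self.params
        att = cache["att"]
        T = cache["tokens"]
        h = self.attention.n_heads
        dk = self.attention.key_dim

        grads["att_Wo"] = np.einsum("npk,npd->kd", att["cat"], dout)
        dcat = dout @ P["att_Wo"].T
        dT = np.zeros_like(T)
        grads["att_Wq"] = np.zeros_like(P["att_Wq"])
        grads["att_Wk"] = np.zeros_like(P["att_Wk"])
        grads["att_Wv"] = np.zeros_like(P["att_Wv"])
        for i in range(h):
            hc = att["per_head"][i]
            dH = dcat[..., i * dk : (i + 1) * dk]
            dA = dH @ hc["V"].transpose(0, 2, 1)
            dV = hc["A"].transpose(0, 2, 1) @ dH
            A = hc["A"]
            dS = A * (dA - (A * dA).sum(axis=-1, keepdims=True))
            dS = dS / np.sqrt(dk)
            dQ = dS @ hc["K"]
            dK = dS.transpose(0, 2, 1) @ hc["Q"]
            dT += dQ @ P["att_Wq"][i].T
            dT += dK @ P["att_Wk"][i].T
            dT += dV @ P["att_Wv"][i].T
            grads["att_Wq"][i] = np.einsum("npd,npk->dk", T, dQ)
            grads["att_Wk"][i] = np.einsum("npd,npk->dk", T, dK)
            grads["att_Wv"][i] = np.einsum("npd,npk->dk", T, dV)
        return dT

    # -- persistence --------------------------------------------------------

    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()


class _Adam:
    """Standard Adam optimiser over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= (
                self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            )


# --------------------------------------------------------------------------
# public model classes


class TeacherModel:
    """Wide-Deep(+MHA) teacher: full-size network for the source cohort."""

    role = "teacher"

    def __init__(
        self,
        n_snps: int,
        wide: WideConfig | None = None,
        deep: DeepConfig | None = None,
        attention: AttentionConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.wide_config = wide or WideConfig()
        self.deep_config = deep or DeepConfig()
        self.attention_config = attention
        self.net = WideDeepNet(
            n_snps, self.wide_config, self.deep_config, attention, seed
        )
        self.n_snps = n_snps
        self.history: dict | None = None

    # inference ----------------------------------------------------------

    def logits(self, X: np.ndarray) -> np.ndarray:
        """Class-logit pairs ``(0, z)`` per sample (distillation convention)."""
        z, _ = self.net.forward(X, train=False)
        return np.stack([np.zeros_like(z), z], axis=1)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(case | x) = sigmoid of the fused logit."""
        z, _ = self.net.forward(X, train=False)
        return expit(z)

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def parameter_count(self) -> int:
        return self.net.parameter_count()

    # layer access ---------------------------------------------------------

    def layer_names(self) -> list[str]:
        names = ["embedding", "pooled"]
        if self.attention_config is not None:
            names.insert(1, "attention")
        names += [
            f"hidden_{i}"
            for i in range(len(self.deep_config.hidden_layer_sizes))
        ]
        names.append("fusion")
        return names

    def architecture_dict(self) -> dict:
        return {
            "role": self.role,
            "n_snps": self.n_snps,
            "wide": asdict(self.wide_config),
            "deep": {
                **asdict(self.deep_config),
                "hidden_layer_sizes": list(self.deep_config.hidden_layer_sizes),
            },
            "attention": (
                asdict(self.attention_config)
                if self.attention_config is not None
                else None
            ),
            "seed": self.net.seed,
            "parameter_count": self.parameter_count(),
        }

    # persistence ----------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.net.params)
        (directory / "architecture.json").write_text(
            json.dumps(self.architecture_dict(), indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TeacherModel":
        directory = Path(directory)
        arch = json.loads((directory / "architecture.json").read_text())
        model = _model_from_arch(arch)
        weights = np.load(directory / "weights.npz")
        model.net.set_params({k: weights[k] for k in weights.files})
        return model


class StudentModel(TeacherModel):
    """Reduced Wide-Deep network; strictly fewer parameters than its teacher."""

    role = "student"

    def __init__(
        self,
        n_snps: int,
        wide: WideConfig | None = None,
        deep: DeepConfig | None = None,
        attention: AttentionConfig | None = None,
        seed: int = 0,
        teacher_parameter_count: int | None = None,
    ) -> None:
        super().__init__(n_snps, wide, deep, attention, seed)
        self.teacher_parameter_count = teacher_parameter_count
        if (
            teacher_parameter_count is not None
            and self.parameter_count() >= teacher_parameter_count
        ):
            raise ValueError(
                f"student has {self.parameter_count()} parameters, "
                f"not strictly fewer than teacher's {teacher_parameter_count}"
            )


def _model_from_arch(arch: dict) -> TeacherModel:
    cls = StudentModel if arch.get("role") == "student" else TeacherModel
    wide = WideConfig(
        cross_product_pairs=[tuple(p) for p in arch["wide"]["cross_product_pairs"]],
        include_raw=arch["wide"]["include_raw"],
    )
    deep = DeepConfig(**arch["deep"])
    att = AttentionConfig(**arch["attention"]) if arch["attention"] else None
    kwargs = {}
    if cls is StudentModel:
        kwargs["teacher_parameter_count"] = None
    return cls(arch["n_snps"], wide, deep, att, seed=arch.get("seed", 0), **kwargs)


# --------------------------------------------------------------------------
# spec operations


def wide_forward(x: np.ndarray, wide: WideConfig, w_wide: np.ndarray, b: float = 0.0):
    """Wide-path output ``W_wide^T [x, phi(x)] + b`` for one dosage vector."""
    x = np.asarray(x, dtype=float)
    feats = [x] if wide.include_raw else []
    for a, bb in wide.cross_product_pairs:
        if a >= x.size or bb >= x.size:
            raise ValueError("cross-product index out of range")
        feats.append(np.array([x[a] * x[bb]]))
    vec = np.concatenate(feats) if feats else np.zeros(0)
    w_wide = np.asarray(w_wide, dtype=float)
    if w_wide.shape != vec.shape:
        raise ValueError(f"weight length {w_wide.size} != feature length {vec.size}")
    return float(vec @ w_wide + b)


def multi_head_attention(
    X: np.ndarray,
    attention: AttentionConfig,
    Wq: np.ndarray,
    Wk: np.ndarray,
    Wv: np.ndarray,
    Wo: np.ndarray,
    return_weights: bool = False,
):
    """Self-attention over token rows of ``X`` with explicit projections.

    ``Wq/Wk/Wv`` have shape ``(n_heads, d_model, key_dim)`` and ``Wo``
    ``(n_heads*key_dim, d_model)``. Returns the transformed token matrix
    (and per-head attention weights when requested).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a (tokens, d_model) matrix")
    h, dk = attention.n_heads, attention.key_dim
    if Wq.shape != (h, X.shape[1], dk):
        raise ValueError("Wq shape mismatch with attention config and X")
    heads, weights = [], []
    for i in range(h):
        Q, K, V = X @ Wq[i], X @ Wk[i], X @ Wv[i]
        A = _softmax_lastaxis(Q @ K.T / np.sqrt(dk))
        heads.append(A @ V)
        weights.append(A)
    out = np.concatenate(heads, axis=-1) @ Wo
    if return_weights:
        return out, weights
    return out


def teacher_forward(model: TeacherModel, X: np.ndarray):
    """Run the fused forward pass: returns (logit pairs, probabilities)."""
    z, _ = model.net.forward(np.asarray(X, dtype=float), train=False)
    pairs = np.stack([np.zeros_like(z), z], axis=1)
    return pairs, expit(z)


def extract_features(
    model: TeacherModel, X: np.ndarray, layer: str | None = None
) -> np.ndarray:
    """Activations of a named layer in inference mode (default: last hidden).

    Layer names: ``embedding`` (pooled over tokens for a 2-D result),
    ``attention`` (pooled), ``pooled``, ``hidden_0`` .. ``hidden_{L-1}``,
    and ``fusion`` — the last hidden activations concatenated with the
    wide-path output, i.e. the full representation feeding the output unit.
    """
    names = model.layer_names()
    if layer is None:
        layer = f"hidden_{len(model.deep_config.hidden_layer_sizes) - 1}"
    if layer not in names:
        raise ValueError(f"unknown layer {layer!r}; available: {names}")
    X = np.asarray(X, dtype=float)
    _, cache = model.net.forward(X, train=False)
    if layer == "embedding":
        return cache["tokens"].mean(axis=1)
    if layer == "attention":
        return cache["att_out"].mean(axis=1)
    if layer == "pooled":
        return cache["pooled"]
    if layer == "fusion":
        if model.net.n_wide:
            y_wide = model.net.wide_features(X) @ model.net.params["w_wide"]
        else:
            y_wide = np.zeros(X.shape[0])
        return np.column_stack([cache["a_last"], y_wide])
    i = int(layer.split("_")[1])
    return cache["acts"][i]["a"]


@dataclass
class StudentReduction:
    """Shrink factors in (0, 1] applied to the teacher architecture."""

    head_factor: float = 0.5
    layer_factor: float = 0.5
    width_factor: float = 0.5

    def __post_init__(self) -> None:
        for f in (self.head_factor, self.layer_factor, self.width_factor):
            if not 0 < f <= 1:
                raise ValueError("shrink factors must lie in (0, 1]")


def default_student_reduction() -> StudentReduction:
    return StudentReduction()


def build_student(
    teacher: TeacherModel,
    reduction: StudentReduction | None = None,
    seed: int = 0,
) -> StudentModel:
    """Shrink the teacher's architecture into a strictly smaller student."""
    red = reduction or StudentReduction()
    t_deep = teacher.deep_config
    n_layers = max(1, int(round(len(t_deep.hidden_layer_sizes) * red.layer_factor)))
    sizes = [
        max(1, int(round(s * red.width_factor)))
        for s in t_deep.hidden_layer_sizes[:n_layers]
    ]
    deep = DeepConfig(
        embedding_dim=max(1, int(round(t_deep.embedding_dim * red.width_factor))),
        hidden_layer_sizes=sizes,
        activation=t_deep.activation,
        dropout_rate=t_deep.dropout_rate,
    )
    att = None
    if teacher.attention_config is not None:
        t_att = teacher.attention_config
        att = AttentionConfig(
            n_heads=max(1, int(round(t_att.n_heads * red.head_factor))),
            key_dim=max(1, int(round(t_att.key_dim * red.width_factor))),
        )
    return StudentModel(
        teacher.n_snps,
        wide=teacher.wide_config,
        deep=deep,
        attention=att,
        seed=seed,
        teacher_parameter_count=teacher.parameter_count(),
    )


# --------------------------------------------------------------------------
# training


def train_teacher(
    model: TeacherModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 30,
    batch_size: int = 64,
    learning_rate: float = 0.01,
    seed: int = 0,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int = 10,
) -> dict:
    """Fit the teacher with binary cross-entropy and Adam.

    Early stopping monitors validation loss with the given patience and
    restores the best weights. Returns a history dict of per-epoch losses.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    opt = _Adam(model.net.params, lr=learning_rate)
    n = X.shape[0]
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = model.net.get_params()
    stale = 0

    for _epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logit, cache = model.net.forward(X[idx], train=True, rng=rng)
            p = expit(logit)
            eps = 1e-12
            loss = -np.mean(
                y[idx] * np.log(p + eps) + (1 - y[idx]) * np.log(1 - p + eps)
            )
            dlogit = (p - y[idx]) / idx.size
            grads = model.net.backward(dlogit, cache)
            opt.step(model.net.params, grads)
            losses.append(loss)
        history["train_loss"].append(float(np.mean(losses)))

        if X_val is not None:
            zv, _ = model.net.forward(X_val, train=False)
            pv = expit(zv)
            eps = 1e-12
            val_loss = -np.mean(
                y_val * np.log(pv + eps) + (1 - y_val) * np.log(1 - pv + eps)
            )
            history["val_loss"].append(float(val_loss))
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = model.net.get_params()
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break

    if X_val is not None:
        model.net.set_params(best_params)
    model.history = history
    return history


def default_teacher_configs(
    n_snps: int,
    cross_product_pairs: list[tuple[int, int]] | None = None,
    with_attention: bool = True,
) -> tuple[WideConfig, DeepConfig, AttentionConfig | None]:
    """Default teacher layout: embed 16, 4 heads, hidden [128, 64]."""
    wide = WideConfig(cross_product_pairs=cross_product_pairs or [])
    deep = DeepConfig()
    att = AttentionConfig() if with_attention else None
    return wide, deep, att
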