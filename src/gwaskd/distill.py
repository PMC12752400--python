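"""Temperature-softmax knowledge distillation from teacher to student.

The teacher's class-logit pairs are softened with a temperature softmax

    p_i = exp(z_i / T) / sum_j exp(z_j / T),

and the student minimises the weighted objective

    L = alpha * L_CE(labels, student at T=1)
        + (1 - alpha) * L_distill(teacher at T, student at T),

where ``L_distill`` is the teacher-weighted cross-entropy (mean over
samples of ``-sum_i p_i^teacher log p_i^student``). No T^2 gradient
rescaling is applied to the distillation term; the objective is optimised
exactly as written above (see docs/methods.md for discussion).

The student is trained on the *target* cohort's training split, with
teacher logits computed in inference mode — the teacher carries source
knowledge, the hard labels carry target supervision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit

from gwaskd.models import StudentModel, TeacherModel, _Adam

__all__ = [
    "DistillationConfig",
    "SoftTargets",
    "temperature_softmax",
    "distillation_loss",
    "combined_loss",
    "train_student",
    "tune_alpha",
]

_LOG_CLAMP = 1e-12


@dataclass
class DistillationConfig:
    """Distillation hyperparameters: temperature, mixing weight, optimiser."""

    temperature: float = 4.0
    alpha: float = 0.5
    alpha_grid: Sequence[float] = (
        0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
    )
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 0.01
    seed: int = 0
    patience: int = 10

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if any(not 0.1 - 1e-9 <= a <= 1.0 + 1e-9 for a in self.alpha_grid):
            raise ValueError("alpha_grid values must lie in [0.1, 1.0]")


@dataclass
class SoftTargets:
    """Temperature-softened class probabilities from a model."""

    probabilities: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        self.probabilities = p


def temperature_softmax(z: np.ndarray, T: float) -> np.ndarray:
    """Softmax of logits divided by temperature, with max-subtraction.

    Accepts a single logit vector or a batch of logit rows; rows sum to 1.
    Shift-invariant in the logits; T -> infinity approaches uniform.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("non-finite logits")
    s = z / T
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def distillation_loss(
    teacher_probs: np.ndarray, student_probs: np.ndarray
) -> float:
    """Teacher-weighted cross-entropy, mean over samples.

    ``-sum_i p_i^teacher log p_i^student`` with the log clamped at 1e-12.
    """
    tp = np.atleast_2d(np.asarray(teacher_probs, dtype=float))
    sp = np.atleast_2d(np.asarray(student_probs, dtype=float))
    if tp.shape != sp.shape:
        raise ValueError(f"shape mismatch {tp.shape} vs {sp.shape}")
    return float(-(tp * np.log(np.maximum(sp, _LOG_CLAMP))).sum(axis=1).mean())


def _hard_ce(labels: np.ndarray, probs: np.ndarray) -> float:
    """Two-class cross-entropy against integer labels (T = 1 softmax)."""
    onehot = np.zeros_like(probs)
    onehot[np.arange(labels.size), labels.astype(int)] = 1.0
    return float(
        -(onehot * np.log(np.maximum(probs, _LOG_CLAMP))).sum(axis=1).mean()
    )


def combined_loss(
    labels: np.ndarray,
    student_logits: np.ndarray,
    teacher_logits: np.ndarray,
    config: DistillationConfig,
) -> float:
    """alpha * CE(labels, student at T=1) + (1-alpha) * distillation at T."""
    alpha, T = config.alpha, config.temperature
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    labels = np.asarray(labels, dtype=int)
    s1 = temperature_softmax(np.atleast_2d(student_logits), 1.0)
    sT = temperature_softmax(np.atleast_2d(student_logits), T)
    tT = temperature_softmax(np.atleast_2d(teacher_logits), T)
    return alpha * _hard_ce(labels, s1) + (1 - alpha) * distillation_loss(tT, sT)


def train_student(
    teacher: TeacherModel,
    student: StudentModel,
    target_train: tuple[np.ndarray, np.ndarray],
    target_val: tuple[np.ndarray, np.ndarray] | None,
    config: DistillationConfig,
) -> tuple[StudentModel, dict]:
    """Optimise the student on the combined objective over the target split.

    Teacher logits are computed once in inference mode. The history records
    both loss components per epoch; early stopping (when a validation set
    is given) monitors the combined validation loss and restores the best
    weights. Deterministic given ``config.seed``.
    """
    X, y = target_train
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[1] != student.n_snps or X.shape[1] != teacher.n_snps:
        raise ValueError(
            f"feature mismatch: data has {X.shape[1]} SNPs, teacher expects "
            f"{teacher.n_snps}, student expects {student.n_snps}"
        )
    T, alpha = config.temperature, config.alpha
    teacher_logit = teacher.logits(X)[:, 1]  # scalar fused logits
    t_soft = expit(teacher_logit / T)  # teacher P(case) at temperature T

    rng = np.random.default_rng(config.seed)
    opt = _Adam(student.net.params, lr=config.learning_rate)
    n = X.shape[0]
    history: dict = {"l_ce": [], "l_distill": [], "total": [], "val_total": []}
    best_val = np.inf
    best_params = student.net.get_params()
    stale = 0

    if target_val is not None:
        Xv = np.asarray(target_val[0], dtype=float)
        yv = np.asarray(target_val[1], dtype=int)
        tv_logit = teacher.logits(Xv)[:, 1]

    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        ce_sum = kd_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logit, cache = student.net.forward(X[idx], train=True, rng=rng)
            p1 = expit(logit)  # student P(case) at T=1
            pT = expit(logit / T)  # student P(case) at temperature T
            tT = t_soft[idx]

            eps = _LOG_CLAMP
            l_ce = -np.mean(
                y[idx] * np.log(p1 + eps) + (1 - y[idx]) * np.log(1 - p1 + eps)
            )
            l_kd = -np.mean(
                tT * np.log(np.maximum(pT, eps))
                + (1 - tT) * np.log(np.maximum(1 - pT, eps))
            )
            # d/dlogit of the combined objective (logit pair (0, z))
            dlogit = (
                alpha * (p1 - y[idx]) + (1 - alpha) * (pT - tT) / T
            ) / idx.size
            grads = student.net.backward(dlogit, cache)
            opt.step(student.net.params, grads)
            ce_sum += l_ce * idx.size
            kd_sum += l_kd * idx.size
        history["l_ce"].append(ce_sum / n)
        history["l_distill"].append(kd_sum / n)
        history["total"].append(
            alpha * ce_sum / n + (1 - alpha) * kd_sum / n
        )

        if target_val is not None:
            zv, _ = student.net.forward(Xv, train=False)
            val = combined_loss(
                yv,
                np.stack([np.zeros_like(zv), zv], axis=1),
                np.stack([np.zeros_like(tv_logit), tv_logit], axis=1),
                config,
            )
            history["val_total"].append(val)
            if val < best_val - 1e-6:
                best_val = val
                best_params = student.net.get_params()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break

    if target_val is not None and config.epochs > 0:
        student.net.set_params(best_params)
    student.history = history
    return student, history


def tune_alpha(
    teacher: TeacherModel,
    student_builder,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    config: DistillationConfig,
) -> tuple[float, list[dict]]:
    """Grid-search alpha on validation F1; ties favour the smaller alpha.

    ``student_builder(seed)`` must return a fresh student; one student is
    trained per grid point with the same seed. Returns the best alpha and
    a per-grid-point score table.
    """
    from sklearn.metrics import f1_score

    if not config.alpha_grid:
        raise ValueError("empty alpha grid")
    scores: list[dict] = []
    best_alpha, best_f1 = None, -np.inf
    for a in config.alpha_grid:
        cfg = DistillationConfig(
            temperature=config.temperature,
            alpha=a,
            alpha_grid=config.alpha_grid,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            seed=config.seed,
            patience=config.patience,
        )
        student = student_builder(cfg.seed)
        student, _ = train_student(teacher, student, train, val, cfg)
        pred = student.predict(val[0])
        f1 = f1_score(val[1], pred, average="macro", zero_division=0)
        scores.append({"alpha": a, "val_f1": float(f1)})
        # strictly-better wins; ties keep the smaller (more distillation)
        if f1 > best_f1 + 1e-12:
            best_f1 = f1
            best_alpha = a
    return float(best_alpha), scores
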