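"""Training stack: mixup augmentation, focal loss, RAdam + LookAhead,
and the stratified K-fold cross-validation loop.

The loss is the focal loss ``FL(p_t) = -(1 - p_t)^gamma * log(p_t)``
(gamma = 0 recovers cross-entropy), generalized to soft targets as the
target-weighted sum so mixed labels remain meaningful.  Mixup draws one
coefficient per batch from ``Beta(alpha, beta)`` with alpha = beta = 0.5
so the coefficient concentrates symmetrically around 0.5, and forms
convex combinations of both the pair tensors and the one-hot labels.

Optimization is rectified Adam (the adaptive denominator is switched
off while its variance estimate is unreliable in early steps) wrapped
in LookAhead slow weights; validation and inference use the slow
weights, the stabilized set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import MetricReport, compute_metrics
from .model import ModelConfig, SiameseCNN, softmax

logger = logging.getLogger(__name__)

_EPS_LOG = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Training constants.

    gamma
        Focal-loss exponent (>= 0); 2 by default, 0 gives cross-entropy.
    mixup_alpha, mixup_beta
        Beta-distribution shape parameters of the mixing coefficient;
        both 0.5 by default.
    mixup_per_sample
        Draw one coefficient per sample instead of one per batch.
    k_folds
        Cross-validation folds; 5 by default.
    lookahead_k, lookahead_step
        Slow-weight sync period (inner steps) and interpolation factor.
    """

    gamma: float = 2.0
    mixup_alpha: float = 0.5
    mixup_beta: float = 0.5
    mixup_enabled: bool = True
    mixup_per_sample: bool = False
    k_folds: int = 5
    batch_size: int = 256
    epochs: int = 100
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    lookahead_k: int = 5
    lookahead_step: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.mixup_alpha <= 0 or self.mixup_beta <= 0:
            raise ValueError("mixup_alpha and mixup_beta must be > 0")
        if not (0 < self.lookahead_step <= 1):
            raise ValueError("lookahead_step must lie in (0, 1]")
        if self.lookahead_k < 1:
            raise ValueError("lookahead_k must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


# ---------------------------------------------------------------------------
# Focal loss
# ---------------------------------------------------------------------------

def focal_loss(probs: np.ndarray, targets: np.ndarray, gamma: float) -> float:
    """Mean focal loss over a batch of probability rows and soft targets.

    Per sample: ``-sum_c t_c * (1 - p_c)^gamma * log(p_c)``; with
    one-hot targets this is exactly the single-class focal loss.
    Probabilities are clipped to ``[1e-12, 1]`` before the logarithm.
    """
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    p = np.clip(np.atleast_2d(np.asarray(probs, float)), _EPS_LOG, 1.0)
    t = np.atleast_2d(np.asarray(targets, float))
    per_sample = -(t * (1.0 - p) ** gamma * np.log(p)).sum(axis=1)
    return float(per_sample.mean())


def focal_loss_grad_logits(
    probs: np.ndarray, targets: np.ndarray, gamma: float
) -> np.ndarray:
    """Gradient of the mean focal loss w.r.t. the logits.

    With p = softmax(z) and per-sample loss
    ``l = -sum_c t_c (1-p_c)^g log p_c``,
    ``dl/dp_c = t_c [ g (1-p_c)^(g-1) log p_c - (1-p_c)^g / p_c ]`` and
    the softmax Jacobian gives
    ``dl/dz_k = p_k (dl/dp_k - sum_c dl/dp_c p_c)``.
    """
    p = np.atleast_2d(np.asarray(probs, float))
    t = np.atleast_2d(np.asarray(targets, float))
    pc = np.clip(p, _EPS_LOG, 1.0)
    one_m = 1.0 - pc
    if gamma == 0:
        dldp = -t / pc
    else:
        dldp = t * (gamma * one_m ** (gamma - 1) * np.log(pc) - one_m ** gamma / pc)
    inner = (dldp * p).sum(axis=1, keepdims=True)
    return p * (dldp - inner) / p.shape[0]


# ---------------------------------------------------------------------------
# Mixup
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixedBatch:
    """Convex combination of two batches and their label distributions."""

    xa: np.ndarray
    xb: np.ndarray
    soft_labels: np.ndarray
    lam: np.ndarray  # scalar array () or per-sample (n,)


def draw_mixup_lambda(
    rng: np.random.Generator, alpha: float, beta: float, size=None
) -> np.ndarray:
    """Draw mixing coefficients from Beta(alpha, beta)."""
    return np.asarray(rng.beta(alpha, beta, size=size))


def mixup_batch(
    batch1: tuple[np.ndarray, np.ndarray, np.ndarray],
    batch2: tuple[np.ndarray, np.ndarray, np.ndarray],
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    per_sample: bool = False,
    lam: float | None = None,
) -> MixedBatch:
    """Mix two batches of (xa, xb, one-hot/soft labels) with one
    Beta-distributed coefficient (per batch by default).

    ``lam`` forces the coefficient (used in tests of the convex
    endpoints); inputs and labels are mixed with the same coefficient,
    so soft-label rows keep unit mass.
    """
    (xa1, xb1, y1), (xa2, xb2, y2) = batch1, batch2
    if xa1.shape != xa2.shape or xb1.shape != xb2.shape or y1.shape != y2.shape:
        raise ValueError(
            f"batch shape mismatch: {xa1.shape}/{xb1.shape}/{y1.shape} vs "
            f"{xa2.shape}/{xb2.shape}/{y2.shape}"
        )
    n = xa1.shape[0]
    if lam is not None:
        lam_arr = np.asarray(lam, float)
    else:
        lam_arr = draw_mixup_lambda(rng, alpha, beta, size=(n,) if per_sample else None)
    lx = lam_arr.reshape((-1,) + (1,) * (xa1.ndim - 1)) if lam_arr.ndim else lam_arr
    ly = lam_arr.reshape(-1, 1) if lam_arr.ndim else lam_arr
    return MixedBatch(
        xa=lx * xa1 + (1 - lx) * xa2,
        xb=lx * xb1 + (1 - lx) * xb2,
        soft_labels=ly * y1 + (1 - ly) * y2,
        lam=lam_arr,
    )


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class RAdam:
    """Rectified Adam over a dict of named parameter arrays (in place).

    Exponential moments as in Adam; the length of the approximated SMA,
    ``rho_t = rho_inf - 2 t beta2^t / (1 - beta2^t)`` with
    ``rho_inf = 2/(1-beta2) - 1``, gates the update: when ``rho_t > 4``
    the variance-rectified adaptive step

        ``r_t = sqrt( (rho_t-4)(rho_t-2) rho_inf /
                      ((rho_inf-4)(rho_inf-2) rho_t) )``

    scales ``lr * m_hat / (sqrt(v_hat) + eps)``; otherwise the variance
    estimate is unreliable and a plain momentum step ``lr * m_hat`` is
    taken.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.rho_inf = 2.0 / (1.0 - beta2) - 1.0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for name, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(
                    f"non-finite gradient for parameter {name!r}"
                )
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        rho_t = self.rho_inf - 2.0 * t * b2**t / (1.0 - b2**t)
        for name, p in self.params.items():
            g = grads[name]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1.0 - b1**t)
            if rho_t > 4.0:
                v_hat = np.sqrt(self.v[name] / (1.0 - b2**t))
                r_t = np.sqrt(
                    (rho_t - 4.0)
                    * (rho_t - 2.0)
                    * self.rho_inf
                    / ((self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t)
                )
                p -= self.lr * r_t * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat


class Lookahead:
    """Slow/fast weight interpolation around an inner optimizer.

    Every ``period`` inner steps: ``slow += step_factor * (fast - slow)``
    and the fast weights are reset to the slow weights.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        step_factor: float = 0.5,
        period: int = 5,
    ):
        if period < 1:
            raise ValueError(f"period must be >= 1, got {period}")
        if not (0 < step_factor <= 1):
            raise ValueError(f"step_factor must lie in (0, 1], got {step_factor}")
        self.fast = params
        self.slow = {k: v.copy() for k, v in params.items()}
        self.step_factor = step_factor
        self.period = period
        self.counter = 0

    def after_step(self) -> bool:
        """Call once after each inner-optimizer step; returns True on sync."""
        self.counter += 1
        if self.counter % self.period:
            return False
        for k, fast in self.fast.items():
            self.slow[k] += self.step_factor * (fast - self.slow[k])
            fast[...] = self.slow[k]
        return True


def lookahead_sync(
    fast: dict[str, np.ndarray],
    slow: dict[str, np.ndarray],
    step_factor: float,
    counter: int,
    period: int,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Functional form of one LookAhead decision point.

    Interpolates (and copies back) only when ``counter`` is a positive
    multiple of ``period``; otherwise both sets are returned unchanged.
    """
    if period < 1:
        raise ValueError(f"period must be >= 1, got {period}")
    fast = {k: v.copy() for k, v in fast.items()}
    slow = {k: v.copy() for k, v in slow.items()}
    if counter > 0 and counter % period == 0:
        for k in fast:
            slow[k] = slow[k] + step_factor * (fast[k] - slow[k])
            fast[k] = slow[k].copy()
    return fast, slow


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.zeros((len(labels), n_classes))
    y[np.arange(len(labels)), np.asarray(labels, int)] = 1.0
    return y


@dataclass
class FoldResult:
    """Trained parameters plus validation metrics for one fold."""

    model: SiameseCNN
    report: MetricReport
    epoch_log: list[dict] = field(default_factory=list)


def _evaluate(model, xa, xb, labels, batch_size=512) -> MetricReport:
    scores = np.vstack(
        [
            model.predict_proba(xa[i : i + batch_size], xb[i : i + batch_size])
            for i in range(0, len(xa), batch_size)
        ]
    )
    return compute_metrics(labels, scores)


def train_one_fold(
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    model_config: ModelConfig,
    train_config: TrainConfig,
    fold_index: int = 0,
) -> FoldResult:
    """Train one model on one fold and evaluate on its validation split.

    ``train_data``/``val_data`` are ``(xa, xb, labels)`` with pair
    tensors of shape ``(n, n_drugs, 3)`` and integer event labels.  Each
    epoch: shuffle, mix each mini-batch with a permuted counterpart
    batch (mixup), forward, focal loss, backward, RAdam step, LookAhead
    sync.  Validation metrics are computed with the LookAhead slow
    weights.  Deterministic given the seed on a fixed thread count.
    """
    xa_tr, xb_tr, y_tr = train_data
    xa_va, xb_va, y_va = val_data
    if len(y_tr) == 0:
        warnings.warn("empty training set", RuntimeWarning)
    missing = set(np.unique(y_va)) - set(np.unique(y_tr))
    if missing:
        warnings.warn(
            f"classes present in validation but absent from training: "
            f"{sorted(int(c) for c in missing)}",
            RuntimeWarning,
        )
    rng = np.random.default_rng(train_config.seed + 7919 * fold_index)
    n_classes = model_config.n_classes
    model = SiameseCNN(
        model_config, n_drugs=xa_tr.shape[1], seed=train_config.seed + fold_index
    )
    params = model.parameters()
    opt = RAdam(
        params,
        learning_rate=train_config.learning_rate,
        beta1=train_config.beta1,
        beta2=train_config.beta2,
        eps=train_config.adam_eps,
    )
    la = Lookahead(
        params, step_factor=train_config.lookahead_step, period=train_config.lookahead_k
    )
    y_onehot = one_hot(y_tr, n_classes)
    n = len(y_tr)
    bs = min(train_config.batch_size, max(n, 1))
    epoch_log: list[dict] = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        # counterpart stream: the same fold re-shuffled, resampled each epoch
        partner = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            jdx = partner[start : start + bs]
            batch = (xa_tr[idx], xb_tr[idx], y_onehot[idx])
            if train_config.mixup_enabled:
                mixed = mixup_batch(
                    batch,
                    (xa_tr[jdx], xb_tr[jdx], y_onehot[jdx]),
                    train_config.mixup_alpha,
                    train_config.mixup_beta,
                    rng,
                    per_sample=train_config.mixup_per_sample,
                )
                bxa, bxb, by = mixed.xa, mixed.xb, mixed.soft_labels
            else:
                bxa, bxb, by = batch
            model.zero_grad()
            logits = model.forward(bxa, bxb, train=True)
            probs = softmax(logits)
            losses.append(focal_loss(probs, by, train_config.gamma))
            model.backward(focal_loss_grad_logits(probs, by, train_config.gamma))
            opt.step(model.gradients())
            la.after_step()
        epoch_log.append(
            {"epoch": epoch, "fold": fold_index, "train_loss": float(np.mean(losses))}
        )
        logger.debug(
            "fold %d epoch %d loss %.5f", fold_index, epoch, epoch_log[-1]["train_loss"]
        )
    # evaluate with the stabilized slow weights
    model.set_parameters(la.slow)
    report = (
        _evaluate(model, xa_va, xb_va, y_va)
        if len(y_va)
        else MetricReport.empty()
    )
    return FoldResult(model=model, report=report, epoch_log=epoch_log)


def stratified_fold_indices(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified-by-event K-fold (train, validation) index pairs.

    Classes with fewer samples than ``k`` cannot appear in every fold;
    they are kept in the training split of every fold, with a warning.
    """
    labels = np.asarray(labels, int)
    counts = {int(c): int((labels == c).sum()) for c in np.unique(labels)}
    rare = sorted(c for c, cnt in counts.items() if cnt < k)
    if rare:
        warnings.warn(
            f"classes with fewer than {k} samples kept in training folds: {rare}",
            RuntimeWarning,
        )
    rare_mask = np.isin(labels, rare)
    common_idx = np.flatnonzero(~rare_mask)
    rare_idx = np.flatnonzero(rare_mask)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(common_idx, labels[common_idx]):
        train_idx = np.sort(np.concatenate([common_idx[tr], rare_idx]))
        folds.append((train_idx, np.sort(common_idx[va])))
    return folds


def average_reports(reports: list[MetricReport]) -> MetricReport:
    """Field-wise arithmetic mean of fold reports (None fields stay None
    unless every fold defines them)."""
    return MetricReport.mean(reports)


@dataclass
class KFoldResult:
    fold_results: list[FoldResult]
    averaged: MetricReport

    @property
    def fold_reports(self) -> list[MetricReport]:
        return [fr.report for fr in self.fold_results]


def train_kfold(
    xa: np.ndarray,
    xb: np.ndarray,
    labels: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> KFoldResult:
    """Stratified K-fold cross-validation training.

    Every sample lands in exactly one validation fold (rare classes
    excepted, see :func:`stratified_fold_indices`); the averaged report
    is the arithmetic mean of the fold reports.
    """
    labels = np.asarray(labels, int)
    if train_config.k_folds > len(labels):
        raise ValueError(
            f"k_folds={train_config.k_folds} exceeds sample count {len(labels)}"
        )
    folds = stratified_fold_indices(labels, train_config.k_folds, train_config.seed)
    results = []
    for i, (tr, va) in enumerate(folds):
        results.append(
            train_one_fold(
                (xa[tr], xb[tr], labels[tr]),
                (xa[va], xb[va], labels[va]),
                model_config,
                train_config,
                fold_index=i,
            )
        )
        logger.info("fold %d/%d: %s", i + 1, len(folds), results[-1].report)
    return KFoldResult(
        fold_results=results, averaged=average_reports([r.report for r in results])
    )
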