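"""The minimalist feed-forward subtype classifier.

Architecture: two fully-connected "representation" layers (default 768 and
128 ReLU neurons) and a 4-way softmax output, one class per consensus
molecular subtype.  Each layer computes ``alpha(W a - theta)`` where
``theta`` is a per-neuron threshold.  Inverted dropout masks the outputs of
the two hidden layers at train time (no mask on the raw input); L1 and L2
penalties apply to the two hidden weight matrices only, never to the
output layer.  The loss is mean categorical cross-entropy plus those
penalties, gradients are computed analytically, and parameters are updated
with Adam (bias-corrected first/second moments).

Everything is plain NumPy by design: the gradient math is the point, and
the analytic backward pass is validated against central finite differences
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .data_io import (
    CMS_LABELS,
    DataError,
    ExpressionDataset,
    GeneSet,
    ModelBundle,
    align_to_genes,
)

PROB_CLIP = 1e-12  # floor on the true-class probability inside the log

PARAM_NAMES = ("W1", "theta1", "W2", "theta2", "W3", "theta3")


@dataclass
class TrainConfig:
    """Hyperparameters of the classifier and its optimizer.

    The network keeps three distinct knobs that are often conflated: the
    Adam step size ``learning_rate`` (reduced on plateau down to
    ``min_learning_rate``), and the regularization coefficients ``l1_coef``
    and ``l2_coef`` on the hidden weight matrices (default 0.3 each, the
    best-performing setting of the coefficient scan).
    """

    hidden1: int = 768
    hidden2: int = 128
    n_classes: int = 4
    dropout_keep_p: float = 0.5
    l1_coef: float = 0.3
    l2_coef: float = 0.3
    learning_rate: float = 1e-3
    min_learning_rate: float = 1e-5
    lr_reduce_factor: float = 0.5
    lr_patience: int = 10
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 20
    min_delta: float = 1e-4
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass
class NetworkParams:
    """Weights W_l and per-neuron thresholds theta_l of the three layers,
    plus the dropout/regularization configuration they were trained with."""

    W1: np.ndarray
    theta1: np.ndarray
    W2: np.ndarray
    theta2: np.ndarray
    W3: np.ndarray
    theta3: np.ndarray
    dropout_keep_p: float = 0.5
    l1_coef: float = 0.0
    l2_coef: float = 0.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        h1, d_in = self.W1.shape
        h2 = self.W2.shape[0]
        k = self.W3.shape[0]
        if self.W2.shape != (h2, h1) or self.W3.shape != (k, h2):
            raise DataError("inconsistent layer shapes")
        if (
            self.theta1.shape != (h1,)
            or self.theta2.shape != (h2,)
            or self.theta3.shape != (k,)
        ):
            raise DataError("threshold shapes do not match layer widths")
        if not 0 < self.dropout_keep_p <= 1:
            raise DataError("dropout_keep_p must lie in (0, 1]")
        if self.l1_coef < 0 or self.l2_coef < 0:
            raise DataError("regularization coefficients must be non-negative")

    @property
    def d_in(self) -> int:
        return self.W1.shape[1]

    @property
    def n_classes(self) -> int:
        return self.W3.shape[0]

    def tensors(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            **{name: getattr(self, name).copy() for name in PARAM_NAMES},
            dropout_keep_p=self.dropout_keep_p,
            l1_coef=self.l1_coef,
            l2_coef=self.l2_coef,
        )


def init_params(d_in: int, config: TrainConfig, rng: np.random.Generator) -> NetworkParams:
    """He-uniform initialisation for the ReLU layers, Glorot-uniform for the
    softmax output; thresholds start at zero."""

    def he_uniform(fan_out: int, fan_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / fan_in)
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    def glorot_uniform(fan_out: int, fan_in: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=(fan_out, fan_in))

    return NetworkParams(
        W1=he_uniform(config.hidden1, d_in),
        theta1=np.zeros(config.hidden1),
        W2=he_uniform(config.hidden2, config.hidden1),
        theta2=np.zeros(config.hidden2),
        W3=glorot_uniform(config.n_classes, config.hidden2),
        theta3=np.zeros(config.n_classes),
        dropout_keep_p=config.dropout_keep_p,
        l1_coef=config.l1_coef,
        l2_coef=config.l2_coef,
    )


def dropout_mask(
    shape: tuple[int, ...], keep_p: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverted-dropout mask: entries are 0 with probability 1 - keep_p and
    1/keep_p otherwise, so the masked activation is unbiased and eval-mode
    needs no rescaling."""
    if keep_p <= 0 or keep_p > 1:
        raise ValueError("keep probability must lie in (0, 1]")
    if keep_p == 1.0:
        return np.ones(shape)
    return (rng.random(shape) < keep_p) / keep_p


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(
    X: np.ndarray,
    params: NetworkParams,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass over a (n_samples x d_in) standardized input matrix.

    In ``train`` mode inverted-dropout masks are applied to the outputs of
    hidden layers 1 and 2 (drawn from ``rng`` unless ``masks`` pins them,
    which the gradient checker uses to freeze stochasticity); ``eval`` mode
    is deterministic.  Returns class probabilities and the activation cache
    consumed by :func:`backward`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != params.d_in:
        raise DataError(f"input shape {X.shape} incompatible with d_in={params.d_in}")
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in network input")
    if mode not in {"train", "eval"}:
        raise ValueError(f"unknown mode {mode!r}")

    n = X.shape[0]
    Z1 = X @ params.W1.T - params.theta1
    A1 = np.maximum(Z1, 0.0)
    if mode == "train":
        if masks is None:
            if rng is None:
                raise ValueError("train mode requires an rng or explicit masks")
            mask1 = dropout_mask((n, params.W1.shape[0]), params.dropout_keep_p, rng)
            mask2 = dropout_mask((n, params.W2.shape[0]), params.dropout_keep_p, rng)
        else:
            mask1, mask2 = masks
    else:
        mask1 = mask2 = None

    D1 = A1 * mask1 if mask1 is not None else A1
    Z2 = D1 @ params.W2.T - params.theta2
    A2 = np.maximum(Z2, 0.0)
    D2 = A2 * mask2 if mask2 is not None else A2
    Z3 = D2 @ params.W3.T - params.theta3
    probs = _softmax(Z3)

    cache = {
        "X": X, "Z1": Z1, "D1": D1, "Z2": Z2, "D2": D2, "probs": probs,
        "mask1": mask1, "mask2": mask2, "mode": mode,
        "shapes": tuple(t.shape for t in params.tensors().values()),
    }
    return probs, cache


@dataclass
class LossBreakdown:
    """Mean cross-entropy plus the L1/L2 penalties on W1 and W2."""

    data_loss: float
    l1_penalty: float
    l2_penalty: float

    @property
    def total(self) -> float:
        return self.data_loss + self.l1_penalty + self.l2_penalty


def loss(
    probs: np.ndarray, one_hot_labels: np.ndarray, params: NetworkParams
) -> LossBreakdown:
    """Regularized objective.

    ``data_loss`` is the mean negative log probability of the true class,
    with the probability clipped below at 1e-12 so a confidently wrong
    prediction never produces an infinite loss.  The regularized objective
    is the per-sample average of ``sum_i CE_i + l1*(||W1||_1 + ||W2||_1) +
    l2/2*(||W1||_F^2 + ||W2||_F^2)``, so the penalties here carry a 1/n
    factor: this keeps the coefficients on the scale of the per-sample
    objective (a coefficient of 0.3 is mild, matching its observed effect
    in the coefficient scan) rather than letting the penalty swamp the mean
    cross-entropy.  The output layer is never penalized.
    """
    probs = np.asarray(probs, dtype=float)
    Y = np.asarray(one_hot_labels, dtype=float)
    if probs.shape != Y.shape:
        raise DataError("probability and label shapes differ")
    n = probs.shape[0]
    p_true = np.clip((probs * Y).sum(axis=1), PROB_CLIP, None)
    data_loss = float(-np.mean(np.log(p_true)))
    l1 = params.l1_coef * (np.abs(params.W1).sum() + np.abs(params.W2).sum()) / n
    l2 = 0.5 * params.l2_coef * ((params.W1**2).sum() + (params.W2**2).sum()) / n
    return LossBreakdown(data_loss=data_loss, l1_penalty=float(l1), l2_penalty=float(l2))


def softmax_jacobian(probs_row: np.ndarray) -> np.ndarray:
    """Jacobian of softmax output w.r.t. its logits: diagonal y_t(1 - y_t),
    off-diagonal -y_t y_k.  Rows sum to zero."""
    y = np.asarray(probs_row, dtype=float)
    if y.ndim != 1:
        raise ValueError("probs_row must be 1-D")
    if not np.isclose(y.sum(), 1.0, atol=1e-6):
        raise ValueError("probs_row must sum to 1")
    return np.diag(y) - np.outer(y, y)


def backward(
    cache: dict, one_hot_labels: np.ndarray, params: NetworkParams
) -> dict[str, np.ndarray]:
    """Analytic gradients of the regularized loss for every tensor.

    The output-layer error is ``(probs - one_hot)/n`` — the true-class row
    of W3 is strengthened along its input, every other row punished —
    propagated through the ReLU derivatives and the same dropout masks used
    forward.  L1 subgradients use sign(w) with 0 at w = 0; thresholds enter
    the pre-activation with a minus sign, so their gradients are the
    negated error sums.
    """
    if cache.get("shapes") != tuple(t.shape for t in params.tensors().values()):
        raise DataError("cache was produced with different parameter shapes")
    Y = np.asarray(one_hot_labels, dtype=float)
    probs = cache["probs"]
    if probs.shape != Y.shape:
        raise DataError("label shape does not match cached probabilities")
    n = probs.shape[0]

    dZ3 = (probs - Y) / n
    grads: dict[str, np.ndarray] = {}
    grads["W3"] = dZ3.T @ cache["D2"]
    grads["theta3"] = -dZ3.sum(axis=0)

    dD2 = dZ3 @ params.W3
    dA2 = dD2 * cache["mask2"] if cache["mask2"] is not None else dD2
    dZ2 = dA2 * (cache["Z2"] > 0)
    grads["W2"] = dZ2.T @ cache["D1"]
    grads["theta2"] = -dZ2.sum(axis=0)

    dD1 = dZ2 @ params.W2
    dA1 = dD1 * cache["mask1"] if cache["mask1"] is not None else dD1
    dZ1 = dA1 * (cache["Z1"] > 0)
    grads["W1"] = dZ1.T @ cache["X"]
    grads["theta1"] = -dZ1.sum(axis=0)

    for name in ("W1", "W2"):
        W = getattr(params, name)
        grads[name] += (params.l1_coef * np.sign(W) + params.l2_coef * W) / n
    return grads


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    alpha: float = 1e-3

    @classmethod
    def for_params(
        cls,
        params: NetworkParams,
        alpha: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        epsilon: float = 1e-8,
    ) -> "AdamState":
        return cls(
            m={k: np.zeros_like(t) for k, t in params.tensors().items()},
            v={k: np.zeros_like(t) for k, t in params.tensors().items()},
            t=0,
            beta1=beta1,
            beta2=beta2,
            epsilon=epsilon,
            alpha=alpha,
        )


def adam_step(
    params: NetworkParams, grads: dict[str, np.ndarray], state: AdamState
) -> tuple[NetworkParams, AdamState]:
    """One Adam update: m and v are exponential moving averages of the
    gradient and its square, bias-corrected by 1 - beta^t, and the step is
    ``-alpha * m_hat / (sqrt(v_hat) + eps)``.  Updates in place and returns
    the same objects."""
    state.t += 1
    t = state.t
    for name, g in grads.items():
        theta = getattr(params, name)
        if g.shape != theta.shape:
            raise DataError(f"gradient shape mismatch for {name}")
        m = state.m[name]
        v = state.v[name]
        m *= state.beta1
        m += (1 - state.beta1) * g
        v *= state.beta2
        v += (1 - state.beta2) * g * g
        m_hat = m / (1 - state.beta1**t)
        v_hat = v / (1 - state.beta2**t)
        theta -= state.alpha * m_hat / (np.sqrt(v_hat) + state.epsilon)
    return params, state


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def one_hot(labels: Iterable[str], classes: tuple[str, ...] = CMS_LABELS) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    labels = list(labels)
    unknown = sorted({l for l in labels if l not in index})
    if unknown:
        raise DataError(f"unknown labels: {unknown}")
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, index[l]] = 1.0
    return Y


@dataclass
class EpochRecord:
    epoch: int
    loss: LossBreakdown
    train_accuracy: float
    learning_rate: float


@dataclass
class TrainResult:
    params: NetworkParams
    history: list[EpochRecord]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    classes: tuple[str, ...] = CMS_LABELS


def standardize_fit(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-score statistics over samples (columns).  Constant genes
    get sd 1 so standardization never divides by zero."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def standardize_apply(
    values: np.ndarray, mean: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    return (values - mean[:, None]) / sd[:, None]


def train(
    ds_selected: ExpressionDataset,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train on a dataset whose rows are already restricted to the gene set.

    Per-gene standardization is fit here on the training data and carried in
    the result for reuse at prediction time.  Mini-batch Adam with
    reduce-on-plateau step size (floor ``min_learning_rate``) and early
    stopping on the training-loss plateau; fully deterministic under
    ``config.seed``.
    """
    config = config or TrainConfig()
    if ds_selected.labels is None:
        raise DataError("training requires labels")
    classes = CMS_LABELS[: config.n_classes]
    missing = sorted(set(classes) - set(ds_selected.labels))
    if missing:
        raise DataError(f"class(es) absent from training data: {missing}")

    mean, sd = standardize_fit(ds_selected.values)
    X = standardize_apply(ds_selected.values, mean, sd).T  # samples x genes
    Y = one_hot(ds_selected.labels, classes)
    n = X.shape[0]

    rng = np.random.default_rng(config.seed)
    params = init_params(X.shape[1], config, rng)
    state = AdamState.for_params(
        params,
        alpha=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        epsilon=config.epsilon,
    )

    history: list[EpochRecord] = []
    best_loss = np.inf
    epochs_since_best = 0
    epochs_since_lr_drop = 0
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            probs, cache = forward(X[idx], params, mode="train", rng=rng)
            grads = backward(cache, Y[idx], params)
            params, state = adam_step(params, grads, state)

        eval_probs, _ = forward(X, params, mode="eval")
        lb = loss(eval_probs, Y, params)
        acc = float(np.mean(eval_probs.argmax(axis=1) == Y.argmax(axis=1)))
        history.append(
            EpochRecord(epoch=epoch, loss=lb, train_accuracy=acc, learning_rate=state.alpha)
        )

        if lb.total < best_loss - config.min_delta:
            best_loss = lb.total
            epochs_since_best = 0
            epochs_since_lr_drop = 0
        else:
            epochs_since_best += 1
            epochs_since_lr_drop += 1
        if epochs_since_best >= config.early_stop_patience:
            break
        if epochs_since_lr_drop >= config.lr_patience:
            state.alpha = max(
                state.alpha * config.lr_reduce_factor, config.min_learning_rate
            )
            epochs_since_lr_drop = 0

    return TrainResult(
        params=params, history=history, feature_mean=mean, feature_sd=sd, classes=classes
    )


def build_bundle(
    result: TrainResult, gene_set: GeneSet, config: TrainConfig | None = None
) -> ModelBundle:
    return ModelBundle(
        params=result.params,
        gene_set=gene_set,
        feature_mean=result.feature_mean,
        feature_sd=result.feature_sd,
        classes=result.classes,
        train_config=(config or TrainConfig()).to_dict(),
    )


def predict(
    ds: ExpressionDataset,
    bundle: ModelBundle,
    missing_policy: str = "error",
) -> tuple[list[str], np.ndarray]:
    """Annotate samples with CMS labels.

    Rows are aligned to the bundle's gene set (absent genes handled per
    ``missing_policy``, ``fill_mean`` using the stored training means),
    standardized with the stored training statistics, and passed through a
    deterministic eval-mode forward; labels are the argmax classes.
    """
    aligned = align_to_genes(
        ds, bundle.gene_set, missing_policy=missing_policy, fill_means=bundle.gene_means
    )
    X = standardize_apply(aligned.values, bundle.feature_mean, bundle.feature_sd).T
    probs, _ = forward(X, bundle.params, mode="eval")
    labels = [bundle.classes[i] for i in probs.argmax(axis=1)]
    return labels, probs
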