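"""Attention-based multiple-instance learning (ABMIL) slide classifier.

A slide is a bag of patch feature vectors with a single weak label.  The
model projects each patch feature through a ReLU layer, scores every
projected patch with a *gated* attention head (a tanh branch multiplied by
a sigmoid gate, mapped to a scalar), normalises the scores across the bag
with a softmax — so every attention weight lies in [0, 1] and the weights
sum to 1 — pools the projected features with those weights into one
slide-level vector, and classifies it with a linear layer with one output
node per class followed by a softmax.  The slide prediction is therefore
invariant to patch order, and the attention vector is the model's own
estimate of each patch's relevance.

Training minimises class-weighted cross-entropy with one bag per gradient
step (bags have varying sizes, so batching is neither needed nor natural),
using Adam with L2 weight decay on the weight matrices, dropout on the
projected features, and early stopping on validation loss.  Everything is
plain numpy with analytic gradients; a finite-difference check in the test
suite guards the backward pass.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._utils import softmax
from .features import FeatureBag
from .slide import LABELS

N_CLASSES = 2

#: parameter fields that receive weight decay (matrices/vectors, not biases)
_DECAYED = ("W_proj", "V", "U", "w_att", "W_clf")
_PARAM_FIELDS = (
    "W_proj", "b_proj", "V", "b_V", "U", "b_U", "w_att", "b_att", "W_clf", "b_clf",
)


@dataclass
class AbmilParams:
    """All trainable parameters of the attention network and classifier.

    Shapes (D = feature dim, H1/H2 = hidden sizes, C = 2 classes):
    ``W_proj (H1, D)``, ``b_proj (H1,)`` — input projection with ReLU;
    ``V, U (H2, H1)`` with biases — tanh and sigmoid attention branches;
    ``w_att (H2,)``, ``b_att ()`` — scalar attention score head;
    ``W_clf (C, H1)``, ``b_clf (C,)`` — slide-level classifier.
    """

    W_proj: np.ndarray
    b_proj: np.ndarray
    V: np.ndarray
    b_V: np.ndarray
    U: np.ndarray
    b_U: np.ndarray
    w_att: np.ndarray
    b_att: np.ndarray
    W_clf: np.ndarray
    b_clf: np.ndarray
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        return self.W_proj.shape[1]

    @property
    def hidden(self) -> tuple[int, int]:
        return self.W_proj.shape[0], self.V.shape[0]

    def copy(self) -> "AbmilParams":
        return copy.deepcopy(self)

    def check_finite(self) -> None:
        for name in _PARAM_FIELDS:
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"non-finite values in parameter {name}")


@dataclass
class SlidePrediction:
    """Per-class probabilities, hard label and per-patch attention."""

    slide_id: str
    probs: np.ndarray
    predicted_label: str
    attention: np.ndarray

    @property
    def prob_metastatic(self) -> float:
        return float(self.probs[1])


@dataclass
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the CLAM lineage of weakly supervised slide
    classifiers: Adam at learning rate 2e-4, weight decay 1e-5, dropout
    0.25 on the projected features, early stopping with patience 20 after
    a minimum of 50 epochs, inverse-frequency class weighting.
    """

    learning_rate: float = 2e-4
    weight_decay: float = 1e-5
    dropout: float = 0.25
    max_epochs: int = 200
    patience: int = 20
    min_epochs: int = 50
    class_weighting: str = "inverse"  # "inverse" or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_decay < 0 or not 0 <= self.dropout < 1:
            raise ValueError("invalid regularisation settings")
        if self.max_epochs < 0 or self.patience < 1 or self.min_epochs < 0:
            raise ValueError("invalid epoch settings")
        if self.class_weighting not in ("inverse", "none"):
            raise ValueError("class_weighting must be 'inverse' or 'none'")


def default_hidden(feature_dim: int) -> tuple[int, int]:
    """Hidden sizes: (512, 256) for full-size encoders, scaled down to
    (D, 128) when the feature dimension itself is small."""
    h1 = min(feature_dim, 512)
    return (h1, 256) if h1 >= 512 else (h1, 128)


def init_params(
    feature_dim: int, hidden: tuple[int, int] | None = None, seed: int = 0
) -> AbmilParams:
    """Initialise ABMIL parameters (He init for the ReLU projection,
    Xavier for the attention branches and classifier); deterministic for a
    fixed seed."""
    if feature_dim < 1:
        raise ValueError("feature_dim must be >= 1")
    h1, h2 = hidden or default_hidden(feature_dim)
    if h1 < 1 or h2 < 1:
        raise ValueError("hidden sizes must be >= 1")
    rng = np.random.default_rng(seed)
    xav = lambda n_out, n_in: rng.normal(
        0.0, np.sqrt(2.0 / (n_in + n_out)), (n_out, n_in)
    )
    return AbmilParams(
        W_proj=rng.normal(0.0, np.sqrt(2.0 / feature_dim), (h1, feature_dim)),
        b_proj=np.zeros(h1),
        V=xav(h2, h1),
        b_V=np.zeros(h2),
        U=xav(h2, h1),
        b_U=np.zeros(h2),
        w_att=rng.normal(0.0, np.sqrt(1.0 / h2), h2),
        b_att=np.zeros(()),
        W_clf=xav(N_CLASSES, h1),
        b_clf=np.zeros(N_CLASSES),
        seed=seed,
    )


def _check_bag(params: AbmilParams, bag: FeatureBag) -> np.ndarray:
    x = np.asarray(bag.features, dtype=np.float64)
    if x.shape[1] != params.feature_dim:
        raise ValueError(
            f"bag {bag.slide_id!r} has feature dim {x.shape[1]}, model "
            f"expects {params.feature_dim}"
        )
    return x


def _forward(params: AbmilParams, x: np.ndarray, dropout_mask: np.ndarray | None = None):
    """Shared forward pass; returns intermediates needed for backprop."""
    z0 = x @ params.W_proj.T + params.b_proj          # (N, H1)
    h = np.maximum(z0, 0.0)
    if dropout_mask is not None:
        h = h * dropout_mask
    at = np.tanh(h @ params.V.T + params.b_V)         # (N, H2)
    ag = 1.0 / (1.0 + np.exp(-(h @ params.U.T + params.b_U)))
    scores = (at * ag) @ params.w_att + params.b_att  # (N,)
    a = softmax(scores)                               # attention weights
    z = a @ h                                         # (H1,) slide feature
    logits = params.W_clf @ z + params.b_clf
    p = softmax(logits)
    return z0, h, at, ag, scores, a, z, logits, p


def attention_weights(params: AbmilParams, bag: FeatureBag) -> np.ndarray:
    """Per-patch attention weights: softmax-normalised gated attention
    scores, in [0, 1], summing to 1 across the bag."""
    x = _check_bag(params, bag)
    return _forward(params, x)[5]


def aggregate(params: AbmilParams, weights: np.ndarray, bag: FeatureBag) -> np.ndarray:
    """Attention-weighted average of the projected patch features."""
    x = _check_bag(params, bag)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (x.shape[0],):
        raise ValueError(
            f"weights length {weights.shape} does not match bag size {x.shape[0]}"
        )
    h = np.maximum(x @ params.W_proj.T + params.b_proj, 0.0)
    return weights @ h


def classify(params: AbmilParams, slide_feature: np.ndarray) -> np.ndarray:
    """Class probabilities from a slide-level feature (softmax of the two
    class logits; invariant to adding a constant to both logits)."""
    z = np.asarray(slide_feature, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("non-finite slide feature")
    return softmax(params.W_clf @ z + params.b_clf)


def predict_slide(params: AbmilParams, bag: FeatureBag) -> SlidePrediction:
    """Full evaluation-mode slide prediction (dropout off, deterministic)."""
    x = _check_bag(params, bag)
    *_, a, _z, _logits, p = _forward(params, x)
    return SlidePrediction(
        slide_id=bag.slide_id,
        probs=p,
        predicted_label=LABELS[int(np.argmax(p))],
        attention=a,
    )


def ensemble_predict(members: list[AbmilParams], bag: FeatureBag) -> SlidePrediction:
    """Average the members' probability vectors (and attention, renormalised)."""
    if not members:
        raise ValueError("need at least one ensemble member")
    preds = [predict_slide(m, bag) for m in members]
    probs = np.mean([p.probs for p in preds], axis=0)
    att = np.mean([p.attention for p in preds], axis=0)
    att = att / att.sum()
    return SlidePrediction(
        slide_id=bag.slide_id,
        probs=probs,
        predicted_label=LABELS[int(np.argmax(probs))],
        attention=att,
    )


def _loss_and_grads(
    params: AbmilParams,
    x: np.ndarray,
    y: int,
    class_weight: float,
    dropout: float,
    rng: np.random.Generator | None,
):
    """Class-weighted cross-entropy loss of one bag and its analytic
    gradients with respect to every parameter."""
    n, _ = x.shape
    h1 = params.hidden[0]
    mask = None
    if dropout > 0.0 and rng is not None:
        keep = (rng.random((n, h1)) >= dropout).astype(np.float64)
        mask = keep / (1.0 - dropout)
    z0, h, at, ag, scores, a, z, logits, p = _forward(params, x, mask)
    loss = -class_weight * np.log(max(p[y], 1e-300))

    dlogits = class_weight * (p - np.eye(N_CLASSES)[y])      # (C,)
    g = {
        "W_clf": np.outer(dlogits, z),
        "b_clf": dlogits,
    }
    dz = params.W_clf.T @ dlogits                            # (H1,)
    da = h @ dz                                              # (N,)
    dh = np.outer(a, dz)                                     # (N, H1)
    # softmax backward on the attention scores
    dscores = a * (da - float(a @ da))                       # (N,)
    gated = at * ag
    g["w_att"] = gated.T @ dscores
    g["b_att"] = np.asarray(dscores.sum())
    dgated = np.outer(dscores, params.w_att)                 # (N, H2)
    dat = dgated * ag
    dag = dgated * at
    dzt = dat * (1.0 - at**2)                                # pre-tanh
    dzg = dag * ag * (1.0 - ag)                              # pre-sigmoid
    g["V"] = dzt.T @ h
    g["b_V"] = dzt.sum(axis=0)
    g["U"] = dzg.T @ h
    g["b_U"] = dzg.sum(axis=0)
    dh += dzt @ params.V + dzg @ params.U
    if mask is not None:
        dh = dh * mask
    dz0 = dh * (z0 > 0)
    g["W_proj"] = dz0.T @ x
    g["b_proj"] = dz0.sum(axis=0)
    return loss, g


def _validation_loss(
    params: AbmilParams, bags, ys, class_weights: np.ndarray
) -> float:
    total = 0.0
    for bag, y in zip(bags, ys):
        x = _check_bag(params, bag)
        p = _forward(params, x)[-1]
        total += -class_weights[y] * np.log(max(p[y], 1e-300))
    return total / len(bags)


def _labels_to_int(labels) -> np.ndarray:
    try:
        return np.asarray([LABELS.index(l) for l in labels], dtype=np.int64)
    except ValueError:
        raise ValueError(f"labels must be drawn from {LABELS}") from None


def train(
    params: AbmilParams,
    bags: list[FeatureBag],
    labels,
    config: TrainConfig,
    val_bags: list[FeatureBag],
    val_labels,
    case_ids=None,
) -> tuple[AbmilParams, list[dict]]:
    """Train an ABMIL classifier with early stopping.

    One bag per Adam step, shuffled each epoch; after each epoch the
    class-weighted validation loss is evaluated, and training stops once
    it has not improved for ``config.patience`` epochs after
    ``config.min_epochs``.  Returns the parameters of the best validation
    epoch and a per-epoch history.  Fully reproducible for a fixed
    ``config.seed``.  ``case_ids`` is accepted for bookkeeping (splitting
    is the caller's responsibility and must be case-level).
    """
    y = _labels_to_int(labels)
    y_val = _labels_to_int(val_labels)
    for name, arr in (("training", y), ("validation", y_val)):
        if len(np.unique(arr)) < N_CLASSES:
            raise ValueError(f"{name} set must contain both classes")

    if config.class_weighting == "inverse":
        counts = np.bincount(y, minlength=N_CLASSES).astype(np.float64)
        cw = counts.sum() / (N_CLASSES * counts)
    else:
        cw = np.ones(N_CLASSES)

    best = params.copy()
    history: list[dict] = []
    if config.max_epochs == 0:
        return best, history

    work = params.copy()
    rng = np.random.default_rng(config.seed)
    m_state = {k: np.zeros_like(getattr(work, k)) for k in _PARAM_FIELDS}
    v_state = {k: np.zeros_like(getattr(work, k)) for k in _PARAM_FIELDS}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    best_loss = np.inf
    best_epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(bags))
        train_loss = 0.0
        for i in order:
            x = _check_bag(work, bags[i])
            loss, grads = _loss_and_grads(
                work, x, int(y[i]), float(cw[y[i]]), config.dropout, rng
            )
            train_loss += loss
            t += 1
            for k in _PARAM_FIELDS:
                gk = grads[k]
                if config.weight_decay > 0 and k in _DECAYED:
                    gk = gk + config.weight_decay * getattr(work, k)
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gk
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gk**2
                m_hat = m_state[k] / (1 - beta1**t)
                v_hat = v_state[k] / (1 - beta2**t)
                setattr(
                    work,
                    k,
                    getattr(work, k)
                    - config.learning_rate * m_hat / (np.sqrt(v_hat) + eps),
                )
        val_loss = _validation_loss(work, val_bags, y_val, cw)
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss / len(bags),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_epoch = epoch
            best = work.copy()
        if epoch >= config.min_epochs and epoch - best_epoch >= config.patience:
            break
    return best, history


def save_checkpoint(
    params: AbmilParams,
    path: str | Path,
    extractor_id: str | None = None,
    train_config: TrainConfig | None = None,
) -> Path:
    """Serialise parameters plus provenance metadata to a single .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": params.seed,
        "feature_dim": params.feature_dim,
        "hidden": list(params.hidden),
        "extractor_id": extractor_id,
        "train_config": asdict(train_config) if train_config else None,
    }
    arrays = {k: getattr(params, k) for k in _PARAM_FIELDS}
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path) -> tuple[AbmilParams, dict]:
    """Load a checkpoint; returns (params, metadata dict)."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["_meta"]).decode())
        params = AbmilParams(
            **{k: f[k] for k in _PARAM_FIELDS}, seed=int(meta.get("seed", 0))
        )
    return params, meta
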