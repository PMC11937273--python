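"""Shallow 1-D CNN glucose regressor with pretrain / per-subject fine-tune scheme.

The network maps one preprocessed 700-point Raman spectrum to a glucose
concentration in mmol/L through exactly four layers: a single 1-D convolution
(8 filters, kernel 25, stride 5, ReLU), a flatten, a single dense layer
(96 units, ReLU), and a one-neuron linear output — about 105k trainable
parameters in the default configuration. Calibration happens in two phases:
population pretraining on a large multi-subject corpus (MSE loss, Adam,
subject-grouped early stopping), then per-subject fine-tuning on the morning
calibration sessions with the convolutional layer frozen.

Implemented directly in NumPy (forward, analytic backprop, Adam); the model is
small enough that a deep-learning framework adds nothing.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .preprocessing import MeanSpectrum, N_AXIS_POINTS, ProcessedSpectrum

__all__ = [
    "ArchitectureSpec",
    "TrainingHyper",
    "TrainedModel",
    "build_model",
    "count_params",
    "pretrain",
    "finetune",
    "predict",
    "predict_session",
]

PREDICTION_FLOOR_MMOL = 0.5  # clamp below: a linear output neuron can go negative


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes of the four-layer network (conv -> flatten -> dense -> output)."""

    input_length: int = N_AXIS_POINTS
    conv_filters: int = 8
    conv_kernel: int = 25
    conv_stride: int = 5
    conv_activation: str = "relu"
    dense_units: int = 96
    output_units: int = 1

    @property
    def conv_output_length(self) -> int:
        return (self.input_length - self.conv_kernel) // self.conv_stride + 1

    @property
    def flat_dim(self) -> int:
        return self.conv_output_length * self.conv_filters

    def param_count(self) -> int:
        """Closed-form trainable-parameter count across the four layers."""
        conv = self.conv_kernel * self.conv_filters + self.conv_filters
        dense = self.flat_dim * self.dense_units + self.dense_units
        out = self.dense_units * self.output_units + self.output_units
        return conv + dense + out


#: Parameter budget guard for the default architecture (~105k).
PARAM_BUDGET = (95_000, 115_000)


@dataclass
class TrainingHyper:
    """Optimization settings for both training phases (Adam on MSE in mmol/L)."""

    lr_pretrain: float = 1e-3
    lr_finetune: float = 1e-4
    batch_pretrain: int = 64
    batch_finetune: int = 8
    epochs_pretrain: int = 150
    epochs_finetune: int = 200
    patience: int = 50
    val_fraction: float = 0.2       # subject-grouped validation split, pretrain
    freeze_conv_on_finetune: bool = True
    finetune_mode: str = "proximal"  # "proximal" (closed form) | "sgd"
    finetune_lambda: float = 10.0    # proximal ridge strength, relative units
    gain_shrink: float = 0.0         # 0 = full 1/gain slope correction (unbiased)
    # pretrain regularization: a small corpus of simulated subjects memorizes
    # easily, so L2 decay and optional minibatch augmentation (random gain,
    # additive input noise) discourage subject-fingerprint shortcuts
    weight_decay: float = 0.01
    augment_noise_sd: float = 0.0    # additive noise, units of input RMS
    augment_gain_sd: float = 0.0     # multiplicative log-gain jitter

    def validate(self) -> None:
        if not self.lr_finetune < self.lr_pretrain:
            raise ValueError("fine-tune learning rate must be below pretrain rate")


@dataclass
class TrainedModel:
    """Network weights plus the preprocessing mean spectrum and training metadata."""

    spec: ArchitectureSpec
    weights: dict[str, np.ndarray]
    mean_spectrum: MeanSpectrum | None = None
    phase: str = "untrained"            # untrained | pretrained | finetuned
    seed: int | None = None
    loss_history: list = field(default_factory=list)
    parent_phase: str | None = None     # provenance of a fine-tuned model
    subject_id: str | None = None
    input_scale: float = 1.0            # fixed standardization of input spectra
    population_gain: float = 1.0        # held-out pred-vs-ref slope after pretrain

    def copy(self) -> "TrainedModel":
        return TrainedModel(
            spec=self.spec,
            weights={k: v.copy() for k, v in self.weights.items()},
            mean_spectrum=self.mean_spectrum,
            phase=self.phase, seed=self.seed,
            loss_history=list(self.loss_history),
            parent_phase=self.parent_phase, subject_id=self.subject_id,
            input_scale=self.input_scale, population_gain=self.population_gain,
        )


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_model(spec: ArchitectureSpec | None = None, seed: int = 0) -> TrainedModel:
    """Initialize the four-layer network with He-scaled weights (deterministic).

    For the default architecture the trainable-parameter count is guarded to the
    published ~105k budget; a default spec falling outside [95k, 115k] is a
    build error.
    """
    spec = spec or ArchitectureSpec()
    if spec == ArchitectureSpec():
        n = spec.param_count()
        if not (PARAM_BUDGET[0] <= n <= PARAM_BUDGET[1]):
            raise ValueError(
                f"default architecture has {n} parameters, outside {PARAM_BUDGET}")
    rng = np.random.default_rng(seed)
    w = {
        "W_conv": rng.normal(0.0, np.sqrt(2.0 / spec.conv_kernel),
                             (spec.conv_filters, spec.conv_kernel)),
        "b_conv": np.zeros(spec.conv_filters),
        "W_dense": rng.normal(0.0, np.sqrt(2.0 / spec.flat_dim),
                              (spec.flat_dim, spec.dense_units)),
        "b_dense": np.zeros(spec.dense_units),
        "W_out": rng.normal(0.0, np.sqrt(2.0 / spec.dense_units),
                            (spec.dense_units, spec.output_units)),
        "b_out": np.zeros(spec.output_units),
    }
    return TrainedModel(spec=spec, weights=w, phase="untrained", seed=seed)


def count_params(model: TrainedModel) -> int:
    """Exact count of trainable scalars in the model."""
    return int(sum(v.size for v in model.weights.values()))


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------


def _patches(X: np.ndarray, spec: ArchitectureSpec) -> np.ndarray:
    """(N, conv_out, kernel) strided view of the input for the conv layer."""
    win = sliding_window_view(X, spec.conv_kernel, axis=1)
    return win[:, :: spec.conv_stride, :]


def _forward(weights: dict, spec: ArchitectureSpec, X: np.ndarray,
             patches: np.ndarray | None = None) -> dict:
    P = _patches(X, spec) if patches is None else patches     # (N, L, K)
    z1 = P @ weights["W_conv"].T + weights["b_conv"]          # (N, L, F)
    a1 = np.maximum(z1, 0.0)
    flat = a1.reshape(a1.shape[0], -1)                        # (N, L*F)
    z2 = flat @ weights["W_dense"] + weights["b_dense"]
    a2 = np.maximum(z2, 0.0)
    out = a2 @ weights["W_out"] + weights["b_out"]            # (N, 1)
    return {"P": P, "z1": z1, "a1": a1, "flat": flat, "z2": z2, "a2": a2,
            "out": out[:, 0]}


def _backward(weights: dict, spec: ArchitectureSpec, cache: dict,
              y: np.ndarray) -> dict:
    """Gradients of mean squared error wrt all weights."""
    n = len(y)
    d_out = (2.0 / n) * (cache["out"] - y)[:, None]           # (N, 1)
    g = {
        "W_out": cache["a2"].T @ d_out,
        "b_out": d_out.sum(axis=0),
    }
    d_a2 = d_out @ weights["W_out"].T
    d_z2 = d_a2 * (cache["z2"] > 0)
    g["W_dense"] = cache["flat"].T @ d_z2
    g["b_dense"] = d_z2.sum(axis=0)
    d_flat = d_z2 @ weights["W_dense"].T
    d_a1 = d_flat.reshape(cache["a1"].shape)
    d_z1 = d_a1 * (cache["z1"] > 0)                           # (N, L, F)
    g["W_conv"] = np.einsum("nlf,nlk->fk", d_z1, cache["P"])
    g["b_conv"] = d_z1.sum(axis=(0, 1))
    return g


class _Adam:
    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 frozen: frozenset = frozenset()):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.frozen = frozen
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k in params:
            if k in self.frozen:
                continue
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _as_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
    else:
        X = np.stack([
            s.values if isinstance(s, ProcessedSpectrum) else np.asarray(s, dtype=float)
            for s in spectra
        ])
    return X


def _train(weights: dict, spec: ArchitectureSpec, X: np.ndarray, y: np.ndarray,
           lr: float, batch: int, epochs: int, patience: int,
           rng: np.random.Generator, frozen: frozenset = frozenset(),
           X_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
           weight_decay: float = 0.0, augment_noise_sd: float = 0.0,
           augment_gain_sd: float = 0.0) -> list[dict]:
    """Minibatch Adam on MSE with early stopping; returns the loss history.

    Early stopping monitors validation loss when a validation set is given,
    else training loss; the best weights seen are restored at the end.
    """
    opt = _Adam(weights, lr=lr, frozen=frozen)
    patches = _patches(X, spec).copy()
    patches_val = _patches(X_val, spec).copy() if X_val is not None else None
    history: list[dict] = []
    best_loss, best_w, since_best = np.inf, None, 0
    n = len(y)
    for epoch in range(epochs):
        order = rng.permutation(n)
        augment = augment_noise_sd > 0 or augment_gain_sd > 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Pb = patches[idx]
            if augment:
                Pb = Pb.copy()
                if augment_gain_sd > 0:
                    Pb *= np.exp(rng.normal(
                        0.0, augment_gain_sd, size=(len(idx), 1, 1)))
                if augment_noise_sd > 0:
                    Pb += rng.normal(0.0, augment_noise_sd, size=Pb.shape)
            cache = _forward(weights, spec, X[idx], patches=Pb)
            grads = _backward(weights, spec, cache, y[idx])
            if weight_decay > 0:
                for k in ("W_conv", "W_dense", "W_out"):
                    grads[k] = grads[k] + 2.0 * weight_decay * weights[k]
            if not all(np.all(np.isfinite(g)) for g in grads.values()):
                raise FloatingPointError(
                    f"non-finite gradients at epoch {epoch}; aborting training")
            opt.step(weights, grads)
        train_loss = float(np.mean(
            (_forward(weights, spec, X, patches=patches)["out"] - y) ** 2))
        if not np.isfinite(train_loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        rec = {"epoch": epoch, "train_mse": train_loss}
        monitor = train_loss
        if patches_val is not None:
            val_loss = float(np.mean(
                (_forward(weights, spec, X_val, patches=patches_val)["out"] - y_val) ** 2))
            rec["val_mse"] = val_loss
            monitor = val_loss
        history.append(rec)
        if monitor < best_loss - 1e-12:
            best_loss, since_best = monitor, 0
            best_w = {k: v.copy() for k, v in weights.items()}
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_w is not None:
        weights.update(best_w)
    return history


# ---------------------------------------------------------------------------
# public training API
# ---------------------------------------------------------------------------


def pretrain(corpus_X, corpus_y, groups, hyper: TrainingHyper | None = None,
             seed: int = 0, spec: ArchitectureSpec | None = None,
             mean_spectrum: MeanSpectrum | None = None) -> TrainedModel:
    """Population pretraining on a multi-subject corpus of (spectrum, glucose) pairs.

    ``groups`` holds one subject id per row; early stopping uses a
    subject-grouped hold-out so the stopping criterion measures generalization
    to unseen subjects, mirroring how the pretrained model is deployed.
    """
    hyper = hyper or TrainingHyper()
    hyper.validate()
    X = _as_matrix(corpus_X)
    y = np.asarray(corpus_y, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("pretraining requires a corpus with >= 2 subjects")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(hyper.val_fraction * len(uniq))))
    val_subjects = set(rng.choice(uniq, size=n_val, replace=False).tolist())
    val_mask = np.isin(groups, list(val_subjects))
    model = build_model(spec, seed=seed)
    # fixed input standardization: centered spectra are O(1e-4); bring them to
    # unit RMS so gradient magnitudes are sane, and store the scale with the model
    rms = float(np.sqrt(np.mean(X[~val_mask] ** 2)))
    model.input_scale = 1.0 / rms if rms > 0 else 1.0
    Xs = X * model.input_scale
    # start the output bias at the training-target mean: harmless, faster start
    model.weights["b_out"][:] = float(np.mean(y[~val_mask]))
    history = _train(
        model.weights, model.spec, Xs[~val_mask], y[~val_mask],
        lr=hyper.lr_pretrain, batch=hyper.batch_pretrain,
        epochs=hyper.epochs_pretrain, patience=hyper.patience, rng=rng,
        X_val=Xs[val_mask], y_val=y[val_mask],
        weight_decay=hyper.weight_decay,
        augment_noise_sd=hyper.augment_noise_sd,
        augment_gain_sd=hyper.augment_gain_sd,
    )
    model.phase = "pretrained"
    model.loss_history = history
    model.mean_spectrum = mean_spectrum
    # held-out regression gain: mean per-subject slope of prediction vs
    # reference on the validation subjects; a measure of the shrinkage the
    # MSE-optimal predictor applies to within-subject glucose excursions
    slopes = []
    for s in val_subjects:
        idx = groups == s
        yv = y[idx]
        if np.std(yv) < 1e-6:
            continue
        pv = _forward(model.weights, model.spec, Xs[idx])["out"]
        slopes.append(float(np.cov(pv, yv)[0, 1] / np.var(yv)))
    if slopes:
        model.population_gain = float(np.clip(np.mean(slopes), 0.2, 1.5))
    return model


def finetune(pretrained: TrainedModel, cal_X, cal_y,
             hyper: TrainingHyper | None = None, seed: int = 0,
             subject_id: str | None = None) -> TrainedModel:
    """Fine-tune a pretrained model to one subject's calibration sessions.

    The convolutional layer (population-level spectral features) is always
    frozen; the parent pretrained model is left untouched. Two modes:

    ``proximal`` (default): closed-form recalibration of the output layer.
    Ten morning calibration sessions span a narrow glucose range, which
    identifies the subject's offset but not a new regression surface, so the
    update (i) anchors the prediction at the calibration references while
    undoing most of the population-level shrinkage measured at pretrain time
    (slope 1/lambda, partially shrunk toward 1 by ``gain_shrink``), and then
    (ii) applies a ridge fit of the remaining calibration residuals penalized
    toward the pretrained output weights (bias unpenalized), absorbing
    subject-specific spectral interference. Deterministic.

    ``sgd``: Adam on the dense and output layers at the fine-tune learning
    rate with early stopping on training loss. Prone to collapsing toward a
    constant on narrow-range calibration data; retained for comparison.
    """
    hyper = hyper or TrainingHyper()
    hyper.validate()
    X = _as_matrix(cal_X)
    y = np.asarray(cal_y, dtype=float)
    if len(y) == 0:
        raise ValueError(
            "no calibration sessions given; use the pretrained model directly")
    if pretrained.phase == "untrained":
        raise ValueError("finetune requires a pretrained model")
    model = pretrained.copy()
    Xs = X * model.input_scale
    if hyper.finetune_mode == "proximal":
        # (i) anchor + partial shrinkage correction around the calibration point
        p0 = _forward(model.weights, model.spec, Xs)["out"]
        lam_use = model.population_gain + hyper.gain_shrink * (
            1.0 - model.population_gain)
        p_bar, r_bar = float(np.mean(p0)), float(np.mean(y))
        model.weights["W_out"] = model.weights["W_out"] / lam_use
        model.weights["b_out"] = (model.weights["b_out"] - p_bar) / lam_use + r_bar
        # (ii) proximal ridge on the remaining residuals
        cache = _forward(model.weights, model.spec, Xs)
        resid = y - cache["out"]
        A = np.hstack([cache["a2"], np.ones((len(y), 1))])
        pen = np.ones(A.shape[1])
        pen[-1] = 1e-6                      # offset is free, weights are tied
        lam = hyper.finetune_lambda * np.trace(A.T @ A) / A.shape[1]
        delta = np.linalg.solve(A.T @ A + lam * np.diag(pen), A.T @ resid)
        model.weights["W_out"] = model.weights["W_out"] + delta[:-1][:, None]
        model.weights["b_out"] = model.weights["b_out"] + delta[-1:]
        history = [{"epoch": 0,
                    "train_mse": float(np.mean((y - _forward(
                        model.weights, model.spec, Xs)["out"]) ** 2))}]
    elif hyper.finetune_mode == "sgd":
        frozen = frozenset({"W_conv", "b_conv"}) if hyper.freeze_conv_on_finetune \
            else frozenset()
        rng = np.random.default_rng(seed)
        history = _train(
            model.weights, model.spec, Xs, y,
            lr=hyper.lr_finetune, batch=hyper.batch_finetune,
            epochs=hyper.epochs_finetune, patience=hyper.patience, rng=rng,
            frozen=frozen,
        )
    else:
        raise ValueError(f"unknown finetune mode: {hyper.finetune_mode!r}")
    model.phase = "finetuned"
    model.parent_phase = pretrained.phase
    model.subject_id = subject_id
    model.loss_history = history
    return model


def predict(model: TrainedModel, spectra) -> np.ndarray | float:
    """Glucose prediction(s) in mmol/L, clamped below at 0.5 mmol/L."""
    single = isinstance(spectra, ProcessedSpectrum) or (
        isinstance(spectra, np.ndarray) and spectra.ndim == 1)
    X = _as_matrix([spectra] if single else spectra)
    if X.shape[1] != model.spec.input_length:
        raise ValueError(
            f"spectrum length {X.shape[1]} != model input {model.spec.input_length}")
    out = _forward(model.weights, model.spec, X * model.input_scale)["out"]
    out = np.maximum(out, PREDICTION_FLOOR_MMOL)
    return float(out[0]) if single else out


def predict_session(model: TrainedModel, placements) -> float:
    """Session-level NIGM value: mean of the per-placement predictions (1-4)."""
    placements = list(placements)
    if len(placements) == 0:
        raise ValueError("a session needs at least one placement spectrum")
    preds = predict(model, placements)
    return float(np.mean(preds))
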