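"""Training protocol for the change-detection models.

The task is treated as per-frame binary classification: label 1 on change
presentations, 0 on repeat/sham presentations, with the loss masked to image
frames only.  The loss is a weighted binary cross entropy (positive weight 5
on change frames, mean over masked-in frames) plus an L2 penalty on hidden
activations.  Parameters are updated with Adam (lr 1e-3, betas 0.9/0.999);
gradients are computed by backpropagation through time over one full session
per epoch, truncated at session boundaries.  Training stops when the d-prime
of Bernoulli-sampled responses stays at or above the criterion (1.5) for
``patience`` (5) consecutive epochs, or at ``max_epochs``.

The networks are small (64-16-1) so forward and backward passes are written
directly in NumPy; for the purely feedforward STPNet both passes are fully
vectorized over time, while recurrent models loop over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models import ModelConfig, ModelKind, ModelState, init_model
from .stp_dynamics import STPParams
from .synthetic_data import EmbeddingMatrix, StimulusSequence, generate_session

__all__ = [
    "TaskParams",
    "TrainConfig",
    "TrainHistory",
    "TrainingError",
    "compute_loss",
    "dprime",
    "train_model",
    "train_ensemble",
    "sweep",
]


@dataclass(frozen=True)
class TaskParams:
    """Session-generation parameters shared by training and evaluation."""

    n_images: int = 8
    p_go: float = 0.5
    p_omit: float = 0.0
    min_repeats: int = 4
    max_repeats: int = 11
    repeat_hazard: float = 0.3
    n_gray: int = 2
    dt: float = 0.25

    def make_session(self, n_trials: int, rng: np.random.Generator) -> StimulusSequence:
        return generate_session(
            n_trials=n_trials,
            n_images=self.n_images,
            p_go=self.p_go,
            p_omit=self.p_omit,
            min_repeats=self.min_repeats,
            max_repeats=self.max_repeats,
            repeat_hazard=self.repeat_hazard,
            n_gray=self.n_gray,
            dt=self.dt,
            seed=rng,
        )


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    pos_weight: float = 5.0
    l2_act_weight: float = 1e-3
    max_epochs: int = 5000
    dprime_criterion: float = 1.5
    patience: int = 5
    n_seeds: int = 10
    trials_per_epoch: int = 100

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if min(self.lr, self.pos_weight) <= 0 or self.max_epochs < 1:
            raise ValueError("lr, pos_weight, max_epochs must be positive")
        if self.l2_act_weight < 0:
            raise ValueError("l2_act_weight must be non-negative")


@dataclass
class TrainHistory:
    loss: np.ndarray
    dprime: np.ndarray
    hit_rate: np.ndarray
    fa_rate: np.ndarray
    stop_epoch: int
    stop_reason: str  # "criterion" or "max_epochs"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.loss)),
                "loss": self.loss,
                "dprime": self.dprime,
                "hit_rate": self.hit_rate,
                "fa_rate": self.fa_rate,
            }
        )


class TrainingError(RuntimeError):
    """Raised when training diverges; carries the partial history."""

    def __init__(self, message: str, history: TrainHistory | None = None):
        super().__init__(message)
        self.history = history


# ---------------------------------------------------------------------------
# loss and d-prime
# ---------------------------------------------------------------------------

def compute_loss(
    logits: np.ndarray,
    labels: np.ndarray,
    presentation_mask: np.ndarray,
    hidden_activities: np.ndarray,
    config: TrainConfig,
) -> float:
    """Masked weighted BCE plus L2 activity penalty.

    BCE is averaged over masked-in frames with label-1 terms multiplied by
    ``pos_weight``; an all-masked-out batch yields the penalty term alone.
    """
    logits = np.asarray(logits, float)
    labels = np.asarray(labels, float)
    mask = np.asarray(presentation_mask, float)
    if not (logits.shape == labels.shape == mask.shape):
        raise ValueError("logits, labels and mask must have identical shapes")
    nm = mask.sum()
    if nm > 0:
        # numerically stable BCE-with-logits; pos_weight scales the label-1 term
        z, y = logits, labels
        softplus = np.log1p(np.exp(-np.abs(z)))
        per = config.pos_weight * y * (np.maximum(z, 0) - z + softplus) + (1 - y) * (
            np.maximum(z, 0) + softplus
        )
        bce = float((mask * per).sum() / nm)
    else:
        bce = 0.0
    penalty = config.l2_act_weight * float(np.mean(np.square(hidden_activities)))
    return bce + penalty


def dprime(hit_rate: float, fa_rate: float, n_go: int, n_catch: int) -> float:
    """Signal-detection sensitivity with rates clipped to [1/2n, 1 - 1/2n]."""
    if n_go <= 0 or n_catch <= 0:
        raise ValueError("d-prime undefined for zero trial counts")
    if not (0 <= hit_rate <= 1 and 0 <= fa_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    h = np.clip(hit_rate, 1 / (2 * n_go), 1 - 1 / (2 * n_go))
    f = np.clip(fa_rate, 1 / (2 * n_catch), 1 - 1 / (2 * n_catch))
    return float(norm.ppf(h) - norm.ppf(f))


# ---------------------------------------------------------------------------
# session forward/backward (BPTT)
# ---------------------------------------------------------------------------

def _session_arrays(sequence: StimulusSequence, embeddings: EmbeddingMatrix):
    """Per-step input features, labels and loss mask for one session."""
    T = sequence.n_steps
    feats = np.zeros((T, embeddings.n_features))
    shown = sequence.is_presentation
    feats[shown] = embeddings.values[sequence.image_id[shown]]
    labels = sequence.is_change.astype(float)
    mask = shown.astype(float)
    return feats, labels, mask


def _depression_trajectory(R: np.ndarray, stp: STPParams) -> np.ndarray:
    a = stp.dt / stp.tau_x
    b = stp.U * stp.dt
    X = np.empty_like(R)
    x = np.ones(R.shape[1])
    for t in range(R.shape[0]):
        x = (x + a) / (1.0 + a + b * R[t])
        X[t] = x
    return X


def _forward_backward(
    state: ModelState,
    config: ModelConfig,
    feats: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray,
    tcfg: TrainConfig,
    rng: np.random.Generator,
):
    """One session: forward with noise, loss, gradients, per-frame sigmoids."""
    T, ni = feats.shape
    nh = config.n_hidden
    sd = config.noise_sd
    if sd > 0:
        R = np.maximum(feats * (1 + rng.normal(0, sd, size=feats.shape)), 0)
        nu = 1 + rng.normal(0, sd, size=(T, nh))
    else:
        R = feats.copy()
        nu = np.ones((T, nh))

    if config.has_stp:
        X = _depression_trajectory(R, config.stp)
        U_in = X * R
    else:
        U_in = R

    Wi, bh, Wo, bo = state.W_in, state.b_h, state.W_out, state.b_out
    if config.has_recurrence:
        Wr = state.W_rec
        pre_in = U_in @ Wi.T + bh
        if config.kind is ModelKind.STPRNN:
            pre_in += R @ state.W_plain.T
        H = np.empty((T, nh))  # post-noise hidden
        h = np.zeros(nh)
        for t in range(T):
            a_t = pre_in[t] + Wr @ h
            h = np.maximum(np.maximum(a_t, 0) * nu[t], 0)
            H[t] = h
    else:
        A = U_in @ Wi.T + bh
        H = np.maximum(np.maximum(A, 0) * nu, 0)
    logits = H @ Wo + bo
    sig = 1.0 / (1.0 + np.exp(-logits))

    loss = compute_loss(logits, labels, mask, H, tcfg)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")

    nm = mask.sum()
    dz = mask * (tcfg.pos_weight * labels * (sig - 1) + (1 - labels) * sig)
    if nm > 0:
        dz = dz / nm
    dl2 = 2.0 * tcfg.l2_act_weight / H.size

    grads: dict[str, np.ndarray] = {}
    grads["W_out"] = H.T @ dz
    grads["b_out"] = np.asarray(dz.sum())
    dH = np.outer(dz, Wo) + dl2 * H  # (T, nh)
    act = (H > 0).astype(float) * nu  # dH/da through noise and both rectifiers
    if config.has_recurrence:
        dA = np.empty((T, nh))
        dh_next = np.zeros(nh)
        WrT = state.W_rec.T
        for t in range(T - 1, -1, -1):
            da = (dH[t] + dh_next) * act[t]
            dA[t] = da
            dh_next = WrT @ da
        grads["W_rec"] = dA[1:].T @ H[:-1]
    else:
        dA = dH * act
    grads["W_in"] = dA.T @ U_in
    grads["b_h"] = dA.sum(axis=0)
    if config.kind is ModelKind.STPRNN:
        grads["W_plain"] = dA.T @ R
    return loss, logits, sig, grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, betas: tuple[float, float]):
        self.lr = lr
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * mh / (np.sqrt(vh) + 1e-8)
        return out


def _apply_params(state: ModelState, params: dict[str, np.ndarray]) -> None:
    state.W_in = params["W_in"]
    state.b_h = params["b_h"]
    state.W_out = params["W_out"]
    state.b_out = float(params["b_out"])
    if "W_rec" in params:
        state.W_rec = params["W_rec"]
    if "W_plain" in params:
        state.W_plain = params["W_plain"]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_model(
    model_kind: ModelKind | str,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    task_params: TaskParams | None = None,
    embeddings: EmbeddingMatrix | None = None,
    seed: int = 0,
) -> tuple[ModelState, TrainHistory]:
    """Train one model to the d-prime criterion.

    One epoch = one freshly generated session of ``trials_per_epoch`` trials.
    After each update the epoch's Bernoulli-sampled responses on change (go)
    and sham-change (catch) presentations give hit and false-alarm rates and
    a d-prime value; training stops once d-prime has been at or above the
    criterion for ``patience`` consecutive epochs.  Training sessions contain
    no omissions.  Fully deterministic given ``seed`` and the configs.
    """
    kind = ModelKind(model_kind)
    tcfg = train_config or TrainConfig()
    task = task_params or TaskParams()
    if task.p_omit != 0:
        task = replace(task, p_omit=0.0)  # omissions are withheld during training
    config = model_config or ModelConfig(kind=kind)
    if config.kind != kind:
        raise ValueError(f"model_config.kind {config.kind} != requested {kind}")

    ss = np.random.SeedSequence(seed)
    init_rng, session_rng, noise_rng, eval_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    if embeddings is None:
        embeddings = _default_embeddings(session_rng)

    state = init_model(config, init_rng)
    params = state.parameters()
    adam = _Adam(params, tcfg.lr, tcfg.betas)

    losses, dprimes, hits, fas = [], [], [], []
    consec = 0
    stop_reason = "max_epochs"
    epoch = 0
    for epoch in range(1, tcfg.max_epochs + 1):
        sequence = task.make_session(tcfg.trials_per_epoch, session_rng)
        feats, labels, mask = _session_arrays(sequence, embeddings)
        try:
            loss, logits, sig, grads = _forward_backward(
                state, config, feats, labels, mask, tcfg, noise_rng
            )
        except FloatingPointError as err:
            history = _history(losses, dprimes, hits, fas, epoch - 1, "diverged")
            raise TrainingError(f"training diverged at epoch {epoch}: {err}", history) from err
        params = adam.step(params, grads)
        _apply_params(state, params)

        resp = eval_rng.random(len(sig)) < sig
        go = sequence.is_change
        catch = sequence.is_sham_change
        d = dprime(resp[go].mean(), resp[catch].mean(), int(go.sum()), int(catch.sum()))
        losses.append(loss); dprimes.append(d)
        hits.append(resp[go].mean()); fas.append(resp[catch].mean())
        consec = consec + 1 if d >= tcfg.dprime_criterion else 0
        if consec >= tcfg.patience:
            stop_reason = "criterion"
            break

    state.reset_dynamic(config)
    return state, _history(losses, dprimes, hits, fas, epoch, stop_reason)


def _history(losses, dprimes, hits, fas, stop_epoch, stop_reason) -> TrainHistory:
    return TrainHistory(
        loss=np.array(losses),
        dprime=np.array(dprimes),
        hit_rate=np.array(hits),
        fa_rate=np.array(fas),
        stop_epoch=stop_epoch,
        stop_reason=stop_reason,
    )


def _default_embeddings(rng: np.random.Generator) -> EmbeddingMatrix:
    from .synthetic_data import generate_embeddings

    return generate_embeddings(seed=rng)


def train_ensemble(
    model_kind: ModelKind | str,
    n_seeds: int | None = None,
    base_seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    task_params: TaskParams | None = None,
    embeddings: EmbeddingMatrix | None = None,
) -> list[tuple[ModelState, TrainHistory]]:
    """Train ``n_seeds`` models with seeds derived deterministically from ``base_seed``."""
    tcfg = train_config or TrainConfig()
    n = n_seeds if n_seeds is not None else tcfg.n_seeds
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n) % (2**31)
    return [
        train_model(model_kind, model_config, tcfg, task_params, embeddings, seed=int(s))
        for s in child_seeds
    ]


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

def sweep(
    parameter: str,
    values: list[float],
    model_kind: ModelKind | str = ModelKind.STPNET,
    n_seeds: int = 3,
    base_seed: int = 0,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    task_params: TaskParams | None = None,
    embeddings: EmbeddingMatrix | None = None,
) -> pd.DataFrame:
    """Train across values of ``tau_x`` or ``isi_duration`` (seconds).

    Per-cell failures are recorded in the ``error`` column without aborting
    the sweep.  Returns one row per (value, seed) with stop epoch, reason and
    final d-prime.
    """
    if parameter not in ("tau_x", "isi_duration"):
        raise ValueError("parameter must be 'tau_x' or 'isi_duration'")
    kind = ModelKind(model_kind)
    config = model_config or ModelConfig(kind=kind)
    task = task_params or TaskParams()
    rows = []
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31)
    for value in values:
        if parameter == "tau_x":
            if not config.has_stp:
                raise ValueError("tau_x sweep requires a depressing model")
            cfg_v = replace(config, stp=replace(config.stp, tau_x=float(value)))
            task_v = task
        else:
            n_gray = round(float(value) / task.dt)
            if not np.isclose(n_gray * task.dt, value) or n_gray < 1:
                raise ValueError(
                    f"isi_duration {value} is not a positive multiple of dt={task.dt}"
                )
            cfg_v = config
            task_v = replace(task, n_gray=int(n_gray))
        for s in child_seeds:
            row = {"parameter": parameter, "value": value, "seed": int(s)}
            try:
                _, hist = train_model(kind, cfg_v, train_config, task_v, embeddings, seed=int(s))
                row.update(
                    stop_epoch=hist.stop_epoch,
                    stop_reason=hist.stop_reason,
                    final_dprime=float(hist.dprime[-1]) if len(hist.dprime) else np.nan,
                    error="",
                )
            except Exception as err:  # noqa: BLE001 - per-cell isolation is the contract
                row.update(stop_epoch=-1, stop_reason="error", final_dprime=np.nan,
                           error=str(err))
            rows.append(row)
    return pd.DataFrame(rows)
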