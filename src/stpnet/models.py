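"""The three network models mapping embedding sequences to a decision variable.

* ``STPNET`` -- feedforward 64-16-1 network whose input synapses depress
  according to the Tsodyks-Markram resource dynamics; the memory of recent
  stimuli lives entirely in the synaptic efficacies.
* ``RNN`` -- 64-16-1 network with a recurrently connected hidden layer and
  static synapses; the memory lives in persistent hidden activity.
* ``STPRNN`` -- both pathways: an adapting and a non-adapting input block
  plus recurrence.  Zeroing the adapting block recovers the RNN; zeroing the
  non-adapting block and the recurrence recovers STPNet.

All units are linearly rectified.  Independent multiplicative Gaussian noise
(sd 0.5 by default) perturbs the input features and the hidden activities to
make responses non-deterministic; zero activity stays zero under this noise.
The single output unit produces a logit whose sigmoid is the per-frame
probability of reporting an image change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import h5py
import numpy as np

from .stp_dynamics import STPParams, SynapseState, step_depression
from .synthetic_data import EmbeddingMatrix, StimulusSequence

__all__ = [
    "ModelKind",
    "ModelConfig",
    "ModelState",
    "SimRecord",
    "init_model",
    "apply_noise",
    "forward_step",
    "run_sequence",
    "save_checkpoint",
    "load_checkpoint",
]


class ModelKind(str, Enum):
    STPNET = "stpnet"
    RNN = "rnn"
    STPRNN = "stprnn"


@dataclass(frozen=True)
class ModelConfig:
    kind: ModelKind = ModelKind.STPNET
    n_input: int = 64
    n_hidden: int = 16
    n_output: int = 1
    noise_sd: float = 0.5
    stp: STPParams | None = field(default_factory=STPParams)

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is ModelKind.RNN:
            object.__setattr__(self, "stp", None)
        elif self.stp is None:
            object.__setattr__(self, "stp", STPParams())

    @property
    def has_stp(self) -> bool:
        return self.kind in (ModelKind.STPNET, ModelKind.STPRNN)

    @property
    def has_recurrence(self) -> bool:
        return self.kind in (ModelKind.RNN, ModelKind.STPRNN)


@dataclass
class ModelState:
    """Trainable weights plus the dynamic state carried across timesteps.

    ``W_in`` is the (single) input block for STPNet/RNN; for STPRNN it is the
    *adapting* block and ``W_plain`` the non-adapting one.  One hidden bias
    and one output bias, matching the reference parameter counts.
    """

    W_in: np.ndarray
    b_h: np.ndarray
    W_out: np.ndarray
    b_out: float
    W_rec: np.ndarray | None = None
    W_plain: np.ndarray | None = None
    synapse: SynapseState | None = None
    hidden: np.ndarray | None = None

    def reset_dynamic(self, config: ModelConfig) -> None:
        """Fresh session: resources fully recovered, hidden activity zero."""
        self.synapse = SynapseState.full(config.n_input) if config.has_stp else None
        self.hidden = np.zeros(config.n_hidden)

    def parameters(self) -> dict[str, np.ndarray]:
        out = {"W_in": self.W_in, "b_h": self.b_h, "W_out": self.W_out,
               "b_out": np.asarray(self.b_out, dtype=float)}
        if self.W_rec is not None:
            out["W_rec"] = self.W_rec
        if self.W_plain is not None:
            out["W_plain"] = self.W_plain
        return out


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    # uniform in +-1/sqrt(fan_in), the convention the reference models used
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_model(config: ModelConfig, seed: int | np.random.Generator = 0) -> ModelState:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nh, ni = config.n_hidden, config.n_input
    state = ModelState(
        W_in=_uniform_fan_in(rng, (nh, ni), ni),
        b_h=_uniform_fan_in(rng, (nh,), ni),
        W_out=_uniform_fan_in(rng, (nh,), nh),
        b_out=float(_uniform_fan_in(rng, (), nh)),
    )
    if config.has_recurrence:
        state.W_rec = _uniform_fan_in(rng, (nh, nh), nh)
    if config.kind is ModelKind.STPRNN:
        state.W_plain = _uniform_fan_in(rng, (nh, ni), ni)
    state.reset_dynamic(config)
    return state


def apply_noise(activity: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise, rectified: ``max(0, a * (1 + eps))``."""
    activity = np.asarray(activity, dtype=float)
    if noise_sd == 0:
        return activity.copy()
    eps = rng.normal(0.0, noise_sd, size=activity.shape)
    return np.maximum(activity * (1.0 + eps), 0.0)


def forward_step(
    state: ModelState,
    config: ModelConfig,
    input_features: np.ndarray,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Advance the model one frame; returns (logit, noised hidden activity).

    The input is noised and rectified; for depressing pathways the resource
    state is advanced with the noised input (noise models encoder
    variability, which drives release) and the drive is gated by the updated
    resources.  Hidden activity receives the same multiplicative noise and is
    carried to the next step for recurrent models.
    """
    r = np.asarray(input_features, dtype=float)
    if r.shape != (config.n_input,):
        raise ValueError(f"expected input of shape ({config.n_input},), got {r.shape}")
    r_noised = apply_noise(r, config.noise_sd, rng)

    drive = np.zeros(config.n_hidden)
    if config.has_stp:
        state.synapse = step_depression(state.synapse, r_noised, config.stp)
        gated = state.synapse.x * r_noised
        drive += state.W_in @ gated
        if config.kind is ModelKind.STPRNN:
            drive += state.W_plain @ r_noised
    else:
        drive += state.W_in @ r_noised
    if config.has_recurrence:
        drive += state.W_rec @ state.hidden
    drive += state.b_h

    hidden = np.maximum(drive, 0.0)
    hidden_noised = apply_noise(hidden, config.noise_sd, rng)
    state.hidden = hidden_noised
    logit = float(state.W_out @ hidden_noised + state.b_out)
    if not np.isfinite(logit):
        raise FloatingPointError("non-finite logit in forward step")
    return logit, hidden_noised


@dataclass
class SimRecord:
    """Everything recorded while running a model over a session."""

    logits: np.ndarray  # (T,)
    hidden: np.ndarray  # (T, n_hidden), post-noise
    input_noised: np.ndarray  # (T, n_input), post-noise pre-depression
    input_gated: np.ndarray  # (T, n_input); equals input_noised for RNN
    resources: np.ndarray | None  # (T, n_input) for STP models, else None


def run_sequence(
    state: ModelState,
    config: ModelConfig,
    sequence: StimulusSequence,
    embeddings: EmbeddingMatrix,
    rng: np.random.Generator,
    reset: bool = True,
) -> SimRecord:
    """Run the model over a full session; gray/omitted frames feed zero input."""
    if embeddings.n_features != config.n_input:
        raise ValueError(
            f"embedding has {embeddings.n_features} features, model expects {config.n_input}"
        )
    if sequence.n_images > embeddings.n_images:
        raise ValueError("sequence references more images than the embedding provides")
    if reset:
        state.reset_dynamic(config)
    T = sequence.n_steps
    rec = SimRecord(
        logits=np.zeros(T),
        hidden=np.zeros((T, config.n_hidden)),
        input_noised=np.zeros((T, config.n_input)),
        input_gated=np.zeros((T, config.n_input)),
        resources=np.zeros((T, config.n_input)) if config.has_stp else None,
    )
    shown = sequence.is_presentation
    zero = np.zeros(config.n_input)
    for t in range(T):
        feats = embeddings.values[sequence.image_id[t]] if shown[t] else zero
        r_noised = apply_noise(feats, config.noise_sd, rng)
        if config.has_stp:
            state.synapse = step_depression(state.synapse, r_noised, config.stp)
            gated = state.synapse.x * r_noised
            drive = state.W_in @ gated
            if config.kind is ModelKind.STPRNN:
                drive = drive + state.W_plain @ r_noised
            rec.resources[t] = state.synapse.x
        else:
            gated = r_noised
            drive = state.W_in @ r_noised
        if config.has_recurrence:
            drive = drive + state.W_rec @ state.hidden
        drive = drive + state.b_h
        hidden = apply_noise(np.maximum(drive, 0.0), config.noise_sd, rng)
        state.hidden = hidden
        rec.logits[t] = state.W_out @ hidden + state.b_out
        rec.hidden[t] = hidden
        rec.input_noised[t] = r_noised
        rec.input_gated[t] = gated
    if not np.all(np.isfinite(rec.logits)):
        bad = int(np.flatnonzero(~np.isfinite(rec.logits))[0])
        raise FloatingPointError(f"non-finite logit at step {bad}")
    return rec


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, state: ModelState, config: ModelConfig,
                    seed: int | None = None) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("model")
        g.attrs["kind"] = config.kind.value
        g.attrs["n_input"] = config.n_input
        g.attrs["n_hidden"] = config.n_hidden
        g.attrs["n_output"] = config.n_output
        g.attrs["noise_sd"] = config.noise_sd
        if seed is not None:
            g.attrs["seed"] = seed
        if config.stp is not None:
            g.attrs["stp_U"] = config.stp.U
            g.attrs["stp_tau_x"] = config.stp.tau_x
            g.attrs["stp_dt"] = config.stp.dt
        for name, value in state.parameters().items():
            g.create_dataset(name, data=value)
        if state.synapse is not None:
            g.create_dataset("synapse_x", data=state.synapse.x)
        if state.hidden is not None:
            g.create_dataset("hidden", data=state.hidden)


def load_checkpoint(path: str | Path) -> tuple[ModelState, ModelConfig]:
    with h5py.File(path, "r") as fh:
        g = fh["model"]
        stp = None
        if "stp_U" in g.attrs:
            stp = STPParams(U=float(g.attrs["stp_U"]), tau_x=float(g.attrs["stp_tau_x"]),
                            dt=float(g.attrs["stp_dt"]))
        config = ModelConfig(
            kind=ModelKind(g.attrs["kind"]),
            n_input=int(g.attrs["n_input"]),
            n_hidden=int(g.attrs["n_hidden"]),
            n_output=int(g.attrs["n_output"]),
            noise_sd=float(g.attrs["noise_sd"]),
            stp=stp,
        )
        state = ModelState(
            W_in=g["W_in"][:],
            b_h=g["b_h"][:],
            W_out=g["W_out"][:],
            b_out=float(g["b_out"][()]),
            W_rec=g["W_rec"][:] if "W_rec" in g else None,
            W_plain=g["W_plain"][:] if "W_plain" in g else None,
        )
        state.synapse = SynapseState(x=g["synapse_x"][:]) if "synapse_x" in g else None
        state.hidden = g["hidden"][:] if "hidden" in g else None
    return state, config
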