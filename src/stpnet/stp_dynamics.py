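"""Rate-based Tsodyks-Markram short-term synaptic depression.

The resource variable ``x`` (fraction of neurotransmitter available) of each
presynaptic unit evolves as

    dx/dt = (1 - x) / tau_x - U * x * r(t)

where ``U`` is the release fraction, ``tau_x`` the recovery time constant and
``r(t)`` the presynaptic firing rate.  The effective drive delivered to a
postsynaptic population is ``W @ (x * r)``: all synapses of one presynaptic
unit share that unit's resource state.

Time is discretized with the implicit backward Euler method.  Because the
equation is linear in ``x`` the implicit update has a closed form,

    x' = (x + dt / tau_x) / (1 + dt / tau_x + U * dt * r),

which is unconditionally stable, keeps ``x`` in (0, 1] for any non-negative
rate, and shares its fixed point with the continuous-time steady state
``x* = (1/tau_x) / (1/tau_x + U * r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "STPParams",
    "SynapseState",
    "step_depression",
    "effective_input",
    "run_depression",
    "steady_state",
]


@dataclass(frozen=True)
class STPParams:
    """Parameters of the depression model.

    U : release fraction per presentation, dimensionless, in (0, 1].
    tau_x : recovery time constant in seconds.
    dt : integration timestep in seconds (one stimulus frame).
    """

    U: float = 0.5
    tau_x: float = 1.5
    dt: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.U <= 1.0:
            raise ValueError(f"U must be in (0, 1], got {self.U}")
        if self.tau_x <= 0:
            raise ValueError(f"tau_x must be positive, got {self.tau_x}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")


@dataclass
class SynapseState:
    """Per-presynaptic-unit resource fraction, initialized fully recovered."""

    x: np.ndarray = field(default_factory=lambda: np.ones(1))

    @classmethod
    def full(cls, n_units: int) -> "SynapseState":
        return cls(x=np.ones(n_units))


def step_depression(
    state: SynapseState, r: np.ndarray, params: STPParams
) -> SynapseState:
    """Advance the resource variable one timestep (closed-form backward Euler).

    Parameters
    ----------
    state : current synapse state with ``x`` in (0, 1].
    r : non-negative presynaptic activity vector, same length as ``state.x``.
    params : depression parameters.

    Returns a new :class:`SynapseState`; the input state is not modified.
    """
    r = np.asarray(r, dtype=float)
    x = np.asarray(state.x, dtype=float)
    if r.shape != x.shape:
        raise ValueError(f"activity shape {r.shape} != state shape {x.shape}")
    if np.any(r < 0):
        raise ValueError("presynaptic activity must be non-negative")
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite synapse state")
    a = params.dt / params.tau_x
    x_new = (x + a) / (1.0 + a + params.U * params.dt * r)
    return SynapseState(x=x_new)


def effective_input(W: np.ndarray, state: SynapseState, r: np.ndarray) -> np.ndarray:
    """Postsynaptic drive ``W @ (x * r)`` under the current depression state."""
    W = np.asarray(W, dtype=float)
    r = np.asarray(r, dtype=float)
    x = np.asarray(state.x, dtype=float)
    if r.shape != x.shape or W.shape[-1] != r.shape[0]:
        raise ValueError(
            f"shape mismatch: W {W.shape}, x {x.shape}, r {r.shape}"
        )
    return W @ (x * r)


def run_depression(rates: np.ndarray, params: STPParams, x0: np.ndarray | None = None) -> np.ndarray:
    """Resource trajectory for a full rate sequence.

    Parameters
    ----------
    rates : array (T, n_units) of non-negative activities.
    x0 : initial resources (default: fully recovered).

    Returns array (T, n_units); row ``t`` is the state *after* the implicit
    update with ``rates[t]``, i.e. the value that gates the drive at step t.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    state = SynapseState(x=np.ones(rates.shape[1]) if x0 is None else np.asarray(x0, float))
    out = np.empty_like(rates)
    for t in range(rates.shape[0]):
        state = step_depression(state, rates[t], params)
        out[t] = state.x
    return out


def steady_state(r: np.ndarray | float, params: STPParams) -> np.ndarray | float:
    """Fixed point ``x* = (1/tau_x) / (1/tau_x + U r)`` of discrete and continuous dynamics."""
    k = 1.0 / params.tau_x
    return k / (k + params.U * np.asarray(r, dtype=float))
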