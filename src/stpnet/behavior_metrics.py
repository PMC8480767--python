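"""Behavioral readout: response sampling, the transition matrix and its symmetry.

Model "behavior" is obtained by sampling a binary response from a Bernoulli
distribution with probability ``sigmoid(logit)`` at every image presentation.
Each change (go) or sham-change (catch) presentation defines a trial with a
transition ``(from_image, to_image)``; aggregating responses over trials
yields the 8x8 response-probability matrix (catch trials on the diagonal).

Asymmetry of detectability is quantified by

    Q = (||M_sym|| - ||M_anti||) / (||M_sym|| + ||M_anti||)

where ``M`` is the response matrix with the off-diagonal mean subtracted and
the diagonal ignored, ``M_sym/anti = (M +- M^T)/2``, and ``||.||`` is the
Frobenius norm over off-diagonal entries.  Q is 1 for symmetric and -1 for
anti-symmetric matrices, and invariant to relabeling of the images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .models import ModelConfig, ModelState, SimRecord, run_sequence
from .synthetic_data import EmbeddingMatrix, StimulusSequence
from .training import dprime

__all__ = [
    "ResponseMatrix",
    "sample_responses",
    "trial_records",
    "response_matrix",
    "matrix_symmetry",
    "compare_matrices",
    "evaluate_behavior",
    "BehaviorSummary",
]


def sample_responses(
    logits: np.ndarray,
    rng: np.random.Generator,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Bernoulli(sigmoid(logit)) response per step; zero where masked out.

    ``mask`` selects the steps at which a response can occur (image or
    omitted presentations); by default responses are sampled at every step.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits) | np.isinf(logits)):
        raise ValueError("logits must not contain NaN")
    p = 1.0 / (1.0 + np.exp(-logits))
    draws = rng.random(logits.shape) < p
    if mask is not None:
        draws = draws & np.asarray(mask, dtype=bool)
    return draws


def trial_records(sequence: StimulusSequence, responses: np.ndarray) -> pd.DataFrame:
    """One row per go/catch trial with its transition and the sampled response.

    ``responses`` is the per-step binary response vector.  The omission
    context of each trial is carried along (the generator never schedules an
    omission immediately before a (sham) change, but externally supplied
    sequences are not trusted to guarantee this).
    """
    responses = np.asarray(responses, dtype=bool)
    if responses.shape != (sequence.n_steps,):
        raise ValueError("responses must align with sequence steps")
    df = sequence.presentations()
    flagged = df[df["is_change"] | df["is_sham_change"]]
    prev_omitted = df["is_omitted"].shift(1, fill_value=False)[flagged.index]
    return pd.DataFrame(
        {
            "trial_id": flagged["trial_id"].to_numpy(),
            "from_image": flagged["prev_image_id"].to_numpy(),
            "to_image": flagged["image_id"].to_numpy(),
            "is_go": flagged["is_change"].to_numpy(),
            "responded": responses[flagged["step"].to_numpy()],
            "preceded_by_omission": prev_omitted.to_numpy(),
        }
    )


@dataclass
class ResponseMatrix:
    """Response probabilities and trial counts per image transition.

    ``M[i, j]`` is the responded fraction among trials with transition
    ``i -> j``; cells with no trials are NaN (missing, not zero).
    """

    M: np.ndarray
    counts: np.ndarray

    @property
    def n_images(self) -> int:
        return self.M.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_images
        return pd.DataFrame(self.M, index=[f"from_{i}" for i in range(n)],
                            columns=[f"to_{j}" for j in range(n)])


def response_matrix(trials: pd.DataFrame, n_images: int = 8) -> ResponseMatrix:
    """Aggregate trial records into the transition response-probability matrix."""
    counts = np.zeros((n_images, n_images), dtype=int)
    hits = np.zeros((n_images, n_images), dtype=float)
    frm = trials["from_image"].to_numpy(int)
    to = trials["to_image"].to_numpy(int)
    resp = trials["responded"].to_numpy(float)
    valid = (frm >= 0) & (to >= 0)
    np.add.at(counts, (frm[valid], to[valid]), 1)
    np.add.at(hits, (frm[valid], to[valid]), resp[valid])
    with np.errstate(invalid="ignore"):
        M = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    return ResponseMatrix(M=M, counts=counts)


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def matrix_symmetry(matrix: ResponseMatrix | np.ndarray) -> float:
    """The symmetry metric Q of a response-probability matrix."""
    M = matrix.M if isinstance(matrix, ResponseMatrix) else np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("response matrix must be square")
    off = _offdiag_mask(M.shape[0])
    if np.any(~np.isfinite(M[off])):
        raise ValueError("all off-diagonal cells must be populated to compute Q")
    C = np.zeros_like(M, dtype=float)
    C[off] = M[off] - M[off].mean()
    sym = 0.5 * (C + C.T)
    anti = 0.5 * (C - C.T)
    ns = np.linalg.norm(sym[off])
    na = np.linalg.norm(anti[off])
    scale = max(1.0, float(np.abs(M[off]).max()))
    if ns + na <= 1e-10 * scale:
        raise ValueError("Q undefined: off-diagonal entries are constant")
    return float((ns - na) / (ns + na))


def compare_matrices(Ma: ResponseMatrix | np.ndarray, Mb: ResponseMatrix | np.ndarray) -> float:
    """Pearson correlation between two matrices over off-diagonal cells."""
    A = Ma.M if isinstance(Ma, ResponseMatrix) else np.asarray(Ma, float)
    B = Mb.M if isinstance(Mb, ResponseMatrix) else np.asarray(Mb, float)
    if A.shape != B.shape:
        raise ValueError("matrices must have identical shapes")
    off = _offdiag_mask(A.shape[0])
    ok = np.isfinite(A[off]) & np.isfinite(B[off])
    return float(pearsonr(A[off][ok], B[off][ok]).statistic)


@dataclass
class BehaviorSummary:
    trials: pd.DataFrame
    matrix: ResponseMatrix
    hit_rate: float
    fa_rate: float
    dprime: float
    record: SimRecord
    sequence: StimulusSequence
    responses: np.ndarray  # per-step binary


def evaluate_behavior(
    state: ModelState,
    config: ModelConfig,
    sequence: StimulusSequence,
    embeddings: EmbeddingMatrix,
    seed: int | np.random.Generator = 0,
) -> BehaviorSummary:
    """Run a model over an evaluation session and summarize its behavior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    record = run_sequence(state, config, sequence, embeddings, rng)
    resp_mask = sequence.is_presentation | sequence.is_omitted
    responses = sample_responses(record.logits, rng, mask=resp_mask)
    trials = trial_records(sequence, responses)
    matrix = response_matrix(trials, n_images=sequence.n_images)
    go = trials["is_go"].to_numpy(bool)
    hit = float(trials.loc[go, "responded"].mean())
    fa = float(trials.loc[~go, "responded"].mean())
    d = dprime(hit, fa, int(go.sum()), int((~go).sum()))
    return BehaviorSummary(
        trials=trials, matrix=matrix, hit_rate=hit, fa_rate=fa, dprime=d,
        record=record, sequence=sequence, responses=responses,
    )
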