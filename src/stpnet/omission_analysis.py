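"""Omission perturbation analysis.

Omitting a flash lengthens the inter-stimulus interval -- a probe the models
never saw in training that dissociates the two memory mechanisms.  A model
storing the memory in persistent activity keeps responding during the
omitted frame (the vanished input looks like a change); a model storing it
in depressed synapses stays silent during the omission but responds more to
the next image, because the extra recovery time releases the synapses from
depression.

Response probabilities are tabulated for five presentation categories: go
trials, catch trials, all (non-omitted) presentations, omitted
presentations, and post-omitted presentations.  Following the trial-abort
logic of the experiments, a response during an omission forces that trial's
post-omitted score to zero.  Consecutive double omissions are excluded from
both omission categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import StimulusSequence

__all__ = ["OmissionTable", "omission_response_probabilities"]

CATEGORIES = ("go", "catch", "all_presentations", "omitted", "post_omitted")


@dataclass
class OmissionTable:
    """Response probability and trial count per presentation category."""

    probabilities: dict[str, float]  # NaN when the category has no samples
    counts: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(CATEGORIES),
                "response_probability": [self.probabilities[c] for c in CATEGORIES],
                "n": [self.counts[c] for c in CATEGORIES],
            }
        )


def omission_response_probabilities(
    sequence: StimulusSequence, responses: np.ndarray
) -> OmissionTable:
    """Score per-category response probabilities for one session.

    ``responses`` is the per-step binary response vector (sampled at image
    and omitted frames).  The omitted category scores responses during the
    frame where the image would have appeared; the post-omitted category
    scores the next scheduled presentation, forced to 0 whenever the model
    responded during the omission.  An omission followed by another omission
    is dropped from both categories.
    """
    responses = np.asarray(responses, dtype=bool)
    if responses.shape != (sequence.n_steps,):
        raise ValueError("responses must align with sequence steps")
    df = sequence.presentations().reset_index(drop=True)
    resp = responses[df["step"].to_numpy()]

    omitted = df["is_omitted"].to_numpy(bool)
    go = df["is_change"].to_numpy(bool)
    catch = df["is_sham_change"].to_numpy(bool)
    shown = ~omitted

    probs: dict[str, float] = {}
    counts: dict[str, int] = {}

    def _score(mask: np.ndarray, values: np.ndarray, name: str) -> None:
        counts[name] = int(mask.sum())
        probs[name] = float(values[mask].mean()) if mask.any() else float("nan")

    _score(go, resp, "go")
    _score(catch, resp, "catch")
    _score(shown, resp, "all_presentations")

    nxt_omitted = np.append(omitted[1:], False)
    prv_omitted = np.append(False, omitted[:-1])
    single_om = omitted & ~nxt_omitted & ~prv_omitted  # drop double omissions
    has_next = np.arange(len(df)) < len(df) - 1
    om_scored = single_om & has_next
    _score(om_scored, resp, "omitted")

    post_idx = np.flatnonzero(om_scored) + 1
    post_vals = resp[post_idx] & ~resp[post_idx - 1]  # conditioning rule
    counts["post_omitted"] = int(len(post_idx))
    probs["post_omitted"] = float(post_vals.mean()) if len(post_idx) else float("nan")

    return OmissionTable(probabilities=probs, counts=counts)
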