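"""Population-level geometry: PCA and distance-from-origin across repeats.

Presentation response vectors are centered on the mean across all image
presentations -- that mean defines the origin of the space, which for an
adapting population lies close to the gray-screen state.  PCA retains the
components explaining 95% of the variance.  The collapse of the population
response with stimulus repetition is quantified as the mean distance from
the origin per repeat index, both in the full space (Euclidean norm, equal
to the root-sum-square over all PCs) and along the first principal
component alone.  Adapting populations show a decreasing curve; populations
without repeat-dependent dynamics a flat one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .neural_metrics import PresentationResponses

__all__ = ["RepeatDistanceCurve", "repeat_distance"]


@dataclass
class RepeatDistanceCurve:
    """Mean distance from the population-mean origin per repeat index."""

    repeat_index: np.ndarray
    full_distance: np.ndarray  # Euclidean, all dimensions
    pc1_distance: np.ndarray  # |projection on first PC|
    n_per_repeat: np.ndarray
    n_components: int
    variance_explained: np.ndarray  # per retained component

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, vals in (("full", self.full_distance), ("pc1", self.pc1_distance)):
            for r, v, n in zip(self.repeat_index, vals, self.n_per_repeat):
                rows.append({"repeat_index": int(r), "metric": metric,
                             "value": float(v), "n": int(n)})
        return pd.DataFrame(rows)


def repeat_distance(
    responses: PresentationResponses,
    variance_threshold: float = 0.95,
    max_repeat: int | None = None,
) -> RepeatDistanceCurve:
    """Distance-from-origin vs number of repeats, full space and first PC.

    Omitted presentations are excluded.  Repeat index 1 is the change (or
    first) presentation of an image; presentations are pooled across images
    at each repeat index.  Degenerate (rank-deficient) inputs retain all
    available components.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    lab = responses.labels
    shown = ~lab["is_omitted"].to_numpy(bool)
    if shown.sum() < 2:
        raise ValueError("need at least two shown presentations")
    X = responses.responses[:, shown].T  # (n_pres, n_units)
    reps = lab["repeat_index"].to_numpy(int)[shown]
    Xc = X - X.mean(axis=0)

    n_comp = min(Xc.shape)
    if np.allclose(Xc, 0.0):
        # fully degenerate input: all presentations identical
        scores = np.zeros((Xc.shape[0], n_comp))
        var = np.zeros(n_comp)
        var[0] = 1.0
    else:
        pca = PCA(n_components=n_comp)
        scores = pca.fit_transform(Xc)
        var = pca.explained_variance_ratio_
    cum = np.cumsum(var)
    keep = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    keep = min(keep, n_comp)

    full = np.linalg.norm(Xc, axis=1)
    pc1 = np.abs(scores[:, 0])

    uniq = np.unique(reps)
    if max_repeat is not None:
        uniq = uniq[uniq <= max_repeat]
    mean_full = np.array([full[reps == r].mean() for r in uniq])
    mean_pc1 = np.array([pc1[reps == r].mean() for r in uniq])
    n_per = np.array([(reps == r).sum() for r in uniq])
    return RepeatDistanceCurve(
        repeat_index=uniq,
        full_distance=mean_full,
        pc1_distance=mean_pc1,
        n_per_repeat=n_per,
        n_components=keep,
        variance_explained=var[:keep],
    )
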