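"""Unit-level analyses: change modulation, linear decoding, behavior agreement.

The change modulation index (CMI) of a unit compares its mean response on
change presentations (go trials) with its mean response on the presentations
immediately preceding a change:

    CMI = (r_change - r_pre) / (r_change + r_pre)

Positive values indicate adaptation (stronger responses to novel images),
negative values facilitation.  Units with a negative mean response on either
class are excluded, as are units with a zero denominator.

Decoding uses linear SVMs (C = 1) with stratified three-fold cross
validation, either for image identity (8-way) or change vs pre-change
(binary; this pairing avoids the class imbalance of go vs catch trials).
Decoder agreement with behavior is quantified by the Jaccard score between
the decoder's predicted-change vector on go/catch trials and the sampled
behavioral choices, against a shuffle null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .models import SimRecord
from .synthetic_data import StimulusSequence, SyntheticPopulation

__all__ = [
    "PresentationResponses",
    "CMITable",
    "DecodingResult",
    "change_modulation_index",
    "decode",
    "subsample_accuracy_curve",
    "weight_cmi_correlation",
    "jaccard_agreement",
]

_LABEL_COLUMNS = [
    "step", "image_id", "is_omitted", "is_change", "is_sham_change",
    "is_pre_change", "repeat_index", "trial_id",
]


@dataclass
class PresentationResponses:
    """Per-presentation responses of a set of units with presentation labels.

    ``responses[u, p]`` is unit ``u``'s response on presentation ``p``;
    ``labels`` has one row per presentation with at least the columns in
    ``_LABEL_COLUMNS``.  Model-unit responses are the activity at the single
    presentation frame; external dF/F tables must state their own windowing.
    """

    responses: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        missing = set(_LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns: {sorted(missing)}")
        if self.responses.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.responses.shape[1]} response columns vs {len(self.labels)} label rows"
            )
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")

    @property
    def n_units(self) -> int:
        return self.responses.shape[0]

    @classmethod
    def from_record(
        cls,
        record: SimRecord,
        sequence: StimulusSequence,
        layer: str = "hidden",
    ) -> "PresentationResponses":
        """Extract per-presentation unit responses from a simulation record.

        ``layer`` is one of ``"input"`` (post-noise input units),
        ``"input_depressed"`` (post-noise, depression-gated input units; for
        non-depressing models identical to ``"input"``) or ``"hidden"``.
        """
        arrays = {
            "input": record.input_noised,
            "input_depressed": record.input_gated,
            "hidden": record.hidden,
        }
        if layer not in arrays:
            raise ValueError(f"unknown layer {layer!r}; choose from {sorted(arrays)}")
        df = sequence.presentations().reset_index(drop=True)
        resp = arrays[layer][df["step"].to_numpy()].T
        return cls(responses=resp, labels=df[_LABEL_COLUMNS + ["is_post_omitted"]].copy())

    @classmethod
    def from_synthetic_population(cls, pop: SyntheticPopulation) -> "PresentationResponses":
        df = pop.presentations.reset_index(drop=True)
        cols = [c for c in _LABEL_COLUMNS + ["is_post_omitted"] if c in df.columns]
        return cls(responses=pop.traces, labels=df[cols].copy())


@dataclass
class CMITable:
    """Per-unit change modulation with exclusion bookkeeping."""

    table: pd.DataFrame  # columns: unit, cmi, excluded, reason

    @property
    def retained(self) -> pd.DataFrame:
        return self.table[~self.table["excluded"]]

    @property
    def values(self) -> np.ndarray:
        return self.retained["cmi"].to_numpy()

    def mean(self) -> float:
        return float(self.values.mean())


def change_modulation_index(responses: PresentationResponses) -> CMITable:
    """CMI per unit from mean change vs pre-change presentation responses."""
    lab = responses.labels
    is_change = lab["is_change"].to_numpy(bool) & ~lab["is_omitted"].to_numpy(bool)
    is_pre = lab["is_pre_change"].to_numpy(bool) & ~lab["is_omitted"].to_numpy(bool)
    if is_change.sum() == 0 or is_pre.sum() == 0:
        raise ValueError("need at least one change and one pre-change presentation")
    r_change = responses.responses[:, is_change].mean(axis=1)
    r_pre = responses.responses[:, is_pre].mean(axis=1)
    denom = r_change + r_pre
    negative = (r_change < 0) | (r_pre < 0)
    zero = (~negative) & (denom == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cmi = (r_change - r_pre) / denom
    excluded = negative | zero
    reason = np.where(negative, "negative_mean", np.where(zero, "zero_denominator", ""))
    table = pd.DataFrame(
        {
            "unit": np.arange(responses.n_units),
            "cmi": np.where(excluded, np.nan, cmi),
            "r_change": r_change,
            "r_pre_change": r_pre,
            "excluded": excluded,
            "reason": reason,
        }
    )
    return CMITable(table=table)


@dataclass
class DecodingResult:
    task: str  # "identity" or "change"
    fold_accuracies: np.ndarray
    mean_accuracy: float
    weights: np.ndarray | None = None  # per-unit, change task only
    predictions: pd.DataFrame | None = field(default=None, repr=False)
    unit_index: np.ndarray | None = None


def _task_data(responses: PresentationResponses, target: str):
    lab = responses.labels
    shown = ~lab["is_omitted"].to_numpy(bool)
    if target == "identity":
        sel = shown
        y = lab["image_id"].to_numpy(int)[sel]
    elif target == "change":
        is_change = lab["is_change"].to_numpy(bool) & shown
        is_pre = lab["is_pre_change"].to_numpy(bool) & shown
        sel = is_change | is_pre
        y = lab["is_change"].to_numpy(bool)[sel].astype(int)
    else:
        raise ValueError("target must be 'identity' or 'change'")
    X = responses.responses[:, sel].T
    return X, y, sel


def decode(
    responses: PresentationResponses,
    target: str = "change",
    n_folds: int = 3,
    C: float = 1.0,
    seed: int = 0,
    unit_subset: np.ndarray | None = None,
) -> DecodingResult:
    """Cross-validated linear-SVM decoding of image identity or image change.

    For the change task the decoder is additionally refit on all
    change/pre-change presentations to expose per-unit weights and to predict
    a change/no-change label on every go and catch trial.
    """
    X, y, _ = _task_data(responses, target)
    if unit_subset is not None:
        X = X[:, unit_subset]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("decoding needs at least two classes")
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} presentations < {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = LinearSVC(C=C, random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(clf.score(X[test_idx], y[test_idx]))
    accs = np.array(accs)

    weights = None
    predictions = None
    if target == "change":
        clf = LinearSVC(C=C, random_state=seed)
        clf.fit(X, y)
        weights = clf.coef_.ravel().copy()
        lab = responses.labels
        shown = ~lab["is_omitted"].to_numpy(bool)
        trial_sel = (lab["is_change"].to_numpy(bool) | lab["is_sham_change"].to_numpy(bool)) & shown
        Xt = responses.responses[:, trial_sel].T
        if unit_subset is not None:
            Xt = Xt[:, unit_subset]
        predictions = pd.DataFrame(
            {
                "trial_id": lab.loc[trial_sel, "trial_id"].to_numpy(),
                "is_go": lab.loc[trial_sel, "is_change"].to_numpy(bool),
                "predicted_change": clf.predict(Xt).astype(bool),
            }
        )
    return DecodingResult(
        task=target,
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        weights=weights,
        predictions=predictions,
        unit_index=unit_subset,
    )


def subsample_accuracy_curve(
    responses: PresentationResponses,
    target: str = "change",
    unit_counts: list[int] | None = None,
    n_samples: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean decoding accuracy as a function of the number of units included."""
    n_units = responses.n_units
    counts = unit_counts or [c for c in (10, 20, 40, 80, 160) if c <= n_units]
    rng = np.random.default_rng(seed)
    rows = []
    for count in counts:
        if count > n_units:
            raise ValueError(f"cannot sample {count} of {n_units} units")
        reps = 1 if count == n_units else n_samples
        accs = []
        for _ in range(reps):
            subset = np.sort(rng.choice(n_units, size=count, replace=False))
            res = decode(responses, target, seed=seed, unit_subset=subset)
            accs.append(res.mean_accuracy)
        rows.append({"n_units": count, "mean_accuracy": float(np.mean(accs)),
                     "sd": float(np.std(accs)), "n_samples": reps})
    return pd.DataFrame(rows)


def weight_cmi_correlation(result: DecodingResult, cmi: CMITable) -> float:
    """Pearson r between change-decoder weights and CMI over retained units."""
    if result.weights is None:
        raise ValueError("decoder weights only available for the change task")
    retained = cmi.retained
    units = retained["unit"].to_numpy(int)
    if result.unit_index is not None:
        pos = {u: i for i, u in enumerate(result.unit_index)}
        keep = np.array([u in pos for u in units])
        units = units[keep]
        w = result.weights[[pos[u] for u in units]]
        c = retained["cmi"].to_numpy()[keep]
    else:
        w = result.weights[units]
        c = retained["cmi"].to_numpy()
    if len(w) < 2:
        raise ValueError("need at least two retained units")
    return float(pearsonr(w, c).statistic)


def jaccard_agreement(
    decoder_predictions: np.ndarray,
    behavioral_choices: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float]]:
    """Jaccard similarity of two binary vectors with a shuffle null.

    Returns ``(score, null_mean, (null_lo, null_hi))`` where the null is the
    2.5-97.5 percentile band of the score after permuting the predictions.
    """
    a = np.asarray(decoder_predictions, dtype=bool)
    b = np.asarray(behavioral_choices, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D binary vectors")

    def _jaccard(u: np.ndarray, v: np.ndarray) -> float:
        union = np.logical_or(u, v).sum()
        if union == 0:
            raise ValueError("Jaccard undefined: both vectors are all-zero")
        return float(np.logical_and(u, v).sum() / union)

    score = _jaccard(a, b)
    rng = np.random.default_rng(seed)
    null = np.array([_jaccard(rng.permutation(a), b) for _ in range(n_shuffles)])
    lo, hi = np.percentile(null, [2.5, 97.5])
    return score, float(null.mean()), (float(lo), float(hi))
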