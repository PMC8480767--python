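"""Synthetic inputs for the change-detection pipeline.

Three generators:

* :func:`generate_session` -- stimulus sequences with the task's statistics:
  each image is flashed for one 250 ms frame followed by two gray frames,
  images repeat a truncated-geometric number of times (4-11) before a change
  (go trial) or sham change (catch trial), and a small fraction of flashes
  can be omitted, never immediately before a (sham) change.
* :func:`generate_embeddings` -- sparse non-negative image feature vectors
  standing in for the output of a pretrained convolutional encoder: each of
  the 64 input units responds to 1-4 of the 8 images with graded amplitudes,
  and images differ in overall drive ("saliency") by a lognormal factor.
* :func:`generate_synthetic_population` -- an adapting neural population with
  known ground-truth change modulation, used to validate the metric
  estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .stp_dynamics import STPParams, run_depression

__all__ = [
    "FRAME_IMAGE",
    "FRAME_GRAY",
    "FRAME_OMITTED",
    "StimulusSequence",
    "EmbeddingMatrix",
    "SyntheticPopulation",
    "generate_session",
    "generate_embeddings",
    "generate_synthetic_population",
]

SCHEMA_VERSION = "1"

FRAME_IMAGE = "IMAGE"
FRAME_GRAY = "GRAY"
FRAME_OMITTED = "OMITTED_IMAGE"
_FRAME_CODES = {FRAME_IMAGE: 0, FRAME_GRAY: 1, FRAME_OMITTED: 2}
_FRAME_NAMES = {v: k for k, v in _FRAME_CODES.items()}


@dataclass
class StimulusSequence:
    """Per-timestep schedule of a change-detection session.

    All arrays have one entry per timestep.  ``image_id`` is -1 on gray
    frames; on omitted frames it records the image that was scheduled (and
    not shown).  ``repeat_index`` counts consecutive scheduled presentations
    of the current image (1 on a change presentation); it is 0 on gray
    frames.  ``trial_id`` labels the run of presentations ending at each
    change/sham-change presentation.
    """

    frame_kind: np.ndarray  # int8 codes, see _FRAME_CODES
    image_id: np.ndarray
    is_change: np.ndarray
    is_sham_change: np.ndarray
    repeat_index: np.ndarray
    trial_id: np.ndarray
    dt: float = 0.25
    n_images: int = 8
    n_gray: int = 2  # gray frames after each presentation slot

    # -- basic accessors ---------------------------------------------------

    @property
    def n_steps(self) -> int:
        return len(self.frame_kind)

    @property
    def is_presentation(self) -> np.ndarray:
        """Steps where an image is shown (IMAGE frames)."""
        return self.frame_kind == _FRAME_CODES[FRAME_IMAGE]

    @property
    def is_omitted(self) -> np.ndarray:
        return self.frame_kind == _FRAME_CODES[FRAME_OMITTED]

    def presentations(self) -> pd.DataFrame:
        """One row per scheduled presentation (shown or omitted).

        Columns include the flags needed by all downstream analyses:
        ``is_pre_change`` marks the presentation immediately before a change
        presentation and ``is_post_omitted`` the presentation immediately
        after an omitted one.
        """
        idx = np.flatnonzero(self.is_presentation | self.is_omitted)
        df = pd.DataFrame(
            {
                "step": idx,
                "image_id": self.image_id[idx],
                "is_omitted": self.is_omitted[idx],
                "is_change": self.is_change[idx],
                "is_sham_change": self.is_sham_change[idx],
                "repeat_index": self.repeat_index[idx],
                "trial_id": self.trial_id[idx],
            }
        )
        nxt_change = np.append(df["is_change"].to_numpy()[1:], False)
        df["is_pre_change"] = nxt_change & ~df["is_omitted"].to_numpy()
        prev_om = np.append(False, df["is_omitted"].to_numpy()[:-1])
        df["is_post_omitted"] = prev_om & ~df["is_omitted"].to_numpy()
        prev_img = np.append(-1, df["image_id"].to_numpy()[:-1])
        df["prev_image_id"] = prev_img
        return df

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` if any sequence invariant is violated."""
        kinds = self.frame_kind
        cycle = 1 + self.n_gray
        pres = np.flatnonzero(kinds != _FRAME_CODES[FRAME_GRAY])
        # every presentation slot is followed by exactly n_gray gray frames
        for p in pres:
            if p % cycle != 0:
                raise ValueError(f"presentation at step {p} off the {cycle}-step grid")
        if np.any(kinds[np.arange(self.n_steps) % cycle != 0] != _FRAME_CODES[FRAME_GRAY]):
            raise ValueError("non-gray frame inside an inter-stimulus interval")
        df = self.presentations()
        omitted = df["is_omitted"].to_numpy()
        flagged = (df["is_change"] | df["is_sham_change"]).to_numpy()
        if np.any(omitted[:-1] & flagged[1:]):
            raise ValueError("omission immediately precedes a (sham) change")
        if np.any(flagged & omitted):
            raise ValueError("a (sham) change presentation was omitted")
        img = df["image_id"].to_numpy()
        chg = df["is_change"].to_numpy()
        sham = df["is_sham_change"].to_numpy()
        same = img[1:] == img[:-1]
        if np.any(chg[1:] & same):
            raise ValueError("change presentation repeats the previous image")
        if np.any(sham[1:] & ~same):
            raise ValueError("sham change presentation switches image")

    def pre_change_run_lengths(self) -> np.ndarray:
        """Scheduled-presentation counts between successive (sham) changes."""
        df = self.presentations()
        flagged = np.flatnonzero((df["is_change"] | df["is_sham_change"]).to_numpy())
        if len(flagged) < 2:
            return np.empty(0, dtype=int)
        return np.diff(flagged)

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(self.n_steps),
                "frame_kind": [_FRAME_NAMES[c] for c in self.frame_kind],
                "image_id": self.image_id,
                "is_change": self.is_change.astype(int),
                "is_sham_change": self.is_sham_change.astype(int),
                "repeat_index": self.repeat_index,
                "trial_id": self.trial_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float = 0.25, n_images: int = 8,
                   n_gray: int = 2) -> "StimulusSequence":
        required = {"frame_kind", "image_id", "is_change", "is_sham_change",
                    "repeat_index", "trial_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"stimulus table missing columns: {sorted(missing)}")
        bad = set(df["frame_kind"]) - set(_FRAME_CODES)
        if bad:
            raise ValueError(f"unknown frame kinds: {sorted(bad)}")
        return cls(
            frame_kind=np.array([_FRAME_CODES[k] for k in df["frame_kind"]], dtype=np.int8),
            image_id=df["image_id"].to_numpy(int),
            is_change=df["is_change"].to_numpy(bool),
            is_sham_change=df["is_sham_change"].to_numpy(bool),
            repeat_index=df["repeat_index"].to_numpy(int),
            trial_id=df["trial_id"].to_numpy(int),
            dt=dt,
            n_images=n_images,
            n_gray=n_gray,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(
                f"# stpnet stimulus schema v{SCHEMA_VERSION} dt={self.dt} "
                f"n_images={self.n_images} n_gray={self.n_gray}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "StimulusSequence":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.split() if "=" in tok)
            df = pd.read_csv(fh)
        return cls.from_frame(df, dt=float(meta.get("dt", 0.25)),
                              n_images=int(meta.get("n_images", 8)),
                              n_gray=int(meta.get("n_gray", 2)))

    def to_hdf5(self, path: str | Path, group: str = "stimulus") -> None:
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.attrs["schema_version"] = SCHEMA_VERSION
            g.attrs["dt"] = self.dt
            g.attrs["n_images"] = self.n_images
            g.attrs["n_gray"] = self.n_gray
            for name in ("frame_kind", "image_id", "is_change", "is_sham_change",
                         "repeat_index", "trial_id"):
                g.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path: str | Path, group: str = "stimulus") -> "StimulusSequence":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(
                frame_kind=g["frame_kind"][:],
                image_id=g["image_id"][:],
                is_change=g["is_change"][:].astype(bool),
                is_sham_change=g["is_sham_change"][:].astype(bool),
                repeat_index=g["repeat_index"][:],
                trial_id=g["trial_id"][:],
                dt=float(g.attrs["dt"]),
                n_images=int(g.attrs["n_images"]),
                n_gray=int(g.attrs.get("n_gray", 2)),
            )


@dataclass
class EmbeddingMatrix:
    """Non-negative image feature vectors driving the models.

    ``values[i, f]`` is the activity of input unit ``f`` when image ``i`` is
    shown.  ``saliency`` is the mean drive of each image across features.
    """

    values: np.ndarray
    require_coverage: bool = True  # image-computed embeddings may have dead features

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (n_images, n_features)")
        if np.any(self.values < 0):
            raise ValueError("embeddings must be non-negative")
        if self.require_coverage and np.any(self.values.sum(axis=0) == 0):
            raise ValueError("every feature must respond to at least one image")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def saliency(self) -> np.ndarray:
        return self.values.mean(axis=1)


@dataclass
class SyntheticPopulation:
    """Adapting population with known change modulation, for metric tests.

    ``traces[n, p]`` is neuron ``n``'s response on presentation ``p`` (rows of
    ``presentations``).  ``ground_truth_cmi`` is the tuning-weighted resource
    contrast each neuron's noise-free responses converge to.
    """

    traces: np.ndarray
    ground_truth_cmi: np.ndarray
    noise_sd: float
    presentations: pd.DataFrame = field(repr=False)
    tuning: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def generate_session(
    n_trials: int = 100,
    n_images: int = 8,
    p_go: float = 0.5,
    p_omit: float = 0.0,
    min_repeats: int = 4,
    max_repeats: int = 11,
    repeat_hazard: float = 0.3,
    n_gray: int = 2,
    dt: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> StimulusSequence:
    """Generate one continuous session of the change-detection task.

    A run of the current image lasts at least ``min_repeats`` presentations;
    from then on each further presentation terminates the run with
    probability ``repeat_hazard`` (forced at ``max_repeats``), yielding the
    truncated-geometric repeat distribution of the task.  The terminating
    presentation is a change to a uniformly drawn different image with
    probability ``p_go`` (go trial) or a sham change (catch trial).
    Omissions replace eligible image frames with gray, never immediately
    before a (sham) change and never the (sham) change itself.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not (0.0 <= p_omit < 1.0):
        raise ValueError(f"p_omit must be in [0, 1), got {p_omit}")
    if not (0.0 <= p_go <= 1.0):
        raise ValueError(f"p_go must be in [0, 1], got {p_go}")
    if not (0.0 < repeat_hazard <= 1.0):
        raise ValueError(f"repeat_hazard must be in (0, 1], got {repeat_hazard}")
    if min_repeats < 1 or max_repeats < min_repeats:
        raise ValueError(
            f"need 1 <= min_repeats <= max_repeats, got {min_repeats}, {max_repeats}"
        )
    if n_gray < 1:
        raise ValueError("n_gray must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    img, kind, rep, trial = [], [], [], []  # kind: 0 repeat, 1 change, 2 sham
    cur = int(rng.integers(n_images))
    run = 1  # presentations of current image within the current trial
    consec = 1  # consecutive presentations of the current image (across shams)
    trial_no = 0
    img.append(cur); kind.append(0); rep.append(consec); trial.append(trial_no)
    while trial_no < n_trials:
        end = run >= max_repeats or (run >= min_repeats and rng.random() < repeat_hazard)
        if end:
            if rng.random() < p_go:
                others = [i for i in range(n_images) if i != cur]
                cur = others[int(rng.integers(n_images - 1))]
                kind.append(1)
                consec = 1
            else:
                kind.append(2)
                consec += 1
            img.append(cur)
            rep.append(consec)
            trial.append(trial_no)
            trial_no += 1
            run = 1  # the (sham) change presentation starts the next run
        else:
            run += 1
            consec += 1
            img.append(cur); kind.append(0); rep.append(consec); trial.append(trial_no)

    img = np.array(img); kind = np.array(kind)
    rep = np.array(rep); trial = np.array(trial)

    omitted = np.zeros(len(img), dtype=bool)
    if p_omit > 0:
        nxt = np.append(kind[1:], 0)
        eligible = (kind == 0) & (nxt == 0)
        omitted = eligible & (rng.random(len(img)) < p_omit)

    n_pres = len(img)
    cycle = 1 + n_gray
    frame_kind = np.full(n_pres * cycle, _FRAME_CODES[FRAME_GRAY], dtype=np.int8)
    image_id = np.full(n_pres * cycle, -1, dtype=int)
    is_change = np.zeros(n_pres * cycle, dtype=bool)
    is_sham = np.zeros(n_pres * cycle, dtype=bool)
    repeat_index = np.zeros(n_pres * cycle, dtype=int)
    trial_id = np.zeros(n_pres * cycle, dtype=int)
    t = np.arange(n_pres) * cycle
    frame_kind[t] = np.where(omitted, _FRAME_CODES[FRAME_OMITTED], _FRAME_CODES[FRAME_IMAGE])
    image_id[t] = img
    is_change[t] = kind == 1
    is_sham[t] = kind == 2
    repeat_index[t] = rep
    trial_id[:] = np.repeat(trial, cycle)

    return StimulusSequence(
        frame_kind=frame_kind,
        image_id=image_id,
        is_change=is_change,
        is_sham_change=is_sham,
        repeat_index=repeat_index,
        trial_id=trial_id,
        dt=dt,
        n_images=n_images,
        n_gray=n_gray,
    )


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

DEFAULT_BREADTH_DIST = {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}


def generate_embeddings(
    n_images: int = 8,
    n_features: int = 64,
    tuning_breadth_dist: dict[int, float] | None = None,
    saliency_spread: float = 0.25,
    amplitude_range: tuple[float, float] = (1.0, 5.0),
    seed: int | np.random.Generator = 0,
) -> EmbeddingMatrix:
    """Sparse non-negative embeddings with heterogeneous per-image drive.

    Each feature (input unit) responds to ``k`` images, ``k`` drawn from
    ``tuning_breadth_dist``, with graded amplitudes uniform in
    ``amplitude_range``.  Rows are then rescaled so image ``i``'s total drive
    equals the across-image mean times a lognormal saliency factor
    ``exp(N(0, saliency_spread^2))``; with ``saliency_spread=0`` all images
    drive the population equally.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    if n_features < n_images:
        raise ValueError(
            f"n_features ({n_features}) must be >= n_images ({n_images}) "
            "to guarantee every image drives a feature"
        )
    if saliency_spread < 0:
        raise ValueError("saliency_spread must be non-negative")
    dist = dict(tuning_breadth_dist or DEFAULT_BREADTH_DIST)
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    if np.any(ks < 1) or np.any(ks > n_images) or np.any(ps < 0) or not np.isclose(ps.sum(), 1.0):
        raise ValueError("tuning_breadth_dist must be a distribution over 1..n_images")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    E = np.zeros((n_images, n_features))
    breadth = rng.choice(ks, size=n_features, p=ps)
    lo, hi = amplitude_range
    for f in range(n_features):
        imgs = rng.choice(n_images, size=breadth[f], replace=False)
        E[imgs, f] = rng.uniform(lo, hi, size=breadth[f])
    for i in range(n_images):  # guarantee coverage (rare for default sizes)
        if E[i].sum() == 0:
            E[i, int(rng.integers(n_features))] = rng.uniform(lo, hi)

    row_sums = E.sum(axis=1)
    sal = np.exp(rng.normal(0.0, saliency_spread, size=n_images)) if saliency_spread > 0 else np.ones(n_images)
    E *= (row_sums.mean() * sal / row_sums)[:, None]
    return EmbeddingMatrix(values=E)


# ---------------------------------------------------------------------------
# synthetic adapting population
# ---------------------------------------------------------------------------

def generate_synthetic_population(
    n_neurons: int = 200,
    U: float = 0.5,
    tau_x: float = 1.5,
    noise_sd: float = 0.2,
    sequence: StimulusSequence | None = None,
    tuning_breadth_dist: dict[int, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> SyntheticPopulation:
    """Adapting neural population with analytically known change modulation.

    Each neuron has a non-negative tuning curve over images and is driven
    through a depressing synapse carrying its own stimulus drive: the
    response on presentation ``p`` of image ``i`` is
    ``tuning[i] * x(t_p) * (1 + noise)`` with ``x`` evolved by the
    Tsodyks-Markram update on the neuron's drive.  The ground-truth change
    modulation is the tuning-weighted resource contrast between change and
    pre-change presentations of the noise-free trajectory, which the CMI
    estimator recovers as trials accumulate.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    params = STPParams(U=U, tau_x=tau_x)  # validates U, tau_x
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sequence is None:
        sequence = generate_session(n_trials=400, seed=rng)
    params = STPParams(U=U, tau_x=tau_x, dt=sequence.dt)

    n_images = sequence.n_images
    dist = dict(tuning_breadth_dist or DEFAULT_BREADTH_DIST)
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    tuning = np.zeros((n_neurons, n_images))
    breadth = rng.choice(ks, size=n_neurons, p=ps)
    for n in range(n_neurons):
        imgs = rng.choice(n_images, size=breadth[n], replace=False)
        tuning[n, imgs] = rng.uniform(0.5, 2.0, size=breadth[n])

    df = sequence.presentations()
    shown = ~df["is_omitted"].to_numpy()
    img = df["image_id"].to_numpy()
    # per-neuron drive at every timestep of the session
    drive_pres = np.where(shown[None, :], tuning[:, img], 0.0)  # (n_neurons, n_pres)
    T = sequence.n_steps
    rates = np.zeros((T, n_neurons))
    rates[df["step"].to_numpy()] = drive_pres.T
    x_traj = run_depression(rates, params)  # (T, n_neurons)
    x_pres = x_traj[df["step"].to_numpy()].T  # (n_neurons, n_pres)

    clean = drive_pres * x_pres
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    traces = clean * (1.0 + noise)

    is_change = df["is_change"].to_numpy()
    is_pre = df["is_pre_change"].to_numpy()
    w = drive_pres  # tuning weight of each presentation for each neuron
    with np.errstate(invalid="ignore", divide="ignore"):
        xc = (w[:, is_change] * x_pres[:, is_change]).sum(1) / w[:, is_change].sum(1)
        xp = (w[:, is_pre] * x_pres[:, is_pre]).sum(1) / w[:, is_pre].sum(1)
        gt = (xc - xp) / (xc + xp)
    gt = np.where(np.isfinite(gt), gt, 0.0)

    return SyntheticPopulation(
        traces=traces,
        ground_truth_cmi=gt,
        noise_sd=noise_sd,
        presentations=df,
        tuning=tuning,
    )
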