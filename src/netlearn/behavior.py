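"""Bimanual tracking task: track generation and performance scoring.

The task shows each hand a pseudorandom track — a sum of 20 sine waves

    g(y, t) = sum_i A_i sin(f_i (y + t/6) + phi_i)

with amplitudes A_i ~ U(1, 10), phases phi_i ~ U(-180, 180) degrees and
frequencies f_i drawn from a difficulty-dependent uniform range — and
scores how well the cursor followed it with a Pearson correlation
clipped below at zero, so a score of 1 is perfect tracking and negative
correlations count as complete failure.  Per-hand trial scores are
averaged within a session and the (left, right) session means are
reduced to a single bimanual performance score with a first principal
component.

Conventions (the task definition leaves units open): the vertical
coordinate ``y`` is normalized so a trace is evaluated at the cursor's
row, ``y = 0`` by default; frequencies are in radians per normalized
unit; phases are degree-valued and converted to radians internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Behavioral sampling rate (Hz), the monitor refresh rate.
FS_BEHAVIOR = 50.0

#: Difficulty-dependent frequency ranges for the 20 sine components.
FREQUENCY_RANGES: dict[str, tuple[float, float]] = {
    "easy": (0.01, 0.5),
    "moderate": (0.01, 0.75),
    "hard": (0.01, 1.0),
}

N_SINE_COMPONENTS = 20


@dataclass
class TrackTrace:
    """A generated track: 20 sine components and the sampled trace.

    ``trace`` holds g evaluated at the fixed row ``y`` on the 50 Hz time
    grid ``t``; the component parameters are kept so tests can construct
    degenerate tracks directly.
    """

    t: np.ndarray
    amplitudes: np.ndarray
    frequencies: np.ndarray
    phases_deg: np.ndarray
    y: float = 0.0
    fs: float = FS_BEHAVIOR
    trace: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phases_deg = np.asarray(self.phases_deg, dtype=float)
        n = self.amplitudes.shape[0]
        if self.frequencies.shape[0] != n or self.phases_deg.shape[0] != n:
            raise ValueError("amplitudes, frequencies, phases must align")
        self.trace = self.evaluate(self.y, self.t)

    def evaluate(self, y, t) -> np.ndarray:
        """g(y, t) = sum_i A_i sin(f_i (y + t/6) + phi_i), phases in degrees."""
        t = np.asarray(t, dtype=float)
        arg = (
            self.frequencies[:, None] * (y + t[None, :] / 6.0)
            + np.deg2rad(self.phases_deg)[:, None]
        )
        return (self.amplitudes[:, None] * np.sin(arg)).sum(axis=0)

    @property
    def duration(self) -> float:
        return self.t.shape[0] / self.fs


def generate_track(
    difficulty: str,
    duration: float = 60.0,
    seed: int | None = None,
    y: float = 0.0,
) -> TrackTrace:
    """Draw a pseudorandom track for a difficulty level.

    Amplitudes ~ U(1, 10) and phases ~ U(-180, 180) degrees; frequencies
    ~ U(0.01, 0.5 | 0.75 | 1.0) for easy | moderate | hard.  Sampled at
    50 Hz for ``duration`` seconds; all randomness derives from ``seed``.
    """
    if difficulty not in FREQUENCY_RANGES:
        raise ValueError(
            f"unknown difficulty {difficulty!r}; "
            f"known: {sorted(FREQUENCY_RANGES)}"
        )
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    f_lo, f_hi = FREQUENCY_RANGES[difficulty]
    n = int(round(duration * FS_BEHAVIOR))
    return TrackTrace(
        t=np.arange(n) / FS_BEHAVIOR,
        amplitudes=rng.uniform(1.0, 10.0, N_SINE_COMPONENTS),
        frequencies=rng.uniform(f_lo, f_hi, N_SINE_COMPONENTS),
        phases_deg=rng.uniform(-180.0, 180.0, N_SINE_COMPONENTS),
        y=y,
    )


def performance_r(cursor, track) -> float:
    """Clipped-Pearson tracking score in [0, 1].

    The Pearson correlation between the cursor and track series, set to
    0 when negative; invariant to positive affine transforms of either
    series.  Raises on mismatched lengths, fewer than 3 samples, or a
    zero-variance input (the correlation is undefined there).
    """
    c = np.asarray(cursor, dtype=float)
    g = np.asarray(track, dtype=float)
    if c.shape != g.shape or c.ndim != 1:
        raise ValueError("cursor and track must be equal-length 1-D series")
    if c.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation")
    cc = c - c.mean()
    gg = g - g.mean()
    denom = np.sqrt((cc ** 2).sum() * (gg ** 2).sum())
    if denom == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r = float((cc * gg).sum() / denom)
    return max(0.0, min(1.0, r))


@dataclass
class HandScore:
    """One trial's clipped-Pearson score for one hand."""

    subject: str
    session: str
    trial: int
    hand: str
    r: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def session_scores(trials) -> pd.DataFrame:
    """Mean score per subject x session x hand, across all trials.

    Accepts an iterable of :class:`HandScore` or a DataFrame with
    columns subject, session, trial, hand, r.  Every subject must have
    at least one trial for every observed session x hand cell; a missing
    cell raises with the offending key.
    """
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        df = pd.DataFrame([vars(t) for t in trials])
    required = {"subject", "session", "hand", "r"}
    if df.empty or not required.issubset(df.columns):
        raise ValueError(f"trial table needs columns {sorted(required)}")
    means = (
        df.groupby(["subject", "session", "hand"], sort=True)["r"]
        .mean()
        .reset_index()
    )
    subjects = sorted(df["subject"].unique())
    sessions = sorted(df["session"].unique())
    hands = sorted(df["hand"].unique())
    have = set(map(tuple, means[["subject", "session", "hand"]].to_numpy()))
    missing = [
        (su, se, ha)
        for su in subjects for se in sessions for ha in hands
        if (su, se, ha) not in have
    ]
    if missing:
        raise ValueError(f"missing subject x session x hand cells: {missing}")
    return means


def bimanual_pca(session_means: pd.DataFrame) -> pd.DataFrame:
    """Reduce (left, right) session means to one bimanual score per
    subject x session.

    Both hand columns are standardized over the pooled rows (both
    sessions together) and the first principal component is taken; its
    sign is fixed so the score correlates positively with the mean of
    the two hands.  Returns columns subject, session, pc1,
    explained_variance.

    Accepts the long output of :func:`session_scores` (pivoted on hand)
    or a wide frame with columns subject, session, left, right.
    """
    df = session_means.copy()
    if "hand" in df.columns:
        df = df.pivot_table(
            index=["subject", "session"], columns="hand", values="r"
        ).reset_index()
    for hand in ("left", "right"):
        if hand not in df.columns:
            raise ValueError(f"missing {hand!r}-hand scores")
    if df[["left", "right"]].isna().any().any():
        raise ValueError("incomplete left/right cells in session means")
    if len(df) < 3:
        raise ValueError("need at least 3 subject x session observations")
    X = df[["left", "right"]].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError(
            "degenerate PCA: a hand's scores are constant across observations"
        )
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=1)
    pc1 = pca.fit_transform(Z)[:, 0]
    mean_score = X.mean(axis=1)
    if np.corrcoef(pc1, mean_score)[0, 1] < 0:
        pc1 = -pc1
    out = df[["subject", "session"]].copy()
    out["pc1"] = pc1
    out["explained_variance"] = float(pca.explained_variance_ratio_[0])
    return out
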