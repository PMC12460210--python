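"""Synthetic EEG, cohorts and tracking behavior with known ground truth.

Every downstream stage of the pipeline is testable without recordings
because this module generates data with the exact statistical structure
the analysis assumes:

* :func:`gen_coupled_eeg` — multichannel oscillatory signals where
  chosen channel pairs share a band-limited carrier with a controlled,
  constant phase lag.  The carrier is band-pass-filtered Gaussian noise
  (a stationary narrow-band process); the second channel's copy is
  rotated in phase through the analytic signal, so the expected ciPLV
  of a pair rises monotonically with the coupling strength and a
  zero-lag pair reproduces the volume-conduction trap (PLV near 1,
  ciPLV near 0).  Background activity is independent 1/f-shaped noise
  per channel, giving EEG-like spectra without modelling sources.
* :func:`gen_cohort` — a paired pre/post cohort, either as ciPLV-style
  connectivity matrices directly (fast; used for permutation-test
  calibration at scale) or as raw EEG recordings (full-pipeline tests).
  With ``effect_size = 0`` the two sessions are exchangeable draws from
  one distribution — the null configuration for family-wise error
  simulation; otherwise exactly the requested edges change in
  expectation between sessions.
* :func:`gen_tracker` — a simulated participant: the cursor equals the
  track delayed by a lag plus white noise, so tracking performance is
  tunable from perfect (lag 0, no noise) to chance.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .behavior import TrackTrace
from .connectivity import BANDS, CHANNELS_16, ConnectivityMatrix, EEGRecording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingSpec:
    """A phase-coupled channel pair.

    ``pair`` is an ordered (source, target) pair of channel labels;
    ``band`` a canonical band name or (low, high) Hz interval;
    ``phase_lag`` the constant lag in radians in (-pi, pi] — a lag of 0
    is the zero-lag (volume-conduction-like) case that ciPLV is designed
    to suppress; ``strength`` in [0, 1] scales the shared carrier's
    amplitude, 0 meaning fully independent channels.
    """

    pair: tuple[str, str]
    band: str | tuple[float, float]
    phase_lag: float
    strength: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if not -np.pi < self.phase_lag <= np.pi:
            raise ValueError("phase_lag must lie in (-pi, pi]")
        if isinstance(self.band, str) and self.band not in BANDS:
            raise ValueError(
                f"unknown band {self.band!r}; known: {sorted(BANDS)}"
            )

    @property
    def band_edges(self) -> tuple[float, float]:
        if isinstance(self.band, str):
            return BANDS[self.band]
        return float(self.band[0]), float(self.band[1])


@dataclass(frozen=True)
class CohortSpec:
    """A paired two-session cohort with optional planted edge effects.

    ``effect_edges`` lists the channel pairs whose expected connectivity
    differs between sessions by ``effect_size`` (post minus pre; sign
    matters — negative plants a decrease).  ``noise_sd`` is the
    within-subject session-to-session variability (ciPLV units in
    matrix mode; background-noise amplitude in EEG mode, resolved to a
    mode default when None).  ``effect_size = 0`` is the exchangeable
    null configuration.
    """

    n_subjects: int
    effect_edges: tuple[tuple[str, str], ...] = ()
    effect_size: float = 0.0
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], fs: float) -> np.ndarray:
    """Independent 1/f-power noise per channel, unit variance."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    F = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(F * scale, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Band-pass-filtered white noise (FFT brick-wall), unit variance."""
    white = rng.standard_normal(n)
    F = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    F[(freqs < lo) | (freqs >= hi)] = 0.0
    out = np.fft.irfft(F, n=n)
    sd = out.std()
    if sd == 0:
        raise ValueError(f"band ({lo}, {hi}) Hz empty at this length/fs")
    return out / sd


def _rotate_phase(x: np.ndarray, phi: float) -> np.ndarray:
    """Shift every positive-frequency component of x by -phi radians
    (analytic-signal rotation), preserving the envelope."""
    return np.real(hilbert(x) * np.exp(-1j * phi))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_coupled_eeg(
    spec_list: Sequence[CouplingSpec],
    n_channels: int = 16,
    fs: float = 512.0,
    duration: float = 60.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    channel_labels: Sequence[str] | None = None,
    subject: str = "s01",
    session: str = "pre",
    trial: int = 0,
    min_duration: float = 4.0,
) -> EEGRecording:
    """Generate a multichannel recording with planted phase couplings.

    Background is independent 1/f noise of amplitude ``noise_sd`` per
    channel.  Each :class:`CouplingSpec` adds a shared band-limited
    Gaussian carrier of amplitude ``strength`` to its pair, the second
    channel's copy phase-rotated by ``phase_lag``.  Randomness derives
    entirely from ``seed``.
    """
    if channel_labels is None:
        if n_channels > len(CHANNELS_16):
            channel_labels = tuple(f"ch{i:02d}" for i in range(n_channels))
        else:
            channel_labels = CHANNELS_16[:n_channels]
    channel_labels = tuple(channel_labels)
    if len(channel_labels) != n_channels:
        raise ValueError("channel_labels length must equal n_channels")
    idx = {c: i for i, c in enumerate(channel_labels)}
    for spec in spec_list:
        for c in spec.pair:
            if c not in idx:
                raise ValueError(f"unknown channel label {c!r} in coupling pair")
        hi = spec.band_edges[1]
        if fs <= 2 * hi:
            raise ValueError(
                f"fs={fs} Hz too low for band edge {hi} Hz (need fs > {2 * hi})"
            )
    if duration < min_duration:
        raise ValueError(
            f"duration {duration} s shorter than one {min_duration} s window"
        )
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    data = noise_sd * _pink_noise(rng, (n_channels, n), fs)
    for spec in spec_list:
        lo, hi = spec.band_edges
        carrier = _bandlimited_noise(rng, n, fs, lo, hi)
        a, b = (idx[c] for c in spec.pair)
        data[a] += spec.strength * carrier
        data[b] += spec.strength * _rotate_phase(carrier, spec.phase_lag)
    return EEGRecording(
        data=data, fs=fs, channel_labels=channel_labels,
        subject=subject, session=session, trial=trial,
    )


def _symmetric_noise(
    rng: np.random.Generator, n_ch: int, sd: float
) -> np.ndarray:
    iu, ju = np.triu_indices(n_ch, k=1)
    out = np.zeros((n_ch, n_ch))
    vals = rng.normal(0.0, sd, iu.shape[0])
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def _effect_mask(
    effect_edges: Sequence[tuple[str, str]],
    channel_labels: Sequence[str],
) -> np.ndarray:
    idx = {c: i for i, c in enumerate(channel_labels)}
    mask = np.zeros((len(channel_labels), len(channel_labels)))
    for a, b in effect_edges:
        if a not in idx or b not in idx:
            raise ValueError(f"effect edge ({a}, {b}) names unknown channels")
        mask[idx[a], idx[b]] = mask[idx[b], idx[a]] = 1.0
    return mask


def gen_cohort(
    cohort: CohortSpec,
    mode: str = "matrix",
    channel_labels: Sequence[str] = CHANNELS_16,
    band: str = "beta",
    base_strength: float = 0.3,
    fs: float = 512.0,
    duration: float = 12.0,
    phase_lag: float = np.pi / 2,
):
    """Paired pre/post data for every subject of a cohort.

    ``mode="matrix"`` returns two lists of :class:`ConnectivityMatrix`
    (fast; each subject's sessions are noisy copies of a subject-specific
    base matrix, with ``effect_size`` added to the effect edges of the
    post session).  ``mode="eeg"`` returns two lists of
    :class:`EEGRecording` where the effect edges carry a band-limited
    coupling of strength ``base_strength`` pre and
    ``base_strength + effect_size`` post.
    """
    labels = tuple(channel_labels)
    mask = _effect_mask(cohort.effect_edges, labels)
    rng = np.random.default_rng(cohort.seed)
    n_ch = len(labels)
    if mode == "matrix":
        sd = 0.05 if cohort.noise_sd is None else cohort.noise_sd
        pre_list, post_list = [], []
        for u in range(cohort.n_subjects):
            sid = f"s{u + 1:02d}"
            base = np.zeros((n_ch, n_ch))
            iu, ju = np.triu_indices(n_ch, k=1)
            vals = rng.uniform(0.15, 0.6, iu.shape[0])
            base[iu, ju] = vals
            base[ju, iu] = vals
            pre = np.clip(base + _symmetric_noise(rng, n_ch, sd), 0.0, 1.0)
            post = np.clip(
                base + cohort.effect_size * mask
                + _symmetric_noise(rng, n_ch, sd),
                0.0, 1.0,
            )
            np.fill_diagonal(pre, 0.0)
            np.fill_diagonal(post, 0.0)
            pre_list.append(
                ConnectivityMatrix(
                    values=pre, band=band, subject=sid, session="pre",
                    n_windows=1, channel_labels=labels,
                )
            )
            post_list.append(
                ConnectivityMatrix(
                    values=post, band=band, subject=sid, session="post",
                    n_windows=1, channel_labels=labels,
                )
            )
        return pre_list, post_list
    if mode == "eeg":
        noise_sd = 1.0 if cohort.noise_sd is None else cohort.noise_sd
        pre_list, post_list = [], []
        for u in range(cohort.n_subjects):
            sid = f"s{u + 1:02d}"
            for session, out in (("pre", pre_list), ("post", post_list)):
                strength = base_strength
                if session == "post":
                    strength = float(
                        np.clip(base_strength + cohort.effect_size, 0.0, 1.0)
                    )
                specs = [
                    CouplingSpec(
                        pair=(a, b), band=band,
                        phase_lag=phase_lag, strength=strength,
                    )
                    for a, b in cohort.effect_edges
                ]
                out.append(
                    gen_coupled_eeg(
                        specs, n_channels=n_ch, fs=fs, duration=duration,
                        noise_sd=noise_sd,
                        seed=int(rng.integers(2 ** 31)),
                        channel_labels=labels, subject=sid, session=session,
                    )
                )
        return pre_list, post_list
    raise ValueError(f"unknown mode {mode!r}; use 'matrix' or 'eeg'")


def gen_tracker(
    track: TrackTrace,
    lag: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulated cursor: the track delayed by ``lag`` seconds plus white
    noise of amplitude ``noise_sd`` (track units).  lag 0 and noise 0
    reproduce the track exactly."""
    if lag < 0:
        raise ValueError("lag must be non-negative")
    trace = track.trace
    n = trace.shape[0]
    shift = int(round(lag * track.fs))
    if shift >= n:
        raise ValueError("lag longer than the track")
    if shift > 0:
        delayed = np.concatenate([np.full(shift, trace[0]), trace[:-shift]])
    else:
        delayed = trace.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        delayed = delayed + rng.normal(0.0, noise_sd, n)
    return delayed
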