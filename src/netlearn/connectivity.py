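"""Band-wise phase-coupling connectivity from multichannel EEG.

This module carries an EEG trial from raw samples to a symmetric
connectivity matrix:

1. :func:`preprocess` — zero-phase Butterworth band-pass (0.5–100 Hz,
   8th order) followed by a 50 Hz Butterworth notch (4th order), the
   standard conditioning chain for scalp EEG recorded under mains power.
2. :func:`sliding_windows` — cut the trial into overlapping epochs
   (4 s windows, 2 s stride by default).
3. :func:`ciplv` — corrected imaginary phase-locking value per channel
   pair, estimated per frequency bin from Hann-tapered window
   cross-spectra and averaged over the bins of a canonical band.

The ciPLV statistic uses only the imaginary part of the unit-normalized
cross-spectrum, renormalized so that it still spans [0, 1]:

    ciPLV = |E[Im(S_xy/|S_xy|)]| / sqrt(1 - |E[Re(S_xy/|S_xy|)]|^2)

where the expectation E runs over windows.  Zero-lag synchrony — the
signature of volume conduction, where one cortical source leaks into
several electrodes — has a purely real normalized cross-spectrum and
therefore scores 0, while any consistent non-zero phase lag scores up
to 1.  The classical PLV (:func:`plv`), |E[S_xy/|S_xy|]|, is also
provided as the zero-lag-sensitive contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

#: Electrode montage of the 16-channel recording setup, in fixed order.
CHANNELS_16: tuple[str, ...] = (
    "AF3", "AF4", "FC3", "FCz", "FC4", "C3", "Cz", "C4",
    "T7", "T8", "CP3", "CPz", "CP4", "Pz", "O1", "O2",
)

#: Canonical frequency bands (Hz); bins are selected with low <= f < high
#: so that shared edges (e.g. 7 Hz) are not double-counted.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (3.0, 7.0),
    "alpha": (7.0, 13.0),
    "beta": (13.0, 35.0),
    "gamma": (35.0, 50.0),
}

#: Default study sampling rate (Hz).
FS_EEG = 512.0

#: 1 - |E[Re]|^2 below this is treated as a degenerate denominator
#: (purely real coupling; the imaginary part is identically 0 there).
_DEGENERATE_TOL = 1e-12

#: Fixed nearest-neighbour map for the optional Hjorth-style Laplacian
#: re-reference.  Approximate scalp adjacency for the 16-channel montage;
#: a coarse substitute for a geometry-derived operator, default off.
HJORTH_NEIGHBOURS: dict[str, tuple[str, ...]] = {
    "AF3": ("AF4", "FC3"),
    "AF4": ("AF3", "FC4"),
    "FC3": ("AF3", "FCz", "C3"),
    "FCz": ("FC3", "FC4", "Cz"),
    "FC4": ("AF4", "FCz", "C4"),
    "C3": ("FC3", "T7", "Cz", "CP3"),
    "Cz": ("FCz", "C3", "C4", "CPz"),
    "C4": ("FC4", "T8", "Cz", "CP4"),
    "T7": ("C3", "CP3"),
    "T8": ("C4", "CP4"),
    "CP3": ("C3", "T7", "CPz", "Pz"),
    "CPz": ("Cz", "CP3", "CP4", "Pz"),
    "CP4": ("C4", "T8", "CPz", "Pz"),
    "Pz": ("CP3", "CPz", "CP4", "O1", "O2"),
    "O1": ("Pz", "O2"),
    "O2": ("Pz", "O1"),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """One trial's channels x samples matrix with its identity.

    Parameters
    ----------
    data
        Real-valued array of shape ``(n_channels, n_samples)`` (µV).
    fs
        Sampling rate in Hz (512 for study-faithful runs).
    channel_labels
        Ordered, unique channel labels; defaults to the fixed
        16-electrode montage.
    subject, session, trial
        Identity of the recording; ``session`` is ``"pre"`` or ``"post"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = CHANNELS_16
    subject: str = "s01"
    session: str = "pre"
    trial: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be 2-D (channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class WindowSet:
    """Sliding-window epochs cut from one or more recordings.

    ``windows`` has shape ``(n_windows, n_channels, window_samples)``;
    ``provenance`` records the ``(subject, session, trial)`` of each
    window so pooled sets keep track of their origin.
    """

    windows: np.ndarray
    fs: float
    window_length: float
    stride: float
    channel_labels: tuple[str, ...]
    provenance: tuple[tuple[str, str, int], ...]

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be 3-D (window, channel, sample)")
        self.channel_labels = tuple(self.channel_labels)
        self.provenance = tuple(tuple(p) for p in self.provenance)
        if len(self.provenance) != self.windows.shape[0]:
            raise ValueError("one provenance entry per window required")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band connectivity matrix for one subject x session.

    ``values`` is an ``(n, n)`` symmetric matrix with zero diagonal and
    entries in [0, 1] (ciPLV units).
    """

    values: np.ndarray
    band: str
    subject: str = "s01"
    session: str = "pre"
    n_windows: int = 0
    channel_labels: tuple[str, ...] = CHANNELS_16

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("connectivity diagonal must be zero")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("connectivity entries must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        np.fill_diagonal(self.values, 0.0)
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    rec: EEGRecording,
    l_freq: float = 0.5,
    h_freq: float = 100.0,
    bandpass_order: int = 8,
    notch_freq: float = 50.0,
    notch_order: int = 4,
    notch_halfwidth: float = 2.0,
    laplacian: bool = False,
) -> EEGRecording:
    """Zero-phase band-pass and mains-notch filtering, per channel.

    The band-pass is an 8th-order Butterworth (0.5–100 Hz) and the notch
    a 4th-order Butterworth band-stop centred on the 50 Hz power line,
    both applied forward-backward (``sosfiltfilt``) so that no group
    delay distorts the phase estimates downstream.  Signal length is
    preserved.

    ``laplacian=True`` additionally applies a nearest-neighbour (Hjorth)
    surface-Laplacian re-reference using a fixed montage neighbour map.
    This is a coarse spatial high-pass, not a geometry-faithful
    Laplacian, and is off by default.
    """
    if rec.fs <= 2 * h_freq:
        raise ValueError(
            f"fs={rec.fs} Hz too low for a {h_freq} Hz band edge "
            f"(need fs > {2 * h_freq})"
        )
    if bandpass_order % 2 or notch_order % 2:
        raise ValueError("filter orders must be even (band-pass/stop designs)")
    sos_bp = sps.butter(
        bandpass_order // 2, [l_freq, h_freq], btype="bandpass",
        fs=rec.fs, output="sos",
    )
    sos_notch = sps.butter(
        notch_order // 2,
        [notch_freq - notch_halfwidth, notch_freq + notch_halfwidth],
        btype="bandstop", fs=rec.fs, output="sos",
    )
    out = sps.sosfiltfilt(sos_bp, rec.data, axis=-1)
    out = sps.sosfiltfilt(sos_notch, out, axis=-1)
    rec = replace(rec, data=out)
    if laplacian:
        rec = hjorth_laplacian(rec)
    return rec


def hjorth_laplacian(rec: EEGRecording) -> EEGRecording:
    """Nearest-neighbour Laplacian: subtract the mean of each channel's
    mapped neighbours.  Requires the fixed 16-channel montage labels."""
    missing = [c for c in rec.channel_labels if c not in HJORTH_NEIGHBOURS]
    if missing:
        raise ValueError(f"no neighbour map for channels: {missing}")
    idx = {c: i for i, c in enumerate(rec.channel_labels)}
    out = rec.data.copy()
    for c in rec.channel_labels:
        nbrs = [idx[n] for n in HJORTH_NEIGHBOURS[c] if n in idx]
        if nbrs:
            out[idx[c]] = rec.data[idx[c]] - rec.data[nbrs].mean(axis=0)
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def window_count(n_samples: int, window_samples: int, stride_samples: int) -> int:
    """Number of full-length windows: floor((T - w)/s) + 1."""
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // stride_samples + 1


def sliding_windows(
    rec: EEGRecording,
    window_length: float = 4.0,
    stride: float = 2.0,
) -> WindowSet:
    """Cut a recording into full-length overlapping windows.

    Windows start at offsets 0, stride, 2·stride, …; any ragged tail
    shorter than ``window_length`` is dropped, so the count equals
    ``floor((T - window_length)/stride) + 1``.
    """
    if window_length <= 0:
        raise ValueError("window_length must be positive")
    if stride <= 0:
        raise ValueError("stride must be positive")
    w = int(round(window_length * rec.fs))
    s = int(round(stride * rec.fs))
    n = window_count(rec.n_samples, w, s)
    if n < 1:
        raise ValueError(
            f"recording of {rec.duration:.3f} s shorter than one "
            f"{window_length} s window"
        )
    starts = np.arange(n) * s
    windows = np.stack([rec.data[:, st:st + w] for st in starts])
    prov = tuple((rec.subject, rec.session, rec.trial) for _ in range(n))
    return WindowSet(
        windows=windows, fs=rec.fs, window_length=window_length,
        stride=stride, channel_labels=rec.channel_labels, provenance=prov,
    )


def pool_windows(wsets: Sequence[WindowSet]) -> WindowSet:
    """Concatenate window sets (e.g. the trials of one session)."""
    if not wsets:
        raise ValueError("no window sets to pool")
    first = wsets[0]
    for ws in wsets[1:]:
        if ws.fs != first.fs or ws.channel_labels != first.channel_labels:
            raise ValueError("window sets differ in fs or channel labels")
        if ws.windows.shape[2] != first.windows.shape[2]:
            raise ValueError("window sets differ in window length")
    return WindowSet(
        windows=np.concatenate([ws.windows for ws in wsets]),
        fs=first.fs,
        window_length=first.window_length,
        stride=first.stride,
        channel_labels=first.channel_labels,
        provenance=tuple(p for ws in wsets for p in ws.provenance),
    )


# ---------------------------------------------------------------------------
# Phase-locking estimators
# ---------------------------------------------------------------------------

def _resolve_band(band) -> tuple[str, float, float]:
    if isinstance(band, str):
        if band not in BANDS:
            raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}")
        lo, hi = BANDS[band]
        return band, lo, hi
    lo, hi = float(band[0]), float(band[1])
    return f"{lo:g}-{hi:g}Hz", lo, hi


def _unit_cross_spectra(ws: WindowSet, lo: float, hi: float) -> np.ndarray:
    """Unit-normalized cross-spectra S_xy/|S_xy| for the band's bins.

    Returns a complex array of shape (n_windows, n_ch, n_ch, n_bins).
    Per window the spectrum is a single Hann-tapered rfft at the native
    frequency grid of the window length; bins with |S_xy| = 0 (possible
    only for numerically silent channels) are set to 0.
    """
    n = ws.windows.shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / ws.fs)
    sel = (freqs >= lo) & (freqs < hi)
    if not sel.any():
        raise ValueError(
            f"band ({lo}, {hi}) Hz contains no frequency bins at "
            f"window length {n / ws.fs:g} s"
        )
    taper = sps.get_window("hann", n, fftbins=True)
    X = np.fft.rfft(ws.windows * taper, axis=-1)[..., sel]
    S = X[:, :, None, :] * np.conj(X[:, None, :, :])
    mag = np.abs(S)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = np.where(mag > 0, S / mag, 0.0)
    return U


def _band_checks(ws: WindowSet, lo: float, hi: float) -> None:
    if ws.n_windows < 2:
        raise ValueError("need at least 2 windows for a phase-locking estimate")
    if not (0 < lo < hi):
        raise ValueError("band must satisfy 0 < low < high")
    if hi > ws.fs / 2:
        raise ValueError(f"band edge {hi} Hz above Nyquist {ws.fs / 2} Hz")


def ciplv(
    windows: WindowSet,
    band,
    subject: str | None = None,
    session: str | None = None,
) -> ConnectivityMatrix:
    """Corrected imaginary PLV per channel pair, band-averaged.

    Per frequency bin the unit-normalized cross-spectrum is averaged
    over windows and

        ciPLV = |E[Im]| / sqrt(1 - |E[Re]|^2)

    is formed; the band value is the mean over the band's bins.  Where
    the denominator degenerates (|E[Re]| = 1, purely real coupling) the
    imaginary part is identically zero and the bin scores 0.

    ``band`` is a canonical band name or an explicit ``(low, high)``
    interval in Hz (bins selected with low <= f < high).
    """
    name, lo, hi = _resolve_band(band)
    _band_checks(windows, lo, hi)
    U = _unit_cross_spectra(windows, lo, hi)
    E = U.mean(axis=0)  # (n_ch, n_ch, n_bins)
    im = np.abs(E.imag)
    denom_sq = 1.0 - np.abs(E.real) ** 2
    degenerate = denom_sq < _DEGENERATE_TOL
    if degenerate.any():
        logger.debug(
            "ciplv: %d degenerate (purely real) channel-pair bins set to 0",
            int(np.count_nonzero(degenerate)),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(degenerate, 0.0, im / np.sqrt(np.abs(denom_sq)))
    values = per_bin.mean(axis=-1)
    values = np.clip(0.5 * (values + values.T), 0.0, 1.0)
    np.fill_diagonal(values, 0.0)
    prov = windows.provenance[0]
    return ConnectivityMatrix(
        values=values,
        band=name,
        subject=subject if subject is not None else prov[0],
        session=session if session is not None else prov[1],
        n_windows=windows.n_windows,
        channel_labels=windows.channel_labels,
    )


def plv(
    windows: WindowSet,
    band,
    subject: str | None = None,
    session: str | None = None,
) -> ConnectivityMatrix:
    """Classical phase-locking value |E[S_xy/|S_xy|]|, band-averaged.

    Unlike ciPLV this scores zero-lag (volume-conducted) synchrony as 1;
    it is kept as the contrast for the zero-lag suppression property.
    """
    name, lo, hi = _resolve_band(band)
    _band_checks(windows, lo, hi)
    U = _unit_cross_spectra(windows, lo, hi)
    values = np.abs(U.mean(axis=0)).mean(axis=-1)
    values = np.clip(0.5 * (values + values.T), 0.0, 1.0)
    np.fill_diagonal(values, 0.0)
    prov = windows.provenance[0]
    return ConnectivityMatrix(
        values=values,
        band=name,
        subject=subject if subject is not None else prov[0],
        session=session if session is not None else prov[1],
        n_windows=windows.n_windows,
        channel_labels=windows.channel_labels,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def average_matrices(mats: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise arithmetic mean of matrices sharing one band."""
    if not mats:
        raise ValueError("no matrices to average")
    bands = {m.band for m in mats}
    if len(bands) > 1:
        raise ValueError(f"cannot average mixed bands: {sorted(bands)}")
    labels = {m.channel_labels for m in mats}
    if len(labels) > 1:
        raise ValueError("cannot average matrices with different channel sets")
    values = np.mean([m.values for m in mats], axis=0)
    first = mats[0]
    subject = first.subject if len({m.subject for m in mats}) == 1 else "pooled"
    session = first.session if len({m.session for m in mats}) == 1 else "pooled"
    return ConnectivityMatrix(
        values=values, band=first.band, subject=subject, session=session,
        n_windows=sum(m.n_windows for m in mats),
        channel_labels=first.channel_labels,
    )


def average_sessions(
    mats: Iterable[ConnectivityMatrix],
) -> list[ConnectivityMatrix]:
    """Average matrices per (subject, session, band) group.

    Collapses per-trial (or per-window-block) matrices to one matrix per
    subject x session x band, the unit all downstream analyses consume.
    """
    groups: dict[tuple[str, str, str], list[ConnectivityMatrix]] = {}
    for m in mats:
        groups.setdefault((m.subject, m.session, m.band), []).append(m)
    if not groups:
        raise ValueError("no matrices to average")
    return [average_matrices(g) for g in groups.values()]


# ---------------------------------------------------------------------------
# I/O: columnar CSV + JSON sidecar; tidy long-format connectivity tables
# ---------------------------------------------------------------------------

def write_eeg_csv(rec: EEGRecording, stem: str | Path) -> tuple[Path, Path]:
    """Write a recording as ``<stem>.csv`` (samples x channels, headered)
    plus a ``<stem>.json`` sidecar with fs and identity metadata."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    pd.DataFrame(rec.data.T, columns=list(rec.channel_labels)).to_csv(
        csv_path, index=False
    )
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "subject": rec.subject,
        "session": rec.session,
        "trial": rec.trial,
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path, json_path


def read_eeg_csv(stem: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_eeg_csv` (path with or
    without suffix)."""
    stem = Path(stem)
    if stem.suffix in {".csv", ".json"}:
        stem = stem.with_suffix("")
    meta = json.loads(stem.with_suffix(".json").read_text())
    df = pd.read_csv(stem.with_suffix(".csv"))
    labels = tuple(meta["channel_labels"])
    data = df[list(labels)].to_numpy().T
    return EEGRecording(
        data=data, fs=float(meta["fs"]), channel_labels=labels,
        subject=str(meta.get("subject", "s01")),
        session=str(meta.get("session", "pre")),
        trial=int(meta.get("trial", 0)),
    )


def connectivity_to_frame(mats: Iterable[ConnectivityMatrix]) -> pd.DataFrame:
    """Tidy long table of unique edges: one row per
    (subject, session, band, node_i, node_j) with the ciPLV value."""
    rows = []
    for m in mats:
        iu, ju = np.triu_indices(m.n_channels, k=1)
        for i, j in zip(iu, ju):
            rows.append(
                {
                    "subject": m.subject,
                    "session": m.session,
                    "band": m.band,
                    "node_i": m.channel_labels[i],
                    "node_j": m.channel_labels[j],
                    "ciplv": m.values[i, j],
                    "n_windows": m.n_windows,
                }
            )
    return pd.DataFrame(rows)


def frame_to_matrices(
    df: pd.DataFrame,
    channel_labels: Sequence[str] = CHANNELS_16,
) -> list[ConnectivityMatrix]:
    """Rebuild ConnectivityMatrix objects from a tidy long table."""
    labels = tuple(channel_labels)
    idx = {c: i for i, c in enumerate(labels)}
    out = []
    for (subject, session, band), g in df.groupby(
        ["subject", "session", "band"], sort=True
    ):
        v = np.zeros((len(labels), len(labels)))
        for _, row in g.iterrows():
            i, j = idx[row["node_i"]], idx[row["node_j"]]
            v[i, j] = v[j, i] = row["ciplv"]
        n_windows = int(g["n_windows"].iloc[0]) if "n_windows" in g else 0
        out.append(
            ConnectivityMatrix(
                values=v, band=str(band), subject=str(subject),
                session=str(session), n_windows=n_windows,
                channel_labels=labels,
            )
        )
    return out
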