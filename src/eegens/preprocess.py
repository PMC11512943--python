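"""Cleaning and segmentation of continuous EEG.

The preprocessing chain applied to every recording before modelling:

1. channel quality control — exclude channels whose amplitude SD exceeds
   75 µV or shows no variation at all, iterating until stable;
2. recording rejection — drop a file when more than 30% of its channels
   failed QC;
3. interpolation — replace excluded channels with inverse-distance-weighted
   averages of nearby kept channels, so array dimensions never change;
4. band-pass filtering — zero-phase 1–45 Hz for the broadband signal, or the
   canonical six-band decomposition for band-restricted models;
5. epoching — discard the first 30 s, cut a role-specific window (120 s
   train / 60 s validation / 80 s test by default) into non-overlapping 2-s
   epochs, and thin every other training epoch to reduce the correlation
   between successive windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.spatial.distance import cdist

from .bands import BROADBAND, CANONICAL_BANDS, BandDefinition
from .synthdata import ConfigurationError, Recording

__all__ = [
    "ChannelQCReport",
    "EpochArray",
    "qc_channels",
    "reject_recording",
    "interpolate_channels",
    "bandpass",
    "decompose_bands",
    "segment_epochs",
    "thin_training_epochs",
    "preprocess_recording",
    "BandDefinition",
]

SD_THRESHOLD_UV = 75.0
MAX_EXCLUDED_FRACTION = 0.30
EPOCH_SECONDS = 2.0
DISCARD_INITIAL_SECONDS = 30.0
#: Role-specific extraction lengths in seconds (train / validation / test).
DEFAULT_EXTRACT_SECONDS = {"train": 120.0, "validation": 60.0, "test": 80.0}

ROLES = ("train", "validation", "test")


@dataclass
class ChannelQCReport:
    per_channel_sd: np.ndarray
    excluded: list[tuple[int, str]]       # (channel index, "high_sd" | "flat")
    n_iterations: int
    n_channels: int

    @property
    def excluded_indices(self) -> list[int]:
        return [i for i, _ in self.excluded]

    @property
    def fraction_excluded(self) -> float:
        return len(self.excluded) / self.n_channels


@dataclass
class EpochArray:
    """Segmented 2-s windows of one subject — the unit of model prediction."""

    data: np.ndarray          # [n_epochs, n_channels, samples_per_epoch] µV
    subject_id: str
    label: int
    epoch_onsets: np.ndarray  # seconds, relative to recording start
    role: str
    band: str = BROADBAND
    sampling_rate: float = 500.0

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")


def qc_channels(rec: Recording, sd_threshold: float = SD_THRESHOLD_UV) -> ChannelQCReport:
    """Iterative channel QC by amplitude standard deviation.

    A channel is excluded when its SD exceeds ``sd_threshold`` (µV) or is
    exactly zero (no amplitude variation).  The pass is repeated on the
    unchanged signals until a pass excludes nothing; with a fixed threshold
    this converges after one productive pass, but the loop keeps the
    procedure explicit.
    """
    if rec.n_channels < 1 or rec.n_samples == 0:
        raise ValueError("recording has no signal to QC")
    sds = rec.data.std(axis=1)
    excluded: dict[int, str] = {}
    n_iter = 0
    while True:
        n_iter += 1
        new = {}
        for i, sd in enumerate(sds):
            if i in excluded:
                continue
            if sd == 0.0:
                new[i] = "flat"
            elif sd > sd_threshold:
                new[i] = "high_sd"
        if not new:
            break
        excluded.update(new)
    return ChannelQCReport(
        per_channel_sd=sds,
        excluded=sorted(excluded.items()),
        n_iterations=n_iter,
        n_channels=rec.n_channels,
    )


def reject_recording(report: ChannelQCReport,
                     max_fraction: float = MAX_EXCLUDED_FRACTION) -> bool:
    """True when the recording should be rejected (strictly > 30% excluded)."""
    return report.fraction_excluded > max_fraction


def interpolate_channels(rec: Recording, excluded: Sequence[int],
                         k_neighbours: int = 6) -> Recording:
    """Replace excluded channels by inverse-distance-weighted neighbours.

    Each excluded channel becomes a convex combination (weights 1/d,
    normalised) of its ``k_neighbours`` nearest *kept* channels on the unit
    sphere; kept channels pass through untouched.  A coincident kept
    electrode (d = 0) is copied verbatim.
    """
    excluded = sorted(set(excluded))
    if not excluded:
        return rec.copy_with(rec.data.copy())
    kept = [i for i in range(rec.n_channels) if i not in set(excluded)]
    if not kept:
        raise ValueError("cannot interpolate: every channel is excluded")
    out = rec.data.copy()
    dists = cdist(rec.channel_positions[excluded], rec.channel_positions[kept])
    for row, ch in enumerate(excluded):
        d = dists[row]
        order = np.argsort(d)[: min(k_neighbours, len(kept))]
        dn = d[order]
        if dn[0] < 1e-12:
            out[ch] = rec.data[kept[order[0]]]
            continue
        w = 1.0 / dn
        w /= w.sum()
        out[ch] = w @ rec.data[np.asarray(kept)[order]]
    return rec.copy_with(out)


def _bandpass_sos(low: float, high: float, fs: float):
    if not 0.0 < low < high < fs / 2:
        raise ConfigurationError(
            f"band edges ({low}, {high}) Hz invalid at fs={fs} Hz"
        )
    # 8th order gives the roll-off needed to suppress mains-range content
    # (60 Hz leakage < 1% RMS through a 1-45 Hz pass-band) while the
    # forward-backward application keeps the phase response flat.
    return signal.butter(8, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(rec: Recording, low: float = 1.0, high: float = 45.0) -> Recording:
    """Zero-phase 8th-order Butterworth band-pass, applied forward-backward."""
    sos = _bandpass_sos(low, high, rec.sampling_rate)
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=1))


def decompose_bands(rec: Recording) -> dict[str, Recording]:
    """Filter a recording into the six canonical bands."""
    if rec.sampling_rate / 2 <= CANONICAL_BANDS["gamma"].high:
        raise ConfigurationError(
            f"sampling rate {rec.sampling_rate} Hz too low for the gamma band"
        )
    return {
        name: bandpass(rec, band.low, band.high)
        for name, band in CANONICAL_BANDS.items()
    }


def segment_epochs(rec: Recording, extract_s: float, role: str,
                   epoch_s: float = EPOCH_SECONDS,
                   discard_initial_s: float = DISCARD_INITIAL_SECONDS,
                   band: str = BROADBAND) -> EpochArray:
    """Cut the window after the initial discard into consecutive 2-s epochs."""
    if role not in ROLES:
        raise ConfigurationError(f"unknown role {role!r}")
    n_epochs_f = extract_s / epoch_s
    if abs(n_epochs_f - round(n_epochs_f)) > 1e-9:
        raise ConfigurationError("extract_s must be a multiple of epoch_s")
    n_epochs = int(round(n_epochs_f))
    fs = rec.sampling_rate
    samples_per_epoch = int(round(epoch_s * fs))
    start = int(round(discard_initial_s * fs))
    needed = start + n_epochs * samples_per_epoch
    if rec.n_samples < needed:
        raise ValueError(
            f"recording {rec.subject_id} too short: has {rec.n_samples} samples, "
            f"needs {needed} ({needed - rec.n_samples} short)"
        )
    segment = rec.data[:, start: start + n_epochs * samples_per_epoch]
    data = segment.reshape(rec.n_channels, n_epochs, samples_per_epoch)
    data = np.ascontiguousarray(data.transpose(1, 0, 2))
    onsets = discard_initial_s + epoch_s * np.arange(n_epochs)
    return EpochArray(
        data=data,
        subject_id=rec.subject_id,
        label=rec.label,
        epoch_onsets=onsets,
        role=role,
        band=band,
        sampling_rate=fs,
    )


def thin_training_epochs(epochs: EpochArray) -> EpochArray:
    """Keep every other epoch (0-based even indices) of a training array.

    Successive 2-s windows of resting EEG are highly correlated; dropping
    alternate epochs halves the training set while increasing its diversity.
    """
    if epochs.role != "train":
        raise ConfigurationError("thinning applies to training epochs only")
    keep = np.arange(0, epochs.n_epochs, 2)
    return EpochArray(
        data=epochs.data[keep],
        subject_id=epochs.subject_id,
        label=epochs.label,
        epoch_onsets=epochs.epoch_onsets[keep],
        role=epochs.role,
        band=epochs.band,
        sampling_rate=epochs.sampling_rate,
    )


def preprocess_recording(rec: Recording,
                         sd_threshold: float = SD_THRESHOLD_UV,
                         max_fraction: float = MAX_EXCLUDED_FRACTION,
                         low: float = 1.0, high: float = 45.0) -> Recording | None:
    """QC → reject → interpolate → broadband filter; None when rejected."""
    report = qc_channels(rec, sd_threshold)
    if reject_recording(report, max_fraction):
        return None
    clean = interpolate_channels(rec, report.excluded_indices)
    return bandpass(clean, low, high)
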