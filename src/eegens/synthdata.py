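"""Synthetic resting-state EEG cohorts with class-specific band effects.

Generates multi-channel recordings in which the separation between the two
subject classes lives in chosen frequency bands: each channel is a sum of six
narrowband stochastic oscillations (one per canonical EEG band) plus broadband
Gaussian noise.  Band amplitudes are scaled per class, so a cohort can be made
trivially separable, subtly separable, or pure noise — which is exactly what is
needed to exercise classifiers, ensembles and the epoch-rejection machinery
without any real EEG.

Amplitudes are RMS values in microvolts.  A recording is reproducibly derived
from the cohort seed alone: the same :class:`CohortSpec` always yields
bit-identical data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from .bands import CANONICAL_BANDS

__all__ = [
    "CohortSpec",
    "Recording",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "fibonacci_sphere",
]

#: Baseline per-band RMS amplitude in µV (1/f-flavoured: slow bands larger).
#: Chosen so clean channels sit well under the 75 µV channel-QC threshold.
BASE_AMPLITUDE_UV = {
    "delta": 20.0,
    "theta": 12.0,
    "alpha": 15.0,
    "low_beta": 8.0,
    "high_beta": 6.0,
    "gamma": 5.0,
}

#: Default class amplitude multipliers (class 0, class 1).  Class 1 carries
#: moderately larger amplitudes in delta, alpha and the beta range, echoing
#: reported female-vs-male resting amplitude differences.
DEFAULT_BAND_EFFECTS: Mapping[str, tuple[float, float]] = {
    "delta": (1.0, 1.2),
    "theta": (1.0, 1.0),
    "alpha": (1.0, 1.2),
    "low_beta": (1.0, 1.2),
    "high_beta": (1.0, 1.2),
    "gamma": (1.0, 1.0),
}


class ConfigurationError(ValueError):
    """Raised when a spec or parameter set is internally inconsistent."""


@dataclass(frozen=True)
class CohortSpec:
    """Declarative description of a synthetic cohort.

    Defaults mirror the structure of the large paediatric resting-state
    dataset this generator stands in for: 1780 balanced subjects, 129
    channels, 500 Hz, about six minutes per subject.  Tests and desk-scale
    experiments pass smaller values explicitly.
    """

    n_subjects: int = 1780
    class_balance: float = 0.5
    n_channels: int = 129
    sampling_rate: float = 500.0
    duration: float = 360.0
    band_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EFFECTS)
    )
    subject_sd: float = 0.2        # lognormal sigma of the per-subject factor
    noise_sd: float = 5.0          # additive broadband noise, µV
    p_flat_channel: float = 0.0
    p_noisy_channel: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigurationError("class_balance must lie in (0, 1)")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("duration and sampling_rate must be positive")
        if self.n_channels < 1:
            raise ConfigurationError("need at least one channel")
        for name in self.band_effects:
            if name not in CANONICAL_BANDS:
                raise ConfigurationError(
                    f"unknown band {name!r}; canonical bands are "
                    f"{sorted(CANONICAL_BANDS)}"
                )
        highest_edge = max(
            CANONICAL_BANDS[name].high for name in self.band_effects
        ) if self.band_effects else 0.0
        if self.sampling_rate <= 2 * highest_edge:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent a band "
                f"reaching {highest_edge} Hz"
            )

    @property
    def n_samples(self) -> int:
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration × sampling_rate must be an integer")
        return int(round(n))


@dataclass
class Recording:
    """One subject's continuous multi-channel signal in µV."""

    subject_id: str
    label: int
    data: np.ndarray               # [n_channels, n_samples], µV
    sampling_rate: float
    channel_positions: np.ndarray  # [n_channels, 3], unit sphere

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere montage of ``n`` electrode positions.

    Only relative inter-electrode distances matter downstream (channel
    interpolation), so a Fibonacci lattice is an adequate stand-in for any
    real high-density montage.
    """
    i = np.arange(n, dtype=float)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      low: float, high: float) -> np.ndarray:
    """Unit-RMS stochastic oscillation confined to [low, high] Hz.

    White noise filtered into the band with a forward-backward Butterworth,
    then RMS-normalised.  Stochastic (unlike a pure tone), so epochs of the
    same subject genuinely differ.  Power is concentrated in the interior
    of the band (15% margin off each edge): real rhythms peak inside their
    band, and adjacent canonical bands share an edge frequency, so an
    oscillation spanning its full band would bleed into the neighbouring
    band's filtered copy.
    """
    margin = 0.15 * (high - low)
    low, high = low + margin, high - margin
    white = rng.standard_normal(n + int(4 * fs))  # pad to absorb transients
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[int(2 * fs): int(2 * fs) + n]
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def _assign_labels(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n1 = int(round(spec.n_subjects * spec.class_balance))
    n1 = min(max(n1, 1), spec.n_subjects - 1)
    labels = np.array([1] * n1 + [0] * (spec.n_subjects - n1))
    rng.shuffle(labels)
    return labels


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """Generate ``spec.n_subjects`` recordings; pure function of the spec."""
    spec.validate()
    n_samples = spec.n_samples
    positions = fibonacci_sphere(spec.n_channels)

    root = np.random.SeedSequence(spec.seed)
    label_rng = np.random.default_rng(root.spawn(1)[0])
    labels = _assign_labels(spec, label_rng)
    subject_seeds = root.spawn(spec.n_subjects + 1)[1:]

    recordings: list[Recording] = []
    width = len(str(spec.n_subjects - 1))
    for idx, (label, ss) in enumerate(zip(labels, subject_seeds)):
        rng = np.random.default_rng(ss)
        subject_factor = float(np.exp(rng.normal(0.0, spec.subject_sd)))
        data = np.zeros((spec.n_channels, n_samples))
        for name, (m0, m1) in spec.band_effects.items():
            band = CANONICAL_BANDS[name]
            mult = m1 if label == 1 else m0
            amp = BASE_AMPLITUDE_UV[name] * mult * subject_factor
            for ch in range(spec.n_channels):
                data[ch] += amp * _narrowband_noise(
                    rng, n_samples, spec.sampling_rate, band.low, band.high
                )
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

        # Bad-channel injection: flat channels are constant; noisy channels
        # get extra broadband noise pushing their SD above the 75 µV QC rule.
        for ch in range(spec.n_channels):
            u = rng.random()
            if u < spec.p_flat_channel:
                data[ch] = 0.0
            elif u < spec.p_flat_channel + spec.p_noisy_channel:
                data[ch] += rng.normal(0.0, 150.0, size=n_samples)

        recordings.append(
            Recording(
                subject_id=f"S{idx:0{width}d}",
                label=int(label),
                data=data,
                sampling_rate=spec.sampling_rate,
                channel_positions=positions,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# Cohort I/O: one file per subject plus manifest.csv.
# Default dialect is .npy with a JSON sidecar; "edf" writes 16-bit EDF files
# readable by any standard EDF reader.
# ---------------------------------------------------------------------------

def write_cohort(recordings: Sequence[Recording], directory, fmt: str = "npy") -> Path:
    """Write a cohort directory; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        if fmt == "npy":
            path = directory / f"{rec.subject_id}.npy"
            np.save(path, rec.data)
            sidecar = directory / f"{rec.subject_id}.json"
            sidecar.write_text(json.dumps({
                "subject_id": rec.subject_id,
                "label": rec.label,
                "sampling_rate": rec.sampling_rate,
                "channel_positions": rec.channel_positions.tolist(),
            }))
        elif fmt == "edf":
            path = directory / f"{rec.subject_id}.edf"
            _write_edf(path, rec)
            sidecar = directory / f"{rec.subject_id}.json"
            sidecar.write_text(json.dumps({
                "subject_id": rec.subject_id,
                "label": rec.label,
                "sampling_rate": rec.sampling_rate,
                "channel_positions": rec.channel_positions.tolist(),
            }))
        else:
            raise ConfigurationError(f"unknown cohort format {fmt!r}")
        rows.append((rec.subject_id, rec.label, path.name, rec.sampling_rate))

    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label", "path", "sampling_rate"])
        w.writerows(rows)
    return manifest


def read_cohort(directory) -> list[Recording]:
    """Read a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise IOError(f"no manifest.csv in {directory}")
    recordings = []
    with open(manifest) as fh:
        for row in csv.DictReader(fh):
            path = directory / row["path"]
            if not path.exists():
                raise IOError(
                    f"file {path.name} for subject {row['subject_id']} is missing"
                )
            sidecar = directory / f"{row['subject_id']}.json"
            meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
            if path.suffix == ".npy":
                data = np.load(path)
            elif path.suffix == ".edf":
                data = _read_edf(path)
            else:
                raise IOError(f"unsupported file {path.name}")
            positions = np.asarray(
                meta.get("channel_positions", fibonacci_sphere(data.shape[0]))
            )
            recordings.append(Recording(
                subject_id=row["subject_id"],
                label=int(row["label"]),
                data=data,
                sampling_rate=float(row["sampling_rate"]),
                channel_positions=positions,
            ))
    return recordings


def _write_edf(path: Path, rec: Recording) -> None:
    """Minimal EDF writer: 1-second data records, 16-bit samples.

    Quantises each channel to its own physical range, so the round-trip is
    lossless up to the format's 16-bit resolution.  Requires an integer
    sampling rate and an integer number of seconds.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF dialect needs an integer sampling rate")
    fs = int(round(fs))
    n_records, rem = divmod(rec.n_samples, fs)
    if rem:
        raise ConfigurationError("EDF dialect needs a whole number of seconds")
    nch = rec.n_channels

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    phys_min = np.floor(rec.data.min(axis=1)) - 1.0
    phys_max = np.ceil(rec.data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.subject_id}", 80),
        pad("Startdate 01-JAN-2000 X X X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + nch)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(nch), 4),
    ])
    header += b"".join(pad(f"EEG {i:03d}", 16) for i in range(nch))
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(nch))
    header += b"".join(pad("uV", 8) for _ in range(nch))
    header += b"".join(pad(f"{phys_min[i]:.0f}", 8) for i in range(nch))
    header += b"".join(pad(f"{phys_max[i]:.0f}", 8) for i in range(nch))
    header += b"".join(pad(str(dig_min), 8) for _ in range(nch))
    header += b"".join(pad(str(dig_max), 8) for _ in range(nch))
    header += b"".join(pad("", 80) for _ in range(nch))
    header += b"".join(pad(str(fs), 8) for _ in range(nch))
    header += b"".join(pad("", 32) for _ in range(nch))

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    digital = np.round((rec.data - offset[:, None]) / gain[:, None])
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def _read_edf(path: Path) -> np.ndarray:
    """Read back an EDF file written by :func:`_write_edf` (µV)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_records = int(head[236:244].decode().strip())
        nch = int(head[252:256].decode().strip())
        sig_head = fh.read(256 * nch)
        pmin = np.array([float(v) for v in _sig_field(sig_head, nch, 3)])
        pmax = np.array([float(v) for v in _sig_field(sig_head, nch, 4)])
        dmin = np.array([float(v) for v in _sig_field(sig_head, nch, 5)])
        dmax = np.array([float(v) for v in _sig_field(sig_head, nch, 6)])
        ns = np.array([int(v) for v in _sig_field(sig_head, nch, 8)])
        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_record = int(ns.sum())
    raw = raw[: n_records * per_record].reshape(n_records, nch, ns[0])
    digital = raw.transpose(1, 0, 2).reshape(nch, -1).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    offset = pmin - gain * dmin
    return digital * gain[:, None] + offset[:, None]


_SIG_FIELD_WIDTHS = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]


def _sig_field(sig_head: bytes, nch: int, index: int) -> list[str]:
    start = sum(w * nch for w in _SIG_FIELD_WIDTHS[:index])
    width = _SIG_FIELD_WIDTHS[index]
    return [
        sig_head[start + i * width: start + (i + 1) * width].decode().strip()
        for i in range(nch)
    ]
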