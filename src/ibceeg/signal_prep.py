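"""Epoching, band filtering, and differential-entropy feature extraction.

Multichannel EEG is cut into fixed-length epochs, decomposed into the five
canonical frequency bands (delta 1-4 Hz, theta 4-8 Hz, alpha 8-13 Hz,
beta 13-30 Hz, gamma 30-50 Hz), and each epoch/channel/band is summarized
by its differential entropy (DE).  For a zero-mean Gaussian signal with
variance ``s2`` the DE is the closed form ``0.5 * ln(2*pi*e*s2)`` (nats);
for a band-limited EEG segment this equals, up to an additive constant,
half the log of the in-band energy spectrum, which is why log band power
and DE are used interchangeably as EEG features.

Two estimators are provided:

``variance``
    band-pass filter the epoch (zero-phase Butterworth) and plug its sample
    variance into the Gaussian closed form — the default.
``spectrum``
    half the log of the mean in-band power from a Hann-windowed periodogram.
    Differs from ``variance`` by an additive per-band constant; classifiers
    applied after per-feature standardization are invariant to that shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "EpochedEEG",
    "BandDEFeatures",
    "segment_epochs",
    "bandpass",
    "notch",
    "de_gaussian",
    "extract_band_de",
    "read_edf",
    "save_epochs_h5",
    "load_epochs_h5",
    "save_de_h5",
    "load_de_h5",
    "de_to_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[low, high]`` in Hz."""

    name: str
    low: float
    high: float

    def validate(self, fs: float | None = None) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got [{self.low}, {self.high}]"
            )
        if fs is not None and self.high >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: high edge {self.high} Hz >= Nyquist {fs / 2} Hz"
            )


#: The five canonical EEG bands.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)


@dataclass
class EpochedEEG:
    """Epoched multichannel EEG with per-epoch labels and block ids.

    ``data`` is ``(n_epochs, n_channels, n_samples)`` in microvolts; ``labels``
    are integer classes ``0..c-1``; ``block_ids`` identify the stimulus clip
    (block) each epoch came from, used for block-wise cross-validation.
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    labels: np.ndarray
    block_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.data.shape[0]
        if len(self.labels) != n or len(self.block_ids) != n:
            raise ValueError("labels and block_ids must have one entry per epoch")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class BandDEFeatures:
    """Per-epoch, per-channel, per-band differential entropy values (nats)."""

    values: np.ndarray
    bands: list[BandDefinition]
    labels: np.ndarray
    block_ids: np.ndarray
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.block_ids = np.asarray(self.block_ids, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_epochs, n_channels, n_bands)")
        if self.values.shape[2] != len(self.bands):
            raise ValueError("third axis must match number of bands")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("DE values must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.values.shape[1])]

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_matrix(self, band: int | str) -> np.ndarray:
        """The ``(n_epochs, n_channels)`` DE matrix of one band."""
        if isinstance(band, str):
            names = [b.name for b in self.bands]
            band = names.index(band)
        return self.values[:, :, band]

    def flattened(self) -> np.ndarray:
        """Per-epoch feature rows of width ``n_channels * n_bands``."""
        return self.values.reshape(self.n_epochs, -1)


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def segment_epochs(
    segments: list[np.ndarray] | np.ndarray,
    fs: float,
    labels: list[int] | np.ndarray,
    epoch_seconds: float,
    overlap_seconds: float = 0.0,
    channel_names: list[str] | None = None,
    block_ids: list[int] | np.ndarray | None = None,
) -> EpochedEEG:
    """Cut continuous segments into fixed-length epochs.

    Each *segment* is one continuous recording ``(n_channels, n_samples)``
    (e.g. one film clip) with a single class label; windows of
    ``epoch_seconds`` are taken consecutively (default non-overlapping) and
    any trailing partial window is discarded.  Labels and block ids are
    replicated onto every window of their segment; by default each segment
    becomes its own block.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    if overlap_seconds >= epoch_seconds:
        raise ValueError("overlap_seconds must be smaller than epoch_seconds")
    n_per = fs * epoch_seconds
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("fs * epoch_seconds must be an integer number of samples")
    n_per = int(round(n_per))
    step = int(round(fs * (epoch_seconds - overlap_seconds)))

    if isinstance(segments, np.ndarray) and segments.ndim == 2:
        segments = [segments]
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if block_ids is None:
        block_ids = np.arange(len(segments))
    block_ids = np.atleast_1d(np.asarray(block_ids, dtype=int))
    if len(labels) != len(segments) or len(block_ids) != len(segments):
        raise ValueError("one label and one block id per segment required")

    epochs, ep_labels, ep_blocks = [], [], []
    for i, seg in enumerate(segments):
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2:
            raise ValueError(f"segment {i}: expected (channels, samples)")
        if seg.shape[1] < n_per:
            raise ValueError(
                f"segment {i}: {seg.shape[1]} samples is shorter than one "
                f"epoch of {n_per} samples"
            )
        for start in range(0, seg.shape[1] - n_per + 1, step):
            epochs.append(seg[:, start : start + n_per])
            ep_labels.append(labels[i])
            ep_blocks.append(block_ids[i])

    data = np.stack(epochs)
    if channel_names is None:
        channel_names = [f"ch{i:02d}" for i in range(data.shape[1])]
    return EpochedEEG(
        data=data,
        fs=fs,
        channel_names=channel_names,
        labels=np.asarray(ep_labels),
        block_ids=np.asarray(ep_blocks),
    )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _butter_sos(band: BandDefinition, fs: float, order: int = 4):
    band.validate(fs)
    return sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, band: BandDefinition, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    sos = _butter_sos(band, fs, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def notch(x: np.ndarray, fs: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (mains-hum removal) along the last axis."""
    if not (0 < freq < fs / 2):
        raise ValueError(f"notch frequency {freq} Hz must lie in (0, {fs / 2}) Hz")
    b, a = sps.iirnotch(freq, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# differential entropy
# ---------------------------------------------------------------------------

_HALF_LOG_2PIE = 0.5 * math.log(2.0 * math.pi * math.e)


def de_gaussian(variance: float | np.ndarray) -> float | np.ndarray:
    """Differential entropy of N(mu, variance): ``0.5 * ln(2*pi*e*var)`` nats."""
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be positive (degenerate epoch)")
    out = _HALF_LOG_2PIE + 0.5 * np.log(variance)
    return float(out) if out.ndim == 0 else out


def extract_band_de(
    eeg: EpochedEEG,
    bands: list[BandDefinition] | tuple[BandDefinition, ...] = DEFAULT_BANDS,
    estimator: str = "variance",
) -> BandDEFeatures:
    """Per-epoch, per-channel, per-band differential entropy.

    ``variance``: band-pass each epoch and apply the Gaussian closed form to
    its unbiased sample variance.  ``spectrum``: half the log of the mean
    in-band periodogram power (the log-energy-spectrum equivalent, offset by
    an additive constant from the variance estimator).
    """
    if estimator not in ("variance", "spectrum"):
        raise ValueError(f"unknown DE estimator {estimator!r}")
    bands = list(bands)
    for b in bands:
        b.validate(eeg.fs)

    raw_var = eeg.data.var(axis=-1)
    if np.any(raw_var == 0):
        e, c = np.argwhere(raw_var == 0)[0]
        raise ValueError(f"zero-variance epoch: epoch {e}, channel {c}")

    n_e, n_c = eeg.n_epochs, eeg.n_channels
    values = np.empty((n_e, n_c, len(bands)))
    if estimator == "variance":
        for j, band in enumerate(bands):
            filtered = bandpass(eeg.data, eeg.fs, band)  # vectorized over epochs/channels
            var = filtered.var(axis=-1, ddof=1)
            if np.any(var <= 0):
                e, c = np.argwhere(var <= 0)[0]
                raise ValueError(
                    f"zero-variance epoch: epoch {e}, channel {c}, band {band.name}"
                )
            values[:, :, j] = de_gaussian(var)
    else:
        freqs, psd = sps.periodogram(eeg.data, fs=eeg.fs, window="hann", axis=-1)
        for j, band in enumerate(bands):
            sel = (freqs >= band.low) & (freqs <= band.high)
            power = psd[:, :, sel].mean(axis=-1)
            if np.any(power <= 0):
                e, c = np.argwhere(power <= 0)[0]
                raise ValueError(
                    f"zero in-band power: epoch {e}, channel {c}, band {band.name}"
                )
            values[:, :, j] = 0.5 * np.log(power)

    return BandDEFeatures(
        values=values,
        bands=bands,
        labels=eeg.labels,
        block_ids=eeg.block_ids,
        channel_names=list(eeg.channel_names),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_edf(path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF recording -> (channels x samples, fs, labels)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"]), list(raw.ch_names)


def save_epochs_h5(eeg: EpochedEEG, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=eeg.data)
        f.create_dataset("labels", data=eeg.labels)
        f.create_dataset("block_ids", data=eeg.block_ids)
        f.attrs["fs"] = eeg.fs
        f.attrs["channel_names"] = [str(c) for c in eeg.channel_names]


def load_epochs_h5(path: str) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        return EpochedEEG(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            labels=f["labels"][()],
            block_ids=f["block_ids"][()],
        )


def save_de_h5(de: BandDEFeatures, path: str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=de.values)
        f.create_dataset("labels", data=de.labels)
        f.create_dataset("block_ids", data=de.block_ids)
        f.attrs["channel_names"] = [str(c) for c in de.channel_names]
        f.attrs["band_names"] = [b.name for b in de.bands]
        f.attrs["band_edges"] = np.array([[b.low, b.high] for b in de.bands])


def load_de_h5(path: str) -> BandDEFeatures:
    with h5py.File(path, "r") as f:
        names = [str(n) for n in f.attrs["band_names"]]
        edges = np.asarray(f.attrs["band_edges"], dtype=float)
        bands = [BandDefinition(n, lo, hi) for n, (lo, hi) in zip(names, edges)]
        return BandDEFeatures(
            values=f["data"][()],
            bands=bands,
            labels=f["labels"][()],
            block_ids=f["block_ids"][()],
            channel_names=[str(c) for c in f.attrs["channel_names"]],
        )


def de_to_table(de: BandDEFeatures) -> tuple[np.ndarray, list[str]]:
    """Flattened DE matrix plus ``channel_band`` column headers for text export."""
    headers = [
        f"{ch}_{b.name}" for ch in de.channel_names for b in de.bands
    ]
    return de.flattened(), headers
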