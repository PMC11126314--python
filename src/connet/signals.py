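"""Ingestion, channel-label parsing, filtering and epoching of multichannel iEEG.

Recordings are held as a channels x samples float array (microvolts) plus an
ordered list of :class:`ChannelInfo`.  All cleaning steps operate on the
machine-referenced data before any montage transformation.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

logger = logging.getLogger("connet")

HEMISPHERES = ("L", "R", "unknown")
TISSUES = ("grey", "white", "csf", "unknown")

_LABEL_RE = re.compile(r"^(\D+?)[\s\-]*(\d+)\s*$")


class LabelError(ValueError):
    """Raised when a channel label cannot be parsed into electrode + contact."""


class ConfigError(ValueError):
    """Raised for infeasible filter or selection settings."""


class SelectionError(RuntimeError):
    """Raised when not enough data is available to draw the requested epochs."""


def parse_channel_label(label: str) -> tuple[str, int]:
    """Split an iEEG channel label into (electrode, contact_index).

    The electrode name is the maximal leading non-numeric prefix, with
    whitespace and hyphens stripped; the contact index is the trailing
    integer (``"LA01"`` and ``"LA1"`` both map to ``("LA", 1)``).
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise LabelError(f"channel label {label!r} has no trailing contact number")
    electrode = re.sub(r"[\s\-]+", "", m.group(1))
    return electrode, int(m.group(2))


def format_channel_label(electrode: str, contact_index: int) -> str:
    """Canonical label: electrode prefix + 2-digit zero-padded contact."""
    return f"{electrode}{contact_index:02d}"


@dataclass
class ChannelInfo:
    """Metadata for one recording contact."""

    label: str
    electrode: str
    contact_index: int
    hemisphere: str = "unknown"
    tissue: str = "unknown"
    retained: bool = True

    @classmethod
    def from_label(cls, label: str, tissue: str = "unknown",
                   hemisphere: str | None = None) -> "ChannelInfo":
        electrode, idx = parse_channel_label(label)
        if hemisphere is None:
            hemisphere = electrode[0] if electrode[:1] in ("L", "R") else "unknown"
        return cls(label=label, electrode=electrode, contact_index=idx,
                   hemisphere=hemisphere, tissue=tissue)

    def copy(self) -> "ChannelInfo":
        return replace(self)


@dataclass
class Recording:
    """A channels x samples voltage matrix with metadata.

    ``scheme`` tracks the referencing state (machine on ingest, then car or
    bipolar after montage transformation).  ``epoch_start`` is the start time
    in seconds (seconds-of-day for clock-windowed epoch selection).
    """

    data: np.ndarray
    fs: float
    channels: list[ChannelInfo]
    scheme: str = "machine"
    epoch_start: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def retained_mask(self) -> np.ndarray:
        return np.array([c.retained for c in self.channels], dtype=bool)

    def with_data(self, data: np.ndarray, scheme: str | None = None,
                  channels: list[ChannelInfo] | None = None) -> "Recording":
        return Recording(data=data, fs=self.fs,
                         channels=self.channels if channels is None else channels,
                         scheme=self.scheme if scheme is None else scheme,
                         epoch_start=self.epoch_start)


@dataclass
class EpochSet:
    """Equal-length epochs sharing one channel list (the ChannelInfo objects
    are shared between epochs so retention flags stay in sync)."""

    epochs: list[Recording]
    epoch_length_s: float = 120.0

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("EpochSet needs at least one epoch")
        labels0 = self.epochs[0].labels
        fs0 = self.epochs[0].fs
        for ep in self.epochs[1:]:
            if ep.labels != labels0 or ep.fs != fs0:
                raise ValueError("epochs must share channel list and sampling rate")

    @property
    def channels(self) -> list[ChannelInfo]:
        return self.epochs[0].channels

    @property
    def fs(self) -> float:
        return self.epochs[0].fs


def screen_tissue(channels: list[ChannelInfo]) -> int:
    """Drop CSF-localized contacts (retained=False). Returns number dropped."""
    n = 0
    for ch in channels:
        if ch.tissue == "csf" and ch.retained:
            ch.retained = False
            n += 1
    if n:
        logger.info("screen_tissue: %d CSF contact(s) excluded", n)
    return n


# --------------------------------------------------------------------------
# Filtering
# --------------------------------------------------------------------------

def _notch_sos(fs: float, freq_hz: float, bandwidth_hz: float = 2.0) -> np.ndarray:
    # 2nd-order Butterworth band-stop -> 4th-order IIR (two biquads)
    return scipy.signal.butter(
        2, [freq_hz - bandwidth_hz / 2, freq_hz + bandwidth_hz / 2],
        btype="bandstop", fs=fs, output="sos")


def notch_filter(rec: Recording, freq_hz: float = 60.0, order: int = 4,
                 bandwidth_hz: float = 2.0) -> Recording:
    """Zero-phase 4th-order IIR notch (power-line removal).

    Realized as a 2nd-order Butterworth band-stop (two second-order sections,
    i.e. a 4th-order transfer function) applied forward-backward so the
    montage sees no phase distortion.
    """
    if order != 4:
        raise ConfigError("only the 4th-order notch realization is provided")
    if freq_hz >= rec.fs / 2:
        raise ConfigError(
            f"notch frequency {freq_hz} Hz is at/above Nyquist ({rec.fs / 2} Hz)")
    sos = _notch_sos(rec.fs, freq_hz, bandwidth_hz)
    return rec.with_data(scipy.signal.sosfiltfilt(sos, rec.data, axis=-1))


def bandpass_array(data: np.ndarray, fs: float, low: float, high: float,
                   order: int = 4, warn_clip: bool = True) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass on the last axis.

    An upper edge at or above Nyquist is clipped to 0.9 * Nyquist (with a
    warning) so that e.g. a ripple band request survives a 256 Hz recording.
    """
    if low >= fs / 2:
        raise ConfigError(f"band low edge {low} Hz is not below Nyquist ({fs / 2} Hz)")
    nyq = fs / 2
    if high >= nyq:
        high_clipped = 0.9 * nyq
        if warn_clip:
            msg = (f"band upper edge {high} Hz >= Nyquist {nyq} Hz; "
                   f"clipped to {high_clipped} Hz")
            logger.warning(msg)
            warnings.warn(msg, UserWarning, stacklevel=2)
        high = high_clipped
    if low >= high:
        raise ConfigError(f"band ({low}, {high}) is empty after clipping")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, data, axis=-1)


def bandpass_filter(rec: Recording, band) -> Recording:
    """Band-limit a recording to ``band`` (an object with .low/.high in Hz)."""
    return rec.with_data(bandpass_array(rec.data, rec.fs, band.low, band.high))


# --------------------------------------------------------------------------
# Epoch selection
# --------------------------------------------------------------------------

def select_epochs(rec: Recording, n_epochs: int = 5, epoch_s: float = 120.0,
                  window: tuple[float, float] = (13 * 3600.0, 15 * 3600.0),
                  seed: int | None = None, max_tries: int = 10000) -> EpochSet:
    """Draw non-overlapping epochs uniformly at random inside a clock window.

    ``rec.epoch_start`` gives the recording's start in seconds-of-day; only
    the part of the recording inside the half-open ``window`` (default
    13:00-15:00) is eligible.  Placement is rejection-sampled uniformly over
    feasible non-overlapping start times, reproducible from ``seed``.
    """
    if seed is None:
        raise ConfigError("select_epochs requires an explicit seed")
    t0 = max(rec.epoch_start, window[0])
    t1 = min(rec.epoch_start + rec.duration_s, window[1])
    avail = t1 - t0
    if avail < n_epochs * epoch_s:
        raise SelectionError(
            f"cannot place {n_epochs} epochs of {epoch_s} s: only {max(avail, 0):.1f} s "
            f"available in window [{window[0]}, {window[1]}) "
            f"(recording spans [{rec.epoch_start}, {rec.epoch_start + rec.duration_s}))")
    rng = np.random.default_rng(seed)
    span = avail - epoch_s
    for _ in range(max_tries):
        starts = np.sort(rng.uniform(0.0, span, size=n_epochs))
        if np.all(np.diff(starts) >= epoch_s):
            break
    else:  # dense case: fall back to shuffled placement on the slack
        slack = avail - n_epochs * epoch_s
        cuts = np.sort(rng.uniform(0.0, slack, size=n_epochs))
        starts = cuts + np.arange(n_epochs) * epoch_s
    n_per = int(round(epoch_s * rec.fs))
    epochs = []
    for s in starts:
        i0 = int(round((t0 - rec.epoch_start + s) * rec.fs))
        ep = Recording(data=rec.data[:, i0:i0 + n_per].copy(), fs=rec.fs,
                       channels=rec.channels, scheme=rec.scheme,
                       epoch_start=t0 + s)
        epochs.append(ep)
    return EpochSet(epochs=epochs, epoch_length_s=epoch_s)


# --------------------------------------------------------------------------
# Artifact-channel rejection
# --------------------------------------------------------------------------

def _line_power_ratio(x: np.ndarray, fs: float, line_hz: float = 60.0,
                      half_width_hz: float = 2.0) -> np.ndarray:
    """Power in the line band divided by total broadband power, per channel."""
    nper = min(x.shape[-1], int(4 * fs))
    f, pxx = scipy.signal.welch(x, fs=fs, nperseg=nper, axis=-1)
    inband = (f >= line_hz - half_width_hz) & (f <= line_hz + half_width_hz)
    total = pxx.sum(axis=-1)
    total = np.where(total > 0, total, np.inf)
    return pxx[..., inband].sum(axis=-1) / total


def reject_artifact_channels(es: EpochSet, amp_thresh_uv: float = 500.0,
                             line_ratio_thresh: float = 0.5,
                             max_amp_fraction: float = 0.01) -> EpochSet:
    """Flag channels with overwhelming noise as not retained.

    Two rules, evaluated over all epochs pooled:
      * amplitude — |x| exceeds ``amp_thresh_uv`` in more than
        ``max_amp_fraction`` of samples;
      * line noise — 60 Hz-band power exceeds ``line_ratio_thresh`` times the
        broadband power.
    """
    if amp_thresh_uv <= 0 or line_ratio_thresh <= 0:
        raise ConfigError("artifact thresholds must be positive")
    pooled = np.concatenate([ep.data for ep in es.epochs], axis=1)
    amp_frac = np.mean(np.abs(pooled) > amp_thresh_uv, axis=1)
    line_ratio = _line_power_ratio(pooled, es.fs)
    n_amp = n_line = 0
    for i, ch in enumerate(es.channels):
        if not ch.retained:
            continue
        if amp_frac[i] > max_amp_fraction:
            ch.retained = False
            n_amp += 1
        elif line_ratio[i] > line_ratio_thresh:
            ch.retained = False
            n_line += 1
    logger.info("reject_artifact_channels: %d by amplitude (>%g uV in >%g%% of "
                "samples), %d by line ratio (>%g)", n_amp, amp_thresh_uv,
                100 * max_amp_fraction, n_line, line_ratio_thresh)
    if not any(c.retained for c in es.channels):
        warnings.warn("all channels rejected", UserWarning, stacklevel=2)
    return es


# --------------------------------------------------------------------------
# Readers / writers
# --------------------------------------------------------------------------

def read_channel_metadata(path) -> list[ChannelInfo]:
    """Read a sidecar channel table (CSV: label, electrode, contact,
    hemisphere, tissue); missing columns are derived from the label."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        label = str(row["label"])
        ch = ChannelInfo.from_label(
            label,
            tissue=str(row["tissue"]) if "tissue" in df.columns else "unknown",
            hemisphere=str(row["hemisphere"]) if "hemisphere" in df.columns else None,
        )
        if "electrode" in df.columns and not pd.isna(row["electrode"]):
            ch.electrode = str(row["electrode"])
        if "contact" in df.columns and not pd.isna(row["contact"]):
            ch.contact_index = int(row["contact"])
        out.append(ch)
    return out


def read_edf(path, meta_csv=None) -> Recording:
    """Read an EDF file into a machine-referenced Recording (labels from the
    EDF header unless a metadata CSV is given). Voltages are in microvolts."""
    import mne  # deferred: heavy import

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    if meta_csv is not None:
        channels = read_channel_metadata(meta_csv)
        if len(channels) != data.shape[0]:
            raise ValueError("metadata row count does not match EDF channel count")
    else:
        channels = [ChannelInfo.from_label(lbl) for lbl in raw.ch_names]
    return Recording(data=data, fs=float(raw.info["sfreq"]), channels=channels)


def read_array(npy_path, meta_csv, fs: float, epoch_start: float = 0.0) -> Recording:
    """Read the plain array container (``.npy`` matrix + metadata CSV)."""
    data = np.load(npy_path)
    channels = read_channel_metadata(meta_csv)
    return Recording(data=data, fs=fs, channels=channels,
                     epoch_start=epoch_start)


def write_array(rec: Recording, prefix) -> None:
    """Write ``<prefix>.npy`` + ``<prefix>_channels.csv``."""
    np.save(f"{prefix}.npy", rec.data)
    pd.DataFrame(
        {"label": [c.label for c in rec.channels],
         "electrode": [c.electrode for c in rec.channels],
         "contact": [c.contact_index for c in rec.channels],
         "hemisphere": [c.hemisphere for c in rec.channels],
         "tissue": [c.tissue for c in rec.channels],
         "retained": [c.retained for c in rec.channels]}
    ).to_csv(f"{prefix}_channels.csv", index=False)
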