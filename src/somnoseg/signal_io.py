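"""PSG signal containers, EDF I/O and the preprocessing chain.

A :class:`PsgRecord` holds named channels (microvolt samples + sampling
rate) together with the offset of its first sample from the recording
origin, so that annotation times remain alignable after trimming.

The preprocessing chain applied before segmentation is::

    derive -> bandpass (0.3-35 Hz) -> resample to 128 Hz -> robust clip
           -> robust normalize -> trim to the scored region

All times are seconds from the recording start; intervals are half-open
``[onset, offset)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

TARGET_FS = 128.0
#: default band edges (Hz) of the pre-segmentation band-pass
BAND_LOW_HZ = 0.3
BAND_HIGH_HZ = 35.0
#: default clipping constant: samples outside median +/- k*IQR are clipped
CLIP_K = 20.0


@dataclass(frozen=True)
class Channel:
    """One named signal: samples (µV) at a fixed sampling rate (Hz)."""

    name: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ContractError(f"channel {self.name!r}: fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class PsgRecord:
    """A set of channels spanning the same time window.

    ``start_offset_s`` is the time of the first sample relative to the
    recording origin (it becomes nonzero after trimming).
    """

    channels: tuple[Channel, ...]
    start_offset_s: float = 0.0

    def __post_init__(self) -> None:
        chans = tuple(self.channels)
        if not chans:
            raise FormatError("PsgRecord requires at least one channel")
        object.__setattr__(self, "channels", chans)
        durations = [c.duration_s for c in chans]
        tol = max(1.0 / c.fs for c in chans)
        if max(durations) - min(durations) > tol + 1e-9:
            raise ContractError(
                "channel durations differ by more than one sample period: "
                f"{dict((c.name, c.duration_s) for c in chans)}"
            )

    @property
    def duration_s(self) -> float:
        return max(c.duration_s for c in self.channels)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def channel(self, name: str) -> Channel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}; have {self.channel_names}")

    def with_channels(self, channels) -> "PsgRecord":
        return PsgRecord(tuple(channels), self.start_offset_s)


@dataclass(frozen=True)
class ScoredRegion:
    """Half-open manually scored window ``[onset_s, offset_s)``."""

    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ContractError(
                f"need 0 <= onset < offset, got [{self.onset_s}, {self.offset_s})"
            )


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def read_edf(path, return_annotations: bool = False):
    """Read an EDF/EDF+ file into a :class:`PsgRecord`.

    Samples are returned in microvolts (volt-scaled EDF physical
    dimensions are assumed). Files whose channels carry different native
    rates are returned at the unified rate chosen by the reader backend.
    When ``return_annotations`` is true, EDF+ annotations are returned
    separately as a list of ``(onset_s, duration_s, description)``.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"could not read EDF file {path}: {exc}") from exc
    if len(raw.ch_names) == 0:
        raise FormatError(f"EDF file {path} contains zero signal channels")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    record = PsgRecord(
        tuple(Channel(name, data[i], fs) for i, name in enumerate(raw.ch_names))
    )
    if return_annotations:
        ann = [
            (float(o), float(d), str(desc))
            for o, d, desc in zip(
                raw.annotations.onset, raw.annotations.duration,
                raw.annotations.description,
            )
        ]
        return record, ann
    return record


def write_edf(record: PsgRecord, path) -> None:
    """Write a :class:`PsgRecord` as a plain 16-bit EDF file.

    All channels must share one integer sampling rate and an integer
    number of seconds (one EDF data record per second). Physical
    dimension is microvolts; amplitudes are quantized to the per-channel
    peak range, so round-tripping is exact only up to 16-bit resolution.
    """
    path = Path(path)
    fs_set = {c.fs for c in record.channels}
    if len(fs_set) != 1:
        raise ContractError("EDF writer requires a single sampling rate")
    fs = fs_set.pop()
    if fs != int(fs):
        raise ContractError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(fs)
    n = record.channels[0].samples.size
    if n % fs != 0:
        raise ContractError("EDF writer requires an integer number of seconds")
    n_records = n // fs
    ns = len(record.channels)

    def _f(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        _f("0", 8), _f("X", 80), _f("somnoseg", 80),
        _f("01.01.00", 8), _f("00.00.00", 8),
        _f(256 * (ns + 1), 8), _f("", 44), _f(n_records, 8), _f(1, 8), _f(ns, 4),
    ])
    phys_ranges = []
    for c in record.channels:
        peak = float(np.max(np.abs(c.samples))) if c.samples.size else 0.0
        peak = peak if peak > 0 else 1.0
        phys_ranges.append(peak)
    fields = []
    for getter, width in [
        (lambda i, c: c.name, 16), (lambda i, c: "", 80), (lambda i, c: "uV", 8),
        (lambda i, c: f"{-phys_ranges[i]:.6g}"[:8], 8),
        (lambda i, c: f"{phys_ranges[i]:.6g}"[:8], 8),
        (lambda i, c: -32767, 8), (lambda i, c: 32767, 8),
        (lambda i, c: "", 80), (lambda i, c: fs, 8), (lambda i, c: "", 32),
    ]:
        for i, c in enumerate(record.channels):
            fields.append(_f(getter(i, c), width))
    header += b"".join(fields)

    digital = np.empty((ns, n), dtype="<i2")
    for i, c in enumerate(record.channels):
        # phys range as parsed back from the truncated ASCII field
        pr = float(f"{phys_ranges[i]:.6g}"[:8])
        scaled = np.clip(c.samples / pr, -1.0, 1.0) * 32767.0
        digital[i] = np.round(scaled).astype("<i2")
    # interleave per-second data records: [ch0 sec0, ch1 sec0, ..., ch0 sec1, ...]
    blocks = digital.reshape(ns, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(blocks.tobytes())


def read_scored_region(path) -> ScoredRegion:
    """Read a one-line tab-separated ``onset_s<TAB>offset_s`` file."""
    text = Path(path).read_text().strip()
    parts = text.split("\t")
    if len(parts) != 2:
        raise FormatError(f"{path}: expected one line 'onset_s<TAB>offset_s'")
    return ScoredRegion(float(parts[0]), float(parts[1]))


def save_record_hdf5(record: PsgRecord, path) -> None:
    """Persist a preprocessed record to HDF5 (one dataset per channel)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["start_offset_s"] = record.start_offset_s
        for i, c in enumerate(record.channels):
            ds = fh.create_dataset(f"ch{i:03d}", data=c.samples)
            ds.attrs["name"] = c.name
            ds.attrs["fs"] = c.fs


def load_record_hdf5(path) -> PsgRecord:
    with h5py.File(path, "r") as fh:
        keys = sorted(k for k in fh.keys() if k.startswith("ch"))
        channels = tuple(
            Channel(fh[k].attrs["name"], fh[k][...], float(fh[k].attrs["fs"]))
            for k in keys
        )
        return PsgRecord(channels, float(fh.attrs["start_offset_s"]))


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def derive_channel(record: PsgRecord, active: str, reference: str,
                   name: str | None = None) -> Channel:
    """Referential derivation ``active - reference`` (e.g. C4-M1)."""
    a, r = record.channel(active), record.channel(reference)
    if a.fs != r.fs:
        raise ContractError(
            f"cannot derive {active}-{reference}: fs {a.fs} != {r.fs}"
        )
    n = min(a.samples.size, r.samples.size)
    return Channel(name or f"{active}-{reference}", a.samples[:n] - r.samples[:n], a.fs)


def bandpass(channel: Channel, low_hz: float = BAND_LOW_HZ,
             high_hz: float = BAND_HIGH_HZ, order: int = 4) -> Channel:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    if high_hz >= channel.fs / 2:
        raise ContractError(
            f"high cutoff {high_hz} Hz must be below Nyquist ({channel.fs / 2} Hz)"
        )
    if channel.samples.size == 0:
        return channel
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=channel.fs,
                     output="sos")
    # even-reflection padding sized for the slow 0.3 Hz edge; the default
    # (short, odd) padding leaves visible edge transients
    padlen = min(channel.samples.size - 1, int(3 * channel.fs / low_hz))
    return replace(channel,
                   samples=sps.sosfiltfilt(sos, channel.samples,
                                           padtype="even", padlen=padlen))


def resample_to_128(channel: Channel, target_fs: float = TARGET_FS) -> Channel:
    """Polyphase resampling to the model rate (identity if already there)."""
    if channel.fs == target_fs:
        return channel
    ratio = Fraction(target_fs / channel.fs).limit_denominator(10000)
    out = sps.resample_poly(channel.samples, ratio.numerator, ratio.denominator)
    return Channel(channel.name, out, target_fs)


def robust_clip(channel: Channel, k: float = CLIP_K) -> Channel:
    """Clip samples to ``median +/- k*IQR`` (order statistics over the
    whole channel). Constant channels (IQR = 0) pass through unchanged."""
    x = channel.samples
    if x.size == 0:
        raise ContractError("robust_clip requires a nonempty channel")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        logger.warning("robust_clip: channel %r has zero IQR, left unchanged",
                       channel.name)
        return channel
    return replace(channel, samples=np.clip(x, med - k * iqr, med + k * iqr))


def normalize(channel: Channel) -> Channel:
    """Robust scaling: subtract median, divide by IQR.

    Falls back to the standard deviation when the IQR is zero, and to a
    unit divisor when the SD is also zero (constant channel -> zeros).
    """
    x = channel.samples
    if x.size == 0:
        raise ContractError("normalize requires a nonempty channel")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    scale = q3 - q1
    if scale == 0:
        scale = float(np.std(x))
    if scale == 0:
        scale = 1.0
    return replace(channel, samples=(x - med) / scale)


def trim_to_scored(record: PsgRecord, region: ScoredRegion) -> PsgRecord:
    """Cut all channels to the scored window ``[onset, offset)``.

    ``start_offset_s`` is advanced by the onset so annotation times stay
    alignable with the trimmed record.
    """
    if region.offset_s > record.duration_s + 1e-9:
        raise ContractError(
            f"scored region [{region.onset_s}, {region.offset_s}) extends past "
            f"the {record.duration_s} s recording"
        )
    channels = []
    for c in record.channels:
        i0 = int(round(region.onset_s * c.fs))
        i1 = int(round(region.offset_s * c.fs))
        channels.append(replace(c, samples=c.samples[i0:i1]))
    return PsgRecord(tuple(channels), record.start_offset_s + region.onset_s)


class PsgPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the full preprocessing chain.

    Parameters
    ----------
    derivations : list of (active, reference) channel-name pairs, or None
        Referential montages to construct first; when None the record's
        existing channels are used as-is.
    low_hz, high_hz : float
        Band-pass edges in Hz.
    target_fs : float
        Output sampling rate (polyphase resampling).
    clip_k : float
        Robust clipping constant (median +/- clip_k * IQR).
    """

    def __init__(self, derivations=None, low_hz: float = BAND_LOW_HZ,
                 high_hz: float = BAND_HIGH_HZ, target_fs: float = TARGET_FS,
                 clip_k: float = CLIP_K):
        self.derivations = derivations
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.target_fs = target_fs
        self.clip_k = clip_k

    def fit(self, X=None, y=None):
        return self

    def transform_record(self, record: PsgRecord,
                         region: ScoredRegion | None = None) -> PsgRecord:
        """Preprocess one record; ``region`` trims to the scored window."""
        if self.derivations:
            chans = [derive_channel(record, a, r) for a, r in self.derivations]
        else:
            chans = list(record.channels)
        chans = [bandpass(c, self.low_hz, self.high_hz) for c in chans]
        chans = [resample_to_128(c, self.target_fs) for c in chans]
        chans = [robust_clip(c, self.clip_k) for c in chans]
        chans = [normalize(c) for c in chans]
        out = record.with_channels(chans)
        if region is not None:
            out = trim_to_scored(out, region)
        return out

    def transform(self, X, regions=None):
        """Preprocess a sequence of records (optionally paired with regions)."""
        if regions is None:
            regions = [None] * len(X)
        return [self.transform_record(rec, reg) for rec, reg in zip(X, regions)]
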