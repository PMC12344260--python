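"""EDF input/output and epoch segmentation.

Scalp EEG arrives as continuous European Data Format (EDF / EDF+C) files:
a fixed-layout ASCII header, per-signal calibration (physical and digital
ranges), and interleaved little-endian 16-bit data records.  This module
reads such files into a :class:`Recording` (samples in microvolts), writes
them back, and cuts a recording into the fixed-length epochs (default 10 s)
on which the codec operates.

Only continuous recordings with a single shared sampling rate are handled;
the codec treats the referential montage as stored and never re-montages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np

from .exceptions import (
    DataError,
    FormatError,
    ParameterError,
    ShapeError,
    UnsupportedFormatError,
)

logger = logging.getLogger(__name__)

DEFAULT_EPOCH_SECONDS = 10.0

_ANNOTATION_LABEL = "EDF Annotations"


@dataclass
class Recording:
    """A continuous multichannel recording in physical units (microvolts).

    Parameters
    ----------
    data : ndarray, shape (m, n)
        One row per channel, samples in microvolts.
    fs : float
        Sampling rate in Hz, shared by all channels.
    channel_labels : list of str
        Ordered channel names (10-20 convention when applicable).
    start_time : datetime
        Recording start.
    physical_range : ndarray, shape (m, 2)
        Per-channel (physical_min, physical_max) in microvolts.
    digital_range : ndarray, shape (m, 2)
        Per-channel integer (digital_min, digital_max).
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: datetime = field(default_factory=lambda: datetime(2000, 1, 1))
    physical_range: np.ndarray | None = None
    digital_range: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError("recording data must be 2-D (channels x samples)")
        m, n = self.data.shape
        if n == 0:
            raise DataError("recording has zero length")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != m:
            raise ShapeError(
                f"{len(self.channel_labels)} labels for {m} channels"
            )
        if self.physical_range is None:
            self.physical_range = np.tile([-1000.0, 1000.0], (m, 1))
        self.physical_range = np.asarray(self.physical_range, dtype=np.float64)
        if self.digital_range is None:
            self.digital_range = np.tile([-32768, 32767], (m, 1))
        self.digital_range = np.asarray(self.digital_range, dtype=np.int64)
        if self.physical_range.shape != (m, 2) or self.digital_range.shape != (m, 2):
            raise ShapeError("calibration ranges must have shape (m, 2)")
        if np.any(self.physical_range[:, 0] >= self.physical_range[:, 1]):
            raise DataError("physical_min must be < physical_max for every channel")
        if np.any(self.digital_range[:, 0] >= self.digital_range[:, 1]):
            raise DataError("digital_min must be < digital_max for every channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def quantization_step(self) -> np.ndarray:
        """Physical size of one digital step, per channel (microvolts)."""
        pr = self.physical_range
        dr = self.digital_range
        return (pr[:, 1] - pr[:, 0]) / (dr[:, 1] - dr[:, 0])


@dataclass
class EpochMatrix:
    """One fixed-length page of referential EEG: an m x n matrix in microvolts."""

    data: np.ndarray
    fs: float
    epoch_index: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError("epoch must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise DataError("an epoch needs at least 2 channels")
        if not np.all(np.isfinite(self.data)):
            raise DataError("epoch contains non-finite samples")

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# EDF reading / writing
# ---------------------------------------------------------------------------

def _ascii(field_bytes: bytes) -> str:
    return field_bytes.decode("ascii", errors="replace").strip()


def _fixed(text: str, width: int) -> bytes:
    """Render ``text`` into a fixed-width ASCII field (EDF headers)."""
    s = text[:width]
    return s.ljust(width).encode("ascii")


def _fmt_float(value: float, width: int = 8) -> bytes:
    """Format a float into EDF's 8-char numeric field."""
    for spec in (f"{value:.10g}", f"{value:.6g}", f"{value:.4g}", f"{value:.2g}"):
        if len(spec) <= width:
            return spec.ljust(width).encode("ascii")
    raise FormatError(f"cannot format {value!r} into {width} chars")


def read_edf(path, channels: list[str] | None = None) -> Recording:
    """Read a continuous EDF or EDF+C file into a :class:`Recording`.

    Samples are rescaled to physical units using the header's
    physical/digital calibration; channel order is preserved as stored.
    ``channels`` optionally selects a subset by label (clinical files often
    carry non-EEG channels such as ECG; inclusion is left to the caller).
    An annotation channel ("EDF Annotations") is dropped automatically.

    Raises
    ------
    FormatError
        Malformed or truncated header.
    UnsupportedFormatError
        Discontinuous EDF+D files, or mixed per-channel sampling rates.
    """
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: file shorter than an EDF header")
        try:
            reserved = _ascii(fixed[192:236])
            n_records = int(_ascii(fixed[236:244]))
            record_dur = float(_ascii(fixed[244:252]))
            ns = int(_ascii(fixed[252:256]))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF header ({exc})") from exc
        if reserved.startswith("EDF+D"):
            raise UnsupportedFormatError(
                f"{path}: discontinuous EDF+D is not supported"
            )
        if ns <= 0 or n_records < 0 or record_dur <= 0:
            raise FormatError(f"{path}: implausible EDF header fields")

        try:
            start = datetime.strptime(
                _ascii(fixed[168:176]) + " " + _ascii(fixed[176:184]),
                "%d.%m.%y %H.%M.%S",
            )
        except ValueError:
            start = datetime(2000, 1, 1)
            logger.warning("%s: unparseable start date/time; using placeholder", path)

        sig = fh.read(ns * 256)
        if len(sig) < ns * 256:
            raise FormatError(f"{path}: truncated signal header")

        def col(offset, width):
            return [
                _ascii(sig[offset * ns + i * width : offset * ns + (i + 1) * width])
                for i in range(ns)
            ]

        labels = col(0, 16)
        try:
            pmin = [float(x) for x in col(16 + 80 + 8, 8)]
            pmax = [float(x) for x in col(16 + 80 + 8 + 8, 8)]
            dmin = [int(float(x)) for x in col(16 + 80 + 8 + 16, 8)]
            dmax = [int(float(x)) for x in col(16 + 80 + 8 + 24, 8)]
            spr = [int(x) for x in col(16 + 80 + 8 + 32 + 80, 8)]
        except ValueError as exc:
            raise FormatError(f"{path}: malformed signal header ({exc})") from exc

        raw = np.frombuffer(fh.read(), dtype="<i2")

    expected = n_records * sum(spr)
    if raw.size < expected:
        raise FormatError(
            f"{path}: data section has {raw.size} samples, header promises {expected}"
        )
    raw = raw[:expected].reshape(n_records, sum(spr))

    keep = [i for i, lab in enumerate(labels) if lab != _ANNOTATION_LABEL]
    if len(keep) < len(labels):
        logger.info("%s: dropping annotation channel", path)
    if channels is not None:
        wanted = set(channels)
        keep = [i for i in keep if labels[i] in wanted]
        missing = wanted - {labels[i] for i in keep}
        if missing:
            raise ParameterError(f"channels not in file: {sorted(missing)}")
    if not keep:
        raise FormatError(f"{path}: no data channels")

    rates = {spr[i] / record_dur for i in keep}
    if len(rates) != 1:
        raise UnsupportedFormatError(
            f"{path}: channels have differing sampling rates {sorted(rates)}"
        )
    fs = rates.pop()

    offsets = np.concatenate([[0], np.cumsum(spr)])
    m = len(keep)
    n = n_records * spr[keep[0]]
    data = np.empty((m, n), dtype=np.float64)
    for row, i in enumerate(keep):
        dig = raw[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        data[row] = (dig - dmin[i]) * gain + pmin[i]

    return Recording(
        data=data,
        fs=fs,
        channel_labels=[labels[i] for i in keep],
        start_time=start,
        physical_range=np.array([[pmin[i], pmax[i]] for i in keep]),
        digital_range=np.array([[dmin[i], dmax[i]] for i in keep]),
    )


def write_edf(recording: Recording, path) -> None:
    """Write a :class:`Recording` as a plain continuous 16-bit EDF file.

    Samples outside a channel's physical range are clipped to that range
    with a warning.  Labels longer than EDF's 16-character field are
    truncated with a warning, never an error.  One data record spans one
    second; a trailing fraction of a second is zero-padded (the epoch
    pipeline always produces whole-second recordings).
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    m = recording.n_channels

    data = recording.data
    pr = recording.physical_range
    low = pr[:, 0][:, None]
    high = pr[:, 1][:, None]
    if np.any(data < low) or np.any(data > high):
        n_clip = int(np.sum((data < low) | (data > high)))
        warnings.warn(
            f"{n_clip} samples outside the physical range were clipped",
            stacklevel=2,
        )
        logger.warning("write_edf: clipped %d out-of-range samples", n_clip)
        data = np.clip(data, low, high)

    n = data.shape[1]
    n_records = -(-n // spr)  # ceil
    if n_records * spr != n:
        warnings.warn(
            "recording length is not a whole number of seconds; "
            "final EDF record is zero-padded",
            stacklevel=2,
        )
        pad = np.zeros((m, n_records * spr - n))
        data = np.hstack([data, pad])

    labels = []
    for lab in recording.channel_labels:
        if len(lab) > 16:
            warnings.warn(f"channel label {lab!r} truncated to 16 chars", stacklevel=2)
        labels.append(lab[:16])

    dr = recording.digital_range
    gain = (dr[:, 1] - dr[:, 0]) / (pr[:, 1] - pr[:, 0])
    dig = np.rint((data - pr[:, 0][:, None]) * gain[:, None] + dr[:, 0][:, None])
    dig = np.clip(dig, dr[:, 0][:, None], dr[:, 1][:, None]).astype("<i2")

    start = recording.start_time
    header = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate X X X X", 80),
            _fixed(start.strftime("%d.%m.%y"), 8),
            _fixed(start.strftime("%H.%M.%S"), 8),
            _fixed(str(256 * (1 + m)), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed(str(m), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_fixed(lab, 16) for lab in labels),
            b"".join(_fixed("AgAgCl electrode", 80) for _ in range(m)),
            b"".join(_fixed("uV", 8) for _ in range(m)),
            b"".join(_fmt_float(pr[i, 0]) for i in range(m)),
            b"".join(_fmt_float(pr[i, 1]) for i in range(m)),
            b"".join(_fmt_float(float(dr[i, 0])) for i in range(m)),
            b"".join(_fmt_float(float(dr[i, 1])) for i in range(m)),
            b"".join(_fixed("", 80) for _ in range(m)),
            b"".join(_fixed(str(spr), 8) for _ in range(m)),
            b"".join(_fixed("", 32) for _ in range(m)),
        ]
    )

    # interleave: each record holds spr consecutive samples of every channel
    records = dig.reshape(m, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(records.tobytes())


# ---------------------------------------------------------------------------
# Epoch segmentation
# ---------------------------------------------------------------------------

def segment_epochs(
    recording: Recording, epoch_seconds: float = DEFAULT_EPOCH_SECONDS
) -> list[EpochMatrix]:
    """Cut a recording into consecutive non-overlapping epochs.

    A trailing partial epoch is dropped with a warning (padding would
    distort the epoch spectra the codec relies on).  Concatenating the
    returned epochs reproduces the retained prefix exactly.
    """
    if epoch_seconds <= 0:
        raise ParameterError("epoch_seconds must be positive")
    n_per = recording.fs * epoch_seconds
    if abs(n_per - round(n_per)) > 1e-9:
        raise ParameterError(
            f"fs * epoch_seconds = {n_per} is not an integer sample count"
        )
    n_per = int(round(n_per))
    n_epochs = recording.n_samples // n_per
    if n_epochs == 0:
        warnings.warn(
            "recording shorter than one epoch; returning no epochs", stacklevel=2
        )
        return []
    if n_epochs * n_per != recording.n_samples:
        dropped = recording.n_samples - n_epochs * n_per
        warnings.warn(
            f"dropping trailing partial epoch of {dropped} samples", stacklevel=2
        )
    return [
        EpochMatrix(
            data=recording.data[:, i * n_per : (i + 1) * n_per].copy(),
            fs=recording.fs,
            epoch_index=i,
        )
        for i in range(n_epochs)
    ]


def concatenate_epochs(
    epochs: list[EpochMatrix], template: Recording
) -> Recording:
    """Concatenate epochs back into a continuous recording.

    ``template`` supplies labels, calibration and start time.  Inverse of
    :func:`segment_epochs` on recordings whose length is an exact epoch
    multiple.
    """
    if not epochs:
        raise ParameterError("cannot concatenate an empty epoch list")
    shape = epochs[0].data.shape
    fs = epochs[0].fs
    for e in epochs:
        if e.data.shape != shape or e.fs != fs:
            raise ShapeError("epochs disagree in shape or sampling rate")
    if shape[0] != template.n_channels:
        raise ShapeError("template channel count does not match epochs")
    return Recording(
        data=np.hstack([e.data for e in epochs]),
        fs=fs,
        channel_labels=list(template.channel_labels),
        start_time=template.start_time,
        physical_range=template.physical_range.copy(),
        digital_range=template.digital_range.copy(),
    )
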