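"""Seeded synthetic multichannel scalp EEG for exercising the codec.

Every scenario is a pure function of its :class:`ScenarioSpec` (including
the seed), so fixtures are reproducible bit-for-bit.  The scenarios mimic
the pattern classes seen in long-term monitoring of acute neurological
patients:

``diffuse_slowing``
    polymorphic delta-theta background with broad spatial fields — built
    from a handful of smooth scalp topographies (low effective rank by
    construction) plus low-amplitude pink noise;
``focal_slowing``
    faster diffuse background with high-amplitude delta confined to one
    hemisphere;
``lpd``
    lateralized periodic discharges: sharp biphasic transients followed by
    a slow wave, recurring at ~1/s over one hemisphere, on a diffuse slow
    background;
``seizure``
    an evolving rhythmic discharge (frequency glide, amplitude ramp);
``burst_suppression``
    alternating high-amplitude mixed-frequency bursts and near-flat
    suppression;
``line_noise_overlay``
    diffuse slowing plus a small 60 Hz mains sinusoid on every channel.

Amplitudes are in microvolts and sit in the clinically typical range for
scalp EEG; none of this is a biophysical forward model — spatial fields
are smooth head-topography-like mixing vectors, not dipole projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime

import numpy as np
from scipy.signal import periodogram

from .edf_io import Recording
from .exceptions import ParameterError

#: The 21 electrodes of the International 10-20 system (19 scalp + ears).
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "A1", "A2",
]

# approximate flattened scalp coordinates: x left(-)/right(+), y post(-)/ant(+)
_COORDS_1020 = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.0, 0.58),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.0, -0.58),
    "P4": (0.43, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "A1": (-1.15, 0.0), "A2": (1.15, 0.0),
}

SCENARIOS = (
    "diffuse_slowing",
    "focal_slowing",
    "lpd",
    "seizure",
    "burst_suppression",
    "line_noise_overlay",
)

START_TIME = datetime(2024, 1, 1, 0, 0, 0)


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic recording.

    ``amplitude_uv`` scales the dominant pattern, ``noise_uv`` the pink
    broadband floor (set 0 for exactly low-rank output), ``n_modes`` the
    number of spatial modes of diffuse backgrounds (at most 5),
    ``discharge_rate_hz`` the periodic-discharge rate for ``lpd``,
    ``line_noise_uv`` the 60 Hz amplitude for ``line_noise_overlay``.
    """

    scenario: str = "diffuse_slowing"
    duration_s: float = 600.0
    fs: float = 256.0
    m: int = 21
    amplitude_uv: float = 50.0
    noise_uv: float = 2.0
    lateralization: str = "none"
    discharge_rate_hz: float = 1.0
    n_modes: int = 3
    line_noise_uv: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.duration_s <= 0 or self.fs <= 0:
            raise ParameterError("duration_s and fs must be positive")
        if self.m < 2:
            raise ParameterError("need at least 2 channels")
        if self.discharge_rate_hz < 0:
            raise ParameterError("discharge_rate_hz must be >= 0")
        if not (1 <= self.n_modes <= 5):
            raise ParameterError("n_modes must be between 1 and 5")
        if self.lateralization not in ("left", "right", "none"):
            raise ParameterError("lateralization must be left, right or none")


def _layout(m: int) -> tuple[list[str], np.ndarray]:
    if m == 21:
        labels = list(CHANNELS_1020)
        xy = np.array([_COORDS_1020[c] for c in labels])
    else:
        labels = [f"CH{i + 1:02d}" for i in range(m)]
        ang = 2 * np.pi * np.arange(m) / m
        xy = np.column_stack([np.sin(ang), np.cos(ang)])
    return labels, xy


def _spatial_modes(xy: np.ndarray, n_modes: int) -> np.ndarray:
    """Smooth head-topography-like mixing vectors, one per column,
    normalized to unit maximum."""
    x, y = xy[:, 0], xy[:, 1]
    basis = [
        np.ones_like(x),          # global field
        y,                        # anterior-posterior gradient
        x,                        # left-right gradient
        x * y,                    # quadrant tilt
        1.0 - (x**2 + y**2) / 2,  # centro-peripheral bowl
    ]
    modes = np.column_stack(basis[:n_modes])
    return modes / np.max(np.abs(modes), axis=0)


def _hemi_field(xy: np.ndarray, side: str) -> np.ndarray:
    """Spatial weight concentrated over one hemisphere (Gaussian fall-off)."""
    cx = -0.6 if side == "left" else 0.6
    d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - 0.2) ** 2
    return np.exp(-d2 / 0.30)


def _slow_osc(rng, n: int, fs: float, f_lo=1.0, f_hi=7.0, n_comp=3) -> np.ndarray:
    """A polymorphic delta-theta oscillation: a few sinusoids with random
    frequencies/phases under a slow amplitude modulation; unit RMS."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    for _ in range(n_comp):
        f = rng.uniform(f_lo, f_hi)
        phase = rng.uniform(0, 2 * np.pi)
        am_f = rng.uniform(0.05, 0.2)
        am_ph = rng.uniform(0, 2 * np.pi)
        env = 0.6 + 0.4 * np.sin(2 * np.pi * am_f * t + am_ph)
        out += env * np.sin(2 * np.pi * f * t + phase)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _pink_noise(rng, shape: tuple[int, int]) -> np.ndarray:
    """1/f ('pink') noise per channel, unit RMS."""
    m, n = shape
    white = rng.standard_normal((m, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    weight = np.zeros_like(freqs)
    weight[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * weight, n=n, axis=1)
    rms = np.sqrt(np.mean(pink**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return pink / rms


def discharge_waveform(fs: float) -> np.ndarray:
    """The periodic-discharge template: a 70 ms biphasic sharp transient
    followed by a 350 ms slow wave; unit peak amplitude."""
    n_sharp = max(int(round(0.070 * fs)), 4)
    n_slow = max(int(round(0.350 * fs)), 4)
    ts = np.linspace(0, 1, n_sharp, endpoint=False)
    sharp = np.sin(2 * np.pi * ts) * np.hanning(n_sharp) * 1.6
    tw = np.linspace(0, np.pi, n_slow)
    slow = -0.45 * np.sin(tw)
    w = np.concatenate([sharp, slow])
    return w / np.max(np.abs(w))


def discharge_onsets(spec: ScenarioSpec) -> np.ndarray:
    """Deterministic event times (s) of the lpd scenario: one discharge
    per period, centred in it, so a 10-s run at 1/s has exactly 10."""
    if spec.discharge_rate_hz <= 0:
        return np.empty(0)
    n_events = int(round(spec.duration_s * spec.discharge_rate_hz))
    return (np.arange(n_events) + 0.5) / spec.discharge_rate_hz


def template_channel(spec: ScenarioSpec) -> int:
    """Index of the channel where the lateralized pattern is strongest."""
    _, xy = _layout(spec.m)
    side = spec.lateralization if spec.lateralization != "none" else "left"
    return int(np.argmax(_hemi_field(xy, side)))


def _background(rng, spec: ScenarioSpec, xy, amplitude: float) -> np.ndarray:
    n = int(round(spec.duration_s * spec.fs))
    modes = _spatial_modes(xy, spec.n_modes)
    data = np.zeros((spec.m, n))
    for i in range(spec.n_modes):
        tc = _slow_osc(rng, n, spec.fs)
        data += (amplitude / (i + 1)) * np.outer(modes[:, i], tc)
    return data


def generate(spec: ScenarioSpec) -> Recording:
    """Generate one synthetic recording; bit-identical for a given spec."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels, xy = _layout(spec.m)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    side = spec.lateralization if spec.lateralization != "none" else "left"

    if spec.scenario in ("diffuse_slowing", "line_noise_overlay"):
        data = _background(rng, spec, xy, spec.amplitude_uv)
        if spec.scenario == "line_noise_overlay":
            gains = rng.uniform(0.8, 1.2, size=spec.m)
            data += spec.line_noise_uv * np.outer(
                gains, np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
            )
    elif spec.scenario == "focal_slowing":
        data = _background(rng, spec, xy, 0.5 * spec.amplitude_uv)
        field = _hemi_field(xy, side)
        delta = _slow_osc(rng, n, spec.fs, f_lo=1.0, f_hi=3.0, n_comp=2)
        data += spec.amplitude_uv * np.outer(field, delta)
    elif spec.scenario == "lpd":
        data = _background(rng, spec, xy, 0.8 * spec.amplitude_uv)
        field = _hemi_field(xy, side)
        wave = discharge_waveform(spec.fs)
        train = np.zeros(n)
        for onset in discharge_onsets(spec):
            i0 = int(round(onset * spec.fs))
            seg = min(wave.size, n - i0)
            if seg > 0:
                train[i0 : i0 + seg] += wave[:seg]
        data += (2.4 * spec.amplitude_uv) * np.outer(field, train)
    elif spec.scenario == "seizure":
        data = _background(rng, spec, xy, 0.4 * spec.amplitude_uv)
        field = (
            _hemi_field(xy, side)
            if spec.lateralization != "none"
            else _spatial_modes(xy, 1)[:, 0]
        )
        freq = np.linspace(3.5, 2.0, n)       # decelerating rhythm
        phase = 2 * np.pi * np.cumsum(freq) / spec.fs
        ramp = np.linspace(0.3, 1.6, n)       # recruiting amplitude
        data += spec.amplitude_uv * np.outer(field, ramp * np.sin(phase))
    elif spec.scenario == "burst_suppression":
        period, burst_len = 5.0, 1.5
        env = np.where((t % period) < burst_len, 1.0, 0.04)
        edge = np.hanning(max(int(0.1 * spec.fs) * 2, 4))
        half = edge.size // 2
        env = np.convolve(env, edge / edge.sum(), mode="same")
        data = _background(rng, spec, xy, spec.amplitude_uv) * env
    else:  # pragma: no cover - validate() already rejects unknowns
        raise ParameterError(f"unknown scenario {spec.scenario!r}")

    if spec.noise_uv > 0:
        data += spec.noise_uv * _pink_noise(rng, (spec.m, n))

    return Recording(
        data=data,
        fs=spec.fs,
        channel_labels=labels,
        start_time=START_TIME,
        physical_range=np.tile([-1000.0, 1000.0], (spec.m, 1)),
        digital_range=np.tile([-32768, 32767], (spec.m, 1)),
    )


def spectral_peak(
    recording: Recording, channel: int, band: tuple[float, float] | None = None
) -> float:
    """Dominant frequency (Hz) of one channel by periodogram magnitude;
    used to assert scenario content (e.g. the 60 Hz mains peak).  ``band``
    optionally restricts the search to [lo, hi] Hz — a small mains spike is
    only dominant above the slow background."""
    x = recording.data[channel]
    if x.size < 2 * recording.fs:
        raise ParameterError("need at least 2 s of signal")
    freqs, power = periodogram(x, fs=recording.fs)
    if band is not None:
        sel = (freqs >= band[0]) & (freqs <= band[1])
        freqs, power = freqs[sel], power[sel]
    return float(freqs[int(np.argmax(power))])
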