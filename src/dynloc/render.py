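"""Stimulus synthesis and head-tracked dynamic binaural rendering.

Stimuli are band-limited white-noise bursts with raised-cosine on/off
ramps.  Dynamic rendering runs weighted overlap-add block convolution
(triangular windows at 50% overlap, which sum exactly to one): per block
the world-fixed source is re-expressed in the current head frame (with the
tracker's rendering latency applied) and convolved with the nearest dense
HRTF.  The stimulus is gated off with a short cosine ramp once the head
has rotated a threshold angle about the instructed axis, so dynamic cues
are only delivered over that rotation.

The free-field condition is represented by its loudspeaker amplitude-gain
stage (VBAP over the physical array), not by rendered audio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from . import hrtf as _hrtf
from .coords import DirectionSph, HeadOrientation, head_relative_direction, sph_to_unit
from .hrtf import HRTFSet, TriMesh, flatten_spectrum, freeze_spectrum, vbap_gains

__all__ = [
    "Stimulus",
    "HeadTrajectory",
    "make_noise_burst",
    "gate_at_rotation",
    "render_dynamic",
    "vbap_speaker_gains",
]


@dataclass
class Stimulus:
    """A mono stimulus waveform with its synthesis metadata."""

    fs: float
    samples: np.ndarray
    band_hz: tuple[float, float]
    ramp_ms: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class HeadTrajectory:
    """Time series of head orientations for one trial.

    ``latency_s`` models the motion-to-sound latency of the rendering
    chain: orientation lookups at time t return the orientation recorded
    at t − latency.
    """

    t: np.ndarray
    yaw_deg: np.ndarray
    pitch_deg: np.ndarray
    roll_deg: np.ndarray | None = None
    latency_s: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if len(self.t) < 1 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be nonempty and strictly increasing")
        self.yaw_deg = np.asarray(self.yaw_deg, dtype=float)
        self.pitch_deg = np.asarray(self.pitch_deg, dtype=float)
        if self.roll_deg is None:
            self.roll_deg = np.zeros_like(self.yaw_deg)

    def angle(self, axis: str) -> np.ndarray:
        if axis not in ("yaw", "pitch", "roll"):
            raise ValueError(f"unknown axis {axis!r}")
        return getattr(self, f"{axis}_deg")

    def orientation_at(self, t: float) -> HeadOrientation:
        """Orientation at time t, latency applied, linearly interpolated."""
        tq = np.clip(t - self.latency_s, self.t[0], self.t[-1])
        return HeadOrientation(
            float(np.interp(tq, self.t, self.yaw_deg)),
            float(np.interp(tq, self.t, self.pitch_deg)),
            float(np.interp(tq, self.t, self.roll_deg)),
        )

    def max_excursion(self, axis: str) -> float:
        """Largest unsigned rotation about one axis relative to the start."""
        a = self.angle(axis)
        return float(np.max(np.abs(a - a[0])))


def make_noise_burst(
    fs: float,
    duration_ms: float = 2000.0,
    band_hz: tuple[float, float] = (20.0, 20000.0),
    ramp_ms: float = 5.0,
    seed: int | np.random.SeedSequence = 0,
    peak: float = 0.95,
) -> Stimulus:
    """Seeded white-noise burst, band-limited and cosine-ramped.

    The band is intersected with [0, fs/2]; the first and last ``ramp_ms``
    follow a raised-cosine envelope from and to zero.
    """
    lo, hi = band_hz
    if lo < 0 or lo >= hi:
        raise ValueError("invalid band")
    if fs <= 2 * lo:
        raise ValueError("fs too low for the requested band")
    if duration_ms < 2 * ramp_ms:
        raise ValueError("duration must cover both ramps")
    n = int(round(fs * duration_ms / 1000.0))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > min(hi, fs / 2))] = 0.0
    x = np.fft.irfft(spec, n=n)
    nr = int(round(fs * ramp_ms / 1000.0))
    if nr > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        x[:nr] *= ramp
        x[-nr:] *= ramp[::-1]
        x[-1] = 0.0
    x *= peak / np.max(np.abs(x))
    return Stimulus(fs=fs, samples=x, band_hz=(lo, hi), ramp_ms=ramp_ms)


def gate_at_rotation(
    traj: HeadTrajectory,
    axis: str,
    threshold_deg: float = 10.0,
    default: float | None = None,
) -> float:
    """First time the unsigned rotation about ``axis`` (from the trial-start
    orientation) reaches the threshold, linearly interpolated between
    samples; inclusive when the threshold is hit exactly at a sample.

    Returns ``default`` (or the trajectory's end time) if never reached.
    """
    a = np.abs(traj.angle(axis) - traj.angle(axis)[0])
    hit = np.flatnonzero(a >= threshold_deg)
    if len(hit) == 0:
        return float(traj.t[-1]) if default is None else float(default)
    i = hit[0]
    if i == 0 or a[i] == threshold_deg:
        return float(traj.t[i])
    # linear crossing between samples i-1 and i
    frac = (threshold_deg - a[i - 1]) / (a[i] - a[i - 1])
    return float(traj.t[i - 1] + frac * (traj.t[i] - traj.t[i - 1]))


def _nearest_direction(hset: HRTFSet, d: DirectionSph) -> int:
    units = getattr(hset, "_units", None)
    if units is None:
        units = np.column_stack(sph_to_unit(hset.az_deg, hset.el_deg))
        hset._units = units
    return int(np.argmax(units @ d.to_unit()))


def render_dynamic(
    stim: Stimulus,
    source: DirectionSph,
    traj: HeadTrajectory,
    hset: HRTFSet,
    condition: str = "full",
    block_ms: float = 5.0,
    gate_axis: str | None = None,
    gate_threshold_deg: float = 10.0,
    gate_ramp_ms: float = 5.0,
) -> np.ndarray:
    """Render one trial to a (2, n) stereo signal.

    ``condition`` selects the cue manipulation: ``full`` uses the set
    as-is, ``flat`` flattens its spectral contrast first, and ``frozen``
    freezes all magnitude spectra to those of the head-relative source
    direction at stimulus onset (leaving the dynamic ITD intact).  When
    ``gate_axis`` is given, the output is gated off with a cosine ramp once
    the head has rotated ``gate_threshold_deg`` about that axis.
    """
    if abs(stim.fs - hset.fs) > 1e-9:
        raise ValueError("stimulus and HRTF sampling rates differ")
    if condition == "flat":
        hset = flatten_spectrum(hset)
    elif condition == "frozen":
        onset = head_relative_direction(source, traj.orientation_at(0.0))
        ref = _nearest_direction(hset, onset)
        hset = freeze_spectrum(hset, hset.az_deg[ref], hset.el_deg[ref])
    elif condition != "full":
        raise ValueError(f"unknown condition {condition!r}")

    x = stim.samples
    fs = stim.fs
    n = len(x)
    nir = hset.n_samples
    hop = max(1, int(round(block_ms * fs / 1000.0)))
    out = np.zeros((2, n + nir - 1))
    # triangular windows, 50% overlap: shifted copies sum exactly to one
    win = np.concatenate([np.arange(1, hop + 1), np.arange(hop - 1, -1, -1)]) / hop
    starts = np.arange(-hop, n, hop)
    for s in starts:
        lo, hi = max(s, 0), min(s + 2 * hop, n)
        if lo >= hi:
            continue
        seg = x[lo:hi] * win[lo - s : hi - s]
        t_center = (s + hop) / fs
        d_rel = head_relative_direction(source, traj.orientation_at(t_center))
        ir = hset.ir[_nearest_direction(hset, d_rel)]
        y = fftconvolve(seg[None, :], ir, axes=-1)
        out[:, lo : lo + y.shape[1]] += y

    if gate_axis is not None:
        t_gate = gate_at_rotation(
            traj, gate_axis, gate_threshold_deg, default=stim.duration_s
        )
        i0 = int(round(t_gate * fs))
        nr = int(round(gate_ramp_ms * fs / 1000.0))
        if i0 < out.shape[1]:
            ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(1, nr + 1) / nr))
            hi = min(i0 + nr, out.shape[1])
            out[:, i0:hi] *= ramp[: hi - i0]
            out[:, hi:] = 0.0
    return out


def vbap_speaker_gains(layout: TriMesh, az_deg: float, el_deg: float) -> np.ndarray:
    """Loudspeaker amplitude gains for a virtual source over a physical array.

    Returns a full gain vector (one entry per loudspeaker) with at most
    three nonzero gains (the enclosing triangle), normalized to unit
    Euclidean norm.
    """
    idx, g = vbap_gains(layout, az_deg, el_deg)
    gains = np.zeros(layout.n_vertices)
    gains[idx] = g
    return gains
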