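import numpy as np
import pytest
from scipy.signal import fftconvolve

from dynloc import render
from dynloc.coords import DirectionSph
from dynloc.render import (
    HeadTrajectory,
    gate_at_rotation,
    make_noise_burst,
    render_dynamic,
    vbap_speaker_gains,
)

FS = 48000.0


def static_trajectory(duration=2.0, fs_track=90.0):
    t = np.arange(0.0, duration, 1.0 / fs_track)
    return HeadTrajectory(t, np.zeros_like(t), np.zeros_like(t))


# ---------------------------------------------------------------------------
# stimulus

def test_noise_burst_length_and_ramps():
    stim = make_noise_burst(FS, duration_ms=2000.0, seed=0)
    assert len(stim.samples) == 96000
    assert stim.samples[0] == 0.0
    assert stim.samples[-1] == 0.0
    assert np.max(np.abs(stim.samples)) <= 1.0


def test_noise_burst_band_limits():
    stim = make_noise_burst(FS, duration_ms=500.0, band_hz=(500.0, 4000.0), seed=1)
    spec = np.abs(np.fft.rfft(stim.samples))
    freqs = np.fft.rfftfreq(len(stim.samples), 1 / FS)
    in_band = spec[(freqs > 600) & (freqs < 3900)]
    out_band = spec[(freqs < 350) | (freqs > 4500)]
    assert np.median(in_band) > 100 * np.max(out_band)


def test_noise_burst_determinism_and_validation():
    a = make_noise_burst(FS, seed=5)
    b = make_noise_burst(FS, seed=5)
    np.testing.assert_array_equal(a.samples, b.samples)
    with pytest.raises(ValueError):
        make_noise_burst(FS, band_hz=(4000.0, 100.0))
    with pytest.raises(ValueError):
        make_noise_burst(FS, duration_ms=5.0, ramp_ms=5.0)


# ---------------------------------------------------------------------------
# gating

def test_gate_time_constant_velocity():
    t = np.arange(0.0, 1.0, 1.0 / 90.0)
    traj = HeadTrajectory(t, 30.0 * t, np.zeros_like(t))
    assert gate_at_rotation(traj, "yaw") == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_gate_static_returns_default():
    traj = static_trajectory()
    assert gate_at_rotation(traj, "yaw", default=2.0) == 2.0
    assert gate_at_rotation(traj, "yaw") == pytest.approx(traj.t[-1])


def test_gate_inclusive_at_exact_sample():
    t = np.array([0.0, 0.1, 0.2, 0.3])
    traj = HeadTrajectory(t, np.array([0.0, 5.0, 10.0, 15.0]), np.zeros(4))
    assert gate_at_rotation(traj, "yaw") == pytest.approx(0.2)


def test_gate_measures_instructed_axis_only():
    t = np.arange(0.0, 1.0, 1.0 / 90.0)
    traj = HeadTrajectory(t, np.zeros_like(t), 40.0 * t)
    assert gate_at_rotation(traj, "yaw") == pytest.approx(traj.t[-1])
    assert gate_at_rotation(traj, "pitch") == pytest.approx(0.25, abs=1e-9)


# ---------------------------------------------------------------------------
# rendering

def test_static_render_equals_direct_convolution(sparse_set):
    stim = make_noise_burst(FS, duration_ms=200.0, seed=3)
    src = DirectionSph(30.0, 0.0)
    out = render_dynamic(stim, src, static_trajectory(), sparse_set, "full")
    i = int(np.argmin((sparse_set.az_deg - 30.0) ** 2 + sparse_set.el_deg**2))
    ref = fftconvolve(stim.samples[None, :], sparse_set.ir[i], axes=-1)
    assert out.shape == ref.shape
    assert np.max(np.abs(out - ref)) < 1e-9


def test_static_full_and_frozen_agree(sparse_set):
    stim = make_noise_burst(FS, duration_ms=200.0, seed=3)
    src = DirectionSph(30.0, 0.0)
    traj = static_trajectory()
    full = render_dynamic(stim, src, traj, sparse_set, "full")
    frozen = render_dynamic(stim, src, traj, sparse_set, "frozen")
    assert np.max(np.abs(full - frozen)) < 1e-9


def test_post_gate_energy_is_zero(sparse_set):
    stim = make_noise_burst(FS, duration_ms=1000.0, seed=4)
    t = np.arange(0.0, 1.2, 1.0 / 90.0)
    traj = HeadTrajectory(t, 40.0 * t, np.zeros_like(t))
    out = render_dynamic(
        stim, DirectionSph(0.0, 0.0), traj, sparse_set, "full", gate_axis="yaw"
    )
    t_gate = gate_at_rotation(traj, "yaw")  # 10/40 = 0.25 s
    assert t_gate == pytest.approx(0.25)
    i_end = int(round((t_gate + 0.005) * FS))
    assert np.sum(out[:, i_end:] ** 2) == 0.0
    assert np.sum(out[:, :i_end] ** 2) > 0.0


def test_frozen_rendering_keeps_spectrum_static_while_itd_moves(dense_set):
    """During a yaw rotation under frozen cues, the interaural lag tracks
    the rotation while the monaural spectrum stays pinned to its onset."""
    stim = make_noise_burst(FS, duration_ms=600.0, band_hz=(500.0, 16000.0), seed=6)
    t = np.arange(0.0, 0.7, 1.0 / 180.0)
    traj = HeadTrajectory(t, 100.0 * t, np.zeros_like(t))  # fast yaw sweep
    src = DirectionSph(0.0, 0.0)
    frozen = render_dynamic(stim, src, traj, dense_set, "frozen")

    def block_lag(sig, lo, hi):
        xc = fftconvolve(sig[0, lo:hi], sig[1, lo:hi][::-1])
        return np.argmax(xc) - (hi - lo - 1)

    early = block_lag(frozen, 2400, 7200)     # head-relative azimuth ~ -10
    late = block_lag(frozen, 19200, 24000)    # head-relative azimuth ~ -45
    # head turns left past the source: source swings right, the right ear
    # leads more and more, so the interaural lag must grow by several samples
    assert abs(late - early) >= 4

    # under frozen cues the left-ear magnitude spectrum in the late window
    # matches the onset spectrum better than an elevation/azimuth-dependent
    # full-cue rendering does
    full = render_dynamic(stim, src, traj, dense_set, "full")

    def spec_db(sig, lo, hi):
        return 20 * np.log10(np.abs(np.fft.rfft(sig[0, lo:hi])) + 1e-12)

    drift_frozen = np.median(np.abs(
        spec_db(frozen, 2400, 7200) - spec_db(frozen, 19200, 24000)
    ))
    drift_full = np.median(np.abs(
        spec_db(full, 2400, 7200) - spec_db(full, 19200, 24000)
    ))
    assert drift_frozen < drift_full


def test_block_boundaries_are_click_free(sparse_set):
    """A rotating head must not introduce level steps at block boundaries:
    the rendered level relative to a fixed-filter reference stays smooth."""
    stim = make_noise_burst(FS, duration_ms=400.0, seed=8)
    t = np.arange(0.0, 0.5, 1.0 / 180.0)
    traj = HeadTrajectory(t, 20.0 * t, np.zeros_like(t))
    out = render_dynamic(stim, DirectionSph(45.0, 0.0), traj, sparse_set, "full")
    i = int(np.argmin((sparse_set.az_deg - 45.0) ** 2 + sparse_set.el_deg**2))
    ref = fftconvolve(stim.samples[None, :], sparse_set.ir[i], axes=-1)
    win = int(round(0.020 * FS))
    n = out.shape[1] - len(sparse_set.ir[0][0]) - win
    ratio = [
        np.sqrt(np.mean(out[0, j : j + win] ** 2) / np.mean(ref[0, j : j + win] ** 2))
        for j in range(win, n, win)
    ]
    steps_db = np.abs(20 * np.log10(np.array(ratio[1:]) / np.array(ratio[:-1])))
    assert np.max(steps_db) < 1.0


def test_render_validates_sampling_rate(sparse_set):
    stim = make_noise_burst(44100.0, duration_ms=100.0, seed=0)
    with pytest.raises(ValueError, match="sampling"):
        render_dynamic(
            stim, DirectionSph(0, 0), static_trajectory(), sparse_set, "full"
        )


def test_speaker_gain_vector(icosahedron):
    from dynloc.coords import unit_to_sph

    az, el = unit_to_sph(*icosahedron.vertices[0])
    g = vbap_speaker_gains(icosahedron, float(az), float(el))
    assert len(g) == 12
    assert np.count_nonzero(g > 1e-9) == 1
    assert g[0] == pytest.approx(1.0, abs=1e-9)
    g2 = vbap_speaker_gains(icosahedron, 10.0, 20.0)
    assert np.count_nonzero(g2 > 1e-12) <= 3
    assert np.linalg.norm(g2) == pytest.approx(1.0, abs=1e-12)


def test_gain_continuity_across_face_edges(icosahedron):
    """Sweeping a target across the sphere, speaker gains vary continuously
    (the exiting vertex's gain goes to zero at the face edge)."""
    az_sweep = np.linspace(-60.0, 60.0, 241)
    gains = np.array([vbap_speaker_gains(icosahedron, a, 10.0) for a in az_sweep])
    step = np.max(np.abs(np.diff(gains, axis=0)))
    assert step < 0.05


def test_trajectory_validation():
    with pytest.raises(ValueError):
        HeadTrajectory(np.array([0.0, 0.0]), np.zeros(2), np.zeros(2))
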