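import numpy as np
import pytest

from conftest import db_mag
from dynloc import hrtf
from dynloc.hrtf import (
    HRTFSet,
    SphericalHeadModel,
    apply_delay,
    estimate_toa,
    flatten_spectrum,
    freeze_spectrum,
    interpolate_to_dense,
    minimum_phase,
    model_toa,
    subdivide,
    triangulate,
    vbap_gains,
)

FS = 48000.0


# ---------------------------------------------------------------------------
# minimum phase

def test_minimum_phase_identity_cases():
    d = np.zeros(64)
    d[0] = 1.0
    np.testing.assert_allclose(minimum_phase(d), d, atol=1e-12)
    delayed = np.zeros(64)
    delayed[9] = 1.0
    np.testing.assert_allclose(minimum_phase(delayed), d, atol=1e-12)
    # already minimum phase (zero at -0.5, inside the unit circle)
    x = np.zeros(64)
    x[:2] = [1.0, 0.5]
    np.testing.assert_allclose(minimum_phase(x), x, atol=1e-12)


def test_minimum_phase_rejects_silence():
    with pytest.raises(ValueError, match="zero"):
        minimum_phase(np.zeros(32))


def test_minimum_phase_magnitude_and_energy_delay():
    rng = np.random.default_rng(11)
    ir = rng.standard_normal((50, 64))
    mp = minimum_phase(ir)
    err_db = np.abs(db_mag(mp) - db_mag(ir))
    assert np.max(err_db) < 1e-9
    cum = np.cumsum(mp**2, axis=-1) - np.cumsum(ir**2, axis=-1)
    tot = np.sum(ir**2, axis=-1, keepdims=True)
    assert np.min(cum / tot) > -1e-9


# ---------------------------------------------------------------------------
# TOA

def test_model_toa_values_and_continuity():
    m = SphericalHeadModel()
    rc = m.radius_m / m.c_ms
    # source at the left ear: zero delay to that ear
    assert model_toa(m, 90.0, 0.0, 0) == pytest.approx(0.0, abs=1e-15)
    # frontal source is 90 degrees from either ear
    assert model_toa(m, 0.0, 0.0, 0) == pytest.approx(rc, rel=1e-12)
    assert model_toa(m, 0.0, 0.0, 0) == pytest.approx(0.2551e-3, rel=1e-3)
    # maximal ITD: (r/c)(1 + pi/2) ~ 0.656 ms, below the 0.7 ms bound
    itd = model_toa(m, 90.0, 0.0, 1) - model_toa(m, 90.0, 0.0, 0)
    assert itd == pytest.approx(rc * (1 + np.pi / 2), rel=1e-12)
    assert itd == pytest.approx(0.656e-3, rel=1e-2)
    assert itd < 0.7e-3
    # continuity at the 90-degree shadow boundary: both branches approach
    # rc with slope rc (per radian), so the jump vanishes as delta -> 0
    at_boundary = rc
    for delta in (0.01, 1e-4):
        lo = model_toa(m, delta, 0.0, 0)
        hi = model_toa(m, -delta, 0.0, 0)
        assert abs(lo - at_boundary) < 2 * rc * np.deg2rad(delta)
        assert abs(hi - at_boundary) < 2 * rc * np.deg2rad(delta)


def test_estimate_toa_examples():
    d = np.zeros((1, 2, 64))
    d[0, :, 9] = 1.0
    s = HRTFSet([0.0], [0.0], FS, d)
    est = estimate_toa(s)
    np.testing.assert_allclose(est.toa, 9 / FS, atol=1e-12)
    # a minimum-phase response has zero TOA
    mp = np.zeros((1, 2, 64))
    mp[0, :, 0] = 1.0
    mp[0, :, 1] = 0.4
    assert np.all(estimate_toa(HRTFSet([0.0], [0.0], FS, mp)).toa == 0.0)


def test_estimate_toa_recovers_model_itd(sparse_set):
    est = estimate_toa(sparse_set)
    err_samples = np.abs(est.itd_s() - sparse_set.itd_s()) * sparse_set.fs
    assert np.max(err_samples) <= 1.0


def test_apply_delay_is_allpass():
    rng = np.random.default_rng(5)
    ir = rng.standard_normal(128) * np.exp(-np.arange(128) / 8.0)
    for d in (3.0, 7.25, 31.5):
        shifted = apply_delay(ir, d)
        np.testing.assert_allclose(
            np.abs(np.fft.rfft(shifted))[:-1], np.abs(np.fft.rfft(ir))[:-1],
            atol=1e-12,
        )
    # integer delay is an exact (circular) shift
    np.testing.assert_allclose(apply_delay(ir, 4.0), np.roll(ir, 4), atol=1e-10)


# ---------------------------------------------------------------------------
# meshes and VBAP

def test_triangulate_known_solids(icosahedron):
    tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    from dynloc.coords import unit_to_sph

    az, el = unit_to_sph(tet[:, 0], tet[:, 1], tet[:, 2])
    mesh = triangulate(az, el)
    assert mesh.n_faces == 4 and mesh.n_edges == 6
    assert icosahedron.n_vertices == 12
    assert icosahedron.n_faces == 20
    assert icosahedron.n_edges == 30


def test_triangulate_rejects_degenerate_input():
    with pytest.raises(ValueError):
        triangulate([0.0, 10.0, 20.0], [0.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        triangulate([0.0, 0.0, 90.0, 180.0], [0.0, 0.0, 0.0, 0.0])  # duplicate


def test_triangulate_random_directions_closed():
    rng = np.random.default_rng(2)
    az = rng.uniform(-180, 180, 91)
    el = np.rad2deg(np.arcsin(rng.uniform(-1, 1, 91)))
    mesh = triangulate(az, el)
    assert mesh.euler_characteristic() == 2


def test_subdivision_counts(icosahedron):
    mesh = icosahedron
    expected_v = [12, 42, 162, 642]
    for i in range(1, 4):
        mesh = subdivide(mesh, 1)
        assert mesh.n_vertices == expected_v[i]
        assert mesh.n_faces == 20 * 4**i
        assert mesh.euler_characteristic() == 2
    assert subdivide(icosahedron, 0).n_vertices == 12
    assert subdivide(icosahedron, 2).n_vertices == 162


def test_vbap_gains_geometry(icosahedron):
    # target at a vertex: that vertex takes all the gain
    from dynloc.coords import unit_to_sph

    v = icosahedron.vertices[3]
    az, el = unit_to_sph(*v)
    idx, g = vbap_gains(icosahedron, float(az), float(el))
    assert g[idx == 3][0] == pytest.approx(1.0, abs=1e-9)
    assert np.sum(g) == pytest.approx(1.0, abs=1e-9)

    # axis-aligned face: target along (1,1,1)/sqrt(3) gets equal gains
    axes = triangulate([0.0, 90.0, 0.0, -90.0, 180.0, 0.0],
                       [0.0, 0.0, 90.0, 0.0, 0.0, -90.0])
    az, el = unit_to_sph(*(np.ones(3) / np.sqrt(3)))
    idx, g = vbap_gains(axes, float(az), float(el))
    np.testing.assert_allclose(g, 1 / np.sqrt(3), atol=1e-9)

    # edge midpoint: third vertex gain vanishes
    mid = icosahedron.vertices[icosahedron.faces[0][:2]].sum(axis=0)
    mid /= np.linalg.norm(mid)
    az, el = unit_to_sph(*mid)
    idx, g = vbap_gains(icosahedron, float(az), float(el))
    assert np.min(g) == pytest.approx(0.0, abs=1e-9)
    assert np.count_nonzero(g > 1e-9) == 2


def test_vbap_reconstructs_target_direction(icosahedron):
    from dynloc.coords import sph_to_unit

    rng = np.random.default_rng(9)
    az = rng.uniform(-180, 180, 200)
    el = np.rad2deg(np.arcsin(rng.uniform(-1, 1, 200)))
    for a, e in zip(az, el):
        idx, g = vbap_gains(icosahedron, a, e)
        rec = icosahedron.vertices[idx].T @ g
        rec /= np.linalg.norm(rec)
        target = np.array(sph_to_unit(a, e))
        cross = np.linalg.norm(np.cross(rec, target))
        ang = np.rad2deg(np.arctan2(cross, rec @ target))
        assert ang < 1e-6
        assert np.linalg.norm(g) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# interpolation chain

def test_self_interpolation_is_exact(sparse_set, dense_set):
    i_map = [
        dense_set.index_of(a, e)
        for a, e in zip(sparse_set.az_deg, sparse_set.el_deg)
    ]
    err = np.abs(db_mag(dense_set.ir[i_map]) - db_mag(sparse_set.ir))
    assert np.max(err) < 0.1
    # and the dense TOAs at those points match the sparse model TOAs
    np.testing.assert_allclose(dense_set.toa[i_map], sparse_set.toa, atol=1e-12)


def test_subdivision_vertex_bookkeeping(icosahedron):
    # V' = V + E at each step: 12 -> 42 -> 162 -> 642 -> 2562
    assert subdivide(icosahedron, 3).n_vertices == 642
    assert subdivide(icosahedron, 4).n_vertices == 2562


# ---------------------------------------------------------------------------
# cue manipulation

def band_mask(n, fs, lo=1000.0, hi=16000.0):
    f = np.abs(np.fft.fftfreq(n, 1 / fs))
    return (f >= lo) & (f <= hi)


def test_flatten_removes_contrast_but_not_level(dense_set):
    flat = flatten_spectrum(dense_set)
    band = band_mask(dense_set.n_samples, dense_set.fs)
    assert np.max(db_mag(flat.ir)[..., band].std(axis=-1)) < 1e-9
    # per-ear broadband energy is preserved
    def level(s):
        return 10 * np.log10(np.sum(np.abs(np.fft.fft(s.ir, axis=-1)) ** 2, axis=-1))

    assert np.max(np.abs(level(flat) - level(dense_set))) < 0.2
    # ITD untouched
    np.testing.assert_allclose(flat.toa, dense_set.toa, atol=1e-15)


def test_flatten_identity_and_idempotence(dense_set):
    ident = flatten_spectrum(dense_set, contrast=1.0)
    assert np.max(np.abs(db_mag(ident.ir) - db_mag(dense_set.ir))) < 1e-9
    flat = flatten_spectrum(dense_set)
    again = flatten_spectrum(flat)
    np.testing.assert_allclose(again.ir, flat.ir, atol=1e-12)


def test_flatten_validates_band(dense_set):
    with pytest.raises(ValueError):
        flatten_spectrum(dense_set, f_lo=16000.0, f_hi=1000.0)


def test_freeze_equalizes_spectra_and_keeps_itd(dense_set):
    frozen = freeze_spectrum(dense_set, 0.0, 0.0)
    mags = db_mag(frozen.ir)
    assert np.max(mags.max(axis=0) - mags.min(axis=0)) < 1e-9
    est_f = estimate_toa(HRTFSet(frozen.az_deg, frozen.el_deg, frozen.fs, frozen.ir))
    est_d = estimate_toa(HRTFSet(dense_set.az_deg, dense_set.el_deg, dense_set.fs,
                                 dense_set.ir))
    err = np.abs(est_f.itd_s() - est_d.itd_s()) * dense_set.fs
    assert np.max(err) <= 1.0
    # at the reference itself the impulse response is unchanged
    i = dense_set.index_of(0.0, 0.0)
    np.testing.assert_allclose(frozen.ir[i], dense_set.ir[i], atol=1e-9)


def test_freeze_requires_on_grid_reference(dense_set):
    with pytest.raises(KeyError):
        freeze_spectrum(dense_set, 1.2345, 3.4567)


def test_freeze_commutes_with_flatten(dense_set):
    # with a flattened reference spectrum, freeze->flatten == flatten->freeze
    a = flatten_spectrum(freeze_spectrum(dense_set, 0.0, 0.0))
    b = freeze_spectrum(flatten_spectrum(dense_set), 0.0, 0.0)
    assert np.max(np.abs(db_mag(a.ir) - db_mag(b.ir))) < 1e-6


def test_hrtfset_validation():
    with pytest.raises(ValueError):
        HRTFSet([0.0], [0.0], -1.0, np.zeros((1, 2, 8)))
    with pytest.raises(ValueError):
        HRTFSet([0.0], [0.0], FS, np.zeros((1, 3, 8)))
    with pytest.raises(ValueError):
        HRTFSet([0.0], [0.0], FS, np.full((1, 2, 8), np.nan))
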