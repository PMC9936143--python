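"""HRTF container and the directional-filter processing chain.

The chain that turns a sparse measured/synthetic HRTF set into a dense,
cue-manipulable one:

1. estimate and remove each impulse response's time of arrival (TOA) by
   taking its minimum-phase version;
2. triangulate the sparse directions on the sphere and subdivide the mesh
   to obtain a dense direction grid;
3. interpolate log-magnitude spectra onto the dense grid with vector-base
   amplitude panning (VBAP) weights over the enclosing sparse triangle;
4. re-introduce a dense TOA from a spherical-head model, so the interaural
   time difference (ITD) varies smoothly with direction.

On top of that sit the two cue manipulations used to isolate localization
cues: spectral *flattening* (contrast compression of the log-magnitude
between two band edges, removing monaural spectral shape while preserving
ITD and broadband ILD) and spectral *freezing* (every direction receives
one reference direction's magnitude spectrum while keeping its own TOA, so
only the dynamic ITD remains direction-dependent).

Delays are applied as cyclic band-limited phase ramps, which preserve the
magnitude spectrum exactly; impulse responses must therefore be long
enough that the minimum-phase decay plus the largest TOA fits the buffer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import ConvexHull

from .coords import angular_distance, sph_to_unit, unit_to_sph

__all__ = [
    "HRTFSet",
    "SphericalHeadModel",
    "TriMesh",
    "minimum_phase",
    "minimum_phase_from_logmag",
    "apply_delay",
    "estimate_toa",
    "model_toa",
    "triangulate",
    "subdivide",
    "vbap_gains",
    "interpolate_to_dense",
    "flatten_spectrum",
    "freeze_spectrum",
]

#: Relative amplitude floor applied to magnitude spectra before taking logs.
MAG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# containers

@dataclass
class HRTFSet:
    """A set of per-direction, per-ear head-related impulse responses.

    Attributes
    ----------
    az_deg, el_deg : (n,) arrays of source directions (degrees).
    fs : sampling rate in Hz.
    ir : (n, 2, N) array; ear axis is [left, right].
    toa : (n, 2) per-ear time of arrival in seconds, or None until
        estimated/assigned.  Only TOA *differences* (the ITD) are
        physically meaningful; a constant offset is allowed.
    """

    az_deg: np.ndarray
    el_deg: np.ndarray
    fs: float
    ir: np.ndarray
    toa: np.ndarray | None = None

    def __post_init__(self):
        self.az_deg = np.atleast_1d(np.asarray(self.az_deg, dtype=float))
        self.el_deg = np.atleast_1d(np.asarray(self.el_deg, dtype=float))
        self.ir = np.asarray(self.ir, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.ir.ndim != 3 or self.ir.shape[:2] != (len(self.az_deg), 2):
            raise ValueError("ir must have shape (n_directions, 2, N)")
        if not np.all(np.isfinite(self.ir)):
            raise ValueError("impulse responses must be finite")
        if self.toa is not None:
            self.toa = np.asarray(self.toa, dtype=float)

    def __len__(self) -> int:
        return len(self.az_deg)

    @property
    def n_samples(self) -> int:
        return self.ir.shape[2]

    def copy(self) -> "HRTFSet":
        return HRTFSet(
            self.az_deg.copy(), self.el_deg.copy(), self.fs, self.ir.copy(),
            None if self.toa is None else self.toa.copy(),
        )

    def index_of(self, az_deg: float, el_deg: float, tol_deg: float = 1e-3) -> int:
        dist = angular_distance(self.az_deg, self.el_deg, az_deg, el_deg)
        i = int(np.argmin(dist))
        if dist[i] > tol_deg:
            raise KeyError(
                f"direction (az={az_deg}, el={el_deg}) not on the grid "
                f"(closest is {dist[i]:.3g}° away)"
            )
        return i

    def itd_s(self) -> np.ndarray:
        """Interaural time difference toa_right − toa_left, per direction
        (positive when the source is on the listener's left)."""
        if self.toa is None:
            raise ValueError("toa not set; run estimate_toa first")
        return self.toa[:, 1] - self.toa[:, 0]


@dataclass(frozen=True)
class SphericalHeadModel:
    """Rigid-sphere head for the TOA model.

    radius_m: head radius (default 8.75 cm); c_ms: speed of sound;
    ear directions default to the interaural poles at azimuth ±90°.
    """

    radius_m: float = 0.0875
    c_ms: float = 343.0
    ear_az_deg: tuple[float, float] = (90.0, -90.0)
    ear_el_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.radius_m <= 0 or self.c_ms <= 0:
            raise ValueError("radius and speed of sound must be positive")


@dataclass
class TriMesh:
    """Triangle mesh on the unit sphere."""

    vertices: np.ndarray  # (V, 3) unit vectors
    faces: np.ndarray     # (F, 3) vertex indices

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face references a nonexistent vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def edges(self) -> np.ndarray:
        e = np.sort(
            np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
            ),
            axis=1,
        )
        return np.unique(e, axis=0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces


# ---------------------------------------------------------------------------
# minimum phase and delays

def _logmag(ir: np.ndarray) -> np.ndarray:
    """Natural-log magnitude of the FFT along the last axis, floored."""
    mag = np.abs(np.fft.fft(ir, axis=-1))
    floor = np.max(mag, axis=-1, keepdims=True) * MAG_FLOOR
    if np.any(np.max(mag, axis=-1) == 0):
        raise ValueError("all-zero impulse response")
    return np.log(np.maximum(mag, floor))


def minimum_phase_from_logmag(logmag: np.ndarray) -> np.ndarray:
    """Minimum-phase impulse response with the given N-point log magnitude.

    Cyclic (DFT-grid) construction via the folded real cepstrum: the result
    has exactly the requested magnitude at every FFT bin and concentrates
    its energy at the earliest possible samples.
    """
    n = logmag.shape[-1]
    cep = np.fft.ifft(logmag, axis=-1).real
    fold = np.zeros_like(cep)
    fold[..., 0] = cep[..., 0]
    half = n // 2
    fold[..., 1:half] = 2.0 * cep[..., 1:half]
    if n % 2 == 0:
        fold[..., half] = cep[..., half]
    else:
        fold[..., half] = 2.0 * cep[..., half]
    return np.fft.ifft(np.exp(np.fft.fft(fold, axis=-1)), axis=-1).real


def _minimum_phase_1d(x: np.ndarray) -> np.ndarray:
    n = len(x)
    mx = np.max(np.abs(x))
    if mx == 0:
        raise ValueError("all-zero impulse response")
    nz = np.flatnonzero(np.abs(x) > mx * 1e-14)
    c = x[nz[0] : nz[-1] + 1]
    mag = np.abs(np.fft.fft(x))
    if len(c) == 1:
        out = np.zeros(n)
        out[0] = c[0]
        return out
    r = np.roots(c)
    r = np.where(np.abs(r) > 1.0, 1.0 / np.conj(r), r)
    w = np.exp(-2j * np.pi * np.arange(n) / n)
    phase = np.angle(c[0]) + np.sum(np.angle(1.0 - r[:, None] * w[None, :]), axis=0)
    return np.real(np.fft.ifft(mag * np.exp(1j * phase)))


def minimum_phase(ir: np.ndarray) -> np.ndarray:
    """Exact minimum-phase version of an impulse response (last axis = time).

    A length-N signal's minimum-phase counterpart is again length N
    (reflect the z-plane zeros outside the unit circle to their conjugate
    reciprocals), so it is computed exactly: zeros via the companion
    matrix, then the spectrum is reassembled from the *original* FFT
    magnitude — preserved bin for bin by construction — and the
    minimum-phase phase evaluated stably in the log domain.  The result
    removes any time of arrival and maximizes partial energy at every
    sample among signals with the same magnitude response.
    """
    ir = np.asarray(ir, dtype=float)
    if ir.ndim == 1:
        return _minimum_phase_1d(ir)
    flat = ir.reshape(-1, ir.shape[-1])
    return np.stack([_minimum_phase_1d(x) for x in flat]).reshape(ir.shape)


def apply_delay(ir: np.ndarray, delay_samples) -> np.ndarray:
    """Delay by a (fractional) number of samples, cyclically and allpass.

    Multiplies the N-point spectrum by ``exp(-j ω D)``; the Nyquist bin is
    forced to ±1 so the output stays real with its magnitude untouched.
    Energy pushed past the end of the buffer wraps around, so the buffer
    must be longer than the delay plus the response's decay.
    """
    ir = np.asarray(ir, dtype=float)
    n = ir.shape[-1]
    d = np.asarray(delay_samples, dtype=float)[..., None]
    k = np.arange(n // 2 + 1)
    phase = np.exp(-2j * np.pi * k * d / n)
    if n % 2 == 0:
        # keep the Nyquist coefficient real; sign follows the rounded delay
        phase[..., -1] = np.where(np.cos(np.pi * d[..., 0]) >= 0, 1.0, -1.0)
    return np.fft.irfft(np.fft.rfft(ir, axis=-1) * phase, n=n, axis=-1)


def estimate_toa(hrtf: HRTFSet) -> HRTFSet:
    """Fill per-direction/ear TOA as the lag maximizing the cross-correlation
    between each impulse response and its minimum-phase version (seconds, ≥ 0).

    The cepstral (cyclic) minimum-phase construction is used as the
    zero-delay reference here; it matches the exact one to well below the
    one-sample resolution of the lag estimate and is much faster on large
    sets.
    """
    mp = minimum_phase_from_logmag(_logmag(hrtf.ir))
    # cross-correlate via FFT over nonnegative lags
    n = hrtf.n_samples
    spec = np.fft.rfft(hrtf.ir, n=2 * n, axis=-1) * np.conj(
        np.fft.rfft(mp, n=2 * n, axis=-1)
    )
    xc = np.fft.irfft(spec, n=2 * n, axis=-1)[..., :n]
    lag = np.argmax(xc, axis=-1)
    out = hrtf.copy()
    out.toa = lag / hrtf.fs
    return out


def model_toa(model: SphericalHeadModel, az_deg, el_deg, ear: int) -> np.ndarray:
    """Spherical-head time of arrival for one ear (0 = left, 1 = right).

    With γ the angle between the source direction and the ear direction:
    ``τ = (r/c)(1 − cos γ)`` on the ear's side (γ ≤ 90°) and
    ``τ = (r/c)(1 + γ − π/2)`` in the acoustic shadow (γ in radians),
    continuous at γ = 90° and zero for a source at the ear.
    """
    gamma = np.deg2rad(
        angular_distance(az_deg, el_deg, model.ear_az_deg[ear], model.ear_el_deg[ear])
    )
    rc = model.radius_m / model.c_ms
    return np.where(
        gamma <= np.pi / 2,
        rc * (1.0 - np.cos(gamma)),
        rc * (1.0 + gamma - np.pi / 2),
    )


# ---------------------------------------------------------------------------
# spherical meshes and VBAP

def triangulate(az_deg, el_deg) -> TriMesh:
    """Convex-hull triangulation of directions on the unit sphere,
    faces oriented outward."""
    v = np.column_stack(sph_to_unit(np.asarray(az_deg, float), np.asarray(el_deg, float)))
    if len(v) < 4:
        raise ValueError("need at least 4 directions to triangulate")
    if len(np.unique(np.round(v, 9), axis=0)) != len(v):
        raise ValueError("duplicate directions")
    try:
        hull = ConvexHull(v)
    except Exception as exc:  # qhull raises on coplanar input
        raise ValueError(f"directions do not span the sphere: {exc}") from exc
    if len(hull.vertices) != len(v):
        raise ValueError("some directions fall inside the convex hull")
    faces = hull.simplices.copy()
    # orient faces so normals point away from the origin
    tri = v[faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", normals, tri.mean(axis=1)) < 0
    faces[flip] = faces[flip][:, ::-1]
    return TriMesh(v, faces)


def subdivide(mesh: TriMesh, iterations: int = 1) -> TriMesh:
    """Split each face into four via edge midpoints projected to the sphere.

    Midpoints are shared across adjacent faces, so each iteration maps
    V → V + E and F → 4F (closed meshes keep Euler characteristic 2).
    """
    verts = mesh.vertices.copy()
    faces = mesh.faces.copy()
    for _ in range(iterations):
        verts_list = list(verts)
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint_cache:
                m = verts_list[i] + verts_list[j]
                m = m / np.linalg.norm(m)
                midpoint_cache[key] = len(verts_list)
                verts_list.append(m)
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    return TriMesh(verts, faces)


def mesh_directions(mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
    """Vertex directions of a mesh as (azimuth, elevation) arrays."""
    az, el = unit_to_sph(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.vertices[:, 2])
    return np.asarray(az), np.asarray(el)


def _face_inverses(mesh: TriMesh) -> np.ndarray:
    inv = getattr(mesh, "_face_inv", None)
    if inv is None:
        mats = mesh.vertices[mesh.faces].transpose(0, 2, 1)  # columns = vertices
        inv = np.linalg.inv(mats)
        mesh._face_inv = inv
    return inv


def vbap_gains(
    mesh: TriMesh, az_deg: float, el_deg: float, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    """Vector-base amplitude panning gains for one target direction.

    Finds the mesh face enclosing the target, solves ``L g = p`` with L the
    three vertex vectors as columns, and normalizes the gains to unit
    Euclidean norm.  Returns ``(vertex_indices, gains)``.  If no face yields
    all-nonnegative gains (numerical edge cases), the least-violating face
    is used with negative gains clamped, with a warning.
    """
    p = np.array(sph_to_unit(float(az_deg), float(el_deg)))
    inv = _face_inverses(mesh)
    g = inv @ p  # (F, 3)
    worst = g.min(axis=1)
    best = int(np.argmax(worst))
    gains = g[best]
    if worst[best] < -tol:
        warnings.warn(
            f"target (az={az_deg}, el={el_deg}) not enclosed by any face; "
            "clamping negative gains",
            RuntimeWarning,
        )
        gains = np.maximum(gains, 0.0)
    else:
        gains = np.maximum(gains, 0.0)
    gains = gains / np.linalg.norm(gains)
    return mesh.faces[best].copy(), gains


def _batch_vbap(mesh: TriMesh, az_deg, el_deg) -> tuple[np.ndarray, np.ndarray]:
    """Enclosing-face vertex indices and sum-one weights for many targets."""
    p = np.column_stack(sph_to_unit(np.asarray(az_deg, float), np.asarray(el_deg, float)))
    inv = _face_inverses(mesh)
    g = np.einsum("fij,tj->tfi", inv, p)
    best = np.argmax(g.min(axis=2), axis=1)
    gains = np.maximum(g[np.arange(len(p)), best], 0.0)
    weights = gains / gains.sum(axis=1, keepdims=True)
    return mesh.faces[best], weights


# ---------------------------------------------------------------------------
# interpolation and cue manipulation

def interpolate_to_dense(
    sparse: HRTFSet,
    dense_az_deg,
    dense_el_deg,
    model: SphericalHeadModel | None = None,
) -> HRTFSet:
    """Interpolate a sparse HRTF set onto a dense direction grid.

    Per dense direction and ear, the log-magnitude spectrum is the
    VBAP-weighted combination of the sparse directions' minimum-phase
    log-magnitudes (weights normalized to sum to one, so a dense direction
    coinciding with a sparse one reproduces it exactly); the phase is the
    minimum phase of that magnitude; and the spherical-head model TOA is
    applied as a fractional delay.
    """
    if model is None:
        model = SphericalHeadModel()
    dense_az = np.atleast_1d(np.asarray(dense_az_deg, dtype=float))
    dense_el = np.atleast_1d(np.asarray(dense_el_deg, dtype=float))
    mesh = triangulate(sparse.az_deg, sparse.el_deg)
    # taking the minimum phase leaves the magnitude untouched, so the
    # sparse log-magnitudes can be read off the raw impulse responses
    sparse_logmag = _logmag(sparse.ir)  # (n, 2, N)
    idx, w = _batch_vbap(mesh, dense_az, dense_el)     # (t, 3), (t, 3)
    logmag = np.einsum("tk,tkeN->teN", w, sparse_logmag[idx])
    mp = minimum_phase_from_logmag(logmag)
    toa = np.stack(
        [model_toa(model, dense_az, dense_el, ear) for ear in (0, 1)], axis=1
    )
    ir = apply_delay(mp, toa * sparse.fs)
    return HRTFSet(dense_az, dense_el, sparse.fs, ir, toa)


def _require_toa(hrtf: HRTFSet) -> HRTFSet:
    return hrtf if hrtf.toa is not None else estimate_toa(hrtf)


def flatten_spectrum(
    hrtf: HRTFSet,
    f_lo: float = 1000.0,
    f_hi: float = 16000.0,
    contrast: float = 0.0,
) -> HRTFSet:
    """Compress spectral contrast between two band edges.

    Within [f_lo, f_hi] each log-magnitude is replaced by
    ``pivot + contrast · (logmag − pivot)`` where the pivot is the ear's
    in-band *power* mean (in the log domain); contrast 0 flattens the band
    completely while preserving each ear's in-band energy exactly — hence
    the broadband ILD — and contrast 1 is the identity.  Phase is rebuilt
    as minimum phase and the set's TOA re-applied, so the ITD is untouched.
    """
    if f_lo >= f_hi:
        raise ValueError("f_lo must be below f_hi")
    hrtf = _require_toa(hrtf)
    n = hrtf.n_samples
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / hrtf.fs))
    if hrtf.fs < 2 * f_hi:
        warnings.warn(
            f"fs = {hrtf.fs} Hz cannot represent {f_hi} Hz; "
            "flattening up to Nyquist only",
            RuntimeWarning,
        )
    band = (freqs >= f_lo) & (freqs <= f_hi)
    logmag = _logmag(hrtf.ir)
    if contrast != 1.0:
        # pivot on the in-band power mean so flattening is energy-neutral
        pivot = 0.5 * np.log(
            np.mean(np.exp(2.0 * logmag[..., band]), axis=-1, keepdims=True)
        )
        flat = logmag.copy()
        flat[..., band] = pivot + contrast * (logmag[..., band] - pivot)
    else:
        flat = logmag
    ir = apply_delay(minimum_phase_from_logmag(flat), hrtf.toa * hrtf.fs)
    return HRTFSet(hrtf.az_deg.copy(), hrtf.el_deg.copy(), hrtf.fs, ir, hrtf.toa.copy())


def freeze_spectrum(hrtf: HRTFSet, ref_az_deg: float = 0.0, ref_el_deg: float = 0.0) -> HRTFSet:
    """Give every direction the reference direction's magnitude spectrum
    while keeping each direction's own TOA.

    The result carries no direction-dependent monaural spectral shape or
    ILD; only the (dynamic) ITD still varies with direction.  The reference
    must lie on the set's grid.
    """
    hrtf = _require_toa(hrtf)
    i = hrtf.index_of(ref_az_deg, ref_el_deg)
    ref_logmag = _logmag(hrtf.ir[i])  # (2, N)
    mp = minimum_phase_from_logmag(ref_logmag)  # (2, N)
    ir = apply_delay(np.broadcast_to(mp, hrtf.ir.shape), hrtf.toa * hrtf.fs)
    return HRTFSet(hrtf.az_deg.copy(), hrtf.el_deg.copy(), hrtf.fs, ir, hrtf.toa.copy())
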