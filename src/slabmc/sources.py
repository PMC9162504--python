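"""Photon source models: emission times and launch rays.

Emission times are drawn from the pulse's temporal intensity profile — for a
sech² pulse this is a logistic distribution, whose closed-form quantile
Q(ξ) = μ + s·ln(ξ/(1−ξ)) makes sampling exact. Launch geometry comes from one
of three beam models:

* ``pencil`` — all photons on the axis, travelling along +z;
* ``gaussian_pencil`` — Gaussian transverse intensity at the entrance plane,
  zero divergence (the traditional "focal distribution" initialization);
* ``ray_bundle`` — the Gaussian ray bundle: each ray connects a random point
  in the launch plane at z = −d (waist ws) to a random point in the focal
  plane (waist w0), both Gaussian-distributed. The envelope of the resulting
  bundle reproduces the true Gaussian-beam width w(z) = w0·√(1+(z/zR)²) at
  every plane, giving the correct divergence a tightly focused beam has.

Transverse Gaussians use 1/e²-radius semantics throughout: a waist w means
intensity ∝ exp(−2r²/w²), i.e. per-axis standard deviation w/2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from .optics_utils import PulseShape, PulseSpec, rayleigh_length

__all__ = [
    "BeamKind",
    "BeamSpec",
    "Ray",
    "PhotonState",
    "sample_emission_time",
    "sample_emission_times",
    "sample_ray_bundle",
    "sample_gaussian_pencil",
    "free_space",
    "thin_lens",
    "flat_interface",
    "abcd_transform",
    "make_photon",
    "make_photons",
]

#: Gaussian FWHM = 2√(2 ln 2)·σ
_GAUSS_FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class BeamKind(str, enum.Enum):
    PENCIL = "pencil"
    GAUSSIAN_PENCIL = "gaussian_pencil"
    RAY_BUNDLE = "ray_bundle"


@dataclass(frozen=True)
class BeamSpec:
    """Spatial source model.

    Parameters
    ----------
    kind : BeamKind or str
    focal_waist : float
        w0, 1/e² intensity radius in the focal plane, μm.
    wavelength : float
        Vacuum wavelength λ, μm (sets the Rayleigh length).
    launch_distance : float, optional
        d, distance of the launch plane before the focus, μm. Defaults to
        100·zR so the bundle is launched deep in the far field.
    launch_waist : float, optional
        ws, 1/e² radius in the launch plane, μm. Defaults to the Gaussian
        far-field value w0·√(1+(d/zR)²), which makes the bundle envelope
        follow the true beam profile.
    focus_z : float
        Axial coordinate of the focal plane, μm (slab entrance is z = 0).
    """

    kind: BeamKind = BeamKind.RAY_BUNDLE
    focal_waist: float = 5.0
    wavelength: float = 1.51
    launch_distance: float | None = None
    launch_waist: float | None = None
    focus_z: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "kind", BeamKind(self.kind))
        if self.kind is not BeamKind.PENCIL:
            if not self.focal_waist > 0:
                raise ValueError("focal_waist must be > 0 for Gaussian beams")
            if not self.wavelength > 0:
                raise ValueError("wavelength must be > 0")

    @property
    def rayleigh(self) -> float:
        """Rayleigh length zR = πw0²/λ, μm."""
        return rayleigh_length(self.focal_waist, self.wavelength)

    @property
    def d(self) -> float:
        """Effective launch distance, μm (default 100·zR ≫ zR)."""
        return self.launch_distance if self.launch_distance is not None else 100.0 * self.rayleigh

    @property
    def ws(self) -> float:
        """Effective launch-plane waist, μm."""
        if self.launch_waist is not None:
            return self.launch_waist
        zr = self.rayleigh
        return self.focal_waist * math.sqrt(1.0 + (self.d / zr) ** 2)


@dataclass
class Ray:
    """A straight ray: origin (μm) and unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or n == 0:
            raise ValueError("ray direction must be a finite non-zero vector")
        self.direction = d / n


@dataclass
class PhotonState:
    """Monte Carlo walker: position (μm), unit direction, weight, clock (ps)."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    time: float = 0.0


# ---------------------------------------------------------------------------
# temporal sampling
# ---------------------------------------------------------------------------

def sample_emission_time(pulse: PulseSpec, xi: float) -> float:
    """Emission-time offset (fs) from one uniform variate ξ ∈ (0, 1).

    sech² pulses use the logistic quantile μ + s·ln(ξ/(1−ξ)) with μ = 0 and
    s = 1/(2γp); Gaussian pulses the normal quantile scaled to the FWHM;
    delta pulses return 0. ξ = 0 or 1 is rejected — resample instead.
    """
    if pulse.shape is PulseShape.DELTA:
        return 0.0
    if not 0.0 < xi < 1.0:
        raise ValueError(f"xi must lie strictly inside (0, 1), got {xi}; resample")
    if pulse.shape is PulseShape.SECH2:
        return pulse.logistic_scale * math.log(xi / (1.0 - xi))
    sigma = pulse.fwhm_fs / _GAUSS_FWHM_SIGMA
    return sigma * float(ndtri(xi))


def sample_emission_times(pulse: PulseSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized draw of ``n`` emission offsets (fs)."""
    if pulse.shape is PulseShape.DELTA:
        return np.zeros(n)
    xi = rng.random(n)
    # rng.random() ∈ [0, 1); 0 has measure ~2⁻⁵³ but the quantile needs (0,1)
    xi[xi == 0.0] = 0.5
    if pulse.shape is PulseShape.SECH2:
        return pulse.logistic_scale * np.log(xi / (1.0 - xi))
    return pulse.fwhm_fs / _GAUSS_FWHM_SIGMA * ndtri(xi)


# ---------------------------------------------------------------------------
# spatial sampling
# ---------------------------------------------------------------------------

def _gauss_quantile(xi, waist):
    """Inverse-CDF for one transverse axis of a 1/e²-radius-w Gaussian.

    (w/2)·Φ⁻¹(ξ), identical to (w/√2)·erf⁻¹(2ξ−1)."""
    return 0.5 * waist * ndtri(xi)


def sample_ray_bundle(beam: BeamSpec, xi1: float, xi2: float, xi3: float, xi4: float) -> Ray:
    """One Gaussian-ray-bundle ray from four uniform variates.

    (xs, ys) is drawn in the launch plane z = focus_z − d with waist ws and
    (xf, yf) in the focal plane with waist w0; the ray passes through both
    points, with its origin advanced to the slab entrance plane z = 0.
    """
    if beam.kind is not BeamKind.RAY_BUNDLE:
        raise ValueError(f"sample_ray_bundle requires a ray_bundle beam, got {beam.kind.value}")
    xs = _gauss_quantile(xi1, beam.ws)
    ys = _gauss_quantile(xi2, beam.ws)
    xf = _gauss_quantile(xi3, beam.focal_waist)
    yf = _gauss_quantile(xi4, beam.focal_waist)
    d = beam.d
    direction = np.array([(xf - xs) / d, (yf - ys) / d, 1.0])
    direction /= np.linalg.norm(direction)
    # advance from the focal point to z = 0
    s = (0.0 - beam.focus_z) / direction[2]
    origin = np.array([xf, yf, beam.focus_z]) + s * direction
    return Ray(origin, direction)


def sample_ray_bundle_batch(beam: BeamSpec, n: int, rng: np.random.Generator):
    """Vectorized bundle sampling: (origins[n,3], directions[n,3])."""
    xi = np.clip(rng.random((4, n)), 1e-16, None)
    xs = _gauss_quantile(xi[0], beam.ws)
    ys = _gauss_quantile(xi[1], beam.ws)
    xf = _gauss_quantile(xi[2], beam.focal_waist)
    yf = _gauss_quantile(xi[3], beam.focal_waist)
    d = beam.d
    dirs = np.stack([(xf - xs) / d, (yf - ys) / d, np.ones(n)], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    s = (0.0 - beam.focus_z) / dirs[:, 2]
    origins = np.stack([xf, yf, np.full(n, beam.focus_z)], axis=1) + s[:, None] * dirs
    return origins, dirs


def sample_gaussian_pencil(beam: BeamSpec, xi1: float, xi2: float) -> Ray:
    """Gaussian-pencil ray: Gaussian transverse position, direction exactly +z."""
    if beam.kind is not BeamKind.GAUSSIAN_PENCIL:
        raise ValueError("sample_gaussian_pencil requires a gaussian_pencil beam")
    x = _gauss_quantile(xi1, beam.focal_waist)
    y = _gauss_quantile(xi2, beam.focal_waist)
    return Ray(np.array([x, y, 0.0]), np.array([0.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# ray-transfer (ABCD) optics
# ---------------------------------------------------------------------------

def free_space(d: float) -> np.ndarray:
    """Propagation over distance d (μm)."""
    return np.array([[1.0, d], [0.0, 1.0]])


def thin_lens(f: float) -> np.ndarray:
    """Ideal thin lens of focal length f (μm)."""
    if f == 0:
        raise ValueError("focal length must be non-zero")
    return np.array([[1.0, 0.0], [-1.0 / f, 1.0]])


def flat_interface(n1: float, n2: float) -> np.ndarray:
    """Flat refractive interface n1 → n2 (paraxial Snell)."""
    return np.array([[1.0, 0.0], [0.0, n1 / n2]])


_PARAXIAL_BOUND = 0.3  # rad; |slope| beyond this is no longer paraxial


def abcd_transform(ray: Ray, elements, slope_bound: float = _PARAXIAL_BOUND) -> Ray:
    """Apply a sequence of 2×2 ray-transfer matrices to a paraxial ray.

    Each transverse plane (x–z and y–z) transforms independently as
    (height, slope) vectors. ``elements`` are matrices from ``free_space``,
    ``thin_lens`` or ``flat_interface``. Emits a warning if a slope exceeds
    the paraxial bound; z bookkeeping follows the free-space distances.
    """
    import warnings

    sx = ray.direction[0] / ray.direction[2]
    sy = ray.direction[1] / ray.direction[2]
    vx = np.array([ray.origin[0], sx])
    vy = np.array([ray.origin[1], sy])
    z = ray.origin[2]
    for m in elements:
        m = np.asarray(m, dtype=float)
        vx = m @ vx
        vy = m @ vy
        if m[0, 0] == 1.0 and m[1, 0] == 0.0 and m[1, 1] == 1.0:
            z += m[0, 1]  # free-space element advances z
        if max(abs(vx[1]), abs(vy[1])) > slope_bound:
            warnings.warn(
                f"ray slope {max(abs(vx[1]), abs(vy[1])):.3f} exceeds the paraxial bound "
                f"{slope_bound}; ABCD results are approximate",
                stacklevel=2,
            )
    direction = np.array([vx[1], vy[1], 1.0])
    return Ray(np.array([vx[0], vy[0], z]), direction / np.linalg.norm(direction))


# ---------------------------------------------------------------------------
# photon assembly
# ---------------------------------------------------------------------------

#: vacuum speed of light, μm/ps
C_UM_PS = 299.792458


def make_photon(pulse: PulseSpec, beam: BeamSpec, rng: np.random.Generator) -> PhotonState:
    """One photon at the slab entrance plane: sampled ray + emission time.

    The clock is the pulse offset at the moment the ray crosses the focal
    plane (an aplanatic focusing system is isochronous at focus); if the
    focal plane is not the entrance plane, the external free-flight between
    them is added at vacuum speed.
    """
    if beam.kind is BeamKind.PENCIL:
        ray = Ray(np.zeros(3), np.array([0.0, 0.0, 1.0]))
    elif beam.kind is BeamKind.GAUSSIAN_PENCIL:
        ray = sample_gaussian_pencil(beam, _open_unit(rng), _open_unit(rng))
    else:
        ray = sample_ray_bundle(beam, _open_unit(rng), _open_unit(rng), _open_unit(rng), _open_unit(rng))
    t_fs = sample_emission_time(pulse, _open_unit(rng)) if pulse.shape is not PulseShape.DELTA else 0.0
    t_ps = t_fs * 1e-3 + (0.0 - beam.focus_z) / ray.direction[2] / C_UM_PS
    return PhotonState(ray.origin, ray.direction, 1.0, t_ps)


def make_photons(pulse: PulseSpec, beam: BeamSpec, n: int, rng: np.random.Generator):
    """Vectorized launch: (origins[n,3], directions[n,3], times_ps[n])."""
    if beam.kind is BeamKind.PENCIL:
        origins = np.zeros((n, 3))
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    elif beam.kind is BeamKind.GAUSSIAN_PENCIL:
        xi = rng.random((2, n))
        x = _gauss_quantile(np.clip(xi[0], 1e-16, None), beam.focal_waist)
        y = _gauss_quantile(np.clip(xi[1], 1e-16, None), beam.focal_waist)
        origins = np.stack([x, y, np.zeros(n)], axis=1)
        dirs = np.tile([0.0, 0.0, 1.0], (n, 1))
    else:
        origins, dirs = sample_ray_bundle_batch(beam, n, rng)
    times = sample_emission_times(pulse, n, rng) * 1e-3
    times = times + (0.0 - beam.focus_z) / dirs[:, 2] / C_UM_PS
    return origins, dirs, times


def _open_unit(rng: np.random.Generator) -> float:
    """Uniform variate strictly inside (0, 1)."""
    while True:
        u = rng.random()
        if 0.0 < u < 1.0:
            return u
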