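"""Monte Carlo photon transport through a plane-parallel scattering slab.

MCML-style kernel: photons are launched at the entrance plane z = 0, refract
into the slab through an unpolarized-Fresnel interface, perform an
exponential random walk with Henyey–Greenstein scattering, lose weight
continuously to absorption (exp(−μa·path)), and exit through either face
after a stochastic Fresnel decision. The elapsed time advances by
path·n_slab/c, which is what makes the simulation time-resolved.

Conventions: lengths in μm, time in ps, c = 299.792458 μm/ps; z ∈ [0, L]
with the entrance at z = 0; transverse extent unbounded. Weights terminate
by Russian roulette (threshold 1e−4, survival 0.1) with exact per-photon
energy bookkeeping: transmitted + reflected + absorbed + truncated equals
the launched weight to machine precision.

The hot loop is compiled with numba and uses numba's internal
Mersenne-Twister stream; step lengths use the same memorylessness tail
recursion as :mod:`slabmc.step_sampling`, so their support is unbounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .sources import BeamSpec, PulseSpec, make_photons
from .step_sampling import StepSampler

__all__ = [
    "C_UM_PS",
    "SlabSpec",
    "ExitRecords",
    "henyey_greenstein_scatter",
    "fresnel_interaction",
    "propagate_photon",
    "propagate_batch",
    "run_simulation",
]

#: vacuum speed of light, μm/ps
C_UM_PS = 299.792458

# exit codes written by the kernel
EXIT_TRANSMIT = 0
EXIT_REFLECT = 1
EXIT_ABSORBED = 2
EXIT_TRUNCATED = 3

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 0.1
_TAIL_XI = 2.0**-32
_TAIL_OFFSET = 32.0 * math.log(2.0)


@dataclass(frozen=True)
class SlabSpec:
    """Plane-parallel scattering slab.

    Parameters
    ----------
    thickness : float
        L, μm.
    n_slab : float
        Internal (effective) refractive index.
    n_front, n_back : float
        External indices (default air on both sides).
    mu_s : float
        Scattering coefficient μs, μm⁻¹ (0 for a clear slab).
    mu_a : float
        Absorption coefficient μa, μm⁻¹.
    g : float
        Henyey–Greenstein anisotropy, ⟨cosθ⟩ ∈ (−1, 1).
    """

    thickness: float
    n_slab: float = 1.526
    n_front: float = 1.0
    n_back: float = 1.0
    mu_s: float = 0.0
    mu_a: float = 0.0
    g: float = 0.0

    def __post_init__(self):
        if not self.thickness > 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if self.mu_s < 0 or self.mu_a < 0:
            raise ValueError("mu_s and mu_a must be >= 0")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        for n in (self.n_slab, self.n_front, self.n_back):
            if n < 1.0:
                raise ValueError("refractive indices must be >= 1")

    @property
    def ls(self) -> float:
        """Scattering mean free path 1/μs, μm (inf for a clear slab)."""
        return 1.0 / self.mu_s if self.mu_s > 0 else math.inf

    @property
    def transport_mfp(self) -> float:
        """Transport mean free path ls′ = ls/(1−g), μm."""
        return self.ls / (1.0 - self.g)

    @property
    def energy_velocity(self) -> float:
        """v = c/n_slab, μm/ps."""
        return C_UM_PS / self.n_slab

    @classmethod
    def from_transport_mfp(cls, thickness: float, transport_mfp: float, g: float,
                           mu_a: float = 0.0, n_slab: float = 1.526,
                           n_front: float = 1.0, n_back: float = 1.0) -> "SlabSpec":
        """Build a slab from (ls′, g) instead of μs: μs = 1/(ls′·(1−g))."""
        return cls(thickness=thickness, n_slab=n_slab, n_front=n_front,
                   n_back=n_back, mu_s=1.0 / (transport_mfp * (1.0 - g)),
                   mu_a=mu_a, g=g)


@dataclass
class ExitRecords:
    """Per-photon outcome arrays from a propagation batch.

    ``code`` is 0 transmit / 1 reflect / 2 absorbed (roulette) /
    3 truncated (time cap, reported — never silently dropped). ``x, y`` are
    the exit-plane coordinates (μm), ``time`` the exit clock (ps),
    ``weight`` the exit weight, ``scatter_count`` the number of scattering
    events, ``absorbed`` the per-photon absorbed weight and ``path`` the
    total internal pathlength (μm).
    """

    code: np.ndarray
    x: np.ndarray
    y: np.ndarray
    time: np.ndarray
    weight: np.ndarray
    scatter_count: np.ndarray
    absorbed: np.ndarray
    path: np.ndarray

    @property
    def rho(self) -> np.ndarray:
        """Radial exit distance √(x²+y²), μm."""
        return np.hypot(self.x, self.y)

    def select(self, code: int) -> "ExitRecords":
        m = self.code == code
        return ExitRecords(self.code[m], self.x[m], self.y[m], self.time[m],
                           self.weight[m], self.scatter_count[m],
                           self.absorbed[m], self.path[m])

    @property
    def transmitted(self) -> "ExitRecords":
        return self.select(EXIT_TRANSMIT)

    @property
    def reflected(self) -> "ExitRecords":
        return self.select(EXIT_REFLECT)

    @staticmethod
    def concatenate(parts: list["ExitRecords"]) -> "ExitRecords":
        return ExitRecords(*[np.concatenate([getattr(p, f) for p in parts])
                             for f in ("code", "x", "y", "time", "weight",
                                       "scatter_count", "absorbed", "path")])


# ---------------------------------------------------------------------------
# elementary interactions (python-level API; the kernel inlines the same math)
# ---------------------------------------------------------------------------

def henyey_greenstein_scatter(direction: np.ndarray, g: float,
                              xi1: float, xi2: float) -> np.ndarray:
    """Deflect a unit direction by a Henyey–Greenstein polar angle.

    cosθ is drawn from the HG inverse CDF (uniform in [−1, 1] for g = 0),
    the azimuth uniformly in [0, 2π); ⟨cosθ⟩ = g.
    """
    if not -1.0 < g < 1.0:
        raise ValueError("g must lie in (-1, 1)")
    if g != 0.0:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi1)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    else:
        ct = 2.0 * xi1 - 1.0
    ct = min(1.0, max(-1.0, ct))
    st = math.sqrt(1.0 - ct * ct)
    phi = 2.0 * math.pi * xi2
    return _rotate_direction(np.asarray(direction, dtype=float), ct, st,
                             math.cos(phi), math.sin(phi))


def _rotate_direction(u, ct, st, cp, sp):
    ux, uy, uz = u
    if abs(uz) > 0.99999:
        out = np.array([st * cp, st * sp, ct if uz > 0 else -ct])
    else:
        den = math.sqrt(1.0 - uz * uz)
        out = np.array([
            st * (ux * uz * cp - uy * sp) / den + ux * ct,
            st * (uy * uz * cp + ux * sp) / den + uy * ct,
            -den * st * cp + uz * ct,
        ])
    return out / np.linalg.norm(out)


def fresnel_reflectance(cos_i: float, n1: float, n2: float) -> float:
    """Unpolarized Fresnel power reflectance for incidence cosine ``cos_i``."""
    cos_i = abs(cos_i)
    sin2_t = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin2_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin2_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_interaction(direction: np.ndarray, n1: float, n2: float,
                        xi: float) -> tuple[np.ndarray, bool]:
    """Stochastic unpolarized Fresnel decision at a z-normal interface.

    Returns ``(new_direction, transmitted)``: with probability R(θi) the
    specular reflection (z-component flipped), otherwise the Snell-refracted
    direction. Beyond the critical angle reflection is certain.
    """
    u = np.asarray(direction, dtype=float)
    R = fresnel_reflectance(u[2], n1, n2)
    if xi < R:
        return np.array([u[0], u[1], -u[2]]), False
    if n1 == n2:
        return u.copy(), True
    scale = n1 / n2
    tz2 = 1.0 - scale * scale * (1.0 - u[2] * u[2])
    tz = math.copysign(math.sqrt(max(tz2, 0.0)), u[2])
    out = np.array([u[0] * scale, u[1] * scale, tz])
    return out / np.linalg.norm(out), True


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _exp_step(ls):
    """Exponential step with unbounded support (memorylessness recursion)."""
    off = 0.0
    while True:
        xi = np.random.random()
        if xi <= 1.0 - _TAIL_XI:
            return off - ls * np.log(1.0 - xi)
        off += ls * _TAIL_OFFSET


@njit(cache=True, fastmath=True)
def _fresnel_R(ci, n1, n2):
    ci = abs(ci)
    sin2_t = (n1 / n2) ** 2 * (1.0 - ci * ci)
    if sin2_t >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - sin2_t)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _kernel(seed, x0, y0, z0, ux0, uy0, uz0, t0,
            L, n_slab, n_front, n_back, mu_s, mu_a, g, time_cap,
            apply_entry_fresnel,
            out_code, out_x, out_y, out_t, out_w, out_ns, out_abs, out_path):
    np.random.seed(seed)
    n = x0.size
    v = C_UM_PS / n_slab
    ls = 1.0 / mu_s if mu_s > 0.0 else 1e300
    for i in range(n):
        x = x0[i]; y = y0[i]; z = z0[i]
        ux = ux0[i]; uy = uy0[i]; uz = uz0[i]
        t = t0[i]
        w = 1.0
        absorbed = 0.0
        path = 0.0
        nscat = 0

        if apply_entry_fresnel:
            R = _fresnel_R(uz, n_front, n_slab)
            if np.random.random() < R:
                # specular reflection at the entrance: photon never enters
                out_code[i] = EXIT_REFLECT
                out_x[i] = x; out_y[i] = y; out_t[i] = t
                out_w[i] = w; out_ns[i] = 0; out_abs[i] = 0.0; out_path[i] = 0.0
                continue
            scale = n_front / n_slab
            tz2 = 1.0 - scale * scale * (1.0 - uz * uz)
            if tz2 < 0.0:
                tz2 = 0.0
            tz = np.sqrt(tz2)
            if uz < 0.0:
                tz = -tz
            nrm = np.sqrt(ux * ux * scale * scale + uy * uy * scale * scale + tz * tz)
            ux = ux * scale / nrm; uy = uy * scale / nrm; uz = tz / nrm

        code = EXIT_ABSORBED
        while True:
            step = _exp_step(ls)
            if uz > 0.0:
                s_b = (L - z) / uz
            elif uz < 0.0:
                s_b = -z / uz
            else:
                s_b = 1e300
            hit = step >= s_b
            s = s_b if hit else step
            x += ux * s; y += uy * s; z += uz * s
            t += s / v
            path += s
            if mu_a > 0.0:
                surv = np.exp(-mu_a * s)
                absorbed += w * (1.0 - surv)
                w *= surv
            if t > time_cap:
                code = EXIT_TRUNCATED
                break
            if hit:
                n_out = n_back if uz > 0.0 else n_front
                R = _fresnel_R(uz, n_slab, n_out)
                if np.random.random() < R:
                    uz = -uz
                    # clamp tiny numerical drift back inside
                    if z < 0.0:
                        z = 0.0
                    elif z > L:
                        z = L
                    continue
                # refract and exit
                scale = n_slab / n_out
                tz2 = 1.0 - scale * scale * (1.0 - uz * uz)
                if tz2 < 0.0:
                    tz2 = 0.0
                tz = np.sqrt(tz2)
                if uz < 0.0:
                    tz = -tz
                nrm = np.sqrt(ux * ux * scale * scale + uy * uy * scale * scale + tz * tz)
                ux = ux * scale / nrm; uy = uy * scale / nrm; uz = tz / nrm
                code = EXIT_TRANSMIT if uz > 0.0 else EXIT_REFLECT
                break
            # scatter
            nscat += 1
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
            else:
                ct = 2.0 * np.random.random() - 1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            cp = np.cos(phi); sp = np.sin(phi)
            if uz > 0.99999 or uz < -0.99999:
                ux = st * cp; uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -den * st * cp + uz * ct
                nrm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux = nux / nrm; uy = nuy / nrm; uz = nuz / nrm
            # Russian roulette with exact weight bookkeeping
            if w < _ROULETTE_THRESHOLD:
                if np.random.random() < _ROULETTE_SURVIVAL:
                    boost = w / _ROULETTE_SURVIVAL - w
                    absorbed -= boost
                    w += boost
                else:
                    absorbed += w
                    w = 0.0
                    code = EXIT_ABSORBED
                    break

        out_code[i] = code
        out_x[i] = x; out_y[i] = y; out_t[i] = t
        out_w[i] = w if (code == EXIT_TRANSMIT or code == EXIT_REFLECT or code == EXIT_TRUNCATED) else 0.0
        out_ns[i] = nscat
        out_abs[i] = absorbed
        out_path[i] = path
        if code == EXIT_TRUNCATED:
            out_w[i] = w
    return 0


def propagate_batch(origins: np.ndarray, directions: np.ndarray, times: np.ndarray,
                    slab: SlabSpec, seed: int, time_cap: float = 50.0,
                    apply_entry_fresnel: bool = True) -> ExitRecords:
    """Propagate a batch of photons with given launch states.

    ``origins[n,3]`` (μm), unit ``directions[n,3]``, ``times[n]`` (ps).
    ``seed`` seeds the kernel's internal stream (keep < 2³¹). The entry
    Fresnel interaction (n_front → n_slab) is applied stochastically per
    photon unless the launch states are already inside the slab.
    """
    n = len(times)
    out = {k: np.empty(n) for k in ("x", "y", "t", "w", "abs", "path")}
    code = np.empty(n, dtype=np.int64)
    ns = np.empty(n, dtype=np.int64)
    _kernel(int(seed) % (2**31), np.ascontiguousarray(origins[:, 0]),
            np.ascontiguousarray(origins[:, 1]), np.ascontiguousarray(origins[:, 2]),
            np.ascontiguousarray(directions[:, 0]), np.ascontiguousarray(directions[:, 1]),
            np.ascontiguousarray(directions[:, 2]), np.ascontiguousarray(times, dtype=float),
            slab.thickness, slab.n_slab, slab.n_front, slab.n_back,
            slab.mu_s, slab.mu_a, slab.g, time_cap, apply_entry_fresnel,
            code, out["x"], out["y"], out["t"], out["w"], ns, out["abs"], out["path"])
    return ExitRecords(code, out["x"], out["y"], out["t"], out["w"], ns,
                       out["abs"], out["path"])


def propagate_photon(position, direction, time, slab: SlabSpec,
                     sampler: StepSampler | None = None, seed: int = 0,
                     time_cap: float = 50.0):
    """Propagate a single photon already inside the slab (no entry Fresnel).

    Convenience wrapper over the batch kernel; returns a 1-photon
    :class:`ExitRecords`. ``sampler`` is accepted for interface symmetry —
    the kernel draws its steps from the same unbounded-support scheme.
    """
    o = np.asarray(position, dtype=float)[None, :]
    d = np.asarray(direction, dtype=float)[None, :]
    return propagate_batch(o, d, np.array([float(time)]), slab, seed,
                           time_cap=time_cap, apply_entry_fresnel=False)


def run_simulation(pulse: PulseSpec, beam: BeamSpec, slab: SlabSpec,
                   n_photons: int, seed: int, time_cap: float = 50.0,
                   batch_size: int = 1_000_000) -> ExitRecords:
    """Launch ``n_photons`` through the slab and return all exit records.

    Deterministic given (specs, n_photons, seed): source sampling uses a
    PCG64 stream and the kernel a Mersenne-Twister stream, with per-batch
    seeds derived from ``seed`` via ``SeedSequence``. Runs in fixed-size
    sequential batches so results do not depend on memory or scheduling.
    """
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    master = np.random.SeedSequence(seed)
    n_batches = max(1, -(-n_photons // batch_size)) if n_photons else 0
    if n_photons == 0:
        empty = np.empty(0)
        return ExitRecords(np.empty(0, dtype=np.int64), empty, empty, empty,
                           empty, np.empty(0, dtype=np.int64), empty.copy(), empty.copy())
    children = master.spawn(n_batches)
    parts = []
    done = 0
    for b in range(n_batches):
        nb = min(batch_size, n_photons - done)
        done += nb
        src_seq, ker_seq = children[b].spawn(2)
        rng = np.random.Generator(np.random.PCG64(src_seq))
        kernel_seed = int(ker_seq.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        origins, dirs, times = make_photons(pulse, beam, nb, rng)
        parts.append(propagate_batch(origins, dirs, times, slab, kernel_seed,
                                     time_cap=time_cap))
    return ExitRecords.concatenate(parts)
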