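"""Fitting and optical-property retrieval.

Two observables characterize the slab:

* the late-time transmittance decay time τ (exponential tail of the total
  time-resolved transmittance), which feels both scattering confinement and
  absorption: 1/τ = 1/τ₀(ls′) + μa·v, because a homogeneous absorber acts as
  a pure multiplicative factor exp(−μa·v·t) on any time-of-flight curve;
* the mean-square-width growth rate d⟨ρ²⟩/dt of the transmitted profile,
  which is amplitude-invariant and therefore completely insensitive to μa.

That split enables the two-step retrieval implemented here: first invert
the μa = 0 Monte Carlo forward model so its MSW growth matches the measured
one (fixing ls′), then read μa off the decay-rate difference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .detectors import RadialTimeMap, TimeHistogram, mean_square_width
from .transport import SlabSpec

__all__ = [
    "FitResult",
    "RetrievalResult",
    "convolve_irf",
    "fit_decay_rate",
    "fit_msw_growth",
    "retrieve_optical_properties",
]


@dataclass(frozen=True)
class FitResult:
    """Weighted least-squares fit summary."""

    params: tuple
    stderr: tuple
    window: tuple
    chi2_reduced: float

    @property
    def value(self) -> float:
        return self.params[0]

    @property
    def error(self) -> float:
        return self.stderr[0]


@dataclass(frozen=True)
class RetrievalResult:
    """Outcome of the two-step (ls′, μa) retrieval."""

    transport_mfp: float
    mu_a: float
    mu_a_stderr: float
    tau_mc: float
    slope_mc: float
    n_evaluations: int
    flags: tuple = ()


def convolve_irf(h: TimeHistogram, irf: np.ndarray, irf_dt: float | None = None) -> TimeHistogram:
    """Convolve a time histogram with a tabulated instrument response.

    ``irf`` is sampled on the histogram's own time step (pass ``irf_dt`` to
    assert the step; a mismatch raises rather than silently resampling) and
    is normalized to unit area before convolution, so the total tallied
    weight is preserved. A single-sample IRF is the identity. The output
    grid is extended to hold the full convolution.
    """
    dt = h.dt
    if irf_dt is not None and not math.isclose(irf_dt, dt, rel_tol=1e-9):
        raise ValueError(f"IRF step {irf_dt} does not match histogram step {dt}; resample first")
    if not np.allclose(np.diff(h.edges), dt):
        raise ValueError("convolve_irf requires a uniform time grid")
    irf = np.asarray(irf, dtype=float)
    s = irf.sum()
    if s <= 0:
        raise ValueError("IRF must have positive total weight")
    out = np.convolve(h.weights, irf / s)
    n_extra = irf.size - 1
    edges = np.concatenate([h.edges, h.edges[-1] + dt * np.arange(1, n_extra + 1)])
    return TimeHistogram(edges, side=h.side, weights=out, out_of_range=h.out_of_range)


def _wls_line(t, y, w):
    """Weighted straight-line fit y = a + b·t; returns a, b, their standard
    errors and reduced χ²."""
    W = np.asarray(w, dtype=float)
    A = np.stack([np.ones_like(t), t], axis=1)
    Aw = A * W[:, None]
    cov = np.linalg.inv(A.T @ Aw)
    beta = cov @ (Aw.T @ y)
    resid = y - A @ beta
    dof = max(len(t) - 2, 1)
    chi2 = float((W * resid**2).sum() / dof)
    se = np.sqrt(np.diag(cov) * max(chi2, 1.0)) if dof > 0 else np.full(2, np.nan)
    return beta, se, chi2


def fit_decay_rate(h: TimeHistogram, window: tuple[float, float]) -> FitResult:
    """Exponential decay time τ (ps) from the transmittance tail.

    Weighted least squares of ln(weight) vs t over ``window``, with
    Poisson-motivated weights proportional to the bin weight (var[ln n] ≈
    1/n). Non-positive bins are excluded with a warning.
    """
    t = h.centers
    m = (t >= window[0]) & (t <= window[1])
    if not np.any(m):
        raise ValueError(f"fit window {window} contains no bins")
    t, y = t[m], h.weights[m]
    pos = y > 0
    if np.count_nonzero(~pos):
        warnings.warn(f"excluding {np.count_nonzero(~pos)} non-positive bins from the decay fit",
                      stacklevel=2)
    t, y = t[pos], y[pos]
    if t.size < 10:
        raise ValueError(f"only {t.size} populated bins in window {window}; need >= 10")
    beta, se, chi2 = _wls_line(t, np.log(y), y)
    slope = beta[1]
    if slope >= 0:
        raise ValueError("no decay in the fit window (non-negative slope)")
    tau = -1.0 / slope
    tau_se = se[1] / slope**2
    return FitResult(params=(tau,), stderr=(float(tau_se),), window=tuple(window),
                     chi2_reduced=chi2)


def fit_msw_growth(msw_time, msw=None, stderr=None,
                   window: tuple[float, float] = (1.0, 3.5)) -> FitResult:
    """Linear growth rate of ⟨ρ²⟩(t) (μm²/ps) over ``window``.

    Accepts either a :class:`RadialTimeMap` or explicit (t, ⟨ρ²⟩, σ)
    arrays. Weighted by 1/σ² when standard errors are available.
    """
    if isinstance(msw_time, RadialTimeMap):
        t, y, s = mean_square_width(msw_time)
    else:
        t, y, s = (np.asarray(msw_time, dtype=float), np.asarray(msw, dtype=float),
                   None if stderr is None else np.asarray(stderr, dtype=float))
    m = (t >= window[0]) & (t <= window[1]) & np.isfinite(y)
    if np.count_nonzero(m) < 5:
        raise ValueError(f"only {np.count_nonzero(m)} populated MSW bins in window {window}; need >= 5")
    t, y = t[m], y[m]
    if s is not None and np.all(np.isfinite(s[m])) and np.all(s[m] > 0):
        w = 1.0 / s[m] ** 2
    else:
        w = np.ones_like(t)
    beta, se, chi2 = _wls_line(t, y, w)
    return FitResult(params=(float(beta[1]), float(beta[0])),
                     stderr=(float(se[1]), float(se[0])),
                     window=tuple(window), chi2_reduced=chi2)


def retrieve_optical_properties(measured_slope: float, measured_tau: float,
                                slab_geometry: SlabSpec, forward,
                                bracket: tuple[float, float] = (10.0, 100.0),
                                tol: float = 0.25, max_iter: int = 12,
                                tau_uncertainty: float = 0.0) -> RetrievalResult:
    """Two-step retrieval of (ls′, μa) from measured MSW slope and decay time.

    Step 1: bisection over the transport mean free path ls′ ∈ ``bracket``
    so that the μa = 0 forward Monte Carlo reproduces ``measured_slope``
    (μm²/ps). The MSW is absorption-independent, so μa = 0 is exact here.
    ``forward(transport_mfp)`` must run the MC with common random numbers
    and return ``(msw_slope, tau_mc)`` for the μa = 0 slab. The objective is
    checked for monotonicity across the bracket.

    Step 2: μa = (1/τ_measured − 1/τ_MC)/v, from absorption acting as the
    multiplicative factor exp(−μa·v·t) with energy velocity v = c/n_slab.
    A negative estimate is reported (with uncertainty) and flagged, never
    clipped.
    """
    v = slab_geometry.energy_velocity
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("invalid bracket")
    f_lo, _ = forward(lo)
    f_hi, _ = forward(hi)
    n_eval = 2
    if not (min(f_lo, f_hi) <= measured_slope <= max(f_lo, f_hi)):
        raise ValueError(
            f"measured slope {measured_slope:.4g} not bracketed by forward model "
            f"([{f_lo:.4g}, {f_hi:.4g}] over ls' in {bracket})")
    increasing = f_hi > f_lo
    while hi - lo > tol and n_eval < max_iter + 2:
        mid = 0.5 * (lo + hi)
        f_mid, _ = forward(mid)
        n_eval += 1
        # monotonicity assertion of the step-1 objective over the bracket
        if increasing and not (f_lo <= f_mid <= f_hi) or (not increasing and not (f_hi <= f_mid <= f_lo)):
            warnings.warn("MSW slope objective is not monotone at this noise level; "
                          "result may be bracket-dependent", stacklevel=2)
        if (f_mid < measured_slope) == increasing:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    ls_p = 0.5 * (lo + hi)
    slope_mc, tau_mc = forward(ls_p)
    n_eval += 1
    mu_a = (1.0 / measured_tau - 1.0 / tau_mc) / v
    mu_a_se = tau_uncertainty / (measured_tau**2 * v) if tau_uncertainty else 0.0
    flags = ()
    if not math.isfinite(mu_a):
        flags = ("tau_mc_unavailable",)
    elif mu_a < 0:
        flags = ("negative_mu_a",)
    return RetrievalResult(transport_mfp=ls_p, mu_a=mu_a, mu_a_stderr=mu_a_se,
                           tau_mc=tau_mc, slope_mc=slope_mc,
                           n_evaluations=n_eval, flags=flags)
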