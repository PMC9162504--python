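"""Exponential free-path generation with unbounded support.

A naive inverse-CDF step sampler ℓ = −ls·ln(1−ξ) inherits the resolution of
its uniform source: with 32-bit uniforms the largest representable step is
−ls·ln(2⁻³²) ≈ 22.18·ls, so the probability of any longer step is identically
zero instead of 2⁻³². Once a simulation draws more than ~2³² steps this
truncation biases the step distribution toward short steps — precisely the
regime of large time-resolved runs through thin films, where rare long steps
dominate the late tail.

Two production samplers avoid the truncation:

* ``inverse_cdf_64`` — 53-bit-resolution uniform doubles plus a
  memorylessness recursion: when ξ falls in the deep tail (ξ < 2⁻³²) the
  sampler banks the corresponding offset −ls·ln(2⁻³²) and redraws, so the
  support is genuinely unbounded and the distribution exactly exponential.
* ``ziggurat`` — NumPy's rejection-based exponential generator.

A deliberately 32-bit truncated sampler is provided for demonstrating the
artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "StepSampler",
    "truncated_32bit_steps",
    "truncation_bound",
    "tail_audit",
    "TailAudit",
]

#: deep-tail threshold for the memorylessness recursion: P(ξ < 2⁻³²) = 2⁻³²
_TAIL_XI = 2.0**-32
#: the offset banked per recursion, −ln(2⁻³²) ≈ 22.18 mean free paths
_TAIL_OFFSET = 32.0 * math.log(2.0)


class StepSampler:
    """Exponential step-length sampler with mean ``mean_free_path`` (μm).

    ``method`` is ``inverse_cdf_64`` (default) or ``ziggurat``; both have
    unbounded support. Deterministic given the seed; use
    :meth:`spawn` to derive independent substreams from a master seed.
    """

    def __init__(self, mean_free_path: float, method: str = "inverse_cdf_64",
                 seed=None):
        if not mean_free_path > 0:
            raise ValueError(f"mean_free_path must be > 0, got {mean_free_path}")
        if method not in ("inverse_cdf_64", "ziggurat"):
            raise ValueError(f"unknown method {method!r}")
        self.mean_free_path = float(mean_free_path)
        self.method = method
        self._seed_seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        self.rng = np.random.Generator(np.random.PCG64(self._seed_seq))

    def spawn(self, n: int) -> list["StepSampler"]:
        """``n`` independent child samplers (documented substream contract)."""
        return [StepSampler(self.mean_free_path, self.method, seq)
                for seq in self._seed_seq.spawn(n)]

    def sample(self) -> float:
        """One exponential step, μm."""
        return float(self.sample_n(1)[0])

    def sample_n(self, n: int) -> np.ndarray:
        """``n`` exponential steps, μm."""
        ls = self.mean_free_path
        if self.method == "ziggurat":
            return ls * self.rng.standard_exponential(n)
        out = np.zeros(n)
        idx = np.arange(n)
        while idx.size:
            xi = self.rng.random(idx.size)
            deep = xi > 1.0 - _TAIL_XI  # 1−ξ below 2⁻³²: bank the offset, redraw
            out[idx[~deep]] += -ls * np.log1p(-xi[~deep])
            out[idx[deep]] += ls * _TAIL_OFFSET
            idx = idx[deep]
        return out


def truncated_32bit_steps(mean_free_path: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Reference 32-bit inverse-CDF sampler: ℓ = −ls·ln(1−j/2³²).

    Reproduces the truncation artifact: no step can exceed
    ``truncation_bound(32)``·ls ≈ 22.18·ls.
    """
    j = rng.integers(0, 2**32, size=n, dtype=np.uint64)
    xi = j.astype(np.float64) / 2.0**32
    return -mean_free_path * np.log1p(-xi)


def truncation_bound(mantissa_bits: int) -> float:
    """Largest step (in units of ls) a ``mantissa_bits``-resolution naive
    inverse-CDF sampler can produce: −ln(2^−bits) = bits·ln 2.

    32 bits → ≈22.18; 64 bits → ≈44.36.
    """
    if mantissa_bits < 1:
        raise ValueError("mantissa_bits must be >= 1")
    return mantissa_bits * math.log(2.0)


@dataclass(frozen=True)
class TailAudit:
    """Empirical tail probability P(ℓ > k·ls) with a binomial CI."""

    k: float
    n: int
    exceed: int
    fraction: float
    ci_low: float
    ci_high: float
    expected: float


def tail_audit(sampler: StepSampler, k: float, n: int, confidence: float = 0.99) -> TailAudit:
    """Draw ``n`` steps and compare the fraction exceeding k·ls with e⁻ᵏ.

    The CI is the Clopper–Pearson binomial interval at ``confidence``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    steps = sampler.sample_n(n)
    exceed = int(np.count_nonzero(steps > k * sampler.mean_free_path))
    alpha = 1.0 - confidence
    lo = stats.beta.ppf(alpha / 2, exceed, n - exceed + 1) if exceed > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, exceed + 1, n - exceed) if exceed < n else 1.0
    return TailAudit(k=k, n=n, exceed=exceed, fraction=exceed / n,
                     ci_low=float(lo), ci_high=float(hi), expected=math.exp(-k))
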