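"""Uncertainty distributions for probabilistic sensitivity analysis.

Cost and utility inputs are published as a point estimate plus one of
three uncertainty formats: mean + standard error (utilities, sampled
Beta), mean + standard deviation (cost items, sampled Gamma), or mode +
[min, max] range (cost items, sampled Triangular). Beta and Gamma shapes
are recovered by the method of moments; inputs without published
uncertainty are held fixed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

#: Below this SE/SD the family degenerates to a point mass.
_DEGENERATE_TOL = 1e-12


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (alpha, beta) with the given mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError(f"beta se must be positive, got {se}")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: se^2={se*se:.6g} >= mean(1-mean)={mean*(1-mean):.6g}"
        )
    k = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * k, (1.0 - mean) * k


def gamma_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the given mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError(f"gamma moments must be positive, got mean={mean}, sd={sd}")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return shape, scale


def sample_triangular(mode: float, lo: float, hi: float, u: float | np.ndarray):
    """Inverse-CDF triangular sampling; density zero at lo/hi, peak at mode."""
    if not lo <= mode <= hi:
        raise ValueError(f"triangular requires lo <= mode <= hi, got {lo}, {mode}, {hi}")
    if not lo < hi:
        raise ValueError("triangular requires lo < hi")
    u = np.asarray(u, dtype=float)
    fc = (mode - lo) / (hi - lo)
    left = lo + np.sqrt(u * (hi - lo) * (mode - lo))
    right = hi - np.sqrt((1.0 - u) * (hi - lo) * (hi - mode))
    out = np.where(u < fc, left, right)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DistributionSpec:
    """One sampled input: family plus its published moments.

    family "beta":       mean + se       (utilities)
    family "gamma":      mean + sd       (costs)
    family "triangular": mode + lo + hi  (costs; mode stored in `mean`)
    family "fixed":      mean only
    """

    family: str
    mean: float
    se: float | None = None
    sd: float | None = None
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "triangular", "fixed"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "beta":
            if self.se is None:
                raise ValueError("beta spec requires se")
            if self.se > _DEGENERATE_TOL:
                beta_from_moments(self.mean, self.se)  # feasibility check, eager
        elif self.family == "gamma":
            if self.sd is None:
                raise ValueError("gamma spec requires sd")
            if self.sd > _DEGENERATE_TOL:
                gamma_from_moments(self.mean, self.sd)
        elif self.family == "triangular":
            if self.lo is None or self.hi is None:
                raise ValueError("triangular spec requires lo and hi")
            if not self.lo < self.hi:
                raise ValueError(f"triangular requires lo < hi, got {self.lo}, {self.hi}")

    @classmethod
    def triangular_clamped(cls, mode: float, lo: float, hi: float) -> "DistributionSpec":
        """Triangular spec, clamping an out-of-range mode into [lo, hi]."""
        clamped = min(max(mode, lo), hi)
        if clamped != mode:
            log.warning(
                "triangular mode %.4f outside [%.4f, %.4f]; clamped to %.4f",
                mode, lo, hi, clamped,
            )
        return cls(family="triangular", mean=clamped, lo=lo, hi=hi)

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.mean
        if self.family == "beta":
            if self.se <= _DEGENERATE_TOL:
                return self.mean
            a, b = beta_from_moments(self.mean, self.se)
            return float(rng.beta(a, b))
        if self.family == "gamma":
            if self.sd <= _DEGENERATE_TOL:
                return self.mean
            shape, scale = gamma_from_moments(self.mean, self.sd)
            return float(rng.gamma(shape, scale))
        # triangular
        return float(sample_triangular(self.mean, self.lo, self.hi, rng.random()))
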