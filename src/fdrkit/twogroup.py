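"""Two-group Gaussian mixture model on the Z scale.

Each feature's Z-value is drawn from the null density f0 ~ N(null_mean,
null_sd^2) with probability pi0, or from the alternative f1 ~ N(alt_mean,
alt_sd^2) with probability pi1 = 1 - pi0.  The mixture CDF is
F = pi0*F0 + pi1*F1, and for a rejection region R the empirical-Bayes FDR is

    FDR(R) = Pr(null | z in R) = pi0 * F0(R) / F(R).

Regions are one- or two-tailed half-lines: ``("greater", c)`` means z >= c,
``("less", c)`` means z <= c, and ``("two.sided", c)`` means |z| >= c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["TwoGroupModel", "mixture_density", "fdr_region"]

_REGION_KINDS = ("greater", "less", "two.sided")


@dataclass
class TwoGroupModel:
    """Mixture of a Gaussian null and a Gaussian alternative."""

    pi0: float
    alt_mean: float = 2.0
    alt_sd: float = 1.0
    null_mean: float = 0.0
    null_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")
        if self.null_sd <= 0.0 or self.alt_sd <= 0.0:
            raise ValueError("standard deviations must be positive")

    @property
    def null(self):
        return stats.norm(self.null_mean, self.null_sd)

    @property
    def alt(self):
        return stats.norm(self.alt_mean, self.alt_sd)


def mixture_density(model: TwoGroupModel, z):
    """Mixture density pi0*f0(z) + (1-pi0)*f1(z)."""
    z = np.asarray(z, dtype=float)
    out = model.pi0 * model.null.pdf(z) + (1.0 - model.pi0) * model.alt.pdf(z)
    return float(out) if out.ndim == 0 else out


def _tail_mass(dist, kind: str, cutoff: float) -> float:
    if kind == "greater":
        return float(dist.sf(cutoff))
    if kind == "less":
        return float(dist.cdf(cutoff))
    # two.sided: |z| >= cutoff (cutoff taken as its magnitude)
    c = abs(cutoff)
    return float(dist.sf(c) + dist.cdf(-c))


def fdr_region(model: TwoGroupModel, region) -> float:
    """Empirical-Bayes FDR of a tail rejection region.

    ``region`` is ``(kind, cutoff)`` with kind in {"greater", "less",
    "two.sided"}.  Raises when the region carries no mixture mass.
    """
    kind, cutoff = region
    if kind not in _REGION_KINDS:
        raise ValueError(f"unknown region kind {kind!r}; expected one of {_REGION_KINDS}")
    f0 = _tail_mass(model.null, kind, cutoff)
    f1 = _tail_mass(model.alt, kind, cutoff)
    f = model.pi0 * f0 + (1.0 - model.pi0) * f1
    if f <= 0.0:
        raise ZeroDivisionError("rejection region has zero mixture mass; FDR undefined")
    return model.pi0 * f0 / f
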