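"""Univariate Gaussian lower bound on the FDR.

For a single test with observed Z-statistic ``z`` and prior odds of the
alternative ``odds = pi1/pi0``, the posterior probability of the null — the
per-feature FDR — is bounded below by

    LB(z) = (1 + exp(z^2 / 2) * odds)^-1

the asymptotic chi-square form of the likelihood-ratio bound.  It depends only
on that feature's own data, so it applies even when a single p-value is all
there is, and it serves as a best-case benchmark for model-based FDR
estimates: an estimated FDR below the bound signals optimism in the estimate.
At z = 0 the bound equals 1/(1 + odds) (1/2 at the default odds of 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transforms import p_to_z, _check_sidedness

__all__ = ["LowerBoundConfig", "fdr_lower_bound_z", "fdr_lower_bound_p"]


@dataclass
class LowerBoundConfig:
    """Prior odds pi1/pi0 (default 1) and the sidedness of the p-values."""

    default_odds: float = 1.0
    sidedness: str = "two.sided"

    def __post_init__(self) -> None:
        if not self.default_odds > 0.0:
            raise ValueError(f"odds must be positive, got {self.default_odds}")
        _check_sidedness(self.sidedness)


def fdr_lower_bound_z(z, odds: float = 1.0):
    """Lower bound on the FDR at Z-statistic ``z`` with prior odds ``odds``."""
    if not odds > 0.0:
        raise ValueError(f"odds must be positive, got {odds}")
    arr = np.asarray(z, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("Z-values must be finite")
    # numerically stable form of (1 + exp(z^2/2) * odds)^-1
    expo = np.exp(-(arr**2) / 2.0)
    out = expo / (expo + odds)
    return float(out) if np.isscalar(z) else out


def fdr_lower_bound_p(p, config: LowerBoundConfig | None = None):
    """Lower bound on the FDR computed from raw p-values.

    Transforms p to Z under the configured sidedness and applies
    :func:`fdr_lower_bound_z`; vectorized, and valid for a single test.
    """
    config = config or LowerBoundConfig()
    z = p_to_z(p, config.sidedness)
    return fdr_lower_bound_z(z, config.default_odds)
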