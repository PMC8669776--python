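"""Null-proportion (pi0) estimation from raw p-values.

Under the two-group model a fraction pi0 of features is truly null, and null
p-values are Uniform(0, 1).  The estimators here exploit that flatness near
p = 1, where alternative p-values are scarce:

* ``last.hist`` (Last Histogram Height): bin the p-values into B equal-width
  bins over [0, 1] and read the occupancy H_B of the bin adjacent to 1;
  pi0_hat = H_B * B / m.  B defaults to Scott's normal reference rule.
* ``storey``: pi0_hat(lambda) = #{p_i > lambda} / (m * (1 - lambda)) over a
  lambda grid, smoothed with a natural cubic spline and read off at the
  largest lambda.
* ``pounds``: pi0_hat = min(1, 2 * mean(p)) — twice the mean of a Uniform(0,1)
  is 1, and alternatives drag the mean down.
* ``set.pi0``: a fixed, user-asserted value (default 1, the conservative
  choice).

All estimates are capped into [0, 1] before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .transforms import RawPValueSet

__all__ = [
    "Pi0Config",
    "Pi0Estimate",
    "scott_bin_count",
    "pi0_last_hist",
    "pi0_storey",
    "pi0_pounds",
    "get_pi0",
]

PI0_METHODS = ("set.pi0", "last.hist", "storey", "pounds")


def _default_lambda_grid() -> np.ndarray:
    # 0.05, 0.10, ..., 0.95 — the conventional Storey tuning grid
    return np.arange(1, 20) * 0.05


@dataclass
class Pi0Config:
    """Configuration for null-proportion estimation.

    ``estim_method`` selects the estimator; ``set_pi0`` is the fixed value
    used by ``set.pi0`` (default 1 — all features assumed null);
    ``hist_breaks`` is a bin count or the token ``"scott"``; ``lambda_grid``
    applies to Storey only.
    """

    estim_method: str = "set.pi0"
    set_pi0: float = 1.0
    hist_breaks: int | str = "scott"
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)

    def __post_init__(self) -> None:
        if self.estim_method not in PI0_METHODS:
            raise ValueError(
                f"unknown pi0 method {self.estim_method!r}; expected one of {PI0_METHODS}"
            )
        if not 0.0 <= self.set_pi0 <= 1.0:
            raise ValueError(f"set_pi0 must lie in [0, 1], got {self.set_pi0}")
        grid = np.asarray(self.lambda_grid, dtype=float).ravel()
        if grid.size and (np.any(grid <= 0.0) or np.any(grid >= 1.0)):
            raise ValueError("lambda grid values must lie strictly in (0, 1)")
        if grid.size > 1 and np.any(np.diff(grid) <= 0.0):
            raise ValueError("lambda grid must be strictly increasing")
        self.lambda_grid = grid


@dataclass
class Pi0Estimate:
    """A null-proportion estimate with provenance.

    ``bins_used`` and ``last_bin_height`` are populated by the histogram
    estimator only.  ``pi1 = 1 - value`` by definition.
    """

    value: float
    method: str
    bins_used: int | None = None
    last_bin_height: int | None = None

    @property
    def pi1(self) -> float:
        return 1.0 - self.value


def scott_bin_count(pset: RawPValueSet) -> int:
    """Number of equal-width bins over [0, 1] from Scott's reference rule.

    Bin width ``h = 3.49 * sd(p) * m^(-1/3)``; the count is ``ceil(1/h)``.
    Falls back to ``ceil(sqrt(m))`` when the spread is degenerate (sd = 0 or
    h >= 1), where the rule would give a single uninformative bin.
    """
    m = pset.m
    if m < 2:
        raise ValueError("Scott's rule needs at least 2 p-values")
    sd = float(np.std(pset.values, ddof=1))
    h = 3.49 * sd * m ** (-1.0 / 3.0)
    # degenerate spread (constant vector up to float noise, or a single bin)
    if h < 1e-9 or h >= 1.0:
        return math.ceil(math.sqrt(m))
    return math.ceil(1.0 / h)


def _resolve_breaks(pset: RawPValueSet, breaks: int | str) -> int:
    if isinstance(breaks, str):
        if breaks != "scott":
            raise ValueError(f"unknown hist_breaks token {breaks!r}")
        return scott_bin_count(pset)
    b = int(breaks)
    if b < 1:
        raise ValueError(f"bin count must be >= 1, got {b}")
    return b


def pi0_last_hist(pset: RawPValueSet, breaks: int | str = "scott") -> Pi0Estimate:
    """Last Histogram Height estimator: pi0_hat = min(1, H_B * B / m).

    Bins are half-open ``[a, b)`` with the final bin closed ``[a, 1]`` so that
    p = 1 is counted in H_B.
    """
    m = pset.m
    if m < 2:
        raise ValueError("last.hist needs at least 2 p-values")
    b = _resolve_breaks(pset, breaks)
    counts, _ = np.histogram(pset.values, bins=b, range=(0.0, 1.0))
    h_b = int(counts[-1])
    value = min(1.0, h_b * b / m)
    return Pi0Estimate(value=value, method="last.hist", bins_used=b, last_bin_height=h_b)


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    # Truncated-power natural cubic spline basis (linear beyond boundary knots)
    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[-1], 0.0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    for k in range(len(knots) - 2):
        cols.append(d(k) - d(len(knots) - 2))
    return np.column_stack(cols)


def pi0_storey(pset: RawPValueSet, lambda_grid=None) -> Pi0Estimate:
    """Storey's tunable estimator with natural-cubic-spline smoothing.

    For each lambda, ``pi0_hat(lambda) = #{p_i > lambda} / (m (1 - lambda))``.
    With a multi-point grid the curve is smoothed by an OLS fit on a 3-knot
    natural cubic spline basis (3 effective degrees of freedom) and evaluated
    at the largest lambda; a single-point grid returns the raw ratio.  The
    result is capped to [0, 1].
    """
    m = pset.m
    if m < 2:
        raise ValueError("storey needs at least 2 p-values")
    grid = np.asarray(
        _default_lambda_grid() if lambda_grid is None else lambda_grid, dtype=float
    ).ravel()
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(grid <= 0.0) or np.any(grid >= 1.0):
        raise ValueError("lambda grid values must lie strictly in (0, 1)")
    p = pset.values
    raw = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    if grid.size == 1:
        value = raw[0]
    elif grid.size < 3:
        coef = np.polyfit(grid, raw, 1)
        value = float(np.polyval(coef, grid[-1]))
    else:
        knots = np.quantile(grid, [0.0, 0.5, 1.0])
        basis = _natural_cubic_basis(grid, knots)
        beta, *_ = np.linalg.lstsq(basis, raw, rcond=None)
        value = float((_natural_cubic_basis(grid[-1:], knots) @ beta)[0])
    return Pi0Estimate(value=float(min(1.0, max(0.0, value))), method="storey")


def pi0_pounds(pset: RawPValueSet) -> Pi0Estimate:
    """Pounds-Morris estimator: pi0_hat = min(1, 2 * mean(p))."""
    if pset.m < 1:
        raise ValueError("pounds needs at least 1 p-value")
    value = min(1.0, 2.0 * float(np.mean(pset.values)))
    return Pi0Estimate(value=value, method="pounds")


def get_pi0(pset: RawPValueSet, config: Pi0Config | None = None) -> Pi0Estimate:
    """Dispatch to the configured estimator.

    ``set.pi0`` ignores the data and returns the fixed value unchanged.
    """
    config = config or Pi0Config()
    method = config.estim_method
    if method == "set.pi0":
        return Pi0Estimate(value=config.set_pi0, method="set.pi0")
    if method == "last.hist":
        return pi0_last_hist(pset, config.hist_breaks)
    if method == "storey":
        return pi0_storey(pset, config.lambda_grid)
    if method == "pounds":
        return pi0_pounds(pset)
    raise ValueError(f"unknown pi0 method {method!r}")
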