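"""Conversions between p-values and Z-values, and p-value ranking.

A raw p-value ``p_i`` is mapped onto the Z scale through standard-normal
quantiles: ``z_i = PHI^-1(1 - p_i/2)`` for two-sided tests and
``z_i = PHI^-1(1 - p_i)`` for one-sided "greater" tests.  These Z-values are a
device for empirical-Bayes FDR work on a Gaussian scale; they are not the
original test statistics.  Ranking supports the tie-handling conventions of
R's ``rank`` (first, last, average, min, max, random), with random tie
resolution made reproducible through an explicit or internal fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SIDEDNESS",
    "RawPValueSet",
    "p_to_z",
    "z_to_p",
    "rank_pvalues",
]

#: Recognised sidedness labels for the p <-> Z mapping.
SIDEDNESS = ("two.sided", "greater", "less")

TIES_METHODS = ("first", "last", "average", "min", "max", "random")

# Internal seed for ties_method="random" when the caller supplies none, so
# repeated calls on the same data give identical ranks.
_DEFAULT_TIE_SEED = 1952

# p = 0 is clamped to the smallest positive normal double inside the quantile
# transform so Z stays finite (clamping happens after any division by 2).
_TINY_P = float(np.finfo(float).tiny)


def _check_sidedness(sidedness: str) -> str:
    if sidedness not in SIDEDNESS:
        raise ValueError(
            f"unknown sidedness {sidedness!r}; expected one of {SIDEDNESS}"
        )
    return sidedness


@dataclass
class RawPValueSet:
    """A vector of raw (unadjusted) p-values with NA and tie policy.

    Parameters
    ----------
    values
        Probabilities in ``[0, 1]``; ``NaN`` marks a missing entry.
    na_policy
        ``"remove"`` drops missing entries (the default); ``"fail"`` raises.
        ``m`` always counts retained values only — missing entries never
        inflate the multiplicity correction.
    ties_method
        How tied p-values are ranked; default ``"random"``.
    tie_seed
        Seed driving random tie resolution.  ``None`` uses an internal fixed
        seed so results are reproducible by default.
    """

    values: np.ndarray
    na_policy: str = "remove"
    ties_method: str = "random"
    tie_seed: int | None = None

    def __post_init__(self) -> None:
        if self.na_policy not in ("remove", "fail"):
            raise ValueError(f"unknown na_policy {self.na_policy!r}")
        if self.ties_method not in TIES_METHODS:
            raise ValueError(f"unknown ties_method {self.ties_method!r}")
        vals = np.asarray(self.values, dtype=float).ravel()
        missing = np.isnan(vals)
        if missing.any():
            if self.na_policy == "fail":
                idx = int(np.flatnonzero(missing)[0])
                raise ValueError(f"missing p-value at index {idx} (na_policy='fail')")
            vals = vals[~missing]
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"p-value out of [0, 1] at index {idx}: {vals[idx]!r}"
            )
        self.values = vals

    @property
    def m(self) -> int:
        """Number of retained (non-missing) p-values."""
        return int(self.values.size)

    def ranks(self) -> np.ndarray:
        return rank_pvalues(self)


def _apply_sided(p: np.ndarray, sidedness: str) -> np.ndarray:
    if sidedness == "two.sided":
        return stats.norm.isf(np.clip(p / 2.0, _TINY_P, 1.0))
    if sidedness == "greater":
        return stats.norm.isf(np.clip(p, _TINY_P, 1.0))
    return stats.norm.ppf(np.clip(p, _TINY_P, 1.0))  # "less"


def p_to_z(p, sidedness: str = "two.sided"):
    """Map p-values to Z-values through standard-normal quantiles.

    two.sided: ``PHI^-1(1 - p/2)``; greater: ``PHI^-1(1 - p)``;
    less: ``PHI^-1(p)`` (the mirror convention for left-tailed tests).
    ``p = 0`` is clamped to the smallest positive double so the result is a
    large finite Z rather than infinity.
    """
    _check_sidedness(sidedness)
    arr = np.asarray(p, dtype=float)
    bad = np.isnan(arr) | (arr < 0.0) | (arr > 1.0)
    if bad.any():
        idx = int(np.flatnonzero(np.atleast_1d(bad))[0])
        raise ValueError(f"p-value out of [0, 1] at index {idx}")
    z = _apply_sided(arr, sidedness)
    return float(z) if np.isscalar(p) else z


def z_to_p(z, sidedness: str = "two.sided"):
    """Exact inverse of :func:`p_to_z` for the same sidedness.

    Results are clipped to ``[0, 1]`` (a negative Z under ``two.sided`` lies
    outside the image of the forward map and saturates at 1).
    """
    _check_sidedness(sidedness)
    arr = np.asarray(z, dtype=float)
    if not np.isfinite(arr).all():
        idx = int(np.flatnonzero(~np.isfinite(np.atleast_1d(arr)))[0])
        raise ValueError(f"non-finite Z-value at index {idx}")
    if sidedness == "two.sided":
        p = 2.0 * stats.norm.sf(arr)
    elif sidedness == "greater":
        p = stats.norm.sf(arr)
    else:
        p = stats.norm.cdf(arr)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.isscalar(z) else p


def rank_pvalues(pset: RawPValueSet) -> np.ndarray:
    """Rank p-values ascending (1..m) under the set's tie policy.

    ``first``/``last``/``random`` resolve ties to distinct integers, so the
    result is a permutation of 1..m; ``average``/``min``/``max`` follow the
    usual conventions and may repeat or fractionalise ranks.
    """
    p = pset.values
    m = p.size
    if m == 0:
        raise ValueError("cannot rank an empty p-value set")
    method = pset.ties_method
    if method in ("average", "min", "max"):
        return stats.rankdata(p, method=method).astype(float)
    if method == "first":
        order = np.argsort(p, kind="stable")
    elif method == "last":
        # reverse occurrence order within tied blocks
        order = np.lexsort((-np.arange(m), p))
    else:  # random
        seed = pset.tie_seed if pset.tie_seed is not None else _DEFAULT_TIE_SEED
        rng = np.random.default_rng(seed)
        order = np.lexsort((rng.permutation(m), p))
    ranks = np.empty(m, dtype=float)
    ranks[order] = np.arange(1, m + 1)
    return ranks
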