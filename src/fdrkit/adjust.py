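"""FDR estimation and FDR control for six adjustment methods.

The same machinery (Benjamini-Hochberg, Benjamini-Yekutieli, Bonferroni,
Sidak, Holm, Hochberg) yields two distinct per-feature quantities that are
routinely confused:

* the **FDR estimate** — the method's plug-in estimate of the propensity for
  that specific finding to be a false discovery (e.g. BH:
  ``p_i * m / rank(p_i) * pi0``).  No step-up/step-down smoothing is applied,
  so these need not be monotone in p-value rank.
* the **adjusted p-value** — the smallest threshold gamma at which the feature
  would be selected by the method's control procedure (e.g. BH:
  ``min over j >= i of p_(j) * m / j``).  These are monotone by construction.

Rejection decisions compare adjusted p-values to the threshold gamma; a
feature can be selected by the control procedure while its own FDR estimate
exceeds gamma.  All outputs are capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lowerbound import LowerBoundConfig, fdr_lower_bound_p
from .pi0 import Pi0Config, get_pi0
from .transforms import RawPValueSet, rank_pvalues

__all__ = [
    "METHODS",
    "AdjustmentMethod",
    "FDRResult",
    "c_by",
    "fdr_estimates",
    "adjusted_pvalues",
    "step_rejection_set",
    "p_fdr",
]

# Canonical method names, keyed by every accepted alias (the short tokens are
# the command-line spellings).
_ALIASES = {
    "BH": "BH",
    "BY": "BY",
    "Bon": "Bonferroni",
    "Bonferroni": "Bonferroni",
    "Sidak": "Sidak",
    "Holm": "Holm",
    "Hoch": "Hochberg",
    "Hochberg": "Hochberg",
}

METHODS = ("BH", "BY", "Bonferroni", "Sidak", "Holm", "Hochberg")

_STEP_UP = {"BH", "BY", "Hochberg"}


def canonical_method(name: str) -> str:
    try:
        return _ALIASES[name]
    except KeyError:
        raise ValueError(
            f"unknown adjustment method {name!r}; expected one of {sorted(_ALIASES)}"
        ) from None


@dataclass(frozen=True)
class AdjustmentMethod:
    """An adjustment method plus the BY dependence flavour.

    ``by_corr`` is consulted only when ``name`` resolves to BY.
    """

    name: str
    by_corr: str = "positive"

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonical_method(self.name))
        if self.by_corr not in ("positive", "negative"):
            raise ValueError(f"by_corr must be 'positive' or 'negative', got {self.by_corr!r}")


def c_by(m: int, by_corr: str = "positive") -> float:
    """BY dependence correction c(m) = sum_{j=1..m} 1/j.

    The harmonic sum is the published choice for flexible positive
    dependence; the same (most conservative) factor is used for ``negative``.
    Override this hook for a bespoke dependence structure.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if by_corr not in ("positive", "negative"):
        raise ValueError(f"by_corr must be 'positive' or 'negative', got {by_corr!r}")
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def _as_pset(p) -> RawPValueSet:
    return p if isinstance(p, RawPValueSet) else RawPValueSet(np.asarray(p, dtype=float))


def fdr_estimates(pset, method: str = "BH", pi0: float = 1.0, by_corr: str = "positive") -> np.ndarray:
    """Per-feature FDR estimates (input order), capped at 1.

    BH: ``p_i m / rank_i * pi0``;  BY: ``p_i m c(m) / rank_i * pi0``;
    Bonferroni: ``p_i m pi0``;  Sidak: ``(1-(1-p_i)^m) pi0``;
    Holm/Hochberg: ``p_i (m+1-rank_i) pi0``.  No step smoothing is applied —
    these estimates are deliberately allowed to be non-monotone in rank.
    """
    pset = _as_pset(pset)
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError(f"pi0 must lie in [0, 1], got {pi0}")
    meth = canonical_method(method)
    p = pset.values
    m = pset.m
    if m == 0:
        raise ValueError("empty p-value set")
    if meth in ("BH", "BY", "Holm", "Hochberg"):
        ranks = rank_pvalues(pset)
    if meth == "BH":
        est = p * m / ranks
    elif meth == "BY":
        est = p * m * c_by(m, by_corr) / ranks
    elif meth == "Bonferroni":
        est = p * m
    elif meth == "Sidak":
        est = 1.0 - (1.0 - p) ** m
    else:  # Holm, Hochberg share the rank-based estimate
        est = p * (m + 1 - ranks)
    return np.minimum(est * pi0, 1.0)


def adjusted_pvalues(pset, method: str = "BH", by_corr: str = "positive") -> np.ndarray:
    """Multiplicity-adjusted p-values (input order), capped at 1.

    Step-up (BH, BY, Hochberg) and step-down (Holm) smoothing runs over the
    order statistics; Bonferroni and Sidak are elementwise.  pi0 never enters
    an adjusted p-value — it belongs to FDR estimation only.
    """
    pset = _as_pset(pset)
    meth = canonical_method(method)
    p = pset.values
    m = pset.m
    if m == 0:
        raise ValueError("empty p-value set")
    if meth == "Bonferroni":
        adj = p * m
    elif meth == "Sidak":
        adj = 1.0 - (1.0 - p) ** m
    else:
        order = np.argsort(p, kind="stable")
        ps = p[order]
        j = np.arange(1, m + 1, dtype=float)
        if meth == "BH":
            cand = ps * m / j
        elif meth == "BY":
            cand = ps * m * c_by(m, by_corr) / j
        else:  # Holm, Hochberg
            cand = ps * (m + 1 - j)
        if meth == "Holm":
            adj_sorted = np.maximum.accumulate(cand)
        else:
            adj_sorted = np.minimum.accumulate(cand[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = adj_sorted
    return np.minimum(adj, 1.0)


def step_rejection_set(pset, gamma: float, method: str = "BH", by_corr: str = "positive"):
    """Raw step-up/step-down threshold search on the ordered p-values.

    Returns ``(k, flags)`` where features with the k smallest p-values are
    selected and ``flags`` is a boolean vector in input order.  This operates
    directly on Eq-level criteria (e.g. BH: largest i with
    ``p_(i) <= gamma i / m``), so it is an independent oracle for
    ``adjusted_pvalues <= gamma``.
    """
    pset = _as_pset(pset)
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")
    meth = canonical_method(method)
    p = pset.values
    m = pset.m
    if m == 0:
        raise ValueError("empty p-value set")
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1, dtype=float)
    if meth == "BH":
        ok = ps <= gamma * i / m
    elif meth == "BY":
        ok = ps <= gamma * i / (m * c_by(m, by_corr))
    elif meth == "Hochberg":
        ok = ps <= gamma / (m + 1 - i)
    elif meth == "Holm":
        viol = ps > gamma / (m + 1 - i)
        k = int(np.argmax(viol)) if viol.any() else m
        ok = None
    elif meth == "Bonferroni":
        ok = ps <= gamma / m
    else:  # Sidak
        ok = ps <= 1.0 - (1.0 - gamma) ** (1.0 / m)
    if meth in _STEP_UP:
        k = int(np.max(np.flatnonzero(ok)) + 1) if ok.any() else 0
    elif meth in ("Bonferroni", "Sidak"):
        k = int(ok.sum())  # threshold rule: a prefix of the sorted vector
    flags_sorted = np.arange(1, m + 1) <= k
    flags = np.empty(m, dtype=bool)
    flags[order] = flags_sorted
    return k, flags


@dataclass
class FDRResult:
    """Joint output of FDR estimation and FDR control for one method.

    ``reject[i]`` is ``"Reject.H0"`` iff ``adjusted_p[i] <= threshold`` —
    selection is always decided on adjusted p-values, never on FDR estimates.
    """

    fdrs: np.ndarray
    adjusted_p: np.ndarray
    raw_p: np.ndarray
    reject: np.ndarray
    pi0: float
    threshold: float
    method: str
    by_corr: str = "positive"
    sidedness: str = "two.sided"
    pi0_method: str = "set.pi0"
    lower_bound: np.ndarray | None = None

    @property
    def m(self) -> int:
        return int(self.raw_p.size)

    @property
    def n_rejected(self) -> int:
        return int((self.reject == "Reject.H0").sum())

    def to_frame(self, sort_results: bool = False, just_fdr: bool = False):
        """Tidy per-feature table (pandas DataFrame), one row per feature."""
        import pandas as pd

        if just_fdr:
            return pd.DataFrame({"fdr": self.fdrs})
        cols = {
            "feature": np.arange(1, self.m + 1),
            "raw_p": self.raw_p,
            "adjusted_p": self.adjusted_p,
            "fdr": self.fdrs,
        }
        if self.lower_bound is not None:
            cols["lower_bound_fdr"] = self.lower_bound
        cols["reject"] = self.reject
        df = pd.DataFrame(cols)
        if sort_results:
            df = df.sort_values("fdr", kind="stable").reset_index(drop=True)
        return df


def p_fdr(
    pset,
    method: str = "BH",
    threshold: float = 0.05,
    pi0_config: Pi0Config | None = None,
    by_corr: str = "positive",
    sidedness: str = "two.sided",
    default_odds: float = 1.0,
    include_lower_bound: bool = False,
) -> FDRResult:
    """Compute FDR estimates and adjusted p-values from raw p-values.

    Resolves pi0 through the configured estimator (default: fixed at 1, the
    conservative assumption that every feature is null), then assembles the
    full result: per-feature FDR estimates, adjusted p-values, rejection
    decisions at ``threshold``, and optionally the univariate Gaussian lower
    bound on the FDR.
    """
    pset = _as_pset(pset)
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    pi0_config = pi0_config or Pi0Config()
    pi0_est = get_pi0(pset, pi0_config)
    fdrs = fdr_estimates(pset, method, pi0=pi0_est.value, by_corr=by_corr)
    adj = adjusted_pvalues(pset, method, by_corr=by_corr)
    reject = np.where(adj <= threshold, "Reject.H0", "FTR.H0")
    lb = None
    if include_lower_bound:
        lb = fdr_lower_bound_p(
            pset.values, LowerBoundConfig(default_odds=default_odds, sidedness=sidedness)
        )
    return FDRResult(
        fdrs=fdrs,
        adjusted_p=adj,
        raw_p=pset.values.copy(),
        reject=reject,
        pi0=pi0_est.value,
        threshold=threshold,
        method=canonical_method(method),
        by_corr=by_corr,
        sidedness=sidedness,
        pi0_method=pi0_est.method,
        lower_bound=lb,
    )
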