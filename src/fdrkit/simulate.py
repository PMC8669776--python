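"""Two-group p-value simulation and method evaluation.

The generator draws, per replicate, ``round(m * pi0_true)`` null p-values
from Uniform(0, 1) and the remainder from a configurable alternative:

* ``uniform_small``: p ~ Uniform(0, u) — a sharply left-skewed alternative
  (default u = 0.01);
* ``gaussian_shift``: z ~ N(mu, sigma) converted to p under the stated
  sidedness (default N(2, 1), two-sided).

On top of the generator sit the two evaluation designs used to study the
methods: a bias/MSE grid for the pi0 estimators, and empirical-FDR / power
checks of the control procedures against their nominal gamma.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .adjust import step_rejection_set
from .pi0 import Pi0Config, get_pi0
from .transforms import RawPValueSet, _check_sidedness

__all__ = [
    "SimulationSpec",
    "SimulationBatch",
    "simulate_pvalues",
    "evaluate_pi0_methods",
    "empirical_fdr",
    "EmpiricalFDRResult",
]

ALT_KINDS = ("uniform_small", "gaussian_shift")


@dataclass
class SimulationSpec:
    """Design of one simulation cell.

    ``alt_params`` is ``(u,)`` for ``uniform_small`` and ``(mu, sigma)`` for
    ``gaussian_shift``.  Defaults mirror the canonical two-group benchmark:
    100 features, 80% null, alternatives Uniform(0, 0.01).
    """

    m: int = 100
    pi0_true: float = 0.8
    alt_kind: str = "uniform_small"
    alt_params: tuple = (0.01,)
    reps: int = 200
    seed: int = 0
    sidedness: str = "two.sided"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not 0.0 <= self.pi0_true <= 1.0:
            raise ValueError(f"pi0_true must lie in [0, 1], got {self.pi0_true}")
        if self.alt_kind not in ALT_KINDS:
            raise ValueError(f"unknown alt_kind {self.alt_kind!r}; expected one of {ALT_KINDS}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        _check_sidedness(self.sidedness)

    @property
    def n_null(self) -> int:
        return int(round(self.m * self.pi0_true))

    @property
    def n_alt(self) -> int:
        return self.m - self.n_null


@dataclass
class SimulationBatch:
    """Labeled synthetic p-values: a reps x m matrix plus null flags."""

    pvalues: np.ndarray
    is_null: np.ndarray
    spec: SimulationSpec


def simulate_pvalues(spec: SimulationSpec) -> SimulationBatch:
    """Generate a labeled reps x m matrix of two-group p-values."""
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_null, spec.n_alt
    null_p = rng.uniform(0.0, 1.0, size=(spec.reps, n0))
    if n1 == 0:
        alt_p = np.empty((spec.reps, 0))
    elif spec.alt_kind == "uniform_small":
        (u,) = spec.alt_params
        if not 0.0 < u <= 1.0:
            raise ValueError(f"uniform_small upper bound must lie in (0, 1], got {u}")
        alt_p = rng.uniform(0.0, u, size=(spec.reps, n1))
    else:  # gaussian_shift
        mu, sd = spec.alt_params
        if sd <= 0.0:
            raise ValueError(f"gaussian_shift sd must be positive, got {sd}")
        z = rng.normal(mu, sd, size=(spec.reps, n1))
        from scipy import stats as _st

        if spec.sidedness == "two.sided":
            alt_p = 2.0 * _st.norm.sf(np.abs(z))
        elif spec.sidedness == "greater":
            alt_p = _st.norm.sf(z)
        else:
            alt_p = _st.norm.cdf(z)
    pvalues = np.concatenate([null_p, alt_p], axis=1)
    is_null = np.concatenate([np.ones(n0, bool), np.zeros(n1, bool)])
    return SimulationBatch(pvalues=pvalues, is_null=is_null, spec=spec)


def evaluate_pi0_methods(
    pi0_grid: Sequence[float],
    alt_specs: Sequence[tuple],
    reps: int = 200,
    m: int = 1000,
    seed: int = 0,
    methods: Sequence[str] = ("last.hist", "storey", "pounds"),
) -> pd.DataFrame:
    """Bias/MSE grid for the pi0 estimators.

    For each (pi0_true, alternative) cell, estimate pi0 on every replicate
    with each method and report the mean estimate and the MSE against the
    truth.  ``alt_specs`` is a sequence of ``(alt_kind, alt_params)`` pairs.
    The ``set.pi0`` method is evaluated at the cell's true value (its MSE is
    identically zero — a reference row, not an estimator).
    """
    seed_rng = np.random.default_rng(seed)
    rows = []
    for pi0_true in pi0_grid:
        for alt_kind, alt_params in alt_specs:
            cell_seed = int(seed_rng.integers(2**31))
            spec = SimulationSpec(
                m=m, pi0_true=float(pi0_true), alt_kind=alt_kind,
                alt_params=tuple(alt_params), reps=reps, seed=cell_seed,
            )
            batch = simulate_pvalues(spec)
            estimates = {meth: np.empty(reps) for meth in methods}
            for r in range(reps):
                pset = RawPValueSet(batch.pvalues[r])
                for meth in methods:
                    cfg = Pi0Config(
                        estim_method=meth,
                        set_pi0=float(pi0_true) if meth == "set.pi0" else 1.0,
                    )
                    estimates[meth][r] = get_pi0(pset, cfg).value
            for meth in methods:
                est = estimates[meth]
                rows.append(
                    {
                        "method": meth,
                        "pi0_true": float(pi0_true),
                        "alt_kind": alt_kind,
                        "mean_estimate": float(est.mean()),
                        "mse": float(((est - pi0_true) ** 2).mean()),
                    }
                )
    return pd.DataFrame(rows)


class EmpiricalFDRResult(NamedTuple):
    per_replicate: pd.DataFrame
    mean_fdr: float
    mean_power: float


def empirical_fdr(
    batch: SimulationBatch,
    method: str = "BH",
    gamma: float = 0.05,
    by_corr: str = "positive",
) -> EmpiricalFDRResult:
    """Realized FDR and power of a control procedure on a labeled batch.

    Per replicate, run the raw step rejection at level ``gamma``; realized
    FDR = false selections / max(1, selections) (0 when nothing is selected),
    power = true selections / number of alternatives (0 when there are no
    alternatives).  ``gamma = 0`` short-circuits to zero selections.
    """
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"gamma must lie in [0, 1), got {gamma}")
    is_null = batch.is_null
    n_alt = int((~is_null).sum())
    rows = []
    for r in range(batch.pvalues.shape[0]):
        if gamma == 0.0:
            flags = np.zeros(batch.pvalues.shape[1], dtype=bool)
        else:
            _, flags = step_rejection_set(
                RawPValueSet(batch.pvalues[r]), gamma, method, by_corr
            )
        n_sel = int(flags.sum())
        n_false = int((flags & is_null).sum())
        n_true = n_sel - n_false
        rows.append(
            {
                "rep": r,
                "n_selected": n_sel,
                "n_false": n_false,
                "fdr": n_false / max(1, n_sel),
                "power": n_true / n_alt if n_alt else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return EmpiricalFDRResult(df, float(df["fdr"].mean()), float(df["power"].mean()))
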