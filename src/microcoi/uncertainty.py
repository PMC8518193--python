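"""Gamma-based Monte Carlo propagation of unit-cost uncertainty.

Each unit cost is given a gamma distribution — the conventional choice for
non-negative, right-skewed cost data — matched to its mean and SD by the
method of moments (shape = mean^2/SD^2, scale = SD^2/mean). Inputs known
from a single source carry no sample variability; their SD is replaced by
1e-9 so the simulation degenerates to the point estimate. Summaries are
empirical 2.5%/97.5% percentiles and the third/fourth standardised
moments (kurtosis on the normal-is-3 scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cost_inputs import AuditLog, CostInput

__all__ = [
    "SD_FLOOR",
    "GammaSpec",
    "SimulationResult",
    "gamma_from_moments",
    "simulate_unit_costs",
    "percentile_interval",
    "distribution_moments",
    "summarize_draws",
]

#: SD substituted for inputs with no sample variability.
SD_FLOOR = 1e-9


@dataclass(frozen=True)
class GammaSpec:
    """Gamma(shape, scale) matched to a unit cost's first two moments."""

    input_id: str
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError(
                f"gamma parameters must be positive for {self.input_id!r}"
            )

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return self.shape**0.5 * self.scale


def gamma_from_moments(
    mean: float, sd: float, input_id: str = "", log: AuditLog | None = None
) -> GammaSpec:
    """Method-of-moments gamma fit; SD 0 is floored at 1e-9 before fitting."""
    if mean <= 0:
        raise ValueError(
            f"gamma fit needs mean > 0 (got {mean}); zero-mean inputs are "
            "carried as degenerate constants, not gamma"
        )
    if sd < 0:
        raise ValueError("negative SD")
    if sd < SD_FLOOR:  # no (or numerically negligible) sample variability
        sd = SD_FLOOR
        if log is not None:
            log.record(f"SD floor 1e-9 applied to {input_id or 'input'}")
    return GammaSpec(input_id=input_id, shape=mean**2 / sd**2, scale=sd**2 / mean)


def simulate_unit_costs(
    inputs: Sequence[CostInput],
    n_draws: int = 1000,
    seed: int = 0,
    log: AuditLog | None = None,
) -> pd.DataFrame:
    """Independent gamma draws per input: an (n_draws x n_inputs) DataFrame.

    Per-input substreams are spawned deterministically from the master seed
    (one child SeedSequence per input, in input order), so the matrix is
    reproducible and each input's stream does not depend on the draws of
    the others. Inputs with zero mean are carried as constant zero.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    children = np.random.SeedSequence(seed).spawn(len(inputs))
    cols = {}
    for ci, child in zip(inputs, children):
        rng = np.random.default_rng(child)
        if ci.mean_unit_cost == 0:
            cols[ci.input_id] = np.zeros(n_draws)
            continue
        spec = gamma_from_moments(
            ci.mean_unit_cost, ci.sd_unit_cost, input_id=ci.input_id, log=log
        )
        cols[ci.input_id] = rng.gamma(shape=spec.shape, scale=spec.scale, size=n_draws)
    return pd.DataFrame(cols)


def percentile_interval(
    values: Sequence[float], lower: float = 0.025, upper: float = 0.975
) -> tuple[float, float]:
    """Empirical (lower, upper) quantiles, linear interpolation between order
    statistics (the 1 + (n-1)p convention)."""
    if not 0 <= lower <= 1 or not 0 <= upper <= 1:
        raise ValueError("percentile probabilities must lie in [0, 1]")
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = np.quantile(arr, [lower, upper], method="linear")
    return float(lo), float(hi)


def distribution_moments(values: Sequence[float]) -> tuple[float, float]:
    """(skewness, kurtosis) as third and fourth standardised moments.

    Kurtosis is Pearson's (a normal distribution scores 3).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    if np.var(arr) == 0:
        raise ValueError("zero variance")
    skew = float(stats.skew(arr, bias=True))
    kurt = float(stats.kurtosis(arr, fisher=False, bias=True))
    return skew, kurt


@dataclass(frozen=True)
class SimulationResult:
    """Monte Carlo draws and their per-quantity summaries."""

    n_draws: int
    seed: int
    draws: pd.DataFrame
    summary: pd.DataFrame  # index: quantity; cols: mean, p2_5, p97_5, skewness, kurtosis


def summarize_draws(
    draws: pd.DataFrame, seed: int, interval: tuple[float, float] = (0.025, 0.975)
) -> SimulationResult:
    """Summarise a draw matrix column-wise into a SimulationResult."""
    rows = {}
    for col in draws.columns:
        v = draws[col].to_numpy()
        lo, hi = percentile_interval(v, *interval)
        if np.var(v) > 0:
            skew, kurt = distribution_moments(v)
        else:  # degenerate (e.g. SD-floored) quantity
            skew, kurt = float("nan"), float("nan")
        rows[col] = {
            "mean": float(np.mean(v)),
            "p2_5": lo,
            "p97_5": hi,
            "skewness": skew,
            "kurtosis": kurt,
        }
    summary = pd.DataFrame(rows).T[["mean", "p2_5", "p97_5", "skewness", "kurtosis"]]
    return SimulationResult(
        n_draws=len(draws), seed=seed, draws=draws, summary=summary
    )
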