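"""Bone-marrow/bloodstream exchange: mobilization, release, and blood death.

Cellularity :math:`C(t)` is the total bone-marrow cell count relative to its
healthy value.  Mobilization of mitotic cells into the bloodstream switches on
only when the marrow is at or above its healthy capacity:

.. math::

    f(C) = \\begin{cases} 0 & C < 1 \\\\
    \\kappa \\exp(C/K) & C \\ge 1 \\end{cases}

and the per-cell mobilization rate is ``R_k * f`` in mitotic pool I and
``R_k * f * beta`` in mitotic pool II (committed cells mobilize more readily).
Mature cells are released to the bloodstream at the constant per-cell rate
``delta_{n-1} / N_n`` (0.2/day at the default anchors), the rate at which the
level above produces them — this, together with a 12-hour mature lifespan in
blood, fixes the healthy bloodstream at its observed 5x10^10 mature cells.

In the bloodstream no cell divides: blasts die at ``R_k / alpha`` (dormant,
long-lived), committed cells at ``R_k``, and mature cells at
``mature_output / mature_blood_target`` (2/day by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .hierarchy import LevelRates


class ExchangeError(ValueError):
    """Invalid exchange parameters."""


@dataclass(frozen=True)
class ExchangeParams:
    """Marrow-blood exchange parameters.

    ``K = 10`` encodes the cellularity (in units of the healthy marrow total
    of ~1e12 cells) at which mobilization rises steeply, i.e. a 1e13-cell
    ceiling.  ``alpha`` and ``beta`` only weakly affect phase durations and
    keep their reference values of 50.
    """

    alpha: float = 50.0
    beta: float = 50.0
    kappa: float = 0.03
    K: float = 10.0
    mature_blood_target: float = 5.0e10

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ExchangeError("alpha must be > 1")
        if self.beta <= 0:
            raise ExchangeError("beta must be > 0")
        if self.kappa < 0:
            raise ExchangeError("kappa must be >= 0")
        if self.K <= 0:
            raise ExchangeError("K must be > 0")
        if self.mature_blood_target <= 0:
            raise ExchangeError("mature_blood_target must be > 0")


def cellularity(bm_total: float, n_ref: float) -> float:
    """C = total bone-marrow count / healthy bone-marrow count."""
    if n_ref <= 0:
        raise ExchangeError("n_ref must be > 0")
    return bm_total / n_ref


def mobilization_response(C: float, params: ExchangeParams) -> float:
    """Dimensionless mobilization response f(C); zero below full cellularity."""
    if C < 1.0:
        return 0.0
    return params.kappa * math.exp(C / params.K)


def mobilization_rate(
    level: int,
    R_k: float,
    f: float,
    params: ExchangeParams,
    pool2_start: int,
) -> float:
    """Per-cell mobilization rate (1/day) of a mitotic marrow level."""
    if level < pool2_start:
        return R_k * f
    return R_k * f * params.beta


def blood_death_rate(
    level: int,
    R_k: float,
    params: ExchangeParams,
    rates: LevelRates,
) -> float:
    """Per-cell death rate (1/day) of a bloodstream cell of a given level."""
    if level == rates.mature_level:
        return float(rates.delta[-1]) / params.mature_blood_target
    if level < rates.pool2_start:
        return R_k / params.alpha
    return R_k
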