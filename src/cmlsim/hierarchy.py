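"""Healthy hematopoietic hierarchy: level sizes, differentiation cascade, per-cell rates.

The bone marrow is modelled as ``n_levels`` differentiation levels (0 = HSC,
``n_levels - 1`` = mature, non-dividing cells).  Mitotic levels split into two
pools: pool I (levels ``0 .. pool2_start - 1``), whose cells both self-renew
and differentiate symmetrically, and pool II (levels ``pool2_start ..
n_levels - 2``), whose cells only differentiate symmetrically (amplification
factor exactly 2).  Level *k* holds :math:`N_k` cells and emits
:math:`\\delta_k` new cells per day into level *k+1* by symmetric
differentiation; the amplification factor is
:math:`\\gamma_k = \\delta_k/\\delta_{k-1} \\ge 2`.

Per-cell rates follow from homeostasis of the cascade:

.. math::

    r^{\\downarrow\\downarrow}_k = \\frac{\\delta_k}{2 N_k}, \\qquad
    r^{\\circ\\circ}_k = \\frac{1}{N_k}\\Big(\\frac{\\delta_k}{2}
        - \\delta_{k-1}\\Big), \\qquad
    R_k = r^{\\circ\\circ}_k + r^{\\downarrow\\downarrow}_k
        = \\frac{\\delta_k - \\delta_{k-1}}{N_k},

with :math:`\\delta_{-1} = 0` so HSCs are exactly critical
(:math:`r^{\\circ\\circ}_0 = r^{\\downarrow\\downarrow}_0`) in the healthy
state.  All times are in days; 1 year = 365 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.0


class HierarchyError(ValueError):
    """Invalid hierarchy configuration."""


@dataclass(frozen=True)
class HierarchyConfig:
    """Static description of the healthy hierarchy.

    Defaults are the adult-human anchors used throughout: 10^4 HSCs,
    5x10^11 mature bone-marrow cells, 10^11 cells/day of mature-cell
    production, 21 levels with the committed pool starting at level 15.
    The HSC division rate is the model's free physiological parameter
    (estimates span roughly 0.5-6 divisions/year).
    """

    n_levels: int = 21
    pool2_start: int = 15
    n_hsc: float = 1.0e4
    n_mature_bm: float = 5.0e11
    mature_output: float = 1.0e11  # cells/day leaving the marrow
    hsc_divisions_per_year: float = 1.18

    def __post_init__(self) -> None:
        if self.n_levels < 3:
            raise HierarchyError("n_levels must be >= 3")
        if not (0 < self.pool2_start < self.n_levels - 1):
            raise HierarchyError(
                "pool2_start must lie strictly between 0 and n_levels - 1"
            )
        for name in ("n_hsc", "n_mature_bm", "mature_output",
                     "hsc_divisions_per_year"):
            if getattr(self, name) <= 0:
                raise HierarchyError(f"{name} must be strictly positive")

    @property
    def mature_level(self) -> int:
        return self.n_levels - 1

    @property
    def n_pool2_doublings(self) -> int:
        """Number of doubling steps from pool-II start up to the mature level."""
        return self.mature_level - self.pool2_start

    @property
    def pool1_number_ratio(self) -> float:
        """Geometric cell-number ratio of pool-I levels.

        Anchored so that ``n_hsc * ratio**pool2_start_minus_1`` meets the
        pool-II doubling segment coming down from ``n_mature_bm``; with the
        default anchors this is (5e11 / (2^5 * 1e4))^(1/14) = 2.76.
        """
        top = self.n_mature_bm / 2.0 ** self.n_pool2_doublings
        return (top / self.n_hsc) ** (1.0 / (self.pool2_start - 1))


@dataclass(frozen=True)
class LevelRates:
    """Per-level healthy cell numbers and per-cell rates.

    ``delta[k]`` is the symmetric-differentiation output (cells/day) of level
    ``k`` for mitotic levels ``0 .. n_levels - 2``; the mature level has no
    division rates and leaves the marrow at a constant per-cell rate
    ``delta[-1] / N[-1]``.
    """

    N: np.ndarray            # cells, len n_levels
    delta: np.ndarray        # cells/day, len n_levels - 1
    r_selfrenew: np.ndarray  # 1/day per cell, len n_levels (0 at mature level)
    r_symdiff: np.ndarray    # 1/day per cell, len n_levels (0 at mature level)
    R: np.ndarray            # 1/day per cell, len n_levels (0 at mature level)
    pool2_start: int
    gamma_pool1: float = field(default=float("nan"))

    @property
    def n_levels(self) -> int:
        return len(self.N)

    @property
    def mature_level(self) -> int:
        return self.n_levels - 1

    @property
    def gamma(self) -> np.ndarray:
        """Amplification factors gamma_k = delta_k / delta_{k-1}, k >= 1."""
        return self.delta[1:] / self.delta[:-1]

    @property
    def mature_turnover(self) -> float:
        """Per-cell rate (1/day) at which mature marrow cells enter the blood."""
        return float(self.delta[-1] / self.N[-1])

    @property
    def marrow_total(self) -> float:
        return float(self.N.sum())

    def is_pool1(self, level: int) -> bool:
        return level < self.pool2_start

    def describe(self) -> pd.DataFrame:
        """Per-level table of the healthy hierarchy (one row per level)."""
        n = self.n_levels
        delta_full = np.append(self.delta, np.nan)
        gamma_full = np.full(n, np.nan)
        gamma_full[1:n - 1] = self.gamma
        pool = np.where(np.arange(n) < self.pool2_start, "I", "II")
        pool[self.mature_level] = "mature"
        return pd.DataFrame({
            "level": np.arange(n),
            "pool": pool,
            "N": self.N,
            "delta": delta_full,
            "gamma": gamma_full,
            "r_selfrenew": self.r_selfrenew,
            "r_symdiff": self.r_symdiff,
            "R": self.R,
        })


def build_cell_numbers(config: HierarchyConfig) -> np.ndarray:
    """Healthy cell number N_k for every level.

    Pool I is geometric from the HSC anchor with
    :attr:`HierarchyConfig.pool1_number_ratio`; pool II (and the mature level)
    is anchored top-down at ``n_mature_bm`` with doubling per level.  With the
    default anchors the two segments meet with ``N[pool2_start] ==
    N[pool2_start - 1]`` — a quirk forced by the printed anchor formula, kept
    deliberately.
    """
    n = config.n_levels
    N = np.empty(n)
    ratio = config.pool1_number_ratio
    if ratio < 1.0:
        raise HierarchyError(
            "pool-II start count below pool-I end count: the solved pool-I "
            f"number ratio {ratio:.4f} < 1 (n_hsc too large for the mature "
            "anchor)"
        )
    k1 = np.arange(config.pool2_start)
    N[:config.pool2_start] = config.n_hsc * ratio ** k1
    k2 = np.arange(config.pool2_start, n)
    N[config.pool2_start:] = config.n_mature_bm / 2.0 ** (n - 1 - k2)
    if N[config.pool2_start] < N[config.pool2_start - 1] * (1 - 1e-12):
        raise HierarchyError(
            "pool-II start count falls below pool-I end count; "
            "anchors are inconsistent"
        )
    return N


def solve_differentiation_cascade(
    config: HierarchyConfig,
) -> tuple[np.ndarray, float]:
    """Symmetric-differentiation outputs delta_k and the pool-I amplification.

    The cascade is anchored at the mature output (``delta[n-2] =
    mature_output``) with gamma = 2 across pool II, and at the HSC division
    rate (``delta[0] = n_hsc * rate``) with a uniform amplification factor
    ``gamma_I`` across pool I solved in closed form:

    ``gamma_I = (mature_output / (n_hsc * rate_day * 2**d)) ** (1/(p-1))``

    where ``d`` is the number of pool-II doublings and ``p = pool2_start``.

    Returns ``(delta, gamma_I)``; raises if the requested HSC rate forces
    ``gamma_I <= 2`` (pool I would have negative self-renewal).
    """
    n = config.n_levels
    p = config.pool2_start
    rate_day = config.hsc_divisions_per_year / DAYS_PER_YEAR
    delta0 = config.n_hsc * rate_day
    d = config.n_pool2_doublings
    gamma_1 = (config.mature_output / (delta0 * 2.0 ** d)) ** (1.0 / (p - 1))
    if gamma_1 <= 2.0:
        max_rate_day = config.mature_output / (config.n_hsc * 2.0 ** (d + p - 1))
        raise HierarchyError(
            "solved pool-I amplification factor "
            f"{gamma_1:.4f} <= 2: HSC division rate too fast for the fixed "
            f"mature output (maximum admissible rate is "
            f"{max_rate_day * DAYS_PER_YEAR:.3f} divisions/year)"
        )
    delta = np.empty(n - 1)
    delta[:p] = delta0 * gamma_1 ** np.arange(p)
    # anchor the pool boundary top-down so the gamma = 2 segment is exact in
    # floating point (halving is lossless); the solved gamma_1 reproduces the
    # same value to roundoff from below
    delta[p - 1:] = config.mature_output / 2.0 ** (n - 1 - np.arange(p, n))
    return delta, gamma_1


def per_cell_rates(
    N_k: float, delta_k: float, delta_prev: float
) -> tuple[float, float, float]:
    """(r_selfrenew, r_symdiff, R) for one level from its flux anchors.

    ``delta_prev`` is the inflow from the level above (0 for HSCs).  Rejects
    ``delta_k < 2 * delta_prev``, which would require negative self-renewal.
    """
    if N_k <= 0 or delta_k <= 0 or delta_prev < 0:
        raise HierarchyError("N_k and delta_k must be positive, delta_prev >= 0")
    if delta_k < 2.0 * delta_prev * (1 - 1e-12):
        raise HierarchyError(
            f"delta_k={delta_k} < 2*delta_prev={2 * delta_prev}: "
            "amplification factor below 2"
        )
    r_symdiff = delta_k / (2.0 * N_k)
    r_selfrenew = (delta_k / 2.0 - delta_prev) / N_k
    if r_selfrenew < 1e-12 * r_symdiff:  # snap roundoff at gamma == 2 to zero
        r_selfrenew = 0.0
    R = r_selfrenew + r_symdiff
    return r_selfrenew, r_symdiff, R


def build_level_rates(config: HierarchyConfig) -> LevelRates:
    """Assemble the full healthy rate table for a configuration."""
    N = build_cell_numbers(config)
    delta, gamma_1 = solve_differentiation_cascade(config)
    n = config.n_levels
    r_self = np.zeros(n)
    r_diff = np.zeros(n)
    R = np.zeros(n)
    prev = 0.0
    for k in range(n - 1):
        r_self[k], r_diff[k], R[k] = per_cell_rates(N[k], delta[k], prev)
        prev = delta[k]
    return LevelRates(
        N=N, delta=delta, r_selfrenew=r_self, r_symdiff=r_diff, R=R,
        pool2_start=config.pool2_start, gamma_pool1=gamma_1,
    )


def rates_from_tables(
    N: np.ndarray, delta: np.ndarray, pool2_start: int
) -> LevelRates:
    """Build a :class:`LevelRates` from explicit (N_k, delta_k) tables.

    Used for toy hierarchies and round-tripping; applies the same per-cell
    rate formulas and validation as the default builder.
    """
    N = np.asarray(N, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if len(delta) != len(N) - 1:
        raise HierarchyError("need exactly one delta per mitotic level")
    n = len(N)
    r_self = np.zeros(n)
    r_diff = np.zeros(n)
    R = np.zeros(n)
    prev = 0.0
    for k in range(n - 1):
        r_self[k], r_diff[k], R[k] = per_cell_rates(N[k], delta[k], prev)
        prev = delta[k]
    gamma_1 = float(delta[1] / delta[0]) if n > 2 else float("nan")
    return LevelRates(
        N=N, delta=delta, r_selfrenew=r_self, r_symdiff=r_diff, R=R,
        pool2_start=pool2_start, gamma_pool1=gamma_1,
    )
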