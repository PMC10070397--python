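"""Driver mutations: *BCR::ABL1* and generic drivers, and their effect on rates.

Every driver mutation tilts a cell's division balance toward self-renewal
while preserving its total division rate :math:`R_k`:

.. math::

    \\tilde r^{\\circ\\circ}_k = r^{\\circ\\circ}_k + S \\Delta R_k, \\qquad
    \\tilde r^{\\downarrow\\downarrow}_k
        = r^{\\downarrow\\downarrow}_k - S \\Delta R_k,

where the cumulative strength :math:`S` adds the *BCR::ABL1* strength
``s_bcrabl`` and ``n_generic`` equal generic strengths
``(1 - s_bcrabl)/m_crit``, and :math:`\\Delta` is the minimum strength that
makes a cell self-sustainable at the last level of mitotic pool I:

.. math::

    \\Delta = \\frac{r^{\\downarrow\\downarrow} - r^{\\circ\\circ}}{2R}
    \\Big|_{\\mathrm{pool2\\_start} - 1}
    = \\frac{1}{2(\\gamma_\\mathrm{I} - 1)} .

By construction a cell carrying *BCR::ABL1* plus ``m_crit`` generic drivers
has S = 1 and sits exactly on the self-sustainability boundary at that level.
A cell is *washing-out* while its symmetric differentiation outpaces its
self-renewal and *self-sustainable* once the tilt reverses the inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .hierarchy import LevelRates

UNREACHABLE = -1
"""Sentinel returned by :func:`critical_mutation_number` when even ``m_cap``
generic drivers do not reach self-sustainability at the level."""


class MutationError(ValueError):
    """Invalid evolutionary parameters or mutation query."""


@dataclass(frozen=True)
class EvolutionParams:
    """Mutation parameters.

    ``mu`` is the probability that a division produces one daughter carrying
    one additional generic driver; it applies to every dividing cell, healthy
    or leukemic.  ``s_bcrabl`` is the *BCR::ABL1* strength on the (0, 1]
    scale set by Delta; ``m_crit`` fixes the generic strength so that
    *BCR::ABL1* + m_crit generics give S = 1.  Generic counts above ``m_cap``
    are pooled into the cap class.
    """

    mu: float
    s_bcrabl: float
    m_crit: int = 4
    m_cap: int = 20

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise MutationError("mu must lie in [0, 1]")
        if not (0.0 < self.s_bcrabl <= 1.0):
            raise MutationError("s_bcrabl must lie in (0, 1]")
        if self.m_crit < 1:
            raise MutationError("m_crit must be >= 1")
        if self.m_cap < self.m_crit:
            raise MutationError("m_cap must be >= m_crit")

    @property
    def s_generic(self) -> float:
        """Strength of each generic driver, (1 - s_bcrabl)/m_crit."""
        return (1.0 - self.s_bcrabl) / self.m_crit


@dataclass(frozen=True)
class MutantRates:
    """Per-cell rates of a mutated cell and its dynamical regime."""

    r_selfrenew: float
    r_symdiff: float
    regime: str  # "washing-out" | "self-sustainable"


def delta_fraction(rates: LevelRates) -> float:
    """Self-sustainability strength unit Delta.

    Computed from the healthy rates at the last level of mitotic pool I
    (level ``pool2_start - 1``) and then applied, frozen, at every level as
    ``S * Delta * R_k``.
    """
    k = rates.pool2_start - 1
    r_d = rates.r_symdiff[k]
    r_s = rates.r_selfrenew[k]
    R = rates.R[k]
    if R <= 0:
        raise MutationError("anchor level has no division rate")
    if r_d < r_s:
        raise MutationError(
            "anchor level is not washing-out (r_symdiff < r_selfrenew)"
        )
    d = (r_d - r_s) / (2.0 * R)
    if not (0.0 < d <= 0.5):
        raise MutationError(f"Delta={d} outside (0, 1/2]")
    return d


def cumulative_strength(
    has_bcrabl: bool, n_generic: int, params: EvolutionParams
) -> float:
    """Additive cumulative mutation strength S of a cell."""
    if n_generic < 0:
        raise MutationError("n_generic must be >= 0")
    return params.s_bcrabl * bool(has_bcrabl) + n_generic * params.s_generic


def mutated_rates(
    rates: LevelRates, level: int, S: float, delta: float
) -> MutantRates:
    """Tilted per-cell rates at ``level`` for cumulative strength ``S``.

    The self-renewal gain ``S * delta * R_k`` is clamped so the
    symmetric-differentiation rate never goes negative; the total division
    rate R_k is preserved exactly.
    """
    if S < 0:
        raise MutationError("S must be >= 0")
    R = float(rates.R[level])
    gain = min(S * delta * R, float(rates.r_symdiff[level]))
    r_s = float(rates.r_selfrenew[level]) + gain
    r_d = float(rates.r_symdiff[level]) - gain
    # tolerance keeps the exact S = S_crit boundary in the self-sustainable
    # regime despite float roundoff
    regime = ("self-sustainable" if r_s >= r_d - 1e-9 * R
              else "washing-out")
    return MutantRates(r_selfrenew=r_s, r_symdiff=r_d, regime=regime)


def critical_mutation_number(
    level: int,
    rates: LevelRates,
    params: EvolutionParams,
    has_bcrabl: bool,
    delta: float | None = None,
) -> int:
    """Smallest generic-driver count making a cell self-sustainable at ``level``.

    Counts generic drivers on top of the (optional) *BCR::ABL1* mutation.
    Returns :data:`UNREACHABLE` when even ``m_cap`` generics do not reach the
    threshold ``S >= (r_symdiff - r_selfrenew) / (2 * Delta * R)``.
    """
    if delta is None:
        delta = delta_fraction(rates)
    R = float(rates.R[level])
    if R <= 0:
        raise MutationError(f"level {level} has no division rate")
    gap = float(rates.r_symdiff[level] - rates.r_selfrenew[level])
    threshold = gap / (2.0 * delta * R)
    base = params.s_bcrabl * bool(has_bcrabl)
    if base >= threshold:
        return 0
    if params.s_generic == 0.0:
        return UNREACHABLE
    m = math.ceil((threshold - base) / params.s_generic - 1e-12)
    return m if m <= params.m_cap else UNREACHABLE
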