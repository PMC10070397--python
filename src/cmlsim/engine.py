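"""Stochastic simulation engine over aggregated cell classes.

A cell class is the tuple (compartment, *BCR::ABL1* flag, generic-driver
count, level); the system state is the integer count of every class, stored
as a dense float64 array of shape ``(2, 2, m_cap + 1, n_levels)`` indexed
``[compartment, flag, generic count, level]`` (compartment 0 = bone marrow,
1 = bloodstream).  Events:

* self-renewal (marrow, mitotic): class count +1; with probability ``mu`` the
  new daughter carries one more generic driver,
* symmetric differentiation (marrow, mitotic): class -1, two daughters one
  level down (+2); with probability ``mu`` one daughter is mutated,
* mobilization (marrow, mitotic, gated by cellularity >= 1): class -1 in the
  marrow, +1 in the bloodstream,
* mature release (marrow, bottom level): constant per-cell rate into blood,
* death (bloodstream): class -1.

Three stepping modes are provided.  ``exact`` is Gillespie's direct method.
``tau`` is Poisson tau-leaping with a fixed step, safe here because every
class that can be small has per-cell rates well below 1/day.  ``hybrid``
(default) switches to exact stepping whenever the whole system is small
enough that a leap would contain only a handful of events, and leaps
otherwise; a full-scale marrow (~10^12 cells, ~10^11 events/day) always
leaps, which is what makes 20-year runs tractable at all.

At the mobilization discontinuity (cellularity exactly 1, the healthy fixed
point) a raw Poisson leap would overshoot far below capacity each time the
gate opens; the leap therefore caps the total number of mobilized cells per
step at the current excess above the healthy marrow total, the sliding-mode
limit of the exact toggling dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .exchange import ExchangeParams, mobilization_response
from .hierarchy import LevelRates
from .mutation import EvolutionParams, delta_fraction


@dataclass(frozen=True)
class RunControl:
    """Run-control parameters for one simulation."""

    seed: int = 0
    horizon_days: float = 20 * 365.0
    stop_blast_pct: float = 30.0
    sample_interval_days: float = 10.0
    engine_mode: str = "hybrid"      # "exact" | "tau" | "hybrid"
    tau_days: float = 0.25
    hybrid_exact_cells: float = 5e3  # switch to exact below this total count
    variant: str = "standard"        # "standard" | "hsc_mutations_blocked"

    def __post_init__(self) -> None:
        if self.horizon_days < 0:
            raise ValueError("horizon_days must be >= 0")
        if not (0 < self.stop_blast_pct <= 100):
            raise ValueError("stop_blast_pct must be in (0, 100]")
        if self.tau_days <= 0:
            raise ValueError("tau_days must be > 0")
        if self.engine_mode not in ("exact", "tau", "hybrid"):
            raise ValueError(f"unknown engine_mode {self.engine_mode!r}")
        if self.variant not in ("standard", "hsc_mutations_blocked"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class RateTables:
    """Per-class rate tables precomputed for one parameter set.

    Mutation tilt, mobilization weights and blood death rates are all static;
    only the cellularity response f(C) varies during a run.
    """

    r_self: np.ndarray      # (2, M, L-1) per-cell self-renewal, marrow mitotic
    r_diff: np.ndarray      # (2, M, L-1) per-cell symmetric differentiation
    mob_weight: np.ndarray  # (L-1,) per-cell mobilization rate / f(C)
    mature_out: float       # per-cell release rate of mature marrow cells
    death: np.ndarray       # (L,) per-cell bloodstream death rate
    mu_level: np.ndarray    # (L-1,) generic-mutation probability per division
    n_ref: float            # healthy marrow total (cellularity denominator)
    pool2_start: int
    exch: ExchangeParams = field(default_factory=ExchangeParams)

    @property
    def M(self) -> int:
        return self.r_self.shape[1]

    @property
    def n_levels(self) -> int:
        return self.death.shape[0]


@dataclass
class SystemState:
    """Counts of every cell class at time ``t`` (days)."""

    counts: np.ndarray  # (2, 2, M, L) float64, integer-valued
    t: float = 0.0

    @property
    def marrow(self) -> np.ndarray:
        return self.counts[0]

    @property
    def blood(self) -> np.ndarray:
        return self.counts[1]

    def cellularity(self, n_ref: float) -> float:
        return float(self.counts[0].sum()) / n_ref

    def total_cells(self) -> float:
        return float(self.counts.sum())


def build_rate_tables(
    rates: LevelRates,
    evol: EvolutionParams,
    exch: ExchangeParams,
    variant: str = "standard",
    delta: float | None = None,
) -> RateTables:
    """Assemble static per-class rate tables.

    ``delta`` defaults to the self-sustainability unit computed from the
    healthy rates at the last pool-I level and is applied frozen at every
    level as ``S * delta * R_k``.
    """
    if delta is None:
        delta = delta_fraction(rates)
    L = rates.n_levels
    M = evol.m_cap + 1
    Lm = L - 1
    S = (np.array([0.0, 1.0])[:, None] * evol.s_bcrabl
         + np.arange(M)[None, :] * evol.s_generic)  # (2, M)
    R = rates.R[:Lm]
    gain = np.minimum(S[:, :, None] * delta * R, rates.r_symdiff[:Lm])
    r_self = rates.r_selfrenew[:Lm] + gain
    r_diff = rates.r_symdiff[:Lm] - gain
    mob_weight = np.where(
        np.arange(Lm) < rates.pool2_start, R, R * exch.beta
    )
    death = np.where(
        np.arange(L) < rates.pool2_start,
        rates.R / exch.alpha,
        rates.R,
    )
    death[-1] = rates.delta[-1] / exch.mature_blood_target
    mu_level = np.full(Lm, evol.mu)
    if variant == "hsc_mutations_blocked":
        mu_level[0] = 0.0
    n_ref = float(np.round(rates.N).sum())
    return RateTables(
        r_self=r_self, r_diff=r_diff, mob_weight=mob_weight,
        mature_out=rates.mature_turnover, death=death, mu_level=mu_level,
        n_ref=n_ref, pool2_start=rates.pool2_start, exch=exch,
    )


def initialize_state(
    rates: LevelRates,
    exch: ExchangeParams,
    m_cap: int,
    founder: bool = True,
) -> SystemState:
    """Healthy state at t = 0, optionally with one *BCR::ABL1* founder HSC.

    Marrow levels start at their healthy cell numbers (rounded to integers),
    the bloodstream holds the target number of mature cells and no immature
    ones; the founder replaces one wild-type HSC.
    """
    L = rates.n_levels
    counts = np.zeros((2, 2, m_cap + 1, L))
    counts[0, 0, 0, :] = np.round(rates.N)
    if founder:
        if counts[0, 0, 0, 0] < 1:
            raise ValueError("no HSC to replace with the founder")
        counts[0, 0, 0, 0] -= 1
        counts[0, 1, 0, 0] = 1
    counts[1, 0, 0, L - 1] = round(exch.mature_blood_target)
    return SystemState(counts=counts, t=0.0)


def event_propensities(
    state: SystemState, tables: RateTables
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-class event propensities (1/day) at the current state.

    Returns ``(self_renewal, symmetric_differentiation, transfer, death)``;
    the first two cover marrow mitotic classes ``(2, M, L-1)``, ``transfer``
    covers marrow-to-blood movement for all levels ``(2, M, L)`` (mobilization
    for mitotic levels, gated by the cellularity response; constant release
    for the mature level), and ``death`` covers bloodstream classes
    ``(2, M, L)``.
    """
    A = state.marrow
    B = state.blood
    Lm = tables.n_levels - 1
    f = mobilization_response(state.cellularity(tables.n_ref), tables.exch)
    p_self = A[:, :, :Lm] * tables.r_self
    p_diff = A[:, :, :Lm] * tables.r_diff
    trans_rate = np.append(tables.mob_weight * f, tables.mature_out)
    p_trans = A * trans_rate
    p_death = B * tables.death
    return p_self, p_diff, p_trans, p_death


def step_exact(
    state: SystemState, tables: RateTables, rng: np.random.Generator
) -> float | None:
    """One Gillespie step; returns the waiting time, or None at extinction
    (zero total propensity)."""
    p_self, p_diff, p_trans, p_death = event_propensities(state, tables)
    props = np.concatenate([
        p_self.ravel(), p_diff.ravel(), p_trans.ravel(), p_death.ravel()
    ])
    total = props.sum()
    if total <= 0.0:
        return None
    dt = rng.exponential(1.0 / total)
    cum = np.cumsum(props)
    idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    idx = min(idx, len(props) - 1)
    _apply_exact_event(state, tables, idx, p_self.size, p_trans.size, rng)
    state.t += dt
    return dt


def _apply_exact_event(
    state: SystemState, tables: RateTables, idx: int,
    n_div: int, n_full: int, rng: np.random.Generator,
) -> None:
    A = state.marrow
    B = state.blood
    M = tables.M
    L = tables.n_levels
    Lm = L - 1
    top = M - 1
    if idx < n_div:  # self-renewal
        b, m, k = np.unravel_index(idx, (2, M, Lm))
        if rng.random() < tables.mu_level[k]:
            A[b, min(m + 1, top), k] += 1
        else:
            A[b, m, k] += 1
    elif idx < 2 * n_div:  # symmetric differentiation
        b, m, k = np.unravel_index(idx - n_div, (2, M, Lm))
        A[b, m, k] -= 1
        if rng.random() < tables.mu_level[k]:
            A[b, m, k + 1] += 1
            A[b, min(m + 1, top), k + 1] += 1
        else:
            A[b, m, k + 1] += 2
    elif idx < 2 * n_div + n_full:  # mobilization / mature release
        b, m, k = np.unravel_index(idx - 2 * n_div, (2, M, L))
        A[b, m, k] -= 1
        B[b, m, k] += 1
    else:  # bloodstream death
        b, m, k = np.unravel_index(idx - 2 * n_div - n_full, (2, M, L))
        B[b, m, k] -= 1
    if (A[A < 0].size or B[B < 0].size):  # pragma: no cover - bookkeeping guard
        raise AssertionError("negative class count after exact event")



BIG_CHANNEL_EVENTS = 1.0e4
"""Channels expecting at least this many events in one leap are advanced by
their expectation (relative Poisson noise < 1%); all smaller channels draw
true Poisson counts."""


def _draw_channel_counts(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    draws = np.zeros(lam.size, dtype=np.int64)
    nz = np.nonzero(lam)[0]
    if nz.size:
        lnz = lam[nz]
        big = lnz >= BIG_CHANNEL_EVENTS
        small = nz[~big]
        if small.size:
            draws[small] = rng.poisson(lam[small])
        bigidx = nz[big]
        if bigidx.size:
            draws[bigidx] = np.rint(lam[bigidx]).astype(np.int64)
    return draws


def step_tau_leap(
    state: SystemState, tables: RateTables, tau: float,
    rng: np.random.Generator,
) -> None:
    """One Poisson tau-leap of length ``tau`` days.

    Event counts per channel are Poisson with mean propensity*tau; counts
    that would overdraw a class are scaled back proportionally, and the total
    mobilization per step is capped at the marrow excess above its healthy
    total (see module docstring).
    """
    M_full = tables.M
    L = tables.n_levels
    Lm = L - 1
    exch = tables.exch
    # restrict work to the occupied range of the generic-driver axis
    # (+1 headroom for new mutants, capped at the pooling class)
    occ = state.counts.any(axis=(0, 1, 3))
    m_act = int(np.nonzero(occ)[0][-1]) if occ.any() else 0
    M = min(m_act + 2, M_full)
    A = state.counts[0, :, :M, :]
    B = state.counts[1, :, :M, :]
    bm_total = state.counts[0].sum()
    C = bm_total / tables.n_ref
    f = mobilization_response(C, exch)

    Am = A[:, :, :Lm]
    lam_div = Am * tau
    mu = tables.mu_level
    lam_self = lam_div * tables.r_self[:, :M, :]
    lam_diff = lam_div * tables.r_diff[:, :M, :]
    lam_mob = (Am * (tables.mob_weight * (f * tau)) if f > 0.0
               else np.zeros_like(lam_self))

    # one compacted Poisson draw over the non-zero channel intensities
    lam_all = np.concatenate([
        (lam_self * (1.0 - mu)).ravel(),
        (lam_self * mu).ravel(),
        (lam_diff * (1.0 - mu)).ravel(),
        (lam_diff * mu).ravel(),
        lam_mob.ravel(),
        (A[:, :, Lm] * (tables.mature_out * tau)).ravel(),
        (B * (tables.death * tau)).ravel(),
    ])
    draws = _draw_channel_counts(lam_all, rng)
    div_shape = lam_self.shape
    n_div = lam_self.size
    n_mat = A[:, :, Lm].size
    o = 0
    E_self_n = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_self_m = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_diff_n = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_diff_m = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_mob = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_out = draws[o:o + n_mat].reshape(A[:, :, Lm].shape); o += n_mat
    E_death = draws[o:].reshape(B.shape)

    if f > 0.0:
        tot = E_mob.sum()
        budget = max(0.0, bm_total - tables.n_ref)
        if tot > budget:
            E_mob = np.floor(E_mob * (budget / tot)).astype(np.int64)

    # never consume more cells than a class holds
    cons = E_diff_n + E_diff_m + E_mob
    over = cons > Am
    if over.any():
        scale = Am[over] / cons[over]
        E_diff_n[over] = np.floor(E_diff_n[over] * scale)
        E_diff_m[over] = np.floor(E_diff_m[over] * scale)
        E_mob[over] = np.floor(E_mob[over] * scale)
    E_out = np.minimum(E_out, A[:, :, Lm].astype(np.int64))
    E_death = np.minimum(E_death, B.astype(np.int64))

    top = M - 1
    Am += E_self_n
    A[:, 1:, :Lm] += E_self_m[:, :top, :]
    A[:, top, :Lm] += E_self_m[:, top, :]
    diff_tot = E_diff_n + E_diff_m
    Am -= diff_tot
    A[:, :, 1:] += 2 * E_diff_n + E_diff_m
    A[:, 1:, 1:] += E_diff_m[:, :top, :]
    A[:, top, 1:] += E_diff_m[:, top, :]
    Am -= E_mob
    B[:, :, :Lm] += E_mob
    A[:, :, Lm] -= E_out
    B[:, :, Lm] += E_out
    B -= E_death
    state.t += tau


def step_tau_leap_batch(
    counts: np.ndarray,
    tables: RateTables,
    tau: float,
    rng: np.random.Generator,
) -> None:
    """One Poisson tau-leap applied to a batch of replicates.

    ``counts`` has shape ``(n_reps, 2, 2, M, L)``.  Statistically identical
    to :func:`step_tau_leap` applied per replicate, drawing from one stream.
    """
    n_reps = counts.shape[0]
    M_full = counts.shape[3]
    L = tables.n_levels
    Lm = L - 1
    occ = counts.any(axis=(0, 1, 2, 4))
    m_act = int(np.nonzero(occ)[0][-1]) if occ.any() else 0
    M = min(m_act + 2, M_full)
    A = counts[:, 0, :, :M, :]
    B = counts[:, 1, :, :M, :]

    bm_total = counts[:, 0].sum(axis=(1, 2, 3))
    C = bm_total / tables.n_ref
    kappa, K = tables.exch.kappa, tables.exch.K
    f = np.where(C >= 1.0, kappa * np.exp(C / K), 0.0)

    Am = A[:, :, :, :Lm]
    lam_div = Am * tau
    mu = tables.mu_level
    lam_self = lam_div * tables.r_self[:, :M, :]
    lam_diff = lam_div * tables.r_diff[:, :M, :]
    lam_mob = lam_div * (tables.mob_weight * f.reshape(n_reps, 1, 1, 1))

    lam_all = np.concatenate([
        (lam_self * (1.0 - mu)).ravel(),
        (lam_self * mu).ravel(),
        (lam_diff * (1.0 - mu)).ravel(),
        (lam_diff * mu).ravel(),
        lam_mob.ravel(),
        (A[:, :, :, Lm] * (tables.mature_out * tau)).ravel(),
        (B * (tables.death * tau)).ravel(),
    ])
    draws = _draw_channel_counts(lam_all, rng)
    div_shape = lam_self.shape
    n_div = lam_self.size
    n_mat = A[:, :, :, Lm].size
    o = 0
    E_self_n = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_self_m = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_diff_n = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_diff_m = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_mob = draws[o:o + n_div].reshape(div_shape); o += n_div
    E_out = draws[o:o + n_mat].reshape(A[:, :, :, Lm].shape); o += n_mat
    E_death = draws[o:].reshape(B.shape)

    # cap mobilization at each replicate's marrow excess (sliding mode)
    tot = E_mob.sum(axis=(1, 2, 3))
    budget = np.maximum(0.0, bm_total - tables.n_ref)
    need = tot > budget
    if need.any():
        scale = np.ones(n_reps)
        scale[need] = budget[need] / tot[need]
        E_mob = np.floor(E_mob * scale.reshape(n_reps, 1, 1, 1)).astype(np.int64)

    cons = E_diff_n + E_diff_m + E_mob
    over = cons > Am
    if over.any():
        sc = Am[over] / cons[over]
        E_diff_n[over] = np.floor(E_diff_n[over] * sc)
        E_diff_m[over] = np.floor(E_diff_m[over] * sc)
        E_mob[over] = np.floor(E_mob[over] * sc)
    E_out = np.minimum(E_out, A[:, :, :, Lm].astype(np.int64))
    E_death = np.minimum(E_death, B.astype(np.int64))

    top = M - 1
    Am += E_self_n
    A[:, :, 1:, :Lm] += E_self_m[:, :, :top, :]
    A[:, :, top, :Lm] += E_self_m[:, :, top, :]
    Am -= E_diff_n + E_diff_m
    A[:, :, :, 1:] += 2 * E_diff_n + E_diff_m
    A[:, :, 1:, 1:] += E_diff_m[:, :, :top, :]
    A[:, :, top, 1:] += E_diff_m[:, :, top, :]
    Am -= E_mob
    B[:, :, :, :Lm] += E_mob
    A[:, :, :, Lm] -= E_out
    B[:, :, :, Lm] += E_out
    B -= E_death


def run_phase_batch(
    rates: LevelRates,
    evol: EvolutionParams,
    exch: ExchangeParams,
    control: RunControl,
    n_reps: int,
    rng: np.random.Generator | None = None,
    founder: bool = True,
    thresholds_pct: tuple[float, ...] = (3.0, 10.0, 20.0),
    delta: float | None = None,
) -> dict[str, np.ndarray]:
    """Tau-leap a batch of replicates, recording phase-threshold crossings.

    All replicates share one parameter set and advance in lock-step; each
    stops individually once its bloodstream blast percentage exceeds
    ``control.stop_blast_pct``.  Returns first-crossing times (days, nan if
    never crossed; linearly interpolated within a step) for every threshold
    in ``thresholds_pct`` plus the stopping level, and a ``reached_stop``
    flag per replicate.  This is the workhorse behind parameter sweeps, where
    full sampled trajectories are not needed.
    """
    tables = build_rate_tables(rates, evol, exch, control.variant, delta)
    if rng is None:
        rng = np.random.default_rng(control.seed)
    proto = initialize_state(rates, exch, evol.m_cap, founder)
    counts = np.repeat(proto.counts[None, ...], n_reps, axis=0)
    L = tables.n_levels
    levels = np.arange(L)
    pool1 = levels < tables.pool2_start
    all_th = list(thresholds_pct) + [control.stop_blast_pct]
    crossings = np.full((n_reps, len(all_th)), np.nan)
    tau = control.tau_days
    t = 0.0

    def blast_pct() -> np.ndarray:
        blood = counts[:, 1]  # noqa: B023 - reads the loop's current batch
        tot = blood.sum(axis=(1, 2, 3))
        bl = blood[:, :, :, pool1].sum(axis=(1, 2, 3))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tot > 0, 100.0 * bl / np.maximum(tot, 1.0), 0.0)
        return out

    # replicates are dropped from the working arrays as they finish, so the
    # step cost tracks the number of still-running replicates
    idx = np.arange(n_reps)
    prev_bp = blast_pct()
    while t < control.horizon_days and counts.shape[0]:
        step_tau_leap_batch(counts, tables, tau, rng)
        t += tau
        bp = blast_pct()
        for j, th in enumerate(all_th):
            hit = np.isnan(crossings[idx, j]) & (bp >= th)
            if hit.any():
                db = bp[hit] - prev_bp[hit]
                frac = np.where(db > 0, (th - prev_bp[hit]) / np.maximum(db, 1e-300), 1.0)
                crossings[idx[hit], j] = t - tau + tau * np.clip(frac, 0.0, 1.0)
        done = bp > control.stop_blast_pct
        if done.any():
            keep = ~done
            counts = counts[keep]
            idx = idx[keep]
            bp = bp[keep]
        prev_bp = bp
    return {
        "crossings_days": crossings[:, :-1],
        "stop_crossing_days": crossings[:, -1],
        "reached_stop": ~np.isnan(crossings[:, -1]),
        "horizon_days": np.full(n_reps, control.horizon_days),
    }


def run_simulation(
    rates: LevelRates,
    evol: EvolutionParams,
    exch: ExchangeParams,
    control: RunControl,
    founder: bool = True,
    delta: float | None = None,
    rng: np.random.Generator | None = None,
) -> metrics.Trajectory:
    """Simulate from the founder event to the horizon or the blast phase.

    The run starts from the healthy state (plus one founder *BCR::ABL1* HSC
    unless ``founder=False``) and stops when ``t`` exceeds the horizon or the
    bloodstream blast percentage exceeds ``control.stop_blast_pct``.  The
    trajectory is sampled every ``control.sample_interval_days``; a final
    irregular sample is appended at the stopping time.  Fixing the seed and
    the engine mode fixes the trajectory exactly.
    """
    tables = build_rate_tables(rates, evol, exch, control.variant, delta)
    state = initialize_state(rates, exch, evol.m_cap, founder)
    if rng is None:
        rng = np.random.default_rng(control.seed)

    rows: list[tuple] = []
    profiles: list[np.ndarray] = []
    next_sample = 0.0
    stop_reason = "horizon"

    def record() -> None:
        blood = state.blood
        rows.append((
            state.t,
            metrics.blast_percentage(blood, tables.pool2_start),
            metrics.blast_percentage(state.marrow, tables.pool2_start),
            float(blood.sum()),
            float(blood[:, :, tables.n_levels - 1].sum()),
            metrics.transcript_level(blood),
            state.cellularity(tables.n_ref),
        ))
        profiles.append(metrics.max_mutation_profile(state.counts))

    interval = control.sample_interval_days
    while True:
        if state.t >= next_sample - 1e-9:
            record()
            next_sample = (math.floor(state.t / interval + 1e-9) + 1) * interval
        if metrics.blast_percentage(state.blood, tables.pool2_start) \
                > control.stop_blast_pct:
            stop_reason = "blast"
            break
        if state.t >= control.horizon_days:
            break
        mode = control.engine_mode
        if mode == "hybrid":
            mode = ("exact" if state.total_cells() < control.hybrid_exact_cells
                    else "tau")
        if mode == "exact":
            dt = step_exact(state, tables, rng)
            if dt is None:  # nothing can happen anymore
                stop_reason = "quiescent"
                state.t = control.horizon_days
                break
        else:
            step_tau_leap(state, tables, control.tau_days, rng)

    if not rows or rows[-1][0] < state.t:
        record()

    arr = np.array(rows, dtype=float)
    return metrics.Trajectory(
        t=arr[:, 0],
        blast_pct_blood=arr[:, 1],
        blast_pct_bm=arr[:, 2],
        total_blood=arr[:, 3],
        mature_blood=arr[:, 4],
        transcript_pct=arr[:, 5],
        cellularity=arr[:, 6],
        max_generic=np.array(profiles),
        stop_reason=stop_reason,
        stop_time=state.t,
    )
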