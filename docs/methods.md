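# Methods

`cmlsim` simulates blood production as a continuous-time Markov jump process
over aggregated cell classes and uses it to study how chronic myeloid
leukemia (CML) progresses from a single *BCR::ABL1*-positive hematopoietic
stem cell (HSC).  This note records the model, its parameters, the numerical
scheme, and the design choices made where the problem was genuinely open.

## The hierarchy

Bone-marrow hematopoiesis is a cascade of `n_levels = 21` differentiation
levels: level 0 holds `N_0 = 10^4` HSCs, level 20 holds `N_20 = 5x10^11`
mature cells, and the marrow exports `delta_19 = 10^11` mature cells/day to
the bloodstream.  Mitotic levels split into pool I (levels 0–14; cells
self-renew *and* differentiate, amplification factor `gamma_I > 2`) and pool
II (levels 15–19; committed cells that only differentiate symmetrically,
`gamma = 2`).  Level `k` emits `delta_k` cells/day, with
`gamma_k = delta_k / delta_{k-1} >= 2`.

Per-cell rates follow from homeostasis:
`r_symdiff = delta_k / (2 N_k)`, `r_selfrenew = (delta_k/2 - delta_{k-1}) / N_k`,
`R_k = r_selfrenew + r_symdiff`, with `delta_{-1} = 0`, which makes the HSC
level exactly critical (`r_selfrenew = r_symdiff`) in health.  Healthy cell
numbers are geometric in pool I with ratio
`(5x10^11 / (2^5 x 10^4))^(1/14) = 2.7696` and double per level in pool II;
the two anchored segments force `N_15 = N_14`, a quirk of anchoring both ends
that we keep deliberately.  The resulting marrow blast (pool-I) fraction is
2.42%, inside the physiological 0–3% range; reconstructions of this quantity
from the printed anchors cannot reach the sometimes-quoted 2.64%, and we
report our computed value.

The HSC division rate is the free physiological parameter (plausible range
0.5–6 divisions/year).  The pool-I rate amplification `gamma_I` is solved in
closed form from the mature output and the HSC rate
(`gamma_I = (10^11 / (10^4 * rate/365 * 2^5))^(1/14)`; e.g. 3.72 at
1.18 divisions/year) and is *not* assumed equal to the cell-number ratio
2.77 — equating them would contradict the free HSC rate.

## Driver mutations

A cell's state is (level, *BCR::ABL1* flag, generic-driver count,
compartment).  Each driver shifts division balance toward self-renewal while
preserving the total rate:

```
r~_selfrenew = r_selfrenew + S * Delta * R_k
r~_symdiff   = r_symdiff   - S * Delta * R_k        (clamped at 0)
```

`Delta = (r_symdiff - r_selfrenew) / (2 R)` at level 14 — the minimum
strength making a cell self-sustainable at the last pool-I level; for a
uniform pool-I cascade `Delta = 1/(2(gamma_I - 1))`.  Delta is computed once
from the healthy level-14 rates and applied frozen at every level, scaled by
the level's own `R_k` (the alternative — recomputing a per-level Delta — is
not what the rate equations state).  The cumulative strength is additive:
`S = s_bcrabl + m * s_generic` with `s_generic = (1 - s_bcrabl) / m_crit` and
`m_crit = 4`, so *BCR::ABL1* plus four generics is exactly self-sustainable
at level 14.  When the shift would drive `r~_symdiff` negative it is clamped
at zero and the self-renewal rate absorbs the remainder so `R_k` is
preserved exactly.

Generic drivers arise at every division with probability `mu` (one of the
two daughters gains one driver; double hits are ignored since `mu << 1`),
in healthy and leukemic cells alike.  Counts above `m_cap = 20` pool into
the cap class (observed maxima stay near 13).  *BCR::ABL1* itself is never
acquired de novo; it enters only on the single founder HSC.

## Marrow–blood exchange

Cellularity `C(t)` is the marrow total relative to its healthy value.
Mobilization of mitotic cells switches on at full capacity:
`f(C) = 0` for `C < 1`, `kappa * exp(C / K)` for `C >= 1`
(`kappa = 0.03`, `K = 10`), and the per-cell mobilization rate is
`R_k f` in pool I and `R_k f beta` in pool II (`beta = 50`).  Mature marrow
cells are released at the constant per-cell rate `delta_19 / N_20 = 0.2/day`,
the rate at which the level above produces them.  We examined gating the
mature release through `f` as well and rejected it: a gated release cannot
sustain the observed bloodstream steady state (5x10^10 mature cells) —
committed and mature pools deplete, mobilization shuts off permanently, and
the bloodstream collapses within days — whereas the constant release rate
reproduces it exactly (10^11/day influx over a 2/day death rate).

In the bloodstream nothing divides: blasts die at `R_k / alpha`
(`alpha = 50`; dormant, long-lived), committed cells at `R_k`, and mature
cells at `mature_output / mature_blood_target = 2/day` (a 12-hour lifespan).
The bloodstream starts with `5x10^10` mature cells and no immature ones; the
healthy immature leak is orders of magnitude below the 3% diagnosis
threshold, so no burn-in is needed.

## Stochastic engine

The state is a dense integer-valued array over
(compartment, flag, generic count, level).  Events: self-renewal (+1),
symmetric differentiation (−1 parent, +2 one level down), mobilization
(marrow → blood), mature release, and bloodstream death.  Three stepping
modes:

* **exact** — Gillespie's direct method over all channels; used for toy
  systems and oracle tests.
* **tau** — Poisson tau-leaping with a fixed step (default 0.25 days,
  heavier sweeps use 0.5 days).  This is safe here because every class that
  can be *small* has per-cell rates ≤ ~0.2/day (top levels, nascent mutant
  clones), so per-cell event probabilities per step stay ≤ ~0.1; the only
  fast channel (mature-blood death, 2/day) belongs to a ~5x10^10-cell class
  whose relative fluctuations are negligible.  Channel counts that would
  overdraw a class are scaled back proportionally; a step never produces a
  negative count.
* **hybrid** (default) — exact stepping whenever the whole system is below
  ~5x10^3 cells, tau-leaping otherwise.  A full-scale marrow executes
  ~10^11 division events/day; exact simulation of that is impossible at any
  horizon of interest, which is the reason tau-leaping exists here at all.
  The founder clone's early stochasticity — the driver of latency variance —
  is preserved because founder rates are ~3x10^-3/day.

Two numerical regularizations, both validated by the exact-vs-leap
equivalence tests:

* **Sliding-mode mobilization cap.** The healthy state sits exactly on the
  discontinuity of `f` at `C = 1`.  A raw Poisson leap overshoots far below
  capacity whenever the gate opens, injecting spurious immature cells into
  the blood at step resolution.  The leap therefore caps the *total* number
  of mobilized cells per step at the current excess above the healthy marrow
  total — the Filippov sliding-mode limit of the exact toggling dynamics,
  to which it converges as tau → 0.  In health the excess is ~Poisson
  fluctuation sized, so mobilization is quiescent; during disease the cap
  equals the leukemic overproduction, which is exactly what the homeostat
  should skim.
* **Expectation for huge channels.** Channels expecting ≥ 10^4 events in one
  step advance by their expectation instead of a Poisson draw (relative
  noise < 1%).  All small channels — everything that matters for clone fate
  — remain fully stochastic.

Replicate batches (`run_phase_batch`) advance all replicates of one
parameter set in lock-step from a single seeded stream, dropping replicates
from the working arrays as they individually hit the stopping rule, and
record threshold crossings online with linear interpolation inside the step.

All randomness flows from `numpy.random.default_rng(seed)`; a fixed seed and
engine mode reproduce a run exactly.  Derived seeds use `SeedSequence` and
stay below 2^31.

## Disease course and metrics

A run starts with one founder *BCR::ABL1* HSC in healthy production and
stops after 20 years or when bloodstream blasts exceed 30%.  Blast
percentage counts all pool-I levels (including HSCs, whose contribution is
negligible; no finer clinical definition exists).  Phases: latent = founder
to 3% blood blasts, chronic = 3–10%, accelerated = 10–20%, with crossings
linearly interpolated between samples and censoring recorded when a
threshold is never reached.  The transcript level is
`100 * mutated / (mutated + 2 * healthy)` over *all* bloodstream cells (the
restriction to mature cells is a config-flippable choice that changes the
value only marginally).

## Two-stage calibration

For each combination of (mu, HSC divisions/year, s_bcrabl): stage 1 keeps
combinations where ≥ 90% of replicates reach 30% blood blasts within 20
years; stage 2 further requires the median chronic and accelerated durations
to fall inside configured clinical windows.  The windows ship as
literature-derived placeholders — chronic 3–5 years, accelerated 0.5–1.5
years — because the reference ranges the selection was fitted to are not
published.  In this implementation the two placeholder windows are nearly
mutually exclusive: across the explored grid the accelerated phase runs at
roughly 0.6x the chronic phase, so medians satisfying one window rarely
satisfy the other, and the stage-2 filter applied with these placeholders
selects almost nothing.  The smoke-scale selection property we assert
instead is the establishment trade-off at low mutation rate (mu = 10^-4):
there stage 1 itself is selective, its passing set is bounded by a
downward-sloping frontier in (strength, division rate), and the rank
correlation between the two is negative — slow-dividing HSCs demand a
strong *BCR::ABL1* lesion, the qualitative trade-off the calibration is
meant to expose.  The stage-2 machinery itself is exercised with synthetic
durations in the unit tests.

With mu = 0 (no generic drivers) the founder clone survives at the HSC level
only with probability `2 s Delta / (1/2 + s Delta) < ~0.6`, so no mu = 0
combination can satisfy the 90/100 rule here; *BCR::ABL1*-only descriptions
of CML require conditioning on clone establishment.  At mu = 9x10^-4 the
doomed founders are rescued: their downstream progeny amplify enormously
while washing out and accumulate the ~4 generics needed for a
self-sustaining pool-I subclone, which is why ≥ 90% of replicates progress
at the reference combination.

## Problem sizes

Default study conditions are the full-scale system (10^12 marrow cells, 20
year horizon).  Replicate counts: 100 for the progression-rate check and the
variant comparison (per arm), 20 combinations x 20 replicates for the
smoke-scale sweep; engine-equivalence tests use toy hierarchies (≤ 10^3
cells) with 400–500 replicates per arm.  A single full-scale 20-year run
takes a few seconds at tau = 0.25–0.5 days on one core.

## Limitations

* One collapsed lineage: no lymphoid/myeloid split, no niche structure, no
  immune interaction, no treatment or resistance dynamics.
* Wild-type rates are frozen at healthy values; the only feedback is the
  cellularity-gated mobilization.  In particular the HSC pool performs an
  unbiased random walk (critical branching), so a 20-year healthy marrow
  drifts by a few percent in cellularity — visible in long homeostasis runs
  as C(t) excursions of order 1/sqrt(N_0) per filtered year.
* Tau-leaping at 0.25–0.5 day resolution slightly blurs event times within a
  step; phase durations carry an O(tau) interpolation error, negligible
  against their year-scale values.
* The stage-2 windows are placeholders; any quantitative statement that
  depends on their numeric values (not made here) would be unvalidated.
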