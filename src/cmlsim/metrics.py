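"""Clinical summaries: blast percentages, transcript level, phase durations.

Disease phases are delimited by the blast percentage in the bloodstream:
latent until 3%, chronic until 10%, accelerated until 20%, blast phase
beyond.  The latent clock starts when the *BCR::ABL1* founder cell appears
(t = 0 of a simulation).  The tumor-load proxy is the transcript level
``100 * mutated / (mutated + 2 * healthy)`` over bloodstream cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import DAYS_PER_YEAR

PHASE_THRESHOLDS_PCT = (3.0, 10.0, 20.0)


def blast_percentage(comp_counts: np.ndarray, pool2_start: int) -> float:
    """Percentage of pool-I (blast) cells in one compartment.

    ``comp_counts`` has shape ``(2, M, L)`` = (BCR::ABL1 flag, generic count,
    level).  Defined as 0 for an empty compartment.
    """
    total = comp_counts.sum()
    if total <= 0:
        return 0.0
    return 100.0 * float(comp_counts[:, :, :pool2_start].sum()) / float(total)


def transcript_level(blood_counts: np.ndarray) -> float:
    """Approximate *BCR::ABL1*/ABL1 transcript level (%) in the bloodstream."""
    mutated = float(blood_counts[1].sum())
    healthy = float(blood_counts[0].sum())
    if mutated + healthy <= 0:
        return 0.0
    return 100.0 * mutated / (mutated + 2.0 * healthy)


def max_mutation_profile(counts: np.ndarray) -> np.ndarray:
    """Per-level maximum generic-driver count over occupied classes.

    ``counts`` has shape ``(2, 2, M, L)`` (compartment, flag, generic count,
    level); levels with no cells report 0.
    """
    occupied = counts.sum(axis=(0, 1)) > 0  # (M, L)
    M = occupied.shape[0]
    weights = np.arange(M)[:, None]
    return np.where(occupied.any(axis=0), (occupied * weights).max(axis=0), 0)


@dataclass
class Trajectory:
    """Sampled summaries of one simulation run."""

    t: np.ndarray                 # days, strictly increasing
    blast_pct_blood: np.ndarray
    blast_pct_bm: np.ndarray
    total_blood: np.ndarray
    mature_blood: np.ndarray
    transcript_pct: np.ndarray
    cellularity: np.ndarray
    max_generic: np.ndarray       # (n_samples, n_levels)
    stop_reason: str = "horizon"  # "horizon" | "blast" | "quiescent"
    stop_time: float = field(default=float("nan"))

    @property
    def n_levels(self) -> int:
        return self.max_generic.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_days": self.t,
            "blast_pct_blood": self.blast_pct_blood,
            "blast_pct_bm": self.blast_pct_bm,
            "total_blood": self.total_blood,
            "mature_blood": self.mature_blood,
            "transcript_pct": self.transcript_pct,
            "cellularity": self.cellularity,
        })
        for k in range(self.n_levels):
            df[f"max_generic_level_{k}"] = self.max_generic[:, k]
        return df

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, stop_reason: str = "horizon",
        stop_time: float = float("nan"),
    ) -> "Trajectory":
        gen_cols = [c for c in df.columns if c.startswith("max_generic_level_")]
        gen_cols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
        return cls(
            t=df["time_days"].to_numpy(float),
            blast_pct_blood=df["blast_pct_blood"].to_numpy(float),
            blast_pct_bm=df["blast_pct_bm"].to_numpy(float),
            total_blood=df["total_blood"].to_numpy(float),
            mature_blood=df["mature_blood"].to_numpy(float),
            transcript_pct=df["transcript_pct"].to_numpy(float),
            cellularity=df["cellularity"].to_numpy(float),
            max_generic=df[gen_cols].to_numpy(float),
            stop_reason=stop_reason,
            stop_time=stop_time,
        )


@dataclass(frozen=True)
class PhaseDurations:
    """Durations (years) of the latent, chronic and accelerated phases.

    A ``nan`` duration means the corresponding threshold was never crossed
    before the run ended; ``censored_at`` then records the end of observation
    (years).  ``blast_reached`` flags runs whose bloodstream blast percentage
    hit the blast-phase stopping level.
    """

    latent: float
    chronic: float
    accelerated: float
    blast_reached: bool
    censored_at: float | None = None

    @property
    def complete(self) -> bool:
        return not (np.isnan(self.latent) or np.isnan(self.chronic)
                    or np.isnan(self.accelerated))


def first_crossing(t: np.ndarray, y: np.ndarray, threshold: float) -> float:
    """First time ``y`` reaches ``threshold``, linearly interpolated.

    Returns ``nan`` if the series never reaches it.
    """
    above = y >= threshold
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold - y0) * (t1 - t0) / (y1 - y0))


def detect_phase_durations(
    traj: Trajectory,
    thresholds_pct: tuple[float, float, float] = PHASE_THRESHOLDS_PCT,
) -> PhaseDurations:
    """Phase durations from the bloodstream blast-percentage series."""
    t = traj.t
    y = traj.blast_pct_blood
    t3, t10, t20 = (first_crossing(t, y, th) for th in thresholds_pct)
    end_days = traj.stop_time if np.isfinite(traj.stop_time) else float(t[-1])
    latent = t3 / DAYS_PER_YEAR
    chronic = (t10 - t3) / DAYS_PER_YEAR
    accelerated = (t20 - t10) / DAYS_PER_YEAR
    censored = None
    if any(np.isnan(x) for x in (latent, chronic, accelerated)):
        censored = end_days / DAYS_PER_YEAR
    return PhaseDurations(
        latent=latent,
        chronic=chronic,
        accelerated=accelerated,
        blast_reached=(traj.stop_reason == "blast"),
        censored_at=censored,
    )
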