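"""Configuration loading, toy fixtures, and output writers.

Configuration files are YAML (JSON is a YAML subset and works too) with four
optional sections — ``hierarchy``, ``evolution``, ``exchange``, ``run`` —
whose keys map one-to-one onto :class:`~cmlsim.hierarchy.HierarchyConfig`,
:class:`~cmlsim.mutation.EvolutionParams`,
:class:`~cmlsim.exchange.ExchangeParams` and
:class:`~cmlsim.engine.RunControl`.  An empty file yields the reference
defaults.  Unknown sections or keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .engine import RunControl
from .exchange import ExchangeParams
from .hierarchy import HierarchyConfig, HierarchyError, LevelRates, rates_from_tables
from .mutation import EvolutionParams


class ConfigError(ValueError):
    """Malformed configuration file."""


_SECTIONS = {
    "hierarchy": HierarchyConfig,
    "evolution": EvolutionParams,
    "exchange": ExchangeParams,
    "run": RunControl,
}

_DEFAULT_EVOLUTION = dict(mu=9e-4, s_bcrabl=0.67)


def _build_section(name: str, cls: type, data: dict[str, Any]):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{name}': {', '.join(sorted(unknown))}"
        )
    kwargs = dict(data)
    if name == "evolution":
        kwargs = {**_DEFAULT_EVOLUTION, **kwargs}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"section '{name}': {exc}") from exc


def load_config(
    path: str | Path,
) -> tuple[HierarchyConfig, EvolutionParams, ExchangeParams, RunControl]:
    """Load and validate a full parameter set from a YAML/JSON file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")
    out = []
    for name, cls in _SECTIONS.items():
        data = raw.get(name, {})
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"section '{name}' must be a mapping")
        out.append(_build_section(name, cls, data))
    return tuple(out)  # type: ignore[return-value]


def dump_config(
    hier: HierarchyConfig,
    evol: EvolutionParams,
    exch: ExchangeParams,
    run: RunControl,
    path: str | Path,
) -> None:
    """Write a parameter set back to YAML; round-trips through load_config."""
    doc = {
        "hierarchy": dataclasses.asdict(hier),
        "evolution": dataclasses.asdict(evol),
        "exchange": dataclasses.asdict(exch),
        "run": dataclasses.asdict(run),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def make_toy_hierarchy(
    n_levels: int = 4,
    n_hsc: int = 8,
    gamma: float = 2.0,
    output: float = 64.0,
) -> LevelRates:
    """Miniature, fully consistent hierarchy for oracle tests.

    Mitotic levels ``0 .. n_levels - 2`` share a uniform amplification factor
    ``gamma >= 2`` with the topmost output anchored at ``output`` cells/day;
    cell numbers scale with the flux (``N_k = n_hsc * gamma**k``) so per-cell
    division rates are equal across mitotic levels, and the mature level holds
    twice the last mitotic level.  With ``gamma == 2`` every level below the
    HSC is committed (pool II); with ``gamma > 2`` all mitotic levels
    self-renew and the committed pool is empty.
    """
    if n_levels < 2:
        raise HierarchyError("toy hierarchy needs at least 2 levels")
    if gamma < 2.0:
        raise HierarchyError("gamma must be >= 2")
    n_mit = n_levels - 1
    delta = output / gamma ** np.arange(n_mit - 1, -1, -1)
    N = np.empty(n_levels)
    N[:n_mit] = n_hsc * gamma ** np.arange(n_mit)
    N[n_mit] = 2.0 * N[n_mit - 1]
    pool2_start = 1 if gamma == 2.0 else n_levels - 1
    return rates_from_tables(N=N, delta=delta, pool2_start=pool2_start)


def write_trajectory(traj, path: str | Path) -> None:
    """Write a trajectory as tab-separated text with a metadata header line."""
    path = Path(path)
    meta = json.dumps({"stop_reason": traj.stop_reason,
                       "stop_time": traj.stop_time})
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        traj.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: str | Path):
    """Inverse of :func:`write_trajectory`."""
    from .metrics import Trajectory

    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ").strip()) if first.startswith("#") \
            else {}
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return Trajectory.from_frame(
        df,
        stop_reason=meta.get("stop_reason", "horizon"),
        stop_time=float(meta.get("stop_time", "nan")),
    )
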