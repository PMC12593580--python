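"""CSV and YAML interchange for traces, samples and configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abm import DiseaseConfig, EpidemicTrace
from .town import TownConfig

__all__ = [
    "traces_to_frame",
    "write_traces_csv",
    "read_traces_csv",
    "load_config_yaml",
]

TRACE_COLUMNS = ["scenario", "run", "day", "S", "E", "I", "R", "incidence"]


def traces_to_frame(traces: list[EpidemicTrace]) -> pd.DataFrame:
    """Long-format frame, one row per (run, day); day is 1-based."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "scenario": tr.scenario,
                    "run": tr.run,
                    "day": np.arange(1, tr.n_days + 1),
                    "S": tr.S,
                    "E": tr.E,
                    "I": tr.I,
                    "R": tr.R,
                    "incidence": tr.incidence,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[TRACE_COLUMNS]


def write_traces_csv(traces: list[EpidemicTrace], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    traces_to_frame(traces).to_csv(path, index=False, lineterminator="\n")
    return path


def read_traces_csv(path: str | Path, n_agents: int | None = None) -> list[EpidemicTrace]:
    df = pd.read_csv(path)
    traces = []
    for (scenario, run), g in df.groupby(["scenario", "run"], sort=True):
        g = g.sort_values("day")
        traces.append(
            EpidemicTrace(
                scenario=str(scenario),
                run=int(run),
                S=g["S"].to_numpy(int),
                E=g["E"].to_numpy(int),
                I=g["I"].to_numpy(int),
                R=g["R"].to_numpy(int),
                incidence=g["incidence"].to_numpy(int),
                n_agents=n_agents or int(g.iloc[0][["S", "E", "I", "R"]].sum()),
            )
        )
    return traces


def load_config_yaml(path: str | Path) -> dict:
    """Load a YAML config with optional ``town``, ``disease``, ``scenario``
    and ``seeds`` blocks; town/disease blocks override dataclass defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "town" in raw:
        tc = dict(raw["town"])
        if "grid_shape" in tc:
            tc["grid_shape"] = tuple(tc["grid_shape"])
        if "household_size_probs" in tc:
            tc["household_size_probs"] = tuple(tc["household_size_probs"])
        if "adult_status_probs" in tc:
            tc["adult_status_probs"] = tuple(tc["adult_status_probs"])
        out["town"] = TownConfig(**tc)
    if "disease" in raw:
        out["disease"] = DiseaseConfig(**raw["disease"])
    return out
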