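"""Reading and writing run artifacts: snapshots, birth logs, configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .genetics import MutationConfig
from .genome import Genome, genome_from_dict
from .world import RunResult, WorldConfig

__all__ = [
    "write_snapshot",
    "load_snapshot",
    "population_from_snapshot",
    "write_run_result",
    "load_world_config",
    "world_config_to_dict",
]


def write_snapshot(snapshot: dict, path) -> None:
    """Byte-stable snapshot JSON (sorted keys, compact separators)."""
    Path(path).write_text(
        json.dumps(snapshot, sort_keys=True, separators=(",", ":")) + "\n"
    )


def load_snapshot(path) -> dict:
    return json.loads(Path(path).read_text())


def population_from_snapshot(snapshot: dict):
    """``(genome, a)`` pairs for :func:`noiseworld.control.run_control_test`."""
    return [
        (genome_from_dict(agent["genome"]), float(agent["a"]))
        for agent in snapshot["agents"]
    ]


def write_run_result(result: RunResult, out_dir) -> None:
    """Write one snapshot file per island per era, births.csv and events.log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (era, island_id), snap in sorted(result.snapshots.items()):
        write_snapshot(snap, out / f"snapshot_era{era:05d}_island{island_id:03d}.json")
    pd.DataFrame(result.birth_log, columns=["era", "island", "births"]).to_csv(
        out / "births.csv", index=False
    )
    (out / "events.log").write_text("".join(line + "\n" for line in result.events))


def world_config_to_dict(cfg: WorldConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["mutation"]["const_range"] = list(d["mutation"]["const_range"])
    d["mutation"]["v0_replace_range"] = list(d["mutation"]["v0_replace_range"])
    return d


def load_world_config(path) -> WorldConfig:
    """Build a :class:`WorldConfig` from a YAML (or JSON) mapping.

    Keys mirror the dataclass fields; the ``mutation`` sub-mapping mirrors
    :class:`MutationConfig`.  Absent keys keep their defaults.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    return world_config_from_dict(data)


def world_config_from_dict(data: dict) -> WorldConfig:
    data = dict(data)
    mdata = data.pop("mutation", {}) or {}
    allowed = {f.name for f in dataclasses.fields(MutationConfig)}
    unknown = set(mdata) - allowed
    if unknown:
        raise ValueError(f"unknown mutation keys: {sorted(unknown)}")
    for key in ("const_range", "v0_replace_range"):
        if key in mdata:
            mdata[key] = tuple(mdata[key])
    mutation = MutationConfig(**mdata)
    allowed = {f.name for f in dataclasses.fields(WorldConfig)} - {"mutation"}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = WorldConfig(mutation=mutation, **data)
    cfg.validate()
    return cfg
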