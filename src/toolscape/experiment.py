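"""Seeded runs, factorial sweeps, and run persistence.

A run is fully determined by its :class:`~toolscape.config.SimulationConfig`
(which includes the seed). ``run_simulation`` executes it and returns a
:class:`RunRecord`; ``write_run``/``read_run`` round-trip records losslessly
through CSV + JSON; ``run_sweep`` executes a full factorial design over tree
count × source count × tree dynamics with reproducibly derived per-run seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .analysis import summarize_run
from .config import SimulationConfig
from .model import Placements, World, initialize_world, world_step

__all__ = [
    "RunRecord",
    "SweepDesign",
    "run_simulation",
    "run_sweep",
    "derive_seed",
    "write_run",
    "read_run",
]

logger = logging.getLogger(__name__)

TOOLS_COLUMNS = [
    "tool_id",
    "origin_source_id",
    "origin_x",
    "origin_y",
    "x",
    "y",
    "initial_mass",
    "mass",
    "fragility",
    "n_uses",
    "is_fragment",
    "parent_tool_id",
    "created_step",
]
SOURCES_COLUMNS = ["source_id", "x", "y", "fragility"]
TREES_COLUMNS = ["tree_id", "x", "y", "born_step", "death_step"]
TIMESERIES_COLUMNS = ["step", "n_tool_use_locations"]


@dataclass
class RunRecord:
    """Everything a finished run leaves behind.

    ``timeseries`` — tool-use-location count per recording interval;
    ``tools_final`` — one row per tool or fragment ever created, final state;
    ``sources_final`` — source positions and fragilities;
    ``trees_history`` — every tree that ever lived, with birth and (possibly
    open) death step.
    """

    config: SimulationConfig
    seed: int
    timeseries: pd.DataFrame
    tools_final: pd.DataFrame
    sources_final: pd.DataFrame
    trees_history: pd.DataFrame

    def equals(self, other: "RunRecord") -> bool:
        return (
            self.config == other.config
            and self.seed == other.seed
            and self.timeseries.equals(other.timeseries)
            and self.tools_final.equals(other.tools_final)
            and self.sources_final.equals(other.sources_final)
            and self.trees_history.equals(other.trees_history)
        )


def _record_from_world(world: World) -> RunRecord:
    cfg = world.config
    tools = pd.DataFrame(
        [
            (
                t.id,
                t.origin_source_id,
                t.origin_x,
                t.origin_y,
                t.x,
                t.y,
                t.initial_mass,
                t.mass,
                t.fragility,
                t.n_uses,
                bool(t.is_fragment),
                t.parent_tool_id,
                t.created_step,
            )
            for t in world.tools
        ],
        columns=TOOLS_COLUMNS,
    )
    tools = tools.astype(
        {
            "tool_id": "int64",
            "origin_source_id": "int64",
            "origin_x": "int64",
            "origin_y": "int64",
            "x": "int64",
            "y": "int64",
            "initial_mass": "float64",
            "mass": "float64",
            "fragility": "int64",
            "n_uses": "int64",
            "is_fragment": "bool",
            "parent_tool_id": "int64",
            "created_step": "int64",
        }
    )
    sources = pd.DataFrame(
        [(s.id, s.position[0], s.position[1], s.fragility) for s in world.sources],
        columns=SOURCES_COLUMNS,
    ).astype("int64")
    trees = pd.DataFrame(world.tree_history, columns=TREES_COLUMNS)
    trees["death_step"] = trees["death_step"].astype("Int64")
    trees = trees.astype(
        {"tree_id": "int64", "x": "int64", "y": "int64", "born_step": "int64"}
    )
    ts = pd.DataFrame(world.timeseries, columns=TIMESERIES_COLUMNS).astype("int64")
    return RunRecord(
        config=cfg,
        seed=cfg.seed,
        timeseries=ts,
        tools_final=tools,
        sources_final=sources,
        trees_history=trees,
    )


def run_simulation(
    config: SimulationConfig,
    placements: Placements | None = None,
    track_bouts: bool = False,
) -> RunRecord | tuple[RunRecord, World]:
    """Execute a run of ``config.n_steps`` steps and return its RunRecord.

    The tool-use-location count is recorded at step 0 and then at every
    ``config.effective_record_every`` steps (the final step is always
    recorded). With ``track_bouts`` the world keeps a per-bout log and the
    function returns ``(record, world)`` for invariant auditing.
    """
    world = initialize_world(config, placements=placements, track_bouts=track_bouts)
    every = config.effective_record_every
    world.timeseries.append((0, world.count_tool_use_locations()))
    for s in range(config.n_steps):
        world_step(world)
        done = s + 1
        if done % every == 0 or done == config.n_steps:
            world.timeseries.append((done, world.count_tool_use_locations()))
    record = _record_from_world(world)
    if track_bouts:
        return record, world
    return record


# --------------------------------------------------------------------- sweep


@dataclass(frozen=True)
class SweepDesign:
    """Full factorial design: tree levels × source levels × tree dynamics,
    ``iterations`` seeded replicates each. ``base_config`` carries every other
    parameter; per-run seeds are derived from ``base_seed`` (see
    :func:`derive_seed`) and are pairwise distinct."""

    trees_levels: tuple[int, ...] = (100, 500, 1000, 2000)
    sources_levels: tuple[int, ...] = (10, 100, 500)
    dynamic_levels: tuple[bool, ...] = (False, True)
    iterations: int = 10
    base_seed: int = 0
    n_steps: int = 75_000
    base_config: SimulationConfig = field(default_factory=SimulationConfig)

    def combinations(self) -> list[tuple[int, int, bool]]:
        return [
            (nt, ns, dyn)
            for nt in self.trees_levels
            for ns in self.sources_levels
            for dyn in self.dynamic_levels
        ]


def derive_seed(base_seed: int, combo_index: int, iteration: int) -> int:
    """Stable per-run seed: SHA-256 of ``"base:combo:iteration"`` folded to
    31 bits. Platform-independent and documented so sweeps are reproducible."""
    digest = hashlib.sha256(f"{base_seed}:{combo_index}:{iteration}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _one_sweep_run(design: SweepDesign, combo_index: int, iteration: int):
    nt, ns, dyn = design.combinations()[combo_index]
    seed = derive_seed(design.base_seed, combo_index, iteration)
    cfg = design.base_config.replace(
        n_trees=nt, n_sources=ns, dynamic_trees=dyn, n_steps=design.n_steps, seed=seed
    )
    record = run_simulation(cfg)
    run_id = f"combo{combo_index:02d}_iter{iteration:02d}"
    s = summarize_run(record, run_id=run_id)
    row = {
        "run_id": run_id,
        "combo_index": combo_index,
        "iteration": iteration,
        "n_trees": nt,
        "n_sources": ns,
        "dynamic_trees": dyn,
        "seed": seed,
        "max_displacement": s.max_displacement,
        "n_locations_start": s.n_locations_start,
        "n_locations_end": s.n_locations_end,
        "any_transport_beyond_3": s.any_transport_beyond_3,
        "pct_assemblages_with_usable": s.pct_assemblages_with_usable,
        "n_tools": len(record.tools_final),
        "n_assemblage_cells": int(
            record.tools_final.groupby(["x", "y"]).ngroups if len(record.tools_final) else 0
        ),
    }
    return row, record


SUMMARY_COLUMNS = [
    "run_id",
    "combo_index",
    "iteration",
    "n_trees",
    "n_sources",
    "dynamic_trees",
    "seed",
    "max_displacement",
    "n_locations_start",
    "n_locations_end",
    "any_transport_beyond_3",
    "pct_assemblages_with_usable",
    "n_tools",
    "n_assemblage_cells",
]


def run_sweep(
    design: SweepDesign,
    keep_records: bool = False,
    jobs: int = 1,
    progress: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[str, RunRecord]]:
    """Execute every combination × iteration of a design.

    Returns the summary table (one row per run, ordered by combination then
    iteration regardless of execution order); with ``keep_records`` also a
    ``{run_id: RunRecord}`` dict. ``jobs > 1`` runs independent simulations in
    parallel via joblib; results are identical either way.
    """
    tasks = [
        (ci, it)
        for ci in range(len(design.combinations()))
        for it in range(design.iterations)
    ]
    seeds = [derive_seed(design.base_seed, ci, it) for ci, it in tasks]
    if len(set(seeds)) != len(seeds):
        raise RuntimeError("derived sweep seeds collide; change base_seed")
    if jobs > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=jobs)(
            delayed(_one_sweep_run)(design, ci, it) for ci, it in tasks
        )
    else:
        results = []
        for k, (ci, it) in enumerate(tasks):
            if progress:
                logger.info("sweep run %d/%d (combo %d, iter %d)", k + 1, len(tasks), ci, it)
            results.append(_one_sweep_run(design, ci, it))
    rows = [row for row, _ in results]
    summaries = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    summaries = summaries.sort_values(["combo_index", "iteration"], ignore_index=True)
    if keep_records:
        return summaries, {row["run_id"]: rec for row, rec in results}
    return summaries


def load_sweep_design(path: str | Path) -> SweepDesign:
    """Read a sweep design from YAML: keys ``trees_levels``, ``sources_levels``,
    ``dynamic_levels``, ``iterations``, ``base_seed``, ``n_steps``, and an
    optional ``base_config`` mapping of SimulationConfig overrides."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    base_cfg = SimulationConfig.from_dict(data.pop("base_config", {}) or {})
    known = {f.name for f in dataclasses.fields(SweepDesign)} - {"base_config"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown sweep design keys: {sorted(unknown)}")
    for key in ("trees_levels", "sources_levels", "dynamic_levels"):
        if key in data:
            data[key] = tuple(data[key])
    return SweepDesign(base_config=base_cfg, **data)


# ----------------------------------------------------------------------- I/O

_METADATA_FILE = "metadata.json"
_FILES = {
    "timeseries": "timeseries.csv",
    "tools": "tools.csv",
    "sources": "sources.csv",
    "trees": "trees.csv",
}


def write_run(record: RunRecord, out_dir: str | Path) -> None:
    """Persist a RunRecord: config/seed/version as JSON, the four tables as
    headered CSV with fixed column order. Floats are written with ``repr``
    precision, so a read-back record equals the original."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "toolscape-run",
        "version": __version__,
        "seed": record.seed,
        "config": record.config.to_dict(),
    }
    with open(out / _METADATA_FILE, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    # %.17g is the shortest format guaranteed to round-trip float64 exactly
    record.timeseries.to_csv(out / _FILES["timeseries"], index=False)
    record.tools_final.to_csv(out / _FILES["tools"], index=False, float_format="%.17g")
    record.sources_final.to_csv(out / _FILES["sources"], index=False)
    record.trees_history.to_csv(out / _FILES["trees"], index=False)


def read_run(out_dir: str | Path) -> RunRecord:
    """Load a RunRecord written by :func:`write_run`. Missing or malformed
    files raise with the offending path in the message."""
    out = Path(out_dir)
    meta_path = out / _METADATA_FILE
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path}: run metadata file is missing")
    try:
        with open(meta_path) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as e:  # include file and line in the error
        raise ValueError(f"{meta_path}: malformed JSON at line {e.lineno}: {e.msg}") from e
    if meta.get("format") != "toolscape-run":
        raise ValueError(f"{meta_path}: not a toolscape run directory")
    config = SimulationConfig.from_dict(meta["config"])

    def _read(name: str, dtypes: dict) -> pd.DataFrame:
        path = out / _FILES[name]
        if not path.exists():
            raise FileNotFoundError(f"{path}: expected run table is missing")
        try:
            return pd.read_csv(path, dtype=dtypes, float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as e:
            raise ValueError(f"{path}: failed to parse: {e}") from e

    ts = _read("timeseries", {c: "int64" for c in TIMESERIES_COLUMNS})
    tools = _read(
        "tools",
        {
            "tool_id": "int64",
            "origin_source_id": "int64",
            "origin_x": "int64",
            "origin_y": "int64",
            "x": "int64",
            "y": "int64",
            "initial_mass": "float64",
            "mass": "float64",
            "fragility": "int64",
            "n_uses": "int64",
            "is_fragment": "bool",
            "parent_tool_id": "int64",
            "created_step": "int64",
        },
    )
    sources = _read("sources", {c: "int64" for c in SOURCES_COLUMNS})
    trees = _read(
        "trees",
        {"tree_id": "int64", "x": "int64", "y": "int64", "born_step": "int64", "death_step": "Int64"},
    )
    if len(tools) == 0:
        tools = pd.DataFrame(columns=TOOLS_COLUMNS).astype(
            {
                "tool_id": "int64",
                "origin_source_id": "int64",
                "origin_x": "int64",
                "origin_y": "int64",
                "x": "int64",
                "y": "int64",
                "initial_mass": "float64",
                "mass": "float64",
                "fragility": "int64",
                "n_uses": "int64",
                "is_fragment": "bool",
                "created_step": "int64",
            }
        )
    return RunRecord(
        config=config,
        seed=int(meta["seed"]),
        timeseries=ts,
        tools_final=tools,
        sources_final=sources,
        trees_history=trees,
    )
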