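"""Deterministic fixtures and brute-force oracles.

The model is stochastic; these scenarios pin down configurations whose
qualitative outcome is provable by hand (no bout can ever start; a chain of
trees must eventually relay a tool beyond one hop), plus an exhaustive
re-computation of the tool-use-location count to check the fast incremental
implementation against. Scenario configs deliberately allow break probability
0 and mass sd 0 — test-only settings that create deterministic paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import Snapshot
from .config import SimulationConfig
from .model import Placements, World, initialize_world

__all__ = [
    "ScenarioSpec",
    "scenario_no_transport",
    "scenario_chain",
    "build_world",
    "brute_force_locations",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully pinned-down test world: config + explicit placements + the
    qualitative outcome the construction guarantees."""

    config: SimulationConfig
    placements: Placements
    expectation: str = ""


def build_world(spec: ScenarioSpec, track_bouts: bool = False) -> World:
    """Instantiate the scenario's world (placements validated by the model)."""
    return initialize_world(spec.config, placements=spec.placements, track_bouts=track_bouts)


def scenario_no_transport(seed: int = 0) -> ScenarioSpec:
    """Every tree strictly farther than the location radius (3 cells) from
    every source: no bout can ever start, so the tool registry stays empty and
    the tool-use-location count is 0 for any run length.

    Sources sit on the left edge of a 40×40 grid, trees on the right, with a
    gap of well over 3 Chebyshev cells; trees are static so the geometry is
    pinned for the whole run.
    """
    trees = [(30, 4 * i + 2) for i in range(8)]
    sources = [(2, 8 * i + 3, 0) for i in range(4)]
    primates = [(20, 2 * (i % 19) + 1) for i in range(10)]
    cfg = SimulationConfig(
        width=40,
        height=40,
        n_primates=len(primates),
        n_trees=len(trees),
        n_sources=len(sources),
        dynamic_trees=False,
        n_steps=1000,
        fragility_levels=(0,),
        seed=seed,
    )
    return ScenarioSpec(
        config=cfg,
        placements=Placements(trees=trees, sources=sources, primates=primates),
        expectation="no tool is ever created; tool-use-location count is 0 throughout",
    )


def scenario_chain(n_links: int = 5, spacing: int = 3, seed: int = 0) -> ScenarioSpec:
    """One source and a straight chain of trees ``spacing`` cells apart.

    The first tree sits within acquisition range of the source (3 cells), so
    tools are always struck; the remaining trees follow at ``spacing``. With
    spacing ≤ 4 a tool discarded at one tree can end within acquisition range
    of the next (discard reaches 1 cell toward it, acquisition reaches 3 back),
    so over a long run a tool is relayed link by link and some tool's
    displacement from its source exceeds 3 cells. With spacing ≥ 5 the relay
    is broken: tools shuttle around the first tree and never get farther than
    the single-hop bound (≤ 4 cells from the source). Break
    probability is forced to 0 and the initial-mass sd to 0, so tools never
    wear out and the only randomness is the walk itself.
    """
    if n_links < 1:
        raise ValueError("n_links must be at least 1")
    x0 = 2
    row = 5
    height = 11
    first_hop = min(spacing, 3)
    width = x0 + first_hop + spacing * (n_links - 1) + 4
    source = (x0, row, 0)
    trees = [(x0 + first_hop + spacing * k, row) for k in range(n_links)]
    # cluster the walkers on the chain so relays happen quickly
    primates = [(trees[i % n_links][0], (row + 1 + i // n_links) % height) for i in range(20)]
    cfg = SimulationConfig(
        width=width,
        height=height,
        n_primates=len(primates),
        n_trees=len(trees),
        n_sources=1,
        dynamic_trees=False,
        n_steps=5000,
        baseline_break_prob=0.0,
        fragility_levels=(0,),
        initial_mass_mean=4000.0,
        initial_mass_sd=0.0,
        seed=seed,
    )
    expectation = (
        "some tool's displacement from its source exceeds 3 cells"
        if spacing <= 3
        else "no tool ever exceeds the single-hop bound of 4 cells"
    )
    return ScenarioSpec(
        config=cfg,
        placements=Placements(trees=trees, sources=[source], primates=primates),
        expectation=expectation,
    )


def brute_force_locations(snapshot: Snapshot) -> int:
    """O(trees × items) oracle twin of the tool-use-location count: for every
    live tree, scan every source and usable tool and check the Chebyshev
    distance directly. Intended for small snapshots (≤ ~50×50)."""
    items: list[tuple[int, int]] = [tuple(p) for p in np.asarray(snapshot.sources).reshape(-1, 2)]
    masses = np.asarray(snapshot.tool_masses)
    for pos, m in zip(np.asarray(snapshot.tool_positions).reshape(-1, 2), masses):
        if m >= snapshot.usable_threshold:
            items.append(tuple(pos))
    count = 0
    for tx, ty in np.asarray(snapshot.trees).reshape(-1, 2):
        for ix, iy in items:
            if max(abs(int(tx) - int(ix)), abs(int(ty) - int(iy))) <= snapshot.location_radius:
                count += 1
                break
    return count
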