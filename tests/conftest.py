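"""Shared fixtures: one audited mid-size run for the exact property suites and
two larger seeded workloads (a scaled factorial sweep and a full-length
high-density run) shared by the statistical tests. All session-scoped so the
expensive simulations execute once."""

from __future__ import annotations

import numpy as np
import pytest

from toolscape import (
    Placements,
    SimulationConfig,
    SweepDesign,
    initialize_world,
    run_simulation,
    run_sweep,
)


@pytest.fixture(scope="session")
def audit_run():
    """Mid-size dynamic-tree run with per-bout logging, for invariant audits.

    Returns (record, world): the world keeps the bout log and final grids.
    """
    cfg = SimulationConfig(
        width=120,
        height=120,
        n_primates=40,
        n_trees=300,
        n_sources=40,
        dynamic_trees=True,
        tree_lifespan=800,
        n_steps=1500,
        seed=7,
    )
    record, world = run_simulation(cfg, track_bouts=True)
    return record, world


@pytest.fixture(scope="session")
def scaled_sweep():
    """Full factorial (4 tree levels × 3 source levels × static/dynamic),
    3 iterations each, at 7,500 steps — the scaled-down study design used for
    sweep-level statistics."""
    design = SweepDesign(iterations=3, base_seed=1, n_steps=7500)
    return run_sweep(design)


@pytest.fixture(scope="session")
def high_density_run():
    """One full-length (75,000-step) run in the high-tree-density dynamic
    condition (2000 trees, 100 sources, trees turn over) — the material-record
    workhorse for assemblage, distance-decay and use-life checks."""
    cfg = SimulationConfig(
        n_trees=2000, n_sources=100, dynamic_trees=True, n_steps=75_000, seed=11
    )
    return run_simulation(cfg)


def random_snapshot_world(rng: np.random.Generator, size: int = 20):
    """A random small world with trees, sources and spawned tools (some below
    the usability threshold), for oracle-equivalence checks."""
    n_trees = int(rng.integers(1, 13))
    n_sources = int(rng.integers(1, 7))
    cells = rng.choice(size * size, size=n_trees + n_sources, replace=False)
    trees = [(int(c) // size, int(c) % size) for c in cells[:n_trees]]
    sources = [(int(c) // size, int(c) % size, 0) for c in cells[n_trees:]]
    n_prim = 3
    primates = [(int(rng.integers(size)), int(rng.integers(size))) for _ in range(n_prim)]
    cfg = SimulationConfig(
        width=size,
        height=size,
        n_primates=n_prim,
        n_trees=n_trees,
        n_sources=n_sources,
        n_steps=0,
        fragility_levels=(0,),
        seed=int(rng.integers(2**31)),
    )
    world = initialize_world(
        cfg, placements=Placements(trees=trees, sources=sources, primates=primates)
    )
    for _ in range(int(rng.integers(0, 15))):
        pos = (int(rng.integers(size)), int(rng.integers(size)))
        mass = float(rng.uniform(100, 6000))  # some usable, some not
        world.spawn_tool(pos, mass)
    return world
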