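"""Core model: entities and the per-time-step update rules.

The world is a bounded (optionally wrapped) grid of cells. Primates random-walk
one cell per step (Moore moves, 8 directions). When a primate lands next to a
live nut tree it looks for raw material — a source outcrop or a previously
discarded, still-usable pounding tool — within its search radius, carries the
nearest piece to the tree's neighbourhood, uses it once (possibly breaking off
a fragment), and discards it there. Trees age, die and regrow nearby, keeping
the live-tree count constant. Everything stochastic is driven by one seeded
`numpy` Generator in a documented order, so a (config, seed) pair fully
determines a run.

Internal geometry is Chebyshev throughout: a "radius r" neighbourhood is the
(2r+1)×(2r+1) square of cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError, SimulationConfig

__all__ = [
    "Primate",
    "Source",
    "Tree",
    "PoundingTool",
    "World",
    "Placements",
    "initialize_world",
    "chebyshev_distance",
    "move_primate",
    "adjacent_live_tree",
    "find_material",
    "draw_initial_mass",
    "break_probability",
    "apply_breakage",
    "transport_and_use",
    "advance_trees",
    "world_step",
]

logger = logging.getLogger(__name__)

# Moore directions, fixed order: E, W, N, S, NE, NW, SE, SW.
_OFFSETS_8 = np.array(
    [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, 1), (1, -1), (-1, -1)],
    dtype=np.int64,
)


def chebyshev_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Chessboard distance max(|ax−bx|, |ay−by|) between two cells."""
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


@dataclass(frozen=True)
class Primate:
    """A tool-using agent; nothing but an id and a grid position."""

    id: int
    position: tuple[int, int]


@dataclass(frozen=True)
class Source:
    """A raw-material exposure (cobble bed, inselberg). Supplies unlimited new
    tools, each inheriting the source's fragility score."""

    id: int
    position: tuple[int, int]
    fragility: int


@dataclass(frozen=True)
class Tree:
    """A live nut-bearing tree — a place where pounding-tool use can happen."""

    id: int
    position: tuple[int, int]
    age: int
    alive: bool
    born_step: int


class PoundingTool:
    """A stone hammer (or detached fragment) with mass, provenance and use count.

    Mass only ever decreases; a tool is *usable* while mass ≥ the configured
    threshold. Fragments are ordinary tool records flagged ``is_fragment`` and
    inherit fragility and provenance from the tool they broke off.
    """

    __slots__ = (
        "id",
        "x",
        "y",
        "mass",
        "initial_mass",
        "fragility",
        "origin_source_id",
        "origin_x",
        "origin_y",
        "n_uses",
        "is_fragment",
        "parent_tool_id",
        "created_step",
    )

    def __init__(
        self,
        id: int,
        x: int,
        y: int,
        mass: float,
        fragility: int,
        origin_source_id: int,
        origin_x: int,
        origin_y: int,
        created_step: int,
        is_fragment: bool = False,
        parent_tool_id: int = -1,
    ) -> None:
        self.id = id
        self.x = x
        self.y = y
        self.mass = mass
        self.initial_mass = mass
        self.fragility = fragility
        self.origin_source_id = origin_source_id
        self.origin_x = origin_x
        self.origin_y = origin_y
        self.n_uses = 0
        self.is_fragment = is_fragment
        self.parent_tool_id = parent_tool_id
        self.created_step = created_step

    @property
    def position(self) -> tuple[int, int]:
        return (self.x, self.y)

    @property
    def origin_position(self) -> tuple[int, int]:
        return (self.origin_x, self.origin_y)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "fragment" if self.is_fragment else "tool"
        return (
            f"<PoundingTool #{self.id} {kind} {self.mass:.0f}g at ({self.x},{self.y}) "
            f"uses={self.n_uses}>"
        )


@dataclass
class Placements:
    """Explicit entity placements for scenario worlds (bypasses random init).

    ``trees``: list of (x, y); ``sources``: list of (x, y, fragility);
    ``primates``: list of (x, y); ``tree_ages``: optional, parallel to trees.
    """

    trees: list[tuple[int, int]] = field(default_factory=list)
    sources: list[tuple[int, int, int]] = field(default_factory=list)
    primates: list[tuple[int, int]] = field(default_factory=list)
    tree_ages: list[int] | None = None


class World:
    """Full mutable state of one simulation run.

    Maintains, besides the entity registries, three incremental grids that keep
    the hot path fast:

    * ``_tree_adj`` — per cell, how many live trees lie within the interaction
      radius (answers "is this primate next to a tree?" in O(1));
    * ``_coverage`` — per cell, how many sources or usable tools lie within the
      tool-use-location radius (so the monitored location count is one masked
      sum over live-tree cells);
    * ``_blocked`` — cells already holding a live tree or a source (trees and
      sources occupy unique cells).
    """

    def __init__(
        self,
        config: SimulationConfig,
        placements: Placements | None = None,
        track_bouts: bool = False,
    ) -> None:
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.step_index = 0
        self.track_bouts = track_bouts
        self.bout_log: list[dict] = []
        self.timeseries: list[tuple[int, int]] = []

        cfg = config
        w, h = cfg.width, cfg.height
        self._blocked = np.zeros((w, h), dtype=bool)
        self._tree_adj = np.zeros((w, h), dtype=np.int32)
        self._coverage = np.zeros((w, h), dtype=np.int32)

        self._tools: list[PoundingTool] = []
        self._usable_by_cell: dict[int, list[int]] = {}

        if placements is None:
            self._random_init()
        else:
            self._explicit_init(placements)

        if cfg.initial_mass_sd > 0:
            # crude acceptance-rate warning for the truncated initial-mass draw
            z = (cfg.usable_threshold - cfg.initial_mass_mean) / cfg.initial_mass_sd
            if z > 2.33:  # < ~1% of draws land above the threshold
                warnings.warn(
                    "initial_mass_mean is far below usable_threshold; "
                    "initial-mass rejection sampling will be slow",
                    stacklevel=2,
                )

    # ------------------------------------------------------------------ init

    def _random_init(self) -> None:
        cfg = self.config
        rng = self.rng
        w, h = cfg.width, cfg.height
        # unique cells for trees then sources, one draw without replacement
        cells = rng.choice(w * h, size=cfg.n_trees + cfg.n_sources, replace=False)
        tree_cells, source_cells = cells[: cfg.n_trees], cells[cfg.n_trees :]

        self._tree_x = (tree_cells // h).astype(np.int64)
        self._tree_y = (tree_cells % h).astype(np.int64)
        # established stand: ages spread uniformly so trees don't die in lockstep
        self._tree_age = rng.integers(1, cfg.tree_lifespan + 1, size=cfg.n_trees)
        self._finish_tree_init()

        sx = (source_cells // h).astype(np.int64)
        sy = (source_cells % h).astype(np.int64)
        frag = rng.choice(np.array(cfg.fragility_levels), size=cfg.n_sources)
        self._init_sources(
            [(int(x), int(y), int(f)) for x, y, f in zip(sx, sy, frag)]
        )

        self._px = rng.integers(0, w, size=cfg.n_primates).astype(np.int64)
        self._py = rng.integers(0, h, size=cfg.n_primates).astype(np.int64)

    def _explicit_init(self, pl: Placements) -> None:
        cfg = self.config
        if len(pl.trees) != cfg.n_trees or len(pl.sources) != cfg.n_sources:
            raise ConfigurationError("placement counts must match n_trees / n_sources")
        if len(pl.primates) != cfg.n_primates:
            raise ConfigurationError("placement count must match n_primates")
        occupied: set[tuple[int, int]] = set()
        for x, y in pl.trees:
            self._check_in_grid(x, y)
            if (x, y) in occupied:
                raise ConfigurationError(f"duplicate tree/source cell {(x, y)}")
            occupied.add((x, y))
        for x, y, f in pl.sources:
            self._check_in_grid(x, y)
            if (x, y) in occupied:
                raise ConfigurationError(f"duplicate tree/source cell {(x, y)}")
            occupied.add((x, y))
        self._tree_x = np.array([x for x, _ in pl.trees], dtype=np.int64)
        self._tree_y = np.array([y for _, y in pl.trees], dtype=np.int64)
        ages = pl.tree_ages if pl.tree_ages is not None else [1] * cfg.n_trees
        self._tree_age = np.array(ages, dtype=np.int64)
        self._finish_tree_init()
        self._init_sources(list(pl.sources))
        for x, y in pl.primates:
            self._check_in_grid(x, y)
        self._px = np.array([x for x, _ in pl.primates], dtype=np.int64)
        self._py = np.array([y for _, y in pl.primates], dtype=np.int64)

    def _check_in_grid(self, x: int, y: int) -> None:
        if not (0 <= x < self.config.width and 0 <= y < self.config.height):
            raise ConfigurationError(f"placement {(x, y)} outside the grid")

    def _finish_tree_init(self) -> None:
        cfg = self.config
        n = cfg.n_trees
        self._tree_id = np.arange(n, dtype=np.int64)
        self._tree_born = np.zeros(n, dtype=np.int64)
        self._next_tree_id = n
        self._tree_slot_by_cell: dict[int, int] = {}
        self.tree_history: list[dict] = []
        h = cfg.height
        for slot in range(n):
            x, y = int(self._tree_x[slot]), int(self._tree_y[slot])
            key = x * h + y
            if key in self._tree_slot_by_cell:
                raise ConfigurationError(f"duplicate tree cell {(x, y)}")
            self._tree_slot_by_cell[key] = slot
            self._blocked[x, y] = True
            self._patch(self._tree_adj, x, y, cfg.interaction_radius, 1)
            self.tree_history.append(
                {"tree_id": slot, "x": x, "y": y, "born_step": 0, "death_step": None}
            )

    def _init_sources(self, triples: list[tuple[int, int, int]]) -> None:
        cfg = self.config
        self.sources: list[Source] = []
        self._source_by_cell: dict[int, int] = {}
        h = cfg.height
        for i, (x, y, f) in enumerate(triples):
            if f not in cfg.fragility_levels:
                raise ConfigurationError(f"source fragility {f} not in fragility_levels")
            self.sources.append(Source(i, (int(x), int(y)), int(f)))
            self._source_by_cell[x * h + y] = i
            self._blocked[x, y] = True
            self._patch(self._coverage, x, y, cfg.location_radius, 1)

    # ------------------------------------------------------------- grid utils

    def _patch(self, grid: np.ndarray, x: int, y: int, r: int, delta: int) -> None:
        """Add ``delta`` to every cell within Chebyshev radius r of (x, y)."""
        w, h = self.config.width, self.config.height
        if self.config.torus:
            ix = np.arange(x - r, x + r + 1) % w
            iy = np.arange(y - r, y + r + 1) % h
            grid[np.ix_(ix, iy)] += delta
        else:
            grid[max(0, x - r) : min(w, x + r + 1), max(0, y - r) : min(h, y + r + 1)] += delta

    def _window_cells(self, x: int, y: int, r: int):
        """Yield (cx, cy, d) for in-grid cells within radius r, by ascending
        Chebyshev distance d, row-major within each ring."""
        w, h = self.config.width, self.config.height
        torus = self.config.torus
        yield (x % w, y % h, 0) if torus else (x, y, 0)
        for d in range(1, r + 1):
            for dx in range(-d, d + 1):
                for dy in range(-d, d + 1):
                    if max(abs(dx), abs(dy)) != d:
                        continue
                    cx, cy = x + dx, y + dy
                    if torus:
                        yield cx % w, cy % h, d
                    elif 0 <= cx < w and 0 <= cy < h:
                        yield cx, cy, d

    # ------------------------------------------------------------- registries

    @property
    def n_primates(self) -> int:
        return self.config.n_primates

    @property
    def primates(self) -> list[Primate]:
        return [Primate(i, (int(self._px[i]), int(self._py[i]))) for i in range(self.n_primates)]

    def primate_position(self, primate_id: int) -> tuple[int, int]:
        return (int(self._px[primate_id]), int(self._py[primate_id]))

    def set_primate_position(self, primate_id: int, position: tuple[int, int]) -> None:
        x, y = position
        self._check_in_grid(x, y)
        self._px[primate_id], self._py[primate_id] = x, y

    @property
    def trees(self) -> list[Tree]:
        """Live trees only."""
        return [self._tree_at_slot(s) for s in range(self.config.n_trees)]

    def _tree_at_slot(self, slot: int) -> Tree:
        return Tree(
            id=int(self._tree_id[slot]),
            position=(int(self._tree_x[slot]), int(self._tree_y[slot])),
            age=int(self._tree_age[slot]),
            alive=True,
            born_step=int(self._tree_born[slot]),
        )

    @property
    def tools(self) -> list[PoundingTool]:
        """Every tool and fragment ever created, with current state."""
        return self._tools

    def is_usable(self, tool: PoundingTool) -> bool:
        return tool.mass >= self.config.usable_threshold

    def tree_positions(self) -> np.ndarray:
        return np.column_stack([self._tree_x, self._tree_y])

    def source_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sources], dtype=np.int64).reshape(-1, 2)

    # ------------------------------------------------------- tool bookkeeping

    def _register_usable(self, tool: PoundingTool) -> None:
        key = tool.x * self.config.height + tool.y
        self._usable_by_cell.setdefault(key, []).append(tool.id)
        self._patch(self._coverage, tool.x, tool.y, self.config.location_radius, 1)

    def _unregister_usable(self, tool: PoundingTool) -> None:
        key = tool.x * self.config.height + tool.y
        bucket = self._usable_by_cell[key]
        bucket.remove(tool.id)
        if not bucket:
            del self._usable_by_cell[key]
        self._patch(self._coverage, tool.x, tool.y, self.config.location_radius, -1)

    def spawn_tool(
        self,
        position: tuple[int, int],
        mass: float,
        fragility: int = 0,
        origin_source_id: int = -1,
        origin_position: tuple[int, int] | None = None,
        is_fragment: bool = False,
    ) -> PoundingTool:
        """Place a tool record directly (scenario construction; normal runs
        only create tools at sources). Registered as usable if it clears the
        threshold."""
        x, y = position
        self._check_in_grid(x, y)
        ox, oy = origin_position if origin_position is not None else position
        tool = PoundingTool(
            id=len(self._tools),
            x=x,
            y=y,
            mass=float(mass),
            fragility=fragility,
            origin_source_id=origin_source_id,
            origin_x=ox,
            origin_y=oy,
            created_step=self.step_index,
            is_fragment=is_fragment,
        )
        self._tools.append(tool)
        if tool.mass >= self.config.usable_threshold:
            self._register_usable(tool)
        return tool

    def count_tool_use_locations(self) -> int:
        """Number of live trees with a source or usable tool within the
        tool-use-location radius (incremental-grid fast path)."""
        return int(np.count_nonzero(self._coverage[self._tree_x, self._tree_y]))

    def snapshot(self):
        """Frozen arrays view for the analysis layer (import-cycle-free)."""
        from .analysis import Snapshot

        tools = self._tools
        return Snapshot(
            trees=self.tree_positions().copy(),
            sources=self.source_positions().copy(),
            tool_positions=np.array([(t.x, t.y) for t in tools], dtype=np.int64).reshape(-1, 2),
            tool_masses=np.array([t.mass for t in tools], dtype=float),
            usable_threshold=self.config.usable_threshold,
            location_radius=self.config.location_radius,
        )


def initialize_world(
    config: SimulationConfig,
    placements: Placements | None = None,
    track_bouts: bool = False,
) -> World:
    """Build a world: random unique-cell placement of trees and sources, random
    primate positions, source fragilities uniform over the configured levels,
    initial tree ages uniform on {1, …, lifespan}, empty tool registry.

    ``placements`` bypasses random placement for scenario fixtures (entity
    counts must still match the config).
    """
    return World(config, placements=placements, track_bouts=track_bouts)


# ------------------------------------------------------------------ movement


def move_primate(world: World, primate: Primate | int) -> tuple[int, int]:
    """Move one primate one cell in a random Moore direction, uniform over the
    in-grid neighbours (all 8 on a torus). Returns the new position."""
    i = primate.id if isinstance(primate, Primate) else primate
    cfg = world.config
    x, y = int(world._px[i]), int(world._py[i])
    while True:
        dx, dy = _OFFSETS_8[world.rng.integers(8)]
        nx, ny = x + int(dx), y + int(dy)
        if cfg.torus:
            nx, ny = nx % cfg.width, ny % cfg.height
            break
        if 0 <= nx < cfg.width and 0 <= ny < cfg.height:
            break
    world._px[i], world._py[i] = nx, ny
    return (nx, ny)


def _move_all_primates(world: World, order: np.ndarray) -> None:
    """Vectorised equivalent of calling :func:`move_primate` for every primate:
    one batched direction draw (in scheduler order), with rejection redraws for
    off-grid proposals so boundary moves stay uniform over valid neighbours."""
    cfg = world.config
    rng = world.rng
    px = world._px[order]
    py = world._py[order]
    d = rng.integers(0, 8, size=px.size)
    nx = px + _OFFSETS_8[d, 0]
    ny = py + _OFFSETS_8[d, 1]
    if cfg.torus:
        nx %= cfg.width
        ny %= cfg.height
    else:
        bad = (nx < 0) | (nx >= cfg.width) | (ny < 0) | (ny >= cfg.height)
        while bad.any():
            idx = np.nonzero(bad)[0]
            d = rng.integers(0, 8, size=idx.size)
            nx[idx] = px[idx] + _OFFSETS_8[d, 0]
            ny[idx] = py[idx] + _OFFSETS_8[d, 1]
            bad = (nx < 0) | (nx >= cfg.width) | (ny < 0) | (ny >= cfg.height)
    world._px[order] = nx
    world._py[order] = ny


# ------------------------------------------------------------------ foraging


def adjacent_live_tree(world: World, position: tuple[int, int]) -> Tree | None:
    """Nearest live tree within the interaction radius of ``position`` (the
    tree's own cell counts), ties broken uniformly at random; None if none."""
    cfg = world.config
    h = cfg.height
    best_d = None
    slots: list[int] = []
    for cx, cy, d in world._window_cells(position[0], position[1], cfg.interaction_radius):
        if best_d is not None and d > best_d:
            break
        slot = world._tree_slot_by_cell.get(cx * h + cy)
        if slot is not None:
            best_d = d
            slots.append(slot)
    if not slots:
        return None
    slot = slots[0] if len(slots) == 1 else slots[world.rng.integers(len(slots))]
    return world._tree_at_slot(slot)


def find_material(
    world: World, position: tuple[int, int]
) -> Source | PoundingTool | None:
    """Nearest source or *usable* pounding tool within the search radius of
    ``position``; sources and tools are pooled, equally-near candidates are
    chosen uniformly at random; None if nothing is in range."""
    cfg = world.config
    h = cfg.height
    best_d = None
    cands: list[Source | PoundingTool] = []
    for cx, cy, d in world._window_cells(position[0], position[1], cfg.search_radius):
        if best_d is not None and d > best_d:
            break
        key = cx * h + cy
        sidx = world._source_by_cell.get(key)
        if sidx is not None:
            best_d = d
            cands.append(world.sources[sidx])
        for tid in world._usable_by_cell.get(key, ()):
            best_d = d
            cands.append(world._tools[tid])
    if not cands:
        return None
    chosen = cands[0] if len(cands) == 1 else cands[world.rng.integers(len(cands))]
    if isinstance(chosen, PoundingTool):
        assert chosen.mass >= cfg.usable_threshold, "sub-threshold tool offered for reuse"
    return chosen


def draw_initial_mass(world: World) -> float:
    """Draw a fresh hammer mass from Normal(mean, sd), redrawing until the
    draw clears the usability threshold (sources supply functional hammers)."""
    cfg = world.config
    if cfg.initial_mass_sd == 0:
        return float(cfg.initial_mass_mean)
    while True:
        m = world.rng.normal(cfg.initial_mass_mean, cfg.initial_mass_sd)
        if m >= cfg.usable_threshold:
            return float(m)


def break_probability(tool: PoundingTool, config: SimulationConfig) -> float:
    """Per-use breakage probability: baseline plus the tool's source-inherited
    fragility score (percentage points), clamped to [0, 1]."""
    return min(1.0, max(0.0, config.baseline_break_prob + tool.fragility / 100.0))


def apply_breakage(world: World, tool: PoundingTool) -> PoundingTool:
    """Detach a fragment from ``tool`` at its current cell.

    The fragment mass is drawn from the configured fragment distribution and
    capped at the tool's remaining mass, so lineage mass is conserved exactly:
    mass before = mass after + fragment mass. The fragment is its own tool
    record (inheriting fragility and provenance) and is itself reusable if it
    clears the threshold. Returns the fragment."""
    cfg = world.config
    was_usable = tool.mass >= cfg.usable_threshold
    m = min(cfg.fragment_distribution.sample(world.rng), tool.mass)
    tool.mass -= m
    frag = PoundingTool(
        id=len(world._tools),
        x=tool.x,
        y=tool.y,
        mass=m,
        fragility=tool.fragility,
        origin_source_id=tool.origin_source_id,
        origin_x=tool.origin_x,
        origin_y=tool.origin_y,
        created_step=world.step_index,
        is_fragment=True,
        parent_tool_id=tool.id,
    )
    world._tools.append(frag)
    if frag.mass >= cfg.usable_threshold:
        world._register_usable(frag)
    if was_usable and tool.mass < cfg.usable_threshold:
        world._unregister_usable(tool)
    return frag


def transport_and_use(
    world: World,
    primate: Primate | int,
    tree: Tree,
    material: Source | PoundingTool,
) -> PoundingTool:
    """One acquisition–transport–use–discard bout, completed within the step.

    If ``material`` is a source, a new tool is struck there (fresh mass draw,
    source fragility and provenance); otherwise the found tool is reused. The
    tool is carried to the tree's cell or one of its in-grid Moore neighbours
    (uniform), used once (n_uses += 1), breaks with :func:`break_probability`
    (in which case a fragment is discarded in place), and stays at the discard
    cell for future reuse. Returns the tool that was used."""
    cfg = world.config
    rng = world.rng
    if isinstance(material, Source):
        sx, sy = material.position
        tool = PoundingTool(
            id=len(world._tools),
            x=sx,
            y=sy,
            mass=draw_initial_mass(world),
            fragility=material.fragility,
            origin_source_id=material.id,
            origin_x=sx,
            origin_y=sy,
            created_step=world.step_index,
        )
        world._tools.append(tool)
        world._register_usable(tool)
    else:
        tool = material
    start_pos = tool.position

    # discard cell: tree's cell plus in-grid Moore neighbours, uniform
    tx, ty = tree.position
    cands = [(cx, cy) for cx, cy, _ in world._window_cells(tx, ty, 1)]
    dest = cands[rng.integers(len(cands))]
    if dest != tool.position:
        world._unregister_usable(tool)
        tool.x, tool.y = dest
        world._register_usable(tool)

    tool.n_uses += 1
    broke = rng.random() < break_probability(tool, cfg)
    if broke:
        apply_breakage(world, tool)

    if world.track_bouts:
        pid = primate.id if isinstance(primate, Primate) else primate
        world.bout_log.append(
            {
                "step": world.step_index,
                "primate_id": pid,
                "tool_id": tool.id,
                "material_position": start_pos,
                "tree_position": (tx, ty),
                "discard_position": dest,
                "from_source": isinstance(material, Source),
                "broke": broke,
            }
        )
    return tool


# --------------------------------------------------------------------- trees


def advance_trees(world: World) -> None:
    """Age every live tree by one step; trees reaching the lifespan die and are
    replaced by an age-0 tree at a random free cell within the regrow radius,
    so the live-tree count never changes. No-op (ages frozen) when
    ``dynamic_trees`` is off — the static condition pins the tree map."""
    cfg = world.config
    if not cfg.dynamic_trees:
        return
    world._tree_age += 1
    dying = np.nonzero(world._tree_age >= cfg.tree_lifespan)[0]
    for slot in dying:
        _replace_tree(world, int(slot))


def _replace_tree(world: World, slot: int) -> None:
    cfg = world.config
    h = cfg.height
    x, y = int(world._tree_x[slot]), int(world._tree_y[slot])
    # remove the dead tree
    old_id = int(world._tree_id[slot])
    world.tree_history[old_id]["death_step"] = world.step_index
    del world._tree_slot_by_cell[x * h + y]
    world._blocked[x, y] = False
    world._patch(world._tree_adj, x, y, cfg.interaction_radius, -1)

    # dict.fromkeys dedupes wrapped windows on small torus grids, keeps order
    cands = [
        cell
        for cell in dict.fromkeys(
            (cx, cy) for cx, cy, _ in world._window_cells(x, y, cfg.regrow_radius)
        )
        if not world._blocked[cell]
    ]
    if not cands:
        logger.warning("no free cell within regrow radius of (%d, %d); widening to full grid", x, y)
        fx, fy = np.nonzero(~world._blocked)
        cands = list(zip(fx.tolist(), fy.tolist()))
        if not cands:
            raise ConfigurationError("grid saturated: no free cell for tree regrowth")
    nx, ny = cands[world.rng.integers(len(cands))]

    new_id = world._next_tree_id
    world._next_tree_id += 1
    world._tree_id[slot] = new_id
    world._tree_x[slot], world._tree_y[slot] = nx, ny
    world._tree_age[slot] = 0
    world._tree_born[slot] = world.step_index
    world._tree_slot_by_cell[nx * h + ny] = slot
    world._blocked[nx, ny] = True
    world._patch(world._tree_adj, nx, ny, cfg.interaction_radius, 1)
    world.tree_history.append(
        {"tree_id": new_id, "x": nx, "y": ny, "born_step": world.step_index, "death_step": None}
    )


# ---------------------------------------------------------------------- step


def world_step(world: World) -> None:
    """Advance the world by one time step.

    Scheduler order (all randomness from the world's single stream, in this
    order): (1) draw a fresh uniform permutation of primates; (2) move every
    primate one Moore cell, directions drawn in permutation order; (3) in the
    same order, each primate next to a live tree runs at most one bout —
    nearest adjacent live tree (ties random), nearest material in the search
    radius (ties random), transport/use/discard; (4) trees age and turn over;
    (5) the step counter increments."""
    order = world.rng.permutation(world.n_primates)
    _move_all_primates(world, order)
    adj = world._tree_adj
    px, py = world._px, world._py
    for i in order:
        x, y = int(px[i]), int(py[i])
        if not adj[x, y]:
            continue
        tree = adjacent_live_tree(world, (x, y))
        if tree is None:  # pragma: no cover - adj grid guarantees a tree
            continue
        material = find_material(world, (x, y))
        if material is None:
            continue  # nothing in reach: the primate does nothing this step
        transport_and_use(world, int(i), tree, material)
    advance_trees(world)
    world.step_index += 1
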