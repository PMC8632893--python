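import numpy as np
import pytest
from scipy import stats

from toolscape import (
    ConfigurationError,
    Placements,
    SimulationConfig,
    adjacent_live_tree,
    advance_trees,
    apply_breakage,
    break_probability,
    chebyshev_distance,
    draw_initial_mass,
    find_material,
    initialize_world,
    move_primate,
    transport_and_use,
)
from toolscape.model import PoundingTool, Source


def make_world(
    trees=(),
    sources=(),
    primates=((0, 0),),
    width=20,
    height=20,
    tree_ages=None,
    **cfg_kwargs,
):
    cfg = SimulationConfig(
        width=width,
        height=height,
        n_primates=len(primates),
        n_trees=max(len(trees), 1) if trees else 1,
        n_sources=max(len(sources), 1) if sources else 1,
        n_steps=0,
        fragility_levels=cfg_kwargs.pop("fragility_levels", (0, 25, 50, 75)),
        seed=cfg_kwargs.pop("seed", 0),
        **cfg_kwargs,
    )
    trees = list(trees) or [(width - 1, height - 1)]
    sources = list(sources) or [(width - 2, height - 1, cfg.fragility_levels[0])]
    cfg = cfg.replace(n_trees=len(trees), n_sources=len(sources))
    return initialize_world(
        cfg,
        placements=Placements(
            trees=trees, sources=sources, primates=list(primates), tree_ages=tree_ages
        ),
    )


@pytest.mark.parametrize(
    "a, b, expected",
    [((0, 0), (3, 0), 3), ((0, 0), (2, 3), 3), ((5, 5), (5, 5), 0), ((2, 7), (0, 3), 4)],
)
def test_chebyshev_distance(a, b, expected):
    assert chebyshev_distance(a, b) == expected


class TestInitialization:
    def test_entity_counts_and_unique_cells(self):
        cfg = SimulationConfig(n_trees=2000, n_sources=500, n_steps=0, seed=5)
        world = initialize_world(cfg)
        assert len(world.trees) == 2000
        assert len(world.sources) == 500
        assert len(world.primates) == 100
        cells = {t.position for t in world.trees} | {s.position for s in world.sources}
        assert len(cells) == 2500  # trees and sources never share a cell
        assert len(world.tools) == 0 and world.step_index == 0

    def test_initial_tree_ages_in_range(self):
        cfg = SimulationConfig(n_trees=500, n_sources=10, n_steps=0, seed=3)
        world = initialize_world(cfg)
        ages = np.array([t.age for t in world.trees])
        assert ages.min() >= 1 and ages.max() <= cfg.tree_lifespan

    def test_source_fragilities_from_levels(self):
        cfg = SimulationConfig(n_trees=10, n_sources=200, n_steps=0, seed=4)
        world = initialize_world(cfg)
        assert {s.fragility for s in world.sources} <= set(cfg.fragility_levels)

    def test_same_seed_same_world(self):
        cfg = SimulationConfig(n_trees=50, n_sources=20, n_steps=0, seed=9)
        w1, w2 = initialize_world(cfg), initialize_world(cfg)
        assert [t.position for t in w1.trees] == [t.position for t in w2.trees]
        assert w1.sources == w2.sources
        assert [p.position for p in w1.primates] == [p.position for p in w2.primates]

    def test_placement_impossible_is_config_error(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(width=5, height=5, n_trees=20, n_sources=10)

    def test_tiny_grid_distinct_cells(self):
        cfg = SimulationConfig(width=5, height=5, n_primates=1, n_trees=1, n_sources=1, n_steps=0, seed=1)
        world = initialize_world(cfg)
        assert world.trees[0].position != world.sources[0].position


class TestMovement:
    def test_interior_move_is_moore_neighbor(self):
        world = make_world(primates=[(10, 10)], width=25, height=25)
        new = move_primate(world, 0)
        assert chebyshev_distance((10, 10), new) == 1

    def test_corner_moves_uniform_over_valid_neighbors(self):
        counts = {}
        world = make_world(primates=[(0, 0)], seed=12)
        for _ in range(3000):
            world.set_primate_position(0, (0, 0))
            new = move_primate(world, 0)
            assert new in {(1, 0), (0, 1), (1, 1)}
            counts[new] = counts.get(new, 0) + 1
        _, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3

    def test_center_moves_uniform_over_8_directions(self):
        world = make_world(primates=[(10, 10)], width=25, height=25, seed=13)
        counts = {}
        for _ in range(10_000):
            world.set_primate_position(0, (10, 10))
            new = move_primate(world, 0)
            counts[new] = counts.get(new, 0) + 1
        assert len(counts) == 8
        _, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3


class TestTorusMode:
    def test_corner_moves_wrap_to_all_8_neighbors(self):
        world = make_world(primates=[(0, 0)], torus=True, seed=14)
        seen = set()
        for _ in range(500):
            world.set_primate_position(0, (0, 0))
            seen.add(move_primate(world, 0))
        assert seen == {
            (1, 0), (19, 0), (0, 1), (0, 19), (1, 1), (19, 1), (1, 19), (19, 19)
        }

    def test_search_wraps_across_the_edge(self):
        world = make_world(sources=[(19, 10, 0)], primates=[(0, 10)], torus=True)
        found = find_material(world, (0, 10))
        assert found is not None and found.position == (19, 10)


class TestAdjacentLiveTree:
    def test_neighboring_tree_found(self):
        world = make_world(trees=[(5, 5)], primates=[(5, 6)])
        tree = adjacent_live_tree(world, (5, 6))
        assert tree is not None and tree.position == (5, 5)

    def test_tree_at_distance_two_not_adjacent(self):
        world = make_world(trees=[(5, 5)], primates=[(5, 7)])
        assert adjacent_live_tree(world, (5, 7)) is None

    def test_dead_tree_excluded(self):
        # tree A dies this step (replaced elsewhere); neighbour B remains
        world = make_world(
            trees=[(5, 5), (6, 5)],
            primates=[(5, 6)],
            tree_ages=[799, 1],
            tree_lifespan=800,
            regrow_radius=10,
            dynamic_trees=True,
            width=30,
            height=30,
        )
        advance_trees(world)
        found = adjacent_live_tree(world, (5, 6))
        assert found is None or found.position != (5, 5) or found.age == 0


class TestFindMaterial:
    def test_nearest_wins_tool_over_source(self):
        world = make_world(sources=[(7, 5, 0)], primates=[(5, 5)])
        world.spawn_tool((6, 5), 3000.0)
        found = find_material(world, (5, 5))
        assert isinstance(found, PoundingTool)

    def test_subthreshold_tool_invisible(self):
        world = make_world(sources=[(15, 15, 0)], primates=[(5, 5)])
        world.spawn_tool((6, 5), 1999.0)
        assert find_material(world, (5, 5)) is None

    def test_nothing_in_radius(self):
        world = make_world(sources=[(15, 15, 0)], primates=[(5, 5)])
        assert find_material(world, (5, 5)) is None

    def test_equal_distance_tie_is_even(self):
        # source and usable tool both at Chebyshev distance 2: ~50/50 split
        world = make_world(sources=[(7, 5, 0)], primates=[(5, 5)], seed=21)
        world.spawn_tool((3, 5), 3000.0)
        picks = [find_material(world, (5, 5)) for _ in range(10_000)]
        n_source = sum(isinstance(p, Source) for p in picks)
        # two-sided binomial check at p=0.5
        assert stats.binomtest(n_source, 10_000, 0.5).pvalue > 1e-3


class TestInitialMass:
    def test_degenerate_sd_zero(self):
        world = make_world(initial_mass_mean=4000.0, initial_mass_sd=0.0)
        assert draw_initial_mass(world) == 4000.0

    def test_truncated_normal_moments(self):
        world = make_world(initial_mass_mean=4000.0, initial_mass_sd=1000.0, seed=31)
        draws = np.array([draw_initial_mass(world) for _ in range(10_000)])
        assert draws.min() >= 2000.0
        a = (2000.0 - 4000.0) / 1000.0  # scipy's truncnorm as the closed form
        expected = stats.truncnorm.mean(a, np.inf, loc=4000.0, scale=1000.0)
        se = draws.std() / 100.0
        assert abs(draws.mean() - expected) < 3 * se


@pytest.mark.parametrize(
    "fragility, expected", [(0, 0.25), (25, 0.50), (50, 0.75), (75, 1.00)]
)
def test_break_probability(fragility, expected):
    cfg = SimulationConfig()
    tool = PoundingTool(0, 0, 0, 5000.0, fragility, 0, 0, 0, 0)
    assert break_probability(tool, cfg) == pytest.approx(expected)


class TestBreakage:
    def test_fragment_mass_conserved(self):
        from toolscape import FragmentDistribution

        world = make_world(
            fragment_distribution=FragmentDistribution(kind="constant", value=300.0)
        )
        tool = world.spawn_tool((3, 3), 5000.0)
        frag = apply_breakage(world, tool)
        assert tool.mass + frag.mass == pytest.approx(5000.0)
        assert frag.position == tool.position
        assert frag.is_fragment and frag.parent_tool_id == tool.id
        assert frag.fragility == tool.fragility
        assert frag.origin_source_id == tool.origin_source_id

    def test_fragment_capped_at_remaining_mass(self):
        from toolscape import FragmentDistribution

        world = make_world()
        world.config = world.config.replace(
            fragment_distribution=FragmentDistribution(kind="constant", value=5000.0)
        )
        tool = world.spawn_tool((3, 3), 2100.0)
        frag = apply_breakage(world, tool)
        assert frag.mass == pytest.approx(2100.0)
        assert tool.mass == pytest.approx(0.0)


class TestTransportAndUse:
    def test_acquire_from_source_creates_tool_with_provenance(self):
        world = make_world(
            trees=[(10, 10)], sources=[(8, 9, 25)], primates=[(9, 9)],
            initial_mass_sd=0.0, initial_mass_mean=4000.0,
        )
        tree = adjacent_live_tree(world, (9, 9))
        src = find_material(world, (9, 9))
        tool = transport_and_use(world, 0, tree, src)
        assert tool.origin_position == (8, 9)
        assert tool.fragility == 25
        assert tool.n_uses == 1
        assert chebyshev_distance(tool.position, (10, 10)) <= 1

    def test_reuse_increments_without_new_tool(self):
        world = make_world(
            trees=[(10, 10)], sources=[(0, 0, 0)], primates=[(9, 9)],
            baseline_break_prob=0.0, fragility_levels=(0,),
        )
        existing = world.spawn_tool((9, 8), 2500.0)
        tree = adjacent_live_tree(world, (9, 9))
        mat = find_material(world, (9, 9))
        assert mat is existing
        used = transport_and_use(world, 0, tree, mat)
        assert used is existing and used.n_uses == 1
        assert len(world.tools) == 1

    def test_forced_break_always_sheds_fragment(self):
        world = make_world(
            trees=[(10, 10)], sources=[(8, 9, 75)], primates=[(9, 9)],
            initial_mass_sd=0.0, initial_mass_mean=9000.0,
        )
        for k in range(5):
            tree = adjacent_live_tree(world, (9, 9))
            mat = find_material(world, (9, 9))
            transport_and_use(world, 0, tree, mat)
            n_frags = sum(t.is_fragment for t in world.tools)
            n_uses = sum(t.n_uses for t in world.tools)
            assert n_frags == n_uses  # fragility 75 + baseline 0.25 → certain break


class TestTreeTurnover:
    def test_death_and_regrowth_nearby(self):
        world = make_world(
            trees=[(15, 15)], sources=[(0, 0, 0)], primates=[(0, 1)],
            tree_ages=[799], tree_lifespan=800, dynamic_trees=True,
            width=40, height=40,
        )
        advance_trees(world)
        (tree,) = world.trees
        assert tree.age == 0
        assert chebyshev_distance(tree.position, (15, 15)) <= world.config.regrow_radius
        assert len(world.trees) == 1

    def test_static_trees_frozen(self):
        world = make_world(
            trees=[(15, 15)], sources=[(0, 0, 0)], primates=[(0, 1)],
            tree_ages=[799], tree_lifespan=800, dynamic_trees=False,
        )
        before = [(t.id, t.position, t.age) for t in world.trees]
        for _ in range(10):
            advance_trees(world)
        assert [(t.id, t.position, t.age) for t in world.trees] == before

    def test_replacement_avoids_occupied_cells(self):
        # regrow window saturated except one free cell → replacement lands there
        trees = [(x, y) for x in range(5) for y in range(5) if (x, y) != (4, 4)]
        world = make_world(
            trees=trees,
            sources=[(4, 4, 0)],
            primates=[(0, 0)],
            tree_ages=[799] + [1] * (len(trees) - 1),
            tree_lifespan=800,
            regrow_radius=2,
            dynamic_trees=True,
            width=5,
            height=5,
        )
        advance_trees(world)
        positions = {t.position for t in world.trees}
        assert len(positions) == len(trees)
        assert (4, 4) not in positions  # source cell stays blocked
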