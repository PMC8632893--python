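# Methods

## The model

`toolscape` simulates how repeated, individually short transport bouts of
stone pounding tools — the pattern documented for wild chimpanzee nut-cracking
— accumulate over archaeological time into landscape-scale redistribution of
stone, and what material record that process leaves behind.

The world is a bounded `width × height` grid (default 250 × 250 cells)
holding four kinds of entities:

* **Primates** (default 100): agents performing an unbiased random walk, one
  Moore step (8 directions) per time step. One time step corresponds roughly
  to one nut-cracking episode. There is no memory, goal-direction, or social
  behaviour: movement is a pure random walk by design, so any landscape
  structure in the output is produced by the transport mechanics alone.
* **Sources**: fixed raw-material exposures. Each carries a *fragility* score
  drawn uniformly from {0, 25, 50, 75} percentage points.
* **Trees** (nut-bearing): the only places tool use can occur. In the
  *dynamic* condition trees age one unit per step, die at a lifespan of
  10,000 steps, and are immediately replaced by an age-0 tree at a uniformly
  chosen free cell within a 10-cell radius, keeping the live count constant;
  initial ages are uniform on {1, …, 10,000} so deaths are staggered. In the
  *static* condition the tree map is frozen (no aging).
* **Pounding tools**: stone hammers with mass (g), fragility and provenance
  (the source they were struck at). A tool is *usable* while its mass is at
  least 2,000 g — the exhaustion threshold below which it is never picked up
  again.

A bout happens when a primate's walk lands it within the interaction radius
(1 cell) of a live tree: it searches within 2 cells for the nearest source or
usable tool (sources and tools pooled; equally-near candidates chosen
uniformly), acquires a fresh tool at a source (mass drawn from a normal
distribution truncated below at the usability threshold) or reuses the found
tool, carries it to the tree's cell or one of its in-grid Moore neighbours
(uniform choice), uses it once, and discards it there. Geometry therefore
bounds a single bout: material-to-tree distance ≤ 3 cells and per-bout
displacement ≤ 4 cells (Chebyshev). Long-distance displacement can only
emerge from chains of bouts relaying a tool from tree to tree.

On every use the tool breaks with probability `min(1, 0.25 + fragility/100)`
(so fragility 25 → 0.50, fragility 75 → certain breakage). A break detaches a
fragment whose mass is drawn from the configured fragment distribution,
capped at the remaining mass; the fragment becomes its own tool record at the
discard cell, inheriting fragility and provenance, and mass is conserved
exactly per lineage. Fragments at or above the threshold are themselves
reusable; in practice (see defaults below) virtually all fragments are small
and permanent members of the local assemblage.

A *tool-use location* is a live tree within 3 cells (= search + interaction
radius) of a source or usable tool; the count of such trees is the model's
running measure of how much of the landscape is accessible to tool-assisted
foraging.

## Scheduling and randomness

One seeded `numpy` PCG64 stream drives everything, in a documented order per
step: (1) a fresh uniform permutation of primates; (2) all movement
directions drawn in that order (off-grid proposals redrawn, which keeps
boundary moves uniform over valid neighbours); (3) bouts executed
sequentially in the same order — nearest adjacent live tree (ties random),
nearest material (ties random), initial-mass draw if acquiring from a source,
discard cell, break draw, fragment-mass draw; (4) tree aging and turnover,
dying slots processed in ascending index. Tie-break draws are only consumed
when a tie actually occurs. A `(config, seed)` pair therefore fully
determines every output byte (CSV floats are written at `%.17g`, which
round-trips float64 exactly).

The grid is bounded and non-wrapping by default: the model represents a
forest stand, and a torus would distort distance-to-source statistics. A
`torus` flag (wrapping movement, discard, regrowth and search neighbourhoods)
exists purely for sensitivity checks against ABM frameworks whose grids wrap
by default. All internal distances are Chebyshev — the natural metric of a
Moore-neighbourhood world, and the one that keeps the "within 3 cells"
acquisition bound and the ">3 cells" displacement criterion mutually
consistent; Euclidean reporting is available in the analysis layer behind a
`metric` argument.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| `n_trees` | {100, 500, 1000, 2000} in sweeps | resource density; the dominant control on displacement |
| `n_sources` | {10, 100, 500} in sweeps | raw-material abundance |
| `dynamic_trees` | varied | whether the tree map turns over |
| `n_steps` | 75,000 | run length; most runs approach displacement fixation by then |
| `usable_threshold` | 2,000 g | exhaustion threshold (smallest functional hammer) |
| `baseline_break_prob` | 0.25 | per-use breakage floor |
| `initial_mass_mean`, `initial_mass_sd` | 6,000 g, 2,000 g | fresh-hammer mass distribution, truncated at the threshold |
| `fragment_distribution` | lognormal mixture, mean ≈ 20 g | per-break mass loss |

The hammer-mass and fragment parameters deserve comment, because the field
data they stand for (masses of *Panda oleosa* nut-cracking hammers and of
fragments shed during observed nut-cracking) are not shipped with this
package. The defaults are chosen once, on two grounds: multi-kilogram
hammers (mean 6 kg, sd 2 kg, truncated below 2 kg) are realistic for Panda
nut cracking, and the fragment mixture — 90 % small flakes (lognormal,
median 6 g) plus 10 % larger chunks (median 100 g), mixture mean ≈ 20 g —
yields expected use-lives of roughly `(6000 − 2000) / (p_break × 20)` ≈ 200
uses at certain breakage up to ≈ 800 at the 0.25 floor, i.e. the low
hundreds. Users with an empirical fragment-mass table can substitute it
directly (`fragment_distribution: path/to/table.csv`, column `mass_g`);
hammer mass moments are plain config fields.

## Analysis layer

All derived quantities are recomputed from persisted run records alone:

* **max displacement** — per run, the farthest any non-fragment tool ends up
  from the source it was struck at.
* **assemblage table** — per grid cell with ≥ 1 tool record: usable,
  exhausted (worn-out non-fragment) and fragment counts, total mass, and the
  Chebyshev distance to the nearest source. A usable fragment is tallied
  under `n_usable`, matching the reuse rule (anything ≥ 2,000 g is a
  functional hammer); the raw `is_fragment` flag is retained in the record
  for alternative tallies.
* **distance decay** — two deliberately distinct pairings: assemblage *count*
  against distance to the *nearest* source (cells are not tied to a source,
  so their relation to raw material is the minimum distance), and usable-tool
  *mass* against the distance to the tool's *own origin* source (provenance
  is known per tool). Each side reports a Spearman rank correlation (the
  robust statistic) and the slope of an OLS fit of `log(value + 1)` on
  distance (the `+1` guards zeros; assemblage counts are ≥ 1 so the offset is
  a small bias, which is why the rank correlation is reported alongside).
* **sweep statistics** — Kruskal–Wallis tests of max displacement across
  tree-count and source-count groups, an OLS of max displacement on
  `(n_trees, n_sources)` with R², and pooled run fractions (any tool beyond
  3 cells from the nearest source; more tool-use locations at the end than at
  the start). Raw OLS coefficients are per-unit and the two predictors have
  very different ranges, so standardized coefficients are reported for
  effect-size comparison. Statistical routines delegate to
  `scipy`/`statsmodels`; runs are pooled with equal weight.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full factorial design (24
combinations) at 3 iterations × 7,500 steps, plus two full-length 75,000-step
runs in the high-tree-density dynamic condition (100 and 10 sources) for the
material-record statistics — a scale chosen so the whole battery completes on
a single CPU in minutes while preserving every qualitative contrast of the
full design. Fractions estimated from 72 runs are checked via binomial
(Wilson) confidence intervals rather than point equality. Exact invariants
(mass conservation, geometric bout bounds, tree-count constancy, determinism,
oracle equivalence against brute-force recomputation on 1,000 randomized
snapshots) do not depend on scale.

## Scope of the synthetic setting

The generator *is* the study system: landscapes are uniform random
scatters of trees and sources on an otherwise featureless grid, and movement
is an unbiased random walk. Passing tests show that the transport/breakage/
turnover mechanics produce the documented emergent patterns under those
idealized conditions; they say nothing about real forests, where tree and
stone distributions are clumped, movement is directed, and nut production is
seasonal. The model also omits nut-energy bookkeeping, demography (the
primate count is fixed), cognition and social learning, by design.

## Numerical and degenerate-input choices

* Initial placement draws tree and source cells jointly without replacement
  (unique cells); primates and tools may co-occupy any cell.
* Initial-mass draws below the threshold are rejected and redrawn (a "new"
  tool that is instantly unusable would contradict the acquisition rule);
  config validation warns when the acceptance rate would be pathologically
  low and rejects sd = 0 with a sub-threshold mean outright.
* Tree regrowth excludes cells holding a live tree or source; if the regrow
  window is saturated the search widens to the whole grid with a logged
  warning.
* Break probabilities are clamped to [0, 1]; the break check runs on every
  use, including the first after acquisition.
* `distance_decay` flags a side as degenerate (no fit) when it has fewer than
  3 points or fewer than 2 distinct distances; Kruskal–Wallis is skipped with
  a message for a single group and reported as H = 0 when all values are
  identical.
* Scenario configs may set break probability 0 and mass sd 0 — test-only
  settings that create fully deterministic causal paths.

## Known limitations

* The headline assemblage-scarcity figure is sensitive to the hammer-mass and
  fragment-mass distributions, whose empirical forms are not bundled; with
  the documented defaults the minimum share of assemblages containing a
  usable tool (high tree density, 10 sources, dynamic trees, 75,000 steps)
  comes out near 4–5 % rather than lower values attainable under other
  plausible fragment regimes. The sweep-level fractions and all qualitative
  contrasts are robust to this choice.
* Fixation (no further displacement possible) is not detected; runs use a
  fixed step budget.
* `trees_history` records birth and death steps but not the within-run
  trajectory of the location count per tree generation; the time series of
  tool-use locations is recorded instead (default: every step for runs up to
  10,000 steps, every 50 steps beyond — a storage choice, overridable with
  `record_every`).
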