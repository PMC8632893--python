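# toolscape

Spatially explicit agent-based simulation of **primate stone-tool transport**
and the archaeological record it generates.

Wild chimpanzees carry stone hammers only short distances — a few metres, to
the nearest nut tree — yet used hammers are found kilometres from any natural
stone source, and their mass and density fall off with distance from sources
the way early Pleistocene artifact scatters do. `toolscape` is for behavioural
ecologists and archaeologists who want to test whether *accumulated*
short-distance transport bouts, playing out over tens of thousands of
nut-cracking episodes with tool breakage and resource turnover, are enough to
produce that landscape-scale pattern — and what the resulting time-averaged
material record does (and does not) reveal about the behaviour that made it.

## The model in brief

Primates random-walk a bounded grid (one Moore step per time step). When a
primate lands within 1 cell of a live nut tree it searches within 2 cells for
raw material — a source outcrop or a previously discarded, still-usable
pounding tool — carries the nearest piece to the tree's neighbourhood, uses
it once and discards it there. Geometry bounds every bout: material-to-tree
distance ≤ 3 cells, per-bout displacement ≤ 4 cells (Chebyshev). On each use
a tool of fragility *f* (inherited from its source, *f* ∈ {0, 25, 50, 75})
breaks with probability

> P(break) = min(1, 0.25 + *f*/100),

shedding a fragment whose mass is subtracted from the tool (lineage mass is
conserved exactly). Tools below 2,000 g are exhausted and never move again.
Trees age and die (lifespan 10,000 steps), each replaced by a new tree within
10 cells, so resource locations drift while their number stays fixed. A
*tool-use location* is a live tree within 3 cells of a source or usable tool
— the model's measure of tool-assisted foraging access.

Everything downstream of the seed is deterministic: one seeded PCG64 stream,
documented draw order, byte-stable outputs.

## Worked example

`examples/01_single_run.py` builds a 150×150 forest (40 primates, 600
dynamic trees, 60 sources), runs 5,000 steps and prints:

```
tool records created:    8028 (7511 fragments)
max displacement:        24 cells
tool-use locations:      55 -> 232
any tool >3 cells from a source: True
assemblages with a usable tool:  17.5%
```

Single bouts can never move material more than 4 cells, so a 24-cell maximum
displacement is pure accumulation — tools relayed from tree to tree. The
growth of tool-use locations (55 → 232) is the niche-construction feedback:
discarded hammers open previously inaccessible trees to nut-cracking. Most of
the record is fragments; only 17.5 % of the cells holding material still
contain a usable hammer.

The other examples isolate single capabilities: `02_chain_relay.py` shows the
relay mechanism on a constructed chain of trees (and its break point),
`03_factorial_sweep.py` runs a toy factorial design through the sweep and
statistics machinery, `04_distance_decay.py` measures distance-decay of
assemblage size and tool mass on a high-density landscape.

The same machinery is scriptable from the shell:

```bash
toolscape run    --config cfg.yaml --seed 1 --out out/run1
toolscape sweep  --design design.yaml --out out/sweep --jobs 1
toolscape analyze --runs out/sweep/runs --report out/report
toolscape fixtures --out tests/fixtures
```

Run directories are plain CSV + JSON (`metadata.json`, `timeseries.csv`,
`tools.csv`, `sources.csv`, `trees.csv`) with frozen column orders, e.g.
`tools.csv`:

```
tool_id,origin_source_id,origin_x,origin_y,x,y,initial_mass,mass,fragility,n_uses,is_fragment,parent_tool_id,created_step
```

## Layout

```
src/toolscape/
  config.py       SimulationConfig, fragment-mass distributions, YAML/TOML I/O
  model.py        entities and the per-step update rules (the model proper)
  experiment.py   seeded runs, factorial sweeps, run persistence
  analysis.py     displacement, assemblages, distance decay, sweep statistics
  scenarios.py    deterministic fixtures and brute-force oracles
  cli.py          thin click front end
docs/methods.md   model description, parameter rationale, numerical choices
examples/         one narrative script per capability
```

See `docs/methods.md` for assumptions, parameter defaults (and why), and
known limitations.
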