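"""Tool relay along a chain of trees.

A single source and five trees in a line. With breakage turned off, the only
way a tool can end up more than 4 cells from the source is by being relayed
tree to tree across many independent bouts. Relays work while consecutive
trees are within 4 cells of each other (a discarded tool can land 1 cell
toward the next tree, which can pull material from 3 cells away); at 5 cells
the chain is broken and no tool ever passes the first hop.
"""

from toolscape import max_displacement, run_simulation
from toolscape.scenarios import scenario_chain

for spacing in (3, 5):
    spec = scenario_chain(n_links=5, spacing=spacing, seed=1)
    record = run_simulation(spec.config, placements=spec.placements)
    print(f"spacing {spacing}: max displacement {max_displacement(record):.0f} cells "
          f"({len(record.tools_final)} tool records)  -- expected: {spec.expectation}")
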