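"""Generate a complete synthetic study as plain-text files.

Writes the edge list, driver seeds, disease rank table, GMT pathways
with an FDR table, per-compound signature tables and truth labels — the
exact formats the CLI consumes — into ./synthetic_study/.
"""

from fmodscreen import SyntheticScenario, generate
from fmodscreen.simulate import write_bundle

scenario = SyntheticScenario(seed=123)
bundle = generate(scenario)
paths = write_bundle(bundle, "synthetic_study")
for name, p in sorted(paths.items()):
    print(f"{name:16s} {p}")
print(f"\n{len(bundle.compounds)} compounds "
      f"({len(bundle.effective)} truly effective), "
      f"{bundle.network.universe_size} genes. Run the screen on these "
      "files with: fmodscreen screen --network synthetic_study/fln.tsv ...")
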