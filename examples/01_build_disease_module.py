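"""Build a mutation-associated gene module (MAG) on a synthetic study.

Thresholds the functional linkage network to its strongest 5% of links,
expands the mutated driver genes to their first neighbors, and keeps the
neighbors that are both highly up-regulated in the disease profile and
members of significantly perturbed pathways.
"""

from fmodscreen import SyntheticScenario, generate, threshold_by_quantile
from fmodscreen.disease import build_mag, pathway_member_set

bundle = generate(SyntheticScenario(seed=0))
net, thr = threshold_by_quantile(bundle.network, keep_fraction=0.05)
print(f"network: {bundle.network.universe_size} genes, "
      f"{bundle.network.n_edges} links; kept {net.n_edges} links "
      f"with weight >= {thr:.3f}")

pathway_genes = pathway_member_set(bundle.pathways, fdr_cutoff=0.05)
mag = build_mag(net, bundle.seeds, bundle.disease_profile,
                m=25, direction="up", depth=1, pathway_genes=pathway_genes)
print(f"module: {len(mag.seeds)} driver seeds + {mag.n_neighbors} filtered "
      f"neighbors = {len(mag.members)} members")

in_truth = len(mag.members & set(bundle.truth["disease_module"]))
print(f"{in_truth}/{len(mag.members)} members lie in the planted disease "
      "module — the expression and pathway filters concentrate the module "
      "on the true disease neighborhood.")
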