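"""Ecological statistics on a planted multi-ecosystem design.

Five ecosystems x three replicates share a compound core, carry
ecosystem-specific tails, and hide 24 wetland-exclusive compounds.
Computes Shannon/Gini-Simpson diversity, Bray-Curtis dissimilarity,
PERMANOVA for wetland-vs-upland separation, and the wetland-exclusive
compound count.
"""

import pandas as pd

from pyrosom import (
    align,
    build_network,
    ecosystem_distribution,
    gen_design,
    permanova,
    shannon,
    simpson,
)
from pyrosom.annotation import Annotation
from pyrosom.ecostats import AbundanceTable, bray_curtis_matrix

features, truth = gen_design(ecosystems=5, samples_per=3,
                             wetland_exclusive=24, n_compounds=40, seed=9)

names = [c.name for c in truth.compounds]
rows = {sid: [{f.feature_id.split(":")[1]: f.height for f in fs}.get(n, 0.0)
              for n in names] for sid, fs in features.items()}
table = AbundanceTable(pd.DataFrame.from_dict(rows, orient="index",
                                              columns=names),
                       truth.sample_to_ecosystem)

print("per-sample diversity (compound level):")
for sid in sorted(table.samples)[:5]:
    v = table.values.loc[sid]
    p = v / v.sum()
    print(f"  {sid:<18} Shannon {shannon(p):5.3f}  "
          f"Gini-Simpson {simpson(p):5.3f}")

D = bray_curtis_matrix(table)
labels = ["wetland" if truth.sample_to_ecosystem[s] in truth.wetlands
          else "upland" for s in table.samples]
res = permanova(D.to_numpy(), labels, n_perm=999, seed=9)
print(f"\nPERMANOVA wetland vs upland: pseudo-F {res.pseudo_f:.2f}, "
      f"R2 {res.r2:.3f}, p {res.p_value:.3f}")

aligned = align(features)
net = build_network(aligned, [Annotation(g.node_id) for g in aligned])
dist = ecosystem_distribution(net, truth.sample_to_ecosystem)
print(f"wetland-exclusive compounds found: "
      f"{len(dist.exclusive_nodes(truth.wetlands))} (planted: 24)")

# A small p confirms the planted wetland/upland compositional split; the
# exclusive count matching 24 shows presence/absence is tracked exactly.
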