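"""Build a molecular network and propagate classes to unannotated nodes.

Sixty compounds from three structural families form the nodes; half the
class labels are hidden. Edges connect spectra with cosine >= 0.7 under
mutual-TopK-10 pruning, and each unclassified node then takes the class of
its most similar annotated neighbor.
"""

import numpy as np

from pyrosom import build_network, clusters, gen_compound, propagate_classes
from pyrosom.alignment import AlignedFeature
from pyrosom.annotation import UNCLASSIFIED, Annotation
from pyrosom.deconvolution import Feature

rng = np.random.default_rng(3)
nodes, anns, truth = [], [], {}
for fam, cls in (("resin", "lignin"), ("aromatic", "MAH"),
                 ("phenolic", "phenols")):
    for k in range(20):
        c = gen_compound(int(rng.integers(0, 2**31 - 1)), fam,
                         compound_class=cls)
        nid = f"{fam}{k:02d}"
        member = Feature(rt=1.0, spectrum=c.spectrum, height=c.height,
                         area=0.0, sample_id="s")
        nodes.append(AlignedFeature(node_id=nid, members=[member],
                                    consensus_spectrum=c.spectrum, rt=1.0,
                                    per_sample_height={"s": c.height}))
        truth[nid] = cls

hidden = set(rng.choice(sorted(truth), size=30, replace=False))
for n in nodes:
    if n.node_id in hidden:
        anns.append(Annotation(n.node_id))
    else:
        anns.append(Annotation(n.node_id, compound=n.node_id, score=0.9,
                               compound_class=truth[n.node_id]))

net = build_network(nodes, anns, min_cosine=0.7, topk=10)
comps = clusters(net)
print(f"{len(net.nodes)} nodes, {len(net.edges)} edges, "
      f"{len(comps)} clusters, {len(net.singletons)} singletons")
print(f"cluster sizes: {[len(c) for c in comps]}")

after = propagate_classes(net)
recovered = [nid for nid in hidden if after.classes[nid] != UNCLASSIFIED]
correct = sum(1 for nid in recovered if after.classes[nid] == truth[nid])
print(f"hidden labels: {len(hidden)}; propagated: {len(recovered)}; "
      f"correct: {correct} ({100 * correct / max(len(recovered), 1):.0f}%)")

# Clusters should separate the three structural families, and propagation
# should recover the hidden class labels from annotated neighbors.
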