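"""Build a sequence similarity network and pick its threshold by centrality.

Two synthetic families (80% within, unrelated between) are aligned
all-vs-all; the alignment score AS = −log10(E-value-like) feeds a threshold
sweep.  The selected threshold is where the cluster count plateaus and mean
betweenness collapses — the point at which inter-family bridge edges vanish.
"""

import numpy as np

from sqgsuite.pairalign import all_vs_all
from sqgsuite.ssn import build_graph, select_threshold
from sqgsuite.syndata import FamilySpec, make_family

famA = make_family(FamilySpec(8, 80.0, 200, seed=1, prefix="A",
                              taxonomy="taxon1"))
famB = make_family(FamilySpec(8, 80.0, 200, seed=2, prefix="B",
                              taxonomy="taxon2"))
edges = all_vs_all(famA + famB)

intra_min = min(e.alignment_score_AS for e in edges if e.id_a[0] == e.id_b[0])
inter_max = max(e.alignment_score_AS for e in edges if e.id_a[0] != e.id_b[0])
print(f"intra-family AS >= {intra_min:.1f}; inter-family AS <= {inter_max:.1f}")

sweep = select_threshold(np.linspace(0, intra_min - 1, 15), edges)
print(sweep.table[["threshold", "n_clusters", "mean_betweenness"]]
      .to_string(index=False))
print(f"\nselected threshold: AS = {sweep.selected:.1f} ({sweep.status})")

graph = build_graph(edges, sweep.selected)
for i, cluster in enumerate(graph.clusters(), 1):
    print(f"cluster {i}: {len(cluster)} members, e.g. {sorted(cluster)[0]}")
print("\nAt the selected threshold the network splits into exactly the two "
      "generating families — the SSN behaviour used to delineate the family "
      "into taxon-aligned clusters.")
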