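"""Gene-set enrichment of an induced-gene list with redundancy clustering.

Builds a small annotation collection over a 400-gene universe, plants a
DEG list drawn mostly from one term, scores every term with the
one-sided hypergeometric test, and groups enriched terms that share at
least 50% of their differentially expressed members.
"""

import numpy as np

import striatal_ensembles as se

rng = np.random.default_rng(0)
universe = [f"gene{i:03d}" for i in range(400)]

sets = {"synaptic_signaling": set(universe[:40])}
# a near-duplicate term (high member overlap) and unrelated terms
sets["glutamatergic_synapse"] = set(universe[:25]) | set(universe[380:385])
for j in range(8):
    sets[f"unrelated_{j}"] = set(rng.choice(universe, 30, replace=False))
collection = se.GeneSetCollection(sets, set(universe))

deg = set(rng.choice(universe[:40], 15, replace=False))
deg |= set(rng.choice(universe, 5, replace=False))

table = se.enrich(deg, collection, correction="Bonferroni")
print("top enriched terms:")
print(
    table.head(3)[["term", "overlap", "set_size", "p", "p_adj"]]
    .to_string(index=False)
)

clusters = se.cluster_terms([table], threshold=0.5)
print(f"\n{len(clusters)} clusters after 50%-shared-gene grouping:")
for c in clusters:
    print(f"  cluster {c.cluster_id}: {c.members} (representative {c.representative})")
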