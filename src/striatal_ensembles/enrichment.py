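"""Hypergeometric gene-set enrichment and term redundancy clustering.

Enrichment of a differentially-expressed gene (DEG) list against a
gene-set collection is scored with the one-sided hypergeometric tail;
enriched terms are then de-redundified by grouping terms that share at
least half of their differentially expressed members (overlap
coefficient) in any analysed structure, taking connected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Term id -> member genes, with the enrichment universe.

    The universe defaults to all genes detected in the experiment (e.g.
    the rows of the count matrix); memberships are restricted to it.
    """

    sets: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        harmonized = {}
        for term, members in self.sets.items():
            kept = set(members) & self.universe
            if kept:
                harmonized[term] = kept
        dropped = len(self.sets) - len(harmonized)
        if dropped:
            logger.info("dropped %d terms with no member in the universe", dropped)
        self.sets = harmonized


@dataclass
class TermCluster:
    cluster_id: int
    members: list[str]
    genes: set[str]  # union of member DEG overlaps
    representative: str  # member term with the largest gene set


def enrich(
    deg: set[str],
    collection: GeneSetCollection,
    correction: str = "BH",
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a DEG list.

    For each term with K members in a universe of N genes and a DEG list
    of size n, p = P(X >= overlap) under Hypergeometric(N, K, n).
    ``correction`` is 'BH' or 'Bonferroni' across the tested terms.
    """
    if correction not in ("BH", "Bonferroni"):
        raise ValueError("correction must be 'BH' or 'Bonferroni'")
    outside = set(deg) - collection.universe
    if outside:
        logger.warning("%d DEGs outside the universe dropped", len(outside))
    deg_h = set(deg) & collection.universe
    if not deg_h:
        raise ValueError("no DEGs remain after harmonization with the universe")
    N, n = len(collection.universe), len(deg_h)
    rows = []
    for term, members in collection.sets.items():
        K = len(members)
        overlap = deg_h & members
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": collection.names.get(term, term),
                "overlap": k,
                "set_size": K,
                "universe_size": N,
                "deg_count": n,
                "p": min(p, 1.0),
                "genes": ",".join(sorted(overlap)),
            }
        )
    table = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    m = len(table)
    if correction == "Bonferroni":
        table["p_adj"] = np.minimum(table["p"] * m, 1.0)
    else:
        ranked = table["p"].to_numpy() * m / np.arange(1, m + 1)
        table["p_adj"] = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    return table


def _overlap_coefficient(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def _jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def cluster_terms(
    tables: list[pd.DataFrame],
    threshold: float = 0.5,
    metric: str = "overlap",
    p_adj_max: float = 0.05,
) -> list[TermCluster]:
    """Group enriched terms sharing >= ``threshold`` of their DEG members.

    ``tables`` holds one enrichment table per structure. Terms A and B
    are linked when, in ANY structure, the chosen similarity of their
    DEG-restricted memberships (overlap coefficient by default, Jaccard
    as alternative) reaches the threshold; clusters are the connected
    components of that graph. The representative of a cluster is its
    member with the largest DEG set (union over structures).
    """
    sim = {"overlap": _overlap_coefficient, "jaccard": _jaccard}[metric]
    per_structure: list[dict[str, set]] = []
    union_genes: dict[str, set] = {}
    for tab in tables:
        enriched = tab[tab["p_adj"] <= p_adj_max]
        d = {
            row["term"]: set(row["genes"].split(",")) if row["genes"] else set()
            for _, row in enriched.iterrows()
        }
        per_structure.append(d)
        for term, genes in d.items():
            union_genes.setdefault(term, set()).update(genes)
    terms = sorted(union_genes)
    if not terms:
        raise ValueError("no enriched terms to cluster")

    parent = {t: t for t in terms}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for d in per_structure:
        present = [t for t in terms if t in d]
        for i, a in enumerate(present):
            for b in present[i + 1:]:
                if sim(d[a], d[b]) >= threshold:
                    parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for t in terms:
        groups.setdefault(find(t), []).append(t)
    clusters = []
    for cid, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        genes = set().union(*(union_genes[t] for t in members))
        rep = max(members, key=lambda t: (len(union_genes[t]), t))
        clusters.append(TermCluster(cid, sorted(members), genes, rep))
    return clusters
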