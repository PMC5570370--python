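"""Over-representation testing and functional annotation clustering.

Terms are tested for over-representation in a selected gene set with the
upper-tail hypergeometric test; related terms (by Jaccard similarity of
their overlapping-gene sets) are grouped by single linkage, and each group
is scored with the enrichment score: the negative log10 of the geometric
mean of the member p-values, equivalently the arithmetic mean of the
members' -log10 p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def hypergeom_test(selected, term, universe) -> float:
    """Upper-tail hypergeometric p-value P(X >= |selected & term|).

    With N = |universe|, K = |term|, n = |selected|, the null draws n genes
    without replacement; over-representation is the upper tail.
    """
    universe = set(universe)
    selected = set(selected)
    term = set(term)
    if not universe:
        raise ValueError("empty universe")
    if not selected <= universe:
        raise ValueError("selected genes must lie in the universe")
    if not term <= universe:
        raise ValueError("term genes must lie in the universe")
    overlap = len(selected & term)
    return float(stats.hypergeom.sf(overlap - 1, len(universe), len(term), len(selected)))


def enrich_terms(
    selected,
    annotations: pd.DataFrame,
    universe=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every annotation term overlapping the selection.

    ``annotations`` has columns ``term_id``, ``term_name``, ``gene``.  The
    universe defaults to all annotated genes; genes outside it are ignored.
    Returns one row per term with overlap >= 1: overlap, term size, p, BH q,
    and the overlapping gene set (semicolon-joined in ``overlap_genes``).
    """
    if universe is None:
        universe = set(annotations["gene"])
    else:
        universe = set(universe)
    selected = set(selected) & universe
    rows = []
    overlap_sets = []
    for term_id, sub in annotations.groupby("term_id", sort=True):
        term_genes = set(sub["gene"]) & universe
        ov = selected & term_genes
        if not ov:
            continue
        p = hypergeom_test(selected, term_genes, universe)
        rows.append(
            (
                term_id,
                sub["term_name"].iloc[0],
                len(ov),
                len(term_genes),
                p,
                ";".join(sorted(ov)),
            )
        )
        overlap_sets.append(frozenset(ov))
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "overlap", "term_size", "pvalue", "overlap_genes"]
    )
    if len(result):
        result["qvalue"] = bh_adjust(result["pvalue"])
        result["significant"] = result["qvalue"] < alpha
        result = result.sort_values(
            ["pvalue", "term_id"], ignore_index=False
        ).reset_index(drop=True)
    else:
        result["qvalue"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


@dataclass
class EnrichmentCluster:
    """A group of related terms with its enrichment score.

    score = mean(-log10 p over member terms) = -log10(geometric mean p).
    """

    terms: list[str]
    pvalues: list[float]

    @property
    def score(self) -> float:
        return float(np.mean(-np.log10(self.pvalues)))

    def __len__(self) -> int:
        return len(self.terms)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def cluster_terms(
    results: pd.DataFrame, similarity_threshold: float = 0.5
) -> list[EnrichmentCluster]:
    """Single-linkage grouping of enriched terms by overlap-gene Jaccard.

    Terms whose overlapping-gene sets have Jaccard similarity >= the
    threshold are linked; connected components become clusters, scored per
    :class:`EnrichmentCluster` and returned sorted by score descending.
    """
    n = len(results)
    if n == 0:
        return []
    gene_sets = [
        frozenset(s.split(";")) if s else frozenset()
        for s in results["overlap_genes"]
    ]
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _jaccard(gene_sets[i], gene_sets[j]) >= similarity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = [
        EnrichmentCluster(
            terms=[results["term_id"].iloc[i] for i in idxs],
            pvalues=[float(results["pvalue"].iloc[i]) for i in idxs],
        )
        for idxs in groups.values()
    ]
    clusters.sort(key=lambda c: (-c.score, c.terms))
    return clusters


def cluster_table(clusters: list[EnrichmentCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i + 1, c.score, len(c), ";".join(c.terms))
            for i, c in enumerate(clusters)
        ],
        columns=["cluster", "enrichment_score", "n_terms", "terms"],
    )
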