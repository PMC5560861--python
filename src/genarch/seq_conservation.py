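"""Coding-sequence conservation from gene-tree cophenetic distances.

Each gene tree contributes the pairwise leaf-to-leaf path-length distances
(substitutions per alignment position); distances to a focal reference are
pooled per species pair across trees and compared between lineages with
the two-sided Wilcoxon rank-sum test (exact for small tie-free samples).
"""

from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger("genarch")

EXACT_MAX_N = 25


def read_gene_tree(source: str | Path) -> dendropy.Tree:
    """Read a Newick gene tree, requiring branch lengths on every edge."""
    try:
        is_path = Path(str(source)).exists()
    except OSError:
        is_path = False
    text = Path(source).read_text() if is_path else str(source)
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("gene tree has missing branch lengths")
    return tree


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length distance matrix of one gene tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(taxa[i], taxa[j])
    return pd.DataFrame(D, index=labels, columns=labels)


def collect_pair_distances(trees: list[dendropy.Tree], reference: str,
                           species: list[str], per_tree_mean: bool = False
                           ) -> dict[str, list[float]]:
    """Distances from the reference species to each listed species.

    Pooled across trees by default; with ``per_tree_mean`` each tree
    contributes one averaged value per species.
    """
    out: dict[str, list[float]] = {sp: [] for sp in species}
    for tree in trees:
        D = cophenetic_distances(tree)
        if reference not in D.index:
            continue
        for sp in species:
            if sp in D.columns and sp != reference:
                out[sp].append(float(D.loc[reference, sp]))
    if per_tree_mean:
        pass  # one value per tree already (single reference leaf per tree)
    return out


def compare_lineage_distances(group_a: list[float], group_b: list[float]
                              ) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) between two groups.

    Exact null distribution when the combined sample size is <= 25 and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValueError("empty group")
    pooled = list(group_a) + list(group_b)
    ties = len(set(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(group_a, group_b, alternative="two-sided",
                                   method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(dist: dict[str, list[float]], groups: dict[str, list[str]],
                   fdr: bool = False) -> pd.DataFrame:
    """All pairwise group comparisons of pooled distances.

    ``groups`` maps a lineage label to its member species; each pair of
    lineages is compared once.  Benjamini-Hochberg-adjusted p-values are
    appended when ``fdr`` (raw p is always reported).
    """
    labels = sorted(groups)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = [d for sp in groups[labels[i]] for d in dist.get(sp, [])]
            b = [d for sp in groups[labels[j]] for d in dist.get(sp, [])]
            stat, p = compare_lineage_distances(a, b)
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "n_a": len(a), "n_b": len(b), "statistic": stat,
                         "p_value": p})
    df = pd.DataFrame(rows)
    if fdr and not df.empty:
        df["p_adjusted"] = scipy.stats.false_discovery_control(df["p_value"])
    return df
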