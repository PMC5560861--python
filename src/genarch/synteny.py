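"""Pairwise microsynteny from collinear single-copy ortholog pairs.

For each species pair, collinearity is the number of unordered ortholog
pairs that are adjacent in both genomes, irrespective of gene orientation.
A permutation null (gene identities shuffled over fixed gene positions)
estimates the spurious count s, and the ratio

    r_ij = ((c_ij - s_ij) / N_ij) / ((c_max - s_max) / N_max)

normalises each pair's excess over the null to the best pair of the
dataset, yielding values on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io_formats import GeneModel, OrthologTable
from .synthetic_data import substream

logger = logging.getLogger("genarch")


@dataclass
class SyntenyResult:
    """Collinearity between one species pair."""

    sp_i: str
    sp_j: str
    c: int          # observed collinear ortholog pairs
    s: float        # mean spurious collinear pairs over the null rounds
    N: int          # comparable single-copy ortholog pairs
    n_rounds: int
    r: float | None = None


def _ortholog_orders(models: list[GeneModel], gene_to_og: dict[str, str],
                     mode: str) -> list[list[str]]:
    """Per-scaffold position-ordered orthogroup sequences for one genome.

    mode="ortholog": order over the single-copy-ortholog genes only
    (intervening non-ortholog genes ignored); mode="strict": an ortholog
    pair counts as adjacent only if the genes are genomically consecutive.
    """
    if not models:
        raise ValueError("species has no annotated genes")
    by_scaffold: dict[str, list[GeneModel]] = {}
    for gm in models:
        by_scaffold.setdefault(gm.scaffold, []).append(gm)
    orders = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.gene_id))
        if mode == "ortholog":
            seq = [gene_to_og[g.gene_id] for g in genes if g.gene_id in gene_to_og]
        elif mode == "strict":
            seq = [gene_to_og.get(g.gene_id) for g in genes]
        else:
            raise ValueError(f"unknown adjacency mode {mode!r}")
        orders.append(seq)
    return orders


def _adjacency_set(orders: list[list[str]]) -> set[frozenset]:
    out = set()
    for seq in orders:
        for a, b in zip(seq, seq[1:]):
            if a is not None and b is not None and a != b:
                out.add(frozenset((a, b)))
    return out


def count_collinear_pairs(annot_i: list[GeneModel], annot_j: list[GeneModel],
                          orthologs: OrthologTable, *,
                          mode: str = "ortholog") -> tuple[int, int]:
    """Collinear pair count c_ij and comparable-pair count N_ij.

    Only orthogroups with exactly one gene in each species are used; a pair
    of orthogroups is collinear if adjacent on the same scaffold in both
    genomes, in either orientation.
    """
    if not annot_i or not annot_j:
        raise ValueError("species has no annotated genes")
    sp_i, sp_j = annot_i[0].species, annot_j[0].species
    single = orthologs.single_copy_pairs(sp_i, sp_j)
    to_og_i = {gi: og for og, (gi, _) in single.items()}
    to_og_j = {gj: og for og, (_, gj) in single.items()}
    adj_i = _adjacency_set(_ortholog_orders(annot_i, to_og_i, mode))
    adj_j = _adjacency_set(_ortholog_orders(annot_j, to_og_j, mode))
    return len(adj_i & adj_j), len(single)


def shuffle_null(annot_i: list[GeneModel], annot_j: list[GeneModel],
                 orthologs: OrthologTable, n_rounds: int = 100,
                 seed: int = 0, *, mode: str = "ortholog") -> float:
    """Mean spurious collinear count over identity-permutation rounds.

    Gene positions are fixed; per round the assignment of orthogroup
    identities to positions is permuted independently in each genome.  The
    permutation stream depends only on the master seed (common random
    numbers), so null estimates are directly comparable across species
    pairs.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    if not annot_i or not annot_j:
        raise ValueError("species has no annotated genes")
    sp_i, sp_j = annot_i[0].species, annot_j[0].species
    rng = substream(seed, "shuffle_null")
    single = orthologs.single_copy_pairs(sp_i, sp_j)
    to_og_i = {gi: og for og, (gi, _) in single.items()}
    to_og_j = {gj: og for og, (_, gj) in single.items()}
    orders_i = _ortholog_orders(annot_i, to_og_i, mode)
    orders_j = _ortholog_orders(annot_j, to_og_j, mode)

    def permuted(orders, rng):
        labels = [og for seq in orders for og in seq if og is not None]
        perm = list(np.array(labels, dtype=object)[rng.permutation(len(labels))])
        it = iter(perm)
        return [[next(it) if og is not None else None for og in seq]
                for seq in orders]

    total = 0
    for _ in range(n_rounds):
        a = _adjacency_set(permuted(orders_i, rng))
        b = _adjacency_set(permuted(orders_j, rng))
        total += len(a & b)
    return total / n_rounds


def synteny_ratio(results: list[SyntenyResult]) -> pd.DataFrame:
    """Fill r for every pair and return the symmetric r matrix.

    The reference pair maximises (c - s)/N; its r is exactly 1.  Pairs with
    c <= s are clamped to 0.
    """
    if not results:
        raise ValueError("need at least one species pair")
    best = max(results, key=lambda x: (x.c - x.s) / x.N)
    denom = (best.c - best.s) / best.N
    if denom <= 0:
        raise ValueError("no signal above null: maximum pair has c - s <= 0")
    species = sorted({s for res in results for s in (res.sp_i, res.sp_j)})
    mat = pd.DataFrame(np.nan, index=species, columns=species)
    for res in results:
        res.r = max(0.0, ((res.c - res.s) / res.N) / denom)
        mat.loc[res.sp_i, res.sp_j] = mat.loc[res.sp_j, res.sp_i] = res.r
    np.fill_diagonal(mat.values, 1.0)
    return mat


def pairwise_synteny(annotations: dict[str, list[GeneModel]],
                     orthologs: OrthologTable, n_rounds: int = 100,
                     seed: int = 0, *, mode: str = "ortholog",
                     ) -> tuple[list[SyntenyResult], pd.DataFrame]:
    """All-pairs collinearity with permutation nulls and the r matrix."""
    species = sorted(annotations)
    results = []
    for a in range(len(species)):
        for b in range(a + 1, len(species)):
            sp_i, sp_j = species[a], species[b]
            c, N = count_collinear_pairs(annotations[sp_i], annotations[sp_j],
                                         orthologs, mode=mode)
            s = shuffle_null(annotations[sp_i], annotations[sp_j], orthologs,
                             n_rounds=n_rounds, seed=seed, mode=mode)
            results.append(SyntenyResult(sp_i=sp_i, sp_j=sp_j, c=c, s=s, N=N,
                                         n_rounds=n_rounds))
    return results, synteny_ratio(results)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick dendrogram."""
    n = len(labels)

    def render(k: int) -> str:
        if k < n:
            return labels[k]
        a, b, h, _ = Z[k - n]
        ha = h - (Z[int(a) - n][2] if a >= n else 0.0)
        hb = h - (Z[int(b) - n][2] if b >= n else 0.0)
        return f"({render(int(a))}:{ha / 2:.6g},{render(int(b))}:{hb / 2:.6g})"

    return render(2 * n - 2) + ";"


def cluster_species_by_synteny(matrix: pd.DataFrame,
                               ) -> tuple[np.ndarray, list[str], str]:
    """Ward clustering of species on Euclidean distances between r rows.

    Rows are pre-sorted lexicographically so that equal-distance merges
    break ties deterministically by species name.  Returns the linkage
    matrix, the dendrogram leaf order, and a Newick rendering.
    """
    if matrix.isna().any().any():
        raise ValueError("synteny matrix contains NaN entries")
    order = sorted(matrix.index)
    m = matrix.loc[order, order]
    Z = sch.linkage(m.values, method="ward", metric="euclidean")
    leaves = [order[i] for i in sch.leaves_list(Z)]
    return Z, leaves, linkage_to_newick(Z, order)
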