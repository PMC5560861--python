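"""Transposable-element landscape statistics.

From a copy->family table and blastn-style self-alignment hits, computes
per-genome landscape descriptors: total copies N_c, family count N_f, the
family-saturation percentages P_25f / P_75f (share of the most copy-rich
families accounting for 25% / 75% of all copies), and the within-complement
sequence-identity histogram whose shape dates TE amplification bursts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

logger = logging.getLogger("genarch")

MIN_IDENTITY = 70.0
MIN_LENGTH = 80


def filter_hits(hits: pd.DataFrame, min_identity: float = MIN_IDENTITY,
                min_length: int = MIN_LENGTH, dedupe: bool = False
                ) -> pd.DataFrame:
    """Keep hits at >= min identity and >= min alignment length.

    Boundary values are kept; query==subject self-hits are dropped.  With
    ``dedupe``, reciprocal duplicates (A-B and B-A) collapse to one row.
    """
    out = hits[(hits["pident"] >= min_identity)
               & (hits["length"] >= min_length)
               & (hits["query"] != hits["subject"])].copy()
    if dedupe:
        key = out.apply(lambda r: tuple(sorted((r["query"], r["subject"]))), axis=1)
        out = out.loc[~key.duplicated()].copy()
    return out.reset_index(drop=True)


def family_saturation(copy_counts: pd.Series, q: float) -> float:
    """Percentage of most-frequent families covering fraction q of copies.

    Families sort by copy count descending (ties by name); the smallest k
    whose cumulative copies reach q * N_c gives 100 * k / N_f.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if copy_counts.empty or copy_counts.sum() == 0:
        raise ValueError("empty TE copy table")
    ordered = copy_counts.sort_index().sort_values(ascending=False,
                                                   kind="stable")
    cum = ordered.cumsum()
    k = int(np.searchsorted(cum.to_numpy(), q * copy_counts.sum()) + 1)
    return 100.0 * k / len(copy_counts)


@dataclass
class TEProfile:
    species: str
    n_copies: int
    n_families: int
    p25f: float
    p75f: float
    identities: np.ndarray


def te_profile(copies: pd.DataFrame, hits: pd.DataFrame,
               species: str | None = None,
               prefiltered: bool = False) -> TEProfile:
    """Landscape profile of one genome from its copies and (raw) hits."""
    if species is not None:
        copies = copies[copies["species"] == species]
    elif copies["species"].nunique() == 1:
        species = copies["species"].iloc[0]
    else:
        raise ValueError("multiple species in copy table: pass species=")
    counts = copies.groupby("family_id")["copy_id"].nunique()
    kept = hits if prefiltered else filter_hits(hits)
    members = set(copies["copy_id"])
    kept = kept[kept["query"].isin(members) & kept["subject"].isin(members)]
    return TEProfile(species=species, n_copies=int(counts.sum()),
                     n_families=int(len(counts)),
                     p25f=family_saturation(counts, 0.25),
                     p75f=family_saturation(counts, 0.75),
                     identities=kept["pident"].to_numpy(dtype=float))


def identity_profile(hits: pd.DataFrame, bin_width: float = 1.0,
                     lo: float = 70.0, hi: float = 100.0) -> pd.DataFrame:
    """Binned identity histogram with a normalised density column."""
    edges = np.arange(lo, hi + bin_width, bin_width)
    if hits.empty:
        logger.warning("no hits: empty identity histogram")
        counts = np.zeros(len(edges) - 1)
        dens = counts
    else:
        counts, _ = np.histogram(hits["pident"].to_numpy(dtype=float),
                                 bins=edges)
        total = counts.sum()
        dens = counts / (total * bin_width) if total else counts
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts.astype(int), "density": dens})


def shared_family_matrix(family_lists: dict[str, set[str]]
                         ) -> tuple[pd.DataFrame, pd.Series, np.ndarray, list[str]]:
    """Presence/absence of TE families across species, Ward-clustered.

    Returns the binary families x species matrix, per-family species
    counts, the Ward linkage over families (Euclidean distances) and the
    dendrogram leaf order.
    """
    if len(family_lists) < 2:
        raise ValueError("need at least 2 species")
    species = sorted(family_lists)
    families = sorted(set().union(*family_lists.values()))
    mat = pd.DataFrame(
        [[int(f in family_lists[sp]) for sp in species] for f in families],
        index=families, columns=species)
    species_counts = mat.sum(axis=1)
    Z = sch.linkage(mat.values, method="ward", metric="euclidean")
    leaves = [families[i] for i in sch.leaves_list(Z)]
    return mat, species_counts, Z, leaves
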