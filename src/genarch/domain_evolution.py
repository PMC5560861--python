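"""Protein domain architecture evolution via directed binary domain pairs.

Each protein's N-to-C domain architecture is decomposed into all ordered
domain pairs after collapsing consecutive repeats (A-B-B-C -> A-B, A-C,
B-C), and each (pair, orthocluster) combination becomes a presence/absence
character across species.  Pair histories are reconstructed on the species
tree with the same two-state gain/loss machinery as intron sites; single
domains are additionally reconstructed under Dollo parsimony (one gain at
the LCA of the carriers, minimal losses below it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .intron_evolution import (AncestralReconstruction,
                               fit_gain_loss_model, gain_loss_ratio,
                               reconstruct_ancestral_sites)
from .io_formats import OrthologTable, SpeciesTree

logger = logging.getLogger("genarch")

ANCESTRAL_CALL_PROB = 0.9


@dataclass
class DomainArchitecture:
    """Ordered (N- to C-terminal) domain content of one protein."""

    protein_id: str
    species: str
    domains: list[str]


def architectures_from_table(df: pd.DataFrame) -> list[DomainArchitecture]:
    """Order each protein's domain calls by alignment start."""
    out = []
    for (pid, sp), sub in df.groupby(["protein_id", "species"], sort=True):
        sub = sub.sort_values(["ali_start", "ali_end", "domain_id"])
        out.append(DomainArchitecture(protein_id=pid, species=sp,
                                      domains=list(sub["domain_id"])))
    return out


def decompose_architecture(domains: list[str]) -> set[tuple[str, str]]:
    """All ordered domain pairs over the collapsed architecture.

    Consecutive repeats collapse first (A-B-B-C -> A-B-C), then every
    ordered pair (d_i, d_j), i < j, is emitted.  Non-consecutive repeats
    survive collapsing, so self-pairs like (A, A) can arise from A-B-A.
    """
    collapsed = [d for i, d in enumerate(domains) if i == 0 or d != domains[i - 1]]
    return {(collapsed[i], collapsed[j])
            for i in range(len(collapsed)) for j in range(i + 1, len(collapsed))}


def build_pair_profile(architectures: list[DomainArchitecture],
                       orthologs: OrthologTable) -> pd.DataFrame:
    """Per-species occurrence counts of each (ordered pair, orthocluster).

    Rows are MultiIndexed by (domain_a, domain_b, orthocluster); proteins
    outside any orthocluster are skipped (count logged).
    """
    to_og = orthologs.gene_to_orthogroup()
    species = orthologs.species
    counts: dict[tuple[str, str, str], dict[str, int]] = {}
    skipped = 0
    for arch in architectures:
        og = to_og.get(arch.protein_id)
        if og is None:
            skipped += 1
            continue
        for a, b in decompose_architecture(arch.domains):
            row = counts.setdefault((a, b, og), {sp: 0 for sp in species})
            row[arch.species] = row.get(arch.species, 0) + 1
    if skipped:
        logger.info("%d proteins outside any orthocluster ignored", skipped)
    if not counts:
        return pd.DataFrame(columns=species)
    idx = pd.MultiIndex.from_tuples(sorted(counts),
                                    names=["domain_a", "domain_b", "orthocluster"])
    return pd.DataFrame([counts[k] for k in sorted(counts)], index=idx,
                        columns=species).fillna(0).astype(int)


def profile_presence(profile: pd.DataFrame) -> pd.DataFrame:
    """Binarise the pair profile (any occurrence -> present)."""
    return (profile > 0).astype(float)


def reconstruct_pair_history(presence: pd.DataFrame, tree: SpeciesTree,
                             call_threshold: float = ANCESTRAL_CALL_PROB,
                             ) -> tuple[AncestralReconstruction, pd.DataFrame]:
    """Two-state ML reconstruction of pair presence across the tree.

    Returns the posterior reconstruction and hard ancestral calls at
    posterior >= ``call_threshold``.
    """
    fit = fit_gain_loss_model(presence, tree)
    recon = reconstruct_ancestral_sites(presence, tree, fit)
    calls = (recon.posterior >= call_threshold).astype(int)
    return recon, calls


# ---------------------------------------------------------------------------
# Dollo parsimony for single domains
# ---------------------------------------------------------------------------

@dataclass
class DolloHistory:
    """Single-gain history: the gain node and the minimal loss branches."""

    character: str
    gain_node: str | None
    loss_branches: list[str]
    present_nodes: list[str]


def dollo_reconstruct(presence: dict[str, int] | pd.Series, tree: SpeciesTree,
                      character: str = "") -> DolloHistory:
    """Dollo parsimony: one gain at the LCA of carriers, minimal losses.

    Within the gain clade a node is reconstructed present iff some
    descendant leaf carries the character; each edge from a present node to
    an all-absent subtree is one loss.
    """
    presence = dict(presence)
    carriers = [sp for sp, v in presence.items() if v]
    if not carriers:
        return DolloHistory(character=character, gain_node=None,
                            loss_branches=[], present_nodes=[])
    idx = tree.index()
    gain_node = tree.mrca(carriers)
    gain_i = idx.names.index(gain_node)
    any_below = np.zeros(idx.n_nodes, dtype=bool)
    for i in range(idx.n_nodes):
        if idx.is_leaf(i):
            any_below[i] = bool(presence.get(idx.names[i], 0))
        else:
            any_below[i] = any(any_below[c] for c in idx.children[i])

    in_clade = np.zeros(idx.n_nodes, dtype=bool)
    in_clade[gain_i] = True
    for i in range(idx.n_nodes - 1, -1, -1):
        if in_clade[i]:
            for c in idx.children[i]:
                in_clade[c] = True

    losses, present = [], []
    for i in range(idx.n_nodes):
        if not in_clade[i]:
            continue
        if any_below[i]:
            present.append(idx.names[i])
            for c in idx.children[i]:
                if not any_below[c]:
                    losses.append(idx.names[c])
    return DolloHistory(character=character, gain_node=gain_node,
                        loss_branches=sorted(losses),
                        present_nodes=sorted(present))


# ---------------------------------------------------------------------------
# Per-node diversification
# ---------------------------------------------------------------------------

BIAS_MARGIN = 5.0    # percentage-point gain/loss difference calling a bias


def node_diversification(recon: AncestralReconstruction,
                         call_threshold: float = ANCESTRAL_CALL_PROB,
                         bias_margin: float = BIAS_MARGIN) -> pd.DataFrame:
    """Gains/losses per node as percentages of the pairs present there.

    A node is gain- or loss-biased when the percentages differ by more
    than ``bias_margin`` points; otherwise it is in (possibly dynamic)
    stasis.  Nodes with no pairs present are flagged undefined.
    """
    present = (recon.posterior >= call_threshold).sum(axis=0)
    gains = recon.expected_gains
    losses = recon.expected_losses
    rows = []
    for node in present.index:
        n = int(present[node])
        if n == 0:
            rows.append({"node": node, "pairs_present": 0, "gains": gains[node],
                         "losses": losses[node], "p_gain": np.nan,
                         "p_loss": np.nan, "log_gain_loss_ratio": np.nan,
                         "classification": "undefined"})
            continue
        p_g = 100.0 * gains[node] / n
        p_l = 100.0 * losses[node] / n
        if p_g - p_l > bias_margin:
            cls = "gain-biased"
        elif p_l - p_g > bias_margin:
            cls = "loss-biased"
        else:
            cls = "stasis"
        rows.append({"node": node, "pairs_present": n, "gains": gains[node],
                     "losses": losses[node], "p_gain": p_g, "p_loss": p_l,
                     "log_gain_loss_ratio": gain_loss_ratio(p_g, p_l),
                     "classification": cls})
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# Family enrichment among node gains
# ---------------------------------------------------------------------------

def pair_contains(pair: tuple[str, str], family_domains: set[str]) -> bool:
    return pair[0] in family_domains or pair[1] in family_domains


def enrichment_test(focal_gains: list[tuple[str, str]],
                    background_gains: list[tuple[str, str]],
                    family_domains: set[str]) -> tuple[np.ndarray, float]:
    """Fisher test: is a domain family over-represented in a node's gains?

    2x2 of {gained at the focal node, gained elsewhere} x {pair contains a
    family domain, does not}.  Empty margins give p = 1 with a warning.
    """
    if not background_gains and not focal_gains:
        raise ValueError("empty background: nothing rearranges")
    a = sum(pair_contains(p, family_domains) for p in focal_gains)
    b = len(focal_gains) - a
    c = sum(pair_contains(p, family_domains) for p in background_gains)
    d = len(background_gains) - c
    table = np.array([[a, b], [c, d]])
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        logger.warning("degenerate enrichment table margin: p = 1")
        return table, 1.0
    _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return table, float(p)


def node_gain_pairs(recon: AncestralReconstruction, node: str,
                    threshold: float = 0.5) -> list[tuple[str, str]]:
    """Pairs whose gain localises to the branch above ``node``."""
    gp = recon.gain_posterior[node]
    return [(ix[0], ix[1]) for ix in gp.index[gp > threshold]]
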