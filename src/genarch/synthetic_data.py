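"""Simulators that generate toy datasets with recorded ground truth.

Each simulator emulates the statistical structure one downstream stage
assumes — two-state intron site histories on a tree, single-copy gene
orders under inversion/translocation rearrangement, ordered domain
architectures with append/remove events, and family-structured TE identity
landscapes — and can write the exact file formats :mod:`genarch.io_formats`
reads, plus a ground-truth JSON.

A single master seed is supplied per run; each component derives its own
independent sub-stream from it, so adding a stage never perturbs the draws
of an earlier one.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (GeneModel, OrthologTable, SpeciesTree, TreeIndex,
                         write_gene_models, write_orthogroups, write_tree,
                         OUTFMT6_COLUMNS)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG sub-stream derived from a master seed and a label."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _rate_map(rates, idx: TreeIndex) -> np.ndarray:
    """Scalar or {node name: rate} -> per-node array (branch above node)."""
    if np.isscalar(rates):
        arr = np.full(idx.n_nodes, float(rates))
    else:
        arr = np.array([float(rates.get(nm, 0.0)) for nm in idx.names])
    arr[idx.root] = 0.0
    if (arr < 0).any():
        raise ValueError("rates must be >= 0")
    return arr


def transition_probs(g: float, l: float, t: float) -> np.ndarray:
    """2x2 transition matrix of the absent/present chain over time t.

    P(0->1; t) = (g/(g+l)) (1 - exp(-(g+l) t)); rows index the parent state.
    """
    tot = g + l
    if tot == 0 or t == 0:
        return np.eye(2)
    decay = np.exp(-tot * t)
    p01 = (g / tot) * (1.0 - decay)
    p10 = (l / tot) * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# ---------------------------------------------------------------------------
# Intron site histories
# ---------------------------------------------------------------------------

@dataclass
class IntronHistorySim:
    """True per-node site states plus per-branch event counts."""

    tree: SpeciesTree
    states: pd.DataFrame            # sites x all node names, values {0,1}
    true_gains: dict[str, int]      # branch above node -> 0->1 flips
    true_losses: dict[str, int]
    config: dict

    @property
    def extant_matrix(self) -> pd.DataFrame:
        return self.states[self.tree.leaf_names]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.states.to_csv(outdir / "intron_states.tsv", sep="\t", index_label="site")
        write_tree(self.tree, outdir / "tree.nwk")
        truth = {"config": self.config, "true_gains": self.true_gains,
                 "true_losses": self.true_losses}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_intron_history(tree: SpeciesTree, n_sites: int, gain_rate,
                            loss_rate, root_presence_prob: float,
                            seed: int) -> IntronHistorySim:
    """Evolve binary intron-site presence along the tree.

    The root state is Bernoulli(root_presence_prob) per site; each branch
    applies the two-state transition with its own gain/loss rates over its
    length.  True gain/loss event counts per branch are recorded as state
    flips between parent and child.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = substream(seed, "intron_history")
    idx = tree.index()
    g = _rate_map(gain_rate, idx)
    l = _rate_map(loss_rate, idx)
    states = np.zeros((n_sites, idx.n_nodes), dtype=np.int8)
    states[:, idx.root] = rng.random(n_sites) < root_presence_prob
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    for i in range(idx.n_nodes - 2, -1, -1):      # preorder, root excluded
        p = idx.parent[i]
        P = transition_probs(g[i], l[i], idx.edge_length[i])
        parent_state = states[:, p]
        pr_present = np.where(parent_state == 1, P[1, 1], P[0, 1])
        states[:, i] = rng.random(n_sites) < pr_present
        gains[idx.names[i]] = int(((parent_state == 0) & (states[:, i] == 1)).sum())
        losses[idx.names[i]] = int(((parent_state == 1) & (states[:, i] == 0)).sum())
    df = pd.DataFrame(states, columns=idx.names,
                      index=[f"site{k}" for k in range(n_sites)])
    cfg = {"seed": int(seed), "n_sites": n_sites,
           "root_presence_prob": root_presence_prob}
    return IntronHistorySim(tree=tree, states=df, true_gains=gains,
                            true_losses=losses, config=cfg)


# ---------------------------------------------------------------------------
# Gene orders
# ---------------------------------------------------------------------------

@dataclass
class GeneOrderSim:
    """Single-copy gene orders at every node, rearranged along branches."""

    tree: SpeciesTree
    orders: dict[str, list[int]]        # node name -> ancestral gene index order
    orthologs: OrthologTable
    config: dict

    def gene_models(self, species: str) -> list[GeneModel]:
        """Lay the species' gene order on one scaffold, 1 kb per gene."""
        out = []
        for pos, k in enumerate(self.orders[species]):
            start = pos * 1000 + 1
            out.append(GeneModel(gene_id=f"{species}_g{k}", species=species,
                                 scaffold="scf1", strand="+",
                                 cds_segments=[(start, start + 899)]))
        return out

    def shared_adjacencies(self, sp_i: str, sp_j: str) -> int:
        """True count of ancestral-gene adjacencies shared by two leaves."""
        def adj(order):
            return {frozenset(p) for p in zip(order, order[1:])}
        return len(adj(self.orders[sp_i]) & adj(self.orders[sp_j]))

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.tree.leaf_names:
            write_gene_models(self.gene_models(sp), outdir / f"{sp}.gff3")
        write_orthogroups(self.orthologs, outdir / "orthogroups.tsv")
        write_tree(self.tree, outdir / "tree.nwk")
        truth = {"config": self.config,
                 "orders": {nm: list(map(int, o)) for nm, o in self.orders.items()}}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def _rearrange(order: list[int], n_events: int, rng: np.random.Generator) -> list[int]:
    order = list(order)
    n = len(order)
    for _ in range(n_events):
        if rng.random() < 0.5:                      # inversion
            i, j = sorted(rng.choice(n + 1, size=2, replace=False))
            order[i:j] = order[i:j][::-1]
        else:                                       # translocation
            i, j = sorted(rng.choice(n + 1, size=2, replace=False))
            block, rest = order[i:j], order[:i] + order[j:]
            k = rng.integers(0, len(rest) + 1)
            order = rest[:k] + block + rest[k:]
    return order


def simulate_gene_orders(tree: SpeciesTree, n_genes: int, breakpoints_per_branch,
                         seed: int) -> GeneOrderSim:
    """Evolve a single-scaffold gene order by inversions and translocations.

    The ancestral order is 1..n; each branch applies Poisson(rate) events.
    No gene gain or loss, so every orthogroup stays single-copy.
    """
    if n_genes < 3:
        raise ValueError("n_genes must be >= 3")
    rng = substream(seed, "gene_orders")
    idx = tree.index()
    rates = _rate_map(breakpoints_per_branch, idx)
    orders: dict[str, list[int]] = {idx.names[idx.root]: list(range(1, n_genes + 1))}
    for i in range(idx.n_nodes - 2, -1, -1):
        parent_order = orders[idx.names[idx.parent[i]]]
        n_events = rng.poisson(rates[i] * idx.edge_length[i])
        orders[idx.names[i]] = _rearrange(parent_order, n_events, rng)
    leaf_names = tree.leaf_names
    groups = {f"OG{k:05d}": {sp: [f"{sp}_g{k}"] for sp in leaf_names}
              for k in range(1, n_genes + 1)}
    table = OrthologTable(groups=groups, species=leaf_names)
    cfg = {"seed": int(seed), "n_genes": n_genes}
    return GeneOrderSim(tree=tree, orders=orders, orthologs=table, config=cfg)


# ---------------------------------------------------------------------------
# Domain architecture histories
# ---------------------------------------------------------------------------

def _collapse_pairs(arch) -> set[tuple[str, str]]:
    """Ordered pairs over the consecutive-duplicate-collapsed sequence."""
    collapsed = [d for i, d in enumerate(arch) if i == 0 or d != arch[i - 1]]
    return {(collapsed[i], collapsed[j])
            for i in range(len(collapsed)) for j in range(i + 1, len(collapsed))}


@dataclass
class DomainHistorySim:
    """Evolving ordered domain architectures, one per orthocluster."""

    tree: SpeciesTree
    architectures: dict[str, dict[str, tuple[str, ...]]]  # node -> og -> arch
    true_pair_presence: dict[str, dict[str, set[tuple[str, str]]]]
    true_gains: dict[str, int]   # branch -> pair-appearance events
    true_losses: dict[str, int]
    config: dict

    def domain_table(self) -> pd.DataFrame:
        """Extant architectures as a pfam_scan-style table."""
        rows = []
        for sp in self.tree.leaf_names:
            for og, arch in self.architectures[sp].items():
                pid = f"{sp}_{og}_p1"
                for pos, dom in enumerate(arch):
                    rows.append({"protein_id": pid, "domain_id": dom,
                                 "ali_start": pos * 100 + 1,
                                 "ali_end": pos * 100 + 90, "species": sp})
        return pd.DataFrame(rows, columns=["protein_id", "domain_id",
                                           "ali_start", "ali_end", "species"])

    def orthologs(self) -> OrthologTable:
        leaf_names = self.tree.leaf_names
        ogs = sorted({og for sp in leaf_names for og in self.architectures[sp]})
        groups = {og: {sp: ([f"{sp}_{og}_p1"] if og in self.architectures[sp]
                            and self.architectures[sp][og] else [])
                       for sp in leaf_names}
                  for og in ogs}
        return OrthologTable(groups=groups, species=leaf_names)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.domain_table().to_csv(outdir / "domains.tsv", sep="\t", index=False)
        write_orthogroups(self.orthologs(), outdir / "orthogroups.tsv")
        write_tree(self.tree, outdir / "tree.nwk")
        truth = {"config": self.config, "true_gains": self.true_gains,
                 "true_losses": self.true_losses}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_domain_histories(tree: SpeciesTree, n_orthoclusters: int,
                              n_domains: int, gain_rate, loss_rate,
                              seed: int) -> DomainHistorySim:
    """Evolve ordered domain architectures by domain append/remove events.

    Each orthocluster starts from a short random root architecture; along a
    branch, Poisson(g t) gains insert a random domain at a random position
    and Poisson(l t) losses delete a random position.  Truth records the
    ordered-pair presence at every node and per-branch counts of pair
    appearances (gains) and disappearances (losses).
    """
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    rng = substream(seed, "domain_histories")
    idx = tree.index()
    g = _rate_map(gain_rate, idx)
    l = _rate_map(loss_rate, idx)
    pool = [f"D{k:03d}" for k in range(n_domains)]
    root_name = idx.names[idx.root]
    archs: dict[str, dict[str, tuple[str, ...]]] = {root_name: {}}
    for c in range(n_orthoclusters):
        size = int(rng.integers(1, 4))
        archs[root_name][f"OG{c:04d}"] = tuple(rng.choice(pool, size=size))
    gains: dict[str, int] = {}
    losses: dict[str, int] = {}
    for i in range(idx.n_nodes - 2, -1, -1):
        parent = archs[idx.names[idx.parent[i]]]
        node: dict[str, tuple[str, ...]] = {}
        n_gain, n_loss = 0, 0
        t = idx.edge_length[i]
        for og, arch in parent.items():
            arch = list(arch)
            events = (["gain"] * rng.poisson(g[i] * t) +
                      ["loss"] * rng.poisson(l[i] * t))
            rng.shuffle(events)
            before = _collapse_pairs(arch)
            for ev in events:
                if ev == "gain":
                    pos = int(rng.integers(0, len(arch) + 1))
                    arch.insert(pos, str(rng.choice(pool)))
                elif arch:
                    arch.pop(int(rng.integers(0, len(arch))))
            after = _collapse_pairs(arch)
            n_gain += len(after - before)
            n_loss += len(before - after)
            node[og] = tuple(arch)
        archs[idx.names[i]] = node
        gains[idx.names[i]] = n_gain
        losses[idx.names[i]] = n_loss
    presence = {nm: {og: _collapse_pairs(a) for og, a in per_og.items()}
                for nm, per_og in archs.items()}
    cfg = {"seed": int(seed), "n_orthoclusters": n_orthoclusters,
           "n_domains": n_domains}
    return DomainHistorySim(tree=tree, architectures=archs,
                            true_pair_presence=presence, true_gains=gains,
                            true_losses=losses, config=cfg)


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def simulate_gene_trees(tree: SpeciesTree, n_trees: int, seed: int,
                        rate_sigma: float = 0.4) -> list[str]:
    """Gene trees as the species tree with lognormal branch-rate jitter.

    Each tree multiplies every branch length by an independent
    LogNormal(0, rate_sigma) factor, emulating among-gene rate variation
    around the species tree; no topology changes.  Returns Newick strings.
    """
    rng = substream(seed, "gene_trees")
    out = []
    for _ in range(n_trees):
        clone = SpeciesTree.from_newick(tree.to_newick())
        for nd in clone.tree.postorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = float(nd.edge.length *
                                       rng.lognormal(0.0, rate_sigma))
        out.append(clone.to_newick())
    return out


# ---------------------------------------------------------------------------
# TE landscapes
# ---------------------------------------------------------------------------

@dataclass
class TESpec:
    """TE landscape parameters for one genome.

    ``bursts`` is a list of (mean identity %, spread %, weight); each family
    is assigned to one burst by weight, and within-family pairwise hit
    identities are drawn Normal(burst mean, spread), clipped to [50, 100].
    """

    species: str = "spA"
    n_families: int = 20
    total_copies: int = 500
    copy_exponent: float = 1.5
    bursts: tuple = ((92.0, 3.0, 1.0),)
    min_hit_length: int = 50
    max_hit_length: int = 600


@dataclass
class TESim:
    copies: pd.DataFrame
    hits: pd.DataFrame
    family_burst: dict[str, float]
    config: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.copies.to_csv(outdir / "te_copies.tsv", sep="\t", index=False)
        self.hits.to_csv(outdir / "te_hits.tsv", sep="\t", index=False,
                         header=False)
        truth = {"config": self.config, "family_burst": self.family_burst}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def simulate_te_landscape(spec: TESpec, seed: int) -> TESim:
    """Draw family copy counts from a rank-power law and pairwise hits.

    Family f (rank k) receives copies proportional to k^-exponent (at least
    one each); every within-family copy pair yields one alignment hit whose
    identity reflects the family's burst.  Self-hits at 100% identity and
    hits below the consumer's 70%/80 bp filter are emitted on purpose —
    filtering is the analysis stage's job.
    """
    if spec.n_families < 1:
        raise ValueError("need at least one TE family")
    rng = substream(seed, f"te_landscape:{spec.species}")
    ranks = np.arange(1, spec.n_families + 1, dtype=float)
    w = ranks ** (-spec.copy_exponent)
    counts = np.maximum(1, np.floor(w / w.sum() * spec.total_copies)).astype(int)
    fam_ids = [f"{spec.species}_fam{k:03d}" for k in range(1, spec.n_families + 1)]
    bursts = np.array([b[:2] for b in spec.bursts], dtype=float)
    weights = np.array([b[2] for b in spec.bursts], dtype=float)
    fam_burst_idx = rng.choice(len(bursts), size=spec.n_families,
                               p=weights / weights.sum())
    copy_rows, hit_rows = [], []
    family_burst = {}
    for fam, c, bi in zip(fam_ids, counts, fam_burst_idx):
        mean_id, spread = bursts[bi]
        family_burst[fam] = float(mean_id)
        copy_ids = [f"{fam}_c{j}" for j in range(1, c + 1)]
        for cid in copy_ids:
            copy_rows.append({"copy_id": cid, "family_id": fam,
                              "species": spec.species})
            hit_rows.append((cid, cid, 100.0,
                             int(rng.integers(spec.min_hit_length,
                                              spec.max_hit_length))))
        if c > 1:
            ii, jj = np.triu_indices(c, k=1)
            idents = np.clip(rng.normal(mean_id, spread, size=len(ii)), 50.0, 100.0)
            lengths = rng.integers(spec.min_hit_length, spec.max_hit_length,
                                   size=len(ii))
            for a, b, pid, ln in zip(ii, jj, idents, lengths):
                hit_rows.append((copy_ids[a], copy_ids[b], round(float(pid), 2),
                                 int(ln)))
    hits = pd.DataFrame(
        [{"query": q, "subject": s, "pident": p, "length": ln, "mismatch": 0,
          "gapopen": 0, "qstart": 1, "qend": ln, "sstart": 1, "send": ln,
          "evalue": 0.0, "bitscore": round(ln * 1.8, 1)}
         for q, s, p, ln in hit_rows], columns=OUTFMT6_COLUMNS)
    copies = pd.DataFrame(copy_rows, columns=["copy_id", "family_id", "species"])
    cfg = {"seed": int(seed), "species": spec.species,
           "n_families": spec.n_families, "total_copies": int(counts.sum())}
    return TESim(copies=copies, hits=hits, family_burst=family_burst, config=cfg)
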