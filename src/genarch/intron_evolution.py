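"""Intron-site evolution: mapping, classification, gain/loss reconstruction.

Homologous intron sites are defined by protein-alignment column plus codon
phase.  Presence/absence across species is modelled with a two-state
continuous-time Markov chain (absent <-> present) with branch-specific gain
and loss rates; rates are estimated by maximum likelihood with Felsenstein
pruning, conditioning on each site being present in at least one extant
species, and ancestral states are posterior probabilities from the standard
up-down recursion.  Per-node summaries (expected gains/losses, intron
density, signed log10 gain/loss ratio, bootstrap variance-to-mean ratio),
presence-profile clustering and the phylostratigraphic Fisher test follow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import scipy.stats

from .io_formats import GeneModel, OrthologTable, SpeciesTree, TreeIndex
from .synthetic_data import substream, transition_probs

logger = logging.getLogger("genarch")

LOG_RATIO_EPS = 1e-6   # pseudo-rate in the signed log gain/loss ratio


# ---------------------------------------------------------------------------
# Marker selection
# ---------------------------------------------------------------------------

def select_marker_orthoclusters(table: OrthologTable, min_fraction: float = 0.8,
                                max_paralog_species: int = 1,
                                paralog_scores: dict[str, float] | None = None,
                                protein_lengths: dict[str, int] | None = None,
                                ) -> dict[str, dict[str, str]]:
    """Select near-universal single-copy marker orthoclusters.

    Keeps orthoclusters that are single-copy in at least ``min_fraction`` of
    the species set, tolerating paralogs in at most ``max_paralog_species``
    species; for tolerated paralogs the best-scoring copy is kept (highest
    ``paralog_scores``, ties broken by lexicographic gene id; without scores
    the longest protein, with a logged warning).

    Returns orthocluster id -> species -> representative gene id.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    n_species = len(table.species)
    kept: dict[str, dict[str, str]] = {}
    for og, per_sp in table.groups.items():
        single = [sp for sp in table.species if len(per_sp.get(sp, [])) == 1]
        multi = [sp for sp in table.species if len(per_sp.get(sp, [])) >= 2]
        if len(single) < min_fraction * n_species or len(multi) > max_paralog_species:
            continue
        reps = {sp: per_sp[sp][0] for sp in single}
        for sp in multi:
            genes = per_sp[sp]
            if paralog_scores is not None:
                reps[sp] = sorted(genes, key=lambda g: (-paralog_scores.get(g, float("-inf")), g))[0]
            elif protein_lengths is not None:
                logger.warning("no paralog scores for %s/%s: keeping longest protein",
                               og, sp)
                reps[sp] = sorted(genes, key=lambda g: (-protein_lengths.get(g, 0), g))[0]
            else:
                logger.warning("no paralog scores for %s/%s: keeping first gene id",
                               og, sp)
                reps[sp] = sorted(genes)[0]
        kept[og] = reps
    return kept


# ---------------------------------------------------------------------------
# Intron site mapping and classification
# ---------------------------------------------------------------------------

@dataclass
class IntronSite:
    """A homologous intron position: alignment column (1-based) + phase."""

    orthocluster: str
    column: int
    phase: int
    presence: dict[str, str]    # species -> present / absent / missing
    classification: str = "unclassified"


def _codon_for_intron(coding_nt: int, phase: int, anchor: str) -> int:
    """1-based index of the amino acid anchoring an intron.

    Phase 1/2 introns interrupt a codon: that codon anchors.  Phase 0
    introns fall between codons: the codon immediately 3' anchors by
    default (``anchor='downstream'``); ``anchor='upstream'`` uses the 5' one.
    """
    if phase:
        return coding_nt // 3 + 1
    return coding_nt // 3 if anchor == "upstream" else coding_nt // 3 + 1


def _ungapped_to_column(aligned: str) -> list[int]:
    """1-based alignment column of each ungapped residue."""
    return [i + 1 for i, ch in enumerate(aligned) if ch not in "-."]


def map_intron_sites(orthocluster: str, alignment: dict[str, str],
                     genes: dict[str, GeneModel], all_species: list[str] | None = None,
                     anchor: str = "downstream") -> list[IntronSite]:
    """Project each gene's introns onto the protein alignment and merge.

    Two species share a site iff their introns map to the same (alignment
    column, phase); the same column with different phases yields distinct
    sites.  Genes whose CDS length is not divisible by 3 are excluded with
    a logged message.
    """
    per_site: dict[tuple[int, int], dict[str, str]] = {}
    participating: list[str] = []
    for sp, gm in genes.items():
        if sp not in alignment:
            continue
        if gm.cds_length % 3 != 0:
            logger.warning("%s/%s: CDS length not divisible by 3, excluded",
                           orthocluster, gm.gene_id)
            continue
        aligned = alignment[sp]
        cols = _ungapped_to_column(aligned)
        if len(cols) != gm.protein_length:
            raise ValueError(
                f"{orthocluster}/{gm.gene_id}: ungapped alignment length "
                f"{len(cols)} != protein length {gm.protein_length}")
        participating.append(sp)
        for coding_nt, phase in gm.intron_coding_offsets():
            codon = _codon_for_intron(coding_nt, phase, anchor)
            codon = min(codon, len(cols))     # phase-0 intron after last codon
            key = (cols[codon - 1], phase)
            per_site.setdefault(key, {})[sp] = "present"
    universe = all_species if all_species is not None else sorted(alignment)
    sites = []
    for (col, phase), found in sorted(per_site.items()):
        presence = {}
        for sp in universe:
            if sp in found:
                presence[sp] = "present"
            elif sp in alignment and sp in genes:
                presence[sp] = "absent"
            else:
                presence[sp] = "missing"
        sites.append(IntronSite(orthocluster=orthocluster, column=col,
                                phase=phase, presence=presence))
    return sites


def classify_sites(sites: list[IntronSite], alignment: dict[str, str],
                   n_species_total: int | None = None,
                   min_presence: float = 0.8, max_gap_fraction: float = 0.1,
                   window: int = 3) -> list[IntronSite]:
    """Classify sites by local alignment quality and orthocluster coverage.

    conserved: every column of the window (the site's column and its
    immediate neighbours) has a gap fraction <= ``max_gap_fraction`` and
    the orthocluster covers >= ``min_presence`` of all species (boundary
    inclusive).  ambiguous: the gap criterion fails (or coverage falls
    short).  unclassifiable: some window column is a gap in more than half
    of the rows, i.e. the region is essentially unaligned.
    """
    if not (0 < min_presence <= 1 and 0 < max_gap_fraction <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    rows = list(alignment.values())
    if not rows:
        return sites
    aln_len = len(rows[0])
    gap_frac = np.array([sum(r[c] in "-." for r in rows) / len(rows)
                         for c in range(aln_len)])
    n_total = n_species_total if n_species_total is not None else len(rows)
    coverage = len(rows) / n_total
    half = window // 2
    for site in sites:
        c0 = site.column - 1
        cols = range(max(0, c0 - half), min(aln_len, c0 + half + 1))
        if any(gap_frac[c] > 0.5 for c in cols):
            site.classification = "unclassifiable"
        elif any(gap_frac[c] > max_gap_fraction for c in cols):
            site.classification = "ambiguous"
        elif coverage >= min_presence:
            site.classification = "conserved"
        else:
            site.classification = "ambiguous"
    return sites


def sites_to_matrix(sites: list[IntronSite], species: list[str],
                    only: str | None = "conserved") -> pd.DataFrame:
    """Stack sites into a sites x species matrix (1/0/NaN for missing)."""
    code = {"present": 1.0, "absent": 0.0, "missing": np.nan}
    rows, names = [], []
    for site in sites:
        if only is not None and site.classification != only:
            continue
        rows.append([code[site.presence.get(sp, "missing")] for sp in species])
        names.append(f"{site.orthocluster}:{site.column}.{site.phase}")
    return pd.DataFrame(rows, index=names, columns=species, dtype=float)


# ---------------------------------------------------------------------------
# Two-state maximum-likelihood machinery
# ---------------------------------------------------------------------------

@dataclass
class TwoStateFit:
    """Branch-specific gain/loss rates and root presence probability."""

    tree: SpeciesTree
    gain: dict[str, float]       # rate on the branch above each named node
    loss: dict[str, float]
    root_prior: float            # probability the character is present at root
    log_likelihood: float
    converged: bool
    n_iter: int

    def rate_arrays(self, idx: TreeIndex) -> tuple[np.ndarray, np.ndarray]:
        g = np.array([self.gain.get(nm, 0.0) for nm in idx.names])
        l = np.array([self.loss.get(nm, 0.0) for nm in idx.names])
        return g, l


def _encode_patterns(matrix: pd.DataFrame, leaf_order: list[str]
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse the site x leaf matrix to unique patterns with counts.

    Returns (patterns, counts, site_to_pattern); entries are {0,1,-1(miss)}.
    """
    data = matrix[leaf_order].to_numpy(dtype=float)
    enc = np.where(np.isnan(data), -1, data).astype(np.int8)
    patterns, site_to_pattern, counts = np.unique(
        enc, axis=0, return_inverse=True, return_counts=True)
    return patterns, counts, site_to_pattern


def _branch_matrices(idx: TreeIndex, g: np.ndarray, l: np.ndarray) -> np.ndarray:
    P = np.empty((idx.n_nodes, 2, 2))
    for i in range(idx.n_nodes):
        P[i] = transition_probs(g[i], l[i], idx.edge_length[i]) \
            if idx.parent[i] != -1 else np.eye(2)
    return P


def _pruning_partials(patterns: np.ndarray, idx: TreeIndex, P: np.ndarray,
                      leaf_cols: dict[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Post-order conditional likelihoods with per-node scaling.

    Returns (L, logscale): L[i, p, s] is the scaled likelihood of pattern
    p's data below node i given state s; logscale[p] accumulates the
    removed factors.
    """
    n_pat = patterns.shape[0]
    L = np.ones((idx.n_nodes, n_pat, 2))
    logscale = np.zeros(n_pat)
    for i in range(idx.n_nodes):
        if idx.is_leaf(i):
            obs = patterns[:, leaf_cols[i]]
            L[i, obs == 0] = [1.0, 0.0]
            L[i, obs == 1] = [0.0, 1.0]
        else:
            acc = np.ones((n_pat, 2))
            for c in idx.children[i]:
                acc *= L[c] @ P[c].T
            mx = acc.max(axis=1)
            mx[mx == 0] = 1.0
            logscale += np.log(mx)
            L[i] = acc / mx[:, None]
    return L, logscale


def _pattern_loglik(patterns: np.ndarray, idx: TreeIndex, P: np.ndarray,
                    root_prior: float, leaf_cols: dict[int, int]) -> np.ndarray:
    L, logscale = _pruning_partials(patterns, idx, P, leaf_cols)
    pi = np.array([1.0 - root_prior, root_prior])
    lik = L[idx.root] @ pi
    return np.log(np.maximum(lik, 1e-300)) + logscale


def _all_absent_logprob(idx: TreeIndex, P: np.ndarray, root_prior: float,
                        leaf_cols: dict[int, int], n_leaves: int) -> float:
    absent = np.zeros((1, n_leaves), dtype=np.int8)
    return float(_pattern_loglik(absent, idx, P, root_prior, leaf_cols)[0])


def fit_gain_loss_model(matrix: pd.DataFrame, tree: SpeciesTree,
                        condition_observable: bool = True,
                        max_iter: int = 1000, tol: float = 1e-6,
                        x0: np.ndarray | None = None) -> TwoStateFit:
    """ML branch-specific gain/loss rates for extant presence/absence data.

    ``matrix`` is sites x species with entries 1 (present), 0 (absent) or
    NaN (missing).  The likelihood is computed by pruning over site
    patterns and, when ``condition_observable``, divided by the probability
    that a site is present in at least one extant species (ascertainment
    correction for unobservable all-absent sites).
    """
    if matrix.shape[0] < 1:
        raise ValueError("need at least one site")
    vals = matrix.to_numpy(dtype=float)
    if np.nansum(vals) == 0:
        raise ValueError("all-absent site matrix: rates unidentifiable")
    idx = tree.index()
    leaf_order = [nm for nm in idx.names if nm in idx.leaf_indices]
    missing = set(leaf_order) - set(matrix.columns)
    if missing:
        raise ValueError(f"matrix lacks leaves: {sorted(missing)}")
    patterns, counts, _ = _encode_patterns(matrix, leaf_order)
    leaf_cols = {idx.leaf_indices[nm]: j for j, nm in enumerate(leaf_order)}
    branch_nodes = [i for i in range(idx.n_nodes) if idx.parent[i] != -1]
    nb = len(branch_nodes)
    has_missing = (patterns == -1).any()

    def unpack(x):
        g = np.zeros(idx.n_nodes)
        l = np.zeros(idx.n_nodes)
        g[branch_nodes] = np.exp(x[:nb])
        l[branch_nodes] = np.exp(x[nb:2 * nb])
        root_prior = 1.0 / (1.0 + np.exp(-x[-1]))
        return g, l, root_prior

    def negloglik(x):
        g, l, root_prior = unpack(x)
        P = _branch_matrices(idx, g, l)
        ll = _pattern_loglik(patterns, idx, P, root_prior, leaf_cols)
        total = float(ll @ counts)
        if condition_observable:
            if has_missing:
                # correct per unique missingness mask
                masks, inv = np.unique(patterns == -1, axis=0, return_inverse=True)
                for m, mask in enumerate(masks):
                    pat0 = np.where(mask, -1, 0)[None, :].astype(np.int8)
                    l0 = _pattern_loglik(pat0, idx, P, root_prior, leaf_cols)[0]
                    n_m = counts[inv == m].sum()
                    total -= n_m * np.log1p(-min(np.exp(l0), 1 - 1e-12))
            else:
                l0 = _all_absent_logprob(idx, P, root_prior, leaf_cols,
                                         len(leaf_order))
                total -= counts.sum() * np.log1p(-min(np.exp(l0), 1 - 1e-12))
        return -total

    if x0 is None:
        x0 = np.concatenate([np.full(2 * nb, np.log(0.5)), [0.0]])
    bounds = [(-9.0, 4.0)] * (2 * nb) + [(-8.0, 8.0)]
    res = scipy.optimize.minimize(negloglik, x0, method="L-BFGS-B",
                                  bounds=bounds,
                                  options={"maxiter": max_iter, "ftol": tol * 1e-3})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"non-finite likelihood; parameters: {res.x}")
    g, l, root_prior = unpack(res.x)
    return TwoStateFit(
        tree=tree,
        gain={idx.names[i]: float(g[i]) for i in branch_nodes},
        loss={idx.names[i]: float(l[i]) for i in branch_nodes},
        root_prior=float(root_prior), log_likelihood=float(-res.fun),
        converged=bool(res.success), n_iter=int(res.nit))


@dataclass
class AncestralReconstruction:
    """Posterior presence per node and per-branch expected transitions."""

    posterior: pd.DataFrame      # sites x all node names, in [0, 1]
    gain_posterior: pd.DataFrame  # sites x nodes: P(parent absent, node present)
    loss_posterior: pd.DataFrame
    fit: TwoStateFit

    @property
    def expected_gains(self) -> pd.Series:
        return self.gain_posterior.sum(axis=0)

    @property
    def expected_losses(self) -> pd.Series:
        return self.loss_posterior.sum(axis=0)

    @property
    def node_counts(self) -> pd.Series:
        """Expected number of characters present at each node."""
        return self.posterior.sum(axis=0)


def reconstruct_ancestral_sites(matrix: pd.DataFrame, tree: SpeciesTree,
                                fit: TwoStateFit) -> AncestralReconstruction:
    """Posterior ancestral presence by the up-down (inside-outside) recursion.

    Expected gains on a branch are the summed per-site joint posterior
    P(parent absent, child present | data); losses analogously.
    """
    idx = tree.index()
    leaf_order = [nm for nm in idx.names if nm in idx.leaf_indices]
    patterns, counts, site_to_pattern = _encode_patterns(matrix, leaf_order)
    leaf_cols = {idx.leaf_indices[nm]: j for j, nm in enumerate(leaf_order)}
    g, l = fit.rate_arrays(idx)
    P = _branch_matrices(idx, g, l)
    L, _ = _pruning_partials(patterns, idx, P, leaf_cols)
    n_pat = patterns.shape[0]
    pi = np.array([1.0 - fit.root_prior, fit.root_prior])

    # S[c, p, s] = P(data below c | parent state s), up the branch above c
    S = np.empty((idx.n_nodes, n_pat, 2))
    for c in range(idx.n_nodes):
        S[c] = L[c] @ P[c].T
    A = np.empty((idx.n_nodes, n_pat, 2))    # outside likelihood, scaled per node
    A[idx.root] = pi
    for i in range(idx.n_nodes - 2, -1, -1):  # preorder
        p = idx.parent[i]
        sib = np.ones((n_pat, 2))
        for c in idx.children[p]:
            if c != i:
                sib *= S[c]
        upper = A[p] * sib                    # outside-at-parent x siblings
        A[i] = upper @ P[i]
        mx = A[i].max(axis=1)
        mx[mx == 0] = 1.0
        A[i] /= mx[:, None]

    post = np.empty((n_pat, idx.n_nodes))
    gain_post = np.zeros((n_pat, idx.n_nodes))
    loss_post = np.zeros((n_pat, idx.n_nodes))
    for i in range(idx.n_nodes):
        joint = A[i] * L[i]
        norm = joint.sum(axis=1)
        norm[norm == 0] = 1.0
        post[:, i] = joint[:, 1] / norm
        if idx.parent[i] != -1:
            p = idx.parent[i]
            sib = np.ones((n_pat, 2))
            for c in idx.children[p]:
                if c != i:
                    sib *= S[c]
            upper = A[p] * sib
            # J[s_parent, s_child] ∝ upper[s_p] P[i][s_p, s_c] L[i][s_c]
            J = upper[:, :, None] * P[i][None, :, :] * L[i][:, None, :]
            Jn = J.sum(axis=(1, 2))
            Jn[Jn == 0] = 1.0
            gain_post[:, i] = J[:, 0, 1] / Jn
            loss_post[:, i] = J[:, 1, 0] / Jn

    expand = site_to_pattern
    posterior = pd.DataFrame(post[expand], index=matrix.index, columns=idx.names)
    # pin observed leaf states exactly
    for nm in leaf_order:
        obs = matrix[nm].to_numpy(dtype=float)
        ok = ~np.isnan(obs)
        posterior.loc[ok, nm] = obs[ok]
    return AncestralReconstruction(
        posterior=posterior,
        gain_posterior=pd.DataFrame(gain_post[expand], index=matrix.index,
                                    columns=idx.names),
        loss_posterior=pd.DataFrame(loss_post[expand], index=matrix.index,
                                    columns=idx.names),
        fit=fit)


def pruning_loglik(matrix: pd.DataFrame, tree: SpeciesTree, fit: TwoStateFit,
                   condition_observable: bool = False) -> float:
    """Pruning log-likelihood of the data under fixed rates."""
    idx = tree.index()
    leaf_order = [nm for nm in idx.names if nm in idx.leaf_indices]
    patterns, counts, _ = _encode_patterns(matrix, leaf_order)
    leaf_cols = {idx.leaf_indices[nm]: j for j, nm in enumerate(leaf_order)}
    g, l = fit.rate_arrays(idx)
    P = _branch_matrices(idx, g, l)
    ll = _pattern_loglik(patterns, idx, P, fit.root_prior, leaf_cols)
    total = float(ll @ counts)
    if condition_observable:
        l0 = _all_absent_logprob(idx, P, fit.root_prior, leaf_cols,
                                 len(leaf_order))
        total -= counts.sum() * np.log1p(-min(np.exp(l0), 1 - 1e-12))
    return total


def brute_force_loglik(matrix: pd.DataFrame, tree: SpeciesTree,
                       fit: TwoStateFit,
                       condition_observable: bool = False) -> float:
    """Likelihood by explicit enumeration of all internal-state assignments.

    Exponential in the number of internal nodes; the independent check for
    the pruning recursion on small trees.
    """
    import itertools
    idx = tree.index()
    g, l = fit.rate_arrays(idx)
    P = _branch_matrices(idx, g, l)
    internal = [i for i in range(idx.n_nodes) if not idx.is_leaf(i)]
    pi = np.array([1.0 - fit.root_prior, fit.root_prior])
    leaf_order = [nm for nm in idx.names if nm in idx.leaf_indices]

    def site_lik(obs: dict[int, float]) -> float:
        total = 0.0
        for assign in itertools.product((0, 1), repeat=len(internal)):
            state = dict(zip(internal, assign))
            state.update(obs)
            term = pi[state[idx.root]]
            for i in range(idx.n_nodes - 1):
                term *= P[i][state[idx.parent[i]], state[i]]
            total += term
        return total

    def leaf_obs(row) -> dict[int, float]:
        obs = {}
        for nm in leaf_order:
            v = row[nm]
            if not np.isnan(v):
                obs[idx.leaf_indices[nm]] = int(v)
        return obs

    total = 0.0
    for _, row in matrix.iterrows():
        obs = leaf_obs(row)
        missing_leaves = [idx.leaf_indices[nm] for nm in leaf_order
                          if idx.leaf_indices[nm] not in obs]
        lik = 0.0
        for miss in itertools.product((0, 1), repeat=len(missing_leaves)):
            o = dict(obs)
            o.update(dict(zip(missing_leaves, miss)))
            lik += site_lik(o)
        if condition_observable:
            lik /= 1.0 - site_lik({idx.leaf_indices[nm]: 0 for nm in leaf_order})
        total += np.log(lik)
    return total


# ---------------------------------------------------------------------------
# Per-node summaries
# ---------------------------------------------------------------------------

def gain_loss_ratio(p_gain: float, p_loss: float,
                    eps: float = LOG_RATIO_EPS) -> float:
    """Signed log10 ratio of gain to loss percentages.

    Positive when gains dominate, negative when losses do, 0 at parity;
    the pseudo-count eps keeps the ratio finite when one side is 0.
    """
    if p_gain < 0 or p_loss < 0:
        raise ValueError("percentages must be >= 0")
    return float(np.log10((p_gain + eps) / (p_loss + eps)))


def intron_density(count: float, cds_kbp: float) -> float:
    """Introns per kbp of coding sequence."""
    if cds_kbp <= 0:
        raise ValueError("total CDS length must be > 0")
    return count / cds_kbp


def total_cds_kbp(models: list[GeneModel]) -> float:
    return sum(gm.cds_length for gm in models) / 1000.0


def variance_to_mean(counts: np.ndarray) -> float:
    """Dispersion of replicate counts; > 1 flags unreliable inference."""
    counts = np.asarray(counts, dtype=float)
    mean = counts.mean()
    if mean == 0:
        logger.warning("zero mean count: variance-to-mean ratio undefined")
        return float("nan")
    return float(counts.var(ddof=1) / mean)


def summarize_branches(recon: AncestralReconstruction,
                       cds_kbp: float | None = None,
                       vmr: pd.Series | None = None) -> pd.DataFrame:
    """Per-node event summary: counts, gains, losses, p_G, p_L, r, density."""
    counts = recon.node_counts
    gains = recon.expected_gains
    losses = recon.expected_losses
    rows = []
    for node in counts.index:
        n = counts[node]
        p_g = 100.0 * gains[node] / n if n > 0 else 0.0
        p_l = 100.0 * losses[node] / n if n > 0 else 0.0
        rows.append({
            "node": node, "introns": n, "gains": gains[node],
            "losses": losses[node], "p_gain": p_g, "p_loss": p_l,
            "log_gain_loss_ratio": gain_loss_ratio(p_g, p_l),
            "density": intron_density(n, cds_kbp) if cds_kbp else np.nan,
            "vmr": vmr[node] if vmr is not None else np.nan,
        })
    return pd.DataFrame(rows).set_index("node")


def bootstrap_vmr(matrix: pd.DataFrame, tree: SpeciesTree, fit: TwoStateFit,
                  n_reps: int = 100, seed: int = 0,
                  refit: bool = False) -> pd.Series:
    """Variance-to-mean ratio of inferred node intron counts over bootstraps.

    Sites are resampled with replacement; node counts are re-inferred per
    replicate (optionally re-fitting rates, warm-started from the full-data
    estimate).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = substream(seed, "bootstrap_vmr")
    n_sites = matrix.shape[0]
    replicate_counts = []
    for _ in range(n_reps):
        take = rng.integers(0, n_sites, size=n_sites)
        boot = matrix.iloc[take]
        boot.index = [f"bs{k}" for k in range(n_sites)]
        model = fit
        if refit:
            try:
                model = fit_gain_loss_model(boot, tree)
            except ValueError:
                pass
        recon = reconstruct_ancestral_sites(boot, tree, model)
        replicate_counts.append(recon.node_counts)
    reps = pd.DataFrame(replicate_counts)
    return pd.Series({node: variance_to_mean(reps[node].to_numpy())
                      for node in reps.columns})


# ---------------------------------------------------------------------------
# Presence-profile clustering
# ---------------------------------------------------------------------------

def spearman_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """1 - Spearman correlation between rows; constant rows get distance 1."""
    names = list(profiles.index)
    n = len(names)
    D = np.zeros((n, n))
    vals = profiles.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if np.all(vals[i] == vals[i][0]) or np.all(vals[j] == vals[j][0]):
                logger.warning("constant profile row: Spearman undefined, "
                               "distance set to 1")
                d = 1.0
            else:
                rho = scipy.stats.spearmanr(vals[i], vals[j]).statistic
                d = 1.0 - rho
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=names, columns=names)


def cluster_presence_profiles(profiles: pd.DataFrame,
                              ) -> tuple[np.ndarray, list[str], str]:
    """Ward clustering of node presence profiles on Spearman distances."""
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 profiles to cluster")
    from .synteny import linkage_to_newick
    order = sorted(profiles.index)
    D = spearman_distance_matrix(profiles.loc[order])
    condensed = D.values[np.triu_indices(len(order), k=1)]
    Z = sch.linkage(condensed, method="ward")
    leaves = [order[i] for i in sch.leaves_list(Z)]
    return Z, leaves, linkage_to_newick(Z, order)


# ---------------------------------------------------------------------------
# Phylostratigraphy
# ---------------------------------------------------------------------------

def assign_site_ages(recon: AncestralReconstruction, focal_species: str,
                     threshold: float = 0.5) -> pd.Series:
    """'recent' if the site's gain localises to the focal terminal branch.

    A site is recent when the posterior probability of a gain on the focal
    species' terminal branch exceeds ``threshold``; otherwise ancestral.
    """
    gp = recon.gain_posterior[focal_species]
    return pd.Series(np.where(gp > threshold, "recent", "ancestral"),
                     index=recon.gain_posterior.index)


def regulatory_overlap(introns: pd.DataFrame, intervals: pd.DataFrame,
                       overlap_fraction: float = 0.5) -> pd.Series:
    """Flag introns overlapped by a regulatory interval.

    ``introns``: chrom, start, end (0-based half-open) indexed by intron id;
    ``intervals``: BED-style chrom, start, end.  An intron bears a site iff
    some interval overlaps it by at least ``overlap_fraction`` of the
    interval's own length.
    """
    flags = pd.Series(False, index=introns.index)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in intervals.iterrows():
        by_chrom.setdefault(str(row["chrom"]), []).append(
            (int(row["start"]), int(row["end"])))
    for iid, row in introns.iterrows():
        for s, e in by_chrom.get(str(row["chrom"]), []):
            ov = min(e, int(row["end"])) - max(s, int(row["start"]))
            if e > s and ov >= overlap_fraction * (e - s):
                flags[iid] = True
                break
    return flags


def phylostratigraphy_table(ages: pd.Series, has_regulatory: pd.Series
                            ) -> np.ndarray:
    """2x2 counts: rows recent/ancestral, columns without/with sites."""
    table = np.array([
        [int(((ages == "recent") & ~has_regulatory).sum()),
         int(((ages == "recent") & has_regulatory).sum())],
        [int(((ages == "ancestral") & ~has_regulatory).sum()),
         int(((ages == "ancestral") & has_regulatory).sum())],
    ])
    if table.sum(axis=1).min() == 0:
        raise ValueError("empty age class in phylostratigraphy table")
    return table


def phylostratigraphy_test(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact test on the recent/ancestral x sites table."""
    odds, p = scipy.stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)
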