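import itertools

import numpy as np
import pytest

from genarch.io_formats import SpeciesTree

BALANCED8 = ("(((A:1,B:1)N1:1,(C:1,D:1)N2:1)N3:1,"
             "((E:1,F:1)N4:1,(G:1,H:1)N5:1)N6:1)R;")
QUARTET = "((A:1,B:1)N1:1,(C:1,D:1)N2:1)R;"
TRIPLET = "((A:1,B:1)N1:1,C:2)R;"
STAR8 = "(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1)R;"


@pytest.fixture
def balanced8():
    return SpeciesTree.from_newick(BALANCED8)


@pytest.fixture
def quartet():
    return SpeciesTree.from_newick(QUARTET)


@pytest.fixture
def triplet():
    return SpeciesTree.from_newick(TRIPLET)


@pytest.fixture
def star8():
    return SpeciesTree.from_newick(STAR8)


def brute_force_posteriors(matrix, tree, fit):
    """Independent enumeration oracle for node and branch-event posteriors.

    Enumerates every assignment of states to internal nodes and missing
    leaves; returns (node posterior, gain posterior, loss posterior) arrays
    of shape (n_sites, n_nodes) in the tree's postorder node order.
    """
    from genarch.synthetic_data import transition_probs
    idx = tree.index()
    g, l = fit.rate_arrays(idx)
    P = [transition_probs(g[i], l[i], idx.edge_length[i])
         if idx.parent[i] != -1 else np.eye(2) for i in range(idx.n_nodes)]
    pi = [1 - fit.root_prior, fit.root_prior]
    leaf_order = [nm for nm in idx.names if nm in idx.leaf_indices]
    n_sites = matrix.shape[0]
    post = np.zeros((n_sites, idx.n_nodes))
    gain = np.zeros((n_sites, idx.n_nodes))
    loss = np.zeros((n_sites, idx.n_nodes))
    for s in range(n_sites):
        obs = {}
        for nm in leaf_order:
            v = matrix.iloc[s][nm]
            if not np.isnan(v):
                obs[idx.leaf_indices[nm]] = int(v)
        free = [i for i in range(idx.n_nodes) if i not in obs]
        z = 0.0
        acc_post = np.zeros(idx.n_nodes)
        acc_gain = np.zeros(idx.n_nodes)
        acc_loss = np.zeros(idx.n_nodes)
        for assign in itertools.product((0, 1), repeat=len(free)):
            state = dict(obs)
            state.update(dict(zip(free, assign)))
            w = pi[state[idx.root]]
            for i in range(idx.n_nodes - 1):
                w *= P[i][state[idx.parent[i]], state[i]]
            z += w
            for i in range(idx.n_nodes):
                if state[i]:
                    acc_post[i] += w
                if idx.parent[i] != -1:
                    ps, cs = state[idx.parent[i]], state[i]
                    if ps == 0 and cs == 1:
                        acc_gain[i] += w
                    elif ps == 1 and cs == 0:
                        acc_loss[i] += w
        post[s] = acc_post / z
        gain[s] = acc_gain / z
        loss[s] = acc_loss / z
    return post, gain, loss
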