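import itertools

import numpy as np
import pytest

import nodulemap as nm
from nodulemap.treedata_io import Chronogram, TipObservations


@pytest.fixture
def three_tip_tree():
    return nm.read_chronogram("((A:1,B:1):1,C:2);")


@pytest.fixture
def default_model():
    return nm.build_rate_matrix(
        {"FT->NON": 0.0174, "FT->SYM": 0.01, "SYM->NON": 0.0028}
    )


def single_branch_tree(t1: float, t2: float) -> Chronogram:
    """A two-tip cherry with pendant branch lengths t1, t2 (built directly)."""
    return Chronogram(
        parent=np.array([-1, 0, 0]),
        children=[[1, 2], [], []],
        branch_length=np.array([0.0, t1, t2]),
        labels=["root", "X", "Y"],
        is_tip=np.array([False, True, True]),
    )


def enumeration_loglik(tree, obs, model) -> float:
    """Brute-force likelihood: sum over all internal-node state assignments.

    Independent of the pruning recursion; tips are integrated against their
    observation vectors.
    """
    P = [model.transition_matrix(float(tree.branch_length[i])) for i in range(tree.n_nodes)]
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip[i]]
    tipvec = {int(i): obs.vector(tree.labels[i]) for i in tree.tip_indices}
    total = 0.0
    for assign in itertools.product(range(3), repeat=len(internals)):
        st = dict(zip(internals, assign))
        p = float(model.root_prior[st[0]])
        for c in range(1, tree.n_nodes):
            par = st[tree.parent[c]]
            if tree.is_tip[c]:
                p *= float(P[c][par] @ tipvec[c])
            else:
                p *= float(P[c][par, st[c]])
        total += p
    return np.log(total) if total > 0 else -np.inf


def enumeration_node_marginals(tree, obs, model) -> np.ndarray:
    """Exact joint-posterior node-state marginals by full enumeration."""
    P = [model.transition_matrix(float(tree.branch_length[i])) for i in range(tree.n_nodes)]
    tipvec = {int(i): obs.vector(tree.labels[i]) for i in tree.tip_indices}
    n = tree.n_nodes
    marg = np.zeros((n, 3))
    for assign in itertools.product(range(3), repeat=n):
        p = float(model.root_prior[assign[0]])
        for c in range(1, n):
            p *= float(P[c][assign[tree.parent[c]], assign[c]])
        for i in tree.tip_indices:
            p *= float(tipvec[int(i)][assign[i]])
        for i in range(n):
            marg[i, assign[i]] += p
    return marg / marg[0].sum()


def random_tree_and_obs(rng, n_tips=None, mask=None, rate_scale=0.5):
    """Random small tree + random categories + random allowed-rate model."""
    cats = ["nonnodulating", "ft", "sym", "nodulating_unknown_type", "unknown"]
    n = int(rng.integers(2, 7)) if n_tips is None else n_tips
    tree = nm.simulate_chronogram(n, 0.5, 0.0, seed=int(rng.integers(2**31)))
    if mask is None:
        mask = nm.constrained_mask() if rng.random() < 0.5 else nm.all_transitions_mask()
    rates = {
        (i, j): float(rng.uniform(0, rate_scale))
        for i in range(3)
        for j in range(3)
        if mask[i, j]
    }
    prior = np.array([0.0, 1.0, 0.0]) if rng.random() < 0.5 else np.full(3, 1 / 3)
    model = nm.build_rate_matrix(rates, mask, prior)
    obs = TipObservations({lab: cats[rng.integers(5)] for lab in tree.tip_labels})
    return tree, obs, model
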