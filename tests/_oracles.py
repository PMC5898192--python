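"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or
direct simulation, independent of the package's implementations.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np

from paleomem.ancestral import GainLossModel, TreeIndex


def random_binary_tree(
    n_leaves: int, rng: np.random.Generator, min_bl: float = 0.05,
    max_bl: float = 2.0,
) -> dendropy.Tree:
    """Random rooted bifurcating tree with uniform branch lengths."""
    ns = dendropy.TaxonNamespace([f"T{i}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    nodes = [dendropy.Node(taxon=ns.get_taxon(f"T{i}")) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            child.edge.length = float(rng.uniform(min_bl, max_bl))
            parent.add_child(child)
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    return tree


def enumeration_loglik(
    idx: TreeIndex, pattern, model: GainLossModel
) -> float:
    """Log-likelihood by summing over all internal-state assignments."""
    internal = [i for i in range(len(idx.nodes)) if idx.children[i]]
    leaf_state = dict(zip(idx.leaf_indices, (int(s) for s in pattern)))
    prior = model.root_prior
    total = 0.0
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(leaf_state)
        p = prior[st[idx.root_index]]
        for i in range(len(idx.nodes)):
            if i == idx.root_index:
                continue
            P = model.transition_matrix(idx.branch_lengths[i])
            p *= P[st[idx.parent[i]], st[i]]
        total += p
    return float(np.log(total))


def enumeration_root_posterior(
    idx: TreeIndex, pattern, model: GainLossModel
) -> float:
    """Root posterior by enumeration: restrict the sum to root state 1."""
    internal = [i for i in range(len(idx.nodes)) if idx.children[i]]
    leaf_state = dict(zip(idx.leaf_indices, (int(s) for s in pattern)))
    prior = model.root_prior
    by_root = [0.0, 0.0]
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(leaf_state)
        p = prior[st[idx.root_index]]
        for i in range(len(idx.nodes)):
            if i == idx.root_index:
                continue
            P = model.transition_matrix(idx.branch_lengths[i])
            p *= P[st[idx.parent[i]], st[i]]
        by_root[st[idx.root_index]] += p
    return by_root[1] / (by_root[0] + by_root[1])


def dollo_minimum_change(idx: TreeIndex, pattern) -> tuple[bool, int]:
    """Minimum-loss reconstruction constrained to a single gain.

    Enumerates all internal-state assignments, keeps those with exactly
    one gain (a 0->1 edge, or presence at the root), and returns the
    root state and loss count of the loss-minimal one.
    """
    internal = [i for i in range(len(idx.nodes)) if idx.children[i]]
    leaf_state = dict(zip(idx.leaf_indices, (int(s) for s in pattern)))
    if sum(leaf_state.values()) == 0:
        return False, 0
    best: tuple[int, bool] | None = None
    for assign in itertools.product((0, 1), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(leaf_state)
        gains = 1 if st[idx.root_index] == 1 else 0
        losses = 0
        for i in range(len(idx.nodes)):
            if i == idx.root_index:
                continue
            a, b = st[idx.parent[i]], st[i]
            gains += (a, b) == (0, 1)
            losses += (a, b) == (1, 0)
        if gains != 1:
            continue
        if best is None or losses < best[0]:
            best = (losses, st[idx.root_index] == 1)
    assert best is not None
    return best[1], best[0]


def match_segments(
    predicted, planted, min_overlap: int = 10
) -> tuple[int, int, int]:
    """(true positives, false positives, false negatives) for segment sets.

    A predicted segment is correct when it overlaps a planted span by at
    least ``min_overlap`` residues.
    """
    matched_pred: set[int] = set()
    matched_true: set[int] = set()
    for i, seg in enumerate(predicted):
        for j, (a, b) in enumerate(planted):
            if min(seg.end, b) - max(seg.start, a) >= min_overlap:
                matched_pred.add(i)
                matched_true.add(j)
    tp = len(matched_true)
    return tp, len(predicted) - len(matched_pred), len(planted) - tp
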