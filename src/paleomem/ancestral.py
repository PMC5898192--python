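"""Ancestral gene-content projection onto the root of a species tree.

Two complementary calls are made for every family's phyletic pattern:

* a Dollo parsimony call -- a single gain placed at the most recent
  common ancestor of all genomes carrying the family, with unlimited
  losses below it; the family is root-present iff that ancestor is the
  root;
* a probabilistic call under a two-state (absent/present)
  continuous-time Markov chain with global gain rate g and loss rate l.
  Conditional likelihoods are computed by Felsenstein's pruning
  algorithm, the root is combined with a prior (stationary by default),
  and the family "projects" to the ancestor when the posterior
  probability of presence at the root reaches a threshold (default 0.9).

The transition probabilities over a branch of length t are
P(0->1) = g/(g+l) * (1 - exp(-(g+l) t)) and
P(1->0) = l/(g+l) * (1 - exp(-(g+l) t)).

Rates are fitted by maximizing the summed log-likelihood over families
with a deterministic grid-plus-golden-section coordinate ascent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_formats import SpeciesTree
from .phyletic import PhyleticMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GainLossModel:
    """Two-state gain/loss CTMC with a root prior for presence.

    ``root_p1`` of ``None`` means the stationary probability
    g / (g + l). Rates are per unit branch length.
    """

    gain: float
    loss: float
    root_p1: float | None = None

    def __post_init__(self) -> None:
        if self.gain < 0 or self.loss < 0:
            raise ValueError("rates must be non-negative")
        if self.gain + self.loss <= 0:
            raise ValueError("degenerate model: gain + loss must be positive")
        if self.root_p1 is not None and not (0.0 <= self.root_p1 <= 1.0):
            raise ValueError("root_p1 must lie in [0, 1]")

    @property
    def stationary_p1(self) -> float:
        return self.gain / (self.gain + self.loss)

    @property
    def root_prior(self) -> np.ndarray:
        p1 = self.stationary_p1 if self.root_p1 is None else self.root_p1
        return np.array([1.0 - p1, p1])

    def transition_matrix(self, t: float) -> np.ndarray:
        """Stochastic matrix P[s_from, s_to] over a branch of length t."""
        r = self.gain + self.loss
        f = 1.0 - np.exp(-r * t)
        p01 = self.gain / r * f
        p10 = self.loss / r * f
        return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


class TreeIndex:
    """Postorder array view of a rooted dendropy tree for vectorized work."""

    def __init__(self, tree: dendropy.Tree | SpeciesTree):
        if isinstance(tree, SpeciesTree):
            tree = tree.tree
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.root_index = self.index[id(tree.seed_node)]
        self.parent = np.full(len(self.nodes), -1, dtype=int)
        self.branch_lengths = np.ones(len(self.nodes))
        self.children: list[list[int]] = [[] for _ in self.nodes]
        n_defaulted = 0
        for i, node in enumerate(self.nodes):
            if node.parent_node is not None:
                self.parent[i] = self.index[id(node.parent_node)]
                self.children[self.parent[i]].append(i)
                if node.edge.length is None:
                    n_defaulted += 1
                else:
                    self.branch_lengths[i] = node.edge.length
        if n_defaulted:
            logger.info("%d branch lengths missing; defaulted to 1.0", n_defaulted)
        self.leaf_indices = [
            i for i, n in enumerate(self.nodes) if n.is_leaf()
        ]
        self.leaf_labels = [self.nodes[i].taxon.label for i in self.leaf_indices]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    def pattern_array(
        self, pattern: Mapping[str, int] | Sequence[int]
    ) -> np.ndarray:
        """Coerce a genome->state mapping (or leaf-ordered sequence) to an
        array in this index's leaf order."""
        if isinstance(pattern, Mapping):
            missing = [lb for lb in self.leaf_labels if lb not in pattern]
            if missing:
                raise ValueError(f"pattern does not cover leaves: {missing}")
            return np.array([int(pattern[lb]) for lb in self.leaf_labels])
        arr = np.asarray(pattern, dtype=int)
        if arr.shape[-1] != self.n_leaves:
            raise ValueError(
                f"pattern length {arr.shape[-1]} != {self.n_leaves} leaves"
            )
        return arr


def _as_index(tree) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex(tree)


def dollo_root_presence(
    pattern: Mapping[str, int] | Sequence[int],
    tree: dendropy.Tree | SpeciesTree | TreeIndex,
) -> tuple[bool, int]:
    """Dollo parsimony call for one phyletic pattern.

    The single gain is placed at the MRCA of all present leaves;
    ``root_present`` iff that node is the root. ``n_losses`` counts the
    maximal subtrees under the gain node that contain no present leaf.
    All-absent patterns return ``(False, 0)``.
    """
    idx = _as_index(tree)
    states = idx.pattern_array(pattern)
    n_nodes = len(idx.nodes)
    has_present = np.zeros(n_nodes, dtype=bool)
    for leaf_i, state in zip(idx.leaf_indices, states):
        has_present[leaf_i] = bool(state)
    for i in range(n_nodes):  # postorder: children precede parents
        for c in idx.children[i]:
            has_present[i] |= has_present[c]
    if not has_present[idx.root_index]:
        return False, 0
    # gain node = MRCA of present leaves: walk root-ward from any present
    # leaf to the shallowest node below which *all* present leaves sit.
    count = np.zeros(n_nodes, dtype=int)
    for i in range(n_nodes):
        if not idx.children[i]:
            count[i] = int(has_present[i])
        else:
            count[i] = sum(count[c] for c in idx.children[i])
    start = next(
        leaf_i
        for leaf_i, state in zip(idx.leaf_indices, states)
        if state
    )
    gain = start
    while count[gain] < count[idx.leaf_indices].sum():
        gain = idx.parent[gain]
    # losses: edges from a present-bearing node to an empty child subtree,
    # within the gain node's clade.
    n_losses = 0
    stack = [gain]
    while stack:
        node = stack.pop()
        for c in idx.children[node]:
            if has_present[c]:
                stack.append(c)
            else:
                n_losses += 1
    return gain == idx.root_index, n_losses


def _root_conditionals(
    patterns: np.ndarray, idx: TreeIndex, model: GainLossModel
) -> np.ndarray:
    """Conditional likelihoods at the root, shape (n_families, 2).

    ``patterns`` is (n_families, n_leaves) of 0/1 leaf states in the
    index's leaf order.
    """
    patterns = np.atleast_2d(patterns)
    n_fam = patterns.shape[0]
    n_nodes = len(idx.nodes)
    cond = np.ones((n_fam, n_nodes, 2))
    for col, leaf_i in enumerate(idx.leaf_indices):
        cond[:, leaf_i, 0] = patterns[:, col] == 0
        cond[:, leaf_i, 1] = patterns[:, col] == 1
    for i in range(n_nodes):
        if not idx.children[i]:
            continue
        acc = np.ones((n_fam, 2))
        for c in idx.children[i]:
            P = model.transition_matrix(idx.branch_lengths[c])
            acc *= cond[:, c, :] @ P.T
        cond[:, i, :] = acc
    return cond[:, idx.root_index, :]


def pruning_loglik(
    pattern: Mapping[str, int] | Sequence[int] | np.ndarray,
    tree: dendropy.Tree | SpeciesTree | TreeIndex,
    model: GainLossModel,
) -> float | np.ndarray:
    """Log-likelihood of one pattern (or a stack of patterns) by pruning."""
    idx = _as_index(tree)
    arr = idx.pattern_array(pattern) if not isinstance(pattern, np.ndarray) else pattern
    arr = np.atleast_2d(np.asarray(arr, dtype=int))
    root_cond = _root_conditionals(arr, idx, model)
    lik = root_cond @ model.root_prior
    out = np.log(lik)
    return float(out[0]) if out.shape[0] == 1 and arr.shape[0] == 1 else out


def root_posterior(
    pattern: Mapping[str, int] | Sequence[int] | np.ndarray,
    tree: dendropy.Tree | SpeciesTree | TreeIndex,
    model: GainLossModel,
) -> float | np.ndarray:
    """Posterior probability of presence at the root given a pattern."""
    idx = _as_index(tree)
    arr = idx.pattern_array(pattern) if not isinstance(pattern, np.ndarray) else pattern
    arr = np.atleast_2d(np.asarray(arr, dtype=int))
    root_cond = _root_conditionals(arr, idx, model)
    prior = model.root_prior
    num = prior[1] * root_cond[:, 1]
    den = prior[0] * root_cond[:, 0] + prior[1] * root_cond[:, 1]
    post = num / den
    return float(post[0]) if arr.shape[0] == 1 else post


class RateFitError(RuntimeError):
    """Raised when coordinate ascent fails to converge; carries the trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message + f"; trace: {trace}")
        self.trace = trace


def fit_rates(
    matrix: PhyleticMatrix,
    tree: dendropy.Tree | SpeciesTree | TreeIndex,
    grid: np.ndarray | None = None,
    max_cycles: int = 12,
    tol: float = 1e-4,
) -> GainLossModel:
    """Fit global (gain, loss) by maximum likelihood over all families.

    Coordinate ascent: each rate in turn is optimized on a log-spaced
    grid and refined by bounded scalar minimization in log-space, until
    the summed log-likelihood improves by less than ``tol``. The root
    prior is set to the stationary distribution of the fitted rates.
    Deterministic given inputs; raises :class:`RateFitError` with the
    ascent trace on non-convergence.
    """
    idx = _as_index(tree)
    presence = matrix.presence()
    if presence.shape[0] < 10:
        raise ValueError(
            f"need at least 10 families to fit rates, got {presence.shape[0]}"
        )
    patterns = presence[idx.leaf_labels].to_numpy().astype(int)
    if grid is None:
        grid = np.logspace(-3, 1, 25)
    log_lo, log_hi = np.log(grid[0]), np.log(grid[-1])

    def objective(g: float, l: float) -> float:
        model = GainLossModel(g, l)
        return float(np.sum(pruning_loglik(patterns, idx, model)))

    g, l = 0.5, 0.5
    best = objective(g, l)
    trace: list[tuple[float, float, float]] = [(g, l, best)]
    converged = False
    for _ in range(max_cycles):
        prev = best
        for coord in ("gain", "loss"):
            def neg(logx: float) -> float:
                x = float(np.exp(logx))
                return -(objective(x, l) if coord == "gain" else objective(g, x))

            grid_vals = [neg(np.log(x)) for x in grid]
            k = int(np.argmin(grid_vals))
            lo = np.log(grid[max(0, k - 1)])
            hi = np.log(grid[min(len(grid) - 1, k + 1)])
            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded")
            x = float(np.exp(res.x))
            if coord == "gain":
                g = x
            else:
                l = x
            best = -float(res.fun)
        trace.append((g, l, best))
        if abs(best - prev) < tol:
            converged = True
            break
    if not converged:
        raise RateFitError(
            f"rate fit did not converge in {max_cycles} cycles", trace
        )
    logger.info("fitted gain=%.4g loss=%.4g loglik=%.2f", g, l, best)
    return GainLossModel(g, l)


def project_to_ancestor(
    matrix: PhyleticMatrix,
    tree: dendropy.Tree | SpeciesTree | TreeIndex,
    model: GainLossModel | None = None,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Project every family to the root ancestor.

    Returns a DataFrame indexed by family with columns
    ``dollo_root_present``, ``n_losses``, ``root_posterior``, ``loglik``
    and ``projected`` (posterior >= threshold). ``model`` defaults to
    rates fitted on the matrix itself.
    """
    idx = _as_index(tree)
    if model is None:
        model = fit_rates(matrix, idx)
    presence = matrix.presence()
    patterns = presence[idx.leaf_labels].to_numpy().astype(int)
    posts = np.atleast_1d(root_posterior(patterns, idx, model))
    logliks = np.atleast_1d(pruning_loglik(patterns, idx, model))
    dollo = [dollo_root_presence(p, idx) for p in patterns]
    df = pd.DataFrame(
        {
            "dollo_root_present": [d[0] for d in dollo],
            "n_losses": [d[1] for d in dollo],
            "root_posterior": posts,
            "loglik": logliks,
            "projected": posts >= threshold,
        },
        index=pd.Index(matrix.families, name="family"),
    )
    df.attrs["model"] = model
    df.attrs["threshold"] = threshold
    return df
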