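"""Felsenstein pruning over the joint 4-state chain (and 2-state chains).

Trees are flattened once into index arrays (postorder, children lists,
branch lengths); the pruning pass is then pure numpy with per-node
rescaling, so the same tree can be re-scored cheaply inside MCMC.
Polytomies are handled directly (a node may have any number of
children); resolving them with zero-length branches would give the same
likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .data import MISSING, BinaryTraitMatrix
from .model import PagelModel, STATES, branch_probabilities, build_rate_matrix


@dataclass
class TreeTable:
    """Flattened rooted tree: level-ordered node arrays for fast pruning.

    Nodes are grouped into levels (tips at level 0, a parent one level
    above its deepest child); within each level the partial-times-
    transition "messages" of every node are computed in one batched
    einsum and multiplied into the parents, so a full pruning pass is a
    handful of numpy calls regardless of tree size.
    """

    postorder: np.ndarray          # node indices in postorder (root last)
    children: list[list[int]]      # per node, child indices
    parent: np.ndarray             # parent index per node (root: -1)
    levels: list[np.ndarray]       # node indices grouped by level
    lengths: np.ndarray            # branch length above each node (root: 0)
    tip_index: dict                # taxon label -> node index
    n_nodes: int

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "TreeTable":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        children: list[list[int]] = [[] for _ in nodes]
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        tip_index: dict = {}
        for nd in nodes:
            i = index[id(nd)]
            lengths[i] = nd.edge.length or 0.0
            for ch in nd.child_nodes():
                j = index[id(ch)]
                children[i].append(j)
                parent[j] = i
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon else None
                if label is None:
                    raise ValueError("tip without a taxon label")
                if label in tip_index:
                    raise ValueError(f"duplicate tip label {label!r}")
                tip_index[label] = i
        post = [index[id(nd)] for nd in tree.postorder_node_iter()]
        level = np.zeros(len(nodes), dtype=int)
        for i in post:
            if children[i]:
                level[i] = 1 + max(level[c] for c in children[i])
        levels = [np.flatnonzero(level == k) for k in range(level.max() + 1)]
        return cls(postorder=np.array(post), children=children, parent=parent,
                   levels=levels, lengths=lengths, tip_index=tip_index,
                   n_nodes=len(nodes))

    @property
    def tip_labels(self) -> list[str]:
        return list(self.tip_index)


def _prune(table: TreeTable, P: np.ndarray, partials: np.ndarray,
           root_prior: np.ndarray) -> float:
    """Level-batched pruning pass; returns the log-likelihood.

    ``P[i]`` is the transition matrix on the branch above node i,
    ``partials[i]`` the tip partial (ones for internal nodes).
    """
    L = partials.copy()
    logscale = 0.0
    root = table.postorder[-1]
    for k, nodes in enumerate(table.levels):
        # rescale completed nodes to avoid underflow
        s = L[nodes].max(axis=1)
        if np.any(s <= 0.0):
            return -np.inf
        L[nodes] /= s[:, None]
        logscale += float(np.log(s).sum())
        senders = nodes[table.parent[nodes] >= 0]
        if senders.size == 0:
            continue
        msg = np.einsum("nij,nj->ni", P[senders], L[senders])
        np.multiply.at(L, table.parent[senders], msg)
    like = float(root_prior @ L[root])
    if like <= 0.0:
        return -np.inf
    return float(np.log(like) + logscale)


def _tip_partials_joint(table: TreeTable, data: BinaryTraitMatrix) -> np.ndarray:
    labels = list(table.tip_index)
    missing_rows = set(labels) - set(data.data.index)
    if missing_rows:
        raise ValueError(f"tip {sorted(missing_rows)[0]!r} has no trait row")
    df = data.data.loc[labels]
    idx = np.array([table.tip_index[sp] for sp in labels])
    d = df["D"].to_numpy(dtype=int)
    e = df["E"].to_numpy(dtype=int)
    partials = np.ones((table.n_nodes, 4))
    sd = np.array([s[0] for s in STATES])
    se = np.array([s[1] for s in STATES])
    mask = (((d[:, None] == MISSING) | (d[:, None] == sd[None, :]))
            & ((e[:, None] == MISSING) | (e[:, None] == se[None, :])))
    partials[idx] = mask.astype(float)
    return partials


def log_likelihood(
    table: TreeTable | dendropy.Tree,
    data: BinaryTraitMatrix,
    model: PagelModel,
    root_prior: str | np.ndarray = "uniform",
    partials: np.ndarray | None = None,
) -> float:
    """Pruning log-likelihood of the joint 4-state model.

    ``root_prior`` may be "uniform" (default), "stationary", or an
    explicit 4-vector.  Precomputed tip ``partials`` can be supplied to
    skip rebuilding them (MCMC re-scores the same data thousands of
    times).
    """
    if isinstance(table, dendropy.Tree):
        table = TreeTable.from_dendropy(table)
    Q = build_rate_matrix(model)
    P = branch_probabilities(Q, table.lengths)
    if partials is None:
        partials = _tip_partials_joint(table, data)
    prior = _root_prior(root_prior, Q)
    return _prune(table, P, partials, prior)


def _root_prior(spec, Q) -> np.ndarray:
    n = Q.shape[0]
    if isinstance(spec, str):
        if spec == "uniform":
            return np.full(n, 1.0 / n)
        if spec == "stationary":
            w, v = np.linalg.eig(Q.T)
            k = int(np.argmin(np.abs(w)))
            pi = np.real(v[:, k])
            pi = np.abs(pi)
            return pi / pi.sum()
        raise ValueError(f"unknown root prior {spec!r}")
    arr = np.asarray(spec, dtype=float)
    if arr.shape != (n,) or arr.min() < 0 or arr.sum() <= 0:
        raise ValueError("root prior must be a nonnegative vector")
    return arr / arr.sum()


def log_likelihood_single_trait(
    table: TreeTable | dendropy.Tree,
    states: dict,
    q01: float,
    q10: float,
    root_prior: str | np.ndarray = "uniform",
) -> float:
    """2-state pruning likelihood of one binary trait (gain rate q01,
    loss rate q10); ``states`` maps tip label -> 0/1/MISSING."""
    if isinstance(table, dendropy.Tree):
        table = TreeTable.from_dendropy(table)
    Q = np.array([[-q01, q01], [q10, -q10]])
    P = branch_probabilities(Q, table.lengths)
    partials = np.ones((table.n_nodes, 2))
    for sp, i in table.tip_index.items():
        s = states[sp]
        if s != MISSING:
            partials[i] = 0.0
            partials[i, int(s)] = 1.0
    prior = _root_prior(root_prior, Q)
    return _prune(table, P, partials, prior)
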