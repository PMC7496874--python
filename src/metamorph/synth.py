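"""Synthetic inputs: Yule trees, discrete traits evolved along them, and
the packaged bioenergetic parameter presets.

These generators stand in for the empirical inputs of the original
analyses (a dated amphibian phylogeny and a life-history trait database,
which are not redistributed here).  Trees are pure-birth (Yule) and
ultrametric; traits evolve by exact Gillespie simulation of the joint
4-state chain down each branch, so dual transitions never occur by
construction; missingness is applied per trait per tip to emulate the
partial coverage of real trait compilations (for amphibians,
developmental mode is known for roughly 79% of species with
phylogenetic data, egg size for only about 28%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .params import BioenergeticParams, load_preset
from .phylo.data import MISSING, BinaryTraitMatrix
from .phylo.model import PagelModel, STATES, build_rate_matrix


@dataclass
class TreeSimConfig:
    n_tips: int = 100
    birth_rate: float = 0.03          # speciations per lineage per Myr
    seed: int = 1
    target_root_age: float | None = None   # rescale tree depth to this (Myr)

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("a tree needs at least 2 tips")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")


@dataclass
class TraitSimConfig:
    model: PagelModel = field(
        default_factory=lambda: PagelModel("dependent", (0.005,) * 8))
    root_state: tuple | None = None   # joint (D, E) state; None -> uniform draw
    missing_D: float = 0.21
    missing_E: float = 0.72
    seed: int = 1

    def __post_init__(self) -> None:
        for frac in (self.missing_D, self.missing_E):
            if not (0.0 <= frac < 1.0):
                raise ValueError("missingness fractions must lie in [0, 1)")


def simulate_yule_tree(config: TreeSimConfig) -> dendropy.Tree:
    """Ultrametric pure-birth tree with ``n_tips`` extant tips.

    Lineages split at rate ``birth_rate`` each; the returned tree is
    optionally rescaled so the root age equals ``target_root_age``.
    Reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # start from the root split: two live lineages
    live = [tree.seed_node.new_child(), tree.seed_node.new_child()]
    depth = {id(tree.seed_node): 0.0}
    t = 0.0
    while len(live) < config.n_tips:
        k = len(live)
        t += rng.exponential(1.0 / (config.birth_rate * k))
        nd = live.pop(rng.integers(k))
        depth[id(nd)] = t
        live.extend((nd.new_child(), nd.new_child()))
    # final waiting time so tip branches are not zero
    t += rng.exponential(1.0 / (config.birth_rate * len(live)))
    for i, nd in enumerate(live):
        depth[id(nd)] = t
        nd.taxon = taxa.new_taxon(label=f"t{i + 1}")
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = depth[id(nd)] - depth[id(nd.parent_node)]
        else:
            nd.edge.length = 0.0
    if config.target_root_age is not None:
        scale = config.target_root_age / t
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                e.length *= scale
    return tree


def simulate_discrete_traits(
    tree: dendropy.Tree,
    config: TraitSimConfig,
    return_events: bool = False,
):
    """Evolve the joint (D, E) chain down the tree by Gillespie simulation.

    Each event changes exactly one trait (the generator has structural
    zeros on dual transitions).  Missingness is applied independently per
    trait per tip.  Reproducible given the seed.  With ``return_events``
    the (from_state, to_state) log of every substitution is returned too.
    """
    rng = np.random.default_rng(config.seed)
    Q = build_rate_matrix(config.model)
    exit_rates = -np.diag(Q)
    if config.root_state is None:
        root = int(rng.integers(4))
    else:
        root = STATES.index(tuple(config.root_state))

    state: dict = {id(tree.seed_node): root}
    events: list[tuple[int, int]] = []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        s = state[id(nd.parent_node)]
        remaining = nd.edge.length or 0.0
        while True:
            rate = exit_rates[s]
            if rate <= 0.0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait > remaining:
                break
            remaining -= wait
            probs = Q[s].clip(min=0.0)
            probs[s] = 0.0
            s_new = int(rng.choice(4, p=probs / probs.sum()))
            events.append((s, s_new))
            s = s_new
        state[id(nd)] = s

    D, E = {}, {}
    for leaf in tree.leaf_node_iter():
        d, e = STATES[state[id(leaf)]]
        label = leaf.taxon.label
        D[label] = MISSING if rng.random() < config.missing_D else d
        E[label] = MISSING if rng.random() < config.missing_E else e
    data = BinaryTraitMatrix.from_dicts(D, E)
    if return_events:
        return data, events
    return data


def make_preset(name: str) -> BioenergeticParams:
    """Return a packaged bioenergetic parameter preset by name."""
    return load_preset(name)
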