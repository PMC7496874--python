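"""Metropolis-Hastings sampling of transition rates.

The prior is hierarchical: every free rate is exponential with a common
mean m, and the hypermean itself is uniform on (0, 100) (a fixed-
dimension stand-in for BayesTraits' reversible-jump hyperprior; the
rate-grouping moves are an extension point, not implemented).  Proposals
are log-normal multiplicative steps on one rate at a time (plus the
hypermean), with the proposal scale adapted during burn-in only.

The sampler targets power posteriors prior * likelihood**beta, which
makes it reusable for stepping-stone marginal-likelihood estimation
(beta = 1 is the ordinary posterior; beta = 0 samples the prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import TreeTable, log_likelihood
from .model import N_FREE, PagelModel

HYPERMEAN_MAX = 100.0


@dataclass
class ChainConfig:
    generations: int = 100_000
    burnin_fraction: float = 0.1
    thin: int = 20
    proposal_scale: float = 0.8
    adapt: bool = True


@dataclass
class ChainResult:
    samples: np.ndarray            # (n_kept, n_free) rate draws
    hypermean: np.ndarray          # (n_kept,) hypermean draws
    log_likelihoods: np.ndarray    # (n_kept,)
    acceptance: float
    seed: int


class PagelPosterior:
    """Posterior (or power posterior) of a Pagel model on one dataset."""

    def __init__(self, kind: str, table: TreeTable, data, root_prior="uniform"):
        from .likelihood import _tip_partials_joint

        self.kind = kind
        self.n_free = N_FREE[kind]
        self.table = table
        self.data = data
        self.root_prior = root_prior
        self._partials = _tip_partials_joint(table, data)

    # --- model interface used by the generic sampler -------------------
    def init_params(self, rng) -> np.ndarray:
        # start at slow-rate scales (a few transitions over a typical tree);
        # the likelihood has a wide saturation plateau at fast rates that a
        # chain initialized there can take long to leave
        m = rng.uniform(0.001, 0.05)
        return np.concatenate([rng.exponential(m, self.n_free), [m]])

    def log_prior(self, params: np.ndarray) -> float:
        rates, m = params[:-1], params[-1]
        if m <= 0.0 or m >= HYPERMEAN_MAX or np.any(rates < 0):
            return -np.inf
        return float(-self.n_free * np.log(m) - rates.sum() / m)

    def log_likelihood(self, params: np.ndarray) -> float:
        model = PagelModel(self.kind, tuple(params[:-1]))
        return log_likelihood(self.table, self.data, model, self.root_prior,
                              partials=self._partials)

    def propose(self, params: np.ndarray, rng, scale: float):
        """Log-normal multiplier moves: usually one coordinate, sometimes
        all rates together (crosses the fast-rate likelihood plateau);
        returns (proposal, log Hastings ratio)."""
        out = params.copy()
        factor = np.exp(scale * (rng.random() - 0.5))
        if rng.random() < 0.15:
            out[:-1] = params[:-1] * factor
            return out, self.n_free * np.log(factor)
        i = rng.integers(params.size)
        out[i] = params[i] * factor
        return out, np.log(factor)


def run_chain(model, config: ChainConfig, seed: int, beta: float = 1.0,
              init: np.ndarray | None = None) -> ChainResult:
    """Generic MH chain on a model object with the interface above."""
    rng = np.random.default_rng(seed)
    params = model.init_params(rng) if init is None else init.copy()
    lp = model.log_prior(params)
    ll = model.log_likelihood(params) if beta > 0.0 else 0.0
    if not np.isfinite(lp):
        raise RuntimeError("initial parameters have zero prior support")
    n_burn = int(config.burnin_fraction * config.generations)
    scale = config.proposal_scale
    kept_params, kept_ll = [], []
    n_acc = 0
    n_prop = 0
    for g in range(config.generations):
        prop, log_hastings = model.propose(params, rng, scale)
        lp_new = model.log_prior(prop)
        if np.isfinite(lp_new):
            ll_new = model.log_likelihood(prop) if beta > 0.0 else 0.0
            log_alpha = (lp_new - lp) + beta * (ll_new - ll) + log_hastings
            if np.log(rng.random()) < log_alpha:
                params, lp, ll = prop, lp_new, ll_new
                n_acc += 1
        n_prop += 1
        if config.adapt and g < n_burn and g > 0 and g % 200 == 0:
            rate = n_acc / n_prop
            if rate < 0.15:
                scale *= 0.8
            elif rate > 0.5:
                scale *= 1.25
        if g >= n_burn and (g - n_burn) % config.thin == 0:
            # at beta = 0 the chain never scores the data; score kept draws
            kept_ll.append(ll if beta > 0.0 else model.log_likelihood(params))
            kept_params.append(params.copy())
    kept = np.array(kept_params)
    return ChainResult(
        samples=kept,
        hypermean=np.array([]),
        log_likelihoods=np.array(kept_ll),
        acceptance=n_acc / max(n_prop, 1),
        seed=seed,
    )


def mcmc_sample(
    kind: str,
    table: TreeTable,
    data,
    *,
    config: ChainConfig | None = None,
    seed: int = 1,
    root_prior="uniform",
    beta: float = 1.0,
) -> ChainResult:
    """Posterior rate samples for one model kind on one dataset.

    The returned ``samples`` hold the free rates; ``hypermean`` the
    exponential-prior mean draws.
    """
    post = PagelPosterior(kind, table, data, root_prior=root_prior)
    res = run_chain(post, config or ChainConfig(), seed, beta=beta)
    return ChainResult(
        samples=res.samples[:, :-1],
        hypermean=res.samples[:, -1],
        log_likelihoods=res.log_likelihoods,
        acceptance=res.acceptance,
        seed=seed,
    )
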