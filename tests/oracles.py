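"""Independent oracles used by the test suite.

Each implements its quantity by a route independent of the package code
it checks: age-domain ODE integration of the life history (vs the
mass-domain spectral integrator), brute-force enumeration of internal
node states (vs the pruning likelihood), and grid search over diet
effort splits (vs the disc-equation intake).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import solve_ivp

from metamorph import bioenergetics as be
from metamorph.bioenergetics import Stage
from metamorph.phylo.likelihood import TreeTable, _tip_partials_joint
from metamorph.phylo.model import branch_probabilities, build_rate_matrix


def life_history_by_age(traits, X1, X2, params, max_age=100_000.0, rtol=1e-10):
    """Age-domain life-history integration (events handled by stages).

    Returns (R0, gamma1, gamma2, age_at_maturation).  Independent of the
    mass-domain integrator: time is the independent variable and the
    metamorphosis and maturation events are located by solve_ivp event
    functions.
    """
    out = {"R0": 0.0, "g1": 0.0, "g2": 0.0, "age_mat": None}

    def run_stage(stage, psi, w0, age0, surv0, w_stop):
        mu = be.background_mortality(stage, params)

        def rhs(t, u):
            w, logs, g1, g2 = u
            i1, i2 = be.intake_rates(w, psi, X1, X2, params)
            e = float(be.net_production(w, psi, X1, X2, params))
            growth = params.kappa_adult * e if (stage is Stage.ADULT and e > 0) else e
            if stage is not Stage.ADULT and growth < 0:
                growth = 0.0  # parked at the stall in the deterministic model
            s = np.exp(logs)
            return [growth, -mu, s * float(i1), s * float(i2)]

        def reach(t, u):
            return u[0] - w_stop
        reach.terminal = True
        reach.direction = 1.0

        def dead(t, u):
            return u[1] - np.log(1e-14)
        dead.terminal = True

        sol = solve_ivp(rhs, (age0, max_age), [w0, np.log(surv0), 0.0, 0.0],
                        events=(reach, dead), rtol=rtol, atol=1e-14,
                        method="LSODA", max_step=200.0)
        w, logs, g1, g2 = sol.y[:, -1]
        out["g1"] += g1
        out["g2"] += g2
        reached = sol.t_events[0].size > 0
        return reached, float(sol.t[-1]), float(w), float(np.exp(logs))

    if traits.direct_development:
        surv = be.metamorphosis_survival(traits.theta, params)
        stage, psi, w = Stage.JUVENILE, traits.psi_post, traits.w_b
        age = 0.0
    else:
        surv = 1.0
        stage, psi, w = Stage.LARVA, traits.psi_L, traits.w_b
        age = 0.0
        reached, age, w, surv = run_stage(stage, psi, w, age, surv, traits.w_J)
        if not reached:
            return out["R0"], out["g1"], out["g2"], out["age_mat"]
        surv *= be.metamorphosis_survival(traits.theta, params)
        w = be.mass_after_metamorphosis(traits.w_J, traits.theta, params)
        stage, psi = Stage.JUVENILE, traits.psi_post

    if w < params.w_A:
        reached, age, w, surv = run_stage(stage, psi, w, age, surv, params.w_A)
        if not reached:
            return out["R0"], out["g1"], out["g2"], out["age_mat"]
    out["age_mat"] = age

    # adult stage (determinate growth: kappa_adult = 0)
    mu_A = be.background_mortality(Stage.ADULT, params)
    e = float(be.net_production(w, traits.psi_post, X1, X2, params))
    i1, i2 = be.intake_rates(w, traits.psi_post, X1, X2, params)
    cost = be.offspring_cost(traits, params)
    expected_time = surv / mu_A
    if e > 0:
        out["R0"] = surv * ((1.0 - params.kappa_adult) * e / cost) / mu_A
    out["g1"] += float(i1) * expected_time
    out["g2"] += float(i2) * expected_time
    return out["R0"], out["g1"], out["g2"], out["age_mat"]


def enumeration_log_likelihood(tree, data, model, root_prior=None):
    """Joint-model log-likelihood by brute-force summation over every
    assignment of internal-node states (trees of ~<= 6 tips)."""
    table = TreeTable.from_dendropy(tree)
    Q = build_rate_matrix(model)
    P = branch_probabilities(Q, table.lengths)
    partials = _tip_partials_joint(table, data)
    internal = [i for i in range(table.n_nodes) if table.children[i]]
    tips = [i for i in range(table.n_nodes) if not table.children[i]]
    root = table.postorder[-1]
    prior = np.full(4, 0.25) if root_prior is None else np.asarray(root_prior)
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        term = prior[amap[root]]
        for i in internal + tips:
            if i == root:
                continue
            pa = amap[table.parent[i]]
            if i in amap:
                term *= P[i][pa, amap[i]]
            else:
                term *= float(P[i][pa] @ partials[i])
        total += term
    return float(np.log(total))


def best_effort_split_intake(w, psi, X1, X2, params, n_grid=201):
    """Grid search over foraging-effort splits phi in [0, 1]:
    max_phi (phi*e1 + (1-phi)*e2) / (1 + H*(phi*e1 + (1-phi)*e2))."""
    e1 = float(be.attack_rate(w, psi, 1, params) * X1)
    e2 = float(be.attack_rate(w, psi, 2, params) * X2)
    H = float(be.handling_time(w, params))
    best = 0.0
    for phi in np.linspace(0.0, 1.0, n_grid):
        enc = phi * e1 + (1 - phi) * e2
        best = max(best, enc / (1.0 + H * enc))
    return best
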