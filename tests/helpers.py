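"""Shared independent oracles and tree builders for the test suite.

Everything here deliberately avoids the code paths it is used to check:
the birth-death oracle integrates the survival/flow ODEs with an adaptive
Runge-Kutta solver (the package uses closed forms and cumulative Simpson
quadrature), the patristic oracle walks explicit root paths, and the Mk
oracle enumerates internal state assignments exhaustively.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from radiad.tree import DatedTree, Node


def ladder_tree_from_branching_times(bt) -> DatedTree:
    """Ladderized (caterpillar) ultrametric tree with the given
    branching times (descending ages)."""
    bt = sorted(bt, reverse=True)
    k = [0]

    def tip():
        k[0] += 1
        return Node(f"t{k[0]}", 0.0)

    node = tip()
    for age in reversed(bt):  # youngest split first
        parent = Node(None, age)
        parent.add_child(node)
        parent.add_child(tip())
        node = parent
    return DatedTree(node)


def bd_loglik_ode_oracle(tree: DatedTree, lam_fn, mu_fn, rho=1.0,
                         rtol=1e-11, atol=1e-13) -> float:
    """Birth-death log-likelihood via direct ODE integration.

    Solves E' = mu - (lam+mu) E + lam E^2 (E(0) = 1-rho) for the
    no-sampled-descendant probability and, jointly, the log-flow
    d(log psi)/dt = -(lam+mu) + 2 lam E for log p1; assembles the crown-
    conditioned likelihood from the branching times.
    """
    bt = tree.branching_times()
    T = bt[0]

    def rhs(t, yv):
        E, logpsi = yv
        l, m = float(lam_fn(t)), float(mu_fn(t))
        dE = m - (l + m) * E + l * E * E
        dlog = -(l + m) + 2.0 * l * E
        return [dE, dlog]

    sol = solve_ivp(
        rhs, (0.0, T), [1.0 - rho, 0.0], t_eval=np.sort(np.unique(bt)),
        rtol=rtol, atol=atol, dense_output=True, method="RK45",
    )
    if not sol.success:
        raise RuntimeError(sol.message)

    def parts(t):
        E, logpsi = sol.sol(t)
        return float(E), float(logpsi)

    def log_p1(t):
        E, logpsi = parts(t)
        return math.log(rho) + logpsi

    ll = 0.0
    for x in bt[1:]:
        ll += math.log(float(lam_fn(x))) + log_p1(x)
    E_T, _ = parts(T)
    ll += 2.0 * log_p1(T)
    ll -= 2.0 * math.log(1.0 - E_T)  # condition on both crown lineages
    return ll


def patristic_bruteforce(tree: DatedTree):
    """Tip-tip distances by summing branch lengths along explicit
    root-to-tip paths."""
    paths = {}
    for tip in tree.tips:
        node, path = tip, []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path
    labels = tree.tip_labels
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[labels[i]]
            pj = paths[labels[j]]
            si = {id(x) for x in pi}
            sj = {id(x) for x in pj}
            d = sum(x.length for x in pi if id(x) not in sj)
            d += sum(x.length for x in pj if id(x) not in si)
            D[i, j] = D[j, i] = d
    return labels, D


def mk_marginals_bruteforce(tree: DatedTree, tip_states: dict, states, Q):
    """Marginal ancestral probabilities by exhaustive enumeration of all
    internal-node state assignments (uniform root prior)."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    P = {}
    nodes = [n for n in tree.postorder]
    internals = [n for n in nodes if not n.is_tip]
    for n in nodes:
        if n.parent is not None:
            P[n.index] = expm(np.asarray(Q) * n.length)
    from itertools import product

    post = {n.index: np.zeros(k) for n in internals}
    total = 0.0
    for assign in product(range(k), repeat=len(internals)):
        amap = {n.index: a for n, a in zip(internals, assign)}
        for n in tree.tips:
            amap[n.index] = sidx[tip_states[n.name]]
        p = 1.0 / k  # root prior
        for n in nodes:
            if n.parent is None:
                continue
            p *= P[n.index][amap[n.parent.index], amap[n.index]]
        total += p
        for n in internals:
            post[n.index][amap[n.index]] += p
    return {i: v / total for i, v in post.items()}, total


def gower_bruteforce(df, continuous, categorical):
    """Per-pair loop Gower dissimilarity."""
    n = len(df)
    ranges = {c: (df[c].max() - df[c].min()) for c in continuous}
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            terms = []
            for c in continuous:
                if ranges[c] > 0:
                    terms.append(abs(df[c].iloc[i] - df[c].iloc[j]) / ranges[c])
            for c in categorical:
                terms.append(0.0 if df[c].iloc[i] == df[c].iloc[j] else 1.0)
            D[i, j] = np.mean(terms)
    return D
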