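"""Stepwise AICc search for diversification-rate shifts (MEDUSA-style),
with a simulation-calibrated acceptance threshold.

The tree is partitioned into rate regimes by "breakpoints" placed on
branches (the stem of an internal node or a terminal branch).  Each
regime is fitted with a constant-rate pure-birth or birth-death model
(chosen per regime by information score), and breakpoints are added
greedily one at a time while the total AICc improves by at least a
threshold.  Because stepwise searches of this kind are prone to false
positives, the threshold is calibrated by simulating single-regime trees
and taking the smallest value that rejects a shift on every one of them.

Incomplete terminal sampling is handled by assigning each tip a species
richness: a tip representing ``m`` species contributes the probability
that a single lineage at the start of its terminal branch leaves exactly
``m`` extant species, rather than the exactly-one-descendant flow term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .tree import DatedTree

__all__ = [
    "RegimeFit",
    "Shift",
    "ShiftConfig",
    "ThresholdCalibration",
    "stepwise_search",
    "calibrate_threshold",
]


# ----------------------------------------------------------------------
# Constant-rate likelihood pieces (rho = 1 inside a regime; incomplete
# sampling enters through terminal richness)


def _log_y(t, lam, mu):
    """log y(t) with y = (lambda - mu e^{-rt})/r, stable for r -> 0."""
    r = lam - mu
    t = np.asarray(t, dtype=float)
    if abs(r) < 1e-10:
        return np.log1p(lam * t)
    # y = e^{-rt} + lam * (1 - e^{-rt}) / r
    em = np.exp(-r * t)
    return np.log(em + lam * (1.0 - em) / r)


def _regime_loglik(lam, mu, node_ages, edge_tops, edge_bots, term_lens, term_m):
    """Log-likelihood of one constant-rate regime.

    ``node_ages``: ages of branching nodes whose split belongs to the
    regime; ``edge_tops``/``edge_bots``: internal-edge endpoint ages;
    ``term_lens``/``term_m``: terminal branch lengths and tip richness.
    """
    if lam <= 0 or mu < 0:
        return -np.inf
    r = lam - mu
    ll = 0.0
    if node_ages.size:
        ll += node_ages.size * math.log(lam)
    if edge_tops.size:
        # log Psi(s, t) = r (s - t) + 2 [log y(s) - log y(t)]
        ll += float(
            np.sum(
                r * (edge_bots - edge_tops)
                + 2.0 * (_log_y(edge_bots, lam, mu) - _log_y(edge_tops, lam, mu))
            )
        )
    if term_lens.size:
        t = term_lens
        if abs(r) < 1e-10:
            denom = 1.0 + lam * t
            log_alpha = np.log(mu * t) - np.log(denom) if mu > 0 else None
            alpha = (mu * t) / denom
            eta = (lam * t) / denom
        else:
            ert = np.exp(np.clip(r * t, -700, 700))
            denom = lam * ert - mu
            if np.any(denom <= 0):
                return -np.inf
            alpha = mu * (ert - 1.0) / denom
            eta = lam * (ert - 1.0) / denom
        alpha = np.clip(alpha, 0.0, 1.0 - 1e-15)
        eta = np.clip(eta, 1e-300, 1.0 - 1e-15)
        # P(N = m | stem of age t) = (1-alpha)(1-eta) eta^{m-1}
        ll += float(
            np.sum(np.log1p(-alpha) + np.log1p(-eta) + (term_m - 1) * np.log(eta))
        )
    return ll if np.isfinite(ll) else -np.inf


@dataclass
class RegimeFit:
    lam: float
    mu: float
    pure_birth: bool
    logL: float
    k: int

    def to_dict(self):
        return {
            "lambda": float(self.lam),
            "mu": float(self.mu),
            "model": "pure birth" if self.pure_birth else "birth-death",
            "logL": float(self.logL),
            "k": self.k,
        }


_LAM_LO, _LAM_HI = 1e-7, 50.0


def _fit_regime(node_ages, edge_tops, edge_bots, term_lens, term_m) -> RegimeFit:
    """Best constant-rate model (pure birth vs birth-death) for one
    regime, chosen by AIC contribution.  Deterministic.

    With complete terminal sampling the pure-birth MLE is closed form
    (events per unit lineage-time); birth-death is attempted only when
    the regime contains at least two branching nodes, below which the
    extinction fraction is unidentifiable.
    """
    data = (node_ages, edge_tops, edge_bots, term_lens, term_m)
    n_events = node_ages.size
    tot_time = float(np.sum(edge_tops - edge_bots) + np.sum(term_lens))
    tot_time = max(tot_time, 1e-9)

    if np.all(term_m == 1):
        lam_pb = min(max(n_events / tot_time, _LAM_LO), _LAM_HI)
        ll_pb = (n_events * math.log(lam_pb) if n_events else 0.0) - lam_pb * tot_time
    else:
        def nll_pb(x):
            return -_regime_loglik(math.exp(x[0]), 0.0, *data)

        start = math.log(min(max(max(n_events, 1) / tot_time, _LAM_LO), _LAM_HI))
        res_pb = optimize.minimize(
            nll_pb, [start], method="L-BFGS-B",
            bounds=[(math.log(_LAM_LO), math.log(_LAM_HI))],
            options={"ftol": 1e-10, "maxiter": 80},
        )
        lam_pb, ll_pb = math.exp(res_pb.x[0]), -res_pb.fun

    if n_events < 2:
        return RegimeFit(lam_pb, 0.0, True, ll_pb, 1)

    def nll_bd(x):
        lam = math.exp(x[0])
        eps = 1.0 / (1.0 + math.exp(-x[1]))  # mu/lambda in (0, 1)
        return -_regime_loglik(lam, eps * lam, *data)

    best_bd = None
    for eps0 in (-2.0, 0.5):
        res = optimize.minimize(
            nll_bd, [math.log(lam_pb) + 0.2, eps0], method="L-BFGS-B",
            bounds=[(math.log(_LAM_LO), math.log(_LAM_HI)), (-12.0, 9.0)],
            options={"ftol": 1e-10, "maxiter": 60},
        )
        if best_bd is None or res.fun < best_bd.fun:
            best_bd = res
    ll_bd = -best_bd.fun
    # per-regime AIC choice (the global AICc is computed on the summed k)
    if -2 * ll_pb + 2 <= -2 * ll_bd + 4:
        return RegimeFit(lam_pb, 0.0, True, ll_pb, 1)
    lam = math.exp(best_bd.x[0])
    eps = 1.0 / (1.0 + math.exp(-best_bd.x[1]))
    return RegimeFit(lam, eps * lam, False, ll_bd, 2)


# ----------------------------------------------------------------------
# Tree flattening


class _FlatTree:
    """Arrays for fast regime-likelihood assembly.

    Nodes are numbered by DatedTree indices (tips first).  For every
    non-root node i the branch above it has endpoints (parent age, own
    age); a breakpoint on that branch moves the branch and the whole
    subtree below it into a new regime.  A branching node's lambda
    factor follows its stem branch (the root's split is conditioned on
    and carries no factor).
    """

    def __init__(self, tree: DatedTree, richness: pd.Series | None):
        n_nodes = len(tree.postorder)
        self.tree = tree
        self.n_tips = tree.n_tips
        self.parent_age = np.zeros(n_nodes)
        self.age = np.zeros(n_nodes)
        self.is_tip = np.zeros(n_nodes, dtype=bool)
        self.richness = np.ones(n_nodes)
        self.has_edge = np.zeros(n_nodes, dtype=bool)
        if richness is not None:
            missing = set(tree.tip_labels) - set(richness.index)
            if missing:
                raise ValueError(
                    f"tips missing from richness table: {sorted(missing)[:5]}"
                )
        for node in tree.postorder:
            i = node.index
            self.age[i] = node.age
            self.is_tip[i] = node.is_tip
            if node.parent is not None:
                self.parent_age[i] = node.parent.age
                self.has_edge[i] = True
            if node.is_tip and richness is not None:
                self.richness[i] = int(richness.loc[node.name])
        # descendant index lists (subtree below-and-including each node)
        desc: dict[int, list] = {}
        for node in tree.postorder:
            ids = [node.index]
            for c in node.children:
                ids.extend(desc[c.index])
            desc[node.index] = ids
        self.desc = {i: np.asarray(v, dtype=np.int64) for i, v in desc.items()}
        self.root_index = tree.root.index
        self.node_label = {
            node.index: (node.name if node.name else f"node{node.index}")
            for node in tree.postorder
        }

    def regime_data(self, members: np.ndarray):
        """Likelihood arrays for the regime consisting of ``members``
        (node indices whose stem branch belongs to the regime)."""
        mask = np.zeros_like(self.is_tip)
        mask[members] = True
        mask[self.root_index] = False  # root has no stem
        edge = mask & self.has_edge
        internal_edge = edge & ~self.is_tip
        term_edge = edge & self.is_tip
        node_sel = edge & ~self.is_tip  # lambda factors follow the stem
        return (
            self.age[node_sel],
            self.parent_age[internal_edge],
            self.age[internal_edge],
            self.parent_age[term_edge],  # terminal branch length (tip age 0)
            self.richness[term_edge],
        )


@dataclass
class Shift:
    node_index: int
    node_label: str
    stem_age: float
    node_age: float
    n_tips: int
    regime: RegimeFit

    def to_dict(self):
        return {
            "node_index": self.node_index,
            "node_label": self.node_label,
            "stem_age": float(self.stem_age),
            "node_age": float(self.node_age),
            "n_tips": int(self.n_tips),
            "regime": self.regime.to_dict(),
        }


@dataclass
class ShiftConfig:
    shifts: list
    background: RegimeFit
    aicc: float
    logL: float
    k: int
    n_obs: int
    aicc_path: list = field(default_factory=list)

    @property
    def n_shifts(self) -> int:
        return len(self.shifts)

    def to_dict(self):
        return {
            "n_shifts": self.n_shifts,
            "shifts": [s.to_dict() for s in self.shifts],
            "background": self.background.to_dict(),
            "AICc": float(self.aicc),
            "logL": float(self.logL),
            "k": self.k,
            "AICc_path": [float(a) for a in self.aicc_path],
        }


def _aicc(logL, k, n_obs):
    if n_obs - k - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def _total(fits: list[RegimeFit], n_shifts: int, n_obs: int):
    logL = sum(f.logL for f in fits)
    k = sum(f.k for f in fits) + n_shifts
    return logL, k, _aicc(logL, k, n_obs)


def _pb_score(flat: _FlatTree, members: np.ndarray) -> float:
    """Closed-form pure-birth log-likelihood of a regime (shortlisting
    heuristic; tips with richness > 1 enter via a plug-in correction)."""
    mask = np.zeros_like(flat.is_tip)
    mask[members] = True
    mask[flat.root_index] = False
    edge = mask & flat.has_edge
    N = int(np.count_nonzero(edge & ~flat.is_tip))
    T = float(np.sum(flat.parent_age[edge] - flat.age[edge]))
    T = max(T, 1e-9)
    lam = min(max(N / T, _LAM_LO), _LAM_HI)
    ll = (N * math.log(lam) if N else 0.0) - lam * T
    multi = edge & flat.is_tip & (flat.richness > 1)
    if np.any(multi):
        ell = flat.parent_age[multi]
        m = flat.richness[multi]
        ll += float(np.sum((m - 1) * np.log1p(-np.exp(-lam * np.maximum(ell, 1e-9)))))
    return ll


def _first_step(flat: _FlatTree, assign: np.ndarray, regime_fits: dict,
                shortlist: int = 8):
    """Find the best breakpoint to add, given the current assignment
    (``assign[i]`` = regime id of node i's stem; root carries the
    background id).

    All candidate branches are first scored with the closed-form
    pure-birth likelihood; the ``shortlist`` highest-scoring candidates
    are then refitted exactly (pure birth vs birth-death per regime) and
    the best full AICc wins.
    """
    n_obs = flat.n_tips
    scored = []
    for i in range(len(assign)):
        if not flat.has_edge[i]:
            continue
        host = assign[i]
        sub = flat.desc[i]
        # only split members currently in the host regime (keep nested
        # foreign regimes intact)
        sub = sub[assign[sub] == host]
        host_members = np.flatnonzero(assign == host)
        if len(sub) >= len(host_members):
            continue  # would empty the host regime
        remaining = np.setdiff1d(host_members, sub, assume_unique=True)
        if not np.any(flat.has_edge[remaining] & (remaining != flat.root_index)):
            continue
        score = _pb_score(flat, sub) + _pb_score(flat, remaining)
        scored.append((score, i, host, sub, remaining))
    if not scored:
        return None
    scored.sort(key=lambda x: -x[0])
    best = None
    for score, i, host, sub, remaining in scored[:shortlist]:
        fit_new = _fit_regime(*flat.regime_data(sub))
        fit_host = _fit_regime(*flat.regime_data(remaining))
        others = [f for rid, f in regime_fits.items() if rid != host]
        fits = others + [fit_host, fit_new]
        logL, k, aicc = _total(fits, n_shifts=len(regime_fits), n_obs=n_obs)
        if best is None or aicc < best["aicc"]:
            best = {
                "node": i, "aicc": aicc, "logL": logL, "k": k,
                "fit_new": fit_new, "fit_host": fit_host, "host": host,
                "sub": sub,
            }
    return best


def stepwise_search(
    tree: DatedTree,
    richness: pd.Series | None = None,
    threshold: float = 4.0,
    max_shifts: int = 10,
) -> ShiftConfig:
    """Greedy stepwise breakpoint search.

    Adds the single best breakpoint per iteration (each regime fitted
    with pure-birth or birth-death, chosen by information score) and
    stops when the best AICc improvement falls below ``threshold`` or
    ``max_shifts`` is reached.  ``threshold`` should come from
    :func:`calibrate_threshold`.  Deterministic given its inputs.
    """
    flat = _FlatTree(tree, richness)
    n_nodes = len(tree.postorder)
    assign = np.zeros(n_nodes, dtype=np.int64)  # all in background (id 0)
    bg_members = np.arange(n_nodes)
    regime_fits = {0: _fit_regime(*flat.regime_data(bg_members))}
    logL, k, aicc = _total(list(regime_fits.values()), 0, flat.n_tips)
    path = [aicc]
    shifts: list[Shift] = []

    while len(shifts) < max_shifts:
        best = _first_step(flat, assign, regime_fits)
        if best is None or aicc - best["aicc"] < threshold:
            break
        new_id = max(regime_fits) + 1
        assign[best["sub"]] = new_id
        regime_fits[best["host"]] = best["fit_host"]
        regime_fits[new_id] = best["fit_new"]
        logL, k, aicc = best["logL"], best["k"], best["aicc"]
        path.append(aicc)
        i = best["node"]
        shifts.append(
            Shift(
                node_index=i,
                node_label=flat.node_label[i],
                stem_age=float(flat.parent_age[i]),
                node_age=float(flat.age[i]),
                n_tips=int(np.sum(flat.is_tip[flat.desc[i]])),
                regime=best["fit_new"],
            )
        )

    return ShiftConfig(
        shifts=shifts,
        background=regime_fits[0],
        aicc=float(aicc),
        logL=float(logL),
        k=int(k),
        n_obs=flat.n_tips,
        aicc_path=path,
    )


@dataclass
class ThresholdCalibration:
    threshold: float
    improvements: np.ndarray
    n_sims: int
    template_tips: int
    lam: float
    mu: float
    epsilon: float

    def to_dict(self):
        return {
            "threshold": float(self.threshold),
            "n_sims": self.n_sims,
            "template_tips": self.template_tips,
            "lambda": self.lam,
            "mu": self.mu,
            "max_improvement": float(np.max(self.improvements)),
            "epsilon": self.epsilon,
        }


def best_first_improvement(tree: DatedTree, richness: pd.Series | None = None) -> float:
    """AICc improvement of the single best breakpoint over no breakpoint
    (positive = the shifted model scores better)."""
    flat = _FlatTree(tree, richness)
    n_nodes = len(tree.postorder)
    assign = np.zeros(n_nodes, dtype=np.int64)
    regime_fits = {0: _fit_regime(*flat.regime_data(np.arange(n_nodes)))}
    _, _, aicc0 = _total(list(regime_fits.values()), 0, flat.n_tips)
    best = _first_step(flat, assign, regime_fits)
    if best is None:
        return 0.0
    return float(aicc0 - best["aicc"])


def calibrate_threshold(
    template_tips: int = 120,
    lam: float = 0.15,
    mu: float = 0.05,
    n_sims: int = 100,
    seed: int | None = None,
    epsilon: float = 0.01,
) -> ThresholdCalibration:
    """Calibrate the stepwise acceptance threshold on single-regime trees.

    Simulates ``n_sims`` constant-rate trees of ``template_tips`` tips,
    records the best first-breakpoint AICc improvement on each, and
    returns the smallest threshold that rejects a shift on every
    simulated tree (the maximum improvement plus ``epsilon``).
    """
    from .synth import simulate_bd_tree

    if n_sims < 20:
        raise ValueError("n_sims >= 20 required for a stable calibration")
    rng = np.random.default_rng(seed)
    improvements = np.empty(n_sims)
    for s in range(n_sims):
        t = simulate_bd_tree(
            lam, mu, stop="tips", tips=template_tips,
            seed=int(rng.integers(2**31 - 1)),
        )
        improvements[s] = best_first_improvement(t)
    thr = float(np.max(improvements) + epsilon)
    return ThresholdCalibration(
        threshold=thr, improvements=improvements, n_sims=n_sims,
        template_tips=template_tips, lam=lam, mu=mu, epsilon=epsilon,
    )
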