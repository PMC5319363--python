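"""Phylogenetic models of continuous-trait and discrete-niche evolution.

Continuous traits (ln body mass) are modelled as multivariate normal on
the tree: Brownian motion (BM), Pagel's lambda, Ornstein-Uhlenbeck (OU)
and ACDC/early-burst (exponentially time-rescaled BM).  PGLS regresses
the trait on niche categories under any of these correlation structures.
Discrete niches evolve under a continuous-time Markov (Mk) process:
ancestral states come from maximum-likelihood marginal reconstruction,
stochastic character maps from endpoint-conditioned simulation.  A
regime painting of the tree then drives state-dependent (multi-regime)
BM/OU models with per-regime optima, constraints and rates.

Conventions
-----------
* Single-model OU uses the stationary covariance by default
  (``ou_root="stationary"``); the fixed-root form is available and is
  the form to which the multi-regime models reduce with one regime.
* Multi-regime models anchor the root value at the root regime's
  optimum; optima are profiled out by GLS, so optimizers only search the
  constraint/rate parameters.
* AICc sample size is the number of species with trait data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.linalg import expm

from .tree import DatedTree, TreeError
from .painting import RegimePaint

__all__ = [
    "TraitModelFit",
    "fit_trait_model",
    "PGLSFit",
    "pgls",
    "pgls_model_average",
    "trait_adequacy",
    "MkFit",
    "mk_asr",
    "stochastic_map",
    "MultiRegimeFit",
    "fit_multiregime",
    "fit_multiregime_candidates",
    "multiregime_over_posterior",
    "MULTIREGIME_MODELS",
]


def _aicc(logL: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ----------------------------------------------------------------------
# Shared MVN machinery


def _mvn_profile(C: np.ndarray, X: np.ndarray, y: np.ndarray):
    """ML of y ~ N(X beta, s2 * C) with beta, s2 profiled out.

    Returns (logL, beta, s2, cov_beta_unit) where cov_beta_unit * s2 is
    the covariance of beta-hat.
    """
    n = len(y)
    cho = linalg.cho_factor(C, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Ci_X = linalg.cho_solve(cho, X)
    Ci_y = linalg.cho_solve(cho, y)
    XtCiX = X.T @ Ci_X
    beta = np.linalg.solve(XtCiX, X.T @ Ci_y)
    r = y - X @ beta
    Ci_r = linalg.cho_solve(cho, r)
    s2 = float(r @ Ci_r) / n
    if s2 <= 0:
        return -np.inf, beta, s2, None
    logL = -0.5 * (n * math.log(2 * math.pi) + n * math.log(s2) + logdet + n)
    return logL, beta, s2, np.linalg.inv(XtCiX)


def _tip_matrices(tree: DatedTree, species: pd.Index):
    """Shared-time (S) and patristic (D) matrices restricted to species."""
    labels = tree.tip_labels
    pos = {s: i for i, s in enumerate(labels)}
    missing = [s for s in species if s not in pos]
    if missing:
        raise ValueError(f"species not in tree: {missing[:5]}")
    idx = np.array([pos[s] for s in species])
    heights = tree.node_heights()
    M = tree.mrca_matrix()
    S = heights[M][np.ix_(idx, idx)]
    hi = heights[idx]
    D = hi[:, None] + hi[None, :] - 2.0 * S
    np.fill_diagonal(D, 0.0)
    return S, D


# ----------------------------------------------------------------------
# Single-model continuous-trait fits

TRAIT_MODELS = ("BM", "lambda", "OU", "ACDC")


@dataclass
class TraitModelFit:
    model: str
    sigma2: float
    logL: float
    k: int
    aicc: float
    n: int
    mean: float  # ancestral state (BM-type) or optimum theta (OU)
    alpha: float = 0.0
    lambda_: float = 1.0
    g_rate: float = 0.0  # ACDC exponent (/My); negative = early burst
    ou_root: str = "stationary"
    flags: list = field(default_factory=list)

    def to_dict(self):
        return {
            "model": self.model, "sigma2": self.sigma2, "logL": self.logL,
            "k": self.k, "AICc": self.aicc, "n": self.n, "mean": self.mean,
            "alpha": self.alpha, "lambda": self.lambda_, "g_rate": self.g_rate,
            "flags": list(self.flags),
        }


def _trait_corr(model: str, S: np.ndarray, D: np.ndarray, psi: float,
                ou_root: str) -> np.ndarray:
    """Correlation-structure matrix (up to the profiled scale)."""
    if model == "BM":
        return S.copy()
    if model == "lambda":
        C = psi * S
        np.fill_diagonal(C, np.diag(S))
        return C
    if model == "OU":
        alpha = psi
        if ou_root == "stationary":
            return np.exp(-alpha * D)
        return np.exp(-alpha * D) * (1.0 - np.exp(-2.0 * alpha * S))
    if model == "ACDC":
        g = psi
        if abs(g) < 1e-12:
            return S.copy()
        return np.expm1(g * S) / g
    raise ValueError(f"unknown trait model {model!r}")


def fit_trait_model(
    tree: DatedTree,
    trait: pd.Series,
    model: str = "BM",
    ou_root: str = "stationary",
    fixed: dict | None = None,
) -> TraitModelFit:
    """ML fit of a single-process trait model via the phylogenetic
    multivariate-normal likelihood.

    ``trait`` maps species (a subset of the tips, >= 10) to values.
    ``fixed`` pins the structure parameter (``alpha``, ``lambda_`` or
    ``g_rate``) instead of estimating it.
    """
    if model not in TRAIT_MODELS:
        raise ValueError(f"model must be one of {TRAIT_MODELS}")
    trait = trait.dropna()
    if len(trait) < 10:
        raise ValueError("trait must cover at least 10 tips")
    S, D = _tip_matrices(tree, trait.index)
    y = trait.to_numpy(dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    T = float(np.max(np.diag(S)))
    flags = []

    def fit_at(psi):
        C = _trait_corr(model, S, D, psi, ou_root)
        try:
            return _mvn_profile(C, X, y)
        except linalg.LinAlgError:
            return -np.inf, np.zeros(1), np.nan, None

    if model == "BM":
        psi_hat, k = 0.0, 2
    else:
        bounds = {
            "lambda": (0.0, 1.0),
            "OU": (1e-8, 50.0 / T),
            "ACDC": (-5.0 / T, 5.0 / T),
        }[model]
        key = {"lambda": "lambda_", "OU": "alpha", "ACDC": "g_rate"}[model]
        if fixed and key in fixed:
            psi_hat = float(fixed[key])
            k = 2
        else:
            if model == "OU":  # optimize on log alpha
                res = optimize.minimize_scalar(
                    lambda u: -fit_at(math.exp(u))[0],
                    bounds=(math.log(bounds[0]), math.log(bounds[1])),
                    method="bounded", options={"xatol": 1e-10},
                )
                psi_hat = math.exp(res.x)
            else:
                res = optimize.minimize_scalar(
                    lambda u: -fit_at(u)[0], bounds=bounds, method="bounded",
                    options={"xatol": 1e-12},
                )
                psi_hat = float(res.x)
            k = 3
            if model == "OU" and psi_hat > 0.97 * bounds[1]:
                flags.append("alpha at upper bound")
    logL, beta, s2, _ = fit_at(psi_hat)
    if not np.isfinite(logL):
        raise RuntimeError(f"singular covariance in {model} fit")
    sigma2 = s2
    alpha = lam = g = 0.0
    lam = 1.0
    if model == "OU":
        alpha = psi_hat
        sigma2 = 2.0 * alpha * s2  # scale parameter was sigma^2 / (2 alpha)
    elif model == "lambda":
        lam = psi_hat
    elif model == "ACDC":
        g = psi_hat
    return TraitModelFit(
        model=model, sigma2=float(sigma2), logL=float(logL), k=k,
        aicc=_aicc(logL, k, n), n=n, mean=float(beta[0]), alpha=float(alpha),
        lambda_=float(lam), g_rate=float(g), ou_root=ou_root, flags=flags,
    )


# ----------------------------------------------------------------------
# PGLS


@dataclass
class PGLSFit:
    corr_model: str
    coef: pd.Series
    se: pd.Series
    sigma2: float
    structure_param: float
    logL: float
    k: int
    aicc: float
    n: int
    levels: list

    def to_dict(self):
        return {
            "corr_model": self.corr_model,
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "sigma2": self.sigma2,
            "structure_param": self.structure_param,
            "logL": self.logL, "k": self.k, "AICc": self.aicc, "n": self.n,
        }


def _niche_design(niche: pd.Series):
    """Sum-to-zero (deviation) coding: an intercept (grand mean) plus
    K-1 columns; the last level's coefficient is minus the sum of the
    others, so every coefficient is a deviation from the mean."""
    levels = sorted(niche.unique())
    if len(levels) < 2:
        raise ValueError("niche must have at least 2 levels")
    counts = niche.value_counts()
    empty = [l for l in levels if counts.get(l, 0) == 0]
    if empty:
        raise ValueError(f"empty niche level: {empty}")
    n = len(niche)
    X = np.ones((n, len(levels)))
    codes = niche.map({l: i for i, l in enumerate(levels)}).to_numpy()
    for j in range(len(levels) - 1):
        X[:, j + 1] = np.where(codes == j, 1.0, np.where(codes == len(levels) - 1, -1.0, 0.0))
    return X, levels


def pgls(
    tree: DatedTree,
    trait: pd.Series,
    niche: pd.Series,
    corr_model: str = "BM",
    ou_root: str = "stationary",
    fixed_structure: float | None = None,
) -> PGLSFit:
    """Phylogenetic GLS of the trait on niche categories.

    The correlation-structure parameter (Pagel's lambda, OU alpha or the
    ACDC exponent) is ML-estimated jointly with the coefficients; AICc
    values are comparable across the four correlation models.
    Coefficients are deviations from the grand mean (sum-to-zero
    coding), with the omitted level's deviation reported as well.
    """
    if corr_model not in TRAIT_MODELS:
        raise ValueError(f"corr_model must be one of {TRAIT_MODELS}")
    common = trait.dropna().index.intersection(niche.dropna().index)
    trait = trait.loc[common].astype(float)
    niche = niche.loc[common]
    S, D = _tip_matrices(tree, common)
    y = trait.to_numpy()
    n = len(y)
    X, levels = _niche_design(niche)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design from niche coding")
    T = float(np.max(np.diag(S)))

    def fit_at(psi):
        C = _trait_corr(corr_model, S, D, psi, ou_root)
        return _mvn_profile(C, X, y)

    if corr_model == "BM":
        psi_hat = 0.0
        k_extra = 0
    elif fixed_structure is not None:
        psi_hat = float(fixed_structure)
        k_extra = 0
    else:
        bounds = {
            "lambda": (0.0, 1.0),
            "OU": (1e-8, 50.0 / T),
            "ACDC": (-5.0 / T, 5.0 / T),
        }[corr_model]
        if corr_model == "OU":
            res = optimize.minimize_scalar(
                lambda u: -fit_at(math.exp(u))[0],
                bounds=(math.log(bounds[0]), math.log(bounds[1])),
                method="bounded", options={"xatol": 1e-10},
            )
            psi_hat = math.exp(res.x)
        else:
            res = optimize.minimize_scalar(
                lambda u: -fit_at(u)[0], bounds=bounds, method="bounded",
                options={"xatol": 1e-12},
            )
            psi_hat = float(res.x)
        k_extra = 1
    logL, beta, s2, covb_unit = fit_at(psi_hat)
    se = np.sqrt(np.diag(covb_unit) * s2 * n / max(n - X.shape[1], 1))
    names = ["(grand mean)"] + [f"dev[{l}]" for l in levels[:-1]]
    coef = pd.Series(beta, index=names)
    se_s = pd.Series(se, index=names)
    # recover the omitted level's deviation (sum-to-zero constraint)
    coef[f"dev[{levels[-1]}]"] = -float(np.sum(beta[1:]))
    se_s[f"dev[{levels[-1]}]"] = float(np.sqrt(
        np.sum((covb_unit[1:, 1:]) * s2 * n / max(n - X.shape[1], 1))
    ))
    k = X.shape[1] + 1 + k_extra  # coefficients + sigma2 + structure
    return PGLSFit(
        corr_model=corr_model, coef=coef, se=se_s, sigma2=float(s2),
        structure_param=float(psi_hat), logL=float(logL), k=k,
        aicc=_aicc(logL, k, n), n=n, levels=levels,
    )


def pgls_model_average(
    tree: DatedTree,
    trait: pd.Series,
    niche: pd.Series,
    corr_models: tuple = TRAIT_MODELS,
    delta_max: float = 3.0,
) -> dict:
    """PGLS across correlation models with averaging of coefficients
    over models within ``delta_max`` AICc of the best, weighting by
    Akaike weights."""
    fits = [pgls(tree, trait, niche, m) for m in corr_models]
    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc.min()
    keep = delta < delta_max
    w = np.exp(-delta[keep] / 2.0)
    w = w / w.sum()
    coef = sum(wi * f.coef for wi, f in zip(w, [f for f, k in zip(fits, keep) if k]))
    return {
        "fits": fits,
        "delta_aicc": delta.tolist(),
        "weights_within_window": w.tolist(),
        "kept_models": [f.corr_model for f, k in zip(fits, keep) if k],
        "averaged_coef": coef,
    }


# ----------------------------------------------------------------------
# Trait-model adequacy (contrast statistics on the rescaled tree)


def _rescaled_heights(fit: TraitModelFit, heights: np.ndarray, T: float) -> np.ndarray:
    """Transform root-to-node heights so the fitted model becomes
    unit-rate BM on the rescaled tree."""
    m = fit.model
    if m == "BM":
        return fit.sigma2 * heights
    if m == "lambda":
        # internal covariances scaled by lambda; tips keep total depth
        out = fit.sigma2 * fit.lambda_ * heights
        return out  # tip heights adjusted by caller
    if m == "OU":
        a = max(fit.alpha, 1e-12)
        scale = fit.sigma2 / (2.0 * a)
        return scale * (np.exp(-2.0 * a * (T - heights)) - math.exp(-2.0 * a * T))
    if m == "ACDC":
        g = fit.g_rate
        if abs(g) < 1e-12:
            return fit.sigma2 * heights
        return fit.sigma2 * np.expm1(g * heights) / g
    raise ValueError(m)


def _rescale_tree(tree: DatedTree, fit: TraitModelFit) -> DatedTree:
    t = tree.copy()
    heights = tree.node_heights()
    T = float(tree.crown_age)
    new_h = _rescaled_heights(fit, heights, T)
    tip_h = _rescaled_heights(fit, np.array([T]), T)[0]
    if fit.model == "lambda":
        tip_h = fit.sigma2 * T
    total = tip_h
    for node in t.postorder:
        if node.is_tip:
            node.age = 0.0
        else:
            node.age = max(total - new_h[node.index], 0.0)
    return DatedTree(t.root, require_ultrametric=False)


def _pic(tree: DatedTree, values: dict):
    """Felsenstein's independent contrasts.

    Returns arrays (standardized contrasts, expected sd, node height on
    the tree used).  ``values`` maps tip label -> value.
    """
    x: dict[int, float] = {}
    v: dict[int, float] = {}
    contrasts, esd, node_h = [], [], []
    T = tree.crown_age
    for node in tree.postorder:
        if node.is_tip:
            x[node.index] = float(values[node.name])
            v[node.index] = node.length or 0.0
        else:
            (c1, c2) = node.children
            v1, v2 = v[c1.index], v[c2.index]
            s = v1 + v2
            if s <= 0:
                s = 1e-12
            contrasts.append((x[c1.index] - x[c2.index]) / math.sqrt(s))
            esd.append(math.sqrt(s))
            node_h.append(T - node.age)
            x[node.index] = (v2 * x[c1.index] + v1 * x[c2.index]) / s
            v[node.index] = (node.length or 0.0) + v1 * v2 / s
    return np.asarray(contrasts), np.asarray(esd), np.asarray(node_h)


def _sim_bm_unit(tree: DatedTree, rng) -> dict:
    """One draw of unit-rate BM tip values on ``tree``."""
    vals = {tree.root.index: 0.0}
    out = {}
    for node in tree.preorder():
        if node.parent is not None:
            bl = max(node.length, 0.0)
            vals[node.index] = vals[node.parent.index] + rng.standard_normal() * math.sqrt(bl)
        if node.is_tip:
            out[node.name] = vals[node.index]
    return out


def _contrast_stats(c: np.ndarray, esd: np.ndarray, h: np.ndarray) -> dict:
    absc = np.abs(c)
    out = {
        "msig": float(np.mean(c ** 2)),
        "cvar": float(np.std(absc, ddof=1) / np.mean(absc)) if np.mean(absc) > 0 else 0.0,
        "sasr": _slope(h, absc),
        "svar": _slope(esd, absc),
        "dcdf": float(stats.kstest(c, "norm").statistic),
    }
    return out


def _slope(x, y) -> float:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) < 1e-12:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])


def trait_adequacy(
    tree: DatedTree,
    trait: pd.Series,
    fit: TraitModelFit,
    n_sims: int = 1000,
    seed=None,
) -> dict:
    """Adequacy of a fitted trait model by contrast statistics.

    Rescales the tree so the fitted model becomes unit-rate BM,
    computes standardized independent contrasts of the observed data,
    simulates ``n_sims`` unit-BM datasets on the rescaled tree, and
    reports the observed two-sided quantile of each statistic:
    mean squared standardized contrast (``msig``), coefficient of
    variation of |contrasts| (``cvar``), slope of |contrasts| on node
    height (``sasr``), slope on expected contrast SD (``svar``), and the
    KS distance of contrasts from standard normal (``dcdf``).
    """
    trait = trait.dropna()
    sub_labels = set(trait.index)
    if sub_labels != set(tree.tip_labels):
        from .tree import extract_clade
        # adequacy requires trait values for every tip of the tree used;
        # restrict to the covered subtree
        keep = [l for l in tree.tip_labels if l in sub_labels]
        tree = _prune_to(tree, keep)
    rtree = _rescale_tree(tree, fit)
    rng = np.random.default_rng(seed)
    c_obs, esd, h = _pic(rtree, trait.to_dict())
    obs = _contrast_stats(c_obs, esd, h)
    sims = {k: np.empty(n_sims) for k in obs}
    for s in range(n_sims):
        vals = _sim_bm_unit(rtree, rng)
        c_s, esd_s, h_s = _pic(rtree, vals)
        for k, vv in _contrast_stats(c_s, esd_s, h_s).items():
            sims[k][s] = vv
    report = {"n_sims": n_sims, "statistics": {}}
    adequate = True
    for k, o in obs.items():
        arr = sims[k]
        q = float((np.sum(arr < o) + 0.5 * np.sum(arr == o)) / n_sims)
        ok = 0.025 <= q <= 0.975
        adequate &= ok
        report["statistics"][k] = {"observed": o, "quantile": q, "within_bounds": ok}
    report["adequate"] = bool(adequate)
    return report


def _prune_to(tree: DatedTree, labels: list) -> DatedTree:
    """Subtree restricted to the given tips (non-MRCA-spanning prune)."""
    from .tree import Node as _N

    keep = set(labels)

    def rec(node):
        if node.is_tip:
            return _copy(node) if node.name in keep else None
        kids = [rec(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        out = _N(node.name, node.age)
        for k in kids:
            out.add_child(k)
        return out

    def _copy(node):
        return _N(node.name, node.age)

    root = rec(tree.root)
    if root is None or root.is_tip:
        raise ValueError("fewer than 2 tips retained")
    return DatedTree(root, require_ultrametric=False)


# ----------------------------------------------------------------------
# Mk ancestral states and stochastic mapping


@dataclass
class MkFit:
    states: tuple
    Q: pd.DataFrame
    rate: float
    logL: float
    model: str
    marginals: pd.DataFrame  # rows: node index, cols: states
    map_states: dict  # node index -> state
    paint: RegimePaint


def _mk_messages(tree: DatedTree, tip_idx: dict, Q: np.ndarray, k: int):
    """Post-order partial likelihoods and per-branch transition matrices."""
    P: dict[int, np.ndarray] = {}
    up: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}
    for node in tree.postorder:
        if node.is_tip:
            vec = np.zeros(k)
            vec[tip_idx[node.name]] = 1.0
            up[node.index] = vec
        else:
            vec = np.ones(k)
            for c in node.children:
                vec = vec * msg[c.index]
            up[node.index] = vec
        if node.parent is not None:
            P[node.index] = expm(Q * node.length)
            msg[node.index] = P[node.index] @ up[node.index]
    return up, msg, P


def _mk_loglik(tree, tip_idx, Q, k) -> float:
    up, _, _ = _mk_messages(tree, tip_idx, Q, k)
    root = up[tree.root.index]
    lik = float(np.mean(root))  # uniform root prior
    return math.log(lik) if lik > 0 else -np.inf


def mk_asr(
    tree: DatedTree,
    niche: pd.Series,
    model: str = "equal-rates",
    states: tuple | None = None,
) -> MkFit:
    """ML Mk model with marginal ancestral states and a MAP painting.

    ``model`` is ``"equal-rates"`` (one transition rate) or
    ``"symmetric"`` (free symmetric rates).  Marginal probabilities use
    the standard two-pass (up/down message) algorithm with a uniform
    root prior; the MAP painting assigns each branch its parent node's
    MAP state.
    """
    niche = niche.dropna().astype(str)
    missing = set(tree.tip_labels) - set(niche.index)
    if missing:
        raise ValueError(f"tips without niche data: {sorted(missing)[:5]}")
    states = tuple(states) if states else tuple(sorted(niche.unique()))
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    tip_idx = {lab: sidx[niche.loc[lab]] for lab in tree.tip_labels}

    if k == 1:
        warnings.warn("single observed state; trivial painting returned")
        paint = RegimePaint.uniform(tree, states[0], states)
        marg = pd.DataFrame(
            1.0, index=[n.index for n in tree.postorder], columns=list(states)
        )
        Q = pd.DataFrame([[0.0]], index=list(states), columns=list(states))
        return MkFit(states, Q, 0.0, 0.0, model, marg,
                     {n.index: states[0] for n in tree.postorder}, paint)

    T = tree.crown_age

    def build_Q(x):
        if model == "equal-rates":
            q = math.exp(x[0])
            Q = np.full((k, k), q)
        elif model == "symmetric":
            Q = np.zeros((k, k))
            it = iter(x)
            for i in range(k):
                for j in range(i + 1, k):
                    Q[i, j] = Q[j, i] = math.exp(next(it))
        else:
            raise ValueError("model must be 'equal-rates' or 'symmetric'")
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    n_par = 1 if model == "equal-rates" else k * (k - 1) // 2
    x0 = np.full(n_par, math.log(max(1.0 / T, 1e-3)))
    res = optimize.minimize(
        lambda x: -_mk_loglik(tree, tip_idx, build_Q(x), k),
        x0, method="L-BFGS-B",
        bounds=[(math.log(1e-7), math.log(100.0))] * n_par,
        options={"ftol": 1e-12},
    )
    Qm = build_Q(res.x)
    logL = -res.fun

    up, msg, P = _mk_messages(tree, tip_idx, Qm, k)
    down: dict[int, np.ndarray] = {tree.root.index: np.full(k, 1.0 / k)}
    for node in tree.preorder():
        if node.is_tip:
            continue
        for c in node.children:
            other = down[node.index].copy()
            for s in node.children:
                if s is not c:
                    other = other * msg[s.index]
            down[c.index] = P[c.index].T @ other
    marg = {}
    for node in tree.postorder:
        m = up[node.index] * down[node.index]
        tot = m.sum()
        marg[node.index] = m / tot if tot > 0 else np.full(k, 1.0 / k)
    marg_df = pd.DataFrame.from_dict(marg, orient="index")
    marg_df.columns = list(states)
    map_states = {i: states[int(np.argmax(v))] for i, v in marg.items()}
    paint = RegimePaint.from_node_states(tree, map_states, states)
    rate = float(Qm[0, 1]) if model == "equal-rates" else float(np.mean(Qm[~np.eye(k, dtype=bool)]))
    return MkFit(
        states=states,
        Q=pd.DataFrame(Qm, index=list(states), columns=list(states)),
        rate=rate, logL=float(logL), model=model, marginals=marg_df,
        map_states=map_states, paint=paint,
    )


def stochastic_map(
    tree: DatedTree,
    niche: pd.Series,
    Q: pd.DataFrame,
    n_maps: int = 100,
    seed=None,
    max_rejects: int = 100_000,
) -> list[RegimePaint]:
    """Stochastic character maps conditioned on the tip states.

    Node states are drawn from their joint conditional distribution
    (root from the posterior, children given parents), then each branch
    history is simulated conditional on its endpoints by rejection
    sampling.  Tip states are honoured exactly.
    """
    niche = niche.dropna().astype(str)
    states = tuple(Q.index)
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    Qm = Q.to_numpy()
    tip_idx = {lab: sidx[niche.loc[lab]] for lab in tree.tip_labels}
    up, msg, P = _mk_messages(tree, tip_idx, Qm, k)
    rng = np.random.default_rng(seed)
    root_post = up[tree.root.index] * (1.0 / k)
    root_post = root_post / root_post.sum()

    leave = -np.diag(Qm)
    jump = Qm.copy()
    np.fill_diagonal(jump, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(leave[:, None] > 0, jump / np.where(leave[:, None] > 0, leave[:, None], 1.0), 0.0)

    def sample_path(i, j, length):
        """CTMC path from state i to j over ``length`` (list of
        (duration, state)); rejection sampling."""
        if length <= 0:
            return [(0.0, states[j])]
        for _ in range(max_rejects):
            segs = []
            s = i
            t = 0.0
            while True:
                rate = leave[s]
                w = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                if t + w >= length:
                    segs.append((length - t, states[s]))
                    break
                segs.append((w, states[s]))
                t += w
                s = int(rng.choice(k, p=jump[s]))
            if s == j:
                return segs
        raise RuntimeError(
            f"rejection limit exceeded on a branch (states {states[i]}"
            f" -> {states[j]}, length {length:g})"
        )

    maps = []
    for _ in range(n_maps):
        node_state: dict[int, int] = {}
        node_state[tree.root.index] = int(rng.choice(k, p=root_post))
        segments = {}
        for node in tree.preorder():
            for c in node.children:
                pstate = node_state[node.index]
                w = P[c.index][pstate] * up[c.index]
                w = w / w.sum()
                cstate = int(rng.choice(k, p=w))
                node_state[c.index] = cstate
                segments[c.index] = sample_path(pstate, cstate, c.length)
        maps.append(
            RegimePaint(
                tree, segments, states[node_state[tree.root.index]],
                states, source="stochastic-map",
            )
        )
    return maps


# ----------------------------------------------------------------------
# Multi-regime (state-dependent) BM/OU models

MULTIREGIME_MODELS = ("BM1", "OU1", "BMS", "OUM", "OUMA", "OUMV", "OUMVA")


@dataclass
class MultiRegimeFit:
    model: str
    states: tuple
    theta: pd.Series | None
    alpha: pd.Series
    sigma2: pd.Series
    x0: float
    logL: float
    k: int
    aicc: float
    n: int
    theta_se: pd.Series | None = None
    flags: list = field(default_factory=list)
    weight: float | None = None

    def to_dict(self):
        return {
            "model": self.model,
            "theta": None if self.theta is None else self.theta.to_dict(),
            "alpha": self.alpha.to_dict(),
            "sigma2": self.sigma2.to_dict(),
            "x0": self.x0, "logL": self.logL, "k": self.k,
            "AICc": self.aicc, "n": self.n,
            "flags": list(self.flags),
        }


class _PaintArrays:
    """Per-tip path segments and pair MRCA bookkeeping for the painted
    multivariate-normal computation."""

    def __init__(self, tree: DatedTree, paint: RegimePaint, species: pd.Index):
        self.tree = tree
        self.paint = paint
        labels = tree.tip_labels
        pos = {s: i for i, s in enumerate(labels)}
        self.tip_rows = np.array([pos[s] for s in species])
        self.mrca = tree.mrca_matrix()
        # preorder list of (node, [(duration, state_index), ...])
        self.states = paint.observed_states()
        self.sidx = {s: i for i, s in enumerate(self.states)}
        self.branch_segs = {}
        for node in tree.postorder:
            if node.parent is None:
                continue
            self.branch_segs[node.index] = [
                (d, self.sidx[s]) for d, s in paint.segments[node.index]
            ]
        self.root_state = self.sidx[paint.root_state]
        self.n_states = len(self.states)
        self.preorder = tree.preorder()
        self.n_nodes = len(tree.postorder)

    def moments(self, alpha_vec: np.ndarray, sig_vec: np.ndarray):
        """Stable accumulation of the regime-OU mean weights and
        covariance building blocks.

        Returns (W, cov) for the selected tip rows, where the tip mean is
        ``W @ theta`` (root anchored at the root regime's optimum) and
        ``cov`` is the full covariance for unit overall scale.
        """
        nn = self.n_nodes
        K = self.n_states
        B = np.zeros(nn)  # cumulative alpha from root
        H = np.zeros(nn)  # variance accumulated with decay to the node
        Mw = np.zeros((nn, K))  # theta weights with decay
        root = self.tree.root.index
        Mw[root, self.root_state] = 1.0  # x0 = theta(root regime)
        for node in self.preorder:
            if node.parent is None:
                continue
            i, p = node.index, node.parent.index
            b = B[p]
            h = H[p]
            mw = Mw[p].copy()
            for (d, s) in self.branch_segs[node.index]:
                a, s2 = alpha_vec[s], sig_vec[s]
                ad = a * d
                decay = math.exp(-ad)
                if a > 0:
                    h = h * decay * decay + s2 * (1.0 - decay * decay) / (2.0 * a)
                    mw = mw * decay
                    mw[s] += 1.0 - decay
                else:
                    h = h + s2 * d
                b += ad
            B[i], H[i] = b, h
            Mw[i] = mw
        tips = self.tip_rows
        Bt = B[tips]
        sub_mrca = self.mrca[np.ix_(tips, tips)]
        # cov_ij = H(mrca) * exp(-(B_i - B_mrca)) * exp(-(B_j - B_mrca))
        cov = H[sub_mrca] * np.exp(-(Bt[:, None] - B[sub_mrca])) * np.exp(
            -(Bt[None, :] - B[sub_mrca])
        )
        W = Mw[tips]
        return W, cov


def _model_spec(model: str, K: int):
    """Which parameter blocks are free, and the AICc parameter count."""
    if model == "BM1":
        return {"alpha": "zero", "sigma": "one", "mean": "x0", "k": 2}
    if model == "OU1":
        return {"alpha": "one", "sigma": "one", "mean": "theta", "k": 3}
    if model == "BMS":
        return {"alpha": "zero", "sigma": "multi", "mean": "x0", "k": K + 1}
    if model == "OUM":
        return {"alpha": "one", "sigma": "one", "mean": "theta", "k": K + 2}
    if model == "OUMA":
        return {"alpha": "multi", "sigma": "one", "mean": "theta", "k": 2 * K + 1}
    if model == "OUMV":
        return {"alpha": "one", "sigma": "multi", "mean": "theta", "k": 2 * K + 1}
    if model == "OUMVA":
        return {"alpha": "multi", "sigma": "multi", "mean": "theta", "k": 3 * K}
    raise ValueError(f"unknown multi-regime model {model!r}")


def fit_multiregime(
    tree: DatedTree,
    trait: pd.Series,
    paint: RegimePaint,
    model: str = "OUM",
    starts: int = 3,
    seed: int | None = None,
) -> MultiRegimeFit:
    """State-dependent BM/OU fit along a regime painting.

    Candidate models: single-rate BM/OU (``BM1``, ``OU1``), state-
    dependent BM (``BMS``), and the state-dependent OU family with
    unique optima (``OUM``), plus unique constraints (``OUMA``), unique
    rates (``OUMV``), or both (``OUMVA``).  The likelihood is the exact
    multivariate normal implied by piecewise-regime OU along the painted
    branches; the root value is anchored at the root regime's optimum,
    so a one-regime ``OUM`` reduces to the fixed-root single OU.
    """
    spec = _model_spec(model, 1)  # validate name early
    trait = trait.dropna().astype(float)
    pa = _PaintArrays(tree, paint, trait.index)
    K = pa.n_states
    spec = _model_spec(model, K)
    tip_states = pd.Series(paint.tip_states()).loc[trait.index]
    counts = tip_states.value_counts()
    if model not in ("BM1", "OU1") and (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"regimes with fewer than 2 tips: {bad}")
    y = trait.to_numpy()
    n = len(y)
    T = tree.crown_age
    rng = np.random.default_rng(seed)

    uses_single_regime = model in ("BM1", "OU1")

    def unpack(psi):
        """psi -> (alpha_vec, sigma_rel_vec)."""
        i = 0
        if spec["alpha"] == "zero":
            alpha = np.zeros(K)
        elif spec["alpha"] == "one":
            alpha = np.full(K, math.exp(psi[i])); i += 1
        else:
            alpha = np.exp(psi[i:i + K]); i += K
        if spec["sigma"] == "one":
            sig = np.ones(K)
        else:
            sig = np.concatenate([[1.0], np.exp(psi[i:i + K - 1])]); i += K - 1
        return alpha, sig

    n_psi = 0
    n_psi += {"zero": 0, "one": 1, "multi": K}[spec["alpha"]]
    n_psi += {"one": 0, "multi": K - 1}[spec["sigma"]]

    def profile(psi):
        alpha, sig = unpack(psi)
        W, cov = pa.moments(alpha, sig)
        if spec["mean"] == "x0":
            X = np.ones((n, 1))
        else:
            X = W
            if uses_single_regime:
                X = W.sum(axis=1, keepdims=True)
        try:
            logL, beta, s2, covb = _mvn_profile(cov, X, y)
        except linalg.LinAlgError:
            return -np.inf, None
        return logL, (alpha, sig, beta, s2, covb, X)

    if n_psi == 0:
        best_psi = np.zeros(0)
        logL, parts = profile(best_psi)
    else:
        lo, hi = math.log(1e-6), math.log(100.0 / T)
        bounds = [(lo, hi)] * n_psi
        if spec["sigma"] == "multi":
            ns = K - 1
            bounds[n_psi - ns:] = [(-8.0, 8.0)] * ns
        x0s = [np.full(n_psi, math.log(1.0 / T))]
        if spec["sigma"] == "multi":
            x0s[0][n_psi - (K - 1):] = 0.0
        for _ in range(max(starts - 1, 0)):
            x = np.array([rng.uniform(b[0] / 2, b[1] / 2) for b in bounds])
            x0s.append(x)
        best = None
        for x0 in x0s:
            res = optimize.minimize(
                lambda p: -profile(p)[0], x0, method="L-BFGS-B",
                bounds=bounds, options={"ftol": 1e-11, "maxiter": 400},
            )
            if best is None or res.fun < best.fun:
                best = res
        best_psi = best.x
        logL, parts = profile(best_psi)
    if parts is None or not np.isfinite(logL):
        raise RuntimeError(f"multi-regime fit failed for {model}")
    alpha, sig, beta, s2, covb, X = parts
    flags = []
    if spec["alpha"] != "zero" and np.any(alpha > 0.97 * 100.0 / T):
        flags.append("alpha at upper bound")

    states = pa.states
    sigma2 = pd.Series(sig * s2, index=list(states))
    alpha_s = pd.Series(alpha, index=list(states))

    def se_from_observed_info(beta_hat):
        """Standard errors of the mean parameters from the observed
        information over (beta, psi, log scale) jointly, so uncertainty
        in the constraint/rate parameters propagates into the optima."""
        nb = len(beta_hat)
        p_hat = np.concatenate([beta_hat, best_psi, [math.log(s2)]])

        def nll_full(p):
            b = p[:nb]
            psi = p[nb:nb + n_psi]
            scale = math.exp(p[-1])
            a_v, s_v = unpack(psi)
            W, cov = pa.moments(a_v, s_v)
            Xf = np.ones((n, 1)) if spec["mean"] == "x0" else (
                W.sum(axis=1, keepdims=True) if uses_single_regime else W
            )
            r_v = y - Xf @ b
            V = scale * cov
            try:
                cho = linalg.cho_factor(V, lower=True)
            except linalg.LinAlgError:
                return 1e10
            logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
            quad = float(r_v @ linalg.cho_solve(cho, r_v))
            return 0.5 * (n * math.log(2 * math.pi) + logdet + quad)

        d = len(p_hat)
        h = 1e-4 * np.maximum(np.abs(p_hat), 1.0)
        H = np.empty((d, d))
        f0 = nll_full(p_hat)
        for i in range(d):
            for j in range(i, d):
                ei = np.zeros(d); ei[i] = h[i]
                ej = np.zeros(d); ej[j] = h[j]
                fpp = nll_full(p_hat + ei + ej)
                fpm = nll_full(p_hat + ei - ej)
                fmp = nll_full(p_hat - ei + ej)
                fmm = nll_full(p_hat - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
        try:
            vcov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(vcov)[:nb], 0.0))
            if np.all(np.isfinite(se)) and np.all(se > 0):
                return se
        except np.linalg.LinAlgError:
            pass
        return None

    if spec["mean"] == "x0":
        theta = None
        theta_se = None
        x0_val = float(beta[0])
    else:
        se_full = se_from_observed_info(np.atleast_1d(beta))
        if uses_single_regime:
            theta = pd.Series(float(beta[0]), index=list(states))
            se = float(se_full[0]) if se_full is not None else math.sqrt(covb[0, 0] * s2)
            theta_se = pd.Series(se, index=list(states))
        else:
            theta = pd.Series(beta, index=list(states))
            if se_full is not None:
                theta_se = pd.Series(se_full, index=list(states))
            else:
                theta_se = pd.Series(np.sqrt(np.diag(covb) * s2), index=list(states))
        x0_val = float(theta.iloc[pa.root_state])
    return MultiRegimeFit(
        model=model, states=states, theta=theta, alpha=alpha_s,
        sigma2=sigma2, x0=x0_val, logL=float(logL), k=spec["k"],
        aicc=_aicc(logL, spec["k"], n), n=n, theta_se=theta_se, flags=flags,
    )


def fit_multiregime_candidates(
    tree: DatedTree,
    trait: pd.Series,
    paint: RegimePaint,
    models: tuple = MULTIREGIME_MODELS,
    starts: int = 3,
    seed: int | None = None,
) -> list[MultiRegimeFit]:
    """Fit the candidate set and attach Akaike weights."""
    fits = []
    for i, m in enumerate(models):
        fits.append(
            fit_multiregime(tree, trait, paint, m, starts=starts,
                            seed=None if seed is None else seed + i)
        )
    aicc = np.array([f.aicc for f in fits])
    delta = aicc - aicc.min()
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    for f, wi in zip(fits, w):
        f.weight = float(wi)
    return fits


def multiregime_over_posterior(
    trees: list,
    trait: pd.Series,
    niche: pd.Series,
    n_samples: int = 100,
    models: tuple = MULTIREGIME_MODELS,
    mk_model: str = "equal-rates",
    starts: int = 2,
    seed: int | None = None,
) -> dict:
    """Model-preference tally across posterior trees and stochastic maps.

    For each of ``n_samples`` draws, one tree is taken (cycling through
    ``trees``), a stochastic map of the niche character is simulated
    under that tree's ML Mk rates, the candidate models are fitted, and
    the AICc-best model is tallied.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    rng = np.random.default_rng(seed)
    tally: dict[str, int] = {m: 0 for m in models}
    details = []
    mk_cache: dict[int, MkFit] = {}
    for s in range(n_samples):
        ti = s % len(trees)
        tr = trees[ti]
        if ti not in mk_cache:
            mk_cache[ti] = mk_asr(tr, niche, model=mk_model)
        mk = mk_cache[ti]
        for attempt in range(20):
            paint = stochastic_map(
                tr, niche, mk.Q, n_maps=1, seed=int(rng.integers(2**31 - 1))
            )[0]
            tip_states = pd.Series(paint.tip_states()).loc[trait.dropna().index]
            if (tip_states.value_counts() >= 2).all():
                break
        best = None
        for m in models:
            try:
                f = fit_multiregime(tr, trait, paint, m, starts=starts,
                                    seed=int(rng.integers(2**31 - 1)))
            except (ValueError, RuntimeError):
                continue
            if best is None or f.aicc < best.aicc:
                best = f
        if best is not None:
            tally[best.model] += 1
            details.append({"tree": ti, "best": best.model, "AICc": best.aicc})
    return {"tally": tally, "n_samples": n_samples, "details": details}
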