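"""Likelihood-based birth-death diversification models on dated trees.

Implements the reconstructed-process likelihood for ultrametric trees
under time-constant, time-varying and covariate-dependent speciation and
extinction rates, with incomplete sampling and conditioning on the crown
age and the survival of both crown lineages.

All rate functions are parameterized on the *age* axis: ``t`` is My
before present, so a negative slope/exponent means rates that increase
toward the present.

Notation (age axis, present = 0):

* ``r(t) = lambda(t) - mu(t)``, ``R(t) = int_0^t r(u) du``
* ``Phi(t)``: probability a lineage alive at age ``t`` has at least one
  sampled descendant at present; ``y = 1/Phi`` satisfies the linear ODE
  ``y' = -r y + lambda`` with ``y(0) = 1/rho``
* ``p1(t) = exp(-R(t)) / (rho * y(t)^2)``: probability a lineage at age
  ``t`` leaves exactly one sampled descendant lineage

The log-likelihood of branching times ``x_1 > ... > x_{n-1}`` (crown age
``x_1``), conditioned on the crown age and survival of both crown
lineages, is::

    sum_{i>=2} [ log lambda(x_i) + log p1(x_i) ]
        + 2 log p1(x_1) - 2 log Phi(x_1)

For constant rates everything is closed form; otherwise ``R`` and the
integral ``int lambda e^R`` are computed by cumulative Simpson quadrature
on a fine grid containing every branching time.  Instantaneous
mass-extinction events (each lineage survives with probability ``s``)
enter as multiplicative jumps ``y -> y/s``; each reconstructed lineage
crossing the event contributes its survival factor ``s`` times the
``1/s^2`` flow discontinuity from the jump in ``y``, i.e. ``1/s`` net.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate, optimize

from .tree import DatedTree, lineages_at

__all__ = [
    "BDModel",
    "BDFit",
    "ModelSet",
    "CovariateCurve",
    "bd_loglik",
    "fit_bd",
    "candidate_models",
    "fit_candidates",
    "compare_and_average",
    "akaike_weights",
    "rate_through_time",
    "mass_extinction_test",
    "covariate_bd",
    "ltt_to_diversity_curve",
    "adequacy_check",
]

_LAMBDA_FORMS = ("constant", "linear", "exponential", "covariate")
_MU_FORMS = ("zero", "constant", "linear", "exponential")


class CovariateCurve:
    """A (age, value) time series usable as a speciation-rate covariate.

    ``kind="linear"`` interpolates linearly; ``kind="step"`` treats the
    series as piecewise-constant between successive ages (the form
    produced by a lineage-through-time curve).
    """

    def __init__(self, ages, values, kind: str = "linear"):
        ages = np.asarray(ages, dtype=float)
        values = np.asarray(values, dtype=float)
        if ages.ndim != 1 or ages.shape != values.shape:
            raise ValueError("ages and values must be matching 1-D arrays")
        order = np.argsort(ages)
        self.ages = ages[order]
        self.values = values[order]
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("covariate ages must be strictly monotone")
        if kind not in ("linear", "step"):
            raise ValueError("kind must be 'linear' or 'step'")
        self.kind = kind

    @property
    def span(self) -> tuple[float, float]:
        return float(self.ages[0]), float(self.ages[-1])

    def check_span(self, max_age: float, allow_extrapolation: bool = False):
        lo, hi = self.span
        if (lo > 0 or hi < max_age) and not allow_extrapolation:
            raise ValueError(
                f"covariate spans [{lo:g}, {hi:g}] My but [0, {max_age:g}] "
                "is required; pass allow_extrapolation=True to clamp"
            )

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "linear":
            return np.interp(t, self.ages, self.values)
        idx = np.clip(np.searchsorted(self.ages, t, side="right") - 1, 0, len(self.ages) - 1)
        return self.values[idx]

    @classmethod
    def read_csv(cls, path, kind: str = "linear") -> "CovariateCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), kind=kind)


@dataclass
class BDModel:
    """A birth-death model: functional forms plus parameter values.

    Parameters (all on the age axis, rates in lineages/My):

    * ``lambda0``: speciation rate at present
    * ``a_lam``: slope (linear) or exponent (exponential) of lambda(t);
      negative values mean speciation increasing toward the present
    * ``mu0``, ``a_mu``: likewise for extinction
    * ``beta``: sensitivity of log-speciation to the covariate
    """

    lambda_form: str = "constant"
    mu_form: str = "zero"
    params: dict = field(default_factory=dict)
    rho: float = 1.0
    covariate: CovariateCurve | None = None
    name: str | None = None

    def __post_init__(self):
        if self.lambda_form not in _LAMBDA_FORMS:
            raise ValueError(f"unknown lambda_form {self.lambda_form!r}")
        if self.mu_form not in _MU_FORMS:
            raise ValueError(f"unknown mu_form {self.mu_form!r}")
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if self.lambda_form == "covariate" and self.covariate is None:
            raise ValueError("covariate form requires a CovariateCurve")
        defaults = {"lambda0": 0.1, "a_lam": 0.0, "mu0": 0.0, "a_mu": 0.0, "beta": 0.0}
        self.params = {**defaults, **self.params}

    # raw (unclipped) rates; clipping happens in the likelihood
    def lambda_raw(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.lambda_form == "constant":
            return np.full_like(t, p["lambda0"])
        if self.lambda_form == "linear":
            return p["lambda0"] + p["a_lam"] * t
        if self.lambda_form == "exponential":
            return p["lambda0"] * np.exp(np.clip(p["a_lam"] * t, -700, 700))
        return p["lambda0"] * np.exp(np.clip(p["beta"] * self.covariate(t), -700, 700))

    def mu_raw(self, t):
        t = np.asarray(t, dtype=float)
        p = self.params
        if self.mu_form == "zero":
            return np.zeros_like(t)
        if self.mu_form == "constant":
            return np.full_like(t, p["mu0"])
        if self.mu_form == "linear":
            return p["mu0"] + p["a_mu"] * t
        return p["mu0"] * np.exp(np.clip(p["a_mu"] * t, -700, 700))

    def lambda_at(self, t):
        return np.maximum(self.lambda_raw(t), 0.0)

    def mu_at(self, t):
        return np.maximum(self.mu_raw(t), 0.0)

    @property
    def is_constant_rate(self) -> bool:
        return self.lambda_form == "constant" and self.mu_form in ("zero", "constant")

    def default_free(self) -> tuple[str, ...]:
        free = ["lambda0"]
        if self.lambda_form in ("linear", "exponential"):
            free.append("a_lam")
        if self.lambda_form == "covariate":
            free.append("beta")
        if self.mu_form != "zero":
            free.append("mu0")
        if self.mu_form in ("linear", "exponential"):
            free.append("a_mu")
        return tuple(free)

    def label(self) -> str:
        if self.name:
            return self.name
        return f"lambda-{self.lambda_form}/mu-{self.mu_form}"


# ----------------------------------------------------------------------
# Likelihood


def _closed_form_parts(model: BDModel, ages: np.ndarray):
    """R(t), y(t) for constant rates (analytic)."""
    lam = model.params["lambda0"]
    mu = model.params["mu0"] if model.mu_form == "constant" else 0.0
    rho = model.rho
    r = lam - mu
    t = ages
    R = r * t
    if abs(r) < 1e-12:
        y = 1.0 / rho + lam * t
    else:
        y = np.exp(-r * t) / rho + lam * (1.0 - np.exp(-r * t)) / r
    return R, y


class _QuadParts:
    """R(t), I(t) = int lambda e^R, and y(t) with event jumps.

    Integration is composite Simpson on uniform sub-grids between
    "anchor" ages (branching times, event times, 0 and the crown age),
    so every queried age is an exact grid point and each panel keeps
    Simpson's full order.
    """

    def __init__(self, model: BDModel, max_age: float, anchors=None,
                 events=None, grid_size: int = 4096):
        events = sorted(events or [], key=lambda e: e[0])
        pts = {0.0, float(max_age)}
        if anchors is not None:
            pts.update(float(a) for a in anchors)
        pts.update(float(e[0]) for e in events)
        anchor_arr = np.array(sorted(pts))
        nseg = len(anchor_arr) - 1
        # same (even) number of Simpson panels per segment: vectorizes
        # over segments while keeping every anchor an exact grid point
        m = max(8, 2 * int(np.ceil(grid_size / max(nseg, 1) / 2)))
        a = anchor_arr[:-1, None]
        b = anchor_arr[1:, None]
        frac = np.linspace(0.0, 1.0, m + 1)[None, :]
        xs = a + (b - a) * frac  # (nseg, m+1)
        with np.errstate(over="ignore", invalid="ignore"):
            lam = model.lambda_at(xs)
            mu = model.mu_at(xs)
            zero_col = np.zeros((nseg, 1))
            Rseg = np.concatenate(
                [zero_col, integrate.cumulative_simpson(lam - mu, x=xs, axis=1)],
                axis=1,
            )
            R_off = np.concatenate([[0.0], np.cumsum(Rseg[:-1, -1])])
            Rfull = np.clip(Rseg + R_off[:, None], -200.0, 200.0)
            integrand = lam * np.exp(Rfull)
            Iseg = np.concatenate(
                [zero_col, integrate.cumulative_simpson(integrand, x=xs, axis=1)],
                axis=1,
            )
            I_off = np.concatenate([[0.0], np.cumsum(Iseg[:-1, -1])])
            Ifull = Iseg + I_off[:, None]
        grid = np.concatenate([anchor_arr[:1], xs[:, 1:].ravel()])
        R = np.concatenate([[0.0], Rfull[:, 1:].ravel()])
        I = np.nan_to_num(
            np.concatenate([[0.0], Ifull[:, 1:].ravel()]),
            nan=np.inf, posinf=np.inf,
        )
        # piecewise constants c_k: y(t) = exp(-R)(c_k + I(t)) within segment k
        bounds = [e[0] for e in events]
        cs = [1.0 / model.rho]
        for (t_e, s_e) in events:
            idx = np.searchsorted(grid, t_e)
            I_e = I[idx]
            c_new = (cs[-1] + I_e) / s_e - I_e
            cs.append(c_new)
        self.grid, self.R, self.I = grid, R, I
        self.seg_bounds = np.asarray(bounds)
        self.cs = np.asarray(cs)

    def parts_at(self, ages: np.ndarray):
        idx = np.searchsorted(self.grid, ages)
        idx = np.clip(idx, 0, len(self.grid) - 1)
        # ages are grid members by construction; guard tiny fp wiggle
        if not np.allclose(self.grid[idx], ages, rtol=0, atol=1e-9):
            R = np.interp(ages, self.grid, self.R)
            I = np.interp(ages, self.grid, self.I)
        else:
            R = self.R[idx]
            I = self.I[idx]
        seg = np.searchsorted(self.seg_bounds, ages, side="right")
        y = np.exp(-R) * (self.cs[seg] + I)
        return R, y


def bd_loglik(
    tree: DatedTree,
    model: BDModel,
    method: str = "auto",
    events=None,
    grid_size: int = 4096,
    negative_rates: str = "error",
) -> float:
    """Log-likelihood of the tree's branching times under ``model``.

    Conditioned on the crown age and survival of both crown lineages,
    with sampling fraction ``model.rho`` applied at present.

    ``events`` is an optional list of ``(age, survival_prob)`` pairs for
    instantaneous mass-extinction events.  ``negative_rates`` is
    ``"error"`` (reject models whose raw rate functions go negative on
    [0, crown_age]) or ``"penalize"`` (clip at zero and subtract a
    smooth penalty; used internally during optimization).
    """
    if method not in ("auto", "closed", "quadrature"):
        raise ValueError("method must be auto|closed|quadrature")
    bt = tree.branching_times()
    T = bt[0]
    n = tree.n_tips

    check_grid = np.linspace(0.0, T, 257)
    lam_raw = model.lambda_raw(check_grid)
    mu_raw = model.mu_raw(check_grid)
    penalty = 0.0
    if np.any(lam_raw < 0) or np.any(mu_raw < 0):
        if negative_rates == "error":
            raise ValueError("rate function negative on [0, crown_age]")
        neg = np.maximum(-lam_raw, 0.0) + np.maximum(-mu_raw, 0.0)
        penalty = 1e3 * float(np.trapezoid(neg, check_grid))

    if events:
        for (t_e, s_e) in events:
            if not 0 < t_e < T:
                raise ValueError(f"event age {t_e} outside (0, crown_age)")
            if not 0 < s_e <= 1:
                raise ValueError("event survival probability must be in (0, 1]")

    use_closed = model.is_constant_rate and not events and method != "quadrature"
    if method == "closed" and not use_closed:
        raise ValueError("closed form only available for constant rates without events")

    if use_closed:
        ages = np.concatenate([bt, [T]])
        R_all, y_all = _closed_form_parts(model, ages)
        R_bt, y_bt = R_all[:-1], y_all[:-1]
        R_T, y_T = R_all[-1], y_all[-1]
    else:
        qp = _QuadParts(model, T, anchors=bt, events=events, grid_size=grid_size)
        R_bt, y_bt = qp.parts_at(bt)
        R_T, y_T = (x[0] for x in qp.parts_at(np.array([T])))

    if np.any(y_bt <= 0) or y_T <= 0 or not np.all(np.isfinite(y_bt)):
        return -np.inf

    lam_bt = model.lambda_at(bt)
    if np.any(lam_bt <= 0):
        return -np.inf
    log_p1_bt = -R_bt - math.log(model.rho) - 2.0 * np.log(y_bt)
    # non-root nodes: indices 1..n-2 of bt
    ll = float(np.sum(np.log(lam_bt[1:]) + log_p1_bt[1:]))
    ll += 2.0 * log_p1_bt[0]
    ll += 2.0 * math.log(y_T)  # divide by Phi(T)^2
    if events:
        # each reconstructed lineage crossing an event carries the
        # survival factor s and a (y+/y-)^2 = 1/s^2 flow-boundary factor
        # (y jumps by 1/s at the event), i.e. 1/s net per crossing
        for (t_e, s_e) in events:
            ll -= lineages_at(tree, t_e) * math.log(s_e)
    if not np.isfinite(ll):
        return -np.inf
    return ll - penalty


# ----------------------------------------------------------------------
# Fitting


@dataclass
class BDFit:
    model: BDModel
    logL: float
    k: int
    aicc: float
    n_obs: int
    crown_age: float
    free: tuple
    converged: bool = True
    events: tuple = ()
    message: str = ""

    def rates_at(self, ages):
        return self.model.lambda_at(ages), self.model.mu_at(ages)

    def to_dict(self) -> dict:
        return {
            "model": self.model.label(),
            "lambda_form": self.model.lambda_form,
            "mu_form": self.model.mu_form,
            "params": {k: float(v) for k, v in self.model.params.items()},
            "rho": self.model.rho,
            "logL": float(self.logL),
            "k": self.k,
            "AICc": float(self.aicc),
            "n_obs": self.n_obs,
        }


def _aicc(logL: float, k: int, n_obs: int) -> float:
    if n_obs - k - 1 <= 0:
        return np.inf
    return -2.0 * logL + 2 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


_LOG_PARAMS = {"lambda0", "mu0"}
_DEFAULT_BOUNDS = {
    "lambda0": (1e-6, 10.0),
    "mu0": (1e-9, 10.0),
    "a_lam": (-1.0, 1.0),
    "a_mu": (-1.0, 1.0),
    "beta": (-10.0, 10.0),
    "s": (1e-3, 1.0),
}


def _transform(name, value):
    return math.log(value) if name in _LOG_PARAMS or name == "s" else value


def _untransform(name, value):
    return math.exp(value) if name in _LOG_PARAMS or name == "s" else value


def fit_bd(
    tree: DatedTree,
    model: BDModel,
    free: tuple | None = None,
    starts: int = 10,
    seed: int | None = None,
    bounds: dict | None = None,
    events_t0: float | None = None,
    grid_size: int = 4096,
) -> BDFit:
    """Maximum-likelihood fit of a birth-death model by multi-start
    bounded optimization (L-BFGS-B on log-rates).

    ``free`` names the free parameters (default: the model form's natural
    set).  If ``events_t0`` is given, an instantaneous mass-extinction
    survival probability ``s`` at that age is estimated as an extra free
    parameter.
    """
    free = tuple(free) if free is not None else model.default_free()
    if events_t0 is not None and "s" not in free:
        free = free + ("s",)
    if not free:
        raise ValueError("at least one free parameter is required")
    bnds = {**_DEFAULT_BOUNDS, **(bounds or {})}
    rng = np.random.default_rng(seed)

    bt = tree.branching_times()
    T = bt[0]
    n = tree.n_tips
    # Yule moment start for lambda0
    tbl = tree.total_branch_length()
    lam_guess = max((n - 2) / tbl, 1e-4) if tbl > 0 else 0.1

    def build(x) -> tuple[BDModel, list]:
        params = dict(model.params)
        ev = []
        for name, xv in zip(free, x):
            v = _untransform(name, xv)
            if name == "s":
                ev = [(events_t0, v)]
            else:
                params[name] = v
        return replace(model, params=params), ev

    def nll(x):
        m, ev = build(x)
        ll = bd_loglik(
            tree, m, method="auto", events=ev or None,
            grid_size=grid_size, negative_rates="penalize",
        )
        if not np.isfinite(ll):
            return 1e10
        return -ll

    x0_list = []
    base = {
        "lambda0": lam_guess,
        "mu0": max(lam_guess / 10.0, 1e-6),
        "a_lam": 0.0,
        "a_mu": 0.0,
        "beta": 0.0,
        "s": 0.9,
    }
    x0_list.append([_transform(nm, base[nm]) for nm in free])
    for _ in range(max(starts - 1, 0)):
        x = []
        for nm in free:
            lo, hi = bnds[nm]
            if nm in _LOG_PARAMS or nm == "s":
                x.append(rng.uniform(math.log(max(lo, 1e-9)), math.log(hi)))
            else:
                x.append(rng.uniform(lo / 4, hi / 4))
        x0_list.append(x)

    tb = []
    for nm in free:
        lo, hi = bnds[nm]
        if nm in _LOG_PARAMS or nm == "s":
            tb.append((math.log(max(lo, 1e-300)), math.log(hi)))
        else:
            tb.append((lo, hi))

    best = None
    any_ok = False
    for x0 in x0_list:
        res = optimize.minimize(
            nll, x0, method="L-BFGS-B", bounds=tb,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or res.success
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(
            f"fit_bd failed to converge for {model.label()}; "
            f"best incumbent objective {None if best is None else best.fun}"
        )
    m, ev = build(best.x)
    ll = -best.fun
    k = len(free)
    fit = BDFit(
        model=m,
        logL=ll,
        k=k,
        aicc=_aicc(ll, k, n),
        n_obs=n,
        crown_age=T,
        free=free,
        converged=bool(any_ok),
        events=tuple(ev),
        message=str(best.message),
    )
    return fit


def candidate_models(rho: float = 1.0) -> list[BDModel]:
    """The default candidate set: pure birth, constant birth-death, and
    linear/exponential time-varying speciation with zero or constant
    extinction."""
    return [
        BDModel("constant", "zero", rho=rho, name="pure birth"),
        BDModel("constant", "constant", rho=rho, name="constant birth-death"),
        BDModel("linear", "zero", rho=rho, name="linear speciation, no extinction"),
        BDModel("exponential", "zero", rho=rho, name="exponential speciation, no extinction"),
        BDModel("linear", "constant", rho=rho, name="linear speciation, constant extinction"),
        BDModel("exponential", "constant", rho=rho, name="exponential speciation, constant extinction"),
    ]


def fit_candidates(
    tree: DatedTree,
    models: list[BDModel] | None = None,
    starts: int = 10,
    seed: int | None = None,
) -> "ModelSet":
    models = models if models is not None else candidate_models()
    fits = []
    for i, m in enumerate(models):
        fits.append(fit_bd(tree, m, starts=starts, seed=None if seed is None else seed + i))
    return ModelSet(fits)


def akaike_weights(aicc_values) -> np.ndarray:
    """exp(-Delta/2) normalized Akaike weights from AICc scores."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


class ModelSet:
    """A set of BDFits on the same tree, with AICc weights."""

    def __init__(self, fits: list[BDFit]):
        if not fits:
            raise ValueError("empty model set")
        n_obs = {f.n_obs for f in fits}
        if len(n_obs) != 1:
            raise ValueError("fits in a ModelSet must share n_obs")
        self.fits = list(fits)
        self.aicc = np.array([f.aicc for f in fits])
        self.delta = self.aicc - self.aicc.min()
        self.weights = akaike_weights(self.aicc)

    @property
    def best(self) -> BDFit:
        return self.fits[int(np.argmin(self.aicc))]

    @property
    def crown_age(self) -> float:
        return self.fits[0].crown_age

    def averaged_rates(self, eval_age: float = 0.0) -> dict:
        """Model-averaged speciation/extinction at ``eval_age`` plus the
        averaged time-varying coefficient (absent parameters count as 0,
        following the convention of summing weighted parameter values)."""
        lam = mu = a_lam = 0.0
        for w, f in zip(self.weights, self.fits):
            lam += w * float(f.model.lambda_at(eval_age))
            mu += w * float(f.model.mu_at(eval_age))
            if f.model.lambda_form in ("linear", "exponential"):
                a_lam += w * f.model.params["a_lam"]
        return {"lambda": lam, "mu": mu, "a_lam": a_lam, "eval_age": eval_age}

    def table(self) -> list[dict]:
        rows = []
        for f, d, w in zip(self.fits, self.delta, self.weights):
            row = f.to_dict()
            row["dAICc"] = float(d)
            row["weight"] = float(w)
            rows.append(row)
        return rows


def compare_and_average(fits, eval_age: float = 0.0) -> dict:
    """Akaike-weight table plus model-averaged rates at ``eval_age``."""
    ms = fits if isinstance(fits, ModelSet) else ModelSet(list(fits))
    out = ms.averaged_rates(eval_age)
    out["weights"] = ms.weights.tolist()
    out["table"] = ms.table()
    return out


def rate_through_time(fit_or_set, ages) -> np.ndarray:
    """Net diversification lambda(t) - mu(t) on an age grid
    (model-averaged for a ModelSet)."""
    ages = np.asarray(ages, dtype=float)
    if isinstance(fit_or_set, ModelSet):
        crown = fit_or_set.crown_age
        if np.any(ages < 0) or np.any(ages > crown + 1e-9):
            raise ValueError("age grid outside [0, crown_age]")
        out = np.zeros_like(ages)
        for w, f in zip(fit_or_set.weights, fit_or_set.fits):
            out += w * (f.model.lambda_at(ages) - f.model.mu_at(ages))
        return out
    fit = fit_or_set
    if np.any(ages < 0) or np.any(ages > fit.crown_age + 1e-9):
        raise ValueError("age grid outside [0, crown_age]")
    return fit.model.lambda_at(ages) - fit.model.mu_at(ages)


# ----------------------------------------------------------------------
# Mass-extinction test


@dataclass
class MassExtinctionReport:
    t0: float
    s_hat: float
    logL_base: float
    logL_event: float
    aicc_base: float
    aicc_event: float
    delta_aicc: float  # positive favours the event model
    favoured: bool

    def to_dict(self):
        return {k: (float(v) if not isinstance(v, bool) else v) for k, v in self.__dict__.items()}


def mass_extinction_test(
    tree: DatedTree,
    t0: float,
    base: BDModel | None = None,
    starts: int = 8,
    seed: int | None = None,
    favour_margin: float = 0.0,
) -> MassExtinctionReport:
    """Fixed-time mass-extinction test.

    Fits ``base`` (default: constant birth-death) and the same model
    augmented with an instantaneous survival probability ``s`` at age
    ``t0``, and compares by AICc (the event model is favoured when its
    AICc is lower by more than ``favour_margin`` and the estimated
    survival is clearly below 1).  "No evidence" corresponds to the base
    model favoured or ``s_hat`` near 1.
    """
    T = tree.crown_age
    if not 0 < t0 < T:
        raise ValueError(f"t0={t0} outside the tree's span (0, {T:g})")
    if base is None:
        base = BDModel("constant", "constant", name="constant birth-death")
    f0 = fit_bd(tree, base, starts=starts, seed=seed)
    f1 = fit_bd(tree, base, starts=starts, seed=None if seed is None else seed + 1,
                events_t0=t0)
    s_hat = f1.events[0][1] if f1.events else 1.0
    delta = f0.aicc - f1.aicc
    return MassExtinctionReport(
        t0=t0,
        s_hat=float(s_hat),
        logL_base=f0.logL,
        logL_event=f1.logL,
        aicc_base=f0.aicc,
        aicc_event=f1.aicc,
        delta_aicc=float(delta),
        favoured=bool(delta > favour_margin and s_hat < 0.95),
    )


# ----------------------------------------------------------------------
# Covariate models


def covariate_bd(
    tree: DatedTree,
    curve: CovariateCurve,
    rho: float = 1.0,
    mu_form: str = "zero",
    starts: int = 10,
    seed: int | None = None,
    allow_extrapolation: bool = False,
) -> BDFit:
    """Fit lambda(t) = lambda0 * exp(beta * V(t)) with V the covariate."""
    curve.check_span(tree.crown_age, allow_extrapolation)
    model = BDModel(
        "covariate", mu_form, rho=rho, covariate=curve,
        name="covariate-dependent speciation",
    )
    return fit_bd(tree, model, starts=starts, seed=seed)


def ltt_to_diversity_curve(tree: DatedTree) -> CovariateCurve:
    """Step diversity-through-time curve from a reconstructed tree,
    usable as a covariate for diversity-dependence of a competitor
    clade.  At ages older than the competitor's crown the curve is 1
    lineage; at age 0 it equals the tip count."""
    bt = tree.branching_times()
    # steps: at age >= bt[0]: 1 (stem) -- within crown: counts
    ages = np.concatenate([[0.0], bt[::-1]])  # ascending
    counts = np.concatenate([[tree.n_tips], np.arange(tree.n_tips - 1, 0, -1)])
    # ages ascending: value for t in [ages[i], ages[i+1]) is counts[i]
    return CovariateCurve(ages, counts, kind="step")


# ----------------------------------------------------------------------
# Model adequacy


def adequacy_check(
    tree: DatedTree,
    model: BDModel,
    n_sims: int = 1000,
    seed: int | None = None,
    tip_window: tuple[float, float] = (0.5, 2.0),
    max_tries_factor: int = 100,
) -> dict:
    """Posterior-predictive style adequacy check by simulation.

    Simulates ``n_sims`` trees from ``model`` conditioned on the crown
    age, survival of both crown lineages, and a tip count within
    ``tip_window`` (multiples of the empirical tip count); computes the
    summary statistics {gamma, Colless imbalance, tip count, median
    internal branch length} and reports the empirical tree's two-sided
    quantile for each.  "adequate" requires all quantiles within
    [0.025, 0.975].
    """
    from .tree import gamma_statistic, colless_index, median_internal_branch
    from .synth import simulate_bd_tree

    rng = np.random.default_rng(seed)
    n = tree.n_tips
    lo, hi = int(np.floor(tip_window[0] * n)), int(np.ceil(tip_window[1] * n))
    lo = max(lo, 3)
    stats = {"gamma": [], "colless": [], "n_tips": [], "median_internal_bl": []}
    tries = 0
    got = 0
    max_tries = max_tries_factor * n_sims
    while got < n_sims and tries < max_tries:
        tries += 1
        sim = simulate_bd_tree(
            model.lambda_at, model.mu_at, stop="age", age=tree.crown_age,
            seed=int(rng.integers(2**31 - 1)), crown=True, max_retries=1,
            raise_on_failure=False, max_lineages=5 * hi + 50,
        )
        if sim is None or not (lo <= sim.n_tips <= hi):
            continue
        got += 1
        stats["gamma"].append(gamma_statistic(sim))
        stats["colless"].append(colless_index(sim))
        stats["n_tips"].append(sim.n_tips)
        stats["median_internal_bl"].append(median_internal_branch(sim))
    if got < n_sims:
        accept = got / max(tries, 1)
        if accept < 0.01:
            raise RuntimeError(
                f"simulation rejection rate {1-accept:.3f} too high; "
                "fitted parameters may not match the empirical tree"
            )
    obs = {
        "gamma": gamma_statistic(tree),
        "colless": colless_index(tree),
        "n_tips": n,
        "median_internal_bl": median_internal_branch(tree),
    }
    report = {"n_sims": got, "statistics": {}}
    adequate = True
    for key, sims in stats.items():
        sims = np.asarray(sims, dtype=float)
        q = float((np.sum(sims < obs[key]) + 0.5 * np.sum(sims == obs[key])) / len(sims))
        ok = 0.025 <= q <= 0.975
        adequate = adequate and ok
        report["statistics"][key] = {
            "observed": float(obs[key]),
            "quantile": q,
            "within_bounds": ok,
        }
    report["adequate"] = adequate
    return report
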