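"""Synthetic data with the statistical structure the analyses assume.

Generates birth-death trees (forward simulation with pruning of extinct
lineages, so instantaneous mass-extinction events can be injected),
discrete niche characters under a continuous-time Markov (Mk) process,
continuous traits under regime-specific Ornstein-Uhlenbeck processes,
covariate curves, and complete input bundles emulating the study system:
a ~120-tip ultrametric tree of two sister clades (a species-rich island
radiation of ~101 tips and a ~19-tip mainland clade, crown age ~50 My,
speciation ~0.15 vs ~0.08 lineages/My), a diet x activity-pattern niche
character, and ln body mass (ln grams) tracking niche-specific optima.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tree import DatedTree, Node
from .painting import RegimePaint
from .diversification import CovariateCurve

__all__ = [
    "plant_shift",
    "simulate_bd_tree",
    "simulate_niche",
    "simulate_trait",
    "mk_rate_matrix",
    "SyntheticScenario",
    "SyntheticBundle",
    "make_scenario",
    "temperature_curve",
    "jitter_posterior",
]


# ----------------------------------------------------------------------
# Birth-death tree simulation


def _as_rate_fn(rate):
    if callable(rate):
        return rate
    val = float(rate)
    return lambda t: np.full_like(np.asarray(t, dtype=float), val, dtype=float)


def _prune_extinct(root: Node) -> Node | None:
    """Drop lineages without extant (age 0) descendants; suppress the
    resulting unifurcations.  Returns the new root or None."""

    def rec(node: Node) -> Node | None:
        if node.is_tip:
            return node if node.age == 0.0 else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        out = Node(node.name, node.age)
        for c in kept:
            out.add_child(c)
        return out

    return rec(root)


def simulate_bd_tree(
    lam,
    mu=0.0,
    stop: str = "age",
    age: float | None = None,
    tips: int | None = None,
    seed=None,
    crown: bool = True,
    events=None,
    max_retries: int = 1000,
    raise_on_failure: bool = True,
    max_lineages: int = 100_000,
) -> DatedTree | None:
    """Forward-time birth-death simulation, extinct lineages pruned.

    ``lam``/``mu`` are rates (lineages/My), either constants or callables
    of age (My before present; time-varying rates require ``stop="age"``).
    ``stop="age"`` runs the crown process for ``age`` My and conditions on
    survival of both crown lineages (resimulating up to ``max_retries``).
    ``stop="tips"`` (constant rates only) stops when the extant lineage
    count first reaches ``tips``, cutting the tree at a uniform time
    before the next event to avoid the stop-at-birth bias.
    ``events`` is a list of ``(age, survival_prob)`` mass extinctions
    (age-stop mode only).
    """
    rng = np.random.default_rng(seed)
    if stop == "age":
        if age is None or age <= 0:
            raise ValueError("age-stop requires a positive age")
        lam_fn, mu_fn = _as_rate_fn(lam), _as_rate_fn(mu)
        for _ in range(max_retries):
            tree = _simulate_age(lam_fn, mu_fn, age, rng, crown, events, max_lineages)
            if tree is not None:
                return tree
        if raise_on_failure:
            raise RuntimeError(
                f"no surviving crown tree in {max_retries} attempts"
            )
        return None
    if stop == "tips":
        if callable(lam) or callable(mu):
            raise ValueError("tips-stop supports constant rates only")
        if tips is None or tips < 3:
            raise ValueError("tips-stop requires tips >= 3")
        for _ in range(max_retries):
            tree = _simulate_tips(float(lam), float(mu), tips, rng, max_lineages)
            if tree is not None:
                return tree
        if raise_on_failure:
            raise RuntimeError(f"no tree reached {tips} tips in {max_retries} attempts")
        return None
    raise ValueError("stop must be 'age' or 'tips'")


def _simulate_age(lam_fn, mu_fn, duration, rng, crown, events, max_lineages):
    """One attempt at an age-stop crown simulation (thinning algorithm)."""
    events = sorted(events or [], key=lambda e: -e[0])  # old -> young
    # per-lineage rate bound for the thinning sampler
    grid = np.linspace(0.0, duration, 513)
    bound = float(np.max(lam_fn(grid) + mu_fn(grid))) * 1.05 + 1e-12

    root = Node(None, duration)
    # each entry of ``alive`` is the node a live lineage hangs from; every
    # node enters the list exactly twice at creation and each occurrence
    # eventually attaches exactly one child, keeping the tree binary
    alive = [root, root]
    t = duration  # current age, decreasing
    ev_idx = 0
    tip_counter = [0]

    def close(parent, age_now, extinct):
        tip_counter[0] += 1
        node = Node(f"t{tip_counter[0]}", age_now if extinct else 0.0)
        parent.add_child(node)

    while t > 0 and alive:
        n_alive = len(alive)
        if n_alive > max_lineages:
            return None
        dt = rng.exponential(1.0 / (n_alive * bound))
        t_next = t - dt
        # stop at a mass-extinction breakpoint first: the candidate event
        # is discarded and the clock redrawn (memorylessness of the bound)
        if ev_idx < len(events) and t_next <= events[ev_idx][0] < t:
            t_ev, s_ev = events[ev_idx]
            survivors = []
            for lin in alive:
                if rng.random() < s_ev:
                    survivors.append(lin)
                else:
                    close(lin, t_ev, extinct=True)
            alive = survivors
            ev_idx += 1
            t = t_ev
            if not alive:
                return None
            continue
        t = t_next
        if t <= 0:
            break
        lam_t = float(lam_fn(np.array([t]))[0])
        mu_t = float(mu_fn(np.array([t]))[0])
        if rng.random() >= (lam_t + mu_t) / bound:
            continue  # thinned (no event)
        i = int(rng.integers(len(alive)))
        lin = alive[i]
        if rng.random() < lam_t / (lam_t + mu_t):
            node = Node(None, t)
            lin.add_child(node)
            alive[i] = node
            alive.append(node)
        else:
            close(lin, t, extinct=True)
            alive.pop(i)

    if not alive:
        return None
    for lin in alive:
        close(lin, 0.0, extinct=False)
    pruned = _prune_extinct(root)
    if pruned is None or pruned.is_tip:
        return None
    if crown and pruned.age != duration:
        return None  # a crown lineage died out entirely
    return DatedTree(pruned)


def _simulate_tips(lam, mu, target, rng, max_lineages):
    """One attempt at a tips-stop constant-rate crown simulation."""
    root = Node(None, 0.0)  # ages assigned after the duration is known
    alive = [root, root]  # forward clock; see _simulate_age for the scheme
    times = {id(root): 0.0}  # forward time at which each node was created
    t = 0.0
    reach_time = None
    while True:
        n_alive = len(alive)
        if n_alive == 0:
            return None
        if n_alive > max_lineages:
            return None
        dt = rng.exponential(1.0 / (n_alive * (lam + mu)))
        t_event = t + dt
        if reach_time is not None:
            # cut at (just before) the first event after reaching the
            # target, so the final inter-event interval keeps its full
            # exponential length -- the construction under which the
            # gamma statistic is standard normal for pure birth
            duration = t_event
            break
        t = t_event
        i = int(rng.integers(n_alive))
        lin = alive[i]
        if rng.random() < lam / (lam + mu):
            node = Node(None, 0.0)
            lin.add_child(node)
            times[id(node)] = t
            alive[i] = node
            alive.append(node)
            if len(alive) == target:
                reach_time = t
        else:
            tipn = Node(f"x{len(times)}", 0.0)
            lin.add_child(tipn)
            times[id(tipn)] = t
            alive.pop(i)

    # assign ages: age = duration - forward creation time; survivors at 0
    def finalize(node: Node):
        node.age = duration - times.get(id(node), 0.0)
        for c in node.children:
            finalize(c)

    finalize(root)
    k = 0
    for lin in alive:
        k += 1
        lin.add_child(Node(f"t{k}", 0.0))
    # extinct tips carry age (duration - death time) > 0, so pruning
    # keeps only the age-0 survivors
    pruned = _prune_extinct(root)
    if pruned is None or pruned.is_tip:
        return None
    if pruned.age != duration:  # crown survival of both sides
        return None
    tree = DatedTree(pruned)
    if tree.n_tips != target:
        return None
    return tree


def plant_shift(
    tree: DatedTree,
    lam_fast: float,
    mu_fast: float = 0.0,
    age_window: tuple[float, float] | None = None,
    seed=None,
) -> tuple[DatedTree, set]:
    """Replace one subtree of ``tree`` with a clade simulated at elevated
    rates of the same crown age (a planted diversification-rate shift).

    The host node is the internal node whose age is closest to the middle
    of ``age_window`` (default: 10-40% of the crown age).  Returns the
    new tree and the set of tip labels belonging to the planted clade.
    """
    rng = np.random.default_rng(seed)
    T = tree.crown_age
    lo, hi = age_window if age_window else (0.1 * T, 0.4 * T)
    target_age = 0.5 * (lo + hi)
    host = None
    for node in tree.postorder:
        if node.is_tip or node.parent is None:
            continue
        if lo <= node.age <= hi:
            if host is None or abs(node.age - target_age) < abs(host.age - target_age):
                host = node
    if host is None:
        raise ValueError(f"no internal node in the age window [{lo:g}, {hi:g}]")
    fast = simulate_bd_tree(
        lam_fast, mu_fast, stop="age", age=host.age,
        seed=int(rng.integers(2**31 - 1)),
    )
    existing = set(tree.tip_labels)
    labels = set()
    for i, tip in enumerate(fast.tips, 1):
        tip.name = f"shift_{i:03d}"
        while tip.name in existing:
            tip.name += "b"
        labels.add(tip.name)
    parent = host.parent
    parent.children[parent.children.index(host)] = fast.root
    fast.root.parent = parent
    out = DatedTree(_copy_node(tree.root))
    # restore the original tree object (it was modified in place)
    fast.root.parent = None
    parent.children[parent.children.index(fast.root)] = host
    host.parent = parent
    return out, labels


def _copy_node(node: Node) -> Node:
    new = Node(node.name, node.age)
    for c in node.children:
        new.add_child(_copy_node(c))
    return new


# ----------------------------------------------------------------------
# Discrete niche (Mk) simulation


def mk_rate_matrix(states: tuple, q: float) -> pd.DataFrame:
    """Equal-rates Q: every off-diagonal transition at rate ``q``/My."""
    k = len(states)
    Q = np.full((k, k), q, dtype=float)
    np.fill_diagonal(Q, -(k - 1) * q)
    return pd.DataFrame(Q, index=list(states), columns=list(states))


def simulate_niche(
    tree: DatedTree,
    Q: pd.DataFrame,
    root_state: str | None = None,
    seed=None,
) -> tuple[pd.Series, RegimePaint]:
    """Continuous-time Markov simulation of a discrete character.

    Returns the tip states and the full true history as a
    :class:`RegimePaint` (for validating ancestral-state methods).
    """
    rng = np.random.default_rng(seed)
    states = tuple(Q.index)
    Qm = Q.to_numpy()
    if root_state is None:
        root_state = states[int(rng.integers(len(states)))]
    idx = {s: i for i, s in enumerate(states)}

    segments: dict[int, list] = {}
    node_states = {tree.root.index: root_state}
    for node in tree.preorder():
        if node.parent is None:
            continue
        state = node_states[node.parent.index]
        remaining = node.length
        segs = []
        while True:
            leave = -Qm[idx[state], idx[state]]
            if leave <= 0:
                segs.append((remaining, state))
                break
            wait = rng.exponential(1.0 / leave)
            if wait >= remaining:
                segs.append((remaining, state))
                break
            segs.append((wait, state))
            remaining -= wait
            probs = Qm[idx[state]].copy()
            probs[idx[state]] = 0.0
            probs = probs / probs.sum()
            state = states[int(rng.choice(len(states), p=probs))]
        if not segs:  # zero-length branch
            segs = [(0.0, state)]
        segments[node.index] = segs
        node_states[node.index] = state

    paint = RegimePaint(tree, segments, root_state, states, source="simulation")
    tips = pd.Series({t.name: node_states[t.index] for t in tree.tips}, name="niche")
    return tips, paint


# ----------------------------------------------------------------------
# Continuous trait (regime OU) simulation


def simulate_trait(
    tree: DatedTree,
    paint: RegimePaint,
    theta: dict,
    alpha,
    sigma2,
    seed=None,
    x0: float | None = None,
) -> pd.Series:
    """Exact OU transition sampling segment-by-segment along a painting.

    ``theta`` maps state -> optimum (trait units); ``alpha`` (1/My) and
    ``sigma2`` (trait^2/My) may be scalars or state->value dicts.
    ``alpha = 0`` gives Brownian motion.  The root value defaults to the
    root regime's optimum.
    """
    rng = np.random.default_rng(seed)

    def a_of(s):
        return float(alpha[s]) if isinstance(alpha, dict) else float(alpha)

    def s2_of(s):
        return float(sigma2[s]) if isinstance(sigma2, dict) else float(sigma2)

    values = {tree.root.index: float(x0) if x0 is not None else float(theta[paint.root_state])}
    for node in tree.preorder():
        if node.parent is None:
            continue
        x = values[node.parent.index]
        for (d, s) in paint.segments[node.index]:
            a, s2, th = a_of(s), s2_of(s), float(theta[s])
            if a > 0:
                e = np.exp(-a * d)
                mean = th + (x - th) * e
                var = s2 * (1.0 - e * e) / (2.0 * a)
            else:
                mean = x
                var = s2 * d
            x = mean + rng.standard_normal() * np.sqrt(max(var, 0.0))
        values[node.index] = x
    return pd.Series({t.name: values[t.index] for t in tree.tips}, name="ln_mass_g")


# ----------------------------------------------------------------------
# Posterior-tree surrogate


def jitter_posterior(
    tree: DatedTree, n_trees: int = 100, sd: float = 0.1, seed=None
) -> list[DatedTree]:
    """Surrogate posterior set: multiplicative lognormal jitter (s.d.
    ``sd``) on internal-node ages with ultrametricity re-enforced (each
    node clamped below its parent, tips stay at age 0)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trees):
        t = tree.copy()
        for node in t.preorder():
            if node.is_tip:
                continue
            factor = float(np.exp(rng.normal(0.0, sd)))
            new_age = node.age * factor
            if node.parent is not None:
                new_age = min(new_age, node.parent.age * 0.9999)
            max_child_tipward = max(
                (c.age for c in node.children if not c.is_tip), default=0.0
            )
            node.age = max(new_age, max_child_tipward * 1.0001, 1e-9)
        out.append(DatedTree(t.root))
    return out


# ----------------------------------------------------------------------
# Scenario bundles


def temperature_curve(max_age: float = 66.0, n: int = 200) -> CovariateCurve:
    """Schematic Cenozoic-style global temperature curve (degrees C,
    relative): warm early, an early-Cenozoic optimum, cooling toward the
    present."""
    ages = np.linspace(0.0, max_age, n)
    base = 2.0 + 10.0 * (ages / max_age) ** 1.3
    optimum = 4.0 * np.exp(-(((ages - 0.8 * max_age) / (0.12 * max_age)) ** 2))
    return CovariateCurve(ages, base + optimum, kind="linear")


_DIETS = ("folivore", "frugivore", "omnivore")
_ACTIVITIES = ("nocturnal", "diurnal")


def default_niche_states() -> tuple:
    return tuple(f"{a}-{d}" for a in _ACTIVITIES for d in _DIETS)


def default_theta() -> dict:
    """Niche optima for ln body mass (ln grams): diurnal folivores
    largest, nocturnal omnivores smallest."""
    return {
        "nocturnal-omnivore": 5.0,
        "nocturnal-frugivore": 5.6,
        "nocturnal-folivore": 6.6,
        "diurnal-omnivore": 7.4,
        "diurnal-frugivore": 7.9,
        "diurnal-folivore": 8.6,
    }


@dataclass
class SyntheticScenario:
    """Study conditions for the default synthetic system."""

    seed: int = 42
    clade_sizes: tuple = (101, 19)
    crown_age: float = 50.0
    lam: tuple = (0.15, 0.08)
    mu: tuple = (0.05, 0.0)
    size_tolerance: float = 0.4  # accepted relative deviation of tip counts
    mk_q: float = 0.01  # per-My off-diagonal transition rate
    alpha: float = 0.05  # OU constraint, 1/My
    sigma2: float = 0.05  # OU diffusion, (ln g)^2 / My
    theta: dict = field(default_factory=default_theta)
    root_niche: str = "nocturnal-omnivore"
    n_posterior: int = 100
    posterior_jitter_sd: float = 0.1
    n_missing_mass: int = 1
    n_extinct: int = 17  # recently extinct island species (largest-bodied)
    #: ln-mass boost for the extinct giants: recently extinct island taxa
    #: reached body sizes one to two orders of magnitude above the extant
    #: maximum, so their masses sit well outside the extant distribution
    giant_mass_offset: float = 2.5


@dataclass
class SyntheticBundle:
    tree: DatedTree
    clades: dict  # clade name -> tip labels
    niche: pd.Series
    true_paint: RegimePaint
    traits: pd.Series
    richness: pd.Series
    covariate: CovariateCurve
    posterior: list
    truth: dict
    extinct: pd.Series | None = None  # 0/1 per tip


def _simulate_clade(lam, mu, crown_age, target, tol, rng, prefix):
    lo, hi = int(np.floor(target * (1 - tol))), int(np.ceil(target * (1 + tol)))
    lo = max(lo, 3)
    for _ in range(2000):
        t = simulate_bd_tree(
            lam, mu, stop="age", age=crown_age,
            seed=int(rng.integers(2**31 - 1)),
            max_retries=1, raise_on_failure=False,
        )
        if t is not None and lo <= t.n_tips <= hi:
            for i, tip in enumerate(t.tips, 1):
                tip.name = f"{prefix}_{i:03d}"
            return t
    raise RuntimeError(f"could not simulate a clade of ~{target} tips")


def make_scenario(
    scenario: SyntheticScenario | None = None,
    out_dir: str | None = None,
    seed: int | None = None,
) -> SyntheticBundle:
    """Generate a complete, self-consistent input bundle.

    A two-clade ultrametric tree (sizes near the scenario targets, crown
    age as specified), an Mk niche character with its true history, ln
    body mass under niche-specific OU (with one species' mass dropped to
    mimic a missing measurement), a genus-style richness table, a
    temperature covariate, and a jittered posterior tree set.  The same
    seed reproduces the same bundle byte-for-byte.
    """
    sc = scenario or SyntheticScenario()
    if seed is not None:
        sc = SyntheticScenario(**{**asdict(sc), "seed": seed})
    rng = np.random.default_rng(sc.seed)

    # clade crown ages chosen so the expected extant count matches the
    # target under the clade's net diversification rate
    crowns = []
    for target, la, m in zip(sc.clade_sizes, sc.lam, sc.mu):
        r = la - m
        t_c = float(np.log(target / 2.0) / r)
        crowns.append(min(t_c, sc.crown_age * 0.9))
    clade_a = _simulate_clade(sc.lam[0], sc.mu[0], crowns[0], sc.clade_sizes[0],
                              sc.size_tolerance, rng, "Island")
    clade_b = _simulate_clade(sc.lam[1], sc.mu[1], crowns[1], sc.clade_sizes[1],
                              sc.size_tolerance, rng, "Mainland")
    root = Node(None, sc.crown_age)
    root.add_child(clade_a.root)
    root.add_child(clade_b.root)
    tree = DatedTree(root)
    clades = {
        "island_radiation": [t.name for t in clade_a.tips],
        "mainland_clade": [t.name for t in clade_b.tips],
    }

    # niche: retry until every observed state has >= 2 tips
    states = default_niche_states()
    Q = mk_rate_matrix(states, sc.mk_q)
    for _ in range(200):
        niche, paint = simulate_niche(
            tree, Q, root_state=sc.root_niche, seed=int(rng.integers(2**31 - 1))
        )
        counts = niche.value_counts()
        if (counts >= 2).all() and len(counts) >= 2:
            break
    else:
        raise RuntimeError("could not simulate a niche character with >=2 tips per state")

    traits = simulate_trait(
        tree, paint, sc.theta, sc.alpha, sc.sigma2,
        seed=int(rng.integers(2**31 - 1)),
    )
    if sc.n_missing_mass > 0:
        drop = list(rng.choice(tree.tip_labels, size=sc.n_missing_mass, replace=False))
        traits = traits.drop(index=drop)

    # richness: most tips fully sampled; a handful represent 2-3 species
    richness = pd.Series(1, index=tree.tip_labels, name="n_species")
    n_multi = max(tree.n_tips // 12, 1)
    multi = rng.choice(tree.tip_labels, size=n_multi, replace=False)
    richness.loc[multi] = rng.integers(2, 4, size=n_multi)

    # recently extinct species: the largest-bodied island taxa (they sit
    # in the tree as tips at age 0, like subfossil taxa in a dated tree)
    extinct = pd.Series(0, index=tree.tip_labels, name="extinct")
    if sc.n_extinct > 0:
        island_masses = traits.reindex(clades["island_radiation"]).dropna()
        giants = island_masses.sort_values(ascending=False).index[: sc.n_extinct]
        extinct.loc[giants] = 1
        if sc.giant_mass_offset > 0:
            traits.loc[giants] = traits.loc[giants] + rng.normal(
                sc.giant_mass_offset, 0.4, size=len(giants)
            )

    covariate = temperature_curve(max_age=sc.crown_age * 1.3)
    posterior = jitter_posterior(
        tree, n_trees=sc.n_posterior, sd=sc.posterior_jitter_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    truth = {
        "lambda": list(sc.lam),
        "mu": list(sc.mu),
        "crown_age": sc.crown_age,
        "clade_crown_ages": crowns,
        "mk_q": sc.mk_q,
        "alpha": sc.alpha,
        "sigma2": sc.sigma2,
        "theta": dict(sc.theta),
        "root_niche": sc.root_niche,
        "seed": sc.seed,
    }
    bundle = SyntheticBundle(
        tree=tree, clades=clades, niche=niche, true_paint=paint,
        traits=traits, richness=richness, covariate=covariate,
        posterior=posterior, truth=truth, extinct=extinct,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SyntheticBundle, out_dir: str) -> None:
    """Write the bundle in the package's external formats (Newick trees,
    CSV tables, JSON truth file)."""
    os.makedirs(out_dir, exist_ok=True)
    bundle.tree.write(os.path.join(out_dir, "tree.nwk"))
    with open(os.path.join(out_dir, "posterior.nwk"), "w") as fh:
        for t in bundle.posterior:
            fh.write(t.newick() + "\n")
    species = pd.DataFrame(index=pd.Index(bundle.tree.tip_labels, name="species"))
    niche_split = bundle.niche.str.split("-", expand=True)
    species["ln_mass_g"] = bundle.traits
    species["activity"] = niche_split[0]
    species["diet"] = niche_split[1]
    species["extinct"] = bundle.extinct if bundle.extinct is not None else 0
    species.to_csv(os.path.join(out_dir, "species.csv"))
    rich = bundle.richness.rename_axis("tip_label").reset_index()
    rich.to_csv(os.path.join(out_dir, "richness.csv"), index=False)
    pd.DataFrame(
        {"age_my": bundle.covariate.ages, "value": bundle.covariate.values}
    ).to_csv(os.path.join(out_dir, "covariate.csv"), index=False)
    with open(os.path.join(out_dir, "clades.json"), "w") as fh:
        json.dump(bundle.clades, fh, indent=1)
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
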