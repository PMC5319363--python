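"""End-to-end orchestration of the four-prediction analysis.

Runs, from a configuration of input files: (1) diversification model
fitting and averaging per clade plus the rate-through-time trajectory;
(2) the calibrated stepwise shift scan and the fixed-time
mass-extinction test; (3) single-process trait-model comparison with
adequacy checks; (4) niche ancestral states, state-dependent OU model
comparison, and the ecospace embedding with hull areas.  Emits one JSON
manifest (stage reports, verdicts, seeds, content hashes) plus
per-stage JSON reports in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .tree import (
    DatedTree, read_tree, read_richness, extract_clade, patristic_matrix,
    gamma_statistic,
)
from .diversification import (
    candidate_models, fit_candidates, compare_and_average, rate_through_time,
    mass_extinction_test, CovariateCurve, covariate_bd, adequacy_check,
)
from .rate_shifts import calibrate_threshold, stepwise_search
from .traits import (
    fit_trait_model, pgls_model_average, trait_adequacy, mk_asr,
    fit_multiregime_candidates, TRAIT_MODELS,
)
from .ecospace import ecospace_pipeline

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    tree: str
    species: str
    out_dir: str
    richness: str | None = None
    covariate: str | None = None
    clades: str | None = None  # JSON {clade_name: [tips...]}
    seed: int = 0
    extinction_age: float = 33.9  # My; fixed-time extinction-shift test
    calibrate_sims: int = 100
    calibrate_tips: int | None = None  # default: tree size
    fit_starts: int = 10
    adequacy_sims: int = 1000
    nmds_starts: int = 50
    run_adequacy: bool = True

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        for attr in ("tree", "species", "richness", "covariate", "clades"):
            p = getattr(cfg, attr)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{attr} file not found: {p}")
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump(obj, path: str):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _load_species(path: str):
    df = pd.read_csv(path, index_col=0)
    need = {"ln_mass_g", "diet", "activity"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"species table missing columns: {sorted(missing)}")
    if "extinct" not in df.columns:
        df["extinct"] = 0
    niche = df["activity"].astype(str) + "-" + df["diet"].astype(str)
    return df, df["ln_mass_g"], niche


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stage failures are recorded in the manifest and dependent stages are
    skipped; the manifest's ``"ok"`` flag is False in that case.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    t_start = time.time()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in config.__dict__.items()},
        "stages": {},
        "predictions": {},
        "outputs": {},
        "ok": True,
    }
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(2**31 - 1))

    def run_stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
            manifest["stages"][name] = {"status": "ok", "seconds": time.time() - t0}
            return out
        except Exception as exc:  # noqa: BLE001 - report and skip downstream
            manifest["stages"][name] = {
                "status": "failed",
                "seconds": time.time() - t0,
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(),
            }
            manifest["ok"] = False
            return None

    tree = read_tree(config.tree)
    species, trait, niche = _load_species(config.species)
    richness = read_richness(config.richness) if config.richness else None
    clades = {}
    if config.clades:
        with open(config.clades) as fh:
            clades = json.load(fh)

    # ---- stage 1-2: diversification per clade ------------------------
    div_report = {}

    def _div():
        targets = {"whole_tree": tree}
        for name, tips in clades.items():
            targets[name] = extract_clade(tree, tips)
        for name, tr in targets.items():
            seed = stage_seed()
            ms = fit_candidates(tr, candidate_models(), starts=config.fit_starts, seed=seed)
            avg = compare_and_average(ms, eval_age=0.0)
            grid = np.linspace(0.0, tr.crown_age, 101)
            rtt = rate_through_time(ms, grid)
            div_report[name] = {
                "n_tips": tr.n_tips,
                "crown_age": tr.crown_age,
                "gamma": gamma_statistic(tr),
                "model_average": {k: v for k, v in avg.items() if k != "table"},
                "table": avg["table"],
                "rate_through_time": {"age": grid.tolist(), "net_rate": rtt.tolist()},
                "seed": seed,
            }
        if config.covariate:
            curve = CovariateCurve.read_csv(config.covariate)
            fit_cov = covariate_bd(tree, curve, starts=config.fit_starts,
                                   seed=stage_seed(), allow_extrapolation=True)
            best_aicc = min(r["AICc"] for r in div_report["whole_tree"]["table"])
            div_report["covariate_model"] = {
                "fit": fit_cov.to_dict(),
                "preferred_over_time_only": bool(fit_cov.aicc < best_aicc),
            }
        return div_report

    div = run_stage("diversification", _div)

    def _shift():
        tips = config.calibrate_tips or tree.n_tips
        cal = calibrate_threshold(
            template_tips=tips, n_sims=config.calibrate_sims, seed=stage_seed()
        )
        cfg = stepwise_search(tree, richness, threshold=cal.threshold)
        return {"calibration": cal.to_dict(), "result": cfg.to_dict()}

    shifts = run_stage("rate_shifts", _shift)

    def _ext():
        rep = mass_extinction_test(tree, config.extinction_age, seed=stage_seed())
        return rep.to_dict()

    ext = run_stage("mass_extinction", _ext)

    def _adeq():
        if not config.run_adequacy or div is None:
            return None
        best_row = min(div["whole_tree"]["table"], key=lambda r: r["AICc"])
        from .diversification import BDModel
        model = BDModel(best_row["lambda_form"], best_row["mu_form"],
                        params=best_row["params"], rho=best_row["rho"])
        return adequacy_check(tree, model, n_sims=min(config.adequacy_sims, 1000),
                              seed=stage_seed())

    div_adeq = run_stage("diversification_adequacy", _adeq)

    # ---- stage 3: trait models ---------------------------------------
    def _traits():
        fits = {m: fit_trait_model(tree, trait, m) for m in TRAIT_MODELS}
        aicc = {m: f.aicc for m, f in fits.items()}
        best = min(aicc, key=aicc.get)
        rep = {
            "fits": {m: f.to_dict() for m, f in fits.items()},
            "best_model": best,
        }
        if config.run_adequacy:
            rep["adequacy_of_best"] = trait_adequacy(
                tree, trait, fits[best], n_sims=min(config.adequacy_sims, 1000),
                seed=stage_seed(),
            )
        rep["pgls"] = {
            k: (v if not hasattr(v, "to_dict") else v.to_dict())
            for k, v in pgls_model_average(tree, trait, niche).items()
            if k != "fits"
        }
        rep["pgls"]["averaged_coef"] = (
            rep["pgls"]["averaged_coef"].to_dict()
            if hasattr(rep["pgls"]["averaged_coef"], "to_dict")
            else rep["pgls"]["averaged_coef"]
        )
        return rep

    traits_rep = run_stage("trait_models", _traits)

    def _multi():
        mk = mk_asr(tree, niche.dropna())
        fits = fit_multiregime_candidates(
            tree, trait, mk.paint, starts=2, seed=stage_seed()
        )
        table = [
            {**f.to_dict(), "weight": f.weight, "dAICc": f.aicc - min(x.aicc for x in fits)}
            for f in fits
        ]
        best = min(fits, key=lambda f: f.aicc)
        return {
            "mk_rate": mk.rate,
            "mk_logL": mk.logL,
            "table": table,
            "best_model": best.model,
            "best_theta": None if best.theta is None else best.theta.to_dict(),
        }

    multi = run_stage("multiregime", _multi)

    # ---- stage 4: ecospace -------------------------------------------
    def _eco():
        dp = patristic_matrix(tree)
        common = species.index.intersection(dp.index)
        sp = species.loc[common].dropna(subset=["ln_mass_g"])
        emb = ecospace_pipeline(
            sp, dp.loc[sp.index, sp.index],
            n_starts=config.nmds_starts, seed=stage_seed(),
        )
        coords_path = os.path.join(config.out_dir, "ecospace_coords.csv")
        emb.coords.to_csv(coords_path)
        return {"stress": emb.stress, "hulls": emb.to_dict()["hulls"],
                "coords_file": os.path.basename(coords_path)}

    eco = run_stage("ecospace", _eco)

    # ---- verdicts on the four predictions ----------------------------
    pred = manifest["predictions"]
    if div is not None:
        wt = div["whole_tree"]["model_average"]
        a = wt["a_lam"]
        pred["1_rate_trajectory"] = {
            "averaged_time_coefficient": a,
            "net_rate_present": wt["lambda"] - wt["mu"],
            "gamma": div["whole_tree"]["gamma"],
            "verdict": (
                "increasing toward present" if a < -1e-6
                else "declining toward present" if a > 1e-6
                else "approximately constant"
            ),
        }
        if ext is not None:
            pred["1_rate_trajectory"]["mass_extinction_supported"] = ext["favoured"]
        clade_names = list(clades)
        if len(clade_names) == 2:
            l0 = div[clade_names[0]]["model_average"]["lambda"]
            l1 = div[clade_names[1]]["model_average"]["lambda"]
            hi, lo = max(l0, l1), min(l0, l1)
            pred["2_clade_rates"] = {
                clade_names[0]: l0,
                clade_names[1]: l1,
                "ratio": hi / lo if lo > 0 else np.inf,
                "verdict": "focal clade faster" if hi / max(lo, 1e-12) > 1.5
                else "similar rates",
            }
    if traits_rep is not None:
        g = traits_rep["fits"]["ACDC"]["g_rate"]
        pred["3_phenotypic_rate"] = {
            "best_single_model": traits_rep["best_model"],
            "acdc_g_rate": g,
            "verdict": "early burst (declining rate)" if g < -1e-6
            else "no early burst",
        }
    if multi is not None and eco is not None:
        pred["4_adaptive_divergence"] = {
            "best_multiregime_model": multi["best_model"],
            "state_dependent_preferred": multi["best_model"] not in ("BM1", "OU1"),
            "ecospace_contraction_ratio": eco["hulls"].get("contraction_ratio"),
        }

    # ---- reports + manifest ------------------------------------------
    for name, obj in [
        ("diversification", div), ("rate_shifts", shifts),
        ("mass_extinction", ext), ("diversification_adequacy", div_adeq),
        ("trait_models", traits_rep), ("multiregime", multi), ("ecospace", eco),
    ]:
        if obj is None:
            continue
        path = os.path.join(config.out_dir, f"{name}.json")
        _dump(obj, path)
        manifest["outputs"][f"{name}.json"] = _sha256(path)
    if eco is not None:
        coords_path = os.path.join(config.out_dir, eco["coords_file"])
        if os.path.exists(coords_path):
            manifest["outputs"]["ecospace_coords.csv"] = _sha256(coords_path)
    manifest["wall_seconds"] = time.time() - t_start
    man_path = os.path.join(config.out_dir, "manifest.json")
    _dump(manifest, man_path)
    return manifest
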