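# radiad

Tools for testing the macroevolutionary predictions of **adaptive
radiation** on dated phylogenies, built around the kind of question
posed by island radiations such as the lemurs of Madagascar: did the
focal clade speciate faster than its sister clade, did diversification
decelerate as niches filled, did phenotypes burst early and settle onto
niche-specific optima, and does the clade span a wider multidimensional
ecospace than its relatives?

The package is aimed at comparative biologists who have a
time-calibrated tree (Newick/NEXUS, branch lengths in My), a species
table of ln body mass and diet/activity categories, and optionally
genus-level species richness and environmental covariate curves.

## What it computes

**Diversification** — the reconstructed-process birth–death likelihood
of the branching times `x₁ > … > x_{n−1}` (crown-age and crown-survival
conditioned, sampling fraction ρ at present), for constant,
time-varying and covariate-dependent rates on the age axis:

    log L = Σ_{i≥2} [log λ(x_i) + log p1(x_i)] + 2 log p1(x₁) − 2 log Φ(x₁)

with `p1(t) = e^{−R(t)}/(ρ y(t)²)`, `y = 1/Φ`, `y′ = −(λ−μ)y + λ`.
Candidate models are compared by AICc and model-averaged with Akaike
weights `w_i ∝ exp(−Δ_i/2)`; rate-through-time curves, a
simulation-based adequacy check, a MEDUSA-style stepwise shift search
with a simulation-calibrated ΔAICc threshold, and a fixed-time
mass-extinction test (instantaneous survival fraction `s` folded into
the likelihood) round out the stage.

**Trait evolution** — BM, Pagel's λ, OU and ACDC/early-burst fits of ln
body mass; PGLS of mass on diet×activity niches (sum-to-zero coding,
model-averaged over structures within 3 AICc); contrast-based model
adequacy; Mk ancestral states and stochastic character maps for the
niche; and state-dependent (multi-regime) OU models with per-niche
optima θ_k, constraints α_k and rates σ²_k along the reconstructed
niche history.

**Ecospace** — Gower dissimilarity over mixed traits, residuals of a
matrix regression on patristic distance, non-metric multidimensional
scaling (Kruskal stress-1), and convex-hull areas per group including
the extant/all contraction ratio after recent extinctions.

**Synthetic data** — forward birth–death simulation (with optional
extinction pulses), Mk niche histories, regime-OU traits, jittered
posterior tree sets, and a complete two-clade "island radiation"
scenario for end-to-end validation.

## Worked example

```python
from radiad import (SyntheticScenario, make_scenario, extract_clade,
                    fit_candidates, candidate_models, compare_and_average,
                    mass_extinction_test)

bundle = make_scenario(SyntheticScenario(seed=42), out_dir="demo/")
tree = bundle.tree                      # 118-tip two-clade ultrametric tree

for name, tips in bundle.clades.items():
    clade = extract_clade(tree, tips)
    ms = fit_candidates(clade, candidate_models()[:4], starts=6, seed=1)
    avg = compare_and_average(ms, eval_age=0.0)
    print(name, round(avg["lambda"], 3))

rep = mass_extinction_test(tree, 33.9, seed=0)
print("survival estimate at 33.9 Ma:", round(rep.s_hat, 2),
      "event favoured:", rep.favoured)
```

On the default scenario (seed 42) this prints

```
island_radiation 0.148
mainland_clade 0.105
survival estimate at 33.9 Ma: 0.61 event favoured: False
```

— the island clade's model-averaged speciation rate recovers the
generating 0.15 lineages/My; the 14-tip sister clade's estimate (truth
0.08) is noisier, as expected for so small a clade. The tree was
simulated without an extinction pulse and the test finds no support for
one: the event model loses on AICc. Across seeds the clade rate ratio
fluctuates around its generating value of about two
(`scripts/acceptance.py` below reports a median ratio of 2.27
over five scenario draws at seed 1).

The same pipeline runs from the shell:

```bash
radiad simulate --seed 42 --out demo/
radiad run-all --tree demo/tree.nwk --species demo/species.csv \
    --richness demo/richness.csv --clades demo/clades.json \
    --covariate demo/covariate.csv --out demo/results --seed 7
```

`run-all` writes per-stage JSON reports plus `manifest.json` with
verdicts on the four adaptive-radiation predictions, content hashes of
every output, and all seeds.

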