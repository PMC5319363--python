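# Methods

`radiad` tests the classic macroevolutionary predictions of adaptive
radiation on a dated phylogeny: (1) how diversification rates changed
through time, (2) whether a focal clade speciates faster than its sister
clade, (3) whether phenotypic evolution shows an early burst, and
(4) whether phenotypes evolved toward niche-specific optima, spanning a
wider ecospace than the sister clade. This note documents the models,
their assumptions, the defaults, and what the synthetic data do and do
not establish.

## Time axis and tree model

All rates are functions of *age* `t` in My before present (present = 0,
increasing into the past). A negative time coefficient therefore means a
rate that increases toward the present. Trees are rooted, strictly
binary and ultrametric; tips within a relative tolerance of 1e-6 x crown
age are snapped to age 0 (recently extinct species, gone for centuries
on a My-scale tree, are treated as extant), larger deviations are an
error rather than a silent repair, and polytomies are rejected so the
user resolves them deliberately.

## Birth-death likelihood

For speciation rate λ(t) and extinction rate μ(t) with sampling fraction
ρ applied at present, write r = λ − μ, R(t) = ∫₀ᵗ r. The probability
Φ(t) that a lineage alive at age t has at least one sampled descendant
satisfies, through y = 1/Φ, the linear ODE y′ = −r y + λ with
y(0) = 1/ρ, and the probability of leaving exactly one reconstructed
lineage is p1(t) = e^{−R(t)} / (ρ y(t)²). The log-likelihood of the
branching times x₁ > … > x_{n−1}, conditioned on the crown age x₁ and
survival of both crown lineages, is

    Σ_{i≥2} [ log λ(x_i) + log p1(x_i) ] + 2 log p1(x₁) − 2 log Φ(x₁).

Conditioning on the crown age plus survival of both crown lineages, with
a single clade-level ρ, is the conventional choice for this family of
models; nothing in the interface depends on it beyond the constant.

Constant-rate models use the closed forms. Time-varying and
covariate-dependent models integrate R and ∫ λ e^R by composite Simpson
quadrature on uniform sub-grids *between* branching times, so every
evaluation age is an exact grid point; at the default 4096 total points
the constant-rate cross-check agrees with the closed form to ~1e-13, and
an independent adaptive ODE oracle (used in the tests) to well below
1e-6.

Functional forms: λ(t) = λ₀ + a·t (clipped at 0 with a smooth penalty
during optimization), λ₀ e^{a·t}, and λ₀ e^{β V(t)} for an interpolated
covariate curve V (a schematic Cenozoic temperature series and
lineage-through-time diversity curves are provided); μ analogous.
Fitting is multi-start L-BFGS-B on log-rates (10 seeded starts,
ftol 1e-10); AICc uses n_obs = number of tips. Model averaging weights
every candidate by exp(−ΔAICc/2) (normalized), and averaged parameters
sum weighted parameter values with parameters absent from a model
counted as 0 — so, e.g., a pure-birth-dominated average has a near-zero
averaged extinction rate.

### Mass-extinction pulse

An instantaneous event at age t₀ with per-lineage survival probability
s enters the likelihood as a jump y(t₀⁺) = y(t₀⁻)/s (equivalently
Φ(t₀⁺) = s Φ(t₀⁻)) and, for each reconstructed lineage crossing t₀, a
net factor 1/s: the lineage's own survival contributes s, and the flow
Ψ(a,b) = e^{R(a)−R(b)} (y(a)/y(b))² telescopes only within continuous
segments of y, leaving (y⁺/y⁻)² = 1/s² at the boundary. Both Φ and p1
under an event were validated against forward Monte-Carlo simulation
(40k–60k replicates at two parameter settings, agreement within one
Monte-Carlo s.e.). The test fits the base model and the s-augmented
model by ML and compares AICc; "favoured" means the event model's AICc
is lower (margin configurable) with ŝ clearly below 1. Power scales
with the number of lineages crossing t₀: on ~50 My trees with λ=0.15,
μ=0.05 and an 80% kill, detection is ~70% for trees of ≥40 tips and the
null supports an event in ≤5–10% of replicates. A Bayesian
(compound-Poisson MCMC) treatment of episodic extinction is out of
scope; the ML/AICc form answers the same fixed-time question
deterministically.

### Adequacy

`adequacy_check` simulates trees from the fitted model conditioned on
the crown age, crown survival and a tip-count window, and reports the
empirical tree's two-sided quantiles of {gamma, Colless imbalance, tip
count, median internal branch length}; "adequate" = all quantiles in
[0.025, 0.975]. Simulations that exceed five times the window's upper
tip bound are rejected early, and a >99% rejection rate raises an error
suggesting a parameter mismatch.

## Shift search and its calibration

The stepwise search partitions the tree at breakpoints (any stem or
terminal branch), fits each regime with a constant-rate pure-birth or
birth-death model (chosen per regime by its AIC contribution;
birth-death only when a regime has ≥2 branching nodes, below which the
extinction fraction is unidentifiable), and accepts the best breakpoint
while total AICc (k = Σ regime parameters + number of breakpoints)
improves by at least a threshold. For speed, candidates are ranked by a
closed-form pure-birth score and only the top 8 are refitted exactly;
the search is greedy, non-backtracking and deterministic. Incompletely
sampled terminal taxa enter through tip richness m: the terminal branch
contributes P(m extant species | stem age, λ, μ) instead of the
exactly-one-lineage flow term (for m = 1 the two coincide).

Because stepwise AICc searches are anticonservative, the acceptance
threshold is calibrated: simulate single-regime trees at the reference
setting (λ = 0.15, μ = 0.05; template size an argument, default the
empirical tip count; 100 simulations by default), record the best
first-breakpoint improvement on each, and use the maximum plus
ε = 0.01. By construction the threshold rejects every calibration tree;
on fresh single-regime trees the true-negative rate is ≥95%, while a
planted five-fold speciation shift (a subtree regrown at matched crown
age under elevated rates) is recovered in a strong majority of
replicates.

## Trait models

Single-process models for ln body mass are fitted by the exact
phylogenetic multivariate-normal likelihood with the mean and overall
scale profiled out: Brownian motion (BM), Pagel's lambda (off-diagonal
shared times scaled by λ∈[0,1]), Ornstein–Uhlenbeck (OU), and an
ACDC/early-burst model whose instantaneous rate is σ² e^{g·u} in time u
since the root (g bounded to ±5/crown age; negative g = early burst).
The single-OU default uses the stationary covariance
σ²/(2α) e^{−α d_ij}; the fixed-root form
σ²/(2α) e^{−α d}(1 − e^{−2α S}) is available (`ou_root="fixed"`) and is
the α→0 bridge to BM as well as the exact one-regime limit of the
multi-regime models. AICc uses n = species with data.

PGLS regresses the trait on diet x activity niche categories under any
of the four correlation structures, with the structure parameter
ML-estimated jointly. Niche levels are coded sum-to-zero, so every
coefficient is a deviation from the grand mean (the omitted level's
deviation and s.e. are reported too). Model-averaged coefficients
combine models within 3 AICc of the best, weighted by Akaike weights.

Trait adequacy rescales the tree so the fitted model becomes unit-rate
BM (for OU the fixed-root transform is used, which differs from the
stationary form only by a constant), computes standardized independent
contrasts, and compares five statistics (mean squared contrast,
coefficient of variation of |contrasts|, slopes of |contrasts| on node
height and on expected contrast s.d., and the KS distance of contrasts
from standard normal) against unit-BM simulations on the rescaled tree.

### Discrete niche and regime paintings

The niche character evolves under an Mk model; the default is
equal-rates (one transition rate, uniform stationary distribution), the
symmetric free-rates variant is available. Ancestral marginals use the
standard two-pass (up/down message) algorithm with a uniform root
prior; the MAP painting assigns each branch its parent node's MAP state
(tip branches whose tip state disagrees are split at the midpoint so
the observed tip state is always honoured). Stochastic maps draw joint
node states from their conditional distribution and fill in branch
histories by endpoint-conditioned rejection sampling.

### Multi-regime (state-dependent) models

Along a painting, the trait follows a piecewise OU process with
per-state optima θ_k and, depending on the model, shared or per-state
constraints α_k and rates σ²_k: BM1, OU1, state-dependent BM (BMS), and
the state-dependent OU family OUM / OUMA / OUMV / OUMVA (unique optima,
plus unique constraints, rates, or both). Means and covariances are
accumulated segment-by-segment in a numerically stable decaying form
(all exponents non-positive), the root value is anchored at the root
regime's optimum, optima are profiled out by GLS and only the
constraint/rate parameters are searched. Standard errors of the optima
come from the observed information of the *joint* likelihood (numerical
Hessian over optima, log-constraints, log-rates and log-scale), so
uncertainty in α and σ² propagates into θ — conditional GLS errors were
materially anticonservative for regimes far from the root. Parameter
counts follow the freed blocks (e.g. OUM: K optima + α + σ²). A
posterior-robustness helper tallies the AICc-best model across trees
and stochastic maps.

## Ecospace

Mixed-trait dissimilarity uses the Gower coefficient (continuous:
range-normalized absolute difference; categorical: 0/1 mismatch;
unweighted mean over variables; zero-range variables dropped with a
warning). Phylogeny is removed by OLS of the lower-triangle trait
dissimilarities on patristic distances (intercept + slope; patristic
distance and an intercept are deliberate choices — the ranks, which are
all NMDS uses, are insensitive to the intercept). Residuals (possibly
negative) are shifted by their minimum — rank-preserving, hence
harmless for a non-metric embedding — and embedded in two dimensions by
NMDS (best of 50 random starts; reported stress is Kruskal stress-1 via
isotonic regression). Occupied niche breadth is the planar convex-hull
area per group; the extant/all ratio quantifies post-extinction
contraction (subset hulls can never exceed superset hulls; groups with
<3 or collinear points get area 0 with a degeneracy flag).

## Synthetic data: what it emulates, and what it does not

The default scenario emulates the study system: two sister clades
(~101-tip island radiation at λ = 0.15, μ = 0.05; ~19-tip mainland
clade at λ = 0.08, μ = 0) joined at a 50 My crown, with clade crown
ages set so expected richness matches the targets and simulated sizes
accepted within ±40%; a six-state diet x activity niche (equal-rates
Mk, q = 0.01/My, nocturnal-omnivore root — niches are conserved at
roughly family level at this rate); ln body mass under niche-specific
OU (optima from ln 150 g for nocturnal omnivores to ln 5.4 kg for
diurnal folivores, α = 0.05/My i.e. a ~14 My phylogenetic half-life,
σ² = 0.05 ln²/My); one species lacking a mass measurement; a
genus-style richness table (about 1 tip in 12 representing 2–3
species); the 17 largest-bodied island species flagged as recently
extinct with a gigantism offset of +2.5 ln-units (their masses sit one
to two orders of magnitude above the extant maximum, as the subfossil
record indicates); a schematic warm-early/cool-late temperature curve;
and a posterior-like tree set made by multiplicative lognormal jitter
(s.d. 0.1) of node ages with ultrametricity re-enforced.

Simulators are forward-time with pruning of extinct lineages (so
extinction pulses can be injected), use thinning for time-varying
rates, and under tips-stop cut the tree at the first event *after* the
target count is reached, which makes the pure-birth gamma statistic
exactly standard normal (mean −0.02 ± 0.03, variance 0.97 over 1000
simulated 50-tip trees).

Passing tests on these data show the estimators recover the generating
processes of the assumed model classes at realistic sizes. They do not
show robustness to the things real data add: topological and dating
error beyond branch-length jitter (the surrogate posterior does not
move clades), correlated diet/activity scoring error, body-mass
measurement variance, diversified rather than random incomplete
sampling, or diversification histories outside the fitted families.

## Numerical choices and scales used in the tests

Quadrature 4096 points (32768 where 1e-8 agreement is asserted);
optimizer tolerances 1e-10 to 1e-12; OU α bounded to [1e-8, 50/T] with
a boundary flag; Mk rates bounded to [1e-7, 100]/My; stochastic-map
rejection capped at 1e5 draws per branch. The test suite runs the
recovery studies at 50–120 tips with 20–100 replicates per experiment
(chosen as the smallest sizes at which the assertions are stable under
reasonable seed variation); the acceptance script reproduces the whole
pipeline on the default ~120-tip scenario in well under a minute.

## Known limitations

Diversity-dependent (lineage-count) speciation, reversible-jump shift
inference, protracted speciation and fossilized birth–death simulation
are out of scope. The shift search is greedy without removal steps.
The mass-extinction test has low power on trees with few lineages
crossing the event age. Multi-regime fits assume the painting is known;
uncertainty enters only through the stochastic-map robustness loop.
NMDS stress (not variance explained) is the embedding quality measure.
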