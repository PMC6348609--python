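# Methods

This note defines the models implemented in `hgtclock`, the numerical and
design choices behind them, and what the synthetic-data experiments do and
do not demonstrate.

## Model

### Data model

Inference runs on a *fixed* rooted bifurcating topology; only node ages,
branch rates and hyperparameters are sampled. A chronogram assigns each node
an age in Ma with contemporaneous leaves at age 0 and every parent strictly
older than its children — this ordering is enforced on every construction
and on every MCMC proposal (violations have zero posterior density and can
never be accepted).

### Likelihood

The sequence likelihood is the standard reversible amino-acid pruning
likelihood: a fixed exchangeability matrix (LG, or Poisson/uniform for fast
tests), stationary frequencies (preset or empirical from the alignment),
and K = 4 equal-probability discrete-gamma rate categories with shape α
(category rates are the category means of Gamma(α, α), normalized to mean
1). Branch lengths in expected substitutions/site are the product of branch
duration (Ma) and branch rate (substitutions/site/Ma). Gaps (`-`) and
ambiguities (`X`) are missing data: their partial-likelihood vectors are
all-ones. Transition matrices come from one eigendecomposition of the
symmetrized rate matrix, scaled to one expected substitution per site per
unit length at stationarity; per-node, per-site rescaling protects against
underflow.

A note on scope: the analysis this engine replays used a profile-mixture
substitution model in the original software. Mixture models couple weakly to
the branch-length information that a clock analysis consumes; this package
deliberately uses fixed-exchangeability models, which keep every likelihood
value verifiable against exhaustive enumeration on small cases. Absolute
dates from real alignments will differ somewhat from a mixture-model run;
the machinery around the likelihood (clocks, priors, calibrations, MCMC,
adequacy) is unaffected.

### Relaxed clocks

* **UGAM (uncorrelated gamma multipliers).** Each branch carries an i.i.d.
  multiplier r_b ~ Gamma(shape 1/ν, scale ν), so E[r_b] = 1 and
  Var[r_b] = ν. Branch length = μ_r · r_b · Δt.
* **LN (autocorrelated lognormal).** The log instantaneous rate follows
  Brownian motion along the tree: child log-rate ~ Normal(parent log-rate,
  ν·Δt). The rate of a branch is the arithmetic mean of its endpoint
  instantaneous rates (the conventional discretization); no mean-preserving
  drift term (−νΔt/2) is applied, matching the source implementation family.
  The generative sampler starts the root log-rate at log μ_r; in inference
  the root log-rate gets a Normal(log μ_r, 1) prior.

Both collapse to a strict clock at ν = 0. ν and μ_r are sampled by default
under exponential hyperpriors: ν ~ Exp(mean 1); μ_r ~ Exp(mean 1/(root-age
window midpoint)), i.e. centred on "one substitution root-to-tip". These
hyperpriors are package choices — the original analysis delegates them to
its dating software without stating them — and are configurable.

### Node-age priors

Both priors condition on the root age, whose density comes entirely from
its calibration window:

* **Uniform**: internal non-root ages i.i.d. uniform on (0, root age),
  truncated to order-compatible vectors. The log-density is therefore
  −n_inner · log(root age) plus a constant. The normalization matters: a
  literally flat joint density would tilt the root marginal by the volume
  of the age polytope and biases root estimates old (we observed exactly
  this before adopting the conditional form, which also matches mainstream
  dating software and the rejection-sampler construction).
* **Birth–death**: internal non-root ages i.i.d. from the conditioned
  node-age kernel ∝ λp₁(t), p₁(t) = d²e^(−dt)/(λ − μe^(−dt))² with
  d = λ − μ, normalized on (0, root age); the critical case λ = μ uses
  p₁(t) = 1/(1 + λt)². Sampling fraction is fixed at 1. λ and μ are sampled
  by default under Exp(mean 0.01/Ma) hyperpriors, or can be fixed. The
  kernel's CDF and inverse CDF are closed-form, which gives an exact
  rejection sampler; log-densities switch to an asymptotic branch when
  −dt is large so extinction-dominated parameter excursions stay finite.

With extinction the kernel concentrates node ages near the tips (deep
branches long, shallow branches short); relative to pure birth, extinction
shifts mass rootward. The uniform prior spreads divergences evenly.

### Calibrations

Calibration rows are (name, taxon A, taxon B, lower, upper) with ages in
Ma; each resolves to the MRCA of its taxon pair. Two calibrations resolving
to one node is an error (so the AB-split window and its fossil-minimum
variant are alternatives, never combined), and the row named `Root` must
resolve to the tree root. Bounds are hard — uniform with sharp truncation,
avoiding false precision; there are no soft tails. Relative constraints
(donor node strictly older than recipient node) encode the transfer
polarity; ties are rejected (zero-measure anyway). A root lower bound of
739 Ma is accepted with a warning noting the tabulated 738 Ma convention
(a known one-Ma inconsistency in the source material).

The four calibration structures of the model grid are: (1) root + AB split;
(2) root + AB split + both crowns; (3) root + fossil-minimum AB split;
(4) root + fossil-minimum AB split + both crowns.

## MCMC

Metropolis–Hastings with single-variable and global moves, default weights
in parentheses:

* node-age slide (40): uniform proposal inside the window formed by the
  oldest child, the parent, and the node's own hard bound — symmetric
  because the window depends only on unchanged coordinates;
* root-age slide (10): uniform inside the root window above the oldest
  child;
* branch-rate multiplier (30, UGAM) / node log-rate Gaussian (10, LN);
* hyperparameter log-scale moves (10) for ν, μ_r, λ, μ;
* whole-tree scale (10): every internal age × c = e^u with the rate level
  compensated (μ_r / c for UGAM; all log-rates − u for LN), leaving every
  branch length — and hence the likelihood — exactly invariant. This move
  travels along the rate–time ridge that single-variable moves cross only
  slowly; without it 20k-generation chains show visible root-age bias.

One generation = one proposed move. Likelihood evaluation is incremental: a
proposal recomputes only the transition matrices of changed branches and
the partial likelihoods of their ancestors, with exact rollback on
rejection (verified against full recomputation in tests). Step sizes for
the scale-type moves adapt by Robbins–Monro toward 0.24 acceptance during
the burn-in fraction only, then freeze, so retained samples come from a
fixed transition kernel.

Prior-only mode drops the likelihood factor; retained samples then follow
the calibration-truncated tree prior exactly, which is validated against
the closed-form rejection sampler by per-node Kolmogorov–Smirnov tests on
small trees.

Starting states come from the rejection sampler where feasible, otherwise
from a deterministic top-down midpoint construction that respects all
windows.

### Diagnostics

* **Effective size**: n / integrated autocorrelation time with Geyer's
  initial-positive-sequence truncation (pairs of autocorrelations summed
  while positive). A constant series reports ESS 0 with a warning.
* **Discrepancy**: |mean(A) − mean(B)| / pooled SD between chains; the run
  grid reports the max over monitored variables and the conventional
  cut-offs are ESS > 50 and discrepancy < 0.30.
* **Burn-in**: the first ⌈fraction × records⌉ records are dropped;
  default fraction 0.20.

The exact diagnostic formulas of the original software are not published;
these definitions are declared in every run manifest.

## Summaries and model adequacy

Node summaries are the posterior mean and the equal-tailed 2.5%/97.5%
sample quantiles (linear, type-7 interpolation), reported in Ma and always
in ascending order. Equal-tailed quantiles (not HPD) match the reporting
convention of the dating software family this engine mirrors.

The OE (outside-expected) statistic for a node is

    OE = 100 × length(CI \ expected) / length(CI)   [percent, one decimal]

where `expected` is the literature calibration window for that node. OE is
invariant under joint affine rescaling of both intervals, never increases
when the expected window widens, and reproduces all sixteen published
adequacy percentages from their printed credible intervals (the decisive
check for this interpretation over percent-of-posterior-mass, which cannot
be computed from printed tables).

The model grid crosses {uniform, birth–death} × {LN, UGAM} × calibration
structures 1–4 into models 1–16 (1–4 uniform/LN, 5–8 uniform/UGAM, 9–12
BD/UGAM, 13–16 BD/LN), each with a prior-only twin suffixed `p` — 32 runs.
Per-variant seeds derive deterministically from the base seed and model id,
so any grid re-run is bit-identical.

## Synthetic data

The generator emulates the *shape* of an HGT-propagated dating problem, not
any real taxa:

* a donor subtree of 12 tips split into two 6-tip clades, crowns pinned at
  560 and 520 Ma, joined at an "AB-split" analog at 820 Ma;
* a recipient subtree of 8 tips whose crown (400 Ma) hangs from the root
  (900 Ma) by a single long reticulating branch;
* the five emitted calibration windows are the study-style fungal windows
  — root 738–1145, AB split 518–830, crowns 408–715 and 400–655, fossil
  variant 405–830 Ma — and the pinned true ages satisfy all of them;
* one relative constraint: donor split older than recipient crown.

Subtree shapes come from a birth–death simulator (dendropy's
general-sampling-approach conditioning on the tip count, which avoids the
zero-length cherry of naive stopping); free node ages are then drawn from
the uniform-order process with the crowns pinned — i.e. from the same
node-age process the default dating prior assumes. Sequences evolve
root-to-tips with UGAM rates (μ_r = 10⁻³ substitutions/site/Ma, ν = 0.1)
over 300 sites under LG+Γ₄; each site carries one gamma category. At these
settings a 100-Ma branch accumulates ~0.1 substitutions/site — a realistic
deep-time protein signal. Truth files record every node age and parameter,
keyed by clade leaf sets, so recovery is scorable from files alone.

### What the synthetic experiments show — and don't

The recovery experiment (10 seeds × 2 chains × 20 000 generations;
coverage of true ages by 95% CIs ≥ 90%) is a *calibration check*: data
generated under the model's own assumptions must yield credible intervals
with near-nominal frequentist coverage. It validates the likelihood, the
clock, the priors and the sampler jointly. It does not demonstrate
robustness to the things real alignments add — substitution-model
misspecification (profile mixtures, compositional heterogeneity),
alignment error, among-lineage rate shifts beyond the assumed clock, or
calibration windows that exclude the truth. The prior-sensitivity behavior
(birth–death vs uniform, calibration-structure sensitivity) is exercised
mechanically by the grid, but the synthetic fixture is too small to
reproduce any real system's posterior dates.

## Numerical choices

* Likelihood scaling per node and site; partials floored at 1e-300.
* Kernel/density evaluations switch to asymptotic logarithmic branches when
  |d·t| > 500; the near-critical branch engages when |λ − μ| < 10⁻⁸·λ.
* UGAM density clamps ν at 10⁻⁸ from below so degenerate-limit evaluations
  stay finite.
* Quantiles: numpy linear ("type 7") interpolation, regression-locked in
  tests.
* Burn-in uses the ceiling rule (0.5 on 7 records removes 4, retains 3).
* Site intervals for composite alignments are 1-based inclusive.
* Newick round-trips preserve topology exactly and ages to at least six
  significant digits.
* All randomness flows through numpy `default_rng` (or `random.Random` for
  the dendropy simulator) seeded from explicit integers; identical seeds
  give bit-identical traces, fixtures and grids.

## Problem sizes

Default experiment sizes were chosen for single-workstation turnaround:
the standard fixture is 20 tips × 300 sites; recovery uses 10 seeds × 2
chains × 20 000 generations; prior-vs-rejection checks use 5-leaf trees
with 5000 retained samples; the grid demonstration runs 32 chains at
reduced length. These are the package's test conditions, not limits of the
implementation — chain length, tree size and site count scale linearly.

## Known limitations

* No profile-mixture (CAT-family) likelihood; no codon/nucleotide models.
* No topology sampling, tip dating, fossilized birth–death or skyline
  priors; no soft-bound calibrations.
* Model comparison is by CI adequacy (OE), not Bayes factors.
* The LN clock uses endpoint-mean branch rates; geometric-mean or midpoint
  parameterizations would shift deep-branch rates slightly.
* The uniform-prior normalization treats the root calibration as the root
  age density; combining multiple windows on the root is not supported.
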