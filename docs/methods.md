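# Methods

## The model

`mixclock` estimates divergence times on a fixed rooted binary topology from
nucleotide alignments, under three relaxed molecular clocks:

* **Brownian (lognormal) clock.** The log instantaneous substitution rate
  `x(t)` evolves as Brownian motion with variance `σ²_b` per Myr. The tree
  stores `x` at every node; conditional on the endpoints, the branch-averaged
  rate is approximated by the arithmetic mean of the endpoint rates,
  `r_j = (e^{x_up} + e^{x_dn})/2`. The prior over the node configuration is
  the product of independent normal increments `x_child ~ N(x_parent,
  σ²_b Δt)`.
* **White-noise clock.** Branch-averaged rate multipliers `R_j` are
  independent gamma variables with mean `μ_W` and variance `σ²_W / Δt_j`:
  the stationary-gamma, infinitely-fast-decorrelating limit of a
  continuous-time rate process, whose branch average tightens on long
  branches.
* **Mixed clock.** Log rates add: the effective branch length is
  `l_j = Δt_j · r_j · R_j`, with `μ_W ≡ 1` so that the overall rate scale
  lives in the Brownian component. The across-branch variance of log branch
  rates splits additively into a Brownian part `v_B = Var_j(log r_j)` and a
  white-noise part `v_W = Var_j(log R_j)` (unweighted sample variances over
  the 2P−2 branches, computed per MCMC draw); the summary statistic is the
  white-noise fraction `f_W = v_W / (v_B + v_W)`.

Sequences evolve by a GTR process (exchangeabilities and frequencies on
uniform Dirichlet priors, generator normalized to one expected substitution
per unit effective length). No among-site or among-partition rate variation
is modelled.

### Priors

| parameter | prior | default |
|---|---|---|
| σ_b | Jeffreys 1/σ truncated to [1e−3, 1e3] | — |
| x(0) (root log-rate) | uniform on [−100, 100] | — |
| μ_W, σ²_W | exponential, mean 1 | μ_W ≡ 1 in mixed mode |
| node dating: d = λ−μ, b = λρ | exponential, mean 1 | identifiable pair of the reconstructed birth–death-with-sampling prior |
| tip dating: d = λ−μ; μ; ψ | exponential, means 1, 10, 1 | serial birth–death |
| root age | exponential, mean 100 Myr | |
| cut-off t_c | fixed | 25 Myr |
| N_tot (extant diversity) | fixed | 5000 |

### Time priors

**Node dating.** Conditional on the root age, the P−2 free node ages are
i.i.d. with density `ν(t) ∝ b d² e^{−dt} / (b + (d−b) e^{−dt})²`, normalized
on (0, t_root) in closed form. Hard calibration bounds truncate the density
without renormalization (only ratios enter the MCMC). At `b = d` (μ=0, ρ=1)
this is the Yule order-statistics density — the closed form used as a test
oracle.

**Tip dating.** A serially sampled birth–death process with constant
speciation λ, extinction μ and fossil-sampling ψ rates above a cut-off time
t_c; fossil sampling kills the lineage, so every sampled fossil is a tip.
Nothing happens after t_c and every lineage alive at the cut-off is
represented by exactly one extant tip (diversified sampling). The density is
assembled from the standard survival machinery (`q(z)`, `p0(z)`), telescoped
over branches, conditioned on the root age and on both root children leaving
sampled descendants — the same conventions the forward simulator uses, so
simulation-based calibration closes exactly. The unobserved diversity enters
through a pure-birth factor P(N_tot | n lineages at t_c), a negative-binomial
law; the simulator draws N_tot from the same law. Fossil tip ages are
sampled within their user-supplied intervals.

## The sampler

Each cycle alternates:

1. **Gibbs refresh of substitution histories** (stochastic mapping): node
   states by backward filtering / forward sampling, then endpoint-conditioned
   CTMC paths per branch and site by uniformization (conditioned jump counts,
   conditioned jump chain, uniform-order-statistic jump times). Only the
   sufficient statistics survive: pairwise event counts `n_ab(j)` and
   relative dwell times `w_a(j)` (summing to the site count per branch), so
   the augmented log-likelihood is the explicit function
   `Σ_j [Σ_{a≠b} n_ab log(l_j Q_ab) + l_j Σ_a w_a Q_aa]` of every effective
   length.
2. **Metropolis–Hastings sweeps** over node ages, fossil ages, node
   log-rates, branch multipliers, clock and diversification hyperparameters
   and the GTR simplices, conditional on those sufficient statistics.
   Updates are vectorized over conditionally independent blocks (nodes of
   equal topological depth parity share no edge).

Beyond the standard local moves, several structured moves proved necessary
for acceptable mixing and are part of the default schedule:

* **compensatory move** — adds `m` to every node log-rate and divides every
  multiplier by `q = e^m`; effective lengths are exactly unchanged and the
  acceptance ratio is the prior ratio times the Jacobian `q^{−(2P−2)}` of
  the 2P−2 divided multipliers (derived by change of variables; validated by
  the prior-sampling tests).
* **per-node pattern swap** — shifts `x_v` and rescales the multipliers of
  the incident branches so each `l_j` is unchanged (Jacobian `Π r_j/r'_j`).
  Without it the attribution of rate *patterns* between the two components
  is nearly frozen and the mixed-clock chain is strongly hysteretic.
* **(σ_b, x) joint rescale** — `σ²_b → σ²_b e^u` with all increments scaled
  by `e^{u/2}`; prior terms and Jacobian cancel exactly, decorrelating the
  otherwise sticky scale/field pair.
* **whole-tree age scaling**, **uniform-window independence age proposals**
  (to cross the short-branch funnel of the Brownian prior), prior-conditional
  independence redraws of `x` and `R`, and an exact truncated-inverse-gamma
  Gibbs draw of `σ²_b`.

Proposal windows adapt toward ~30% acceptance during burn-in and are frozen
afterwards. The engine can also run with the exact pruning likelihood
recomputed per update (`likelihood="pruning"`), used only as an independent
cross-check of the augmented scheme, or with no data (`likelihood="none"`)
for prior-sampling validation. Chains are deterministic given the seed and
can be continued; `tracecomp` reports per-statistic effective sample sizes
(Geyer initial-positive-sequence estimator) and the between-chain relative
discrepancy |m₁−m₂|/SD.

## Numerical choices

* Matrix exponentials by symmetric eigendecomposition of the reversible
  generator (π^{1/2} similarity); eigenvalues clipped at 0 to keep huge
  proposals finite; pruning uses per-site scaling.
* Uniformization constant Ω = 1.05 × max|Q_aa|; jump-count tables truncated
  at a Poisson tail below ~1e−12.
* Minimum parent–child age gap 1e−6 Myr; variance partitions computed on the
  log scale via `logaddexp`.
* White-noise multipliers are stored and updated in log space: the gamma
  shape `μ²Δt/σ²_W` can fall far below 1 on short branches under the prior,
  where linear double-precision draws underflow (and any flooring measurably
  distorts the stationary distribution of μ_W); the independence redraw
  samples the log-gamma exactly via `G = G₁·U^{1/a}` with `G₁ ~ Gamma(a+1)`.
* The augmented likelihood includes the sampled root-state counts times
  `log π` — constant for every rate/time update but required for frequency
  updates (its omission is invisible to branch-length oracles and was caught
  by the augmented-vs-exact sampler cross-check).
* Ambiguity codes are unions over compatible states; gaps are fully missing.

## Synthetic data and the recovery study

The generator modules provide serially sampled birth–death trees with
diversified sampling (forward simulation from two root lineages, rejected
until both leave sampled descendants), Yule trees conditioned on root age
and tip count (i.i.d. truncated-exponential ages + uniform ranked
attachment), branch-rate histories under each clock, and GTR alignments.

Study conditions are fixed once, at a scale comparable to a fast nuclear
gene across placental mammals: 30-taxon trees with a 100 Myr root (Yule rate
0.02/Myr), mean substitution rate 0.01/site/Myr, `σ²_b = 0.005`/Myr (SD of
log branch rates ≈ 0.4–0.5), `σ²_W = 0.2`, 1000-site alignments, a mildly
non-uniform transition-rich GTR. The node-dating design fixes one calibrated
tree with hard bounds (±15% of the true age) on ~60% of internal nodes
including the root. The tip-dating design draws trees from the serial BD
process with d = 0.05, μ = 0.10, ψ = 0.02 per Myr, t_c = 25 Myr, root age
80 Myr, accepting 25–55 extant tips and 2–20 fossil tips; fossil age
intervals are the true age ±2.5 Myr, and the analysis conditions on the
replicate's simulated N_tot. A mis-specification design simulates times from
a Yule tree (many nodes younger than the cut-off) and re-analyses them under
the serial BD prior.

The recovery loop re-analyses each replicate under the mixed clock and
records the posterior-mean white-noise fraction next to its true value.
Analysis chains are desk scale — by default 2200 cycles (800 burn-in) with
5 MH sweeps per cycle and a mapping refresh every second cycle; a replicate
whose f_W effective sample size falls below 10 is rerun once and flagged.
These experiment sizes keep a full five-experiment acceptance run within
tens of minutes on one core.

## What the synthetic studies do and do not show

The generator matches the inference model exactly (same clock, same GTR,
same time priors in the matched designs), so recovery experiments measure
the method's internal consistency and the identifiability of the variance
partition — not robustness to model violations (no among-site rate
variation, no gene-tree discordance, no saturation beyond what the GTR
implies, no misdated fossils). Two caveats matter when reading the numbers:

* At this reduced scale (58 branches × 1000 sites, versus hundreds of
  branches × ~5000 sites in a full-size analysis) branch lengths carry
  2–3× more than Poisson-counting noise, and the per-draw variance partition
  includes the posterior jitter of weakly informed short branches. The
  attribution of variance between components is therefore intrinsically less
  sharp than at full scale, and the misattribution fractions for pure-clock
  simulations are larger than a full-size study would give.
* Attribution mixing is the hardest part of the posterior: the two
  components can imitate each other's realized patterns, and only the
  duration-scaling of their priors separates them. The pattern-swap and
  compensatory moves are essential; f_W remains the slowest-mixing statistic
  and its effective sample size should always be checked.

## Design choices made where the design was open

* The node-dating identifiable pair is (d, b) = (λ−μ, λρ), the standard
  choice for reconstructed trees.
* The serial BD density conditions on the root age (not an origin time) and
  on survival of both root lineages, matching the simulator; sampled-ancestor
  configurations are excluded (tips-only approximation).
* The variance partition is unweighted across branches and computed per
  draw; a duration-weighted or posterior-mean-based partition would be less
  noisy at desk scale but changes the estimand.
* Mapping refresh frequency and sweeps per cycle are configuration knobs;
  the posterior is invariant to them, only mixing speed changes.
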