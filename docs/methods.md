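# Methods

`rcclock` implements Bayesian relaxed-clock divergence dating for a
fixed, rooted, strictly bifurcating protein-tree topology, together
with the derived statistics used to study the early evolution of Type
II photosynthetic reaction-center proteins: the span ΔT between the
D1/D2 gene-duplication node (D0) and the ancestral standard-D1 node,
per-node evolutionary rates and their change through time, and the
decay of pairwise sequence identity with divergence time.

## The dating model

The data are an amino-acid alignment; the unknowns are absolute node
ages t (Ga before present, tips fixed at 0), per-node rates r
(substitutions/site/Ga), a clock hyperparameter, and the among-site
rate-variation shape α.  The posterior is

    p(t, r, θ | D) ∝ p(D | t, r, α) · p(t) · p(r | t, θ) · p(θ)

**Likelihood.**  Felsenstein pruning under a reversible 20-state CTMC:
either the Poisson model (equal exchangeabilities, uniform frequencies)
or an empirical matrix in PAML layout (the LG matrix ships with the
package; any user matrix in the same format is accepted).  Q is scaled
to one expected substitution per site per unit branch length.
Among-site variation uses the discrete-Gamma approximation with four
equal-probability categories whose rates are the category means
(mean-normalised to 1).  A site's category is a fixed property of the
site, shared across the tree.  The branch length of the edge above
node j is b_j = r̄_j (t_parent − t_j), where r̄_j is the arithmetic
mean of the two endpoint node rates under the autocorrelated clock
(the Kishino–Thorne convention; node rates are the primary objects) or
the child node's own rate under the uncorrelated clock.  Gap (`-`) and
unknown (`X`) characters are missing data: their tip conditionals are
a vector of ones, so they are summed over.  The per-node conditional
likelihoods are rescaled per pattern and the scale factors accumulated
in log space, which keeps alignments of at least 1,000 sites by 100
taxa exact.  Identical columns are collapsed into weighted patterns.

**Node-time prior.**  A normal root prior N(mean, sd) truncated to
positive ages; fossil calibrations attached to the MRCA of a named tip
set; and a uniform density over the order-constrained simplex of the
remaining internal ages given the root (contributing a
−(n_internal − 1)·log(t_root) term so root moves are weighted
correctly).  Calibrations are *hard* (uniform between the bounds, zero
outside) or *soft*: a uniform core carrying 1 − (tail masses), a
power-shaped lower tail t^θ on (0, min) and an exponential upper tail,
both matched for continuity at the bounds, with 2.5% of mass outside
each two-sided bound and 5% below a minimum-only bound.  A
minimum-only calibration needs a finite core to normalise; its core
runs from the minimum to 4.6 Ga, the age of the planet — no divergence
can be older.  The packaged profiles `calibration_1` and
`calibration_2` hold the eleven fossil events of the reaction-center
analysis (angiosperm, gymnosperm, land-plant, diatom, red-algal and
cyanobacterial constraints), differing only in the minimum age of the
MRCA of Cyanobacteria (2.45 vs 2.70 Ga).

**Rate prior.**  The autocorrelated log-normal clock: for child j with
parent p, log r_j ~ N(log r_p − σ²Δt/2, σ²Δt), the −σ²Δt/2 correction
keeping E[r_j | r_p] = r_p; the root rate has a log-normal prior with
sd 1 on the log scale around a user-set median.  Alternatively the
uncorrelated-gamma clock: node rates i.i.d. Gamma(shape, shape/ν₀)
with mean ν₀.  σ² (or the shape), α, and ν₀ carry broad proper
log-normal hyperpriors (sd 1 on the log scale; medians 0.1 for σ², 1.0
for the shapes, the user's rate guess for ν₀).  These hyperpriors are
a modelling choice of this package: the analysis they support reports
none, and a proper posterior requires them.  Note a consequence of the
Kishino–Thorne construction worth knowing when testing: because the
log-rate variance is σ²Δt, ages and rates are coupled a priori; the
marginal prior of a calibrated node age equals its calibration density
only after rates are integrated out (exactly true, but slow to realise
by MCMC), whereas under the uncorrelated clock the equality holds
conditionally as well.

## Sampling

A Metropolis–Hastings sampler sweeps, per iteration: a sliding-window
move for every internal non-root age (uniform over the full admissible
window (max child age, parent age) — symmetric, since the bounds do
not involve the moved age); a root-age multiplier; a multiplier for
every node rate; multipliers for σ²/shape, ν₀ and α; and a
compensating move that rescales one node's age and its rate in
opposite directions (unit Jacobian), which decorrelates the rate–time
product.  Multiplier moves include the log m Jacobian in the
acceptance ratio.  Scales are adapted every 50 burn-in sweeps toward
~30% acceptance and frozen afterwards, preserving detailed balance of
the recorded portion.  Burn-in defaults to 25% of iterations, thinning
to 10.  Each chain owns one seeded generator; chain seeds are the
master seed plus 1000 × chain index, so traces are bit-reproducible.
Every recorded state is asserted to satisfy the age ordering and rate
positivity.

The likelihood engine caches per-node conditionals and per-edge
contributions; a proposal recomputes only the transition matrices of
changed edges and the path to the root, writing into an overlay that
is committed on accept and dropped on reject.  A numba-compiled kernel
fuses the conditional product and rescaling when numba is available;
a numpy fallback produces identical results.  The cache is invariant
under arbitrary accept/reject histories (tested against fresh
recomputation).

Convergence: split-R̂ and bulk ESS per parameter across ≥2 chains,
plus the largest cross-chain difference of node-age posterior means.
The pass thresholds — R̂ < 1.05, ESS > 100, discrepancy < 0.05 Ga —
operationalise "run until convergence" at the precision at which ages
are reported (two decimals in Ga).

## Derived statistics

* **ΔT** between two clade-specified nodes: difference of posterior
  mean ages.  The companion range combines the two ±1 sd envelopes:
  high = (m_a + s_a) − (m_b − s_b), low = (m_a − s_a) − (m_b + s_b).
  This convention reproduces the published sensitivity tables' printed
  ranges; a quantile on the per-draw age difference is available as an
  alternative.  Clades resolve by MRCA of tip sets or by node label,
  never by internal indices.
* **Rate series and extrema**: per-node posterior mean (age, rate)
  points, restricted to named subsets; ν_max is the posterior mean
  rate at the duplication node, ν_min the unweighted average of the
  baseline (Group-4 D1 and D2) node rates, with the baseline sd taken
  as the spread of the node means.
* **Exponential rate decay**: least squares of
  ν = y_inf + A·exp(−x/τ) with x the time since the root, multi-start
  over a τ grid; a flat series is flagged degenerate rather than fit.
* **Power law**: log–log OLS of ν_max against ΔT, with an exposed
  predictor a·ΔT^b.
* **Waiting times**: 1/ν per site, reported in Ga and Ma.
* **Time to a target identity**: expected identity of two lineages a
  per-lineage distance d apart is Σ_i π_i [P(2d)]_ii (for the Poisson
  model, 1/20 + (19/20)e^{−40d/19}); with a constant or exponentially
  decaying rate trajectory, d(t) is closed-form and the target
  crossing is found by bracketed root finding.  This is the package's
  documented model of identity decay — observable identity under the
  Markov model, with no extra correction.
* **Identity regression**: column-wise percent identity with the
  longest-ungapped-row denominator, OLS of identity on divergence
  time, and extrapolation of the fitted line to deep-paralog identity
  levels (29%, 17%), which shows a constant Proterozoic rate cannot
  produce the observed divergence within the age of the Earth.

## Synthetic data

The generators produce every input the pipeline needs.  Chronograms:
random successive coalescence with internal ages given by sorted
uniforms on (0, root_age), the last join pinned at the configured root
age.  Rates: the autocorrelated log-rate walk, optionally drifting
along a deterministic trend ν(t) = ν_inf + A·exp(−(t_root − t)/τ)
(fast early, slow late), or i.i.d. gamma rates.  Alignments: forward
simulation from π along the tree with site-fixed Gamma categories.
Identity tables: linear decay plus Gaussian noise, clipped to
[0, 100].  All generators derive their streams from (seed, salt) pairs
and are bit-reproducible; truth tables record the generating values.

Default study conditions (chosen once): 20 tips × 300 sites,
Poisson+Γ₄, σ² = 0.1, root 3.5 Ga, root rate 0.25 subs/site/Ga, three
soft calibrations bracketing true clade ages (±15%, 2.5% tails);
identity emulation with slope −0.8%/Ga, noise sd 0.3%, n = 23 pairs
over 0.05–2 Ga; rate trend ν_inf = 0.12, A = 4.91, τ = 0.5 Ga, which
places the early rate at ≈5 subs/site/Ga and the Proterozoic plateau
at 0.12 — the regime the reaction-center analysis reports.  A packaged
74-taxon fixture mirrors the shape of the reaction-center tree (D1
groups G0–G4 with cyanobacterial and eukaryote sequences, D2, L, M;
labeled nodes II, D0, K, standard_d1; true ΔT = 0.60 Ga) with a clade
map binding every fossil-calibration event to a monophyletic synthetic
clade, so ΔT-style analyses run end to end with no external data.

What the generators do *not* emulate: alignment uncertainty and
indels, compositional heterogeneity across sites and lineages (the
CAT-style mixtures the original analysis also used), selection-driven
heterotachy beyond the log-normal walk, and topological error (the
topology is always known).  Passing recovery tests therefore shows the
inference machinery is self-consistent under its own assumptions, not
that those assumptions hold for real reaction-center data.

## Numerical choices and limitations

Transition matrices come from the symmetric eigendecomposition of Q
(exact for reversible models); probabilities are clipped at 0 to
remove −1e-18-scale eigen-noise.  Conditional-likelihood scaling uses
the per-pattern maximum with a 1e-300 floor.  The discrete-Γ category
means are computed through the Gamma(α+1) CDF identity and
renormalised to mean 1.  Curve fits bound parameters to be
nonnegative and report the residual sum of squares; degenerate inputs
(flat series) are flagged, not fitted.  Zero-length branches are
tolerated (P = I).  Non-ultrametric plain-Newick input is rejected
rather than repaired, since all taxa here are extant.

The sampler is a single-site Metropolis scheme: adequate for the tree
sizes used in the packaged analyses (≤ ~100 taxa) but not tuned for
large trees; the full-window age slide mixes slowly through narrow
calibration densities (acceptance ≈ calibration width / window), which
matters for prior-only studies and is why heavy thinning is used
there.  Problem sizes in the packaged recovery studies (sweep counts,
replicate counts) were chosen so the full suite exercises the
20-replicate recovery at the study conditions; longer chains tighten
the posterior summaries but do not change the conclusions.  Marginal
likelihoods and model comparison are out of scope (the original
analysis compares models by re-running, not by Bayes factors), as are
topology search, CAT mixtures, and +I invariant-site modelling.
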