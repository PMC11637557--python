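# Methods

## Model

`mscdate` performs Bayesian inference under the multispecies coalescent
(MSC) for sequence data in which tips carry known sampling ages — ancient
samples alongside modern ones.  The species tree topology is fixed and
known; each sequence is assigned a priori to a tip population, and no
sequences are sampled from ancestral populations.

All internal computation uses the **mutational time scale**: times are
expected substitutions per site.  A population's size parameter is
`theta = 4 N g mu` and a species divergence time is `tau`, both in
substitutions/site.  Sample ages are supplied in years before present
(`ys`) and enter the model as `ts = ys * mu`, where `mu` is the
substitution rate per site per year.  Divergence times in calendar units
are recovered per posterior draw as `tau / mu`; summaries of that ratio
are computed draw-wise, never as a ratio of summaries.

The joint posterior is

    f(mu, tau, theta, G | X)  ∝  f(G | tau, theta) · P(X | G) · f(mu) f(tau) f(theta)

with `G` the per-locus gene trees (topology + coalescent times) and `X`
the alignments.

### Gene-tree density with serial sampling

Within each population, the distinct sample ages `ts_1 < ... < ts_E`
split the population's time interval into `E + 1` epochs in which no
lineages are added and the lineage count can only fall.  A coalescence
taking the count from `j` to `j - 1` after waiting `t_{i,j}` contributes
`(2/theta) exp(-j(j-1)/theta · t_{i,j})`; lineages surviving to the end of
an epoch contribute the no-event probability.  The root population has no
upper boundary and all remaining lineages coalesce there.  The full
density is the product over populations.  Two implementations exist: a
readable epoch-partition path (`coalescent.py`, the reference for tests)
and a compiled event-sweep kernel (`_kernels.py`) used inside the MCMC;
tests assert their agreement and agreement with an independent
edge-overlap oracle.

Degenerate cases: tied sample ages merge into one epoch boundary with
summed multiplicity; a coalescence exactly at a sampling time is treated
as occurring after those samples join (zero waiting time); a sample age
greater than or equal to the parent divergence time is invalid (strict
`ts < tau`).

### Sequence likelihood

Jukes–Cantor with a strict molecular clock, uniform root frequencies, by
Felsenstein pruning.  Branch lengths are age differences in
substitutions/site, so dated tips automatically sit closer to the root in
expected substitutions.  Gaps and IUPAC ambiguity codes contribute
all-ones partial vectors (missing data).  Site patterns are compressed
internally; per-site terms are expanded back to site order before
summation so the result is bit-identical with compression on or off.
Rate variation, non-JC models and base-frequency estimation are out of
scope (the core model matches the simulation studies; empirical mtDNA
analyses elsewhere use richer models).

## Priors

* root age `tau_root ~ Gamma(alpha, beta)` (rate parameterization,
  mean `alpha/beta`);
* non-root divergence times i.i.d. `U(0, tau_root)` conditioned on the
  topology's ordering constraints;
* `mu ~ Gamma`, `theta_p ~ Gamma` i.i.d. across populations.

Fixed tip dates truncate this prior: only states with
`ys * mu < tau_parent` for every dated sample are possible.  The
resulting *effective* prior is what a prior-only MCMC run targets, and
what the rejection samplers in `validate.py` draw from exactly.

## MCMC

One sweep updates, in order: the rate (two moves), every divergence time,
every population size (two moves each), and per locus one SPR plus
sliding-window updates of internal node ages.  All window proposals use a
Bactrian–Laplace step (mixture parameter 0.95, unit variance) and reflect
at their bounds; log-scale walks reflect in log space.  Step sizes are
auto-tuned toward 30% acceptance during burn-in (per divergence time and
per population, since scales differ by orders of magnitude) and frozen
afterwards.  The classical mixing move (scale all times, divide the rate)
is incompatible with tip dates fixed in calendar time and is not used.

* **Rate move.**  `mu* = mu e^{eps x}` reflected in log space between a
  small floor (default 1e-13) and the bound `min tau_parent / ys` over all
  dated samples (a large ceiling, default 1e4 times the prior mean, when
  no tips are dated).  Tip ages become `ys mu*`; each internal node inside
  a dated tip population keeps its relative position between the age `b`
  of its oldest descendant sample and the population's parent divergence
  time `tau`: `t* = tau - h (tau - b*)` with `h = (tau - t)/(tau - b)` and
  `b* = b mu*/mu`.  The proposal ratio is `c · prod (tau - b*)/(tau - b)`;
  the tip-age rescale itself contributes a unit Jacobian.  A proposal that
  makes any parent younger than a child is rejected.  Nodes in ancestral
  populations are untouched (the tip population's parent divergence time
  is the anchor).
* **Auxiliary rate move** (this package's addition).  With many loci the
  `b`-anchored rescale almost always inverts some nested pair for rate
  changes beyond 1–2%, trapping the rate in a micro-step walk.  The
  auxiliary move maps each dated population's interval `(0, tau)` onto
  itself piecewise-linearly with the sample ages as anchors
  (`ys mu -> ys mu*`, `tau` fixed).  The map is strictly increasing, so it
  can never be rejected for ordering; the Hastings factor is `c` times the
  product of segment slopes.
* **Divergence-time move.**  Window on `tau_p` reflected into `(L, U)`:
  `L` = the oldest of the daughter divergence times and the daughter
  populations' sample ages in substitutions, `U` = the parent divergence
  time (for the root: a ceiling of 10 prior means, far in the prior's
  tail).  Gene-tree nodes in the two daughter populations with ages in
  `(L, tau_old)` are rescaled into `(L, tau*)` and nodes in population `p`
  into `(tau*, U)` (translated for the root), the classical rubber band.
  Ages never cross the moving boundary, so population assignments are
  unchanged and the Jacobian is `rb^{n_below} ra^{n_above}`.
* **Population-size moves.**  A log-scale window (ratio `theta*/theta`)
  and a joint scale move that multiplies the within-population coalescent
  offsets by the same factor as `theta` (Jacobian `c^n`), anchored at the
  population's oldest sample age so fixed tips are never crossed.  The
  joint move walks along the tight (theta, waiting-times) ridge that makes
  the plain move mix poorly.
* **Gene-tree SPR (date-aware).**  A non-root node is pruned.  The lower
  reattachment bound is the pruned node's age or, if higher, the earliest
  time at which any outside branch can co-occur with the pruned lineage
  (the minimum over remaining branches of max(branch child age, divergence
  time of the species MRCA of the two lineages)).  A bound placed instead
  at the divergence time of the youngest ancestral population *owning*
  outside nodes is not reversible on trees with more than two species —
  an outside lineage can traverse a population without owning a node
  there, leaving the current attachment below the bound with zero reverse
  density; run-under-the-prior validation caught exactly this as a 5-8%
  bias in the lowest divergence time before the floor above replaced it.
  The reattachment time is proposed by reflection; feasible branches are
  those spanning the proposed time whose lineage occupies the same
  population as the pruned lineage at that time.  If none exists the move
  is rejected; otherwise a branch is drawn uniformly and the
  feasible-branch counts at the new and old times enter the Hastings
  ratio.
* **Node-age moves.**  Sliding windows between the oldest child (and the
  divergence time of the node's species base) and the parent age; the root
  reflects at a large ceiling.  Population assignment follows from the new
  age.  The likelihood is maintained incrementally (only partials on the
  path to the root are recomputed; no per-node rescaling, which is safe
  for the tree sizes and branch lengths targeted here).

Caches (per-locus per-population density terms, per-locus likelihoods,
population assignments) can be verified against full recomputation every
`check_every` iterations; the test suite runs with this on.

## Simulator

Gene trees are simulated backwards in time: lineages activate at their
sample ages; with `k` active lineages the next coalescence waits an
`Exponential(k(k-1)/theta)` time, truncated by memorylessness at the next
activation or population boundary; survivors merge at divergence times;
the root coalesces fully.  Sequences evolve by JC from a uniform root.
Named designs reproduce the simulation-study conditions: the symmetric
four-species tree with divergences 10/7/4 Myr, rate 1e-9/site/year,
`theta` 1e-4, two extinct species sampled at U(5000, 50000) ybp with three
diploid individuals each (`nuclear_extinct`, 2000 x 1000 bp loci by
default); a single-locus mitochondrial variant (`mito_extinct`); and a
recent-divergence tree (root 20 kyr) with ages drawn up to each
population's divergence time (`recent_divergence`; `dates_ignored` writes
the same data with the analysis dates zeroed).  Within a replicate one set
of uniform draws is shared across loci; the nuclear/mito designs also share
dates across replicates, while the recent-divergence design redraws them.
Individual-level draws are made in order, so larger sampling designs nest
smaller ones.

The generator emulates the study conditions (no recombination, no
migration, no rate variation, no post-mortem damage); passing tests
therefore validate the inference machinery under the model, not robustness
to real aDNA artefacts.

One conflict in the printed study conditions: the nuclear theta priors as
printed have means ten-fold below the generating values, contradicting the
stated principle that prior means sit at the truth (and the printed
mean formula).  The generator follows the centering principle
(`Gamma(2, 2/theta_true)`).

## Validation machinery

* `rejection_sample_prior` draws exactly from the effective prior on the
  four-tip symmetric/asymmetric shapes: rate and root age from their
  priors, internal ages uniform given the root (rank-ordered on the
  asymmetric shape), rejecting draws with a node younger than a dated
  sample in a daughter population.
* `bayesian_simulation` draws parameters from the effective prior,
  simulates, re-infers with the same priors, and pools posteriors; if the
  sampler is correct the mixture equals the prior.  The comparison is a
  quantile–quantile table at 99 percentiles with a replicate-bootstrap
  band (the underlying full-scale check is visual); chains failing an ESS
  threshold are excluded, mirroring the practice of re-running or
  excluding non-converged analyses.
* `coverage_experiment` reports the fraction of replicates whose 95% HPD
  interval (shortest contiguous interval on sorted draws) contains the
  generating truth.

## Problem sizes used by the test suite and acceptance script

Everything runs on one CPU; sizes were fixed from pilot convergence runs.

* Run-under-prior: ~160k prior-only sweeps (divergence times updated six
  times per sweep; they are cheap without data) vs 60k rejection draws
  (two-sample KS < 0.03 per parameter).
* Bayesian simulation: 100 replicates of 10 loci x 500 bp, five sequences
  per species, ~900-sweep chains initialized at the drawn parameters with
  the population-size moves repeated three times per sweep (the
  within-replicate posterior tails of the dated-population theta are the
  slowest-mixing quantity; shorter chains leave the pooled mixture
  underdispersed in its upper percentiles).  The acceptance script runs a
  smaller 40 x 8 x 400 version.
* Coverage: 20 replicates of the nuclear two-extinct-species design at 40
  loci x 1000 bp, ~1800 sweeps per chain (the full-scale condition uses
  2000 loci and is not reproducible at desk scale; pilots at 50 and 100
  loci gave the same coverage at 1.3x and 2.5x the cost).
* Dates-ignored reanalysis: 20 replicates of 30 loci x 300 bp.  At this
  size the dated-tip signal is ~1% of the full-scale condition
  (the effect scales with mu x age x sites x loci), and the `E[1/mu]`
  factor of the gamma rate prior (+11%) dominates the direction of the
  calendar-time estimates, so the downward-bias check reflects full-scale
  behaviour only and is expected to fail at desk scale; the companion
  property — the rate posterior equals its prior when dates are ignored —
  holds and is asserted.

## Known limitations

* Strict clock, JC only, no migration or recombination, fixed topology,
  exactly known tip dates.
* Mixing: the rate and the calendar-time divergence estimates share one
  slow posterior mode at large locus counts; the auxiliary moves above
  mitigate but do not eliminate it (integrated autocorrelation times of
  tens of sweeps at 50–100 loci).  Long runs or multiple chains remain
  advisable for production analyses, as in the underlying method.
* The root-age prior is truncated by reflection at 10 prior means
  (negligible mass for the priors used here, but a documented departure
  from an unbounded prior).
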