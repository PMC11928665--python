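# Methods

This note documents the statistical models implemented in `calphase`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations. Ages are cal BP (years before
AD 1950, larger = older) throughout.

## Calibration

A determination x ± σ on a curve with mean μ(θ) and 1σ error σ_c(θ)
(both piecewise-linear between knots) has calendar-age density

p(θ) ∝ exp(−(x − μ(θ))²/2v(θ)) / √v(θ),  v(θ) = σ² + σ_c(θ)².

The 1/√v factor is the error-in-variables form; it matters on steep curve
segments. PDFs live on a regular cell-centre grid (default 5 yr) whose
points are multiples of the resolution, so PDFs from different calls can
be combined cell-wise. Cell masses are integrated with ≤0.25-yr midpoint
strips rather than evaluated at cell centres; this keeps the
total-variation distance to brute-force 0.1-yr integration comfortably
below 1e-4 on wiggly curves (measured ~1.6e-6). Tails carrying less than
1e-12 cumulative mass per side are trimmed. A date with no support on its
curve raises an error; ages are never silently truncated into range,
because truncation biases boundary estimates.

Marine dates: a positive ΔR (locally older water) is subtracted from the
CRA and its sd added in quadrature before calibration on the marine
curve. Hemispheric mixing: stand-alone calibration marginalises the
mixing fraction m ~ U(0,1) with 64-point Gauss–Legendre quadrature over
the effective curve m·μ_N + (1−m)·μ_S (σ interpolated the same way);
inside an MCMC model m is instead a per-determination latent variable
with a Metropolis update, so the data can inform it.

Highest-posterior-density regions are built by accumulating grid cells in
descending mass order (ties toward older cells) and merging contiguous
runs. Reported intervals are rounded to 10 yr, half-way cases rounding
outward so coverage is never lost to rounding. Non-radiocarbon
chronometric ages (e.g. luminescence) enter models directly as normal
calendar-scale PDFs.

## Uniform-phase models and priors

A phase groups exchangeable events between a start boundary a and an end
boundary b; a sequence orders phases oldest→youngest with shared
boundaries. The joint density implemented is

p(a, b, t) ∝ ∏ phases (a_k − b_k)^−(n_k − s) · ∏ events L_i(t_i) · 1[order],

with s = 1 under the default `standard` span construction (events uniform
given boundaries, group span itself uniform a priori — conditional on the
events this is the familiar (a−b)^−(n−1) boundary density) and s = 0 under
the `naive` switch. Boundaries are confined to a model range derived from
the calibrated medians plus padding (default max(1000 yr, half the data
span); configurable). Two numerical guards: a hard span floor of one grid
cell (the standard prior is improper as a−b → 0 once undated events are
involved), and initialisation at calibrated medians with boundaries
placed just outside their group and clipped to satisfy every constraint
(a genuinely empty support raises an initialisation error naming the
offending structure).

Component age queries ("what is the age of this cultural unit?") are
implemented as draws uniform between the enclosing phase's current
boundaries at each retained iteration — an undated virtual event with no
feedback on the model.

## Outlier model

Each dated event may carry an outlier term with activation indicator
z ~ Bernoulli(p), default prior p = 0.05 per event (exposed in config).
The General preset shifts the event on the calendar scale by δ with a
Student-t (5 df) prior scaled by 10^u yr, u ~ U(0, 4); the SSimple preset
(used for pooled replicate measurements) shifts the measurement by a
N(0,1) multiple of its own σ. Replicates are detected by shared sample
identifier and pooled by inverse-variance weighting with a chi-square
consistency test at 5% (n−1 df) before modelling.

## Sampler

Metropolis-within-Gibbs with single-parameter moves: random-walk
Metropolis for boundaries, dated event ages, active shifts, scale
exponents, and mixing fractions; exact uniform redraws for undated
events; exact prior redraws for dormant shifts and scales. Proposal
scales adapt toward 0.2–0.5 acceptance during a discarded burn-in
(default 3,000 iterations) and are frozen afterwards, so retained samples
come from a fixed kernel.

Single-site moves cannot cross between the two modes an outlying date
creates ("shift active, phase tight" vs "shift dormant, phase stretched"),
so three joint moves are added, each preserving the likelihood exactly so
the Hastings ratio involves only priors and proposal densities:

* a swap that flips z while conserving the effective age t + zδ,
  resampling the event age uniformly within the phase and drawing a fresh
  scale exponent (three attempts per sweep);
* deactivate-&-widen: when the effective age of an active shift lies
  outside the phase, move the offending boundary just past it
  (exponential overshoot proposal) and switch the shift off;
* activate-&-shrink (the exact reverse): when an inactive event pins a
  phase edge, flag it and pull the boundary back to the remaining events.

The full kernel was validated against exact numerical integration of the
posterior on single-phase test problems: activation probabilities agree
to Monte-Carlo error (e.g. 0.862–0.883 sampled vs 0.8766 exact for a
+2000-yr contaminant among ten dates; 0.049 vs 0.0495 for clean dates),
and with no data the boundary marginals reproduce their analytic priors
(Kolmogorov–Smirnov distance < 0.01 at 10⁵ samples).

Protocol: an initial 30,000 retained iterations, then convergence checked
in passes of 3,000 iterations with the pass interval doubling until the
criterion exceeds 0.95 or a hard cap of 2²⁰ iterations is reached (then
flagged, not fatal). The convergence statistic is the overlap integral
∫min(f̂₁, f̂₂) between histogram density estimates from the two
interleaved half-chains, taken per parameter with the minimum reported;
a frozen (zero-variance) chain scores 0 because it cannot demonstrate
convergence. The criterion names a threshold, not a formula, in common
usage; the half-chain overlap was chosen because it is assertable and
penalises drifting chains.

Randomness: one PCG64 generator seeded from the run's master seed drives
every draw in a deterministic order, so a rerun with the same seed is
bit-identical on one platform and statistically identical across
platforms. Pipeline stages derive per-site and per-category seeds from
the master seed and the stage label (CRC32), all below 2³¹.

Posterior PDFs from traces are histograms on the standard grid with a
mild fixed Gaussian smoothing (sd 1.5 cells, zero-padded so no mass is
lost at the support edges); this keeps HPD sets contiguous under per-cell
Monte-Carlo noise and moves means by well under one cell. Degenerate
(≤2-cell) posteriors are left unsmoothed.

## Density summaries

* **Sum**: cell-wise average of the input PDFs, renormalised (a PDF, not
  a count surface).
* **KDE plot**: fixed-bandwidth normal-kernel density with Silverman's
  rule h = 0.9·min(sd, IQR/1.34)·n^(−1/5).
* **KDE model**: the true age behind each input PDF is latent; each is
  Metropolis-updated against its PDF-likelihood times the leave-one-out
  KDE of the others, and a bandwidth shrinkage factor σ_h ~ U(0,1)
  multiplying Silverman's rule is Metropolis-updated against the
  leave-one-out pseudo-likelihood. Kernel densities are snapshotted every
  25 post-burn-in iterations; the point estimate is the snapshot mean
  (with a per-cell ±1σ band). The exact joint sampler behind published
  implementations is not specified anywhere testable; this construction
  honours the stated ingredients (normal kernel, Silverman base,
  uniform shrinkage, dependent events) and is validated by parameter
  recovery (170-PDF set generated around N(12050, 350): mean recovered
  within a few years) and by retention of well-separated modes. The
  Silverman base is floored at one grid cell so a degenerate latent
  configuration keeps a proper kernel.
* **Difference**: distribution of (A − B) by discrete cross-correlation;
  positive = first argument older; P(A − B > 0) counts half of any mass
  at exactly zero.
* **Overlap**: the mass of a start PDF older than, inside, and younger
  than a fixed interval; the ACR (14,500–13,000) and YD (13,000–11,700)
  presets enter as fixed uniform blocks, not sampled parameters.

## Timeline pipeline

The component table is loaded **without exclusion**: one record per
cultural component, malformed rows collected in a rejects report with row
numbers, never dropped silently. Curves are assigned by policy — southern
curve by default, north+south uniform mixture for sites between 25° S and
15° N, marine curve with the row's ΔR — with per-site overrides winning.

Site models follow three rules: (1) ≥2 dated stratigraphic levels with a
total order → multi-phase sequence over *all* layers (including those
outside the interval of interest, which constrain their neighbours), with
General outlier terms and replicates pooled under SSimple semantics;
(2) ≥2 dates without usable stratigraphy → single uniform phase (partial
stratigraphic knowledge — some layers unranked — deliberately falls here
and is noted on the model); (3) exactly one cultural date → no model, the
calibrated PDF itself represents the component. Sediment/geological ages
enter rule-1/2 models as non-cultural events (they constrain boundaries
but never join category models).

A component is "interval-aged" when its 95.4% range intersects the
configured window (default 14,500–11,700 cal BP); no numeric inclusion
rule is published for this step, so the window intersection at the
reporting level is this package's documented choice. Each interval-aged
component PDF enters its categories: geographic province (nine-province
vocabulary with the Andes split north/central/south), each of its lithic
labels (a multi-tradition component enters each once), high altitude
(≥2,500 m, inclusive), and megafauna exploitation. Category models are
single uniform phases over the component PDFs; the start boundary
posterior is reported as 95.4/68.2% HPD intervals rounded to 10 yr with
ACR/YD overlap triples, raw (uncorrected) since they are descriptive. A
southern-Andes run restricted to components strictly poleward of 40° S is
available, flagged when n is small. Prior-sensitivity reruns (span prior,
outlier prior) report CI endpoint shifts against the base fit.

Database-completeness statistics count radiocarbon share, charcoal share,
charcoal species reporting, and bone C:N reporting, with the collagen
acceptance window configurable (default 2.9–3.6, the conventional range).
The last-appearance-date comparison (KDE of LADs, per-genus difference
distributions against an exploitation start) is labelled descriptive:
LADs are termini post quem for extinction and not commensurate with
modelled onset estimates.

## Synthetic data

The generator exists so every stage is testable with known truth. Curves
are identity-trend plus a smoothed stationary AR(1) wiggle (sd
configurable; zero gives the exact identity curve). Sites are uniform
phases with known boundaries; measurements add curve error and laboratory
error, plus a N(0, 400 yr) contamination shift with probability 0.05, and
occasional replicate pairs. Databases mirror the shape of a continental
compilation: 150 sites and ~2,000 measurements by default, ~35% stratified
multi-layer sites / ~45% single-phase / ~20% single-date, site start ages
uniform over 16,500–12,200 cal BP so most components fall in the late
Pleistocene window, 95% radiocarbon, 55% charcoal (species unreported 94%),
C:N reported for 11% of bone dates, pretreatment missing 70%. Truth
(boundaries, event ages, outlier shifts) is written to a separate table
the pipeline never reads. Generated rows in the mixing band are simulated
through a per-site random hemispheric mixture so the loader's curve policy
is consistent with the generative process.

What this does *not* emulate: real calibration-curve plateaus and reversals
(wiggles are stationary), spatial autocorrelation of sites, laboratory
inter-comparison offsets, taphonomic loss, or heaping of archaeological
attention on famous sites. Passing recovery tests therefore demonstrates
correctness of the machinery under the stated model, not robustness to
every pathology of real compilations.

## Problem sizes used in tests and the acceptance script

Unit and property tests run reduced chains (3,000–30,000 retained
iterations) chosen so Monte-Carlo error is well inside each assertion's
tolerance. The coverage check uses 100 replicate 20-event phases at 6,000
retained iterations; the acceptance script runs the full 150-site
synthetic study with 4,000 retained iterations per site model — start
boundaries of the category models are insensitive to longer chains at
these sizes (checked against 30,000-iteration runs during development).

## Known limitations

* Only Boundary–Phase–Boundary (uniform) groupings are supported: no
  trapezoidal or exponential phase shapes, no cross-linked constraints
  between separate site trees.
* Model-agreement indices are not computed; convergence overlap and
  outlier posteriors are the diagnostics.
* The start boundary of a pooled category is a terminus estimate for the
  earliest activity among its components; for heterogeneous categories
  with one diffuse old component its 95.4% interval can fall short of the
  single oldest true event age (the acceptance script reports this margin
  rather than hiding it).
* Post-bomb calibration, dendro wiggle-matching and calibration of
  non-radiocarbon clocks are out of scope; OSL/U-series ages enter as
  normal calendar priors supplied by the user.
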