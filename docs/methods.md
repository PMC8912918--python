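# Methods

## Scope and model overview

`poremap` analyses where and how fast electric-field-driven pores form in
coarse-grained plasma-membrane models. The chain is: locate the first
poration event in a trajectory; extract local membrane features at porated
and non-porated locations from the pre-field trajectory; rank features by a
signed symmetrized Kullback–Leibler distance; train classifiers to predict
poration sites from the features; and model first-poration times with a
Bayesian piecewise-exponential proportional-hazards model. A synthetic
membrane/poration generator supplies data with the statistical structure
every stage assumes, so the full chain runs and is tested without any
molecular dynamics input.

## Pore localization

A pore in a coarse-grained bilayer appears as a persistent column of water
beads at the bilayer midplane. Detection follows a two-stage protocol:

* **Coarse stage.** Starting at frame 12 (poration before 1.2 ns is not
  observed at the field strengths of interest) and striding 6 frames, the
  membrane plane is partitioned into 100 regions (a 10 × 10 grid — the only
  square partition consistent with the (i±2, j±2) neighborhood used next).
  A region fires when its midplane slab holds *strictly more than* 12 water
  beads; that count indicates a fully formed pore rather than a transient
  defect.
* **Precise stage.** From five frames before the coarse hit, frames are
  scanned forward; midplane waters are pooled over the 5 × 5 region
  neighborhood with periodic wrap. The first frame with strictly more than
  the precise threshold (default 4; 6 suits stiffer, more curved membranes)
  whose waters persist in each of the following two frames defines the
  poration time; the pooled waters' periodic centroid, divided by the box
  edge lengths, is the pore location in box-relative coordinates.

The midplane slab is |z − z_mid| < 0.5 nm with z_mid the mean of the two
leaflets' mean headgroup heights; the slab half-width is a parameter because
no canonical value exists. When the precise stage fails (strong curvature
can displace the slab), the search retries with a midplane re-estimated from
headgroups near the candidate region and logs a warning — automating what
would otherwise be a visual check — then resumes the coarse scan at the
next stride. Only the first poration event is reported by default;
`locate_all_pores` lists simultaneous pores in distinct regions. A
trajectory with no detection yields a censored event. Times are
frame-index × dt with dt = 0.1 ns by default. Water counting is per bead
(the central bead of multi-bead water models when reading GRO files).

## Local membrane features

Per-leaflet vertex set = lipid headgroup positions (first head bead).
Estimators are deliberately lightweight and assume a near-planar bilayer:

* **Normals** from the smallest principal axis of the 3D covariance of the
  periodic neighborhood (radius 2.5 nm, minimum 7 neighbors), oriented away
  from the midplane; collinear neighborhoods fall back to the global normal.
* **Area per lipid** from a periodic 2D Voronoi tessellation (boundary-band
  images added so the cells tile the box exactly — per-leaflet cell areas
  sum to the box area to machine precision).
* **Thickness**: along-normal distance between the two leaflets'
  Gaussian-smoothed (r = 1.0 nm) height fields.
* **Mean curvature** from a local quadratic height fit over the same
  neighborhood (Monge patch); a spherical-cap fixture of radius R recovers
  1/R within 10%.
* **Tail order** P2 = (3⟨cos θ⟩² − 1)/2 where θ runs over all
  adjacent-bead bonds of both tails against the local normal and the
  *cosines are averaged before squaring* (more sensitive to porated versus
  non-porated separation than the conventional per-bond average of
  cos²θ). Bounded in [−0.5, 1]; undefined for tail-less cholesterol.
* **Dipole cosine**: angle between the local normal and the
  phosphate→amine vector of zwitterionic lipids (PC, PE, SM); undefined
  otherwise and excluded from the smoothed average.
* **Headgroup charge** in elementary charges (PS/PI/PA −1; PIP₁/₂/₃ −3/−5/−7).
* **15 lipid-group densities**: smoothed 0/1 membership indicators for the
  12 headgroup classes and the 3 tail-saturation classes of the standard
  grouping. Cholesterol belongs to CHOL only, so at any query the 12
  headgroup densities sum to 1 and FS + MU + PU = 1 − CHOL, exactly.

All per-vertex values are read out at query points with a Gaussian kernel of
width r_smooth = 1.5 nm (the radius found to best separate porated from
non-porated values), truncated at 3·r_smooth, with minimum-image periodic
distances; a constant field is a fixed point of the smoothing, and a query
with no vertex in range is NaN, never zero. Feature rows are
per-(location, frame); leaflets are averaged by default with a per-leaflet
mode (`_inner`/`_outer` columns) available. Leaflet labels are re-derived
per frame from headgroup height relative to the locally smoothed midplane.

## Porated / non-porated location sets and feature ranking

Non-porated reference locations are drawn from a 31 × 31 lattice after
removing every point within 6.7% of the box edge (~2 nm at 30 nm) of any
pore — expressed as a fraction so it scales with the box, with an
absolute-nm override — then uniformly downsampled to 300.

Each feature's class distributions are estimated by a Gaussian KDE with
Silverman bandwidth on a 512-point grid; the signed distance is

    ± ½ ∫ [p log(p/q) + q log(q/p)] dx

integrated by the trapezoid rule over the contiguous range where both
densities stay at or above 1% of their peaks. The sign is
sign(mean(porated) − mean(non-porated)) — positive when the feature favours
poration. This mean-shift rule is a documented choice: the convention's
meaning is standard but no formula for the sign is canonical. Degenerate
(constant) samples are flagged rather than silently producing numbers, and
densities are floored at a tiny ε when supports barely overlap.

## Classification

The porated class (~60 locations) is balanced against the 300 non-porated
locations by SMOTE (convex interpolation between a minority row and one of
its k = 5 nearest minority neighbours) implemented in-package on sklearn
nearest-neighbour queries. Classifiers: 100-tree random forest (raw
features, exposes importances), RBF-kernel SVM, and one-hidden-layer (100
unit) perceptron, the latter two behind a standardizing pipeline. Accuracy
is the fraction of correctly predicted (location, frame) rows over all rows.
A location is *called* porated only when flagged in strictly more than 90%
of its frames.

Split schemes: membrane-pairwise, cross-composition, cross-polarity, random
60/40 by location, and a first-events holdout. By default oversampling
happens after splitting and train/test location sets must be disjoint
(leakage is an error); an `oversample_before_split` flag balances the data before splitting,
reproducing the historically used protocol together with its acknowledged
optimistic bias. The (x, y) coordinates ride along as row identifiers but
are excluded from the default feature vector — a model allowed to see
coordinates can memorize geography; a flag restores them. The four-feature
reduced model uses the PU, GM, CHOL and FS densities.

On the synthetic data the four-feature model is frequently slightly *better*
cross-membrane than the all-features model (irrelevant features cost
generalization), so the reduced-model check is one-sided: it may lose at
most five accuracy points.

## Survival model

First-poration times follow λᵢ(t) = λ₀(t)·exp(βᵢ) with λ₀ piecewise
constant on 1.5-ns intervals (a width giving a good signal-to-noise ratio
for desk-scale event counts) covering the largest observed time. The
likelihood is the standard piecewise-exponential one via per-system,
per-interval event counts and exposures; censored replicas contribute only
exposure. The likelihood has an exact ridge λ₀ → cλ₀, β → β − log c, so by
default the first system is the reference with β ≡ 0; the unconstrained
all-systems parameterization remains available.

Priors: Gamma(shape 0.2, rate 0.04 ns) on each λⱼ — mean 5 ns⁻¹ but
essentially vague — and Normal(0, 100) on the βs. The shape matters more
than it looks: a gamma prior behaves like `shape` phantom events per
interval, and with ~14 intervals even one phantom event per interval biased
the non-reference coefficients by ≈ −0.2 at 240 total events (verified
against the exact profile MLE, which is unbiased); informative
literature-style choices such as shape 50 are selectable but bias all rates
toward the prior mean whenever real per-interval counts are smaller. A
time-varying variant gives each system a piecewise β(t) on the same grid
with a Gaussian random walk prior (step sd 1, first step centred at 0).

Sampling uses an affine-invariant ensemble MCMC over (log λⱼ, β) —
differential-evolution moves (80% DE, 20% snooker), walkers ≥ max(2·dim+2,
32) rounded to a multiple of 4, 6000 steps with 3000 discarded — and the
rank-normalized potential scale reduction factor over four walker groups;
a worst R-hat above 1.01 flags the fit as unconverged rather than failing
silently. Fits are deterministic given the seed.

Credible intervals are central (equal-tailed) quantile intervals: the 94%
interval is [q₀.₀₃, q₀.₉₇], which always contains the posterior median (a
highest-density interval need not, and is position-unstable for flat
posteriors). Posterior predictive checks simulate first-event times from
a posterior subsample via interval-wise inverse-CDF sampling and report the
two-sample Kolmogorov–Smirnov statistic against the observed times.

Interpretation helpers: exp(βᵢ − βⱼ) is the poration-rate ratio of two
systems; under the nucleation rate law λ = A·exp(−(δ − B·ΔΨ²)/kT) with
comparable prefactors A, βᵢ − βⱼ ≈ −(δᵢ − δⱼ)/kT, so −(βᵢ − βⱼ) is reported
as an effective barrier difference in kT units. The mechanical-response
helper fits Δd/d₀ or ΔA/A₀ = c·E² through the origin by least squares
(Maxwell-stress scaling) and correlates per-system slopes with the βs
(Pearson).

## Synthetic membranes

The generator emulates the statistical structure of equilibrated
coarse-grained plasma-membrane patches; it performs no dynamics.

* **Composition fields.** Per leaflet, independent white noise per lipid
  species is smoothed with a periodic Gaussian filter (correlation length
  3 nm by default — nanodomain scale), scaled (amplitude 1.2 in log space)
  and combined with the configured log fractions through a softmax; because
  the softmax of noisy logits biases areal means, species weights are then
  rescaled to a fixed point where every species' spatial mean equals its
  configured fraction exactly. An infinite correlation length yields a
  spatially uniform membrane. Default fractions follow published
  average-plasma-membrane (APM) and brain-plasma-membrane (BPM) leaflet
  inventories; the headgroup-class and saturation-class marginals are
  reconciled into per-species fractions by iterative proportional fitting
  over the feasible (headgroup × saturation) cells, one representative
  Martini species per cell.
* **Frames.** ~1500 lipids per leaflet (APM scale) on a jittered lattice in
  a 30 × 30 nm box; species drawn from the local field; headgroup charge by
  classification table; zwitterionic lipids get a phosphate bead and a
  tilted amine bead. Tails are two 4-bead kinked sticks; each bond tilts by
  a wrapped-normal polar angle with per-lipid standard deviation
  `base_disorder (0.3 rad) + order_coupling (0.35) × local PU probability +
  disorder_heterogeneity (0.2) × an independent smoothed disorder field`.
  The independent field matters: tail order in real membranes responds to
  many factors besides unsaturation, so order must correlate with PU
  without being a noise-free proxy for it — otherwise the order feature,
  not composition, would dominate every downstream ranking. A water slab
  (1 bead/nm³) fills the box outside the bilayer.
* **Trajectories.** Headgroup anchors random-walk laterally (0.05 nm/frame),
  tails and dipoles are resampled each frame, lipid identities persist;
  zero diffusion reproduces the first frame exactly. `plant_pore` inserts a
  persistent disc of midplane water beads (radius 0.5 nm) from a chosen
  frame, with periodic wrap.
* **Poration events.** First-poration times are sampled exactly from the
  piecewise hazard by interval-wise inverse-CDF (the final rate extends
  beyond the last endpoint; an all-zero hazard without censoring is
  rejected); times beyond `censor_time` are recorded censored. Pore
  locations are drawn over field cells with probability
  ∝ exp(coupling × standardized PU density), with coupling 3 as the default
  study condition; the placement field is first blurred to 1.5 nm because a
  nascent pore is a nanometre-scale object and should respond to
  nanometre-scale composition, not to a single 0.47-nm grid cell.

All randomness flows from one integer seed; independent streams are derived
by hashing stable string labels into a `SeedSequence`, so adding a consumer
never perturbs existing streams.

What the generator does **not** emulate: real force-field energetics,
electrostatics, membrane undulations beyond small height noise, lipid
flip-flop, pore expansion dynamics, box-size fluctuations, or any causal
route from composition to poration other than the planted placement law.
Passing tests therefore demonstrate that the *analysis chain* recovers
known planted structure at realistic sizes and noise levels — not that real
membranes behave this way.

## Problem sizes and numerical choices

The test suite and the acceptance script run, per stage: classification on
two membranes × 1500 lipids/leaflet × 15 frames × ~360 locations (~5400
rows each); divergence oracles at n = 50 000; hazard recovery on 60
events × 4 systems with 20 (tests) or 5 (acceptance script) seed repeats;
pore localization on 50 planted fixtures over a 300-lipid/leaflet base
trajectory. Unit tests use 300-lipid patches. Other numerics: minimum-image
convention for all lateral distances; KDE integration limits at 1% of peak;
log-parameterized rates with a ±50 bound rejecting pre-overflow proposals;
GRO round-trips at the format's 0.001-nm precision via MDAnalysis.

## Known limitations

* Surface estimators are near-planar approximations; they are not a
  replacement for full surface-parameterization pipelines on strongly
  undulating or vesicular membranes, and exactness against such tools is
  not claimed.
* The piecewise-hazard sampler is an ensemble MCMC, adequate at ~15–40
  dimensions; the time-varying-β variant roughly triples the dimension and
  needs longer chains for tight diagnostics.
* The classifier accuracies reported on synthetic data characterize the
  pipeline, not any real membrane; cross-composition transfer in
  particular depends on how similar the two compositions' planted
  mechanisms are, which the generator makes identical by construction.
* SMOTE interpolation in 21 dimensions can place synthetic minority rows in
  low-density corners; the default after-split protocol confines that
  artefact to training data.
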