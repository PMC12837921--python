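# Methods

`felicoex` implements the statistical pipeline of a two-felid coexistence
analysis — density estimation for a dominant forest felid, spatiotemporal
interaction modelling for a dominant/subordinate pair, and scat-based diet
partitioning — together with a synthetic-data generator that reproduces the
statistical structure such surveys produce, so that every stage is testable
without access to sensitive field data (locations of threatened carnivores
are routinely withheld).

## Camera-trap summaries (`captrap`)

Raw photograph records are reduced to *events* by a greedy minimum-gap
filter per species × station: the first record is retained, and each later
record is retained iff it falls at least the gap after the last **retained**
record (1 min for "detections", 30 min for "independent captures").
Anchoring on the last retained event is the standard independent-capture
semantics and is deterministic; a consequence worth knowing is that the
retained *set* is not monotone in the gap (only the retained *count* is), so
tests assert count monotonicity and idempotence rather than set nesting.
Paired cameras at a station are pooled before filtering, and capture rates
use station-level trap nights, because the two cameras of a pair are not
independent samplers.

A trap night is one station (or camera) active during one calendar night;
partial first/last days count as one night. Covariates are centered and
scaled with the sample standard deviation (denominator n−1, the default of
mainstream statistical environments); pairwise Pearson correlations above
0.6 are reported and flagged but do not stop a pipeline run.

## Spatial capture–recapture (`scr`)

Activity centers follow a homogeneous Poisson process of density D over a
discretized habitat mask; detection of an individual centered at x at trap k
on one daily occasion is Bernoulli with half-normal probability
g0·exp(−d²/2σ²). The package uses the full (Poisson-N) likelihood

    logL = Σ_i log[ D·a·Σ_c w_ic π_c Σ_x Pr(ω_i|x,c) ] − D·a·Σ_x Σ_c π_c p·(x,c)

with a two-class sex mixture: π = (pmix, 1−pmix), w selecting the known
class, and unknown-sex individuals entering through both classes (hybrid
mixture). The full likelihood (rather than conditional-on-n) is the form
under which the sex-ratio parameter pmix is estimable and testable. The
−log n! constant is omitted throughout; it cancels in every comparison the
package makes. A labeled-sex dataset and the same data with all sexes
unknown give likelihoods offset by exactly n·log 2 under shared detection
parameters — the fitted parameters are identical, only the constant differs.

Choices a user can override, with defaults:

- **Occasion**: one calendar day (`n_occasions` from the capture table).
- **Mask**: grid of cell centers at 1 km spacing within a buffer of the trap
  array; membership uses Chebyshev distance to the nearest trap by default
  (`metric="euclidean"` available — the two differ only at mask corners and
  wash out in the mask-adequacy iteration). Buffer defaults to 4.5 × RPSV,
  the root-pooled spatial variance of capture locations.
- **Optimizer**: L-BFGS-B on (log D, logit g0, log σ, logit pmix) from
  deterministic multiple starts (σ at RPSV × {1, ½, 2}; g0 from the crude
  capture frequency; D from n over mask area). Standard errors come from the
  numerically differentiated Hessian; the density CI is lognormal-style,
  D/C to D·C with C = exp(1.96·sqrt(ln(1+(SE/D)²))), which reproduces the
  asymmetric intervals typical of SCR density estimates. A singular Hessian
  flags the fit as non-converged rather than reporting unusable intervals.
- **Model set**: null, g0-by-sex, σ-by-sex, both; ranked by AIC.

**Closure**: the span test compares each individual's observed
first-to-last-capture span with its exact expectation and variance under
simple random sampling of occasions without replacement,
P(d=r) = (k−r)·C(r−1, c−2)/C(k, c); the standardized sum is one-sided low
(losses/gains shorten spans). Survey restriction searches all contiguous
occasion windows, longest first, earliest start on ties, and returns the
first window whose closure p exceeds α. Windows without any individual
captured on ≥2 occasions have no p-value and cannot pass; if nothing passes
the survey is left unrestricted, and α ≥ 1 disables restriction.

**Precision**: HRCIW = 100·(UCL−LCL)/(2·estimate), the half relative CI
width used to judge whether a monitoring design could detect a 50% decline.

## Continuous-time two-species occupancy (`ctmso`)

Each station's latent state is one of {neither, species 1 only, species 2
only, both}, with log-linear natural parameters: ψ_z ∝ exp(z1 f1 + z2 f2 +
z1 z2 f12). f12 = 0 gives independence, f12 < 0 avoidance, f12 > 0
aggregation. Each f is a linear predictor in standardized station
covariates; the default candidate set places distance-to-linear-feature on
all three parameters, optionally a site indicator on all three, and prey
RAI on f2 and f12 only (prey availability is hypothesized to act on the
dominant species and on co-occurrence, not on the subordinate's own
presence).

Conditional on presence, detections are a temporal Poisson point process
with log intensity α_s plus a two-harmonic Fourier series in time of day —
flexible enough for unimodal (diurnal) and bimodal (crepuscular) activity —
plus, for the subordinate species only, η·u(t) where u(t) is the time since
the most recent dominant-species detection at that station, capped at
`u_max` (default 72 h; stations never visited by the dominant species sit at
the cap) and standardized against the quadrature grid. Dominant-species
detection times are conditioned on as fixed covariate data, not jointly
modelled. Detection integrals use midpoint quadrature at 60 min (refining to
5 min moves the fitted log likelihood by well under 0.1% on synthetic data).
Model selection is two-stage: the spatial set first, then the lag covariate
added to the AIC winner.

Wald 95% intervals come from the inverse numerical Hessian; a coefficient is
"informative" when its CI excludes zero. Prediction curves (marginal ψ,
co-occurrence ψ11, diel activity, 3-h detection-share bins) propagate
uncertainty by a parametric bootstrap of the coefficient vector (1000
multivariate-normal draws by default, seed-controlled). Activity curves can
condition on the other species' presence either by detection-based station
classes (default) or by latent-state posteriors; with no lag term the two
coincide up to weighting.

## Scat diets (`diet`)

FO is the percentage of scats containing a taxon; CFO splits each scat's
unit weight equally over its items (summing to 100); RBC weights CFO by the
biomass a predator ingests per collectable scat, y = a − b·exp(−c·x) with
x = prey mass / predator mass and defaults a = 0.033, b = 0.025, c = 4.284
(an asymptotic regression for obligate carnivores; the constants are
configuration and were validated cell-by-cell against the published leopard
RBC column). Size classes resolve the published boundary overlaps as:
very small ≤ 2 kg < small < 10 kg ≤ medium < 30 kg ≤ large. Group FO is the
share of scats containing ≥1 member taxon (not a sum); group CFO/RBC are
sums. Pianka overlap and Levins standardized breadth default to FO-derived
proportion vectors — the only basis consistent with the published overlap
value — with CFO/RBC variants available. Sampling adequacy uses Brillouin
diversity (log-gamma form) on pooled per-taxon item counts with bootstrapped
scat-accumulation curves (10,000 resamples with replacement by default);
the final incremental change below 1% flags adequate effort.

The package ships two small scat tables *reconstructed* from the published
per-taxon summary columns (stand-ins for non-public raw data, labelled as
such): the 9-scat dominant-felid table is uniquely determined by its FO/CFO
columns; the 16-scat subordinate table matches every published FO/CFO cell
at one decimal only if one scat holds two items of the same murid category,
which also reconciles the published item total (22) with the occurrence
count implied by FO (21).

## Synthetic data (`synth`)

The generator emulates the study conditions end to end: a 63-station nested
grid (36 one-km cells covering 36 km² centered inside a 6×6 grid of 2-km
cells covering 144 km²; stations jittered uniformly within 200 m of
centroids), SCR histories at the site presets (e.g. D = 6.11/100 km²,
g0 = 0.009/0.012 and σ = 1570/3406 m by sex, female fraction 0.77, 110 daily
occasions), two-species detection times by thinning against the Fourier
intensity (subordinate diurnal via a first harmonic, dominant crepuscular
via a second harmonic peaking at 06:00/18:00, intensity intercepts chosen to
yield the observed ~1.5–2 captures/100 trap days), and scat tables with
1 + Binomial(2, p) items per scat (p matching the observed 1.22–1.38
items/scat). Activity centers are simulated on a buffer (16 km) at least as
wide as any fitted mask to avoid edge bias in recovery tests. One
independent seeded stream per generator makes every dataset reproducible.

What the generator does *not* emulate: landscape covariate surfaces and
spatial autocorrelation, animal movement within home ranges (detections are
independent Bernoulli/Poisson given the center/state), seasonal or
weather-driven intensity changes, camera failures, and misidentification.
Passing recovery tests therefore demonstrate correctness of the estimators
under their own assumptions, not robustness to these violations.

## Problem sizes used in the test suite

Simulation-backed checks are sized to balance statistical resolution and
runtime: density recovery uses 20 replicates at the full survey preset
(63 stations × 110 occasions, 1-km mask with a 14-km buffer); closure and
sex-ratio likelihood-ratio calibrations use 1000 replicates on compact 3×3
trap arrays; occupancy-model calibration and bias checks use 20 replicates
of 63 stations × 45 days. Coverage assertions carry binomial slack (e.g.
≥80% observed coverage for a nominal 95% interval at 20 replicates).

## Known limitations

- Homogeneous density only; no density surfaces, behavioral responses, or
  open-population dynamics.
- Two species only; no third-order co-occurrence parameters and no
  multi-season dynamics.
- The subordinate species' density is out of reach by design (individuals
  are not identifiable), mirroring the motivating survey.
- Levins standardized breadth is sensitive to the category basis and count;
  published breadth values from summary tables are generally not exactly
  recoverable and are not asserted.
- The lag covariate's behaviour before a station's first dominant-species
  detection (held at the cap) is an assumption; `u_max` is configurable.
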