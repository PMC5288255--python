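# Methods

This note documents the models, parameter choices and numerical
conventions behind `gridtrack`, and what the synthetic world does and
does not establish about field data.

## The synthetic world

**Receiver grid.** Receivers sit on a triangular lattice (rows offset by
half a spacing, row height `s·√3/2`), truncated row-major to the
requested node count and perturbed by centred Gaussian placement jitter
(default 3 m), emulating stations strapped to whichever tree is nearest
the ideal point.  Defaults — 40-m spacing, 166 nodes — give a plot of
roughly 25 ha whose mean adjacent-node (Delaunay-edge) spacing is ~41 m.

**Movement.** Each bird is an Ornstein–Uhlenbeck walk per axis around a
territory anchor, discretized with the Euler step
`X(t+Δ) = X(t) + θ(μ−X)Δ + σ√Δ·ε`.  Defaults `θ = 0.01 s⁻¹`,
`σ = 2.8 m·s^-1/2` give a stationary per-axis s.d. of ~20 m (territory
scale) and a relaxation time of ~100 s.  Tracks start at a draw from the
stationary law, so no burn-in is needed.  The discretization is an exact
AR(1) recursion and is computed with a linear filter; its stationary
variance `σ²Δ/(1−(1−θΔ)²)` is the closed-form oracle used in tests
(within 2.6 % of `σ²/2θ` at the 5-s step).  A step `Δ ≥ 1/θ` triggers an
instability warning.

**Intrusion response.** During the response window (intrusion start until
the end of the post hour), the anchor of every non-focal bird shifts
along its own anchor→site axis by `attract_female · v` (females) or
`repel_male · v` (males), where `v` is the focal male's standardized
vocal score and positive values point away from the site.  Defaults
−9 m and +4.5 m per unit score make the implied sex × vocal-score
contrast on the closest-neighbour distance change 13.5 m — the scale of
the field effect this design emulates.  Modelling the response as an
anchor shift (not a velocity bias) keeps the injected effect directly
interpretable in metres of approach distance.  The shift is clamped so
an anchor never crosses the site.

**Radio propagation.** Mean RSSI follows log-distance path loss
`rssi0 − 10·n·log10(d/d0)` with i.i.d. Gaussian dB noise; a node
receives a beacon with logistic probability in distance, 0.5 at
`detect_range_50`.  Defaults: `rssi0 = −40 dB` at 1 m, exponent 2.5,
noise 4 dB, 50 %-range 80 m, logistic scale 10 m.  Nodes beyond the
distance where detection probability falls under 10⁻⁶ (~218 m at the
defaults) never log a record.  These values are chosen to make
localization feasible on a 40-m grid — roughly 15 receiving nodes per
beacon — not calibrated to any particular hardware.

**Playback responses.** Each subject has latent vocal and spatial
response strengths.  The vocal latent is `0.8·age + 0.7·condition +
N(0, 0.8)` (age: second-calendar-year vs older, condition: standardized
residual mass), then standardized; the spatial latent is independent
standard normal.  Six observed variables are `loadings · latents +
N(0, 0.4)` mapped onto field-realistic scales; the default 6×2 loading
matrix puts the four vocal variables at 0.9 on the vocal latent and the
two spatial variables at ±0.9 on the spatial latent (latency negative:
strong responders approach sooner).  These choices give, at large n, a
rotated two-component solution with eigenvalues near 3.6 and 1.9
(~59 % and ~31 % of variance), sampling adequacy ~0.79, and a
condition–PC1 correlation of ~0.6.  Counts are kept continuous so the
correlation structure is exact.

**Colonies, mates, trials.** Male anchors are scattered with ≥ 2-spacing
separation (territoriality); females sit on a 1.5–3-spacing ring around
a host male.  Each male's mate is the nearest-anchored unclaimed female.
Two trial geometries exist: a `global` colony (21 males, 23 females on
the full grid, all birds re-simulated per session) and `local` trials
(focal + 3 male + 3 female neighbours at 60–150 m on a local grid
patch).  Intrusion trials are territories apart, so distant birds never
supply the closest-neighbour minimum; the local design is what the
Monte-Carlo studies use.  Time is seconds from session start; each
session spans one hour before the intrusion to one hour after.

## Localization

Detections are binned into half-open windows `[k·30 s, (k+1)·30 s)`
aligned to t = 0; repeated beacons from one node in a window are
averaged in dB (simple, monotone, and consistent with the dB-scale noise
model).  Windows with fewer than three distinct nodes yield no fix.  The
estimator is two-stage: an RSSI-weighted centroid (weights linear in
RSSI above the window's weakest node) starts a Levenberg–Marquardt
minimization of the summed squared dB residuals under the configured
propagation model (analytic Jacobian, step tolerance 10⁻⁶ m, 100
iterations, batch-vectorized across windows).  If the refinement fails
to converge or would end worse than its start, the centroid is kept and
labelled `weighted_centroid`, so fix density stays comparable across
windows rather than dropping hard cases.  On the default simulator the
median error is ~6.5 m against the true track; noiseless detections are
recovered to solver tolerance.

## Neighbourhood metrics

The closest-male and closest-female minima are evaluated per window, so
the closest individual may differ before vs after.  Birds without a fix
in a window contribute nothing to it; if either window holds no fix for
a sex, that record is flagged incomplete and dropped listwise from the
distance model (with a count in the run log).  Association time credits
one fix window (30 s) per co-located half-minute — the finest statement
the 30-s fix resolution supports; mean association time with zero
partners is reported missing, never zero.

## Scoring

PCA runs on the correlation matrix (the variables mix counts and
seconds).  Components with eigenvalue > 1 are retained, rotated by
varimax with Kaiser normalization (rows scaled to unit communality
before rotation, rescaled after; convergence when the rotation criterion
gains < 10⁻⁸).  Retention is flagged as unstable when the leading
eigenvalue is below `1 + 3√(p/n)`, the scale of the largest eigenvalue
of a null correlation matrix.  Scores use the regression method
`Z R⁻¹ Λ` and are mean-zero by construction; each component is signed so
its largest-|loading| variable loads positively, and the component
dominated by the four vocal variables is labelled vocal regardless of
rotation order.  With n = 14 subjects and 6 variables the eigenvalue
rule is fragile; the module warns below n = 3p but still runs, since
that is the regime the design operates in.  KMO and Bartlett's
sphericity follow the textbook forms (anti-image partial correlations
from R⁻¹; `−(n−1−(2p+5)/6)·ln det R` on `p(p−1)/2` df).

## Inference

The mixed model is `outcome ~ predictor + sex + predictor:sex` with a
random intercept per subject, sex reference level female (so the female
slope is the predictor coefficient and the male slope adds the
interaction).  Both the full and the interaction-free model are fitted
by maximum likelihood — not REML, whose likelihoods are not comparable
across fixed-effect structures — and the interaction is tested by a
1-df LRT.  The fitter profiles the likelihood over the variance ratio
`λ = σ_b²/σ_e²`: given λ the GLS coefficients and σ_e² are closed-form,
leaving a bounded 1-D optimization in log λ with the λ = 0 boundary
checked explicitly (a boundary solution is retained and flagged
singular, not raised).  This is exact for the random-intercept model and
fast enough for the replicate studies below; it agrees with a
general-purpose mixed-model optimizer to ~10⁻⁴ in log-likelihood where
that optimizer converges.

Post-hoc per-sex slopes are Wald chi-square contrasts on the full fit,
gated (configurably) on the PC1 interaction being significant at 0.05,
with no multiplicity correction — matching the analysis convention this
pipeline reproduces.  Influence uses subject-level deletion: Cook's
distance `(β−β₍₋g₎)ᵀ Cov(β)⁻¹ (β−β₍₋g₎)/q` thresholded strictly at 4/N,
combined with standardized conditional residuals > 2; when any row is
flagged (and always for the mean-association-time outcome), the outcome
is rank-transformed (pooled average ranks, ties shared) and refitted.

**Small-sample behaviour of the LRT.** At the design's scale — 13
subjects × 2 rows — the χ²(1) reference is anticonservative.  Even in
the λ = 0 limit the ML LRT reduces to `n·ln(RSS_r/RSS_f)`, whose exact
null rejection rate at the 3.84 cutoff is `P(F(1,22) > 3.50) ≈ 0.075`;
variance-component estimation raises the simulated rate to ~0.086
(10 000 replicates).  Users should read p-values near 0.05 from
13-subject fits accordingly; at 40 subjects the rate is close to
nominal.

## Monte-Carlo studies and problem sizes

The calibration module fixes its study conditions as follows: the direct
fixture uses σ_e = 16.68 m (chosen so the expected interaction SE at 13
subjects is 6.54 m, the scale of the approach-distance models) and
σ_b = 10 m; the null calibration runs 2000 replicates, effect recovery
200 replicates at β = 13.5.  The end-to-end power study runs 16
replicates per arm of a 40-subject study through the complete chain
(simulate → localize → metrics → fit) using local trials; with the
default injected effect the sex × vocal-score interaction on the
distance change is detected in essentially every replicate, while the
associate-count model stays at the nominal rate under the null.  These
sizes keep a full run in minutes on one CPU while leaving binomial noise
well inside the margins being tested.

## What passing tests do and do not show

The simulator reproduces the statistical *structure* the analysis
assumes — distance-decaying detection, a two-factor response table,
a sex-dependent movement response of known size — but not every feature
of field data: no multipath or vegetation attenuation, no diel rhythm,
no behavioural autocorrelation beyond the OU kernel, and an
association network that is sparser than a real colony's (close-range
contacts arise only from independent OU excursions, so the
mean-association-time model is frequently unfittable at 13 subjects).
One emergent caveat: because an OU bird visits within ~2 s.d. of its
anchor every hour, the *closest*-female minimum in a dense global colony
sits near the distance floor, which truncates the injected female
attraction there; effect-recovery studies therefore use the local trial
geometry, where closest distances have room to respond.  Passing the
suite shows the chain is internally correct and calibrated under these
conditions, not that any particular field system meets them.
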