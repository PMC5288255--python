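# gridtrack

Receiver-grid radio tracking and intrusion-response analysis for
territorial songbirds.

Automated telemetry grids (fixed receiver stations logging beacons from
radio-tagged birds) make it possible to watch how a whole neighbourhood —
males and females, signalers and silent eavesdroppers — redistributes
itself when one territory owner is challenged by a (simulated) intruder.
`gridtrack` implements the full computational chain for such experiments:

1. **Localization** — raw RSSI detection logs are binned into half-minute
   windows and multilaterated into position fixes (weighted centroid
   start, Levenberg–Marquardt refinement of the log-distance path-loss
   objective; a window needs ≥ 3 receiving nodes to yield a fix).
2. **Neighbourhood metrics** — per playback trial, the minimum distance
   to the intrusion site of the closest male and closest female in the
   60 min before vs the 60 min after the intrusion (Δ = post − pre;
   negative = conspecifics came closer), and the focal male's close-range
   proximity network: unique associates within 10 m per half-minute
   window and mean association time, mates excluded from female
   associates.
3. **Response scoring** — six playback-response variables (song overlaps,
   total songs, songs during playback, singing duration, time near the
   loudspeaker, approach latency) are summarized by PCA on the
   correlation matrix with Kaiser-normalized varimax rotation
   (eigenvalue > 1 retention), yielding a vocal component (PC1) and a
   spatial component (PC2), with KMO and Bartlett-sphericity diagnostics;
   body condition is the residual of weight regressed on tarsus.
4. **Inference** — linear mixed models
   `Δ ~ vocal score × conspecific sex + (1 | subject)`, fitted by maximum
   likelihood, with a 1-df likelihood-ratio test on the sex interaction,
   per-sex Wald contrasts post hoc, subject-level influence diagnostics
   (|standardized residual| > 2 and group Cook's D > 4/N) with a
   rank-transform fallback, plus Welch-t / Pearson / paired-Wilcoxon
   univariate tests.
5. **Synthetic world** — a fully seeded simulator (triangular 40-m
   receiver grid, 5-s tag beacons, log-distance RSSI with logistic
   detection, Ornstein–Uhlenbeck territory-anchored movement, and a
   playback-response generator with a two-factor latent structure) so
   every stage is testable end to end without field data.  A
   sex-dependent movement response is injected as an anchor shift during
   the response window: females drawn toward, males pushed away from the
   intrusion site, in proportion to the focal male's vocal score.

## Worked example

One command simulates a 13-subject intrusion study, localizes every
beacon window, computes the neighbourhood outcomes, scores the playback
responses and fits the models:

```bash
gridtrack run-all --out demo --seed 1
python - <<'PY'
from gridtrack import pipeline
cfg = pipeline.PipelineConfig(n_subjects=13, trial_mode="local")
pipeline.run_all(cfg, "demo", seed=1)
PY
```

`demo/report.md` from that run:

```
Seed 1, config bda7bd0ba08d, 13 subjects, 1949898 detections, 22295 fixes
(0 windows below 3 nodes).

## Response scoring
KMO = 0.73; Bartlett chi2(15) = 55.5, p = 1.5e-06; 2 components retained
(eigenvalues 3.72, 1.66, 0.26 ...).

## Sex x vocal-response models
- delta_min_dist_m: interaction = 13.55 (SE 5.31), LRT chi2(1) = 5.28, p = 0.0216
  - females: -7.70 (chi2 3.35, p 0.0671); males: 5.86 (chi2 1.94, p 0.164)
- delta_n_assoc: interaction = -1.22 (SE 1.26), LRT chi2(1) = 0.91, p = 0.341
- delta_mean_time_s: not fitted (need >= 5 subjects)
```

Reading it: the response table has the intended two-component structure
(vocal eigenvalue 3.72, spatial 1.66; sampling adequacy 0.73).  The sex ×
vocal-score interaction on the closest-neighbour distance change is
+13.6 m per unit vocal score — females moved closer (negative slope)
while males kept their distance — whereas the associate-count model shows
no effect: the movement response is detected, the proximity network stays
stable.  `results.json` carries the same numbers in machine-readable
form, along with per-stage row counts and the PCA diagnostics.

Individual stages are available as subcommands (`simulate`, `localize`,
`metrics`, `score`, `analyze`) exchanging plain CSV tables, so any stage
can be rerun or replaced; see `gridtrack --help`.

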