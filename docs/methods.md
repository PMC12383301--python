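# Methods

This note documents the models, rules and numerical choices implemented in
`stip`, in the order the pipeline runs them.

## Problem setting

Eight adherent human tumor cell lines are monitored label-free in 96-well
plates for 48 h at hourly resolution after exposure to a non-cytotoxic
phospholipid–protein formulation (treated) or vehicle (control), in
technical triplicates, across independently produced formulation batches.
The readout per well is confluence (% of well surface covered). Optional
channels are a cumulative cell-death percentage per well and a four-analyte
cytokine panel (IL-6, IL-10, IFN-γ, TNF-α in pg/mL). The analysis assigns
each line × formulation a functional phenotype — stimulatory (Type I),
inhibitory (Type II) or neutral (Type III) — then ranks lines by a
composite index (FSI), checks intra-assay and interbatch reproducibility,
builds a line × formulation compatibility matrix, and clusters lines into
functional compatibility groups.

## Kinetic metrics

Raw replicate traces are validated (0–100%, strictly increasing hourly
grid, at most two consecutive missing frames linearly interpolated).
Divergence between arms is assessed on group-mean curves that are baseline
subtracted (value at the first timepoint, clipped at zero) and smoothed
with a centered three-point moving average (two-point windows at the
ends). Final confluence, AUC and the log-phase slope are computed on the
raw percent scale so their units stay interpretable; sample statistics use
the n−1 denominator throughout.

Per treated group and its matched control:

* **Δ (points)** = treated − control mean final confluence;
  **Δ/control** = Δ divided by the control final. Both are reported; the
  classifier and FSI use the relative form, which is what makes the three
  phenotype labels of the reference cohort mutually consistent.
* **Per-timepoint tests**: Welch's unequal-variance two-tailed t-test on
  raw replicate values at every timepoint, no multiplicity correction —
  the classification rule counts raw p < 0.05 points. Columns with zero
  variance in both arms get p = 1 (equal means) or 0 (unequal) by
  convention. With triplicates the test is mildly conservative
  (empirical null rejection ≈ 0.04); it is exact-level at n ≈ 10, which
  is the arm size the null-calibration oracle uses.
* **Divergence onset (ΔT)**: earliest time at which |relative difference|
  ≥ 0.10 and p < α, sustained for ≥ 3 consecutive hourly points. The
  relative difference's denominator is floored at 1 percentage point to
  guard the near-zero early baseline.
* **Sustained divergence duration**: the longest run of consecutive
  points with |relative difference| ≥ 0.20 and p < α; a run of k hourly
  points counts as k hours.
* **Log-phase slope**: the maximum-magnitude least-squares slope over all
  sliding 6 h windows of the smoothed treated mean curve, sign preserved.
* **AUC**: trapezoidal integral of the raw treated mean curve (%·h over
  0–48 h). Note the reference cohort's published AUC column is in an
  unstated arbitrary unit (~200–430); only its ordering and z-scores are
  ever used, never its magnitude.
* **Plateau window**: the longest terminal interval on which the
  forward-looking 7-point least-squares slope stays within 0.15 %/h,
  reported only if ≥ 6 h. Forward windows keep a plateau's first point
  uncontaminated by the preceding growth phase; with a shallow ramp
  (≲1 %/h) the detected boundary can be early by about an hour.
* **Intra-assay CV** = 100 · SD/mean of replicate final confluences.

## Phenotype decision tree

The cytotoxicity gate runs first: if the treated group's mean cumulative
death at 48 h exceeds 5%, the response is `cytotoxic_confounded` and no
type is assigned (death above 2.5% at any time is additionally flagged as
a positive death signal). Otherwise:

* **stimulatory** — Δ/control ≥ +0.20, sustained ≥ 12 h, significant at
  ≥ 5 timepoints; **inhibitory** — the mirror image at ≤ −0.20;
* **neutral** — |Δ/control| < 0.10 with fewer than 5 significant points;
* anything between the 10% and 20% bands, or with too short or
  non-significant divergence, is **indeterminate**: the three defined
  classes are kept pure rather than force-fitting borderline responses.
  Ties at exactly ±0.20 count as active.

Cytokine congruence is recorded as evidence and never overrides kinetics:
a stimulatory call is congruent when the treated panel's IFN-γ/IL-10 ratio
(ratio of group means, below-LLOD samples excluded) is < 3, an inhibitory
call when it is > 6, and a neutral call when no analyte differs from
control (Welch test, Bonferroni over the four analytes, adjusted p ≥ 0.1).
The inhibitory boundary is deliberately strict: the reference inhibitory
group's own ratio is 5.89, so it evaluates as incongruent under the
default 6.0 — the boundary is config-exposed (`ratio_high`) because the
reported cut-offs are not mutually consistent; congruence being advisory,
this affects no category.

## FSI

Five parameters per line — Δ/control, log-phase slope, direction-signed
divergence duration, AUC, intra-assay CV — are z-scored across the cohort
and combined as

    FSI = 15 · (0.30·z(Δrel) + 0.20·z(slope) + 0.15·z(±dur)
                + 0.25·z(AUC) − 0.10·z(CV))

The published description fixes neither weights nor scale; these defaults
were chosen so the composite reproduces the reference cohort's sign
pattern and complete rank order, and they are config-exposed. CV enters
negatively (noise is penalized); duration is signed by response direction
so inhibited lines do not collect positive duration credit. Because
z-columns sum to zero, cohort FSI values sum to zero — the published FSI
column does not, confirming its exact weights are unrecoverable; FSI value
equality is therefore out of scope, only signs and ordering are validated.

## QC

Intra-assay: CV of final confluence ≤ 8% for active lines, ≤ 5% for
neutral lines (indeterminate is held to the active bound). Interbatch
(≥ 2 batches per line × formulation): across-batch CV of final confluence
< 10%, CV of detected onset < 8%, largest pairwise spread of Δ (points)
≤ 10, and category concordance. Concordance is judged over definite
Type I/II/III calls; batches where the classifier abstains
(indeterminate) are counted and reported but do not break concordance by
default — with triplicates and ~49 uncorrected tests per curve, a truly
neutral line accrues ≥ 5 spurious significant points in roughly 8% of
batches, and treating those abstentions as inversions would make the
verdict reflect the test's multiplicity behavior rather than batch
quality. `strict_concordance` restores the literal all-equal rule. The
10-point bound is applied to the treated−control Δ (the quantity whose
batch stability the protocol tracks), not to raw final confluence, which
legitimately carries the batch factor.

## Clustering and similarity

Lines are clustered on z-scored features — by default log-phase slope,
AUC, signed duration and FSI; Δ/control and CV are omitted because FSI
already folds them in — with Euclidean distance and Ward-D2 linkage
(scipy `linkage(method="ward")` on the observation matrix). The cluster
count maximizes the mean silhouette over k = 2..min(5, n−1); the published
analysis simply reports three clusters, so an explicit reproducible
selection rule is used instead. The similarity heatmap matrix is the
max-normalized Euclidean complement s_ij = 1 − d_ij/max(d) (bounded,
monotone in distance, undefined metric in the original figure).

## Synthetic data generator

Controls follow a logistic C(t) = K/(1+exp(−r(t−t_mid))). Treated wells
switch at the effect onset to effect-scaled parameters (K·effect_K,
r·effect_r), re-anchored so the trajectory is continuous at the switch;
the same mechanism produces sustained rises (effect_K > 1), progressive
suppression or decay toward a lower plateau (effect_K < 1) and unchanged
trajectories (effect = 1). The default cohort reproduces the reference
contrasts: effect_K equals each line's treated/control final ratio, each
line's t_mid sits near its onset, and the rate effects (effect_r 1.4–1.8
for stimulated lines, 0.6–0.8 for inhibited ones) make the arms separate
fast enough that the detected onset lands within 1–2 h of the per-line ΔT
and stays stable across batches (sd ≈ 0.4–0.7 h, matching the reported
roughly ±0.6 h interbatch onset range) — slow separation would smear
detection over several hours and inflate the interbatch onset CV beyond
what the study reports.

Well noise is additive Gaussian (default sd 1.0 percentage point,
clipped to [0, 100]) — chosen to satisfy the reported intra-assay CV
bounds, since replicate noise magnitudes are not published. A
multiplicative batch factor (CV 5% by default) is drawn once per
production batch and scales the carrying capacity of **every** well in
the batch, treated and control alike: it models plate/passage-level batch
variation, is visible to interbatch QC through the across-batch spread of
final confluence, and leaves the within-batch treated/control contrast
unbiased. (A factor applied to treated wells only would shift neutral
lines' Δ/control by the full batch CV and manufacture persistent spurious
significance — incompatible with the reported perfect batch concordance.)

Death traces saturate exponentially (τ = 16 h) at class plateaus
(stimulatory 1.2%, inhibitory 2.8–3.2%, neutral 1.0%, cytotoxic 7%) with
small accumulated noise, kept monotone. Cytokine panels are Gaussian
draws truncated at zero with the per-class group means/SDs; controls and
neutral lines share the baseline panel; a fixed 2 pg/mL floor marks
below-LLOD samples.

What the generator does **not** emulate: spatial/edge well effects,
autocorrelated imaging noise, segmentation-mask artifacts, drifting
baselines, non-logistic growth (contact-inhibition release, biphasic
growth), or cytokine–kinetics coupling within a line. Passing recovery
tests therefore demonstrate the pipeline's correctness under its own
assumptions, not robustness to every real-instrument pathology.

## Problem sizes and determinism

Stochastic validation uses 200 seeded 8-line cohorts (1600 calls) for
classification accuracy, 200 seeded 5-batch studies for interbatch QC,
10,000 simulated null timepoints for the test calibration, and 100 random
instances (n ≤ 6) for the exact Ward merge-order oracle. A single integer
seed drives every stochastic stage; analysis itself is deterministic, and
repeated runs write byte-identical outputs.

## Known limitations

* The published AUC normalization and FSI weights are unstated; AUC
  magnitudes and FSI values are deliberately not reproduced.
* Detected onset is the first *detectable* sustained separation and lags
  the generative effect onset by 1–2 h at default noise.
* The indeterminate class means cohorts with borderline (10–20%) effects
  will report abstentions rather than forced labels; downstream rates
  should be read with the abstention count in hand.
* With fewer than 3 cytokine replicates per arm the congruence checks
  are reported as not assessed.
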