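# Methods

## The measure

The pipeline quantifies, per brain region, how often it acts as a
connectivity hub while the functional network reconfigures over a
resting-state scan.

For one subject with parcellated BOLD series `x_i(t)`, i = 1..90 (AAL
cerebral regions, cerebellum excluded), the sample Pearson correlation
`R_ij` over a time window gives a 90 × 90 connectivity matrix.  Windows are
rectangular (no tapering), 25 TR wide (50 s at TR = 2 s), advanced 1 TR at
a time; indices are 0-based half-open `[start, start + 25)` internally and
the window count is `⌊(T − 25)/1⌋ + 1` — 206 windows for a 230-volume scan.
The matrix is binarized and each region's degree `D_i` (neighbor count,
i ≠ j) is Z-scored across the 90 regions of that same graph,
`Z_i = (D_i − D̄)/σ_D`.  A region is a hub in that window iff `Z_i > 1`
(strictly).  **Hub probability** (centrality frequency) is the fraction of
windows in which the region is a hub; the static analogue replaces the
window by the full scan and uses the Z-scored degree itself as the
per-region measure.

Note on window counts: for the acquisition geometry the pipeline emulates
(240 volumes acquired, first 10 discarded, window 25, step 1), the general
formula gives 206 windows.  Descriptions of this design sometimes quote
215 windows, which is inconsistent with those parameters; the package
implements the formula with no special-casing.

## Thresholding

Two binarization families, chosen by `ThresholdSpec`:

* **absolute** — edge iff the signed correlation strictly exceeds the
  threshold (defaults 0.25, validation alternative 0.2).  Strong *negative*
  correlations are not edges: the rule thresholds r, not |r|.
* **proportional (sparsity)** — exactly `round_half_up(s · 4005)` strongest
  off-diagonal edges are kept (4005 = 90·89/2 pairs; s = 0.2 → 801 edges,
  s = 0.25 → 1001).  Edges are ranked on variance-stabilized weights
  (Fisher z = atanh r) by default; since the map is monotone the edge set
  is identical to ranking raw r (asserted by tests), and the transform
  exists for interoperability with practice.  Ties at the cutoff are broken
  toward the lexicographically smaller (i, j) pair so runs are
  bit-reproducible; ties have measure zero on real-valued data.

Degenerate conventions, all explicit and tested: σ_D uses the population
(divide-by-N) standard deviation over the fixed set of 90 regions
(switchable via `ddof`); a graph whose degrees are all equal gets all
Z = 0 and no hubs; correlations of exactly ±1 are clipped to ±(1 − 1e−7)
with a warning before atanh; a region constant within a window is an error
naming the region and window (its correlation is undefined).

## Group-level inference

* **Per-region group test**: pooled-variance (Student) two-sample t-test
  of the measure between NC and SCD, two-tailed, uncorrected.  The pooled
  form is the default because it reproduces the demographic-table
  comparisons recomputable from printed group summaries (age p = 0.421,
  education p = 0.513); Welch is available by flag.  Regions with zero
  variance in both groups are flagged as degenerate rather than tested.
* **Score regressions**: one OLS per (region, score) pair —
  `score ~ measure + age + sex + education` — rather than one 90-predictor
  model, which would be unfittable at n = 40/53 subjects with covariates.
  The readout is the standardized β of the measure
  (`b · sd(measure)/sd(score)`) and its two-tailed p.  Sex is coded
  M = 0 / F = 1 (p is invariant to the coding).  Pooled "ALL" models carry
  no group term by default.  The default score set is
  {AVLT-I, AVLT-D, AVLT-R, MMSE, MoCA, CDT}; which scores enter is a
  configuration choice.
* **Selection**: a region is selected for a group when its minimum p over
  the configured scores is strictly below α = 0.05, with no multiplicity
  correction — deliberately mirroring the uncorrected procedure this
  pipeline reproduces; a Benjamini–Hochberg option exists, default off.
  With 6 scores per region the null selection rate per region is
  1 − 0.95⁶ ≈ 26%, so uncorrected selections are descriptive, not
  confirmatory.

## Topography

The packaged atlas table assigns each AAL region one of three classes.
The anterior class is deliberately broad — frontal lobe, central/
sensorimotor strip, parietal lobe including precuneus, supramarginal and
angular gyri and the paracentral lobule, insula, anterior and middle
cingulate; posterior covers occipital and temporal cortex, posterior
cingulate and fusiform/lingual/cuneus/calcarine; subcortical is
hippocampus, parahippocampal gyrus, amygdala and the deep nuclei.  This is
the only rule consistent with every anterior/posterior assignment
enumerated in the reference results; regions those enumerations never
mention are extrapolated under the same rule and marked `inferred` in the
table.  DMN membership is a constrained reconstruction: membership forced
in or out by the enumerated in-DMN splits, extended bilaterally for
symmetry.  Both classifications are data (`data/aal90_atlas.tsv`), not
code, and can be overridden.

Reports count anterior regions among the selected set at three levels
(whole brain, in DMN, out of DMN); the "other" pool is posterior +
subcortical.  Percentages round half-up to one decimal (matching how such
values are conventionally printed; banker's rounding would differ at
exactly .x5) and are undefined — not zero — on an empty denominator.
Group differences are NC − SCD percentage deltas per level, computed from
the rounded percentages.

The packaged `results_selections` fixture transcribes the four reference
region selections.  Only each selection's *anterior* members were ever
enumerated; the non-anterior remainder is a synthetic completion chosen to
satisfy the reported totals (24/23 dynamic, 17/23 static) and in-DMN
counts (15 and 11, back-solved from the printed 93.3% = 14/15 and
45.5% = 5/11), and is labelled as synthetic in the fixture file.

## The synthetic cohort generator

What it emulates: the study design (53 NC + 40 SCD; 230 usable volumes at
TR = 2 s; 90 regions), block-structured connectivity with regime
switching, group differences in dynamic hub structure, and linear
couplings between cognition and hub probability.

Mechanism and defaults, chosen once as plausible for resting-state dFC:

* **States.**  Three latent connectivity states with 8-region hub sets:
  anterior-DMN (medial prefrontal, rectus, middle cingulate),
  posterior-DMN (posterior cingulate, inferior parietal, angular,
  precuneus), visual/sensorimotor (precentral, calcarine, lingual,
  superior occipital).  NC occupancies 0.45/0.35/0.20; SCD
  0.30/0.40/0.30 — reduced anterior-DMN hub dwell in SCD, mirroring the
  direction of the reference findings.
* **Covariance.**  Within a state, hub regions correlate 0.3 with every
  other region, 0.95 with each other; background pairs correlate 0.1.
  This is the correlation pattern of a one-factor model in which hubs load
  almost entirely on a shared signal.  The ceiling is structural: a region
  cannot correlate more than ≈ √0.1 ≈ 0.316 with 89 mutually
  weakly-correlated series, so "hub rows at 0.6 on background 0.1" is not
  a valid correlation matrix; positive definiteness is verified by
  Cholesky at config validation, before any simulation.
* **Dynamics.**  Per volume the state is resampled from the subject's
  stationary distribution with probability 1/dwell_mean (default 50
  volumes = 100 s), else held — geometric dwell times with exact
  stationary occupancy.  Per-subject occupancies are Dirichlet-jittered
  around the group design (concentration 20), giving realistic
  between-subject variance in hub probability (≈ 0.1–0.2 SD).  Volumes are
  i.i.d. Gaussian within state: no autocorrelation, by design — the
  pipeline is correlation-based and window-level.
* **Planted shifts.**  `planted_group_effect` pairs (region, δ) act on SCD
  subjects through an independent on/off chain with stationary |δ|; while
  "on", the region's hub rows are added (δ > 0) or suppressed (δ < 0).
  Expected SCD probability is p + δ(1 − p) for δ > 0 (union of independent
  processes) and p(1 − |δ|) for δ < 0.  Default: +0.15 on the left
  hippocampus.
* **Scores.**  Each score = group mean + Σ w · (subject's realized true
  hub probability of coupled region − its design expectation) + Gaussian
  noise; group means/SDs follow a typical SCD-study demographic table, and
  the default couplings tie memory/cognition scores to anterior-DMN and
  parietal hub probabilities.
* **Ground truth.**  Per subject: the state sequence and the realized true
  hub probability (fraction of volumes each region's rows were
  hub-elevated); per group: the design-expected profile.

What it does **not** emulate — and what passing tests therefore do not
show about real data: hemodynamics and autocorrelated noise spectra,
head-motion and physiological artifacts, spatially graded (non-block)
connectivity, scanner drift, and continuous (non-switching) connectivity
fluctuation.  Calibration results transfer to real data only insofar as
the state-switching abstraction does.

## Calibration and recovery (what the simulations check)

All in `dynhub.calibration`, seeded and replicable; problem sizes were
chosen to estimate rates with adequate precision at desk scale:

* **Type-I**: 50 null cohorts (30 + 30 subjects, identical group
  dynamics); fraction of non-degenerate per-region tests with p < 0.05
  (≈ 4500 tests).  Regression type-I: 200 replicates of a
  measure-independent score at n = 200.
* **Power**: 50 cohorts with a +0.2 hub-probability overlay on a region
  that is hub in no base state (so the realized shift equals 0.2);
  detection = planted region p < 0.05.
* **Hub recovery**: Spearman between true and estimated hub probability
  pooled over (subject, region) pairs with hub involvement, on a 10 + 10
  study-config cohort.  Regions never hub have true probability exactly 0
  for everyone while their estimates sit on a small chance-call floor
  (≈ 0.05 — windows mixing two states, and the upper tail of correlated
  degree noise, occasionally push a background region over Z = 1); a rank
  correlation across all 90 regions would be dominated by arbitrary
  ordering inside that tied block (its ceiling is ≈ 0.77 even for perfect
  recovery), so the tied block is instead assessed by containment: the 24
  state-designated hub regions must occupy the top 24 ranks of the
  group-mean estimated profile.
* **Score-coupling recovery**: per replicate, one synthetic score per
  coupled region (true hub probability + noise at half the signal SD);
  sign of the standardized β and containment of the coupled regions in
  the selection.

## Known limitations

* Estimated hub probability is upward-biased for high-occupancy states:
  windows overlapping a state boundary still call the plurality state's
  hubs, so a 0.45-occupancy state's hubs are estimated nearer 0.6 with
  window 25 and dwell 50.  Rankings are preserved; absolute occupancies
  are not identifiable from windowed hub calls without deconvolution.
* The uncorrected min-p selection is liberal by construction (see above).
* The anterior/posterior rule and the DMN table are reconstructions
  constrained by enumerated assignments, not canonical atlas products;
  both are overridable data files.
* With fewer than ~7 subjects in a group the covariate-adjusted regression
  is unfittable and the pipeline refuses to run rather than silently
  dropping covariates.
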