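# dynhub

Hub-probability (centrality-frequency) analysis of dynamic functional brain
networks, for researchers studying resting-state fMRI in early cognitive
decline (subjective cognitive decline, SCD, versus normal controls, NC).

Starting from parcellated BOLD time series — one T × 90 matrix per subject
over the 90 cerebral regions of the AAL atlas — the package computes:

1. **Connectivity.** Static (full-scan) and sliding-window Pearson
   correlation matrices, `R_ij = cov(x_i, x_j) / (σ_i σ_j)`, with windows of
   25 TR (50 s at TR = 2 s) advanced in steps of 1 TR.  A 230-volume scan
   yields ⌊(230 − 25)/1⌋ + 1 = 206 windows.
2. **Graphs and hubs.** Each correlation matrix is binarized under an
   *absolute* threshold (edge iff r > 0.25 or r > 0.2; negative correlations
   never form edges) or a *proportional* threshold (sparsity 0.2 or 0.25:
   the strongest s·4005 edges of the variance-stabilized matrix).  Degree
   centrality `D_i = Σ_j d_ij` is Z-scored across the 90 regions,
   `Z_i = (D_i − D̄)/σ_D`, and region i is a **hub** when `Z_i > 1`.  Its
   **hub probability** is the fraction of windows in which it is a hub.
3. **Inference.** Per-region two-sample t-tests of hub probability between
   groups; per-(region, score) OLS regressions of each neuropsychological
   score (AVLT, MMSE, MoCA, CDT, …) on the centrality measure with age, sex
   and education as covariates, read out as the standardized β of the
   measure; regions with any score p < 0.05 (uncorrected) are *selected*.
4. **Topography.** Selected regions are classified as anterior / posterior /
   subcortical and by default-mode-network (DMN) membership, yielding
   anterior percentages at three levels (whole brain, in DMN, out of DMN)
   and their NC − SCD differences.

Because the motivating study's raw fMRI is not publicly deposited, the
package ships a **synthetic cohort generator**: a regime-switching model
(latent connectivity states with designated hub sets, Markov dwell times,
per-group state occupancies, planted per-region hub-probability shifts and
linear score couplings) that emulates the study design — 53 NC + 40 SCD
subjects, 230 volumes at TR 2 s — and returns full ground truth, so every
pipeline stage is testable for calibration and recovery.

## Worked example

Simulate the default cohort and run the dynamic analysis:

```bash
dynhub simulate --seed 7 --out cohort
# wrote 93 subjects (53 NC + 40 SCD), 230 volumes x 90 regions to cohort
dynhub run --timeseries-dir cohort/timeseries --phenotype cohort/phenotypes.tsv \
           --mode dynamic --out results
```

The run log reports, for the default condition (absolute threshold
r > 0.25):

```
condition dynamic/absolute_r0.25: 9 significant group-test regions,
selections NC=41 SCD=42 ALL=40
```

`results/group_tests_dynamic_absolute_r0.25.tsv` holds the per-region
t-tests.  With seed 7, the regions whose hub probability differs between
groups (p < 0.05) include the anterior-DMN hub regions whose state
occupancy the generator reduces in SCD, and the left hippocampus (region
37), where the generator plants a +0.15 hub-probability overlay:

```
region  mean_nc  mean_scd      t     p
    24    0.441     0.307  2.274 0.025   # superior frontal, medial (R)
    27    0.431     0.305  2.145 0.035   # gyrus rectus (L)
    33    0.430     0.311  2.086 0.040   # middle cingulate (L)
    37    0.061     0.213 -4.834 0.000   # hippocampus (L), planted +0.15
```

i.e. the pipeline recovers both planted group effects in direction and
location (a few additional regions appear by chance, as expected at an
uncorrected α = 0.05).  `results/topography_*.json` summarizes the
anterior/DMN composition of each group's selected regions and the NC − SCD
differences at the three levels, and `results/selection_*_NC.json` lists
the selected region indices with their minimum p-values.

The same interface accepts any real parcellated dataset: one TSV per
subject (header = region abbreviations in AAL order, one row per volume)
plus a phenotype TSV with `subject_id`, `group`, `age`, `sex`, `education`
and score columns.  `--sweep --mode both` runs the full validation grid
(absolute r = 0.2/0.25 × proportional sparsity 0.2/0.25 × static/dynamic)
with a stability summary of significant-region overlap across conditions.

## Layout

- `src/dynhub/atlas.py` — AAL-90 region table: anterior/posterior/
  subcortical classes and DMN membership (packaged TSV, user-overridable)
- `src/dynhub/connectivity.py` — static and sliding-window Pearson FC
- `src/dynhub/graphs.py` — thresholding, degree, Z-scores, hub calling,
  hub probability
- `src/dynhub/stats.py` — group t-tests, summary-statistic t-tests,
  covariate-adjusted regressions, region selection
- `src/dynhub/topography.py` — anterior/DMN reports, group differences,
  threshold-validation sweep
- `src/dynhub/synthetic.py` — regime-switching cohort generator with
  ground truth; packaged fixtures
- `src/dynhub/calibration.py` — simulation-based type-I/power/recovery
  checks
- `src/dynhub/pipeline.py`, `src/dynhub/cli.py`, `src/dynhub/io.py` —
  orchestration, command line, plain-text I/O

See `docs/methods.md` for the model, the numerical conventions and the
design decisions.
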