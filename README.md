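# restconn

Resting-state EEG group analysis for case-control cohorts: spectral power,
LCMV source projection, phase- and amplitude-based functional connectivity,
graph-theoretical network measures, cluster-based permutation statistics and
nested cross-validated SVM classification — driven by a synthetic cohort
generator with planted, parameterised effects so that every stage can be
validated against known ground truth.

## The scientific problem

Chronic-pain and other clinical EEG studies ask whether resting brain
activity distinguishes patients from matched controls. The measures involved
span several levels:

- **Oscillatory power.** Multitaper (Slepian) spectra on 2-s epochs with
  1-s overlap, 1–100 Hz at 0.5 Hz resolution (199 bins); alpha peak
  frequency as the highest strict local maximum of the amplitude spectrum in
  6–14 Hz; absolute and relative band power for theta (4–8 Hz), alpha
  (8–13 Hz), beta (14–30 Hz) and gamma (60–100 Hz).
- **Source-space connectivity.** A linearly constrained minimum variance
  (LCMV) beamformer with 5% diagonal loading and SVD orientation selection
  projects band-filtered sensor data onto sources, where three undirected
  estimators are computed for every node pair:
  - PLV, the phase locking value `|⟨e^{iΔφ(t)}⟩|` — sensitive to both
    zero-lag and lagged coupling;
  - dwPLI, the debiased weighted phase lag index built from imaginary
    cross-spectral terms — blind to zero-lag coupling, robust to volume
    conduction;
  - AEC, the orthogonalized amplitude envelope correlation — each signal's
    collinear component is removed sample-wise before enveloping.
- **Network topology.** Connectivity matrices thresholded to the strongest
  5/10/20% of edges and binarised; node degree, local/global clustering
  coefficient, global efficiency (mean inverse shortest-path length),
  small-worldness against degree-preserving rewired surrogates, and the hub
  disruption index k_d — the regression slope of per-node degree differences
  (subject minus control mean) on the control mean.
- **Statistics.** Unpaired-t permutation tests: cluster-based with summed-t
  cluster mass and a max-statistic null for feature maps, scalar for global
  measures, Holm–Bonferroni across the four bands, Cohen's d effect sizes,
  and Pearson correlations between brain measures and clinical covariates.
- **Classification.** A linear SVM (C = 1) with greedy sequential forward
  feature selection inside nested stratified 10-fold cross-validation,
  balanced subsampling of the majority class, and a label-permutation null
  for chance-level calibration.

Because clinical recordings are rarely shareable, the package includes a
first-class synthetic cohort generator: 1/f-background sources with an alpha
peak, a smooth synthetic lead field, EMG channels, clinical covariate
tables, and *planted* frequency-specific phase or amplitude coupling whose
strength differs between groups — the ground truth every downstream stage is
tested against.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a demo cohort
(20 patients + 20 controls, 60-s recordings, stronger frontal theta/gamma
phase coupling planted in the patient group). They write their tables to
`results/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_spectral_power.py
python 03_source_connectivity.py
python 04_graph_networks.py
python 05_group_statistics.py
python 06_classification.py
```

Output of `05_group_statistics.py` (cluster-based permutation tests on
connectivity strength, excerpt):

```
test                  cohens_d   min_p  n_clusters   t_max
strength_plv_gamma      1.5955  0.0020           1  6.1959
strength_plv_theta      0.5399  0.0140           1  3.7212
strength_aec_gamma      0.0105     NaN           0  0.9784
strength_dwpli_theta   -0.1054  0.1497           2  2.3391
```

The planted zero-lag phase effects are detected by PLV at theta and gamma,
while AEC (amplitude-based) and dwPLI (lagged coupling only) stay null —
the expected dissociation for zero-lag coupling. And from
`06_classification.py`:

```
mean accuracy: 75.5% +/- 4.5%
null accuracy: 55.5% +/- 12.6%
permutation test real vs null: p = 0.0005
most frequently selected features:
  degree_plv_gamma_n003: 71%
  local_cc_dwpli_alpha_n002: 65%
```

The classifier separates the groups well above its permutation null, and the
most frequently selected features are phase-based connectivity measures at
the planted gamma node — the multivariate analysis recovers where the effect
was planted.

A `restconn` command-line tool exposes the same stages
(`simulate`, `spectral`, `sources`, `connectivity`, `graph`, `stats`,
`classify`, `run-all`) over a run directory with HDF5/CSV/YAML files.

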