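# Methods

This note documents the models, estimators and numerical choices behind
`restconn`, and what the synthetic cohorts do and do not emulate.

## Synthetic cohort generator

Each subject's sources are Gaussian processes with power spectral density
proportional to `1/f^slope` (default slope 1, unit SD), plus a band-limited
alpha oscillation centred on `alpha_peak_hz` (default 10 Hz, per-source
amplitude jittered uniformly in [0.5, 1.5]). Sensors are
`gain x sources + white noise`, with a fixed random dipole orientation per
source and signals rescaled to a ~10 µV RMS; sensor noise SD defaults to 10%
of the signal. Recordings default to 5 minutes at 250 Hz.

**Lead field.** The synthetic forward model places sources on a regular 3-D
grid with 1 cm spacing and sensors on a flat 2-D layout. Each source
contributes three spatially smooth gain patterns — two orthogonal tangential
dipoles and one radial pattern, all decaying with distance and source depth
— normalised to unit Frobenius norm per source. The three orientation
columns are mutually distinguishable, which is what makes SVD orientation
selection in the beamformer well-posed. This is deliberately *not* a
realistic head model: no tissue conductivities, no spherical geometry. It
preserves the two properties the analysis depends on — spatial smoothness
and linear mixing — and nothing else.

**Planted effects.** A planted effect names a band, a node set, a coupling
type and per-group strengths in [0, 1]:

- *Phase coupling*: the nodes' own background content in the band is
  band-stop filtered out, then each node receives
  `sqrt(1-c^2) * own + c * shared`, where `shared` is one band-limited
  process (optionally phase-lagged for nodes after the first). At `c = 1`,
  zero lag, phases are perfectly locked (PLV ≈ 1); at `c = 0` nodes are
  independent. The shared-variance fraction is `c²`, so PLV grows slowly at
  small `c` and steeply near 1.
- *Amplitude coupling*: independent band-limited carriers are modulated by a
  common slow (0.1–1 Hz) envelope with depth `0.5 c`; envelope correlation
  rises with `c` while phases stay independent.

Default cohort conditions: 101 patients and 84 controls, stronger frontal
phase coupling in patients at theta (0.45 vs 0.30) and gamma (0.50 vs 0.30),
and amplitude coupling at alpha of equal strength in both groups (so
amplitude-based contrasts are null by construction). Strengths get a ±0.05
per-subject jitter. Clinical covariates (pain intensities, duration,
disability, depression, medication, quality of life) are drawn from
plausible conventional ranges — group-structured but independent of the
planted brain effects by default, so brain–clinical correlations are null;
an optional linkage coefficient can couple pain intensity to the subject's
realised coupling strength.

**What the generator does not emulate:** realistic artifact morphologies
(blinks, cardiac, line noise bursts), realistic head geometry and volume
conduction, non-stationarity beyond the planted slow envelopes, eyes-open/
closed differences, or realistic covariate distributions. Passing tests
demonstrate estimator correctness and pipeline validity under known ground
truth — not that the same effect sizes would be observed in patient data.

## Spectral analysis

Recordings are cut into 2-s epochs with 1-s overlap. Epochs overlapping a
±400 ms window around any sample-to-sample jump exceeding ±100 µV (on any
channel, in absolute recording time, so overlapping neighbours are caught)
are rejected; the operation is idempotent.

Power uses Slepian multitapers with ±1 Hz smoothing: time-bandwidth
`NW = 2 s x 1 Hz = 2`, hence `2NW - 1 = 3` tapers, one-sided spectra scaled
so the sum over bins equals signal variance (verified against a sinusoid's
`a²/2` and white-noise variance). The 2-s epoch grid restricted to 1–100 Hz
is exactly 199 bins at 0.5 Hz. A 45–55 Hz line-noise exclusion is available
as a mask on the grid (keeping the 199-bin layout intact), not as a
time-domain filter.

Band edges are half-open `[lo, hi)` except gamma `[60, 100]` — theta and
alpha share the 8 Hz boundary, so a convention is required; 8 Hz belongs to
alpha. Peak frequency offers four methods (highest strict local maximum of
the amplitude spectrum in 6–14 Hz; centre of gravity; re-estimation on 5-s
windows; per-epoch peaks averaged). When no strict local maximum exists the
local-max method returns a missing value rather than fabricating a peak;
ties go to the lowest frequency. Relative power divides by total power
summed over the full grid and all channels.

## Beamformer

Band-specific covariance comes from 4th-order Butterworth band-pass filtered
(zero-phase, forward-backward — phase relations must survive for PLV)
epoch-concatenated data. The LCMV filter is
`w = (l' C_reg^{-1} l)^{-1} l' C_reg^{-1}` with
`C_reg = C + reg * mean(diag(C)) * I` and `reg = 0.05` by default ("5% of
the covariance matrix" read as diagonal loading with 5% of the mean
diagonal, the standard beamformer practice). Orientation per source is the
first eigenvector of the 3-orientation beamformer output covariance
(maximal output variance), sign-fixed for determinism; the 3×3 system is
solved by pseudo-inverse since it can be rank-deficient when few sources are
active. Ill-conditioned covariances (e.g. average-referenced data, rank
deficient by one) fall back to a pseudo-inverse with a warning when
unregularised, and raise with a diagnostic when even loading fails. The
unit-gain constraint `w·l = 1` is enforced to 1e-6 in tests.

## Connectivity

Analytic signals: band-pass then Hilbert transform per epoch, trimming one
cycle of the band's low edge (at least 50 ms, at most a quarter of the
epoch) from each end to drop filter transients.

- **PLV** is computed per epoch over time samples and averaged across
  epochs (robust to nonstationarity across the recording). Under
  independence, `E[PLV] = sqrt(pi)/(2 sqrt(N))` for `N` iid phase samples —
  used as a Monte-Carlo-verified null. Band-limited signals have correlated
  samples, so their effective null sits above this iid level.
- **dwPLI** pools per-epoch, per-sample analytic cross-terms as the repeated
  observations of the debiased squared WPLI,
  `((ΣI)² - ΣI²) / ((Σ|I|)² - ΣI²)` with `I` the imaginary cross-spectral
  terms. Pure zero-lag coupling makes numerator and denominator vanish; the
  value is defined as 0 and the matrix flagged degenerate.
- **AEC** orthogonalizes sample-wise in the complex domain,
  `Y_orth(t) = Im(y conj(x))/|x|`, correlates `|Y_orth|` with `|x|`, and
  averages the two directions. Envelopes are used without a log transform.
  The imaginary part is taken *before* dividing so that self-
  orthogonalization is numerically exact; orthogonalized signals whose
  magnitude is below 1e-10 of the data scale (a signal against itself or a
  duplicate) yield an undefined correlation, flagged missing.

Connectivity strength is the row mean excluding the diagonal, ignoring
flagged-missing entries. The full 2020-voxel problem of source-space EEG is
replaced by a configurable node count; all estimators are node-count
invariant, so desk-scale runs use tens of nodes.

## Graph metrics

Proportional thresholding keeps exactly `round(density * n(n-1)/2)`
strongest undirected edges; ties across the cut are broken by ascending
node-pair index after a stable descending weight sort (deterministic), and
an all-equal matrix triggers a warning since the retained set is then pure
convention. Local clustering is `2t_i / (k_i(k_i-1))` (0 for degree < 2);
global CC is its mean. Global efficiency is the mean of inverse shortest
path lengths over ordered pairs with `1/∞ = 0`, finite under disconnection
— the reason it is preferred over the inverse of the mean path length.
Small-worldness is `(gCC/gCC_rand) x (gEff/gEff_rand)` against the mean of
degree-preserving double-edge-swap surrogates (default 20 in the API, fewer
in desk-scale pipeline runs); graphs that cannot be rewired (complete
graphs) use themselves as reference, and degenerate references yield a
missing value. The hub disruption index is the OLS slope of
`subject_degree - control_mean` on `control_mean`; for control subjects the
reference excludes their own degrees (leave-one-out) to avoid
self-reference bias.

## Group statistics

All permutation tests permute group labels of an unpaired pooled-variance t
statistic, two-tailed at 0.05. The cluster test thresholds feature-wise t at
the two-sided critical value for the cluster-forming alpha (0.05), forms
connected components of supra-threshold features under the supplied
adjacency separately for the two signs, scores clusters by summed t, and
compares against the permutation null of the maximal absolute cluster mass;
`p = (1 + #{null ≥ |mass|}) / (1 + n_perm)`. With an empty adjacency this
degenerates to a max-statistic correction over single features (tested
against an explicit oracle). t extremes are always reported so null
outcomes remain interpretable. The scalar test enumerates all group splits
exactly when feasible (then `p` is exact, matching brute-force enumeration)
and otherwise uses Monte-Carlo permutations with +1 smoothing. Holm's
step-down correction is applied across the four bands within each measure
family; a plain Bonferroni variant is exposed as well, since published
corrected/uncorrected p-value pairs are sometimes consistent with one and
sometimes the other. Sensor adjacency comes from a distance quantile on the
synthetic 2-D layout, source adjacency from 6-connectivity on the
simulation grid, spectral adjacency from bin chaining.

## Classification

Features concatenate, in deterministic column order: peak frequency (1),
power spectrum bins, band power per channel, and — per estimator and band —
connectivity strength, degree and local CC per node plus the four global
graph measures. At full study dimensions (199 bins, 65 channels, 2020
nodes, 4 bands, 3 estimators) this is 73,228 columns.

The outer loop is stratified 10-fold CV; within each training fold features
are standardised with training-fold statistics and sequential forward
selection greedily adds the feature maximising inner stratified 10-fold CV
accuracy of a linear SVM (C = 1), stopping when the best candidate no longer
*strictly* improves accuracy (ties stop selection; first-of-equals gives the
lowest feature index). Test folds never influence selection — verified by a
dedicated leakage test. Sensitivity and specificity are the true
positive/negative counts divided by the number of patient/control
*classifications made* (the convention of the study design this package
follows). Unbalanced groups are handled by repeatedly subsampling the
majority class to the minority size; chance level by rerunning the whole
procedure with shuffled labels; the two accuracy distributions are compared
with a two-sample permutation test on the mean difference.

The inner SVM is solved in-package by dual coordinate descent (the
liblinear hinge-loss algorithm with an augmented bias feature, deterministic
LCG coordinate shuffling), because nested selection needs millions of tiny
fits; prediction agreement with scikit-learn's `LinearSVC(loss='hinge')` is
part of the test suite. Inner-loop scoring runs the solver for up to 40
passes at tolerance 1e-2 (selection only needs accuracy *rankings*); final
per-fold models train to convergence (2000 passes, 1e-4).

## Problem sizes

Repeated-CV experiments (`restconn.study`) use 60-s recordings, 8 sensors,
5 sources, PLV connectivity, a 16-fold-decimated spectrum and a selection
cap of 10 features — a 122-column table. These sizes are the package's
desk-scale choice: every estimator's correctness is independent of node
count and duration, so they trade only statistical resolution. Degenerate
values that tiny graphs produce (undefined small-worldness on unrewirable
graphs, undefined k_d under zero-variance reference degrees) are filled with
their neutral values (1 and 0) before feature assembly. The demo analysis
(`analysis/`) uses 20+20 subjects, 16 sensors and 8 sources with planted
theta/gamma phase effects of strength 0.55–0.60 vs 0.30.

## Known limitations

- The synthetic lead field and flat sensor layout are geometric
  abstractions; localisation accuracy in realistic head geometry is out of
  scope.
- Planted coupling strengths map nonlinearly onto estimator units (PLV
  shared-variance fraction is the squared mixing weight), so group effect
  sizes in estimator space are controlled only indirectly.
- dwPLI's degenerate flag covers exactly-zero imaginary cross-spectra;
  near-degenerate data simply yield small values.
- EDF files can be read (via mne, optional extra) but not written;
  package-internal storage is HDF5/CSV/JSON/YAML.
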