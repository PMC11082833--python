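# Methods

## Problem and model

Trial-averaged oscillatory power in electrophysiological recordings often
shows a sustained increase after a task ends — a post-task response (PTR),
of which the post-movement beta rebound is the best known example.  At the
single-trial level these smooth averages are produced by transient bursts:
short (~100–500 ms) periods of high-amplitude, relatively narrowband
activity whose *probability* is modulated by the task.  `ptrburst`
implements a mass-univariate burst analysis of source-space region
timecourses built around that picture:

1. **Per-region TDE-HMM.** Each region's z-scored 100 Hz timecourse is
   time-delay embedded: the observation at time *t* is the vector of
   signal values in a 230 ms window centred on *t* (23 lags at 100 Hz,
   forced odd so lags are symmetric).  A K-state HMM (K = 3) with
   zero-mean Gaussian observation models is fitted to these vectors, so
   states differ only in their lag-space covariance — i.e. in their
   autocovariance, and hence in their spectral fingerprint.  Three states
   are used: one typically captures bursts, one other task-related
   activity, and one the "nothing else is happening" background required
   for a complete state sequence.
2. **Binarisation.** Posterior state probabilities are thresholded at 2/3
   (strict inequality).  Any threshold above 1/2 makes the binary
   timecourses mutually exclusive; ties at exactly the threshold are
   "off".  Maximal runs of "on" samples are state lifetimes, interpreted
   as burst durations.  Runs touching a concatenation boundary are split
   so no burst spans two participants.
3. **Cross-region grouping.** Because each region's HMM orders its states
   arbitrarily, the (regions × K) binary timecourses (234 rows for 78
   regions) are grouped by k-means (k = 3, Lloyd iterations, best of
   `n_init` by inertia) treating each row as a point in T-dimensional
   space.  Rows with correlated on-periods — e.g. burst states that
   co-activate post-task across regions — cluster together.  The per-row
   Euclidean distance to its centroid is kept as a cluster-quality
   measure.
4. **PTR identification.** Binary/probability timecourses are epoched by
   block and trial-averaged into probability evolutions.  The PTR cluster
   is the one whose cluster-average evolution maximises (mean probability
   in the PTR window) − (mean in a baseline window, default the final
   10 s of rest).  The visual criterion used on real data is
   operationalised as this contrast; a tie within 1e-9 raises an error
   demanding manual selection.  Within the PTR cluster, each region's PTR
   state is its member with the largest individual contrast (a raw
   PTR-window mean would favour dense background states that occasionally
   fall into the cluster).
5. **Characterisation.** Multitaper PSDs over on-samples, band powers
   (theta 4–8, alpha 8–13, beta 13–30 Hz), lifetime summaries, cycles per
   burst (= mean duration × peak frequency), burst rates per window type,
   burst coincidence (Jaccard of on-samples), and TFR reconstruction as
   probability-evolution × PSD outer products.
6. **Statistics.** Between-task regional comparisons by simple OLS
   (reported as R²); per-participant PTR-probability contrasts between
   conditions correlated with reaction-time contrasts (Pearson,
   Bonferroni over the m = 4 tested regions/networks, two-sided).

## Inference details

EM (Baum–Welch) with a scaled forward–backward E-step is used rather than
the variational Bayesian inference of the HMM-MAR lineage.  This is a
deliberate substitution: EM is fully specifiable without priors, and all
downstream quantities are posteriors, binary timecourses and lifetimes,
which are insensitive to the prior at these data sizes.  Details:

- **Initialisation**: timepoints are partitioned into ~60 contiguous
  chunks assigned randomly to states; each state's covariance is the
  sample second moment of its chunks.  Chunk-wise (not sample-wise)
  assignment preserves local structure — chunks containing bursts yield
  burst-like covariances — so the start point is usefully asymmetric.
  Transitions start sticky (0.8 on the diagonal).  Default 5 restarts
  (test fixtures use 1–3); best final log-likelihood wins.
- **Regularisation**: every M-step adds εI to each covariance with
  ε = 1e-6 × mean diagonal, preventing degeneracy on short runs.
- **Convergence**: stop when the log-likelihood improves by less than
  `tol × max(1, |loglik|)` (default `tol = 1e-6`); the trajectory is
  recorded and is non-decreasing up to a relative tolerance of 1e-8
  (the scale-aware form of the EM monotonicity guarantee in float64).
- **Edges**: the embedding zero-pads half a window at each end; those
  columns are excluded from likelihood computations and their posteriors
  reported as uniform 1/K (hence "off" after thresholding).
- **Oracle**: the forward log-likelihood is checked against explicit
  enumeration of all K^T state paths on tiny instances, and against an
  independently configured reference HMM implementation.

## State spectra

The paper-level quantity is the spectral content of a state.  Two routes
are provided:

- **Data route (default)**: multitaper PSD over the samples where the
  state is on.  On-segments of ≥ 3 samples are chopped to ≤ 2 s pieces;
  each piece gets DPSS tapers with time-bandwidth 4 *per 2 s* — shorter
  pieces keep the same ±2 Hz half-bandwidth rather than inheriting one
  inversely proportional to their length, which would smear a 300 ms
  burst over tens of Hz.  Tapered periodograms are zero-padded onto a
  fixed 1–45 Hz, 0.5 Hz grid and averaged with segment-length weights.
- **Model route (cross-check)**: the state's autocovariance is read off
  the mean diagonals of its lag-space covariance and transformed with a
  Hann-windowed Blackman–Tukey estimate on the same grid.

The data route is the default because it does not depend on the inference
engine's parameterisation; both estimate the same quantity and agree on
peak location in tests.

## Synthetic data

The generator emulates what the analysis assumes about source-space MEG:
78-region-style parcellated timecourses at 600 Hz, 1/f Gaussian background
(default exponent 1, standardised to unit SD), and per-region narrowband
bursts — a random-phase carrier sinusoid (theta/alpha/beta defaults 6, 10,
20 Hz), truncated-normal duration (mean 0.3 s, SD 0.05 s, minimum two
carrier cycles), Hann envelope, amplitude 3 × background SD — placed by an
inhomogeneous Poisson process with separate rates during task (0.1/s),
post-task window (0.6/s) and remaining rest (0.05/s).  The elevated
post-task rate *is* the PTR.  Block templates mirror the two paradigms:
n-back (2 s instruction + 30 s task + 30 s rest = 62 s; PTR window 0–7 s
post-task) and grip force (2/5/10 s grip + 30 s rest; PTR window 2–6 s).
Overlapping same-region bursts are merged into one ground-truth interval
so the truth table is unambiguous.

Burst amplitude relative to background is not reported for real
recordings; 3 × background SD makes single-trial bursts clearly visible in
a TFR, which is the regime the method is described in.  The Hann envelope
is the realistic choice for physiological bursts (no amplitude steps); it
also matches the binary state model well, because the sub-threshold taper
tails roughly offset the temporal smearing of the embedding window.

What the generator does **not** emulate: sensor-level physics and
artefacts, inter-regional leakage, heavy-tailed amplitude distributions,
non-stationary background, behaviour-coupled burst timing.  Passing tests
therefore show that the implementation recovers the model's own
generative structure at realistic SNR — not that any real cortex behaves
this way.

## Fixture sizes and numerical choices

Test fixtures use compact block designs (8 s task, 12 s rest, 8–10
blocks, simulated directly at the 100 Hz analysis rate with a 1–45 Hz
band) and 1–3 EM restarts; the full-width checks use 78 regions at short
fixture length.  These sizes are chosen so the whole suite exercises
every stage end to end at desk scale; all thresholds tested (Jaccard
≥ 0.6, lifetimes within 20%, TFR fidelity ≥ 0.7) are met with margin at
these sizes.

The clustering robustness simulation (three mutually exclusive cyclic
binary templates, 78 rows per group, corruption = replacing a fraction of
samples with fair coin flips) uses 21 timepoints by default.  The
breakdown point of k-means recovery depends jointly on timepoint count,
template separation and rows per group; with 234 rows the 21-timepoint
templates place it at 80% noise (median Hungarian-matched agreement
≥ 0.99 up to 40% noise, ≈ 0.75 at 70%, ≈ 0.50 at 80%, stable across root
seeds).  This simulation is a qualitative reconstruction — the original
supplement's exact corruption scheme and sizes are not printed.

Known limitations:

- Lifetimes inherit a positive bias of order +10–20% when bursts occur in
  rapid succession: the 230 ms embedding cannot resolve gaps shorter than
  the window, so near-adjacent bursts are bridged into one state visit.
  The bias is visible in ground-truth comparisons and grows with burst
  rate.
- Absolute lifetime values depend on the state count K; cross-region and
  cross-task *variation* is the robust quantity.
- k-means on raw binary rows is sensitive to overall state density as
  well as temporal pattern; with K = 3 this is benign (burst states are
  sparse and co-activated, background states dense), but larger K may
  need density normalisation.
- `between_task_r2` is simple OLS of one regional metric vector on
  another; regions are treated as independent points, ignoring spatial
  autocorrelation, as in the analysis it reproduces.

## Interfaces

Datasets are an HDF5 container (`/data`, attrs `fs`, `participant_id`,
`seed`) with a JSON sidecar (design + region specs; `fs` duplicated and
validated on read) and a `truth.csv`
(`region,onset_s,offset_s,carrier_hz`).  Pipeline outputs are CSV
(bursts, cluster assignments with distances, regional summaries) plus an
HDF5 of probability evolutions and a JSON run manifest (config hash,
seed, package version, outputs, timings).  All randomness derives from
one root seed through named substreams (`simulate:p`, `hmm:<region>`,
`kmeans`), so reruns are byte-identical and stages are individually
reproducible.  The CLI exposes `simulate`, `preprocess`, `run`
(end-to-end: HMM, clustering and metrics run as one unit since grouping
needs all regions' posteriors in memory), `noise-sim` and `behaviour`.
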