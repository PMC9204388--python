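# Methods

## Scope and model overview

`srcfc` implements two source-space functional-connectivity (FC) pipelines
for developmental (12- and 36-month) resting EEG, together with everything
needed to exercise them without external data:

1. **Phase-synchrony pipeline (ROI level).** Sensor EEG is band-limited,
   epoched and cleaned, projected to a volumetric source grid with an
   eLORETA (or depth-weighted minimum-norm) inverse, reduced to one
   oriented series per source by SVD, parcellated into 48 ROIs, and
   summarized as a 48x48 adjacency matrix of trial-resampled weighted phase
   lag index (wPLI) values, Fisher-z transformed, proportionally
   thresholded (top 50 % of edges), and averaged within/between the four
   major lobes.
2. **Amplitude-coupling pipeline (vertex level).** Complex analytic series
   at source vertices are pairwise orthogonalized; natural-log power
   envelopes are Pearson-correlated (the average of the two
   orthogonalization directions), giving a V x V matrix per subject
   (V = 5000 by default). Matrices are robustly normalized
   (median/MAD), each vertex pair is summarized across subjects by a
   one-sample Student t against zero, and the per-vertex mean of the t
   matrix is the hub-topology vector.

Both FC estimators are "robust" in the volume-conduction sense: wPLI weights
each observation's cross-spectrum by the magnitude of its imaginary part, so
zero-lag (instantaneously mixed) contributions cancel; orthogonalization
removes the instantaneously in-phase component of one analytic signal with
respect to the other before envelopes are correlated.

## Preprocessing

* Broadband filter: Hamming-window FIR bandpass 1–50 Hz applied
  forward–backward (zero phase). The published protocol names the window
  but not the order or phase handling; we target a transition width of 25 %
  of the lower edge frequency, floored at 2 Hz (Hamming rule
  `numtaps ~ 3.3 fs / width`, min `0.1 fs` taps) — without the floor a 1-Hz
  edge demands a ~6600-tap filter at 500 Hz, longer than many recordings,
  with boundary transients dominating the output — and cap the order when a
  signal is too short for the forward–backward padding.
* Epochs: consecutive, non-overlapping 2-s windows; trailing partials
  discarded.
* Artifact rejection: an epoch is dropped if any channel sample satisfies
  `x > +100 uV` or `x < -100 uV` (strict inequalities; a sample at exactly
  100 uV survives). The rule marks the keep-mask only; sample values are
  never modified. The rejection runs before channel interpolation; the
  protocol text does not fix this ordering, so it is a documented package
  convention rather than a claim about the original intent.
* Bad channels: Perrin spherical-spline interpolation (m = 4, 50 Legendre
  terms, regularization 1e-5, positions projected to the unit sphere). A
  subject with >= ceil(0.15 n) bad channels (18 of 124) is rejected,
  mirroring the subject-exclusion rule.
* Inclusion gate: at least 30 clean epochs (60 s of data).
* Band definitions: theta 3–6 / 3–7 Hz, alpha 5–10 / 6–11 Hz (12 / 36
  months), beta 11–22 Hz, gamma 22–45 Hz. Theta/alpha deliberately overlap
  at 12 months; no disjointness is enforced.
* Analytic signal: band FIR then Hilbert transform, both applied to the
  *continuous* signal, which is then (re-)epoched — this avoids per-epoch
  edge artifacts of the analytic signal. Epoched input is supported and is
  processed per epoch.

The invariant `mean |analytic|^2 = 2 x band-limited variance` is tested for
narrowband input.

## Forward model

Realistic FEM/BEM head models require subject MRIs and external solvers;
the package provides a three-shell concentric-sphere model and an import
path for externally computed lead fields. Shells (brain, skull,
scalp) default to radii 0.07 / 0.075 / 0.08 m at 12 months (x1.07 at 36
months) with conductivities 0.33 / 0.066 / 0.33 S/m (12 mo) and
0.33 / 0.036 / 0.33 S/m (36 mo). The age-specific skull values are the
model's anchor; shell radii and soft-tissue conductivity are package
conventions (recorded in output metadata) because only the skull values are
fixed by the protocol. Conductivities are interpreted in S/m — 0.33 S/m is
the standard soft-tissue reference point.

The dipole potential is expanded in Legendre harmonics (default 60 terms).
For each order, the radial boundary problem (continuity of potential and of
radial current at both interfaces, zero radial current at the scalp) is
solved in scalp-normalized radii, giving a per-order gain; in the
homogeneous limit the gain reduces to `(2n+1)/n` and the series matches the
closed-form single-sphere solution (verified to ~1e-3 at 60 terms, machine
precision at 200). The tangential term uses the derivative recurrence
`P_n^1 = sin(gamma) P_n'`, folded into the un-normalized tangent vector so
no division by `sin(gamma)` ever occurs. Sources on the grid must lie
strictly inside 0.95x the brain radius; sensors are radially projected onto
the scalp sphere. Lead fields are average-referenced and expressed in uV
per unit dipole moment.

The source grid is an axis-aligned lattice (6 mm default). ~5000–6000
voxels fall inside the brain shell at 6 mm, matching the scale of the
protocol's grids.

## Inverse operators

* **eLORETA.** Per-source 3x3 weights, initialized at identity, iterated as
  `W_i <- sqrtm(L_i^T M L_i)` with
  `M = pinv(sum_j L_j W_j^-1 L_j^T + alpha mean(diag) H)`, `H` the
  average-reference operator; filter rows `F_i = W_i^-1 L_i^T M`.
  `alpha` (default 0.05) scales the regularizer as a fraction of the mean
  diagonal of the weighted sensor Gram matrix — the protocol gives no
  value. The defining exact-localization property (argmax of filter-output
  power at the true source for any noiseless point source) is tested over a
  50-source sweep.
* **Weighted MNE.** `F = R L^T (L R L^T + lambda2 mean(diag) I)^-1` with
  per-triplet weights `||L_i||^(-2 gamma)`; identity noise covariance ("no
  noise modelling"). Defaults `lambda2 = 1/9` (assumed SNR 3), `gamma = 0.5`.
* Both constructions annihilate the constant channel vector, so source
  estimates are invariant to re-referencing (tested to 1e-9).
* **Orientation.** Per source, the first left singular vector of the
  epoch-concatenated 3xT series (real part for analytic input, so the
  orientation is independent of the Hilbert phase convention), computed
  once and applied to all epochs; sign fixed by making the largest-|.|
  component positive.

The per-subject "PCA reduction over frequency bands" mentioned for the
vertex pipeline's filter post-processing is under-specified in the source
protocol and is not implemented.

## Parcellation

A generic label-table reader accepts any voxel->ROI->lobe table aligned to
the grid; no anatomical atlas is shipped. The bundled toy atlas partitions
inside voxels into 48 k-means cells grouped into 4 angular sectors named
after the major lobes — it reproduces the combinatorial structure (48 ROIs,
4 lobes, complete disjoint cover), not anatomy.

ROI representative series: `centroid` (mean of the k voxels nearest the ROI
centroid, default k = 1 — the phase-synchrony pipeline's recommendation),
`mean` (all member voxels), `pca` (first principal component, sign fixed as
for orientation). For analytic input, PCA loadings are estimated on the
real part and applied to the complex series so phase is not distorted by
the rotation; centroid/mean act on complex data directly.

## Connectivity estimators

Spectral observations: per kept epoch, demean, Hanning taper, FFT; bins
with `f_lo <= f <= f_hi` are retained (2-s epochs at 500 Hz give 0.5-Hz
resolution; the 12-month alpha band holds 11 bins). With
`Z_k = X_k conj(Y_k)`:

* `wpli = |sum Im Z_k| / sum |Im Z_k|` (0/0 -> 0). The plain, non-debiased
  estimator.
* `icoh = |Im sum Z_k| / sqrt(sum |X|^2 sum |Y|^2)`
* `coh  = |sum Z_k| / sqrt(sum |X|^2 sum |Y|^2)`
* `plv  = |mean exp(i (arg X_k - arg Y_k))|`

The band value is the arithmetic mean over retained bins (the protocol
reports one value per band without stating the reduction). The
trial-resampled wPLI draws 30 epochs without replacement, 50 times
(fresh draw per repetition, all driven by the run seed), and averages the
matrices. A draw is treated as a *set* (indices sorted before use); when
exactly 30 epochs are available every draw is the full set, and the
single-draw matrix is returned directly, making the degenerate case exact
to the bit.

Amplitude coupling: `orth(x, y) = Im(y conj(x)/|x|)`; the pair value with
orthogonalization is `(corr1 + corr2)/2`,
`corr1 = corr(ln |y orth x|^2, ln |x|^2)` and conversely. `ln` receives
`+1e-20` to guard exact zeros; no envelope smoothing or down-sampling is
applied (the protocol is silent, so the estimator stays raw). Collinear
pairs produce an identically-zero residual and contribute 0 by convention;
a zero-variance envelope makes the value undefined (missing).

A consequence of the raw estimator worth knowing: for envelope-coupled
pairs with *independent* carriers, `ln |y orth x|^2` equals the log
envelope plus `ln sin^2(delta-phi)` of the carrier phase difference, whose
variance (~pi^2/2) attenuates the orthogonalized correlation well below the
planted envelope correlation (a planted 0.8 typically measures ~0.25–0.3
orthogonalized but ~0.75 plain). Tests therefore assert sign, ranking and
separation from the uncoupled null for the orthogonalized estimator, and
absolute agreement (+/-0.1) for the plain one.

Post-processing: Fisher r-to-z (`atanh`, inputs clipped at +/-0.9999,
applied to wPLI values as the protocol prescribes even though wPLI is not a
Pearson r); proportional threshold retaining exactly
`round(keep_fraction * n(n-1)/2)` strongest unique edges (ties broken by
lexicographic (i, j) order, so the count is exact and deterministic);
4x4 lobe means computed over all ROI pairs *including* zeroed edges,
excluding the diagonal within a lobe. Whether the original protocol
thresholds before averaging, or includes zeroed edges, is unstated; both
choices here are documented conventions. z-then-threshold equals
threshold-then-z in edge selection because atanh is monotone.

## Hub topology

Per-subject V x V orthogonalized AAC matrices are normalized by the median
and the (unscaled) MAD of the unique off-diagonal entries — no 1.4826
consistency factor, since only ranks and contrasts are used downstream.
Centering makes zero the typical connectivity, which reconciles "global
correlation significantly greater than the mean" with the per-pair
one-sample t against zero: `t = mean / (sd / sqrt(n))`, (n-1)-denominator
sd, sign retained, zero-variance pairs undefined (missing). The topology
vector is the per-vertex mean of the t matrix with missing entries
excluded. No multiple-comparison correction is applied: t is a weight for
averaging, not thresholded inference.

## Synthetic data generator

The generator emulates the signal regime of band-limited resting EEG:

* Oscillators are narrowband-filtered Gaussian noise (not sinusoids), so
  envelopes fluctuate and amplitude coupling is meaningful; 1/f background
  noise (`pink_exponent` 1.0) is added at `noise_sd` relative to the
  unit-RMS oscillation (default 0.5, i.e. SNR 2 in amplitude).
* `phase_lag(i, j, s, phi)`: j's carrier becomes
  `s * (z_i e^{-i phi}) + (1 - s) * z_j`, rescaled to unit RMS so
  `noise_sd` keeps a fixed SNR meaning. At s = 1 the phase difference is
  exactly phi.
* `envelope_corr(i, j, s)`: both log envelopes load on a shared slow
  (1 Hz low-passed, standardized) Gaussian innovation with weight sqrt(s),
  so their Pearson correlation is s; carriers keep independent phases
  (log-envelope SD 0.4 — moderate lognormal fluctuation).
* `zero_lag_mix(i, j, s)`: instantaneous leakage `z_j <- z_j + s z_i`,
  rescaled. Purely zero-lag: raises coherence and plain envelope
  correlation, leaves wPLI/orthogonalized AAC at the null. The
  volume-conduction tests plant the mix in both directions (each channel a
  mixture of both carriers), which drives magnitude coherence to ~0.9 while
  lagged metrics stay at chance.
* `simulate_envelope_network(V, loadings)`: vertex-level analytic series
  whose log envelopes load on a single shared slow factor with per-vertex
  weights; expected log-envelope correlation between vertices v, w is
  `loadings[v] * loadings[w]`, so the loading vector is the planted hub
  topology. This factor construction, rather than O(V^2) pairwise
  couplings, is how group-level hub simulations are expressed.

All randomness derives from one integer seed expanded into fixed
per-stream substreams (`default_rng([seed, stream])`); identical seeds give
identical arrays.

What the generator does **not** emulate: ocular/muscle artifacts, ICA-able
component structure, non-stationarity across the recording, realistic
anatomy or electrode-skin physics. Passing tests therefore demonstrate the
estimators' contracts and their volume-conduction behavior, not performance
on real pediatric EEG.

## Problem sizes and numerical choices

* Test- and acceptance-scale runs use a 12-mm grid (~600 sources) and 64
  sensors for the inverse sweeps; the full-scale ROI pipeline contract is
  still exercised at 48 ROIs and the vertex contract at V = 5000 (2
  subjects, 500-sample analytic series — the vector length and all-pairs
  feasibility are what that run checks; group t with n = 2 is defined).
* Hub-congruence runs use V = 200 with 20 subjects per group and 60 s of
  125 Hz analytic data per subject: 60 s matches the preprocessing chain's
  minimum clean-data rule, and ~1 Hz envelopes are generously oversampled
  at 125 Hz. The published cohorts have 30 subjects; 20 is a scaled-down
  group size, and the congruence threshold (rank correlation 0.7) is met
  with margin (~0.9).
* Vertex-level AAC offers a single-precision path (~1e-6 accuracy), used
  for large-V runs where only ranks and contrasts matter.
* eLORETA: convergence when the largest relative weight-block change falls
  below 1e-6 (max 100 iterations); matrix square roots via eigen
  decomposition with negative eigenvalues clipped at zero.
* Numerical guards: Fisher-z clip 0.9999; `ln(. + 1e-20)` in envelopes;
  collinearity detected at a 1e-10 relative residual; orientation of an
  all-zero source is zero with a warning.

## Known limitations

* Concentric spheres cannot represent fontanels, sutures or realistic skull
  geometry; the import path exists precisely so external FEM/BEM lead
  fields can replace the analytic model.
* ICA-based artifact removal is out of scope; only amplitude rejection is
  implemented.
* The wPLI estimator is the plain (non-debiased) form; small observation
  counts bias it upward, which is exactly why the trial-resampling scheme
  (30 x 50) exists.
* wPLI is *not* invariant to per-observation amplitude rescaling (its
  weights are amplitude-dependent by construction); it is invariant to
  global per-signal rescaling, and PLV to per-observation rescaling —
  this is what the property tests assert.
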