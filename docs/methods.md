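# Methods

This note documents the models, conventions and design choices behind
`voicerep`, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic generative model

Beta patterns are simulated directly at the GLM-estimate level — no
BOLD time series, hemodynamics or scanner noise spectra. For event `e`
and voxel `v`:

    beta_ev = (mu_v + a · s_v · 1[vocal(e)]) · (1 + g · 1[speech(e)]) + eps_ev

* `mu_v ~ U(0.5, 1.5)`: positive per-voxel baseline (beta units). A
  positive uniform range avoids zero-variance voxels outside
  deliberately degenerate tests.
* `s_v`: a fixed ±1 selectivity pattern on a random subset of voxels
  (`selectivity_fraction`, default 0.5), drawn once per configuration.
  A signed topographic pattern — rather than a mean shift — is what
  gives the decoder and RSA a categorical signal that is distinct from
  activation level.
* `a` (`vocal_effect`, default 0.6): amplitude of the vocal pattern,
  identical for speech and non-speech vocal events.
* `g` (`speech_gain`, default 1.0): a multiplicative gain applied
  *uniformly across voxels* to speech events, i.e. speech doubles the
  activation by default. Voxel-uniformity is the substantive modelling
  assumption: it encodes the hypothesis that speech drives the same
  voice-selective topography harder rather than recruiting a different
  code, and it is exactly the component that z-scoring along the voxel
  dimension removes.
* `eps_ev ~ N(0, noise_sd²)` i.i.d. across events and voxels (default
  0.4). Betas from separate events are treated as exchangeable; no
  temporal autocorrelation is modelled because betas, not time courses,
  are simulated.

Two runs are generated (each stimulus once per run), matching the
two-fold design. All randomness flows from a single seed; identical
configurations give bit-identical outputs.

What the generator does **not** emulate: spatial noise correlations,
inter-participant topographic variability in selectivity layout,
run-level baseline drifts, and any acoustic-feature tuning beyond the
categorical structure. Passing tests therefore demonstrate that the
analysis machinery recovers the intended categorical/gain structure
when it is present, not that real auditory cortex has that structure.

The effect topography of real A1 vs. TVA voxels is not characterized in
the localizer literature at the level this generator would need; the ±1
selectivity model is an explicit assumption, and the pipeline's control
ROI simply sets `a = g = 0` (pure noise).

## ROI construction

* All distances ("closest voxels") are measured in millimetres through
  the volume affine, so anisotropic voxels are handled correctly.
* "Above threshold" is a strict inequality everywhere (probability
  > 0.5 for A1; t > threshold for the TVAs). The t-map significance
  threshold is a required parameter with no claimed default.
* Ties in map value and in distance break lexicographically by voxel
  coordinate, making ROI construction deterministic.
* A local maximum is strictly greater than all 26 neighbours; plateau
  maxima are not detected (the synthetic maps add small noise precisely
  so peaks are strict).
* When several reference coordinates compete for t-map peaks,
  assignment is greedy over all (reference, peak) pairs in order of
  increasing distance, enforcing distinct centers.
* If fewer voxels pass threshold than requested, construction fails
  loudly with the achievable count — never silent padding.
* Maps are assumed already registered to the functional space; atlas
  registration is out of scope.

## Standardization

`along_stimuli` z-scores each voxel over events; `along_voxels`
z-scores each event over voxels. Sample standard deviation (ddof = 1)
throughout — the convention is arbitrary but must be fixed for
reproducibility. Zero-variance rows/columns map to zeros (with a
warning naming them) rather than NaN, keeping downstream distances and
classifiers total.

For decoding, standardization is applied to all events of both runs
*before* the train/test split, reproducing the published order of
operations. This is a mild train/test leakage; a fold-wise variant
(`standardize_within_fold=True`) is available, with the protocol-
faithful behaviour as default.

## Decoding

Linear-kernel SVC at the conventional regularization (C = 1; the
protocol specifies only "linear kernel"). Two folds by scanning run.
The balanced design takes all 12 stimuli of the tested vocal subset and
a seeded half of the non-vocal stimuli, stratified 6 natural + 6
artificial to preserve the non-vocal category's internal balance (which
half was used originally is unspecified).

**Null distribution.** The dummy-classification null shuffles labels
and scores the same two-fold evaluation with a stratified-guess rule
(predicting classes at their training-fold frequencies). Random labels
are balanced *within each run*: real label vectors are run-balanced
because every run presents each stimulus once, and run-wise balance is
also what centers the null at exactly 0.5 (balancing only across runs
anti-correlates train and test class frequencies and biases the
stratified-guess null mean below 0.5). An SVC-refit permutation null is
available for fidelity checks at reduced iteration counts.

**Discreteness.** Two-fold mean accuracies live on a lattice (multiples
of 1/n_events), so the null is discrete and a large probability mass
sits exactly on the empirical 0.95-quantile atom. Strict exceedance of
the threshold is therefore conservative by construction (≈ 0.032 at 24
events rather than 0.05). Calibration is assessed with the mid-p
(tie-aware) exceedance standard for discrete permutation nulls — ties
with the threshold count half — which lands at the nominal level; both
estimators are exposed (`exceedance_rate(tie_aware=...)`). The
significance rule itself stays strict (`accuracy > threshold`), i.e.
conservative.

Accuracy sets are compared across conditions with exact Wilcoxon
signed-rank tests on per-participant mean accuracies; all-zero
difference vectors are reported as degenerate rather than tested.

## RSA

* Cerebral RDMs: Euclidean distance between stimulus-level patterns
  (event rows averaged across runs first, giving 48 × 57 input).
* Statistics are computed on raw distances; the percentile transform
  (average ranks, `100·(rank−0.5)/n`) is display-only.
* Spearman correlations over the strictly-upper triangle, average
  ranks for ties (binary model RDMs are dominated by ties).
* Within-vs-between tests use the pooled-variance two-sample t of
  between minus within cells, one-tailed. Two null schemes:
  * `resample="cells"` (function default): both cell pools resampled
    with replacement at their own sizes after shifting each to the
    pooled mean. Calibrated when cells are exchangeable; this is the
    literal "bootstrapped two-sample t-test".
  * `resample="conditions"` (pipeline default for brain RDMs): the
    partition labels are permuted over conditions each iteration. Cells
    sharing a condition are strongly dependent (a high-norm stimulus is
    far from *everything*), which makes the cell-level bootstrap
    anticonservative on real or simulated RDMs; permuting condition
    labels preserves that dependence exactly. The package's own
    simulations (see `tests/test_rsa.py`) show the cell-level scheme
    produces corrected false positives on group-averaged noise RDMs
    while the condition-label permutation does not, at no cost in
    sensitivity.
* Bonferroni correction multiplies each one-tailed p by the size of the
  declared factorial (2 ROIs × 2 hemispheres × 2 standardizations ×
  3 models = 24 in the standard configuration), capped at 1.
* MDS over RDM sets is classical (Torgerson) scaling of 1 − ρ between
  RDMs, centered, with signs fixed so each axis's largest-magnitude
  coordinate is positive. Note 1 − ρ is not guaranteed metric; negative
  eigenvalues are clipped, so exact distance reproduction is only
  expected for embeddable configurations.

## Modulation power spectrum

Front end: short-time Fourier spectrogram (20 ms window, 4 ms hop),
linear bins pooled into log-spaced channels by triangular weights
(12 channels/octave, 125 Hz to 0.45·fs), log-amplitude with an −80 dB
floor referenced to the spectrogram maximum. The MPS is the modulus of
the 2D FFT of the mean-subtracted log spectrogram; the temporal-rate
axis (Hz) comes from the hop, the spectral-rate axis (cycles/octave)
from the channel density. These parameters are documented defaults; the
property the analyses rely on — correct calibration of the temporal-
rate axis — is robust to them, and is verified against amplitude-
modulated noise fixtures (a 4 Hz, syllabic-rate modulation is recovered
within one rate bin; with a 0.5 s fixture the bin is ≈ 2.1 Hz).

`peak_temporal_modulation` marginalizes over spectral rates, excludes a
DC floor of one rate bin, and requires the candidate peak to rise at
least 2× above the median of the searched marginal — stationary noise
has a flat marginal and is reported as having no defined peak rather
than an arbitrary argmax.

The acoustic RDM is the Euclidean distance between vectorized log-MPS
grids (correlation distance available); unequal-duration stimuli are
zero-padded to the set maximum so all grids share axes.

## Pipeline and reproducibility

Every stochastic stage derives a stable 31-bit stream seed from the
master seed and a stage tag, so a configuration reproduces its report
exactly. Default problem sizes — 5 participants, 48 stimuli × 2 runs,
57 voxels, 100,000 dummy-null iterations, 10,000 RSA null iterations —
run the full analysis in well under a minute; the test suite uses the
same sizes except for reduced null iteration counts where a
distributional property (not a tail estimate) is being checked.

## Known limitations

* The synthetic generator's i.i.d. Gaussian noise understates spatial
  and temporal correlation in real beta estimates; decoding accuracies
  near 1.0 under strong effects reflect that idealization.
* The protocol-faithful standardization-before-split introduces mild
  leakage into decoding folds (documented above, switchable).
* The cell-level RDM bootstrap is anticonservative under condition
  dependence and is retained only as the literal two-sample scheme;
  inference on brain RDMs should use (and the pipeline does use) the
  condition-label permutation.
* MDS of model/brain RDM sets is a visualization; distances in the
  embedding distort whenever 1 − ρ violates metricity.
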