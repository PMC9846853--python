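# voicerep

Multivariate pattern analysis of voice-selective auditory cortex: a
tested, reusable implementation of the ROI-based decoding and
representational similarity analyses used to ask whether the Temporal
Voice Areas (TVAs) are voice areas or merely speech areas.

## The problem

The TVAs of secondary auditory cortex respond more to human voices than
to other sounds — but they respond more strongly to speech than to
non-speech vocal sounds (laughs, coughs, affect bursts). Does that extra
activation mean the TVAs encode *speech* specifically, or do speech
sounds simply drive the same voice-selective topography harder? Two
analyses on per-event GLM beta patterns separate the hypotheses:

* **Balanced decoding.** A linear support-vector classifier is trained
  to label events as vocal vs. non-vocal from ROI activity patterns
  (96 events × 57 voxels per participant), using 12 vocal stimuli
  (speech only, or non-speech vocal only) against 12 non-vocal stimuli,
  with two-fold cross-validation by scanning run. Chance is calibrated
  with a 100,000-iteration dummy-classification null with shuffled
  labels.
* **Representational similarity analysis (RSA).** The 48×48 matrix of
  Euclidean distances between stimulus patterns (an RDM) is compared,
  via Spearman correlation and one-tailed within-vs-between tests
  (Bonferroni-corrected over the 2 ROI × 2 hemisphere ×
  2 standardization × 3 model factorial of 24 comparisons), against
  binary categorical models: **human** (vocal vs. non-vocal), **speech**
  (speech vs. everything else), **non-speech** (non-speech voice vs.
  everything else), and optionally an acoustic RDM built from
  modulation power spectra (MPS).

The decisive manipulation is the standardization scheme. z-scoring each
voxel *along stimuli* preserves activation-level differences between
stimuli; z-scoring each stimulus *along voxels* removes any
voxel-uniform gain, leaving only pattern shape. If speech merely drives
the voice network harder, the "speech" model should win before gain
removal and the "human" model after — which is exactly what both the
original data and this package's synthetic model show.

ROIs follow the voice-localizer recipes: primary auditory cortex (A1)
as the 57 voxels nearest the maximum of a Heschl's-gyrus probabilistic
map with probability above 50%; the TVAs as the conjunction of three
19-voxel sub-ROIs grown around the supra-threshold local maxima of a
voice > non-voice t-map nearest to reference coordinates.

A first-class synthetic-data generator produces stimulus catalogs, beta
patterns with a controllable vocal-selectivity pattern and a
voxel-uniform speech gain, volumetric probability/t maps, and
amplitude-modulated noise fixtures, so the full pipeline is testable
without any scanner data.

## Worked example

```python
import voicerep as vr

results = vr.run_analysis(vr.AnalysisConfig(seed=0))
print(results.mean_accuracies())
```

Output (five simulated participants; the "TVA" ROI carries a vocal
pattern plus a ×2 speech gain, "A1" is noise-only):

```
roi    vocal_subset standardization  mean_accuracy
 A1 nonspeech_vocal   along_stimuli          0.469
 A1 nonspeech_vocal    along_voxels          0.467
 A1          speech   along_stimuli          0.498
 A1          speech    along_voxels          0.519
TVA nonspeech_vocal   along_stimuli          0.998
TVA nonspeech_vocal    along_voxels          0.992
TVA          speech   along_stimuli          1.000
TVA          speech    along_voxels          1.000
```

Decoding succeeds in the voice-selective ROI for both vocal subsets and
stays at chance in the control ROI (null threshold 0.625 at the 0.95
quantile). The RDM–model correlations show the standardization effect —
for the left TVA, Spearman ρ with the three models:

```
standardization     human  speech  nonspeech
along_stimuli       0.640   0.842      0.145
along_voxels        0.864   0.152      0.050
```

With activation levels preserved the "speech" model ranks highest; once
the voxel-uniform gain is removed the "human" model wins strictly, and
`results.planned_comparisons` marks exactly the TVA human/speech
(along-stimuli) and TVA human (along-voxels) tests as significant after
Bonferroni correction over 24 comparisons, with nothing significant in
A1. `results.summary()` prints all tables; `results.save(dir)` writes
TSV/JSON artifacts.

See `docs/methods.md` for the generative model, the statistical
conventions, and known limitations.

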