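# voicesym

Clustering depressive symptom groups from HAM-D-17 rating profiles, and
separating those groups from acoustic features of fixed-phrase speech.

## The problem

Voice-based depression screening usually estimates the *presence* or
*severity* of depression. Treatment planning, however, hinges on the
*symptoms*: a patient whose picture is dominated by inactivity (guilt, loss
of drive and appetite) is medicated differently from one dominated by
insomnia. `voicesym` implements an analysis that:

1. groups patients by the *shape* of their 17-item Hamilton Depression
   Rating Scale (HAM-D-17) profile — K-means under correlation distance
   `d = 1 − r`, with a three-tier rule (totals of 0 excluded, totals ≥ 4
   seed the clusters, totals 1–3 allocated to the nearest centroid) and
   Wilcoxon rank-sum item tests at Bonferroni-corrected levels (0.05/18);
2. extracts a registry of acoustic features from 21 fixed-phrase
   recordings per subject — fundamental frequency, jitter, shimmer, HNR,
   FFT band powers (0–500/500–1000/1000–4000 Hz), spectral centroid and
   flux, energy RMS, five formants, 12 MFCCs, and the glottal quotients
   NAQ and QOQ via iterative adaptive inverse filtering (IAIF) — each
   aggregated to mean and standard deviation per phrase (1176 predictors
   per subject);
3. predicts the symptom group from the feature vector with a
   gradient-boosted decision-tree ensemble under stratified five-fold
   cross-validation, thresholding each fold at the Youden-index cutoff
   (max sensitivity + specificity − 1) chosen on the training split, and
   pooling the five confusion matrices.

Clinical recordings of this kind are not redistributable, so the package
includes a first-class generative model of both modalities: HAM-D cohorts
with two latent symptom profiles and a controllable inter-item correlation
(0.7 between depressed mood and work/activities by default), and voices as
Rosenberg glottal pulse trains — with controllable F0, open quotient,
jitter, shimmer and aspiration noise — through a five-formant vocal tract.
Every stage is verified against these generators and against closed-form
oracles (e.g. NAQ = OQ/6 for the Rosenberg pulse).

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
run (`examples/04_full_pipeline.py`, 16 subjects × 21 phrases):

```text
clustered groups: {'group_1': 11, 'group_2': 5, 'excluded': 0}
items flagged (Bonferroni tier >= 1): ['item_7']
cross-validated accuracy:    81.2%
sensitivity / specificity:   90.9% / 60.0%
artifacts written: 343 files under pipeline_demo/
```

The clustering found an inactivity-leaning group of 11 (group 1 is, by the
canonical labeling, the group scoring higher on item 7, work and
activities) and an insomnia-leaning group of 5; with only 16 subjects just
item 7 survives the 2.8 × 10⁻³ Bonferroni level. The 81% accuracy says the
voice recordings alone recover most of that questionnaire-defined grouping;
at this tiny n the specificity of the minority group is noisy. With the
benchmark cohort size (80 subjects) the same pipeline reaches ~90% median
accuracy at the default acoustic effect size and chance level when the
groups are acoustically identical.

The parameter-recovery loop (`examples/01_synthesize_voice.py`) shows the
extractors reading back what the synthesizer was told:

```text
estimated F0:      119.0 Hz   (synthesized 120.0)
estimated jitter:   2.28 %    (synthesized 2.0)
estimated shimmer:  4.45 %    (synthesized 4.0)
estimated HNR:       8.9 dB   (aspiration SNR 20.0)
```

(HNR sits below the aspiration SNR because jitter and shimmer are
themselves aperiodicity, which HNR charges against the harmonic part.)

A thin CLI wraps the same pipeline: `voicesym run-all`, `synth`,
`extract`, `cluster`, `classify`, `validate`, `dump-defaults`; every run
is fully determined by a YAML config plus a seed.

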