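# seizdyn

Seizure-dynamotype analysis for surface EEG: blind-source separation of
ictal scalp recordings, bifurcation-morphology (BifM) characterization of
seizure onset and offset transitions, automated transition classification,
inter-rater agreement statistics, and Bayesian multilevel modeling of
BifM prevalence against clinical factors.

## The problem

From a dynamical-systems viewpoint, the transition into or out of a
seizure is a bifurcation, and each bifurcation class prescribes a
signature in the EEG near the transition:

| class | side | signature |
|---|---|---|
| SupH | onset / offset | amplitude grows from zero / shrinks to zero, `A(t) ∝ √(t − t₀)` |
| SNIC (SNIC/SH) | onset / offset | spike frequency rises from zero / falls to zero; ISIs follow `ISI(t) ∝ 1/√(t − t₀)` |
| SN/SubH (onset), FLC (offset) | | no prescribed scaling: constant or arbitrary amplitude and ISI |

(ISI = inter-spike interval.  Without a DC channel, SN vs SubH and SNIC
vs SH cannot be told apart and are merged.)

Surface EEG buries these signatures under eye, muscle and movement
artifacts, so the pipeline first isolates candidate seizure sources:
seizure segments (annotation ± 30% margins) are resampled to 256 Hz,
band-limited to 1–40 Hz, artifact-corrected, standardized over the full
window, reduced to eight principal components, and unmixed with extended
infomax ICA.  Each independent component (IC) is then characterized by a
transition feature set — change-point-anchored amplitude/ISI windows,
scaling-law curve fits scored by RMSE, spectral and entropy descriptors,
autocorrelation width — feeding two depth-3 random-forest classifiers
(clear-transition detection; ISI slowing) evaluated with
leave-one-subject-out cross-validation (balanced accuracy, AUC).
Reviewer labels are reconciled across two raters (Cohen's κ against
overall and within-seizure permutation nulls), and the resolved
per-seizure BifMs enter a Bayesian multilevel categorical model (HMC)
whose posterior contrasts are summarized by median, MAP, 95% CI,
probability of direction (pd) and ROPE fraction.

A ground-truth synthetic generator (sources obeying the scaling laws,
scalp mixing with pink noise, blinks and muscle bursts, cohort metadata
with injectable clinical effects) underpins validation of every stage.
`docs/methods.md` documents the models, parameters and limitations.

## Worked example

Simulate one SNIC-onset seizure source, detect its transition, and read
the morphological features:

```python
from seizdyn import synthetic as syn, features as feat

spec = syn.SeizureSimSpec(
    onset_type=syn.BifurcationType("onset", "SNIC"),
    offset_type=syn.BifurcationType("offset", "FLC"),
    duration_s=60.0, seed=11,
)
src = syn.simulate_source(spec)
cp = feat.detect_change_point(src.signal, src.fs, center_s=src.true_onset_s)
print(f"true onset: {src.true_onset_s:.2f} s, "
      f"detected anchor: {cp.time_s:.2f} s (found={cp.found})")

fv = feat.extract_feature_vector(src.signal, src.fs, "onset", cp)
for name in ("isi_mean", "isi_inverse_sqrt_rmse", "isi_constant_rmse",
             "dominant_freq", "spectral_entropy"):
    print(f"{name:24s} {fv.values[name]:.4f}")
```

prints

```
true onset: 18.00 s, detected anchor: 18.00 s (found=True)
isi_mean                 0.4446
isi_inverse_sqrt_rmse    0.2790
isi_constant_rmse        0.4202
dominant_freq            4.0000
spectral_entropy         0.7073
```

The variance change-point lands on the true onset.  The diverging-ISI
law (`1/√t`) fits the inter-spike intervals markedly better than a
constant — the SNIC signature the ISI-slowing classifier learns — and
the dominant frequency matches the generator's 4 Hz plateau spiking.

The full chain (simulate → features → classifiers → agreement → model)
runs from one YAML config:

```sh
dyn run --config pipeline.yaml        # or: dyn simulate / extract / decompose /
                                      #     features / classify / agreement / model
```

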