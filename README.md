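# vdt2 — vowel-acoustics screening toolkit for type 2 diabetes

Type 2 diabetes mellitus (T2DM) can impair vocal-fold elasticity and the
neural control of phonation, shifting measurable properties of sustained
vowels: fundamental frequency drops, cycle-to-cycle period (jitter) and
amplitude (shimmer) perturbations change, and the harmonic-to-noise ratio
(HNR) falls with breathiness. `vdt2` implements the VDT2 screening
framework around these voice biomarkers, for researchers studying
non-invasive, speech-based disease detection:

* **Synthetic data** — a pulse-train vowel synthesizer with controllable
  F0, jitter, shimmer and HNR (including ground-truth cycle sequences,
  the oracle for the extractor), and a cohort generator that reproduces
  the reference study composition: 32 T2DM + 15 control subjects, six
  Mandarin vowels (/a/, /o/, /e/, /i/, /u/, /ü/) recorded twice each, 542
  recordings retained after simulated cleaning.
* **Feature extraction** — the 14 Praat-convention measures (meanF0,
  stdevF0, meanInten, stdevInten, HNR, 5 shimmer and 4 jitter variants)
  from WAV recordings named `name_M_T/N/sen_a_1.wav`.
* **Validity statistics** — per-feature Welch t-tests with Bonferroni
  correction (m = 14), Cohen's *d*, a histogram total-variation statistic,
  and the voice-information threshold η(N) = 1 / (log₂N + 4.81) it is
  compared against (η(1) = 20.79 %, η(50) = 9.57 %).
* **Feature selection** — training-set z-scoring, cross-validated Lasso,
  Random-Forest RFE (default 6 of 14), and their union.
* **Classifier** — a soft decision tree of logistic units: a complete
  binary tree of depth *D* whose node *j* gates with

  g_j(x) = σ(w_j · (α_j ⊙ x) + b_j),  α_j = softmax(a_j),

  routes inputs softly to all 2^D leaves with path probability
  Π g_j / (1 − g_j), and outputs P(y=1|x) = Σ_ℓ π_ℓ(x) σ(θ_ℓ).
  The per-node attention weights α_j adaptively re-weight each acoustic
  feature along each decision path. All parameters are trained jointly by
  L-BFGS-B on the mean binary cross-entropy.
* **Evaluation** — subject-level 6:2:2 train/validation/test splitting
  (no speaker in two partitions), accuracy / recall / specificity /
  rank-based AUC, and an end-to-end seeded pipeline.

## Worked example

```python
from vdt2 import (CohortConfig, sample_cohort, subject_split, SplitSpec,
                  fit_normalizer, select_features, VowelDiabetesTree,
                  confusion_metrics, roc_auc)
from vdt2.features import FEATURE_NAMES, GROUP_T2DM

cohort = sample_cohort(CohortConfig(seed=42))      # 542 recordings, 47 subjects
train, val, test = subject_split(cohort, SplitSpec(seed=42))

norm = fit_normalizer(train)                       # mu/sigma from train only
train_n, test_n = norm.transform(train), norm.transform(test)

y_train = (train_n.group == GROUP_T2DM).astype(int).to_numpy()
sel = select_features(train_n[list(FEATURE_NAMES)], y_train, seed=42)

model = VowelDiabetesTree.from_dataframe(
    train_n, features=sel.union_set, depth=4, seed=42)
res = model.fit(max_iter=200)

y_test = (test_n.group == GROUP_T2DM).astype(int).to_numpy()
scores = res.predict_proba(test_n)
rep = confusion_metrics(y_test, (scores >= 0.5).astype(int))
print(rep.accuracy, rep.recall, rep.specificity, roc_auc(y_test, scores))
```

On the default synthetic cohort this prints a training loss falling from
0.697 (≈ ln 2, the uninformed start) to 0.298 over 200 L-BFGS-B
iterations, and test metrics

```
accuracy 0.627   recall 0.795   specificity 0.229   auc 0.538
```

i.e. the model recovers most patients (recall ≈ 0.8) at a per-recording
accuracy above the 0.6 property-test floor; specificity and AUC on the
10-subject test split are noisy, as expected when the group signal is
modest and half of each feature's variance is a shared subject effect
(see `docs/methods.md`). `res.summary()` prints the fitted tree's layout
and the dominant attention feature per node.

The same chain is available from a shell:

```bash
vdt2 simulate --out features.csv --seed 42
vdt2 stats    --features features.csv --out validity.csv --group-size 47
vdt2 select   --features features.csv --out selection.json
vdt2 train    --features features.csv --selection selection.json --out model.json
vdt2 eval     --features features.csv --model model.json --out metrics.json
```

or as one configured run, `vdt2 pipeline --config config.yaml --outdir run/`,
which writes `features.csv`, `validity.csv`, `selection.json`,
`model.json` and `metrics.json`, each run byte-reproducible under its
seed.

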