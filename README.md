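# breastmri

Machine-learning diagnosis of breast masses from dynamic contrast-enhanced
MRI (DCE-MRI) and diffusion-weighted MRI (DWI), built for methodologists
who want a fully tested, reproducible implementation of the classical
multiparametric radiomics pipeline:

1. **Phantom simulation** — seeded synthetic cohorts of 2-D lesion slices
   with class-dependent boundary spiculation, enhancement kinetics
   (washout vs. persistent), intra-lesion texture heterogeneity, apparent
   diffusion coefficient and age;
2. **Semi-automated segmentation** — fuzzy c-means (FCM) clustering of the
   region of interest for an initial mask, refined by a gradient-vector-
   flow (GVF) active contour;
3. **Feature extraction** — 28 measurements per lesion in five groups:
   age; kinetic slope = (SI_first − SI_pre)/SI_pre and signal enhancement
   ratio SER = (SI_first − SI_pre)/(SI_last − SI_pre); eleven shape
   descriptors (compactness, spiculation, extent, elongation, solidity,
   circularity, radial-length entropy, fractal dimension, heterogeneity,
   area, eccentricity); the thirteen classical GLCM texture statistics;
   and mean ADC = ln(S₀/S_b)/b from the b = 0/800 s/mm² pair;
4. **Hybrid feature-subset selection** — Welch t-test filter (α = 0.05)
   → genetic-algorithm wrapper around a cross-validated SVM → greedy
   backward ablation of negligible-contribution features, also available
   as a scikit-learn selector (`HybridFeatureSelector`);
5. **Evaluation** — stratified 10-fold cross validation with 5-fold inner
   hyperparameter tuning over SVM, naive Bayes, KNN (k = 6) and logistic
   regression; trained Youden-threshold analysis for single features;
   sensitivity, specificity, accuracy and Mann–Whitney AUC.

The phantom generator's defaults emulate a 234-case cohort (149 malignant,
85 benign, mean age ≈ 46 y) whose published analysis this package
re-implements end to end; see `docs/methods.md` for the model details and
design choices.

## Worked example

```python
import breastmri as bm
from breastmri.features import ExtractionConfig
from breastmri.selection import GAConfig, SelectionConfig, run_hybrid_fss
from breastmri.evaluation import evaluate_feature_sets

cohort = bm.generate_cohort(bm.PhantomConfig(n_cases=100, image_size=96, seed=0))

case = cohort.cases[0]
geom = bm.segment_lesion(case.series, case.phantom.roi_box)

table = bm.extract_cohort_features(cohort, ExtractionConfig(use_segmentation=False))

cfg = SelectionConfig(ga=GAConfig(population_size=24, generations=25,
                                  fitness_cv_folds=3, seed=0))
trace = run_hybrid_fss(table.drop(columns=["case_id", "label"]), table.label, cfg)

sets = {"adc_only": ["adc"], "combined": trace.final_subset}
report = evaluate_feature_sets(table, table.label, sets, k=5, inner_k=3, seed=0)
```

Output:

```
cohort: 100 cases, {'malignant': 64, 'benign': 36}
case case_0000 (benign): Dice vs planted boundary = 0.996
slope=0.59  SER=0.68  ADC=1.25e-3 mm^2/s  spiculation=0.15  entropy=8.44 bits
selected: age, solidity, difference_entropy, info_correlation_2, adc
adc_only  acc=91.0%  auc=0.97  sens=0.91  spec=0.92
combined  acc=94.0%  auc=0.98  sens=0.96  spec=0.90
```

Reading it: segmentation recovers the planted boundary almost exactly
(Dice 0.996); the first case is a benign mass with persistent enhancement
(SER < 1); the hybrid selection keeps a compact multi-group subset
(pathology + morphology + texture + diffusion here), and combining groups
beats the best single feature — at this small n = 100 the margins are
wider and noisier than at full cohort scale.

## Command line

The same stages are exposed as a CLI whose artifacts are plain files
(NIfTI frames, PNG masks, CSV tables, JSON traces/reports):

```bash
breastmri simulate --config cfg.yaml --out cohort/
breastmri segment  --series cohort/case_0000 --roi 20,20,60,60 --out seg/
breastmri extract  --config cfg.yaml --out features.csv
breastmri select   --features features.csv --out trace.json
breastmri evaluate --features features.csv --subset trace.json --out report.json
breastmri run-all  --config cfg.yaml --out run/     # manifest.json for replay
breastmri replay   --manifest run/manifest.json --out run2/
```

`run-all` writes a manifest (config snapshot, per-stage seeds, output
checksums); `replay` re-runs it and verifies bitwise identity.

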