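# pcnradiomics

A tested, reusable implementation of a CECT-radiomics workflow for
preoperative discrimination of pancreatic cystic neoplasm (PCN) subtypes:
serous cystadenoma (SCA, benign — surveillance), mucinous cystic neoplasm
(MCN) and intraductal papillary mucinous neoplasm (IPMN, both with malignant
potential — resection candidates). Radiologic discrimination of the three is
notoriously unreliable; the workflow quantifies the tumor region of an
arterial-phase contrast-enhanced CT into radiomics features, screens them
for robustness and relevance, and builds multi-class classifiers on the
surviving features joined with clinical covariates.

The pipeline, end to end:

1. **Quantification** — resample volume + mask to 1 × 1 × 5 mm, quantize the
   ROI to 64 gray levels, compute histogram, GLCM, GLRLM, GLSZM and NGTDM
   features on the original image and on 8 stationary-wavelet subbands
   (423 named features, e.g. `Histogram_Entropy`, `LLL_GLSZM_GLV`).
2. **Robustness** — random per-slice expansion/erosion (1–4 px) of the mask
   yields two alternative segmentations; features with ICC(2,1) > 0.75
   across the three segmentation sets are kept.
3. **Screening** — Pearson inter-correlation pruning (|r| ≤ 0.75),
   Kruskal–Wallis / chi-squared / Fisher significance across the three
   subtypes (α = 0.05), then Boruta shadow-feature selection with a random
   forest and out-of-bag permutation importance.
4. **Modeling** — stratified 70/30 split; SVM (4 kernels × C = 1..10),
   random forest (trees × mtry, out-of-bag error), and a single-hidden-layer
   neural network (10–15 units × 6 weight decays), each tuned by stratified
   4-fold cross-validation.
5. **Evaluation** — 3 × 3 confusion matrices (predicted × true) with
   per-class precision, recall, F1 = 2PR/(P+R) and overall accuracy.

Because the patient images behind the original study are not deposited, the
package ships a first-class phantom module that generates cohorts with the
statistical structure the analysis assumes — three classes with distinct
histogram shape (entropy, skewness, uniformity, kurtosis) and texture
scale, plus clinical covariates in which CA 19-9, CEA, sex and age carry
class signal. Every stage is tested against brute-force oracles or planted
ground truth; see `docs/methods.md` for models, conventions and limitations.

## Worked example

```python
from pcnradiomics import PipelineConfig, run
from pcnradiomics.pipeline import report_tables

manifest = run(PipelineConfig(class_sizes=(30, 30, 30), seed=7))
print(manifest.counts)
print(manifest.selected_features)
print(report_tables(manifest))
```

Output (seed 7):

```
{'n_cases': 90, 'n_features': 423, 'robust': 180, 'decorrelated': 24,
 'significant': 15, 'clinical_significant': 5, 'selected': 12}
['Histogram_Kurtosis', 'GLCM_Homogeneity', 'GLSZM_LGZE',
 'LLL_Histogram_Kurtosis', 'LLL_GLCM_Correlation', 'LLL_GLSZM_LGZE',
 'LLL_NGTDM_Busyness', 'LLH_GLSZM_LZLGE', 'HHH_GLRLM_RLV',
 'age', 'ca199', 'cea']
```

Of 423 extracted features, 180 survive the segmentation-perturbation ICC
screen, 24 the inter-correlation pruning, 15 differ significantly across
subtypes, and Boruta confirms 9 radiomics features together with the
planted clinical factors age, CA 19-9 and CEA. The per-model report then
mirrors the evaluation-table layout, one block per classifier, e.g. for the
random forest on the held-out 30 % (values printed by the run above):

```
-- validation --
TP      IPMN   MCN   SCA     Pre     Rec      F1
IPMN       9     0     0  1.0000  1.0000  1.0000
MCN        0     9     0  1.0000  1.0000  1.0000
SCA        0     0     9  1.0000  1.0000  1.0000
Total      9     9     9      OA  1.0000
```

With the default well-separated phantom classes the three classifiers reach
0.93–1.00 validation overall accuracy against a chance level of 1/3; the
interesting outputs are the stage-by-stage counts, the recovered feature
set, and the null-control behaviour (permuted labels drive every model back
to chance — enforced in the test suite).

A command-line interface mirrors the library:

```bash
pcn-radiomics simulate --out cohort/ --seed 1 --sizes 10 10 10
pcn-radiomics run-all --out results/ --seed 1 --sizes 10 10 10
```

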