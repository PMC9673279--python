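# tmjoa

Quantitative bone-imaging biomarkers and interaction-aware classification
of temporomandibular joint osteoarthritis (TMJ OA) status.

TMJ OA degrades the subchondral bone of the mandibular condyle and the
temporal-bone articular fossa before gross radiographic damage appears.
This package is for imaging and biomarker researchers who want a tested,
reproducible implementation of the full analysis path from
high-resolution CBCT volumes to a diagnostic classifier:

* **Radiomics** — 30×30×30-voxel volumes of interest are quantised into
  10 grey-level bins over [−1000, 2500] HU, and 18 texture features are
  computed: 8 grey-level co-occurrence (GLCM/Haralick) statistics with
  offsets pooled over a Chebyshev neighbourhood of radius 4, and 10
  grey-level run-length (GLRLM) statistics over the 13 unique 3D
  directions.
* **Bone morphometry** — BV/TV, Tb.Th, Tb.Sp, Tb.N and BS/BV from a
  250-HU binarisation using parallel-plate mean-intercept-length
  estimators (Tb.Th = (BV/TV)/Tb.N, Tb.Sp = (1−BV/TV)/Tb.N,
  BS/BV = 2/Tb.Th). Together with the texture block this gives the
  23-feature radiomic vector per VOI.
* **Joint space** — the five condyle-to-fossa distances (anterior,
  anterolateral, medial, superior, posterior) by deterministic ray
  casting from directional extreme points with sub-voxel interpolation.
* **Screening** — per-feature Mann-Whitney AUC (U/(n₁n₀), ties ½),
  two-sided p-values and Benjamini-Hochberg q-values; ICC(A,1)
  repeatability gating; Levene-gated t-tests.
* **Classifier** — all F(F−1)/2 pairwise products of z-scored features
  (3081 for 79 features) are screened per training fold (mains at
  AUC > 0.7, interactions at AUC > 0.65) and fed to a from-scratch
  depth-1 gradient-boosted stump ensemble under repeated stratified
  5-fold CV (100 repeats → 500 models); each subject is predicted by
  averaging the 100 models that never saw it, and features are ranked by
  normalized split gain with a >90% cumulative-share cut.

Synthetic-data generators (plate phantoms with analytic geometry,
trabecular-like random fields, and 92×79 case-control cohorts with
planted main and interaction effects) make every stage testable without
any imaging download; they are first-class, tested code.

## Worked example

```python
from tmjoa import (compute_metrics, interpret_auc, rank_contributions,
                   run_repeated_cv)
from tmjoa.synthetic import CohortSpec, make_cohort

spec = CohortSpec(
    seed=0,
    main_effects=[("clinical_01", 2.0)],                # shifted in OA class
    interaction_effects=[("fossa_radiomics_01",
                          "condylar_radiomics_01", 3.0)],  # product signal
)
cohort = make_cohort(spec)                               # 92 subjects, 79 features

result = run_repeated_cv(cohort, repeats=10, folds=5, seed=0)
m = compute_metrics(result.oof_probability, result.labels)
print(f"models trained: {result.n_models}")
print(f"out-of-fold AUC: {m['auc']:.3f} ({interpret_auc(m['auc'])})")
print(f"accuracy: {m['accuracy']:.3f}  macro-F1: {m['macro_f1']:.3f}")
print(rank_contributions(result).head(4).to_string(index=False))
```

Output:

```
models trained: 50
out-of-fold AUC: 0.906 (very good)
accuracy: 0.848  macro-F1: 0.848
                                 feature    share  cumulative_share  top_contributor
                             clinical_01 0.528365          0.528365             True
condylar_radiomics_01*fossa_radiomics_01 0.112112          0.640477             True
    condylar_radiomics_23*joint_space_01 0.016766          0.657243             True
             serum_06*fossa_radiomics_02 0.015917          0.673160             True
```

The planted clinical main effect tops the gain ranking, the planted
fossa-condyle product is recovered as the leading interaction even though
neither parent separates the groups on its own (both have marginal
AUC ≈ 0.5), and the held-out ensemble AUC of 0.906 lands in the
"very good" discriminative band. The remaining rows are chance survivors
of the per-fold AUC > 0.65 interaction gate, with correspondingly small
gain shares.

A command-line layer mirrors the stages:

```bash
tmjoa make-phantom --plate-thickness 2 --gap 3 phantom.nrrd
tmjoa extract-texture phantom.nrrd vois.csv features.csv
tmjoa joint-space condyle.nrrd fossa.nrrd distances.csv
tmjoa make-cohort --seed 1 cohort.csv categories.yaml
tmjoa screen cohort.csv categories.yaml screen.csv
tmjoa train-cv cohort.csv run --repeats 100 --seed 1
```

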