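# fcclassify

Whole-brain functional-connectivity classification with
minimum-redundancy / maximum-relevance (mRMR) edge selection.

Resting-state fMRI studies of psychiatric groups face a "wide data"
problem: a P-region parcellation yields E = P(P−1)/2 connectivity
features per subject (35,778 edges for a 268-region atlas) against a few
hundred subjects. `fcclassify` implements the standard remedy as a
tested, reusable pipeline:

1. **Edges.** Per-subject region time series → Pearson correlation →
   Fisher z = atanh(r) → fixed-order upper-triangle edge vector, with a
   head-motion quality filter (subjects with mean framewise displacement
   \> 0.2 mm are discarded).
2. **Selection.** Greedy mRMR ranking by the mutual-information quotient:
   at each step pick the edge f maximising I(f; class) / mean I(f; s)
   over already-selected edges s (plug-in MI on three-bin discretised
   features). The number of edges kept is read off the importance-score
   trajectory at its largest relative drop.
3. **Classification.** Nested stratified 10-fold cross-validation of an
   RBF-kernel SVM, k(x, y) = exp(−‖x−y‖² / 2s²): selection and the inner
   10-fold grid search over (C, s) see only the training folds; the whole
   procedure is repeated over many random partitions and edges selected
   in ≥ 9/10 folds of the best repetition are reported as consensus
   "major features" with region/network annotation.
4. **Fingerprinting.** Inter-subject cosine distances of edge vectors,
   within vs between groups, before and after selection (with
   equal-sized random and lowest-relevance control subsets).
5. **Confounds.** Pearson / t-test screens of consensus edges against
   clinical covariates and head motion with Benjamini–Hochberg FDR, plus
   a pooled two-proportion z-test for comparing classifier accuracies.

Because real cohorts of this kind are rarely shareable, the package
ships a first-class synthetic cohort generator: block-structured latent
correlation matrices (8 functional networks), a sparse set of planted
group-discriminative edges with known sign, optional two-subtype patient
heterogeneity, subject-level jitter, and realistic covariates — so every
stage can be validated against ground truth.

## Worked example

```bash
fcclassify demo --out demo_run --seed 0
```

generates a 60-region, 40 patients + 40 controls cohort (10 planted
edges at a 0.4 correlation shift, heterogeneous patient group), runs the
full pipeline (5 CV repetitions) and prints the across-repetition
metrics. The same analysis through the library:

```python
import numpy as np
import fcclassify as fc

spec = fc.demo_spec(seed=1, subtype_fraction=0.5)   # 60 regions, 40+40
records, truth = fc.generate_cohort(spec)
x, y, ids = fc.features_table(fc.filter_by_fd(records))

rep = fc.repeat_partitions(x, y, n_repetitions=5, base_seed=1,
                           svm_config=fc.SVMConfig.compact(), max_k=30)
print(rep.aggregate())
```

On this cohort the nested-CV test accuracy is 97.25 % (sensitivity
96.0 %, specificity 98.5 %, AUC 0.99) with on average ~2.5 edges kept
per fold — the planted edges are strong enough at desk scale that a
handful suffice. The matched controls make the point of the method: the
same CV machinery on an equal count of *lowest*-relevance edges drops to
53.75 % accuracy (AUC 0.56), and label-permuted null cohorts sit at
52.8 %, i.e. chance.

The similarity panel shows the selection effect on group structure. On
all 1,770 edges the heterogeneous patient group is internally *less*
similar than it is to controls (mean within-patient cosine distance
0.3483 vs between-group 0.3310, controls 0.2814); restricted to the
mRMR-selected edges the order reverses (within-patient 0.0999 vs
between-group 1.4404) — selection finds the connectivity on which
patients are homogeneous.

## Command-line interface

`fcclassify` exposes subcommands `simulate`, `fc`, `classify`,
`similarity`, `confounds`, `run` (full pipeline from one YAML config)
and `demo`. All inputs and outputs are plain text: manifest/atlas/feature
CSVs, time-series TSVs, JSON summaries. See `docs/methods.md` for the
model, parameter and design documentation.
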