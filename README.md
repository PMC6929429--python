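# glioedit

RNA-editing-based classification of adult diffuse glioma.

A-to-I RNA editing leaves a readable footprint in RNA-Seq: at a known
editing site the genome has an A but edited transcripts read G. The
fraction of G reads at site *i* in sample *j* — the editing level
`e_ij = g_ij / n_ij` — varies systematically between the three glioma
molecular subtypes (IDH wildtype, IDH mutant + 1p/19q codeleted, IDH
mutant non-codeleted), so a tumor's editing profile predicts its IDH and
codeletion status from RNA-Seq alone, without immunohistochemistry or
FISH. glioedit implements that analysis end to end for anyone working
with per-site editing counts:

* **Quantification** — site-specific and total editing levels
  (`Σ g / Σ n`), sample-specific and global variant masking,
  Kolmogorov–Smirnov subtype comparisons.
* **Site selection** — per-cell Type I/II/III classification (≥3 edited-G
  reads, ≥10 reads, exact binomial test against a 0.1% background with
  BH-FDR < 0.05), removal of sites Type III in >25% of samples, retention
  of sites Type I in ≥25% of samples with MAD_3Q > 0, where MAD_3Q =
  median |e − Q3(e)| is a robust variability statistic anchored at the
  third quartile.
* **Classification** — linear SVM, random forest and AdaBoost under
  stratified 10-fold cross-validation with in-fold feature selection;
  ACC/SEN/SPE, ROC/AUC, DeLong paired AUC comparison, repeatedly selected
  sites, continuously misclassified samples.
* **Downstream** — genic-category hypergeometric enrichment, z-scoring
  and hierarchical ordering for heatmaps, editing-level quartile groups
  (Q1 vs Q3) with Kaplan–Meier curves and log-rank tests.
* **Synthetic editome generator** — cohorts with planted discriminative
  and prognostic sites and full ground truth, so every stage is testable
  offline.

Read-level editing detection (pileups on a REDIportal-style catalog,
hyper-editing) and site annotation are upstream; glioedit starts from the
paired edited/total count matrices.

## Worked example

Generate the default synthetic cohort (300 samples, 500 sites, 40 planted
discriminative sites per task) and run selection and classification:

```python
import glioedit as g

catalog, cohort, counts, truth = g.simulate_dataset(g.SimulationConfig(seed=42))
levels    = g.compute_site_editing_levels(counts)
types     = g.classify_site_sample_types(counts)          # Type I/II/III
selection = g.select_discriminative_sites(types, levels)  # two-stage filter
features  = g.build_feature_matrix(levels, selection.retained_site_ids)

labels = g.make_task_labels(cohort, g.TaskSpec(task="idh"))
folds, summary = g.run_cv(features, labels,
                          g.CVConfig(n_folds=10, seed=0, learner="svm",
                                     feature_selection="in_fold"))
print(len(selection.retained_site_ids), round(summary.auc, 3))
```

The example scripts under `examples/` narrate each capability; running
them prints, among other things:

```
$ python examples/02_editing_levels.py
mean total editing level by subtype:
mut-codel        0.1492
mut-non-codel    0.1507
wt               0.1561
pairwise KS comparisons (D statistic, raw p):
  all     mut-codel mut-non-codel  0.21   0.0206
  all     mut-codel            wt  0.63   0.0000
  all mut-non-codel            wt  0.47   0.0000
```

IDH-wildtype tumors show the higher total editing, and the KS statistic D
(maximal ECDF gap) separates wildtype from both mutant groups.

```
$ python examples/04_classify_subtypes.py
=== task: idh (200 positive / 300 samples) ===
svm            ACC=1.000 SEN=1.000 SPE=1.000 AUC=1.000  sites/fold 118~136, 126 selected in >=5 folds
random_forest  ACC=1.000 SEN=1.000 SPE=1.000 AUC=1.000  sites/fold 34~41, 36 selected in >=5 folds
adaboost       ACC=1.000 SEN=1.000 SPE=1.000 AUC=1.000  sites/fold 18~21, 19 selected in >=5 folds
DeLong SVM vs RF: AUC 1.000 vs 1.000, p = 1
```

With a planted effect of 0.2 the synthetic task is near-separable — all
three learners reach AUC 1.0 and the paired DeLong test finds no
difference. The per-fold site counts show each learner's in-fold selection
width (AdaBoost is bounded by its 50 stumps).

```
$ python examples/05_enrichment_survival.py
survival at prognostic site chr16:280755:
  OS: log-rank p = 7.32e-08, median survival Q1(low)=3.5y vs Q3(high)=1.2y, 5 samples excluded (missing or >10y)
```

Samples in the top editing quartile (Q3) at the planted prognostic site
die markedly earlier than the bottom quartile (Q1), as planted (hazard
ratio 3 per unit editing level).

## Command line

The same stages are available as a thin CLI for file-based runs:

```sh
glioedit simulate --seed 42 --outdir data/
glioedit quantify --edited data/counts_edited.tsv --total data/counts_total.tsv \
    --annotations data/annotations.tsv --outdir out/
glioedit select-sites --edited data/counts_edited.tsv --total data/counts_total.tsv --outdir out/
glioedit classify --levels out/levels.tsv --annotations data/annotations.tsv \
    --selection out/selection.tsv --task idh --learner svm --outdir out/
glioedit run-all --config config.yaml     # whole pipeline + manifest
```

File formats and the YAML config schema are documented in
`docs/formats.md`; the scientific choices in `docs/methods.md`.

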