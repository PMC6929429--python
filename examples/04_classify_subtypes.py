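"""Cross-validated prediction of IDH mutation and 1p/19q codeletion.

Three learners (linear SVM, random forest, AdaBoost) are evaluated with
stratified 10-fold cross-validation; feature selection is refit inside each
training fold so test folds never leak into the chosen sites.  Pooled
test-fold predictions give ACC/SEN/SPE and AUC; correlated AUCs are
compared with the DeLong test, and samples misclassified by every learner
are flagged.
"""

import pandas as pd

import glioedit as g

catalog, cohort, counts, truth = g.simulate_dataset(g.SimulationConfig(seed=42))
levels = g.compute_site_editing_levels(counts)
types = g.classify_site_sample_types(counts)
selection = g.select_discriminative_sites(types, levels)
features = g.build_feature_matrix(levels, selection.retained_site_ids)

for task in ("idh", "codel"):
    spec = g.TaskSpec(task=task, cohort_restriction=(
        "idh_mutant_only" if task == "codel" else "all"))
    labels = g.make_task_labels(cohort, spec)
    X = features.loc[labels.index]
    print(f"\n=== task: {task} ({labels.sum()} positive / {len(labels)} samples) ===")
    runs, scores = [], {}
    for learner in ("svm", "random_forest", "adaboost"):
        cfg = g.CVConfig(n_folds=10, seed=0, learner=learner,
                         feature_selection="in_fold")
        folds, s = g.run_cv(X, labels, cfg)
        runs.append(folds)
        scores[learner] = pd.concat([f.scores for f in folds]).reindex(labels.index)
        n_sel = sorted(len(f.selected_site_ids) for f in folds)
        rep = g.repeated_selected_sites(folds, min_count=5)
        print(f"{learner:14s} ACC={s.acc:.3f} SEN={s.sen:.3f} SPE={s.spe:.3f} "
              f"AUC={s.auc:.3f}  sites/fold {n_sel[0]}~{n_sel[-1]}, "
              f"{len(rep)} selected in >=5 folds")
    comp = g.delong_test(scores["svm"], scores["random_forest"], labels)
    print(f"DeLong SVM vs RF: AUC {comp.auc_a:.3f} vs {comp.auc_b:.3f}, "
          f"p = {comp.p_value:.3g}")
    mis = g.identify_misclassified(runs, labels)
    print(f"continuously misclassified by all three learners: {len(mis)} sample(s)")
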