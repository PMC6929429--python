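# File formats

All tabular files are UTF-8, tab-separated, with a header row. Missing
values are encoded `NA`. Genomic coordinates are 1-based inclusive; the BED
export converts to 0-based half-open.

## Count matrices (`counts_edited.tsv`, `counts_total.tsv`)

Two matrices with identical headers: first column `site_id`, remaining
columns one per sample. Cells are non-negative integers;
`edited[i,j] <= total[i,j]` everywhere. `edited` holds edited-G read
counts, `total` holds A+G covering read counts.

## Editing-level matrix (`levels.tsv`)

Same layout; cells are fractions in [0,1] or `NA` (zero coverage).

## Site catalog (`catalog.tsv`)

Columns, in order: `site_id`, `chrom`, `pos` (1-based), `strand` (`+`/`-`),
`category`, `known_variant` (0/1). Categories must come from: UTR3, UTR5,
exonic, intronic, intergenic, upstream, downstream, ncRNA or an ncRNA split
variant (`ncRNA_exonic`, `ncRNA_intronic`, `ncRNA_UTR3`, `ncRNA_UTR5`,
`ncRNA_splicing`). Duplicate `site_id`s are rejected.

## Sample annotations (`annotations.tsv`)

Columns: `sample_id`, `subtype` (`wt` / `mut-codel` / `mut-non-codel`),
`idh_status` (`wildtype`/`mutant`), `codel_status` (`codel`/`non-codel`),
`grade` (`G2`/`G3`/`G4`), `os_time`, `os_event`, `pfi_time`, `pfi_event`.
Times are in years; events are 1 = observed, 0 = censored.

## Variant mask (`mask.tsv`)

Columns: `sample_id`, `site_id`. A row with `sample_id = *` marks a global
known-variant site (dropped for all samples); any other row blanks one
(site, sample) cell.

## Selection result (`selection.tsv` + `selection_thresholds.json`)

Columns: `site_id`, `frac_type_I`, `frac_type_III`, `mad3q`, `retained`
(0/1), one row per input site. The JSON sidecar records the thresholds
used.

## Classification artifacts

* `predictions_<task>_<learner>.tsv`: `sample_id`, `fold`, `score`,
  `predicted`, `true`.
* `roc_<task>_<learner>.tsv`: `fpr`, `tpr` points from (0,0) to (1,1).
* `repeated_sites_<task>_<learner>.txt`: one site id per line.
* `misclassified_<task>.txt`: one sample id per line.
* `summary.json`: per-task, per-learner ACC/SEN/SPE/AUC and confusion
  counts.

## Downstream artifacts

* `enrichment_<task>.tsv`: `category`, `k`, `n_sel`, `K`, `N`, `p_enrich`,
  `p_deplete`.
* `km_os.tsv`, `km_pfi.tsv`: `time`, `at_risk`, `survival`, `group`.
* `survival.json`: site, log-rank statistic/p, group sizes, exclusions.

## Pipeline config (YAML, for `glioedit run-all`)

Keys mirror `glioedit.PipelineConfig`: input paths (`edited`, `total`,
`catalog`, `annotations`, optional `mask`), `outdir`, `seed`, thresholds
(`p0`, `alpha`, `max_frac_III`, `min_frac_I`, `fdr_family`), classification
settings (`n_folds`, `learners`, `feature_selection`, `min_repeat`,
`tasks`, `codel_restriction`), and downstream settings (`survival_site`,
`survival_horizon`, `enrichment_learner`).

## Manifest (`manifest.json`)

Inputs, full config, seed, package version, and per-stage record counts.
A rerun from the same manifest reproduces every artifact byte-for-byte.

## Truth file (`truth.json`, synthetic data only)

Planted IDH/codel discriminative site ids, the prognostic site id, and the
per-site subtype mean editing levels.
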