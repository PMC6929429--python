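"""Readers and writers for the pipeline's plain-text formats.

All tabular artifacts are UTF-8, tab-separated files with a header row;
missing values are encoded "NA".  Genomic coordinates are 1-based inclusive
throughout (a BED export converts to 0-based half-open).  Column orders are
documented in docs/formats.md.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import CountTensor, GlioeditError, VariantMask
from .selection import SelectionResult
from .simulate import CATEGORIES, SyntheticTruth

NA = "NA"

#: Genic-category vocabulary accepted in catalogs: the eight editome
#: categories, with the ncRNA split variants ANNOVAR emits also accepted.
ALLOWED_CATEGORIES = frozenset(CATEGORIES) | {
    "ncRNA", "ncRNA_exonic", "ncRNA_intronic", "ncRNA_UTR3", "ncRNA_UTR5",
    "ncRNA_splicing",
}

ANNOTATION_COLUMNS = [
    "subtype", "idh_status", "codel_status", "grade",
    "os_time", "os_event", "pfi_time", "pfi_event",
]


def _read_matrix(path: str | Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    if df.index.has_duplicates:
        raise GlioeditError(f"duplicate site ids in {name} matrix {path}")
    return df


def read_counts(path_edited: str | Path, path_total: str | Path) -> CountTensor:
    """Read the paired edited/total TSV matrices into a validated tensor."""
    edited = _read_matrix(path_edited, "edited")
    total = _read_matrix(path_total, "total")
    if not edited.index.equals(total.index) or not edited.columns.equals(total.columns):
        raise GlioeditError(
            f"edited ({path_edited}) and total ({path_total}) matrices have "
            "mismatched site/sample headers")
    for name, df in (("edited", edited), ("total", total)):
        arr = df.to_numpy()
        if arr.dtype == object or np.isnan(arr.astype(float)).any():
            raise GlioeditError(f"missing or non-numeric cell in {name} matrix")
        if not np.all(np.equal(np.mod(arr.astype(float), 1), 0)):
            raise GlioeditError(f"non-integer cell in {name} matrix")
        if (arr.astype(float) < 0).any():
            raise GlioeditError(f"negative cell in {name} matrix")
    return CountTensor(edited.astype(np.int64), total.astype(np.int64))


def write_counts(
    counts: CountTensor, path_edited: str | Path, path_total: str | Path
) -> None:
    counts.edited.to_csv(path_edited, sep="\t", index_label="site_id")
    counts.total.to_csv(path_total, sep="\t", index_label="site_id")


def read_levels(path: str | Path) -> pd.DataFrame:
    """Read an editing-level matrix (values in [0,1], NA = missing)."""
    df = _read_matrix(path, "level").astype(float)
    vals = df.to_numpy()
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise GlioeditError(f"editing levels outside [0,1] in {path}")
    return df


def write_levels(levels: pd.DataFrame, path: str | Path) -> None:
    levels.to_csv(path, sep="\t", index_label="site_id", na_rep=NA)


def read_catalog(path: str | Path) -> pd.DataFrame:
    """Read a site catalog TSV (site_id, chrom, pos, strand, category, known_variant).

    Positions are 1-based; categories must come from the editome vocabulary
    (ncRNA split variants accepted); duplicate site ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["site_id", "chrom", "pos", "strand", "category", "known_variant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GlioeditError(f"catalog {path} lacks columns {missing}")
    if df["site_id"].duplicated().any():
        dup = df.loc[df["site_id"].duplicated(), "site_id"].iloc[0]
        raise GlioeditError(f"duplicate site_id {dup!r} in catalog")
    if (df["pos"] < 1).any():
        raise GlioeditError("catalog positions must be 1-based (>= 1)")
    bad = sorted(set(df["category"]) - ALLOWED_CATEGORIES)
    if bad:
        raise GlioeditError(
            f"unknown genic categories {bad}; allowed: {sorted(ALLOWED_CATEGORIES)}")
    if not df["strand"].isin(["+", "-"]).all():
        raise GlioeditError("strand must be '+' or '-'")
    df["known_variant"] = df["known_variant"].astype(int).astype(bool)
    df["pos"] = df["pos"].astype(np.int64)
    return df.set_index("site_id")


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    out = catalog.copy()
    out["known_variant"] = out["known_variant"].astype(int)
    out.to_csv(path, sep="\t", index_label="site_id")


def catalog_to_bed(catalog: pd.DataFrame, path: str | Path) -> None:
    """Export the catalog as BED (0-based, half-open intervals of length 1)."""
    bed = pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["pos"] - 1,
            "end": catalog["pos"],
            "name": catalog.index,
            "score": 0,
            "strand": catalog["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-sample annotations (subtype, statuses, grade, survival)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise GlioeditError(f"annotations {path} lack a sample_id column")
    if df["sample_id"].duplicated().any():
        raise GlioeditError("duplicate sample_id in annotations")
    df = df.set_index("sample_id")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise GlioeditError(f"annotations lack columns {missing}")
    for col in ("os_time", "pfi_time", "os_event", "pfi_event"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_annotations(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA)


def read_mask(path: str | Path) -> VariantMask:
    """Read a variant mask TSV (sample_id, site_id); sample_id '*' = global."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "site_id"):
        if col not in df.columns:
            raise GlioeditError(f"mask {path} lacks column {col}")
    per_sample: dict[str, set[str]] = {}
    global_sites: set[str] = set()
    for sample, site in zip(df["sample_id"], df["site_id"]):
        if sample == "*":
            global_sites.add(site)
        else:
            per_sample.setdefault(sample, set()).add(site)
    return VariantMask(per_sample=per_sample, global_sites=global_sites)


def write_mask(mask: VariantMask, path: str | Path) -> None:
    rows = [("*", s) for s in sorted(mask.global_sites)]
    for sample in sorted(mask.per_sample):
        rows.extend((sample, s) for s in sorted(mask.per_sample[sample]))
    pd.DataFrame(rows, columns=["sample_id", "site_id"]).to_csv(
        path, sep="\t", index=False)


def write_selection(result: SelectionResult, path_tsv: str | Path,
                    path_json: str | Path | None = None) -> None:
    """Write selection diagnostics TSV plus a JSON sidecar of thresholds."""
    out = result.diagnostics.copy()
    out["retained"] = out["retained"].astype(int)
    out.to_csv(path_tsv, sep="\t", index_label="site_id", na_rep=NA)
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps(result.thresholds, indent=2, sort_keys=True) + "\n")


def read_selection(path_tsv: str | Path) -> pd.DataFrame:
    return pd.read_csv(path_tsv, sep="\t", index_col=0,
                       na_values=[NA], keep_default_na=False)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    d = json.loads(Path(path).read_text())
    means = pd.DataFrame.from_dict(d["per_site_subtype_means"], orient="index")
    return SyntheticTruth(
        discriminative_site_ids_idh=d["discriminative_site_ids_idh"],
        discriminative_site_ids_codel=d["discriminative_site_ids_codel"],
        prognostic_site_id=d["prognostic_site_id"],
        per_site_subtype_means=means,
    )
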