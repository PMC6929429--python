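"""Editing-level quantification from per-site read counts.

A-to-I editing converts adenosine to inosine, which sequencers read as
guanosine.  The unit of measurement is therefore a pair of read counts per
(site, sample): the number of reads carrying the edited G and the total
number of A+G reads covering the site.  The site-specific editing level is
the ratio of the two; the *total* editing level of a sample pools the counts
over a set of sites before dividing, i.e. it is the coverage-weighted mean
of the site levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats


class GlioeditError(Exception):
    """Base class for domain errors raised by this package."""


@dataclass
class CountTensor:
    """Paired site x sample matrices of edited-G and total A+G read counts.

    Both matrices are pandas DataFrames indexed by site id with sample ids
    as columns.  Counts are non-negative integers and ``edited <= total``
    cell-wise; violations raise at construction.
    """

    edited: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.edited.index.equals(self.total.index):
            raise GlioeditError("edited/total site ids differ")
        if not self.edited.columns.equals(self.total.columns):
            raise GlioeditError("edited/total sample ids differ")
        if self.edited.index.has_duplicates or self.edited.columns.has_duplicates:
            raise GlioeditError("duplicate site or sample ids in count tensor")
        for name, mat in (("edited", self.edited), ("total", self.total)):
            arr = mat.to_numpy()
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.equal(np.mod(arr, 1), 0)):
                    raise GlioeditError(f"{name} counts must be integers")
                mat = mat.astype(np.int64)
                object.__setattr__(self, name, mat)
            if (mat.to_numpy() < 0).any():
                raise GlioeditError(f"negative {name} counts")
        bad = self.edited.to_numpy() > self.total.to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GlioeditError(
                "edited > total at site "
                f"{self.edited.index[i]!r}, sample {self.edited.columns[j]!r}"
            )

    @property
    def site_ids(self) -> pd.Index:
        return self.edited.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.edited.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.edited.shape

    def subset_sites(self, site_ids: Iterable[str]) -> "CountTensor":
        ids = pd.Index(site_ids)
        missing = ids.difference(self.site_ids)
        if len(missing):
            raise GlioeditError(f"unknown site ids: {list(missing)[:5]}")
        return CountTensor(self.edited.loc[ids], self.total.loc[ids])


@dataclass
class VariantMask:
    """Sites to exclude because they overlap DNA variants.

    ``per_sample`` maps a sample id to the site ids flagged by that sample's
    somatic/germline calls (cells are blanked for that sample only);
    ``global_sites`` are known-variant sites dropped for every sample.
    """

    per_sample: dict[str, set[str]] = field(default_factory=dict)
    global_sites: set[str] = field(default_factory=set)


def compute_site_editing_levels(counts: CountTensor) -> pd.DataFrame:
    """Site-specific editing level: edited / total, NaN where total == 0.

    Returns a float DataFrame aligned with the tensor; values lie in [0, 1]
    wherever the site is covered.
    """
    total = counts.total.to_numpy(dtype=float)
    edited = counts.edited.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(total > 0, edited / np.where(total > 0, total, 1.0), np.nan)
    return pd.DataFrame(level, index=counts.site_ids, columns=counts.sample_ids)


def compute_total_editing_level(
    counts: CountTensor,
    site_subset: Iterable[str] | None = None,
    per_sample: bool = True,
) -> pd.Series | float:
    """Total editing level: sum(edited G) / sum(A+G reads) over a site set.

    With ``per_sample=True`` (default) returns a Series over samples, NaN for
    samples with zero summed coverage; otherwise a single cohort-wide scalar.
    """
    if site_subset is None:
        sub = counts
    else:
        ids = pd.Index(site_subset)
        if len(ids) == 0:
            raise GlioeditError("empty site subset for total editing level")
        sub = counts.subset_sites(ids)
    ed = sub.edited.sum(axis=0).astype(float)
    tot = sub.total.sum(axis=0).astype(float)
    if per_sample:
        out = ed.where(tot > 0) / tot.where(tot > 0)
        out.name = "total_editing_level"
        return out
    t = float(tot.sum())
    return float(ed.sum()) / t if t > 0 else float("nan")


def apply_variant_masks(
    counts: CountTensor,
    mask: VariantMask,
    mode: Literal["sample_specific", "global"],
) -> CountTensor:
    """Exclude variant-overlapping editing sites from the count tensor.

    ``sample_specific`` zeroes (site, sample) cells flagged in the per-sample
    mask, turning their level into missing; ``global`` drops every site in
    ``global_sites`` for all samples, preserving the order of the rest.
    """
    known = set(counts.site_ids)
    if mode == "sample_specific":
        edited = counts.edited.copy()
        total = counts.total.copy()
        for sample, sites in mask.per_sample.items():
            if sample not in counts.sample_ids:
                continue
            bad = sites - known
            if bad:
                raise GlioeditError(f"mask references unknown sites: {sorted(bad)[:5]}")
            idx = counts.site_ids.intersection(sorted(sites))
            edited.loc[idx, sample] = 0
            total.loc[idx, sample] = 0
        return CountTensor(edited, total)
    if mode == "global":
        bad = mask.global_sites - known
        if bad:
            raise GlioeditError(f"mask references unknown sites: {sorted(bad)[:5]}")
        keep = [s for s in counts.site_ids if s not in mask.global_sites]
        return CountTensor(counts.edited.loc[keep], counts.total.loc[keep])
    raise GlioeditError(f"unknown mask mode {mode!r}")


def compare_groups_ks(
    values: pd.Series, groups: pd.Series
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of per-sample scalars.

    ``groups`` must take exactly two levels on the non-missing samples.
    Returns (D, asymptotic p).  Used to compare total editing level between
    glioma subtypes, where the distributions differ in location and shape.
    """
    values, groups = values.align(groups, join="inner")
    keep = values.notna() & groups.notna()
    values, groups = values[keep], groups[keep]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise GlioeditError(f"expected two groups, got {list(levels)}")
    a = values[groups == levels[0]].to_numpy()
    b = values[groups == levels[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise GlioeditError("need >=2 non-missing values per group for KS test")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pairwise_subtype_ks(
    total_levels: pd.Series,
    cohort: pd.DataFrame,
    by_grade: bool = False,
) -> pd.DataFrame:
    """All pairwise KS comparisons of total editing between subtypes.

    With ``by_grade=True`` the comparisons are repeated within each tumor
    grade.  P-values are reported raw (no multiplicity adjustment).
    """
    rows = []
    subtypes = sorted(cohort["subtype"].dropna().unique())

    def _compare(sub_cohort: pd.DataFrame, grade: str | None) -> None:
        for i, s1 in enumerate(subtypes):
            for s2 in subtypes[i + 1 :]:
                samples = sub_cohort.index[sub_cohort["subtype"].isin([s1, s2])]
                vals = total_levels.reindex(samples)
                grp = sub_cohort.loc[samples, "subtype"]
                try:
                    d, p = compare_groups_ks(vals, grp)
                except GlioeditError:
                    continue
                rows.append(
                    {"grade": grade or "all", "group_a": s1, "group_b": s2,
                     "ks_D": d, "p_value": p}
                )

    if by_grade:
        for grade in sorted(cohort["grade"].dropna().unique()):
            _compare(cohort[cohort["grade"] == grade], str(grade))
    else:
        _compare(cohort, None)
    if not rows:
        warnings.warn("no subtype pair had enough samples for a KS test")
    return pd.DataFrame(rows, columns=["grade", "group_a", "group_b", "ks_D", "p_value"])
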