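"""Discriminative editing-site selection.

Each (site, sample) cell is classified by coverage and editing evidence:

* **Type I** — >=3 edited-G reads, >=10 A+G reads, and an editing frequency
  significantly above the 0.1% sequencing-error background (one-sided exact
  binomial test, BH-FDR < 0.05): confidently edited.
* **Type II** — >=10 reads but fewer than 3 edited-G reads or a
  non-significant test: covered but not confidently edited.
* **Type III** — under 10 reads: too shallow to call.

Sites are then filtered in two stages: drop sites that are Type III in more
than 25% of samples (unreliable coverage), then keep sites that are Type I
in at least 25% of samples and have MAD_3Q > 0.  MAD_3Q — the median of
absolute deviations of a site's editing levels from their third quartile —
is a robust variability statistic; anchoring at Q3 rather than the median
retains sites edited in only a minority of samples, which an ordinary MAD
would score as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import CountTensor, GlioeditError

TYPE_I, TYPE_II, TYPE_III = 1, 2, 3

#: Coverage below which a cell is Type III regardless of edited reads.
MIN_COVERAGE = 10
#: Minimum edited-G reads for a Type I call.
MIN_EDITED = 3
#: Background editing frequency tested against (sequencing-error scale).
BACKGROUND_RATE = 1e-3


def binomial_tail_p(k: int, n: int, p0: float = BACKGROUND_RATE) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= k | n, p0)."""
    if not 0 < p0 < 1:
        raise GlioeditError("p0 must lie strictly in (0,1)")
    if k < 0 or n < 0 or k > n:
        raise GlioeditError(f"invalid counts k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone in rank, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise GlioeditError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SiteTypeMatrix:
    """Per-cell Type I/II/III calls with the underlying test values.

    ``types`` holds integer codes (1, 2, 3); ``pvalue``/``qvalue`` are NaN
    for cells where no binomial test was computed (total < 10).
    """

    types: pd.DataFrame
    pvalue: pd.DataFrame
    qvalue: pd.DataFrame

    @property
    def site_ids(self) -> pd.Index:
        return self.types.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.types.columns


def classify_site_sample_types(
    counts: CountTensor,
    p0: float = BACKGROUND_RATE,
    alpha: float = 0.05,
    fdr_family: Literal["all_cells", "per_site", "per_sample"] = "all_cells",
) -> SiteTypeMatrix:
    """Assign every (site, sample) cell exactly one of Types I/II/III.

    Binomial upper-tail p-values are computed for all cells with total >=
    10 reads; the BH adjustment is applied over the family given by
    ``fdr_family`` (default: one family over all tested cells, i.e. one FDR
    threshold for the whole screen).
    """
    edited = counts.edited.to_numpy()
    total = counts.total.to_numpy()
    covered = total >= MIN_COVERAGE

    pmat = np.full(total.shape, np.nan)
    k = edited[covered]
    n = total[covered]
    # sf(k-1) == P(X >= k); exact for k == 0 too (sf(-1) == 1).
    pmat[covered] = stats.binom.sf(k - 1, n, p0)

    qmat = np.full(total.shape, np.nan)
    if fdr_family == "all_cells":
        qmat[covered] = bh_fdr(pmat[covered])
    elif fdr_family == "per_site":
        for i in range(total.shape[0]):
            row = covered[i]
            if row.any():
                qmat[i, row] = bh_fdr(pmat[i, row])
    elif fdr_family == "per_sample":
        for j in range(total.shape[1]):
            col = covered[:, j]
            if col.any():
                qmat[col, j] = bh_fdr(pmat[col, j])
    else:
        raise GlioeditError(f"unknown fdr_family {fdr_family!r}")

    types = np.full(total.shape, TYPE_III, dtype=np.int8)
    significant = covered & (qmat < alpha)
    type_i = covered & (edited >= MIN_EDITED) & significant
    types[covered] = TYPE_II
    types[type_i] = TYPE_I

    idx, cols = counts.site_ids, counts.sample_ids
    return SiteTypeMatrix(
        types=pd.DataFrame(types, index=idx, columns=cols),
        pvalue=pd.DataFrame(pmat, index=idx, columns=cols),
        qvalue=pd.DataFrame(qmat, index=idx, columns=cols),
    )


def mad_3q(values: np.ndarray | pd.Series, quantile_method: str = "linear") -> float:
    """Median absolute deviation from the third quartile.

    Q3 uses linear interpolation between order statistics by default (the
    position ``(n-1) * 0.75`` convention); other numpy quantile methods can
    be selected.  NaNs are dropped; an all-NaN input raises.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise GlioeditError("mad_3q needs at least one non-missing value")
    q3 = np.quantile(x, 0.75, method=quantile_method)
    return float(np.median(np.abs(x - q3)))


@dataclass
class SelectionResult:
    """Outcome of the two-stage discriminative-site filter.

    ``diagnostics`` has one row per input site: fraction of Type III and
    Type I calls, MAD_3Q (NaN when no cell had enough coverage to compute
    a level), and the retained flag.  ``retained_site_ids`` preserves the
    input site order.
    """

    retained_site_ids: list[str]
    diagnostics: pd.DataFrame
    thresholds: dict = field(default_factory=dict)


def select_discriminative_sites(
    types: SiteTypeMatrix,
    levels: pd.DataFrame,
    max_frac_III: float = 0.25,
    min_frac_I: float = 0.25,
    quantile_method: str = "linear",
) -> SelectionResult:
    """Two-stage site filter on the Type matrix and level matrix.

    Stage 1 removes sites Type III in strictly more than ``max_frac_III``
    of samples.  Stage 2 keeps sites Type I in at least ``min_frac_I`` of
    samples with MAD_3Q > 0, where MAD_3Q is computed on the site's
    non-missing editing levels from samples with >= 10 reads (Types I/II);
    levels from under-covered cells are unreliable ratios and are excluded.
    """
    if not types.types.index.equals(levels.index) or not types.types.columns.equals(
        levels.columns
    ):
        raise GlioeditError("type matrix and level matrix are not aligned")
    t = types.types.to_numpy()
    n_samples = t.shape[1]
    frac_iii = (t == TYPE_III).sum(axis=1) / n_samples
    frac_i = (t == TYPE_I).sum(axis=1) / n_samples

    lv = levels.to_numpy(dtype=float).copy()
    lv[t == TYPE_III] = np.nan
    mad = np.full(t.shape[0], np.nan)
    for i in range(t.shape[0]):
        row = lv[i]
        row = row[~np.isnan(row)]
        if row.size:
            mad[i] = mad_3q(row, quantile_method=quantile_method)

    pass1 = frac_iii <= max_frac_III
    retained = pass1 & (frac_i >= min_frac_I) & (mad > 0)
    diagnostics = pd.DataFrame(
        {
            "frac_type_I": frac_i,
            "frac_type_III": frac_iii,
            "mad3q": mad,
            "retained": retained,
        },
        index=types.site_ids,
    )
    ids = list(types.site_ids[retained])
    if not ids:
        warnings.warn("no site survived the discriminative-site filters")
    return SelectionResult(
        retained_site_ids=ids,
        diagnostics=diagnostics,
        thresholds={
            "max_frac_III": max_frac_III,
            "min_frac_I": min_frac_I,
            "quantile_method": quantile_method,
        },
    )
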