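"""Post-classification analyses.

Z-scored editing matrices and hierarchical leaf orderings for heatmap-style
displays, exact hypergeometric enrichment/depletion of selected sites across
genic categories against a background site set, quartile grouping of samples
by editing level at a single site, and Kaplan-Meier / log-rank comparison of
those groups' survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .quant import GlioeditError


def zscore_by_site(
    levels: pd.DataFrame,
    sites: Sequence[str] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Standardize each site's editing levels to mean 0, sd 1.

    Statistics are computed over non-missing entries; ``ddof=0`` (population
    sd) by default.  A site with zero variance cannot be standardized and
    raises, naming the site.
    """
    mat = levels if sites is None else levels.loc[pd.Index(sites)]
    mu = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=ddof)
    # levels are O(1); sd below 1e-12 is numerically a constant column
    zero = sd[(sd < 1e-12) | sd.isna()]
    if len(zero):
        raise GlioeditError(f"zero-variance site(s): {list(zero.index)[:5]}")
    return mat.sub(mu, axis=0).div(sd, axis=0)


def hierarchical_order(
    matrix: pd.DataFrame,
    axis: Literal["rows", "columns"] = "rows",
    method: Literal["average", "complete", "ward"] = "average",
    metric: Literal["euclidean", "correlation"] = "euclidean",
) -> list:
    """Deterministic leaf ordering from agglomerative clustering.

    Ties between equal merge distances resolve by observation index (the
    scipy convention), so the ordering is reproducible.  Missing values must
    be imputed beforehand.
    """
    mat = matrix.T if axis == "columns" else matrix
    if mat.shape[0] < 2:
        raise GlioeditError("need at least two items to order")
    data = mat.to_numpy(dtype=float)
    if np.isnan(data).any():
        raise GlioeditError("matrix contains missing values; impute before clustering")
    dist = pdist(data, metric=metric)
    order = leaves_list(linkage(dist, method=method))
    return list(mat.index[order])


@dataclass
class EnrichmentResult:
    """Exact hypergeometric enrichment/depletion of one genic category."""

    category: str
    k: int        # selected sites in category
    n_sel: int    # selected sites total
    K: int        # background sites in category
    N: int        # background sites total
    p_enrich: float
    p_deplete: float


def hypergeometric_enrichment(
    selected: Sequence[str],
    background: Sequence[str],
    catalog: pd.DataFrame,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Category-wise exact hypergeometric tests of a selected site set.

    For each category with K background sites, the count k of selected sites
    in that category is referred to Hypergeometric(N, K, n_sel):
    ``p_enrich`` = P(X >= k) (upper tail), ``p_deplete`` = P(X <= k) (lower
    tail).  ``selected`` must be a subset of ``background``.
    """
    sel = pd.Index(selected)
    bg = pd.Index(background)
    if len(sel.difference(bg)):
        raise GlioeditError("selected sites must be a subset of the background")
    missing = bg.difference(catalog.index)
    if len(missing):
        raise GlioeditError(f"background sites absent from catalog: {list(missing)[:5]}")
    cat_bg = catalog.loc[bg, "category"]
    cat_sel = catalog.loc[sel, "category"]
    if categories is None:
        categories = list(cat_bg.value_counts().index)
    N, n_sel = len(bg), len(sel)
    rows = []
    for cat in categories:
        K = int((cat_bg == cat).sum())
        k = int((cat_sel == cat).sum())
        rows.append(
            {
                "category": cat,
                "k": k,
                "n_sel": n_sel,
                "K": K,
                "N": N,
                "p_enrich": float(stats.hypergeom.sf(k - 1, N, K, n_sel)),
                "p_deplete": float(stats.hypergeom.cdf(k, N, K, n_sel)),
            }
        )
    return pd.DataFrame(rows)


def quartile_groups(
    levels: pd.DataFrame,
    site: str,
    samples: Sequence[str] | None = None,
) -> pd.Series:
    """Assign samples to editing-level quartile groups at one site.

    The bottom 25% of samples by level form group "Q1", the top 25% form
    "Q3"; the middle half is left unassigned (NaN).  Group size is
    ``floor(n/4)``.  Ties are broken by stable sample order, so with heavily
    tied levels membership follows input order (documented policy).
    """
    if site not in levels.index:
        raise GlioeditError(f"site {site!r} absent from level matrix")
    lv = levels.loc[site]
    if samples is not None:
        lv = lv.reindex(pd.Index(samples))
    lv = lv.dropna()
    n = len(lv)
    if n < 4:
        raise GlioeditError("need >= 4 samples with non-missing level")
    k = n // 4
    order = lv.reset_index(drop=True).sort_values(kind="stable").index
    sorted_ids = lv.index[order]
    groups = pd.Series(np.nan, index=lv.index, dtype=object, name="group")
    groups[sorted_ids[:k]] = "Q1"
    groups[sorted_ids[-k:]] = "Q3"
    return groups


@dataclass
class SurvivalComparison:
    """Two-group Kaplan-Meier curves with a log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # per group: time, at_risk, survival
    statistic: float
    p_value: float
    n_excluded: int
    group_sizes: dict[str, int] = field(default_factory=dict)


def km_logrank(
    times: pd.Series,
    events: pd.Series,
    groups: pd.Series,
    horizon: float | None = None,
    horizon_policy: Literal["drop", "censor"] = "drop",
) -> SurvivalComparison:
    """Kaplan-Meier curves and two-group log-rank test.

    Samples with missing time, event or group are excluded; with a
    ``horizon``, samples observed beyond it are dropped entirely by default
    (``horizon_policy="censor"`` instead censors them at the horizon).  A
    group with zero events still yields a statistic, with a warning.
    """
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    # samples without a group assignment are not part of the comparison and
    # do not count as exclusions (e.g. the middle 50% between Q1 and Q3)
    df = df[df["group"].notna()]
    n_input = len(df)
    df = df.dropna()
    if horizon is not None:
        beyond = df["time"] > horizon
        if horizon_policy == "drop":
            df = df[~beyond]
        elif horizon_policy == "censor":
            df.loc[beyond, "event"] = 0
            df.loc[beyond, "time"] = horizon
        else:
            raise GlioeditError(f"unknown horizon policy {horizon_policy!r}")
    n_excluded = n_input - len(df)
    if (df["time"] < 0).any():
        raise GlioeditError("negative survival times")
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise GlioeditError(f"log-rank comparison needs exactly two groups, got {labels}")
    curves: dict[str, pd.DataFrame] = {}
    sizes: dict[str, int] = {}
    for g in labels:
        sub = df[df["group"] == g]
        if sub.empty:
            raise GlioeditError(f"group {g!r} is empty")
        if sub["event"].sum() == 0:
            warnings.warn(f"group {g!r} has zero events")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        table = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": table.index.to_numpy(float),
                "at_risk": table["at_risk"].to_numpy(int),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(float),
            }
        )
        sizes[g] = len(sub)
    a, b = labels
    res = logrank_test(
        df.loc[df["group"] == a, "time"], df.loc[df["group"] == b, "time"],
        event_observed_A=df.loc[df["group"] == a, "event"],
        event_observed_B=df.loc[df["group"] == b, "event"],
    )
    return SurvivalComparison(
        curves=curves,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n_excluded=n_excluded,
        group_sizes=sizes,
    )
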