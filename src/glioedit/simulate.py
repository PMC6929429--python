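"""Synthetic glioma editome generator.

Emulates the statistical structure the analysis pipeline assumes: a cohort of
three glioma subtypes (IDH wildtype, IDH mutant with 1p/19q codeletion, IDH
mutant without codeletion), a catalog of A-to-I editing sites spread over
eight genic categories, overdispersed read coverage with a controlled
fraction of under-covered site-sample pairs, beta-binomially overdispersed
edited-read counts, subtype-shifted editing levels at planted discriminative
sites, and proportional-hazards survival driven by one planted prognostic
site.  Ground truth (which sites were planted, and the subtype means) is
returned alongside the data so recovery can be tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import CountTensor, GlioeditError

#: Genic categories of editing sites, ordered by their typical editome share
#: (3'UTR-dominated, as Alu elements concentrate in untranslated regions).
CATEGORIES: tuple[str, ...] = (
    "UTR3", "intergenic", "intronic", "downstream",
    "ncRNA_intronic", "exonic", "upstream", "UTR5",
)

SUBTYPES: tuple[str, ...] = ("wt", "mut-codel", "mut-non-codel")

# Grade composition per subtype: grade IV (glioblastoma) is concentrated in
# IDH-wildtype tumors, codeleted tumors are essentially never grade IV.
GRADE_DIST: dict[str, dict[str, float]] = {
    "wt": {"G2": 20 / 219, "G3": 72 / 219, "G4": 127 / 219},
    "mut-codel": {"G2": 91 / 163, "G3": 72 / 163, "G4": 0.0},
    "mut-non-codel": {"G2": 127 / 247, "G3": 112 / 247, "G4": 8 / 247},
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic editome.

    Defaults describe a desk-scale cohort: 300 samples (100 per subtype),
    500 sites of which 40 discriminate IDH status and 40 discriminate
    codeletion with an additive editing-level shift of 0.2, negative-binomial
    coverage with mean 50, and 10% of site-sample pairs forced under 10
    reads so the coverage filter is exercised.
    """

    n_sites: int = 500
    n_samples_per_subtype: tuple[int, int, int] = (100, 100, 100)
    category_proportions: tuple[float, ...] = (
        0.40, 0.20, 0.15, 0.08, 0.07, 0.05, 0.03, 0.02)
    known_variant_fraction: float = 0.05
    coverage_mean: float = 50.0
    coverage_dispersion: float = 5.0
    low_coverage_fraction: float = 0.10
    baseline_editing_shape_a: float = 1.5
    baseline_editing_shape_b: float = 8.0
    n_discriminative_idh: int = 40
    n_discriminative_codel: int = 40
    effect_size_idh: float = 0.2
    effect_size_codel: float = 0.2
    within_site_overdispersion: float = 0.02
    prognostic_site_hazard_ratio: float = 3.0
    baseline_hazard: float = 0.17
    pfi_hazard_scale: float = 1.4
    censor_low: float = 2.0
    censor_high: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise GlioeditError("n_sites must be positive")
        if len(self.n_samples_per_subtype) != 3 or any(
            n < 0 for n in self.n_samples_per_subtype
        ):
            raise GlioeditError("n_samples_per_subtype must be three non-negative ints")
        if sum(self.n_samples_per_subtype) == 0:
            raise GlioeditError("at least one subtype must have samples")
        props = np.asarray(self.category_proportions, dtype=float)
        if len(props) != len(CATEGORIES) or (props < 0).any() or abs(props.sum() - 1.0) > 1e-9:
            raise GlioeditError(
                "category_proportions must be a probability vector over the "
                f"{len(CATEGORIES)} genic categories"
            )
        if not 0 <= self.known_variant_fraction <= 1:
            raise GlioeditError("known_variant_fraction must lie in [0,1]")
        if not 0 <= self.low_coverage_fraction <= 1:
            raise GlioeditError("low_coverage_fraction must lie in [0,1]")
        for name in ("coverage_mean", "coverage_dispersion",
                     "baseline_editing_shape_a", "baseline_editing_shape_b",
                     "within_site_overdispersion", "prognostic_site_hazard_ratio"):
            if getattr(self, name) <= 0:
                raise GlioeditError(f"{name} must be positive")
        if max(self.n_discriminative_idh, self.n_discriminative_codel) > self.n_sites:
            raise GlioeditError("more discriminative sites than sites")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated editome, for recovery tests."""

    discriminative_site_ids_idh: list[str]
    discriminative_site_ids_codel: list[str]
    prognostic_site_id: str
    per_site_subtype_means: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "discriminative_site_ids_idh": list(self.discriminative_site_ids_idh),
            "discriminative_site_ids_codel": list(self.discriminative_site_ids_codel),
            "prognostic_site_id": self.prognostic_site_id,
            "per_site_subtype_means": {
                site: {c: float(v) for c, v in row.items()}
                for site, row in self.per_site_subtype_means.iterrows()
            },
        }


def generate_site_catalog(config: SimulationConfig) -> pd.DataFrame:
    """Generate a site catalog: coordinates, strand, genic category, variant flag.

    Sites are distributed over chromosomes 1..22 with strictly increasing
    1-based positions within each chromosome.  ``known_variant_fraction`` of
    sites (in expectation) are flagged as overlapping a known DNA variant.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_sites
    chroms = np.sort(rng.integers(1, 23, size=n))
    pos = np.empty(n, dtype=np.int64)
    for c in np.unique(chroms):
        idx = np.where(chroms == c)[0]
        gaps = rng.integers(1, 50_000, size=len(idx))
        pos[idx] = 10_000 + np.cumsum(gaps)
    strand = rng.choice(["+", "-"], size=n)
    category = rng.choice(
        CATEGORIES, size=n, p=np.asarray(config.category_proportions, float))
    known_variant = rng.random(n) < config.known_variant_fraction
    chrom_names = [f"chr{c}" for c in chroms]
    site_ids = [f"{ch}:{p}" for ch, p in zip(chrom_names, pos)]
    catalog = pd.DataFrame(
        {
            "chrom": chrom_names,
            "pos": pos,
            "strand": strand,
            "category": category,
            "known_variant": known_variant,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    return catalog


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate per-sample annotations: subtype, IDH/codel status and grade.

    Codeletion only occurs together with IDH mutation; grades are drawn from
    a subtype-specific distribution in which grade IV is concentrated in the
    IDH-wildtype group.
    """
    rng = np.random.default_rng([config.seed, 2])
    rows = []
    counter = 0
    for subtype, n in zip(SUBTYPES, config.n_samples_per_subtype):
        gdist = GRADE_DIST[subtype]
        grades = rng.choice(list(gdist), size=n, p=list(gdist.values()))
        for g in grades:
            counter += 1
            rows.append(
                {
                    "sample_id": f"S{counter:04d}",
                    "subtype": subtype,
                    "idh_status": "wildtype" if subtype == "wt" else "mutant",
                    "codel_status": "codel" if subtype == "mut-codel" else "non-codel",
                    "grade": g,
                    "os_time": np.nan,
                    "os_event": np.nan,
                    "pfi_time": np.nan,
                    "pfi_event": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _clip_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def simulate_counts(
    catalog: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[CountTensor, SyntheticTruth]:
    """Draw the paired edited/total count matrices plus ground truth.

    Coverage is negative-binomial (mean ``coverage_mean``, size
    ``coverage_dispersion``); a ``low_coverage_fraction`` of cells is forced
    to a uniform total on {0..9}.  Edited counts are beta-binomial: each
    cell's editing rate is beta-distributed around its site's subtype mean
    with concentration ``1/within_site_overdispersion``.  Discriminative
    sites get an additive mean shift (random sign per site) between the
    relevant groups, clipped to [0, 1].  The prognostic site is given a
    broad, bimodal level distribution so quartile groups separate cleanly.
    """
    if catalog.empty or cohort.empty:
        raise GlioeditError("catalog and cohort must be non-empty")
    rng = np.random.default_rng([config.seed, 3])
    site_ids = catalog.index
    sample_ids = cohort.index
    n_sites, n_samples = len(site_ids), len(sample_ids)

    # Baseline per-site editing rate.
    mu = rng.beta(config.baseline_editing_shape_a, config.baseline_editing_shape_b,
                  size=n_sites)

    # Plant discriminative sites among non-variant-flagged sites.
    eligible = np.where(~catalog["known_variant"].to_numpy())[0]
    n_needed = config.n_discriminative_idh + config.n_discriminative_codel + 1
    if len(eligible) < n_needed:
        raise GlioeditError("not enough non-variant sites to plant effects")
    picked = rng.choice(eligible, size=n_needed, replace=False)
    idh_idx = picked[: config.n_discriminative_idh]
    codel_idx = picked[config.n_discriminative_idh:
                       config.n_discriminative_idh + config.n_discriminative_codel]
    prog_idx = int(picked[-1])

    # Subtype-specific means, additive shift with random sign per site.
    means = pd.DataFrame(
        np.tile(mu[:, None], (1, 3)), index=site_ids, columns=list(SUBTYPES))
    # Shifts are mostly downward in the affected group: IDH-mutant tumors
    # have lower total editing than wildtype, so planted sites lose editing
    # in mutants more often than they gain it.
    sign_idh = rng.choice([-1.0, 1.0], size=len(idh_idx), p=[0.8, 0.2])
    sign_codel = rng.choice([-1.0, 1.0], size=len(codel_idx), p=[0.8, 0.2])
    m = means.to_numpy()
    m[idh_idx, 1] = m[idh_idx, 1] + sign_idh * config.effect_size_idh
    m[idh_idx, 2] = m[idh_idx, 2] + sign_idh * config.effect_size_idh
    m[codel_idx, 1] = m[codel_idx, 1] + sign_codel * config.effect_size_codel
    m = _clip_unit(m)
    degenerate = (
        (np.ptp(m[idh_idx], axis=1) == 0)
        if len(idh_idx) and config.effect_size_idh != 0
        else np.array([], bool)
    )
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} planted IDH site(s) have constant means "
            "after clipping to [0,1]")
    means.iloc[:, :] = m

    subtype_col = cohort["subtype"].map({s: i for i, s in enumerate(SUBTYPES)})
    cell_mean = m[:, subtype_col.to_numpy()]  # sites x samples

    # Prognostic site: broad bimodal level distribution, same for every
    # subtype, so its quartile groups span most of [0,1].
    prog_rates = rng.beta(0.45, 0.45, size=n_samples)
    # Coverage.
    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    total = rng.negative_binomial(config.coverage_dispersion, p_nb,
                                  size=(n_sites, n_samples))
    n_low = int(round(config.low_coverage_fraction * n_sites * n_samples))
    if n_low:
        flat = rng.choice(n_sites * n_samples, size=n_low, replace=False)
        total.ravel()[flat] = rng.integers(0, 10, size=n_low)

    # Beta-binomial edited counts.
    kappa = 1.0 / config.within_site_overdispersion
    p = cell_mean.copy()
    p[prog_idx, :] = prog_rates
    interior = (p > 0) & (p < 1)
    a = np.where(interior, p * kappa, 1.0)
    b = np.where(interior, (1.0 - p) * kappa, 1.0)
    drawn = rng.beta(a, b)
    rates = np.where(interior, drawn, p)
    edited = rng.binomial(total, rates)

    counts = CountTensor(
        pd.DataFrame(edited, index=site_ids, columns=sample_ids),
        pd.DataFrame(total, index=site_ids, columns=sample_ids),
    )
    truth = SyntheticTruth(
        discriminative_site_ids_idh=list(site_ids[idh_idx]),
        discriminative_site_ids_codel=list(site_ids[codel_idx]),
        prognostic_site_id=str(site_ids[prog_idx]),
        per_site_subtype_means=means,
    )
    return counts, truth


def simulate_survival(
    cohort: pd.DataFrame,
    levels: pd.DataFrame,
    truth: SyntheticTruth,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Fill overall-survival and progression-free-interval outcomes.

    Event times are exponential under a proportional-hazards model: a
    sample's hazard is ``baseline_hazard * hazard_ratio ** level`` (per
    year), where ``level`` is its editing level at the planted prognostic
    site (missing levels fall back to the cohort median).  Censoring is
    independent, uniform on [censor_low, censor_high] years.  PFI uses a
    ``pfi_hazard_scale``-fold baseline hazard, drawn independently.
    """
    site = truth.prognostic_site_id
    if site not in levels.index:
        raise GlioeditError(f"prognostic site {site!r} absent from level matrix")
    lv = levels.loc[site].reindex(cohort.index)
    if lv.isna().all():
        raise GlioeditError(f"prognostic site {site!r} has no covered samples")
    lv = lv.fillna(lv.median())
    rng = np.random.default_rng([config.seed, 4])
    hazard = config.baseline_hazard * np.power(
        config.prognostic_site_hazard_ratio, lv.to_numpy(float))
    out = cohort.copy()
    for prefix, scale in (("os", 1.0), ("pfi", config.pfi_hazard_scale)):
        event_t = rng.exponential(1.0 / (hazard * scale))
        censor_t = rng.uniform(config.censor_low, config.censor_high, size=len(out))
        out[f"{prefix}_time"] = np.minimum(event_t, censor_t)
        out[f"{prefix}_event"] = (event_t <= censor_t).astype(int)
    return out


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, CountTensor, SyntheticTruth]:
    """Run the full generator: catalog, cohort with survival, counts, truth."""
    from .quant import compute_site_editing_levels

    catalog = generate_site_catalog(config)
    cohort = generate_cohort(config)
    counts, truth = simulate_counts(catalog, cohort, config)
    levels = compute_site_editing_levels(counts)
    cohort = simulate_survival(cohort, levels, truth, config)
    return catalog, cohort, counts, truth
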