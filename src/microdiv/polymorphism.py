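"""Within-species polymorphism rates under the published coverage filters.

The polymorphism rate of a species in a sample is the proportion of assayed
core-genome sites of a degeneracy class (fourfold-degenerate ≈ synonymous,
onefold ≈ nonsynonymous) whose within-sample alternate-allele frequency lies
in the intermediate window 0.2 ≤ f ≤ 0.8 (inclusive). Sites are assayed only
if their per-sample depth D satisfies 0.3·D̄ ≤ D ≤ 3·D̄ (D̄ the sample's
median coding-site depth), their gene is core, and their gene is neither
blacklisted nor high-copy. Samples with D̄ < 5 are excluded; species need
marker coverage ≥ 10 in ≥ 10 samples to enter the analysis at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .tables import CohortTables, SNVMatrix

CLASS_TO_DEGENERACY = {"synonymous": "fourfold", "nonsynonymous": "onefold"}


@dataclass(frozen=True)
class PolymorphismRecord:
    species_id: str
    sample_id: str
    site_class: str  # 'synonymous' | 'nonsynonymous'
    n_sites_passing: int
    n_intermediate: int

    @property
    def rate(self) -> float | None:
        """n_intermediate / n_sites_passing; None when no site passed."""
        if self.n_sites_passing == 0:
            return None
        return self.n_intermediate / self.n_sites_passing

    @property
    def defined(self) -> bool:
        return self.n_sites_passing > 0


@dataclass(frozen=True)
class PolymorphismChangeRecord:
    species_id: str
    host_id: str
    sample_t1: str
    sample_t2: str
    delta_days: int
    site_class: str
    delta: float


def filter_samples(snv: SNVMatrix, config: RunConfig = DEFAULT_CONFIG) -> list[str]:
    """Samples retained for SNV analysis: median coding-site depth D̄ ≥ 5.

    The threshold is strict on the exclusion side (D̄ < 5 drops the sample),
    so D̄ = 5.0 exactly is retained. Samples with no covered site have
    D̄ = 0 and are excluded.
    """
    dbar = snv.median_depth()
    return [s for s in dbar.index if dbar[s] >= config.min_median_depth]


def eligible_species(cohort: CohortTables, config: RunConfig = DEFAULT_CONFIG) -> list[str]:
    """Species with marker coverage ≥ 10 in ≥ 10 samples (both inclusive)."""
    mc = cohort.abundance.marker_coverage
    n_ok = (mc >= config.min_marker_coverage).sum(axis=0)
    return [sp for sp in mc.columns if n_ok[sp] >= config.min_eligible_samples]


def site_pass_mask(
    snv: SNVMatrix,
    core: set[str],
    blacklist: set[str],
    high_copy: set[str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Boolean sites × samples mask of assayable sites.

    A site passes in a sample iff 0.3·D̄ ≤ D ≤ 3·D̄ for that sample's D̄,
    its gene is in ``core``, and its gene is in neither ``blacklist`` nor
    ``high_copy``. Retention is per-(site, sample): a site may be assayable
    in one sample and not another.
    """
    high_copy = high_copy or set()
    dbar = snv.median_depth().to_numpy()
    d = snv.depth.to_numpy(dtype=float)
    depth_ok = (d >= config.site_depth_lo_frac * dbar) & (d <= config.site_depth_hi_frac * dbar)
    excluded_genes = blacklist | high_copy
    gene_ok = snv.sites["gene_id"].map(
        lambda g: (g in core) and (g not in excluded_genes)
    ).to_numpy()
    mask = depth_ok & gene_ok[:, None]
    return pd.DataFrame(mask, index=snv.depth.index, columns=snv.depth.columns)


def filter_sites(
    snv: SNVMatrix,
    core: set[str],
    blacklist: set[str],
    high_copy: set[str] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> SNVMatrix:
    """SNV matrix with non-assayable (site, sample) cells zeroed out.

    Failing cells get depth 0 / alt 0, the package-wide encoding for
    "unusable here"; site rows that fail everywhere are kept (with all-zero
    depth) so indexes stay aligned with the input.
    """
    mask = site_pass_mask(snv, core, blacklist, high_copy, config).to_numpy()
    depth = snv.depth.where(mask, 0)
    alt = snv.alt_count.where(mask, 0)
    return SNVMatrix(species_id=snv.species_id, sites=snv.sites, depth=depth, alt_count=alt)


def polymorphism_rate(
    snv: SNVMatrix,
    pass_mask: pd.DataFrame,
    sample_id: str,
    site_class: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> PolymorphismRecord:
    """Polymorphism rate for one (species, sample, degeneracy class).

    Denominator: passing sites of the class with D > 0. Numerator: those
    with f in [freq_lo, freq_hi], bounds inclusive. A zero denominator
    yields a record flagged undefined rather than an exception.
    """
    if site_class not in CLASS_TO_DEGENERACY:
        raise ValueError(f"site_class must be one of {list(CLASS_TO_DEGENERACY)}")
    deg = CLASS_TO_DEGENERACY[site_class]
    in_class = (snv.sites["degeneracy"] == deg).to_numpy()
    d = snv.depth[sample_id].to_numpy(dtype=float)
    a = snv.alt_count[sample_id].to_numpy(dtype=float)
    ok = in_class & pass_mask[sample_id].to_numpy() & (d > 0)
    n_pass = int(ok.sum())
    if n_pass == 0:
        return PolymorphismRecord(snv.species_id, sample_id, site_class, 0, 0)
    f = a[ok] / d[ok]
    n_mid = int(((f >= config.freq_lo) & (f <= config.freq_hi)).sum())
    return PolymorphismRecord(snv.species_id, sample_id, site_class, n_pass, n_mid)


def heterozygosity(
    snv: SNVMatrix, pass_mask: pd.DataFrame, sample_id: str, site_class: str
) -> float | None:
    """Mean 2f(1−f) over passing covered sites of the class.

    The classical heterozygosity analogue of the windowed polymorphism rate;
    exposed for the rank-equivalence diagnostic, not used by the pipeline.
    """
    deg = CLASS_TO_DEGENERACY[site_class]
    in_class = (snv.sites["degeneracy"] == deg).to_numpy()
    d = snv.depth[sample_id].to_numpy(dtype=float)
    a = snv.alt_count[sample_id].to_numpy(dtype=float)
    ok = in_class & pass_mask[sample_id].to_numpy() & (d > 0)
    if not ok.any():
        return None
    f = a[ok] / d[ok]
    return float(np.mean(2 * f * (1 - f)))


def polymorphism_table(
    cohort: CohortTables,
    core_by_species: dict[str, set[str]],
    high_copy_by_species: dict[str, set[str]] | None = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-(species, sample, class) polymorphism records for a whole cohort.

    Applies species eligibility, the D̄ ≥ 5 sample filter, and the
    site/gene filters; undefined records (zero denominator) are kept with
    NaN rate so downstream joins can drop them explicitly.
    """
    high_copy_by_species = high_copy_by_species or {}
    rows = []
    for sp in eligible_species(cohort, config):
        if sp not in cohort.snv:
            continue
        snv = cohort.snv[sp]
        core = core_by_species.get(sp, set())
        blacklist = cohort.genes[sp].blacklist if sp in cohort.genes else set()
        mask = site_pass_mask(snv, core, blacklist, high_copy_by_species.get(sp), config)
        for sid in filter_samples(snv, config):
            for cls in CLASS_TO_DEGENERACY:
                rec = polymorphism_rate(snv, mask, sid, cls, config)
                rows.append(
                    {
                        "species_id": sp,
                        "sample_id": sid,
                        "site_class": cls,
                        "n_sites_passing": rec.n_sites_passing,
                        "n_intermediate": rec.n_intermediate,
                        "rate": np.nan if not rec.defined else rec.rate,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["species_id", "sample_id", "site_class", "n_sites_passing", "n_intermediate", "rate"],
    )


def polymorphism_change(
    t1: PolymorphismRecord,
    t2: PolymorphismRecord,
    host_id: str,
    delta_days: int,
) -> PolymorphismChangeRecord:
    """Difference in polymorphism rate between two time points of one host."""
    if t1.species_id != t2.species_id or t1.site_class != t2.site_class:
        raise ValueError("records must describe the same species and site class")
    if delta_days <= 0:
        raise ValueError("delta_days must be positive")
    if not (t1.defined and t2.defined):
        raise ValueError("both records must be defined (nonzero denominators)")
    return PolymorphismChangeRecord(
        species_id=t1.species_id,
        host_id=host_id,
        sample_t1=t1.sample_id,
        sample_t2=t2.sample_id,
        delta_days=delta_days,
        site_class=t1.site_class,
        delta=t2.rate - t1.rate,
    )


def polymorphism_change_table(
    poly: pd.DataFrame,
    sample_meta: pd.DataFrame,
    anchor_first_only: bool = False,
) -> pd.DataFrame:
    """All within-host ordered time-point pairs of polymorphism rates.

    ``poly`` is the output of :func:`polymorphism_table`; ``sample_meta`` the
    frame from ``AbundanceTable.meta_frame``. Every earlier sample is paired
    with every later one (``anchor_first_only=True`` restricts anchors to the
    host's first sample). Pairs with an undefined rate at either end are
    skipped.
    """
    meta = sample_meta
    df = poly.dropna(subset=["rate"]).merge(
        meta[["host_id", "time_point", "collection_day"]],
        left_on="sample_id",
        right_index=True,
    )
    rows = []
    for (sp, host, cls), grp in df.groupby(["species_id", "host_id", "site_class"], sort=False):
        grp = grp.sort_values("time_point")
        recs = list(grp.itertuples())
        for i, r1 in enumerate(recs):
            if anchor_first_only and i > 0:
                break
            for r2 in recs[i + 1 :]:
                rows.append(
                    {
                        "species_id": sp,
                        "host_id": host,
                        "sample_t1": r1.sample_id,
                        "sample_t2": r2.sample_id,
                        "delta_days": int(r2.collection_day - r1.collection_day),
                        "site_class": cls,
                        "rate_t1": r1.rate,
                        "rate_t2": r2.rate,
                        "delta": r2.rate - r1.rate,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "host_id", "sample_t1", "sample_t2",
            "delta_days", "site_class", "rate_t1", "rate_t2", "delta",
        ],
    )
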