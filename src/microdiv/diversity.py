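"""Community diversity per sample: Shannon index, richness, rarefied richness,
and aggregation to higher taxonomic ranks.

Shannon diversity is computed in natural-log units, −Σ pᵢ ln pᵢ over taxa
with positive abundance (renormalized to sum 1), matching the convention of
the vegan ``diversity`` function. Richness counts taxa with abundance > 0.
Rarefied richness subsamples reads without replacement (multivariate
hypergeometric) to a fixed depth; samples under the depth are excluded rather
than upsampled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .tables import AbundanceTable, CohortTables, TAXON_RANKS

RANKS_WITH_SPECIES = ("species",) + TAXON_RANKS


def shannon(abundances, base: float | None = None) -> float:
    """Shannon index H' of one sample's abundance vector.

    Zero entries contribute nothing; the positive entries are renormalized to
    sum 1, so the index is scale-invariant. ``base`` defaults to natural log.
    Raises ``ValueError`` on an all-zero vector (diversity undefined).
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    if p.sum() <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero abundance vector")
    return float(stats.entropy(p[p > 0], base=base))


def richness(abundances) -> int:
    """Number of taxa with strictly positive abundance."""
    p = np.asarray(abundances, dtype=float)
    return int((p > 0).sum())


def rarefy_richness(read_counts, depth: int, seed: int, n_draws: int = 1):
    """Richness after subsampling exactly ``depth`` reads without replacement.

    ``read_counts`` are integer per-species read counts. Returns the mean
    richness over ``n_draws`` hypergeometric subsamples (an integer when
    ``n_draws`` is 1). Returns ``None`` when the sample has fewer than
    ``depth`` reads in total — such samples are excluded from rarefied
    analyses, never upsampled.
    """
    counts = np.asarray(read_counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("read counts must be integers")
        counts = np.round(counts).astype(np.int64)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    total = int(counts.sum())
    if total < depth:
        return None
    rng = np.random.default_rng(seed)
    vals = [
        int((rng.multivariate_hypergeometric(counts, depth) > 0).sum())
        for _ in range(n_draws)
    ]
    if n_draws == 1:
        return vals[0]
    return float(np.mean(vals))


def expected_rarefied_richness(read_counts, depth: int) -> float:
    """Closed-form E[richness] under hypergeometric rarefaction.

    E[S] = Σᵢ [1 − C(N−nᵢ, depth) / C(N, depth)] with N the total read count.
    Used as the analytical oracle for :func:`rarefy_richness`.
    """
    counts = np.asarray(read_counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError("depth exceeds total reads")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    miss = np.zeros(len(counts))
    ok = total - counts >= depth
    miss[ok] = np.exp(log_choose(total - counts[ok], depth) - log_choose(total, depth))
    return float(np.sum(1.0 - miss))


def species_read_counts(abundance: AbundanceTable) -> pd.DataFrame:
    """Per-species read counts: round(relative_abundance × sample read_count)."""
    reads = abundance.meta_frame()["read_count"]
    ra = abundance.relative_abundance
    return (ra.mul(reads, axis=0)).round().astype(np.int64)


def aggregate_rank(abundance: AbundanceTable, taxonomy: pd.DataFrame, rank: str) -> AbundanceTable:
    """Roll species abundances up to a higher taxonomic rank.

    Each taxon's abundance is the sum of its member species' abundances, so
    row sums are preserved. ``rank='species'`` returns the table unchanged.
    Raises ``KeyError`` naming any species that does not resolve at ``rank``.
    """
    if rank == "species":
        return abundance
    if rank not in TAXON_RANKS:
        raise ValueError(f"unknown rank '{rank}'; expected one of {RANKS_WITH_SPECIES}")
    labels = {}
    for sp in abundance.species_ids:
        if sp not in taxonomy.index:
            raise KeyError(f"species {sp} missing from taxonomy at rank {rank}")
        label = taxonomy.loc[sp, rank]
        if not isinstance(label, str) or not label:
            raise KeyError(f"species {sp} has no {rank} label")
        labels[sp] = label
    mapper = pd.Series(labels)
    ra = abundance.relative_abundance.T.groupby(mapper).sum().T
    mc = abundance.marker_coverage.T.groupby(mapper).sum().T
    return AbundanceTable(samples=abundance.samples, relative_abundance=ra, marker_coverage=mc)


def diversity_table(
    cohort: CohortTables,
    rarefaction_depth: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per sample × rank: Shannon, richness, and (at the species
    rank, when a depth is given) rarefied richness.

    Samples whose total reads fall below the rarefaction depth carry NaN in
    ``rarefied_richness``.
    """
    rows = []
    counts = species_read_counts(cohort.abundance)
    ss = np.random.SeedSequence(seed)
    sample_seeds = {
        sid: int(s.generate_state(1)[0] % (2**31))
        for sid, s in zip(cohort.abundance.sample_ids, ss.spawn(len(cohort.abundance.sample_ids)))
    }
    for rank in RANKS_WITH_SPECIES:
        table = aggregate_rank(cohort.abundance, cohort.taxonomy, rank)
        for sid in table.sample_ids:
            vec = table.relative_abundance.loc[sid].to_numpy()
            s_obs = richness(vec)
            h = shannon(vec) if vec.sum() > 0 else 0.0
            rare = np.nan
            if rank == "species" and rarefaction_depth is not None:
                r = rarefy_richness(
                    counts.loc[sid].to_numpy(), rarefaction_depth, sample_seeds[sid]
                )
                rare = np.nan if r is None else r
            rows.append(
                {
                    "sample_id": sid,
                    "rank": rank,
                    "shannon": h,
                    "richness": s_obs,
                    "rarefied_richness": rare,
                    "rarefaction_depth": rarefaction_depth if rank == "species" else np.nan,
                }
            )
    return pd.DataFrame(rows)
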