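"""Gene copy-number estimation, core-gene/prevalence computation, presence
calling, and gain/loss counting between time points.

Copy number c is gene coverage divided by the sample's median single-copy
marker-gene coverage. Presence calling uses deliberately conservative
windows — absent: c ≤ 0.05; single-copy present: 0.6 ≤ c ≤ 1.2 with marker
coverage ≥ 20× — leaving an ambiguous zone that avoids genes whose reads
are stolen by or donated to other species. Genes reaching c ≥ 3 in any
sample are excluded outright, as are blacklisted multi-species genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig, DEFAULT_CONFIG
from .tables import GeneCNMatrix

PRESENT, ABSENT, AMBIGUOUS = "present", "absent", "ambiguous"


@dataclass(frozen=True)
class GainLossRecord:
    species_id: str
    host_id: str
    sample_t1: str
    sample_t2: str
    delta_days: int
    n_gained: int
    n_lost: int
    n_assayed: int


def copy_number(gene_coverage: float, marker_median: float) -> float | None:
    """c = coverage / marker median; None (not callable) when marker ≤ 0."""
    if marker_median <= 0:
        return None
    return gene_coverage / marker_median


def gene_prevalence(cn: GeneCNMatrix, config: RunConfig = DEFAULT_CONFIG) -> pd.Series:
    """Fraction of marker-eligible samples where each gene sits at
    0.3 ≤ c ≤ 3.

    The denominator is restricted to samples with marker coverage ≥ 5×;
    with no eligible sample, prevalence is NaN for every gene.
    """
    c = cn.copy_number()
    eligible = cn.marker_median.reindex(c.columns) >= config.prevalence_min_marker
    if not eligible.any():
        return pd.Series(np.nan, index=c.index, name="prevalence")
    sub = c.loc[:, eligible.to_numpy()]
    ok = (sub >= config.prevalence_c_lo) & (sub <= config.prevalence_c_hi)
    return ok.sum(axis=1) / sub.shape[1]


def core_genes(cn: GeneCNMatrix, config: RunConfig = DEFAULT_CONFIG) -> set[str]:
    """Genes present (0.3 ≤ c ≤ 3) in at least 90% of eligible samples."""
    prev = gene_prevalence(cn, config)
    if prev.isna().all():
        return set()
    return set(prev.index[prev >= config.core_prevalence])


def high_copy_exclusions(cn: GeneCNMatrix, config: RunConfig = DEFAULT_CONFIG) -> set[str]:
    """Genes reaching c ≥ 3 in at least one sample; excluded from all
    polymorphism and gene-change analyses (unioned with the blacklist)."""
    c = cn.copy_number()
    if c.shape[1] == 0 or c.shape[0] == 0:
        return set()
    cmax = c.max(axis=1, skipna=True)
    return set(cmax.index[cmax >= config.high_copy_cutoff])


def call_presence_frame(cn: GeneCNMatrix, config: RunConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Presence state for every (gene, sample): present/absent/ambiguous.

    States partition: absent iff c ≤ 0.05; present iff 0.6 ≤ c ≤ 1.2 and
    marker coverage ≥ 20; everything else — the 0.05–0.6 gap, c > 1.2,
    marker below the confidence floors, or an uncallable sample
    (marker ≤ 0) — is ambiguous. Any call (including absent) requires
    marker coverage ≥ 5.
    """
    c = cn.copy_number().to_numpy()
    marker = cn.marker_median.reindex(cn.coverage.columns).to_numpy(dtype=float)
    callable_ = (marker >= config.call_min_marker)[None, :] & ~np.isnan(c)
    absent = callable_ & (c <= config.absence_c_max)
    present = (
        callable_
        & (c >= config.presence_c_lo)
        & (c <= config.presence_c_hi)
        & (marker >= config.presence_min_marker)[None, :]
    )
    out = np.full(c.shape, AMBIGUOUS, dtype=object)
    out[absent] = ABSENT
    out[present] = PRESENT
    return pd.DataFrame(out, index=cn.coverage.index, columns=cn.coverage.columns)


def call_presence(
    cn: GeneCNMatrix, sample_id: str, gene_id: str, config: RunConfig = DEFAULT_CONFIG
) -> str:
    """Presence state of one gene in one sample."""
    return call_presence_frame(cn, config).loc[gene_id, sample_id]


def count_gains_losses(
    calls_t1: pd.Series,
    calls_t2: pd.Series,
    species_id: str = "",
    host_id: str = "",
    sample_t1: str = "",
    sample_t2: str = "",
    delta_days: int = 0,
) -> GainLossRecord:
    """Gene gains (absent→present) and losses (present→absent) between two
    time points of one host.

    Genes ambiguous at either end are excluded from both the counts and the
    assayed denominator. Swapping the two call sets swaps gains and losses.
    """
    calls_t2 = calls_t2.reindex(calls_t1.index)
    confident = (calls_t1 != AMBIGUOUS) & (calls_t2 != AMBIGUOUS) & calls_t2.notna()
    t1 = calls_t1[confident]
    t2 = calls_t2[confident]
    n_gained = int(((t1 == ABSENT) & (t2 == PRESENT)).sum())
    n_lost = int(((t1 == PRESENT) & (t2 == ABSENT)).sum())
    return GainLossRecord(
        species_id=species_id,
        host_id=host_id,
        sample_t1=sample_t1,
        sample_t2=sample_t2,
        delta_days=delta_days,
        n_gained=n_gained,
        n_lost=n_lost,
        n_assayed=int(confident.sum()),
    )


def gain_loss_table(
    cn_by_species: dict[str, GeneCNMatrix],
    sample_meta: pd.DataFrame,
    config: RunConfig = DEFAULT_CONFIG,
    consecutive_only: bool = True,
) -> pd.DataFrame:
    """Gain/loss records for every within-host ordered pair of time points.

    Genes failing the blacklist or the c ≥ 3 exclusion are dropped before
    calling. ``consecutive_only`` pairs adjacent time points (the sparse
    ~6-month cohort convention); set False for all ordered pairs (the dense
    time-series convention).
    """
    rows = []
    for sp, cn in cn_by_species.items():
        excluded = cn.blacklist | high_copy_exclusions(cn, config)
        keep = [g for g in cn.gene_ids if g not in excluded]
        cn_kept = GeneCNMatrix(
            species_id=sp,
            coverage=cn.coverage.loc[keep],
            marker_median=cn.marker_median,
            blacklist=set(),
        )
        calls = call_presence_frame(cn_kept, config)
        for host, grp in sample_meta.groupby("host_id", sort=False):
            grp = grp.sort_values("time_point")
            sids = [s for s in grp.index if s in calls.columns]
            pairs = (
                list(zip(sids[:-1], sids[1:]))
                if consecutive_only
                else [(a, b) for i, a in enumerate(sids) for b in sids[i + 1 :]]
            )
            for s1, s2 in pairs:
                dd = int(grp.loc[s2, "collection_day"] - grp.loc[s1, "collection_day"])
                rec = count_gains_losses(
                    calls[s1], calls[s2], sp, host, s1, s2, dd
                )
                rows.append(rec.__dict__)
    return pd.DataFrame(
        rows,
        columns=[
            "species_id", "host_id", "sample_t1", "sample_t2",
            "delta_days", "n_gained", "n_lost", "n_assayed",
        ],
    )
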