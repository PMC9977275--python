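"""In-memory data model for a metagenomic cohort.

The pipeline consumes MIDAS-style merged tables: per-sample species relative
abundances with marker-gene coverage, per-species site × sample SNV depth and
alternate-allele counts with site annotations, per-species gene × sample
coverage, a taxonomy table, and sample metadata. Everything is held in pandas
containers with samples as columns (species/site/gene keys as rows), indexed
consistently across members of one :class:`CohortTables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEGENERACY_CLASSES = ("fourfold", "onefold", "other")
TAXON_RANKS = ("genus", "family", "order", "class", "phylum")

ABUNDANCE_TOL = 1e-6


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one stool sample.

    ``collection_day`` is days since the host's first sample (0 at the
    earliest sample, strictly increasing with ``time_point`` within a host);
    ``read_count`` is the total metagenomic read count, used as the
    per-sample coverage covariate in the slope models.
    """

    sample_id: str
    host_id: str
    time_point: int
    collection_day: int
    read_count: int


@dataclass
class AbundanceTable:
    """Species relative abundances and marker-gene coverage per sample.

    ``relative_abundance`` and ``marker_coverage`` are samples × species
    DataFrames sharing index (sample_id) and columns (species_id). Rows of
    ``relative_abundance`` sum to 1 within tolerance (or are all zero for an
    empty sample).
    """

    samples: list[SampleMeta]
    relative_abundance: pd.DataFrame
    marker_coverage: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_ids(self) -> list[str]:
        return list(self.relative_abundance.columns)

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        df = pd.DataFrame(
            [
                (s.sample_id, s.host_id, s.time_point, s.collection_day, s.read_count)
                for s in self.samples
            ],
            columns=["sample_id", "host_id", "time_point", "collection_day", "read_count"],
        )
        return df.set_index("sample_id")


@dataclass
class SNVMatrix:
    """Per-species site × sample read depths and alternate-allele counts.

    ``sites`` is a DataFrame indexed by site_id with columns ``gene_id`` and
    ``degeneracy`` (fourfold / onefold / other). ``depth`` and ``alt_count``
    are sites × samples integer DataFrames with 0 ≤ alt_count ≤ depth.
    """

    species_id: str
    sites: pd.DataFrame
    depth: pd.DataFrame
    alt_count: pd.DataFrame

    def median_depth(self) -> pd.Series:
        """Per-sample median depth D̄ over sites with nonzero coverage.

        Samples with no covered site get D̄ = 0 (and are excluded by the
        D̄ < 5 sample filter downstream).
        """
        import warnings

        d = self.depth.to_numpy(dtype=float)
        masked = np.where(d > 0, d, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(masked, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        return pd.Series(med, index=self.depth.columns, name="median_depth")

    def frequency(self) -> pd.DataFrame:
        """Alternate-allele frequency f = alt/depth; NaN where depth = 0."""
        d = self.depth.to_numpy(dtype=float)
        a = self.alt_count.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(d > 0, a / d, np.nan)
        return pd.DataFrame(f, index=self.depth.index, columns=self.depth.columns)


@dataclass
class GeneCNMatrix:
    """Per-species gene × sample coverage with marker-gene normalization.

    ``coverage`` is per-base read depth of each gene; ``marker_median`` the
    per-sample median coverage of the species' single-copy marker genes.
    Copy number c = coverage / marker_median wherever marker_median > 0.
    """

    species_id: str
    coverage: pd.DataFrame
    marker_median: pd.Series
    blacklist: set[str] = field(default_factory=set)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.coverage.index)

    def copy_number(self) -> pd.DataFrame:
        """c = coverage / marker_median; NaN where marker_median ≤ 0."""
        m = self.marker_median.reindex(self.coverage.columns).to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(m > 0, self.coverage.to_numpy(dtype=float) / m, np.nan)
        return pd.DataFrame(c, index=self.coverage.index, columns=self.coverage.columns)


@dataclass
class CohortTables:
    """The universal input bundle: one cohort's tables, consistently indexed."""

    abundance: AbundanceTable
    taxonomy: pd.DataFrame  # index species_id, columns TAXON_RANKS
    snv: dict[str, SNVMatrix] = field(default_factory=dict)
    genes: dict[str, GeneCNMatrix] = field(default_factory=dict)


class CohortValidationError(ValueError):
    """Raised by the reader when a loaded cohort violates an invariant."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


def validate_cohort(tables: CohortTables) -> list[str]:
    """Check every type invariant; return one message per violation.

    Reports and never raises: an empty list means the cohort is valid.
    Each message carries the coordinates (sample, site, gene ...) of the
    offending cell or row.
    """
    v: list[str] = []
    ab = tables.abundance
    sample_ids = ab.sample_ids

    if len(set(sample_ids)) != len(sample_ids):
        v.append("duplicate sample_ids in sample metadata")

    # abundance rows: non-negative, unit-sum (or all-zero)
    ra = ab.relative_abundance
    if list(ra.index) != sample_ids:
        v.append("relative_abundance index does not match sample metadata order")
    neg = np.argwhere(ra.to_numpy() < 0)
    for i, j in neg:
        v.append(
            f"negative relative abundance at sample={ra.index[i]} species={ra.columns[j]}"
        )
    row_sums = ra.to_numpy(dtype=float).sum(axis=1)
    for i, s in enumerate(row_sums):
        if s != 0 and abs(s - 1.0) > ABUNDANCE_TOL:
            v.append(f"abundance row sum {s:.8f} != 1 at sample={ra.index[i]}")
    if (ab.marker_coverage.to_numpy() < 0).any():
        v.append("negative marker coverage")

    # sample metadata: collection_day 0 at first sample, strictly increasing
    meta = ab.meta_frame()
    for host, grp in meta.groupby("host_id", sort=False):
        grp = grp.sort_values("time_point")
        days = grp["collection_day"].to_numpy()
        if len(days) and days[0] != 0:
            v.append(f"host {host}: collection_day at first time point is {days[0]}, not 0")
        if len(days) > 1 and not (np.diff(days) > 0).all():
            v.append(f"host {host}: collection_day not strictly increasing with time_point")
    if (meta["read_count"] < 0).any():
        bad = meta.index[meta["read_count"] < 0]
        v.append(f"negative read_count for samples {list(bad)}")

    # taxonomy resolves every species at all ranks
    for sp in ab.species_ids:
        if sp not in tables.taxonomy.index:
            v.append(f"species {sp} missing from taxonomy")
            continue
        row = tables.taxonomy.loc[sp]
        for rank in TAXON_RANKS:
            label = row.get(rank, "")
            if not isinstance(label, str) or not label:
                v.append(f"species {sp}: empty {rank} label")

    # per-species SNV matrices
    for sp, snv in tables.snv.items():
        if list(snv.depth.columns) != sample_ids or list(snv.alt_count.columns) != sample_ids:
            v.append(f"{sp}: SNV columns do not match cohort sample_ids")
        if not snv.depth.index.equals(snv.alt_count.index):
            v.append(f"{sp}: depth and alt_count site indexes differ")
        d = snv.depth.to_numpy()
        a = snv.alt_count.to_numpy()
        if (d < 0).any():
            v.append(f"{sp}: negative depth")
        over = np.argwhere(a > d)
        for i, j in over:
            v.append(
                f"{sp}: alt_count > depth at site={snv.depth.index[i]} "
                f"sample={snv.depth.columns[j]}"
            )
        bad_deg = set(snv.sites["degeneracy"]) - set(DEGENERACY_CLASSES)
        if bad_deg:
            v.append(f"{sp}: unknown degeneracy classes {sorted(bad_deg)}")
        if sp not in tables.genes:
            v.append(f"{sp}: has an SNV matrix but no gene coverage matrix")

    # per-species gene matrices
    for sp, g in tables.genes.items():
        if list(g.coverage.columns) != sample_ids:
            v.append(f"{sp}: gene coverage columns do not match cohort sample_ids")
        if (g.coverage.to_numpy() < 0).any():
            v.append(f"{sp}: negative gene coverage")
        if (g.marker_median.reindex(g.coverage.columns).to_numpy() < 0).any():
            v.append(f"{sp}: negative marker_median")
        unknown = g.blacklist - set(g.gene_ids)
        if unknown:
            v.append(f"{sp}: blacklist names unknown genes {sorted(unknown)[:5]}")

    return v
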