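"""Readers/writers for the on-disk cohort layout.

One cohort directory holds tab-separated tables mirroring merged MIDAS-style
output::

    samples.tsv                     sample_id, host_id, time_point,
                                    collection_day, read_count
    abundance.tsv                   species × samples relative abundance
    marker_coverage.tsv             species × samples marker-gene coverage
    taxonomy.tsv                    species_id + genus..phylum columns
    blacklist.txt                   one gene_id per line (may be empty)
    <species>_snv_depth.tsv         sites × samples read depth
    <species>_snv_alt.tsv           sites × samples alternate-allele count
    <species>_site_info.tsv         site_id, gene_id, degeneracy
    <species>_gene_coverage.tsv     genes × samples per-base coverage; the
                                    reserved row ``__marker_median__`` holds
                                    the per-sample median single-copy
                                    marker-gene coverage

All numeric round-trips are lossless for integers and better than 1e-9
relative for reals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .config import RunConfig
from .tables import (
    AbundanceTable,
    CohortTables,
    CohortValidationError,
    GeneCNMatrix,
    SampleMeta,
    SNVMatrix,
    validate_cohort,
)

MARKER_MEDIAN_ROW = "__marker_median__"
_FLOAT_FMT = "%.12g"


def _require(root: Path, name: str) -> Path:
    path = root / name
    if not path.exists():
        raise FileNotFoundError(f"cohort directory {root} is missing required file '{name}'")
    return path


def write_cohort(tables: CohortTables, root_path: str | Path) -> dict:
    """Write a cohort directory; returns a manifest of the files written.

    The manifest maps ``"cohort"`` to the cohort-level files and
    ``"per_species"`` to a dict of species_id → its four table files.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    ab = tables.abundance
    manifest: dict = {"cohort": [], "per_species": {}}

    def _cohort_file(name: str) -> Path:
        manifest["cohort"].append(name)
        return root / name

    meta = ab.meta_frame().reset_index()
    meta.to_csv(_cohort_file("samples.tsv"), sep="\t", index=False)
    # species × samples orientation on disk
    ab.relative_abundance.T.to_csv(
        _cohort_file("abundance.tsv"), sep="\t", index_label="species_id",
        float_format=_FLOAT_FMT,
    )
    ab.marker_coverage.T.to_csv(
        _cohort_file("marker_coverage.tsv"), sep="\t", index_label="species_id",
        float_format=_FLOAT_FMT,
    )
    tables.taxonomy.to_csv(
        _cohort_file("taxonomy.tsv"), sep="\t", index_label="species_id"
    )
    blacklist = sorted(set().union(*(g.blacklist for g in tables.genes.values()), set()))
    _cohort_file("blacklist.txt").write_text("".join(f"{g}\n" for g in blacklist))

    for sp in sorted(tables.snv):
        snv = tables.snv[sp]
        files = []
        for name, frame in (
            (f"{sp}_snv_depth.tsv", snv.depth),
            (f"{sp}_snv_alt.tsv", snv.alt_count),
        ):
            frame.to_csv(root / name, sep="\t", index_label="site_id")
            files.append(name)
        snv.sites.to_csv(root / f"{sp}_site_info.tsv", sep="\t", index_label="site_id")
        files.append(f"{sp}_site_info.tsv")
        manifest["per_species"][sp] = files
    for sp in sorted(tables.genes):
        g = tables.genes[sp]
        out = g.coverage.copy()
        out.loc[MARKER_MEDIAN_ROW] = g.marker_median.reindex(out.columns)
        name = f"{sp}_gene_coverage.tsv"
        out.to_csv(root / name, sep="\t", index_label="gene_id", float_format=_FLOAT_FMT)
        manifest["per_species"].setdefault(sp, []).append(name)
    return manifest


def read_cohort(root_path: str | Path, config: RunConfig | None = None) -> CohortTables:
    """Load and validate a cohort directory written by :func:`write_cohort`.

    Raises ``FileNotFoundError`` naming any missing required file and
    :class:`CohortValidationError` (with cell coordinates) if the loaded
    tables violate a type invariant.
    """
    root = Path(root_path)
    meta = pd.read_csv(_require(root, "samples.tsv"), sep="\t", dtype={"sample_id": str, "host_id": str})
    samples = [
        SampleMeta(
            sample_id=str(r.sample_id),
            host_id=str(r.host_id),
            time_point=int(r.time_point),
            collection_day=int(r.collection_day),
            read_count=int(r.read_count),
        )
        for r in meta.itertuples()
    ]
    sample_ids = [s.sample_id for s in samples]

    def _matrix(name: str, index_col: str) -> pd.DataFrame:
        df = pd.read_csv(_require(root, name), sep="\t", index_col=index_col)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return df

    ra = _matrix("abundance.tsv", "species_id").T.reindex(sample_ids)
    mc = _matrix("marker_coverage.tsv", "species_id").T.reindex(sample_ids)
    taxonomy = pd.read_csv(_require(root, "taxonomy.tsv"), sep="\t", index_col="species_id", dtype=str)
    blacklist_path = _require(root, "blacklist.txt")
    blacklist = {line.strip() for line in blacklist_path.read_text().splitlines() if line.strip()}

    abundance = AbundanceTable(samples=samples, relative_abundance=ra, marker_coverage=mc)

    snv: dict[str, SNVMatrix] = {}
    genes: dict[str, GeneCNMatrix] = {}
    for depth_path in sorted(root.glob("*_snv_depth.tsv")):
        sp = depth_path.name[: -len("_snv_depth.tsv")]
        depth = _matrix(depth_path.name, "site_id")[sample_ids].astype(int)
        alt = _matrix(f"{sp}_snv_alt.tsv", "site_id")[sample_ids].astype(int)
        sites = pd.read_csv(
            _require(root, f"{sp}_site_info.tsv"), sep="\t", index_col="site_id", dtype=str
        )
        snv[sp] = SNVMatrix(species_id=sp, sites=sites, depth=depth, alt_count=alt)
    for cov_path in sorted(root.glob("*_gene_coverage.tsv")):
        sp = cov_path.name[: -len("_gene_coverage.tsv")]
        cov = _matrix(cov_path.name, "gene_id")[sample_ids]
        marker_median = cov.loc[MARKER_MEDIAN_ROW]
        cov = cov.drop(index=MARKER_MEDIAN_ROW)
        genes[sp] = GeneCNMatrix(
            species_id=sp,
            coverage=cov,
            marker_median=marker_median,
            blacklist=blacklist & set(cov.index),
        )

    tables = CohortTables(abundance=abundance, taxonomy=taxonomy, snv=snv, genes=genes)
    violations = validate_cohort(tables)
    if violations:
        raise CohortValidationError(violations)
    return tables
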