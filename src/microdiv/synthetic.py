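"""Synthetic gut-metagenome cohorts with known eco-evolutionary ground truth.

The generator emulates the data structure the downstream pipeline consumes:
per-sample species relative abundances (symmetric Dirichlet communities),
multi-strain colonization of focal species with strain count coupled to
community Shannon diversity (the DBD regime when the coupling is positive,
ecological controls when negative, neutral at zero), per-site binomial read
sampling with sequencing error, fourfold/onefold degeneracy labels,
accessory-gene content per strain, marker-gene coverage consistent with
species depth, and longitudinal gene-loss events whose per-gene rate is
coupled to community diversity (the Black Queen regime).

Every random draw flows from one seed through named substreams, so a cohort
is byte-identical across runs with the same parameters.

Observation-level generators for the slope models (truncated-NB strain
counts, negative-binomial loss counts) live here too; they are the
calibration scaffolding for the statistical stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    CohortTables,
    GeneCNMatrix,
    SampleMeta,
    SNVMatrix,
    TAXON_RANKS,
)


@dataclass
class SimParams:
    """Generator settings; defaults sketch a small HMP-like two-visit cohort.

    ``strain_divergence`` is the expected pairwise fraction of panel sites at
    which two strains differ. ``beta_dbd`` tilts the strain-count
    distribution multiplicatively in standardized community Shannon
    diversity (log-odds between adjacent strain counts). ``gamma_bq`` scales
    the per-gene per-day loss rate by exp(gamma_bq × standardized Shannon).
    """

    n_hosts: int = 50
    time_points_per_host: int = 2
    days_between_samples: int | list = 180
    n_species_pool: int = 80
    abundance_concentration: float = 0.6
    reads_per_sample: int = 5_000_000
    n_focal_species: int = 10
    focal_boost: float = 20.0        # Dirichlet weight multiplier: focal
    # species are the cohort's "relatively abundant, well-covered" species
    sites_per_species: int = 200
    fourfold_fraction: float = 0.25
    onefold_fraction: float = 0.70
    strain_divergence: float = 0.1
    max_strains: int = 4
    beta_dbd: float = 0.5
    seq_error: float = 0.01
    genes_per_species: int = 100
    core_gene_fraction: float = 0.8
    accessory_carry_prob: float = 0.5
    gamma_bq: float = 0.5
    base_loss_rate: float = 1e-4     # per gene per day
    base_gain_rate: float = 1e-5     # per absent gene per day
    freq_walk_sigma: float = 0.3     # logistic-normal strain-frequency step
    read_length: int = 150
    genome_size: float = 3e6
    gene_coverage_cv: float = 0.08   # multiplicative Gamma noise on coverage
    read_count_cv: float = 0.2       # lognormal spread of per-sample reads
    baseline_k_weights: tuple = (0.50, 0.25, 0.15, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_hosts, self.time_points_per_host, self.n_species_pool,
               self.n_focal_species, self.sites_per_species,
               self.genes_per_species, self.reads_per_sample) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("fourfold_fraction", "onefold_fraction", "core_gene_fraction",
                     "accessory_carry_prob", "strain_divergence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fourfold_fraction + self.onefold_fraction > 1:
            raise ValueError("fourfold_fraction + onefold_fraction must be <= 1")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.base_loss_rate < 0 or self.base_gain_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.n_focal_species > self.n_species_pool:
            raise ValueError("n_focal_species cannot exceed n_species_pool")
        if not 1 <= self.max_strains <= len(self.baseline_k_weights):
            raise ValueError("max_strains incompatible with baseline_k_weights")


@dataclass
class SimTruth:
    """Ground-truth ledgers recorded during simulation."""

    community: pd.DataFrame   # sample_id, host_id, time_point, true_shannon,
    # true_richness, z_shannon
    strains: pd.DataFrame     # sample_id, host_id, species_id, K_true, freqs
    events: pd.DataFrame      # host_id, species_id, gene_id, strain, day, kind
    genotypes: dict = field(default_factory=dict)       # (host, sp) -> (K, L)
    gene_presence: dict = field(default_factory=dict)   # (host, sp, t) -> (K, M)


def _divergent_genotypes(rng, K: int, L: int, d: float) -> np.ndarray:
    """K biallelic genotypes with expected pairwise difference fraction d.

    Each strain independently flips each site with probability q chosen so
    that 2q(1−q) = d, giving pairwise Hamming fractions ~ Binomial(L, d)/L.
    """
    if d > 0.5:
        raise ValueError("strain divergence is a pairwise fraction <= 0.5")
    q = 0.5 * (1 - np.sqrt(1 - 2 * d))
    return (rng.random((K, L)) < q).astype(np.int8)


@dataclass
class StrainSampleSim:
    """Output of the unit-scale strain-mixture read generator."""

    depth: np.ndarray
    alt_count: np.ndarray
    genotypes: np.ndarray
    freqs: np.ndarray

    def to_snv_matrix(
        self,
        species_id: str = "sim_species",
        sample_id: str = "s0",
        degeneracy: str | np.ndarray = "fourfold",
        gene_id: str = "gene0000",
    ) -> SNVMatrix:
        """Wrap the single-sample draw as an SNVMatrix for pipeline input."""
        L = len(self.depth)
        deg = np.full(L, degeneracy) if isinstance(degeneracy, str) else np.asarray(degeneracy)
        site_ids = [f"site{i:06d}" for i in range(L)]
        sites = pd.DataFrame(
            {"gene_id": np.full(L, gene_id), "degeneracy": deg}, index=pd.Index(site_ids, name="site_id")
        )
        return SNVMatrix(
            species_id=species_id,
            sites=sites,
            depth=pd.DataFrame({sample_id: self.depth}, index=sites.index),
            alt_count=pd.DataFrame({sample_id: self.alt_count}, index=sites.index),
        )


def simulate_strain_sample(
    K: int,
    pi,
    d: float,
    L: int,
    depth_mean: float,
    eps: float,
    seed: int,
) -> StrainSampleSim:
    """Reads from one K-strain mixture: D ~ Poisson(depth_mean) per site,
    alt ~ Binomial(D, p̃) with p̃ = (1−ε)·Σπ_k g_ks + ε·(1−Σπ_k g_ks)."""
    pi = np.asarray(pi, dtype=float)
    if len(pi) != K or (pi <= 0).any():
        raise ValueError("pi must have K strictly positive entries")
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError(f"pi must sum to 1 within 1e-9, got {pi.sum()!r}")
    rng = np.random.default_rng(seed)
    g = _divergent_genotypes(rng, K, L, d)
    p = pi @ g
    pt = (1 - eps) * p + eps * (1 - p)
    depth = rng.poisson(depth_mean, size=L)
    alt = rng.binomial(depth, pt)
    return StrainSampleSim(depth=depth, alt_count=alt, genotypes=g, freqs=pi)


def _tilted_k(rng, z: float, beta: float, weights) -> int:
    """Strain count in {1..K_max}: log-weights a_k + beta·z·k (log-odds
    between adjacent counts linear in beta·z)."""
    ks = np.arange(1, len(weights) + 1)
    logw = np.log(np.asarray(weights, dtype=float)) + beta * z * ks
    logw -= logw.max()
    w = np.exp(logw)
    return int(rng.choice(ks, p=w / w.sum()))


def simulate_cohort(params: SimParams) -> tuple[CohortTables, SimTruth]:
    """Generate a full cohort plus its ground-truth ledgers.

    See the module docstring for the generative model; identical parameters
    and seed give byte-identical tables.
    """
    params.validate()
    p = params
    root = np.random.SeedSequence(p.seed)
    (s_comm, s_strain, s_obs, s_genes, s_meta) = [
        np.random.default_rng(s) for s in root.spawn(5)
    ]

    n_samples = p.n_hosts * p.time_points_per_host
    species_ids = [f"sp{i:04d}" for i in range(p.n_species_pool)]
    focal = species_ids[: p.n_focal_species]

    # --- sample metadata ---
    if isinstance(p.days_between_samples, int):
        gaps = [p.days_between_samples] * max(p.time_points_per_host - 1, 0)
    else:
        gaps = list(p.days_between_samples)
        if len(gaps) < p.time_points_per_host - 1:
            raise ValueError("days_between_samples list shorter than needed")
    days = np.concatenate([[0], np.cumsum(gaps)]).astype(int)
    samples = []
    for h in range(p.n_hosts):
        for t in range(p.time_points_per_host):
            reads = int(
                p.reads_per_sample
                * np.exp(s_meta.normal(0, p.read_count_cv) - p.read_count_cv**2 / 2)
            )
            samples.append(
                SampleMeta(
                    sample_id=f"h{h:04d}_t{t}",
                    host_id=f"h{h:04d}",
                    time_point=t,
                    collection_day=int(days[t]),
                    read_count=reads,
                )
            )
    sample_ids = [s.sample_id for s in samples]

    # --- community composition and true diversity ---
    alpha = np.full(p.n_species_pool, p.abundance_concentration)
    alpha[: p.n_focal_species] *= p.focal_boost
    ra = s_comm.dirichlet(alpha, size=n_samples)
    pos = ra > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pos, ra * np.log(np.where(pos, ra, 1.0)), 0.0)
    true_shannon = -plogp.sum(axis=1)
    true_richness = pos.sum(axis=1)
    z = (true_shannon - true_shannon.mean()) / true_shannon.std(ddof=1)

    depth_factor = p.read_length / p.genome_size
    reads_arr = np.array([s.read_count for s in samples], dtype=float)
    species_depth = ra * (reads_arr * depth_factor)[:, None]  # samples × species

    marker_cov = species_depth * s_comm.gamma(400.0, 1 / 400.0, size=species_depth.shape)
    abundance = AbundanceTable(
        samples=samples,
        relative_abundance=pd.DataFrame(ra, index=sample_ids, columns=species_ids),
        marker_coverage=pd.DataFrame(marker_cov, index=sample_ids, columns=species_ids),
    )

    # --- taxonomy: nested labels over the species pool ---
    tax_rows = {}
    for i, sp in enumerate(species_ids):
        tax_rows[sp] = {
            "genus": f"g{i // 2:03d}",
            "family": f"f{i // 4:03d}",
            "order": f"o{i // 8:03d}",
            "class": f"c{i // 16:03d}",
            "phylum": f"p{i // 32:03d}",
        }
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")[list(TAXON_RANKS)]
    taxonomy.index.name = "species_id"

    # --- focal species: strains, SNVs, genes ---
    L, M = p.sites_per_species, p.genes_per_species
    m_core = int(round(M * p.core_gene_fraction))
    deg_choices = np.array(["fourfold", "onefold", "other"])
    deg_probs = [p.fourfold_fraction, p.onefold_fraction,
                 1 - p.fourfold_fraction - p.onefold_fraction]
    k_weights = p.baseline_k_weights[: p.max_strains]

    truth_strain_rows = []
    event_rows = []
    genotypes_truth = {}
    presence_truth = {}
    snv_tables: dict[str, SNVMatrix] = {}
    gene_tables: dict[str, GeneCNMatrix] = {}

    sample_index = {
        (s.host_id, s.time_point): (i, s) for i, s in enumerate(samples)
    }
    hosts = [f"h{h:04d}" for h in range(p.n_hosts)]

    for j, sp in enumerate(focal):
        gene_ids = [f"{sp}_gene{g:04d}" for g in range(M)]
        site_gene = np.array([gene_ids[i % M] for i in range(L)])
        site_deg = deg_choices[s_strain.choice(3, size=L, p=deg_probs)]
        site_ids = [f"{sp}_site{i:05d}" for i in range(L)]
        sites = pd.DataFrame(
            {"gene_id": site_gene, "degeneracy": site_deg},
            index=pd.Index(site_ids, name="site_id"),
        )

        depth_mat = np.zeros((L, n_samples), dtype=np.int64)
        alt_mat = np.zeros((L, n_samples), dtype=np.int64)
        cov_mat = np.zeros((M, n_samples))
        marker_median = np.zeros(n_samples)

        for host_i, host in enumerate(hosts):
            i0, s0 = sample_index[(host, 0)]
            K = _tilted_k(s_strain, z[i0], p.beta_dbd, k_weights)
            g = _divergent_genotypes(s_strain, K, L, p.strain_divergence)
            genotypes_truth[(host, sp)] = g
            pi = s_strain.dirichlet(np.full(K, 2.0))
            presence = np.ones((K, M), dtype=bool)
            presence[:, m_core:] = s_strain.random((K, M - m_core)) < p.accessory_carry_prob

            for t in range(p.time_points_per_host):
                i, smeta = sample_index[(host, t)]
                if t > 0:
                    # logistic-normal random walk on strain frequencies
                    if K > 1:
                        logit = np.log(pi) + s_strain.normal(0, p.freq_walk_sigma, K)
                        w = np.exp(logit - logit.max())
                        pi = w / w.sum()
                    # diversity-coupled gene loss, strain-level flips
                    dt = days[t] - days[t - 1]
                    z_prev = z[sample_index[(host, t - 1)][0]]
                    loss_rate = p.base_loss_rate * np.exp(p.gamma_bq * z_prev)
                    p_loss = 1 - np.exp(-loss_rate * dt)
                    p_gain = 1 - np.exp(-p.base_gain_rate * dt)
                    flips_loss = presence & (s_strain.random(presence.shape) < p_loss)
                    flips_gain = (~presence) & (s_strain.random(presence.shape) < p_gain)
                    for k, gi in zip(*np.nonzero(flips_loss)):
                        event_rows.append((host, sp, gene_ids[gi], int(k), int(days[t]), "loss"))
                    for k, gi in zip(*np.nonzero(flips_gain)):
                        event_rows.append((host, sp, gene_ids[gi], int(k), int(days[t]), "gain"))
                    presence = (presence & ~flips_loss) | flips_gain
                presence_truth[(host, sp, t)] = presence.copy()
                truth_strain_rows.append(
                    {
                        "sample_id": smeta.sample_id,
                        "host_id": host,
                        "species_id": sp,
                        "K_true": K,
                        "freqs": ",".join(f"{x:.10g}" for x in pi),
                    }
                )

                # SNV observation
                mean_depth = species_depth[i, j]
                d_site = s_obs.poisson(mean_depth, size=L)
                pvec = pi @ g
                pt = (1 - p.seq_error) * pvec + p.seq_error * (1 - pvec)
                a_site = s_obs.binomial(d_site, pt)
                depth_mat[:, i] = d_site
                alt_mat[:, i] = a_site

                # gene coverage observation
                marker_median[i] = mean_depth * s_genes.gamma(400.0, 1 / 400.0)
                c_true = (pi[:, None] * presence).sum(axis=0)  # (M,)
                shape = 1.0 / p.gene_coverage_cv**2
                noise = s_genes.gamma(shape, 1 / shape, size=M)
                cov_mat[:, i] = marker_median[i] * c_true * noise

        snv_tables[sp] = SNVMatrix(
            species_id=sp,
            sites=sites,
            depth=pd.DataFrame(depth_mat, index=sites.index, columns=sample_ids),
            alt_count=pd.DataFrame(alt_mat, index=sites.index, columns=sample_ids),
        )
        gene_tables[sp] = GeneCNMatrix(
            species_id=sp,
            coverage=pd.DataFrame(cov_mat, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
            marker_median=pd.Series(marker_median, index=sample_ids),
            blacklist=set(),
        )

    community = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "host_id": [s.host_id for s in samples],
            "time_point": [s.time_point for s in samples],
            "true_shannon": true_shannon,
            "true_richness": true_richness,
            "z_shannon": z,
        }
    )
    truth = SimTruth(
        community=community,
        strains=pd.DataFrame(
            truth_strain_rows,
            columns=["sample_id", "host_id", "species_id", "K_true", "freqs"],
        ),
        events=pd.DataFrame(
            event_rows, columns=["host_id", "species_id", "gene_id", "strain", "day", "kind"]
        ),
        genotypes=genotypes_truth,
        gene_presence=presence_truth,
    )
    tables = CohortTables(
        abundance=abundance, taxonomy=taxonomy, snv=snv_tables, genes=gene_tables
    )
    return tables, truth


# ---------------------------------------------------------------------------
# observation-level generators for the slope-model stage
# ---------------------------------------------------------------------------

def _zt_nb2(rng, mu, alpha):
    """Zero-truncated NB2 draws by rejection (vectorized)."""
    mu = np.asarray(mu, dtype=float)
    y = np.zeros(mu.shape, dtype=np.int64)
    todo = np.ones(mu.shape, dtype=bool)
    n = 1.0 / alpha
    while todo.any():
        prob = n / (n + mu[todo])
        y[todo] = rng.negative_binomial(n, prob)
        todo &= y == 0
    return y


def simulate_strain_count_dataset(
    n_hosts: int = 200,
    n_species: int = 20,
    slope: float = 0.5,
    intercept: float = 0.3,
    alpha: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-sectional strain counts from a zero-truncated NB2 whose log-mean
    is ``intercept + slope × standardized Shannon``.

    One Shannon value per host (Normal(2.5, 0.6), gut-like), shared by that
    host's ``n_species`` focal species; read counts are a null covariate.
    """
    rng = np.random.default_rng(seed)
    shannon = rng.normal(2.5, 0.6, n_hosts)
    host = np.repeat(np.arange(n_hosts), n_species)
    # standardize at the observation level — the same convention the slope
    # models use, so `slope` is exactly the coefficient they estimate
    zc = np.repeat(shannon, n_species)
    zc = (zc - zc.mean()) / zc.std(ddof=1)
    mu = np.exp(intercept + slope * zc)
    y = _zt_nb2(rng, mu, alpha)
    reads = rng.lognormal(np.log(5e6), 0.3, n_hosts)
    return pd.DataFrame(
        {
            "host_id": [f"h{h:04d}" for h in host],
            "species_id": [f"sp{s:03d}" for s in np.tile(np.arange(n_species), n_hosts)],
            "shannon": np.repeat(shannon, n_species),
            "read_count": np.repeat(reads, n_species),
            "strain_count": y,
        }
    )


def simulate_gene_loss_dataset(
    n_pairs: int = 1000,
    gamma: float = 0.5,
    base_loss_rate: float = 1e-4,
    n_genes: int = 1500,
    overdispersion: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal gene-loss counts from the Black-Queen mechanism.

    Each row is one (host, species, time-point pair): Shannon at the earlier
    time point, a lag Δdays ~ Uniform{10..300}, and a loss count drawn
    NB2 with mean n_genes × (1 − exp(−λ0·e^{γ·z}·Δdays)) — for small rates,
    log-mean ≈ const + γ·z + log Δdays, so γ is the diversity effect on the
    log scale.
    """
    rng = np.random.default_rng(seed)
    shannon = rng.normal(2.5, 0.6, n_pairs)
    z = (shannon - shannon.mean()) / shannon.std(ddof=1)
    delta_days = rng.integers(10, 301, n_pairs)
    rate = base_loss_rate * np.exp(gamma * z)
    mu = n_genes * (1 - np.exp(-rate * delta_days))
    n = 1.0 / overdispersion
    y = rng.negative_binomial(n, n / (n + mu))
    reads = rng.lognormal(np.log(5e6), 0.3, n_pairs)
    return pd.DataFrame(
        {
            "host_id": [f"h{i:04d}" for i in range(n_pairs)],
            "shannon_t1": shannon,
            "delta_days": delta_days,
            "read_count": reads,
            "genes_lost": y,
        }
    )
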