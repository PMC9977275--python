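"""Coverage filters and intermediate-frequency polymorphism rates."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import microdiv as md
from microdiv.config import RunConfig
from microdiv.polymorphism import (
    eligible_species,
    filter_samples,
    heterozygosity,
    polymorphism_change,
    polymorphism_change_table,
    polymorphism_rate,
    polymorphism_table,
    site_pass_mask,
)
from microdiv.tables import SNVMatrix


def _snv(depth_rows, alt_rows, degeneracy=None, genes=None, samples=None):
    depth = np.atleast_2d(np.asarray(depth_rows))
    alt = np.atleast_2d(np.asarray(alt_rows))
    n_sites, n_samples = depth.shape
    samples = samples or [f"s{j}" for j in range(n_samples)]
    site_ids = [f"site{i}" for i in range(n_sites)]
    sites = pd.DataFrame(
        {
            "gene_id": genes or ["geneA"] * n_sites,
            "degeneracy": degeneracy or ["fourfold"] * n_sites,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    return SNVMatrix(
        species_id="spX",
        sites=sites,
        depth=pd.DataFrame(depth, index=sites.index, columns=samples),
        alt_count=pd.DataFrame(alt, index=sites.index, columns=samples),
    )


class TestSiteFilter:
    def test_depth_window_boundaries(self):
        """Sites pass iff 0.3·D̄ ≤ D ≤ 3·D̄ (D̄ = 30 here): 8 and 95 fail,
        9, 30 and 90 pass."""
        depths = [8, 9, 30, 90, 95] + [30] * 20  # median 30
        snv = _snv(np.array(depths)[:, None], np.zeros((25, 1), dtype=int))
        assert snv.median_depth()["s0"] == 30
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        got = mask["s0"].to_numpy()[:5]
        assert list(got) == [False, True, True, True, False]

    def test_gene_filters_apply(self):
        snv = _snv([[30], [30], [30]], [[0], [0], [0]], genes=["a", "b", "c"])
        mask = site_pass_mask(snv, core={"a", "b"}, blacklist={"b"}, high_copy={"c"})
        assert list(mask["s0"]) == [True, False, False]

    def test_retention_is_per_sample(self):
        snv = _snv([[30, 5], [30, 30], [30, 30]], np.zeros((3, 2), dtype=int))
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        assert mask["s0"].all()
        assert not mask["s1"].iloc[0] and mask["s1"].iloc[1]


class TestSampleFilter:
    @pytest.mark.parametrize("median, kept", [(4, False), (5, True), (30, True)])
    def test_median_depth_threshold_strict_below_five(self, median, kept):
        snv = _snv(np.full((11, 1), median), np.zeros((11, 1), dtype=int))
        assert (filter_samples(snv) == ["s0"]) is kept

    def test_uncovered_sample_excluded(self):
        snv = _snv(np.zeros((5, 1), dtype=int), np.zeros((5, 1), dtype=int))
        assert filter_samples(snv) == []


class TestEligibleSpecies:
    def _cohort_with_marker(self, cov_matrix):
        from microdiv.tables import AbundanceTable, CohortTables, SampleMeta

        n_samples, n_species = cov_matrix.shape
        samples = [SampleMeta(f"s{i}", f"h{i}", 0, 0, 100) for i in range(n_samples)]
        species = [f"sp{j}" for j in range(n_species)]
        ra = np.full((n_samples, n_species), 1.0 / max(n_species, 1))
        ab = AbundanceTable(
            samples=samples,
            relative_abundance=pd.DataFrame(ra, index=[s.sample_id for s in samples], columns=species),
            marker_coverage=pd.DataFrame(cov_matrix, index=[s.sample_id for s in samples], columns=species),
        )
        tax = pd.DataFrame(
            {r: ["x"] * n_species for r in ("genus", "family", "order", "class", "phylum")},
            index=species,
        )
        return CohortTables(abundance=ab, taxonomy=tax)

    def test_ten_by_ten_rule(self):
        cov = np.zeros((12, 2))
        cov[:10, 0] = 12.0  # 10 samples at >= 10x -> retained
        cov[:9, 1] = 12.0   # only 9 -> excluded
        cohort = self._cohort_with_marker(cov)
        assert eligible_species(cohort) == ["sp0"]

    def test_empty_cohort(self):
        cohort = self._cohort_with_marker(np.zeros((0, 0)))
        assert eligible_species(cohort) == []


class TestRate:
    def test_simple_ratio(self):
        """1000 passing fourfold sites, 3 intermediate -> rate 0.003."""
        depth = np.full((1000, 1), 50)
        alt = np.zeros((1000, 1), dtype=int)
        alt[:3, 0] = 25
        snv = _snv(depth, alt)
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        rec = polymorphism_rate(snv, mask, "s0", "synonymous")
        assert rec.n_sites_passing == 1000 and rec.n_intermediate == 3
        assert rec.rate == pytest.approx(0.003)

    def test_fixed_sites_give_zero(self):
        depth = np.full((100, 1), 50)
        alt = np.zeros((100, 1), dtype=int)
        alt[50:, 0] = 50
        snv = _snv(depth, alt)
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        assert polymorphism_rate(snv, mask, "s0", "synonymous").rate == 0.0

    def test_window_bounds_inclusive(self):
        depth = np.full((2, 1), 10)
        alt = np.array([[2], [8]])  # f = 0.2 and 0.8 exactly
        snv = _snv(depth, alt)
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        assert polymorphism_rate(snv, mask, "s0", "synonymous").n_intermediate == 2

    def test_zero_denominator_marks_undefined(self):
        snv = _snv([[30]], [[0]], degeneracy=["onefold"])
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        rec = polymorphism_rate(snv, mask, "s0", "synonymous")
        assert not rec.defined and rec.rate is None

    def test_window_widening_monotone(self, rng):
        depth = rng.integers(20, 60, size=(300, 1))
        alt = rng.binomial(depth, 0.3)
        snv = _snv(depth, alt)
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        rates = [
            polymorphism_rate(snv, mask, "s0", "synonymous",
                              RunConfig(freq_lo=lo, freq_hi=1 - lo)).rate
            for lo in (0.3, 0.2, 0.1, 0.05)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_allele_relabeling_invariance(self, rng):
        depth = rng.integers(20, 60, size=(200, 1))
        alt = rng.binomial(depth, rng.uniform(0, 1, size=(200, 1)))
        snv = _snv(depth, alt)
        flipped = _snv(depth, depth - alt)
        mask = site_pass_mask(snv, core={"geneA"}, blacklist=set())
        r1 = polymorphism_rate(snv, mask, "s0", "synonymous")
        r2 = polymorphism_rate(flipped, mask, "s0", "synonymous")
        assert r1.n_intermediate == r2.n_intermediate


def test_two_strain_mixture_rate_matches_divergence():
    """A 50/50 two-strain mixture read at high depth has synonymous
    polymorphism rate equal to the strain divergence d (divergent sites sit
    at f = 0.5); the estimate lands within 3 Monte-Carlo SE."""
    d, L = 0.01, 20_000
    sim = md.simulate_strain_sample(2, (0.5, 0.5), d, L, 1e4, 0.0, seed=21)
    snv = sim.to_snv_matrix()
    mask = site_pass_mask(snv, core={"gene0000"}, blacklist=set())
    rec = polymorphism_rate(snv, mask, "s0", "synonymous")
    se = np.sqrt(d * (1 - d) / L)
    assert rec.rate == pytest.approx(d, abs=3 * se)


def test_single_strain_error_floor():
    """Sequencing error alone (ε ≤ 0.01 at depth ≥ 50) cannot push sites into
    the intermediate window: median synonymous rate < 1e-3."""
    rates = []
    for s in range(5):
        sim = md.simulate_strain_sample(1, (1.0,), 0.0, 5000, 60, 0.01, seed=100 + s)
        snv = sim.to_snv_matrix()
        mask = site_pass_mask(snv, core={"gene0000"}, blacklist=set())
        rates.append(polymorphism_rate(snv, mask, "s0", "synonymous").rate)
    assert np.median(rates) < 1e-3


def test_rate_tracks_heterozygosity_ranking(small_tables):
    """The windowed rate and mean 2f(1−f) rank samples almost identically
    (the 'quantitatively similar to heterozygosity' property)."""
    pairs = []
    for sp, snv in small_tables.snv.items():
        core = set(snv.sites["gene_id"])
        mask = site_pass_mask(snv, core=core, blacklist=set())
        for sid in filter_samples(snv):
            rec = polymorphism_rate(snv, mask, sid, "synonymous")
            het = heterozygosity(snv, mask, sid, "synonymous")
            if rec.defined and het is not None:
                pairs.append((rec.rate, het))
    rates, hets = zip(*pairs)
    assert len(pairs) > 30
    rho = spearmanr(rates, hets).statistic
    assert rho > 0.9


class TestChange:
    def _rec(self, rate_pair, sample, n=1000):
        return md.PolymorphismRecord("sp", sample, "synonymous", n, int(rate_pair * n))

    def test_delta_arithmetic(self):
        t1 = self._rec(0.004, "a")
        t2 = self._rec(0.006, "b")
        out = polymorphism_change(t1, t2, host_id="h1", delta_days=180)
        assert out.delta == pytest.approx(0.002)
        same = polymorphism_change(t1, t1, host_id="h1", delta_days=180)
        assert same.delta == 0.0

    def test_undefined_record_rejected(self):
        t1 = md.PolymorphismRecord("sp", "a", "synonymous", 0, 0)
        t2 = self._rec(0.004, "b")
        with pytest.raises(ValueError):
            polymorphism_change(t1, t2, host_id="h1", delta_days=10)

    def test_change_table_pairs_and_anchoring(self, small_tables):
        from microdiv.genes import core_genes, high_copy_exclusions

        core = {sp: core_genes(cn) for sp, cn in small_tables.genes.items()}
        high = {sp: high_copy_exclusions(cn) for sp, cn in small_tables.genes.items()}
        poly = polymorphism_table(small_tables, core, high)
        meta = small_tables.abundance.meta_frame()
        ch = polymorphism_change_table(poly, meta)
        assert (ch["delta_days"] > 0).all()
        np.testing.assert_allclose(ch["delta"], ch["rate_t2"] - ch["rate_t1"])
        first_only = polymorphism_change_table(poly, meta, anchor_first_only=True)
        assert len(first_only) <= len(ch)
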