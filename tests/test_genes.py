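"""Copy-number estimation, presence calling, and gain/loss counting."""

import numpy as np
import pandas as pd
import pytest

from microdiv import SimParams, simulate_cohort
from microdiv.genes import (
    ABSENT,
    AMBIGUOUS,
    PRESENT,
    call_presence,
    call_presence_frame,
    copy_number,
    core_genes,
    count_gains_losses,
    gain_loss_table,
    gene_prevalence,
    high_copy_exclusions,
)
from microdiv.tables import GeneCNMatrix


def _cn(coverage_rows, marker, genes=None):
    cov = np.atleast_2d(np.asarray(coverage_rows, dtype=float))
    n_genes, n_samples = cov.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    return GeneCNMatrix(
        species_id="spX",
        coverage=pd.DataFrame(cov, index=pd.Index(genes, name="gene_id"), columns=samples),
        marker_median=pd.Series(np.asarray(marker, dtype=float), index=samples),
    )


def test_copy_number_is_marker_normalized_ratio():
    assert copy_number(12.0, 24.0) == pytest.approx(0.5)
    assert copy_number(0.0, 24.0) == 0.0
    assert copy_number(10.0, 0.0) is None


def test_prevalence_window_and_marker_condition():
    """Prevalence counts samples with 0.3 ≤ c ≤ 3 among samples with marker
    coverage ≥ 5; a sample at marker 4 drops out of the denominator."""
    marker = [10, 10, 10, 10, 4]
    c_values = [0.5, 2.9, 3.1, 0.2, 1.0]
    coverage = [np.array(c_values) * np.array(marker)]
    cn = _cn(coverage, marker)
    prev = gene_prevalence(cn)
    assert prev["g0"] == pytest.approx(0.5)  # 2 of 4 eligible samples


def test_prevalence_all_ones():
    cn = _cn([[10, 10, 10]], [10, 10, 10])
    assert gene_prevalence(cn)["g0"] == 1.0


def test_prevalence_undefined_without_eligible_samples():
    cn = _cn([[10, 10]], [4, 3])
    assert gene_prevalence(cn).isna().all()


def test_core_gene_threshold_inclusive():
    """Prevalence exactly 0.90 is core ('at least 90%'); 0.89 is not."""
    marker = [10.0] * 100
    cov_core = np.full(100, 10.0)
    cov_core[:10] = 0.0  # c in window for 90 of 100
    cov_not = np.full(100, 10.0)
    cov_not[:11] = 0.0
    cn = _cn([cov_core, cov_not], marker, genes=["core", "almost"])
    assert core_genes(cn) == {"core"}


def test_high_copy_exclusion_threshold():
    cn = _cn([[10, 10, 32], [10, 29]+ [10]], [10, 10, 10], genes=["hot", "ok"])
    assert high_copy_exclusions(cn) == {"hot"}


def test_high_copy_empty_matrix():
    cn = _cn(np.zeros((0, 2)), [10, 10], genes=[])
    assert high_copy_exclusions(cn) == set()


class TestPresenceCalls:
    @pytest.mark.parametrize(
        "c, marker, state",
        [
            (0.04, 25, ABSENT),
            (0.7, 25, PRESENT),
            (0.7, 15, AMBIGUOUS),   # marker below the 20x presence floor
            (0.3, 25, AMBIGUOUS),   # the 0.05-0.6 ambiguous zone
            (1.3, 25, AMBIGUOUS),   # above single-copy range
            (0.04, 4, AMBIGUOUS),   # marker below any-call floor
            (0.05, 25, ABSENT),     # boundary: c <= 0.05
            (0.6, 20, PRESENT),     # boundaries inclusive
            (1.2, 20, PRESENT),
        ],
    )
    def test_threshold_partition(self, c, marker, state):
        cn = _cn([[c * marker]], [marker])
        assert call_presence(cn, "s0", "g0") == state

    def test_states_partition_exhaustively(self, rng):
        cov = rng.uniform(0, 40, size=(50, 8))
        marker = rng.uniform(0, 40, size=8)
        cn = _cn(cov, marker)
        frame = call_presence_frame(cn)
        assert set(np.unique(frame.to_numpy())) <= {PRESENT, ABSENT, AMBIGUOUS}
        c = cn.copy_number()
        absent_mask = frame.to_numpy() == ABSENT
        assert (c.to_numpy()[absent_mask] <= 0.05).all()
        present_mask = frame.to_numpy() == PRESENT
        cp = c.to_numpy()[present_mask]
        assert ((cp >= 0.6) & (cp <= 1.2)).all()


class TestGainLoss:
    def test_enumeration_example(self):
        t1 = pd.Series([PRESENT, ABSENT, PRESENT, AMBIGUOUS], index=list("abcd"))
        t2 = pd.Series([ABSENT, PRESENT, PRESENT, PRESENT], index=list("abcd"))
        rec = count_gains_losses(t1, t2)
        assert (rec.n_lost, rec.n_gained, rec.n_assayed) == (1, 1, 3)

    def test_identical_states_no_events(self):
        t = pd.Series([PRESENT, ABSENT, AMBIGUOUS], index=list("abc"))
        rec = count_gains_losses(t, t)
        assert rec.n_gained == 0 and rec.n_lost == 0

    def test_swapping_time_points_swaps_counts(self, rng):
        states = np.array([PRESENT, ABSENT, AMBIGUOUS])
        t1 = pd.Series(rng.choice(states, 60), index=[f"g{i}" for i in range(60)])
        t2 = pd.Series(rng.choice(states, 60), index=t1.index)
        a = count_gains_losses(t1, t2)
        b = count_gains_losses(t2, t1)
        assert (a.n_gained, a.n_lost) == (b.n_lost, b.n_gained)
        assert a.n_assayed == b.n_assayed


def _single_strain_params(**kw):
    """Deep single-strain cohort where community gene content is unambiguous."""
    base = dict(
        n_hosts=12,
        baseline_k_weights=(1.0,),
        max_strains=1,
        beta_dbd=0.0,
        reads_per_sample=20_000_000,
        n_species_pool=20,
        n_focal_species=4,
        sites_per_species=20,
        genes_per_species=60,
        seed=5,
    )
    base.update(kw)
    return SimParams(**base)


def test_planted_losses_recovered(small_truth):
    """Planted community-level gene losses at high marker coverage are
    recovered with high precision and recall."""
    tables, truth = simulate_cohort(_single_strain_params(base_loss_rate=3e-4))
    meta = tables.abundance.meta_frame()
    gl = gain_loss_table(tables.genes, meta)
    # truth: single strain, so community presence == the strain's presence
    true_losses = set()
    for (host, sp, t), pres in truth.gene_presence.items():
        if t == 0:
            continue
        prev = truth.gene_presence[(host, sp, t - 1)]
        for gi in np.flatnonzero(prev[0] & ~pres[0]):
            true_losses.add((host, sp, t, gi))
    # detected: reconstruct per-pair loss counts
    n_detected = gl.n_lost.sum()
    assert len(true_losses) >= 10
    # with clean coverage and marker >> 20x, counts should match closely
    assert abs(n_detected - len(true_losses)) <= max(2, 0.05 * len(true_losses))


def test_no_planted_events_no_false_calls():
    tables, truth = simulate_cohort(
        _single_strain_params(base_loss_rate=0.0, base_gain_rate=0.0, seed=9)
    )
    assert len(truth.events) == 0
    gl = gain_loss_table(tables.genes, tables.abundance.meta_frame())
    false_events = (gl.n_lost + gl.n_gained).mean()
    assert false_events < 0.5


def test_gain_loss_table_respects_exclusions(small_tables):
    gl = gain_loss_table(small_tables.genes, small_tables.abundance.meta_frame())
    assert (gl.n_gained + gl.n_lost <= gl.n_assayed).all()
    assert (gl.delta_days > 0).all()
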