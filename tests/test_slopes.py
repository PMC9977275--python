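"""Diversity-slope model fitting, family selection, and LRT inference."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from microdiv.slopes import (
    ModelSpec,
    drop_one_lrt,
    fit_cross_sectional,
    fit_temporal,
    null_model_comparison,
    signed_log,
    standardize,
)
from microdiv.synthetic import (
    simulate_gene_loss_dataset,
    simulate_strain_count_dataset,
)


class TestStandardize:
    def test_basic(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        x = np.random.default_rng(0).normal(size=50)
        z = standardize(x)
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            standardize([5, 5, 5])


def test_signed_log_is_odd_and_monotone():
    x = np.array([-1e-2, -1e-5, 0, 1e-5, 1e-2])
    y = signed_log(x)
    np.testing.assert_allclose(y, -y[::-1])
    assert (np.diff(y) > 0).all()


def test_strain_count_fit_recovers_slope_and_flags_overdispersion():
    df = simulate_strain_count_dataset(n_hosts=200, slope=0.5, alpha=0.5, seed=0)
    spec = ModelSpec(response="strain_count")
    fit = fit_cross_sectional(df, spec)
    assert fit.success
    assert fit.family in ("trunc_nb_linear", "trunc_nb_quadratic")
    assert fit.slope == pytest.approx(0.5, abs=0.1)
    assert fit.slope_ci[0] < fit.slope < fit.slope_ci[1]
    assert set(fit.diagnostics["family_aic"]) == {
        "trunc_poisson", "trunc_nb_linear", "trunc_nb_quadratic"
    }
    # forcing the equidispersed family onto NB data must show in the
    # Pearson overdispersion statistic
    forced = fit_cross_sectional(df, ModelSpec(response="strain_count", family="trunc_poisson"))
    assert forced.diagnostics["overdispersion"] > 1.3


@pytest.mark.parametrize("regime_slope", [0.5, -0.5])
def test_slope_sign_recovery_in_dbd_and_ec_regimes(regime_slope):
    """The fitted diversity slope matches the generating sign under both the
    DBD (+) and EC (−) regimes in every replicate cohort."""
    spec = ModelSpec(response="strain_count")
    for i in range(5):
        df = simulate_strain_count_dataset(
            n_hosts=200, slope=regime_slope, seed=300 + i
        )
        fit = fit_cross_sectional(df, spec)
        assert np.sign(fit.slope) == np.sign(regime_slope)


def test_flat_response_gives_null_slope():
    rng = np.random.default_rng(4)
    n = 600
    df = pd.DataFrame(
        {
            "shannon": rng.normal(2.5, 0.5, n),
            "read_count": rng.lognormal(np.log(5e6), 0.3, n),
            "strain_count": rng.integers(1, 4, n),
        }
    )
    fit = fit_cross_sectional(df, ModelSpec(response="strain_count"))
    se = (fit.slope_ci[1] - fit.slope_ci[0]) / (2 * 1.96)
    assert abs(fit.slope) < 2 * se


def test_lrt_power_at_large_n():
    df = simulate_strain_count_dataset(n_hosts=100, n_species=20, slope=1.0, seed=2)
    fit = fit_cross_sectional(df, ModelSpec(response="strain_count"))
    r = drop_one_lrt(fit, "shannon")
    assert r.p_value < 1e-6
    nc = null_model_comparison(fit)
    assert nc["delta_aic"] > 0


def test_lrt_invariant_to_predictor_rescaling():
    df = simulate_strain_count_dataset(n_hosts=80, slope=0.3, seed=3)
    spec = ModelSpec(response="strain_count", family="trunc_poisson")
    r1 = drop_one_lrt(fit_cross_sectional(df, spec), "shannon")
    df2 = df.assign(shannon=7.0 * df["shannon"] + 3.0)
    r2 = drop_one_lrt(fit_cross_sectional(df2, spec), "shannon")
    assert r1.statistic == pytest.approx(r2.statistic, abs=1e-5)


def test_drop_of_nothing_is_identity():
    df = simulate_strain_count_dataset(n_hosts=50, seed=5)
    fit = fit_cross_sectional(df, ModelSpec(response="strain_count", family="trunc_poisson"))
    fit.term_columns["noop"] = []
    r = drop_one_lrt(fit, "noop")
    assert r.statistic == 0.0 and r.p_value == 1.0 and r.df == 0


def test_unknown_term_raises():
    df = simulate_strain_count_dataset(n_hosts=50, seed=5)
    fit = fit_cross_sectional(df, ModelSpec(response="strain_count", family="trunc_poisson"))
    with pytest.raises(KeyError):
        drop_one_lrt(fit, "not_a_term")


def test_beta_smooth_fit_for_polymorphism_rate():
    rng = np.random.default_rng(3)
    n = 600
    shannon = rng.normal(2.5, 0.6, n)
    z = standardize(shannon)
    mu = 1 / (1 + np.exp(-(-4 + 0.4 * z)))
    df = pd.DataFrame(
        {
            "shannon": shannon,
            "read_count": rng.lognormal(np.log(5e6), 0.3, n),
            "polymorphism_rate": rng.beta(mu * 60, (1 - mu) * 60),
        }
    )
    fit = fit_cross_sectional(df, ModelSpec(response="polymorphism_rate"))
    assert fit.success and fit.family == "beta_logit"
    assert fit.slope == pytest.approx(0.4, abs=0.1)
    r = drop_one_lrt(fit, "shannon")
    assert r.df >= 2 and r.p_value < 1e-6


def test_temporal_interaction_recovery_and_collinearity_failure():
    df = simulate_gene_loss_dataset(n_pairs=1500, gamma=0.5, seed=0)
    spec = ModelSpec(response="genes_lost", predictor="shannon_t1", interaction_with_lag=True)
    fit = fit_temporal(df, spec)
    assert fit.success and fit.family in ("nb_linear", "nb_quadratic")
    assert fit.params["shannon_t1"] > 0
    assert "shannon_t1:log_lag" in fit.term_columns
    # a single common lag value makes the temporal terms inestimable
    degenerate = df.assign(delta_days=100)
    bad = fit_temporal(degenerate, spec)
    assert not bad.success
    assert "delta_days" in bad.failure_reason or "collinear" in bad.failure_reason


def test_polymorphism_change_uses_gaussian_on_signed_log():
    rng = np.random.default_rng(9)
    n = 400
    df = pd.DataFrame(
        {
            "shannon_t1": rng.normal(2.5, 0.6, n),
            "delta_days": rng.integers(20, 300, n),
            "read_count": rng.lognormal(np.log(5e6), 0.3, n),
            "polymorphism_change": rng.normal(0, 1e-4, n),
        }
    )
    spec = ModelSpec(response="polymorphism_change", predictor="shannon_t1",
                     interaction_with_lag=True)
    fit = fit_temporal(df, spec)
    assert fit.success and fit.family == "gaussian_log_response"
    r = drop_one_lrt(fit, "shannon_t1:log_lag")
    assert 0 <= r.p_value <= 1


def test_multiple_random_effects_reported_unsupported():
    df = simulate_strain_count_dataset(n_hosts=30, seed=1)
    spec = ModelSpec(response="strain_count", random_effects=("host_id", "species_id"))
    fit = fit_cross_sectional(df, spec)
    assert not fit.success and "one random-intercept" in fit.failure_reason


def _make_re_dataset():
    rng = np.random.default_rng(10)
    df = simulate_strain_count_dataset(n_hosts=100, n_species=10, slope=0.5, seed=9)
    u = rng.normal(0, 0.4, 100)
    hostidx = np.repeat(np.arange(100), 10)
    zc = standardize(df["shannon"].to_numpy())
    mu = np.exp(0.3 + 0.5 * zc + u[hostidx])
    y = np.zeros(len(mu), dtype=int)
    todo = np.ones(len(mu), bool)
    while todo.any():
        y[todo] = rng.poisson(mu[todo])
        todo &= y == 0
    return df.assign(strain_count=y)


def test_random_intercept_recovers_group_variance():
    df = _make_re_dataset()
    spec = ModelSpec(response="strain_count", random_effects=("host_id",),
                     family="trunc_poisson")
    fit = fit_cross_sectional(df, spec)
    assert fit.success
    assert 0.15 < fit.random_effect_sd < 0.6  # true sigma_u = 0.4
    assert fit.slope == pytest.approx(0.5, abs=0.15)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_random_intercept_matches_glmmtmb(tmp_path):
    """Independent cross-check: the Gauss-Hermite truncated-Poisson mixed
    model reproduces glmmTMB's coefficients and random-effect SD."""
    df = _make_re_dataset()
    spec = ModelSpec(response="strain_count", random_effects=("host_id",),
                     family="trunc_poisson")
    fit = fit_cross_sectional(df, spec)
    out = df.assign(
        z=standardize(df["shannon"].to_numpy()),
        zr=standardize(np.log(df["read_count"].to_numpy())),
    )
    data_path = tmp_path / "d.tsv"
    out.to_csv(data_path, sep="\t", index=False)
    script = f"""
    suppressMessages(library(glmmTMB))
    d <- read.delim('{data_path}')
    m <- glmmTMB(strain_count ~ z + zr + (1|host_id), family=truncated_poisson, data=d)
    co <- fixef(m)$cond
    sd_u <- attr(VarCorr(m)$cond$host_id, 'stddev')
    cat(co[['(Intercept)']], co[['z']], co[['zr']], sd_u, sep='\\n')
    """
    res = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert res.returncode == 0, res.stderr
    icpt, b_z, b_zr, sd_u = (float(x) for x in res.stdout.strip().splitlines()[-4:])
    assert fit.params["Intercept"] == pytest.approx(icpt, abs=2e-3)
    assert fit.params["shannon"] == pytest.approx(b_z, abs=2e-3)
    assert fit.params["read_count"] == pytest.approx(b_zr, abs=2e-3)
    assert fit.random_effect_sd == pytest.approx(sd_u, abs=5e-3)
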