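"""Within-sample strain-number inference by discrete-genotype mixtures.

A sample's reads at S biallelic sites are modeled as a mixture of K strain
genotypes g ∈ {0,1}^(K×S) with frequencies π on the simplex and a symmetric
per-read error rate ε: at site s the expected alternate-allele fraction is
p̃_s = (1−ε)·p_s + ε·(1−p_s) with p_s = Σ_k π_k g_ks, and the observed
alternate count is Binomial(D_s, p̃_s). The likelihood is maximized by
alternating (i) an exact per-site genotype-column argmax over all 2^K
patterns and (ii) bounded continuous maximization over (π, ε), from several
random restarts. K ∈ {1..4} is selected by BIC = −2·logL + ν·ln(S) with
ν = (K−1) + K·S + 1 (simplex + genotype bits + error), ties toward smaller K.

Input sites are multi-allelic positions (1 ≤ alt ≤ D−1) with depth ≥ 20;
species/sample pairs with fewer than 100 such sites are not analyzable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp

from .config import RunConfig, DEFAULT_CONFIG
from .tables import SNVMatrix

_P_CLIP = 1e-12


@dataclass
class StrainSiteSet:
    """Sites passed to the mixture fit for one (species, sample) pair."""

    species_id: str
    sample_id: str
    site_ids: np.ndarray
    depth: np.ndarray      # int, all >= min_depth
    alt_count: np.ndarray  # int, 1 <= alt <= depth-1 for multi-allelic input

    @property
    def n_sites(self) -> int:
        return len(self.depth)


@dataclass
class StrainModelFit:
    """One fitted K-strain mixture, in canonical (descending-π) order.

    ``logL``/``n_params``/``bic`` are the profile (classification)
    likelihood quantities of the alternating optimizer, with every genotype
    bit counted as a parameter: ν = (K−1) + K·S + 1. ``logL_marginal`` /
    ``bic_marginal`` come from the latent-genotype mixture refinement
    (genotype columns integrated out under per-strain Bernoulli site
    frequencies, ν = 2K); model selection uses the marginal criterion by
    default because the profile criterion's ν grows with S and provably
    under-selects K (see docs).
    """

    species_id: str
    sample_id: str
    K: int
    genotypes: np.ndarray  # (K, S) uint8
    freqs: np.ndarray      # (K,) descending, sums to 1
    eps: float
    logL: float
    n_params: int
    bic: float
    n_restarts_used: int
    seed: int
    logL_marginal: float = np.nan
    n_params_marginal: int = 0
    bic_marginal: float = np.nan
    site_freq: np.ndarray | None = None  # per-strain alt-allele fraction q_k
    converged: bool = True


def select_sites(
    snv: SNVMatrix,
    sample_id: str,
    config: RunConfig = DEFAULT_CONFIG,
) -> StrainSiteSet | None:
    """Multi-allelic sites (1 ≤ alt ≤ D−1) with depth ≥ 20 for one sample.

    Returns None (not analyzable) when the pair has fewer than 100
    qualifying sites. With ``count_floor_multiallelic_only=False`` the
    100-site floor instead counts all sites at ≥ 20× while the fit still
    uses only the multi-allelic ones.
    """
    d = snv.depth[sample_id].to_numpy()
    a = snv.alt_count[sample_id].to_numpy()
    deep = d >= config.strain_min_depth
    multi = deep & (a >= 1) & (a <= d - 1)
    n_floor = int(multi.sum()) if config.count_floor_multiallelic_only else int(deep.sum())
    if n_floor < config.strain_min_sites:
        return None
    return StrainSiteSet(
        species_id=snv.species_id,
        sample_id=sample_id,
        site_ids=snv.depth.index.to_numpy()[multi],
        depth=d[multi].astype(np.int64),
        alt_count=a[multi].astype(np.int64),
    )


def _patterns(K: int) -> np.ndarray:
    """All 2^K binary genotype columns, ordered by number of alternate
    alleles then lexicographically — so argmax ties resolve toward the
    sparser pattern, deterministically."""
    pats = np.array(list(product((0, 1), repeat=K)), dtype=np.int8)
    order = np.lexsort((*(pats[:, k] for k in range(K - 1, -1, -1)), pats.sum(axis=1)))
    return pats[order]


def _loglik_terms(a, d):
    return gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)


def _pattern_loglik(pats: np.ndarray, pi: np.ndarray, eps: float, a, d, logc):
    """(P, S) matrix of per-site log-likelihoods under each genotype column."""
    p = pats @ pi
    pt = np.clip((1 - eps) * p + eps * (1 - p), _P_CLIP, 1 - _P_CLIP)
    return logc + np.outer(np.log(pt), a) + np.outer(np.log1p(-pt), d - a)


def site_set_loglik(
    sites: StrainSiteSet, genotypes: np.ndarray, pi: np.ndarray, eps: float
) -> float:
    """Exact binomial log-likelihood of a full parameterization."""
    a, d = sites.alt_count, sites.depth
    p = genotypes.T @ pi
    pt = np.clip((1 - eps) * p + eps * (1 - p), _P_CLIP, 1 - _P_CLIP)
    return float(np.sum(_loglik_terms(a, d) + a * np.log(pt) + (d - a) * np.log1p(-pt)))


def _continuous_step(pats, A, B, pi0, eps0, eps_max):
    """Maximize logL over (π on the simplex, ε in [0, eps_max]) for a fixed
    genotype assignment.

    Sites sharing an assigned pattern are collapsed to sufficient statistics
    A (alt reads) and B (ref reads) per pattern, so the objective has at
    most 2^K terms. π is parameterized by softmax, ε by a scaled sigmoid.
    Returns (π, ε, logL_term) where logL_term omits the binomial constants.
    """
    K = pats.shape[1]
    used = np.flatnonzero(A + B > 0)
    pu = pats[used].astype(float)
    Au, Bu = A[used], B[used]

    def unpack(theta):
        if K > 1:
            z = np.concatenate([theta[: K - 1], [0.0]])
            z -= z.max()
            w = np.exp(z)
            pi = w / w.sum()
        else:
            pi = np.ones(1)
        eps = eps_max * expit(theta[-1])
        return pi, eps

    def negll_grad(theta):
        pi, eps = unpack(theta)
        p = pu @ pi
        pt = np.clip((1 - eps) * p + eps * (1 - p), _P_CLIP, 1 - _P_CLIP)
        f = -float(Au @ np.log(pt) + Bu @ np.log1p(-pt))
        dl_dpt = -(Au / pt - Bu / (1 - pt))          # (P,)
        g = np.empty_like(theta)
        if K > 1:
            dl_dpi = (1 - 2 * eps) * (pu.T @ dl_dpt)  # (K,)
            # softmax chain rule: dL/dθ_j = π_j (dL/dπ_j − Σ_k π_k dL/dπ_k)
            g[: K - 1] = (pi * (dl_dpi - pi @ dl_dpi))[: K - 1]
        dl_deps = float(dl_dpt @ (1 - 2 * p))
        g[-1] = dl_deps * eps * (1 - eps / eps_max)
        return f, g

    pi0 = np.clip(pi0, 1e-6, None)
    pi0 = pi0 / pi0.sum()
    theta0 = np.empty(K if K > 1 else 1)
    if K > 1:
        theta0[: K - 1] = np.log(pi0[:-1]) - np.log(pi0[-1])
    e0 = min(max(eps0, 1e-4), eps_max * (1 - 1e-4))
    theta0[-1] = np.log(e0 / (eps_max - e0))
    res = minimize(negll_grad, theta0, method="L-BFGS-B", jac=True,
                   options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9})
    pi, eps = unpack(res.x)
    return pi, float(eps), -float(res.fun)


def _marginal_em(
    pats: np.ndarray,
    a: np.ndarray,
    d: np.ndarray,
    logc: np.ndarray,
    pi: np.ndarray,
    eps: float,
    eps_max: float,
    n_em: int = 200,
    tol: float = 1e-6,
):
    """EM on the latent-genotype mixture: genotype columns integrated out.

    Each site's genotype column is latent with weights
    w(pattern) = Π_k q_k^{g_k} (1−q_k)^{1−g_k}, the per-strain alternate
    site frequencies q_k being free parameters — the product-Bernoulli
    structure matches independent per-site strain divergence. Maximizes the
    marginal likelihood over (π, ε, q); returns (logL, π, ε, q).
    """
    K = pats.shape[1]
    S = len(a)
    patsf = pats.astype(float)
    # start q at the profile fit's per-strain alternate fractions
    pmat0 = _pattern_loglik(pats, pi, eps, a, d, logc)
    assign0 = pmat0.argmax(axis=0)
    q = np.clip(patsf[assign0].mean(axis=0), 1e-4, 1 - 1e-4)
    ll_prev = -np.inf
    ll = -np.inf
    for _ in range(n_em):
        logw = patsf @ np.log(q) + (1 - patsf) @ np.log1p(-q)
        pmat = _pattern_loglik(pats, pi, eps, a, d, logc)
        lw = logw[:, None] + pmat
        norm = logsumexp(lw, axis=0)
        ll = float(norm.sum())
        r = np.exp(lw - norm)  # (P, S) responsibilities
        q = np.clip((r.sum(axis=1) @ patsf) / S, 1e-4, 1 - 1e-4)
        A = r @ a
        B = r @ (d - a)
        pi, eps, _ = _continuous_step(pats, A, B, pi, eps, eps_max)
        if ll - ll_prev < tol:
            break
        ll_prev = ll
    return ll, pi, eps, q


def fit_strain_model(
    sites: StrainSiteSet,
    K: int,
    seed: int,
    n_restarts: int = 10,
    tol: float = 1e-6,
    eps_max: float = 0.1,
    max_outer: int = 100,
    warm_start: StrainModelFit | None = None,
) -> StrainModelFit:
    """Fit the K-strain mixture by alternating maximization, best of
    ``n_restarts`` random initializations.

    Each restart draws π from the uniform simplex and genotypes from the
    per-site empirical frequencies, then alternates the continuous (π, ε)
    step with the exact per-site genotype argmax until the log-likelihood
    improves by less than ``tol``; logL is monotone within a restart. A
    ``warm_start`` fit with K−1 strains seeds one extra restart by splitting
    its largest-frequency strain (leaving the likelihood exactly unchanged),
    which makes the maximized logL non-decreasing in K.
    """
    if not 1 <= K <= 8:
        raise ValueError(f"K must be a small positive strain count, got {K}")
    a, d = sites.alt_count.astype(float), sites.depth.astype(float)
    if sites.n_sites == 0:
        raise ValueError("empty site set is not analyzable")
    logc = _loglik_terms(a, d)
    const = float(logc.sum())
    pats = _patterns(K)
    emp_f = a / d
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_restarts)]

    starts: list[tuple[np.ndarray, float, np.ndarray]] = []
    for rng in streams:
        pi = rng.dirichlet(np.ones(K))
        g = (rng.random((K, sites.n_sites)) < emp_f).astype(np.int8)
        starts.append((pi, 0.01, g))
    # deterministic grid starts guard against multimodality; tiny instances
    # (where the profile likelihood is most rugged) get a finer, boundary-
    # dense π grid. Top candidates are polished by the main loop.
    tiny = sites.n_sites <= 20
    if K > 1:
        if tiny:
            ticks = np.concatenate([[0.01, 0.02, 0.03], np.arange(0.05, 1.0, 0.05),
                                    [0.97, 0.98, 0.99]])
        else:
            ticks = np.arange(0.05, 1.0, 0.1)
        if K > 2:
            ticks = ticks[::2] if tiny else ticks
        grid_pis = [
            np.array(list(c) + [1.0 - sum(c)])
            for c in product(ticks, repeat=K - 1)
            if 1.0 - sum(c) >= min(ticks) - 1e-12
        ]
    else:
        grid_pis = [np.ones(1)]
    eps_grid = (0.0005, 0.002, 0.005, 0.01, 0.02, 0.05, 0.09) if tiny else (0.001, 0.01, 0.05)
    scored = []
    for gp in grid_pis:
        for ge in eps_grid:
            pmat = _pattern_loglik(pats, gp, ge, a, d, logc)
            scored.append((float(pmat.max(axis=0).sum()), gp, ge, pmat.argmax(axis=0)))
    scored.sort(key=lambda t: -t[0])
    for _, gp, ge, assign0 in scored[: (6 if tiny else 3)]:
        starts.append((gp, ge, pats[assign0].T.astype(np.int8)))
    if warm_start is not None and warm_start.K == K - 1 and K > 1:
        gw = np.vstack([warm_start.genotypes, warm_start.genotypes[0]])
        piw = np.concatenate([warm_start.freqs, [warm_start.freqs[0] / 2]])
        piw[0] /= 2
        starts.append((piw, warm_start.eps, gw.astype(np.int8)))

    best = None
    for pi, eps, g in starts:
        # map initial genotype columns onto the pattern list
        weights = 1 << np.arange(K)
        codes = {int(np.dot(pats[i], weights)): i for i in range(len(pats))}
        assign = np.array([codes[int(c)] for c in (weights @ g)], dtype=np.intp)
        ll_prev = -np.inf
        for _ in range(max_outer):
            # (π, ε) step on pattern-level sufficient statistics
            A = np.bincount(assign, weights=a, minlength=len(pats))
            B = np.bincount(assign, weights=d - a, minlength=len(pats))
            pi_new, eps_new, ll_cont = _continuous_step(pats, A, B, pi, eps, eps_max)
            pmat = _pattern_loglik(pats, pi, eps, a, d, logc)
            ll_old = float(pmat[assign, np.arange(sites.n_sites)].sum())
            if ll_cont + const > ll_old:
                pi, eps = pi_new, eps_new
            # genotype step: exact argmax over patterns per site
            pmat = _pattern_loglik(pats, pi, eps, a, d, logc)
            assign = np.argmax(pmat, axis=0)
            ll = float(pmat[assign, np.arange(sites.n_sites)].sum())
            if ll - ll_prev < tol:
                ll_prev = max(ll, ll_prev)
                break
            ll_prev = ll
        if best is None or ll_prev > best[0]:
            best = (ll_prev, pi, eps, assign)

    ll, pi, eps, assign = best

    # marginal refinement: integrate genotype columns out and polish (π, ε)
    ll_marg, pi_m, eps_m, q = _marginal_em(pats, a, d, logc, pi, eps, eps_max, tol=tol)
    # keep whichever point estimate profiles better (EM often sharpens π)
    pmat_m = _pattern_loglik(pats, pi_m, eps_m, a, d, logc)
    assign_m = pmat_m.argmax(axis=0)
    ll_m_prof = float(pmat_m[assign_m, np.arange(sites.n_sites)].sum())
    if ll_m_prof > ll:
        ll, pi, eps, assign = ll_m_prof, pi_m, eps_m, assign_m

    genotypes = pats[assign].T.astype(np.uint8)  # (K, S)
    order = np.argsort(-pi, kind="stable")
    genotypes = genotypes[order]
    pi = pi[order]
    q = q[order]
    S = sites.n_sites
    nu = (K - 1) + K * S + 1
    nu_marg = 2 * K  # (K−1) frequencies + K site-frequencies + error
    return StrainModelFit(
        species_id=sites.species_id,
        sample_id=sites.sample_id,
        K=K,
        genotypes=genotypes,
        freqs=pi,
        eps=eps,
        logL=ll,
        n_params=nu,
        bic=-2.0 * ll + nu * np.log(S),
        n_restarts_used=len(starts),
        seed=seed,
        logL_marginal=ll_marg,
        n_params_marginal=nu_marg,
        bic_marginal=-2.0 * ll_marg + nu_marg * np.log(S),
        site_freq=q,
    )


def infer_strain_number(
    sites: StrainSiteSet,
    seed: int,
    config: RunConfig = DEFAULT_CONFIG,
) -> StrainModelFit:
    """Fit K = 1..K_max and return the BIC-optimal fit (ties toward smaller
    K). Successive K values warm-start from the previous best fit, which
    keeps the maximized logL non-decreasing in K.

    Selection uses the marginal-likelihood BIC by default
    (``config.strain_selection``); the profile-likelihood BIC with
    genotype-bit counting is available as ``"profile_bic"``.
    """
    key = {"marginal_bic": lambda f: f.bic_marginal, "profile_bic": lambda f: f.bic}[
        config.strain_selection
    ]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.strain_k_max)]
    best = None
    prev = None
    for K in range(1, config.strain_k_max + 1):
        fit = fit_strain_model(
            sites,
            K,
            seed=seeds[K - 1],
            n_restarts=config.strain_n_restarts,
            tol=config.strain_tol,
            eps_max=config.strain_eps_max,
            warm_start=prev,
        )
        prev = fit
        if best is None or key(fit) < key(best):
            best = fit
    return best


def brute_force_loglik(
    sites: StrainSiteSet,
    K: int,
    pi_step: float = 0.01,
    eps_step: float = 0.005,
    eps_max: float = 0.1,
) -> float:
    """Global maximum log-likelihood by exhaustive grid enumeration.

    Independent oracle for tiny instances: every genotype matrix is covered
    implicitly because, for fixed (π, ε), sites are independent and the best
    matrix is the per-site best pattern; (π, ε) run over a full grid
    (π components on a ``pi_step`` simplex grid, ε on an ``eps_step`` grid
    in [0, eps_max]). Exact up to grid resolution.
    """
    a, d = sites.alt_count.astype(float), sites.depth.astype(float)
    logc = _loglik_terms(a, d)
    pats = _patterns(K)
    eps_grid = np.arange(0.0, eps_max + eps_step / 2, eps_step)
    if K == 1:
        pi_list = [np.array([1.0])]
    else:
        ticks = np.arange(pi_step, 1.0, pi_step)
        pi_list = []
        for combo in product(ticks, repeat=K - 1):
            last = 1.0 - sum(combo)
            if last >= pi_step - 1e-12:
                pi_list.append(np.array(list(combo) + [last]))
    best = -np.inf
    for pi in pi_list:
        for eps in eps_grid:
            pmat = _pattern_loglik(pats, pi, float(eps), a, d, logc)
            best = max(best, float(pmat.max(axis=0).sum()))
    return best


def strain_table(
    cohort, seed: int, config: RunConfig = DEFAULT_CONFIG, species: list[str] | None = None
):
    """BIC-optimal strain fits for every analyzable (species, sample) pair.

    Returns a DataFrame with one row per pair: K, frequencies, ε, logL, BIC
    and the number of sites used; non-analyzable pairs are omitted.
    """
    import pandas as pd

    rows = []
    ss = np.random.SeedSequence(seed)
    species = species if species is not None else sorted(cohort.snv)
    for sp in species:
        snv = cohort.snv[sp]
        for sid, sub in zip(snv.depth.columns, ss.spawn(len(snv.depth.columns))):
            sites = select_sites(snv, sid, config)
            if sites is None:
                continue
            fit = infer_strain_number(
                sites, seed=int(sub.generate_state(1)[0] % (2**31)), config=config
            )
            rows.append(
                {
                    "species_id": sp,
                    "sample_id": sid,
                    "K": fit.K,
                    "freqs": ",".join(f"{x:.4f}" for x in fit.freqs),
                    "eps": fit.eps,
                    "logL": fit.logL,
                    "bic": fit.bic,
                    "n_sites": sites.n_sites,
                }
            )
    return pd.DataFrame(
        rows, columns=["species_id", "sample_id", "K", "freqs", "eps", "logL", "bic", "n_sites"]
    )
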