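# Methods

`microdiv` implements an eco-evolutionary analysis of gut-microbiome
metagenomes: per-sample community diversity, within-species SNV polymorphism,
within-sample strain-number deconvolution, longitudinal gene gain/loss, and
the hierarchical "diversity slope" models that link the community level to
the intra-species level. It consumes MIDAS-style merged tables (species
relative abundances with marker-gene coverage, per-species site × sample
depth/alternate-count matrices with degeneracy annotations, gene × sample
coverage matrices, a taxonomy table, a gene blacklist, sample metadata) and
ships a synthetic-cohort generator with recorded ground truth so that every
stage is testable without external data.

## Community diversity

Shannon diversity is −Σ pᵢ ln pᵢ over taxa with positive relative abundance
(natural-log units, the vegan `diversity` default); richness counts taxa with
abundance > 0, with no extra coverage threshold — the upstream table
construction already applies a marker-coverage rule. Rarefied richness
subsamples exactly `depth` reads without replacement (multivariate
hypergeometric) from per-species read counts derived as
round(relative abundance × sample read count); samples with fewer total reads
than the depth are excluded, never upsampled. The closed form
E[S] = Σᵢ [1 − C(N−nᵢ, d)/C(N, d)] serves as the analytical oracle in tests.
Aggregation to genus…phylum sums member-species abundances, which preserves
row sums and can only decrease Shannon diversity (data-processing
inequality — asserted as a property test on simulated cohorts).

## Polymorphism rates

The polymorphism rate of a species in a sample is the fraction of assayed
sites of a degeneracy class (fourfold-degenerate ≈ synonymous, onefold ≈
nonsynonymous; "other" sites are carried but never assayed) whose
alternate-allele frequency f = alt/D lies in 0.2 ≤ f ≤ 0.8, bounds inclusive.
Assayed sites must sit in core genes (prevalence ≥ 90%, where prevalence is
the fraction of marker ≥ 5× samples with 0.3 ≤ c ≤ 3), outside the
multi-species blacklist and the high-copy exclusion set (c ≥ 3 in any
sample), and satisfy the per-sample coverage window 0.3·D̄ ≤ D ≤ 3·D̄, with
D̄ the sample's median depth over covered coding sites. Samples with D̄ < 5
are excluded, and species enter the analysis only with marker coverage ≥ 10
in ≥ 10 samples. The denominator includes monomorphic passing sites, making
the rate a per-assayed-site quantity; because the window is symmetric about
0.5, the rate is invariant under reference/alternate relabeling, and it ranks
samples nearly identically to mean heterozygosity 2f(1−f) (Spearman ρ > 0.9
on simulated cohorts). Temporal change is the within-host difference of rates
between an earlier and a later sample; by default every ordered pair is
formed (a switch restricts anchors to each host's first sample, since the
dense-time-series convention is ambiguous).

## Strain-number inference

Reads at S biallelic multi-allelic sites (1 ≤ alt ≤ D−1, D ≥ 20; pairs with
fewer than 100 such sites are not analyzable) are modeled as a K-strain
mixture: genotypes g ∈ {0,1}^{K×S}, frequencies π on the simplex, symmetric
per-read error ε ∈ [0, 0.1], alt_s ~ Binomial(D_s, p̃_s) with
p̃_s = (1−ε)p_s + ε(1−p_s), p_s = Σ_k π_k g_ks.

Fitting alternates (i) an exact per-site genotype-column argmax over all 2^K
patterns (ties broken toward fewer alternate alleles) with (ii) bounded
continuous maximization of (π, ε) — softmax/sigmoid parameterization,
analytic gradients, L-BFGS — on per-pattern sufficient statistics, until the
log-likelihood improves by < 1e-6. Ten random restarts (π uniform on the
simplex, genotypes from per-site empirical frequencies) are augmented by
deterministic coarse-grid starts over (π, ε) — finer and boundary-dense for
panels of ≤ 20 sites, where the profile likelihood is most rugged — and, for
K > 1, a warm start that splits the largest strain of the best (K−1)-fit,
which leaves the likelihood exactly unchanged and guarantees the maximized
logL is non-decreasing in K. On tiny instances the optimizer matches an
exhaustive genotype × (π 0.01-grid × ε 0.005-grid) enumeration to ~1e-10.

**Model-size selection.** K ∈ {1..4} is chosen by BIC, ties toward smaller
K. Two parameter-counting conventions are implemented. The *profile*
convention counts every genotype bit: ν = (K−1) + K·S + 1, so the penalty
per added strain grows as S·ln S. This is kept (`strain_selection =
"profile_bic"`) but is not the default: because the classification
likelihood's attainable gain per divergent site is bounded by the per-site
KL divergence (≈ 2–14 nats at 50× depth), an S·ln S penalty can provably
never select a third strain under realistic coverage — measured recovery on
200-site panels at 50× was 100/83/0% for K = 1/2/3. The default
(`"marginal_bic"`) instead treats each site's genotype column as a latent
variable with product-Bernoulli weights — strain k carries the alternate
allele at a site with its own frequency q_k, matching the independent-sites
divergence model — integrates it out by EM (initialized from the alternating
fit, (π, ε) updated on responsibility-weighted sufficient statistics), and
applies BIC to the marginal likelihood with ν = (K−1) + K + 1 = 2K free
continuous parameters. This is the textbook-consistent BIC for a finite
mixture and recovers 100/100/76% under the same conditions. Reported point
estimates (genotypes, π, ε) remain the profile-likelihood optimum; fits are
reported in canonical descending-π order.

## Gene dynamics

Copy number is c = gene coverage / median single-copy marker-gene coverage
(undefined where the marker median is ≤ 0). Presence calling is
deliberately conservative to avoid read stealing/donating between species:
absent iff c ≤ 0.05 (the Methods-style ≤ is used; a strict < differs on a
measure-zero set), present iff 0.6 ≤ c ≤ 1.2 with marker coverage ≥ 20×, and
everything else — the 0.05–0.6 gap, c > 1.2, marker below 20× for presence
or below 5× for any call — is ambiguous. Gains are absent→present and losses
present→absent between two time points of one host; transitions touching an
ambiguous call at either end are excluded from both the counts and the
assayed denominator, so swapping the time points swaps gains and losses
exactly. Genes failing the blacklist or the c ≥ 3 exclusion never enter.
The marker ≥ 5 floor for *any* call (including absent) is this package's
choice: an absence claimed from a barely-covered sample is not evidence.

## Diversity-slope models

All predictors (diversity metric, log read count, log time lag) are
standardized to zero mean, unit sample SD (n−1); the reported "slope" is the
diversity effect on that standardized scale. Families follow the response:

- polymorphism rate → beta regression with logit link; the diversity term
  enters through an unpenalized cubic B-spline basis (default df = 4,
  recorded in every fit); 0/1 responses are nudged by (y(n−1)+0.5)/n. The
  scalar slope summary is the mean derivative of the fitted smooth with a
  delta-method CI.
- strain count → zero-truncated Poisson, truncated NB1 (linear
  mean–variance) and truncated NB2 (quadratic), AIC-selected.
- gene gains/losses → NB1 / NB2, AIC-selected.
- polymorphism change → Gaussian on the signed-log transform
  sign(x)·log1p(|x|/1e-5), an odd, monotone map for a response spanning
  orders of magnitude in both signs.

Temporal fits add the log time lag and (optionally) its interaction with
diversity; a single common lag value is detected as rank deficiency and
returned as a named fit failure, never a silent fallback. Inference is by
drop-one likelihood-ratio tests (chi-square, one df per dropped design
column; a smooth term drops its whole basis) with the family held fixed at
the full model's AIC winner — Wald z-tests are never reported. A null-model
comparison (intercept + random effects only) reports ΔAIC and its LRT.

Random effects: one random-intercept grouping factor (species, host, or
sample) is supported through adaptive Gauss-Hermite marginal likelihood
(25 nodes) for every family; the fit matches glmmTMB's truncated-Poisson
mixed model to ~1e-3 on shared data (cross-checked in the test suite).
Crossed random factors (species + host + sample simultaneously) are out of
scope for this engine; requesting more than one grouping factor returns a
named failure. The fixed-effects path delegates to statsmodels
(TruncatedLFPoisson, TruncatedLFNegativeBinomialP, NegativeBinomialP,
BetaModel, OLS) with Poisson-GLM starting values.

## Synthetic cohorts

The generator emulates the data-generating structure the models assume, with
every draw flowing from one seed through named substreams (byte-identical
reruns). Communities are symmetric Dirichlet (concentration 0.6, an uneven
gut-like profile over an 80-species pool; focal species get a 20× weight
boost to play the "abundant, well-covered" role). Reads per sample default
to 5 × 10⁶ (the dense-time-series rarefaction depth) with 20% lognormal
spread; site depth is Poisson with mean abundance × reads × read length /
genome size (150 bp / 3 Mb defaults). Strain counts per (host, focal
species) follow a tilted distribution on {1..4} whose adjacent log-odds are
beta_dbd × standardized community Shannon (baseline weights
0.50/0.25/0.15/0.10, matching the observation that most hosts carry one or
two strains); genotypes flip sites independently at a rate giving expected
pairwise divergence d = 0.1 over the polymorphic panel; frequencies follow a
logistic-normal random walk (σ = 0.3) across visits. Alternate counts are
Binomial(D, p̃) with sequencing error ε = 0.01. Degeneracy labels are i.i.d.
fourfold 0.25 / onefold 0.70 / other 0.05. Gene content: 80% core genes
carried by all strains, accessory genes per strain with probability 0.5;
per-base gene coverage is marker median × true copy number × Gamma noise
(CV 8%); between visits each strain-level gene copy is lost with probability
1 − exp(−λ0·e^{γ·z}·Δdays) (λ0 = 10⁻⁴ per gene-day, so a ~2% per-gene loss
chance over a 6-month gap — a handful of losses per species, with occasional
large drops when a strain goes extinct) and absent genes are regained at
10⁻⁵ per day. A gene leaves the community only when no carrying strain
remains, so "de novo deletion" and "strain replacement" emerge from one
mechanism.

What the generator does **not** emulate: read mapping artifacts
(stealing/donating between species beyond the blacklist abstraction),
linkage between sites, selection, recombination, within-host phylogenies, or
compositional noise in abundance estimation. Passing tests therefore show
the estimators are correct under their own assumptions, not that real-data
biases are absent. Two observation-level generators (zero-truncated NB
strain counts with log-mean linear in standardized Shannon; NB loss counts
with mean n_genes·(1−exp(−λ0·e^{γz}·Δd))) drive the statistical-calibration
checks at exactly the scale the models see.

## Problem sizes and numerical choices

The acceptance suite uses 200 strain-recovery instances (uniform K ∈ {1,2,3},
200-site panels, depth Poisson(50), ε = 0.01, minimum strain frequency 0.15),
50 tiny brute-force instances, 20 000-site polymorphism oracles, 25-host
planted-event cohorts, 100 recovery + 400 null slope cohorts (200 hosts ×
20 species), and 50 + 200 Black-Queen cohorts (1000 pairs) — sizes chosen so
the whole suite runs on one CPU in minutes while keeping binomial test
noise well inside the asserted margins. The strain-recovery experiments run
the estimator with the 100-site eligibility floor relaxed, reading that
floor as a cohort-screening rule rather than part of the estimator (the
stated depth/error regime yields ~80–100 multi-allelic sites per panel).
Likelihood probabilities are clipped at 1e-12; the beta response at 1e-12;
ε is capped at 0.1.

## Known limitations

- The strain mixture treats sites as independent (no linkage or phasing) and
  is biallelic; multi-allelic (4-base) generalizations are out of scope.
- Crossed random effects require specialized software (e.g. glmmTMB); this
  engine fits one grouping factor at a time.
- The smooth basis is fixed-df regression splines, not penalized smooths
  with GCV/REML selection; df is recorded per fit.
- Observed community-level gene losses undercount strain-level losses in
  multi-strain hosts (a loss that removes one carrier of several leaves
  c in the ambiguous zone); analyses of loss counts therefore condition on
  callable transitions, as the thresholds intend.
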