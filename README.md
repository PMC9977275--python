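# microdiv

Eco-evolutionary analysis of gut-microbiome metagenomes: does community
diversity predict the genetic diversity *within* its member species?

Two opposing hypotheses frame the question. Under **diversity begets
diversity (DBD)**, diverse communities create niches that favor further
intra-species diversification — co-colonization by extra strains, elevated
nucleotide polymorphism. Under **ecological controls (EC)**, saturated niche
space suppresses it. A third process, the **Black Queen hypothesis**,
predicts that species shed genes whose products the surrounding community
supplies as leaky public goods, so gene *loss* should increase with
community diversity. `microdiv` turns these questions into a tested pipeline
over MIDAS-style shotgun-metagenomic tables, with a synthetic-cohort
generator carrying recorded ground truth so every stage can be validated
without any external download.

## What it computes

For each sample and taxonomic rank: Shannon diversity H′ = −Σ pᵢ ln pᵢ,
richness S, and hypergeometric rarefied richness. For each (species, sample):
the polymorphism rate — the fraction of assayed core-genome sites of a
degeneracy class with intermediate allele frequency 0.2 ≤ f ≤ 0.8, under
per-sample coverage filters (0.3·D̄ ≤ D ≤ 3·D̄, D̄ ≥ 5) — and the number of
strains K ∈ {1..4}, fitted by maximum likelihood over genotype mixtures

> alt_s ~ Binomial(D_s, (1−ε)·Σ_k π_k g_ks + ε·(1−Σ_k π_k g_ks))

with K selected by BIC. For each host × species pair of time points: gene
gains and losses from copy number c = coverage / marker-median (absent
c ≤ 0.05, present 0.6 ≤ c ≤ 1.2 at marker ≥ 20×). Finally the **diversity
slope**: regression of each intra-species response on standardized community
diversity — beta-logit smooths for rates, zero-truncated Poisson/NB (AIC
selected) for strain counts, NB for gain/loss counts, with read count as a
covariate, optional random intercepts, and drop-one likelihood-ratio tests.

## Worked example

`analysis/` holds the numbered pipeline over one simulated cohort (20 hosts,
two visits ~180 days apart, 5 focal species, planted DBD coupling
beta_dbd = +0.5 and Black-Queen coupling gamma_bq = +0.5):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_community_diversity.py
python analysis/03_polymorphism.py
python analysis/04_gene_dynamics.py
python analysis/05_strain_inference.py
python analysis/06_diversity_slopes.py
```

which prints (abridged):

```
wrote 40 samples, 5 focal species, 1.78 strains/host on average, 621 strain-level gene-loss events
240 diversity records; observed vs generating Shannon r = 1.0000
400 defined rates, 200 change pairs; median synonymous rate: single-strain 0.00e+00, multi-strain 1.04e-01
100 host × species pairs; called 161 losses and 0 gains; simulator planted 621 strain-level losses
200 analyzable pairs; inferred K matches truth in 94.5%; mean inferred K = 1.75
strain_count ~ shannon: slope +0.183 [0.024, 0.341] (trunc_poisson), LRT p = 0.0215
genes_lost ~ shannon(t1): effect -0.080 [-0.351, 0.191] (nb_linear), LRT p = 0.562
```

Reading: strain inference recovers the planted strain numbers from raw
allele counts in 94.5% of pairs; the fitted diversity slope on strain counts
is positive and significant, recovering the planted DBD coupling through the
whole pipeline. The gene-loss slope is masked here because multi-strain
carriage hides losses that remove only one carrier (copy number lands in the
ambiguous 0.05–0.6 zone) — the calibration experiments in the acceptance
suite isolate that effect on single-strain cohorts, where the planted +0.5
coupling is recovered. Tables land in `results/`.

A `microdiv` CLI wraps the same stages
(`microdiv simulate|diversity|polymorphism|genes|strains|slope`), each with
`--config`, `--seed`, `--out`.

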