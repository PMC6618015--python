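# Methods

## The problem

Males and females share a genome; an allele that raises fitness in one
sex and lowers it in the other experiences balancing selection and keeps
both variants at intermediate frequency. Two population-genomic readouts
separate the flavours of such conflict within a single population:
Tajima's *D* rises whenever intermediate-frequency variants are in
excess (conflict over reproduction or survival), while intersexual
F<sub>ST</sub> — allele-frequency divergence between adult males and
females of the same generation — rises only when genotypes affect
survival differently by sex. The package computes both from RNA-seq
data, contrasts them across gene classes defined by tissue- and
sex-biased expression, and relates the per-species signal to phenotypic
dimorphism on a phylogeny.

All sequence-level inference starts from genotype likelihoods rather
than genotype calls: at transcriptome sequencing depths, per-site depth
varies with expression level and hard calls would bias allele
frequencies. Uncertainty is carried through to the spectrum estimate and
the per-gene statistics.

## Sequence model

**Genotype likelihoods.** A read matching the derived allele arises from
a genotype with *g* ∈ {0,1,2} derived copies with probability
(g/2)(1−ε) + (1−g/2)(ε/3), where ε is the per-base error rate; the
likelihood triple is the product over reads, normalised to sum to one,
and flat when no reads cover the site. This per-read mixture form (the
standard GATK-style model) stands in for samtools-style genotype
likelihoods; the two agree in structure and differ only in error-rate
recalibration details that our generator does not emulate.

**SAF likelihoods.** The likelihood h(j) that j of the 2N sampled
chromosomes carry the derived allele is computed by the usual dynamic
programme: starting from w⁰ = [1], each individual convolves in its
genotype likelihood weighted by C(2, g), and h(j) = wᴺ(j)/C(2N, j),
rescaled to max 1 per site. This is exact (it equals brute-force
enumeration over all 3ᴺ genotype configurations, which the tests verify
to 1e−12 for N ≤ 3).

**SFS estimation.** The unfolded spectrum ξ over j = 0..2N is estimated
by EM: posteriors q_s(j) ∝ ξ_j h_s(j), then ξ ← mean_s q_s. The marginal
log-likelihood is tracked each iteration and is non-decreasing (asserted
in tests); convergence tolerance 1e−8, at most 200 iterations,
non-convergence flags the result rather than failing. An optional
stochastic initialisation (sampling one allele count per site from its
SAF likelihood) is available for parity with sampling-based estimators
but is strictly noisier and off by default; both starts reach the same
optimum on well-behaved data.

**Thetas and Tajima's D.** With posteriors as weights, each site
contributes P(variable) = 1 − post(0) − post(2N) to Watterson's
estimator (divided by a₁ = Σ 1/i) and E[j(2N−j)]/C(2N,2) to pairwise
diversity; per-gene values are sums over sites, and *D* uses the Tajima
(1989) normalisation with S replaced by the effective (posterior-
expected) number of segregating sites. When likelihoods are certain the
whole chain collapses to the classic textbook estimator exactly. The
nominal 2N is the number of informative chromosomes in the analysis
panel; per-site variation in N is not modelled.

**Chromosome classes.** Autosomes use all individuals. The Z chromosome
is diploid in male birds but haploid in females, so Z-linked genes are
analysed from male samples only; the spectrum is estimated separately
per chromosome class. Z-linked genes are excluded from intersexual
F<sub>ST</sub> entirely (no power with haploid females).

**Site filters.** Sites need data in at least half the individuals
(pooled for *D*; within each sex separately for F<sub>ST</sub>, so that
sex-limited genes survive). Base-quality (≥13) and mapping-quality (≥20)
filtering is an upstream responsibility recorded in provenance — the
BEAGLE input is assumed to be post-filter.

**Inbreeding.** Per-individual F is estimated by EM on the mixture prior
P(g | p, F) = (1−F)·HWE + F·{1−p, 0, p}; the E-step computes the
posterior identity-by-descent probability per site, the M-step averages
it. Deep-coverage recovery of a planted F = 0.3 is within ±0.05.

## Intersexual F_ST

Per site and sex, the ML allele frequency maximises the HWE-mixture
likelihood of the genotype triples; the public single-site function uses
bounded scalar search (tolerance 1e−6) and the batch path uses the
equivalent EM update run from two starts (0.1 and 0.9), keeping the
higher-likelihood solution because the marginal likelihood can be
bimodal in p for weakly informative sites. Hudson's components are
combined per gene as a ratio of sums — not a mean of per-site ratios —
which is the small-sample-robust form; genes whose total component is
zero have undefined F_ST. The elevated-F_ST count test takes the
expected number of focal-class genes with F_ST > 0 from the background
fraction and computes a 2×2 chi-squared (class × sign, df = 1, no
continuity correction). A one-sample goodness-of-fit against the fixed
expectation would be the main alternative construction; the 2×2 form
was chosen because it accounts for sampling error in the background
fraction, and it is exactly calibrated under class exchangeability,
which the null tests confirm. Strictly positive F_ST defines "elevated"; sex-biased genes are
removed from this test by the pipeline (their elevated F_ST reflects
sex-specific architecture, not survival selection).

## Expression classification

Counts are TMM-normalised (trim 30% on M, 5% on A, precision-weighted
mean of M, reference = sample with most typical upper quartile, factors
rescaled to geometric mean 1; verified against edgeR's implementation).
Classification fold changes are computed on TMM-scaled CPM with a
pseudo-expression offset of 1 CPM so that sex-limited genes are retained
with large finite fold changes; CPM vs FPKM for this step is a free
choice (the filter threshold is FPKM-based, the fold changes CPM-based
here). Tissue bias (|log2 FC| ≥ 2, gonad vs spleen) is called within one
sex — the gonad is transcriptionally dimorphic, and pooling sexes would
penalise sex-limited genes — males by default, females via a switch.
Z-linked genes are classified in a separate pass (avian dosage
compensation is incomplete, so pooling them with autosomes would shift
the fold-change distribution). Sex bias (|log2 FC| ≥ 1, male vs female)
is called within each tissue. Thresholds are inclusive so boundary cases
are deterministic. The genes-below-2-FPKM filter removes a gene when at
least ceil(n/2) individuals fall below threshold in either tissue. No
significance screen accompanies the fold-change rules (the rule set is
fold-change-only by design).

Reciprocal-best-hit orthologue selection filters hits at e-value ≤ 1e−10
and identity ≥ 30%, takes the highest bitscore per query, breaks ties by
identity, discards queries with unresolvable ties, and retains mutual
best pairs. Immune/MHC-flagged genes are removed before all conflict
statistics (heterozygote advantage in immunity mimics the balancing
signal).

## Gene-class statistics

Relative Tajima's *D* is the class median minus the non-tissue-biased
median — a difference, not a ratio (the difference is what the
comparative analysis regresses, and it removes the species-level
demographic location of *D*). Contrasts use the two-sided Wilcoxon
rank-sum test, exact when both samples are ≤ 25 and tie-free. The
covariate regression is OLS with tissue class categorical (reference:
non-tissue-biased) and log-transformed θ_W, gene length, GC and mean
expression; zeros in a covariate are offset by its smallest positive
observed value. Top-quantile flags use the type-7 (linear interpolation)
empirical quantile with inclusive ties; "universal" means flagged in
every species. Permutation enrichment draws same-size classes without
replacement; the empirical p is two-sided by distance from the
permutation mean with the +1 correction (never exactly zero), and a
df = 1 chi-squared against the permutation-mean expectation is reported
alongside (the permutation p is the primary quantity; the chi-squared
matches the way such results are conventionally reported). The
Z-subsampling test draws autosomal focal genes down to each species' Z
count, recomputes relative *D* and the cross-species Pearson r and OLS
slope per replicate, and reports one-sided p-values (fraction of
replicates at or below the observed Z value, ties counted) — one-sided
because the question is specifically whether the Z relationship is
weaker than gene numbers alone explain.

No multiple-testing correction is applied across species by default;
per-species tests are reported individually.

## Comparative analysis

PGLS assumes residuals covary as Brownian motion on the phylogeny:
V_ij = depth of the most recent common ancestor of tips i and j, with
Pagel's λ multiplying the off-diagonal entries only (tip depths stay on
the diagonal). λ is estimated by maximising the profile likelihood on
[0, 1] by bounded scalar search (tolerance 1e−6, boundary candidates
checked explicitly), or fixed. Estimation is ML, not REML (a switchable
convention; ML keeps the profile likelihood comparable across λ and
matches the small-n use here). The slope p-value is a t-test with n − 2
degrees of freedom; r² is computed in the V^(−1/2)-whitened space
against the GLS intercept-only fit (the exact r² convention of
comparative packages is not standardised; this one is stated so it can
be compared). On an ultrametric tree, λ = 0 makes V proportional to the
identity and the fit reduces to OLS exactly (verified to 1e−10); a
cross-check against R's `nlme::gls` + `ape::corBrownian` agrees to
1e−6.

With six species the slope test has four degrees of freedom; the null
calibration below shows the test holds its nominal level even so.

## Synthetic data: what it emulates and what it does not

The generator produces the complete input set for a configurable number
of species: BEAGLE genotype likelihoods, counts, sample sheets,
annotation, a Newick tree and a trait table, plus truth labels for
recovery tests. Defaults mirror the targeted study design — six species,
five individuals per sex, gonad and spleen per individual — at desk
scale (200 genes × 30 sites by default; the acceptance battery uses
60–300 genes and 15–30 sites per gene, chosen so the full battery runs
in about a minute).

**Balancing selection as an SFS bump.** Rather than a coalescent with
selection, balanced genes draw site frequencies from neutral 1/j weights
multiplied by exp(−4·strength·(j/two_n − ½)²) — a bump at intermediate
frequency whose intensity directly controls the quantity *D* measures.
Strength 4 yields median per-gene *D* around +2 at 2N = 20 against ~0.15
for neutral genes (the small positive neutral offset reflects the
finite-granularity frequency draw plus posterior shrinkage, and is well
inside the ±0.3 neutrality band the tests enforce). Sampled genotypes
are Hardy–Weinberg (optionally inbred); sites are unlinked; the
ancestral allele is known (unfolded spectra), with folding available but
off by default.

**Which genes are balanced.** A configurable fraction (default 0.3) of
non-tissue-biased genes carries the balancing spectrum — ongoing
conflict sits in genes expressed similarly in both sexes, which is what
makes gonad-biased relative *D* negative (resolved conflict). When
`coupling` > 0, gonad-biased genes additionally receive a species-level
strength max(0, coupling·dichromatism + noise), planting the positive
relationship between gonadal relative *D* and dimorphism across species.
Dichromatism evolves as Brownian motion around a positive baseline
(+2.0) — it is a nonnegative plumage score, and a positive baseline
keeps the floor at zero from erasing the planted coupling; sperm number
and residual testes mass are 0.7-correlated satellites of the same axis.
The coupling noise (sd 0.25) makes the trait–strength link imperfect, as
any phenotypic proxy would be.

**Sequencing model.** Depth is Poisson per individual and site, scaled
by the gene's expression decile (0.55–1.45×) to emulate the
depth–expression coupling of transcriptome data; reads err at a flat
per-base rate (default 0.01); likelihood triples use exactly the model
the inference assumes. Real RNA-seq additionally has allele-specific
expression, splice-form effects, PCR duplicates and mapping biases —
none are modelled, so passing tests demonstrate correctness of the
inference under its own model, not robustness to those artefacts.

**Counts.** Negative binomial (dispersion 0.1 by default) around
2^(baseline + planted effects) × length/1kb × library factor, with
tissue effects of +3 log2 (safely above the 2.0 call threshold) and sex
effects of +2 log2 (above 1.0) — effect sizes are configuration, not an
empirical claim about any real transcriptome. Sample-count asymmetries
of real studies (missing tissues, removed relatives) are not emulated;
the design is balanced.

**Determinism.** A single integer seed drives everything; each stage
derives an independent stream from (seed, stage-name), so outputs are
bit-for-bit reproducible and adding a stage never shifts another
stage's draws. Pipeline reruns with the same config are byte-identical
(fixed float formatting, no timestamps in the manifest).

## Numerical and design choices

- SAF recursion rescales per individual to avoid underflow; the final
  vector is max-normalised per site (only ratios matter downstream).
- EM tolerances: SFS 1e−8/200 iterations; allele-frequency EM 1e−8 with
  an active-set update (converged sites drop out); inbreeding 1e−6.
- Allele-frequency estimates are clipped to [1e−9, 1 − 1e−9]; flat-
  likelihood sites are flagged uninformative (NaN) and skipped.
- Tajima's *D* is NaN (missing), not an error, when S_eff = 0.
- Inbreeding coefficients enter the analysis only when estimated
  F > 0.05 (small estimated F is indistinguishable from noise at these
  sample sizes and would only perturb the SAF weights).
- BEAGLE triples that are exactly flat are treated as missing data on
  read-in; the generator writes flat triples for zero-depth sites, so
  the round trip preserves missingness.
- The χ² in the enrichment and F_ST count tests returns p = 1 for
  degenerate margins instead of dividing by zero.

## Known limitations

- Genotype-likelihood model ignores base-quality recalibration and
  strand/cycle error structure.
- Per-gene *D* uses a single nominal 2N; genes with heavy site-level
  missingness are summarised slightly optimistically.
- The SFS bump is a phenomenological stand-in for balancing selection;
  it makes no prediction about linked diversity or haplotype structure.
- PGLS supports a single predictor per fit (the analyses here are
  single-proxy regressions); no OU or other correlation structures.
- With six species, comparative power is intrinsically low; the package
  reports per-proxy fits without cross-proxy correction, as the analyses
  it implements do.
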