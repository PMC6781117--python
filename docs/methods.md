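# Methods

`matesel` implements the statistical machinery of an MHC-based mate-choice
study in a pond-structured population of Chinese alligators (*Alligator
sinensis*): adults live in breeding ponds that are physically isolated from
one another, so every mating happens within a pond, and each adult carries
a 13-locus microsatellite genotype and genotypes at two biallelic MHC
class I exonic loci whose alleles have known coding sequences.

## Statistics

**Individual diversity indices** (module `diversity`). For an individual
typed at microsatellite loci with population allele frequencies
`p_{lk}`:

- Standardised heterozygosity `SH = PHt / mean(Ho_l)`, the proportion of
  the individual's typed loci that are heterozygous divided by the mean
  population *observed* heterozygosity of those same loci. The population
  mean of SH over fully typed individuals is ~1. The observed-Ho
  denominator follows the convention of the Genhet implementation cited in
  the mate-choice literature; an expected-heterozygosity denominator can be
  assembled from `allele_frequencies` if wanted.
- Heterozygosity by locus `HL = sum_h E_l / (sum_h E_l + sum_j E_l)` with
  `E_l = 1 - sum_k p_{lk}^2`, `h` running over the individual's homozygous
  typed loci and `j` over heterozygous ones. Range [0, 1], 0 = fully
  heterozygous.
- Internal relatedness `IR = (2H - sum f_i) / (2N - sum f_i)` with `H`
  homozygous loci, `N` typed loci and `f_i` the reference frequency of each
  of the `2N` carried allele copies. Range ~[-1, 1].
- `d2 = (1/n) sum_l ((i_a - i_b) / motif_l)^2`, the mean squared difference
  of the two allele lengths, expressed in repeat units by default
  (`unit="bp"` skips the motif division). The repeat-unit default is a
  deliberate reading of "length of the repeat motif"; the unit is recorded
  in output metadata because the two conventions differ by the squared
  motif length.
- `Ho`: proportion of MHC-heterozygous males in a declared male set. The
  reporting basis is unique breeding males (a male that sired several
  clutches counts once); a pair-weighted basis is available through the
  randomisation engine.
- Good-gene score `AF`: the sum of the reference-population frequencies of
  a male's two allele copies at an MHC locus, range [0, 2] (a homozygote
  for an allele at frequency p scores 2p). This definition reproduces the
  magnitude range of published observed values that exceed 1, which a plain
  frequency cannot; `carried_mean` halves it.

**Pair compatibility** (module `mhcdist`). With the female carrying
alleles A/a and the male B/b at one locus:

- `Nsa` = size of a maximum matching between the two 2-allele multisets
  (0, 1 or 2 copies shared).
- `AAdist = D(A,B) + D(A,b) + D(a,B) + D(a,b)` where D is the p-distance
  (proportion of differing aligned residues) between allele proteins; a
  Poisson-corrected variant `-ln(1-p)` is available. Alleles of one locus
  must be equal length — the package never aligns implicitly.
- `AAfunc.dist`: the same four-term sum with D replaced by the mean (over
  aligned sites) Euclidean distance between the two residues' five
  z-descriptor vectors. The z-scales are the five-factor physiochemical
  scores of the 87-amino-acid extended principal-property analysis
  (Sandberg and colleagues' five z-scales), shipped as
  `src/matesel/data/zscales.tsv`. The per-site mean (rather than sum) puts
  loci with different exon lengths on one scale; `normalize=False` gives
  the summed variant.

Pair statistics are computed and tested per locus; the two MHC loci are
never pooled by default.

**Pairwise relatedness** (module `relatedness`). Three moment estimators,
all referenced to a declared allele-frequency table (default: all adults,
both sexes, all ponds, including the focal dyad — the common Co-ancestry
convention):

- Queller-Goodnight: locus numerator
  `0.5(I_ac + I_ad + I_bc + I_bd) - p_a - p_b`, denominator
  `1 + I_ab - p_a - p_b`, summed over loci before dividing, then averaged
  over the two focal choices.
- Wang's joint-genotype estimator: each locus assigns the dyad to one of
  four similarity categories (identical genotypes / homozygote vs
  heterozygote carrying its allele / heterozygotes sharing one allele / no
  sharing). The category probabilities are linear in the two identity
  coefficients (Delta = both allele pairs IBD, phi = exactly one pair),
  with coefficients b-g that are polynomials in the allele-frequency power
  sums a2, a3, a4 (these coefficients were re-derived here and verified
  against exhaustive enumeration in the test suite). Loci are weighted by
  1/(2*a2 - a4) and the two coefficients solved by generalised least
  squares under the null multinomial covariance; `r = Delta + phi/2`. The
  GLS solution is computed numerically with a pseudo-inverse (biallelic
  loci make the third category impossible and the covariance singular).
- Lynch-Ritland: the regression estimator with its published locus weights
  `w_l = [(1+S_ab)(p_a+p_b) - 4 p_a p_b] / (2 p_a p_b)`, symmetrised
  across the focal choice.

Monomorphic loci are skipped (no information); loci missing in either
member are dropped pairwise; a dyad with no informative locus returns an
undefined flag (`None`), never 0.

## The stratified randomisation null

The inference engine (`randomization`) compares the observed mean of a
statistic over the true mating pairs with its distribution over random
pairings. One null replicate draws, for each pond, as many pairs as that
pond has true mating pairs, each pair formed by drawing one female and one
male uniformly and independently *with replacement* from that pond's
candidates (all adult females/males of the pond). Replicate means pool the
ponds; 9999 replicates (default) form the null sample. Two quantities are
reported:

- the empirical two-tailed p-value with the add-one correction,
  `p = 2 min(#{null <= obs}+1, #{null >= obs}+1) / (n_iter+1)`, capped at
  1 (never exactly 0);
- the significance *decision* by the CI rule: observed outside the null's
  [2.5, 97.5] percentile band.

Male-mode statistics (AF, SH, d2) evaluate the statistic on the male of
each sampled pair, so males are weighted by pond pair counts, matching the
observed side (mean over the true pairs' males). `Ho` instead uses the
unique-male basis on *both* sides: the observed value is the heterozygote
fraction among distinct breeding males, and each null replicate computes
the same fraction over the distinct males it sampled. Using a pair-weighted
null against a unique-male observation would shrink the observed spread
relative to the null and make the CI rule conservative; the matched basis
keeps the type-I rate at the nominal 5% (verified by the calibration test).

True pairs are de-duplicated to unique female x male pairs for pair
statistics (a pair observed in several seasons counts once); per-clutch
weighting is available via `dedup_pairs=False`. No multiple-testing
correction is applied — the suite prints all 13 tests so readers can apply
their own; with 13 two-tailed tests per dataset, one borderline flag among
truly null statistics is expected about half the time.

Randomness: one numpy `Generator` per `randomize()` call draws all
replicate indices in a single vectorised pass, and the suite derives one
seed per statistic from the master seed, so a full run is reproducible
byte-for-byte from (data, config, seed). The exhaustive-enumeration
invariant (the null mean equals the pond-weighted mean of the statistic
over all within-pond female x male combinations) is asserted against an
independent enumeration on a toy design in the test suite.

## Reproductive success

`glmm` fits `count_ij ~ Poisson(exp(beta0 + beta_zyg z_i + u_i))`,
`u_i ~ N(0, sigma_u^2)`, for clutches j of male i, with z the male's MHC
zygosity (0 homozygote / 1 heterozygote, per locus by default; an
"heterozygous at >=1 locus" coding is a caller-side recode). The marginal
likelihood integrates u per male by the Laplace approximation (the lme4
default it mirrors); `nagq > 1` switches to adaptive Gauss-Hermite
quadrature centred at the per-male posterior mode. Optimisation is
Nelder-Mead polished by BFGS on (beta0, beta_zyg, log sigma_u); standard
errors come from the numerical Hessian and beta_zyg gets a Wald z-test.
When the optimum lands on the sigma_u = 0 boundary the fit falls back to
the constrained Poisson GLM (an internal IRLS solver), whose fixed-effect
SEs are exact for that model; the constrained fit is also the nested-model
check, matched in the tests against statsmodels GLM and an independent
Newton-Raphson oracle to 1e-6, and the free fit against R lme4::glmer to
~1e-3. Uncertainty for the class predictions `exp(beta0 + beta_zyg z)`
(conditional on u = 0) comes from a cluster bootstrap that resamples males
with replacement (default 10,000 resamples).

## Parentage audit

`parentage` checks assigned trios against Mendelian inheritance only: a
locus is consistent iff the offspring's two alleles can be split
one-from-mother, one-from-father (both orderings tried); a trio passes iff
mismatching loci <= `max_mismatch` (default 0, the rule for the two MHC
loci; a small positive tolerance absorbs the ~1% mistyping rate allowed on
microsatellite panels). Likelihood-based paternity assignment and sibship
reconstruction are external concerns and out of scope; no mutation or null
-allele model is attempted.

## Synthetic data generator

`simulate` produces study-shaped datasets with known truth. Defaults are
the study conditions: 3 ponds holding (41F+20M, 41F+20M, 41F+19M) — the
123/59 adult split allocated proportionally, since the true per-pond split
is not public — 13 microsatellite loci (4-10 alleles, Dirichlet(1)
founder frequencies, 2-4 bp motifs), 2 biallelic MHC loci with 270 bp
coding fragments, 11 founders, 105 clutches at Poisson rate 16 (~1684
offspring).

Design choices that matter for interpreting the tests:

- **Pedigree.** Adults are offspring of random founder x founder matings:
  they carry background relatedness (sib/half-sib structure through 11
  shared founders) but are themselves non-inbred. `pedigree=False` draws
  adults straight from the base frequencies (unrelated).
- **MHC assignment.** Adult MHC genotypes are drawn i.i.d. from the pond
  gene pool (HWE at the founder frequency, default common-allele frequency
  0.65) rather than inherited through the founder pedigree. With only ~30
  founder sibships, pedigree-inherited MHC would tie MHC zygosity to
  family-level microsatellite genotypes, so a purely MHC-targeted
  preference would mechanically drag SH and d2 with it; the i.i.d.
  assignment keeps "MHC preference with no genome-wide correlate" an
  expressible condition, which is the pattern the study design is meant to
  distinguish. Offspring inherit both panels Mendelian from their assigned
  parents, so parentage audits are unaffected. Consequence: passing tests
  demonstrate the statistics separate MHC-specific from genome-wide
  signals when they are separable; they do not quantify behaviour under
  strong identity disequilibrium.
- **Founder MHC frequency 0.65.** Both study loci segregate at skewed
  intermediate frequencies (published observed AF magnitudes ~1.27 and
  ~0.68 imply a common allele near 0.65-0.7). At exactly 0.5 the AF
  statistic degenerates (every heterozygote scores p+q = 1), so 0.65 is
  both the realistic and the numerically sensible default.
- **Mating.** Clutches are allocated to ponds proportionally to female
  counts (largest remainder). Each clutch draws its female uniformly with
  replacement — females can breed in several seasons, as in a multi-year
  study — and the female picks her male with probability proportional to
  `exp(beta * het(male) + gamma * AAfunc.dist(female, male))` (softmax over
  her pond's males; AAfunc.dist summed over MHC loci, het at a configurable
  locus). `beta = gamma = 0` is an exact uniform null, which also makes the
  true pairs i.i.d. draws from the very process the stratified null
  resamples — the property behind the 5% calibration of the CI rule.
- **Preference strengths for the power conditions.** The heterozygote
  condition uses beta = 2 (choice odds e^2 ~ 7.4 for heterozygous males).
  The compatibility condition uses gamma = 6: at the default allele
  divergence (amino-acid p-distance 0.05 per locus) one step of
  AAfunc.dist between male genotypes is ~0.47, so gamma * 0.47 ~ e^2.8
  gives a preference odds comparable to the beta condition. Both chosen
  once as the canonical strong-preference conditions.
- **MHC allele sequences** are random sense codons with a requested
  amino-acid p-distance realised exactly (k of n codons substituted to a
  different residue), so `AAdist` has a controlled true value.
- **Noise.** `noise_rate` mistypes each offspring allele with that
  probability (replacement from the locus allele pool), for audit power
  tests; adults are always error-free. There is no mutation model, no
  viability selection, no overlapping generations, and no missing-data
  generation (missingness is exercised by hand fixtures in the tests).

What the generator does *not* emulate of real data: genotyping error in
adults, null alleles, linkage, selection at MHC, inbreeding (identity
disequilibrium), and pond-specific allele frequencies. Tests passing on
these simulations validate the estimators and the inference machinery
under their stated assumptions, not robustness to those artefacts.

## Numerical conventions

- Undefined statistics (monomorphic denominators, untyped individuals)
  are `None`/flagged, never silently 0; the randomisation engine drops
  undefined pair values from a replicate's mean (NaN-aware) and reports
  means over what remains.
- Null-distribution percentiles use numpy's default (linear
  interpolation); significance requires the observed value strictly
  outside the band.
- Problem sizes in the checks: the calibration study uses 400 generated
  datasets at 999 replicates per statistic, the power studies 20 datasets
  per condition, relatedness oracles 500 dyads, and the reproductive-
  success recovery 40 males x 3 clutches — sizes at which the Monte-Carlo
  error of each assertion is comfortably inside its tolerance.
- Seeds: every stochastic entry point takes an explicit seed; derived
  seeds come from `numpy.random.SeedSequence` spawning or fixed offsets.

## Known limitations

- The AF (good-gene) definition is a reconstruction consistent with the
  published magnitudes, not a confirmed formula; it is config-switchable
  and excluded from any cross-study numerical comparison.
- Wang's estimator follows the derived moment model with GLS weighting
  (coefficients verified by enumeration); the original closed-form algebra
  was not available to transcribe term-by-term, so agreement with other
  implementations is established behaviourally (unbiasedness, correlation
  with the other estimators), not symbolically.
- The Poisson mixed model offers no overdispersion correction
  (negative-binomial) and a single binary predictor by design.
- Reading frame for MHC exon fragments defaults to 1 and is configurable
  per locus; real exon-3 amplicons may need a different frame or trimming
  before use.
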