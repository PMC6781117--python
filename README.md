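# matesel

Statistics for MHC-based mate-choice studies in pond-structured
populations, built around the Chinese alligator (*Alligator sinensis*)
semi-natural breeding system: adults live in physically isolated breeding
ponds, mate freely within a pond, and are genotyped at 13 microsatellite
loci and two biallelic MHC class I loci with known allele coding
sequences.

The package asks the three classical questions about female choice and
answers them with a stratified Monte-Carlo randomisation test:

- **Good genes** — do breeding males carry particular (common) MHC
  alleles? Statistic: AF, the summed reference-population frequency of a
  male's two allele copies at a locus.
- **Heterozygosity advantage** — are breeding males more heterozygous
  than chance, genome-wide (standardised heterozygosity SH, mean squared
  allele-length difference d²) or specifically at MHC (Ho, the fraction of
  heterozygous breeding males)?
- **Compatible genes** — are mates MHC-dissimilar? Pair statistics per
  locus: allele sharing Nsa ∈ {0,1,2}, amino-acid distance
  AAdist = D(A,B)+D(A,b)+D(a,B)+D(a,b) over the four inter-partner allele
  pairs (p-distance between allele proteins), and the physiochemical
  analogue AAfunc.dist built from Sandberg five-factor z-descriptor
  vectors (per-site Euclidean distance, averaged over the exon).

The null model mirrors the breeding design: for each pond, as many random
female × male pairs as there are true mating pairs, drawn uniformly with
replacement from that pond's adults; 9999 pooled replicate means form the
null, and an observed mean is significant when it falls outside the
two-tailed 95% CI (an add-one empirical p-value is reported alongside).
Inbreeding avoidance is tested the same way with Queller–Goodnight
relatedness (Wang and Lynch–Ritland estimators included), and male
reproductive success is modelled as
`Offspring_number ~ zygosity_status + (1|paternal_ID)` with a Poisson
GLMM (log link, Laplace-approximated likelihood, cluster bootstrap for
effect bands).

Everything runs end-to-end on a built-in synthetic population generator
with known ground truth (founder pedigree, tunable heterozygote and
compatibility preferences, Mendelian clutches), so the whole pipeline is
testable without any field data. `docs/methods.md` documents the models,
conventions and the generator's assumptions.

## Worked example

Simulate a study-scale population in which females prefer males
heterozygous at the first MHC locus (β = 2) and MHC-dissimilar mates
(γ = 6), then test all hypotheses:

```bash
python analysis/01_simulate_population.py   # writes results/data/
python analysis/02_parentage_audit.py
python analysis/03_hypothesis_tests.py
python analysis/04_relatedness_estimators.py
python analysis/05_reproductive_success.py
```

`03_hypothesis_tests.py` prints (seed 42):

```
         statistic  observed  null_mean  ci_low  ci_high      p  significant
         Ho_mhc_M1    0.5556     0.4233  0.3673   0.4792 0.0002         True
         Ho_mhc_M2    0.3889     0.4066  0.3478   0.4600 0.5614        False
                SH    0.9529     0.9524  0.9163   0.9883 0.9690        False
     AAdist_mhc_M1    0.1164     0.0824  0.0720   0.0923 0.0002         True
AAfunc.dist_mhc_M1    0.6879     0.4861  0.4301   0.5451 0.0002         True
        Nsa_mhc_M1    1.0300     1.2359  1.1048   1.3619 0.0020         True
               Rqg   -0.0102    -0.0067 -0.0516   0.0378 0.8920        False
```

(abridged; the full table has 13 rows). Reading it: breeding males are
heterozygous at the preferred locus far above the null band (Ho 0.56 vs
CI 0.37–0.48) but not at the other locus; mates are more MHC-dissimilar
than random (higher AAdist/AAfunc.dist, lower allele sharing); the
genome-wide index SH and pairwise relatedness sit inside their null bands
— the generated preference targeted MHC, and only MHC statistics fire.
The parentage audit passes 1684/1684 error-free trios, and the
reproductive-success fit on data simulated at (β₀ = 2.5, β_zyg = 0.3,
σ_u = 0.2) recovers β₀ = 2.45, β_zyg = 0.37 ± 0.07, σ_u = 0.15.

The same stages are available as a CLI (`matesel simulate | diversity |
mhcdist | relatedness | mendel | test | glmm | run`); `matesel run
--config cfg.yaml --out results/` executes the whole pipeline from a YAML
config, with figures and a reproducibility manifest.

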