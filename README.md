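# sweepkit

Population-genetics analysis of resequenced gene regions: site-class-aware
polymorphism and divergence estimation, frequency-spectrum neutrality tests
with coalescent-simulation null distributions, polymorphism–divergence
tests (multilocus HKA, McDonald–Kreitman), and a composite-likelihood
selective-sweep scan with a goodness-of-fit follow-up.

## Who it is for

The package targets the classic single-region resequencing design: a sample
of 10–12 aligned haplotypes from one species over a multi-kilobase region of
mixed coding/noncoding structure, plus one aligned outgroup sequence. The
motivating setting is a derived (European) *Drosophila melanogaster*
population with *D. simulans* as outgroup, where the scientific question is
whether a region's pattern of variation departs from neutrality, and if so
whether a recent selective sweep explains it better than the population's
bottleneck history.

## The statistics at its core

Per functional class (synonymous, nonsynonymous, intronic, silent = 
synonymous + noncoding, total) with NG86 fractional site counting:

- S (with singleton counts), π, θ_W = S/(a_n·sites), θ_L = Σi·ξ_i/((n−1)·sites),
  h and Hd, Jukes–Cantor-corrected divergence K, and NG86 K_a/K_s (ω).
- Tajima's D and the normalized Fay–Wu H = (θ_π − θ_L)/√Var̂ (unfolded
  spectrum, outgroup-polarized by parsimony), with empirical p-values from
  coalescent simulation under the standard neutral model (SNM) and a
  configurable bottleneck (BN), fixing the observed S and drawing θ from a
  uniform prior (rejection algorithm), at two recombination rates R_M and
  R_M/4.
- Multilocus HKA (χ² and parametric-bootstrap p) and the MK 2×2 Fisher
  exact test.
- A composite likelihood ratio (CLR) sweep scan over a grid of selection
  strengths α = 2Ns and target positions X, scored against simulated
  max-CLR null distributions, and a goodness-of-fit (GOF) test comparing
  the fitted sweep model to a saturated per-site binomial alternative.

The coalescent engine (time in 4N₀ units, piecewise-constant demography,
independent-windows recombination approximation, infinite- or finite-sites
mutation, fixed-S rejection sampling, sweep-conditioned genealogies) is
part of the package; msprime is used only as an independent cross-check in
the test suite. See `docs/methods.md` for the models and their assumptions.

## Worked example

Generate the four bundled synthetic regions (they emulate a typical derived-population resequencing design:
7424/3201/2352/699 bp, n = 10 or 12, silent π 0.003–0.011, silent K
0.05–0.16, an injected α = 2000 sweep at the center of the large region)
and summarize one:

```
$ sweepkit synth --outdir wk --seed 11
$ sweepkit stats wk/regionB.fasta wk/regionB.gff3 --outgroup outgroup
region regionB (n=12)
        intronic: sites=71 S=2 (0) pi=0.009 K=0.019
      synonymous: sites=79 S=0 (0) pi=0.000 K=0.066
          silent: sites=2959 S=71 (17) pi=0.008 K=0.058
   nonsynonymous: sites=242 S=1 (0) pi=0.002 K=0.006
           total: sites=3201 S=72 (17) pi=0.008 K=0.054
  h=12 Hd=1.000 Ka=0.006 Ks=0.066 omega=0.088
```

Reading: of the 3201 aligned columns, 2959 effective sites are silent
(noncoding plus the fractional synonymous parts of coding columns — hence
the non-integer class totals); 71 of the 72 segregating sites are silent
(17 singletons); silent diversity π = 0.008 per site against a silent
divergence of K = 0.058 to the outgroup; all 12 haplotypes are distinct
(Hd = 1.000); and protein evolution is strongly constrained (ω = 0.088).

Scan the large region for a sweep and run a fixed-S simulation:

```
$ sweepkit sweep wk/regionA.fasta wk/regionA.gff3 --outgroup outgroup --rho 0.063
CLR=7.203 alpha_hat=910.30 X_hat=2800.0

$ sweepkit simulate --n 10 --length 2000 --theta-prior 0.001 0.06 \
      --fixed-s 25 --reps 3 --seed 5
acceptance rate: 0.0007324
rep     S       theta   tree_length     tmrca   pi
0       25      0.00399 3.0455  0.9764  7.689
1       25      0.00925 1.4342  0.3422  7.244
2       25      0.00435 2.5393  0.7749  10.067
```

The scan reports the maximized composite likelihood ratio Λ, the fitted
selection strength α̂ (2Ns units) and target position X̂; whether Λ is
significant is decided against simulated nulls (the `all` pipeline does
this, plus the GOF follow-up, and writes three TSV tables and a
reproducibility manifest). The fixed-S run shows the rejection-algorithm
conditioning: every accepted replicate has exactly S = 25, the accepted θ
values scatter over the prior, and the acceptance rate is logged.

The full config-driven pipeline:

```
$ sweepkit all --config pipeline.yaml
```

where the YAML lists per-region FASTA/GFF3 paths, outgroup ids, inheritance
factors and R_M values, the bottleneck demography (a documented placeholder
ships in `src/sweepkit/data/bottleneck.yaml`), replicate counts and the
master seed.

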