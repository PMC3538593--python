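# Methods

`sweepkit` implements the inference chain used to ask whether a resequenced
multi-kilobase gene region in a single focal species (the motivating setting
is a derived European *Drosophila melanogaster* population with
*D. simulans* as outgroup) shows departures from neutral expectations, and
whether any departure is better explained by a recent selective sweep than
by demography. This note records the models, the numerical choices, and the
places where the design was genuinely open.

## Site classification and summary statistics

Every alignment column receives one functional class (coding, intronic,
intergenic/flanking) or an exclusion reason. Missing data are handled by
complete deletion: a column with a gap or N in any sample sequence is
excluded, and a codon containing an excluded column is excluded whole,
because the NG86 synonymous fraction of the remaining positions is defined
only with the full codon context. Coding columns carry fractional site
weights in the Nei–Gojobori (1986) style: at each codon position the
synonymous fraction is the number of the three possible point mutations
preserving the amino acid divided by three, computed on each sample
sequence's codon and averaged over the sample (not just the reference).
Effective per-class site counts are sums of these fractions and are
non-integer for coding classes. Changes to or from stop codons count as
nonsynonymous; terminal stop codons are excluded from site counting.

Within-sample statistics follow the classical estimators: π (Nei's per-site
pairwise diversity, with a coding difference apportioned by the synonymous
weight of the observed change in each sequence's own codon background),
Watterson's θ_W = S/(a_n·sites), θ_L = Σ i·ξ_i/((n−1)·sites) from the
unfolded spectrum, haplotype number and Nei's Hd with the n/(n−1)
correction. Divergence to the single outgroup sequence is averaged over all
sample sequences (deterministic and uses all data, rather than picking one
arbitrary sequence) and Jukes–Cantor corrected; K_a/K_s uses NG86
pathway counting with equal weighting of all shortest mutational pathways,
discarding pathways through stops (when every pathway is blocked the pair
is averaged over all pathways — a corner that essentially never occurs in
realistic data). ω is reported as undefined, not 0 or ∞, when K_s = 0.

Variants are polarized by parsimony: at a biallelic site whose outgroup
base equals one of the two sample alleles the other allele is derived;
outgroup gap/N/third-state and multiallelic sites are retained for folded
statistics but excluded from the unfolded spectrum and from the sweep scan.
A multiallelic site counts once in S. Singletons are derived-count-1 when
polarized, minor-count-1 otherwise.

## Frequency-spectrum tests

Tajima's D uses the standard constants. The normalized Fay–Wu H is
(θ_π − θ_L)/√Var with Var evaluated at θ̂ = θ_W and
θ̂² = S(S−1)/(a_n² + b_n):

    Var = θ̂ (n−2)/(6(n−1))
        + θ̂² [18n²(3n+2) b_{n+1} − (88n³ + 9n² − 13n + 6)] / (9n(n−1)²),

with b_m = Σ_{i<m} 1/i². One property worth knowing: although
E[θ_π − θ_L] = 0 exactly under neutrality, the *normalized* statistic has a
small positive mean (≈ +0.1 for n = 12 at θ ≈ 0.01/site over 2 kb), because
the genealogies that produce strongly negative numerators are the same ones
that produce large variance estimates in the denominator. The package's
variance formula was verified against the empirical variance of the
numerator at the true θ, and the positive mean reproduces with an
independent simulator (msprime), so this is a property of the statistic,
not of the implementation. The test is used one-sided (lower tail), where
this offset is conservative.

Empirical p-values are lower-tail, P(stat_sim ≤ stat_obs), which reproduces
the usual reporting convention in which a positive D has p near 1 and a strongly
negative D has p near 0; when no replicate is as extreme the p-value is
reported as the bound "<1/reps".

## Polymorphism–divergence tests

The MK test builds the 2×2 table of synonymous/nonsynonymous ×
polymorphic/fixed changes; fixed changes are monomorphic sample columns
with a different called outgroup base (sites polymorphic in the sample are
excluded from the fixed class), and significance is the two-tailed Fisher
exact test summing point probabilities ≤ the observed one. An optional
second outgroup restricts fixations to the focal lineage by parsimony.

The multilocus HKA test uses the one-species form (polymorphism in the
focal species, one outgroup sequence). With f the inheritance factor (1
autosomal, 3/4 X-linked) and θ_i the autosomal-equivalent per-locus
population mutation parameter, the moment equations are E[S_i] = f θ_i a_n
and E[D_i] = θ_i (T + f), where T is the divergence time in 2N₀ units and
the f term is the ancestral-polymorphism contribution. Given T the θ_i
follow in closed form; T solves a one-dimensional equation (Brent). The
statistic sums (obs − exp)²/Var over both S and D with Var[S] = fθa + (fθ)²b
and Var[D] = E[D] + (fθ)²; significance comes from χ²(L−1) and, optionally,
from refitting parametric-bootstrap replicates simulated at the fitted
parameters.

## Coalescent engine

Time is in 4N₀-generation units (ms convention): k lineages coalesce at
total rate k(k−1), scaled by 1/(size_ratio × inheritance_factor) within
each epoch of a piecewise-constant demography. Mutations are Poisson on
branch length at rate θ per site; the default is infinite sites (continuous
positions), with an optional finite-sites mode that drops mutations onto
discrete sites under Jukes–Cantor symmetry, so multiple hits can produce
multiallelic or back-mutated sites, which downstream code handles by the
multiallelic rule above.

Recombination input is per site in 2N units (the genetic-map convention)
and is converted internally by a factor of 2. It is modeled by an
independent-windows approximation: the locus is split into
min(round(ρ₄N·L), 256) equal windows, each with its own marginal genealogy
— complete linkage within a window, free recombination between windows. A
full ancestral-recombination-graph is deliberately not implemented: the
composite-likelihood sweep statistic assumes across-site independence
anyway, and at the recombination rates relevant here (ρ ≈ 0.01–0.13 per
site in 4N units) adjacent windows of tens of bp are already nearly
unlinked, so the approximation errs only in ignoring the residual decay of
linkage within/between neighboring windows. With ρ = 0 the engine is the
exact standard coalescent, and that is the regime in which it is
cross-validated distributionally against msprime.

Fixed-S conditioning follows the rejection-algorithm recipe: θ is drawn
from a uniform prior — default (0.001, 0.06) per site, a range that
brackets plausible silent diversity in derived Drosophila populations — a genealogy set is simulated, and the candidate is accepted only
if its Poisson segregating-site total equals the target exactly. The
candidate stage is vectorized (only interval times and tree lengths are
needed to decide acceptance); topologies are built and the S mutations
placed multinomially by branch length only for accepted candidates. The
acceptance rate is always recorded, and the run aborts with a diagnostic
below a configurable floor (default 10⁻⁴).

Sweep-conditioned genealogies implement an instantaneous partial sweep at
time t_s (default 0 = the present): the genealogy is neutral below t_s,
each surviving lineage escapes independently with probability p_esc at the
sweep, all non-escaping lineages coalesce into one, and the process
continues neutrally above. This is the star-like strong-selection limit;
there is no selected phase of finite duration.

## Sweep model, CLR scan, and GOF

The escape probability at distance d bp from the selected site is
p_esc = 1 − ε^(ρd/α), with α = 2Ns, ρ per site in 2N units, and ε = 10⁻⁶ by
default (≈ 1/2N for a large *Drosophila* population). The post-sweep
spectrum has a closed form under the collapse model: with B ~ Binomial(n,
p_esc) escapees, the pre-sweep sample is a neutral coalescent of m = B+1
lineages, a mutation of multiplicity j among the m maps to full-sample
derived count j−1+(n−B) with probability j/m (the collapsed lineage is a
carrier) and j otherwise, and expected branch lengths are 1/j. This yields
φ(k | p_esc) and the expected polymorphism retention λ(p_esc) =
E[a_{B+1}]/a_n. Both were validated against the engine's sweep simulator to
total-variation distance < 0.01 at 5×10⁴ replicates.

The composite log likelihood of a site configuration given (α, X) is
Σ_seg [ln q_i + ln φ(k_i | p_esc(d_i))] + Σ_mono ln(1 − q_i) with
q_i = min(1, θ_W a_n λ(p_esc(d_i))); the neutral model is the same with
p_esc ≡ 1 and the 1/(k a_n) spectrum. Λ = 2(max ln L − ln L₀) is maximized
over 50 log-spaced α in [10, 10⁵] × X at every 100 bp plus every
segregating-site position, with the neutral model always a candidate (so
Λ ≥ 0) and ties broken toward smaller α then smaller X. φ and λ are
precomputed on a 513-point p_esc grid and interpolated linearly; the
monomorphic sum over all L sites is computed once per α by prefix sums over
distance. Significance compares Λ to max-Λ distributions from the engine's
neutral (or bottleneck) simulations at matched n, L, ρ; the pipeline uses
fixed-S nulls at the observed S with the θ prior, while the calibration
experiments in the acceptance suite use θ-matched plain nulls shared across
datasets (exact by construction, and ~200× cheaper than per-dataset
fixed-S nulls).

The GOF statistic is 2(ln L_general − ln L_sweep) with the saturated
alternative Σ_seg ln Binom(k_i; n, k_i/n) (each site's derived-count
probability fitted freely; monomorphic sites contribute ln 1 = 0). Its null
distribution re-simulates data under the fitted (α̂, X̂) at θ = the observed
θ_W per site, re-fits the scan, and re-scores; p is the fraction of null
statistics ≥ observed, so a *large* p means the sweep model is not rejected.

## Synthetic data

The generator's default region set emulates the motivating design: four regions of 7424, 3201,
2352 and 699 bp; n = 10 for the large region and 12 elsewhere; silent π
targets 0.003–0.011 and silent divergence targets 0.05–0.16; mixed
coding/noncoding layouts, one region with an excluded ~390 bp spacer inside
an intron; per-site recombination rates 0.047–0.063 (2N units); and an
injected α = 2000 sweep at the center of the large region so the scan has a
true positive to find. θ is tuned by bisection against realized silent π in
a 50-replicate pilot to 15% tolerance. Purifying selection is emulated by
suppressing each nonsynonymous mutation with probability `constraint`
(default 0.8); mutations creating stops are always discarded. The outgroup
is the ancestral sequence evolved along a single unbroken branch with
substitution probability given by the JC inversion of the target K, with
the same nonsynonymous suppression.

What the fixtures do *not* emulate: sequencing error, alignment error,
indel polymorphism (gaps appear only as the masked spacer), outgroup
polymorphism and polarization error (the outgroup never carries a derived
sample allele by state, so parsimony polarization is nearly exact), codon
usage bias, and linkage between the sweep and demography. Tests passing on
fixtures therefore demonstrate correctness of the estimators and the
internal consistency of the chain, not robustness to real-data artifacts.
Mutation effects are classified against the ancestral codon background,
ignoring epistasis with other segregating mutations in the same codon
(rare at these diversities).

## Numerical choices and degenerate inputs

- Statistics with empty denominators (zero effective sites, S = 0, K_s = 0)
  return an explicit undefined sentinel that prints as "n. a."; they are
  never silently zero.
- JC correction raises a saturation error at p ≥ 0.75.
- Log-likelihoods floor ln φ at −700 on the interpolation grid; q is capped
  at 1 − 10⁻⁹.
- All simulations are driven by a single `numpy` Generator per run; the
  pipeline derives per-task seeds from the master seed and stable task
  labels (CRC32 into a SeedSequence), so every table is bit-reproducible
  from the manifest.
- Problem sizes in the default test and acceptance runs (e.g. 10⁵ moment
  replicates, 2000 calibration replicates, 200-dataset recovery
  experiments, 600–1000-replicate CLR nulls) were chosen as the smallest
  sizes at which the Monte-Carlo error is comfortably below the decision
  thresholds being checked.

## Known limitations

- No ARG: linkage disequilibrium decay within a window is not modeled; LD-
  based statistics should not be computed from this engine's output.
- The sweep model is the instantaneous-collapse limit; a finite sweep
  duration, recurrent sweeps and background selection are out of scope.
- The bottleneck parameter file ships with clearly marked placeholder
  values; region-level conclusions under the bottleneck null require the
  published demographic estimates for the population under study.
- The normalized Fay–Wu H carries the small positive neutral mean discussed
  above; its lower-tail use is conservative.
- NG86 (not a codon model) is the only divergence estimator, by design.
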