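# Methods

`crosspred` studies when Bayesian variable selection outperforms GBLUP
for *across-population* genomic prediction — predicting breeding values
of selection candidates in one breed from a phenotyped reference
population of another breed — and how the crossover relates to the
number of independent chromosome segments (M_e). Because the question
only involves simulated traits, every stage runs on synthetic
multi-breed genotypes; all quantitative claims the package reproduces
are properties of its own stated simulation world.

## Genotype simulation (`popsim`)

The simulator has to reproduce three structural properties of a real
multi-breed SNP panel, not real haplotypes:

1. **LD that decays with genetic distance.** A pool of base haplotypes
   is built as first-order mosaics of `n_founder_haplotypes` founder
   sequences; the copying process switches founders between adjacent
   SNPs with probability `mosaic_switch_rate × distance` (default 30
   per Morgan, i.e. haplotype blocks on a ~3 cM scale). Founder allele
   frequencies are drawn per SNP from a U-shaped Beta(0.5, 0.5)
   truncated to [0.05, 0.95].
2. **Between-breed divergence with partially shared LD.** Three
   populations are founded from disjoint draws of the pool and evolve
   `divergence_generations` (default 50) of Wright–Fisher random mating
   with Poisson-recombination gametes (Haldane, no interference,
   crossover positions uniform on a 1 Morgan/chromosome map spread
   evenly over SNPs). Divergence is pure drift: no mutation, no
   selection, no migration.
3. **Family structure.** The genotyped generation of the largest
   population is produced by a limited set of sires
   (`half_sib_family_size` daughters each, default 20), giving paternal
   half-sib families. The pedigree records the final two generations;
   the parent generation are unknown-parent base animals, so breeds are
   never connected through the pedigree.

SNPs with a pooled-data minor allele frequency *equal to or below*
`maf_threshold` (default 0.5 %) are deleted.

**Founder depth and effective size.** In this founder-mosaic design the
only LD component that is *shared* between breeds is the realized
covariance among the founder sequences, which scales as 1/n_founders;
everything drift builds after the split is private to one breed. The
founder pool therefore plays the role of the small ancestral effective
population that gives real cattle breeds their consistent short-range
LD. Two defaults follow from this:

- `n_founder_haplotypes = 10`. With substantially more founders (e.g.
  60) the breeds share so little LD that across-population prediction
  collapses to accuracy ≈ 0 even at a genetic correlation of 1, which
  contradicts the phenomenon the package exists to study. Ten founders
  give across-population SSVS accuracies of ~0.2–0.5 on the default
  panels — the regime the cattle data shows.
- `within_pop_ne = (500, 250, 250)`. Chosen once so that 50 generations
  of drift produce F_ST ≈ 0.05–0.1 between breeds, the range reported
  for European cattle breeds. Smaller Ne both over-differentiates the
  breeds and buries the shared LD under breed-private drift LD.

Defaults emulate a panel of 1033 + 105 + 147 cows (labels HF, GWH, MRY)
on three chromosomes ("13", "23", "28"); a `desk_config()` profile
(400/100/120 individuals, ~2.5k retained SNPs) runs every stage in
seconds and is what the tests and the acceptance script use.

**What a green test does not establish.** The generator has no
mutation, no selection, no variable recombination map, no genotyping
error, and its ancestral LD is a single-scale block process rather than
a coalescent. Conclusions transfer as orderings and ratios (SSVS vs
GBLUP, within vs across, accuracy ∝ r_g), not as absolute accuracies of
any real cattle panel.

## Trait simulation (`phenosim`)

A fixed random subset of SNPs (default 5000 of the panel) are candidate
QTL; the complement is the marker set given to the predictors, so causal
loci are never among the markers. Per replicate, m ∈ {3, 30, 300, 3000}
candidates become active QTL and their allele substitution effects are
drawn i.i.d. per QTL from a zero-mean multivariate normal with unit
variances and correlation r_g across populations (unit variances are
harmless: accuracy is scale-free). TBV_ij = Σ_k X_ijk α_jk with raw
{0,1,2} genotypes and the individual's own population column of α.
Environmental noise is N(0, (1/h² − 1) · var_within-pop(TBV)) with
h² = 0.95, emulating deregressed proofs. The standard-normal draws
behind the effects depend only on (m, P, seed), so paired designs
across r_g values share randomness by construction.

With 3 QTL the realized effect correlation is biased downward — the
exact finite-sample expectation at r_g = 0.8 is 0.6975 (n = 3 pairs),
rising to 0.795 at 30 QTL — which is why scenarios with 3 QTL
under-perform their nominal genetic correlation.

## SSVS sampler (`ssvs`)

Model: y = 1μ + Σ_j X_j β_j + e. Each marker effect has the mixture
prior β_j | γ_j ~ (1−γ_j) N(0, σ²_β/100) + γ_j N(0, σ²_β), with
P(γ_j = 1) = 1 − π = 0.01. The Gibbs sampler uses right-hand-side
updating: the residual vector is maintained incrementally, and each
marker update forms r_j = X_j'e + X_j'X_j β_j, samples γ_j from its
Bernoulli full conditional (log-space, never 0/0) and β_j from the
corresponding normal full conditional. σ²_β has a scaled inverse
chi-square full conditional shared by both components up to the fixed
ratio of 100 (df 4.2; scale auto-calibrated so the prior expected total
marker variance, Σ_j 2p_jq_j[(1−π)σ²_β + πσ²_β/100], matches an assumed
h² = 0.95 times the phenotypic variance — the original hyperparameters
are not recoverable). σ²_e gets a flat prior (draw e'e/χ²_n). Defaults:
5000 iterations, 1000 burn-in, no thinning; marker update order is
panel order with a randomized-order flag.

Numerical choices: marker columns are centered by the combined
reference + candidate mean allele count (stabilizes mixing; shifts all
GEBVs by a constant, so correlation-based accuracy is untouched); with
a multi-breed reference a separate intercept per population is fitted
by default, mirroring GBLUP's fixed breed effect (a flag restores the
literal single-μ model). GEBVs are the candidate marker matrix times
the posterior-mean effects, which equals averaging per-iteration
products because accumulation is linear. Validation hooks: γ can be
forced to 1 with fixed variances (the chain then converges to the
analytic ridge solution), and a debug mode verifies the incremental
residual against full recomputation to 1e-8.

## GREML / GBLUP (`greml`)

G = WW'/(2Σp_jq_j) with W column-centered at twice the combined-data
allele frequency; monomorphic markers drop out of numerator and
denominator. Variance components of y = Xb + Zg + e, g ~ N(0, G σ²_a)
with a fixed breed effect, are estimated by average-information REML; an
AI step is accepted only if it keeps both components above the floor
(1e-8 × phenotypic variance) and does not decrease the restricted
likelihood, otherwise the monotone EM update is taken (convergence:
relative log-likelihood change < 1e-8; non-convergence is flagged, not
raised; G gets a 1e-6 diagonal ridge). Candidate GEBVs propagate
reference information through G: ĝ = σ²_a G[cand, ref] V⁻¹(y − Xb̂),
algebraically identical to the mixed-model equations and to
centered-marker ridge (SNP-BLUP) with λ = σ²_e/(σ²_a/2Σpq) — both
identities are exercised in tests against brute-force solves.

## Independent chromosome segments (`segments`)

A is built by the tabular method from the recorded two-generation
pedigree (unknown parents contribute zero; breeds share no recorded
ancestor, so across-breed A = 0). M_e = 1/Var(G_ij − A_ij) with the
variance (divisor N; the pair counts make N vs N−1 immaterial) over all
reference × candidate pairs across populations — a two-breed reference
is pooled into one pair set — or over all unordered distinct pairs
within a population. Close relatives and strong LD make G track A
tightly within a breed, so M_e is systematically larger across breeds
than within; the package asserts this ordering (the cattle study's
~10× ratio is not a calibration target).

## Scenarios (`scenarios`)

Five designs: within-population HF→HF via 20-fold cross-validation
(fold sizes differ by at most one; per-replicate GEBVs are pooled over
folds before correlating, the only reading that yields one accuracy per
replicate), and four across-population designs with one- or two-breed
references. Accuracy is the Pearson correlation between candidate GEBV
and TBV per replicate; reliability is its square, averaged over
replicates; SE = sd/√n_replicates. Replicate seeds derive from
(scenario seed, replicate) only, so conditions differing in r_g, n_QTL
or model are paired draw-for-draw; a replicate in which any requested
model fails is dropped from every model (pairwise exclusion, counts
reported). Genotypes are simulated once per study; only QTL, effects
and noise are redrawn per replicate. Reliability-vs-ln(n_QTL) lines are
ordinary least squares through the per-level mean reliabilities, and
the SSVS/GBLUP crossing point solves the two fitted lines (parallel
lines are flagged absent, not an error).

## Known limitations

- Absolute accuracies depend on the invented ancestral-LD scale; only
  orderings and ratios are meaningful.
- The 3-QTL scenarios are dominated by the realized-correlation bias
  and by which segments the QTL land on; their replicate spread is
  intrinsically large.
- REML is O(n³) per iteration; fine for panels up to a few thousand
  reference individuals, not for national evaluations.
- No missing genotypes, no imputation, no dominance or epistasis, no
  estimation of π from data, and no deterministic accuracy formulas.
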