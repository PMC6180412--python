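# Methods

This note documents the models and procedures implemented in `crossboa`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data generator does and does not emulate.

## The BOA model

One phenotype (say backfat) is analysed as four traits: purebred
performance in each line S, LR, LW, and crossbred performance. For line b
the additive effects are a bivariate animal effect — (purebred-trait
effect, b-origin partial crossbred effect) — with covariance

    Var(u_b) = K_b ⊗ G^(b),   K_b = [[σ²_PB(b), σ_PB,CB(b)],
                                     [σ_PB,CB(b), σ²_CB(b)]]

where G^(b) is the breed-b partial genomic relationship matrix over the
breed-b purebreds and the crossbreds. Effects of different lines are
independent: the model has no cross-line genetic covariance term, which is
the structural counterpart of building three separate partial matrices.
Common-litter effects are i.i.d. within population; residual variances are
population-specific and residual covariances between populations are fixed
at zero because the purebred and crossbred animal sets are disjoint (such
covariances are not estimable from the data).

The genetic correlation between purebred and crossbred performance is
r_pc(b) = σ_PB,CB(b) / √(σ²_PB(b) σ²_CB(b)).

### Partial relationship matrices

VanRaden's first method per origin. Purebred rows center the 0/1/2 dosage
by 2p_b; crossbred rows center the 0/1 b-origin allele content by p_b
(haploid centering — the asymmetry is intentional and kept exactly), and an
allele without an assigned origin contributes a zero centered entry, which
biases crossbred diagonals slightly downward; no correction is applied.
p_b is the counted-allele frequency among *all* breed-b alleles (purebred
plus crossbred b-origin), and the scaling factor F_b = Σ_j 2 p_bj(1−p_bj)
is shared by all three blocks of origin b. All origins use one common kept
SNP set.

Two structural facts worth knowing:

- With data-derived frequencies the assembled partial matrix is exactly
  singular (the centered columns sum to zero over the pooled animal set),
  exactly as a standard VanRaden G with observed frequencies is. The MME
  solver therefore blends G towards the identity on its own diagonal scale
  with ridge 1e-6 by default; back-solving runs at ridge 0 on the block
  actually inverted and falls back to a pseudo-inverse with the
  reconstruction residual reported, never hidden.
- Crossbred partial diagonals average ≈ 0.5 / 0.25 / 0.25 for S / LR / LW —
  the genome shares of the three origins in the terminal cross. The
  crossbred heritability is therefore computed from the mean-diagonal-
  weighted variance contributions, h²_CB = Σ_b d̄_b σ²_CB(b) / (Σ_b d̄_b
  σ²_CB(b) + σ²_c + σ²_e) with d̄_b the mean diagonal of G_CB,CB(b); the
  raw parameter sum would count each origin at full weight and overstate
  the genetic variance roughly two-fold.

### Estimation

Variance components come from average-information REML on the record-level
covariance V = Σ_k θ_k C_k (dense patterns; exact likelihood). Newton steps
use the AI matrix with step halving against the REML log-likelihood; when
no AI step improves, pure variances fall back to a damped EM-style
multiplicative update. Each line's 2×2 genetic block is kept positive
semi-definite by flooring the variances slightly above zero and clipping
the covariance to |r| ≤ 0.999 — clipping rather than eigenvalue projection
avoids fighting the Newton step at the boundary. Convergence is declared at
a relative parameter change below 1e-8 (default; 200 iterations maximum) or
after three consecutive negligible log-likelihood improvements, which is
the typical signature of a boundary estimate. Standard errors are read from
the inverse AI matrix.

GEBVs come from Henderson's mixed-model equations built with
K_b⁻¹ ⊗ G_b⁻¹ genetic precision blocks, solved densely. Purebred animals
receive their own line's purebred-trait GEBV; crossbreds receive three
partial GEBVs whose sum is the total crossbred GEBV (exact by
construction).

### Back-solving

α̂ = F⁻¹ W' G⁻¹ â. The purebred conversion inverts the purebred block
G_bb with the purebred GEBVs; the crossbred conversion inverts G_CB,CB(b)
with the b-origin partial GEBVs (the `use_full_matrix` flag switches both
to the assembled matrix). With full-rank G and ridge 0 the identity
W α̂ = â holds to machine precision; this is verified against a 60-animal,
500-SNP simulation at 1e-8.

## LD blocks and variance mapping

Nonrandom association between two loci is tested within one breed-of-origin
of the crossbred population: the 2×2 table of gametic types is counted over
crossbred gametes carrying that origin at *both* loci, and Fisher's exact
two-sided test decides D ≠ 0. Tables with up to 200 observations are
evaluated in exact integer arithmetic (the support's point probabilities
share one denominator, so the two-sided tie rule is exact); larger tables
use scipy's implementation. No multiple-testing correction is applied — the
raw P < 0.01 rule is the procedure. Blocks partition each chromosome's kept
SNPs; breakpoints fall between consecutive SNPs whose D is not significant.

The percentage of genetic variance of block i is
Var(Σ_j z_j α̂_j)/σ²_a × (x̄_n/n_i) × 100, with z_j the genotypes of all
purebred individuals of the block's breed (the literal convention; a flag
allows origin-coded crossbred genotypes instead), variances taken across
individuals as population variances, σ²_a the REML total genetic variance
of the scenario (a flag substitutes Var(Zα̂)), and x̄_n the mean block size
of the scenario. Top-k blocks (k = 10) are matched across scenarios when
their bp intervals overlap or lie closer than 1 Mb on the same chromosome;
ties in the ranking break by genomic position.

## Focal-locus analysis

For a known biallelic causal mutation (mutant allele m = code 1), the LD
block per origin collects every same-chromosome SNP whose gametic table
against the focal SNP is significant at P < 0.01 — breakpoints are defined
against the focal SNP, not between consecutive SNPs. The cross-origin
intersection block supports the comparisons. Block haplotypes are
enumerated with per-origin copy counts; a haplotype string observed with
both focal alleles keeps the majority allele and its minority copies are
excluded as presumed genotyping errors. A haplotype's effect per origin is
the centered sum Σ_j (allele_j − p_bj) α̂_bj over the block SNPs (the
centered sum keeps the frequency-weighted within-origin mean near zero; an
uncentered variant is available). The m- and w-class means are weighted by
haplotype copy counts within origin, and their difference (w replacing m)
approximates the allele-substitution effect. Because the block-SNP effects
are BLUP solutions they are strongly shrunken; the haplotype-based
difference is expected to carry the right sign but a much smaller magnitude
than a fixed-effect estimate of the same substitution.

The direct estimate fits, on crossbred phenotypes pre-corrected for fixed
effects, a mixed model with the three origin-specific centered m-allele
contents as fixed regressions, a pedigree-based additive effect with
variance fixed at the BOA model's total crossbred genetic variance, a
common-litter effect and a residual (the latter two estimated by REML with
the genetic part held as a fixed covariance offset). An origin whose
content never varies is reported inestimable rather than zero.

By default the focal driver solves the BOA model at the variance components
implied by the generator targets rather than re-estimating them: the
substitution analysis conditions on variance components obtained in a
separate estimation step, and re-running REML inside the scenario only adds
origin-variance estimation noise to a mechanism-level comparison.
(`vc_source="reml"` re-estimates them.)

## The synthetic-data generator

The generator emulates the study design end to end:

- **Founder divergence.** Ancestral allele frequencies uniform on
  (0.1, 0.9); per-line frequencies Beta-distributed around them
  (Balding–Nichols), with per-line drift parameters solved from the
  pairwise F_ST targets via F_ST(a,b) ≈ (F_a + F_b)/2. Defaults: 0.17
  (S–LR), 0.12 (S–LW), 0.14 (LR–LW). Founder haplotypes are drawn in
  linkage equilibrium; realized multi-locus Weir–Cockerham F_ST converges
  to the targets as SNPs grow.
- **Pedigree and gene dropping.** Founders → phenotyped gen-1 purebreds in
  full-sib litters → F1 dams (gen-1 LR sires × gen-1 LW dams) → crossbreds
  (gen-1 S sires × F1 dams). Phenotyped purebreds are thus parents and
  maternal grandparents of the crossbreds, which is what makes the
  purebred–crossbred genetic covariance identifiable, as in combined
  crossbred–purebred recording schemes. Meiosis is Haldane (Poisson
  crossover counts at 1 cM/Mb, no interference); every transmitted allele
  keeps its founder line's label, giving the truth breed-of-origin matrix.
- **Phenotypes.** Additive origin-specific QTL effects with per-line
  correlation between purebred- and crossbred-performance effect vectors
  (this correlation is what sets r_pc); a common-litter effect; a Gaussian
  residual; Table-style fixed effects (farm/sex/trial levels and one
  covariate per trait/population). Crossbred origin-b breeding values are
  defined on the origin-frequency-centered allele content — (x − p_b) for
  b-origin alleles, 0 otherwise — i.e. exactly the partial-GRM convention;
  defining them on raw content would add an origin-composition variance
  term that the BOA model does not attribute to genetic variance. Effect
  vectors are rescaled against realized variance so the targets (per-line
  h²_PB, h²_CB split by genome share, c², r_pc) are met by construction in
  each realization.
- **Trait targets.** Defaults: BF h²_PB 0.31/0.33/0.34, h²_CB 0.41, r_pc
  0.80/0.71/0.89; ADG 0.09/0.22/0.20, 0.29, 0.69/0.60/0.68; RFI S 0.15 and
  LW 0.61 with h²_CB 0.40 and r_pc 0.37/0.60 — the LR RFI parameters are
  not estimable in the source populations (too few records), so the
  generator uses plausible mid-range stand-ins (h²_PB 0.15, r_pc 0.50).
  The litter-variance ratio c² defaults to 0.10 of phenotypic variance, a
  typical value for pig growth traits. Phenotypic scales: BF 12 ± 2.5 mm,
  ADG 900 ± 90 g/d, ADFI ≈ 2300 g/d with RFI derived by the four-covariate
  regression fitted separately within purebreds and crossbreds.
- **Focal scenario.** One biallelic mutation mid-chromosome 1 with m-allele
  frequencies 0.85 (S), 0.06 (LR), 0.39 (LW), an equal substitution effect
  of +20 g/d ADG per m allele in every origin, excluded from the analysis
  panel; flanking panel SNPs within 12 Mb copy the focal allele with a
  distance-increasing flip probability (0.03 → 0.35), creating strong
  breed-specific LD. Scenario scale: 300 founders and 400 phenotyped gen-1
  purebreds per line, 300 F1 dams, 1200 crossbreds, 4 × 400 SNPs on 250-Mb
  (2.5-Morgan) chromosomes. The long chromosomes and wide family base
  matter: with few sire–dam pairs and short genetic maps, within-family
  linkage is detectable as gametic association at P < 0.01 across a whole
  chromosome, and the focal "LD block" degenerates into the chromosome.
  At this scale the per-region polygenic variance share is also small
  relative to the focal contribution, as with a genome-wide chip panel.
  Because single realizations still carry family noise of the same order
  as the mechanism for the weaker origins, the scenario-level checks are
  made on averages over three seeded replicates.

**What the generator does not emulate:** genotyping and imputation error
(data are truth-phased and complete), selection (matings are random, no
drift from truncation), genotype-by-environment differences between
purebred and crossbred housing, dominance and epistasis (r_pc < 1 arises
purely from origin-specific additive effects), real linkage-disequilibrium
decay within lines (founders are in linkage equilibrium; LD in descendants
comes from family structure and the focal construction), and measurement
differences between purebred and crossbred trait recording. Passing tests
therefore validate the estimation machinery under the model's own
assumptions — they do not certify behavior under phasing errors, real LD
patterns, or selection.

## Numerical choices

- All randomness flows from one integer seed per routine; fixed seeds make
  the full pipeline byte-reproducible.
- MME and REML work on dense matrices at desk scale (hundreds to a few
  thousand records); no sparse/iterative machinery is included.
- Ridge default 1e-6 (identity-blend on the diagonal scale) for G
  inversion inside the solver; 0 for back-solving validation.
- Tied majority votes in assignment and zero-vote alleles yield a missing
  origin; the counted-allele rule for the minimum-copies filter checks
  both alleles (each must be seen ≥ 5 times in every origin present).
- "90% of the genome assigned" is interpreted per allele slot (fraction of
  2 × SNP slots), not per bp.
- Block intervals and positions are 1-based inclusive bp; the relatedness
  subset utility (`most_related_purebreds`) mirrors the practice of
  reducing a purebred population to the members closest to the crossbreds
  before variance-component estimation.

## Known limitations

- The vote-aggregation rule (strict majority, ties missing) is one concrete
  choice among the variants used with multi-length haplotype libraries;
  published pipelines defer to their phasing software's internals, which
  also exploit locus zygosity.
- REML origin variances for LR and LW partially confound (their maternal
  contents are complementary per locus), so single-run estimates can land
  on the parameter boundary at small crossbred counts; standard errors from
  the AI matrix are approximate near boundaries.
- The equal-frequency consistency between summed partial diagonals and a
  pooled VanRaden diagonal holds only approximately in finite samples
  (cross-products between origins do not vanish exactly).
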