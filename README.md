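# crossboa

Breed-of-origin genomic analysis for three-way crossbred pigs.

In a terminal cross — a sire-line boar (S) mated to an F1 dam from two dam
lines (LR × LW) — every crossbred allele was inherited from one of three
purebred populations, and the *same* SNP allele can have a different
estimated effect on crossbred performance depending on that breed-of-origin:
the tagged causal variants segregate at different frequencies, sit on
different local haplotypes, and meet different genetic backgrounds in each
line. `crossboa` implements the full analysis chain that quantifies this,
for geneticists working on crossbred genomic prediction:

1. **Breed-of-origin assignment** (`crossboa.boa_assign`): purebred
   haplotypes are catalogued window by window (nine core lengths, each tiled
   twice with a half-window offset, so every allele is seen up to 18 times);
   a window haplotype is assigned to a breed when ≥ 80% of its copies occur
   there, and crossbred alleles take the majority vote of their views.
   Standard filters remove SNPs assigned in < 90% of crossbreds on either
   gamete, animals with < 90% of their genome assigned, and SNPs with an
   allele seen < 5 times in any origin.
2. **Partial genomic relationship matrices** (`crossboa.relationship`),
   VanRaden method 1 per breed-of-origin b:

   ```
   G_bb    = (M^b  − 2·1 p_b')(M^b  − 2·1 p_b')' / F_b      purebreds
   G_b,CB  = (M^b  − 2·1 p_b')(M^CB − 1 p_b')'   / F_b      purebred × crossbred
   G_CB,CB = (M^CB − 1 p_b')(M^CB  − 1 p_b')'    / F_b      crossbreds
   ```

   where `M^CB` holds the b-origin allele content (0/1; unassigned → 0 after
   centering), `p_b` is the counted-allele frequency among all breed-b
   alleles, and `F_b = Σ_j 2 p_bj (1 − p_bj)`.
3. **The BOA model** (`crossboa.mixedmodel.BOAModel`): a 4-trait GBLUP
   (S, LR, LW purebred traits + the crossbred trait) where breed b's
   purebred effect and b-origin crossbred partial effect covary as a 2×2
   genetic covariance ⊗ G^(b), with common-litter effects and
   population-specific residuals. `fit()` runs average-information REML
   (EM-safeguarded, PSD-projected) and solves Henderson's mixed-model
   equations; the returned `BOAResults` carries variance components with
   standard errors, heritabilities, the purebred–crossbred genetic
   correlations r_pc, GEBVs, and a `summary()` table.
4. **Back-solving** (`crossboa.backsolve`): GEBVs convert to per-SNP allele
   effects by origin, `α̂ = F⁻¹ W' G⁻¹ â`, exactly reproducing `â = W α̂`
   when G has full rank.
5. **LD blocks and variance mapping** (`crossboa.ldblocks`): Fisher's exact
   test on same-origin gametic counts segments each chromosome into LD
   blocks (breakpoint where D between consecutive SNPs is not significant at
   P < 0.01); each block's share of genetic variance is
   `Var(Σ z_j α̂_j)/σ²_a × (x̄_n/n_i) × 100%`, and top-10 blocks are matched
   across origins within 1 Mb.
6. **Focal-locus analysis** (`crossboa.focal_locus`): for a known causal
   mutation (the motivating case is the MC4R missense variant affecting
   backfat and growth), builds its LD block per origin, scores the block
   haplotypes with back-solved effects, forms frequency-weighted m/w allele
   means, and estimates origin-specific allele-substitution effects with a
   pedigree-based fixed-regression mixed model.

A synthetic-data generator (`crossboa.simdata`) produces the whole study
design — three lines at pairwise F_ST ≈ 0.12–0.17, the three-way cross with
truth phase and breed-of-origin, origin-specific QTL effects inducing
r_pc < 1, litter effects, and the BF/ADG/ADFI trait panel with residual feed
intake derived by regression — so every stage is testable without
proprietary data.

## Worked example

```python
from crossboa.pipeline_io import RunConfig, run_pipeline

cfg = RunConfig(seed=1, n_founders=80, n_purebred=200, n_f1=120,
                n_crossbred=400, n_chrom=4, n_snps_per_chrom=250)
report = run_pipeline(cfg, write_files=False)

assign = report["stages"]["assignment"]
print(f"assigned: {assign['assigned_fraction']:.3f}  "
      f"accuracy: {assign['accuracy']:.3f}  kept SNPs: {assign['kept_snps']}")
bf = report["stages"]["traits"]["BF"]
print(f"h2_cb = {bf['h2_cb']:.2f}")
for b in ("S", "LR", "LW"):
    print(f"{b}: h2_pb = {bf['h2_pb'][b]:.2f}  r_pc = {bf['r_pc'][b]:.2f}  "
          f"blocks = {bf['blocks'][b]['n_blocks']} "
          f"(mean {bf['blocks'][b]['mean_len']:.1f} SNPs)")
```

prints (≈20 s on one core):

```
assigned: 0.959  accuracy: 0.998  kept SNPs: 717
h2_cb = 0.52
S: h2_pb = 0.19  r_pc = 1.00  blocks = 444 (mean 1.6 SNPs)
LR: h2_pb = 0.29  r_pc = 0.34  blocks = 509 (mean 1.4 SNPs)
LW: h2_pb = 0.13  r_pc = 0.56  blocks = 482 (mean 1.5 SNPs)
```

Reading this: 95.9% of crossbred alleles received a breed-of-origin, 99.8%
of them correctly (the simulation truth is known); 717 of 1000 SNPs survive
the assignment filters. The single-run REML estimates scatter widely around
the generator's targets (h²_PB 0.31/0.33/0.34, h²_CB 0.41, r_pc
0.80/0.71/0.89) — at 200 phenotyped purebreds per line the standard error of
a genomic heritability is of order 0.1–0.2 and a correlation can hit the
parameter boundary, which is why the test suite checks parameter recovery on
averages over 20 replicates. LD blocks are short here because the simulated
panel is sparse (founders are in linkage equilibrium; blocks come from
family structure and drift).

The same pipeline is scriptable from a shell:

```bash
crossboa simulate --seed 1 --out sim/           # VCF + CSV/TSV dataset
crossboa assign --vcf sim/genotypes.vcf --pedigree sim/pedigree.csv
crossboa run config.yaml                        # full pipeline from YAML
```

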