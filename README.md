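# chukarpop

Demographic inference for chukar partridge (*Alectoris chukar*)
phylogeography — and for any study with the same shape: mtDNA
haplotype alignments from many local populations plus a diploid
microsatellite panel, analysed for expansion history, divergence
scenarios and dispersal barriers.

The package re-implements, as one tested Python library, the three
inference layers such studies chain together:

1. **Mismatch-distribution demography.** For each population, the
   histogram of pairwise nucleotide differences is fitted to the
   sudden-expansion model F(τ, θ₀, θ₁) of Rogers & Harpending by
   bounded multi-start least squares, with SSD and Harpending's
   raggedness index as goodness-of-fit statistics (parametric
   bootstrap p-values), and τ converted to calendar time through
   τ = 2µt with a calibrated clock (µ_site = 2.1×10⁻⁷ /site/generation,
   1024 bp, 3.9 yr/generation by default).
2. **ABC model choice on microsatellites.** A backwards-in-time
   structured coalescent with generalized stepwise mutation (GSM)
   simulates reference tables under three explicit
   divergence/admixture hypotheses for four regional clusters
   (Thrace, West, East, Central Anatolia: splits at t₃/t₂, admixture
   forming Central Anatolia with rate *ra* at t₁). Model choice uses
   both the direct rejection estimate (closest k points) and weighted
   polychotomous logistic regression; parameters are estimated by
   local-linear regression after a logit transform to the prior
   bounds; pseudo-observed datasets (PODs) give type-I/II error rates
   and RMAE.
3. **Monmonier barrier detection.** On a Delaunay triangulation of
   population coordinates, barriers are traced across the Voronoi
   dual through the edges of maximal genetic distance, with bootstrap
   support from replicate F_ST matrices.

Supporting layers: FASTA/GenePop/CSV IO, diversity indices (k, h, s,
π, d), Kimura-2-parameter distances, Tajima's D and Fu's Fs, AMOVA
Φ_ST and Weir–Cockerham θ, and a synthetic-data generator that
emulates the 16-population study design (277 Cyt-b-like sequences,
347 individuals × 13 loci with ~22% missing data, an optional
divergent "clade-B" contaminant haplogroup at 23/277 ≈ 8%).

## Worked example

```python
import numpy as np
from chukarpop import (StudyConfig, generate_study_like, mismatch_analysis,
                       expansion_time, contamination_rate)

bundle = generate_study_like(StudyConfig(seed=42))
print(bundle.genotypes.n, bundle.genotypes.n_loci,
      round(bundle.genotypes.missing_rate(), 3))
# 347 13 0.224

rounded, exact = contamination_rate(bundle.contaminant_labels)
print(rounded, round(exact, 2))
# 8 8.3        <- 23 contaminants among 277 sequences

pop3 = bundle.alignment.by_population()["pop3"]
fit = mismatch_analysis(pop3)
print(round(fit.tau, 2), round(fit.ssd, 4), expansion_time(fit.tau))
# 3.47 0.0079 31.46    <- tau, fit SSD, expansion age in kyBP
```

The last line says population 3's simulated mismatch distribution
fits a sudden expansion with τ ≈ 3.5 mutational time units, dated to
≈ 31 kyBP under the default clock (τ and the date are stochastic in
the simulated bundle; SSD near zero means the sudden-expansion model
fits well).

A full pipeline run from the shell:

```bash
chukarpop synth --seed 7 --out-dir data/
chukarpop run --synthetic --seed 7 --out-dir run/
chukarpop abc simulate --n-sims 10000 --seed 1 --out table.csv
chukarpop abc infer --table table.csv --genepop data/microsats.gen --out abc.json
```

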