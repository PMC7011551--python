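# rohscan

Runs-of-homozygosity (ROH) analysis for diploid SNP-array genotype
panels: ROH detection under explicit per-run criteria, four genomic
inbreeding coefficients, ROH-island (selection-signature) scanning, and
a synthetic-data generator with known planted autozygosity so every
stage can be validated against ground truth.

The package is aimed at livestock and conservation geneticists working
with medium-density array data (tens of thousands of SNPs, hundreds of
animals, PLINK PED/MAP or BED/BIM/FAM files) who want the standard
ROH-based inbreeding workflow as a tested, scriptable library rather
than a chain of one-off shell commands.

## What it computes

**ROH detection.** A run of homozygosity for one animal is a maximal
stretch of consecutive markers on one chromosome with

1. span ≥ 1 Mb,
2. at most one heterozygous and one missing call,
3. at least *l* markers, where
   *l* = ⌈ln(α / (nₐ·nₛ)) / ln(1 − het)⌉ keeps the panel-wide expected
   number of chance all-homozygous runs at or below the false-positive
   rate α (default 0.5); nₐ = animals, nₛ = SNPs per animal, het = mean
   heterozygous-call fraction,
4. average density of at least one SNP per 100 kb, and
5. no inter-marker gap of 1 Mb or more.

Detected runs are summarised in the conventional 1–2 / 2–4 / 4–8 /
8–16 / >16 Mb length classes, whose mix indicates the age structure of
inbreeding (long runs = recent common ancestors).

**Inbreeding coefficients.** Per animal, with x the allele dosage,
p the (per-population) allele frequency and h = 2p(1 − p):

- F_ROH = Σ ROH length / L_aut (marker-covered autosome length),
- F_GRM = mean[(x − 2p)² / h] − 1 (genomic-relationship diagonal),
- F_HOM = 1 − mean[x(2 − x) / h] (excess of homozygosity),
- F_UNI = mean[(x² − (1 + 2p)x + 2p²) / h] (uniting-gamete correlation),

plus their pairwise Pearson correlations per population.

**ROH islands.** Per population, the fraction of animals whose ROH cover
each SNP; maximal runs of SNPs strictly above a 20% threshold become
islands, annotated with the ratio of mean adjacent-SNP r² inside the
island to the chromosome-wide mean (islands in low-recombination or
swept regions show ratios above 1).

**Population structure.** Identity-by-state similarity, classical-MDS
principal components of the IBS matrix, and a deterministic
centroid ± 3 SD rule for flagging animals outside their breed cluster.

## Worked example

```python
from rohscan import (SimConfig, simulate_panel, apply_qc, ROHParams,
                     detect_roh, mean_heterozygosity, inbreeding_table,
                     correlate_estimators)

cfg = SimConfig(seed=1, n_samples=(40, 25), n_chromosomes=4,
                chromosome_length_bp=25_000_000, n_snps_per_chromosome=500,
                tracts_per_sample=(3.0, 4.0))
panel, truth = simulate_panel(cfg)          # 65 animals x 2,000 SNPs
panel, report = apply_qc(panel)
params = ROHParams().resolved(panel.n_samples, panel.n_snps,
                              mean_heterozygosity(panel))
segments = detect_roh(panel, params)
records = inbreeding_table(panel, segments, l_aut=4 * 25_000_000)
print(params.min_snps, len(segments))
print(records.groupby("population")[["F_ROH", "F_HOM"]].mean().round(3))
```

prints

```
34 161
            F_ROH  F_HOM
population
AZ          0.108  0.089
KHZ         0.165  0.138
```

i.e. the minimum-run criterion resolves to 34 SNPs for this panel
geometry, 161 runs are detected, and the mean detected autozygous
fraction is ~10.8% / 16.5% in the two simulated breeds — tracking the
planted tract load (3 vs 4 tracts per animal), with the
excess-homozygosity estimator agreeing in rank.

The same workflow is available from the shell:

```bash
rohscan simulate --seed 1 --out-prefix /tmp/sim --n-samples 40,25
rohscan run --input-prefix /tmp/sim --output-dir /tmp/out --seed 1
```

`analysis/01_simulate_cohort.py` … `06_roh_islands.py` run the full
study-shaped workflow (two breeds, 365 animals, ~62 k SNPs on 29
autosomes) step by step, writing tables under `results/`.

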