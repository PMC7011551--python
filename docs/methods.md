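# Methods

## Scope and model

`rohscan` implements the genotype-counting approach to runs of
homozygosity (ROH): an ROH is a maximal stretch of consecutive array
markers, homozygous up to small error allowances, interpreted as a
likely autozygous (identical-by-descent) segment. This is the approach
of PLINK-style pipelines; model-based hidden-Markov alternatives (which
classify homozygous-by-descent segments into age classes) are out of
scope. Everything operates on a `GenotypePanel`: an int8 samples × SNPs
dosage matrix over {0, 1, 2, MISSING} counting copies of the B allele,
with a marker map and per-sample population labels.

## ROH detection

A run for one sample is a window of consecutive markers on one
chromosome that

- starts and ends on a homozygous non-missing call,
- contains at most `max_het_in_roh` heterozygous and
  `max_missing_in_roh` missing calls (defaults 1 and 1 — independent
  budgets, so one het *and* one missing may co-occur),
- spans at least `min_length_bp` (default 1 Mb),
- holds at least `min_snps` markers,
- averages at least one marker per `min_density_bp_per_snp` (default
  100 kb) — the density reading of "at least one SNP over 100 kb",
  since the literal reading is vacuous for a megabase run,
- contains no inter-marker gap of `max_gap_bp` (default 1 Mb) or more,

and is *maximal*: extending either end to further homozygous calls
would violate the het/missing budgets or the gap bound. Two maximal
candidates can overlap (each absorbing the same interior het from a
different side); the longer in bp wins, ties to the leftmost, so the
reported segments of one sample never overlap. The scanning
implementation is a two-pointer sweep (the admissible right end is
monotone in the left end); the test suite holds it equal to exhaustive
enumeration of every contiguous window on hundreds of random fixtures.

Segment length is `end_bp − start_bp + 1` (1-based inclusive first/last
marker positions); Mb = bp / 1e6. Length classes are left-closed
right-open: [1,2), [2,4), [4,8), [8,16), [16,∞) Mb, so a 2.000000 Mb
run falls in 2–4. Class genome-coverage % is
(class bp total / population sample count) / L_aut × 100 — the average
fraction of an animal's autosomes in runs of that class.

### The minimum-SNP rule

`min_snps` defaults to l = ⌈ln(α/(nₐ·nₛ)) / ln(1 − het)⌉ with α = 0.5,
nₐ samples, nₛ SNPs per sample and het the mean heterozygous-call
fraction of the analysis cohort, computed per population. Rationale:
each of roughly nₐ·nₛ window starts yields a chance all-homozygous run
of l markers with probability (1 − het)^l, so the ceiling keeps the
panel-wide expected count of such runs at or below α (a union bound;
the ceiling is chosen over rounding precisely to preserve it). Because
allele frequencies are drawn independently per SNP, the bound holds
with het equal to the *mean* heterozygosity even though per-SNP
heterozygosity varies.

Two caveats are deliberate and tested rather than hidden. First, the
bound is derived for *unbroken* homozygous stretches; the one-het
allowance multiplies the per-window pass probability by roughly
1 + l·het/(1 − het) (an order of magnitude at l ≈ 40, het ≈ 0.35), so
with the default allowance the expected chance-run count on null panels
exceeds α. The acceptance suite therefore checks the bound in the
setting where it is stated (zero allowances; measured ≈ 0.1 runs/panel
against α = 0.5) and reports the one-het count (≈ 1.8 runs/panel) as a
separate diagnostic. The allowance is kept because a single genotyping
error otherwise splits — and usually destroys — a long genuine run.
Second, maximality lets a run overshoot a true autozygous tract into
its flanks: a handful of chance homozygous flank markers, plus a
flank-het absorption when the budget is unspent. The overshoot is a
spacing-independent ~5–15 *markers*, so its bp size scales with marker
spacing (~100–150 kb at the 40–50 kb spacing of a medium-density
array). Recovery at ≥ 95% reciprocal overlap for every ≥ 2 Mb tract
consequently holds only on dense maps; the property test uses 2.5 kb
spacing, while pipeline-level sensitivity/precision use the
conventional reciprocal-overlap ≥ 0.5 matching rule.

## Inbreeding coefficients

With x the dosage, p the B-allele frequency and h = 2p(1 − p), per
sample over its non-missing SNPs (h = 0 SNPs excluded; the MAF filter
normally removes them first):

- F_ROH = Σⱼ L_ROH,j / L_aut, L_aut defaulting to 2.5 Gb (a
  bovine-order autosome set; the simulator and analysis scripts pass
  the marker-covered length of their own genome);
- F_GRM = mean[(x − 2p)²/h] − 1;
- F_HOM = 1 − mean[x(2 − x)/h];
- F_UNI = mean[(x² − (1 + 2p)x + 2p²)/h].

The weight is h = 2p(1 − p) — the form that makes all three estimators
well-defined for p > 0.5 and zero-mean under random mating.
Frequencies default to per-population estimation (a pooled mode
exists), since inbreeding summaries are conventionally per breed. All
three weighted estimators equal ±1 at p = ½ for x ∈ {2, 1, 0} and are
invariant under allele relabelling (x → 2 − x, p → 1 − p) — both are
asserted in tests, as is the HWE centring of F_HOM (|mean| < 3 SE over
1,000 random-mating samples). The weighted estimators are strongly
frequency-dependent: evaluating them under another population's drifted
frequencies shifts their means while F_ROH is untouched, which is why
F_ROH is the preferred cross-population comparison and is the anchor of
the correlation table (Pearson, per population; zero-variance pairs
reported as undefined rather than as a number).

## Population structure

IBS similarity of two samples is the mean over jointly called SNPs of
(2 − |xᵢ − xⱼ|)/2. Principal components come from classical
multidimensional scaling of this matrix: double-centre, eigendecompose,
scale eigenvectors by root-eigenvalues, clip negative eigenvalues, and
report eigenvalue shares of the positive spectrum as variance
explained. Because the IBS distance (1 − similarity) is of negative
type, the embedding reproduces the IBS geometry exactly
(‖yᵢ − yⱼ‖² = 2(1 − Sᵢⱼ)); this identity is the PCA test oracle.
Eigen-sign ambiguity is fixed by making each component's
largest-magnitude loading positive. Cluster outliers — conventionally
removed by eye from a PC plot — are flagged deterministically: a sample
whose PC1–PC2 distance from its own population centroid exceeds
`n_sd` (default 3) times the population's root-mean-square centroid
distance. The rule is monotone in `n_sd` and flags nothing for a
dispersion-free cluster.

## Quality control

Filter order is fixed: sample missingness (> 5% removed) → unmapped and
sex-chromosome markers → SNP missingness (> 5%) → MAF (< 2%, strict) →
HWE (1-df chi-square p < 1e-6). Marker statistics are computed on the
cohort remaining after sample removal, matching the conventional
sequencing of sample filters before marker filters; a per-population
mode removes a SNP failing in any population. The HWE test is the plain
chi-square (not the exact test); monomorphic SNPs get p = 1 by
convention and are left to the MAF filter. QC is idempotent, and every
surviving SNP provably satisfies every threshold (asserted in tests).

## ROH islands and LD

Per population, each SNP's ROH incidence is the count of samples whose
segments cover its position (overlapping same-sample segments are an
upstream contract violation and raise rather than double-count).
Islands are maximal runs of consecutive SNPs with incidence *strictly*
above the threshold (default 0.20 — "more than 20%" excludes exactly
20%), merged across bp gaps of at most `max_join_gap_bp` (default
500 kb) and dropped below `min_island_snps` (default 5) members. How
above-threshold SNPs group into islands is not standardised; these two
knobs are the package's own conservative defaults and are configurable.
LD uses the composite genotypic r² — squared Pearson correlation of
dosage vectors over jointly called samples, the standard unphased
surrogate — averaged over consecutive SNP pairs; degenerate pairs
(zero variance, < 2 joint calls) are skipped and counted, never paired
across chromosomes. Each island's `r2_ratio` divides its internal mean
adjacent-SNP r² by the chromosome-wide mean. External selection-score
tables (e.g. published iHS values) are only intersected with island
intervals and ranked; no haplotype statistics are computed.

## Synthetic data

The generator emulates the structure a two-breed array study assumes,
not its full population genetics:

- per-SNP ancestral B-allele frequencies uniform on [maf_min, 0.5],
  mirrored to the upper half with probability ½; population frequencies
  drift from them under the Balding–Nichols beta model (default
  Fst 0.05);
- genotypes outside tracts are two independent Bernoulli(p) allele
  draws — sites are in HWE and in linkage equilibrium;
- autozygous tracts per sample: Poisson count (per-population rate),
  exponential lengths truncated to [min, max], placed uniformly without
  same-sample overlap; inside a tract one drawn haplotype is duplicated,
  so every tract SNP is homozygous before error. A
  `generations_to_ancestor` preset maps g generations to a mean tract
  length of 100/(2g) Mb (morgan ≈ 100 Mb heuristic);
- an island: with probability `carrier_freq` a sample carries two
  copies of one fixed haplotype across a region — the footprint a sweep
  leaves;
- symmetric state-flip genotyping error (hom→het, het→random hom; an
  allele-dropout mode disables hom→het) and uniform missingness, in
  that order.

Defaults are the study-shaped cohort: 252 + 113 samples, 29 autosomes
× 86.2 Mb × 2,142 SNPs (≈ 2.5 Gb, ≈ 62 k markers, one per ~40 kb),
tract rates 21.2/33.2 per animal with mean length 4 Mb (together ≈ 4–6%
autozygosity), carrier frequency 0.30 for one ~3.3 Mb island per
breed, 0.2% genotyping error and 0.4% missingness (≈ 99.6% call rate).
Every draw descends from one master seed through per-sample substreams
(`default_rng([seed, population, sample])`), so panels are
byte-reproducible and single samples can be regenerated in isolation.

What the generator does *not* emulate — and what passing tests
therefore do not show about real data: background LD and recombination
maps (sites are independent outside tracts/islands, so chromosome-wide
r² baselines are lower than on real arrays), allele-frequency
ascertainment bias of array design, family structure and admixture,
non-uniform marker spacing beyond sampling jitter, and error rates that
correlate along the genome.

## Problem sizes in the checks

The acceptance script and test suite size their simulations to make
each property measurable with comfortable margins: 500 random ≤200-SNP
fixtures for detector-vs-enumeration equality; 20 null panels of
50 × 5,000 for the false-positive bound; one 200 × 20,000 error-free
panel (10 × 100 Mb chromosomes, 50 kb spacing, tracts ≥ 2 Mb) for the
F_ROH slope (observed ≈ 1.02, slightly above 1 from run-end overshoot)
and sensitivity/precision; 1,000 × 400 for HWE centring; 60 × 1,800
with a 4 Mb island at 35% carriers for island recovery. The analysis
scripts run the full default cohort.

## Known limitations

- PED files cannot preserve the identity of an allele never observed in
  the data, so monomorphic-in-A SNPs round-trip orientation-flipped
  through PED (BED/BIM round-trips are always exact).
- The false-positive guarantee of the minimum-SNP rule applies to the
  zero-allowance setting, as discussed above.
- Detected run ends overshoot true tract boundaries by a few markers;
  F_ROH inherits a small positive bias (~2% of the autozygous
  fraction at 50 kb spacing).
- Island grouping parameters (join gap, minimum members) have no
  community standard; different choices change island counts on noisy
  tracks (the threshold semantics and per-SNP incidence do not change).
- The centroid ± n·SD outlier rule is a formalisation of a visual
  judgement; with very small clusters (< ~10 members) a single extreme
  point inflates the RMS enough to mask itself.
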