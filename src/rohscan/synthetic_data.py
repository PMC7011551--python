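"""Synthetic diploid genotype panels with planted autozygosity.

The generator emulates the structure a SNP-array study of two diverged
livestock populations assumes: per-SNP allele frequencies drawn from a
mirrored-uniform law and diverged between populations by Balding–Nichols
drift; per-sample autozygous (IBD) tracts inside which one drawn haplotype
is duplicated, so every tract SNP is homozygous before error; an optional
shared "island" haplotype that a fixed fraction of a population carries in
two copies over one region; symmetric genotyping error; and missingness.

Every random draw descends from one master seed through per-sample
substreams, so panels are reproducible byte-for-byte and individual samples
can be regenerated without touching the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel


@dataclass
class IslandSpec:
    """A shared homozygous haplotype region planted in one population.

    With probability ``carrier_freq`` a sample of ``population`` receives
    two copies of a fixed haplotype across ``[start_bp, end_bp]`` of
    ``chromosome`` — the signature a selection sweep leaves as an
    ROH island.
    """

    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    carrier_freq: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq outside [0, 1]")
        if self.end_bp <= self.start_bp:
            raise ValueError("island end must exceed start")


@dataclass
class SimConfig:
    """Conditions for one simulated cohort.

    Defaults mirror a two-breed water-buffalo array study: 252 + 113
    samples, 29 autosomes of ~86 Mb carrying ~2,142 SNPs each (~2.5 Gb,
    ~62 k SNPs, one SNP per ~40 kb), per-animal autozygous-tract counts of
    21.2 and 33.2 with exponential tract lengths of mean 4 Mb (truncated to
    [1, 40] Mb), a 99.6% call rate and a 0.2% genotyping-error rate.
    ``preset_generations(g)`` sets the tract-length mean to 100/(2g) Mb,
    the morgan ≈ 100 Mb heuristic for autozygosity tracing back g
    generations.
    """

    seed: int = 0
    n_samples: tuple[int, ...] = (252, 113)
    population_labels: tuple[str, ...] = ("AZ", "KHZ")
    n_chromosomes: int = 29
    chromosome_length_bp: int = 86_200_000
    n_snps_per_chromosome: int = 2_142
    maf_min: float = 0.05
    fst: float = 0.05
    tracts_per_sample: tuple[float, ...] = (21.2, 33.2)
    tract_length_mean_bp: float = 4_000_000.0
    tract_length_min_bp: float = 1_000_000.0
    tract_length_max_bp: float = 40_000_000.0
    islands: tuple[IslandSpec, ...] | None = None
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.004
    error_mode: str = "flip"  # "flip" or "dropout"

    def __post_init__(self) -> None:
        if len(self.n_samples) != len(self.population_labels):
            raise ValueError("n_samples and population_labels lengths differ")
        if len(self.tracts_per_sample) != len(self.population_labels):
            raise ValueError("tracts_per_sample must give one rate per population")
        for r in (self.genotyping_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0.0 < self.maf_min < 0.5:
            raise ValueError("maf_min must lie in (0, 0.5)")
        if self.tract_length_min_bp > self.chromosome_length_bp:
            raise ValueError("minimum tract length exceeds the chromosome")
        if self.tract_length_max_bp < self.tract_length_min_bp:
            raise ValueError("tract length bounds inverted")
        if self.error_mode not in ("flip", "dropout"):
            raise ValueError("error_mode must be 'flip' or 'dropout'")
        if self.islands is None:
            # default: one moderate-frequency island per population, echoing
            # peaks carried by ~30% of animals over a few-Mb span
            specs = []
            span = int(min(3_300_000, self.chromosome_length_bp // 4))
            for i, pop in enumerate(self.population_labels):
                chrom = str((i % self.n_chromosomes) + 1)
                start = int(self.chromosome_length_bp * (0.1 + 0.4 * (i % 2)))
                specs.append(IslandSpec(pop, chrom, start, start + span, 0.30))
            self.islands = tuple(specs)

    @classmethod
    def preset_generations(cls, g: float, **kwargs) -> "SimConfig":
        """Tract-length mean from generations to the common ancestor."""
        mean = 100.0 / (2.0 * g) * 1e6
        return cls(tract_length_mean_bp=mean, **kwargs)


@dataclass
class TruthSet:
    """Ground truth of a simulated panel.

    ``tracts``: one row per planted tract (sample_id, population,
    chromosome, start_bp, end_bp). ``phi``: per-sample autozygous fraction
    (total tract bp / total genome bp). ``islands``: the planted specs with
    their per-sample carrier flags.
    """

    tracts: pd.DataFrame
    phi: pd.Series
    islands: list[tuple[IslandSpec, list[str]]] = field(default_factory=list)
    genome_bp: int = 0


def _draw_tracts(
    rng: np.random.Generator, cfg: SimConfig, rate: float
) -> list[tuple[int, int, int]]:
    """Non-overlapping (chrom_idx, start, end) tracts for one sample."""
    n = rng.poisson(rate)
    tracts: list[tuple[int, int, int]] = []
    attempts = 0
    while len(tracts) < n and attempts < 50 * (n + 1):
        attempts += 1
        length = rng.exponential(cfg.tract_length_mean_bp)
        length = float(np.clip(length, cfg.tract_length_min_bp, cfg.tract_length_max_bp))
        c = int(rng.integers(cfg.n_chromosomes))
        start = int(rng.integers(1, max(2, cfg.chromosome_length_bp - int(length))))
        end = min(start + int(length) - 1, cfg.chromosome_length_bp)
        if any(c == tc and start <= te and end >= ts for tc, ts, te in tracts):
            continue
        tracts.append((c, start, end))
    return sorted(tracts)


def _apply_errors(
    rng: np.random.Generator, row: np.ndarray, error_rate: float, mode: str
) -> np.ndarray:
    """Flip genotype state with probability ``error_rate`` per call.

    ``flip``: hom -> het; het -> a random hom. ``dropout``: het -> a random
    hom only (allele dropout cannot create a heterozygote). MISSING cells
    are never altered.
    """
    if error_rate <= 0:
        return row
    hit = (rng.random(row.size) < error_rate) & (row != MISSING)
    if mode == "dropout":
        hit &= row == 1
    out = row.copy()
    het_targets = np.where(rng.random(row.size) < 0.5, 0, 2).astype(np.int8)
    out[hit & (row == 1)] = het_targets[hit & (row == 1)]
    if mode == "flip":
        out[hit & (row != 1)] = 1
    return out


def _marker_map(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for c in range(cfg.n_chromosomes):
        n = cfg.n_snps_per_chromosome
        pos = np.unique(rng.integers(1, cfg.chromosome_length_bp, size=2 * n + 16))
        while pos.size < n:  # vanishingly unlikely unless SNPs ~ chromosome length
            extra = rng.integers(1, cfg.chromosome_length_bp, size=n)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        for k, p in enumerate(pos):
            rows.append((f"snp_{c + 1}_{k + 1}", str(c + 1), int(p)))
    df = pd.DataFrame(rows, columns=["snp_id", "chromosome", "position_bp"])
    df["allele_a"] = "A"
    df["allele_b"] = "B"
    return df


def _population_frequencies(
    rng: np.random.Generator, cfg: SimConfig, n_snps: int
) -> np.ndarray:
    """(n_populations, n_snps) allele_b frequencies.

    Ancestral frequencies are uniform on [maf_min, 0.5], mirrored to
    [0.5, 1 - maf_min] with probability 1/2; population frequencies drift
    from them under the Balding–Nichols beta model with divergence ``fst``.
    """
    p = rng.uniform(cfg.maf_min, 0.5, size=n_snps)
    flip = rng.random(n_snps) < 0.5
    p = np.where(flip, 1.0 - p, p)
    n_pop = len(cfg.population_labels)
    if cfg.fst <= 0:
        return np.tile(p, (n_pop, 1))
    scale = (1.0 - cfg.fst) / cfg.fst
    out = rng.beta(p * scale, (1.0 - p) * scale, size=(n_pop, n_snps))
    return np.clip(out, 1e-4, 1.0 - 1e-4)


def simulate_panel(cfg: SimConfig) -> tuple[GenotypePanel, TruthSet]:
    """Generate a genotype panel and its ground truth.

    Outside planted tracts the two alleles of each call are independent
    Bernoulli(p_j) draws from the sample's population frequency p_j; inside
    a tract one haplotype draw is duplicated (homozygous everywhere before
    error); island carriers receive two copies of the island haplotype;
    error then missingness are applied last, in that order.
    """
    seed = int(cfg.seed)
    rng_map = np.random.default_rng([seed, 1])
    rng_freq = np.random.default_rng([seed, 2])
    rng_island = np.random.default_rng([seed, 3])

    markers = _marker_map(rng_map, cfg)
    n_snps = len(markers)
    chrom_idx = markers["chromosome"].astype(int).to_numpy() - 1
    pos = markers["position_bp"].to_numpy()
    freqs = _population_frequencies(rng_freq, cfg, n_snps)

    islands: list[IslandSpec] = list(cfg.islands or ())
    island_haplotypes = []
    for isl in islands:
        pop_i = cfg.population_labels.index(isl.population)
        island_haplotypes.append(
            (rng_island.random(n_snps) < freqs[pop_i]).astype(np.int8)
        )

    sample_rows: list[tuple[str, str]] = []
    tract_rows: list[tuple[str, str, str, int, int]] = []
    phi: dict[str, float] = {}
    carriers: list[list[str]] = [[] for _ in islands]
    genome_bp = cfg.n_chromosomes * cfg.chromosome_length_bp
    dosages = np.empty((sum(cfg.n_samples), n_snps), dtype=np.int8)

    row = 0
    for pop_i, (pop, n) in enumerate(zip(cfg.population_labels, cfg.n_samples)):
        p = freqs[pop_i]
        for k in range(n):
            sid = f"{pop}_{k + 1:04d}"
            rng = np.random.default_rng([seed, 10 + pop_i, k])
            d = (rng.random(n_snps) < p).astype(np.int8) + (
                rng.random(n_snps) < p
            ).astype(np.int8)
            tracts = _draw_tracts(rng, cfg, cfg.tracts_per_sample[pop_i])
            total_bp = 0
            for c, start, end in tracts:
                in_tract = (chrom_idx == c) & (pos >= start) & (pos <= end)
                hap = (rng.random(int(in_tract.sum())) < p[in_tract]).astype(np.int8)
                d[in_tract] = 2 * hap
                tract_rows.append((sid, pop, str(c + 1), start, end))
                total_bp += end - start + 1
            for isl_i, isl in enumerate(islands):
                if isl.population != pop:
                    continue
                if rng.random() < isl.carrier_freq:
                    in_isl = (
                        (markers["chromosome"].to_numpy() == isl.chromosome)
                        & (pos >= isl.start_bp)
                        & (pos <= isl.end_bp)
                    )
                    d[in_isl] = 2 * island_haplotypes[isl_i][in_isl]
                    carriers[isl_i].append(sid)
            d = _apply_errors(rng, d, cfg.genotyping_error_rate, cfg.error_mode)
            if cfg.missing_rate > 0:
                d[rng.random(n_snps) < cfg.missing_rate] = MISSING
            dosages[row] = d
            sample_rows.append((sid, pop))
            phi[sid] = total_bp / genome_bp
            row += 1

    panel = GenotypePanel(
        dosages,
        pd.DataFrame(sample_rows, columns=["sample_id", "population"]),
        markers,
    )
    truth = TruthSet(
        tracts=pd.DataFrame(
            tract_rows,
            columns=["sample_id", "population", "chromosome", "start_bp", "end_bp"],
        ),
        phi=pd.Series(phi, name="phi"),
        islands=list(zip(islands, carriers)),
        genome_bp=genome_bp,
    )
    return panel, truth


def perturb_panel(
    panel: GenotypePanel,
    error_rate: float,
    missing_rate: float,
    seed: int,
) -> GenotypePanel:
    """Inject genotyping error and missingness into an existing panel.

    Each non-missing call is state-flipped with probability ``error_rate``
    (hom -> het, het -> random hom) and then hidden with probability
    ``missing_rate``. Cells already MISSING are never "corrected".
    """
    if not 0.0 <= error_rate <= 1.0 or not 0.0 <= missing_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng([int(seed), 99])
    d = panel.dosages.copy()
    for i in range(d.shape[0]):
        d[i] = _apply_errors(rng, d[i], error_rate, "flip")
        if missing_rate > 0:
            hide = (rng.random(d.shape[1]) < missing_rate) & (d[i] != MISSING)
            d[i, hide] = MISSING
    return GenotypePanel(d, panel.samples.copy(), panel.markers.copy())
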