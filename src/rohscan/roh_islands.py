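"""ROH incidence track, island calling and adjacent-SNP LD.

An ROH island is a run of markers at which the fraction of a population's
samples covered by an ROH is *strictly greater than* a threshold (default
20%) — the hallmark of a haplotype driven up in frequency by selection.
Runs separated by at most ``max_join_gap_bp`` are merged; islands with
fewer than ``min_island_snps`` member SNPs are dropped.

Linkage disequilibrium between adjacent SNPs uses the composite genotypic
r²: the squared Pearson correlation of the two dosage vectors over samples
non-missing at both markers, the standard unphased surrogate for
haplotype r².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel
from .roh_detection import ROHSegment


@dataclass
class ROHIsland:
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    peak_fraction: float
    mean_fraction: float
    r2_ratio: float = float("nan")
    snp_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def roh_frequency(
    segments: list[ROHSegment],
    markers: pd.DataFrame,
    n_samples: int,
) -> pd.DataFrame:
    """Per-SNP count and fraction of samples whose ROH cover it.

    A SNP is covered by a segment when ``start_bp <= position <= end_bp``
    on the segment's chromosome. Overlapping segments from one sample are
    an upstream contract violation and raise rather than double-count.
    """
    chroms = markers["chromosome"].astype(str).to_numpy()
    pos = markers["position_bp"].to_numpy(dtype=np.int64)
    known = set(chroms)
    n_covered = np.zeros(len(markers), dtype=np.int64)
    seen: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for s in segments:
        if s.chromosome not in known:
            raise KeyError(f"segment chromosome {s.chromosome!r} absent from marker map")
        key = (s.sample_id, s.chromosome)
        for a, b in seen.setdefault(key, []):
            if s.start_bp <= b and s.end_bp >= a:
                raise ValueError(
                    f"overlapping segments for sample {s.sample_id} on "
                    f"chromosome {s.chromosome}"
                )
        seen[key].append((s.start_bp, s.end_bp))
        sel = (chroms == s.chromosome) & (pos >= s.start_bp) & (pos <= s.end_bp)
        n_covered[sel] += 1
    out = markers[["snp_id", "chromosome", "position_bp"]].copy()
    out["n_covered"] = n_covered
    out["fraction"] = n_covered / n_samples if n_samples else np.nan
    return out


def call_islands(
    track: pd.DataFrame,
    threshold: float = 0.20,
    min_island_snps: int = 5,
    max_join_gap_bp: int = 500_000,
    population: str = "",
) -> list[ROHIsland]:
    """Maximal runs of consecutive SNPs with fraction strictly above
    ``threshold``, merged across gaps of at most ``max_join_gap_bp``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    islands: list[ROHIsland] = []
    for chrom in pd.unique(track["chromosome"]):
        sub = track[track["chromosome"] == chrom]
        pos = sub["position_bp"].to_numpy(dtype=np.int64)
        frac = sub["fraction"].to_numpy(dtype=float)
        idx_global = sub.index.to_numpy()
        above = np.flatnonzero(frac > threshold)
        if above.size == 0:
            continue
        # split above-threshold SNPs into runs: break where non-member SNPs
        # intervene AND the bp gap between members exceeds the join limit
        groups: list[list[int]] = [[above[0]]]
        for prev, cur in zip(above, above[1:]):
            contiguous = cur == prev + 1
            joinable = pos[cur] - pos[prev] <= max_join_gap_bp
            if contiguous or joinable:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        for g in groups:
            members = np.array(g)
            if members.size < min_island_snps:
                continue
            islands.append(
                ROHIsland(
                    population=population,
                    chromosome=str(chrom),
                    start_bp=int(pos[members[0]]),
                    end_bp=int(pos[members[-1]]),
                    n_snps=int(members.size),
                    peak_fraction=float(frac[members].max()),
                    mean_fraction=float(frac[members].mean()),
                    snp_indices=idx_global[members],
                )
            )
    return islands


def adjacent_r2(panel: GenotypePanel, snp_indices: np.ndarray) -> float:
    """Mean squared Pearson correlation of dosages over consecutive SNP
    pairs among ``snp_indices`` (marker-map order).

    Pairs with fewer than two jointly called samples or zero variance at
    either SNP are skipped; if every pair is degenerate the mean is
    undefined and NaN is returned with a warning.
    """
    idx = np.sort(np.asarray(snp_indices, dtype=int))
    if idx.size < 2:
        raise ValueError("need at least 2 SNPs")
    chroms = panel.markers["chromosome"].to_numpy()
    vals, skipped = [], 0
    for a, b in zip(idx, idx[1:]):
        if chroms[a] != chroms[b]:  # never pair across chromosomes
            continue
        xa = panel.dosages[:, a].astype(float)
        xb = panel.dosages[:, b].astype(float)
        ok = (xa != MISSING) & (xb != MISSING)
        if ok.sum() < 2 or np.std(xa[ok]) == 0 or np.std(xb[ok]) == 0:
            skipped += 1
            continue
        r = np.corrcoef(xa[ok], xb[ok])[0, 1]
        vals.append(r * r)
    if not vals:
        warnings.warn("all adjacent pairs degenerate; mean r^2 undefined")
        return float("nan")
    return float(np.mean(vals))


def annotate_island_ld(
    islands: list[ROHIsland], panel: GenotypePanel
) -> list[ROHIsland]:
    """Fill each island's ``r2_ratio``: mean adjacent r² over the island's
    SNPs divided by the mean adjacent r² over its whole chromosome."""
    chroms = panel.markers["chromosome"].astype(str).to_numpy()
    chrom_r2: dict[str, float] = {}
    for isl in islands:
        if isl.chromosome not in chrom_r2:
            chrom_r2[isl.chromosome] = adjacent_r2(
                panel, np.flatnonzero(chroms == isl.chromosome)
            )
        inside = adjacent_r2(panel, isl.snp_indices)
        denom = chrom_r2[isl.chromosome]
        isl.r2_ratio = inside / denom if denom and not np.isnan(denom) else float("nan")
    return islands


def islands_to_frame(islands: list[ROHIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                i.population,
                i.chromosome,
                i.start_bp,
                i.end_bp,
                i.n_snps,
                round(i.peak_fraction, 6),
                round(i.mean_fraction, 6),
                round(i.r2_ratio, 6) if not np.isnan(i.r2_ratio) else float("nan"),
            )
            for i in islands
        ],
        columns=[
            "population",
            "chromosome",
            "start_bp",
            "end_bp",
            "n_snps",
            "peak_fraction",
            "mean_fraction",
            "r2_ratio",
        ],
    )


def overlap_with_scores(
    islands: list[ROHIsland], score_table: pd.DataFrame
) -> pd.DataFrame:
    """Bookkeeping overlap of islands with an external per-SNP score table
    (e.g. published iHS values): lists contained SNPs with their global
    rank by descending score. No scores are computed here.

    ``score_table`` columns: snp, chromosome, position, score.
    """
    required = {"snp", "chromosome", "position", "score"}
    if not required.issubset(score_table.columns):
        raise ValueError(f"score table must have columns {sorted(required)}")
    if score_table.empty:
        return pd.DataFrame(
            columns=[
                "population", "island_chromosome", "island_start_bp",
                "island_end_bp", "snp", "position", "score", "score_rank",
            ]
        )
    tab = score_table.copy()
    tab["chromosome"] = tab["chromosome"].astype(str)
    tab["score_rank"] = tab["score"].rank(ascending=False, method="min").astype(int)
    rows = []
    for isl in islands:
        chrom_max = tab.loc[tab["chromosome"] == isl.chromosome, "position"].max()
        if pd.notna(chrom_max) and isl.end_bp > 1.5 * chrom_max:
            warnings.warn(
                f"island {isl.chromosome}:{isl.start_bp}-{isl.end_bp} extends far "
                "beyond the scored positions; coordinate systems may differ"
            )
        hit = tab[
            (tab["chromosome"] == isl.chromosome)
            & (tab["position"] >= isl.start_bp)
            & (tab["position"] <= isl.end_bp)
        ]
        for r in hit.itertuples(index=False):
            rows.append(
                (
                    isl.population, isl.chromosome, isl.start_bp, isl.end_bp,
                    r.snp, r.position, r.score, r.score_rank,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "population", "island_chromosome", "island_start_bp",
            "island_end_bp", "snp", "position", "score", "score_rank",
        ],
    )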