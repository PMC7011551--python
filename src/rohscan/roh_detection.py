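"""Runs-of-homozygosity detection and length-class summaries.

A run of homozygosity (ROH) is reported for a sample when a maximal
stretch of consecutive markers on one chromosome satisfies five criteria:

1. span of at least ``min_length_bp`` (default 1 Mb);
2. at most ``max_het_in_roh`` heterozygous and ``max_missing_in_roh``
   missing calls (defaults 1 and 1, independent budgets);
3. at least ``min_snps`` markers, where ``min_snps`` defaults to the
   false-positive bound l = ceil(ln(alpha / (n_a * n_s)) / ln(1 - het)) —
   the smallest run length whose chance occurrence under random mating has
   panel-wide expectation at most ``alpha``;
4. average marker density of at least one SNP per
   ``min_density_bp_per_snp`` (default 100 kb) within the run;
5. no gap between neighbouring run markers of ``max_gap_bp`` (default
   1 Mb) or more.

Runs start and end on homozygous non-missing calls. Maximality means a run
cannot be extended to further homozygous endpoints without violating the
het/missing budgets or the gap bound. When two maximal candidates overlap
(they can, sharing a het between them) the longer wins, ties to the
leftmost, so segments of one sample never overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel

LENGTH_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("1-2", 1.0, 2.0),
    ("2-4", 2.0, 4.0),
    ("4-8", 4.0, 8.0),
    ("8-16", 8.0, 16.0),
    (">16", 16.0, math.inf),
)

#: Autosome length covered by the marker panel, denominator of genome
#: coverage (matches a ~2.5 Gb bovine-order autosome set).
DEFAULT_L_AUT: float = 2.5e9


@dataclass
class ROHParams:
    """Detection thresholds; see the module docstring for semantics."""

    min_length_bp: int = 1_000_000
    max_het_in_roh: int = 1
    max_missing_in_roh: int = 1
    alpha: float = 0.5
    min_snps: int | None = None
    min_density_bp_per_snp: int = 100_000
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0 or self.max_gap_bp <= 0:
            raise ValueError("length/gap bounds must be positive")
        if self.max_het_in_roh < 0 or self.max_missing_in_roh < 0:
            raise ValueError("het/missing budgets must be >= 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_snps is not None and self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")

    def resolved(self, n_samples: int, n_snps: int, het: float) -> "ROHParams":
        """Fill ``min_snps`` from the false-positive bound if unset."""
        if self.min_snps is not None:
            return self
        return replace(self, min_snps=min_snp_count(self.alpha, n_samples, n_snps, het))


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run: 1-based inclusive first/last marker positions."""

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def min_snp_count(alpha: float, n_a: int, n_s: int, het: float) -> int:
    """Minimum run length l such that a chance all-homozygous run of l
    markers has panel-wide expected count at most ``alpha``.

    l = ceil( ln(alpha / (n_a * n_s)) / ln(1 - het) ), where ``het`` is the
    mean per-call heterozygous fraction: each of roughly n_a * n_s window
    starts yields a false run with probability (1 - het)^l, and the ceiling
    keeps the union bound at or below alpha.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_a < 1 or n_s < 1:
        raise ValueError("n_a and n_s must be >= 1")
    if not 0 < het < 1:
        raise ValueError("het must lie strictly between 0 and 1")
    ratio = math.log(alpha / (n_a * n_s)) / math.log(1.0 - het)
    # absorb float noise so an analytically integral ratio is not bumped up
    return math.ceil(ratio - 1e-9)


def mean_heterozygosity(panel: GenotypePanel) -> float:
    """Mean fraction of heterozygous calls among non-missing calls."""
    d = panel.dosages
    obs = d != MISSING
    return float((d == 1).sum() / obs.sum())


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _candidate_windows(
    is_het: np.ndarray,
    is_miss: np.ndarray,
    gap_break_after: np.ndarray,
    max_het: int,
    max_miss: int,
) -> list[tuple[int, int]]:
    """Maximal [l, r] windows with homozygous endpoints and budgets met.

    Two-pointer sweep: for each left endpoint the admissible right end is
    monotone, so maximal windows are exactly the first left endpoint
    achieving each distinct right end.
    """
    n = is_het.size
    is_hom = ~(is_het | is_miss)
    out: list[tuple[int, int]] = []
    het = miss = 0
    r = -1  # last index included in the running window
    last_r = -2
    for l in range(n):
        if r < l - 1:
            r = l - 1
            het = miss = 0
        while r + 1 < n:
            if r >= l and gap_break_after[r]:
                break
            nh = het + (1 if is_het[r + 1] else 0)
            nm = miss + (1 if is_miss[r + 1] else 0)
            if nh > max_het or nm > max_miss:
                break
            het, miss = nh, nm
            r += 1
        if is_hom[l] and r >= l:
            rr = r
            while rr >= l and not is_hom[rr]:
                rr -= 1
            if rr > l and rr != last_r:
                out.append((l, rr))
                last_r = rr
        # slide left endpoint out of the window
        if r >= l:
            if is_het[l]:
                het -= 1
            elif is_miss[l]:
                miss -= 1
    return out


def _select_non_overlapping(
    windows: Sequence[tuple[int, int]], pos: np.ndarray
) -> list[tuple[int, int]]:
    """Greedy selection by (bp length desc, start asc); no shared SNPs."""
    ranked = sorted(
        windows, key=lambda w: (-(int(pos[w[1]]) - int(pos[w[0]])), w[0])
    )
    taken: list[tuple[int, int]] = []
    for l, r in ranked:
        if all(r < tl or l > tr for tl, tr in taken):
            taken.append((l, r))
    return sorted(taken)


def detect_roh(panel: GenotypePanel, params: ROHParams) -> list[ROHSegment]:
    """Detect ROH for every sample of a QC-passing, position-sorted panel."""
    if params.min_snps is None:
        params = params.resolved(
            panel.n_samples, panel.n_snps, mean_heterozygosity(panel)
        )
    if not panel.markers_sorted():
        raise ValueError("markers must be sorted by (chromosome, position)")
    segments: list[ROHSegment] = []
    chroms = panel.markers["chromosome"].to_numpy()
    pos_all = panel.markers["position_bp"].to_numpy(dtype=np.int64)
    sample_ids = panel.samples["sample_id"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        pos = pos_all[sel]
        gap_break_after = np.zeros(pos.size, dtype=bool)
        gap_break_after[:-1] = np.diff(pos) >= params.max_gap_bp
        block = panel.dosages[:, sel]
        for i in range(panel.n_samples):
            d = block[i]
            segments.extend(
                _segments_for_calls(
                    d, pos, gap_break_after, params, str(sample_ids[i]), str(chrom)
                )
            )
    return segments


def _segments_for_calls(
    d: np.ndarray,
    pos: np.ndarray,
    gap_break_after: np.ndarray,
    params: ROHParams,
    sample_id: str,
    chrom: str,
) -> list[ROHSegment]:
    is_het = d == 1
    is_miss = d == MISSING
    windows = _candidate_windows(
        is_het,
        is_miss,
        gap_break_after,
        params.max_het_in_roh,
        params.max_missing_in_roh,
    )
    valid = []
    for l, r in windows:
        span = int(pos[r]) - int(pos[l]) + 1
        n_snps = r - l + 1
        if span < params.min_length_bp:
            continue
        if n_snps < params.min_snps:
            continue
        if span / n_snps > params.min_density_bp_per_snp:
            continue
        valid.append((l, r))
    chosen = _select_non_overlapping(valid, pos)
    return [
        ROHSegment(
            sample_id=sample_id,
            chromosome=chrom,
            start_bp=int(pos[l]),
            end_bp=int(pos[r]),
            n_snps=r - l + 1,
            n_het=int(is_het[l : r + 1].sum()),
            n_missing=int(is_miss[l : r + 1].sum()),
        )
        for l, r in chosen
    ]


def segments_to_frame(
    segments: Iterable[ROHSegment], populations: dict[str, str] | None = None
) -> pd.DataFrame:
    rows = [
        (
            s.sample_id,
            (populations or {}).get(s.sample_id, ""),
            s.chromosome,
            s.start_bp,
            s.end_bp,
            s.n_snps,
            s.n_het,
            s.n_missing,
            s.length_bp / 1e6,
        )
        for s in segments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "population",
            "chromosome",
            "start_bp",
            "end_bp",
            "n_snps",
            "n_het",
            "n_missing",
            "length_mb",
        ],
    )


def segments_to_bed(segments: Iterable[ROHSegment]) -> pd.DataFrame:
    """0-based half-open intervals for genome-browser use."""
    return pd.DataFrame(
        [(s.chromosome, s.start_bp - 1, s.end_bp, s.sample_id) for s in segments],
        columns=["chrom", "start", "end", "name"],
    )


# ---------------------------------------------------------------------------
# Length-class summary
# ---------------------------------------------------------------------------

def classify_length_mb(length_mb: float) -> str:
    """Length class of one segment; bins left-closed right-open in Mb."""
    for name, lo, hi in LENGTH_CLASSES:
        if lo <= length_mb < hi:
            return name
    raise ValueError(f"segment of {length_mb} Mb below the 1 Mb floor")


def classify_and_summarise(
    segments: Iterable[ROHSegment],
    populations: dict[str, str],
    population_sizes: dict[str, int],
    l_aut: float = DEFAULT_L_AUT,
) -> pd.DataFrame:
    """Per-population, per-length-class summary.

    Columns: segment count, percentage of that population's segments, mean
    and sample-SD length (Mb), and genome coverage % = (class bp total /
    population sample count) / l_aut * 100 — the average fraction of an
    animal's autosomes in segments of that class.
    """
    df = segments_to_frame(segments)
    if len(df):
        unknown = set(df["sample_id"]) - set(populations)
        if unknown:
            raise KeyError(f"samples without population label: {sorted(unknown)[:5]}")
        df["population"] = df["sample_id"].map(populations)
        df["roh_class"] = df["length_mb"].map(classify_length_mb)
    rows = []
    for pop in sorted(population_sizes):
        sub = df[df["population"] == pop] if len(df) else df
        total = len(sub)
        for name, lo, hi in LENGTH_CLASSES:
            cls = sub[sub["roh_class"] == name] if total else sub
            n = len(cls)
            rows.append(
                {
                    "population": pop,
                    "roh_class": name,
                    "n_roh": n,
                    "percentage": 100.0 * n / total if total else 0.0,
                    "mean_length_mb": float(cls["length_mb"].mean()) if n else float("nan"),
                    "sd_length_mb": float(cls["length_mb"].std(ddof=1)) if n > 1 else float("nan"),
                    "genome_coverage_pct": (
                        100.0
                        * float(cls["length_mb"].sum())
                        * 1e6
                        / (population_sizes[pop] * l_aut)
                        if population_sizes[pop]
                        else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)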