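"""Genomic inbreeding coefficients and their correlations.

Four per-sample estimators:

* ``F_ROH`` — fraction of the autosomal length ``L_aut`` covered by the
  sample's ROH segments.
* ``F_GRM`` — diagonal of the VanRaden genomic relationship matrix minus
  one: mean over SNPs of (x - 2p)^2 / h - 1.
* ``F_HOM`` — excess of homozygosity: 1 - mean of x(2 - x) / h.
* ``F_UNI`` — correlation between uniting gametes: mean of
  (x^2 - (1 + 2p) x + 2 p^2) / h.

Here x is the sample's allele_b dosage, p the allele_b frequency and
h = 2p(1 - p) the heterozygosity weight; sums run over the sample's
non-missing SNPs, and SNPs monomorphic in the frequency cohort (h = 0)
are excluded. The frequency-weighted three are unbounded below and highly
frequency-sensitive, which is why F_ROH is usually preferred when
populations are drifted; F_ROH lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypePanel
from .roh_detection import DEFAULT_L_AUT, ROHSegment

COEFFICIENTS = ("F_ROH", "F_GRM", "F_HOM", "F_UNI")


@dataclass
class AlleleStats:
    """Per-SNP allele_b frequency ``p`` and weight ``h = 2p(1-p)``."""

    p: np.ndarray
    n_nonmissing: np.ndarray

    @property
    def h(self) -> np.ndarray:
        return 2.0 * self.p * (1.0 - self.p)

    @classmethod
    def from_panel(cls, panel: GenotypePanel, sample_mask: np.ndarray | None = None) -> "AlleleStats":
        sub = panel if sample_mask is None else panel.subset(sample_mask=sample_mask)
        obs = sub.dosages != MISSING
        return cls(p=sub.allele_frequencies(), n_nonmissing=obs.sum(axis=0))


def f_roh(segments: Sequence[ROHSegment], l_aut: float = DEFAULT_L_AUT) -> float:
    """Fraction of ``l_aut`` covered by one sample's (non-overlapping) ROH."""
    if l_aut <= 0:
        raise ValueError("l_aut must be positive")
    by_chrom: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for group in by_chrom.values():
        group.sort(key=lambda s: s.start_bp)
        for a, b in zip(group, group[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping segments on chromosome {a.chromosome}: "
                    f"{a.start_bp}-{a.end_bp} and {b.start_bp}-{b.end_bp}"
                )
    return sum(s.length_bp for s in segments) / l_aut


def _kernel_mean(x: np.ndarray, stats_: AlleleStats, kernel) -> float:
    x = np.asarray(x, dtype=float)
    keep = (x != MISSING) & (stats_.h > 0) & ~np.isnan(stats_.p)
    if not keep.any():
        raise ValueError("no usable SNPs: all missing or monomorphic")
    return float(np.mean(kernel(x[keep], stats_.p[keep], stats_.h[keep])))


def f_grm(x: np.ndarray, stats_: AlleleStats) -> float:
    """Mean of (x - 2p)^2 / h over non-missing SNPs, minus 1."""
    return _kernel_mean(x, stats_, lambda x, p, h: (x - 2 * p) ** 2 / h) - 1.0


def f_hom(x: np.ndarray, stats_: AlleleStats) -> float:
    """1 minus the mean of x(2 - x) / h — excess of homozygosity."""
    return 1.0 - _kernel_mean(x, stats_, lambda x, p, h: x * (2 - x) / h)


def f_uni(x: np.ndarray, stats_: AlleleStats) -> float:
    """Mean of (x^2 - (1 + 2p)x + 2p^2) / h — uniting-gamete correlation."""
    return _kernel_mean(
        x, stats_, lambda x, p, h: (x**2 - (1 + 2 * p) * x + 2 * p**2) / h
    )


def inbreeding_table(
    panel: GenotypePanel,
    segments: Iterable[ROHSegment],
    l_aut: float = DEFAULT_L_AUT,
    frequencies: str = "per_population",
) -> pd.DataFrame:
    """Per-sample F_ROH/F_GRM/F_HOM/F_UNI.

    ``frequencies`` chooses the allele-frequency cohort for the weighted
    estimators: ``per_population`` (default — each breed's own p) or
    ``pooled``.
    """
    if frequencies not in ("per_population", "pooled"):
        raise ValueError("frequencies must be 'per_population' or 'pooled'")
    by_sample: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    pops = panel.samples["population"].to_numpy()
    stats_by_pop: dict[str, AlleleStats] = {}
    if frequencies == "pooled":
        pooled = AlleleStats.from_panel(panel)
        stats_by_pop = {p: pooled for p in pd.unique(pops)}
    else:
        for p in pd.unique(pops):
            stats_by_pop[p] = AlleleStats.from_panel(panel, sample_mask=pops == p)
    rows = []
    for i, row in enumerate(panel.samples.itertuples(index=False)):
        st = stats_by_pop[row.population]
        x = panel.dosages[i]
        segs = by_sample.get(row.sample_id, [])
        usable = (x != MISSING) & (st.h > 0) & ~np.isnan(st.p)
        rows.append(
            {
                "sample_id": row.sample_id,
                "population": row.population,
                "F_ROH": f_roh(segs, l_aut),
                "F_GRM": f_grm(x, st),
                "F_HOM": f_hom(x, st),
                "F_UNI": f_uni(x, st),
                "n_snps_used": int(usable.sum()),
                "total_roh_bp": int(sum(s.length_bp for s in segs)),
            }
        )
    return pd.DataFrame(rows)


def correlate_estimators(
    records: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between coefficient columns, per population.

    A pair with zero variance in either coefficient is reported with NaN
    and ``defined=False`` rather than a spurious number.
    """
    if pairs is None:
        pairs = [(a, "F_ROH") for a in ("F_GRM", "F_HOM", "F_UNI")]
    rows = []
    for pop, sub in records.groupby("population", sort=True):
        if len(sub) < 3:
            raise ValueError(f"population {pop!r} has fewer than 3 records")
        for a, b in pairs:
            xa = sub[a].to_numpy(dtype=float)
            xb = sub[b].to_numpy(dtype=float)
            if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                rows.append((pop, a, b, float("nan"), False))
                continue
            if a == b:
                rows.append((pop, a, b, 1.0, True))
                continue
            r = float(stats.pearsonr(xa, xb).statistic)
            rows.append((pop, a, b, r, True))
    return pd.DataFrame(
        rows, columns=["population", "coef_a", "coef_b", "pearson_r", "defined"]
    )


def summarise_inbreeding(records: pd.DataFrame) -> pd.DataFrame:
    """Population means with dispersion (sample SD and SE) per coefficient."""
    rows = []
    for pop, sub in records.groupby("population", sort=True):
        for c in COEFFICIENTS:
            v = sub[c].to_numpy(dtype=float)
            rows.append(
                {
                    "population": pop,
                    "coefficient": c,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
                    "se": float(np.std(v, ddof=1) / np.sqrt(v.size))
                    if v.size > 1
                    else float("nan"),
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(rows)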