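"""Independent oracles used by the unit and acceptance tests.

The ROH oracle enumerates every contiguous marker window from first
principles (vectorised prefix sums over all O(n^2) windows) and applies
the detection criteria literally; it shares no code with the scanning
implementation it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rohscan.genotype_io import MISSING, GenotypePanel
from rohscan.roh_detection import ROHParams


def brute_force_roh(d: np.ndarray, pos: np.ndarray, params: ROHParams) -> list[tuple[int, int]]:
    """All reported (left, right) marker-index runs for one sample on one
    chromosome, by exhaustive window enumeration."""
    n = len(d)
    if n < 2:
        return []
    is_het = d == 1
    is_miss = d == MISSING
    is_hom = ~(is_het | is_miss)
    chet = np.concatenate([[0], np.cumsum(is_het)])
    cmiss = np.concatenate([[0], np.cumsum(is_miss)])
    gaps = np.diff(pos)
    # big_gap_before[k] true when the gap between k-1 and k is disallowed
    cgap = np.concatenate([[0], np.cumsum(gaps >= params.max_gap_bp)])

    l_idx, r_idx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    window = r_idx > l_idx
    hom_ends = is_hom[l_idx] & is_hom[r_idx]
    het_ok = (chet[r_idx + 1] - chet[l_idx]) <= params.max_het_in_roh
    miss_ok = (cmiss[r_idx + 1] - cmiss[l_idx]) <= params.max_missing_in_roh
    gap_ok = (cgap[r_idx] - cgap[l_idx]) == 0  # no disallowed gap inside
    valid_abf = window & hom_ends & het_ok & miss_ok & gap_ok

    # maximal: no strictly containing hom-endpoint window also valid_abf
    pairs = np.argwhere(valid_abf)
    maximal = []
    for l, r in pairs:
        contained = valid_abf[: l + 1, r:]
        if contained.sum() == 1:  # only (l, r) itself
            maximal.append((int(l), int(r)))

    span = pos[r_idx] - pos[l_idx] + 1
    n_snps = r_idx - l_idx + 1
    passing = []
    for l, r in maximal:
        if span[l, r] < params.min_length_bp:
            continue
        if n_snps[l, r] < params.min_snps:
            continue
        if span[l, r] / n_snps[l, r] > params.min_density_bp_per_snp:
            continue
        passing.append((l, r))

    # longer-first, leftmost-first non-overlapping selection
    passing.sort(key=lambda w: (-(int(pos[w[1]]) - int(pos[w[0]])), w[0]))
    taken: list[tuple[int, int]] = []
    for l, r in passing:
        if all(r < tl or l > tr for tl, tr in taken):
            taken.append((l, r))
    return sorted(taken)


def one_sample_panel(d: np.ndarray, pos: np.ndarray, chrom: str = "1") -> GenotypePanel:
    n = len(d)
    markers = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(n)],
            "chromosome": chrom,
            "position_bp": np.asarray(pos, dtype=np.int64),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame({"sample_id": ["x1"], "population": ["P"]})
    return GenotypePanel(np.asarray(d, dtype=np.int8).reshape(1, -1), samples, markers)


def random_roh_fixture(rng: np.random.Generator):
    """A random single-sample chromosome and random detection thresholds."""
    n = int(rng.integers(10, 200))
    pos = np.sort(rng.choice(np.arange(1, 4_000_000, dtype=np.int64), n, replace=False))
    d = rng.choice(
        np.array([0, 1, 2, MISSING], dtype=np.int8),
        size=n,
        p=[0.42, 0.12, 0.42, 0.04],
    )
    params = ROHParams(
        min_length_bp=int(rng.integers(100_000, 800_000)),
        max_het_in_roh=int(rng.integers(0, 3)),
        max_missing_in_roh=int(rng.integers(0, 3)),
        min_snps=int(rng.integers(2, 12)),
        min_density_bp_per_snp=int(rng.integers(50_000, 200_000)),
        max_gap_bp=int(rng.integers(200_000, 1_000_000)),
    )
    return d, pos, params


def segment_index_pairs(segments, pos) -> list[tuple[int, int]]:
    return sorted(
        (int(np.searchsorted(pos, s.start_bp)), int(np.searchsorted(pos, s.end_bp)))
        for s in segments
    )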