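"""Truth-set evaluation of detected ROH on simulated panels.

A planted tract counts as *detectable* when it satisfies the detection
criteria at all: span at least ``min_length_bp`` and at least ``min_snps``
markers on the panel's map. Matching uses reciprocal overlap — the overlap
length divided by the longer-relevant span, taken as the minimum of the
two one-sided fractions — with the conventional 0.5 threshold unless a
stricter one is requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel
from .roh_detection import ROHParams, ROHSegment
from .synthetic_data import TruthSet


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """min(overlap/len_a, overlap/len_b) for 1-based inclusive intervals."""
    o = min(a_end, b_end) - max(a_start, b_start) + 1
    if o <= 0:
        return 0.0
    return min(o / (a_end - a_start + 1), o / (b_end - b_start + 1))


@dataclass
class RecoveryMetrics:
    sensitivity: float
    precision: float
    n_detectable_tracts: int
    n_segments_evaluated: int


def detectable_tracts(
    truth: TruthSet,
    panel: GenotypePanel,
    params: ROHParams,
    min_tract_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Planted tracts long enough and marker-dense enough to be callable."""
    if params.min_snps is None:
        raise ValueError("params.min_snps must be resolved")
    chroms = panel.markers["chromosome"].astype(str).to_numpy()
    pos = panel.markers["position_bp"].to_numpy()
    keep = []
    for r in truth.tracts.itertuples(index=False):
        if r.end_bp - r.start_bp + 1 < min_tract_bp:
            continue
        n = int(((chroms == str(r.chromosome)) & (pos >= r.start_bp) & (pos <= r.end_bp)).sum())
        if n >= params.min_snps:
            keep.append(r)
    return pd.DataFrame(keep, columns=truth.tracts.columns)


def tract_recovery(
    segments: Sequence[ROHSegment],
    truth: TruthSet,
    panel: GenotypePanel,
    params: ROHParams,
    min_tract_bp: int = 2_000_000,
    overlap: float = 0.5,
) -> RecoveryMetrics:
    """Per-tract sensitivity and per-segment precision.

    Sensitivity: fraction of detectable tracts (>= ``min_tract_bp``, with
    >= min_snps markers) matched by a same-sample same-chromosome segment
    at reciprocal overlap >= ``overlap``. Precision: fraction of detected
    segments >= ``min_tract_bp`` matching any planted tract of that sample
    the same way.
    """
    by_sample: dict[tuple[str, str], list[ROHSegment]] = {}
    for s in segments:
        by_sample.setdefault((s.sample_id, str(s.chromosome)), []).append(s)
    det = detectable_tracts(truth, panel, params, min_tract_bp)
    hits = 0
    for r in det.itertuples(index=False):
        cands = by_sample.get((r.sample_id, str(r.chromosome)), [])
        if any(
            reciprocal_overlap(s.start_bp, s.end_bp, r.start_bp, r.end_bp) >= overlap
            for s in cands
        ):
            hits += 1
    truth_by: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in truth.tracts.itertuples(index=False):
        truth_by.setdefault((r.sample_id, str(r.chromosome)), []).append(
            (int(r.start_bp), int(r.end_bp))
        )
    big_segs = [s for s in segments if s.length_bp >= min_tract_bp]
    tp = 0
    for s in big_segs:
        cands = truth_by.get((s.sample_id, str(s.chromosome)), [])
        if any(
            reciprocal_overlap(s.start_bp, s.end_bp, a, b) >= overlap for a, b in cands
        ):
            tp += 1
    return RecoveryMetrics(
        sensitivity=hits / len(det) if len(det) else float("nan"),
        precision=tp / len(big_segs) if big_segs else float("nan"),
        n_detectable_tracts=len(det),
        n_segments_evaluated=len(big_segs),
    )


def froh_phi_slope(
    segments: Sequence[ROHSegment], truth: TruthSet, sample_ids: Iterable[str]
) -> float:
    """Least-squares slope of detected F_ROH on planted autozygous
    fraction phi, both over the simulated genome length."""
    froh = {sid: 0.0 for sid in sample_ids}
    for s in segments:
        froh[s.sample_id] += s.length_bp / truth.genome_bp
    x = np.array([truth.phi[sid] for sid in froh])
    y = np.array([froh[sid] for sid in froh])
    return float(np.polyfit(x, y, 1)[0])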