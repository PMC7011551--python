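"""Identity-by-state distances, principal components, cluster outliers.

The IBS similarity of two samples is the mean, over SNPs called in both,
of (2 - |x_i - x_j|) / 2 — 1 for identical genotypes, 1/2 for a
hom/het pair, 0 for opposite homozygotes. Principal components come from
the classical multidimensional-scaling route: eigendecomposition of the
double-centred similarity matrix, so the configuration reproduces the
IBS geometry rather than the raw genotype covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypePanel


@dataclass
class PairwiseMatrix:
    """Square symmetric matrix over samples; ``kind`` is 'similarity'
    (diagonal 1) or 'distance' (diagonal 0, distance = 1 - similarity)."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "similarity"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("matrix shape does not match sample list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if self.kind not in ("similarity", "distance"):
            raise ValueError("kind must be 'similarity' or 'distance'")
        self.values = v

    def as_distance(self) -> "PairwiseMatrix":
        if self.kind == "distance":
            return self
        return PairwiseMatrix(self.sample_ids, 1.0 - self.values, "distance")

    def as_similarity(self) -> "PairwiseMatrix":
        if self.kind == "similarity":
            return self
        return PairwiseMatrix(self.sample_ids, 1.0 - self.values, "similarity")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PCResult:
    coordinates: np.ndarray  # samples x components
    variance_explained: np.ndarray
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, columns=[f"PC{i + 1}" for i in range(k)]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


def ibs_similarity(panel: GenotypePanel) -> PairwiseMatrix:
    """Pairwise IBS similarity, averaging over jointly non-missing SNPs."""
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = panel.dosages
    a = (d == 0).astype(np.float32)
    h = (d == 1).astype(np.float32)
    b = (d == 2).astype(np.float32)
    valid = (d != MISSING).astype(np.float32)
    # per-SNP similarity: 1 for equal states, 0.5 for hom/het, 0 for opposite homs
    same = a @ a.T + h @ h.T + b @ b.T
    half = a @ h.T + h @ a.T + h @ b.T + b @ h.T
    counts = valid @ valid.T
    if (counts == 0).any():
        i, j = np.argwhere(counts == 0)[0]
        ids = panel.samples["sample_id"]
        raise ValueError(
            f"samples {ids.iloc[int(i)]!r} and {ids.iloc[int(j)]!r} share no "
            "non-missing SNPs"
        )
    sim = (same + 0.5 * half) / counts
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return PairwiseMatrix(panel.samples["sample_id"].tolist(), sim.astype(float))


def pca_from_similarity(m: PairwiseMatrix, k: int) -> PCResult:
    """Classical-MDS principal components of an IBS matrix.

    The similarity matrix S (a distance input is converted by S = 1 - D)
    is double-centred, B = J S J; coordinates are the top-k eigenvectors
    scaled by the square roots of their (non-negative) eigenvalues, and
    variance explained is each eigenvalue over the sum of positive
    eigenvalues. Squared distances in the embedding equal 2(1 - S_ij) for
    an L1-type similarity, so the configuration reproduces IBS geometry.
    The sign of each component is fixed by making its largest-magnitude
    loading positive.
    """
    n = len(m.sample_ids)
    if not 0 < k < n:
        raise ValueError("k must satisfy 0 < k < n_samples")
    s = m.as_similarity().values
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = j @ s @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    total = pos.sum()
    coords = eigvec[:, :k] * np.sqrt(pos[:k])
    for c in range(k):
        col = coords[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, c] = -col
    ve = pos[:k] / total if total > 0 else np.zeros(k)
    return PCResult(coords, ve, list(m.sample_ids))


def flag_cluster_outliers(
    pcs: PCResult, labels: pd.Series | dict[str, str], n_sd: float = 3.0
) -> list[str]:
    """Samples lying outside their own population's PC1-PC2 cluster.

    A sample is flagged when its Euclidean distance from its population
    centroid exceeds ``n_sd`` times that population's root-mean-square
    centroid distance. This makes the visual "outside its breed cluster"
    judgement deterministic.
    """
    if pcs.coordinates.shape[1] < 2:
        raise ValueError("need at least 2 components")
    lab = pd.Series(labels)
    missing = [s for s in pcs.sample_ids if s not in lab.index]
    if missing:
        raise KeyError(f"samples without population label: {missing[:5]}")
    xy = pcs.coordinates[:, :2]
    pops = lab.loc[pcs.sample_ids].to_numpy()
    flagged: list[str] = []
    for pop in pd.unique(pops):
        idx = np.flatnonzero(pops == pop)
        if idx.size < 3:
            raise ValueError(f"population {pop!r} has fewer than 3 members")
        centroid = xy[idx].mean(axis=0)
        dist = np.linalg.norm(xy[idx] - centroid, axis=1)
        rms = float(np.sqrt(np.mean(dist**2)))
        if rms == 0.0:
            continue
        for i in idx[dist > n_sd * rms]:
            flagged.append(pcs.sample_ids[int(i)])
    return sorted(flagged, key=pcs.sample_ids.index)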