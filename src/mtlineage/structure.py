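"""Population structure: haplotypic AMOVA, pairwise ΦST, classical MDS.

AMOVA decomposes the total molecular variance of inter-individual
distances into among- and within-population components.  The haplotypic
formulation operates on squared Euclidean inter-individual distances;
with the per-site 0/1 difference kernel used throughout this package the
squared Euclidean distance *is* the number of differing sites, so the
site-difference counts enter the sums of squares directly
(pairwise-difference AMOVA, as in ARLEQUIN):

    SS_total      = (1 / N)  Σ_{i<j} d_ij
    SS_within(k)  = (1 / n_k) Σ_{i<j in k} d_ij
    σ²_w = MS_within;   σ²_a = (MS_among − MS_within) / n'

with the usual n-weighted coefficient n' = (N − Σ n_k²/N) / (P − 1) for
unequal sample sizes, and ΦST = σ²_a / (σ²_a + σ²_w).  Significance is
assessed by permuting individuals among populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codec import pairwise_distance
from .diversity import PopulationSample


@dataclass(frozen=True)
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    phi_st: float
    pct_among: float
    pct_within: float
    ss_among: float
    ss_within: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    raw: np.ndarray | None = None  # un-floored values where applicable

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise ValueError("distance matrix must be symmetric, zero-diagonal, non-negative")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls(labels=[str(c) for c in df.columns], d=df.to_numpy(dtype=float))


@dataclass(frozen=True)
class MdsResult:
    labels: list[str]
    coordinates: np.ndarray  # (n_labels, k)
    eigenvalues: np.ndarray  # descending, all returned

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def _distance_matrix(pops: list[PopulationSample]) -> tuple[np.ndarray, list[int]]:
    """Full inter-individual site-difference matrix and population sizes."""
    frame, policy = pops[0].frame, pops[0].policy
    for p in pops:
        if p.frame != frame:
            raise ValueError("all populations must share a reading frame")
    hs = [h for p in pops for h in p.haplotypes]
    n = len(hs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(hs[i], hs[j], policy)
    return d, [p.n for p in pops]


def _variance_components(d: np.ndarray, groups: list[np.ndarray]) -> tuple[float, ...]:
    """(sigma2_among, sigma2_within, phi, ss_among, ss_within) from a
    squared-distance matrix and index arrays per population."""
    n_tot = sum(len(g) for g in groups)
    n_pops = len(groups)
    ss_total = d.sum() / 2 / n_tot
    ss_within = 0.0
    for g in groups:
        sub = d[np.ix_(g, g)]
        ss_within += sub.sum() / 2 / len(g)
    ss_among = ss_total - ss_within
    df_among = n_pops - 1
    df_within = n_tot - n_pops
    ms_within = ss_within / df_within
    ms_among = ss_among / df_among
    n_prime = (n_tot - sum(len(g) ** 2 for g in groups) / n_tot) / df_among
    sigma2_within = ms_within
    sigma2_among = (ms_among - ms_within) / n_prime
    denom = sigma2_among + sigma2_within
    phi = sigma2_among / denom if denom > 0 else 0.0
    return sigma2_among, sigma2_within, phi, ss_among, ss_within


def amova_two_level(
    pops: list[PopulationSample],
    n_permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level haplotypic AMOVA across populations.

    With n_permutations > 0 a permutation p-value for ΦST is computed by
    reshuffling individuals among populations (fixed sizes); a seed is
    then mandatory for reproducibility.
    """
    if len(pops) < 2:
        raise ValueError("AMOVA requires at least two populations")
    for p in pops:
        if p.n < 2:
            raise ValueError(f"population {p.name!r} has n < 2")
    d, sizes = _distance_matrix(pops)
    bounds = np.cumsum([0] + sizes)
    groups = [np.arange(bounds[i], bounds[i + 1]) for i in range(len(sizes))]
    s2a, s2w, phi, ssa, ssw = _variance_components(d, groups)
    total = s2a + s2w
    pct_among = 100.0 * s2a / total if total > 0 else 0.0
    p_value = None
    if n_permutations > 0:
        if seed is None:
            raise ValueError("a seed is mandatory when permuting")
        rng = np.random.default_rng(seed)
        n_tot = sum(sizes)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n_tot)
            pg = [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
            phi_p = _variance_components(d, pg)[2]
            if phi_p >= phi:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return AmovaResult(
        sigma2_among=s2a,
        sigma2_within=s2w,
        phi_st=phi,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        ss_among=ssa,
        ss_within=ssw,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_fst_matrix(pops: list[PopulationSample]) -> DistanceMatrix:
    """Pairwise ΦST matrix from two-population AMOVAs.

    Negative estimates are floored at 0 in `d` (for use as a distance
    matrix, e.g. MDS input); the raw values are kept in `raw`.
    """
    labels = [p.name for p in pops]
    k = len(pops)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = amova_two_level([pops[i], pops[j]])
            raw[i, j] = raw[j, i] = res.phi_st
    return DistanceMatrix(labels=labels, d=np.maximum(raw, 0.0), raw=raw)


def classical_mds(D: DistanceMatrix, k: int = 2) -> MdsResult:
    """Classical (metric) multidimensional scaling.

    Double-centers −½·J·D²·J, eigendecomposes, and returns the top-k
    coordinates scaled by the square roots of the eigenvalues.  Axis
    signs are fixed by forcing the largest-magnitude coordinate on each
    axis positive, so embeddings are fully deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = D.d
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d * d) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int(np.sum(eigval > max(1e-12, 1e-9 * abs(eigval[0]))))
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} dimensions",
            stacklevel=2,
        )
        k = max(n_pos, 0)
    coords = eigvec[:, :k] * np.sqrt(np.maximum(eigval[:k], 0.0))
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return MdsResult(labels=list(D.labels), coordinates=coords, eigenvalues=eigval)
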