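"""HKY85 substitution model with discrete-Γ rate heterogeneity.

The HKY85 model distinguishes transitions from transversions (ratio
parameter κ) under arbitrary base frequencies π.  Rate variation across
sites follows a mean-one gamma distribution with shape α, discretised
into equal-probability categories whose rates are the category means
(Yang 1994).  The rate matrix is normalised so branch lengths are in
expected substitutions per site.

Provides transition probabilities, a Felsenstein pruning log-likelihood
over site patterns, and forward sequence simulation on a tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in (("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")):
    _TRANSITION[_BASE_INDEX[_a], _BASE_INDEX[_b]] = True


@dataclass(frozen=True)
class HkyModel:
    kappa: float = 10.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float | None = 0.5  # None = rate homogeneity
    n_categories: int = 4

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        f = np.asarray(self.freqs, dtype=float)
        if f.min() <= 0 or not np.isclose(f.sum(), 1.0):
            raise ValueError("base frequencies must be positive and sum to 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """Normalised HKY85 rate matrix (rows sum to 0, mean rate 1)."""
        f = np.asarray(self.freqs)
        q = np.where(_TRANSITION, self.kappa, 1.0) * f[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(f * np.diag(q)).sum()
        return q / scale

    def category_rates(self) -> np.ndarray:
        """Mean-one discrete gamma rates (equal-probability categories)."""
        if self.alpha is None:
            return np.array([1.0])
        a = self.alpha
        k = self.n_categories
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        # category means via the incomplete-gamma identity
        upper = gamma_dist.cdf(edges[1:], a + 1, scale=1.0 / a)
        lower = gamma_dist.cdf(edges[:-1], a + 1, scale=1.0 / a)
        return (upper - lower) * k

    def _eigen(self):
        f = np.asarray(self.freqs)
        q = self.rate_matrix()
        s = np.sqrt(f)
        sym = (q * s[:, None]) / s[None, :]
        w, u = np.linalg.eigh((sym + sym.T) / 2)
        right = u / s[:, None]  # diag(1/s) @ u
        left = u.T * s[None, :]  # u.T @ diag(s)
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for a branch of t expected substitutions per site."""
        w, right, left = self._eigen()
        p = (right * np.exp(w * t)[None, :]) @ left
        return np.clip(p, 0.0, 1.0)


def encode_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """(names, matrix of base codes), columns = sites; non-ACGT -> -1."""
    names = list(sequences)
    length = {len(s) for s in sequences.values()}
    if len(length) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    mat = np.full((len(names), length.pop()), -1, dtype=np.int8)
    for i, name in enumerate(names):
        seq = sequences[name].upper()
        for j, b in enumerate(seq):
            mat[i, j] = _BASE_INDEX.get(b, -1)
    return names, mat


def site_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress alignment columns to unique patterns with counts."""
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts


def tree_log_likelihood(
    post_order: list,
    children: dict,
    branch_lengths: dict,
    leaf_rows: dict,
    patterns: np.ndarray,
    counts: np.ndarray,
    model: HkyModel,
) -> float:
    """Felsenstein pruning over pattern-compressed sites.

    `post_order` lists node ids, children last-to-first resolved before
    parents; `children[n]` lists child ids; `branch_lengths[n]` is the
    length of the branch above n; `leaf_rows[n]` indexes the pattern
    matrix row for leaves.
    """
    f = np.asarray(model.freqs)
    rates = model.category_rates()
    n_pat = patterns.shape[1]
    lik_total = np.zeros(n_pat)
    w, right, left = model._eigen()
    for rate in rates:
        partial: dict = {}
        for node in post_order:
            kids = children.get(node, [])
            if not kids:
                row = patterns[leaf_rows[node]]
                L = np.zeros((n_pat, 4))
                known = row >= 0
                L[known, row[known]] = 1.0
                L[~known] = 1.0
                partial[node] = L
            else:
                L = np.ones((n_pat, 4))
                for kid in kids:
                    t = branch_lengths[kid] * rate
                    p = np.clip((right * np.exp(w * t)[None, :]) @ left, 0.0, None)
                    L *= partial.pop(kid) @ p.T
                partial[node] = L
        root = post_order[-1]
        lik_total += partial[root] @ f / len(rates)
    if np.any(lik_total <= 0):
        return -np.inf
    return float(counts @ np.log(lik_total))


def evolve_sequences(
    root_seq: str,
    post_order: list,
    children: dict,
    branch_lengths: dict,
    model: HkyModel,
    rng: np.random.Generator,
) -> dict:
    """Simulate sequences down a tree; returns {node: sequence} for all
    nodes.  Per-site rates are drawn from the continuous Gamma(α) when the
    model has rate heterogeneity."""
    n = len(root_seq)
    site_rates = (
        rng.gamma(model.alpha, 1.0 / model.alpha, size=n)
        if model.alpha is not None
        else np.ones(n)
    )
    w, right, left = model._eigen()
    root = post_order[-1]
    seqs = {root: np.array([_BASE_INDEX[b] for b in root_seq.upper()], dtype=np.int64)}

    def simulate(node, parent_codes):
        t = branch_lengths[node]
        # per-site transition probabilities P(t * r_site)[parent_base, :]
        expo = np.exp(np.outer(site_rates * t, w))  # (n, 4)
        probs = np.einsum("ik,ik,kj->ij", right[parent_codes], expo, left)
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        out = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
        out = np.minimum(out, 3).astype(np.int64)
        seqs[node] = out
        for kid in children.get(node, []):
            simulate(kid, out)

    for kid in children.get(root, []):
        simulate(kid, seqs[root])
    return {
        node: "".join(BASES[c] for c in codes) for node, codes in seqs.items()
    }
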