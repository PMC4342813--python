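"""Molecular divergence and founder-age estimation.

Two complementary routes from a mutation-annotated genealogy to an age:

* the ρ statistic (see :mod:`mtlineage.genealogy`): average mutational
  distance of a clade's haplotypes to the clade root, with the
  genealogy-based heuristic standard error σ;
* maximum-likelihood molecular divergence under HKY85 with Γ-distributed
  rates: branch lengths are optimised by Felsenstein pruning on a fixed
  (parsimony) topology, and a clade's divergence is the mean root-to-tip
  expected number of substitutions over the whole molecule, with a
  standard error from the curvature of the profile likelihood.

Divergences (in substitutions on the whole molecule) are converted to
years by a molecular clock: either a plain linear rate (years per
substitution), or a user-supplied corrected (mildly non-linear,
purifying-selection-aware) mapping.  ``fit_effective_rate`` calibrates an
effective linear rate from published (divergence, age) pairs when the
corrected clock's coefficients are not at hand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .genealogy import Genealogy, Node
from .hky import HkyModel, encode_alignment, site_patterns, tree_log_likelihood


@dataclass(frozen=True)
class DivergenceEstimate:
    ml_divergence: float  # substitutions over the whole molecule
    se: float
    n: int  # leaves in the clade


@dataclass(frozen=True)
class AgeEstimate:
    T: float  # kiloyears
    dT: float  # kiloyears


@dataclass(frozen=True)
class ClockModel:
    """Mapping from whole-molecule substitutions to years.

    kind='linear': T = divergence * rate.  kind='corrected': T via a
    tabulated monotone map (divergence_grid, years_grid) with T(0)=0;
    errors propagate through the local slope.
    """

    kind: str = "linear"
    rate: float = 2824.0  # years per substitution, whole molecule
    correction: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "corrected"):
            raise ValueError("clock kind must be 'linear' or 'corrected'")
        if self.kind == "corrected":
            if self.correction is None:
                raise ValueError("corrected clock requires a correction table")
            div, yrs = (np.asarray(a, dtype=float) for a in self.correction)
            if div[0] != 0 or yrs[0] != 0:
                raise ValueError("correction table must start at (0, 0)")
            if np.any(np.diff(div) <= 0) or np.any(np.diff(yrs) < 0):
                raise ValueError("correction table must be monotone non-decreasing")


def convert_to_years(div: float, err: float, clock: ClockModel) -> AgeEstimate:
    """Divergence (whole-molecule substitutions) -> age in kiloyears."""
    if div < 0 or err < 0:
        raise ValueError("divergence and error must be non-negative")
    if clock.kind == "linear":
        return AgeEstimate(T=div * clock.rate / 1000.0, dT=err * clock.rate / 1000.0)
    grid_d, grid_y = (np.asarray(a, dtype=float) for a in clock.correction)
    if div > grid_d[-1]:
        raise ValueError(
            f"divergence {div} outside correction table domain (max {grid_d[-1]})"
        )
    years = float(np.interp(div, grid_d, grid_y))
    seg = min(int(np.searchsorted(grid_d, div, side="right")), len(grid_d) - 1)
    slope = (grid_y[seg] - grid_y[seg - 1]) / (grid_d[seg] - grid_d[seg - 1])
    return AgeEstimate(T=years / 1000.0, dT=err * slope / 1000.0)


@dataclass(frozen=True)
class RateFit:
    rate: float  # years per substitution
    residuals: tuple[float, ...]  # years, observed - fitted
    relative_spread: float  # max |residual| / fitted, flags non-linearity


def fit_effective_rate(pairs: list[tuple[float, float]]) -> RateFit:
    """Least-squares effective linear clock rate through the origin.

    `pairs` are (divergence in substitutions, age in years).  The residual
    report flags curvature of the underlying (corrected) clock.
    """
    if not pairs:
        raise ValueError("need at least one (divergence, age) pair")
    d = np.array([p[0] for p in pairs], dtype=float)
    t = np.array([p[1] for p in pairs], dtype=float)
    if np.any(d <= 0):
        raise ValueError("divergences must be positive")
    rate = float((d * t).sum() / (d * d).sum())
    fitted = rate * d
    resid = t - fitted
    return RateFit(
        rate=rate,
        residuals=tuple(float(r) for r in resid),
        relative_spread=float(np.max(np.abs(resid) / fitted)),
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood divergence on a fixed topology


def _tree_arrays(tree: Genealogy, names: list[str]):
    """Flatten a Genealogy into pruning arrays; the root haplotype's
    sequence (if present in `names`) is attached as a zero-length pendant
    tip so the ancestral state is anchored by its observed sequence."""
    nodes = list(tree.root.walk())
    node_id = {n: i for i, n in enumerate(nodes)}
    children: dict[int, list[int]] = {}
    leaf_rows: dict[int, int] = {}
    free_branches: list[int] = []
    init: list[float] = []
    for n in nodes:
        i = node_id[n]
        if n.children:
            children[i] = [node_id[c] for c in n.children]
        else:
            if n.name not in names:
                raise ValueError(f"no sequence for leaf {n.name!r}")
            leaf_rows[i] = names.index(n.name)
        if n.parent is not None:
            free_branches.append(i)
            init.append(max(len(n.mutations), 0.5))
    root_name = tree.root.name or "root"
    pseudo = None
    if root_name in names:
        pseudo = len(nodes)
        children.setdefault(node_id[tree.root], []).append(pseudo)
        leaf_rows[pseudo] = names.index(root_name)
    post = [node_id[n] for n in reversed(nodes)]
    if pseudo is not None:
        post = [pseudo] + post
    return node_id, post, children, leaf_rows, free_branches, np.array(init), pseudo


def ml_divergence(
    tree: Genealogy,
    sequences: dict[str, str],
    model: HkyModel | None = None,
    clades: dict[str, Node] | None = None,
    estimate_kappa: bool = True,
    estimate_alpha: bool = True,
) -> dict[str, DivergenceEstimate]:
    """ML branch lengths under HKY85+Γ on the fixed topology; per-clade
    divergence = mean root-to-tip substitutions x sequence length.

    `sequences` maps leaf names (and optionally the root name, anchoring
    the ancestral node) to aligned sequences.  Base frequencies are
    empirical.  Raises RuntimeError if the optimiser fails to converge.
    """
    names, mat = encode_alignment(sequences)
    L = mat.shape[1]
    patterns, counts = site_patterns(mat)
    if model is None:
        obs = np.bincount(mat[mat >= 0], minlength=4).astype(float)
        freqs = tuple(obs / obs.sum())
        model = HkyModel(kappa=10.0, freqs=freqs, alpha=0.5)
    node_id, post, children, leaf_rows, free, init, pseudo = _tree_arrays(tree, names)

    n_b = len(free)
    x0 = np.concatenate(
        [
            np.log(init / L + 1e-7),
            [np.log(model.kappa)] if estimate_kappa else [],
            [np.log(model.alpha)] if (estimate_alpha and model.alpha is not None) else [],
        ]
    )

    def unpack(x):
        lengths = dict(zip(free, np.exp(x[:n_b])))
        if pseudo is not None:
            lengths[pseudo] = 0.0
        k = n_b
        kappa = model.kappa
        alpha = model.alpha
        if estimate_kappa:
            kappa = float(np.exp(x[k]))
            k += 1
        if estimate_alpha and model.alpha is not None:
            alpha = float(np.exp(x[k]))
            k += 1
        m = HkyModel(kappa=kappa, freqs=model.freqs, alpha=alpha,
                     n_categories=model.n_categories)
        return lengths, m

    def negloglik(x):
        lengths, m = unpack(x)
        ll = tree_log_likelihood(post, children, lengths, leaf_rows,
                                 patterns, counts, m)
        return -ll

    res = minimize(negloglik, x0, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-12})
    if not np.isfinite(res.fun) or (not res.success and res.status not in (1, 2)):
        raise RuntimeError(f"branch-length optimisation failed: {res.message}")
    lengths, fitted_model = unpack(res.x)

    if clades is None:
        clades = {"root": tree.root}
    out: dict[str, DivergenceEstimate] = {}
    for name, top in clades.items():
        leaves = [lf for lf in top.leaves() if lf.name in sequences]
        paths = []
        clade_nodes = set()
        for lf in leaves:
            node, total = lf, 0.0
            while node is not top:
                clade_nodes.add(node_id[node])
                total += lengths[node_id[node]]
                node = node.parent
            paths.append(total)
        div_per_site = float(np.mean(paths))
        divergence = div_per_site * L

        # profile-curvature SE: scale the clade's branch lengths jointly
        def nll_scale(s: float) -> float:
            scaled = dict(lengths)
            for i in clade_nodes:
                scaled[i] = lengths[i] * s
            return -tree_log_likelihood(post, children, scaled, leaf_rows,
                                        patterns, counts, fitted_model)

        h = 0.02
        d2 = (nll_scale(1 + h) - 2 * nll_scale(1.0) + nll_scale(1 - h)) / h**2
        se = divergence / np.sqrt(d2) if d2 > 0 else float("nan")
        out[name] = DivergenceEstimate(
            ml_divergence=divergence, se=float(se), n=len(leaves)
        )
    return out


def ml_pairwise_distance(seq_a: str, seq_b: str, model: HkyModel) -> float:
    """ML distance (substitutions/site) between two aligned sequences.

    With κ=1, equal base frequencies and no rate heterogeneity this is the
    Jukes-Cantor distance.
    """
    names, mat = encode_alignment({"a": seq_a, "b": seq_b})
    patterns, counts = site_patterns(mat)
    post = [0, 1, 2]
    children = {2: [0, 1]}
    leaf_rows = {0: 0, 1: 1}

    def nll(t):
        lengths = {0: float(t) / 2, 1: float(t) / 2}
        return -tree_log_likelihood(post, children, lengths, leaf_rows,
                                    patterns, counts, model)

    res = minimize_scalar(nll, bounds=(1e-9, 5.0), method="bounded",
                          options={"xatol": 1e-12})
    return float(res.x)
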