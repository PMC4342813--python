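"""Mutation-annotated genealogies and maximum-parsimony tree search.

A Genealogy is a rooted tree whose branches carry explicit mutation
lists: each branch records the variants gained (or reverted) between its
parent and child node, so every leaf haplotype equals the root haplotype
edited along its root path.  This is the substrate shared by parsimony
reconstruction, the ρ founder-age statistic, and likelihood dating.

Parsimony uses multistate nucleotide characters at variable sites (not
binary presence/absence), so back-mutations are represented naturally;
Fitch optimisation assigns branch mutations, with ambiguous placements
resolved deterministically toward the root.  Recurrent mutations (same
site changing on more than one branch) are flagged, and reversions —
mutations restoring a state the lineage carried higher up — are rendered
with the conventional ``@`` prefix.

Search strategy: exhaustive enumeration of all topologies for small
inputs (up to 7 haplotypes plus the supplied ancestral root, i.e. at
most 10,395 unrooted topologies), and seeded stepwise addition with NNI
hill-climbing beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .codec import (
    DELETION,
    Haplotype,
    Variant,
    deletion,
    insertion,
    substitution,
)

REF_STATE = "."  # reference (no-variant) state
GAP_STATE = "-"  # deleted
NOINS_STATE = ""  # insertion absent


@dataclass(frozen=True)
class Mutation:
    """A state change on a branch at one site (np, insertion index)."""

    site: tuple[int, int]
    from_state: str
    to_state: str
    recurrent: bool = False
    reversion: bool = False

    @property
    def token(self) -> str:
        pos, idx = self.site
        if self.reversion:
            return f"@{pos}" if idx == 0 else f"@{pos}.{idx}"
        if idx >= 1:
            return f"{pos}.{idx}{self.to_state}" if self.to_state else f"{pos}.{idx}d"
        if self.to_state == GAP_STATE:
            return f"{pos}del"
        if self.to_state == REF_STATE:
            return f"@{pos}"
        return f"{pos}{self.to_state}"

    def rendered(self) -> str:
        """Token with recurrent sites marked by underscores (text stand-in
        for the underlining used in published tree figures)."""
        return f"_{self.token}_" if self.recurrent else self.token


class Node:
    """Tree node; `mutations` annotate the branch from the parent."""

    __slots__ = ("children", "parent", "name", "mutations", "states")

    def __init__(self, name: str | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.name = name
        self.mutations: list[Mutation] = []
        self.states: dict[tuple[int, int], str] = {}

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Genealogy:
    """Rooted, mutation-annotated tree over sampled haplotypes."""

    root: Node
    root_haplotype: Haplotype
    parsimony_score: int = 0
    leaves: dict[str, Node] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.leaves:
            self.leaves = {lf.name: lf for lf in self.root.leaves() if lf.name}

    def n_leaves(self, node: Node | None = None) -> int:
        return len((node or self.root).leaves())

    def path_mutation_count(self, leaf: Node, top: Node | None = None) -> int:
        """Number of mutations on the path from `top` (default root) down to `leaf`."""
        top = top or self.root
        count, node = 0, leaf
        while node is not top:
            if node.parent is None:
                raise ValueError("leaf is not below the given clade root")
            count += len(node.mutations)
            node = node.parent
        return count

    def leaf_haplotype(self, sample_id: str) -> Haplotype:
        """Reconstruct a leaf by editing the root haplotype along its root
        path (reversions cancel earlier mutations)."""
        leaf = self.leaves[sample_id]
        states: dict[tuple[int, int], str] = {
            v.site: _variant_state(v) for v in self.root_haplotype.variants
        }
        path = []
        node = leaf
        while node is not self.root:
            path.append(node)
            node = node.parent
        for node in reversed(path):
            for m in node.mutations:
                states[m.site] = m.to_state
        variants = []
        for (pos, idx), state in states.items():
            v = _state_to_variant(pos, idx, state)
            if v is not None:
                variants.append(v)
        return Haplotype(tuple(variants), self.root_haplotype.frame, sample_id=sample_id)

    def total_mutations(self) -> int:
        return sum(len(n.mutations) for n in self.root.walk())

    # -- output ------------------------------------------------------------

    def newick(self, lengths: dict[Node, float] | None = None) -> str:
        def render(node: Node) -> str:
            label = node.name or ""
            muts = " ".join(m.rendered() for m in node.mutations)
            comment = f"[&muts={muts!r}]" if muts else ""
            length = lengths[node] if lengths else len(node.mutations)
            body = (
                label
                if node.is_leaf
                else "(" + ",".join(render(c) for c in node.children) + ")" + label
            )
            return f"{body}{comment}:{length:g}"

        inner = (
            "(" + ",".join(render(c) for c in self.root.children) + ")"
            if self.root.children
            else ""
        )
        return f"{inner}{self.root.name or 'root'};"

    def indented_text(self) -> str:
        """Figure-style plain-text rendering: one branch per line with its
        mutations; recurrent sites underlined (_token_), reversions @."""
        lines = [f"{self.root.name or 'root'}"]

        def render(node: Node, depth: int) -> None:
            muts = " ".join(m.rendered() for m in node.mutations) or "(no change)"
            tag = f"  {node.name}" if node.is_leaf else ""
            lines.append("  " * depth + f"|- {muts}{tag}")
            for c in node.children:
                render(c, depth + 1)

        for c in self.root.children:
            render(c, 1)
        return "\n".join(lines)


def _variant_state(v: Variant) -> str:
    if v.kind == DELETION:
        return GAP_STATE
    return v.derived


def _state_to_variant(pos: int, idx: int, state: str) -> Variant | None:
    if idx >= 1:
        return insertion(pos, idx, state) if state not in (NOINS_STATE, REF_STATE) else None
    if state == REF_STATE:
        return None
    if state == GAP_STATE:
        return deletion(pos)
    return substitution(pos, state)


# ---------------------------------------------------------------------------
# Character coding


def _encode_characters(taxa: list[Haplotype]):
    """Multistate characters at variable sites.

    Returns (sites, state_names, matrix) where matrix[t, c] is the state
    code of taxon t at character c.  Absent variant = reference state
    ('.' for np sites, '' for insertion slots).
    """
    sites = sorted({v.site for h in taxa for v in h.variants})
    site_index = {s: i for i, s in enumerate(sites)}
    raw = []
    for h in taxa:
        states = [REF_STATE if s[1] == 0 else NOINS_STATE for s in sites]
        for v in h.variants:
            states[site_index[v.site]] = _variant_state(v)
        raw.append(states)
    keep, state_names, columns = [], [], []
    for c in range(len(sites)):
        col = [raw[t][c] for t in range(len(taxa))]
        names = sorted(set(col))
        if len(names) < 2:
            continue  # invariant across taxa
        code = {s: i for i, s in enumerate(names)}
        keep.append(sites[c])
        state_names.append(names)
        columns.append([code[s] for s in col])
    matrix = (
        np.array(columns, dtype=np.int64).T
        if columns
        else np.zeros((len(taxa), 0), dtype=np.int64)
    )
    return keep, state_names, matrix


# ---------------------------------------------------------------------------
# Fitch scoring over nested-tuple topologies
#
# An unrooted topology over m taxa is represented as a rooted binary
# nested tuple over taxa 1..m-1, with taxon 0 (the supplied ancestral
# haplotype) attached at the top.


def _fitch(tree, leaf_masks: np.ndarray):
    if not isinstance(tree, tuple):
        return leaf_masks[tree], 0
    ml, sl = _fitch(tree[0], leaf_masks)
    mr, sr = _fitch(tree[1], leaf_masks)
    inter = ml & mr
    empty = inter == 0
    mask = np.where(empty, ml | mr, inter)
    return mask, sl + sr + int(empty.sum())


def _score(tree, leaf_masks: np.ndarray) -> int:
    mask, score = _fitch(tree, leaf_masks)
    return score + int((mask & leaf_masks[0] == 0).sum())


def _rooted_trees(taxa: list[int]):
    """All rooted binary tree shapes over `taxa` (nested tuples)."""
    if len(taxa) == 1:
        yield taxa[0]
        return
    first, rest = taxa[0], taxa[1:]
    for sub in _rooted_trees(rest):
        yield from _insertions(sub, first)


def _insertions(tree, leaf: int):
    yield (leaf, tree)
    if isinstance(tree, tuple):
        for left in _insertions(tree[0], leaf):
            yield (left, tree[1])
        for right in _insertions(tree[1], leaf):
            yield (tree[0], right)


def _nni_neighbors(tree):
    if not isinstance(tree, tuple):
        return
    x, y = tree
    if isinstance(x, tuple):
        a, b = x
        yield ((a, y), b)
        yield ((b, y), a)
    if isinstance(y, tuple):
        c, d = y
        yield (c, (x, d))
        yield (d, (x, c))
    for xn in _nni_neighbors(x):
        yield (xn, y)
    for yn in _nni_neighbors(y):
        yield (x, yn)


def _canon(tree):
    """Canonical form for deduplicating unordered topologies."""
    if not isinstance(tree, tuple):
        return tree

    def key(t):
        return t if not isinstance(t, tuple) else min(key(t[0]), key(t[1]))

    a, b = _canon(tree[0]), _canon(tree[1])
    return (a, b) if key(a) <= key(b) else (b, a)


@dataclass(frozen=True)
class SearchConfig:
    method: str = "auto"  # auto | exhaustive | heuristic
    exhaustive_limit: int = 7  # max haplotypes (root excluded) for full enumeration
    n_addition_orders: int = 10
    max_trees: int = 100
    seed: int = 0


def build_mp_tree(
    haplotypes: list[Haplotype],
    root: Haplotype,
    search: SearchConfig | None = None,
) -> list[Genealogy]:
    """All most-parsimonious trees (up to a cap) for the haplotypes, rooted
    at the supplied ancestral haplotype."""
    search = search or SearchConfig()
    if len(haplotypes) < 2:
        raise ValueError("need at least two haplotypes")
    ids = [h.sample_id or f"sample{i}" for i, h in enumerate(haplotypes)]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    taxa = [root] + list(haplotypes)
    sites, state_names, matrix = _encode_characters(taxa)
    leaf_masks = (np.uint32(1) << matrix.astype(np.uint32)).astype(np.uint32)

    method = search.method
    if method == "auto":
        method = "exhaustive" if len(haplotypes) <= search.exhaustive_limit else "heuristic"

    indices = list(range(1, len(taxa)))
    if method == "exhaustive":
        best, best_score = [], None
        for tree in _rooted_trees(indices):
            s = _score(tree, leaf_masks)
            if best_score is None or s < best_score:
                best, best_score = [tree], s
            elif s == best_score:
                best.append(tree)
    else:
        rng = np.random.default_rng(search.seed)
        best, best_score = [], None
        for _ in range(search.n_addition_orders):
            order = list(rng.permutation(indices))
            tree = order[0]
            for nxt in order[1:]:
                cands = list(_insertions(tree, nxt))
                scores = [_score(t, leaf_masks) for t in cands]
                tree = cands[int(np.argmin(scores))]
            s = _score(tree, leaf_masks)
            improved = True
            while improved:
                improved = False
                for nb in _nni_neighbors(tree):
                    sn = _score(nb, leaf_masks)
                    if sn < s:
                        tree, s = nb, sn
                        improved = True
                        break
            if best_score is None or s < best_score:
                best, best_score = [tree], s
            elif s == best_score:
                best.append(tree)
            # harvest equally parsimonious NNI neighbours of the optimum
            for nb in _nni_neighbors(tree):
                if _score(nb, leaf_masks) == best_score:
                    best.append(nb)

    unique, seen = [], set()
    for t in best:
        c = _canon(t)
        if c not in seen:
            seen.add(c)
            unique.append(t)
    if len(unique) > search.max_trees:
        warnings.warn(
            f"{len(unique)} equally parsimonious trees; keeping {search.max_trees}",
            stacklevel=2,
        )
        unique = unique[: search.max_trees]

    genealogies = [
        _annotate(t, taxa, ids, sites, state_names, matrix, root, best_score)
        for t in unique
    ]
    return genealogies


def _annotate(tree, taxa, ids, sites, state_names, matrix, root_hap, score) -> Genealogy:
    """Root the topology at the ancestral taxon and assign branch mutations
    by Fitch downpass + deterministic parent-preferring uppass."""
    n_chars = matrix.shape[1]
    root_codes = matrix[0] if n_chars else np.zeros(0, dtype=np.int64)

    def build(sub) -> tuple[Node, np.ndarray]:
        node = Node()
        if not isinstance(sub, tuple):
            node.name = ids[sub - 1]
            mask = (np.uint32(1) << matrix[sub].astype(np.uint32)).astype(np.uint32)
            return node, mask
        left, ml = build(sub[0])
        right, mr = build(sub[1])
        node.add_child(left)
        node.add_child(right)
        inter = ml & mr
        mask = np.where(inter == 0, ml | mr, inter).astype(np.uint32)
        node.states["__mask__"] = mask  # stashed, removed below
        return node, mask

    root_node = Node(name=root_hap.sample_id or "root")
    top, _ = build(tree)
    root_node.add_child(top)

    # uppass: assign state codes, preferring the parent's state
    def assign(node: Node, parent_codes: np.ndarray) -> None:
        if node.is_leaf:
            idx = ids.index(node.name) + 1
            codes = matrix[idx].copy()
        else:
            mask = node.states.pop("__mask__")
            codes = np.empty(n_chars, dtype=np.int64)
            for c in range(n_chars):
                if mask[c] >> parent_codes[c] & 1:
                    codes[c] = parent_codes[c]
                else:
                    codes[c] = _lowest_bit(int(mask[c]))
        node.states = {
            sites[c]: state_names[c][codes[c]] for c in range(n_chars)
        }
        node.mutations = [
            Mutation(
                site=sites[c],
                from_state=state_names[c][parent_codes[c]],
                to_state=state_names[c][codes[c]],
            )
            for c in range(n_chars)
            if codes[c] != parent_codes[c]
        ]
        for child in node.children:
            assign(child, codes)

    root_node.states = {sites[c]: state_names[c][root_codes[c]] for c in range(n_chars)}
    for child in root_node.children:
        assign(child, root_codes)

    _flag_recurrence_and_reversion(root_node)
    gen = Genealogy(root=root_node, root_haplotype=root_hap, parsimony_score=score)
    return gen


def _lowest_bit(mask: int) -> int:
    return (mask & -mask).bit_length() - 1


def _flag_recurrence_and_reversion(root: Node) -> None:
    site_branches: dict[tuple[int, int], int] = {}
    for node in root.walk():
        for m in node.mutations:
            site_branches[m.site] = site_branches.get(m.site, 0) + 1

    def descend(node: Node, history: dict[tuple[int, int], list[str]]) -> None:
        local: dict[tuple[int, int], list[str]] = {}
        new_muts = []
        for m in node.mutations:
            past = history.get(m.site, [])
            new_muts.append(
                Mutation(
                    site=m.site,
                    from_state=m.from_state,
                    to_state=m.to_state,
                    recurrent=site_branches[m.site] > 1,
                    reversion=m.to_state in past,
                )
            )
            local.setdefault(m.site, []).append(m.from_state)
        node.mutations = new_muts
        if node.children:
            child_hist = {k: list(v) for k, v in history.items()}
            for site, states in local.items():
                child_hist.setdefault(site, []).extend(states)
            for c in node.children:
                descend(c, child_hist)

    for c in root.children:
        descend(c, {})


# ---------------------------------------------------------------------------
# rho / sigma founder statistics


@dataclass(frozen=True)
class RhoEstimate:
    rho: float
    sigma: float
    n: int


def rho_sigma(tree: Genealogy, clade_root: Node | None = None) -> RhoEstimate:
    """ρ: mean mutation count from the clade root to its sampled leaves.

    σ is the genealogy-based heuristic standard error:
    σ² = Σ_branches (n_i / n)² · l_i, summing over all branches below the
    clade root, with n_i descendant leaves and l_i mutations per branch.
    """
    top = clade_root or tree.root
    leaves = top.leaves()
    if not leaves:
        raise ValueError("empty clade")
    n = len(leaves)
    rho = sum(tree.path_mutation_count(lf, top) for lf in leaves) / n
    var = 0.0
    for node in top.walk():
        if node is top:
            continue
        n_i = len(node.leaves())
        var += (n_i / n) ** 2 * len(node.mutations)
    return RhoEstimate(rho=rho, sigma=float(np.sqrt(var)), n=n)
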