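"""Maximum-parsimony machinery for binary somatic-variant characters.

Trees are built over tumor samples plus an all-absent germline
outgroup, which roots the display (the germline state is biologically
known to be ancestral). Internally a tree is a nested tuple of leaf
indices; leaf 0 is the outgroup and attaches at the root, so the set of
rooted ingroup shapes enumerated here is exactly the set of unrooted
topologies over all leaves.

Identical matrix columns are collapsed to weighted site patterns, which
makes Fitch scoring, tree search and 500-replicate bootstraps on
low-burden cohorts (a handful of distinct presence patterns) fast.

Search: exhaustive enumeration guarantees the global minimum up to 9
leaves; beyond that, greedy stepwise addition followed by
nearest-neighbor-interchange hill climbing is used, with deterministic
lexicographic tie-breaking throughout.
"""

from __future__ import annotations

import numpy as np

Tree = int | tuple  # leaf index, or (left, right)

EXHAUSTIVE_LEAF_LIMIT = 9


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tree utilities
# ---------------------------------------------------------------------------


def min_leaf(t: Tree) -> int:
    while isinstance(t, tuple):
        t = t[0]
    return t


def canonical(t: Tree) -> Tree:
    """Sort children by smallest contained leaf index, recursively."""
    if isinstance(t, int):
        return t
    a, b = canonical(t[0]), canonical(t[1])
    return (a, b) if min_leaf(a) <= min_leaf(b) else (b, a)


def leaves_of(t: Tree) -> frozenset:
    if isinstance(t, int):
        return frozenset((t,))
    return leaves_of(t[0]) | leaves_of(t[1])


def clades(t: Tree) -> set:
    """All clades (leaf sets of internal nodes) of an ingroup tree,
    including the full ingroup and excluding singletons."""
    out: set = set()

    def rec(node: Tree) -> frozenset:
        if isinstance(node, int):
            return frozenset((node,))
        s = rec(node[0]) | rec(node[1])
        out.add(s)
        return s

    rec(t)
    return out


def internal_splits(t: Tree) -> set:
    """Non-trivial unrooted splits of the full tree (outgroup at root),
    encoded as the ingroup-side leaf sets."""
    n = len(leaves_of(t))
    return {c for c in clades(t) if 1 < len(c) < n}


def insertions(t: Tree, leaf: int) -> list:
    """All trees obtained by attaching ``leaf`` onto any edge of ``t``
    (including above the root)."""
    out = [(t, leaf)]
    if isinstance(t, tuple):
        a, b = t
        out.extend((x, b) for x in insertions(a, leaf))
        out.extend((a, x) for x in insertions(b, leaf))
    return out


def enumerate_trees(leaf_ids: list[int]):
    """Yield every distinct rooted ingroup shape over ``leaf_ids``."""
    if len(leaf_ids) == 1:
        yield leaf_ids[0]
        return
    if len(leaf_ids) == 2:
        yield (leaf_ids[0], leaf_ids[1])
        return

    def rec(partial: Tree, remaining: list[int]):
        if not remaining:
            yield partial
            return
        head, rest = remaining[0], remaining[1:]
        for t in insertions(partial, head):
            yield from rec(t, rest)

    yield from rec((leaf_ids[0], leaf_ids[1]), leaf_ids[2:])


def nni_neighbors(t: Tree) -> list:
    """One-step nearest-neighbor interchanges of an ingroup tree."""
    out = []
    if isinstance(t, int):
        return out
    a, b = t
    if isinstance(a, tuple):
        x, y = a
        out.append(((x, b), y))
        out.append(((y, b), x))
    if isinstance(b, tuple):
        x, y = b
        out.append(((x, a), y))
        out.append(((y, a), x))
    out.extend((sub, b) for sub in nni_neighbors(a))
    out.extend((a, sub) for sub in nni_neighbors(b))
    return [canonical(n) for n in out]


# ---------------------------------------------------------------------------
# pattern compression and Fitch scoring
# ---------------------------------------------------------------------------


def compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical columns of a (leaves x sites) binary matrix.

    Returns ``(patterns, weights)`` with ``patterns`` of shape
    (leaves, n_patterns) and integer ``weights`` summing to the number
    of sites.
    """
    m = np.asarray(matrix, dtype=np.int8)
    if m.ndim != 2:
        raise TreeError("matrix must be 2-D (leaves x sites)")
    if m.shape[1] == 0:
        return m, np.zeros(0)
    patterns, counts = np.unique(m, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class FitchScorer:
    """Weighted-pattern Fitch small-parsimony scorer with subtree caching.

    State sets per pattern are encoded as int8 bitmasks: 1 = {absent},
    2 = {present}, 3 = both.
    """

    def __init__(self, patterns: np.ndarray, weights: np.ndarray):
        self.patterns = np.asarray(patterns, dtype=np.int8)
        self.weights = np.asarray(weights, dtype=float)
        self.n_leaves = self.patterns.shape[0]
        self._leaf_states = np.where(self.patterns == 1, 2, 1).astype(np.int8)
        self._cache: dict = {}

    def set_weights(self, weights: np.ndarray) -> None:
        self.weights = np.asarray(weights, dtype=float)
        self._cache.clear()

    def _down(self, t: Tree) -> tuple[np.ndarray, float]:
        if isinstance(t, int):
            return self._leaf_states[t], 0.0
        hit = self._cache.get(t)
        if hit is not None:
            return hit
        (ls, lc), (rs, rc) = self._down(t[0]), self._down(t[1])
        inter = ls & rs
        empty = inter == 0
        out = np.where(empty, ls | rs, inter)
        cost = lc + rc + float(self.weights[empty].sum())
        self._cache[t] = (out, cost)
        return out, cost

    def score(self, ingroup: Tree, outgroup: int = 0) -> float:
        """Parsimony length of the full tree (outgroup joined at the root)."""
        return self._down((outgroup, ingroup))[1]


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _tree_key(t: Tree) -> str:
    return repr(canonical(t))


def exhaustive_search(scorer: FitchScorer, leaf_ids: list[int]) -> tuple[Tree, float]:
    best, best_score, best_key = None, np.inf, None
    for t in enumerate_trees(leaf_ids):
        s = scorer.score(t)
        if s < best_score - 1e-9:
            best, best_score, best_key = canonical(t), s, _tree_key(t)
        elif abs(s - best_score) <= 1e-9:
            k = _tree_key(t)
            if k < best_key:
                best, best_key = canonical(t), k
    return best, best_score


def _stepwise_nni_once(scorer: FitchScorer, order: list[int]) -> tuple[Tree, float]:
    t: Tree = (order[0], order[1])
    for leaf in order[2:]:
        cands = [canonical(c) for c in insertions(t, leaf)]
        scored = sorted((scorer.score(c), _tree_key(c), c) for c in cands)
        t = scored[0][2]
    score = scorer.score(t)
    improved = True
    while improved:
        improved = False
        neighbors = {_tree_key(n): n for n in nni_neighbors(t)}
        scored = sorted((scorer.score(n), k) for k, n in neighbors.items())
        if scored and scored[0][0] < score - 1e-9:
            score = scored[0][0]
            t = neighbors[scored[0][1]]
            improved = True
    return canonical(t), score


def stepwise_nni_search(
    scorer: FitchScorer, leaf_ids: list[int], n_restarts: int = 5
) -> tuple[Tree, float]:
    """Greedy stepwise addition followed by NNI hill climbing.

    NNI alone can stall in local optima, so the search restarts from
    ``n_restarts`` deterministic addition orders (the given order plus
    fixed-seed shuffles) and keeps the best tree, breaking score ties
    lexicographically."""
    best: tuple[tuple[float, str], Tree] | None = None
    for r in range(max(1, n_restarts)):
        order = list(leaf_ids)
        if r > 0:
            np.random.default_rng(1_000_003 * r).shuffle(order)
        t, s = _stepwise_nni_once(scorer, order)
        key = (s, _tree_key(t))
        if best is None or key < best[0]:
            best = (key, t)
    return best[1], best[0][0]


def search_mp(
    patterns: np.ndarray,
    weights: np.ndarray,
    exhaustive_limit: int = EXHAUSTIVE_LEAF_LIMIT,
) -> tuple[Tree, float]:
    """Maximum-parsimony ingroup tree for a pattern matrix whose row 0
    is the outgroup. Exhaustive (global optimum) up to
    ``exhaustive_limit`` total leaves, heuristic beyond."""
    n_leaves = patterns.shape[0]
    if n_leaves < 3:
        raise TreeError(f"tree search needs >= 3 leaves including the outgroup, got {n_leaves}")
    scorer = FitchScorer(patterns, weights)
    ingroup_ids = list(range(1, n_leaves))
    if n_leaves <= exhaustive_limit:
        return exhaustive_search(scorer, ingroup_ids)
    return stepwise_nni_search(scorer, ingroup_ids)


# ---------------------------------------------------------------------------
# branch assignment and bootstrap
# ---------------------------------------------------------------------------


def assign_changes(
    ingroup: Tree, patterns: np.ndarray, weights: np.ndarray, outgroup: int = 0
) -> dict[frozenset, float]:
    """Per-branch state-change counts from a deterministic Fitch backtrace.

    The root is fixed to the germline (absent) state whenever the Fitch
    root set allows it; descending, a node takes its parent's state when
    compatible, otherwise prefers absent. For homoplasy-free columns the
    resulting placement is the unique most-parsimonious one. Branches
    are keyed by the leaf set below them (singleton = terminal branch).
    """
    scorer = FitchScorer(patterns, weights)
    full: Tree = (outgroup, ingroup)
    down: dict[int, np.ndarray] = {}
    children: dict[int, tuple[int, int]] = {}
    leafsets: dict[int, frozenset] = {}
    counter = [0]

    def build(t: Tree) -> int:
        nid = counter[0]
        counter[0] += 1
        if isinstance(t, int):
            down[nid] = scorer._leaf_states[t]
            leafsets[nid] = frozenset((t,))
            return nid
        a = build(t[0])
        b = build(t[1])
        inter = down[a] & down[b]
        down[nid] = np.where(inter == 0, down[a] | down[b], inter)
        children[nid] = (a, b)
        leafsets[nid] = leafsets[a] | leafsets[b]
        return nid

    root = build(full)
    n_pat = patterns.shape[1]
    state: dict[int, np.ndarray] = {}
    state[root] = np.where(down[root] & 1, 0, 1).astype(np.int8)  # prefer absent at root
    counts: dict[frozenset, float] = {}
    order = [root]
    while order:
        nid = order.pop()
        for child in children.get(nid, ()):
            parent_state = state[nid]
            # child takes parent state when its Fitch set allows it
            parent_bit = np.left_shift(np.int8(1), parent_state)
            compatible = (down[child] & parent_bit) != 0
            prefer = np.where(down[child] & 1, 0, 1).astype(np.int8)
            state[child] = np.where(compatible, parent_state, prefer).astype(np.int8)
            changed = state[child] != parent_state
            branch = leafsets[child]
            counts[branch] = counts.get(branch, 0.0) + float(weights[changed].sum())
            order.append(child)
    return counts


def bootstrap_splits(
    ingroup: Tree,
    patterns: np.ndarray,
    weights: np.ndarray,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
    exhaustive_limit: int = 6,
) -> dict[frozenset, float]:
    """Bootstrap support (percent of replicates, column resampling) for
    each internal split of ``ingroup``.

    Replicate searches use exhaustive enumeration for small trees and
    the stepwise+NNI heuristic otherwise.
    """
    if n_reps <= 0:
        raise TreeError("n_reps must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_leaves = patterns.shape[0]
    total = weights.sum()
    if total <= 0:
        raise TreeError("empty matrix")
    probs = weights / total
    n_cols = int(round(total))
    targets = internal_splits(ingroup)
    hits = {s: 0 for s in targets}
    scorer = FitchScorer(patterns, weights)
    ingroup_ids = list(range(1, n_leaves))
    exhaustive = n_leaves <= exhaustive_limit
    for _ in range(n_reps):
        scorer.set_weights(rng.multinomial(n_cols, probs).astype(float))
        if exhaustive:
            rep_tree, _ = exhaustive_search(scorer, ingroup_ids)
        else:
            rep_tree, _ = stepwise_nni_search(scorer, ingroup_ids)
        rep_splits = internal_splits(rep_tree)
        for s in targets:
            if s in rep_splits:
                hits[s] += 1
    return {s: 100.0 * h / n_reps for s, h in hits.items()}


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def to_newick(
    ingroup: Tree,
    names: list[str],
    branch_counts: dict[frozenset, float] | None = None,
    supports: dict[frozenset, float] | None = None,
    outgroup: int = 0,
) -> str:
    """Rooted newick with branch lengths = assigned SNV counts and
    bootstrap supports as internal node labels."""

    def blen(leafset: frozenset) -> str:
        if branch_counts is None:
            return ""
        return f":{branch_counts.get(leafset, 0.0):g}"

    def rec(t: Tree) -> tuple[str, frozenset]:
        if isinstance(t, int):
            return f"{names[t]}{blen(frozenset((t,)))}", frozenset((t,))
        ls, lset = rec(t[0])
        rs, rset = rec(t[1])
        full = lset | rset
        label = ""
        if supports is not None and full in supports:
            label = f"{supports[full]:g}"
        return f"({ls},{rs}){label}{blen(full)}", full

    ing, ingset = rec(ingroup)
    out = f"{names[outgroup]}{blen(frozenset((outgroup,)))}"
    return f"({out},{ing});"
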