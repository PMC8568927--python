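"""Fitch scoring, MP search, branch assignment, bootstrap — checked
against dendropy's Fitch pass and brute-force enumeration."""

import numpy as np
import pytest

from clonetrace import parsimony as P


def random_matrix(rng, n_leaves, n_cols, p=0.4):
    m = (rng.random((n_leaves, n_cols)) < p).astype(np.int8)
    m[0] = 0  # outgroup all-absent
    keep = m.sum(axis=0) > 0
    return m[:, keep]


def random_tree(rng, leaf_ids):
    ids = list(leaf_ids)
    rng.shuffle(ids)
    t = (ids[0], ids[1])
    for leaf in ids[2:]:
        options = P.insertions(t, leaf)
        t = options[int(rng.integers(len(options)))]
    return P.canonical(t)


# --- independent oracles -----------------------------------------------------


def fitch_oracle(full_tree, column):
    """Set-based single-column Fitch, written independently of the
    package's vectorised scorer."""

    def rec(t):
        if isinstance(t, int):
            return {column[t]}, 0
        (ls, lc), (rs, rc) = rec(t[0]), rec(t[1])
        inter = ls & rs
        if inter:
            return inter, lc + rc
        return ls | rs, lc + rc + 1

    return rec(full_tree)[1]


def dendropy_score(full_tree, matrix):
    import dendropy
    from dendropy.model.parsimony import fitch_down_pass

    n = matrix.shape[0]
    names = [f"t{i}" for i in range(n)]
    nexus = (
        "#NEXUS\nBEGIN DATA;\n"
        f"DIMENSIONS NTAX={n} NCHAR={matrix.shape[1]};\n"
        'FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\nMATRIX\n'
        + "\n".join(f"{names[i]} {''.join(map(str, matrix[i]))}" for i in range(n))
        + "\n;\nEND;\n"
    )
    taxa = dendropy.TaxonNamespace()
    chars = dendropy.StandardCharacterMatrix.get(data=nexus, schema="nexus", taxon_namespace=taxa)

    def newick(t):
        if isinstance(t, int):
            return names[t]
        return f"({newick(t[0])},{newick(t[1])})"

    tree = dendropy.Tree.get(
        data=newick(full_tree) + ";", schema="newick", taxon_namespace=taxa
    )
    tree.encode_bipartitions()
    state_map = chars.taxon_state_sets_map(gaps_as_missing=True)
    return fitch_down_pass(tree.postorder_node_iter(), taxon_state_sets_map=state_map)


# --- tests -------------------------------------------------------------------


def test_fitch_all_zero_matrix():
    m = np.zeros((4, 5), dtype=np.int8)
    pats, w = P.compress_patterns(m)
    assert P.FitchScorer(pats, w).score((1, (2, 3))) == 0


def test_fitch_perfect_phylogeny_equals_columns():
    """Nested carrier sets: each character changes exactly once."""
    # outgroup, then 4 samples; columns: {1,2,3,4}, {1,2}, {3,4}, {1}, {3}
    m = np.array(
        [
            [0, 0, 0, 0, 0],
            [1, 1, 0, 1, 0],
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 1],
            [1, 0, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    pats, w = P.compress_patterns(m)
    tree = ((1, 2), (3, 4))
    assert P.FitchScorer(pats, w).score(tree) == m.shape[1]


@pytest.mark.parametrize("seed", range(8))
def test_fitch_matches_dendropy_and_set_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 8))
    m = random_matrix(rng, n, 15)
    if m.shape[1] == 0:
        pytest.skip("degenerate draw")
    tree = random_tree(rng, range(1, n))
    full = (0, tree)
    pats, w = P.compress_patterns(m)
    ours = P.FitchScorer(pats, w).score(tree)
    by_columns = sum(fitch_oracle(full, m[:, j]) for j in range(m.shape[1]))
    assert ours == by_columns
    assert ours == dendropy_score(full, m)


@pytest.mark.parametrize("seed", range(5))
def test_search_equals_bruteforce_minimum(seed):
    rng = np.random.default_rng(100 + seed)
    n = 6
    m = random_matrix(rng, n, 12)
    pats, w = P.compress_patterns(m)
    tree, score = P.search_mp(pats, w)
    brute = min(
        P.FitchScorer(pats, w).score(t) for t in P.enumerate_trees(list(range(1, n)))
    )
    assert score == brute
    # heuristic path reaches the same optimum on these small instances
    _, h_score = P.stepwise_nni_search(P.FitchScorer(pats, w), list(range(1, n)))
    assert h_score == brute


def test_label_invariance():
    rng = np.random.default_rng(7)
    m = random_matrix(rng, 6, 20)
    perm = np.array([0, 3, 1, 4, 2, 5])  # keep outgroup fixed
    pats, w = P.compress_patterns(m)
    t1, s1 = P.search_mp(pats, w)
    pats2, w2 = P.compress_patterns(m[perm])
    t2, s2 = P.search_mp(pats2, w2)
    assert s1 == s2
    inv = {int(np.where(perm == i)[0][0]): i for i in range(6)}
    splits2_mapped = {
        frozenset(perm[i] for i in c) for c in P.internal_splits(t2)
    }
    assert splits2_mapped == P.internal_splits(t1)
    del inv


def test_star_matrix_deterministic_and_terminal_counts():
    """All-private variants: no grouping signal; the tie-break returns
    one canonical topology and every change sits on a terminal branch."""
    m = np.vstack([np.zeros(5, dtype=np.int8), np.eye(5, dtype=np.int8)])
    pats, w = P.compress_patterns(m)
    t1, s1 = P.search_mp(pats, w)
    t2, s2 = P.search_mp(pats, w)
    assert t1 == t2 and s1 == s2 == 5
    counts = P.assign_changes(t1, pats, w)
    for clade, c in counts.items():
        if len(clade) > 1:
            assert c == 0
        elif clade != frozenset({0}):
            assert c == 1


def test_branch_counts_conserved_when_homoplasy_free():
    m = np.array(
        [
            [0, 0, 0, 0, 0],
            [1, 1, 0, 1, 0],
            [1, 1, 0, 0, 0],
            [1, 0, 1, 0, 1],
            [1, 0, 1, 0, 0],
        ],
        dtype=np.int8,
    )
    pats, w = P.compress_patterns(m)
    tree, score = P.search_mp(pats, w)
    counts = P.assign_changes(tree, pats, w)
    assert sum(counts.values()) == m.shape[1] == score


def test_homoplastic_column_backtrace_placement():
    """Carriers {A, B} on a tree grouping A with C: the documented
    backtrace places one change on the ingroup stem and one reversal on
    the C terminal branch."""
    m = np.array([[0], [1], [1], [0]], dtype=np.int8)  # O, A, B, C
    tree = ((1, 3), 2)
    pats, w = P.compress_patterns(m)
    assert P.FitchScorer(pats, w).score(tree) == 2
    counts = {k: v for k, v in P.assign_changes(tree, pats, w).items() if v}
    assert counts == {frozenset({1, 2, 3}): 1.0, frozenset({3}): 1.0}


def _trunk_matrix(rng, trunk, clade=(1, 2, 3), n_leaves=6, n_noise=300):
    cols = []
    for _ in range(trunk):
        c = np.zeros(n_leaves, dtype=np.int8)
        c[list(clade)] = 1
        cols.append(c)
    for _ in range(n_noise):
        c = np.zeros(n_leaves, dtype=np.int8)
        c[rng.choice(range(1, n_leaves), size=2, replace=False)] = 1
        cols.append(c)
    return np.array(cols).T


def test_bootstrap_support_monotone_in_trunk_signal():
    rng = np.random.default_rng(3)
    clade = frozenset({1, 2, 3})
    target_tree = (((1, 2), 3), (4, 5))
    supports = {}
    for trunk in (0, 8, 200):
        m = _trunk_matrix(np.random.default_rng(3), trunk)
        pats, w = P.compress_patterns(m)
        sup = P.bootstrap_splits(target_tree, pats, w, n_reps=100, seed=rng)
        supports[trunk] = sup[clade]
    assert supports[0] < 50
    assert supports[0] <= supports[8] <= supports[200]
    assert supports[200] >= 98


def test_bootstrap_rejects_bad_reps():
    m = np.vstack([np.zeros(4, dtype=np.int8), np.eye(4, dtype=np.int8)])
    pats, w = P.compress_patterns(m)
    with pytest.raises(P.TreeError):
        P.bootstrap_splits(((1, 2), (3, 4)), pats, w, n_reps=0)


def test_newick_roundtrips_through_dendropy():
    import dendropy

    tree = ((1, 2), 3)
    names = ["normal", "A", "B", "C"]
    counts = {frozenset({1, 2}): 5.0, frozenset({1}): 1.0, frozenset({2}): 2.0,
              frozenset({3}): 3.0, frozenset({1, 2, 3}): 10.0, frozenset({0}): 0.0}
    sup = {frozenset({1, 2}): 97.0}
    nwk = P.to_newick(tree, names, counts, sup)
    t = dendropy.Tree.get(data=nwk, schema="newick")
    assert {leaf.taxon.label for leaf in t.leaf_node_iter()} == set(names)
    assert "97" in nwk and ":5" in nwk
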