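"""Pairwise shared-SNV analysis, overlap classification and
maximum-parsimony phylogenies over tumor samples.

The clonality question for multifocal tumors is settled by exact
set-intersection of filtered somatic SNV keys between samples: clonally
related samples (a metastatic primary and its metastases) share their
trunk mutations by the hundreds, while independent primaries share
essentially nothing. Small overlaps are classified by count and VAF
structure into contamination traces (low-VAF in exactly one sample),
early-developmental ("embryonic") variants (few, clonal VAF in all
carriers), or left unexplained.

Phylogenies are maximum-parsimony trees over the binary
presence/absence character matrix, rooted at an all-absent germline
outgroup, with per-branch assigned SNV counts and column-resampling
bootstrap supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd

from . import parsimony
from .filtering import InputError, is_snv, variant_keys
from .genome import chrom_sort_key

OUTGROUP = "normal"


# ---------------------------------------------------------------------------
# pairwise shared variants
# ---------------------------------------------------------------------------


@dataclass
class SharedMatrix:
    """Symmetric pairwise shared-SNV counts; diagonal = per-sample totals."""

    samples: tuple[str, ...]
    counts: pd.DataFrame
    pair_variants: dict[frozenset, frozenset]
    keysets: dict[str, frozenset]

    def shared(self, a: str, b: str) -> int:
        return int(self.counts.loc[a, b])

    def variants(self, a: str, b: str) -> frozenset:
        return self.pair_variants[frozenset((a, b))]


def _keyset(df: pd.DataFrame, sample: str) -> frozenset:
    if df.empty:
        return frozenset()
    keys = variant_keys(df)
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise InputError(f"duplicate variant key {dup} in sample {sample}")
    return frozenset(keys)


def pairwise_shared(callsets: dict[str, pd.DataFrame]) -> SharedMatrix:
    """Exact pairwise intersection counts of (chrom, pos, ref, alt) keys."""
    if len(callsets) < 2:
        raise InputError("pairwise analysis needs >= 2 samples")
    samples = tuple(callsets)
    keysets = {s: _keyset(df, s) for s, df in callsets.items()}
    counts = pd.DataFrame(0, index=samples, columns=samples, dtype=int)
    pair_variants: dict[frozenset, frozenset] = {}
    for i, a in enumerate(samples):
        counts.loc[a, a] = len(keysets[a])
        for b in samples[i + 1 :]:
            inter = keysets[a] & keysets[b]
            pair_variants[frozenset((a, b))] = frozenset(inter)
            counts.loc[a, b] = counts.loc[b, a] = len(inter)
    return SharedMatrix(samples, counts, pair_variants, keysets)


def shared_in_all(callsets: dict[str, pd.DataFrame], samples) -> frozenset:
    """Variant keys present in every one of ``samples`` (n-way overlap)."""
    sets = [_keyset(callsets[s], s) for s in samples]
    return frozenset(frozenset.intersection(*sets)) if sets else frozenset()


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapThresholds:
    """Decision thresholds for classifying a cross-sample SNV overlap.

    Defaults separate the three observed regimes by wide margins: clonal
    trunks run in the hundreds at clonal VAF; handling-contamination
    traces sit below 10% VAF in exactly one sample; early-developmental
    overlaps are small (<= 20) with clonal VAF in every carrier.
    """

    min_trunk: int = 50
    clonal_floor: float = 0.10
    trace_ceiling: float = 0.10
    embryonic_max: int = 20


@dataclass
class OverlapClass:
    label: str  # clonal_trunk | contamination_trace | embryonic | unexplained
    count: int
    median_vaf: dict[str, float]


def classify_overlap(
    vafs_by_sample: dict[str, list[float]],
    thresholds: OverlapThresholds | None = None,
) -> OverlapClass:
    """Classify a shared-variant set from its per-sample VAF distributions.

    ``vafs_by_sample`` maps each carrier sample to the VAFs of the
    shared variants in that sample (equal lengths, one entry per shared
    variant).
    """
    th = thresholds or OverlapThresholds()
    if not vafs_by_sample:
        raise InputError("empty shared set")
    lengths = {len(v) for v in vafs_by_sample.values()}
    if len(lengths) != 1 or lengths == {0}:
        raise InputError(f"inconsistent or empty VAF lists: lengths {sorted(lengths)}")
    for s, vs in vafs_by_sample.items():
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vs):
            raise InputError(f"missing VAF for a shared variant in sample {s}")
    count = lengths.pop()
    med = {s: float(median(v)) for s, v in vafs_by_sample.items()}
    clonal = {s: m >= th.clonal_floor for s, m in med.items()}
    low = [s for s, m in med.items() if m < th.trace_ceiling]
    if count >= th.min_trunk and all(clonal.values()):
        label = "clonal_trunk"
    elif len(low) == 1 and all(clonal[s] for s in med if s not in low):
        label = "contamination_trace"
    elif count <= th.embryonic_max and all(clonal.values()):
        label = "embryonic"
    else:
        label = "unexplained"
    return OverlapClass(label, count, med)


def overlap_vafs(
    callsets: dict[str, pd.DataFrame], samples, keys: frozenset
) -> dict[str, list[float]]:
    """Per-sample VAFs of the shared variant set, in a fixed key order."""
    order = sorted(keys)
    out: dict[str, list[float]] = {}
    for s in samples:
        df = callsets[s]
        lookup = dict(zip(variant_keys(df), df["vaf"])) if len(df) else {}
        out[s] = [lookup.get(k, float("nan")) for k in order]
    return out


# ---------------------------------------------------------------------------
# character matrix and trees
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Binary samples x SNVs presence matrix with a germline outgroup row."""

    df: pd.DataFrame  # rows: samples then outgroup; columns: variant keys

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(n for n in self.df.index if n != OUTGROUP)

    @property
    def leaf_names(self) -> list[str]:
        """Outgroup first (leaf 0), then samples in matrix order."""
        return [OUTGROUP, *self.samples]

    def to_patterns(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.df.loc[self.leaf_names].to_numpy(dtype=np.int8)
        return parsimony.compress_patterns(m)

    def n_sites(self) -> int:
        return self.df.shape[1]


def build_character_matrix(callsets: dict[str, pd.DataFrame]) -> CharacterMatrix:
    """Binary presence matrix over the union of SNV keys (indels are
    excluded), with deterministic column order (chrom, pos, alt) and an
    all-absent germline outgroup row appended."""
    if not callsets:
        raise InputError("no samples")
    keysets = {}
    for s, df in callsets.items():
        snvs = df[is_snv(df)] if len(df) else df
        keysets[s] = _keyset(snvs, s)
    all_keys = sorted(
        set().union(*keysets.values()),
        key=lambda k: (chrom_sort_key(k[0]), k[1], k[3]),
    )
    data = np.zeros((len(callsets) + 1, len(all_keys)), dtype=np.int8)
    samples = list(callsets)
    for i, s in enumerate(samples):
        ks = keysets[s]
        data[i] = [1 if k in ks else 0 for k in all_keys]
    df = pd.DataFrame(data, index=samples + [OUTGROUP], columns=pd.Index(all_keys))
    return CharacterMatrix(df)


@dataclass
class PhyloTree:
    """Rooted MP tree over samples, rooted at the germline outgroup."""

    matrix: CharacterMatrix
    ingroup: parsimony.Tree  # nested tuple over leaf indices (0 = outgroup)
    score: float
    branch_counts: dict[frozenset, float] = field(default_factory=dict)  # name sets
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return self.matrix.leaf_names

    def clades(self) -> set:
        names = self.leaf_names
        return {frozenset(names[i] for i in c) for c in parsimony.clades(self.ingroup)}

    def newick(self) -> str:
        names = self.leaf_names
        idx = {n: i for i, n in enumerate(names)}

        def reindex(d: dict[frozenset, float]) -> dict[frozenset, float]:
            return {frozenset(idx[n] for n in k): v for k, v in d.items()}

        return parsimony.to_newick(
            self.ingroup,
            names,
            branch_counts=reindex(self.branch_counts) if self.branch_counts else None,
            supports=reindex(self.supports) if self.supports else None,
        )


def _tree_to_indices(tree, name_index: dict[str, int]):
    if isinstance(tree, str):
        return name_index[tree]
    a, b = tree
    return (_tree_to_indices(a, name_index), _tree_to_indices(b, name_index))


def fitch_score(tree, matrix: CharacterMatrix) -> float:
    """Parsimony length of a given topology (nested tuples of sample
    names, outgroup excluded — it joins at the root)."""
    names = matrix.leaf_names
    idx = {n: i for i, n in enumerate(names)}
    ingroup = _tree_to_indices(tree, idx)
    if parsimony.leaves_of(ingroup) != frozenset(range(1, len(names))):
        raise InputError("tree leaves do not match matrix samples")
    patterns, weights = matrix.to_patterns()
    return parsimony.FitchScorer(patterns, weights).score(ingroup)


def search_mp_tree(matrix: CharacterMatrix, exhaustive_limit: int = 9) -> PhyloTree:
    """Maximum-parsimony tree; exhaustive (guaranteed optimum) up to
    ``exhaustive_limit`` leaves, stepwise addition + NNI beyond.
    Refuses with < 3 leaves."""
    patterns, weights = matrix.to_patterns()
    if patterns.shape[0] < 3:
        raise InputError(
            f"tree building needs >= 3 leaves (incl. outgroup), got {patterns.shape[0]}"
        )
    ingroup, score = parsimony.search_mp(patterns, weights, exhaustive_limit)
    return PhyloTree(matrix=matrix, ingroup=ingroup, score=score)


def assign_branch_counts(tree: PhyloTree) -> PhyloTree:
    """Attach per-branch SNV counts from the deterministic Fitch backtrace."""
    patterns, weights = tree.matrix.to_patterns()
    counts = parsimony.assign_changes(tree.ingroup, patterns, weights)
    names = tree.leaf_names
    tree.branch_counts = {
        frozenset(names[i] for i in clade): c for clade, c in counts.items()
    }
    return tree


def bootstrap_support(
    tree: PhyloTree, n_reps: int = 500, seed: int | np.random.Generator = 0
) -> PhyloTree:
    """Column-resampling bootstrap support (%) for each internal branch."""
    if len(tree.leaf_names) < 4:
        raise InputError("bootstrap needs >= 4 leaves")
    patterns, weights = tree.matrix.to_patterns()
    supports = parsimony.bootstrap_splits(tree.ingroup, patterns, weights, n_reps, seed)
    names = tree.leaf_names
    tree.supports = {frozenset(names[i] for i in s): v for s, v in supports.items()}
    return tree


def mp_tree_with_support(
    matrix: CharacterMatrix,
    n_reps: int = 500,
    seed: int | np.random.Generator = 0,
) -> PhyloTree:
    """Convenience: search + branch counts + bootstrap in one call."""
    tree = search_mp_tree(matrix)
    assign_branch_counts(tree)
    if len(tree.leaf_names) >= 4:
        bootstrap_support(tree, n_reps=n_reps, seed=seed)
    return tree
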