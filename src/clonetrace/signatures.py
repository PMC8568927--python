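"""96-channel substitution profiles and signature refitting.

A tumor's autosomal SNVs are binned into the 96 trinucleotide channels
(pyrimidine-centred, purine-reference events reverse-complemented) and
refit against a signature definition matrix by greedy forward
selection with non-negative least squares, capped at four active
signatures per sample — the convention of standard refitting tools.
Weights below a floor are zeroed and the remainder refit, so tiny
spurious loadings do not survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .filtering import InputError
from .genome import CHROM_ORDER
from .signature_bank import SBS96_CHANNELS, channel_for


@dataclass
class Profile96:
    counts: pd.Series  # indexed by SBS96_CHANNELS
    n_skipped: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        t = self.counts.sum()
        if t == 0:
            raise InputError("empty 96-channel profile")
        return self.counts.to_numpy(dtype=float) / t

    def cosine(self, other: np.ndarray | pd.Series) -> float:
        a = self.counts.to_numpy(dtype=float)
        b = np.asarray(other, dtype=float)
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def count_96(mutations: pd.DataFrame, autosomes_only: bool = True) -> Profile96:
    """Build a 96-channel profile from SNV records.

    ``mutations`` needs ``ref``, ``alt`` and ``context`` columns
    (trinucleotide around the site on the reported strand); a ``chrom``
    column restricts counting to autosomes when present. Records with
    malformed contexts are skipped and tallied in ``n_skipped``.
    """
    counts = pd.Series(0, index=pd.Index(SBS96_CHANNELS, name="Type"), dtype=int)
    skipped = 0
    if len(mutations) == 0:
        return Profile96(counts)
    df = mutations
    if autosomes_only and "chrom" in df.columns:
        df = df[df["chrom"].isin(CHROM_ORDER)]
    snv = (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
    df = df[snv]
    for ref, alt, ctx in zip(df["ref"], df["alt"], df["context"]):
        try:
            counts[channel_for(ref, alt, ctx)] += 1
        except (ValueError, TypeError):
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} record(s) with malformed trinucleotide context")
    return Profile96(counts, n_skipped=skipped)


@dataclass
class SignatureFit:
    loadings: pd.Series  # weight per signature; inactive are exactly 0
    residual: float  # L2 norm of (normalized profile - reconstruction)
    n_active: int

    def active(self) -> pd.Series:
        return self.loadings[self.loadings > 0]


def fit_signatures(
    profile: Profile96,
    signature_matrix: pd.DataFrame,
    max_k: int = 4,
    min_weight: float = 0.06,
    tol: float = 1e-4,
) -> SignatureFit:
    """Greedy forward-selection NNLS refit of a 96-channel profile.

    At each step the candidate signature whose inclusion most reduces
    the sum of squared errors between the normalized profile and its
    non-negative least-squares reconstruction is added, stopping at
    ``max_k`` signatures or when the improvement drops below ``tol``.
    Final weights below ``min_weight`` are zeroed and the remaining
    signatures refit. Deterministic; scale-invariant in the profile.
    """
    p = profile.normalized()
    A = signature_matrix.to_numpy(dtype=float)
    if A.shape[0] != 96:
        raise InputError(f"signature matrix has {A.shape[0]} rows, expected 96")
    names = list(signature_matrix.columns)

    def sse_for(active: list[int]) -> tuple[float, np.ndarray]:
        w, rnorm = nnls(A[:, active], p)
        return rnorm**2, w

    active: list[int] = []
    sse = float(p @ p)
    weights = np.zeros(0)
    while len(active) < max_k:
        best = None
        for c in range(A.shape[1]):
            if c in active:
                continue
            cand_sse, cand_w = sse_for(active + [c])
            if best is None or cand_sse < best[0] - 1e-12:
                best = (cand_sse, c, cand_w)
        if best is None or sse - best[0] < tol:
            break
        sse, weights = best[0], best[2]
        active.append(best[1])

    if active:
        keep = [a for a, w in zip(active, weights) if w >= min_weight]
        if keep != active:
            active = keep
            sse, weights = sse_for(active) if active else (float(p @ p), np.zeros(0))

    loadings = pd.Series(0.0, index=pd.Index(names, name="signature"))
    for a, w in zip(active, weights):
        loadings[names[a]] = float(w)
    return SignatureFit(
        loadings=loadings, residual=float(np.sqrt(sse)), n_active=int((loadings > 0).sum())
    )


def fit_table(
    profiles: dict[str, Profile96], signature_matrix: pd.DataFrame, **kwargs
) -> pd.DataFrame:
    """Per-sample loading table (samples x signatures, plus burden and
    residual columns) — the machine-readable 'relative contributions'."""
    rows = {}
    for sample, prof in profiles.items():
        fit = fit_signatures(prof, signature_matrix, **kwargs)
        row = fit.loadings.to_dict()
        row["n_snvs"] = prof.total
        row["residual"] = fit.residual
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")
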