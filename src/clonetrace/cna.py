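"""Copy-number segmentation, whole-chromosome calls, homolog phasing,
the concordance binomial test, chromothripsis detection and a simple
VAF-based purity estimate.

Window read counts (fixed 2,000 bp grid) are turned into median-centred
tumor/normal log2 ratios and segmented by recursive binary splitting on
mean differences. Whole-chromosome loss/gain calls are phased to
chromosome homologs by comparing germline heterozygous-SNP allelic
imbalance between a reference sample and a test sample: a monoallelic
loss pushes retained-homolog SNP alleles toward VAF 1/(2-p) and lost
ones toward (1-p)/(2-p) at purity p, so co- or anti-orientation of the
imbalance identifies same- versus different-homolog events, while VAFs
pinned at 0.5 despite a copy loss indicate a biallelic event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .filtering import InputError
from .genome import chrom_sort_key

LOSS_LOG2 = -0.25
GAIN_LOG2 = 0.20


@dataclass
class WholeChromEvent:
    chrom: str
    sample: str
    kind: str  # loss | gain
    covered_fraction: float
    homolog_call: str = "unphased"
    concordance_fraction: float = float("nan")


@dataclass
class PhaseResult:
    homolog_call: str  # same_as_reference | different_from_reference | biallelic | indeterminate
    concordance_fraction: float
    n_informative: int
    reason: str = ""


@dataclass
class ChromothripsisCall:
    chrom: str
    sample: str
    n_segments: int
    n_state_switches: int
    oscillation_fraction: float
    two_state_fraction: float
    positive: bool


@dataclass
class PurityEstimate:
    purity: float
    n_snvs: int
    below_30pct: bool


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _best_split(vals: np.ndarray, min_windows: int) -> tuple[int, float] | None:
    """Split index maximizing the between-segment SSE reduction; returns
    (index, |mean difference|) or None when no legal split exists."""
    n = len(vals)
    if n < 2 * min_windows:
        return None
    cs = np.cumsum(vals)
    total = cs[-1]
    k = np.arange(min_windows, n - min_windows + 1)
    ml = cs[k - 1] / k
    mr = (total - cs[k - 1]) / (n - k)
    gain = k * (n - k) / n * (ml - mr) ** 2
    i = int(np.argmax(gain))
    return int(k[i]), float(abs(ml[i] - mr[i]))


def _segment_array(vals: np.ndarray, min_windows: int, min_delta: float) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []

    def rec(lo: int, hi: int) -> None:
        split = _best_split(vals[lo:hi], min_windows)
        if split is None or split[1] < min_delta:
            out.append((lo, hi))
            return
        rec(lo, lo + split[0])
        rec(lo + split[0], hi)

    rec(0, len(vals))
    return out


def _state(mean_lr: float, loss_thr: float, gain_thr: float) -> str:
    if mean_lr < loss_thr:
        return "loss"
    if mean_lr > gain_thr:
        return "gain"
    return "neutral"


def segment_logratio(
    windows: pd.DataFrame,
    sample: str,
    min_windows: int = 5,
    min_delta: float = 0.15,
    loss_thr: float = LOSS_LOG2,
    gain_thr: float = GAIN_LOG2,
) -> pd.DataFrame:
    """Segment one sample's window counts against the normal.

    ``windows`` carries ``chrom, start, end, count_normal, count_<sample>``
    on a uniform grid. Log2 ratios are median-centred genome-wide (the
    bulk of the genome is assumed copy-neutral), then each chromosome is
    segmented by recursive binary splitting: the best mean-difference
    split is applied while the difference exceeds ``min_delta`` and both
    sides keep ``min_windows`` windows. Adjacent same-state segments are
    merged, so segments tile each chromosome exactly.
    """
    col = f"count_{sample}"
    if col not in windows.columns:
        raise InputError(f"no column {col} in window table")
    widths = windows["end"] - windows["start"]
    mode = int(widths.mode().iloc[0])
    for _, grp in windows.groupby("chrom"):
        if (grp["end"] - grp["start"]).iloc[:-1].ne(mode).any():
            raise InputError("window grid is not uniform")  # last window per chrom may be short
    t = windows[col].to_numpy(dtype=float)
    n = windows["count_normal"].to_numpy(dtype=float)
    lr = np.log2((t + 0.5) / (n + 0.5))
    # centre on the copy-neutral mode: a plain median is biased when a
    # sizeable genome fraction is altered, so refine it on the windows
    # near the initial estimate
    centre = np.median(lr)
    for _ in range(2):
        near = lr[np.abs(lr - centre) < 0.2]
        if len(near):
            centre = np.median(near)
    lr = lr - centre

    rows = []
    for chrom in sorted(windows["chrom"].unique(), key=chrom_sort_key):
        mask = (windows["chrom"] == chrom).to_numpy()
        starts = windows.loc[mask, "start"].to_numpy()
        ends = windows.loc[mask, "end"].to_numpy()
        vals = lr[mask]
        for lo, hi in _segment_array(vals, min_windows, min_delta):
            mean_lr = float(vals[lo:hi].mean())
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[lo]),
                    "end": int(ends[hi - 1]),
                    "log2_ratio": mean_lr,
                    "state": _state(mean_lr, loss_thr, gain_thr),
                    "n_windows": hi - lo,
                }
            )
    seg = pd.DataFrame(rows)
    return _merge_same_state(seg)


def _merge_same_state(seg: pd.DataFrame) -> pd.DataFrame:
    if seg.empty:
        return seg
    rows = []
    for _, grp in seg.groupby("chrom", sort=False):
        cur = None
        for _, r in grp.iterrows():
            if cur is not None and r["state"] == cur["state"]:
                w = cur["n_windows"] + r["n_windows"]
                cur["log2_ratio"] = (
                    cur["log2_ratio"] * cur["n_windows"] + r["log2_ratio"] * r["n_windows"]
                ) / w
                cur["end"] = r["end"]
                cur["n_windows"] = w
            else:
                if cur is not None:
                    rows.append(cur)
                cur = r.to_dict()
        rows.append(cur)
    return pd.DataFrame(rows).reset_index(drop=True)


def filter_segments(segments: pd.DataFrame, min_bp: int = 25_000) -> pd.DataFrame:
    """Reporting filter: drop segments shorter than ``min_bp`` (25 kb)."""
    if segments.empty:
        return segments
    return segments[(segments["end"] - segments["start"]) >= min_bp].reset_index(drop=True)


# ---------------------------------------------------------------------------
# whole-chromosome events
# ---------------------------------------------------------------------------


def call_whole_chrom(
    segments: pd.DataFrame,
    chrom: str,
    sample: str,
    chrom_length: int,
    min_fraction: float = 0.9,
) -> WholeChromEvent | None:
    """Emit a whole-chromosome loss/gain when >= ``min_fraction`` of the
    chromosome shares one non-neutral state."""
    seg = segments[segments["chrom"] == chrom]
    if seg.empty:
        return None
    for kind in ("loss", "gain"):
        bp = int((seg.loc[seg["state"] == kind, "end"] - seg.loc[seg["state"] == kind, "start"]).sum())
        frac = bp / chrom_length
        if frac >= min_fraction:
            return WholeChromEvent(chrom=chrom, sample=sample, kind=kind, covered_fraction=frac)
    return None


# ---------------------------------------------------------------------------
# homolog phasing
# ---------------------------------------------------------------------------


def informative_het_snps(
    het: pd.DataFrame, chrom: str, het_range: tuple[float, float] = (0.25, 0.75)
) -> pd.DataFrame:
    """Het SNPs on ``chrom`` with blood-normal VAF inside the het window."""
    lo, hi = het_range
    return het[(het["chrom"] == chrom) & het["vaf_normal"].between(lo, hi)]


def phase_event(
    het: pd.DataFrame,
    chrom: str,
    reference_sample: str,
    test_sample: str,
    delta: float = 0.05,
    concordance_threshold: float = 0.9,
    min_snps: int = 20,
    het_range: tuple[float, float] = (0.25, 0.75),
) -> PhaseResult:
    """Phase a whole-chromosome event in ``test_sample`` against the
    reference sample's event on the same chromosome.

    Each SNP is oriented by which allele is elevated (VAF deviating
    from 0.5 by more than ``delta``) in the reference; the concordance
    fraction is the share of those SNPs whose test-sample VAF deviates
    to the same side.
    """
    snps = informative_het_snps(het, chrom, het_range)
    ref_col, test_col = f"vaf_{reference_sample}", f"vaf_{test_sample}"
    for col in (ref_col, test_col):
        if col not in snps.columns:
            raise InputError(f"no column {col} in het-SNP table")
    vref = snps[ref_col].to_numpy(dtype=float)
    vtest = snps[test_col].to_numpy(dtype=float)
    informative = np.abs(vref - 0.5) > delta
    n_inf = int(informative.sum())
    if n_inf < min_snps:
        return PhaseResult("indeterminate", float("nan"), n_inf, reason=f"only {n_inf} informative SNPs")
    vref, vtest = vref[informative], vtest[informative]
    # orient test VAFs by the allele elevated in the reference: a
    # monoallelic event pushes the oriented median to 1/(2-p) (same
    # homolog) or (1-p)/(2-p) (different); a biallelic event leaves it
    # pinned at 0.5 despite the copy loss
    oriented = np.where(vref > 0.5, vtest, 1.0 - vtest)
    if abs(float(np.median(oriented)) - 0.5) < delta:
        return PhaseResult("biallelic", float("nan"), n_inf)
    concord = float(np.mean(oriented > 0.5))
    if concord >= concordance_threshold:
        call = "same_as_reference"
    elif concord <= 1 - concordance_threshold:
        call = "different_from_reference"
    else:
        call = "indeterminate"
    return PhaseResult(call, concord, n_inf)


def is_monoallelic(
    het: pd.DataFrame, chrom: str, sample: str, min_imbalance: float = 0.1
) -> bool:
    """Whether a sample's het-SNP VAFs on ``chrom`` show the allelic
    imbalance of a monoallelic event.

    The median absolute deviation of VAFs from 0.5 is ~0.21 for a
    monoallelic loss at purity 0.6 but stays at read-noise level for a
    biallelic event; ``min_imbalance`` sits between the two regimes.
    """
    snps = informative_het_snps(het, chrom)
    col = f"vaf_{sample}"
    if col not in snps.columns or snps.empty:
        return False
    return float(np.median(np.abs(snps[col].to_numpy(dtype=float) - 0.5))) > min_imbalance


def concordance_binomial_test(n_concordant: int, n_total: int, p0: float = 0.5) -> float:
    """Exact one-sided binomial tail P(X >= n_concordant | n_total, p0)."""
    if n_total < 1:
        raise InputError("binomial test needs at least one trial")
    if not 0 <= n_concordant <= n_total:
        raise InputError(f"n_concordant {n_concordant} outside [0, {n_total}]")
    return float(binomtest(n_concordant, n_total, p0, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# chromothripsis
# ---------------------------------------------------------------------------


def detect_chromothripsis(
    segments: pd.DataFrame,
    chrom: str,
    sample: str,
    min_segments: int = 10,
    min_oscillation: float = 0.8,
    min_two_state: float = 0.9,
) -> ChromothripsisCall:
    """Flag clustered CNAs oscillating between exactly two copy states."""
    seg = segments[segments["chrom"] == chrom]
    states = seg["state"].tolist()
    n = len(states)
    if n < 2:
        return ChromothripsisCall(chrom, sample, n, 0, 0.0, 1.0 if n else 0.0, False)
    switches = sum(a != b for a, b in zip(states, states[1:]))
    top2 = [s for s, _ in pd.Series(states).value_counts().head(2).items()]
    two_state = sum(s in top2 for s in states) / n
    osc = sum(
        a != b and a in top2 and b in top2 for a, b in zip(states, states[1:])
    ) / (n - 1)
    positive = n >= min_segments and osc >= min_oscillation and two_state >= min_two_state
    return ChromothripsisCall(chrom, sample, n, switches, osc, two_state, positive)


# ---------------------------------------------------------------------------
# purity
# ---------------------------------------------------------------------------


def estimate_purity(clonal_vafs, min_snvs: int = 20) -> PurityEstimate:
    """Purity = 2 x median VAF of clonal copy-neutral SNVs, clipped to
    (0, 1]; flagged when below the 30% inclusion floor."""
    vafs = np.asarray(list(clonal_vafs), dtype=float)
    vafs = vafs[~np.isnan(vafs)]
    if len(vafs) < min_snvs:
        raise InputError(f"purity estimate needs >= {min_snvs} clonal VAFs, got {len(vafs)}")
    p = float(np.clip(2 * np.median(vafs), 1e-6, 1.0))
    return PurityEstimate(purity=p, n_snvs=len(vafs), below_30pct=p < 0.30)
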