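"""Strict somatic-call filtering and whitelist relaxed recall.

The strict contract retains a tumor-normal somatic call only when every
enabled rule holds: >= 2 alt reads, VAF >= 0.01, alt support on both
strands, >= 20 reads covering the site in the matched normal, absence
from the normal, presence in both callers' output, and absence from the
population-variant blacklist. Each rejected call is annotated with the
first rule it fails.

For sensitive pairwise shared-variant analysis, variants confidently
called in either member of a sample pair are *whitelisted* and
re-queried in the relaxed (unfiltered) call tables of both samples,
requiring only the minimum read support. This recovers shared
subclonal variants (e.g. contamination traces) that strict filtering
discards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

VariantKey = tuple  # (chrom, pos, ref, alt)


class InputError(ValueError):
    """Malformed input record or table."""


@dataclass(frozen=True)
class FilterConfig:
    min_normal_depth: int = 20
    min_alt_reads: int = 2
    min_vaf: float = 0.01
    require_both_strands: bool = True
    require_caller_intersection: bool = True
    indel_proximity_bp: int = 3
    reject_near_indels: bool = True
    blacklist: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if min(self.min_normal_depth, self.min_alt_reads, self.indel_proximity_bp) < 0 or self.min_vaf < 0:
            raise InputError("filter thresholds must be >= 0")


def variant_keys(df: pd.DataFrame) -> pd.Series:
    """Normalised (chrom, pos, REF, ALT) key per row."""
    return pd.Series(
        list(zip(df["chrom"], df["pos"].astype(int), df["ref"].str.upper(), df["alt"].str.upper())),
        index=df.index,
    )


def is_snv(df: pd.DataFrame) -> pd.Series:
    return (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)


def load_blacklist(path) -> frozenset:
    """Population-variant blacklist: 4-column TSV (chrom pos ref alt,
    with or without header) or a VCF."""
    path = str(path)
    if path.endswith(".vcf") or path.endswith(".vcf.gz"):
        import pysam

        keys = set()
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    keys.add((rec.chrom, rec.pos, rec.ref.upper(), alt.upper()))
        return frozenset(keys)
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["chrom", "pos", "ref", "alt"])
    if df.iloc[0]["chrom"] == "chrom":  # header row present
        df = df.iloc[1:]
    return frozenset(
        zip(df["chrom"], df["pos"].astype(int), df["ref"].str.upper(), df["alt"].str.upper())
    )


# Rule order defines which failure a rejected call is annotated with.
_RULES = (
    "min_alt_reads",
    "min_vaf",
    "both_strands",
    "normal_coverage",
    "present_in_normal",
    "caller_intersection",
    "population_variant",
    "near_indel",
)


def apply_strict_filters(
    calls: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the strict somatic filter contract to one sample's calls.

    Returns ``(retained, rejected)``; ``rejected`` carries a
    ``failed_rule`` column naming the first violated rule. Input order
    is preserved. Raises :class:`InputError` on malformed records
    (VAF outside [0, 1], negative depth).
    """
    config = config or FilterConfig()
    if calls.empty:
        rej = calls.copy()
        rej["failed_rule"] = pd.Series(dtype=str)
        return calls.copy(), rej

    bad = calls[(calls["vaf"] < 0) | (calls["vaf"] > 1) | (calls["depth"] < 0)]
    if len(bad):
        r = bad.iloc[0]
        raise InputError(
            f"malformed call {r['chrom']}:{r['pos']} {r['ref']}>{r['alt']}: "
            f"vaf={r['vaf']}, depth={r['depth']}"
        )

    alt_reads = calls["alt_fwd"].astype(int) + calls["alt_rev"].astype(int)
    fails: dict[str, pd.Series] = {}
    fails["min_alt_reads"] = alt_reads < config.min_alt_reads
    fails["min_vaf"] = calls["vaf"] < config.min_vaf
    if config.require_both_strands:
        fails["both_strands"] = (calls["alt_fwd"] < 1) | (calls["alt_rev"] < 1)
    fails["normal_coverage"] = calls["normal_depth"] < config.min_normal_depth
    fails["present_in_normal"] = calls["in_normal"].astype(bool)
    if config.require_caller_intersection:
        if "caller_set" in calls.columns:
            cs = calls["caller_set"].fillna("")
            missing = cs == ""
            if missing.any():
                warnings.warn(
                    f"{int(missing.sum())} call(s) lack caller provenance; "
                    "treated as intersection-passing"
                )
            fails["caller_intersection"] = ~missing & ~(
                cs.str.contains("mutect") & cs.str.contains("varscan")
            )
        else:
            warnings.warn("no caller_set column; caller intersection not enforced")
    if config.blacklist:
        fails["population_variant"] = variant_keys(calls).isin(config.blacklist)
    if config.reject_near_indels:
        fails["near_indel"] = _near_indel_mask(calls, config.indel_proximity_bp)

    failed_rule = pd.Series("", index=calls.index)
    for rule in _RULES:
        mask = fails.get(rule)
        if mask is None:
            continue
        failed_rule[(failed_rule == "") & mask] = rule

    retained = calls[failed_rule == ""].copy()
    rejected = calls[failed_rule != ""].copy()
    rejected["failed_rule"] = failed_rule[failed_rule != ""]
    return retained, rejected


def _near_indel_mask(calls: pd.DataFrame, window: int) -> pd.Series:
    """SNVs within ``window`` bp of any indel call in the same table."""
    snv = is_snv(calls)
    indels = calls[~snv]
    mask = pd.Series(False, index=calls.index)
    if indels.empty:
        return mask
    for chrom, grp in indels.groupby("chrom"):
        positions = grp["pos"].to_numpy()
        here = snv & (calls["chrom"] == chrom)
        if not here.any():
            continue
        pos = calls.loc[here, "pos"].to_numpy()
        close = (abs(pos[:, None] - positions[None, :]) <= window).any(axis=1)
        mask.loc[here] = close
    return mask


def build_pair_whitelist(strict_a: pd.DataFrame, strict_b: pd.DataFrame) -> frozenset:
    """Union of strictly-filtered variant keys from a sample pair."""
    keys: set = set()
    for df in (strict_a, strict_b):
        if len(df):
            keys.update(variant_keys(df))
    return frozenset(keys)


def whitelist_recall(
    pair_whitelist: frozenset,
    relaxed_calls: dict[str, pd.DataFrame],
    min_alt_reads: int = 2,
    min_vaf: float = 0.0,
) -> dict[str, pd.DataFrame]:
    """Recall whitelist variants from relaxed per-sample call tables.

    A variant is recalled in a sample when it appears in that sample's
    relaxed (unfiltered) table with at least ``min_alt_reads``
    supporting reads, regardless of strict-filter status.
    """
    for key in pair_whitelist:
        if not (isinstance(key, tuple) and len(key) == 4):
            raise InputError(f"whitelist key {key!r} is not (chrom, pos, ref, alt)")
    out = {}
    for sample, df in relaxed_calls.items():
        if df.empty:
            out[sample] = df.copy()
            continue
        alt_reads = df["alt_fwd"].astype(int) + df["alt_rev"].astype(int)
        keep = (
            variant_keys(df).isin(pair_whitelist)
            & (alt_reads >= min_alt_reads)
            & (df["vaf"] >= min_vaf)
        )
        out[sample] = df[keep].copy()
    return out


def shared_recalled(recalled: dict[str, pd.DataFrame], sample_a: str, sample_b: str) -> frozenset:
    """Variant keys recalled in *both* members of a pair."""
    ka = set(variant_keys(recalled[sample_a])) if len(recalled[sample_a]) else set()
    kb = set(variant_keys(recalled[sample_b])) if len(recalled[sample_b]) else set()
    return frozenset(ka & kb)
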