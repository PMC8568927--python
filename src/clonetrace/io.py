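"""Readers/writers for the call-table dialects.

Somatic calls travel either as a TSV dialect (chrom, pos, ref, alt,
vaf, depth, alt_fwd, alt_rev, in_normal, plus optional provenance
columns) or as uncompressed VCF 4.2 with FORMAT AD/DP and INFO fields
carrying strand counts and provenance. VCF reading goes through pysam;
both formats round-trip the dialect exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .filtering import InputError
from .genome import chrom_sort_key

REQUIRED_COLUMNS = ["chrom", "pos", "ref", "alt", "vaf", "depth", "alt_fwd", "alt_rev", "in_normal"]


def write_calls_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    df["in_normal"] = df["in_normal"].astype(bool)
    if "normal_depth" not in df.columns:
        df["normal_depth"] = df["depth"]
    return df


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=ALTF,Number=1,Type=Integer,Description="Alt reads on forward strand">
##INFO=<ID=ALTR,Number=1,Type=Integer,Description="Alt reads on reverse strand">
##INFO=<ID=NDP,Number=1,Type=Integer,Description="Read depth in matched normal">
##INFO=<ID=INNORMAL,Number=0,Type=Flag,Description="Variant observed in matched normal">
##INFO=<ID=CALLERS,Number=1,Type=String,Description="Callers reporting the variant">
##INFO=<ID=CTX,Number=1,Type=String,Description="Trinucleotide context on reported strand">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_calls_vcf(df: pd.DataFrame, sample: str, path) -> None:
    """Emit one sample's calls as uncompressed VCF 4.2."""
    lines = [_VCF_HEADER]
    chroms = sorted(df["chrom"].unique(), key=chrom_sort_key) if len(df) else []
    for c in chroms:
        lines.append(f"##contig=<ID={c}>\n")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for _, r in df.iterrows():
        alt_reads = int(r["alt_fwd"]) + int(r["alt_rev"])
        depth = int(r["depth"])
        info = [
            f"ALTF={int(r['alt_fwd'])}",
            f"ALTR={int(r['alt_rev'])}",
            f"NDP={int(r.get('normal_depth', depth))}",
        ]
        if bool(r["in_normal"]):
            info.append("INNORMAL")
        if "caller_set" in r and isinstance(r["caller_set"], str) and r["caller_set"]:
            info.append(f"CALLERS={r['caller_set'].replace(',', '|')}")
        if "context" in r and isinstance(r["context"], str) and r["context"]:
            info.append(f"CTX={r['context']}")
        lines.append(
            f"{r['chrom']}\t{int(r['pos'])}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
            f"{';'.join(info)}\tAD:DP\t{depth - alt_reads},{alt_reads}:{depth}\n"
        )
    Path(path).write_text("".join(lines))


def read_calls_vcf(path) -> pd.DataFrame:
    """Read a (single-sample) VCF into the call-table dialect via pysam."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            alt = rec.alts[0] if rec.alts else "."
            dp = None
            ad_alt = None
            if sample_names:
                fmt = rec.samples[sample_names[0]]
                dp = fmt.get("DP")
                ad = fmt.get("AD")
                if ad is not None and len(ad) > 1:
                    ad_alt = ad[1]
            altf = int(rec.info.get("ALTF", 0) or 0)
            altr = int(rec.info.get("ALTR", 0) or 0)
            if ad_alt is None:
                ad_alt = altf + altr
            if dp is None or dp == 0:
                dp = max(ad_alt, 1)
            callers = rec.info.get("CALLERS", "")
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "vaf": ad_alt / dp,
                    "depth": int(dp),
                    "alt_fwd": altf,
                    "alt_rev": altr,
                    "in_normal": "INNORMAL" in rec.info,
                    "normal_depth": int(rec.info.get("NDP", dp) or dp),
                    "caller_set": str(callers).replace("|", ","),
                    "context": str(rec.info.get("CTX", "")) or "",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "vaf", "depth", "alt_fwd", "alt_rev",
            "in_normal", "normal_depth", "caller_set", "context",
        ],
    )


def read_het_snps_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "vaf_normal" not in df.columns:
        raise InputError(f"{path}: missing vaf_normal column")
    return df


def read_windows_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in ("start", "end", "count_normal"):
        if c not in df.columns:
            raise InputError(f"{path}: missing {c} column")
    return df
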