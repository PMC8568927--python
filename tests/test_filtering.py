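"""Strict filter contract, rejection accounting, whitelist recall."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonetrace.filtering import (
    FilterConfig,
    InputError,
    apply_strict_filters,
    build_pair_whitelist,
    load_blacklist,
    shared_recalled,
    variant_keys,
    whitelist_recall,
)
from conftest import clean_calls


def test_empty_input():
    kept, rej = apply_strict_filters(clean_calls(0))
    assert kept.empty and rej.empty


def test_normal_coverage_rule():
    calls = clean_calls(1)
    calls.loc[0, "normal_depth"] = 19
    kept, rej = apply_strict_filters(calls)
    assert kept.empty
    assert rej["failed_rule"].tolist() == ["normal_coverage"]


def test_one_violation_each_plus_clean():
    """Ten calls: six single-rule violations + four clean -> exactly the
    clean four retained, each rejection annotated with its rule."""
    df = clean_calls(10)
    df.loc[0, "normal_depth"] = 10
    df.loc[1, ["alt_fwd", "alt_rev"]] = [16, 0]
    df.loc[2, "in_normal"] = True
    df.loc[3, ["vaf", "alt_fwd", "alt_rev"]] = [0.005, 1, 1]
    df.loc[4, "caller_set"] = "varscan"
    blacklisted = (df.loc[5, "chrom"], int(df.loc[5, "pos"]), "C", "T")
    cfg = FilterConfig(blacklist=frozenset([blacklisted]))
    kept, rej = apply_strict_filters(df, cfg)
    assert len(kept) == 4
    assert kept.index.tolist() == [6, 7, 8, 9]
    expected = {
        0: "normal_coverage",
        1: "both_strands",
        2: "present_in_normal",
        3: "min_vaf",
        4: "caller_intersection",
        5: "population_variant",
    }
    assert rej["failed_rule"].to_dict() == expected


def test_malformed_record_raises():
    df = clean_calls(2)
    df.loc[1, "vaf"] = 1.5
    with pytest.raises(InputError, match="malformed"):
        apply_strict_filters(df)


def test_near_indel_rejection():
    df = clean_calls(2)
    indel = clean_calls(1).assign(ref="CA", alt="C", pos=int(df.loc[0, "pos"]) + 2)
    df = pd.concat([df, indel], ignore_index=True)
    kept, rej = apply_strict_filters(df)
    assert rej["failed_rule"].tolist() == ["near_indel"]
    assert len(kept) == 2  # the distant SNV and the indel itself


def test_missing_caller_set_warns_and_passes():
    df = clean_calls(1).drop(columns="caller_set")
    with pytest.warns(UserWarning, match="caller"):
        kept, _ = apply_strict_filters(df)
    assert len(kept) == 1


def _random_calls(rng, n=40):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": rng.choice(10**6, size=n, replace=False) + 1,
            "ref": "C",
            "alt": "T",
            "vaf": rng.uniform(0, 0.6, n),
            "depth": rng.integers(10, 80, n),
            "alt_fwd": rng.integers(0, 10, n),
            "alt_rev": rng.integers(0, 10, n),
            "in_normal": rng.random(n) < 0.1,
            "normal_depth": rng.integers(5, 60, n),
            "caller_set": rng.choice(["mutect,varscan", "varscan"], n),
        }
    )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    min_normal=st.integers(0, 40),
    min_alt=st.integers(0, 6),
    min_vaf=st.floats(0, 0.3),
)
def test_monotonicity_and_idempotence(seed, min_normal, min_alt, min_vaf):
    """Tightening any threshold never enlarges the retained set;
    refiltering a filtered table is a no-op."""
    rng = np.random.default_rng(seed)
    calls = _random_calls(rng)
    cfg = FilterConfig(min_normal_depth=min_normal, min_alt_reads=min_alt, min_vaf=min_vaf)
    kept, _ = apply_strict_filters(calls, cfg)
    tighter = FilterConfig(
        min_normal_depth=min_normal + 5, min_alt_reads=min_alt + 1, min_vaf=min_vaf + 0.05
    )
    kept_tight, _ = apply_strict_filters(calls, tighter)
    assert set(variant_keys(kept_tight)) <= set(variant_keys(kept))
    again, rej = apply_strict_filters(kept, cfg)
    pd.testing.assert_frame_equal(again, kept)
    assert rej.empty


def test_whitelist_recall_empty():
    assert whitelist_recall(frozenset(), {"A": clean_calls(3)})["A"].empty


def test_whitelist_recall_requires_two_reads():
    df = clean_calls(1)
    df.loc[0, ["alt_fwd", "alt_rev", "vaf"]] = [1, 0, 0.025]
    wl = frozenset(variant_keys(df))
    assert whitelist_recall(wl, {"A": df})["A"].empty


def test_whitelist_bad_key_raises():
    with pytest.raises(InputError, match="whitelist key"):
        whitelist_recall(frozenset({("chr1", 5)}), {"A": clean_calls(1)})


def test_strict_subset_of_recall(contamination_cohort):
    """Strict calls of each sample are always recovered by its own
    whitelist recall."""
    from conftest import strict_all

    strict = strict_all(contamination_cohort)
    for a, b in [("A", "C"), ("B", "C")]:
        wl = build_pair_whitelist(strict[a], strict[b])
        rec = whitelist_recall(
            wl, {a: contamination_cohort.calls[a], b: contamination_cohort.calls[b]}
        )
        for s in (a, b):
            assert set(variant_keys(strict[s])) <= set(variant_keys(rec[s]))


def test_contamination_recall_counts(contamination_cohort):
    """Trace contamination: strict filters keep only a minority of the
    66 injected variants; relaxed recall recovers all 66."""
    from conftest import strict_all

    strict = strict_all(contamination_cohort)
    wl = build_pair_whitelist(strict["A"], strict["C"])
    rec = whitelist_recall(
        wl, {"A": contamination_cohort.calls["A"], "C": contamination_cohort.calls["C"]}
    )
    shared = shared_recalled(rec, "A", "C")
    assert len(shared) == 66
    strict_shared = set(variant_keys(strict["A"])) & set(variant_keys(strict["C"]))
    assert len(strict_shared) < 20


def test_load_blacklist_tsv_and_vcf(tmp_path):
    tsv = tmp_path / "bl.tsv"
    tsv.write_text("chr1\t100\tC\tT\nchr2\t200\tG\tA\n")
    bl = load_blacklist(tsv)
    assert ("chr1", 100, "C", "T") in bl and len(bl) == 2
    vcf = tmp_path / "bl.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n##contig=<ID=chr1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t100\t.\tC\tT\t.\t.\t.\n"
    )
    assert load_blacklist(vcf) == frozenset({("chr1", 100, "C", "T")})
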