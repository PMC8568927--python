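"""Segmentation, whole-chromosome calls, homolog phasing, the binomial
concordance test, chromothripsis and purity estimation."""

import math

import numpy as np
import pandas as pd
import pytest

import clonetrace as ct
from clonetrace import cna
from clonetrace.filtering import InputError
from clonetrace.genome import GenomeModel


def _windows(states_by_chrom, lam=267, depth_noise=None, window=2000):
    """Build a window table from per-chromosome copy-factor arrays."""
    rng = depth_noise
    frames = []
    for chrom, factors in states_by_chrom.items():
        n = len(factors)
        starts = np.arange(n) * window
        normal = rng.poisson(lam, n) if rng is not None else np.full(n, lam)
        tumor = (
            rng.poisson(lam * np.asarray(factors))
            if rng is not None
            else np.round(lam * np.asarray(factors)).astype(int)
        )
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window,
                    "count_normal": normal,
                    "count_T": tumor,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def test_flat_genome_single_neutral_segment():
    win = _windows({"chr1": np.ones(300), "chr2": np.ones(200)})
    seg = cna.segment_logratio(win, "T")
    assert len(seg) == 2
    assert (seg["state"] == "neutral").all()
    assert seg.groupby("chrom")["n_windows"].sum().to_dict() == {"chr1": 300, "chr2": 200}


def test_hemizygous_loss_log2_ratio_closed_form():
    """Whole-chromosome loss at purity 0.6: log2((2(1-p)+p)/2) = log2(0.7)."""
    p = 0.6
    factor = (2 * (1 - p) + p) / 2
    rng = np.random.default_rng(0)
    win = _windows({"chr1": np.ones(800), "chr18": np.full(390, factor)}, depth_noise=rng)
    seg = cna.segment_logratio(win, "T")
    loss = seg[(seg["chrom"] == "chr18")]
    assert len(loss) == 1 and loss.iloc[0]["state"] == "loss"
    assert loss.iloc[0]["log2_ratio"] == pytest.approx(math.log2(0.7), abs=0.05)


def test_breakpoint_recovered_within_two_windows():
    rng = np.random.default_rng(1)
    factors = np.concatenate([np.ones(120), np.full(80, 0.7)])
    win = _windows({"chr1": np.ones(400), "chr2": factors}, depth_noise=rng)
    seg = cna.segment_logratio(win, "T")
    chr2 = seg[seg["chrom"] == "chr2"]
    assert len(chr2) == 2
    bp_window = chr2.iloc[1]["start"] // 2000
    assert abs(bp_window - 120) <= 2


def test_segments_tile_chromosome_exactly():
    rng = np.random.default_rng(2)
    factors = np.concatenate([np.ones(50), np.full(60, 0.7), np.ones(40), np.full(50, 1.3)])
    win = _windows({"chr3": factors}, depth_noise=rng)
    seg = cna.segment_logratio(win, "T")
    assert seg.iloc[0]["start"] == 0
    assert seg.iloc[-1]["end"] == 200 * 2000
    for prev, nxt in zip(seg.itertuples(), seg.iloc[1:].itertuples()):
        assert prev.end == nxt.start


def test_report_filter_drops_small_segments():
    seg = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [0, 100_000],
            "end": [100_000, 120_000],
            "log2_ratio": [0.0, -0.5],
            "state": ["neutral", "loss"],
            "n_windows": [50, 10],
        }
    )
    out = cna.filter_segments(seg, min_bp=25_000)
    assert len(out) == 1 and out.iloc[0]["state"] == "neutral"


def test_whole_chrom_event_thresholds():
    seg = pd.DataFrame(
        {
            "chrom": "chr18",
            "start": [0, 950_000],
            "end": [950_000, 1_000_000],
            "log2_ratio": [-0.5, 0.0],
            "state": ["loss", "neutral"],
            "n_windows": [475, 25],
        }
    )
    ev = cna.call_whole_chrom(seg, "chr18", "S", 1_000_000)
    assert ev is not None and ev.kind == "loss" and ev.covered_fraction == 0.95
    focal = seg.assign(state=["neutral", "loss"])
    assert cna.call_whole_chrom(focal, "chr18", "S", 1_000_000) is None


def test_whole_chrom_event_count_matches_configured_carriers():
    """Cohort configured with a chr18 loss in 4 of 6 samples yields
    exactly 4 whole-chromosome loss events."""
    genome = GenomeModel({f"chr{i}": 400_000 for i in (1, 2, 18)})
    carriers = ("A", "C", "D", "F")
    cfg = ct.SimConfig(
        n_primaries=6,
        private_range=(0, 0),
        genome=genome,
        cna_events=(ct.TruthCNA("chr18", "A", "loss", carriers),),
        noise=True,
        seed=5,
    )
    cohort = ct.simulate_cohort(cfg)
    hits = []
    for s in cfg.samples:
        seg = cna.segment_logratio(cohort.windows, s)
        ev = cna.call_whole_chrom(seg, "chr18", s, genome.lengths["chr18"])
        if ev is not None and ev.kind == "loss":
            hits.append(s)
    assert tuple(hits) == carriers


@pytest.fixture(scope="module")
def phasing_cohort():
    genome = GenomeModel({"chr1": 500_000, "chr18": 500_000})
    cfg = ct.SimConfig(
        n_primaries=4,
        private_range=(0, 0),
        purity=0.6,
        genome=genome,
        het_snp_spacing=4000,
        cna_events=(
            ct.TruthCNA("chr18", "A", "loss", ("A", "B")),
            ct.TruthCNA("chr18", "B", "loss", ("C",)),
            ct.TruthCNA("chr18", "both", "loss", ("D",)),
        ),
        noise=True,
        seed=6,
    )
    return ct.simulate_cohort(cfg)


def test_phasing_same_different_biallelic(phasing_cohort):
    het = phasing_cohort.het_snps
    same = cna.phase_event(het, "chr18", "A", "B")
    assert same.homolog_call == "same_as_reference"
    assert same.concordance_fraction >= 0.9
    diff = cna.phase_event(het, "chr18", "A", "C")
    assert diff.homolog_call == "different_from_reference"
    bial = cna.phase_event(het, "chr18", "A", "D")
    assert bial.homolog_call == "biallelic"


def test_phasing_noise_free_vaf_positions(phasing_cohort):
    """Closed-form check: at purity 0.6 the two het-SNP VAF modes on a
    monoallelically lost chromosome are 1/1.4 and 0.4/1.4."""
    p = 0.6
    cfg = phasing_cohort.config
    clean = ct.simulate_cohort(
        ct.SimConfig(
            n_primaries=1,
            private_range=(0, 0),
            purity=p,
            genome=cfg.genome,
            cna_events=(ct.TruthCNA("chr18", "A", "loss", ("A",)),),
            noise=False,
            seed=1,
        )
    )
    vals = set(clean.het_snps.loc[clean.het_snps["chrom"] == "chr18", "vaf_A"].round(6))
    assert vals == {round(1 / (2 - p), 6), round((1 - p) / (2 - p), 6)}


def test_phasing_min_snps_guard(phasing_cohort):
    res = cna.phase_event(phasing_cohort.het_snps, "chr18", "A", "B", min_snps=10_000)
    assert res.homolog_call == "indeterminate"
    assert "informative" in res.reason


def test_binomial_concordance_values():
    assert cna.concordance_binomial_test(13, 13) == pytest.approx(1.2e-4, rel=0.02)
    assert cna.concordance_binomial_test(1, 1) == 0.5
    assert cna.concordance_binomial_test(10, 12) == pytest.approx(79 / 4096)
    with pytest.raises(InputError):
        cna.concordance_binomial_test(0, 0)
    with pytest.raises(InputError):
        cna.concordance_binomial_test(5, 3)


@pytest.mark.parametrize("n", range(1, 13))
def test_binomial_matches_enumeration_oracle(n):
    """Exact tail agrees with direct enumeration of all C(n, k) outcomes."""
    for k in range(n + 1):
        tail = sum(math.comb(n, j) for j in range(k, n + 1)) / 2**n
        assert cna.concordance_binomial_test(k, n) == pytest.approx(tail, rel=1e-12)


def test_chromothripsis_rule():
    def seg_with_states(states):
        n = len(states)
        return pd.DataFrame(
            {
                "chrom": "chr13",
                "start": np.arange(n) * 50_000,
                "end": (np.arange(n) + 1) * 50_000,
                "log2_ratio": [-0.5 if s == "loss" else 0.0 for s in states],
                "state": states,
                "n_windows": 25,
            }
        )

    oscillating = seg_with_states(["loss", "neutral"] * 10)
    call = cna.detect_chromothripsis(oscillating, "chr13", "S")
    assert call.positive and call.oscillation_fraction == 1.0

    flat = seg_with_states(["neutral"])
    assert not cna.detect_chromothripsis(flat, "chr13", "S").positive

    three_state = seg_with_states(
        ["loss", "neutral", "gain", "neutral", "loss", "gain", "loss", "neutral", "gain", "loss", "neutral", "gain"]
    )
    assert not cna.detect_chromothripsis(three_state, "chr13", "S").positive


def test_chromothripsis_recovered_from_simulation():
    cohort = ct.simulate_cohort(ct.patient2_config(seed=8, noise=True))
    for s in ("G", "L"):
        seg = cna.segment_logratio(cohort.windows, s)
        assert cna.detect_chromothripsis(seg, "chr13", s).positive
    seg_other = cna.segment_logratio(cohort.windows, "A")
    assert not cna.detect_chromothripsis(seg_other, "chr13", "A").positive


def test_purity_estimates():
    assert cna.estimate_purity([0.5] * 30).purity == 1.0
    est = cna.estimate_purity([0.125] * 25)
    assert est.below_30pct and est.purity == pytest.approx(0.25)
    with pytest.raises(InputError, match="needs >="):
        cna.estimate_purity([0.3] * 5)


def test_purity_recovery_from_simulation():
    cfg = ct.SimConfig(
        n_primaries=1, private_range=(200, 200), purity=0.6, depth=40.0, noise=True, seed=9
    )
    cohort = ct.simulate_cohort(cfg)
    kept, _ = ct.apply_strict_filters(cohort.calls["A"])
    est = cna.estimate_purity(kept["vaf"])
    assert est.purity == pytest.approx(0.6, abs=0.05)
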