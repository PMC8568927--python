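"""Per-patient and cohort orchestration.

``analyze_patient`` composes the stages — strict filtering, pairwise
shared-SNV analysis with overlap classification, maximum-parsimony
phylogeny with bootstrap, signature refitting, CNA segmentation,
whole-chromosome calling, homolog phasing and chromothripsis scanning —
into a :class:`PatientReport` of machine-readable tables.
``run_cohort`` pools the per-patient related monoallelic pairs into one
binomial concordance test and a cohort burden/signature matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cna as cna_mod
from . import io as io_mod
from .clonality import (
    OverlapThresholds,
    build_character_matrix,
    classify_overlap,
    mp_tree_with_support,
    overlap_vafs,
    pairwise_shared,
)
from .filtering import (
    FilterConfig,
    InputError,
    build_pair_whitelist,
    is_snv,
    shared_recalled,
    whitelist_recall,
)
from .signature_bank import synthetic_signature_bank
from .signatures import count_96, fit_table

TUMOR_ROLES = {"primary", "lymph_node_met", "liver_met", "peritoneal_met"}


@dataclass
class AnalysisConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    overlap: OverlapThresholds = field(default_factory=OverlapThresholds)
    bootstrap_reps: int = 500
    seed: int = 0
    max_signatures: int = 4
    min_signature_weight: float = 0.06
    whole_chrom_min_fraction: float = 0.9
    phase_delta: float = 0.05
    phase_concordance: float = 0.9
    phase_min_snps: int = 20
    min_report_segment_bp: int = 25_000
    recall_min_alt_reads: int = 2
    reference_sample: str | None = None
    signature_bank: pd.DataFrame | None = None


@dataclass
class PatientReport:
    patient_id: str
    seed: int
    strict_calls: dict[str, pd.DataFrame]
    rejections: dict[str, pd.DataFrame]
    shared: pd.DataFrame | None
    overlaps: pd.DataFrame
    newick: str | None
    branch_counts: pd.DataFrame | None
    signature_table: pd.DataFrame
    segments: dict[str, pd.DataFrame]
    whole_chrom: pd.DataFrame
    phasing: pd.DataFrame
    chromothripsis: pd.DataFrame
    purity: pd.DataFrame
    concordant_pairs: int
    total_pairs: int
    concordance_p: float | None
    exclusions: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s, df in self.strict_calls.items():
            io_mod.write_calls_tsv(df, outdir / f"strict_calls_{s}.tsv")
        for s, df in self.rejections.items():
            df.to_csv(outdir / f"rejections_{s}.tsv", sep="\t", index=False)
        if self.shared is not None:
            self.shared.to_csv(outdir / "shared_matrix.tsv", sep="\t")
        self.overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
        if self.newick:
            (outdir / "tree.nwk").write_text(self.newick + "\n")
        if self.branch_counts is not None:
            self.branch_counts.to_csv(outdir / "branch_counts.tsv", sep="\t", index=False)
        self.signature_table.to_csv(outdir / "signature_loadings.tsv", sep="\t")
        for s, df in self.segments.items():
            df.to_csv(outdir / f"segments_{s}.tsv", sep="\t", index=False)
        self.whole_chrom.to_csv(outdir / "whole_chrom_events.tsv", sep="\t", index=False)
        self.phasing.to_csv(outdir / "phasing.tsv", sep="\t", index=False)
        self.chromothripsis.to_csv(outdir / "chromothripsis.tsv", sep="\t", index=False)
        self.purity.to_csv(outdir / "purity.tsv", sep="\t", index=False)
        self.exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        manifest = {
            "patient": self.patient_id,
            "seed": self.seed,
            "samples": sorted(self.strict_calls),
            "concordant_pairs": self.concordant_pairs,
            "total_pairs": self.total_pairs,
            "concordance_p": self.concordance_p,
            "log": self.log,
        }
        (outdir / "report_manifest.json").write_text(json.dumps(manifest, indent=1))
        return outdir / "report_manifest.json"


def _chrom_lengths_from_windows(windows: pd.DataFrame) -> dict[str, int]:
    return windows.groupby("chrom")["end"].max().astype(int).to_dict()


def analyze_patient(
    patient_id: str,
    relaxed_calls: dict[str, pd.DataFrame],
    het_snps: pd.DataFrame,
    windows: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> PatientReport:
    """Run the full per-patient analysis on in-memory tables.

    ``relaxed_calls`` are the unfiltered per-sample call tables; strict
    filtering, clonality, signatures and CNA/phasing stages run in
    order, and samples missing from any stage are listed in the
    exclusion log with a reason.
    """
    config = config or AnalysisConfig()
    log: list[str] = [f"patient={patient_id} seed={config.seed}"]
    exclusions: list[dict] = []
    samples = list(relaxed_calls)

    # --- stage 1: strict filtering
    strict, rejections = {}, {}
    for s in samples:
        kept, rej = _strict(relaxed_calls[s], config)
        strict[s], rejections[s] = kept, rej
        log.append(f"filter sample={s} in={len(relaxed_calls[s])} kept={len(kept)} rejected={len(rej)}")

    # --- purity
    purity_rows = []
    for s in samples:
        vafs = strict[s].loc[is_snv(strict[s]), "vaf"] if len(strict[s]) else []
        try:
            est = cna_mod.estimate_purity(vafs)
            purity_rows.append(
                {"sample": s, "purity": est.purity, "n_snvs": est.n_snvs, "below_30pct": est.below_30pct}
            )
            if est.below_30pct:
                log.append(f"purity sample={s} flagged below 30%")
        except InputError as e:
            purity_rows.append({"sample": s, "purity": float("nan"), "n_snvs": len(vafs), "below_30pct": True})
            log.append(f"purity sample={s} not estimated: {e}")
    purity = pd.DataFrame(purity_rows)

    # --- stage 2: clonality
    shared_df = None
    newick = None
    branch_counts_df = None
    overlap_rows: list[dict] = []
    related_pairs: list[tuple[str, str]] = []
    if len(samples) >= 2:
        shared = pairwise_shared({s: strict[s][is_snv(strict[s])] if len(strict[s]) else strict[s] for s in samples})
        shared_df = shared.counts
        for i, a in enumerate(samples):
            for b in samples[i + 1 :]:
                if shared.shared(a, b) == 0:
                    continue
                wl = build_pair_whitelist(strict[a], strict[b])
                recalled = whitelist_recall(
                    wl, {a: relaxed_calls[a], b: relaxed_calls[b]},
                    min_alt_reads=config.recall_min_alt_reads,
                )
                keys = shared_recalled(recalled, a, b)
                vafs = overlap_vafs({a: recalled[a], b: recalled[b]}, (a, b), keys)
                oc = classify_overlap(vafs, config.overlap)
                overlap_rows.append(
                    {
                        "sample_a": a,
                        "sample_b": b,
                        "strict_shared": shared.shared(a, b),
                        "recalled_shared": oc.count,
                        "label": oc.label,
                        **{f"median_vaf_{k}": v for k, v in oc.median_vaf.items()},
                    }
                )
                if oc.label == "clonal_trunk":
                    related_pairs.append((a, b))
        matrix = build_character_matrix(strict)
        tree = mp_tree_with_support(
            matrix, n_reps=config.bootstrap_reps, seed=np.random.default_rng(config.seed)
        )
        newick = tree.newick()
        branch_counts_df = pd.DataFrame(
            [
                {"branch": "|".join(sorted(k)), "n_snvs": v, "support": tree.supports.get(k, float("nan"))}
                for k, v in sorted(tree.branch_counts.items(), key=lambda kv: sorted(kv[0]))
            ]
        )
        log.append(f"clonality tree score={tree.score} related_pairs={len(related_pairs)}")
    else:
        exclusions.append({"sample": samples[0] if samples else "", "stage": "clonality",
                           "reason": "fewer than 2 tumor samples"})
        log.append("clonality skipped: fewer than 2 tumor samples")
    overlaps = pd.DataFrame(overlap_rows)

    # --- stage 3: signatures
    bank = config.signature_bank if config.signature_bank is not None else synthetic_signature_bank()
    profiles = {}
    for s in samples:
        df = strict[s]
        if "context" not in df.columns or (len(df) and df["context"].isna().all()):
            exclusions.append({"sample": s, "stage": "signatures", "reason": "no trinucleotide context"})
            continue
        profiles[s] = count_96(df)
    signature_table = (
        fit_table(profiles, bank, max_k=config.max_signatures, min_weight=config.min_signature_weight)
        if profiles
        else pd.DataFrame()
    )

    # --- stage 4: CNA + phasing + chromothripsis
    chrom_lengths = _chrom_lengths_from_windows(windows)
    segments: dict[str, pd.DataFrame] = {}
    wce_rows, chromo_rows = [], []
    events: dict[str, dict[str, cna_mod.WholeChromEvent]] = {}
    for s in samples:
        seg = cna_mod.segment_logratio(windows, s)
        segments[s] = cna_mod.filter_segments(seg, config.min_report_segment_bp)
        events[s] = {}
        for chrom, length in chrom_lengths.items():
            ev = cna_mod.call_whole_chrom(seg, chrom, s, length, config.whole_chrom_min_fraction)
            if ev is not None:
                events[s][chrom] = ev
                wce_rows.append(
                    {"sample": s, "chrom": chrom, "kind": ev.kind, "covered_fraction": ev.covered_fraction}
                )
            call = cna_mod.detect_chromothripsis(seg, chrom, s)
            if call.positive:
                chromo_rows.append(vars(call))
    whole_chrom = pd.DataFrame(wce_rows)
    chromothripsis = pd.DataFrame(chromo_rows)

    # reference sample for phasing display: configured, else the tumor
    # with the largest summed shared counts (the metastatic primary)
    reference = config.reference_sample
    if reference is None and shared_df is not None:
        off_diag = shared_df.to_numpy().sum(axis=1) - np.diag(shared_df.to_numpy())
        reference = samples[int(np.argmax(off_diag))]
    phasing_rows = []
    if reference is not None:
        for chrom in sorted(chrom_lengths):
            if chrom not in events.get(reference, {}):
                continue
            for s in samples:
                if s == reference or chrom not in events[s]:
                    continue
                res = cna_mod.phase_event(
                    het_snps, chrom, reference, s,
                    delta=config.phase_delta,
                    concordance_threshold=config.phase_concordance,
                    min_snps=config.phase_min_snps,
                )
                phasing_rows.append(
                    {
                        "chrom": chrom, "reference": reference, "sample": s,
                        "kind": events[s][chrom].kind, "homolog_call": res.homolog_call,
                        "concordance_fraction": res.concordance_fraction,
                        "n_informative": res.n_informative, "reason": res.reason,
                    }
                )
    phasing = pd.DataFrame(phasing_rows)

    # --- related monoallelic pairs -> concordance counts
    n_conc, n_tot = 0, 0
    for a, b in related_pairs:
        for chrom in sorted(chrom_lengths):
            ev_a, ev_b = events.get(a, {}).get(chrom), events.get(b, {}).get(chrom)
            if ev_a is None or ev_b is None or ev_a.kind != ev_b.kind:
                continue
            if not cna_mod.is_monoallelic(het_snps, chrom, a):
                continue
            res = cna_mod.phase_event(
                het_snps, chrom, a, b,
                delta=config.phase_delta,
                concordance_threshold=config.phase_concordance,
                min_snps=config.phase_min_snps,
            )
            if res.homolog_call == "same_as_reference":
                n_conc += 1
                n_tot += 1
            elif res.homolog_call == "different_from_reference":
                n_tot += 1
    p_value = cna_mod.concordance_binomial_test(n_conc, n_tot) if n_tot else None
    log.append(f"concordance related_monoallelic pairs={n_tot} concordant={n_conc} p={p_value}")

    return PatientReport(
        patient_id=patient_id,
        seed=config.seed,
        strict_calls=strict,
        rejections=rejections,
        shared=shared_df,
        overlaps=overlaps,
        newick=newick,
        branch_counts=branch_counts_df,
        signature_table=signature_table,
        segments=segments,
        whole_chrom=whole_chrom,
        phasing=phasing,
        chromothripsis=chromothripsis,
        purity=purity,
        concordant_pairs=n_conc,
        total_pairs=n_tot,
        concordance_p=p_value,
        exclusions=pd.DataFrame(exclusions, columns=["sample", "stage", "reason"]),
        log=log,
    )


def _strict(calls: pd.DataFrame, config: AnalysisConfig):
    from .filtering import apply_strict_filters

    return apply_strict_filters(calls, config.filter)


# ---------------------------------------------------------------------------
# file-based bundles
# ---------------------------------------------------------------------------


@dataclass
class PatientBundle:
    patient_id: str
    roles: dict[str, str]  # sample -> role
    calls_paths: dict[str, Path]
    het_snps_path: Path
    windows_path: Path

    def __post_init__(self) -> None:
        normals = [s for s, r in self.roles.items() if r == "blood_normal"]
        if len(normals) != 1:
            raise InputError(f"{self.patient_id}: need exactly one blood_normal, got {len(normals)}")
        for s, p in self.calls_paths.items():
            if not Path(p).exists():
                raise InputError(f"{self.patient_id}: missing calls file for {s}: {p}")

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s, r in self.roles.items() if r in TUMOR_ROLES]

    def load_calls(self) -> dict[str, pd.DataFrame]:
        out = {}
        for s in self.tumor_samples:
            p = Path(self.calls_paths[s])
            out[s] = io_mod.read_calls_vcf(p) if p.suffix == ".vcf" else io_mod.read_calls_tsv(p)
        return out


def load_bundle(path) -> PatientBundle:
    """Read a patient bundle manifest (YAML)."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    base = path.parent
    roles, calls = {}, {}
    for entry in cfg["samples"]:
        roles[entry["id"]] = entry["role"]
        if "calls" in entry:
            calls[entry["id"]] = base / entry["calls"]
    return PatientBundle(
        patient_id=str(cfg["patient"]),
        roles=roles,
        calls_paths=calls,
        het_snps_path=base / cfg["het_snps"],
        windows_path=base / cfg["windows"],
    )


def run_patient(
    bundle: PatientBundle,
    config: AnalysisConfig | None = None,
    outdir=None,
    force: bool = False,
) -> PatientReport | None:
    """Analyze one file-based patient bundle; writes a report directory.

    With ``force`` off, an existing report manifest short-circuits the
    run (idempotent reruns change no file) and ``None`` is returned.
    """
    if outdir is not None and not force:
        manifest = Path(outdir) / "report_manifest.json"
        if manifest.exists():
            return None
    calls = bundle.load_calls()
    het = io_mod.read_het_snps_tsv(bundle.het_snps_path)
    windows = io_mod.read_windows_tsv(bundle.windows_path)
    report = analyze_patient(bundle.patient_id, calls, het, windows, config)
    if outdir is not None:
        report.write(outdir)
    return report


@dataclass
class CohortSummary:
    reports: dict[str, PatientReport]
    pooled_concordant: int
    pooled_total: int
    pooled_p: float | None
    burden_matrix: pd.DataFrame


def run_cohort(reports: list[PatientReport]) -> CohortSummary:
    """Pool per-patient reports: one binomial test over all related
    monoallelic pairs, plus a cohort burden/signature matrix."""
    ids = [r.patient_id for r in reports]
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate patient ids in cohort: {ids}")
    n_conc = sum(r.concordant_pairs for r in reports)
    n_tot = sum(r.total_pairs for r in reports)
    p = cna_mod.concordance_binomial_test(n_conc, n_tot) if n_tot else None
    rows = []
    for r in reports:
        for s, df in r.strict_calls.items():
            row = {"patient": r.patient_id, "sample": s, "n_snvs": int(is_snv(df).sum()) if len(df) else 0}
            if len(r.signature_table) and s in r.signature_table.index:
                row.update(r.signature_table.loc[s].to_dict())
            rows.append(row)
    return CohortSummary(
        reports={r.patient_id: r for r in reports},
        pooled_concordant=n_conc,
        pooled_total=n_tot,
        pooled_p=p,
        burden_matrix=pd.DataFrame(rows),
    )
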