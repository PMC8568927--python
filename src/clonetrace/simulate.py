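"""Synthetic multifocal tumor cohort simulator.

Generates ground-truth cohorts of clonally independent primary tumors,
optionally with a shared metastatic trunk, emulating the architecture
seen in multifocal small-intestine neuroendocrine tumors (SI-NET):

* each primary carries its own private somatic SNVs (clock-like,
  SBS5/SBS40-dominated spectra, low burden);
* metastases inherit the full trunk of their seeding primary plus
  private variants of their own;
* small cross-sample overlaps can be injected either as
  early-developmental ("embryonic") variants clonal in a chosen sample
  set, or as handling contamination present at trace VAF in a
  recipient only;
* whole-chromosome and segmental copy-number events carry homolog
  labels (A/B/both) and shape both somatic VAFs, germline het-SNP
  allelic imbalance and window read counts;
* reads are sampled binomially at a configurable mean depth, with VAF
  diluted by tumor purity and local copy number.

Every emitted variant has exactly one lineage label in the ground
truth, which downstream recovery tests compare against.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel, chrom_sort_key, miniature_genome
from .signature_bank import (
    SBS96_CHANNELS,
    parse_channel,
    revcomp,
    synthetic_signature_bank,
)

# Caller support floor: a variant with fewer alt reads is invisible
# even to the relaxed (unfiltered) caller output.
MIN_ALT_EMIT = 2
# The second (Mutect-like) caller is less sensitive to subclonal
# variants: it requires more supporting reads plus both strands.
MUTECT_MIN_ALT = 4


class ConfigurationError(ValueError):
    """Invalid simulation or analysis configuration."""


@dataclass(frozen=True)
class TruthCNA:
    """A ground-truth copy-number event.

    ``homolog`` is 'A', 'B' (monoallelic) or 'both' (biallelic);
    ``start``/``end`` are 0-based half-open, ``None`` for a
    whole-chromosome event; ``carriers`` are the tumor samples bearing
    the event.
    """

    chrom: str
    homolog: str
    kind: str
    carriers: tuple[str, ...]
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.homolog not in ("A", "B", "both"):
            raise ConfigurationError(f"bad homolog {self.homolog!r}")
        if self.kind not in ("loss", "gain"):
            raise ConfigurationError(f"bad CNA kind {self.kind!r}")
        if not self.carriers:
            raise ConfigurationError("CNA with no carrier samples")
        if (self.start is None) != (self.end is None):
            raise ConfigurationError("interval CNA needs both start and end")

    @property
    def whole(self) -> bool:
        return self.start is None


@dataclass(frozen=True)
class Contamination:
    """Trace cross-contamination: ``count`` variants clonal in ``donor``
    appear at VAF in ``vaf_range`` in ``recipient``."""

    donor: str
    recipient: str
    count: int
    vaf_range: tuple[float, float] = (0.02, 0.05)


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic patient cohort.

    Primaries are named A, B, C, ...; metastases continue the alphabet
    in seeding order (6 primaries with C seeding 5 metastases gives
    metastases G-K).
    """

    n_primaries: int
    metastatic_primary_ids: tuple[str, ...] = ()
    n_mets_per_seed: int = 1
    trunk_sizes: dict[str, int] = field(default_factory=dict)
    private_range: tuple[int, int] = (300, 1700)
    embryonic_shared: tuple[tuple[frozenset, int], ...] = ()
    contamination: tuple[Contamination, ...] = ()
    purity: float | dict = 0.6
    depth: float = 40.0
    genome: GenomeModel = field(default_factory=miniature_genome)
    signature_mix: dict[str, float] = field(
        default_factory=lambda: {"SBS5": 0.75, "SBS40": 0.15, "SBS1": 0.10}
    )
    cna_events: tuple[TruthCNA, ...] = ()
    het_snp_spacing: int = 5000
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primaries < 1:
            raise ConfigurationError("need at least one primary")
        prim = set(self.primaries)
        if not set(self.metastatic_primary_ids) <= prim:
            raise ConfigurationError(
                f"metastatic_primary_ids {self.metastatic_primary_ids} not a subset "
                f"of primaries {sorted(prim)}"
            )
        for pid in self.metastatic_primary_ids:
            if self.trunk_sizes.get(pid, 0) <= 0:
                raise ConfigurationError(f"trunk size for seeding primary {pid} must be > 0")
        lo, hi = self.private_range
        if lo > hi or lo < 0:
            raise ConfigurationError(f"bad private_range {self.private_range}")
        mix_total = sum(self.signature_mix.values())
        if abs(mix_total - 1.0) > 1e-6:
            raise ConfigurationError(f"signature_mix sums to {mix_total}, expected 1")
        for s, p in self.purity_map.items():
            if not 0 < p <= 1:
                raise ConfigurationError(f"purity of {s} is {p}, expected (0, 1]")

    @property
    def primaries(self) -> tuple[str, ...]:
        return tuple(itertools.islice(_names(), self.n_primaries))

    @property
    def mets_by_seed(self) -> dict[str, tuple[str, ...]]:
        names = _names()
        for _ in range(self.n_primaries):
            next(names)
        out: dict[str, tuple[str, ...]] = {}
        for seed in self.metastatic_primary_ids:
            out[seed] = tuple(next(names) for _ in range(self.n_mets_per_seed))
        return out

    @property
    def samples(self) -> tuple[str, ...]:
        mets = self.mets_by_seed
        return self.primaries + tuple(m for seed in self.metastatic_primary_ids for m in mets[seed])

    @property
    def purity_map(self) -> dict[str, float]:
        if isinstance(self.purity, dict):
            return dict(self.purity)
        return {s: float(self.purity) for s in self.samples}


def _names():
    """A, B, ..., Z, AA, AB, ..."""
    k = 1
    while True:
        for tup in itertools.product(string.ascii_uppercase, repeat=k):
            yield "".join(tup)
        k += 1


@dataclass
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context: str  # genomic-strand trinucleotide, middle base == ref

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def draw_mutations(
    n: int,
    signature_mix: dict[str, float],
    genome: GenomeModel,
    rng: np.random.Generator,
    bank: pd.DataFrame | None = None,
    used: set | None = None,
) -> list[Variant]:
    """Draw ``n`` SNVs whose 96-channel contexts follow ``signature_mix``.

    Channels are sampled from the mixture of signature columns in
    ``bank`` (default: the synthetic bank); each mutation is placed
    uniformly on a length-weighted random chromosome, and emitted on a
    random strand (half the records carry the purine-reference
    representation, which 96-channel counting must collapse back).
    Positions are unique within a run (``used`` carries state across
    calls).
    """
    if n < 0:
        raise ConfigurationError("n must be >= 0")
    if n == 0:
        return []
    if bank is None:
        bank = synthetic_signature_bank()
    unknown = set(signature_mix) - set(bank.columns)
    if unknown:
        raise ConfigurationError(f"unknown signature name(s): {sorted(unknown)}")
    mix = np.array([signature_mix.get(c, 0.0) for c in bank.columns], dtype=float)
    p96 = bank.to_numpy() @ (mix / mix.sum())
    p96 = p96 / p96.sum()

    chroms, cw = genome.chrom_probs()
    if used is None:
        used = set()
    out: list[Variant] = []
    channels = rng.choice(96, size=n, p=p96)
    flip = rng.random(n) < 0.5
    ci = rng.choice(len(chroms), size=n, p=cw)
    for i in range(n):
        chrom = chroms[ci[i]]
        length = genome.lengths[chrom]
        while True:
            pos = int(rng.integers(2, max(3, length)))  # keep flanks inside the chromosome
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                break
        tri, ref, alt = parse_channel(SBS96_CHANNELS[channels[i]])
        if flip[i]:
            tri, ref, alt = revcomp(tri), revcomp(ref), revcomp(alt)
        out.append(Variant(chrom, pos, ref, alt, tri))
    return out


@dataclass
class CohortTruth:
    """Ground truth for one simulated patient."""

    samples: tuple[str, ...]
    seeding: dict[str, tuple[str, ...]]  # seed primary -> its metastases
    lineages: dict[tuple, str]  # variant key -> lineage label
    true_vaf: dict[tuple, dict[str, float]]  # variant key -> sample -> VAF
    cna_events: tuple[TruthCNA, ...]
    purity: dict[str, float]

    def carriers(self, key: tuple) -> set:
        return {s for s, v in self.true_vaf[key].items() if v > 0}

    def lineage_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.lineages.values():
            out[lab] = out.get(lab, 0) + 1
        return out


@dataclass
class Cohort:
    """A simulated patient: truth plus the observable tables."""

    config: SimConfig
    truth: CohortTruth
    calls: dict[str, pd.DataFrame]  # per-sample relaxed (unfiltered) call tables
    het_snps: pd.DataFrame
    windows: pd.DataFrame

    def write_tables(self, outdir) -> None:
        """Write all tables as TSV (+ VCF per sample) plus the truth sidecar."""
        from pathlib import Path

        from .io import write_calls_tsv, write_calls_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s, df in self.calls.items():
            write_calls_tsv(df, outdir / f"calls_{s}.tsv")
            write_calls_vcf(df, s, outdir / f"calls_{s}.vcf")
        self.het_snps.to_csv(outdir / "het_snps.tsv", sep="\t", index=False)
        self.windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
        (outdir / "truth.json").write_text(truth_to_json(self.truth))


def truth_to_json(truth: CohortTruth) -> str:
    payload = {
        "samples": list(truth.samples),
        "seeding": {k: list(v) for k, v in truth.seeding.items()},
        "purity": truth.purity,
        "cna_events": [
            {
                "chrom": e.chrom,
                "homolog": e.homolog,
                "kind": e.kind,
                "start": e.start,
                "end": e.end,
                "carriers": list(e.carriers),
            }
            for e in truth.cna_events
        ],
        "variants": {
            f"{c}:{p}:{r}:{a}": {"lineage": truth.lineages[(c, p, r, a)], "vaf": vafs}
            for (c, p, r, a), vafs in truth.true_vaf.items()
        },
    }
    return json.dumps(payload, indent=1)


def _homolog_copies(config: SimConfig, sample: str, chrom: str, pos0: int) -> tuple[int, int]:
    """Copy number of homologs (A, B) at a 0-based position in a sample."""
    a, b = 1, 1
    for e in config.cna_events:
        if e.chrom != chrom or sample not in e.carriers:
            continue
        if not e.whole and not (e.start <= pos0 < e.end):
            continue
        delta = -1 if e.kind == "loss" else 1
        if e.homolog in ("A", "both"):
            a = max(0, a + delta)
        if e.homolog in ("B", "both"):
            b = max(0, b + delta)
    return a, b


def _expected_vaf(copies: tuple[int, int], homolog: str, purity: float) -> float:
    """VAF of a clonal somatic variant on one homolog, diluted by purity."""
    ca, cb = copies
    alt_copies = ca if homolog == "A" else cb
    total = purity * (ca + cb) + (1 - purity) * 2
    if total == 0:
        return 0.0
    return purity * alt_copies / total


def _split_strands(alt: int, rng: np.random.Generator, noise: bool) -> tuple[int, int]:
    if not noise:
        fwd = (alt + 1) // 2
        return fwd, alt - fwd
    fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    return fwd, alt - fwd


def _observe(
    vaf: float, depth: float, rng: np.random.Generator, noise: bool, min_alt: int | None = None
) -> tuple[int, int] | None:
    """Sample (alt_reads, site_depth); None when below the caller floor.

    ``min_alt`` forces a zero-truncated draw (used for contamination
    traces, which model *detectable* contamination: fewer than two
    supporting reads is invisible to any caller and would not be part
    of a trace-variant count in the first place).
    """
    if not noise:
        d = max(1, round(depth))
        alt = round(d * vaf)
        if min_alt is not None:
            alt = max(min_alt, alt)
        return (alt, d) if alt >= MIN_ALT_EMIT else None
    d = int(rng.poisson(depth))
    if d == 0:
        return None
    alt = int(rng.binomial(d, min(vaf, 1.0)))
    if min_alt is not None:
        while alt < min_alt:  # zero-truncated redraw
            d = max(int(rng.poisson(depth)), min_alt)
            alt = int(rng.binomial(d, min(vaf, 1.0)))
    return (alt, d) if alt >= MIN_ALT_EMIT else None


CALL_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "depth",
    "alt_fwd",
    "alt_rev",
    "in_normal",
    "normal_depth",
    "caller_set",
    "context",
]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate one patient cohort from a :class:`SimConfig`.

    Deterministic for a fixed config (including seed). Returns the
    ground truth plus per-sample relaxed call tables, the germline
    het-SNP table and the fixed-window read-count table.
    """
    rng = np.random.default_rng(config.seed)
    samples = config.samples
    purity = config.purity_map
    seeding = config.mets_by_seed
    bank = synthetic_signature_bank()
    used: set = set()

    # --- lineage plan: (label, clonal carriers, trace (recipient, vaf range) or None, count)
    plan: list[tuple[str, tuple[str, ...], Contamination | None, int]] = []
    for seed_primary in config.metastatic_primary_ids:
        carriers = (seed_primary, *seeding[seed_primary])
        plan.append((f"trunk:{seed_primary}", carriers, None, config.trunk_sizes[seed_primary]))
    lo, hi = config.private_range
    for s in samples:
        n_priv = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        plan.append((f"private:{s}", (s,), None, n_priv))
    for i, (carrier_set, count) in enumerate(config.embryonic_shared):
        carriers = tuple(sorted(carrier_set))
        bad = set(carriers) - set(samples)
        if bad:
            raise ConfigurationError(f"embryonic carriers {sorted(bad)} not in cohort")
        plan.append((f"embryonic:{'+'.join(carriers)}", carriers, None, count))
    for ct in config.contamination:
        if ct.donor not in samples or ct.recipient not in samples:
            raise ConfigurationError(f"contamination samples {ct.donor}->{ct.recipient} not in cohort")
        plan.append((f"contamination:{ct.donor}->{ct.recipient}", (ct.donor,), ct, ct.count))

    lineages: dict[tuple, str] = {}
    true_vaf: dict[tuple, dict[str, float]] = {}
    rows: dict[str, list] = {s: [] for s in samples}

    for label, clonal_carriers, trace, count in plan:
        muts = draw_mutations(count, config.signature_mix, config.genome, rng, bank, used)
        for v in muts:
            key = v.key
            lineages[key] = label
            # place the variant on a homolog retained in every clonal carrier
            candidates = []
            for h in ("A", "B"):
                copies = [
                    _homolog_copies(config, s, v.chrom, v.pos - 1) for s in clonal_carriers
                ]
                idx = 0 if h == "A" else 1
                if all(c[idx] >= 1 for c in copies):
                    candidates.append(h)
            homolog = candidates[int(rng.integers(len(candidates)))] if candidates else ("A", "B")[int(rng.integers(2))]
            vafs = {s: 0.0 for s in samples}
            for s in clonal_carriers:
                copies = _homolog_copies(config, s, v.chrom, v.pos - 1)
                vafs[s] = _expected_vaf(copies, homolog, purity[s])
            if trace is not None:
                tlo, thi = trace.vaf_range
                vafs[trace.recipient] = float(rng.uniform(tlo, thi))
            true_vaf[key] = vafs
            # observed calls
            for s in samples:
                vaf_s = vafs[s]
                if vaf_s <= 0:
                    continue
                is_trace = trace is not None and s == trace.recipient
                # the donor side of a contamination lineage is by
                # definition a confidently-detected clonal variant (the
                # whitelist that counts trace overlaps is built from
                # detected calls), so its draw is conditioned on
                # detectability in the donor
                is_donor = trace is not None and s == trace.donor
                obs = _observe(
                    vaf_s, config.depth, rng, config.noise,
                    min_alt=MIN_ALT_EMIT if is_trace else (MUTECT_MIN_ALT if is_donor else None),
                )
                if obs is None:
                    continue
                alt_reads, d = obs
                fwd, rev = _split_strands(alt_reads, rng, config.noise)
                if is_donor and alt_reads >= 2:
                    while fwd == 0 or rev == 0:  # detected on both strands
                        fwd, rev = _split_strands(alt_reads, rng, True)
                normal_depth = int(rng.poisson(config.depth)) if config.noise else round(config.depth)
                if is_donor:
                    while normal_depth < 20:
                        normal_depth = int(rng.poisson(config.depth))
                callers = ["varscan"]
                if alt_reads >= MUTECT_MIN_ALT and fwd > 0 and rev > 0:
                    callers.insert(0, "mutect")
                rows[s].append(
                    (
                        v.chrom, v.pos, v.ref, v.alt,
                        alt_reads / d, d, fwd, rev,
                        False, normal_depth, ",".join(callers), v.context,
                    )
                )

    calls = {}
    for s in samples:
        df = pd.DataFrame(rows[s], columns=CALL_COLUMNS)
        df["chrom_order"] = df["chrom"].map(chrom_sort_key)
        df = df.sort_values(["chrom_order", "pos"]).drop(columns="chrom_order").reset_index(drop=True)
        calls[s] = df

    het = _simulate_het_snps(config, rng)
    windows = _simulate_windows(config, rng)
    truth = CohortTruth(
        samples=samples,
        seeding=seeding,
        lineages=lineages,
        true_vaf=true_vaf,
        cna_events=config.cna_events,
        purity=purity,
    )
    return Cohort(config=config, truth=truth, calls=calls, het_snps=het, windows=windows)


def _simulate_het_snps(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Germline het SNPs on a regular grid; ALT allele sits on homolog A
    or B at random, so allelic imbalance tracks the simulated CNAs."""
    frames = []
    base_pairs = np.array(["A", "C", "G", "T"])
    for chrom in config.genome.chroms:
        length = config.genome.lengths[chrom]
        pos = np.arange(config.het_snp_spacing // 2, length, config.het_snp_spacing) + 1
        n = len(pos)
        if n == 0:
            continue
        ref_i = rng.integers(0, 4, size=n)
        alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
        alt_homolog = rng.choice(["A", "B"], size=n)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": base_pairs[ref_i],
                "alt": base_pairs[alt_i],
                "alt_homolog": alt_homolog,
            }
        )
        # blood normal: balanced het
        if config.noise:
            d = rng.poisson(config.depth, size=n).clip(min=1)
            df["vaf_normal"] = rng.binomial(d, 0.5) / d
            df["depth_normal"] = d
        else:
            df["vaf_normal"] = 0.5
            df["depth_normal"] = round(config.depth)
        for s in config.samples:
            p = config.purity_map[s]
            exp = np.empty(n)
            for i, (pp, hom) in enumerate(zip(pos, alt_homolog)):
                ca, cb = _homolog_copies(config, s, chrom, int(pp) - 1)
                total = p * (ca + cb) + (1 - p) * 2
                altc = p * (ca if hom == "A" else cb) + (1 - p) * 1
                exp[i] = altc / total if total > 0 else 0.5
            if config.noise:
                d = rng.poisson(config.depth, size=n).clip(min=1)
                df[f"vaf_{s}"] = rng.binomial(d, exp) / d
                df[f"depth_{s}"] = d
            else:
                df[f"vaf_{s}"] = exp
                df[f"depth_{s}"] = round(config.depth)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _simulate_windows(config: SimConfig, rng: np.random.Generator, window: int = 2000) -> pd.DataFrame:
    """Fixed-window read counts for tumor samples and the blood normal.

    Expected reads per window scale with the purity-mixed total copy
    number; the base rate corresponds to paired 150 bp reads at the
    configured mean depth.
    """
    lam0 = config.depth * window / 300.0
    frames = []
    for chrom in config.genome.chroms:
        length = config.genome.lengths[chrom]
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        n = len(starts)
        df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})
        mids = (starts + ends) // 2
        if config.noise:
            df["count_normal"] = rng.poisson(lam0, size=n)
        else:
            df["count_normal"] = round(lam0)
        for s in config.samples:
            p = config.purity_map[s]
            factor = np.empty(n)
            for i, m in enumerate(mids):
                ca, cb = _homolog_copies(config, s, chrom, int(m))
                factor[i] = (p * (ca + cb) + (1 - p) * 2) / 2.0
            lam = lam0 * factor
            df[f"count_{s}"] = rng.poisson(lam) if config.noise else np.round(lam).astype(int)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort presets mirroring the published multifocal-SI-NET architectures.
# ---------------------------------------------------------------------------


def patient1_config(seed: int = 0, noise: bool = False, trunk: int = 667, **overrides) -> SimConfig:
    """Six independent primaries (A-F); C seeds five metastases (G-K)
    through a shared trunk (default 667 SNVs). Related samples lose the
    same chr18 homolog; unrelated primaries lose different homologs."""
    met_clade = ("C", "G", "H", "I", "J", "K")
    genome = overrides.pop("genome", miniature_genome())
    chr11 = genome.lengths["chr11"]
    cna = (
        TruthCNA("chr18", "A", "loss", met_clade),
        TruthCNA("chr18", "B", "loss", ("A",)),
        TruthCNA("chr18", "A", "loss", ("D",)),
        TruthCNA("chr18", "B", "loss", ("E",)),
        # the segmental chr11 loss shared by the metastatic clade
        TruthCNA("chr11", "A", "loss", met_clade, start=chr11 // 4, end=chr11 // 2),
    )
    cfg = dict(
        n_primaries=6,
        metastatic_primary_ids=("C",),
        n_mets_per_seed=5,
        trunk_sizes={"C": trunk},
        private_range=(300, 1700),
        purity=0.6,
        depth=40.0,
        genome=genome,
        cna_events=cna,
        noise=noise,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def patient2_config(seed: int = 0, noise: bool = False, trunk: int = 1214, **overrides) -> SimConfig:
    """Eleven primaries (A-K); G seeds one lymph-node metastasis (L) with
    a 1,214-SNV trunk; eight embryonic variants shared by F, G and L;
    chromothriptic oscillation on chr13 in G and L."""
    genome = overrides.pop("genome", miniature_genome())
    cna = (
        TruthCNA("chr18", "A", "loss", ("G", "L")),
        TruthCNA("chr18", "B", "loss", ("B", "D")),
        *oscillating_cna("chr13", ("G", "L"), genome, n_segments=20, seg_len=40_000),
    )
    cfg = dict(
        n_primaries=11,
        metastatic_primary_ids=("G",),
        n_mets_per_seed=1,
        trunk_sizes={"G": trunk},
        private_range=(300, 1700),
        embryonic_shared=((frozenset({"F", "G", "L"}), 8),),
        purity=0.6,
        depth=40.0,
        genome=genome,
        cna_events=cna,
        noise=noise,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def contamination_config(
    seed: int = 0, count: int = 66, vaf_range: tuple[float, float] = (0.02, 0.05), **overrides
) -> SimConfig:
    """Two independent primaries; B seeds a metastasis C; ``count``
    variants clonal in donor A leak into C at trace VAF (sample-handling
    contamination scenario)."""
    cfg = dict(
        n_primaries=2,
        metastatic_primary_ids=("B",),
        n_mets_per_seed=1,
        trunk_sizes={"B": 400},
        private_range=(300, 900),
        contamination=(Contamination("A", "C", count, vaf_range),),
        purity=0.6,
        depth=40.0,
        noise=True,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def oscillating_cna(
    chrom: str,
    carriers: tuple[str, ...],
    genome: GenomeModel,
    n_segments: int = 20,
    seg_len: int = 40_000,
    homolog: str = "A",
    offset: int = 0,
) -> tuple[TruthCNA, ...]:
    """Clustered alternating losses emulating chromothripsis: every other
    ``seg_len`` interval on ``chrom`` is a monoallelic loss, producing a
    copy-number profile oscillating between two states."""
    length = genome.lengths[chrom]
    if offset + n_segments * seg_len > length:
        raise ConfigurationError(
            f"{n_segments} x {seg_len} bp oscillation does not fit on {chrom} ({length} bp)"
        )
    events = []
    for i in range(0, n_segments, 2):
        start = offset + i * seg_len
        events.append(TruthCNA(chrom, homolog, "loss", tuple(carriers), start=start, end=start + seg_len))
    return tuple(events)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """A copy of ``config`` with a different RNG seed."""
    return replace(config, seed=seed)
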