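"""Gene models and reading-frame checks for structural-variant fusions.

A rearrangement joining two genic breakpoints yields a putative valid
fusion gene only when the retained pieces transcribe in one direction
and the cumulative coding-sequence length upstream of each breakpoint
leaves the downstream partner in codon phase. Gene models are minimal
transcripts (exons + CDS span + strand) loaded from BED12 or built
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .filtering import InputError


@dataclass(frozen=True)
class Transcript:
    """Exon/CDS structure of one transcript.

    Coordinates are 0-based half-open genomic intervals; ``exons`` are
    sorted by genomic start regardless of strand.
    """

    name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r} for {self.name}")
        for s, e in self.exons:
            if e <= s:
                raise InputError(f"empty exon in {self.name}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end

    def in_cds(self, pos0: int) -> bool:
        return self.cds_start <= pos0 < self.cds_end

    def cds_len_upstream(self, pos0: int) -> int:
        """Coding bases transcribed before (5' of) a genomic position."""
        total = 0
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if ce <= cs:
                continue
            if self.strand == "+":
                total += max(0, min(ce, pos0) - cs)
            else:
                total += max(0, ce - max(cs, pos0))
        return total


def read_bed12(path) -> list[Transcript]:
    """Load transcripts from a BED12 file (blocks = exons, thick = CDS)."""
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    out = []
    for _, r in df.iterrows():
        sizes = [int(x) for x in str(r["block_sizes"]).rstrip(",").split(",")]
        starts = [int(x) for x in str(r["block_starts"]).rstrip(",").split(",")]
        exons = tuple(
            (int(r["start"]) + off, int(r["start"]) + off + size)
            for off, size in zip(starts, sizes)
        )
        out.append(
            Transcript(
                name=str(r["name"]),
                chrom=str(r["chrom"]),
                strand=str(r["strand"]),
                exons=exons,
                cds_start=int(r["thick_start"]),
                cds_end=int(r["thick_end"]),
            )
        )
    return out


@dataclass(frozen=True)
class Breakpoint:
    """One end of a rearrangement junction.

    ``pos`` is 1-based; ``orientation`` '+' means the junction retains
    the left (lower-coordinate) side of the chromosome, '-' the right.
    """

    chrom: str
    pos: int
    orientation: str

    @property
    def pos0(self) -> int:
        return self.pos - 1


def _find_transcript(bp: Breakpoint, transcripts) -> Transcript | None:
    for t in transcripts:
        if t.contains(bp.chrom, bp.pos0):
            return t
    return None


def fusion_frame_check(bp5: Breakpoint, bp3: Breakpoint, transcripts) -> str:
    """Classify a two-breakpoint fusion as in_frame / out_of_frame /
    non_coding.

    ``bp5`` contributes the 5' (promoter-side) piece of its gene, ``bp3``
    the 3' piece of its gene. The call is ``non_coding`` when either
    breakpoint misses an annotated CDS; ``out_of_frame`` when the
    retained pieces cannot transcribe in one direction or when the CDS
    phases at the junction disagree; ``in_frame`` otherwise.
    """
    t5 = _find_transcript(bp5, transcripts)
    t3 = _find_transcript(bp3, transcripts)
    if t5 is None or t3 is None:
        return "non_coding"
    if not (t5.in_cds(bp5.pos0) and t3.in_cds(bp3.pos0)):
        return "non_coding"
    # The 5' piece must retain its transcription start, the 3' piece its
    # CDS end, for the fusion transcript to read through the junction.
    keeps_tss = bp5.orientation == ("+" if t5.strand == "+" else "-")
    keeps_stop = bp3.orientation == ("-" if t3.strand == "+" else "+")
    if not (keeps_tss and keeps_stop):
        return "out_of_frame"
    len5 = t5.cds_len_upstream(bp5.pos0)
    len3_up = t3.cds_len_upstream(bp3.pos0)
    return "in_frame" if (len5 - len3_up) % 3 == 0 else "out_of_frame"


def read_breakpoints_tsv(path) -> tuple[Breakpoint, Breakpoint]:
    """Two-row TSV: chrom, pos, strand, partner_id (5' row first)."""
    df = pd.read_csv(path, sep="\t")
    if len(df) != 2:
        raise InputError(f"{path}: expected exactly 2 breakpoint rows, got {len(df)}")
    rows = [Breakpoint(str(r["chrom"]), int(r["pos"]), str(r["strand"])) for _, r in df.iterrows()]
    return rows[0], rows[1]
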