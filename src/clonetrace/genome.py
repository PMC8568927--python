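"""Genome models used by the synthetic cohort simulator.

The downstream analyses (shared-variant counting, parsimony trees,
signature refitting, window-based CNA calling) depend on variant counts
and relative coordinates, not on absolute genome size, so the default
model is a miniature diploid genome: the 22 human autosomes with hg19
lengths scaled down 100-fold. The full-length hg19 autosomes are
available for runs where absolute coordinates matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# hg19 autosome lengths, chr1..chr22 (bp).
HG19_AUTOSOME_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
}

#: Canonical chromosome sort order (chr1..chr22).
CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(HG19_AUTOSOME_LENGTHS)}


def chrom_sort_key(chrom: str) -> int:
    """Sort key placing autosomes in natural order, unknowns last."""
    return CHROM_ORDER.get(chrom, len(CHROM_ORDER))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths plus (optional) trinucleotide context frequencies.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp.
    trinuc_freqs
        Optional mapping from trinucleotide (pyrimidine-centred, e.g.
        ``"ACA"``) to genome frequency. When absent, contexts are
        treated as uniform and mutation contexts are drawn from the
        signature probabilities directly, matching the refitting
        convention (no genome-composition correction).
    """

    lengths: dict[str, int] = field(default_factory=dict)
    trinuc_freqs: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {n}")

    @property
    def chroms(self) -> list[str]:
        return sorted(self.lengths, key=chrom_sort_key)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths.values()))

    def chrom_probs(self) -> tuple[list[str], np.ndarray]:
        """Chromosomes and their length-proportional sampling weights."""
        chroms = self.chroms
        w = np.array([self.lengths[c] for c in chroms], dtype=float)
        return chroms, w / w.sum()


def miniature_genome(scale: int = 100) -> GenomeModel:
    """hg19 autosomes scaled down ``scale``-fold (default 1/100)."""
    return GenomeModel({c: max(1, n // scale) for c, n in HG19_AUTOSOME_LENGTHS.items()})


def hg19_genome() -> GenomeModel:
    """Full-length hg19 autosomes."""
    return GenomeModel(dict(HG19_AUTOSOME_LENGTHS))
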