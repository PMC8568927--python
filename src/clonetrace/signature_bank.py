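"""96-channel substitution classes and a synthetic signature bank.

The 96 channels follow the COSMIC single-base-substitution convention:
six pyrimidine-centred substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) crossed with the 4 x 4 flanking-base combinations, labelled e.g.
``A[C>T]G``.

Because the real COSMIC v3 definition file is distributed under
controlled terms and is not bundled here, the package ships a
deterministic *synthetic* signature bank that emulates the structural
properties the analysis depends on: a broad, flat clock-like process
("SBS5"), a second near-collinear flat process ("SBS40", cosine > 0.9
to SBS5, reproducing their practical confusability), and several
sharply peaked, well-separated processes. Real COSMIC v3 files load
through :func:`read_signature_tsv` and are interchangeable with the
bank everywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PYRIMIDINE_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical channel order: substitution class, then 5' base, then 3' base.
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in PYRIMIDINE_SUBS for five in BASES for three in BASES
)
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(SBS96_CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def parse_channel(label: str) -> tuple[str, str, str]:
    """Split ``A[C>T]G`` into (trinucleotide ``ACG``, ref ``C``, alt ``T``)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def channel_for(ref: str, alt: str, context: str) -> str:
    """Map an observed substitution to its pyrimidine-centred channel.

    ``context`` is the trinucleotide around the site on the reported
    strand (middle base == ``ref``). Purine-reference events are
    reverse-complemented, per the 96-channel convention.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if any(b not in _COMPLEMENT for b in context) or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT base in {context!r}>{alt!r}")
    if ref in ("A", "G"):
        context = revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def _sub_block(sub: str) -> np.ndarray:
    """Boolean mask over the 96 channels for one substitution class."""
    return np.array([c[2:5] == sub for c in SBS96_CHANNELS])


def _peaked(sub: str, five: str | None = None, three: str | None = None) -> np.ndarray:
    v = np.zeros(96)
    for i, ch in enumerate(SBS96_CHANNELS):
        tri, ref, alt = parse_channel(ch)
        if f"{ref}>{alt}" != sub:
            continue
        if five is not None and tri[0] != five:
            continue
        if three is not None and tri[2] != three:
            continue
        v[i] = 1.0
    return v / v.sum()


def synthetic_signature_bank() -> pd.DataFrame:
    """Deterministic synthetic SBS signature matrix (96 rows x 6 signatures).

    Columns are probability vectors over :data:`SBS96_CHANNELS`. The
    names mirror the COSMIC processes each column emulates; the spectra
    themselves are synthetic.
    """
    rng = np.random.default_rng(961_031)

    # SBS5-like: broad, clock-like; mild T>C and C>T enrichment.
    base = rng.gamma(8.0, 1.0, size=96)
    base[_sub_block("T>C")] *= 1.8
    base[_sub_block("C>T")] *= 1.4
    sbs5 = base / base.sum()

    # SBS40-like: a small multiplicative perturbation of SBS5 -> nearly
    # collinear flat spectrum (cosine > 0.9), reproducing the known
    # SBS5/SBS40 confusability.
    sbs40 = sbs5 * rng.gamma(60.0, 1.0 / 60.0, size=96)
    sbs40 = sbs40 / sbs40.sum()

    # Peaked, well-separated processes.
    sbs1 = 0.9 * _peaked("C>T", three="G") + 0.1 * sbs5  # CpG deamination
    sbs2 = 0.92 * _peaked("C>T", five="T") + 0.08 * sbs5  # APOBEC C>T
    sbs13 = 0.92 * _peaked("C>G", five="T") + 0.08 * sbs5  # APOBEC C>G
    c2a = rng.gamma(4.0, 1.0, size=96) * _sub_block("C>A")
    sbs18 = 0.95 * c2a / c2a.sum() + 0.05 * sbs5  # oxidative C>A

    bank = pd.DataFrame(
        {
            "SBS1": sbs1,
            "SBS2": sbs2,
            "SBS5": sbs5,
            "SBS13": sbs13,
            "SBS18": sbs18,
            "SBS40": sbs40,
        },
        index=pd.Index(SBS96_CHANNELS, name="Type"),
    )
    return bank / bank.sum(axis=0)


def read_signature_tsv(path) -> pd.DataFrame:
    """Read a COSMIC v3-dialect signature TSV (Type column + one column
    per signature) and normalise channel order to :data:`SBS96_CHANNELS`."""
    df = pd.read_csv(path, sep="\t")
    if "Type" not in df.columns:
        raise ValueError(f"{path}: missing 'Type' column (COSMIC v3 dialect expected)")
    df = df.set_index("Type")
    missing = set(SBS96_CHANNELS) - set(df.index)
    if missing:
        raise ValueError(f"{path}: missing {len(missing)} of 96 channels (e.g. {sorted(missing)[:3]})")
    df = df.loc[list(SBS96_CHANNELS)].astype(float)
    return df / df.sum(axis=0)


def write_signature_tsv(bank: pd.DataFrame, path) -> None:
    """Write a signature matrix in the COSMIC v3 tab dialect."""
    out = bank.copy()
    out.index.name = "Type"
    out.to_csv(path, sep="\t")
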