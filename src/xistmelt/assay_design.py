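"""In-silico PCR and empirical amplicon-Tm prediction.

A small utility for checking primer pairs against user-supplied template
sequences by exact matching (both strands), and for predicting the melting
temperature of a PCR product from its length and GC content with the
standard empirical salt-corrected formula

    Tm = 81.5 + 16.6·log10([Na+]) + 0.41·(%GC) − 675/N

used to sanity-check the simulator's default product temperatures. The
ACTB and XIST primer pairs of the duplex assay ship as module constants.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "PrimerPair",
    "AmpliconHit",
    "ACTB_PRIMERS",
    "XIST_PRIMERS",
    "find_amplicons",
    "product_tm",
    "load_templates",
    "hits_to_frame",
]

MIN_PRIMER_LENGTH = 15
_IUPAC = set("ACGTRYSWKMBDHVN")
_STRICT = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'→3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            seq = seq.upper()
            object.__setattr__(self, label, seq)
            if len(seq) < MIN_PRIMER_LENGTH:
                raise ValueError(
                    f"{self.name} {label} primer shorter than {MIN_PRIMER_LENGTH} nt"
                )
            if not _STRICT.match(seq):
                raise ValueError(
                    f"{self.name} {label} primer contains non-ACGT characters"
                )


#: duplex assay primer pairs (β-actin control and the female-specific XIST target)
ACTB_PRIMERS = PrimerPair("ACTB_mn01", "AAGATCCTCACGGAGCGTGG", "TGATCACCTGACCATCGGGC")
XIST_PRIMERS = PrimerPair("XIST_mn01", "CCGTTACATTCTTGGCGGGC", "TCCTCCACTAACTGGCTGCG")


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product on a template.

    Coordinates are 0-based half-open on the forward strand regardless of
    the amplifying orientation (``strand`` is '+' when the forward primer
    sits on the + strand, '−' when the pair amplifies the reverse strand).
    """

    template_id: str
    start: int
    end: int
    strand: str
    length: int
    gc_fraction: float
    predicted_tm: float | None


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _find_all(haystack: str, needle: str) -> list[int]:
    positions, i = [], haystack.find(needle)
    while i != -1:
        positions.append(i)
        i = haystack.find(needle, i + 1)
    return positions


def product_tm(length: int, gc: float, cation: float = 0.2) -> float:
    """Empirical product melting temperature in °C.

    81.5 + 16.6·log10([Na+]) + 0.41·(%GC) − 675/N, with ``cation`` the
    monovalent-cation molarity (default 0.2 M equivalent, typical of qPCR
    master mixes) and N the product length in bp (≥ 40 for the formula's
    validity range).
    """
    if length < 40:
        raise ValueError("product_tm requires length >= 40 bp")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be a fraction in [0, 1]")
    if cation <= 0:
        raise ValueError("cation molarity must be > 0")
    return 81.5 + 16.6 * math.log10(cation) + 0.41 * (100.0 * gc) - 675.0 / length


def find_amplicons(
    template: str,
    pair: PrimerPair,
    max_len: int = 2000,
    template_id: str = "template",
    cation: float = 0.2,
) -> list[AmpliconHit]:
    """Exact-match in-silico PCR on one template.

    Reports every locus where the forward primer matches one strand and the
    reverse primer matches the other strand downstream within ``max_len``
    bp; both orientations are searched, so a pair amplifying the − strand is
    found too. Matching is exact over {A,C,G,T} (IUPAC ambiguity codes in
    the template never match).
    """
    template = str(template).upper().replace("U", "T")
    bad = set(template) - _IUPAC
    if bad:
        raise ValueError(f"template contains non-IUPAC characters {sorted(bad)}")
    hits: list[AmpliconHit] = []

    def emit(start: int, end: int, strand: str) -> None:
        product = template[start:end]
        gc = (product.count("G") + product.count("C")) / len(product)
        tm = product_tm(len(product), gc, cation) if len(product) >= 40 else None
        hits.append(
            AmpliconHit(
                template_id=template_id,
                start=start,
                end=end,
                strand=strand,
                length=end - start,
                gc_fraction=gc,
                predicted_tm=tm,
            )
        )

    # + orientation: forward on + strand, revcomp(reverse) downstream
    rc_rev = _revcomp(pair.reverse)
    for i in _find_all(template, pair.forward):
        for j in _find_all(template[i:], rc_rev):
            end = i + j + len(rc_rev)
            if end - i <= max_len:
                emit(i, end, "+")
    # − orientation: reverse primer on + strand, revcomp(forward) downstream
    rc_fwd = _revcomp(pair.forward)
    for i in _find_all(template, pair.reverse):
        for j in _find_all(template[i:], rc_fwd):
            end = i + j + len(rc_fwd)
            if end - i <= max_len:
                emit(i, end, "-")
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def load_templates(path: str | Path) -> dict[str, str]:
    """Read FASTA templates as {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def hits_to_frame(hits: Iterable[AmpliconHit]) -> pd.DataFrame:
    """Tabulate hits for CSV export
    (``template,start,end,strand,length,gc,predicted_tm``)."""
    return pd.DataFrame(
        [
            {
                "template": h.template_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "length": h.length,
                "gc": round(h.gc_fraction, 4),
                "predicted_tm": None if h.predicted_tm is None else round(h.predicted_tm, 2),
            }
            for h in hits
        ]
    )
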