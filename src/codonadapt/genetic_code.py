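"""Standard nuclear genetic code tables and codon bookkeeping.

Everything downstream (codon counting, tAI, CAI, the 59-dimensional
amino-acid-normalized usage vector) is defined over the 61 sense codons of
the standard code. Only the standard nuclear code is supported; the analysis
is restricted to cytosolic translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_BASES = "TCAG"
# NCBI translation table 1, codons enumerated TTT, TTC, TTA, TTG, TCT, ...
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODON_TO_AA: dict[str, str] = {}
_i = 0
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            CODON_TO_AA[_b1 + _b2 + _b3] = _AA_STRING[_i]
            _i += 1

STOP_CODONS: tuple[str, ...] = tuple(sorted(c for c, a in CODON_TO_AA.items() if a == "*"))
SENSE_CODONS: tuple[str, ...] = tuple(sorted(c for c, a in CODON_TO_AA.items() if a != "*"))

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    _aa = CODON_TO_AA[_c]
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_c,)

#: Amino acids encoded by a single codon (excluded from within-family normalization).
SINGLE_CODON_AAS: frozenset[str] = frozenset(
    aa for aa, codons in AA_TO_CODONS.items() if len(codons) == 1
)

#: The 59 sense codons belonging to synonymous families of size >= 2
#: (61 sense codons minus ATG/Met and TGG/Trp), in lexicographic order.
AA_NORM_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if CODON_TO_AA[c] not in SINGLE_CODON_AAS
)

#: Multi-codon synonymous families, amino acid -> codon tuple.
MULTI_CODON_FAMILIES: dict[str, tuple[str, ...]] = {
    aa: codons for aa, codons in AA_TO_CODONS.items() if len(codons) > 1
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_for(codon: str) -> str:
    """Watson-Crick anticodon (5'->3', DNA alphabet) of a codon."""
    return reverse_complement(codon)


@dataclass(frozen=True)
class GeneticCode:
    """The standard nuclear genetic code as an explicit object.

    Carried around so type signatures are honest about what the metrics are
    defined over; only the standard code instance is shipped.
    """

    codon_to_aa: dict[str, str] = field(default_factory=lambda: dict(CODON_TO_AA))
    sense_codons: tuple[str, ...] = SENSE_CODONS
    stop_codons: tuple[str, ...] = STOP_CODONS
    families: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(AA_TO_CODONS))

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]


STANDARD_CODE = GeneticCode()
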