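"""CDS validation, codon counting, and codon-frequency normalizations.

Two normalizations are provided:

* length-normalized relative frequencies over the 61 sense codons,
  ``rel_freq[c] = count_c / L`` where L is the number of sense codons in
  the CDS; and
* within-amino-acid (synonymous-family) normalized frequencies over the 59
  sense codons belonging to families of size >= 2, which remove the
  confounding effects of amino-acid composition and gene length and are
  the input to codon-usage PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    AA_NORM_CODONS,
    MULTI_CODON_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
)

logger = logging.getLogger(__name__)

_SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
_VALID_BASES = frozenset("ACGT")


class CdsValidationError(ValueError):
    """A CDS record failed validation; ``reason`` is a stable machine code."""

    def __init__(self, gene_id: str, reason: str, detail: str = ""):
        self.gene_id = gene_id
        self.reason = reason
        msg = f"{gene_id}: {reason}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


@dataclass(frozen=True)
class CodingSequence:
    """A validated coding sequence.

    ``sequence`` holds the sense codons only: a trailing stop codon, if
    present in the input, has been stripped. ``n_codons`` is L, the number
    of sense codons.
    """

    gene_id: str
    sequence: str
    n_codons: int

    def codons(self) -> Iterator[str]:
        s = self.sequence
        for i in range(0, len(s), 3):
            yield s[i : i + 3]


@dataclass(frozen=True)
class CodonUsageProfile:
    """Per-gene codon usage in raw, relative and family-normalized form."""

    gene_id: str
    n_codons: int
    raw_counts: pd.Series  # index = 61 sense codons, integer
    rel_freq: pd.Series | None = None  # sums to 1
    aa_norm_freq: pd.Series | None = None  # index = 59 codons, blocks sum to 1 or 0


def parse_cds(record, on_ambiguous: str = "reject") -> CodingSequence:
    """Validate one FASTA record (or ``(id, sequence)`` pair) into a CDS.

    Rules: length must be divisible by 3; internal stop codons reject the
    record; a single trailing stop codon is accepted and excluded from the
    codon count. Ambiguous bases reject the record when
    ``on_ambiguous="reject"`` (default) or silently drop the affected codons
    when ``on_ambiguous="drop_codon"``.
    """
    if isinstance(record, tuple):
        gene_id, seq = record
    elif isinstance(record, str):
        raise TypeError("pass a (gene_id, sequence) tuple or a SeqRecord")
    else:  # Bio.SeqRecord
        gene_id = str(record.id).split()[0]
        seq = str(record.seq)
    seq = seq.upper().replace("U", "T")

    if len(seq) == 0 or len(seq) % 3 != 0:
        raise CdsValidationError(gene_id, "length_not_multiple_of_3", f"len={len(seq)}")

    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(set(c) - _VALID_BASES for c in codons):
        if on_ambiguous == "reject":
            raise CdsValidationError(gene_id, "ambiguous_base")
        if on_ambiguous != "drop_codon":
            raise ValueError(f"unknown ambiguity policy {on_ambiguous!r}")
        codons = [c for c in codons if not set(c) - _VALID_BASES]

    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if any(c in STOP_CODONS for c in codons):
        raise CdsValidationError(gene_id, "internal_stop")
    if not codons:
        raise CdsValidationError(gene_id, "no_sense_codons")

    return CodingSequence(gene_id=gene_id, sequence="".join(codons), n_codons=len(codons))


def read_cds_fasta(
    path, on_ambiguous: str = "reject"
) -> tuple[list[CodingSequence], list[tuple[str, str]]]:
    """Read a CDS FASTA; returns (accepted records, [(gene_id, reason), ...]).

    Identifiers are the first whitespace-delimited token of the header.
    Rejections are logged, not raised.
    """
    from Bio import SeqIO

    accepted: list[CodingSequence] = []
    rejected: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            accepted.append(parse_cds(rec, on_ambiguous=on_ambiguous))
        except CdsValidationError as e:
            logger.warning("rejected CDS %s: %s", e.gene_id, e.reason)
            rejected.append((e.gene_id, e.reason))
    return accepted, rejected


def write_cds_fasta(cds_list: Sequence[CodingSequence], path, append_stop: bool = True) -> None:
    """Write coding sequences as FASTA (with a trailing TAA stop by default)."""
    with open(path, "w") as fh:
        for cds in cds_list:
            fh.write(f">{cds.gene_id}\n")
            seq = cds.sequence + ("TAA" if append_stop else "")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def count_codons(cds: CodingSequence) -> CodonUsageProfile:
    """Count the 61 sense codons of a validated CDS (stops never counted)."""
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for codon in cds.codons():
        counts[_SENSE_INDEX[codon]] += 1
    return CodonUsageProfile(
        gene_id=cds.gene_id,
        n_codons=cds.n_codons,
        raw_counts=pd.Series(counts, index=list(SENSE_CODONS)),
    )


def relative_frequencies(profile: CodonUsageProfile) -> CodonUsageProfile:
    """Fill length-normalized frequencies: count_c / (sense codons in CDS)."""
    rel = profile.raw_counts / profile.n_codons
    return CodonUsageProfile(
        gene_id=profile.gene_id,
        n_codons=profile.n_codons,
        raw_counts=profile.raw_counts,
        rel_freq=rel,
        aa_norm_freq=profile.aa_norm_freq,
    )


def aa_normalized_frequencies(profile: CodonUsageProfile) -> pd.Series:
    """Within-amino-acid normalized frequencies as a 59-entry Series.

    For each synonymous family with >= 2 codons that is present in the CDS,
    entries are count_c / (family total); families absent from the CDS give
    all-zero blocks so every gene maps to a vector of identical
    dimensionality. Met, Trp and stops are excluded.
    """
    counts = profile.raw_counts
    out = pd.Series(0.0, index=list(AA_NORM_CODONS))
    for codons in MULTI_CODON_FAMILIES.values():
        fam = counts[list(codons)]
        total = int(fam.sum())
        if total > 0:
            out[list(codons)] = fam / total
    return out


def usage_profile(cds: CodingSequence) -> CodonUsageProfile:
    """Convenience: raw counts + relative + family-normalized frequencies."""
    prof = relative_frequencies(count_codons(cds))
    return CodonUsageProfile(
        gene_id=prof.gene_id,
        n_codons=prof.n_codons,
        raw_counts=prof.raw_counts,
        rel_freq=prof.rel_freq,
        aa_norm_freq=aa_normalized_frequencies(prof),
    )


def count_matrix(cds_list: Iterable[CodingSequence]) -> pd.DataFrame:
    """Genes x 61 raw codon count matrix."""
    cds_list = list(cds_list)
    mat = np.zeros((len(cds_list), len(SENSE_CODONS)), dtype=np.int64)
    ids = []
    for g, cds in enumerate(cds_list):
        ids.append(cds.gene_id)
        s = cds.sequence
        for i in range(0, len(s), 3):
            mat[g, _SENSE_INDEX[s[i : i + 3]]] += 1
    return pd.DataFrame(mat, index=ids, columns=list(SENSE_CODONS))


def rel_freq_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Genes x 61 relative-frequency matrix from a raw count matrix."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("gene(s) with zero sense codons")
    return counts.div(totals, axis=0)


def aa_norm_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Genes x 59 within-family normalized matrix from a raw count matrix."""
    out = pd.DataFrame(0.0, index=counts.index, columns=list(AA_NORM_CODONS))
    for codons in MULTI_CODON_FAMILIES.values():
        cols = list(codons)
        fam = counts[cols].to_numpy(dtype=float)
        totals = fam.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(totals > 0, fam / totals, 0.0)
        out[cols] = norm
    return out


def usage_table(cds_list: Sequence[CodingSequence]) -> pd.DataFrame:
    """One row per gene: 61 raw counts, 61 relative freqs, 59 normalized entries."""
    counts = count_matrix(cds_list)
    rel = rel_freq_matrix(counts)
    norm = aa_norm_matrix(counts)
    counts = counts.add_prefix("count_")
    rel = rel.add_prefix("freq_")
    norm = norm.add_prefix("aanorm_")
    out = pd.concat([counts, rel, norm], axis=1)
    out.index.name = "gene_id"
    return out
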