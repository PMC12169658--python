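"""Sequence ingestion and sequence-level statistics.

Protein sequences are restricted to the 20 canonical one-letter codes and DNA
sequences to A/C/G/T.  The statistics implemented here are the ones commonly
used to rationalize the phase behavior of disordered proteins: the integer net
charge q = (#Arg + #Lys) - (#Asp + #Glu), a six-way composition breakdown
(positive, negative, aromatic, aliphatic, polar, other), and CpG-site counting
for DNA oligos.  Histidine is treated as neutral and grouped with the
aromatics; termini are ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = frozenset("ACGT")

#: Composition categories (one-letter codes), used by composition_fractions.
CATEGORIES = {
    "positive": frozenset("RK"),
    "negative": frozenset("DE"),
    "aromatic": frozenset("HFYW"),
    "aliphatic": frozenset("AILMV"),
    "polar": frozenset("NQST"),
    "other": frozenset("CGP"),
}

_POSITIVE = frozenset("RK")
_NEGATIVE = frozenset("DE")


class FastaParseError(ValueError):
    """Malformed FASTA input (bad header, empty record...)."""


class AlphabetError(ValueError):
    """A letter outside the declared alphabet, with its 1-based position."""


class SequenceKindError(TypeError):
    """Operation applied to the wrong kind of sequence (protein vs dna)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named protein or DNA sequence.

    Parameters
    ----------
    id : str
        Record label (first whitespace-delimited token of the FASTA header).
    kind : {"protein", "dna"}
    letters : str
        Upper-case residue / nucleotide codes.
    description : str
        Remainder of the FASTA header, retained but unused.
    """

    id: str
    kind: str
    letters: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("protein", "dna"):
            raise ValueError(f"kind must be 'protein' or 'dna', got {self.kind!r}")
        if not self.letters:
            raise ValueError(f"record {self.id!r}: empty sequence")
        alphabet = PROTEIN_ALPHABET if self.kind == "protein" else DNA_ALPHABET
        for pos, letter in enumerate(self.letters, start=1):
            if letter not in alphabet:
                raise AlphabetError(
                    f"record {self.id!r}: illegal {self.kind} letter "
                    f"{letter!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.letters)


@dataclass(frozen=True)
class CompositionBreakdown:
    """Counts and fractions of residues per composition category."""

    counts: dict
    fractions: dict
    length: int

    @property
    def charged_percent(self) -> float:
        """100 x (positive + negative fractions)."""
        return 100.0 * (self.fractions["positive"] + self.fractions["negative"])


def _require_kind(seq: SequenceRecord, kind: str) -> None:
    if seq.kind != kind:
        raise SequenceKindError(
            f"record {seq.id!r}: expected a {kind} sequence, got {seq.kind}"
        )


def read_fasta(source, kind: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file (path or text stream) into SequenceRecord objects.

    Letters are upper-cased before validation; blank lines and trailing
    whitespace are ignored.  A record whose sequence contains a letter outside
    the alphabet of *kind* raises :class:`AlphabetError` naming the position.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_fasta(fh, kind=kind)

    text = source.read()
    # Light structural validation first: Bio.SeqIO silently returns nothing
    # for some malformed inputs, so locate the offending line ourselves.
    lines = text.splitlines()
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(">"):
            if len(stripped) == 1:
                raise FastaParseError(f"line {lineno}: empty FASTA header")
            seen_header = True
        elif not seen_header:
            raise FastaParseError(
                f"line {lineno}: sequence data before any '>' header"
            )
    if not seen_header:
        raise FastaParseError("no FASTA records found")

    records = []
    for bio_rec in SeqIO.parse(io.StringIO(text), "fasta"):
        letters = str(bio_rec.seq).strip().upper()
        description = bio_rec.description
        if description.startswith(bio_rec.id):
            description = description[len(bio_rec.id):].strip()
        records.append(
            SequenceRecord(
                id=bio_rec.id, kind=kind, letters=letters, description=description
            )
        )
    if not records:
        raise FastaParseError("no FASTA records found")
    return records


def write_fasta(records, target) -> None:
    """Write SequenceRecord objects as FASTA (path or text stream).

    Record ids must be unique.
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids on FASTA write")
    if isinstance(target, (str, Path)):
        with open(target, "w") as fh:
            write_fasta(records, fh)
        return
    bio = [
        _BioRecord(Seq(r.letters), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, target, "fasta")


def net_charge(seq: SequenceRecord) -> int:
    """Integer net charge q = (#Arg + #Lys) - (#Asp + #Glu), in units of e.

    Histidine and the termini are treated as neutral; Cys/Ser carry no charge,
    so the Cys->Ser sanitation leaves q unchanged.
    """
    _require_kind(seq, "protein")
    pos = sum(1 for aa in seq.letters if aa in _POSITIVE)
    neg = sum(1 for aa in seq.letters if aa in _NEGATIVE)
    return pos - neg


def composition_fractions(seq: SequenceRecord) -> CompositionBreakdown:
    """Six-way composition breakdown of a protein sequence.

    Categories: positive (R,K), negative (D,E), aromatic (H,F,Y,W),
    aliphatic (A,I,L,M,V), polar (N,Q,S,T), other (C,G,P).
    """
    _require_kind(seq, "protein")
    n = len(seq)
    counts = {name: 0 for name in CATEGORIES}
    for aa in seq.letters:
        for name, members in CATEGORIES.items():
            if aa in members:
                counts[name] += 1
                break
    fractions = {name: counts[name] / n for name in CATEGORIES}
    return CompositionBreakdown(counts=counts, fractions=fractions, length=n)


def count_cpg(seq: SequenceRecord) -> int:
    """Number of CpG sites (CG dinucleotides) on the sense strand."""
    _require_kind(seq, "dna")
    return seq.letters.count("CG")


def sanitize_cysteines(seq: SequenceRecord) -> SequenceRecord:
    """Return a copy with every Cys replaced by Ser.

    Mirrors the common expression-construct mutation used to avoid non-native
    disulfides; length, all non-Cys positions and the net charge are unchanged.
    """
    _require_kind(seq, "protein")
    return SequenceRecord(
        id=seq.id,
        kind="protein",
        letters=seq.letters.replace("C", "S"),
        description=seq.description,
    )


def reverse_complement(seq: SequenceRecord) -> SequenceRecord:
    """Reverse complement of a DNA sequence."""
    _require_kind(seq, "dna")
    return SequenceRecord(
        id=seq.id + "_rc",
        kind="dna",
        letters=str(Seq(seq.letters).reverse_complement()),
        description=seq.description,
    )
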