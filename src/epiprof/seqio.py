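"""Sequence I/O: FASTA reading/writing, protein validation, CDS translation.

Coordinates everywhere in this package are 1-based and inclusive, matching
the convention of epitope tables and topology files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("epiprof")

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_AA_SET = frozenset(STANDARD_AA)
_NT_SET = frozenset("ACGT")


class AlphabetError(ValueError):
    """Raised when a sequence contains letters outside the expected alphabet."""


class FastaFormatError(ValueError):
    """Raised when a file is not parseable as FASTA."""


@dataclass(frozen=True)
class NucleotideRecord:
    """A DNA/mRNA sequence; U is normalized to T, case to upper."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError("empty nucleotide sequence")
        bad = sorted(set(seq) - _NT_SET)
        if bad:
            raise AlphabetError(
                f"nucleotide record {self.id!r} contains non-ACGTU letters: {bad}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteinRecord:
    """A validated protein sequence over the 20 standard one-letter residues.

    ``masked_positions`` lists 1-based positions that were excluded under the
    ``mask`` validation policy; scoring stages skip them.
    """

    id: str
    description: str
    sequence: str
    masked_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = sorted(set(self.sequence) - _STANDARD_AA_SET)
        if bad:
            raise AlphabetError(
                f"protein record {self.id!r} contains non-standard residues: {bad}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a FASTA file into a list of raw ``(id, description, sequence)``.

    The description excludes the id. Order is preserved; sequences are
    whitespace-stripped but not validated (see :func:`validate_protein`).
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise FastaFormatError(f"{path}: no records (empty file)")
        if not first.startswith(">"):
            raise FastaFormatError(
                f"{path}: sequence data before any '>' header"
            )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append((rec.id, desc, str(rec.seq).strip()))
    if not records:
        raise FastaFormatError(f"{path}: no records")
    return records


def write_fasta(
    records: Iterable[NucleotideRecord | ProteinRecord | tuple[str, str, str]],
    path: str | Path,
    wrap: int = 60,
) -> None:
    """Write records as multi-record FASTA, wrapped at ``wrap`` columns."""
    out = []
    for rec in records:
        if isinstance(rec, tuple):
            rid, desc, seq = rec
        else:
            rid, desc, seq = rec.id, rec.description, rec.sequence
        out.append(SeqRecord(Seq(seq), id=rid, description=desc))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(out)


def validate_protein(
    seq: str,
    policy: Literal["reject", "mask"] = "reject",
    id: str = "protein",
    description: str = "",
) -> ProteinRecord:
    """Uppercase and validate a protein sequence.

    Under ``reject`` (default), any letter outside the 20 standard residues
    raises :class:`AlphabetError` naming its 1-based position — every
    downstream scale lookup is undefined for such letters. Under ``mask``,
    offending letters are removed and their original positions recorded in
    ``masked_positions``.
    """
    if not seq or not seq.strip():
        raise ValueError("empty protein sequence")
    seq = seq.strip().upper()
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in _STANDARD_AA_SET]
    if not bad:
        return ProteinRecord(id, description, seq)
    if policy == "reject":
        pos, letter = bad[0]
        raise AlphabetError(
            f"non-standard residue {letter!r} at position {pos} "
            f"({len(bad)} offending letter(s) total); use policy='mask' to skip"
        )
    if policy != "mask":
        raise ValueError(f"unknown policy {policy!r}")
    masked = tuple(p for p, _ in bad)
    kept = "".join(c for c in seq if c in _STANDARD_AA_SET)
    if not kept:
        raise ValueError("all residues non-standard; nothing left after masking")
    return ProteinRecord(id, description, kept, masked_positions=masked)


def translate_cds(
    nt: NucleotideRecord, table: int | str = 1
) -> ProteinRecord:
    """Translate a coding sequence from frame 0 of ``nt``.

    Codons are mapped by the chosen NCBI genetic-code table (1 = standard).
    Translation stops at, and excludes, the first stop codon; a trailing
    partial codon is ignored with a logged warning. No ORF scanning is done:
    the input is assumed to be the CDS itself.
    """
    seq = nt.sequence
    if len(seq) < 3:
        raise ValueError(f"CDS {nt.id!r} shorter than one codon ({len(seq)} nt)")
    if len(seq) % 3:
        logger.warning(
            "CDS %s: trailing partial codon of %d nt ignored", nt.id, len(seq) % 3
        )
        seq = seq[: len(seq) - len(seq) % 3]
    aa = str(Seq(seq).translate(table=table, to_stop=True))
    if not aa:
        raise ValueError(f"CDS {nt.id!r}: zero-length translation (immediate stop)")
    return ProteinRecord(nt.id, nt.description, aa)


def read_protein(
    path: str | Path, policy: Literal["reject", "mask"] = "reject"
) -> list[ProteinRecord]:
    """Read and validate every record of a protein FASTA file."""
    return [
        validate_protein(seq, policy=policy, id=rid, description=desc)
        for rid, desc, seq in read_fasta(path)
    ]


def fetch_accession(accession: str, email: str, db: str = "nucleotide") -> str:
    """Fetch a FASTA record text from NCBI by accession (network access!).

    Convenience only; requires explicit invocation and an email address for
    NCBI etiquette. Never used by the test suite or the analysis pipeline.
    """
    from Bio import Entrez

    Entrez.email = email
    with Entrez.efetch(db=db, id=accession, rettype="fasta", retmode="text") as h:
        return h.read()
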