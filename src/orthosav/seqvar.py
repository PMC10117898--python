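"""Protein sequences and single amino-acid variants (SAVs).

The central bookkeeping problem this module solves is coordinate systems:
secreted proteins such as apolipoprotein E carry an N-terminal signal
peptide that is cleaved off in the mature protein, so the literature refers
to the same substitution under two different residue numbers.  For APOE the
signal peptide is 18 residues, hence the classic APOE4-defining variant is
C112R in mature coordinates and C130R in precursor coordinates.

Internally everything is kept in *precursor* numbering (1-based, first
residue of the signal peptide = 1); mature numbering exists only at I/O
boundaries via :func:`convert_numbering`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Optional

from Bio import SeqIO

from ._errors import (
    ConsistencyError,
    FormatError,
    NumberingError,
    ValidationError,
)

#: The 20 standard amino acids, alphabetical by one-letter code.  This fixed
#: order is also the column order of every L x 20 matrix in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PRECURSOR = "precursor"
MATURE = "mature"

_VARIANT_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

#: Signal-peptide length of the human APOE precursor, in residues.
APOE_SIGNAL_PEPTIDE_LENGTH = 18


@dataclass(frozen=True)
class SAV:
    """A single amino-acid variant, e.g. ``C130R``.

    Attributes
    ----------
    ref_aa, alt_aa:
        Reference and alternate residues, one-letter codes.
    position:
        1-based residue index in the coordinate system given by ``numbering``.
    numbering:
        ``"precursor"`` (includes the signal peptide) or ``"mature"``.
    """

    ref_aa: str
    position: int
    alt_aa: str
    numbering: str = PRECURSOR

    def __post_init__(self) -> None:
        for aa, name in ((self.ref_aa, "ref_aa"), (self.alt_aa, "alt_aa")):
            if aa not in AMINO_ACIDS:
                raise ValidationError(
                    f"{name} {aa!r} is not a standard one-letter amino-acid code"
                )
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"identity substitution {self.ref_aa}{self.position}{self.alt_aa} "
                "is not a variant"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.numbering not in (PRECURSOR, MATURE):
            raise ValidationError(f"unknown numbering {self.numbering!r}")

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @property
    def reverse(self) -> "SAV":
        """The back-substitution (alt -> ref) at the same position."""
        return replace(self, ref_aa=self.alt_aa, alt_aa=self.ref_aa)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence with an optional signal-peptide annotation."""

    id: str
    residues: str
    signal_peptide_length: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = sorted({c for c in self.residues if c not in AMINO_ACIDS})
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-standard residues: {bad}"
            )
        if self.signal_peptide_length < 0:
            raise ValidationError("signal_peptide_length must be non-negative")
        if len(self.residues) <= self.signal_peptide_length:
            raise ValidationError(
                f"sequence length {len(self.residues)} must exceed "
                f"signal peptide length {self.signal_peptide_length}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based precursor position."""
        if not 1 <= position <= len(self):
            raise NumberingError(
                f"position {position} outside sequence of length {len(self)}"
            )
        return self.residues[position - 1]


def read_protein_fasta(
    path: str | Path,
    record_id: Optional[str] = None,
    signal_peptide_length: int = 0,
) -> ProteinSequence:
    """Read one protein record from a FASTA file.

    Returns the first record, or the record whose id matches ``record_id``.
    Residues are upper-cased; non-standard characters raise
    :class:`ValidationError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    if record_id is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise FormatError(f"record {record_id!r} not found in {path}")
        rec = matches[0]
    return ProteinSequence(
        id=rec.id,
        residues=str(rec.seq),
        signal_peptide_length=signal_peptide_length,
    )


def write_protein_fasta(seq: ProteinSequence, path: str | Path, width: int = 60) -> None:
    lines = [f">{seq.id}"]
    for i in range(0, len(seq.residues), width):
        lines.append(seq.residues[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def apoe_precursor() -> ProteinSequence:
    """The packaged human APOE precursor sequence (reference isoform, E3).

    317 residues: an 18-residue signal peptide followed by the 299-residue
    mature protein.  No network access is required.
    """
    ref = resources.files("orthosav.data").joinpath("apoe_precursor.fasta")
    with resources.as_file(ref) as p:
        return read_protein_fasta(p, signal_peptide_length=APOE_SIGNAL_PEPTIDE_LENGTH)


def parse_variant_notation(s: str, numbering: str = PRECURSOR) -> SAV:
    """Parse ``"<REF><POS><ALT>"`` notation, e.g. ``"C130R"``."""
    m = _VARIANT_RE.match(s.strip())
    if m is None:
        raise FormatError(f"cannot parse variant notation {s!r}")
    ref, pos, alt = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return SAV(ref_aa=ref, position=pos, alt_aa=alt, numbering=numbering)


def read_variant_list(path: str | Path, numbering: str = PRECURSOR) -> List[SAV]:
    """Read variants from a file: one notation per line, or tab-delimited
    with a header whose first column is ``variant``."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        return []
    if "\t" in lines[0] or lines[0].lower().startswith("variant"):
        header = lines[0].split("\t")
        if header[0].lower() != "variant":
            raise FormatError(f"expected 'variant' header column in {path}")
        lines = [ln.split("\t")[0] for ln in lines[1:]]
    return [parse_variant_notation(s, numbering) for s in lines]


def convert_numbering(v: SAV, seq: ProteinSequence, target: str) -> SAV:
    """Convert a variant between precursor and mature coordinates.

    mature -> precursor adds ``seq.signal_peptide_length`` to the position;
    the reverse subtracts it.  A conversion that leaves ``[1, L]`` (e.g. a
    signal-peptide variant, which has no mature coordinate) raises
    :class:`NumberingError`.
    """
    if target not in (PRECURSOR, MATURE):
        raise ValidationError(f"unknown target numbering {target!r}")
    if v.numbering == target:
        return v
    offset = seq.signal_peptide_length
    if target == PRECURSOR:
        new_pos = v.position + offset
    else:
        new_pos = v.position - offset
    limit = len(seq) if target == PRECURSOR else len(seq) - offset
    if not 1 <= new_pos <= limit:
        raise NumberingError(
            f"variant {v} has no valid {target} coordinate "
            f"(converted position {new_pos})"
        )
    return replace(v, position=new_pos, numbering=target)


def apply_variant(seq: ProteinSequence, v: SAV) -> ProteinSequence:
    """Return a copy of ``seq`` with the substitution applied.

    ``v`` must be in precursor numbering and its reference residue must match
    the sequence; a mismatch signals the wrong numbering system or the wrong
    sequence and raises :class:`ConsistencyError`.
    """
    if v.numbering != PRECURSOR:
        raise ValidationError(
            f"apply_variant requires precursor numbering, got {v.numbering!r}"
        )
    actual = seq.residue_at(v.position)
    if actual != v.ref_aa:
        raise ConsistencyError(
            f"variant {v}: sequence {seq.id!r} has {actual} at position "
            f"{v.position}, expected {v.ref_aa}"
        )
    residues = seq.residues[: v.position - 1] + v.alt_aa + seq.residues[v.position :]
    return replace(seq, residues=residues)


def enumerate_savs(seq: ProteinSequence) -> List[SAV]:
    """All 19*L possible single substitutions of ``seq``, precursor-numbered.

    For the 317-residue APOE precursor this is the full in-silico mutagenesis
    space of 6,023 variants.
    """
    out: List[SAV] = []
    for pos, ref in enumerate(seq.residues, start=1):
        for alt in AMINO_ACIDS:
            if alt != ref:
                out.append(SAV(ref_aa=ref, position=pos, alt_aa=alt))
    return out
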