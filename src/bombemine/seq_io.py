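"""Sequence records, translation, and six-frame ORF extraction.

Conventions used throughout the package:

* coordinates are 0-based, half-open, stored on the forward strand;
* reading frames are ``+1, +2, +3`` (forward, offset ``frame-1``) and
  ``-1, -2, -3`` (reverse complement, offset ``|frame|-1``);
* translation uses the standard genetic code (NCBI table 1) only.

Open reading frames are maximal stop-to-stop stretches; a Met start is
*not* required, because precursor screens work on translated fragments
whose true start codon may lie upstream of the fragment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

FRAMES = (1, 2, 3, -1, -2, -3)


class FastaParseError(ValueError):
    """Malformed FASTA input (bad header, duplicate id, ...)."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the declared alphabet."""


@dataclass
class SeqRecord:
    """A named sequence over a declared alphabet.

    ``species_tag`` / ``group_tag`` carry optional taxon metadata used by
    the clustering and conservation stages (e.g. ``"Arub"`` /
    ``"echinoderm"``).
    """

    id: str
    residues: str
    description: str = ""
    species_tag: Optional[str] = None
    group_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Orf:
    """An open reading frame located on the forward strand of its parent.

    ``nt_start``/``nt_end`` always refer to forward-strand coordinates;
    for reverse frames the protein is the translation of the reverse
    complement of that interval.
    """

    parent_id: str
    frame: int
    nt_start: int
    nt_end: int
    protein: str

    def __post_init__(self) -> None:
        if (self.nt_end - self.nt_start) % 3 != 0:
            raise ValueError("ORF interval not a multiple of 3")
        if (self.nt_end - self.nt_start) // 3 != len(self.protein):
            raise ValueError("ORF protein length inconsistent with interval")
        if "*" in self.protein:
            raise ValueError("ORF protein contains a stop symbol")


def _check_alphabet(rec_id: str, residues: str, alphabet: str) -> None:
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    bad = set(residues) - allowed
    if bad:
        raise AlphabetError(
            f"record {rec_id!r}: illegal character(s) {sorted(bad)} "
            f"for {alphabet} alphabet"
        )


def read_fasta(path, alphabet: str = "dna") -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects.

    Lowercase is normalized to uppercase; ids must be unique; gap
    characters are rejected (they fail the alphabet check).

    Parameters
    ----------
    path : path-like
    alphabet : ``"dna"`` or ``"protein"``
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    # line-number aware header validation before handing off to Biopython
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1 does not start with '>'")
    for bio in _BioSeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {bio.id!r}")
        seen.add(bio.id)
        residues = str(bio.seq).upper()
        _check_alphabet(bio.id, residues, alphabet)
        records.append(SeqRecord(id=bio.id, residues=residues,
                                 description=bio.description))
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) \
                else f"{rec.id} {rec.description}".strip()
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def revcomp(dna: str) -> str:
    """Reverse complement (N self-complementary)."""
    return str(Seq(dna).reverse_complement())


def translate(dna: str, frame: int = 1) -> str:
    """Translate one reading frame under the standard genetic code.

    Stops render as ``*``; codons containing N render as ``X``; a
    trailing partial codon is dropped. Reverse frames translate the
    reverse complement with the same offset rule.
    """
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame}")
    s = dna.upper()
    if frame < 0:
        s = revcomp(s)
    offset = abs(frame) - 1
    s = s[offset:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    prot = str(Seq(s).translate(table=1))
    # Biopython already yields X for ambiguous codons; normalize just in case
    return re.sub(r"[BJZ]", "X", prot)


def six_frame_orfs(dna: str, min_aa: int = 1, parent_id: str = "seq") -> list[Orf]:
    """Extract maximal stop-to-stop ORFs of length >= ``min_aa`` from all
    six frames, with coordinates mapped back to the forward strand.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    dna = dna.upper()
    n = len(dna)
    orfs: list[Orf] = []
    for frame in FRAMES:
        prot = translate(dna, frame)
        offset = abs(frame) - 1
        # scan stop-to-stop stretches in protein coordinates
        start = 0
        for m in re.finditer(r"\*", prot + "*"):
            stop = m.start()
            if stop - start >= min_aa:
                aa_s, aa_e = start, stop
                if frame > 0:
                    nt_s = offset + 3 * aa_s
                    nt_e = offset + 3 * aa_e
                else:
                    # protein coords are on the revcomp strand
                    nt_e = n - (offset + 3 * aa_s)
                    nt_s = n - (offset + 3 * aa_e)
                orfs.append(Orf(parent_id=parent_id, frame=frame,
                                nt_start=nt_s, nt_end=nt_e,
                                protein=prot[aa_s:aa_e]))
            start = stop + 1
    return orfs


def orf_protein_records(orfs: Iterable[Orf]) -> list[SeqRecord]:
    """Render ORFs as protein records (id = parent|frame|start-end)."""
    return [
        SeqRecord(
            id=f"{o.parent_id}|f{o.frame:+d}|{o.nt_start}-{o.nt_end}",
            residues=o.protein,
        )
        for o in orfs
    ]


def write_orf_table(orfs: Iterable[Orf], path) -> None:
    """ORF table as TSV: parent_id, frame, start, end, length_aa, protein."""
    with open(path, "w") as fh:
        fh.write("parent_id\tframe\tstart\tend\tlength_aa\tprotein\n")
        for o in orfs:
            fh.write(f"{o.parent_id}\t{o.frame:+d}\t{o.nt_start}\t{o.nt_end}"
                     f"\t{len(o.protein)}\t{o.protein}\n")
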