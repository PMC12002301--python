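"""Spliced alignment of cDNA to genomic DNA and intron-phase analysis.

Conserved intron positions and phases are classical evidence of gene
orthology: a phase-1 intron interrupting the neuropeptide-coding region
shared between distantly related genes is unlikely to arise twice.

The spliced aligner is deliberately simple: exact ``anchor_k``-mer
matches between cDNA and genome are chained collinearly by dynamic
programming (maximizing matched cDNA coverage), the genomic gaps
between chained exons become introns, and intron boundaries are shifted
locally (by at most ``anchor_k``) to satisfy the canonical GT...AG rule.

Intron phase is the number of nucleotides of the interrupted codon that
lie 5' of the intron (0, 1, or 2). Introns outside the CDS carry no
phase and are labeled UTR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .seq_io import revcomp, translate


class UnalignableError(ValueError):
    """cDNA could not be spliced-aligned to the genomic sequence."""


@dataclass
class GeneModel:
    """Exon structure of a gene on a genomic sequence.

    ``exons`` are 0-based half-open genomic intervals in ascending
    order; ``cds_offset`` is the CDS start within the spliced
    transcript, ``cds_len`` the CDS length in nt (a multiple of 3).
    """

    genomic_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_offset: int
    cds_len: int

    def __post_init__(self) -> None:
        for (a0, a1), (b0, b1) in zip(self.exons, self.exons[1:]):
            if b0 < a1:
                raise ValueError("exons overlap or are unordered")
        if self.cds_len % 3 != 0:
            raise ValueError("cds_len must be a multiple of 3")

    def spliced(self, genomic: str) -> str:
        return "".join(genomic[a:b] for a, b in self.exons)

    def cds(self, genomic: str) -> str:
        t = self.spliced(genomic)
        return t[self.cds_offset:self.cds_offset + self.cds_len]


@dataclass
class Intron:
    donor_pos: int
    acceptor_pos: int
    length: int
    phase: Optional[int]          # None for UTR introns
    donor_motif: str
    acceptor_motif: str
    cds_nt_before: Optional[int]  # CDS nt upstream of the intron


def _anchors(cdna: str, genomic: str, k: int) -> list[tuple[int, int]]:
    """All (cdna_pos, genomic_pos) exact k-mer matches."""
    index: dict[str, list[int]] = {}
    for g in range(len(genomic) - k + 1):
        index.setdefault(genomic[g:g + k], []).append(g)
    hits = []
    for q in range(len(cdna) - k + 1):
        for g in index.get(cdna[q:q + k], ()):
            hits.append((q, g))
    return hits


def _chain(anchors: list[tuple[int, int]], k: int,
           min_intron: int, max_intron: int) -> list[tuple[int, int]]:
    """Collinear chain maximizing cDNA coverage (O(n^2) DP).

    Consecutive anchors must either sit on the same diagonal (within an
    exon) or be separated by a genomic gap exceeding the cDNA gap by a
    plausible intron length.
    """
    anchors = sorted(anchors)
    n = len(anchors)
    if n == 0:
        return []
    score = [k] * n           # matched cDNA nt (overlap-corrected)
    back = [-1] * n
    for j in range(n):
        qj, gj = anchors[j]
        for i in range(j):
            qi, gi = anchors[i]
            if qj <= qi or gj <= gi:
                continue
            dq, dg = qj - qi, gj - gi
            if dg == dq:
                pass                              # same diagonal
            elif dq >= k and min_intron <= dg - dq <= max_intron:
                pass                              # intron between anchors
            else:
                continue
            gain = min(k, dq)
            if score[i] + gain > score[j]:
                score[j] = score[i] + gain
                back[j] = i
    best = max(range(n), key=lambda j: (score[j], -anchors[j][0]))
    chain = []
    j = best
    while j != -1:
        chain.append(anchors[j])
        j = back[j]
    chain.reverse()
    return chain


def _shift_for_gt_ag(cdna: str, genomic: str, q: int, g_donor: int,
                     g_acceptor: int, k: int) -> Optional[int]:
    """Find a boundary shift s (|s| <= k) making the intron GT...AG.

    ``q`` is the cDNA position of the exon junction; shifting by s moves
    the junction to q+s, extends/shrinks the flanking exons accordingly,
    and requires the moved exon sequence to keep matching the cDNA.
    """
    for s in sorted(range(-k, k + 1), key=abs):
        d, a = g_donor + s, g_acceptor + s
        if d < 0 or a + 1 > len(genomic) or q + s < 0 or q + s > len(cdna):
            continue
        if genomic[d:d + 2] != "GT" or genomic[a - 2:a] != "AG":
            continue
        if s > 0 and genomic[g_donor:g_donor + s] != cdna[q:q + s]:
            continue
        if s < 0 and genomic[a:g_acceptor] != cdna[q + s:q]:
            continue
        return s
    return None


def spliced_align(cdna: str, genomic: str, genomic_id: str = "genomic",
                  anchor_k: int = 12, min_intron: int = 30,
                  max_intron: int = 100_000, require_gt_ag: bool = True,
                  strand: str = "+", cds: Optional[tuple[int, int]] = None,
                  ) -> GeneModel:
    """Align a transcript to genomic DNA, recovering the exon structure.

    Raises :class:`UnalignableError` when no collinear anchor chain
    covers >= 95% of the cDNA or the exon structure is inconsistent.
    ``cds`` optionally stamps (cds_offset, cds_len) onto the model;
    otherwise the model records the full transcript as a single ORF-less
    container (cds_offset=0, cds_len=0).
    """
    cdna, genomic = cdna.upper(), genomic.upper()
    if len(genomic) < len(cdna):
        raise ValueError("genomic sequence shorter than cDNA")
    if strand == "-":
        genomic_work = revcomp(genomic)
    else:
        genomic_work = genomic
    chain = _chain(_anchors(cdna, genomic_work, anchor_k), anchor_k,
                   min_intron, max_intron)
    if not chain:
        raise UnalignableError("no anchor chain found")
    # collapse the chain into exon blocks (same-diagonal runs)
    blocks: list[list[int]] = []  # [q_start, q_end, g_start, g_end]
    for q, g in chain:
        if blocks and g - q == blocks[-1][2] - blocks[-1][0]:
            blocks[-1][1] = q + anchor_k
            blocks[-1][3] = g + anchor_k
        else:
            blocks.append([q, q + anchor_k, g, g + anchor_k])
    # extend the first/last block to the cDNA ends by exact match
    b0 = blocks[0]
    while b0[0] > 0 and b0[2] > 0 and cdna[b0[0] - 1] == genomic_work[b0[2] - 1]:
        b0[0] -= 1
        b0[2] -= 1
    bN = blocks[-1]
    while (bN[1] < len(cdna) and bN[3] < len(genomic_work)
           and cdna[bN[1]] == genomic_work[bN[3]]):
        bN[1] += 1
        bN[3] += 1
    covered = sum(b[1] - b[0] for b in blocks)
    if covered < 0.95 * len(cdna):
        raise UnalignableError(
            f"anchor chain covers only {covered}/{len(cdna)} nt of cDNA")
    if blocks[0][0] != 0 or blocks[-1][1] != len(cdna):
        raise UnalignableError("cDNA termini not alignable")
    # adjacent blocks must abut in cDNA; genomic gap is the intron
    for left, right in zip(blocks, blocks[1:]):
        if left[1] != right[0]:
            raise UnalignableError("gap in cDNA between exon blocks")
        if require_gt_ag:
            s = _shift_for_gt_ag(cdna, genomic_work, left[1],
                                 left[3], right[2], anchor_k)
            if s is None:
                raise UnalignableError("no GT...AG boundary within reach")
            left[1] += s
            left[3] += s
            right[0] += s
            right[2] += s
    exons = [(b[2], b[3]) for b in blocks]
    if strand == "-":
        L = len(genomic)
        exons = [(L - e, L - s) for s, e in reversed(exons)]
    cds_offset, cds_len = cds if cds is not None else (0, 0)
    model = GeneModel(genomic_id=genomic_id, strand=strand, exons=exons,
                      cds_offset=cds_offset, cds_len=cds_len)
    # round-trip check: splicing must reproduce the cDNA
    spliced = model.spliced(genomic) if strand == "+" else \
        revcomp(model.spliced(genomic))
    if spliced != cdna:
        raise UnalignableError("spliced exons do not reproduce the cDNA")
    return model


def intron_phases(model: GeneModel, genomic: str) -> list[Intron]:
    """Annotate every intron of the model with motifs and phase.

    Phase = (CDS nucleotides upstream of the intron) mod 3. Introns
    5' of the CDS start or 3' of the stop are labeled UTR (phase None).
    """
    g = genomic.upper()
    if model.strand == "-":
        g = revcomp(g)
        L = len(genomic)
        exons = [(L - e, L - s) for s, e in reversed(model.exons)]
    else:
        exons = model.exons
    introns: list[Intron] = []
    spliced_pos = 0
    for (a0, a1), (b0, b1) in zip(exons, exons[1:]):
        spliced_pos += a1 - a0
        cds_before = spliced_pos - model.cds_offset
        if model.cds_len and 0 < cds_before < model.cds_len:
            phase: Optional[int] = cds_before % 3
            nt_before: Optional[int] = cds_before
        else:
            phase, nt_before = None, None
        introns.append(Intron(
            donor_pos=a1, acceptor_pos=b0, length=b0 - a1,
            phase=phase, donor_motif=g[a1:a1 + 2],
            acceptor_motif=g[b0 - 2:b0], cds_nt_before=nt_before))
    return introns


def map_introns_to_alignment(models: dict[str, tuple[GeneModel, str]],
                             msa_rows: dict[str, str],
                             ) -> list[dict]:
    """Place each species' CDS introns onto protein-alignment columns.

    ``models`` maps species -> (GeneModel, genomic sequence); ``msa_rows``
    maps species -> gapped protein row. For a phase-1/2 intron the
    assigned column is the one holding the interrupted codon's residue;
    for phase 0 the column of the residue preceding the junction.
    Returns one dict per CDS intron with a ``shared`` flag set where
    >= 2 species carry an intron of equal phase in the same column.
    """
    rows = []
    for species, (model, genomic) in models.items():
        if species not in msa_rows:
            raise ValueError(f"species {species!r} missing from alignment")
        gapped = msa_rows[species]
        degapped = gapped.replace("-", "")
        protein = translate(model.cds(genomic), 1).rstrip("*")
        if protein != degapped:
            raise ValueError(
                f"species {species!r}: translated CDS does not match the "
                f"alignment row")
        # residue index -> alignment column
        cols = [i for i, ch in enumerate(gapped) if ch != "-"]
        for intron in intron_phases(model, genomic):
            if intron.phase is None:
                continue
            codon_idx = intron.cds_nt_before // 3
            if intron.phase == 0:
                col = cols[codon_idx - 1] if codon_idx > 0 else -1
            else:
                col = cols[codon_idx]
            rows.append({"species": species, "column": col,
                         "phase": intron.phase, "length": intron.length,
                         "shared": False})
    seen: dict[tuple[int, int], int] = {}
    for r in rows:
        seen[(r["column"], r["phase"])] = seen.get((r["column"], r["phase"]), 0) + 1
    for r in rows:
        r["shared"] = seen[(r["column"], r["phase"])] >= 2
    return rows


def write_gff3(model: GeneModel, gene_id: str, path, genomic: str) -> None:
    """Write gene/mRNA/exon/CDS features as GFF3 (1-based coordinates)."""
    introns = intron_phases(model, genomic)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        g0 = model.exons[0][0] + 1
        g1 = model.exons[-1][1]
        src = "bombemine"
        fh.write(f"{model.genomic_id}\t{src}\tgene\t{g0}\t{g1}\t.\t"
                 f"{model.strand}\t.\tID={gene_id}\n")
        fh.write(f"{model.genomic_id}\t{src}\tmRNA\t{g0}\t{g1}\t.\t"
                 f"{model.strand}\t.\tID={gene_id}.t1;Parent={gene_id}\n")
        for i, (a, b) in enumerate(model.exons, 1):
            fh.write(f"{model.genomic_id}\t{src}\texon\t{a + 1}\t{b}\t.\t"
                     f"{model.strand}\t.\tID={gene_id}.e{i};"
                     f"Parent={gene_id}.t1\n")
        # CDS features with GFF phase column (= nt to skip to next codon)
        spliced_pos = 0
        cds_seen = 0
        for a, b in model.exons:
            exon_len = b - a
            cds_lo = max(model.cds_offset - spliced_pos, 0)
            cds_hi = min(model.cds_offset + model.cds_len - spliced_pos,
                         exon_len)
            if cds_lo < cds_hi:
                gff_phase = (3 - cds_seen % 3) % 3
                fh.write(f"{model.genomic_id}\t{src}\tCDS\t{a + cds_lo + 1}\t"
                         f"{a + cds_hi}\t.\t{model.strand}\t{gff_phase}\t"
                         f"ID={gene_id}.cds;Parent={gene_id}.t1\n")
                cds_seen += cds_hi - cds_lo
            spliced_pos += exon_len
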