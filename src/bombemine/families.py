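"""Cross-species peptide family detection by shared terminal residues.

Candidate neuropeptide families are recognized by conserved N- or
C-terminal residues among predicted peptides from *distinct* precursor
proteins — e.g. at least 4 identical positions in a 6-residue terminal
window. Pairs passing the threshold are linked and families are the
single-linkage connected components with at least two members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .annotate import MaturePeptide


@dataclass
class ClusterParams:
    terminus: str = "C"            # "N" or "C"
    k: int = 6                     # terminal window length
    m: int = 4                     # min identical positions within the window
    cross_species_only: bool = False

    def __post_init__(self) -> None:
        if self.terminus not in ("N", "C"):
            raise ValueError("terminus must be 'N' or 'C'")
        if not 1 <= self.m <= self.k:
            raise ValueError("require 1 <= m <= k")


@dataclass
class PeptideFamily:
    members: list[MaturePeptide]
    terminus: str
    consensus: str


def terminal_identity(a: str | MaturePeptide, b: str | MaturePeptide,
                      terminus: str = "C", k: int = 6) -> int:
    """Identical positions in the aligned terminal window (no gaps).

    When a peptide is shorter than ``k`` the window shrinks to the
    shorter length.
    """
    sa = a.sequence if isinstance(a, MaturePeptide) else a
    sb = b.sequence if isinstance(b, MaturePeptide) else b
    w = min(k, len(sa), len(sb))
    if w == 0:
        return 0
    if terminus == "C":
        wa, wb = sa[-w:], sb[-w:]
    else:
        wa, wb = sa[:w], sb[:w]
    return sum(x == y for x, y in zip(wa, wb))


def _threshold(m: int, k: int, w: int) -> int:
    """Scale the identity threshold when the window shrank to w < k."""
    return math.ceil(m * w / k) if w < k else m


def _consensus(members: Sequence[MaturePeptide], terminus: str, k: int) -> str:
    w = min([k] + [len(p.sequence) for p in members])
    if w == 0:
        return ""
    windows = [p.sequence[-w:] if terminus == "C" else p.sequence[:w]
               for p in members]
    out = []
    for c in range(w):
        col = [win[c] for win in windows]
        best = max(sorted(set(col)), key=col.count)
        out.append(best if col.count(best) * 2 > len(col) else "x")
    return "".join(out)


def cluster_families(peptides: Sequence[MaturePeptide],
                     params: ClusterParams = ClusterParams(),
                     ) -> list[PeptideFamily]:
    """Single-linkage families of terminally similar peptides.

    Edges require ``terminal_identity >= m`` (scaled for short windows),
    distinct parent precursors, and — when ``cross_species_only`` —
    distinct species tags. Components with >= 2 members are returned,
    largest first, ties broken by consensus string.
    """
    n = len(peptides)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peptides[i], peptides[j]
            if a.parent_id == b.parent_id:
                continue
            if (params.cross_species_only and a.species_tag is not None
                    and a.species_tag == b.species_tag):
                continue
            w = min(params.k, len(a.sequence), len(b.sequence))
            ident = terminal_identity(a, b, params.terminus, params.k)
            if ident >= _threshold(params.m, params.k, w):
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    fams = []
    for idxs in groups.values():
        if len(idxs) < 2:
            continue
        members = [peptides[i] for i in idxs]
        fams.append(PeptideFamily(
            members=members, terminus=params.terminus,
            consensus=_consensus(members, params.terminus, params.k)))
    fams.sort(key=lambda f: (-len(f.members), f.consensus))
    return fams


def write_family_report(families: Sequence[PeptideFamily], path,
                        k: int = 6) -> None:
    """Family report TSV: family_id, member, species, window, consensus."""
    with open(path, "w") as fh:
        fh.write("family_id\tmember_parent\tmember_sequence\tspecies\t"
                 "terminal_window\tconsensus\n")
        for fid, fam in enumerate(families, 1):
            for p in fam.members:
                win = (p.sequence[-k:] if fam.terminus == "C"
                       else p.sequence[:k])
                fh.write(f"fam{fid}\t{p.parent_id}\t{p.sequence}\t"
                         f"{p.species_tag or '.'}\t{win}\t{fam.consensus}\n")
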