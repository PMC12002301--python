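"""Pairwise and progressive multiple alignment with group-aware
conserved-column reporting.

The pairwise engine is Needleman–Wunsch with affine gaps (Gotoh's
three-state recursion) and a deterministic traceback preferring
diagonal > up > left at ties. The progressive aligner orders merges by
a UPGMA guide tree built from pairwise alignment distances and merges
profiles with the same machinery, scoring column pairs by the mean
substitution score over non-gap residue pairs.

``conserved_columns`` implements the cross-taxon conservation rule used
for candidate-ortholog alignments: a column is reported for residue r
when r occurs in at least one group-A row (e.g. echinoderms) and at
least ``min_b`` group-B rows (e.g. chordates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from Bio.Align import substitution_matrices

from .seq_io import SeqRecord

NEG_INF = float("-inf")

MatrixLike = Union[str, dict, tuple]


@dataclass
class Alignment:
    """A (multiple) sequence alignment; degapping row i reproduces input i."""

    rows: list[tuple[str, str]]
    score: float = 0.0
    matrix_name: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        lengths = {len(g) for _, g in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def row(self, rid: str) -> str:
        for i, g in self.rows:
            if i == rid:
                return g
        raise KeyError(rid)

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace("-", "")


def _scorer(matrix: MatrixLike):
    """Build a residue-pair scoring function and a display name.

    ``matrix`` may be a substitution-matrix name (e.g. "BLOSUM62"), a
    dict keyed by residue pairs, or ``("simple", match, mismatch)``.
    Unknown residues (incl. X) score 0 against everything.
    """
    if isinstance(matrix, tuple) and matrix and matrix[0] == "simple":
        _, match, mismatch = matrix

        def score(a: str, b: str) -> float:
            if a == "X" or b == "X":
                return 0.0
            return match if a == b else mismatch

        return score, f"simple({match},{mismatch})"
    if isinstance(matrix, str):
        sub = substitution_matrices.load(matrix)

        def score(a: str, b: str) -> float:
            try:
                return float(sub[a, b])
            except (KeyError, IndexError):
                return 0.0

        return score, matrix
    if isinstance(matrix, dict):
        def score(a: str, b: str) -> float:
            return float(matrix.get((a, b), matrix.get((b, a), 0.0)))

        return score, "custom"
    raise TypeError(f"unsupported matrix specification: {matrix!r}")


def _gotoh(a: Sequence, b: Sequence, colscore, gap_open: float,
           gap_extend: float) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global alignment over abstract columns.

    ``a`` and ``b`` are sequences of columns; ``colscore(i, j)`` scores
    pairing a[i] with b[j]. Returns (score, path) where path entries are
    (di, dj) steps: (1,1) diagonal, (1,0) up (gap in b), (0,1) left.
    """
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a; "up")
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a ("left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = colscore(i - 1, j - 1)
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open,
                          X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open,
                          Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    # traceback, preferring diagonal > up > left at ties
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][i, j])
    best = {"M": M, "X": X, "Y": Y}[state][i, j]
    # deterministic state choice at ties: M > X > Y
    for st in ("M", "X", "Y"):
        if {"M": M, "X": X, "Y": Y}[st][i, j] == best:
            state = st
            break
    path: list[tuple[int, int]] = []
    while i > 0 or j > 0:
        if state == "M":
            s = colscore(i - 1, j - 1)
            prev = M[i, j] - s
            path.append((1, 1))
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], prev):
                    state = st
                    break
        elif state == "X":
            val = X[i, j]
            path.append((1, 0))
            if np.isclose(M[i - 1, j] + gap_open, val):
                state = "M"
            elif np.isclose(X[i - 1, j] + gap_extend, val):
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            val = Y[i, j]
            path.append((0, 1))
            if np.isclose(M[i, j - 1] + gap_open, val):
                state = "M"
            elif np.isclose(Y[i, j - 1] + gap_extend, val):
                state = "Y"
            else:
                state = "X"
            j -= 1
        if i == 0 and j > 0:
            state = "Y"
        elif j == 0 and i > 0:
            state = "X"
    path.reverse()
    return float(best), path


def global_align(a: SeqRecord | str, b: SeqRecord | str,
                 matrix: MatrixLike = "BLOSUM62",
                 gap_open: float = -10.0, gap_extend: float = -1.0,
                 ) -> Alignment:
    """Optimal global (Needleman–Wunsch) alignment under affine gaps.

    A gap of length L costs ``gap_open + (L-1)*gap_extend``; pass
    ``gap_open == gap_extend`` for linear gap costs.
    """
    ra = a if isinstance(a, SeqRecord) else SeqRecord(id="a", residues=a) \
        if a else None
    rb = b if isinstance(b, SeqRecord) else SeqRecord(id="b", residues=b) \
        if b else None
    sa = ra.residues if ra else ""
    sb = rb.residues if rb else ""
    ida = ra.id if ra else "a"
    idb = rb.id if rb else "b"
    score_fn, name = _scorer(matrix)
    best, path = _gotoh(sa, sb, lambda i, j: score_fn(sa[i], sb[j]),
                        gap_open, gap_extend)
    ga, gb = [], []
    i = j = 0
    for di, dj in path:
        ga.append(sa[i] if di else "-")
        gb.append(sb[j] if dj else "-")
        i += di
        j += dj
    return Alignment(rows=[(ida, "".join(ga)), (idb, "".join(gb))],
                     score=best, matrix_name=name,
                     gap_open=gap_open, gap_extend=gap_extend)


def _profile_columns(aln_rows: list[tuple[str, str]]) -> list[str]:
    """Transpose gapped rows into column strings."""
    if not aln_rows:
        return []
    return ["".join(row[c] for _, row in aln_rows)
            for c in range(len(aln_rows[0][1]))]


def _merge_profiles(p1: list[tuple[str, str]], p2: list[tuple[str, str]],
                    score_fn, gap_open: float, gap_extend: float,
                    ) -> list[tuple[str, str]]:
    cols1 = _profile_columns(p1)
    cols2 = _profile_columns(p2)

    def colscore(i: int, j: int) -> float:
        pairs = [(x, y) for x in cols1[i] for y in cols2[j]
                 if x != "-" and y != "-"]
        if not pairs:
            return 0.0
        return sum(score_fn(x, y) for x, y in pairs) / len(pairs)

    _, path = _gotoh(cols1, cols2, colscore, gap_open, gap_extend)
    out1 = ["" for _ in p1]
    out2 = ["" for _ in p2]
    i = j = 0
    for di, dj in path:
        for k in range(len(p1)):
            out1[k] += cols1[i][k] if di else "-"
        for k in range(len(p2)):
            out2[k] += cols2[j][k] if dj else "-"
        i += di
        j += dj
    return ([(rid, g) for (rid, _), g in zip(p1, out1)]
            + [(rid, g) for (rid, _), g in zip(p2, out2)])


def progressive_msa(seqs: Sequence[SeqRecord],
                    matrix: MatrixLike = "BLOSUM62",
                    gap_open: float = -10.0, gap_extend: float = -1.0,
                    ) -> Alignment:
    """Progressive multiple alignment with a UPGMA guide tree.

    Pairwise NW alignment identities define the guide distances
    (d = 1 - identical/alignment length); merges follow average-linkage
    clustering with ties broken by record id order.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs >= 2 sequences")
    seqs = sorted(seqs, key=lambda r: r.id)
    score_fn, name = _scorer(matrix)
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[i], seqs[j], matrix, gap_open, gap_extend)
            g1, g2 = aln.rows[0][1], aln.rows[1][1]
            ident = sum(x == y and x != "-" for x, y in zip(g1, g2))
            d = 1.0 - ident / len(g1)
            dist[i, j] = dist[j, i] = d
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform
    Z = linkage(squareform(dist, checks=False), method="average")
    profiles: dict[int, list[tuple[str, str]]] = {
        i: [(seqs[i].id, seqs[i].residues)] for i in range(n)}
    for k, (ia, ib, _, _) in enumerate(Z):
        merged = _merge_profiles(profiles.pop(int(ia)), profiles.pop(int(ib)),
                                 score_fn, gap_open, gap_extend)
        profiles[n + k] = merged
    rows = list(profiles.values())[0]
    rows.sort(key=lambda r: r[0])
    return Alignment(rows=rows, matrix_name=name,
                     gap_open=gap_open, gap_extend=gap_extend)


def conserved_columns(msa: Alignment, group_a_ids: Sequence[str],
                      group_b_ids: Sequence[str], min_b: int = 3,
                      ) -> list[tuple[int, str]]:
    """Columns where a residue occurs in >=1 group-A row and >= ``min_b``
    group-B rows; reported per (column, residue)."""
    if not group_a_ids or not group_b_ids:
        raise ValueError("both groups must be non-empty")
    if set(group_a_ids) & set(group_b_ids):
        raise ValueError("groups must be disjoint")
    if min_b < 2:
        raise ValueError("min_b must be >= 2")
    rows_a = [msa.row(i) for i in group_a_ids]
    rows_b = [msa.row(i) for i in group_b_ids]
    out = []
    for c in range(msa.length):
        col_a = [r[c] for r in rows_a if r[c] != "-"]
        col_b = [r[c] for r in rows_b if r[c] != "-"]
        for residue in sorted(set(col_a)):
            if col_b.count(residue) >= min_b:
                out.append((c, residue))
    return out
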