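"""Prohormone-processing grammar for neuropeptide precursor annotation.

A secreted neuropeptide precursor (prepropeptide) carries an N-terminal
signal peptide followed by one or more peptide segments bounded by
prohormone-convertase cleavage sites — adjacent basic residue pairs
(KR or RR by default). The basic residues are trimmed by
carboxypeptidase activity, so they belong to neither flanking product.
A product ending in glycine is a substrate for C-terminal amidation
(the Gly is consumed); a product beginning with glutamine may cyclize
to pyroglutamate.

The precursor-likeness score is a transparent additive surrogate for
HMM-based precursor screens: it rewards a predicted signal peptide, an
amidated dibasic-bounded peptide, a motif hit, and a peptide located
immediately after the signal peptide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .seq_io import SeqRecord

DEFAULT_DIBASIC = ("KR", "RR")
ALLOWED_DIBASIC = {"KR", "RR", "KK", "RK"}

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

_SMALL = set("AGSC")  # small residues acceptable at the -1 cleavage position


@dataclass(frozen=True)
class CleavageSite:
    """A convertase cleavage site; cleavage occurs after ``position``."""

    position: int  # 0-based index of the residue after which cleavage occurs
    kind: str      # "dibasic" | "monobasic" | "signal_end"
    basic_pair: str

    def __post_init__(self) -> None:
        if self.kind == "dibasic" and len(self.basic_pair) != 2:
            raise ValueError("dibasic site requires a 2-character basic_pair")


@dataclass
class MaturePeptide:
    """A predicted processed peptide.

    ``sequence`` is post-processing: the amide-donor Gly is removed when
    ``amidated``. ``span`` is the pre-processing interval on the
    precursor (including the Gly when amidated). ``parent_peptide``
    names the full-length peptide this one was truncated from, if any.
    """

    sequence: str
    amidated: bool
    pyroglutamate: bool
    span: tuple[int, int]
    parent_id: str
    species_tag: Optional[str] = None
    parent_peptide: Optional[str] = None

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PrecursorAnnotation:
    record: SeqRecord
    signal: Optional[tuple[int, int]]
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    motif_hits: list[tuple[str, tuple[int, int]]]
    score: float = 0.0


def predict_signal_peptide(protein: str,
                           override: Optional[tuple[int, int]] = None,
                           ) -> Optional[tuple[int, int]]:
    """Heuristic signal-peptide call, returning ``[0, c)`` or ``None``.

    Fires when a basic residue (K/R) occurs in the first 5 positions and
    a window of >= 8 residues with mean Kyte-Doolittle hydropathy >= 2.0
    lies within positions 3-25 (1-based). The cleavage point ``c`` is
    the first position after the hydrophobic window with a small residue
    (A/G/S/C) at ``c-1``, constrained to ``15 <= c <= 35``.

    ``override`` passes through an externally predicted span (e.g. from
    a dedicated signal-peptide predictor) unchanged.
    """
    if override is not None:
        return override
    if len(protein) < 25:
        return None
    if not any(r in "KR" for r in protein[:5]):
        return None
    # hydrophobic window search within 1-based positions 3..25
    region_start, region_end = 2, min(25, len(protein))
    window_end = None
    for w0 in range(region_start, region_end - 8 + 1):
        scores = [KYTE_DOOLITTLE.get(r, 0.0) for r in protein[w0:w0 + 8]]
        if sum(scores) / 8 >= 2.0:
            # extend while hydropathy stays favorable
            w1 = w0 + 8
            while w1 < len(protein) and KYTE_DOOLITTLE.get(protein[w1], 0.0) >= 1.5:
                w1 += 1
            window_end = w1
            break
    if window_end is None:
        return None
    for c in range(max(15, window_end), min(35, len(protein) - 1) + 1):
        if protein[c - 1] in _SMALL:
            return (0, c)
    return None


def find_cleavage_sites(protein: str,
                        dibasic_set: Sequence[str] = DEFAULT_DIBASIC,
                        allow_monobasic: bool = False) -> list[CleavageSite]:
    """Locate convertase cleavage sites.

    Dibasic pairs are matched non-overlapping, leftmost-greedy
    ("KRR" yields the pair at positions 0-1); cleavage is C-terminal to
    the pair. Monobasic sites (a single R not adjacent to another basic
    residue) are reported only when ``allow_monobasic``.
    """
    if not set(dibasic_set) <= ALLOWED_DIBASIC:
        raise ValueError(f"dibasic_set must be a subset of {ALLOWED_DIBASIC}")
    sites: list[CleavageSite] = []
    in_pair = [False] * len(protein)
    i = 0
    while i < len(protein) - 1:
        pair = protein[i:i + 2]
        if pair in dibasic_set:
            sites.append(CleavageSite(position=i + 1, kind="dibasic",
                                      basic_pair=pair))
            in_pair[i] = in_pair[i + 1] = True
            i += 2
        else:
            i += 1
    if allow_monobasic:
        for j, r in enumerate(protein):
            if r != "R" or in_pair[j]:
                continue
            prev_basic = j > 0 and protein[j - 1] in "KR"
            next_basic = j < len(protein) - 1 and protein[j + 1] in "KR"
            if not prev_basic and not next_basic:
                sites.append(CleavageSite(position=j, kind="monobasic",
                                          basic_pair=r))
    sites.sort(key=lambda s: s.position)
    return sites


def _process_segment(protein: str, start: int, end: int, parent_id: str,
                     min_len: int, max_len: int,
                     parent_peptide: Optional[str] = None,
                     species_tag: Optional[str] = None,
                     ) -> Optional[MaturePeptide]:
    seg = protein[start:end]
    if not seg:
        return None
    amidated = seg.endswith("G")
    seq = seg[:-1] if amidated else seg
    if not (min_len <= len(seq) <= max_len):
        return None
    return MaturePeptide(
        sequence=seq,
        amidated=amidated,
        pyroglutamate=seq.startswith("Q"),
        span=(start, end),
        parent_id=parent_id,
        species_tag=species_tag,
        parent_peptide=parent_peptide,
    )


def segment_precursor(protein: str,
                      signal: Optional[tuple[int, int]],
                      sites: Sequence[CleavageSite],
                      ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a precursor into minimal inter-boundary segments.

    Returns ``(segments, cuts)`` where ``cuts`` are the excised
    intervals (signal peptide span; each dibasic pair; each monobasic
    residue) and ``segments`` are the intervals between them, in order.
    Concatenating cuts and segments in coordinate order reconstructs
    the precursor exactly.
    """
    cuts: list[tuple[int, int]] = []
    if signal is not None and signal[1] > 0:
        cuts.append((0, signal[1]))
    for s in sorted(sites, key=lambda s: s.position):
        if s.kind == "dibasic":
            cuts.append((s.position - 1, s.position + 1))
        elif s.kind == "monobasic":
            cuts.append((s.position, s.position + 1))
    cuts.sort()
    segments: list[tuple[int, int]] = []
    prev = 0
    for c0, c1 in cuts + [(len(protein), len(protein))]:
        segments.append((prev, max(prev, c0)))
        prev = max(prev, c1)
    return segments, cuts


def derive_peptides(protein: str,
                    signal: Optional[tuple[int, int]],
                    sites: Sequence[CleavageSite],
                    min_len: int = 4,
                    max_len: int = 40,
                    parent_id: str = "precursor",
                    species_tag: Optional[str] = None,
                    ) -> list[MaturePeptide]:
    """Derive mature peptides from cleavage boundaries.

    Candidate products are the intervals between consecutive
    boundaries (signal end, cleavage sites, termini), with one
    partial-processing refinement: a cleavage site whose upstream
    product would be too short to be a peptide (shorter than
    ``min_len`` after Gly removal) is treated as incompletely
    processed, so the segments on either side merge with the basic
    pair retained. This is how a 14-residue amidated peptide with an
    internal dibasic pair and its C-terminally identical 10-residue
    truncation are both genuine products of one precursor: the merged
    ("full") peptide is reported alongside the C-terminal fragments
    produced when the internal site *is* used, the latter carrying the
    full form in ``parent_peptide``.

    A trailing Gly marks amidation and is removed; a leading Gln sets
    the pyroglutamate flag; the length filter applies after Gly
    removal.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    segments, cuts = segment_precursor(protein, signal, sites)
    n_sig = 1 if (signal is not None and signal[1] > 0) else 0
    peptides: list[MaturePeptide] = []
    j = len(segments) - 1
    while j >= 0:
        end = segments[j][1]
        # extend leftward across sites whose upstream product is too
        # short to stand alone (but never across the signal cut, never
        # into an empty segment, and never into an unsignaled protein
        # N terminus)
        i = j
        while i > 0:
            cut_idx = i - 1
            if cut_idx < n_sig:           # the signal-peptide cut
                break
            left0, left1 = segments[i - 1]
            left_len = left1 - left0
            if left_len == 0:
                break
            if i - 1 == 0 and n_sig == 0:  # protein start segment
                break
            left_seq = protein[left0:left1]
            eff = left_len - 1 if left_seq.endswith("G") else left_len
            if eff >= min_len:
                break
            if end - left0 - 1 > max_len:  # merged product would be too long
                break
            i -= 1
        full = _process_segment(protein, segments[i][0], end, parent_id,
                                min_len, max_len, species_tag=species_tag)
        if full is not None:
            peptides.append(full)
        # C-terminal fragments at each site internal to the full form
        for k in range(i, j):
            frag = _process_segment(
                protein, cuts[k][1], end, parent_id, min_len, max_len,
                parent_peptide=full.sequence if full else None,
                species_tag=species_tag)
            if frag is not None:
                peptides.append(frag)
        j = i - 1
    peptides.sort(key=lambda p: p.span)
    return peptides


def scan_motif(sequence: str, pattern: str, anchor: str = "anywhere",
               amidated: bool = False) -> list[tuple[int, int]]:
    """Scan for a motif pattern with ``x`` wildcards.

    Letters match literally, ``x`` matches any residue. A trailing ``a``
    requires the peptide to be amidated (checked against ``amidated``)
    and anchors the match at the C terminus. ``anchor`` may be
    ``anywhere``, ``C_terminal`` or ``N_terminal``; all (overlapping)
    matches are returned for unanchored scans.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    requires_amide = pattern.endswith("a")
    core = pattern[:-1] if requires_amide else pattern
    if requires_amide:
        if not amidated:
            return []
        anchor = "C_terminal"
    if anchor not in ("anywhere", "C_terminal", "N_terminal"):
        raise ValueError(f"unknown anchor {anchor!r}")
    n, k = len(sequence), len(core)
    if k == 0 or k > n:
        return []
    starts: range
    if anchor == "C_terminal":
        starts = range(n - k, n - k + 1)
    elif anchor == "N_terminal":
        starts = range(0, 1)
    else:
        starts = range(0, n - k + 1)
    hits = []
    for i in starts:
        if all(p == "x" or p == sequence[i + j] for j, p in enumerate(core)):
            hits.append((i, i + k))
    return hits


def score_precursor(annotation: PrecursorAnnotation) -> float:
    """Additive precursor-likeness score.

    ``2·[signal] + 2·[≥1 amidated dibasic-bounded peptide] + 1·[motif hit]
    + 0.5·[peptide starting within 2 residues of the signal end]``.
    """
    score = 0.0
    if annotation.signal is not None:
        score += 2.0
    dibasic_positions = {s.position for s in annotation.sites
                         if s.kind == "dibasic"}
    bounded_cutpoints = set()
    for s in annotation.sites:
        if s.kind == "dibasic":
            bounded_cutpoints.add(s.position - 1)  # segment ending here
            bounded_cutpoints.add(s.position + 1)  # segment starting here
    has_amidated_bounded = any(
        p.amidated and (p.span[0] in bounded_cutpoints
                        or p.span[1] in bounded_cutpoints)
        for p in annotation.peptides
    )
    if has_amidated_bounded:
        score += 2.0
    if annotation.motif_hits:
        score += 1.0
    if annotation.signal is not None:
        sig_end = annotation.signal[1]
        if any(0 <= p.span[0] - sig_end <= 2 for p in annotation.peptides):
            score += 0.5
    return score


def annotate_precursor(record: SeqRecord,
                       dibasic_set: Sequence[str] = DEFAULT_DIBASIC,
                       allow_monobasic: bool = False,
                       min_len: int = 4,
                       max_len: int = 40,
                       motifs: Sequence[str] = ("GPxxG",),
                       signal_override: Optional[tuple[int, int]] = None,
                       ) -> PrecursorAnnotation:
    """Run the full grammar on one protein and score it."""
    protein = record.residues
    signal = (predict_signal_peptide(protein, override=signal_override)
              if len(protein) >= 25 else None)
    sites = find_cleavage_sites(protein, dibasic_set=dibasic_set,
                                allow_monobasic=allow_monobasic)
    peptides = derive_peptides(protein, signal, sites, min_len=min_len,
                               max_len=max_len, parent_id=record.id,
                               species_tag=record.species_tag)
    motif_hits: list[tuple[str, tuple[int, int]]] = []
    for pat in motifs:
        for pep in peptides:
            segment = protein[pep.span[0]:pep.span[1]]
            for span in scan_motif(segment, pat, amidated=pep.amidated):
                motif_hits.append(
                    (pat, (pep.span[0] + span[0], pep.span[0] + span[1])))
    ann = PrecursorAnnotation(record=record, signal=signal, sites=sites,
                              peptides=peptides, motif_hits=motif_hits)
    ann.score = score_precursor(ann)
    return ann
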