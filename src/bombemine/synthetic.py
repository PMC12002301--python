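"""Ground-truth generators for every downstream stage.

The generators emulate the architecture of bombesin-type neuropeptide
precursors and their genes in echinoderms: a ~21-residue N-terminal
signal peptide; dibasic-bounded (KR/RR), C-terminally amidated peptides
carrying a GPxxG-type motif whose final Gly is the amide donor; genes
with a phase-1 intron inside the peptide-coding region, an
echinoderm-specific phase-0 intron, and a phase-0 intron near the 3'
end; luminescence dose-response replicates following a four-parameter
logistic with multiplicative normal noise; and b/y fragment spectra
with uniform noise peaks.

All generators are pure functions of (seed, params): the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seq_io import SeqRecord
from .annotate import find_cleavage_sites
from .genestruct import GeneModel
from .masscalc import ModifiedPeptide, fragment_ions, peptide_mass

# residue pools: no K/R (would create spurious cleavage sites), no G
# (would create spurious amide donors at segment ends)
_LINKER_POOL = "ADENSTHQPY"
_PEPTIDE_POOL = "ADENSTHQPYFVLI"
_HYDROPHOBIC = "ILVF"
# decoy pool: polar/acidic, no basic residues, no strongly hydrophobic run
_DECOY_POOL = "ADENSTHQPYG"

# standard-code codon choice for deterministic reverse translation
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAT", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACA", "V": "GTC", "W": "TGG", "Y": "TAC",
    "*": "TAA",
}


@dataclass
class PlantedTruth:
    """What a generator planted, for closed-loop validation."""

    precursor_protein: str
    signal_span: tuple[int, int]
    peptides: list[tuple[str, bool, bool, tuple[int, int]]]
    gene: Optional[GeneModel] = None
    seed: int = 0


def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(rng.choice(list(pool), size=n))


def make_precursor(seed: int, signal_len: int = 21, n_peptides: int = 1,
                   motif: str = "RIFGPxxG", decoy: bool = False,
                   peptide_len: int = 15,
                   ) -> tuple[SeqRecord, PlantedTruth]:
    """Generate one precursor (or decoy) protein with known truth.

    A non-decoy protein is laid out as::

        M K <hydrophobic core> A | KR <peptide+G> KR | linker | ... | tail

    where each planted peptide segment ends in the instantiated motif
    whose final residue is the amide-donor Gly. Decoys contain neither a
    signal-peptide-like N terminus nor any dibasic-bounded G-terminated
    segment.
    """
    rng = np.random.default_rng(seed)
    if decoy:
        length = int(rng.integers(80, 120))
        residues = list(_draw(rng, _DECOY_POOL, length))
        # sprinkle isolated arginines (never adjacent to another basic)
        for pos in rng.choice(np.arange(5, length - 2), size=2, replace=False):
            if residues[pos - 1] not in "KR" and residues[pos + 1] not in "KR":
                residues[pos] = "R"
        protein = "".join(residues)
        if protein.endswith("G"):
            protein = protein[:-1] + "S"
        rec = SeqRecord(id=f"decoy_{seed}", residues=protein)
        return rec, PlantedTruth(precursor_protein=protein,
                                 signal_span=(0, 0), peptides=[], seed=seed)
    if signal_len < 10:
        raise ValueError("signal_len must be >= 10")
    core_motif = motif if motif.endswith("G") else motif + "G"
    if len(core_motif) > peptide_len:
        raise ValueError("motif longer than the requested peptide")
    flank = lambda: "KR" if rng.random() < 0.5 else "RR"
    signal = ("M" + "K"
              + _draw(rng, _HYDROPHOBIC, signal_len - 3) + "A")
    parts = [signal]
    truth_peps = []
    pos = len(signal)
    for i in range(n_peptides):
        left = flank()
        prefix_len = peptide_len - len(core_motif)
        prefix = _draw(rng, _PEPTIDE_POOL, prefix_len)
        inst = "".join(rng.choice(list(_PEPTIDE_POOL)) if ch == "x" else ch
                       for ch in core_motif)
        segment = prefix + inst          # ends with the amide-donor G
        right = flank()
        parts.append(left + segment + right)
        seg_start = pos + len(left)
        truth_peps.append((segment[:-1], True, segment.startswith("Q"),
                           (seg_start, seg_start + len(segment))))
        pos += len(left) + len(segment) + len(right)
        if i < n_peptides - 1:
            linker = _draw(rng, _LINKER_POOL, int(rng.integers(5, 12)))
            parts.append(linker)
            pos += len(linker)
    tail = _draw(rng, _LINKER_POOL, int(rng.integers(8, 16)))
    parts.append(tail)
    protein = "".join(parts)
    rec = SeqRecord(id=f"planted_{seed}", residues=protein)
    truth = PlantedTruth(precursor_protein=protein,
                         signal_span=(0, signal_len),
                         peptides=truth_peps, seed=seed)
    # closed loop: planted peptides must be bounded by dibasic pairs
    sites = {s.position for s in find_cleavage_sites(protein)}
    for _, _, _, (s0, s1) in truth_peps:
        assert s0 - 1 in sites and s1 + 1 in sites, "planted flank violated"
    return rec, truth


def make_proteome(seed: int, n_planted: int = 10, n_decoys: int = 500,
                  **kwargs) -> tuple[list[SeqRecord], list[PlantedTruth]]:
    """A synthetic proteome of planted precursors plus decoys.

    Sub-seeds are derived deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=n_planted + n_decoys)
    records, truths = [], []
    for i in range(n_planted):
        rec, tr = make_precursor(int(subseeds[i]), decoy=False, **kwargs)
        rec.id = f"planted_{seed}_{i}"
        rec.species_tag = f"sp{i % 3}"
        records.append(rec)
        truths.append(tr)
    for j in range(n_decoys):
        rec, _ = make_precursor(int(subseeds[n_planted + j]), decoy=True)
        rec.id = f"decoy_{seed}_{j}"
        rec.species_tag = f"sp{j % 3}"
        records.append(rec)
    return records, truths


def reverse_translate(protein: str, stop: bool = True) -> str:
    """Deterministic reverse translation under the fixed codon table."""
    cds = "".join(_CODON[a] for a in protein)
    return cds + (_CODON["*"] if stop else "")


def make_gene(precursor_cds: str,
              intron_spec: Sequence[tuple[int, int, int]],
              seed: int, utr5: int = 40, utr3: int = 40,
              ) -> tuple[SeqRecord, GeneModel, str]:
    """Insert GT...AG introns into a CDS at specified positions/phases.

    ``intron_spec`` is a list of (cds_nt_position, phase, length) with
    strictly increasing positions inside the CDS; the requested phase
    must equal ``cds_nt_position mod 3``. Returns the genomic record,
    the true :class:`GeneModel`, and the cDNA (UTRs + CDS).
    """
    rng = np.random.default_rng(seed)
    n = len(precursor_cds)
    prev = 0
    for pos, phase, length in intron_spec:
        if not (0 < pos < n):
            raise ValueError(f"intron position {pos} outside CDS")
        if pos <= prev:
            raise ValueError("intron positions must be strictly increasing")
        if pos % 3 != phase:
            raise ValueError(
                f"requested phase {phase} inconsistent with position {pos}")
        if length < 6:
            raise ValueError("intron length must be >= 6")
        prev = pos
    five = _draw(rng, "ACGT", utr5)
    three = _draw(rng, "ACGT", utr3)
    cdna = five + precursor_cds + three
    pieces = []
    exons = []
    gpos = 0
    prev_cut = 0
    cuts = [utr5 + pos for pos, _, _ in intron_spec] + [len(cdna)]
    for (cut, spec) in zip(cuts, list(intron_spec) + [None]):
        exon_seq = cdna[prev_cut:cut]
        pieces.append(exon_seq)
        exons.append((gpos, gpos + len(exon_seq)))
        gpos += len(exon_seq)
        if spec is not None:
            _, _, length = spec
            intron = "GT" + _draw(rng, "ACGT", length - 4) + "AG"
            pieces.append(intron)
            gpos += length
        prev_cut = cut
    genomic = "".join(pieces)
    rec = SeqRecord(id=f"gene_{seed}", residues=genomic)
    model = GeneModel(genomic_id=rec.id, strand="+", exons=exons,
                      cds_offset=utr5, cds_len=n)
    return rec, model, cdna


def make_dose_response(log_ec50: float, hill: float = 1.0,
                       bottom: float = 0.0, top: float = 100.0,
                       concentrations: Optional[Sequence[float]] = None,
                       n_reps: int = 4, cv: float = 0.05, seed: int = 0,
                       ) -> pd.DataFrame:
    """Simulate 4PL luminescence replicates with multiplicative noise.

    response = 4PL(conc) * (1 + eps), eps ~ Normal(0, cv). Returns a
    tidy table with columns experiment, concentration_M, response.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if concentrations is None:
        concentrations = [10.0 ** e for e in range(-13, -5)]
    conc = np.asarray(sorted(concentrations), dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        mean = bottom + (top - bottom) / (
            1 + 10 ** (hill * (log_ec50 - np.log10(conc))))
        eps = rng.normal(0.0, cv, size=conc.size) if cv > 0 else 0.0
        resp = mean * (1 + eps)
        for c, r in zip(conc, resp):
            rows.append({"experiment": f"exp{rep + 1}",
                         "concentration_M": c, "response": r})
    return pd.DataFrame(rows)


def make_spectrum(peptide: ModifiedPeptide, n_noise_peaks: int = 0,
                  seed: int = 0, noise_mz_lo: float = 100.0,
                  ) -> pd.DataFrame:
    """Theoretical singly-charged b/y peak list plus uniform noise peaks."""
    rng = np.random.default_rng(seed)
    rows = []
    for series, idx, z, mz in fragment_ions(peptide, ("b", "y"), 1):
        rows.append({"mz": mz,
                     "intensity": float(rng.uniform(50, 100))})
    hi = peptide_mass(peptide) + 20.0
    for _ in range(n_noise_peaks):
        rows.append({"mz": float(rng.uniform(noise_mz_lo, hi)),
                     "intensity": float(rng.uniform(1, 30))})
    df = pd.DataFrame(rows).sort_values("mz", ignore_index=True)
    return df
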