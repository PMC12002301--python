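"""Peptide mass and b/y fragment-ion prediction with neuropeptide PTMs.

Neuropeptide confirmation by MS hinges on two modifications: C-terminal
amidation (replacing the C-terminal -OH with -NH2, monoisotopic delta
-0.98402 Da relative to the free acid) and N-terminal pyroglutamate
(cyclization of Gln with loss of NH3, -17.02655 Da).

All masses derive from the single constants table below so that tests
can check them against an independent elemental-composition oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

# monoisotopic residue masses (Da), standard 20 amino acids
MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVG_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.010565
WATER_AVG = 18.0153
PROTON = 1.007276
AMIDE_DELTA_MONO = -0.98402      # -OH -> -NH2
PGLU_DELTA_MONO = -17.02655      # Gln -> pyroGlu (NH3 loss)
AMIDE_DELTA_AVG = -0.9847
PGLU_DELTA_AVG = -17.0305


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with optional terminal modifications."""

    sequence: str
    c_term: str = "free_acid"      # "free_acid" | "amide"
    n_term: str = "free"           # "free" | "pyroglutamate"
    fixed_mods: tuple = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if self.n_term == "pyroglutamate" and not self.sequence.startswith("Q"):
            raise ValueError("pyroglutamate requires an N-terminal Q")
        if self.c_term not in ("free_acid", "amide"):
            raise ValueError(f"unknown c_term {self.c_term!r}")
        if self.n_term not in ("free", "pyroglutamate"):
            raise ValueError(f"unknown n_term {self.n_term!r}")


@dataclass
class SpectrumMatch:
    """Result of matching a peak list against a peptide's b/y ions."""

    matched_ions: list  # (series, index, charge, theo_mz, obs_mz, ppm_error)
    coverage: float     # fraction of inter-residue bonds with >=1 supporting ion


def _residue_sum(sequence: str, table: dict) -> float:
    try:
        return sum(table[r] for r in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def _term_deltas(p: ModifiedPeptide, kind: str) -> tuple[float, float]:
    if kind == "mono":
        c = AMIDE_DELTA_MONO if p.c_term == "amide" else 0.0
        n = PGLU_DELTA_MONO if p.n_term == "pyroglutamate" else 0.0
    else:
        c = AMIDE_DELTA_AVG if p.c_term == "amide" else 0.0
        n = PGLU_DELTA_AVG if p.n_term == "pyroglutamate" else 0.0
    return n, c


def peptide_mass(p: ModifiedPeptide, kind: str = "mono") -> float:
    """Neutral peptide mass in Da (monoisotopic or average)."""
    if kind not in ("mono", "average"):
        raise ValueError(f"kind must be 'mono' or 'average', got {kind!r}")
    table = MONO_RESIDUE if kind == "mono" else AVG_RESIDUE
    water = WATER_MONO if kind == "mono" else WATER_AVG
    n_delta, c_delta = _term_deltas(p, kind)
    return _residue_sum(p.sequence, table) + water + n_delta + c_delta


def fragment_ions(p: ModifiedPeptide, series: Sequence[str] = ("b", "y"),
                  max_charge: int = 1) -> list[tuple[str, int, int, float]]:
    """Singly-to-``max_charge`` b/y fragment ions as (series, index, z, m/z).

    Neutral b_i is the sum of the first i residues (plus the N-terminal
    modification); neutral y_j is the sum of the last j residues plus
    water (plus the C-terminal modification). m/z = (neutral + z*proton)/z.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    bad = set(series) - {"b", "y"}
    if bad:
        raise ValueError(f"unsupported ion series {sorted(bad)}")
    seq = p.sequence
    n = len(seq)
    n_delta, c_delta = _term_deltas(p, "mono")
    ions = []
    for i in range(1, n):  # fragments exclude the intact peptide
        if "b" in series:
            neutral = _residue_sum(seq[:i], MONO_RESIDUE) + n_delta
            for z in range(1, max_charge + 1):
                ions.append(("b", i, z, (neutral + z * PROTON) / z))
        if "y" in series:
            neutral = (_residue_sum(seq[n - i:], MONO_RESIDUE)
                       + WATER_MONO + c_delta)
            for z in range(1, max_charge + 1):
                ions.append(("y", i, z, (neutral + z * PROTON) / z))
    return ions


def match_spectrum(peaks: Iterable[tuple[float, float]], p: ModifiedPeptide,
                   tol_ppm: float = 10.0, max_charge: int = 1,
                   ) -> SpectrumMatch:
    """Match observed peaks to theoretical b/y ions within ``tol_ppm``.

    Greedy nearest-peak assignment; each observed peak is used at most
    once. Coverage is the fraction of the ``len-1`` inter-residue bonds
    supported by at least one matched b or y ion.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    peak_list = sorted((float(mz), float(inten)) for mz, inten in peaks)
    n = len(p.sequence)
    theo = fragment_ions(p, ("b", "y"), max_charge)
    used = [False] * len(peak_list)
    matched = []
    supported_bonds: set[int] = set()
    import bisect
    mzs = [mz for mz, _ in peak_list]
    for series, idx, z, tmz in theo:
        tol = tmz * tol_ppm * 1e-6
        lo = bisect.bisect_left(mzs, tmz - tol)
        hi = bisect.bisect_right(mzs, tmz + tol)
        best, best_err = None, None
        for k in range(lo, hi):
            if used[k]:
                continue
            err = abs(mzs[k] - tmz)
            if best is None or err < best_err:
                best, best_err = k, err
        if best is not None:
            used[best] = True
            ppm = (mzs[best] - tmz) / tmz * 1e6
            matched.append((series, idx, z, tmz, mzs[best], ppm))
            # bond b_i / y_i sits after residue i (from the respective end)
            bond = idx if series == "b" else n - idx
            supported_bonds.add(bond)
    coverage = len(supported_bonds) / (n - 1) if n > 1 else 0.0
    return SpectrumMatch(matched_ions=matched, coverage=coverage)
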