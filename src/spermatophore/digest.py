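"""In-silico tryptic digestion and observable-peptide counting.

The emPAI abundance estimate needs, for every protein, the number of
peptides an LC-MS/MS run could in principle have observed
(``N_observable``).  We operationalise "observable" as a fully tryptic
peptide — produced by cleavage C-terminal of lysine (K) or arginine (R)
except when the next residue is proline (P) — carrying at most a
configured number of missed cleavages, whose monoisotopic mass falls
inside the instrument's detectable window.

Peptide masses are monoisotopic, computed from the standard residue
mass table plus one water.  Residues outside the 20-letter standard
alphabet never block a cleavage decision but contribute zero mass (a
warning is emitted), so a sequence containing an ``X`` still digests
deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "DigestParams",
    "digest_trypsin",
    "peptide_mass",
    "count_observable",
]

# Monoisotopic residue masses for the 20 standard amino acids.
RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}
WATER_MONO = _pmass.calculate_mass(formula="H2O")


@dataclass(frozen=True)
class DigestParams:
    """Parameters defining which peptides count as observable.

    Attributes
    ----------
    missed_cleavages:
        Maximum number of internal uncut K/R sites a peptide may carry.
    min_da, max_da:
        Monoisotopic mass window (daltons) the instrument can detect.
    """

    missed_cleavages: int = 0
    min_da: float = 400.0
    max_da: float = 6000.0

    def __post_init__(self) -> None:
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if not self.min_da < self.max_da:
            raise ValueError("mass window requires min_da < max_da")


def _cut_points(sequence: str) -> List[int]:
    """Indices i such that the bond between i-1 and i is cleaved.

    Trypsin cuts after K or R unless the following residue is P.
    """
    cuts = []
    n = len(sequence)
    for i in range(1, n):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            cuts.append(i)
    return cuts


def digest_trypsin(sequence: str, params: DigestParams | None = None) -> List[str]:
    """Digest ``sequence`` with trypsin, returning ordered peptides.

    With ``missed_cleavages == 0`` the returned peptides concatenate to
    the input sequence.  With ``missed_cleavages == m`` the list
    additionally contains every run of up to ``m + 1`` consecutive
    fragments, ordered by start position then length.
    """
    if params is None:
        params = DigestParams()
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    bounds = [0] + _cut_points(sequence) + [len(sequence)]
    fragments = [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    if params.missed_cleavages == 0:
        return fragments
    peptides: List[str] = []
    nfrag = len(fragments)
    for start in range(nfrag):
        for span in range(1, params.missed_cleavages + 2):
            if start + span > nfrag:
                break
            peptides.append("".join(fragments[start : start + span]))
    return peptides


def peptide_mass(peptide: str) -> float:
    """Monoisotopic mass of ``peptide``; non-standard residues weigh 0."""
    total = WATER_MONO
    for aa in peptide:
        m = RESIDUE_MASS.get(aa)
        if m is None:
            warnings.warn(
                f"non-standard residue {aa!r} excluded from mass computation",
                stacklevel=2,
            )
        else:
            total += m
    return total


def count_observable(peptides: Iterable[str], params: DigestParams | None = None) -> int:
    """Number of *distinct* peptides whose mass lies in the window."""
    if params is None:
        params = DigestParams()
    seen = set()
    for pep in peptides:
        if pep in seen:
            continue
        seen.add(pep)
    return sum(1 for pep in seen if params.min_da <= peptide_mass(pep) <= params.max_da)


def observable_peptides(sequence: str, params: DigestParams | None = None) -> List[str]:
    """Distinct digest peptides of ``sequence`` inside the mass window."""
    if params is None:
        params = DigestParams()
    out, seen = [], set()
    for pep in digest_trypsin(sequence, params):
        if pep in seen:
            continue
        seen.add(pep)
        if params.min_da <= peptide_mass(pep) <= params.max_da:
            out.append(pep)
    return out
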