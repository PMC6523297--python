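"""In-silico tryptic digestion and isoform-signature peptide discovery.

A signature peptide is a tryptic fragment that spans an isoform-specific
junction (a bond joining residues that are not adjacent in the canonical
protein) and does not occur anywhere in the canonical protein or its
digest. Such peptides give direct, targeted mass-spectrometric evidence
that a predicted protein isoform is actually translated; the inclusion
list collects their precursor m/z values for the instrument.

Trypsin cleaves C-terminal to K or R except when the next residue is
proline. Monoisotopic masses come from pyteomics; carbamidomethylation of
cysteine (+57.02146 Da) is applied as a fixed modification by default,
matching standard iodoacetamide alkylation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from pyteomics import mass as _pmass

PROTON_MASS = 1.007276
WATER_MASS = 18.010565
CARBAMIDOMETHYL = 57.02146
DEFAULT_FIXED_MODS: Mapping[str, float] = {"C": CARBAMIDOMETHYL}

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Peptide:
    seq: str
    start: int  # 0-based residue position in the parent protein
    end: int
    missed_cleavages: int


@dataclass(frozen=True)
class SignaturePeptide:
    peptide: str
    isoform_id: str
    junction_span: Tuple[int, int]  # residue span of the peptide in the isoform
    monoisotopic_mass: float
    mz_by_charge: Tuple[Tuple[int, float], ...]
    missed_cleavages: int


def _check_residues(protein: str) -> None:
    bad = [(i, aa) for i, aa in enumerate(protein) if aa not in _STANDARD_AA]
    if bad:
        detail = ", ".join(f"{aa!r} at {i}" for i, aa in bad[:5])
        raise ValueError(f"non-standard residue(s): {detail}")


def tryptic_digest(protein: str, max_missed: int = 0) -> List[Peptide]:
    """Tryptic peptides of a protein with 0..max_missed missed cleavages.

    Cleavage occurs after K or R unless followed by P. Peptides are returned
    in (start, missed) order; the 0-missed set tiles the protein exactly.
    """
    if not protein:
        raise ValueError("empty protein")
    protein = protein.upper()
    _check_residues(protein)
    cuts = [0]
    for i, aa in enumerate(protein[:-1]):
        if aa in "KR" and protein[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein))

    peptides = []
    for i in range(len(cuts) - 1):
        for missed in range(0, max_missed + 1):
            j = i + 1 + missed
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            peptides.append(Peptide(protein[start:end], start, end, missed))
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def monoisotopic_mass(
    peptide: str, fixed_mods: Optional[Mapping[str, float]] = None
) -> float:
    """Neutral monoisotopic peptide mass in Da, fixed modifications included."""
    if not peptide:
        raise ValueError("empty peptide")
    peptide = peptide.upper()
    _check_residues(peptide)
    mods = DEFAULT_FIXED_MODS if fixed_mods is None else fixed_mods
    base = _pmass.fast_mass(peptide)
    return base + sum(mods.get(aa, 0.0) for aa in peptide)


def mz(mass: float, charge: int) -> float:
    """Precursor m/z of a neutral mass at the given positive charge."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return (mass + charge * PROTON_MASS) / charge


def canonical_digest_set(canonical_protein: str, max_missed: int = 2) -> Set[str]:
    return {p.seq for p in tryptic_digest(canonical_protein, max_missed)}


def signature_peptides(
    isoform_protein: str,
    junctions: Sequence[int],
    canonical_protein: str,
    isoform_id: str = "isoform",
    max_missed: int = 1,
    min_len: int = 6,
    charges: Iterable[int] = (2, 3),
    fixed_mods: Optional[Mapping[str, float]] = None,
) -> List[SignaturePeptide]:
    """Tryptic peptides unique to an isoform that span one of its junctions.

    ``junctions`` are 0-based residue positions j such that the bond between
    residues j-1 and j of the isoform joins residues that are non-adjacent
    in the canonical protein. A peptide qualifies if a junction falls
    strictly inside its span, it is at least ``min_len`` residues, and it is
    neither in the canonical digest (any missed-cleavage level up to
    ``max_missed``) nor a substring of the canonical protein.
    """
    if not junctions:
        return []
    canon_set = canonical_digest_set(canonical_protein, max_missed)
    out = []
    for pep in tryptic_digest(isoform_protein, max_missed):
        if len(pep.seq) < min_len:
            continue
        if not any(pep.start < j < pep.end for j in junctions):
            continue
        if pep.seq in canon_set or pep.seq in canonical_protein:
            continue
        m = monoisotopic_mass(pep.seq, fixed_mods)
        out.append(
            SignaturePeptide(
                peptide=pep.seq,
                isoform_id=isoform_id,
                junction_span=(pep.start, pep.end),
                monoisotopic_mass=m,
                mz_by_charge=tuple((z, mz(m, z)) for z in sorted(charges)),
                missed_cleavages=pep.missed_cleavages,
            )
        )
    # distinct sequences only, 5'-most occurrence kept
    seen: Set[str] = set()
    unique = []
    for sp in out:
        if sp.peptide not in seen:
            seen.add(sp.peptide)
            unique.append(sp)
    return unique


def inclusion_list(
    signatures: Sequence[SignaturePeptide], charges: Iterable[int] = (2, 3)
) -> pd.DataFrame:
    """Targeted-MS inclusion list: one row per (peptide, charge), sorted by m/z."""
    rows = []
    for sp in signatures:
        for z in sorted(set(charges)):
            rows.append(
                {
                    "peptide": sp.peptide,
                    "isoform_id": sp.isoform_id,
                    "charge": z,
                    "monoisotopic_mass": sp.monoisotopic_mass,
                    "mz": mz(sp.monoisotopic_mass, z),
                }
            )
    df = pd.DataFrame(
        rows, columns=["peptide", "isoform_id", "charge", "monoisotopic_mass", "mz"]
    )
    return df.sort_values(["mz", "peptide", "charge"], kind="mergesort").reset_index(drop=True)
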