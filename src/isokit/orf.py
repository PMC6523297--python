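"""ORF prediction from transcript sequences.

Full-length cDNAs retain the genuine 5' end of the mRNA, so the ORF used
by the ribosome is taken to be the *first* AUG-initiated reading frame with
an in-frame stop — not necessarily the largest. ``largest_orf`` is provided
for the cases where both are of interest (suffix letters a/b downstream).
Open-ended ORFs (no stop before the transcript end) are rejected: a
full-length transcript includes its 3' end, so a real coding region
terminates within it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

from Bio.Seq import Seq


@dataclass(frozen=True)
class OrfRecord:
    """An ORF on a transcript; coordinates 0-based half-open, stop included."""

    transcript_id: str
    start: int
    end: int
    protein: str
    rule: str  # "first" or "largest"

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF coordinates")
        if not self.protein.startswith("M"):
            raise ValueError("ORF protein must start with M")


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide sequence; stop codons terminate.

    Codons containing bases outside {A,C,G,T} translate to 'X' unless the
    ambiguity still resolves to a single residue.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i:i + 3].upper()
        try:
            aa = str(Seq(codon).translate())
        except Exception:
            aa = "X"
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def _orfs(seq: str) -> List[tuple]:
    """All (start, end, protein) ORFs: each ATG to its first in-frame stop."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    found = []
    for start in range(len(seq) - 2):
        if seq[start:start + 3] != "ATG":
            continue
        for j in range(start + 3, len(seq) - 2, 3):
            if seq[j:j + 3] in stops:
                protein = translate(seq[start:j])
                found.append((start, j + 3, protein))
                break
    return found


def first_orf(seq: str, min_aa: int = 30, transcript_id: str = "") -> Optional[OrfRecord]:
    """The 5'-most ATG-initiated ORF encoding at least ``min_aa`` residues."""
    for start, end, protein in _orfs(seq):
        if len(protein) >= min_aa:
            return OrfRecord(transcript_id, start, end, protein, "first")
    return None


def largest_orf(seq: str, min_aa: int = 30, transcript_id: str = "") -> Optional[OrfRecord]:
    """The longest ATG-initiated ORF (ties broken 5'-most)."""
    best: Optional[tuple] = None
    for start, end, protein in _orfs(seq):
        if len(protein) < min_aa:
            continue
        if best is None or len(protein) > len(best[2]):
            best = (start, end, protein)
    if best is None:
        return None
    return OrfRecord(transcript_id, best[0], best[1], best[2], "largest")


def orf_status(orf: Optional[OrfRecord], match_score: int, canonical_protein: str) -> str:
    """Classify an ORF as C (all canonical), C* (canonical protein from a
    novel transcript) or novel.

    ``match_score`` is the isoform's annotation agreement score; 5 means the
    transcript itself is canonical.
    """
    if not canonical_protein:
        raise ValueError("canonical protein sequence is required")
    if orf is None:
        return "novel"
    if orf.protein == canonical_protein:
        return "C" if match_score == 5 else "C*"
    return "novel"
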