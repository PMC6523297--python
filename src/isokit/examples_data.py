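"""Worked-example data: an elongation-factor-like canonical protein.

The bundled sequence is SYNTHETIC: a deterministic 462-residue stand-in for
a canonical translation elongation factor, generated from realistic
amino-acid frequencies with a tyrosine fixed at residue 86 and a valine at
residue 344 (1-based). It is not the UniProt P68104 sequence; it shares
only the two properties the worked example depends on — overall length and
the identity of the residues flanking the internal deletion.

The example isoform mirrors a deletion isoform in which residue Y86 is
joined directly to V344: the first 86 residues followed by residues
344..462, a 205-aa protein (86 + 119) missing the central block. Signature
tryptic peptides spanning that junction are discoverable against the
canonical digest.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

CANONICAL_LENGTH = 462
JUNCTION_LEFT = 86   # 1-based position of the last retained N-terminal residue (Y)
JUNCTION_RIGHT = 344  # 1-based position of the first retained C-terminal residue (V)

# Rounded vertebrate proteome amino-acid frequencies.
_AA = "ACDEFGHIKLMNPQRSTVWY"
_FREQ = np.array(
    [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6,
     1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)


def synthetic_eef1a1_like_canonical(seed: int = 2019) -> str:
    """Deterministic synthetic 462-aa canonical protein (see module docstring)."""
    rng = np.random.default_rng(seed)
    p = _FREQ / _FREQ.sum()
    residues = rng.choice(list(_AA), size=CANONICAL_LENGTH, p=p)
    seq = list("".join(residues))
    seq[0] = "M"
    seq[JUNCTION_LEFT - 1] = "Y"
    seq[JUNCTION_RIGHT - 1] = "V"
    return "".join(seq)


def junction_isoform(canonical: str) -> Tuple[str, List[int]]:
    """The deletion isoform joining Y86 directly to V344, with its junction.

    Returns the isoform protein (canonical[1..86] + canonical[344..end]) and
    the 0-based junction positions for signature-peptide discovery.
    """
    if len(canonical) < JUNCTION_RIGHT:
        raise ValueError("canonical protein shorter than the junction span")
    isoform = canonical[:JUNCTION_LEFT] + canonical[JUNCTION_RIGHT - 1:]
    return isoform, [JUNCTION_LEFT]
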