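"""Predict ORFs by the first-ORF rule and find isoform-signature peptides.

The worked example mirrors an internal-deletion isoform of a 462-residue
elongation-factor-like protein (synthetic stand-in sequence): residue Y86
is joined directly to V344, leaving a 205-aa protein. Tryptic peptides
spanning that junction and absent from the canonical digest are direct
targeted-MS evidence that the isoform is translated.
"""

from isokit import first_orf, largest_orf, inclusion_list, signature_peptides
from isokit.examples_data import junction_isoform, synthetic_eef1a1_like_canonical

# first vs largest ORF on a toy transcript: the 5'-most short ORF wins
seq = "GGG" + "ATGGTTTAA" + "ATG" + "GAAGAA" * 20 + "TGA"
f = first_orf(seq, min_aa=1)
l = largest_orf(seq, min_aa=1)
print(f"first ORF: {f.protein!r} at ({f.start},{f.end}); "
      f"largest ORF: {len(l.protein)} aa at ({l.start},{l.end})")

canonical = synthetic_eef1a1_like_canonical()
isoform, junctions = junction_isoform(canonical)
print(f"canonical: {len(canonical)} aa; deletion isoform: {len(isoform)} aa "
      f"(junction after residue {junctions[0]})")

sigs = signature_peptides(isoform, junctions, canonical, max_missed=1, min_len=6)
print(f"signature peptides: {len(sigs)}")
table = inclusion_list(sigs, charges={2, 3})
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# Each row is a precursor the mass spectrometer should target; the peptides
# cover the deletion junction and occur nowhere in the canonical protein.
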