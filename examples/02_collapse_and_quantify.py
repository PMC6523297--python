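"""Collapse redundant full-length transcripts and convert counts to TPM.

Full-length reads of one isoform differ in their terminal ends; collapse
groups them by intron chain, keeps the longest, and sums the counts.
Master IDs then name each distinct chain across samples.
"""

from isokit import (
    TranscriptModel,
    assign_master_ids,
    collapse_to_longest,
    counts_to_tpm,
    fpkm_to_tpm,
)

# three reads of the same splice structure (jittered ends) + one distinct
reads = [
    TranscriptModel("r1", "g1", "chr1", "+", ((100, 500), (800, 1200))),
    TranscriptModel("r2", "g1", "chr1", "+", ((160, 500), (800, 1150))),
    TranscriptModel("r3", "g1", "chr1", "+", ((130, 500), (800, 1180))),
    TranscriptModel("r4", "g1", "chr1", "+", ((100, 500), (850, 1200))),
]
records = collapse_to_longest(reads, [3, 1, 2, 5], sample_id="T")
registry = assign_master_ids([records])

print(f"{len(reads)} transcripts -> {len(records)} collapsed isoforms")
for rec in records:
    print(f"  {rec.master_id}: representative={rec.model.transcript_id} "
          f"count={rec.read_count} members={rec.member_ids}")

tpm = counts_to_tpm([rec.read_count for rec in records])
print(f"TPM: {tpm.round(1).tolist()}  (sum = {tpm.sum():.0f})")
print(f"FPKM [10, 30, 60] -> TPM {fpkm_to_tpm([10, 30, 60]).round(0).tolist()}")
# Reads are conserved (3+1+2 merge into count 6); each sample's TPM vector
# sums to one million by construction.
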