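"""Collapse redundant full-length transcripts, assign master IDs, compute TPM.

Full-length reads of the same underlying isoform differ mainly in their
terminal-exon ends (5' degradation, polyA priming); the splice structure —
the intron chain — is the stable signal. Collapse therefore merges
transcripts with identical intron chains, keeps the longest member as the
representative, and sums the read counts. Master IDs name each distinct
intron chain consistently across samples so isoform composition can be
compared between cell populations.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import TranscriptModel, chain_key

TPM_SCALE = 1_000_000.0


@dataclass
class IsoformRecord:
    """A collapsed isoform with its abundance in one sample."""

    model: TranscriptModel
    sample_id: str = "S"
    population: str = "other"
    read_count: int = 0
    master_id: Optional[str] = None
    tpm: Optional[float] = None
    member_ids: Tuple[str, ...] = ()

    @property
    def key(self) -> tuple:
        return chain_key(self.model)


def _reciprocal_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _cluster_monoexonic(
    txs: List[Tuple[TranscriptModel, int]], min_overlap: float
) -> List[List[Tuple[TranscriptModel, int]]]:
    """Single-linkage clustering of monoexonic transcripts by reciprocal overlap."""
    n = len(txs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: txs[i][0].exons[0])
    for ia, i in enumerate(order):
        for j in order[ia + 1:]:
            ei, ej = txs[i][0].exons[0], txs[j][0].exons[0]
            if ej[0] >= ei[1]:
                break
            if _reciprocal_overlap(ei, ej) >= min_overlap:
                parent[find(i)] = find(j)
    groups: Dict[int, List[Tuple[TranscriptModel, int]]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(txs[i])
    return list(groups.values())


def collapse_to_longest(
    transcripts: Sequence[TranscriptModel],
    counts: Sequence[int],
    sample_id: str = "S",
    population: str = "other",
    mono_min_overlap: float = 0.95,
) -> List[IsoformRecord]:
    """Merge transcripts sharing an intron chain; keep the longest as representative.

    Multi-exon transcripts are grouped by exact (chrom, strand, intron chain)
    identity; monoexonic transcripts by >= ``mono_min_overlap`` reciprocal
    overlap on the same chrom/strand. The representative is the member with
    the greatest exonic length (ties by transcript_id) and the record's count
    is the sum over members, so total reads are conserved.
    """
    if len(transcripts) != len(counts):
        raise ValueError("transcripts and counts must have equal length")
    multi: Dict[tuple, List[Tuple[TranscriptModel, int]]] = defaultdict(list)
    mono: Dict[tuple, List[Tuple[TranscriptModel, int]]] = defaultdict(list)
    for tx, c in zip(transcripts, counts):
        if len(tx.exons) > 1:
            multi[chain_key(tx)].append((tx, int(c)))
        else:
            mono[(tx.chrom, tx.strand)].append((tx, int(c)))

    groups: List[List[Tuple[TranscriptModel, int]]] = list(multi.values())
    for members in mono.values():
        groups.extend(_cluster_monoexonic(members, mono_min_overlap))

    records = []
    for members in groups:
        rep = max(members, key=lambda m: (m[0].exonic_length, m[0].transcript_id))[0]
        records.append(
            IsoformRecord(
                model=rep,
                sample_id=sample_id,
                population=population,
                read_count=sum(c for _, c in members),
                member_ids=tuple(sorted(m[0].transcript_id for m in members)),
            )
        )
    records.sort(key=lambda r: (r.model.chrom, r.model.start, r.model.transcript_id))
    return records


def assign_master_ids(samples: Iterable[List[IsoformRecord]]) -> Dict[tuple, str]:
    """Assign one master ID per distinct intron-chain key across all samples.

    Records are updated in place; the registry maps chain key -> master ID.
    IDs are assigned in sorted key order, so the mapping is deterministic
    and identical chains in different samples always share an ID.
    """
    sample_lists = [list(s) for s in samples]
    keys = sorted({rec.key for s in sample_lists for rec in s})
    registry = {key: f"M{i + 1:06d}" for i, key in enumerate(keys)}
    for s in sample_lists:
        for rec in s:
            rec.master_id = registry[rec.key]
    return registry


def fpkm_to_tpm(fpkm: Sequence[float]) -> np.ndarray:
    """TPM_i = FPKM_i / sum(FPKM) * 1e6."""
    v = np.asarray(fpkm, dtype=float)
    if (v < 0).any():
        raise ValueError("FPKM values must be non-negative")
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero FPKM vector")
    return v / total * TPM_SCALE


def counts_to_tpm(
    counts: Sequence[int],
    lengths: Optional[Sequence[int]] = None,
    length_normalize: bool = False,
) -> np.ndarray:
    """Convert full-length read counts to TPM.

    Each full-length read is one transcript molecule, so by default no
    length normalization is applied: TPM_i = count_i / sum(counts) * 1e6.
    ``length_normalize=True`` divides by transcript length first (the
    short-read convention) for comparability experiments.
    """
    v = np.asarray(counts, dtype=float)
    if (v < 0).any():
        raise ValueError("counts must be non-negative")
    if length_normalize:
        if lengths is None:
            raise ValueError("length_normalize requires transcript lengths")
        v = v / np.asarray(lengths, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count vector")
    return v / total * TPM_SCALE


def abundance_table(samples: Mapping[str, List[IsoformRecord]]) -> pd.DataFrame:
    """Build a per-(master_id, sample) abundance table with TPM columns."""
    rows = []
    for sample_id, records in sorted(samples.items()):
        counts = [r.read_count for r in records]
        tpm = counts_to_tpm(counts) if sum(counts) > 0 else np.zeros(len(records))
        for rec, t in zip(records, tpm):
            rec.tpm = float(t)
            rows.append(
                {
                    "master_id": rec.master_id,
                    "sample_id": sample_id,
                    "population": rec.population,
                    "count": rec.read_count,
                    "tpm": float(t),
                }
            )
    return pd.DataFrame(rows, columns=["master_id", "sample_id", "population", "count", "tpm"])
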