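"""Core genomic data types: genome sequences, transcript models, annotations.

All internal coordinates are 0-based, half-open genomic intervals. File
readers/writers convert at the boundary (GTF is 1-based closed, BED is
0-based half-open). A transcript is an ordered chain of non-overlapping,
non-adjacent exons on one chromosome and strand; everything downstream
(collapse keys, splice-event calls, ORF inputs) is derived from that chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]

_VALID_BASES = frozenset("ACGTN")


class ModelValidationError(ValueError):
    """A transcript or genome object violates its structural invariants."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome sequence over the alphabet {A, C, G, T, N}."""

    chrom_name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ModelValidationError(f"genome {self.chrom_name!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ModelValidationError(
                f"genome {self.chrom_name!r} contains invalid bases: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-aware exon chain on a chromosome.

    ``exons`` are genomic intervals (0-based, half-open), sorted ascending,
    pairwise disjoint and non-adjacent (an intron of length >= 1 separates
    consecutive exons). Exons are stored in genomic order regardless of
    strand; transcript-orientation accessors (``five_prime_end``,
    ``junction_positions``) handle the strand flip.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ModelValidationError(f"{self.transcript_id}: needs at least one exon")
        for a, b in exons:
            if a < 0 or b <= a:
                raise ModelValidationError(
                    f"{self.transcript_id}: invalid exon interval ({a}, {b})"
                )
        for (a1, b1), (a2, b2) in zip(exons, exons[1:]):
            if b1 >= a2:
                raise ModelValidationError(
                    f"{self.transcript_id}: exons ({a1},{b1}) and ({a2},{b2}) "
                    "overlap or are adjacent"
                )

    # -- chain geometry ----------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> Tuple[Interval, ...]:
        return intron_chain(self)

    @property
    def five_prime_end(self) -> int:
        """Genomic coordinate of the transcription start (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    def exon_lengths_transcript_order(self) -> List[int]:
        lens = [b - a for a, b in self.exons]
        return lens if self.strand == "+" else lens[::-1]

    def junction_positions(self) -> List[int]:
        """Exon-exon junction positions in transcript coordinates.

        Position j means the junction lies between transcript bases j-1 and
        j; a read covering [j - w, j + w) spans the junction by w on each
        side. Monoexonic transcripts have no junctions.
        """
        lens = self.exon_lengths_transcript_order()
        out: List[int] = []
        acc = 0
        for ln in lens[:-1]:
            acc += ln
            out.append(acc)
        return out

    def donor_sites(self) -> List[int]:
        """Splice-donor coordinates (transcription-downstream exon edge).

        On '+' a donor is an intron's genomic start (= upstream-exon end);
        on '-' it is the intron's genomic end.
        """
        if self.strand == "+":
            return [a for a, _ in self.introns]
        return [b for _, b in self.introns]

    def acceptor_sites(self) -> List[int]:
        if self.strand == "+":
            return [b for _, b in self.introns]
        return [a for a, _ in self.introns]

    def shifted(self, offset: int) -> "TranscriptModel":
        """Return a copy with every exon translated by ``offset``."""
        return TranscriptModel(
            self.transcript_id,
            self.gene_id,
            self.chrom,
            self.strand,
            tuple((a + offset, b + offset) for a, b in self.exons),
        )


def intron_chain(tx: TranscriptModel) -> Tuple[Interval, ...]:
    """Ordered intron intervals between consecutive exons; empty if monoexonic."""
    return tuple(
        (b1, a2) for (_, b1), (a2, _) in zip(tx.exons, tx.exons[1:])
    )


def chain_key(tx: TranscriptModel) -> tuple:
    """Identity key used for collapse and master-ID assignment.

    Multi-exon transcripts are identified by (chrom, strand, intron chain);
    monoexonic transcripts, which have no introns, carry their exact exon
    interval instead.
    """
    introns = intron_chain(tx)
    if introns:
        return (tx.chrom, tx.strand, introns)
    return (tx.chrom, tx.strand, (), tx.exons)


def transcript_sequence(genome: GenomeSequence, tx: TranscriptModel) -> str:
    """Spliced transcript sequence, reverse-complemented for '-' strand."""
    if tx.chrom != genome.chrom_name:
        raise ValueError(
            f"{tx.transcript_id}: chromosome {tx.chrom!r} does not match "
            f"genome {genome.chrom_name!r}"
        )
    if tx.end > len(genome):
        raise IndexError(
            f"{tx.transcript_id}: exon end {tx.end} beyond chromosome "
            f"length {len(genome)}"
        )
    seq = "".join(genome.sequence[a:b] for a, b in tx.exons)
    if tx.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


@dataclass
class GenomeAnnotation:
    """A collection of transcript models grouped by gene.

    Each gene carries exactly one canonical transcript (the reference model
    splice events are called against). When the canonical flag is absent
    from the source the transcript with the greatest exonic length is used.
    """

    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)
    canonical_by_gene: Dict[str, str] = field(default_factory=dict)

    def add(self, tx: TranscriptModel, canonical: bool = False) -> None:
        if tx.transcript_id in self.transcripts:
            raise ModelValidationError(f"duplicate transcript_id {tx.transcript_id!r}")
        self.transcripts[tx.transcript_id] = tx
        if canonical:
            self.canonical_by_gene[tx.gene_id] = tx.transcript_id

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    @property
    def gene_ids(self) -> List[str]:
        return sorted({tx.gene_id for tx in self})

    def by_gene(self, gene_id: str) -> List[TranscriptModel]:
        return [tx for tx in self if tx.gene_id == gene_id]

    def canonical(self, gene_id: str) -> TranscriptModel:
        tx_id = self.canonical_by_gene.get(gene_id)
        if tx_id is None:
            members = self.by_gene(gene_id)
            if not members:
                raise KeyError(f"unknown gene_id {gene_id!r}")
            best = max(members, key=lambda t: (t.exonic_length, t.transcript_id))
            self.canonical_by_gene[gene_id] = best.transcript_id
            return best
        return self.transcripts[tx_id]

    def finalize(self) -> "GenomeAnnotation":
        """Ensure every gene has a canonical transcript; return self."""
        for gid in self.gene_ids:
            self.canonical(gid)
        return self

    def overlapping(self, tx: TranscriptModel) -> List[TranscriptModel]:
        """Same-chromosome, same-strand references with exonic overlap."""
        hits = []
        for ref in self:
            if ref.chrom != tx.chrom or ref.strand != tx.strand:
                continue
            if _exonic_overlap(tx, ref) > 0:
                hits.append(ref)
        return hits


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    total = 0
    for xa, xb in a.exons:
        for ya, yb in b.exons:
            total += max(0, min(xb, yb) - max(xa, ya))
    return total
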