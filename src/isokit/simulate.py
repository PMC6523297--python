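"""Synthetic transcriptome with known isoform truth.

This module stands in for the sequencing data: a toy genome with multi-exon
gene models (2-16 exons by default), two cell populations (T, total; N,
lineage-negative) sharing some isoforms while each carries
population-specific ones, per-isoform splice-event labels, full-length read
counts, degraded short-read junction evidence with a per-locus detection
ceiling, paralogous gene pairs of tunable identity, and a subsampled set of
"observed" tryptic peptides.

Every novel isoform is built by applying exactly one labeled splice event
to the canonical transcript of its locus, with geometric margins (alternate
sites shifted >= 10 nt, split introns >= 20 nt inside an exon, novel exons
>= 12 nt from reference splice sites) chosen so the event classifier can
recover the label set exactly — ambiguity is excluded by construction.
Canonical introns carry GT..AG motifs on the coding strand so that
sequence-level operations see realistic splice boundaries.

All generators are fully deterministic for a fixed seed; independent
substreams are derived per stage so adding one stage never perturbs another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .evidence import CoverageIntervals
from .matching import (
    ALT_ACCEPTOR,
    ALT_DONOR,
    EXON_SKIPPING,
    EXON_SPLITTING,
    INTRON_RETENTION,
    NOVEL_EXON,
)
from .models import GenomeAnnotation, GenomeSequence, TranscriptModel
from .peptides import tryptic_digest

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

SIMULATED_EVENTS = (
    EXON_SKIPPING, EXON_SPLITTING, ALT_DONOR, ALT_ACCEPTOR,
    INTRON_RETENTION, NOVEL_EXON,
)


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 20
    exon_count_range: Tuple[int, int] = (2, 16)
    exon_len_range: Tuple[int, int] = (80, 300)
    intron_len_range: Tuple[int, int] = (60, 400)
    intergenic_gap_range: Tuple[int, int] = (200, 800)
    novel_isoforms_per_locus: Tuple[int, int] = (0, 12)
    novel_rate_per_intron: float = 0.6
    event_profile: Mapping[str, float] = field(
        default_factory=lambda: {e: 1.0 for e in SIMULATED_EVENTS}
    )
    population_specific_fraction: float = 0.5
    fl_depth: float = 30.0
    sr_junction_dropout: float = 0.2
    sr_max_isoforms_per_locus: int = 4
    chrom_name: str = "chr1"
    chrom_length: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        def _range_ok(r: Tuple[int, int], lo: int) -> bool:
            return len(r) == 2 and lo <= r[0] <= r[1]

        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not _range_ok(self.exon_count_range, 1):
            raise ConfigurationError("invalid exon_count_range")
        if not _range_ok(self.exon_len_range, 20):
            raise ConfigurationError("exon_len_range minimum is 20 nt")
        if not _range_ok(self.intron_len_range, 20):
            raise ConfigurationError("intron_len_range minimum is 20 nt")
        if not _range_ok(self.novel_isoforms_per_locus, 0):
            raise ConfigurationError("invalid novel_isoforms_per_locus")
        unknown = set(self.event_profile) - set(SIMULATED_EVENTS)
        if unknown:
            raise ConfigurationError(f"unknown events in profile: {sorted(unknown)}")
        weights = list(self.event_profile.values())
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigurationError("event weights must be non-negative, not all zero")
        for name in ("population_specific_fraction", "sr_junction_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.fl_depth < 0:
            raise ConfigurationError("fl_depth must be >= 0")
        if self.novel_rate_per_intron < 0:
            raise ConfigurationError("novel_rate_per_intron must be >= 0")
        if self.sr_max_isoforms_per_locus < 1:
            raise ConfigurationError("sr_max_isoforms_per_locus must be >= 1")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stage])


@dataclass
class TruthRecord:
    """One simulated isoform with its ground-truth label set and populations."""

    isoform: TranscriptModel
    gene_id: str
    true_events: FrozenSet[str]
    populations: FrozenSet[str]
    true_count: Optional[Dict[str, int]] = None

    @property
    def is_novel(self) -> bool:
        return bool(self.true_events)


# ---------------------------------------------------------------------------
# genome + annotation


def _set_motif(genome: np.ndarray, intron: Tuple[int, int], strand: str) -> None:
    a, b = intron
    if strand == "+":
        genome[a], genome[a + 1] = b"G", b"T"
        genome[b - 2], genome[b - 1] = b"A", b"G"
    else:  # reverse complement of GT..AG as seen on the forward strand
        genome[a], genome[a + 1] = b"C", b"T"
        genome[b - 2], genome[b - 1] = b"A", b"C"


def generate_genome_and_annotation(
    config: SimulationConfig,
) -> Tuple[GenomeSequence, GenomeAnnotation]:
    """One chromosome of non-overlapping genes, each with a canonical transcript."""
    rng = config.rng(0)
    annotation = GenomeAnnotation()
    cursor = 0
    gene_layout: List[Tuple[str, str, List[Tuple[int, int]]]] = []
    for i in range(config.n_genes):
        gid = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        cursor += int(rng.integers(*_incl(config.intergenic_gap_range)))
        exons = []
        pos = cursor
        for j in range(n_exons):
            if j > 0:
                pos += int(rng.integers(*_incl(config.intron_len_range)))
            ln = int(rng.integers(*_incl(config.exon_len_range)))
            exons.append((pos, pos + ln))
            pos += ln
        cursor = pos
        gene_layout.append((gid, strand, exons))

    total_len = cursor + 100
    if config.chrom_length is not None:
        if config.chrom_length < total_len:
            raise ConfigurationError(
                f"chrom_length {config.chrom_length} too short for layout "
                f"requiring {total_len} nt"
            )
        total_len = config.chrom_length
    genome = rng.choice(_BASES, size=total_len)

    for gid, strand, exons in gene_layout:
        tx = TranscriptModel(f"{gid}.c", gid, config.chrom_name, strand, tuple(exons))
        for intron in tx.introns:
            _set_motif(genome, intron, strand)
        _plant_orf(genome, tx)
        annotation.add(tx, canonical=True)
    seq = genome.tobytes().decode("ascii")
    return GenomeSequence(config.chrom_name, seq), annotation


def _incl(r: Tuple[int, int]) -> Tuple[int, int]:
    return r[0], r[1] + 1


_COMPLEMENT = {b"A": b"T", b"C": b"G", b"G": b"C", b"T": b"A"}
_STOPS = {"TAA", "TAG", "TGA"}


def _plant_orf(genome: np.ndarray, tx: TranscriptModel,
               cds_start: int = 12, utr3: int = 30) -> None:
    """Write a coding sequence into a transcript's exons.

    Plants ATG at transcript position ``cds_start``, clears in-frame stop
    codons (and any upstream ATG) and places a TAA stop ``utr3`` nt before
    the 3' end, so the canonical transcript encodes a real protein and
    frame-disrupting events downstream have realistic consequences.
    """
    # transcript position -> genomic position, strand-aware
    positions = [p for a, b in tx.exons for p in range(a, b)]
    if tx.strand == "-":
        positions = positions[::-1]
    length = len(positions)
    if length < cds_start + 9:
        return

    def tx_base(p: int) -> str:
        g = genome[positions[p]]
        return (g if tx.strand == "+" else _COMPLEMENT[bytes(g)]).decode()

    def set_base(p: int, base: str) -> None:
        b = base.encode()
        genome[positions[p]] = b if tx.strand == "+" else _COMPLEMENT[b]

    # no ATG upstream of (or overlapping) the planted start codon
    for p in range(0, cds_start):
        if p + 2 < length and tx_base(p) == "A" and tx_base(p + 1) == "T" and tx_base(p + 2) == "G":
            set_base(p + 1, "C")
    for base, off in zip("ATG", range(3)):
        set_base(cds_start + off, base)
    stop_at = cds_start + 3 * ((length - utr3 - cds_start) // 3) - 3
    stop_at = max(stop_at, cds_start + 3)
    for p in range(cds_start + 3, stop_at, 3):
        codon = tx_base(p) + tx_base(p + 1) + tx_base(p + 2)
        if codon in _STOPS:
            set_base(p + 1, "C")  # TAA/TAG/TGA -> TCA/TCG/TCA (Ser)
    if stop_at + 2 < length:
        for base, off in zip("TAA", range(3)):
            set_base(stop_at + off, base)


# ---------------------------------------------------------------------------
# splice-event constructors (each returns a new exon tuple or None)


def _apply_exon_skipping(exons, rng, _cfg):
    if len(exons) < 3:
        return None
    i = int(rng.integers(1, len(exons) - 1))
    return exons[:i] + exons[i + 1:]


def _apply_intron_retention(exons, rng, _cfg):
    if len(exons) < 3:  # retaining the only intron would leave a monoexonic model
        return None
    i = int(rng.integers(0, len(exons) - 1))
    merged = (exons[i][0], exons[i + 1][1])
    return exons[:i] + (merged,) + exons[i + 2:]


def _apply_exon_splitting(exons, rng, _cfg, flank: int = 10, min_intron: int = 20):
    candidates = [i for i, (a, b) in enumerate(exons) if b - a >= 2 * flank + min_intron]
    if not candidates:
        return None
    i = candidates[int(rng.integers(len(candidates)))]
    a, b = exons[i]
    max_intron = min(60, b - a - 2 * flank)
    ilen = int(rng.integers(min_intron, max_intron + 1))
    s = int(rng.integers(a + flank, b - flank - ilen + 1))
    return exons[:i] + ((a, s), (s + ilen, b)) + exons[i + 1:]


def _shrinkable(exons, i, min_keep=20, min_shift=10):
    return exons[i][1] - exons[i][0] >= min_keep + min_shift


def _apply_alt_site(exons, rng, strand, which):
    """Shift one splice site >= 10 nt into its exon.

    ``which`` is 'donor' or 'acceptor' in the strand-aware sense. Requires
    >= 2 introns so at least one reference intron stays shared (keeping the
    annotation-agreement score at the acceptable level).
    """
    n_introns = len(exons) - 1
    if n_introns < 2:
        return None
    # the exon whose edge moves, and which edge, depend on strand and role
    shrink_right = (strand == "+") == (which == "donor")
    candidates = []
    for i in range(n_introns):
        e = i if shrink_right else i + 1
        if _shrinkable(exons, e):
            candidates.append((i, e))
    if not candidates:
        return None
    i, e = candidates[int(rng.integers(len(candidates)))]
    a, b = exons[e]
    max_shift = min(40, (b - a) - 20)
    shift = int(rng.integers(10, max_shift + 1))
    new_exon = (a, b - shift) if shrink_right else (a + shift, b)
    return exons[:e] + (new_exon,) + exons[e + 1:]


def _apply_novel_exon(exons, rng, _cfg, gap: int = 12, min_len: int = 20):
    introns = [(b1, a2) for (_, b1), (a2, _) in zip(exons, exons[1:])]
    if len(introns) < 2:
        # inserting into the only intron would leave no shared intron,
        # dropping the annotation-agreement score below the acceptable level
        return None
    candidates = [
        i for i, (a, b) in enumerate(introns) if b - a >= 2 * gap + min_len + 1
    ]
    if not candidates:
        return None
    i = candidates[int(rng.integers(len(candidates)))]
    a, b = introns[i]
    max_len = min(60, b - a - 2 * gap - 1)
    ln = int(rng.integers(min_len, max_len + 1))
    s = int(rng.integers(a + gap, b - gap - ln + 1))
    return exons[:i + 1] + ((s, s + ln),) + exons[i + 1:]


def _apply_event(event, exons, strand, rng, cfg):
    if event == EXON_SKIPPING:
        return _apply_exon_skipping(exons, rng, cfg)
    if event == INTRON_RETENTION:
        return _apply_intron_retention(exons, rng, cfg)
    if event == EXON_SPLITTING:
        return _apply_exon_splitting(exons, rng, cfg)
    if event == ALT_DONOR:
        return _apply_alt_site(exons, rng, strand, "donor")
    if event == ALT_ACCEPTOR:
        return _apply_alt_site(exons, rng, strand, "acceptor")
    if event == NOVEL_EXON:
        return _apply_novel_exon(exons, rng, cfg)
    raise ValueError(f"unknown event {event!r}")


# ---------------------------------------------------------------------------
# isoform truth


def simulate_isoform_truth(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> List[TruthRecord]:
    """Novel isoforms with single-event labels, plus canonical records.

    Each novel isoform applies one splice event to its locus's canonical
    transcript. Events inapplicable to a locus geometry (e.g. skipping at a
    two-exon gene) are resampled from the remaining profile; loci where no
    event applies yield no novel isoform. A ``population_specific_fraction``
    of novel isoforms is assigned to exactly one population; canonical
    isoforms and the remainder appear in both.
    """
    rng = config.rng(1)
    events = sorted(config.event_profile)
    weights = np.array([config.event_profile[e] for e in events], float)
    records: List[TruthRecord] = []
    for gid in annotation.gene_ids:
        canonical = annotation.canonical(gid)
        records.append(
            TruthRecord(canonical, gid, frozenset(), frozenset({"T", "N"}))
        )
        seen = {canonical.exons}
        # isoform diversity scales with locus complexity: more introns, more
        # opportunities for alternative processing
        lo, hi = config.novel_isoforms_per_locus
        n_introns = len(canonical.exons) - 1
        n_novel = int(
            np.clip(rng.poisson(config.novel_rate_per_intron * max(1, n_introns)), lo, hi)
        )
        made = 0
        attempts = 0
        while made < n_novel and attempts < 30 * max(1, n_novel):
            attempts += 1
            event = str(rng.choice(events, p=weights / weights.sum()))
            new_exons = _apply_event(event, canonical.exons, canonical.strand, rng, config)
            if new_exons is None:
                logger.debug("%s: event %s not applicable, resampling", gid, event)
                continue
            new_exons = tuple(new_exons)
            if new_exons in seen:
                continue
            seen.add(new_exons)
            made += 1
            iso = TranscriptModel(
                f"{gid}.n{made}", gid, canonical.chrom, canonical.strand, new_exons
            )
            if rng.random() < config.population_specific_fraction:
                pops = frozenset({"T" if rng.random() < 0.5 else "N"})
            else:
                pops = frozenset({"T", "N"})
            records.append(TruthRecord(iso, gid, frozenset({event}), pops))
    return records


def simulate_fl_counts(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> pd.DataFrame:
    """Poisson full-length read counts per isoform per population.

    Counts are zero where the isoform is absent from a population. Records
    are updated in place (``true_count``); the returned table is indexed by
    transcript id with columns T and N.
    """
    if not truth:
        raise ValueError("empty truth set")
    rng = config.rng(2)
    rows = {}
    for rec in truth:
        counts = {
            pop: int(rng.poisson(config.fl_depth)) if pop in rec.populations else 0
            for pop in ("T", "N")
        }
        rec.true_count = counts
        rows[rec.isoform.transcript_id] = counts
    return pd.DataFrame.from_dict(rows, orient="index", columns=["T", "N"])


def simulate_sr_evidence(
    truth: Sequence[TruthRecord], config: SimulationConfig
) -> Tuple[Dict[str, CoverageIntervals], FrozenSet[str]]:
    """Short-read junction coverage with dropout, and the SR-detected subset.

    Each junction of each isoform is spanned gaplessly with probability
    1 - sr_junction_dropout; a dropped junction leaves a 2-nt gap at the
    junction position. The SR-detected set truncates each locus to at most
    ``sr_max_isoforms_per_locus`` isoforms, highest total count first —
    emulating the detection ceiling of assembly from short reads.
    """
    rng = config.rng(3)
    coverage: Dict[str, CoverageIntervals] = {}
    for rec in truth:
        tx = rec.isoform
        length = tx.exonic_length
        gaps = [
            (j - 1, j + 1)
            for j in tx.junction_positions()
            if rng.random() < config.sr_junction_dropout
        ]
        intervals = []
        pos = 0
        for a, b in gaps:
            if a > pos:
                intervals.append((pos, a))
            pos = b
        if pos < length:
            intervals.append((pos, length))
        coverage[tx.transcript_id] = CoverageIntervals(tx.transcript_id, tuple(intervals))

    if any(rec.true_count is None for rec in truth):
        raise ValueError("run simulate_fl_counts before simulate_sr_evidence")
    by_gene: Dict[str, List[TruthRecord]] = {}
    for rec in truth:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    detected: Set[str] = set()
    for gid, recs in by_gene.items():
        ranked = sorted(
            recs,
            key=lambda r: (-sum(r.true_count.values()), r.isoform.transcript_id),
        )
        detected.update(r.isoform.transcript_id for r in ranked[: config.sr_max_isoforms_per_locus])
    return coverage, frozenset(detected)


# ---------------------------------------------------------------------------
# paralogs and peptide observations


def simulate_paralogs(
    config: SimulationConfig, identity: float
) -> Tuple[GenomeSequence, GenomeAnnotation]:
    """A gene and its paralog at a target exonic sequence identity.

    The second locus duplicates the first; point substitutions are placed at
    exonic positions so the measured exonic identity lands within +/- 1% of
    the target (e.g. 0.78, the order of identity at which paralog pairs
    confound short-read mapping).
    """
    if not 0.5 < identity <= 1.0:
        raise ConfigurationError("identity must be in (0.5, 1.0]")
    rng = config.rng(4)
    n_exons = int(rng.integers(*_incl(config.exon_count_range)))
    exons = []
    pos = int(rng.integers(*_incl(config.intergenic_gap_range)))
    for j in range(n_exons):
        if j > 0:
            pos += int(rng.integers(*_incl(config.intron_len_range)))
        ln = int(rng.integers(*_incl(config.exon_len_range)))
        exons.append((pos, pos + ln))
        pos += ln
    gap = int(rng.integers(*_incl(config.intergenic_gap_range)))
    offset = pos + gap - exons[0][0]
    exons2 = [(a + offset, b + offset) for a, b in exons]
    total = exons2[-1][1] + 100
    genome = rng.choice(_BASES, size=total)

    strand = "+" if rng.random() < 0.5 else "-"
    tx1 = TranscriptModel("PARA1.c", "PARA1", "chrP", strand, tuple(exons))
    tx2 = TranscriptModel("PARA2.c", "PARA2", "chrP", strand, tuple(exons2))
    for intron in tx1.introns:
        _set_motif(genome, intron, strand)

    # copy locus 1 onto locus 2, then substitute exonic positions
    src_lo, src_hi = exons[0][0], exons[-1][1]
    genome[src_lo + offset: src_hi + offset] = genome[src_lo:src_hi]
    exonic_positions = np.concatenate(
        [np.arange(a + offset, b + offset) for a, b in exons]
    )
    n_sub = int(round((1.0 - identity) * exonic_positions.size))
    if n_sub > 0:
        targets = rng.choice(exonic_positions, size=n_sub, replace=False)
        for t in targets:
            current = genome[t]
            choices = [b for b in _BASES if b != current]
            genome[t] = choices[int(rng.integers(3))]

    annotation = GenomeAnnotation()
    annotation.add(tx1, canonical=True)
    annotation.add(tx2, canonical=True)
    return GenomeSequence("chrP", genome.tobytes().decode("ascii")), annotation


def simulate_peptide_observations(
    proteins: Mapping[str, str], detect_prob: float, seed: int
) -> pd.DataFrame:
    """Independently "observe" each tryptic peptide (>= 7 aa) with detect_prob."""
    if not proteins:
        raise ValueError("empty protein set")
    if not 0.0 <= detect_prob <= 1.0:
        raise ConfigurationError("detect_prob must be in [0, 1]")
    rng = np.random.default_rng([int(seed) % (2**31), 5])
    rows = []
    for pid in sorted(proteins):
        for pep in tryptic_digest(proteins[pid], max_missed=0):
            if len(pep.seq) < 7:
                continue
            if rng.random() < detect_prob:
                rows.append({"protein_id": pid, "peptide": pep.seq})
    return pd.DataFrame(rows, columns=["protein_id", "peptide"])
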