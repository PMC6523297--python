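"""Readers and writers for GTF, BED12 and FASTA transcript-model files.

GTF parsing is delegated to :mod:`gffutils` (in-memory database); a light
pre-scan reports malformed lines with their line number, which the database
layer does not. BED12 has no structured reader among the installed genomics
libraries that preserves the block layout round-trip, so it is read and
written directly here.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, List, Optional, Union

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GenomeAnnotation, GenomeSequence, ModelValidationError, TranscriptModel

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """Raised for a structurally malformed GTF line, naming the line number."""


def _prescan_gtf(path: str) -> int:
    """Validate basic GTF line structure; return the number of feature lines."""
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise GtfParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}..{end}"
                )
            n_features += 1
    return n_features


def read_gtf(path: str) -> GenomeAnnotation:
    """Read exon features from a GTF file into a :class:`GenomeAnnotation`.

    Coordinates are converted from GTF's 1-based closed convention to
    0-based half-open. Transcripts whose exon lines carry a
    ``canonical "1"`` attribute are flagged canonical for their gene;
    otherwise the longest transcript per gene is used.
    """
    if _prescan_gtf(path) == 0:
        logger.warning("GTF file %s contains no feature lines; empty annotation", path)
        return GenomeAnnotation()

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: Dict[str, dict] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes["gene_id"][0]
        rec = exons.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
             "exons": [], "canonical": False},
        )
        rec["exons"].append((feat.start - 1, feat.end))  # 1-based closed -> half-open
        if feat.attributes.get("canonical", ["0"])[0] == "1":
            rec["canonical"] = True

    annotation = GenomeAnnotation()
    for tx_id in sorted(exons):
        rec = exons[tx_id]
        try:
            tx = TranscriptModel(
                tx_id, rec["gene_id"], rec["chrom"], rec["strand"],
                tuple(sorted(rec["exons"])),
            )
        except ModelValidationError as exc:
            raise ModelValidationError(f"{path}: {exc}") from exc
        annotation.add(tx, canonical=rec["canonical"])
    return annotation.finalize()


def write_gtf(
    annotation: Union[GenomeAnnotation, Iterable[TranscriptModel]],
    path: str,
    source: str = "isokit",
) -> None:
    """Write transcripts as GTF exon features (1-based closed coordinates).

    Output order is deterministic: (chrom, transcript start, transcript_id).
    """
    if isinstance(annotation, GenomeAnnotation):
        canonical_ids = set(annotation.canonical_by_gene.values())
        transcripts = list(annotation)
    else:
        canonical_ids = set()
        transcripts = list(annotation)
    transcripts.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for tx in transcripts:
            canon = ' canonical "1";' if tx.transcript_id in canonical_ids else ""
            for i, (a, b) in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{i}";{canon}'
                )
                fh.write(
                    f"{tx.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def read_bed12(path: str) -> List[TranscriptModel]:
    """Read transcript models from a BED12 file (blocks define the exon chain)."""
    out: List[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise GtfParseError(
                    f"{path}:{lineno}: BED12 requires 12 fields, got {len(fields)}"
                )
            chrom, start, name, strand = fields[0], int(fields[1]), fields[3], fields[5]
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise GtfParseError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + s, start + s + ln) for s, ln in zip(starts, sizes))
            gene_id = name.rsplit(".", 1)[0] if "." in name else name
            out.append(TranscriptModel(name, gene_id, chrom, strand, exons))
    return out


def write_bed12(transcripts: Iterable[TranscriptModel], path: str) -> None:
    txs = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for tx in txs:
            start, end = tx.start, tx.end
            sizes = ",".join(str(b - a) for a, b in tx.exons) + ","
            starts = ",".join(str(a - start) for a, _ in tx.exons) + ","
            fh.write(
                f"{tx.chrom}\t{start}\t{end}\t{tx.transcript_id}\t0\t{tx.strand}\t"
                f"{start}\t{end}\t0\t{len(tx.exons)}\t{sizes}\t{starts}\n"
            )


def read_genome_fasta(path: str) -> Dict[str, GenomeSequence]:
    return {
        rec.id: GenomeSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    """Write a name -> sequence mapping as FASTA in sorted-name order."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    SeqIO.write(records, path, "fasta")


def read_protein_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
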