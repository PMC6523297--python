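"""End-to-end orchestration: simulate -> collapse -> classify -> ORF ->
peptides -> confirm -> compare, with a JSON summary and a file manifest.

The pipeline runs on synthetic data (the default demo) or on user-supplied
GTF/FASTA/TSV inputs for the individual stages. Every stage writes its
table under the run directory; the summary JSON holds only numbers that are
recomputable from those tables. All randomness flows from the single seed
in the configuration, so repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import io as iio
from .collapse import IsoformRecord, abundance_table, assign_master_ids, collapse_to_longest
from .compare import bin_top_k_mean, composition_sets, mapping_fraction_by_exon_threshold, trend_test
from .evidence import (
    confirm_junction_coverage,
    confirmation_summary,
    cross_sample_confirm,
    match_observed_peptides,
    tss_match,
)
from .matching import assign_label, best_reference_match, classify_events
from .models import GenomeAnnotation, GenomeSequence, TranscriptModel, chain_key, transcript_sequence
from .orf import first_orf, orf_status
from .peptides import canonical_digest_set, inclusion_list, signature_peptides, tryptic_digest
from .simulate import (
    SimulationConfig,
    TruthRecord,
    generate_genome_and_annotation,
    simulate_fl_counts,
    simulate_isoform_truth,
    simulate_peptide_observations,
    simulate_sr_evidence,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of the demo pipeline in one serializable object."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    end_tolerance: int = 50
    min_aa: int = 10
    coverage_half_window: int = 50
    tss_tolerance: int = 50
    top_k: int = 5
    peptide_max_missed: int = 1
    peptide_min_len: int = 6
    peptide_detect_prob: float = 0.5
    replicate_presence_prob: float = 0.8
    run_peptides: bool = True
    run_confirm: bool = True
    run_compare: bool = True

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("simulation", {}).items()
        })
        return cls(simulation=sim, **raw)


def _protein_junctions(tx: TranscriptModel, ref: TranscriptModel, orf_start: int,
                       orf_end: int) -> List[int]:
    """Residue positions of novel splice junctions inside the ORF.

    A junction at transcript position j maps to the protein bond before
    residue ceil((j - orf_start) / 3); junctions shared with the reference
    intron chain are excluded.
    """
    ref_introns = set(ref.introns)
    n = len(tx.introns)
    out = []
    junction_pos = tx.junction_positions()
    for gi, intron in enumerate(tx.introns):
        if intron in ref_introns:
            continue
        ti = gi if tx.strand == "+" else n - 1 - gi
        j = junction_pos[ti]
        if orf_start + 3 <= j <= orf_end - 6:
            out.append(-(-(j - orf_start) // 3))
    return sorted(set(out))


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str) -> Dict[str, object]:
    """Run all enabled stages on synthetic data; return the summary dict."""
    os.makedirs(outdir, exist_ok=True)
    summary: Dict[str, object] = {"seed": config.simulation.seed}
    sim = config.simulation

    # --- simulate ---------------------------------------------------------
    genome, annotation = generate_genome_and_annotation(sim)
    truth = simulate_isoform_truth(annotation, sim)
    counts = simulate_fl_counts(truth, sim)
    coverage, sr_detected = simulate_sr_evidence(truth, sim)

    iio.write_fasta({genome.chrom_name: genome.sequence}, os.path.join(outdir, "genome.fa"))
    iio.write_gtf(annotation, os.path.join(outdir, "annotation.gtf"))
    iio.write_gtf([r.isoform for r in truth], os.path.join(outdir, "isoforms.gtf"))
    counts.rename_axis("transcript_id").to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    truth_df = pd.DataFrame(
        {
            "transcript_id": [r.isoform.transcript_id for r in truth],
            "gene_id": [r.gene_id for r in truth],
            "events": [";".join(sorted(r.true_events)) for r in truth],
            "populations": [",".join(sorted(r.populations)) for r in truth],
        }
    )
    truth_df.to_csv(os.path.join(outdir, "truth_labels.tsv"), sep="\t", index=False)
    cov_rows = [
        {"transcript_id": tid, "start": a, "end": b}
        for tid, ci in sorted(coverage.items())
        for a, b in ci.intervals
    ]
    pd.DataFrame(cov_rows).to_csv(os.path.join(outdir, "sr_coverage.tsv"), sep="\t", index=False)

    # --- collapse + master IDs + TPM -------------------------------------
    samples: Dict[str, List[IsoformRecord]] = {}
    for pop in ("T", "N"):
        observed = [r for r in truth if r.true_count[pop] >= 1]
        samples[pop] = collapse_to_longest(
            [r.isoform for r in observed],
            [r.true_count[pop] for r in observed],
            sample_id=pop,
            population=pop,
        )
    registry = assign_master_ids(samples.values())
    abundance = abundance_table(samples)
    abundance.to_csv(os.path.join(outdir, "abundance.tsv"), sep="\t", index=False)
    summary["n_isoforms"] = {pop: len(recs) for pop, recs in samples.items()}
    summary["n_master_ids"] = len(registry)

    # --- classify ---------------------------------------------------------
    truth_by_id = {r.isoform.transcript_id: r for r in truth}
    rows = []
    recovered = 0
    n_novel = 0
    score_hist: Dict[int, int] = {}
    for rec in truth:
        tx = rec.isoform
        match = best_reference_match(tx, annotation, config.end_tolerance)
        canonical = annotation.canonical(rec.gene_id)
        events = classify_events(tx, canonical, config.end_tolerance)
        score_hist[match.score] = score_hist.get(match.score, 0) + 1
        if rec.is_novel:
            n_novel += 1
            recovered += events.events == set(rec.true_events)
        rows.append(
            {
                "transcript_id": tx.transcript_id,
                "master_id": registry.get(chain_key(tx)),
                "gene_id": rec.gene_id,
                "best_ref": match.best_ref,
                "score": match.score,
                "events": ";".join(sorted(events.events)),
            }
        )
    classified = pd.DataFrame(rows)
    classified.to_csv(os.path.join(outdir, "classified.tsv"), sep="\t", index=False)
    summary["score_histogram"] = {str(k): v for k, v in sorted(score_hist.items())}
    event_counts: Dict[str, int] = {}
    for ev_str in classified["events"]:
        for ev in filter(None, str(ev_str).split(";")):
            event_counts[ev] = event_counts.get(ev, 0) + 1
    summary["event_counts"] = dict(sorted(event_counts.items()))
    summary["event_recovery_fraction"] = recovered / n_novel if n_novel else 1.0

    # --- ORFs -------------------------------------------------------------
    canonical_proteins: Dict[str, str] = {}
    for gid in annotation.gene_ids:
        ctx = annotation.canonical(gid)
        orf = first_orf(transcript_sequence(genome, ctx), config.min_aa, ctx.transcript_id)
        if orf is not None:
            canonical_proteins[gid] = orf.protein
    orf_rows = []
    proteins: Dict[str, str] = {}
    orf_info: Dict[str, tuple] = {}
    for rec in truth:
        tx = rec.isoform
        seq = transcript_sequence(genome, tx)
        orf = first_orf(seq, config.min_aa, tx.transcript_id)
        canon = canonical_proteins.get(rec.gene_id)
        score = int(classified.loc[classified["transcript_id"] == tx.transcript_id, "score"].iloc[0])
        status = orf_status(orf, score, canon) if (orf and canon) else "novel"
        if orf is not None:
            proteins[tx.transcript_id] = orf.protein
            orf_info[tx.transcript_id] = (orf.start, orf.end, status)
        orf_rows.append(
            {
                "transcript_id": tx.transcript_id,
                "orf_start": orf.start if orf else None,
                "orf_end": orf.end if orf else None,
                "protein_length": len(orf.protein) if orf else 0,
                "orf_status": status if orf else "none",
            }
        )
    pd.DataFrame(orf_rows).to_csv(os.path.join(outdir, "orfs.tsv"), sep="\t", index=False)
    iio.write_fasta(proteins, os.path.join(outdir, "proteins.fa"))
    summary["n_orfs"] = len(proteins)
    summary["orf_status_counts"] = (
        pd.DataFrame(orf_rows)["orf_status"].value_counts().sort_index().to_dict()
    )

    # --- signature peptides ----------------------------------------------
    if config.run_peptides:
        signatures = []
        for rec in truth:
            tid = rec.isoform.transcript_id
            if tid not in orf_info or rec.gene_id not in canonical_proteins:
                continue
            start, end, status = orf_info[tid]
            if status != "novel":
                continue
            canonical = annotation.canonical(rec.gene_id)
            junctions = _protein_junctions(rec.isoform, canonical, start, end)
            if not junctions:
                continue
            signatures.extend(
                signature_peptides(
                    proteins[tid],
                    junctions,
                    canonical_proteins[rec.gene_id],
                    isoform_id=tid,
                    max_missed=config.peptide_max_missed,
                    min_len=config.peptide_min_len,
                )
            )
        incl = inclusion_list(signatures)
        incl.to_csv(os.path.join(outdir, "inclusion_list.tsv"), sep="\t", index=False)
        summary["n_signature_peptides"] = int(len(incl["peptide"].unique())) if len(incl) else 0

    # --- confirmation -----------------------------------------------------
    if config.run_confirm:
        rep_rng = sim.rng(6)
        replicate_models = [
            r.isoform for r in truth if rep_rng.random() < config.replicate_presence_prob
        ]
        replicate_registry = {chain_key(m): m.transcript_id for m in replicate_models}
        ref_tss = [annotation.canonical(g).five_prime_end for g in annotation.gene_ids]

        observed_peptides = (
            simulate_peptide_observations(proteins, config.peptide_detect_prob, sim.seed)
            if proteins
            else pd.DataFrame(columns=["protein_id", "peptide"])
        )
        digests = {
            tid: {p.seq for p in tryptic_digest(prot, 0) if len(p.seq) >= 6}
            for tid, prot in proteins.items()
        }
        pep_match = match_observed_peptides(set(observed_peptides["peptide"]), digests)
        pep_confirmed = dict(zip(pep_match["isoform_id"], pep_match["peptide_confirmed"]))

        conf_rows = []
        for rec in truth:
            tx = rec.isoform
            canonical = annotation.canonical(rec.gene_id)
            ref_introns = set(canonical.introns)
            flags = confirm_junction_coverage(
                tx, coverage[tx.transcript_id], config.coverage_half_window
            )
            n_ti = len(tx.introns)
            novel_idx = [
                (gi if tx.strand == "+" else n_ti - 1 - gi)
                for gi, intron in enumerate(tx.introns)
                if intron not in ref_introns
            ]
            conf_rows.append(
                {
                    "isoform_id": tx.transcript_id,
                    "novel": rec.is_novel,
                    "junctions_total": len(novel_idx),
                    "junctions_confirmed": sum(flags[i].confirmed for i in novel_idx),
                    "cross_sample_confirmed": cross_sample_confirm(tx, [replicate_registry]),
                    "tss_matched": tss_match(tx, ref_tss, config.tss_tolerance),
                    "peptide_confirmed": bool(pep_confirmed.get(tx.transcript_id, False)),
                }
            )
        conf_df = pd.DataFrame(conf_rows)
        conf_df.to_csv(os.path.join(outdir, "confirmation.tsv"), sep="\t", index=False)
        summary["confirmation"] = confirmation_summary(conf_df)
        summary["tss_match_fraction"] = float(conf_df["tss_matched"].mean())
        summary["peptide_confirmed_count"] = int(conf_df["peptide_confirmed"].sum())

    # --- population comparison -------------------------------------------
    if config.run_compare:
        membership = {
            pop: {
                g: {
                    registry[chain_key(r.isoform)]
                    for r in truth
                    if r.gene_id == g and r.true_count[pop] >= 1
                }
                for g in annotation.gene_ids
            }
            for pop in ("T", "N")
        }
        comp = composition_sets(membership)
        comp_out = comp.copy()
        for col in comp_out.columns:
            if col not in ("locus", "n_total"):
                comp_out[col] = comp_out[col].map(lambda v: ",".join(v))
        comp_out.to_csv(os.path.join(outdir, "composition.tsv"), sep="\t", index=False)

        locus_rows = []
        for gid in annotation.gene_ids:
            exon_count = len(annotation.canonical(gid).exons)
            fl = sum(1 for r in truth if r.gene_id == gid)
            sr = sum(
                1 for r in truth
                if r.gene_id == gid and r.isoform.transcript_id in sr_detected
            )
            locus_rows.append(
                {"locus": gid, "exon_count": exon_count, "fl_isoforms": fl, "sr_isoforms": sr}
            )
        locus_df = pd.DataFrame(locus_rows)
        locus_df.to_csv(os.path.join(outdir, "locus_counts.tsv"), sep="\t", index=False)

        fl_binned = bin_top_k_mean(
            locus_df.rename(columns={"fl_isoforms": "isoform_count"}), config.top_k
        )
        sr_binned = bin_top_k_mean(
            locus_df.rename(columns={"sr_isoforms": "isoform_count"}), config.top_k
        )
        binned = pd.DataFrame({"FL": fl_binned, "SR": sr_binned})
        binned.rename_axis("exon_count").to_csv(
            os.path.join(outdir, "binned_means.tsv"), sep="\t"
        )

        fl_by_bin = locus_df.groupby("exon_count")["fl_isoforms"].sum()
        sr_by_bin = locus_df.groupby("exon_count")["sr_isoforms"].sum()
        bins = sorted(set(fl_by_bin.index) | set(sr_by_bin.index))
        table = [
            [float(fl_by_bin.get(b, 0)) for b in bins],
            [float(sr_by_bin.get(b, 0)) for b in bins],
        ]
        trend = trend_test(table, scores=bins)
        summary["trend"] = {
            "z": trend.z_statistic,
            "chi_square": trend.chi_square,
            "p_value": trend.p_value,
        }
        iso_table = pd.DataFrame(
            {
                "locus_exon_count": [
                    len(annotation.canonical(r.gene_id).exons) for r in truth
                ]
            }
        )
        summary["fraction_ge_4_exons"] = mapping_fraction_by_exon_threshold(iso_table, 4)
        summary["fraction_ge_8_exons"] = mapping_fraction_by_exon_threshold(iso_table, 8)
        summary["sr_max_isoforms_per_locus"] = int(locus_df["sr_isoforms"].max())

    # --- summary + manifest ----------------------------------------------
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    manifest = {
        name: _sha256(os.path.join(outdir, name))
        for name in sorted(os.listdir(outdir))
        if name != "manifest.json" and os.path.isfile(os.path.join(outdir, name))
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
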