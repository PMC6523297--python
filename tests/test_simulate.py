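"""Synthetic-data generator: determinism, geometry, motifs, calibrations."""

import numpy as np
import pytest
from scipy import stats

from isokit.models import transcript_sequence
from isokit.peptides import tryptic_digest
from isokit.simulate import (
    ConfigurationError,
    SimulationConfig,
    generate_genome_and_annotation,
    simulate_fl_counts,
    simulate_isoform_truth,
    simulate_paralogs,
    simulate_peptide_observations,
    simulate_sr_evidence,
)


class TestGenomeGeneration:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_genes=5, seed=7)
        g1, a1 = generate_genome_and_annotation(cfg)
        g2, a2 = generate_genome_and_annotation(cfg)
        assert g1.sequence == g2.sequence
        assert [t.exons for t in a1] == [t.exons for t in a2]

    def test_exon_count_range_respected(self):
        cfg = SimulationConfig(n_genes=8, exon_count_range=(3, 3), seed=1)
        _, ann = generate_genome_and_annotation(cfg)
        assert all(len(t.exons) == 3 for t in ann)

    def test_splice_motifs_on_coding_strand(self):
        cfg = SimulationConfig(n_genes=10, seed=3)
        genome, ann = generate_genome_and_annotation(cfg)
        for t in ann:
            seq = genome.sequence
            for a, b in t.introns:
                if t.strand == "+":
                    assert seq[a:a + 2] == "GT" and seq[b - 2:b] == "AG"
                else:
                    assert seq[a:a + 2] == "CT" and seq[b - 2:b] == "AC"

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(n_genes=15, seed=5)
        _, ann = generate_genome_and_annotation(cfg)
        spans = sorted((t.start, t.end) for t in ann)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_infeasible_chromosome_length_rejected(self):
        cfg = SimulationConfig(n_genes=10, chrom_length=100, seed=0)
        with pytest.raises(ConfigurationError):
            generate_genome_and_annotation(cfg)

    def test_canonical_transcripts_encode_proteins(self):
        cfg = SimulationConfig(n_genes=6, seed=9)
        genome, ann = generate_genome_and_annotation(cfg)
        from isokit.orf import first_orf

        for t in ann:
            orf = first_orf(transcript_sequence(genome, t), min_aa=10)
            assert orf is not None


class TestIsoformTruth:
    def test_pure_event_profile_yields_that_label(self):
        cfg = SimulationConfig(
            n_genes=10, exon_count_range=(4, 8),
            event_profile={"exon_skipping": 1.0}, seed=2,
        )
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        novel = [r for r in truth if r.is_novel]
        assert novel and all(r.true_events == {"exon_skipping"} for r in novel)

    def test_fully_population_specific(self):
        cfg = SimulationConfig(n_genes=10, population_specific_fraction=1.0, seed=4)
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        for r in truth:
            if r.is_novel:
                assert len(r.populations) == 1

    def test_canonical_records_have_empty_events_and_both_populations(self):
        cfg = SimulationConfig(n_genes=5, seed=6)
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        for r in truth:
            assert bool(r.true_events) == (r.isoform.exons != ann.canonical(r.gene_id).exons)
            if not r.is_novel:
                assert r.populations == {"T", "N"}


class TestCounts:
    def test_zero_depth_gives_all_zero(self, sim_config):
        cfg = SimulationConfig(n_genes=5, fl_depth=0.0, seed=8)
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        counts = simulate_fl_counts(truth, cfg)
        assert (counts.values == 0).all()

    def test_reproducible_and_zero_outside_population(self, simulated):
        truth, cfg = simulated["truth"], simulated["config"]
        again = simulate_fl_counts(truth, cfg)
        assert (again.values == simulated["counts"].values).all()
        for r in truth:
            for pop in ("T", "N"):
                if pop not in r.populations:
                    assert r.true_count[pop] == 0

    def test_total_counts_near_poisson_expectation(self, simulated):
        truth, cfg = simulated["truth"], simulated["config"]
        n_slots = sum(len(r.populations) for r in truth)
        expected = n_slots * cfg.fl_depth
        total = int(simulated["counts"].values.sum())
        assert abs(total - expected) <= 5 * np.sqrt(expected)


class TestShortReadEvidence:
    def test_no_dropout_covers_every_junction(self):
        cfg = SimulationConfig(n_genes=8, sr_junction_dropout=0.0, seed=10)
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        simulate_fl_counts(truth, cfg)
        coverage, _ = simulate_sr_evidence(truth, cfg)
        for r in truth:
            ci = coverage[r.isoform.transcript_id]
            assert ci.intervals == ((0, r.isoform.exonic_length),)

    def test_per_locus_cap_of_one(self):
        cfg = SimulationConfig(n_genes=8, sr_max_isoforms_per_locus=1, seed=12)
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        simulate_fl_counts(truth, cfg)
        _, detected = simulate_sr_evidence(truth, cfg)
        per_gene = {}
        for r in truth:
            if r.isoform.transcript_id in detected:
                per_gene[r.gene_id] = per_gene.get(r.gene_id, 0) + 1
        assert set(per_gene.values()) == {1}

    def test_detected_set_is_subset_of_truth(self, simulated):
        ids = {r.isoform.transcript_id for r in simulated["truth"]}
        assert simulated["sr_detected"] <= ids

    def test_dropout_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(n_genes=60, sr_junction_dropout=0.3, seed=14)
        _, ann = generate_genome_and_annotation(cfg)
        truth = simulate_isoform_truth(ann, cfg)
        simulate_fl_counts(truth, cfg)
        coverage, _ = simulate_sr_evidence(truth, cfg)
        n = dropped = 0
        for r in truth:
            tx = r.isoform
            ci = coverage[tx.transcript_id]
            for j in tx.junction_positions():
                n += 1
                dropped += not ci.covers(j - 1, j + 1)
        lo, hi = stats.binom.interval(0.99, n, 0.3)
        assert lo <= dropped <= hi


class TestParalogs:
    def test_full_identity_copies_exons_exactly(self):
        cfg = SimulationConfig(seed=16)
        genome, ann = simulate_paralogs(cfg, identity=1.0)
        t1, t2 = ann.transcripts["PARA1.c"], ann.transcripts["PARA2.c"]
        assert transcript_sequence(genome, t1) == transcript_sequence(genome, t2)
        assert t1.gene_id != t2.gene_id

    def test_target_identity_achieved(self):
        cfg = SimulationConfig(seed=18)
        genome, ann = simulate_paralogs(cfg, identity=0.78)
        s1 = transcript_sequence(genome, ann.transcripts["PARA1.c"])
        s2 = transcript_sequence(genome, ann.transcripts["PARA2.c"])
        assert len(s1) == len(s2)
        identity = sum(a == b for a, b in zip(s1, s2)) / len(s1)
        assert abs(identity - 0.78) <= 0.01

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_paralogs(SimulationConfig(seed=0), identity=0.3)


class TestPeptideObservations:
    PROTEINS = {"p1": "MKAAAAAAAR" * 5, "p2": "MLLLLLLLKGGGGGGGR" * 3}

    def test_full_detection_observes_every_long_peptide(self):
        obs = simulate_peptide_observations(self.PROTEINS, 1.0, seed=1)
        expected = sum(
            1
            for prot in self.PROTEINS.values()
            for p in tryptic_digest(prot)
            if len(p.seq) >= 7
        )
        assert len(obs) == expected

    def test_zero_detection_observes_nothing(self):
        assert len(simulate_peptide_observations(self.PROTEINS, 0.0, seed=1)) == 0

    def test_observed_fraction_within_binomial_ci(self):
        proteins = {f"p{i}": "MKAAAAAAAR" * 20 for i in range(20)}
        obs = simulate_peptide_observations(proteins, 0.4, seed=3)
        n = sum(
            1 for prot in proteins.values() for p in tryptic_digest(prot) if len(p.seq) >= 7
        )
        lo, hi = stats.binom.interval(0.99, n, 0.4)
        assert lo <= len(obs) <= hi
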