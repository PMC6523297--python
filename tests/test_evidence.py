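"""Junction coverage, replicate recurrence, TSS matching, peptide evidence."""

import pandas as pd
import pytest

from isokit.collapse import assign_master_ids, collapse_to_longest
from isokit.evidence import (
    CoverageIntervals,
    confirm_junction_coverage,
    confirmation_summary,
    cross_sample_confirm,
    match_observed_peptides,
    tss_match,
)
from isokit.models import TranscriptModel, chain_key


def tx(exons, strand="+", tid="iso"):
    return TranscriptModel(tid, "g", "chr1", strand, tuple(exons))


# transcript with one junction at transcript position 150
TWO_EXON = tx([(0, 150), (250, 400)])


class TestJunctionCoverage:
    def test_gapless_window_confirms(self):
        cov = CoverageIntervals("m", ((90, 210),))
        flags = confirm_junction_coverage(TWO_EXON, cov, half_window=50)
        assert [f.confirmed for f in flags] == [True]

    def test_two_nt_gap_breaks_confirmation(self):
        cov = CoverageIntervals("m", ((90, 149), (151, 210)))
        flags = confirm_junction_coverage(TWO_EXON, cov, half_window=50)
        assert [f.confirmed for f in flags] == [False]

    def test_window_clipped_at_transcript_ends_flagged_partial(self):
        short = tx([(0, 30), (100, 140)])  # junction at 30, window would start at -20
        cov = CoverageIntervals("m", ((0, 70),))
        flags = confirm_junction_coverage(short, cov, half_window=50)
        assert flags[0].partial_window and flags[0].confirmed

    def test_adding_coverage_never_unconfirms(self):
        base = CoverageIntervals("m", ((100, 200),))
        more = CoverageIntervals("m", ((100, 200), (0, 100)))
        f1 = confirm_junction_coverage(TWO_EXON, base, 50)
        f2 = confirm_junction_coverage(TWO_EXON, more, 50)
        for a, b in zip(f1, f2):
            assert b.confirmed >= a.confirmed

    def test_intervals_are_merged_and_validated(self):
        ci = CoverageIntervals("m", ((0, 10), (10, 20), (5, 12)))
        assert ci.intervals == ((0, 20),)
        with pytest.raises(ValueError):
            CoverageIntervals("m", ((5, 5),))


class TestCrossSample:
    def test_chain_found_in_replicate(self):
        iso = tx([(0, 100), (200, 300)])
        replicate = collapse_to_longest([tx([(10, 100), (200, 290)], tid="r")], [1])
        registry = assign_master_ids([replicate])
        assert cross_sample_confirm(iso, [registry])

    def test_chain_absent_from_replicates(self):
        iso = tx([(0, 100), (210, 300)])
        replicate = collapse_to_longest([tx([(0, 100), (200, 300)], tid="r")], [1])
        registry = assign_master_ids([replicate])
        assert not cross_sample_confirm(iso, [registry])

    def test_agrees_with_brute_force_chain_search(self, simulated):
        truth = simulated["truth"]
        models = [r.isoform for r in truth[::2]]
        registry = {chain_key(m): m.transcript_id for m in models}
        chains = {chain_key(m) for m in models}
        for r in truth:
            assert cross_sample_confirm(r.isoform, [registry]) == (
                chain_key(r.isoform) in chains
            )


class TestTssMatch:
    def test_within_tolerance(self):
        assert tss_match(tx([(1030, 1200)]), [1000], tolerance=50)

    def test_beyond_tolerance(self):
        assert not tss_match(tx([(1080, 1200)]), [1000], tolerance=50)

    def test_minus_strand_uses_chain_maximum(self):
        iso = tx([(500, 600), (900, 1010)], strand="-")
        assert tss_match(iso, [1000], tolerance=50)
        assert not tss_match(iso, [520], tolerance=50)

    def test_empty_tss_set_is_false(self):
        assert not tss_match(tx([(0, 10)]), [], tolerance=50)


class TestPeptideMatching:
    DIGESTS = {"iso1": {"LQRSTK", "MKAAAR"}, "iso2": {"GGGGGGK"}}
    SIGNATURES = {"iso1": {"LQRSTK"}}

    def test_signature_peptide_confirms_signature(self):
        df = match_observed_peptides(["LQRSTK"], self.DIGESTS, self.SIGNATURES)
        row = df.set_index("isoform_id").loc["iso1"]
        assert row["peptide_confirmed"] and row["signature_confirmed"]

    def test_shared_peptide_confirms_without_signature(self):
        df = match_observed_peptides(["MKAAAR"], self.DIGESTS, self.SIGNATURES)
        row = df.set_index("isoform_id").loc["iso1"]
        assert row["peptide_confirmed"] and not row["signature_confirmed"]

    def test_isoleucine_leucine_distinct(self):
        df = match_observed_peptides(["LQRSTK".replace("L", "I")], self.DIGESTS)
        assert not df.set_index("isoform_id").loc["iso1"]["peptide_confirmed"]


class TestSummary:
    def make_reports(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "isoform_id", "novel", "junctions_total",
                "junctions_confirmed", "cross_sample_confirmed",
            ],
        )

    def test_three_of_four_confirmed(self):
        df = self.make_reports(
            [
                ("a", True, 2, 2, False),
                ("b", True, 2, 1, True),
                ("c", True, 3, 3, False),
                ("d", True, 2, 0, False),
            ]
        )
        assert confirmation_summary(df)["fraction_confirmed"] == 0.75

    def test_no_novel_isoforms_reports_one_with_note(self):
        df = self.make_reports([("a", False, 2, 2, False)])
        out = confirmation_summary(df)
        assert out["fraction_confirmed"] == 1.0 and "note" in out

    def test_matches_hand_count_on_fixture(self):
        rows = [
            (f"i{k}", True, 3, 3 if k % 2 else 1, k % 3 == 0) for k in range(10)
        ]
        df = self.make_reports(rows)
        expected = sum(1 for k in range(10) if (k % 2) or (k % 3 == 0)) / 10
        assert confirmation_summary(df)["fraction_confirmed"] == expected
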