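"""Score isoforms against reference annotation and classify splice events.

The 0-5 agreement score grades how well an isoform's splice structure
matches its best annotated transcript:

* 5 — identical intron chain and both terminal ends within tolerance;
* 4 — identical intron chain, terminal ends differ beyond tolerance;
* 3 — every isoform splice site is annotated but the intron set differs
  (novel combinations of known junctions, e.g. exon skipping);
* 2 — at least one shared intron plus at least one unannotated splice site;
* 1 — exonic overlap only, no shared introns;
* 0 — no same-strand exonic overlap at the locus.

Scores of 2 or greater are conventionally treated as acceptable matches
with interpretable alternative splicing; 0-1 are poor matches.

Event classification compares an isoform with one reference transcript and
labels each structural difference: exon skipping, exon splitting,
alternative donor/acceptor sites, intron retention, novel exons, novel
junctions and terminal-end variation. Donor and acceptor are strand-aware:
the donor is the transcription-downstream edge of the upstream exon (on
'+' an exon end; on '-' an exon start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .models import GenomeAnnotation, TranscriptModel, _exonic_overlap, intron_chain

EXON_SKIPPING = "exon_skipping"
EXON_SPLITTING = "exon_splitting"
ALT_DONOR = "alt_donor"
ALT_ACCEPTOR = "alt_acceptor"
INTRON_RETENTION = "intron_retention"
NOVEL_EXON = "novel_exon"
NOVEL_JUNCTION = "novel_junction"
TERMINAL_5 = "terminal_5_variation"
TERMINAL_3 = "terminal_3_variation"

EVENT_LABELS = (
    EXON_SKIPPING, EXON_SPLITTING, ALT_DONOR, ALT_ACCEPTOR,
    INTRON_RETENTION, NOVEL_EXON, NOVEL_JUNCTION, TERMINAL_5, TERMINAL_3,
)


@dataclass(frozen=True)
class MatchResult:
    isoform_id: str
    best_ref: Optional[str]
    score: int
    shared_intron_count: int


@dataclass
class EventClassification:
    events: Set[str] = field(default_factory=set)
    intron_labels: Dict[Tuple[int, int], str] = field(default_factory=dict)

    def __contains__(self, label: str) -> bool:
        return label in self.events


def _score_against(
    iso: TranscriptModel, ref: TranscriptModel, end_tolerance: int
) -> Tuple[int, int]:
    """Return (score, shared_intron_count) of ``iso`` against one reference."""
    overlap = _exonic_overlap(iso, ref)
    if overlap == 0 or iso.strand != ref.strand:
        return 0, 0

    iso_introns, ref_introns = set(iso.introns), set(ref.introns)
    shared = len(iso_introns & ref_introns)

    if len(iso.exons) == 1:
        # Monoexonic: graded by containment within the reference exonic span.
        contained = overlap / iso.exonic_length
        return (4 if contained >= 0.90 else 1), shared

    if iso.introns == ref.introns:
        d5 = abs(iso.five_prime_end - ref.five_prime_end)
        d3 = abs(iso.three_prime_end - ref.three_prime_end)
        return (5 if d5 < end_tolerance and d3 < end_tolerance else 4), shared

    ref_donors, ref_acceptors = set(ref.donor_sites()), set(ref.acceptor_sites())
    all_known = all(d in ref_donors for d in iso.donor_sites()) and all(
        a in ref_acceptors for a in iso.acceptor_sites()
    )
    if all_known:
        return 3, shared
    if shared >= 1:
        return 2, shared
    return 1, shared


def best_reference_match(
    isoform: TranscriptModel,
    annotation: GenomeAnnotation,
    end_tolerance: int = 50,
) -> MatchResult:
    """Find the annotated transcript that best matches an isoform.

    Every same-strand overlapping reference is scored; ties are broken by
    shared intron count, then by reference exonic length, then by id.
    An isoform overlapping no annotated transcript scores 0 with no match.
    """
    best: Optional[Tuple[int, int, int, str]] = None
    best_ref: Optional[str] = None
    for ref in annotation.overlapping(isoform):
        score, shared = _score_against(isoform, ref, end_tolerance)
        # higher score, more shared introns, longer reference; id breaks ties
        cand = (score, shared, ref.exonic_length, ref.transcript_id)
        if best is None or (cand[0], cand[1], cand[2]) > (best[0], best[1], best[2]) or (
            (cand[0], cand[1], cand[2]) == (best[0], best[1], best[2])
            and cand[3] < best[3]
        ):
            best = cand
            best_ref = ref.transcript_id
    if best is None:
        return MatchResult(isoform.transcript_id, None, 0, 0)
    return MatchResult(isoform.transcript_id, best_ref, best[0], best[1])


def classify_events(
    isoform: TranscriptModel,
    ref: TranscriptModel,
    end_tolerance: int = 50,
) -> EventClassification:
    """Label the splice events distinguishing an isoform from a reference.

    Intron-level decision order (first matching rule wins):

    1. intron present in the reference -> no label;
    2. intron strictly inside one reference exon -> exon_splitting;
    3. donor annotated, acceptor novel -> alt_acceptor;
    4. acceptor annotated, donor novel -> alt_donor;
    5. both sites annotated, pair novel, encloses >= 1 whole reference
       exon -> exon_skipping;
    6. both sites annotated, pair novel, nothing enclosed -> novel_junction;
    7. both sites novel -> novel_junction.

    Introns flanking a novel exon (an isoform exon with zero reference-exon
    overlap) are attributed to that exon and receive no intron-level label.
    Reference introns wholly inside one isoform exon add intron_retention;
    terminal-end shifts beyond ``end_tolerance`` add strand-aware
    terminal_5/terminal_3 variation labels.
    """
    if isoform.strand != ref.strand:
        raise ValueError(
            f"strand mismatch: {isoform.transcript_id} ({isoform.strand}) vs "
            f"{ref.transcript_id} ({ref.strand})"
        )
    result = EventClassification()
    ref_intron_set = set(ref.introns)
    ref_donors, ref_acceptors = set(ref.donor_sites()), set(ref.acceptor_sites())

    # Novel exons first: their flanking introns are explained by the exon.
    novel_exons = [
        e for e in isoform.exons
        if all(min(e[1], rb) - max(e[0], ra) <= 0 for ra, rb in ref.exons)
    ]
    if novel_exons:
        result.events.add(NOVEL_EXON)
    novel_exon_edges = {x for e in novel_exons for x in e}

    plus = isoform.strand == "+"
    for a, b in isoform.introns:
        if (a, b) in ref_intron_set:
            continue
        if a in novel_exon_edges or b in novel_exon_edges:
            continue
        donor, acceptor = (a, b) if plus else (b, a)
        if any(ra < a and b < rb for ra, rb in ref.exons):
            label = EXON_SPLITTING
        else:
            donor_known = donor in ref_donors
            acceptor_known = acceptor in ref_acceptors
            if donor_known and not acceptor_known:
                label = ALT_ACCEPTOR
            elif acceptor_known and not donor_known:
                label = ALT_DONOR
            elif donor_known and acceptor_known:
                encloses = any(a <= ra and rb <= b for ra, rb in ref.exons)
                label = EXON_SKIPPING if encloses else NOVEL_JUNCTION
            else:
                label = NOVEL_JUNCTION
        result.intron_labels[(a, b)] = label
        result.events.add(label)

    for ra, rb in ref.introns:
        if any(ea <= ra and rb <= eb for ea, eb in isoform.exons):
            result.events.add(INTRON_RETENTION)

    # "within tolerance" is strict, matching the score-5 criterion
    if abs(isoform.five_prime_end - ref.five_prime_end) >= end_tolerance:
        result.events.add(TERMINAL_5)
    if abs(isoform.three_prime_end - ref.three_prime_end) >= end_tolerance:
        result.events.add(TERMINAL_3)
    return result


def assign_label(
    population: str,
    index: int,
    orf_status: str,
    orf_id: Optional[str] = None,
) -> str:
    """Compose the display name of an isoform.

    ``<pop><index>-C`` for a canonical transcript with the canonical ORF,
    ``<pop><index>-C*`` for a novel transcript still encoding the canonical
    protein, and ``<pop><index>-<orf_id>`` for a novel ORF.
    """
    if orf_status == "C":
        suffix = "C"
    elif orf_status == "C*":
        suffix = "C*"
    else:
        if orf_id is None:
            raise ValueError("novel ORF requires an orf_id for the label")
        suffix = str(orf_id)
    return f"{population}{index}-{suffix}"
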