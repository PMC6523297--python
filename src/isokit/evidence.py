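"""Orthogonal confirmation of novel isoforms.

Four independent lines of evidence are modeled: (i) short-read junction
support — every novel junction must be covered gaplessly across a
100-nt window centered on the junction; (ii) recurrence of the identical
intron chain in replicate full-length libraries; (iii) agreement of the
strand-aware 5' end with an annotated transcription start site; and
(iv) detection of predicted tryptic peptides by mass spectrometry. An
isoform counts as confirmed when all its novel junctions have coverage
support OR its chain recurs in a replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .models import TranscriptModel, chain_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageIntervals:
    """Disjoint sorted coverage intervals in transcript coordinates."""

    master_id: str
    intervals: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        merged: List[List[int]] = []
        for a, b in sorted((int(a), int(b)) for a, b in self.intervals):
            if a < 0 or b <= a:
                raise ValueError(f"invalid coverage interval ({a}, {b})")
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        object.__setattr__(self, "intervals", tuple((a, b) for a, b in merged))

    def covers(self, start: int, end: int) -> bool:
        """True iff [start, end) is contained in a single coverage interval."""
        return any(a <= start and end <= b for a, b in self.intervals)


@dataclass(frozen=True)
class JunctionSupport:
    position: int
    confirmed: bool
    partial_window: bool


def confirm_junction_coverage(
    isoform: TranscriptModel,
    coverage: CoverageIntervals,
    half_window: int = 50,
) -> List[JunctionSupport]:
    """Check gapless coverage of a +/- half_window window at each junction.

    A junction at transcript position j is confirmed iff
    [j - half_window, j + half_window) is fully covered with zero gaps.
    Windows that would extend past the transcript ends are shrunk to the
    transcript bounds and flagged partial.
    """
    length = isoform.exonic_length
    out = []
    for j in isoform.junction_positions():
        lo, hi = j - half_window, j + half_window
        partial = lo < 0 or hi > length
        lo, hi = max(0, lo), min(length, hi)
        out.append(JunctionSupport(j, coverage.covers(lo, hi), partial))
    return out


def cross_sample_confirm(
    isoform: TranscriptModel, replicate_registries: Sequence[Mapping[tuple, str]]
) -> bool:
    """True iff the identical intron chain occurs in any replicate registry."""
    key = chain_key(isoform)
    return any(key in reg for reg in replicate_registries)


def tss_match(
    isoform: TranscriptModel,
    reference_tss: Iterable[int],
    tolerance: int = 50,
) -> bool:
    """True iff the strand-aware 5' end lies within ``tolerance`` of a TSS."""
    tss = list(reference_tss)
    if not tss:
        logger.warning("empty reference TSS set for %s", isoform.transcript_id)
        return False
    five = isoform.five_prime_end
    return min(abs(five - t) for t in tss) <= tolerance


def match_observed_peptides(
    observed: Iterable[str],
    predicted_digests: Mapping[str, Set[str]],
    signature_sets: Optional[Mapping[str, Set[str]]] = None,
) -> pd.DataFrame:
    """Match observed peptides (exact string, I/L distinct) to isoform digests."""
    obs = set(observed)
    rows = []
    for iso_id in sorted(predicted_digests):
        hits = obs & predicted_digests[iso_id]
        sig_hits = obs & signature_sets.get(iso_id, set()) if signature_sets else set()
        rows.append(
            {
                "isoform_id": iso_id,
                "n_matched": len(hits),
                "peptide_confirmed": len(hits) > 0,
                "signature_confirmed": len(sig_hits) > 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["isoform_id", "n_matched", "peptide_confirmed", "signature_confirmed"]
    )


def confirmation_summary(reports: pd.DataFrame) -> Dict[str, object]:
    """Cohort-level confirmed fraction over novel isoforms.

    ``reports`` needs columns: isoform_id, novel (bool), junctions_total,
    junctions_confirmed, cross_sample_confirmed. An isoform is confirmed
    when all its novel junctions are coverage-confirmed OR its chain recurs
    in a replicate library (disjunctive rule).
    """
    if len(reports) == 0:
        raise ValueError("no isoforms to summarize")
    novel = reports[reports["novel"]]
    if len(novel) == 0:
        return {"n_novel": 0, "n_confirmed": 0, "fraction_confirmed": 1.0,
                "note": "no novel isoforms"}
    coverage_ok = novel["junctions_confirmed"] >= novel["junctions_total"]
    confirmed = coverage_ok | novel["cross_sample_confirmed"].astype(bool)
    n_conf = int(confirmed.sum())
    return {
        "n_novel": int(len(novel)),
        "n_confirmed": n_conf,
        "fraction_confirmed": n_conf / len(novel),
    }
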