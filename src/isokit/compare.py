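"""Isoform-composition comparison between populations and trend statistics.

Two questions are addressed. First, which isoforms are shared between cell
populations and which are population-specific (composition sets). Second,
does the number of isoforms detected per locus grow with locus complexity
(canonical exon count)? Loci are binned by canonical exon count, the mean
of the top-k isoform counts per bin is taken, and a Cochran-Armitage
chi-square test for trend compares two detection methods or conditions
across the ordered bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TrendResult:
    z_statistic: float
    chi_square: float
    p_value: float


def composition_sets(
    membership: Mapping[str, Mapping[str, Set[str]]]
) -> pd.DataFrame:
    """Partition per-locus isoform sets into shared and population-specific.

    ``membership`` maps population -> locus -> set of master IDs. An isoform
    is specific when present in exactly one population and shared when
    present in two or more. Per locus the specific sets plus the shared set
    partition the union of isoforms at that locus.
    """
    pops = sorted(membership)
    loci = sorted({loc for m in membership.values() for loc in m})
    rows = []
    for loc in loci:
        present: Dict[str, Set[str]] = {p: set(membership[p].get(loc, set())) for p in pops}
        union: Set[str] = set().union(*present.values()) if present else set()
        shared = {m for m in union if sum(m in present[p] for p in pops) >= 2}
        row: Dict[str, object] = {"locus": loc, "n_total": len(union),
                                  "shared": tuple(sorted(shared))}
        for p in pops:
            row[f"{p}_only"] = tuple(sorted(present[p] - shared))
        rows.append(row)
    return pd.DataFrame(rows)


def bin_top_k_mean(locus_table: pd.DataFrame, k: int = 5) -> pd.Series:
    """Mean of the k largest per-locus isoform counts within each exon-count bin.

    ``locus_table`` needs columns ``exon_count`` and ``isoform_count``; bins
    are the integer canonical exon counts (width 1), empty bins omitted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(locus_table) == 0:
        raise ValueError("empty locus table")
    return (
        locus_table.groupby("exon_count")["isoform_count"]
        .apply(lambda s: float(s.nlargest(k).mean()))
        .sort_index()
    )


def trend_test(
    table: Sequence[Sequence[float]],
    scores: Optional[Sequence[float]] = None,
) -> TrendResult:
    """Cochran-Armitage chi-square test for trend on a 2 x k count table.

    Rows are the two conditions (e.g. full-length vs short-read detection),
    columns the ordered exon-count bins, ``scores`` the bin scores (default:
    1..k, or pass the exon counts themselves). The statistic conditions on
    all margins (hypergeometric null):

        T = sum_j s_j n_1j,  Var(T) = R1 R2 [N sum c_j s_j^2 - (sum c_j s_j)^2]
                                      / (N^2 (N - 1))

    z = (T - E[T]) / sqrt(Var); chi_square = z^2; two-sided p from the
    standard normal. Positive z means row 1 is shifted toward higher scores.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError("trend test requires a 2 x k table with k >= 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row margin is zero")
    if (arr.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a column margin is zero")
    k = arr.shape[1]
    s = np.arange(1, k + 1, dtype=float) if scores is None else np.asarray(scores, float)
    if s.shape != (k,):
        raise ValueError("scores length must equal the number of bins")

    n1 = arr[0]
    c = arr.sum(axis=0)
    N = arr.sum()
    r1, r2 = arr[0].sum(), arr[1].sum()
    t = float(np.dot(s, n1))
    expect = r1 / N * float(np.dot(s, c))
    var = r1 * r2 * (N * float(np.dot(c, s**2)) - float(np.dot(c, s)) ** 2) / (
        N**2 * (N - 1)
    )
    if var <= 0:
        return TrendResult(0.0, 0.0, 1.0)
    z = (t - expect) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(float(z), float(z * z), float(min(p, 1.0)))


def mapping_fraction_by_exon_threshold(
    isoform_table: pd.DataFrame, threshold: int
) -> float:
    """Fraction of isoforms whose locus has >= threshold canonical exons.

    ``isoform_table`` needs one row per isoform with a ``locus_exon_count``
    column.
    """
    if len(isoform_table) == 0:
        return 0.0
    return float((isoform_table["locus_exon_count"] >= threshold).mean())
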