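"""Taxon-resolved coverage, non-coverage and terminal-mismatch tables.

A sequence is predicted amplifiable by a primer pair when both primers
find a site at or below the score threshold, neither site is truncated,
and the forward site lies 5' of the reverse site on the plus strand.
Coverage of a taxon is the percentage of its sequences predicted
amplifiable; non-coverage is the complement.  Records that do not span
the primer locus (truncated sites) are excluded from the denominator by
default — a database fragment says nothing about whether the primer
would bind the full gene — or counted as misses when the scoring config
sets ``count_truncated_as_miss``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import pandas as pd

from .records import ReferenceRecord, rank_index, UNCLASSIFIED
from .scoring import PrimerHit, ScoringConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageRow",
    "sequence_amplifiable",
    "coverage_by_taxon",
    "last_base_mismatch_fraction",
    "compare_methods",
    "coverage_table",
]


@dataclass
class CoverageRow:
    """Per-taxon aggregation of primer-pair (or single-primer) hits."""

    taxon: str
    rank: str
    primer_or_pair: str
    n_total: int
    n_hit: int
    coverage_pct: float
    non_coverage_pct: float
    last_base_mm_pct: float
    method: str


def sequence_amplifiable(
    fwd_hit: PrimerHit,
    rev_hit: PrimerHit | None,
    config: ScoringConfig | None = None,
) -> bool:
    """Would this record amplify with the pair under the configured method?

    With ``rev_hit`` None the test degenerates to single-primer binding
    (threshold and truncation only).
    """
    config = config or ScoringConfig()
    if rev_hit is not None and fwd_hit.record_id != rev_hit.record_id:
        raise ValueError(
            f"hit pair spans different records: "
            f"{fwd_hit.record_id!r} vs {rev_hit.record_id!r}"
        )
    if fwd_hit.truncated or fwd_hit.score(config) > config.hit_threshold:
        return False
    if rev_hit is None:
        return True
    if rev_hit.truncated or rev_hit.score(config) > config.hit_threshold:
        return False
    return fwd_hit.end < rev_hit.start


def _pair_label(fwd: PrimerHit, rev: PrimerHit | None) -> str:
    return fwd.primer_name if rev is None else f"{fwd.primer_name}/{rev.primer_name}"


def _is_truncated(fwd: PrimerHit, rev: PrimerHit | None) -> bool:
    return fwd.truncated or (rev is not None and rev.truncated)


def coverage_by_taxon(
    hits: Sequence[tuple[PrimerHit, PrimerHit | None]],
    records: Sequence[ReferenceRecord],
    rank: str,
    config: ScoringConfig | None = None,
) -> list[CoverageRow]:
    """Aggregate per-record hit pairs into one coverage row per taxon.

    ``hits`` is parallel to ``records`` (one (forward, reverse-or-None)
    tuple per record).  Rows are sorted by descending ``n_total``; taxa
    with an empty denominator are omitted; records lacking taxonomy at
    the requested rank fall into the Unclassified bucket.
    """
    config = config or ScoringConfig()
    if len(hits) != len(records):
        raise ValueError(f"{len(hits)} hit pairs for {len(records)} records")
    ridx = rank_index(rank)
    if records and not any(len(r.taxonomy) > ridx for r in records):
        logger.warning("no record has taxonomy at rank %r; empty coverage table", rank)
        return []
    agg: dict[str, list[int]] = {}  # taxon -> [n_total, n_hit, n_last_mm]
    label = None
    for (fwd, rev), rec in zip(hits, records):
        if fwd.record_id != rec.id:
            raise ValueError(f"hit/record order mismatch at {rec.id!r}")
        label = label or _pair_label(fwd, rev)
        truncated = _is_truncated(fwd, rev)
        if truncated and not config.count_truncated_as_miss:
            continue
        taxon = rec.taxon_at(ridx)
        entry = agg.setdefault(taxon, [0, 0, 0])
        entry[0] += 1
        if not truncated and sequence_amplifiable(fwd, rev, config):
            entry[1] += 1
        if not truncated and (
            fwd.last_base_mismatch or (rev is not None and rev.last_base_mismatch)
        ):
            entry[2] += 1
    rows = []
    for taxon, (n_total, n_hit, n_last) in agg.items():
        cov = 100.0 * n_hit / n_total
        rows.append(
            CoverageRow(
                taxon=taxon,
                rank=rank,
                primer_or_pair=label or "",
                n_total=n_total,
                n_hit=n_hit,
                coverage_pct=cov,
                non_coverage_pct=100.0 - cov,
                last_base_mm_pct=100.0 * n_last / n_total,
                method=config.method,
            )
        )
    rows.sort(key=lambda r: (-r.n_total, r.taxon))
    return rows


def coverage_table(rows: Iterable[CoverageRow]) -> pd.DataFrame:
    """CoverageRows as a DataFrame (column order fixed)."""
    return pd.DataFrame([asdict(r) for r in rows], columns=[
        "primer_or_pair", "method", "rank", "taxon", "n_total", "n_hit",
        "coverage_pct", "non_coverage_pct", "last_base_mm_pct",
    ])


def last_base_mismatch_fraction(
    hits: Iterable[PrimerHit],
    records: Sequence[ReferenceRecord],
    group_by: str = "domain",
) -> pd.DataFrame:
    """Percentage of sequences whose best site mismatches at the final
    3' base, per taxon at a rank.

    The denominator is the records with a non-truncated site; empty
    groups are omitted.
    """
    ridx = rank_index(group_by)
    agg: dict[str, list[int]] = {}
    for hit, rec in zip(hits, records):
        if hit.record_id != rec.id:
            raise ValueError(f"hit/record order mismatch at {rec.id!r}")
        if hit.truncated:
            continue
        entry = agg.setdefault(rec.taxon_at(ridx), [0, 0])
        entry[0] += 1
        if hit.last_base_mismatch:
            entry[1] += 1
    data = [
        {"taxon": t, "n": n, "last_base_mm_pct": 100.0 * k / n}
        for t, (n, k) in sorted(agg.items(), key=lambda kv: -kv[1][0])
    ]
    return pd.DataFrame(data, columns=["taxon", "n", "last_base_mm_pct"])


def compare_methods(
    hits: Sequence[tuple[PrimerHit, PrimerHit | None]],
    records: Sequence[ReferenceRecord],
    rank: str,
    config: ScoringConfig | None = None,
) -> pd.DataFrame:
    """Per-taxon non-coverage under the weighted and the tp method.

    With the default weights every defect the tp score counts costs the
    weighted method at least as much only in the 3' region; terminal-
    base mismatches in particular push the weighted score past the
    threshold while contributing just 1.0 to the tp score — the source
    of the two methods' divergence.
    """
    config = config or ScoringConfig()
    out: dict[str, dict] = {}
    for method in ("weighted", "tp"):
        for row in coverage_by_taxon(hits, records, rank, config.with_method(method)):
            rec = out.setdefault(row.taxon, {"taxon": row.taxon, "n_total": row.n_total})
            rec[f"non_coverage_{method}"] = row.non_coverage_pct
    df = pd.DataFrame(
        sorted(out.values(), key=lambda r: -r["n_total"]),
        columns=["taxon", "n_total", "non_coverage_weighted", "non_coverage_tp"],
    )
    return df
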