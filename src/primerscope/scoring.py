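"""Primer binding-site search and 3'-weighted mismatch scoring.

The central quantity is the weighted score of a primer/template
alignment,

    weighted = non3p_mm * 0.40 + 3p_mm * 1.00 + non3p_gap * 1.00
               + 3p_gap * 3.00  (+ 3.00 if the final 3' base mismatches)

which penalises defects near the primer's 3' end — where polymerase
extension starts — far more than defects elsewhere.  The position-blind
alternative (the "total primer mismatch" or tp score) counts every
mismatch and gap with unit weight and no terminal penalty.

:func:`align_primer` separates site *localization* from *scoring*, as
in-silico PCR tools do: the binding site is the alignment minimising the
unit cost (total mismatches plus gaps, at most ``max_gaps`` indels,
ties broken by lower weighted score and then by position), and both the
weighted and the tp score are then computed on that one alignment.
Localization cannot use the weighted score itself: non-3' mismatches
cost only 0.40, so over a long template some random off-target window
almost always out-scores a genuine binding site that carries a 3'
defect, which would corrupt terminal-base statistics.  Unit cost keeps
genuine sites (a few defects) well separated from background (about
three quarters of positions mismatching).

The search is a fast vectorised scan over every ungapped offset,
followed — only when an indel could still improve the optimum — by a
gap-budgeted semi-global dynamic program (primer global, template
local).  Both stages optimise the lexicographic (unit, weighted)
objective encoded as ``unit * _LEX + weighted``, exact because every
weighted score is far below ``_LEX``.  One hard rule: the 3'-terminal
primer base must anneal — no gap may absorb it — otherwise a terminal
deletion (3.00) would always undercut a terminal mismatch (4.00) and
the terminal penalty could never be observed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Iterator

import numpy as np

from .iupac import encode, reverse_complement
from .primers import Primer

if TYPE_CHECKING:  # pragma: no cover
    from .records import ReferenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringConfig",
    "PrimerHit",
    "weighted_score",
    "tp_score",
    "align_primer",
    "score_primer_against_set",
]

#: Template length at or above which a record is treated as a full-length
#: 16S gene, enabling the E.-coli-coordinate tie-break.
FULL_LENGTH_NT = 1200

#: Lexicographic encoding factor: combined cost = unit_cost * _LEX + weighted.
#: Any weighted score is bounded by primer_len * max weight + terminal
#: penalty << _LEX, so the combined minimum is the lexicographic minimum.
_LEX = 1024.0


@dataclass(frozen=True)
class ScoringConfig:
    """Weights, thresholds and search options for primer scoring.

    ``three_prime_len`` bases at the primer's 3' end form the 3' region
    (5 by convention).  ``hit_threshold`` is the largest score still
    counted as amplifiable; ``max_gaps`` bounds the number of indels the
    site search may introduce; ``method`` selects which score the
    coverage layer thresholds ("weighted" or "tp").
    """

    three_prime_len: int = 5
    w_non3p_mm: float = 0.40
    w_3p_mm: float = 1.00
    w_non3p_gap: float = 1.00
    w_3p_gap: float = 3.00
    terminal_penalty: float = 3.00
    hit_threshold: float = 1.0
    max_gaps: int = 2
    method: str = "weighted"
    count_truncated_as_miss: bool = False

    def __post_init__(self):
        for name in ("w_non3p_mm", "w_3p_mm", "w_non3p_gap", "w_3p_gap",
                     "terminal_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.three_prime_len < 0:
            raise ValueError("three_prime_len must be >= 0")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        if self.method not in ("weighted", "tp"):
            raise ValueError(f"method must be 'weighted' or 'tp', got {self.method!r}")

    def with_method(self, method: str) -> "ScoringConfig":
        return replace(self, method=method)


@dataclass
class PrimerHit:
    """Best binding site of one primer on one record.

    Mismatch/gap counts are split by primer region; ``start``/``end``
    are 1-based inclusive plus-strand coordinates of the site.  A
    ``truncated`` hit means the record cannot contain the primer locus
    (no valid site; scores are +inf, serialised as null).
    """

    primer_name: str
    record_id: str
    non3p_mismatches: int = 0
    threep_mismatches: int = 0
    non3p_gaps: int = 0
    threep_gaps: int = 0
    last_base_mismatch: bool = False
    weighted_score: float = math.inf
    tp_score: float = math.inf
    start: int = 0
    end: int = 0
    truncated: bool = False

    def score(self, config: ScoringConfig) -> float:
        """The score the configured method thresholds on."""
        return self.tp_score if config.method == "tp" else self.weighted_score


def weighted_score(
    non3p_mm: int,
    threep_mm: int,
    non3p_gap: int,
    threep_gap: int,
    last_base_mismatch: bool,
    config: ScoringConfig | None = None,
) -> float:
    """Positionally weighted penalty of an alignment's defect counts."""
    config = config or ScoringConfig()
    counts = (non3p_mm, threep_mm, non3p_gap, threep_gap)
    if any(c < 0 for c in counts):
        raise ValueError(f"defect counts must be non-negative, got {counts}")
    return round(
        non3p_mm * config.w_non3p_mm
        + threep_mm * config.w_3p_mm
        + non3p_gap * config.w_non3p_gap
        + threep_gap * config.w_3p_gap
        + (config.terminal_penalty if last_base_mismatch else 0.0),
        9,  # scores are short sums of 2-decimal weights; keep them canonical
    )


def tp_score(total_mismatches: int, total_gaps: int) -> float:
    """Unit-weight total of mismatches plus gaps (position-blind)."""
    if total_mismatches < 0 or total_gaps < 0:
        raise ValueError("defect counts must be non-negative")
    return round(float(total_mismatches + total_gaps), 9)


# ---------------------------------------------------------------------------
# site search


def _region_is_3p(j: int, m: int, l3: int) -> bool:
    """Is 1-based primer position j inside the 3' region (final l3 bases)?"""
    return j > m - l3


def _mm_cost(j: int, m: int, cfg: ScoringConfig) -> float:
    c = cfg.w_3p_mm if _region_is_3p(j, m, cfg.three_prime_len) else cfg.w_non3p_mm
    if j == m:
        c += cfg.terminal_penalty
    return c


def _del_cost(j: int, m: int, cfg: ScoringConfig) -> float:
    # gap aligned to primer base j; never triggers the terminal penalty
    return cfg.w_3p_gap if _region_is_3p(j, m, cfg.three_prime_len) else cfg.w_non3p_gap


def _ins_cost(j: int, m: int, cfg: ScoringConfig) -> float:
    # template base inserted between primer positions j and j+1
    return cfg.w_3p_gap if _region_is_3p(j + 1, m, cfg.three_prime_len) else cfg.w_non3p_gap


def _no_site_hit(primer: Primer, record_id: str) -> PrimerHit:
    return PrimerHit(primer_name=primer.name, record_id=record_id, truncated=True)


def _ungapped_scan(penc: np.ndarray, tenc: np.ndarray, cfg: ScoringConfig):
    """Combined (unit, weighted) cost of every ungapped offset (vectorised).

    Returns (combined costs over offsets, per-offset mismatch counts).
    """
    m, n = len(penc), len(tenc)
    k = n - m + 1
    costs = np.zeros(k)
    counts = np.zeros(k)
    for j in range(1, m + 1):
        mm = (tenc[j - 1 : j - 1 + k] & ~penc[j - 1]) != 0
        costs += mm * (_LEX + _mm_cost(j, m, cfg))
        counts += mm
    return costs, counts


def _pick_offset(candidates: np.ndarray, expected_start: int | None) -> int:
    """Tie-break equal-score offsets: nearest to the expected E. coli
    start when known (full-length template), else leftmost."""
    if expected_start is not None:
        dist = np.abs(candidates - (expected_start - 1))
        candidates = candidates[dist == dist.min()]
    return int(candidates[0])


def _counts_at_offset(penc, tenc, off, cfg):
    m = len(penc)
    l3 = cfg.three_prime_len
    non3p = threep = 0
    for j in range(1, m + 1):
        if tenc[off + j - 1] & ~penc[j - 1]:
            if _region_is_3p(j, m, l3):
                threep += 1
            else:
                non3p += 1
    last = bool(tenc[off + m - 1] & ~penc[m - 1])
    return non3p, threep, last


def _gapped_dp(penc: np.ndarray, tenc: np.ndarray, cfg: ScoringConfig):
    """Gap-budgeted semi-global DP; returns (best score, traceback info).

    State (g, j, i): first j primer bases aligned, last consumed template
    position i, g gaps used.  Leading/trailing template insertions are
    excluded (they are equivalent to shifting the site).
    """
    m, n = len(penc), len(tenc)
    G = cfg.max_gaps
    INF = math.inf
    sub = np.empty((m, n))  # sub[j-1, i-1]: cost of aligning primer j to template i
    for j in range(1, m + 1):
        mm = (tenc & ~penc[j - 1]) != 0
        sub[j - 1] = mm * (_LEX + _mm_cost(j, m, cfg))
    dp = np.full((G + 1, m + 1, n + 1), INF)
    dp[0, 0, :] = 0.0  # free start anywhere; gaps cannot precede the site
    for g in range(G + 1):
        for j in range(1, m + 1):
            row = dp[g, j]
            diag = dp[g, j - 1, :-1] + sub[j - 1]
            row[1:] = diag
            if g >= 1:
                # the 3'-terminal base must anneal: no gap may absorb it,
                # so deletions stop at j = m-1 and insertions are interior
                if j < m:
                    np.minimum(
                        row, dp[g - 1, j - 1, :] + (_LEX + _del_cost(j, m, cfg)),
                        out=row,
                    )
                    np.minimum(
                        row[1:], dp[g - 1, j, :-1] + (_LEX + _ins_cost(j, m, cfg)),
                        out=row[1:],
                    )
    return dp, sub


def _traceback(dp, sub, penc, tenc, cfg, g, i):
    """Recover defect counts and start coordinate of an optimal path."""
    m = len(penc)
    j = m
    non3p_mm = threep_mm = non3p_gap = threep_gap = 0
    last_mm = False
    while j > 0:
        v = dp[g, j, i]
        if i >= 1 and dp[g, j - 1, i - 1] + sub[j - 1, i - 1] == v:
            if tenc[i - 1] & ~penc[j - 1]:
                if _region_is_3p(j, m, cfg.three_prime_len):
                    threep_mm += 1
                else:
                    non3p_mm += 1
                if j == m:
                    last_mm = True
            i -= 1
            j -= 1
        elif g >= 1 and j < m and dp[g - 1, j - 1, i] + (_LEX + _del_cost(j, m, cfg)) == v:
            if _region_is_3p(j, m, cfg.three_prime_len):
                threep_gap += 1
            else:
                non3p_gap += 1
            g -= 1
            j -= 1
        elif g >= 1 and i >= 1 and j < m and dp[g - 1, j, i - 1] + (_LEX + _ins_cost(j, m, cfg)) == v:
            if _region_is_3p(j + 1, m, cfg.three_prime_len):
                threep_gap += 1
            else:
                non3p_gap += 1
            g -= 1
            i -= 1
        else:  # pragma: no cover - defensive; an optimal cell always has a parent
            raise AssertionError("traceback failed to find a predecessor")
    return non3p_mm, threep_mm, non3p_gap, threep_gap, last_mm, i + 1  # 1-based start


def _best_site(primer_seq: str, template: str, cfg: ScoringConfig,
               expected_start: int | None):
    """Best site of a forward-oriented primer sequence on a template.

    Minimises the lexicographic (unit cost, weighted score) objective.
    Returns (counts..., last_mm, weighted, start, end) in template
    coordinates (1-based inclusive), or None when no placement exists.
    """
    penc = encode(primer_seq, context="primer")
    tenc = encode(template)
    m, n = len(penc), len(tenc)
    if n < m:
        return None
    costs, _ = _ungapped_scan(penc, tenc, cfg)
    best_ungapped = float(costs.min())
    off = _pick_offset(np.flatnonzero(costs == best_ungapped), expected_start)
    # a gapped alignment carries at least one gap's combined cost, so the
    # DP can only help when the ungapped optimum exceeds that floor
    min_gap_w = _LEX + min(cfg.w_non3p_gap, cfg.w_3p_gap)
    use_dp = cfg.max_gaps >= 1 and best_ungapped > min_gap_w
    if use_dp:
        dp, sub = _gapped_dp(penc, tenc, cfg)
        finals = dp[:, m, :]  # (g, i)
        best_dp = float(finals.min())
        if best_dp < best_ungapped:
            gs, iis = np.nonzero(finals == best_dp)
            # prefer fewer gaps, then the end nearest the expected site
            order = np.lexsort((iis, gs))
            gs, iis = gs[order], iis[order]
            g0 = gs[0]
            iis = iis[gs == g0]
            if expected_start is not None:
                # expected end of the site given the gap count is uncertain
                # by +-g0; compare on start after traceback of the nearest few
                exp_end = expected_start - 1 + m
                dist = np.abs(iis - exp_end)
                iis = iis[dist == dist.min()]
            i0 = int(iis[0])
            n3mm, t3mm, n3g, t3g, last, start = _traceback(
                dp, sub, penc, tenc, cfg, int(g0), i0
            )
            score = weighted_score(n3mm, t3mm, n3g, t3g, last, cfg)
            return n3mm, t3mm, n3g, t3g, last, score, start, i0
    n3mm, t3mm, last = _counts_at_offset(penc, tenc, off, cfg)
    score = weighted_score(n3mm, t3mm, 0, 0, last, cfg)
    return n3mm, t3mm, 0, 0, last, score, off + 1, off + m


def align_primer(primer: Primer, template, config: ScoringConfig | None = None) -> PrimerHit:
    """Locate the primer's best binding site on one record.

    Reverse-orientation primers are scanned against the reverse
    complement of the template and the site coordinates are mapped back
    to the plus strand.  Deterministic: score ties are broken towards
    the primer's E. coli coordinates on full-length templates, else
    leftmost.  A template shorter than the primer yields a truncated
    non-hit with infinite scores.
    """
    config = config or ScoringConfig()
    record_id = getattr(template, "id", "<anonymous>")
    seq = getattr(template, "sequence", template)
    m = len(primer)
    if config.three_prime_len > m:
        raise ValueError(
            f"three_prime_len {config.three_prime_len} exceeds primer length {m}"
        )
    n = len(seq)
    if n < m:
        return _no_site_hit(primer, record_id)

    if primer.orientation == "reverse":
        scan_seq = reverse_complement(seq)
        # the planted/expected site start in rc coordinates
        expected = (n - primer.ecoli_end + 1) if n >= FULL_LENGTH_NT else None
    else:
        scan_seq = seq
        expected = primer.ecoli_start if n >= FULL_LENGTH_NT else None

    res = _best_site(primer.sequence, scan_seq, config, expected)
    if res is None:
        return _no_site_hit(primer, record_id)
    n3mm, t3mm, n3g, t3g, last, wscore, start, end = res
    if primer.orientation == "reverse":
        start, end = n - end + 1, n - start + 1
    return PrimerHit(
        primer_name=primer.name,
        record_id=record_id,
        non3p_mismatches=n3mm,
        threep_mismatches=t3mm,
        non3p_gaps=n3g,
        threep_gaps=t3g,
        last_base_mismatch=last,
        weighted_score=wscore,
        tp_score=tp_score(n3mm + t3mm, n3g + t3g),
        start=start,
        end=end,
        truncated=False,
    )


def score_primer_against_set(
    primer: Primer,
    records: Iterable["ReferenceRecord"],
    config: ScoringConfig | None = None,
    progress_every: int = 10_000,
    stats: dict | None = None,
) -> Iterator[PrimerHit]:
    """Score one primer against every record, in order.

    Unreadable records (invalid alphabet) are logged, skipped and
    tallied under ``stats["skipped"]`` when a stats dict is supplied.
    """
    config = config or ScoringConfig()
    n_done = 0
    skipped = 0
    for rec in records:
        try:
            hit = align_primer(primer, rec, config)
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping record %s: %s", getattr(rec, "id", "?"), exc)
            continue
        n_done += 1
        if progress_every and n_done % progress_every == 0:
            logger.info("%s: scored %d records", primer.name, n_done)
        yield hit
    if n_done == 0:
        logger.warning("%s: empty record set, no hits produced", primer.name)
    if stats is not None:
        stats["skipped"] = stats.get("skipped", 0) + skipped
        stats["scored"] = stats.get("scored", 0) + n_done
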