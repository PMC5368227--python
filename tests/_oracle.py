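"""Brute-force reference oracle for the binding-site search.

Enumerates every semi-global alignment of a primer against a template —
every start offset, every interleaving of up to ``max_gaps`` indels
(template insertions only strictly inside the primer span, and the
3'-terminal primer base always aligned to a template base) — and ranks
alignments by the same lexicographic objective the production search
uses: fewest mismatches-plus-gaps first, lowest weighted score second.
The weighted score comes from the public formula applied to the defect
counts.  Exponential, so only usable on toy sizes; intentionally shares
no code with the production dynamic program.
"""

import math

from primerscope import weighted_score
from primerscope.iupac import IUPAC_BASES


def _matches(primer_char: str, template_char: str) -> bool:
    return IUPAC_BASES[template_char] <= IUPAC_BASES[primer_char]


def oracle_best(primer: str, template: str, cfg) -> tuple[float, float]:
    """(unit cost, weighted score) of the best alignment, lexicographic.

    Returns (inf, inf) when no alignment exists.
    """
    m, n = len(primer), len(template)
    l3 = cfg.three_prime_len
    best = (math.inf, math.inf)

    def in_3p(j):  # 1-based primer position
        return j > m - l3

    def rec(j, i, gaps, n3mm, t3mm, n3g, t3g, last):
        nonlocal best
        if j == m:
            unit = n3mm + t3mm + n3g + t3g
            cand = (unit, weighted_score(n3mm, t3mm, n3g, t3g, last, cfg))
            if cand < best:
                best = cand
            return
        pos = j + 1  # primer position being placed next
        if i < n:  # align primer base to template base
            if _matches(primer[j], template[i]):
                rec(j + 1, i + 1, gaps, n3mm, t3mm, n3g, t3g, last)
            elif in_3p(pos):
                rec(j + 1, i + 1, gaps, n3mm, t3mm + 1, n3g, t3g,
                    last or pos == m)
            else:
                rec(j + 1, i + 1, gaps, n3mm + 1, t3mm, n3g, t3g, last)
        if gaps < cfg.max_gaps:
            # delete primer base `pos` (gap in template); the terminal 3'
            # base must anneal, so it can never be deleted
            if pos < m:
                if in_3p(pos):
                    rec(j + 1, i, gaps + 1, n3mm, t3mm, n3g, t3g + 1, last)
                else:
                    rec(j + 1, i, gaps + 1, n3mm, t3mm, n3g + 1, t3g, last)
            # insert template base between primer positions j and j+1
            if 1 <= j <= m - 1 and i < n:
                if in_3p(j + 1):
                    rec(j, i + 1, gaps + 1, n3mm, t3mm, n3g, t3g + 1, last)
                else:
                    rec(j, i + 1, gaps + 1, n3mm, t3mm, n3g + 1, t3g, last)

    for start in range(n + 1):
        rec(0, start, 0, 0, 0, 0, 0, False)
    return best
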