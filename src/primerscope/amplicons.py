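"""In-silico PCR: amplicon prediction and length distributions.

An amplicon spans the forward primer's 5' end through the plus-strand
image of the reverse primer's 5' end, both sites included, so its
length is the coordinate span of the two binding sites.  Length
histograms grouped by taxon expose length polymorphisms between the
primer sites — e.g. a taxon carrying an internal deletion produces a
second, shorter mode offset by exactly the deletion length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .coverage import sequence_amplifiable
from .primers import Primer
from .records import ReferenceRecord, rank_index
from .scoring import PrimerHit, ScoringConfig, align_primer

logger = logging.getLogger(__name__)

__all__ = ["Amplicon", "extract_amplicons", "extract_amplicons_from_set",
           "length_distribution", "write_amplicon_fasta", "write_lengths_tsv"]


@dataclass
class Amplicon:
    """One predicted PCR product on a reference record."""

    record_id: str
    start: int  # 1-based inclusive, plus strand, incl. forward site
    end: int  # 1-based inclusive, incl. reverse site
    length: int
    taxonomy: tuple[str, ...]
    sequence: str = ""
    fwd_hit: PrimerHit | None = None
    rev_hit: PrimerHit | None = None


def extract_amplicons(
    fwd: Primer,
    rev: Primer,
    record: ReferenceRecord,
    config: ScoringConfig | None = None,
) -> list[Amplicon]:
    """Predict the amplicon of one primer pair on one record.

    At most one amplicon is emitted (the best-scoring site pair); the
    list is empty when either primer misses the threshold, a site is
    truncated, or the sites overlap or are mis-ordered.
    """
    config = config or ScoringConfig()
    if fwd.orientation != "forward" or rev.orientation != "reverse":
        raise ValueError(
            f"pair {fwd.name}/{rev.name}: need forward+reverse orientations"
        )
    fhit = align_primer(fwd, record, config)
    rhit = align_primer(rev, record, config)
    if fhit.truncated or rhit.truncated:
        return []
    if fhit.score(config) > config.hit_threshold or rhit.score(config) > config.hit_threshold:
        return []
    if fhit.end >= rhit.start:
        logger.warning(
            "%s: overlapping or mis-ordered sites for %s/%s (fwd %d-%d, rev %d-%d)",
            record.id, fwd.name, rev.name, fhit.start, fhit.end, rhit.start, rhit.end,
        )
        return []
    start, end = fhit.start, rhit.end
    return [
        Amplicon(
            record_id=record.id,
            start=start,
            end=end,
            length=end - start + 1,
            taxonomy=record.taxonomy,
            sequence=record.sequence[start - 1 : end],
            fwd_hit=fhit,
            rev_hit=rhit,
        )
    ]


def extract_amplicons_from_set(
    fwd: Primer,
    rev: Primer,
    records: Iterable[ReferenceRecord],
    config: ScoringConfig | None = None,
) -> list[Amplicon]:
    """One best amplicon per record across a reference set."""
    out: list[Amplicon] = []
    for rec in records:
        out.extend(extract_amplicons(fwd, rev, rec, config))
    return out


def length_distribution(
    amplicons: Sequence[Amplicon],
    group_by: str = "phylum",
    bin_width: int = 1,
) -> pd.DataFrame:
    """Histogram of amplicon lengths per taxon.

    Returns (taxon, bin, count) rows where ``bin`` is the lower edge of
    a ``bin_width``-nt bin; binning conserves the total count.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    ridx = rank_index(group_by)
    rows = []
    for a in amplicons:
        taxon = a.taxonomy[ridx] if ridx < len(a.taxonomy) else "Unclassified"
        rows.append((taxon, (a.length // bin_width) * bin_width))
    if not rows:
        return pd.DataFrame(columns=["taxon", "bin", "count"])
    df = pd.DataFrame(rows, columns=["taxon", "bin"])
    out = df.value_counts(["taxon", "bin"]).reset_index(name="count")
    return out.sort_values(["taxon", "bin"]).reset_index(drop=True)


def modal_lengths(amplicons: Sequence[Amplicon], group_by: str = "phylum") -> pd.Series:
    """Most frequent amplicon length per taxon (ties -> shortest)."""
    dist = length_distribution(amplicons, group_by=group_by, bin_width=1)
    if dist.empty:
        return pd.Series(dtype=int)
    best = dist.sort_values(["count", "bin"], ascending=[False, True])
    return best.groupby("taxon", sort=True)["bin"].first()


def write_amplicon_fasta(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a in amplicons:
            fh.write(f">{a.record_id}|{a.start}-{a.end} {';'.join(a.taxonomy)}\n")
            for i in range(0, len(a.sequence), 70):
                fh.write(a.sequence[i : i + 70] + "\n")


def write_lengths_tsv(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\ttaxonomy\tlength\n")
        for a in amplicons:
            fh.write(f"{a.record_id}\t{';'.join(a.taxonomy)}\t{a.length}\n")
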