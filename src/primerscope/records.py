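"""Taxonomy-annotated reference records and their file formats.

Reference sets arrive either as FASTA with SILVA-style headers —
``>ID taxonomy;path;here`` where the description after the first
whitespace is a semicolon-delimited rank path — or as plain FASTA plus a
two-column taxonomy TSV (id, semicolon path).  Sequences are normalised
at ingest: uppercased, U converted to T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .iupac import clean_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceRecord",
    "read_reference_fasta",
    "read_taxonomy_tsv",
    "write_reference_fasta",
    "write_taxonomy_tsv",
]

UNCLASSIFIED = "Unclassified"


@dataclass
class ReferenceRecord:
    """One taxonomy-annotated nucleotide sequence under evaluation."""

    id: str
    sequence: str
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self):
        self.sequence = clean_sequence(self.sequence)
        self.taxonomy = tuple(t.strip() for t in self.taxonomy if t.strip())

    def taxon_at(self, rank_index: int) -> str:
        """Taxon name at a 0-based rank depth (0=domain, 1=phylum, ...)."""
        if rank_index < len(self.taxonomy):
            return self.taxonomy[rank_index]
        return UNCLASSIFIED

    @property
    def taxonomy_string(self) -> str:
        return ";".join(self.taxonomy)

    def __len__(self) -> int:
        return len(self.sequence)


#: Standard SILVA-style rank order used to translate rank names to depths.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def rank_index(rank: str) -> int:
    """Depth of a named rank in the SILVA-style rank order."""
    try:
        return RANKS.index(rank.lower())
    except ValueError:
        raise ValueError(
            f"unknown rank {rank!r}; expected one of {', '.join(RANKS)}"
        ) from None


def _parse_taxonomy(text: str) -> tuple[str, ...]:
    return tuple(t.strip() for t in text.split(";") if t.strip())


def read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column (id, semicolon-path) taxonomy TSV."""
    out: dict[str, tuple[str, ...]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        out[parts[0]] = _parse_taxonomy(parts[1])
    return out


def read_reference_fasta(
    fasta: str | Path,
    taxonomy: str | Path | None = None,
) -> list[ReferenceRecord]:
    """Load a reference set from FASTA, with taxonomy from headers or TSV.

    When a taxonomy TSV is given it takes precedence; otherwise the
    FASTA description after the first whitespace is parsed as a
    semicolon path.  Records with no taxonomy anywhere are kept and
    later reported under the Unclassified bucket.
    """
    tax_map = read_taxonomy_tsv(taxonomy) if taxonomy is not None else None
    records = []
    for i, rec in enumerate(SeqIO.parse(str(fasta), "fasta"), 1):
        if tax_map is not None:
            tax = tax_map.get(rec.id, ())
            if not tax:
                logger.warning("record %s absent from taxonomy TSV", rec.id)
        else:
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            tax = _parse_taxonomy(desc)
        try:
            records.append(ReferenceRecord(id=rec.id, sequence=str(rec.seq), taxonomy=tax))
        except ValueError as exc:
            raise ValueError(f"malformed FASTA record #{i} ({rec.id}): {exc}") from exc
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r} in {fasta}")
        seen.add(r.id)
    return records


def write_reference_fasta(records, path: str | Path, width: int = 70) -> None:
    """Write records as FASTA with SILVA-style taxonomy headers."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.taxonomy else f"{rec.id} {rec.taxonomy_string}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_taxonomy_tsv(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.taxonomy_string}\n")
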