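"""Primer definitions and loaders.

A primer is a named degenerate oligonucleotide written 5'->3' with an
orientation and its binding coordinates on the E. coli 16S reference
gene (1-based inclusive) — the community convention that gives primers
names like 341f.  A packaged TSV ships eight widely used bacterial 16S
primers (the four pairs 68f/518r, 341f/785r, 799f/1193r, 967f/1391r).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .iupac import clean_sequence

__all__ = ["Primer", "load_primers", "default_primers", "default_pairs"]

_ORIENTATIONS = ("forward", "reverse")


@dataclass(frozen=True)
class Primer:
    """A named degenerate primer with E. coli reference coordinates."""

    name: str
    sequence: str  # IUPAC, 5'->3', uppercase
    orientation: str  # "forward" | "reverse"
    ecoli_start: int  # 1-based inclusive
    ecoli_end: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(
                f"primer {self.name}: orientation must be one of {_ORIENTATIONS}, "
                f"got {self.orientation!r}"
            )
        span = self.ecoli_end - self.ecoli_start + 1
        if span != len(self.sequence):
            raise ValueError(
                f"primer {self.name}: E. coli span {self.ecoli_start}-{self.ecoli_end} "
                f"({span} nt) does not equal sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _primer_from_row(row: dict) -> Primer:
    return Primer(
        name=str(row["name"]),
        sequence=str(row["sequence"]),
        orientation=str(row["orientation"]),
        ecoli_start=int(row["ecoli_start"]),
        ecoli_end=int(row["ecoli_end"]),
    )


def load_primers(path: str | Path) -> list[Primer]:
    """Load primers from a TSV (header row) or YAML file.

    TSV columns / YAML keys: name, sequence, orientation, ecoli_start,
    ecoli_end.  YAML may be a list of mappings or {"primers": [...]}.
    """
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if isinstance(data, dict):
            data = data.get("primers", [])
        return [_primer_from_row(r) for r in data]
    return _parse_tsv(path.read_text())


def _parse_tsv(text: str) -> list[Primer]:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        out.append(_primer_from_row(dict(zip(header, ln.split("\t")))))
    return out


def default_primers() -> list[Primer]:
    """The eight packaged 16S primers (four pairs)."""
    text = (
        resources.files("primerscope").joinpath("data/primers_16s.tsv").read_text()
    )
    return _parse_tsv(text)


def default_pairs() -> list[tuple[Primer, Primer]]:
    """The four packaged primer pairs, forward/reverse, in V-region order."""
    by_name = {p.name: p for p in default_primers()}
    pairing = [("68f", "518r"), ("341f", "785r"), ("799f", "1193r"), ("967f", "1391r")]
    return [(by_name[f], by_name[r]) for f, r in pairing]
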