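"""IUPAC nucleotide algebra shared by all other modules.

Each IUPAC code denotes a non-empty subset of {A, C, G, T}; internally a
code is a 4-bit mask (A=1, C=2, G=4, T=8) so subset tests are single AND
operations.  U is treated as T everywhere (rRNA databases store RNA
alphabet), and parsing is case-insensitive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "IUPAC_BASES",
    "InvalidAlphabetError",
    "expand_degenerate",
    "base_match",
    "reverse_complement",
    "encode",
    "mask_of",
]

_A, _C, _G, _T = 1, 2, 4, 8

#: IUPAC code -> set of concrete bases it denotes.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASE_BIT = {"A": _A, "C": _C, "G": _G, "T": _T}

_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_BASES.items()
}

# complement mask: swap A<->T bits and C<->G bits
_COMP_MASK = {
    m: ((m & _A) and _T) | ((m & _T) and _A) | ((m & _C) and _G) | ((m & _G) and _C)
    for m in range(1, 16)
}
_MASK_TO_CODE = {m: c for c, m in _MASK.items()}
_COMP_CHAR = {c: _MASK_TO_CODE[_COMP_MASK[m]] for c, m in _MASK.items()}

# 256-entry lookup for fast byte-level encoding; 0 marks an invalid char.
_ENCODE_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _m in _MASK.items():
    _ENCODE_TABLE[ord(_code)] = _m
    _ENCODE_TABLE[ord(_code.lower())] = _m
_ENCODE_TABLE[ord("U")] = _T
_ENCODE_TABLE[ord("u")] = _T


class InvalidAlphabetError(ValueError):
    """A sequence or primer contains a character outside the IUPAC alphabet."""

    def __init__(self, char: str, position: int, context: str = "sequence"):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid IUPAC character {char!r} at position {position} in {context}"
        )


def _norm(code: str, position: int = 1, context: str = "sequence") -> str:
    c = code.upper()
    if c == "U":
        c = "T"
    if c not in IUPAC_BASES:
        raise InvalidAlphabetError(code, position, context)
    return c


def expand_degenerate(code: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC code denotes.

    Case-insensitive; U is treated as T.  Raises
    :class:`InvalidAlphabetError` for anything outside the 15-letter
    IUPAC nucleotide alphabet.
    """
    if len(code) != 1:
        raise InvalidAlphabetError(code, 1, "code")
    return IUPAC_BASES[_norm(code, 1, "code")]


def mask_of(code: str) -> int:
    """4-bit base-set mask of a single IUPAC character."""
    return _MASK[_norm(code)]


def base_match(primer_base: str, template_base: str) -> bool:
    """True iff the template base set is contained in the primer base set.

    A concrete template base matches iff it is among the bases the
    (possibly degenerate) primer position accepts.  An ambiguous template
    base matches only when every base it could be is acceptable, so
    template N never matches a non-N primer position — the conservative
    reading for reference databases where ambiguity codes are rare.
    """
    p = _MASK[_norm(primer_base, context="primer")]
    t = _MASK[_norm(template_base, context="template")]
    return (t & ~p) == 0


def reverse_complement(seq: str) -> str:
    """Degenerate-aware reverse complement (an involution).

    Complementing swaps A<->T and C<->G within each code's base set, so
    W (A/T) and S (C/G) and N are self-complementary while R (A/G) maps
    to Y (C/T).
    """
    out = []
    for i, ch in enumerate(reversed(seq)):
        out.append(_COMP_CHAR[_norm(ch, len(seq) - i)])
    return "".join(out)


def encode(seq: str, context: str = "sequence") -> np.ndarray:
    """Encode a sequence as a uint8 array of 4-bit base-set masks.

    Vectorised via a byte lookup table; invalid characters are reported
    with their 1-based position.
    """
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    enc = _ENCODE_TABLE[raw]
    if (enc == 0).any():
        pos = int(np.argmax(enc == 0))
        raise InvalidAlphabetError(seq[pos], pos + 1, context)
    return enc


def clean_sequence(seq: str) -> str:
    """Uppercase a sequence and convert U to T (ingest normalisation)."""
    s = seq.upper().replace("U", "T")
    encode(s)  # validate
    return s
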