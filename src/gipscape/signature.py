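"""Degenerate protein-motif (GIP signature) parsing, scanning and classification.

The GIP family (MZT1 orthologs) is defined by a PROSITE-style degenerate
signature: an ordered list of position constraints, each either a literal
residue, a residue class (``[MILVT]``), or a single-position wildcard (``x``).
The motif has no variable-length elements, so a match is a fixed-width window.
The canonical GIP signature (34 positions, one invariant glycine) ships as
package data and is available through :func:`load_gip_signature`.

Coordinates are 1-based inclusive throughout, matching the convention used for
residue annotations such as the invariant glycine at residue 42 of AtGIP1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

__all__ = [
    "AMINO_ACIDS",
    "SEQUENCE_ALPHABET",
    "PatternElement",
    "SignaturePattern",
    "Match",
    "PatternSyntaxError",
    "parse_pattern",
    "load_gip_signature",
    "scan_sequence",
    "classify_set",
    "locate_anchor",
]

#: The 20 standard amino-acid one-letter codes.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Characters legal in a scanned sequence: the 20 standard residues plus the
#: ambiguity/rare codes X (unknown), B (Asx), Z (Glx) and U (selenocysteine).
SEQUENCE_ALPHABET = AMINO_ACIDS | frozenset("XBZU")

_SEPARATORS = frozenset(" -,\t\n\r")


class PatternSyntaxError(ValueError):
    """Malformed motif string; carries the 0-based offset of the error."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PatternElement:
    """One fixed-width position constraint.

    kind is ``"literal"``, ``"class"`` or ``"wildcard"``. ``residues`` holds
    the allowed residue set for literals and classes; it is empty for
    wildcards, which accept any legal sequence character (including X/B/Z/U).
    """

    kind: str
    residues: frozenset = field(default_factory=frozenset)

    def matches(self, ch: str) -> bool:
        if self.kind == "wildcard":
            return True
        # Ambiguity codes never satisfy a class or literal constraint:
        # conservative matching avoids false positives in database screens.
        return ch in self.residues


@dataclass(frozen=True)
class SignaturePattern:
    """Compiled degenerate motif: ordered constraints plus the raw source."""

    elements: tuple[PatternElement, ...]
    source_text: str

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def window_length(self) -> int:
        """Width of a match window (no variable-length elements)."""
        return len(self.elements)

    def literal_positions(self, residue: str) -> list[int]:
        """1-based element indices that are a literal of ``residue``."""
        return [
            i + 1
            for i, e in enumerate(self.elements)
            if e.kind == "literal" and residue in e.residues
        ]


@dataclass(frozen=True)
class Match:
    """A signature hit: 1-based inclusive coordinates on the sequence."""

    sequence_id: str
    start: int
    end: int
    matched_subsequence: str


def parse_pattern(text: str) -> SignaturePattern:
    """Compile a degenerate motif string into a :class:`SignaturePattern`.

    Grammar: ``[...]`` encloses a residue class; an uppercase standard residue
    letter is a literal; lowercase ``x`` is a single-position wildcard; spaces,
    hyphens, commas and line breaks are separators with no semantic content.

    Raises
    ------
    PatternSyntaxError
        On unbalanced brackets, an empty class, or any illegal character,
        reporting the 0-based offset of the problem.
    """
    if not text or not text.strip(" -,\t\n\r"):
        raise PatternSyntaxError("empty pattern", 0)
    elements: list[PatternElement] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in _SEPARATORS:
            i += 1
        elif ch == "x":
            elements.append(PatternElement("wildcard"))
            i += 1
        elif ch == "[":
            j = text.find("]", i + 1)
            if j == -1:
                raise PatternSyntaxError("unbalanced '['", n)
            body = text[i + 1 : j]
            if not body:
                raise PatternSyntaxError("empty residue class", i + 1)
            for k, c in enumerate(body):
                if c not in AMINO_ACIDS:
                    raise PatternSyntaxError(
                        f"illegal residue {c!r} in class", i + 1 + k
                    )
            elements.append(PatternElement("class", frozenset(body)))
            i = j + 1
        elif ch == "]":
            raise PatternSyntaxError("unbalanced ']'", i)
        elif ch in AMINO_ACIDS:
            elements.append(PatternElement("literal", frozenset(ch)))
            i += 1
        else:
            raise PatternSyntaxError(f"illegal character {ch!r}", i)
    if not elements:
        raise PatternSyntaxError("pattern has no elements", 0)
    return SignaturePattern(tuple(elements), text)


def load_gip_signature() -> SignaturePattern:
    """The canonical GIP signature compiled from the packaged motif string."""
    text = (
        resources.files("gipscape.data").joinpath("gip_signature.txt").read_text()
    )
    return parse_pattern(text.strip())


def _validate_sequence(seq: str, seq_id: str) -> str:
    up = seq.upper()
    for pos, ch in enumerate(up):
        if ch not in SEQUENCE_ALPHABET:
            raise ValueError(
                f"illegal residue character {ch!r} at position {pos + 1}"
                f" in sequence {seq_id!r}"
            )
    return up


def scan_sequence(
    seq: str, pattern: SignaturePattern, sequence_id: str = ""
) -> list[Match]:
    """All (possibly overlapping) windows of ``seq`` satisfying the pattern.

    Matching is case-insensitive. X satisfies only wildcard positions; B/Z/U
    fail class and literal constraints. Matches are returned in ascending
    start order with 1-based inclusive coordinates.
    """
    up = _validate_sequence(seq, sequence_id)
    w = pattern.window_length
    out: list[Match] = []
    elements = pattern.elements
    for start in range(len(up) - w + 1):
        window = up[start : start + w]
        if all(e.matches(c) for e, c in zip(elements, window)):
            out.append(Match(sequence_id, start + 1, start + w, window))
    return out


def classify_set(
    sequences: dict[str, str] | Iterable[tuple[str, str]],
    pattern: SignaturePattern,
) -> tuple[dict[str, bool], dict]:
    """Classify each sequence as signature-positive (≥1 match) or negative.

    Returns the per-sequence boolean calls and a summary with counts and the
    positive rate.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if not items:
        raise ValueError("empty sequence set")
    calls = {
        sid: bool(scan_sequence(s, pattern, sequence_id=sid)) for sid, s in items
    }
    n_pos = sum(calls.values())
    summary = {
        "n_sequences": len(calls),
        "n_positive": n_pos,
        "n_negative": len(calls) - n_pos,
        "positive_rate": n_pos / len(calls),
    }
    return calls, summary


def locate_anchor(match: Match, pattern: SignaturePattern) -> int:
    """1-based sequence position of the pattern's invariant glycine.

    The pattern must contain exactly one literal-G element (the GIP signature
    does, at element 24); the anchor position is
    ``match.start + (element index − 1)``.
    """
    g_positions = pattern.literal_positions("G")
    if len(g_positions) != 1:
        raise ValueError(
            f"pattern has {len(g_positions)} literal-G elements; need exactly 1"
        )
    return match.start + g_positions[0] - 1
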