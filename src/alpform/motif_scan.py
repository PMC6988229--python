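"""PROSITE-style pattern grammar and sequence scanner.

Implements the subset of PROSITE syntax needed for fixed-width protein
motifs: fixed residues (``G``), inclusion sets (``[STAGCN]``), exclusion
sets (``{P}``) and fixed-count wildcards (``x`` / ``x(2)``), joined by
dashes.  Variable-range repeats and the ``<``/``>`` anchors are out of
scope.

The default pattern is the classical N-myristoylation consensus
``G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}``: a glycine whose following residue is
not large/acidic/proline, any two residues, then a small residue, then
anything but proline.  In this pipeline the motif marks candidate cleavage
points rather than confirmed lipidation sites, so every position in the
sequence is scanned — internal matches are reported, not just N-terminal
ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

from alpform.seq_model import AMINO_ACIDS, ProteinRecord, mature_sequence

__all__ = [
    "MYRISTOYLATION_PATTERN",
    "Fixed",
    "Inclusion",
    "Exclusion",
    "Wildcard",
    "PrositePattern",
    "MotifHit",
    "PatternParseError",
    "parse_pattern",
    "scan",
    "scan_all",
    "hits_to_frame",
]

#: N-myristoylation consensus used for cleavage-site prediction.
MYRISTOYLATION_PATTERN = "G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}"


class PatternParseError(ValueError):
    """Raised on malformed pattern text; carries the character offset."""

    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Fixed:
    residue: str

    width = 1

    def matches(self, window: str) -> bool:
        return window[0] == self.residue


@dataclass(frozen=True)
class Inclusion:
    residues: frozenset[str]

    width = 1

    def matches(self, window: str) -> bool:
        return window[0] in self.residues


@dataclass(frozen=True)
class Exclusion:
    residues: frozenset[str]

    width = 1

    def matches(self, window: str) -> bool:
        return window[0] not in self.residues


@dataclass(frozen=True)
class Wildcard:
    count: int

    @property
    def width(self) -> int:
        return self.count

    def matches(self, window: str) -> bool:
        return True


Element = Union[Fixed, Inclusion, Exclusion, Wildcard]


@dataclass(frozen=True)
class PrositePattern:
    """A parsed fixed-width pattern."""

    elements: tuple[Element, ...]
    source_text: str
    name: str = "pattern"

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("pattern has no elements")

    @property
    def width(self) -> int:
        return sum(el.width for el in self.elements)

    def matches_at(self, seq: str, start0: int) -> bool:
        """True if the window starting at 0-based *start0* satisfies every element."""
        pos = start0
        for el in self.elements:
            if not el.matches(seq[pos : pos + el.width]):
                return False
            pos += el.width
        return True


@dataclass(frozen=True)
class MotifHit:
    """One positioned motif match; coordinates are 1-based inclusive."""

    record_id: str
    start: int
    matched: str
    pattern_name: str = "pattern"

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


def _parse_set(text: str, start: int, open_ch: str, close_ch: str) -> tuple[frozenset[str], int]:
    end = text.find(close_ch, start)
    if end == -1:
        raise PatternParseError(f"unbalanced '{open_ch}'", start)
    residues = text[start + 1 : end]
    if not residues:
        raise PatternParseError("empty residue set", start)
    for i, ch in enumerate(residues):
        if ch not in AMINO_ACIDS:
            raise PatternParseError(f"invalid residue {ch!r} in set", start + 1 + i)
    return frozenset(residues), end + 1


def parse_pattern(text: str, name: str = "pattern") -> PrositePattern:
    """Parse a dash-separated PROSITE-style pattern string.

    >>> parse_pattern("G-{EDRKHPFYW}-x(2)-[STAGCN]-{P}").width
    6
    """
    stripped = text.strip().rstrip(".")
    if not stripped:
        raise PatternParseError("empty pattern", 0)
    elements: list[Element] = []
    pos = 0
    for part in stripped.split("-"):
        if not part:
            raise PatternParseError("empty pattern element", pos)
        if part.startswith("["):
            residues, consumed = _parse_set(stripped, pos, "[", "]")
            if stripped[pos : pos + len(part)] != part:  # pragma: no cover - guard
                raise PatternParseError("malformed set", pos)
            elements.append(Inclusion(residues))
        elif part.startswith("{"):
            residues, _ = _parse_set(stripped, pos, "{", "}")
            elements.append(Exclusion(residues))
        elif part == "x":
            elements.append(Wildcard(1))
        elif part.startswith("x(") and part.endswith(")"):
            body = part[2:-1]
            if not body.isdigit() or int(body) < 1:
                raise PatternParseError(f"invalid repeat count {body!r}", pos + 2)
            elements.append(Wildcard(int(body)))
        elif len(part) == 1 and part in AMINO_ACIDS:
            elements.append(Fixed(part))
        else:
            raise PatternParseError(f"unrecognised element {part!r}", pos)
        pos += len(part) + 1  # account for the dash
    return PrositePattern(tuple(elements), source_text=text, name=name)


def scan(seq: str, pattern: PrositePattern, record_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) matches of *pattern* on *seq*.

    Returns hits in ascending 1-based start order.
    """
    width = pattern.width
    hits = []
    for start0 in range(len(seq) - width + 1):
        if pattern.matches_at(seq, start0):
            hits.append(
                MotifHit(
                    record_id=record_id,
                    start=start0 + 1,
                    matched=seq[start0 : start0 + width],
                    pattern_name=pattern.name,
                )
            )
    return hits


def scan_all(
    records: Iterable[ProteinRecord],
    pattern: PrositePattern,
    mature: bool = True,
) -> list[MotifHit]:
    """Concatenated hits over many records, keyed by record id.

    With ``mature=True`` (default) the signal peptide is stripped first and
    hit coordinates are on the mature frame; pass ``mature=False`` to scan
    precursor coordinates.
    """
    hits: list[MotifHit] = []
    for rec in records:
        seq = mature_sequence(rec) if mature else rec.sequence
        hits.extend(scan(seq, pattern, record_id=rec.id))
    return hits


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    """Tabulate hits as (record_id, start, end, matched, pattern_name)."""
    return pd.DataFrame(
        [
            {
                "record_id": h.record_id,
                "start": h.start,
                "end": h.end,
                "matched": h.matched,
                "pattern_name": h.pattern_name,
            }
            for h in hits
        ],
        columns=["record_id", "start", "end", "matched", "pattern_name"],
    )
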