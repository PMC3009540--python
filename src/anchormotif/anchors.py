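"""Gap-tolerant anchor patterns: matching, enumeration, and ranking.

An anchor is the short highly conserved core of a sorting motif.  The
pattern language is ``<left literal of n residues> <gap of min..max any
residues> <right literal of m residues>``; with ``m == 0`` the anchor is a
plain n-mer.  ``X`` in a sequence never matches a literal position; gap
positions match anything.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .alphabet import AMINO_ACIDS
from .io import TerminalSegment
from .util import ResourceError


@dataclass(frozen=True)
class AnchorPattern:
    """A concrete (literal-instantiated) anchor."""

    left: str
    right: str = ""
    gap_min: int = 0
    gap_max: int = 0

    def __post_init__(self) -> None:
        if len(self.left) < 1:
            raise ValueError("left literal must have length >= 1")
        if not (0 <= self.gap_min <= self.gap_max):
            raise ValueError("need 0 <= gap_min <= gap_max")
        for ch in self.left + self.right:
            if ch not in AMINO_ACIDS:
                raise ValueError(f"literal residue {ch!r} outside the 20-letter alphabet")

    @property
    def n(self) -> int:
        return len(self.left)

    @property
    def m(self) -> int:
        return len(self.right)

    @property
    def min_span(self) -> int:
        return self.n + (self.gap_min + self.m if self.m else 0)

    @property
    def max_span(self) -> int:
        return self.n + (self.gap_max + self.m if self.m else 0)

    def __str__(self) -> str:
        if not self.m:
            return self.left
        return f"{self.left}x{{{self.gap_min},{self.gap_max}}}{self.right}"


@dataclass(frozen=True)
class AnchorHit:
    """One occurrence of an anchor in a terminal segment."""

    sequence_id: str
    segment_end: str
    start: int  # 0-based offset into the segment
    span: int  # matched length including the gap

    @property
    def stop(self) -> int:
        return self.start + self.span


@dataclass(frozen=True)
class AnchorTemplate:
    """The search space for anchor enumeration."""

    n: int = 2
    m: int = 0
    gap_min: int = 0
    gap_max: int = 0
    left_alphabet: str = AMINO_ACIDS
    right_alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 0:
            raise ValueError("need n >= 1 and m >= 0")
        if not (0 <= self.gap_min <= self.gap_max):
            raise ValueError("need 0 <= gap_min <= gap_max")

    @property
    def space_size(self) -> int:
        size = len(self.left_alphabet) ** self.n
        if self.m:
            size *= len(self.right_alphabet) ** self.m
        return size


def match_anchor(pattern: AnchorPattern, segment: TerminalSegment) -> list[AnchorHit]:
    """All occurrences of ``pattern`` in ``segment`` (overlaps included).

    For gapped patterns every distinct (start, gap) combination is one hit.
    """
    seq = segment.residues
    hits: list[AnchorHit] = []
    n, m = pattern.n, pattern.m
    for start in range(len(seq) - pattern.min_span + 1):
        if seq[start : start + n] != pattern.left:
            continue
        if not m:
            hits.append(AnchorHit(segment.parent_id, segment.end, start, n))
            continue
        for gap in range(pattern.gap_min, pattern.gap_max + 1):
            rstart = start + n + gap
            if rstart + m > len(seq):
                break
            if seq[rstart : rstart + m] == pattern.right:
                hits.append(
                    AnchorHit(segment.parent_id, segment.end, start, n + gap + m)
                )
    return hits


def _scan_occurrences(
    segments: Sequence[TerminalSegment], template: AnchorTemplate
) -> dict[AnchorPattern, tuple[set[str], int]]:
    """Occurrence-driven scan: pattern -> (ids with a hit, total hits)."""
    left_ok = set(template.left_alphabet)
    right_ok = set(template.right_alphabet)
    acc: dict[AnchorPattern, list] = {}
    for seg in segments:
        seq = seg.residues
        length = len(seq)
        for start in range(length - template.n + 1):
            left = seq[start : start + template.n]
            if not left_ok.issuperset(left):
                continue
            if template.m == 0:
                entry = acc.setdefault(AnchorPattern(left), [set(), 0])
                entry[0].add(seg.parent_id)
                entry[1] += 1
                continue
            for gap in range(template.gap_min, template.gap_max + 1):
                rstart = start + template.n + gap
                if rstart + template.m > length:
                    break
                right = seq[rstart : rstart + template.m]
                if not right_ok.issuperset(right):
                    continue
                key = AnchorPattern(left, right, template.gap_min, template.gap_max)
                entry = acc.setdefault(key, [set(), 0])
                entry[0].add(seg.parent_id)
                entry[1] += 1
    return {pat: (ids, total) for pat, (ids, total) in acc.items()}


def enumerate_anchors(
    pos_segments: Sequence[TerminalSegment],
    neg_segments: Sequence[TerminalSegment],
    template: AnchorTemplate = AnchorTemplate(),
    min_support: float = 0.30,
    space_cap: int = 10**7,
) -> pd.DataFrame:
    """Enumerate anchors with positive-set support >= ``min_support``.

    Support is the fraction of distinct positive sequences containing at
    least one hit.  The table is sorted by sequence support descending,
    ties broken lexicographically by pattern string.
    """
    if template.space_size > space_cap:
        raise ResourceError(
            f"anchor space of {template.space_size} literal instantiations exceeds "
            f"the cap of {space_cap}; restrict the anchor alphabets"
        )
    n_pos = len(pos_segments)
    if n_pos == 0:
        raise ValueError("positive segment set is empty")
    pos_found = _scan_occurrences(pos_segments, template)
    needed = {
        pat for pat, (ids, _) in pos_found.items() if len(ids) / n_pos >= min_support
    }
    neg_support: dict[AnchorPattern, int] = {pat: 0 for pat in needed}
    if needed and neg_segments:
        neg_found = _scan_occurrences(neg_segments, template)
        for pat in needed:
            if pat in neg_found:
                neg_support[pat] = len(neg_found[pat][0])
    n_neg = max(len(neg_segments), 1)
    rows = []
    for pat in needed:
        ids, total = pos_found[pat]
        rows.append(
            {
                "pattern": str(pat),
                "left": pat.left,
                "right": pat.right,
                "gap_min": pat.gap_min,
                "gap_max": pat.gap_max,
                "n_sequences_with_hit": len(ids),
                "total_hits": total,
                "positive_frequency": len(ids) / n_pos,
                "negative_frequency": neg_support[pat] / n_neg,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pattern", "left", "right", "gap_min", "gap_max",
            "n_sequences_with_hit", "total_hits",
            "positive_frequency", "negative_frequency",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["n_sequences_with_hit", "pattern"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def rank_anchors(table: pd.DataFrame, top_k: int) -> list[AnchorPattern]:
    """Top-k patterns in the table's sort order."""
    if top_k <= 0:
        raise ValueError("top_k must be positive")
    if table is None or len(table) == 0:
        raise ValueError("anchor table is empty")
    out = []
    for _, row in table.head(top_k).iterrows():
        out.append(
            AnchorPattern(
                row["left"], row["right"], int(row["gap_min"]), int(row["gap_max"])
            )
        )
    return out


def all_literals(template: AnchorTemplate) -> Iterable[AnchorPattern]:
    """Exhaustively instantiate a template (used by tests and small spaces)."""
    lefts = ("".join(t) for t in itertools.product(template.left_alphabet, repeat=template.n))
    if template.m == 0:
        for left in lefts:
            yield AnchorPattern(left)
        return
    rights = [
        "".join(t) for t in itertools.product(template.right_alphabet, repeat=template.m)
    ]
    for left in lefts:
        for right in rights:
            yield AnchorPattern(left, right, template.gap_min, template.gap_max)
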