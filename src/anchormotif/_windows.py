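"""Internal helpers: packing segments into matrices and gathering windows."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .alphabet import PAD_CODE, encode
from .anchors import AnchorHit
from .io import TerminalSegment


@dataclass
class AnchoredSegments:
    """A packed set of segments with one chosen anchor occurrence each.

    ``starts[i] == -1`` marks a sequence with no anchor occurrence; such
    sequences can only contribute randomly placed windows.
    """

    ids: list[str]
    mat: np.ndarray  # (n, max_len) int8, PAD_CODE beyond each length
    lengths: np.ndarray  # (n,)
    starts: np.ndarray  # (n,) chosen anchor start, -1 when absent
    spans: np.ndarray  # (n,) chosen anchor span, 0 when absent
    hits: list[list[AnchorHit]]  # all occurrences per sequence

    @classmethod
    def build(
        cls,
        segments: Sequence[TerminalSegment],
        hits_by_id: Mapping[str, Sequence[AnchorHit]] | None = None,
    ) -> "AnchoredSegments":
        ids = [s.parent_id for s in segments]
        lengths = np.array([len(s) for s in segments], dtype=np.int64)
        mat = np.full((len(segments), int(lengths.max(initial=1))), PAD_CODE, dtype=np.int8)
        for i, seg in enumerate(segments):
            mat[i, : lengths[i]] = encode(seg.residues)
        starts = np.full(len(segments), -1, dtype=np.int64)
        spans = np.zeros(len(segments), dtype=np.int64)
        hits: list[list[AnchorHit]] = []
        for i, seg in enumerate(segments):
            seq_hits = list(hits_by_id.get(seg.parent_id, ())) if hits_by_id else []
            hits.append(seq_hits)
            if seq_hits:
                first = min(seq_hits, key=lambda h: h.start)  # left-most default
                starts[i] = first.start
                spans[i] = first.span
        return cls(ids, mat, lengths, starts, spans, hits)

    def __len__(self) -> int:
        return len(self.ids)

    def select(self, keep: np.ndarray) -> "AnchoredSegments":
        keep = np.asarray(keep)
        return AnchoredSegments(
            [self.ids[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.ids[i] for i in keep],
            self.mat[keep],
            self.lengths[keep],
            self.starts[keep],
            self.spans[keep],
            [self.hits[i] for i in np.flatnonzero(keep)] if keep.dtype == bool
            else [self.hits[i] for i in keep],
        )


def gather_windows(
    packed: AnchoredSegments, starts: np.ndarray, width: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extract width-W windows at per-sequence starts.

    Returns (windows, valid): windows only for sequences whose window lies
    fully inside the segment; ``valid`` is the boolean mask over sequences.
    Starts may be negative or -1 (both invalid).
    """
    starts = np.asarray(starts)
    valid = (starts >= 0) & (starts + width <= packed.lengths)
    idx = starts[valid, None] + np.arange(width)[None, :]
    windows = packed.mat[np.flatnonzero(valid)[:, None], idx]
    return windows.astype(np.int8), valid


def random_starts(
    packed: AnchoredSegments, width: int, rng: np.random.Generator
) -> np.ndarray:
    """One uniform random valid window start per sequence (-1 if too short)."""
    out = np.full(len(packed), -1, dtype=np.int64)
    room = packed.lengths - width
    ok = room >= 0
    out[ok] = rng.integers(0, room[ok] + 1)
    return out


def anchor_relative_starts(
    packed: AnchoredSegments,
    width: int,
    offset: int,
    align: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Window starts at a signed offset from each sequence's anchor.

    ``align="left"`` places the window start at ``anchor_start + offset``;
    ``align="right"`` places the window *end* at ``anchor_end + offset``.
    Sequences without an anchor get a fresh random placement (background
    role), drawn from ``rng``.
    """
    if align == "left":
        starts = packed.starts + offset
    elif align == "right":
        starts = packed.starts + packed.spans + offset - width
    else:
        raise ValueError(f"unknown alignment {align!r}")
    starts = np.where(packed.starts >= 0, starts, -1)
    unanchored = packed.starts < 0
    if unanchored.any():
        rand = random_starts(packed, width, rng)
        starts = np.where(unanchored, rand, starts)
    return starts
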