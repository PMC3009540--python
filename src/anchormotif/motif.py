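"""Motif boundary determination, discrimination score, and conservation.

Starting from an anchor seat, a width-W window slides outward one residue
at a time; at every offset a fresh window model is trained and scored by
stratified cross-validation, and the boundary in each direction is the
outermost offset whose min(precision, recall) stays at or above the
accuracy threshold.  The boundary-delimited instances give the final
motif: its position weight matrix, its discrimination (motif) score, and
its information content in bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._windows import AnchoredSegments, gather_windows, random_starts
from .alphabet import AMINO_ACIDS, N_RESIDUES, X_CODE, encode
from .anchors import AnchorHit, AnchorPattern
from .bayes import cross_validated_score
from .io import TerminalSegment
from .util import derive_seed

LOG2_ALPHABET = float(np.log2(N_RESIDUES))


@dataclass(frozen=True)
class BoundaryConfig:
    """Tunables of the sliding-window boundary search."""

    window: int = 10
    accuracy_threshold: float = 0.5
    folds: int = 5
    alpha: float = 1.0
    seed: int = 0
    max_extension: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.accuracy_threshold < 1):
            raise ValueError("accuracy_threshold must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.max_extension < 0:
            raise ValueError("max_extension must be >= 0")


@dataclass
class MotifModel:
    """A discovered anchored motif and its summary statistics."""

    anchor: AnchorPattern
    segment_end: str
    left_ext: int
    right_ext: int
    anchor_span: int
    length: int
    instances: list[str]
    consensus: str
    motif_score: float
    information_content: float
    pwm: pd.DataFrame = field(repr=False)
    _audit: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def to_dict(self) -> dict:
        return {
            "anchor": str(self.anchor),
            "segment_end": self.segment_end,
            "left_ext": self.left_ext,
            "right_ext": self.right_ext,
            "anchor_span": self.anchor_span,
            "length": self.length,
            "n_instances": self.n_instances,
            "consensus": self.consensus,
            "motif_score": round(float(self.motif_score), 9),
            "information_content": round(float(self.information_content), 9),
            "pwm": np.round(self.pwm.to_numpy(), 9).tolist(),
        }


def _packed(
    segments: Sequence[TerminalSegment],
    chosen: Mapping[str, tuple[int, int]],
) -> AnchoredSegments:
    hits = {
        sid: [AnchorHit(sid, segments[0].end if segments else "N", start, span)]
        for sid, (start, span) in chosen.items()
    }
    return AnchoredSegments.build(segments, hits)


def _boundary_starts(
    packed: AnchoredSegments, dist: int, direction: str, width: int
) -> np.ndarray:
    """Starts of windows centred on the candidate boundary residue.

    Leftward, the candidate boundary at distance ``dist`` is the residue
    ``anchor_start - dist``; rightward it is ``anchor_end - 1 + dist``.
    The test window is centred on that residue, so the score collapses
    roughly when the candidate residue itself leaves the conserved region.
    """
    half = width // 2
    if direction == "left":
        centre = packed.starts - dist
        starts = centre - half
    else:
        centre = packed.starts + packed.spans - 1 + dist
        starts = centre - half + 1
    return np.where(packed.starts >= 0, starts, -1)


def _offset_score(
    pos: AnchoredSegments,
    neg: AnchoredSegments,
    dist: int,
    direction: str,
    cfg: BoundaryConfig,
    rng: np.random.Generator,
) -> float | None:
    """CV min(precision, recall) for windows centred at one boundary candidate.

    Anchored negatives use the same window arithmetic relative to their
    own anchor; anchor-free negatives get a random placement.  Returns
    None when either class cannot field ``folds`` valid windows.
    """
    pos_starts = _boundary_starts(pos, dist, direction, cfg.window)
    neg_starts = _boundary_starts(neg, dist, direction, cfg.window)
    unanchored = neg.starts < 0
    if unanchored.any():
        rand = random_starts(neg, cfg.window, rng)
        neg_starts = np.where(unanchored, rand, neg_starts)
    pos_wins, _ = gather_windows(pos, pos_starts, cfg.window)
    neg_wins, _ = gather_windows(neg, neg_starts, cfg.window)
    if pos_wins.shape[0] < cfg.folds or neg_wins.shape[0] < cfg.folds:
        return None
    score = cross_validated_score(
        pos_wins, neg_wins, folds=cfg.folds, alpha=cfg.alpha,
        seed=derive_seed(cfg.seed, "boundary", direction, dist),
    )
    return score.min_pr


def determine_boundaries(
    pos_segments: Sequence[TerminalSegment],
    chosen: Mapping[str, tuple[int, int]],
    neg_segments: Sequence[TerminalSegment],
    neg_hits: Mapping[str, Sequence[AnchorHit]],
    cfg: BoundaryConfig = BoundaryConfig(),
) -> tuple[int, int] | None:
    """Extend the motif region outward from the anchor in both directions.

    Returns ``(left_ext, right_ext)`` in residues beyond the anchor, or
    ``None`` when even the anchor-seated window fails the accuracy
    threshold (the anchor is rejected).
    """
    pos = _packed(pos_segments, chosen)
    neg = AnchoredSegments.build(neg_segments, neg_hits)
    rng = np.random.default_rng(derive_seed(cfg.seed, "boundary-neg"))
    seat = _offset_score(pos, neg, 0, "left", cfg, rng)
    if seat is None or seat < cfg.accuracy_threshold:
        return None
    extents = []
    for direction in ("left", "right"):
        ext = 0
        for dist in range(1, cfg.max_extension + 1):
            score = _offset_score(pos, neg, dist, direction, cfg, rng)
            if score is None or score < cfg.accuracy_threshold:
                break
            ext = dist
        extents.append(ext)
    return extents[0], extents[1]


def extract_instances(
    pos_segments: Sequence[TerminalSegment],
    chosen: Mapping[str, tuple[int, int]],
    left_ext: int,
    right_ext: int,
) -> list[str]:
    """Boundary-delimited subsequences, anchor-aligned and equal length.

    Sequences whose motif interval would cross a segment edge are dropped;
    with a gapped anchor only the modal anchor span is kept so instances
    align column-by-column.
    """
    spans = [span for _, span in chosen.values()]
    if not spans:
        return []
    modal_span = max(set(spans), key=lambda s: (spans.count(s), -s))
    out = []
    for seg in pos_segments:
        if seg.parent_id not in chosen:
            continue
        start, span = chosen[seg.parent_id]
        if span != modal_span:
            continue
        lo, hi = start - left_ext, start + span + right_ext
        if lo < 0 or hi > len(seg.residues):
            continue
        out.append(seg.residues[lo:hi])
    return out


def motif_score(
    instances: Sequence[str],
    neg_segments: Sequence[TerminalSegment],
    neg_hits: Mapping[str, Sequence[AnchorHit]],
    left_ext: int,
    folds: int = 5,
    alpha: float = 1.0,
    seed: int = 0,
) -> float:
    """min(precision, recall) of the motif-region classifier under CV.

    Positive windows are the motif instances; negative windows of the same
    width are anchor-aligned in negatives carrying the anchor and randomly
    placed in the rest.
    """
    if not instances:
        raise ValueError("no motif instances")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("instances must share one length")
    if len(instances) < folds:
        raise ValueError("need at least `folds` instances")
    neg = AnchoredSegments.build(neg_segments, neg_hits)
    rng = np.random.default_rng(derive_seed(seed, "motif-score-neg"))
    # anchored negatives align to the motif frame; anchor-free negatives
    # (and anchored ones whose aligned window falls off the segment) get a
    # random placement so they still contribute background evidence
    neg_starts = np.where(neg.starts >= 0, neg.starts - left_ext, -1)
    invalid = (neg_starts < 0) | (neg_starts + width > neg.lengths)
    room = neg.lengths - width
    need_rand = invalid & (room >= 0)
    if need_rand.any():
        neg_starts[need_rand] = rng.integers(0, room[need_rand] + 1)
    neg_wins, _ = gather_windows(neg, neg_starts, width)
    pos_wins = np.array([encode(s) for s in instances])
    score = cross_validated_score(
        pos_wins, neg_wins, folds=folds, alpha=alpha, seed=derive_seed(seed, "motif-score-cv")
    )
    return score.min_pr


def _column_frequencies(instances: Sequence[str]) -> np.ndarray:
    if len(instances) < 2:
        raise ValueError("need at least 2 instances")
    lengths = {len(s) for s in instances}
    if len(lengths) != 1:
        raise ValueError("instances must have equal length")
    mat = np.array([encode(s) for s in instances])
    length = mat.shape[1]
    freqs = np.zeros((length, N_RESIDUES))
    for j in range(length):
        col = mat[:, j]
        col = col[col < X_CODE]  # 'X' excluded from column counts
        if col.size:
            counts = np.bincount(col, minlength=N_RESIDUES)
            freqs[j] = counts / counts.sum()
    return freqs


def information_content(instances: Sequence[str]) -> float:
    """Shannon information content in bits: sum_j (log2 20 - H_j).

    Column frequencies are the observed ones (no pseudocount); a column
    with no countable residues (all 'X') contributes zero bits.
    """
    freqs = _column_frequencies(instances)
    ic = 0.0
    for row in freqs:
        if row.sum() == 0:
            continue
        nz = row[row > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic += LOG2_ALPHABET - entropy
    return ic


def build_pwm(instances: Sequence[str]) -> tuple[pd.DataFrame, str]:
    """Column frequency matrix and consensus string.

    The consensus letter is each column's modal residue (ties break
    alphabetically); columns without a majority residue (modal frequency
    below 0.5) render as lowercase 'x', giving the familiar NPxY-style
    notation for variable positions.
    """
    freqs = _column_frequencies(instances)
    pwm = pd.DataFrame(freqs, columns=list(AMINO_ACIDS))
    consensus = []
    for row in freqs:
        best = int(np.argmax(row))  # argmax returns first = alphabetical tie-break
        consensus.append(AMINO_ACIDS[best] if row[best] >= 0.5 else "x")
    return pwm, "".join(consensus)


def write_meme(motifs: Sequence[MotifModel], path: str | Path) -> None:
    """Write motif PWMs in MEME minimal motif format for logo tooling."""
    lines = [
        "MEME version 4",
        "",
        f"ALPHABET= {AMINO_ACIDS}",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(
            f"{aa} {1.0 / N_RESIDUES:.5f}" for aa in AMINO_ACIDS
        ),
        "",
    ]
    for i, motif in enumerate(motifs, start=1):
        name = f"{motif.segment_end}_{motif.anchor}_{i}"
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= {N_RESIDUES} w= {motif.length} "
            f"nsites= {motif.n_instances} E= 0"
        )
        for row in motif.pwm.to_numpy():
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def motifs_to_json(motifs: Sequence[MotifModel], path: str | Path | None = None) -> str:
    text = json.dumps([m.to_dict() for m in motifs], indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
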