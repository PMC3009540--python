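"""Iterative false-positive removal for impure positive sets.

Positive sets assembled from localisation annotations are rarely pure:
many sequences reach the compartment through other pathways and carry the
candidate anchor only by chance.  This module implements the iterative
purification loop: seat a window at each sequence's anchor, train the
two-class window model (anchor-bearing negatives are seated the same way;
anchor-free negatives contribute randomly placed windows), slide the
window residue by residue to the left and then to the right of the anchor,
retraining at every offset, and score each positive sequence at each
offset.  A sequence's score trajectory in a direction ends once
``consecutive_low`` successive scores fall below ``score_threshold``; the
scores before that run are averaged, and sequences whose mean falls below
the threshold are removed.  The loop repeats until no sequence is removed
or ``max_iterations`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._windows import AnchoredSegments, anchor_relative_starts, gather_windows
from .anchors import AnchorHit
from .bayes import WindowModel, fit_window_model
from .io import TerminalSegment
from .util import PurificationError, derive_seed


@dataclass(frozen=True)
class FPRemovalConfig:
    """Tunables of the purification loop."""

    window: int = 10
    score_threshold: float = 0.85
    consecutive_low: int = 3
    max_iterations: int = 10
    alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.score_threshold < 1):
            raise ValueError("score_threshold must be in [0, 1)")
        if self.consecutive_low < 1:
            raise ValueError("consecutive_low must be >= 1")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class PurifyResult:
    retained_ids: list[str]
    chosen: dict[str, tuple[int, int]]  # id -> (anchor start, span)
    audit: pd.DataFrame
    n_iterations: int


def choose_occurrence(
    hits: Sequence[AnchorHit],
    model: WindowModel | None,
    segment: TerminalSegment | None = None,
) -> AnchorHit:
    """Pick one anchor occurrence for a sequence.

    With a trained window model, the occurrence whose seated window scores
    the highest posterior wins (ties -> left-most); without a model the
    left-most occurrence is used.
    """
    if not hits:
        raise ValueError("hits must be non-empty")
    ordered = sorted(hits, key=lambda h: h.start)
    if model is None or segment is None:
        return ordered[0]
    from .alphabet import encode  # local import to avoid cycle at module load

    seq = encode(segment.residues)
    best, best_score = ordered[0], -1.0
    for hit in ordered:
        start = _clamped_seat(hit.start, len(seq), model.width)
        if start is None:
            continue
        score = float(model.posteriors(seq[None, start : start + model.width])[0])
        if score > best_score + 1e-12:
            best, best_score = hit, score
    return best


def _clamped_seat(start: int, length: int, width: int) -> int | None:
    """Seat window start clamped into the segment; None if it cannot fit."""
    if length < width:
        return None
    return int(min(max(start, 0), length - width))


def _seat_starts(packed: AnchoredSegments, width: int) -> np.ndarray:
    starts = np.minimum(packed.starts, packed.lengths - width)
    starts = np.where(packed.starts >= 0, np.maximum(starts, 0), -1)
    starts[packed.lengths < width] = -1
    return starts


def _train(
    pos: AnchoredSegments,
    pos_starts: np.ndarray,
    neg: AnchoredSegments,
    neg_starts: np.ndarray,
    width: int,
    alpha: float,
) -> WindowModel | None:
    pos_wins, pos_valid = gather_windows(pos, pos_starts, width)
    neg_wins, neg_valid = gather_windows(neg, neg_starts, width)
    if pos_wins.shape[0] == 0 or neg_wins.shape[0] == 0:
        return None
    return fit_window_model(pos_wins, neg_wins, alpha)


def _rechoose(packed: AnchoredSegments, model: WindowModel) -> None:
    """Re-pick each sequence's occurrence as the best under ``model``."""
    width = model.width
    for i, seq_hits in enumerate(packed.hits):
        if len(seq_hits) <= 1:
            continue
        best_start, best_span, best_score = packed.starts[i], packed.spans[i], -1.0
        for hit in sorted(seq_hits, key=lambda h: h.start):
            seat = _clamped_seat(hit.start, int(packed.lengths[i]), width)
            if seat is None:
                continue
            win = packed.mat[i, seat : seat + width]
            score = float(model.posteriors(win[None, :])[0])
            if score > best_score + 1e-12:
                best_start, best_span, best_score = hit.start, hit.span, score
        packed.starts[i] = best_start
        packed.spans[i] = best_span


def _first_run(scores: list[float], threshold: float, run: int) -> int | None:
    """Index where the first run of ``run`` consecutive sub-threshold scores starts."""
    count = 0
    for i, s in enumerate(scores):
        count = count + 1 if s < threshold else 0
        if count == run:
            return i - run + 1
    return None


def _sweep_direction(
    pos: AnchoredSegments,
    neg: AnchoredSegments,
    seat_scores: np.ndarray,
    direction: int,
    cfg: FPRemovalConfig,
    rng: np.random.Generator,
) -> list[list[float]]:
    """Slide the window in one direction (+1 right / -1 left), retraining
    at every offset; return each sequence's score series starting at the seat."""
    n = len(pos)
    series: list[list[float]] = [[float(seat_scores[i])] for i in range(n)]
    ended = np.zeros(n, dtype=bool)  # window ran off the segment
    max_offset = int(pos.lengths.max(initial=0))
    for dist in range(1, max_offset + 1):
        done = np.array(
            [
                ended[i]
                or _first_run(series[i], cfg.score_threshold, cfg.consecutive_low)
                is not None
                for i in range(n)
            ]
        )
        if done.all():
            break
        offset = direction * dist
        pos_starts = np.where(pos.starts >= 0, pos.starts + offset, -1)
        neg_starts = anchor_relative_starts(neg, cfg.window, offset, "left", rng)
        model = _train(pos, pos_starts, neg, neg_starts, cfg.window, cfg.alpha)
        if model is None:
            break
        wins, valid = gather_windows(pos, pos_starts, cfg.window)
        ended |= ~valid
        if valid.any():
            scores = model.posteriors(wins)
            for row, i in enumerate(np.flatnonzero(valid)):
                series[i].append(float(scores[row]))
    return series


def _mean_before_run(
    left: list[float], right: list[float], threshold: float, run: int
) -> float:
    """Average of the seat score and each direction's scores before its
    terminating low run (the seat is counted once)."""
    collected = [left[0]]
    for series in (left, right):
        r = _first_run(series, threshold, run)
        stop = len(series) if r is None else r
        collected.extend(series[1:max(stop, 1)])
    return float(np.mean(collected))


def purify(
    pos_segments: Sequence[TerminalSegment],
    pos_hits: Mapping[str, Sequence[AnchorHit]],
    neg_segments: Sequence[TerminalSegment],
    neg_hits: Mapping[str, Sequence[AnchorHit]],
    cfg: FPRemovalConfig = FPRemovalConfig(),
) -> PurifyResult:
    """Run the iterative removal loop; return survivors and a full audit."""
    missing = [s.parent_id for s in pos_segments if not pos_hits.get(s.parent_id)]
    if missing:
        raise ValueError(
            f"every positive segment needs an anchor hit; missing for {missing[:3]}"
        )
    if len(pos_segments) < 10 or len(neg_segments) < 10:
        raise ValueError("purification needs at least 10 sequences per class")
    pos = AnchoredSegments.build(pos_segments, pos_hits)
    neg = AnchoredSegments.build(neg_segments, neg_hits)

    audit_rows: list[dict] = []
    active = np.ones(len(pos), dtype=bool)
    n_iter = 0
    for iteration in range(1, cfg.max_iterations + 1):
        n_iter = iteration
        rng = np.random.default_rng(derive_seed(cfg.seed, "fp-removal", iteration))
        sub = pos.select(active)
        # occurrence choice: left-most seats, one seat-model refinement
        seat = _seat_starts(sub, cfg.window)
        neg_seat = anchor_relative_starts(neg, cfg.window, 0, "left", rng)
        model = _train(sub, seat, neg, neg_seat, cfg.window, cfg.alpha)
        if model is None:
            break
        _rechoose(sub, model)
        seat = _seat_starts(sub, cfg.window)
        model = _train(sub, seat, neg, neg_seat, cfg.window, cfg.alpha)
        wins, valid = gather_windows(sub, seat, cfg.window)
        seat_scores = np.full(len(sub), np.nan)
        seat_scores[valid] = model.posteriors(wins)
        # sequences with no seatable window cannot be judged; score them at
        # the threshold so they are never the reason for a removal
        seat_scores[~valid] = cfg.score_threshold

        left = _sweep_direction(sub, neg, seat_scores, -1, cfg, rng)
        right = _sweep_direction(sub, neg, seat_scores, +1, cfg, rng)
        means = np.array(
            [
                _mean_before_run(left[i], right[i], cfg.score_threshold, cfg.consecutive_low)
                for i in range(len(sub))
            ]
        )
        removed = means < cfg.score_threshold
        active_idx = np.flatnonzero(active)
        for i in np.flatnonzero(removed):
            audit_rows.append(
                {
                    "iteration": iteration,
                    "sequence_id": sub.ids[i],
                    "mean_score": means[i],
                    "action": "removed",
                }
            )
        # write refined occurrence choices back to the master packing
        pos.starts[active_idx] = sub.starts
        pos.spans[active_idx] = sub.spans
        if removed.all():
            raise PurificationError(
                "false-positive removal discarded every positive sequence; "
                "lower score_threshold or check the anchor"
            )
        if not removed.any():
            for i in range(len(sub)):
                audit_rows.append(
                    {
                        "iteration": iteration,
                        "sequence_id": sub.ids[i],
                        "mean_score": means[i],
                        "action": "retained",
                    }
                )
            break
        active[active_idx[removed]] = False
        if iteration == cfg.max_iterations:
            for i in np.flatnonzero(~removed):
                audit_rows.append(
                    {
                        "iteration": iteration,
                        "sequence_id": sub.ids[i],
                        "mean_score": means[i],
                        "action": "retained",
                    }
                )
    retained_ids = [pos.ids[i] for i in np.flatnonzero(active)]
    chosen = {
        pos.ids[i]: (int(pos.starts[i]), int(pos.spans[i]))
        for i in np.flatnonzero(active)
    }
    audit = pd.DataFrame(
        audit_rows, columns=["iteration", "sequence_id", "mean_score", "action"]
    )
    return PurifyResult(retained_ids, chosen, audit, n_iter)
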