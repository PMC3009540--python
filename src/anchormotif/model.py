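"""End-to-end anchored-motif discovery as a model/results pair.

:class:`MotifDiscovery` is constructed from a positive (co-sorted) and a
negative (background) dataset plus a :class:`PipelineConfig`; ``fit()``
runs preprocessing, anchor enumeration, optional false-positive removal,
boundary determination and scoring, and returns a
:class:`MotifDiscoveryResults` carrying the ranked motifs, the anchor
table, removal audits, and a ``summary()`` table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .anchors import (
    AnchorPattern,
    AnchorTemplate,
    enumerate_anchors,
    match_anchor,
    rank_anchors,
)
from .bayes import fit_window_model
from ._windows import AnchoredSegments, anchor_relative_starts, gather_windows
from .io import Dataset, extract_terminal, read_fasta, reduce_redundancy
from .motif import (
    BoundaryConfig,
    MotifModel,
    build_pwm,
    determine_boundaries,
    extract_instances,
    information_content,
    motif_score,
    motifs_to_json,
    write_meme,
)
from .purify import FPRemovalConfig, purify
from .util import NoMotifError, PurificationError, derive_seed

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the discovery pipeline, derived from one global seed."""

    terminal_length: int = 200
    ends: tuple[str, ...] = ("N",)
    anchor_template: AnchorTemplate = AnchorTemplate()
    min_support: float = 0.30
    top_k: int = 5
    redundancy_threshold: float = 0.8
    reduce_redundancy: bool = True
    removal_enabled: bool = True
    removal: FPRemovalConfig = FPRemovalConfig()
    boundary: BoundaryConfig = BoundaryConfig()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.terminal_length < 1:
            raise ValueError("terminal_length must be >= 1")
        for end in self.ends:
            if end not in ("N", "C"):
                raise ValueError(f"unknown terminal end {end!r}")
        if not (0 < self.min_support <= 1.01):
            raise ValueError("min_support must be a fraction")


class MotifDiscovery:
    """Discover anchored sorting motifs separating positives from background."""

    def __init__(
        self,
        positives: Dataset,
        negatives: Dataset,
        config: PipelineConfig = PipelineConfig(),
        anchor_literals: Sequence[AnchorPattern] | None = None,
    ) -> None:
        self.positives = positives
        self.negatives = negatives
        self.config = config
        self.anchor_literals = list(anchor_literals) if anchor_literals else None

    @classmethod
    def from_fasta(
        cls,
        pos_path: str | Path,
        neg_path: str | Path,
        config: PipelineConfig = PipelineConfig(),
        anchor_literals: Sequence[AnchorPattern] | None = None,
    ) -> "MotifDiscovery":
        return cls(
            read_fasta(pos_path, "positive"),
            read_fasta(neg_path, "negative"),
            config,
            anchor_literals,
        )

    def fit(self) -> "MotifDiscoveryResults":
        cfg = self.config
        pos, neg = self.positives, self.negatives
        cluster_reports = {}
        if cfg.reduce_redundancy:
            pos, cluster_reports["positive"] = reduce_redundancy(
                pos, cfg.redundancy_threshold
            )
            neg, cluster_reports["negative"] = reduce_redundancy(
                neg, cfg.redundancy_threshold
            )
        motifs: list[MotifModel] = []
        anchor_tables: dict[str, pd.DataFrame] = {}
        audits: dict[str, pd.DataFrame] = {}
        skipped: list[dict] = []
        for end in cfg.ends:
            pos_segs = [
                extract_terminal(r, end, cfg.terminal_length) for r in pos
            ]
            neg_segs = [
                extract_terminal(r, end, cfg.terminal_length) for r in neg
            ]
            if self.anchor_literals is None:
                table = enumerate_anchors(
                    pos_segs, neg_segs, cfg.anchor_template, cfg.min_support
                )
                anchor_tables[end] = table
                if len(table) == 0:
                    continue
                patterns = rank_anchors(table, cfg.top_k)
            else:
                patterns = self.anchor_literals
            for pattern in patterns:
                result = self._fit_anchor(pattern, end, pos_segs, neg_segs)
                if isinstance(result, MotifModel):
                    motifs.append(result)
                    key = f"{end}:{pattern}"
                    if result._audit is not None:
                        audits[key] = result._audit
                else:
                    skipped.append({"end": end, "anchor": str(pattern), "reason": result})
        motifs.sort(key=lambda m: (-m.motif_score, str(m.anchor)))
        return MotifDiscoveryResults(
            model=self,
            motifs=motifs,
            anchor_tables=anchor_tables,
            removal_audits=audits,
            cluster_reports=cluster_reports,
            skipped=skipped,
        )

    # -- single-anchor fit ------------------------------------------------

    def _fit_anchor(self, pattern, end, pos_segs, neg_segs):
        """Returns a MotifModel or a string reason for skipping."""
        cfg = self.config
        pos_hits = {
            s.parent_id: h for s in pos_segs if (h := match_anchor(pattern, s))
        }
        neg_hits = {
            s.parent_id: h for s in neg_segs if (h := match_anchor(pattern, s))
        }
        eligible = [s for s in pos_segs if s.parent_id in pos_hits]
        min_needed = max(10, cfg.boundary.folds)
        if len(eligible) < min_needed:
            return f"only {len(eligible)} positives carry the anchor"
        anchor_seed = derive_seed(cfg.seed, end, str(pattern))
        audit = None
        if cfg.removal_enabled:
            removal_cfg = FPRemovalConfig(
                window=cfg.removal.window,
                score_threshold=cfg.removal.score_threshold,
                consecutive_low=cfg.removal.consecutive_low,
                max_iterations=cfg.removal.max_iterations,
                alpha=cfg.removal.alpha,
                seed=derive_seed(anchor_seed, "removal"),
            )
            try:
                presult = purify(eligible, pos_hits, neg_segs, neg_hits, removal_cfg)
            except PurificationError:
                return "false-positive removal discarded every positive"
            audit = presult.audit
            chosen = presult.chosen
            retained = [s for s in eligible if s.parent_id in chosen]
        else:
            retained = eligible
            chosen = self._choose_without_removal(
                eligible, pos_hits, neg_segs, neg_hits, anchor_seed
            )
        if len(retained) < min_needed:
            return f"only {len(retained)} positives survive purification"
        boundary_cfg = BoundaryConfig(
            window=cfg.boundary.window,
            accuracy_threshold=cfg.boundary.accuracy_threshold,
            folds=cfg.boundary.folds,
            alpha=cfg.boundary.alpha,
            seed=derive_seed(anchor_seed, "boundary"),
            max_extension=cfg.boundary.max_extension,
        )
        bounds = determine_boundaries(retained, chosen, neg_segs, neg_hits, boundary_cfg)
        if bounds is None:
            return "anchor-seated window fails the accuracy threshold"
        left_ext, right_ext = bounds
        instances = extract_instances(retained, chosen, left_ext, right_ext)
        if len(instances) < cfg.boundary.folds:
            return "too few boundary-delimited instances"
        score = motif_score(
            instances,
            neg_segs,
            neg_hits,
            left_ext,
            folds=cfg.boundary.folds,
            alpha=cfg.boundary.alpha,
            seed=derive_seed(anchor_seed, "score"),
        )
        ic = information_content(instances)
        pwm, consensus = build_pwm(instances)
        motif = MotifModel(
            anchor=pattern,
            segment_end=end,
            left_ext=left_ext,
            right_ext=right_ext,
            anchor_span=len(instances[0]) - left_ext - right_ext,
            length=len(instances[0]),
            instances=instances,
            consensus=consensus,
            motif_score=score,
            information_content=ic,
            pwm=pwm,
        )
        motif._audit = audit
        return motif

    def _choose_without_removal(self, eligible, pos_hits, neg_segs, neg_hits, seed):
        """Left-most seats, one seat-model refinement (mirrors purification)."""
        cfg = self.config
        width = cfg.removal.window
        pos = AnchoredSegments.build(eligible, pos_hits)
        neg = AnchoredSegments.build(neg_segs, neg_hits)
        rng = np.random.default_rng(derive_seed(seed, "choose"))
        seat = np.where(
            pos.starts >= 0,
            np.minimum(np.maximum(pos.starts, 0), pos.lengths - width),
            -1,
        )
        neg_seat = anchor_relative_starts(neg, width, 0, "left", rng)
        pos_wins, _ = gather_windows(pos, seat, width)
        neg_wins, _ = gather_windows(neg, neg_seat, width)
        if pos_wins.shape[0] and neg_wins.shape[0]:
            model = fit_window_model(pos_wins, neg_wins, cfg.removal.alpha)
            from .purify import _rechoose

            _rechoose(pos, model)
        return {
            pos.ids[i]: (int(pos.starts[i]), int(pos.spans[i]))
            for i in range(len(pos))
            if pos.starts[i] >= 0
        }


@dataclass
class MotifDiscoveryResults:
    """Ranked motifs plus every audit artefact of a discovery run."""

    model: MotifDiscovery
    motifs: list[MotifModel]
    anchor_tables: dict[str, pd.DataFrame]
    removal_audits: dict[str, pd.DataFrame]
    cluster_reports: dict[str, pd.DataFrame]
    skipped: list[dict] = field(default_factory=list)

    @property
    def top(self) -> MotifModel:
        if not self.motifs:
            raise NoMotifError("no motif passed the accuracy threshold")
        return self.motifs[0]

    def motif_for_anchor(self, literal: str) -> MotifModel | None:
        """Best-scoring motif whose anchor pattern prints as ``literal``."""
        for m in self.motifs:
            if str(m.anchor) == literal:
                return m
        return None

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Anchored motif discovery results",
            "=" * 72,
            f"positives: {len(self.model.positives)}  negatives: {len(self.model.negatives)}"
            f"  ends: {','.join(cfg.ends)}  K: {cfg.terminal_length}",
            f"window: {cfg.boundary.window}  folds: {cfg.boundary.folds}"
            f"  removal: {'on' if cfg.removal_enabled else 'off'}"
            f" (threshold {cfg.removal.score_threshold})"
            f"  boundary threshold: {cfg.boundary.accuracy_threshold}"
            f"  seed: {cfg.seed}",
            "-" * 72,
        ]
        if not self.motifs:
            lines.append("no motif found")
        else:
            header = (
                f"{'rank':>4} {'end':>3} {'anchor':>8} {'L':>3} {'n_inst':>6} "
                f"{'score':>6} {'IC(bits)':>8}  consensus"
            )
            lines.append(header)
            for i, m in enumerate(self.motifs, 1):
                lines.append(
                    f"{i:>4} {m.segment_end:>3} {str(m.anchor):>8} {m.length:>3} "
                    f"{m.n_instances:>6} {m.motif_score:>6.3f} "
                    f"{m.information_content:>8.2f}  {m.consensus}"
                )
        if self.skipped:
            lines.append("-" * 72)
            for s in self.skipped:
                lines.append(f"skipped {s['end']}:{s['anchor']} -- {s['reason']}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write anchors.tsv, removal_audit.tsv, motifs.json, motifs.meme
        and a run log with every threshold actually used."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.anchor_tables:
            pd.concat(
                [t.assign(end=end) for end, t in self.anchor_tables.items()],
                ignore_index=True,
            ).to_csv(outdir / "anchors.tsv", sep="\t", index=False)
        if self.removal_audits:
            pd.concat(
                [a.assign(anchor=key) for key, a in self.removal_audits.items()],
                ignore_index=True,
            ).to_csv(outdir / "removal_audit.tsv", sep="\t", index=False)
        motifs_to_json(self.motifs, outdir / "motifs.json")
        if self.motifs:
            write_meme(self.motifs, outdir / "motifs.meme")
        cfg = self.model.config
        log = {
            "terminal_length": cfg.terminal_length,
            "ends": list(cfg.ends),
            "anchor_template": asdict(cfg.anchor_template),
            "min_support": cfg.min_support,
            "top_k": cfg.top_k,
            "reduce_redundancy": cfg.reduce_redundancy,
            "redundancy_threshold": cfg.redundancy_threshold,
            "removal_enabled": cfg.removal_enabled,
            "removal": asdict(cfg.removal),
            "boundary": asdict(cfg.boundary),
            "seed": cfg.seed,
            "n_motifs": len(self.motifs),
            "skipped": self.skipped,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
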