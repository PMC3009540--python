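"""Boundary determination, motif scoring, information content, PWM."""

from __future__ import annotations

import math

import numpy as np
import pytest

from anchormotif.anchors import AnchorPattern
from anchormotif.motif import (
    BoundaryConfig,
    build_pwm,
    determine_boundaries,
    information_content,
    motif_score,
    write_meme,
)

from .conftest import make_segment
from .test_purify import implanted_world

LOG2_20 = math.log2(20)


class TestInformationContent:
    def test_conserved_column_contributes_log2_20(self):
        assert information_content(["A", "A", "A"]) == pytest.approx(LOG2_20)

    def test_two_conserved_columns(self):
        assert information_content(["AA", "AA", "AA"]) == pytest.approx(8.6439, abs=1e-4)

    def test_half_half_column_loses_one_bit(self):
        assert information_content(["A", "A", "C", "C"]) == pytest.approx(LOG2_20 - 1)

    def test_reorder_invariance_and_column_additivity(self):
        instances = ["ACD", "AWD", "ACE", "AWE"]
        shuffled = list(reversed(instances))
        assert information_content(instances) == pytest.approx(
            information_content(shuffled)
        )
        per_column = sum(
            information_content([s[j] for s in instances]) for j in range(3)
        )
        assert information_content(instances) == pytest.approx(per_column)

    def test_x_excluded_from_column_counts(self):
        assert information_content(["A", "A", "X"]) == pytest.approx(LOG2_20)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            information_content(["AA", "AAA"])

    def test_fewer_than_two_instances_rejected(self):
        with pytest.raises(ValueError):
            information_content(["AA"])

    def test_bounded_by_length_times_log2_20(self):
        rng = np.random.default_rng(0)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        instances = ["".join(rng.choice(letters, 8)) for _ in range(20)]
        ic = information_content(instances)
        assert 0 <= ic <= 8 * LOG2_20


class TestBuildPwm:
    def test_npxy_style_consensus(self):
        pwm, consensus = build_pwm(["NPAY", "NPCY", "NPGY"])
        assert consensus == "NPxY"
        assert np.allclose(pwm.sum(axis=1), 1.0)

    def test_identical_instances_consensus(self):
        _, consensus = build_pwm(["RRLF", "RRLF"])
        assert consensus == "RRLF"

    def test_tie_breaks_alphabetically(self):
        _, consensus = build_pwm(["A", "C"])
        assert consensus == "A"


class TestMemeOutput:
    def test_minimal_meme_format(self, tmp_path):
        from anchormotif.motif import MotifModel

        pwm, consensus = build_pwm(["NPAY", "NPCY", "NPGY"])
        motif = MotifModel(
            anchor=AnchorPattern("NP"),
            segment_end="N",
            left_ext=0,
            right_ext=2,
            anchor_span=2,
            length=4,
            instances=["NPAY", "NPCY", "NPGY"],
            consensus=consensus,
            motif_score=0.9,
            information_content=information_content(["NPAY", "NPCY", "NPGY"]),
            pwm=pwm,
        )
        out = tmp_path / "motifs.meme"
        write_meme([motif], out)
        text = out.read_text()
        assert text.startswith("MEME version")
        assert "letter-probability matrix: alength= 20 w= 4 nsites= 3" in text
        matrix_rows = [
            line for line in text.splitlines() if line and line[0].isdigit()
        ]
        assert len(matrix_rows) == 4
        for row in matrix_rows:
            assert sum(float(v) for v in row.split()) == pytest.approx(1.0, abs=1e-4)


def _world_with_hits(**kwargs):
    pos, pos_hits, neg, neg_hits, implanted = implanted_world(**kwargs)
    chosen = {}
    for seg in pos:
        hit = min(pos_hits[seg.parent_id], key=lambda h: h.start)
        chosen[seg.parent_id] = (hit.start, hit.span)
    return pos, chosen, neg, neg_hits, implanted


class TestBoundaries:
    def test_zero_max_extension_returns_anchor_only(self):
        pos, chosen, neg, neg_hits, _ = _world_with_hits(
            n_pos=20, n_neg=20, implant_fraction=1.0, seed=2
        )
        cfg = BoundaryConfig(max_extension=0, seed=1)
        bounds = determine_boundaries(pos, chosen, neg, neg_hits, cfg)
        assert bounds == (0, 0)

    def test_strong_implant_recovers_flanks(self):
        # leftmost occurrences are mostly the implanted anchors here; the
        # 9-residue hydrophobic flanks should be recovered approximately
        pos, chosen, neg, neg_hits, _ = _world_with_hits(
            n_pos=40, n_neg=40, length=120, implant_fraction=1.0, seed=3
        )
        bounds = determine_boundaries(pos, chosen, neg, neg_hits, BoundaryConfig(seed=1))
        assert bounds is not None
        left, right = bounds
        assert 6 <= left <= 18
        assert 6 <= right <= 18

    def test_indistinct_anchor_rejected(self):
        # positives and negatives are both pure background around a shared
        # coincidental anchor: no conserved flank exists, so the seat window
        # hovers at chance and cannot reach a demanding threshold
        pos, chosen, neg, neg_hits, _ = _world_with_hits(
            n_pos=25, n_neg=25, implant_fraction=0.0, seed=4
        )
        bounds = determine_boundaries(
            pos, chosen, neg, neg_hits, BoundaryConfig(accuracy_threshold=0.75, seed=1)
        )
        assert bounds is None
        # at the default 0.5 threshold the anchor may squeak through on
        # noise, but never with meaningful extensions
        loose = determine_boundaries(
            pos, chosen, neg, neg_hits, BoundaryConfig(seed=1)
        )
        assert loose is None or max(loose) <= 5

    def test_deterministic_given_seed(self):
        pos, chosen, neg, neg_hits, _ = _world_with_hits(
            n_pos=20, n_neg=20, implant_fraction=1.0, seed=6
        )
        cfg = BoundaryConfig(seed=9)
        assert determine_boundaries(pos, chosen, neg, neg_hits, cfg) == (
            determine_boundaries(pos, chosen, neg, neg_hits, cfg)
        )

    def test_higher_threshold_never_extends_further(self):
        pos, chosen, neg, neg_hits, _ = _world_with_hits(
            n_pos=30, n_neg=30, length=120, implant_fraction=1.0, seed=7
        )
        lo = determine_boundaries(
            pos, chosen, neg, neg_hits, BoundaryConfig(accuracy_threshold=0.5, seed=1)
        )
        hi = determine_boundaries(
            pos, chosen, neg, neg_hits, BoundaryConfig(accuracy_threshold=0.9, seed=1)
        )
        assert lo is not None
        if hi is not None:
            assert hi[0] <= lo[0] and hi[1] <= lo[1]


class TestMotifScore:
    def test_identical_distributions_score_near_half(self):
        rng = np.random.default_rng(8)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        instances = ["".join(rng.choice(letters, 12)) for _ in range(60)]
        neg = [make_segment("".join(rng.choice(letters, 80)), f"n{i}") for i in range(60)]
        scores = [
            motif_score(instances, neg, {}, left_ext=0, seed=s) for s in range(6)
        ]
        assert np.mean(scores) == pytest.approx(0.5, abs=0.12)

    def test_separable_instances_score_one(self):
        instances = ["VVVVVVVVVV"] * 20
        rng = np.random.default_rng(9)
        neg = [
            make_segment("".join(rng.choice(list("GPSTNQ"), 60)), f"n{i}")
            for i in range(20)
        ]
        assert motif_score(instances, neg, {}, left_ext=0, seed=1) == 1.0

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            motif_score(["AAAA"] * 3, [make_segment("GGGGGG", "n0")], {}, 0, folds=5)
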