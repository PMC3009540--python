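"""Iterative false-positive removal behaviour."""

from __future__ import annotations

import numpy as np
import pytest

from anchormotif.anchors import AnchorHit, AnchorPattern, match_anchor
from anchormotif.bayes import fit_window_model
from anchormotif.alphabet import encode
from anchormotif.purify import FPRemovalConfig, choose_occurrence, purify

from .conftest import make_segment

ANCHOR = AnchorPattern("AA")


def implanted_world(n_pos=20, n_neg=20, length=80, implant_fraction=1.0, seed=5):
    """Positives carry a strong hydrophobic block around an 'AA' anchor at a
    random position; the rest of every sequence is i.i.d. background.

    Every sequence -- negatives included -- carries at least one bare 'AA',
    mimicking natural backgrounds where a dipeptide anchor is common, so
    that classification signal comes from the flanks, not anchor presence.
    """
    rng = np.random.default_rng(seed)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    flank = np.array(list("VILMFW"))

    def background():
        return "".join(rng.choice(letters, size=length))

    def with_anchor(seq):
        if "AA" not in seq:
            k = int(rng.integers(0, len(seq) - 2))
            seq = seq[:k] + "AA" + seq[k + 2 :]
        return seq

    pos_segments, implanted = [], []
    n_implant = round(implant_fraction * n_pos)
    for i in range(n_pos):
        seq = background()
        if i < n_implant:
            start = int(rng.integers(0, length - 20))
            motif = "".join(rng.choice(flank, 9)) + "AA" + "".join(rng.choice(flank, 9))
            seq = seq[:start] + motif + seq[start + 20 :]
            implanted.append(f"p{i}")
        pos_segments.append(make_segment(with_anchor(seq), f"p{i}"))
    neg_segments = [
        make_segment(with_anchor(background()), f"n{i}") for i in range(n_neg)
    ]
    pos_hits = {s.parent_id: match_anchor(ANCHOR, s) for s in pos_segments}
    neg_hits = {
        s.parent_id: h for s in neg_segments if (h := match_anchor(ANCHOR, s))
    }
    return pos_segments, pos_hits, neg_segments, neg_hits, set(implanted)


class TestPurify:
    def test_pure_strong_motif_no_removals_one_iteration(self):
        pos, pos_hits, neg, neg_hits, _ = implanted_world(implant_fraction=1.0)
        result = purify(pos, pos_hits, neg, neg_hits, FPRemovalConfig(seed=1))
        assert len(result.retained_ids) == len(pos)
        assert result.n_iterations == 1
        assert (result.audit["action"] == "retained").all()

    def test_zero_threshold_removes_nothing(self):
        pos, pos_hits, neg, neg_hits, _ = implanted_world(implant_fraction=0.5)
        result = purify(
            pos, pos_hits, neg, neg_hits, FPRemovalConfig(score_threshold=0.0, seed=1)
        )
        assert len(result.retained_ids) == len(pos)

    def test_impure_set_removes_mostly_nonimplanted(self):
        pos, pos_hits, neg, neg_hits, implanted = implanted_world(
            n_pos=30, n_neg=30, implant_fraction=0.5, seed=9
        )
        result = purify(pos, pos_hits, neg, neg_hits, FPRemovalConfig(seed=2))
        removed = set(result.audit.loc[result.audit["action"] == "removed", "sequence_id"])
        assert removed, "an impure set should lose some sequences"
        non_implanted_removed = len(removed - implanted) / len(removed)
        assert non_implanted_removed >= 0.8
        retained_purity = len(set(result.retained_ids) & implanted) / len(
            result.retained_ids
        )
        assert retained_purity > 0.5

    def test_retained_set_non_increasing_and_audit_disjoint(self):
        pos, pos_hits, neg, neg_hits, _ = implanted_world(
            n_pos=30, n_neg=30, implant_fraction=0.4, seed=11
        )
        result = purify(pos, pos_hits, neg, neg_hits, FPRemovalConfig(seed=3))
        removed_by_iter = result.audit[result.audit["action"] == "removed"]
        ids = removed_by_iter["sequence_id"]
        assert ids.is_unique
        assert result.n_iterations <= FPRemovalConfig().max_iterations
        assert set(result.retained_ids).isdisjoint(set(ids))

    def test_deterministic_given_seed(self):
        pos, pos_hits, neg, neg_hits, _ = implanted_world(implant_fraction=0.5, seed=13)
        cfg = FPRemovalConfig(seed=21)
        r1 = purify(pos, pos_hits, neg, neg_hits, cfg)
        r2 = purify(pos, pos_hits, neg, neg_hits, cfg)
        assert r1.retained_ids == r2.retained_ids
        assert r1.audit.equals(r2.audit)

    def test_positive_without_anchor_rejected(self):
        pos, pos_hits, neg, neg_hits, _ = implanted_world()
        pos_hits[pos[0].parent_id] = []
        with pytest.raises(ValueError, match="anchor hit"):
            purify(pos, pos_hits, neg, neg_hits, FPRemovalConfig())


class TestChooseOccurrence:
    def test_single_hit_returned(self):
        hit = AnchorHit("s", "N", 4, 2)
        assert choose_occurrence([hit], None) == hit

    def test_no_model_uses_leftmost(self):
        hits = [AnchorHit("s", "N", 9, 2), AnchorHit("s", "N", 2, 2)]
        assert choose_occurrence(hits, None).start == 2

    def test_model_prefers_motif_occurrence(self):
        # window model trained on hydrophobic windows; the hit inside the
        # hydrophobic stretch must win over the early background hit
        seg = make_segment("GGAAGGGGGG" + "VVAAVVVVVV", "s")
        hits = match_anchor(ANCHOR, seg)
        assert [h.start for h in hits] == [2, 12]
        motif = np.array([encode("VVAAVVVVVV")] * 4)
        background = np.array([encode("GGGGGGGGGG")] * 4)
        model = fit_window_model(motif, background)
        chosen = choose_occurrence(hits, model, seg)
        assert chosen.start == 12

    def test_tie_prefers_leftmost(self):
        # identical context around both occurrences -> identical seat
        # posteriors -> the left-most one must win
        seg = make_segment("VVAAVVVVVVVVAAVVVVVVVVVV", "s")
        hits = match_anchor(ANCHOR, seg)
        motif = np.array([encode("VVAAVVVVVV")] * 4)
        background = np.array([encode("GGGGGGGGGG")] * 4)
        model = fit_window_model(motif, background)
        assert choose_occurrence(hits, model, seg).start == min(h.start for h in hits)
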