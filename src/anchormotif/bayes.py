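"""Two-class positional naive Bayes over fixed-width sequence windows.

Each window column is modelled as an independent categorical distribution
over the 20 residues, estimated per class with Laplace smoothing; this is
the classifier that decides whether a window looks like a motif region or
like background.  ``X`` (ambiguity) contributes a flat 1/20 likelihood to
both classes, so it carries no evidence.  All products are carried in log
space; posterior probabilities come from a two-class log-sum-exp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .alphabet import N_RESIDUES, PAD_CODE, X_CODE, decode, encode

BACKGROUND, MOTIF = 0, 1


@dataclass(frozen=True)
class WindowSample:
    """A fixed-width window labelled motif or background."""

    residues: str
    source_id: str
    label: Literal["motif", "background"]


@dataclass
class WindowModel:
    """Fitted per-position categorical model for the two window classes.

    ``log_likelihood`` has shape (2, W, 21): class x position x residue
    code, with code 20 ('X') fixed at log(1/20) for both classes.
    """

    width: int
    alpha: float
    log_likelihood: np.ndarray
    class_log_prior: np.ndarray

    def log_joint(self, windows: np.ndarray) -> np.ndarray:
        """Per-class unnormalised log posterior for encoded windows (n, W)."""
        windows = np.atleast_2d(np.asarray(windows))
        if windows.shape[1] != self.width:
            raise ValueError(
                f"window width {windows.shape[1]} != model width {self.width}"
            )
        if (windows >= PAD_CODE).any():
            raise ValueError("windows contain padding codes; mask them upstream")
        cols = np.arange(self.width)
        out = np.empty((2, windows.shape[0]))
        for c in (BACKGROUND, MOTIF):
            out[c] = self.class_log_prior[c] + self.log_likelihood[c][cols, windows].sum(axis=1)
        return out

    def posteriors(self, windows: np.ndarray) -> np.ndarray:
        """Posterior probability of the motif class for each window."""
        lj = self.log_joint(windows)
        # two-class softmax, numerically stable
        return 1.0 / (1.0 + np.exp(lj[BACKGROUND] - lj[MOTIF]))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "width": self.width,
            "alpha": self.alpha,
            "log_likelihood": np.round(self.log_likelihood, 9).tolist(),
            "class_log_prior": np.round(self.class_log_prior, 9).tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "WindowModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            width=payload["width"],
            alpha=payload["alpha"],
            log_likelihood=np.asarray(payload["log_likelihood"]),
            class_log_prior=np.asarray(payload["class_log_prior"]),
        )


@dataclass(frozen=True)
class CVScore:
    """Pooled cross-validated precision/recall of the motif class."""

    precision: float
    recall: float
    min_pr: float
    folds: int


def fit_window_model(
    motif_windows: np.ndarray, background_windows: np.ndarray, alpha: float = 1.0
) -> WindowModel:
    """Fit the model from encoded window matrices (rows = windows).

    Laplace smoothing adds ``alpha`` to every (class, position, residue)
    count; 'X' codes are excluded from the counts.  Class priors come from
    the class sizes.
    """
    motif_windows = np.atleast_2d(np.asarray(motif_windows))
    background_windows = np.atleast_2d(np.asarray(background_windows))
    if motif_windows.shape[0] == 0 or background_windows.shape[0] == 0:
        raise ValueError("both classes need at least one training window")
    if motif_windows.shape[1] != background_windows.shape[1]:
        raise ValueError("class window widths differ")
    if alpha <= 0:
        raise ValueError("pseudocount alpha must be positive")
    width = motif_windows.shape[1]
    ll = np.empty((2, width, PAD_CODE + 1))
    for c, wins in ((MOTIF, motif_windows), (BACKGROUND, background_windows)):
        for j in range(width):
            col = wins[:, j]
            counts = np.bincount(col[col < N_RESIDUES], minlength=N_RESIDUES).astype(float)
            probs = (counts + alpha) / (counts.sum() + N_RESIDUES * alpha)
            ll[c, j, :N_RESIDUES] = np.log(probs)
        ll[c, :, X_CODE] = np.log(1.0 / N_RESIDUES)
        ll[c, :, PAD_CODE] = -np.inf  # padding must never be scored
    n_m, n_b = motif_windows.shape[0], background_windows.shape[0]
    priors = np.log([n_b / (n_m + n_b), n_m / (n_m + n_b)])
    return WindowModel(width, alpha, ll, np.array([priors[0], priors[1]]))


def _split_samples(samples: Sequence[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    widths = {len(s.residues) for s in samples}
    if len(widths) != 1:
        raise ValueError("all window samples must share one width")
    motif = [encode(s.residues) for s in samples if s.label == "motif"]
    background = [encode(s.residues) for s in samples if s.label == "background"]
    if not motif or not background:
        raise ValueError("training needs at least one sample of each class")
    return np.array(motif), np.array(background)


def train_window_model(samples: Sequence[WindowSample], alpha: float = 1.0) -> WindowModel:
    """Fit the window model from labelled :class:`WindowSample` objects."""
    motif, background = _split_samples(samples)
    return fit_window_model(motif, background, alpha)


def window_posterior(model: WindowModel, window: str | np.ndarray) -> float:
    """Posterior probability that one window belongs to the motif class."""
    win = encode(window) if isinstance(window, str) else np.asarray(window)
    if win.ndim != 1 or win.shape[0] != model.width:
        raise ValueError(f"window must have length {model.width}")
    return float(model.posteriors(win[None, :])[0])


def cross_validated_score(
    motif_windows: np.ndarray | Sequence[WindowSample],
    background_windows: np.ndarray | None = None,
    folds: int = 5,
    alpha: float = 1.0,
    seed: int = 0,
) -> CVScore:
    """Stratified k-fold CV; pooled precision/recall of the motif class.

    Held-out windows are classified motif when the posterior is >= 0.5;
    true/false positives and false negatives are pooled over folds (micro
    averaging), which is stable for small classes.  Deterministic given
    ``seed``.
    """
    if background_windows is None:
        motif_windows, background_windows = _split_samples(motif_windows)  # type: ignore[arg-type]
    pos = np.atleast_2d(np.asarray(motif_windows))
    neg = np.atleast_2d(np.asarray(background_windows))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if pos.shape[0] < folds or neg.shape[0] < folds:
        raise ValueError("each class needs at least `folds` samples")
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(pos.shape[0], dtype=int), np.zeros(neg.shape[0], dtype=int)])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = fp = fn = 0
    for train_idx, test_idx in skf.split(X, y):
        model = fit_window_model(
            X[train_idx][y[train_idx] == 1], X[train_idx][y[train_idx] == 0], alpha
        )
        pred = model.posteriors(X[test_idx]) >= 0.5
        truth = y[test_idx] == 1
        tp += int(np.sum(pred & truth))
        fp += int(np.sum(pred & ~truth))
        fn += int(np.sum(~pred & truth))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return CVScore(precision, recall, min(precision, recall), folds)


__all__ = [
    "WindowSample",
    "WindowModel",
    "CVScore",
    "fit_window_model",
    "train_window_model",
    "window_posterior",
    "cross_validated_score",
    "decode",
]
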