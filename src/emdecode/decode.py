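"""Time-resolved binary decoding of condition pairs with cross-validated AUC.

At every timepoint the feature vector is the instantaneous value of all
channels (or ROI traces) of one IMF; an L2-regularized logistic
regression is trained under stratified 30-fold cross-validation and
scored by the area under the ROC curve on the held-out fold.  AUC 0.5 is
chance; downstream group statistics operate on AUC - 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .preprocess import Epochs

logger = logging.getLogger(__name__)

__all__ = ["DecodingResult", "auc", "time_resolved_decode", "decode_pairs"]


@dataclass
class DecodingResult:
    """Participants x timepoints AUC matrix for one condition pair."""

    auc: np.ndarray
    pair: tuple[str, str]
    feature_space: str = "sensors"
    imf: int | None = None  # None = undecomposed signal
    n_folds: int = 30
    seed: int = 0
    times: np.ndarray | None = None  # ms, aligned with the epoch time axis
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.auc = np.atleast_2d(np.asarray(self.auc, dtype=float))
        if np.any((self.auc < 0) | (self.auc > 1)):
            raise ValueError("AUC values must lie in [0, 1]")

    @property
    def effect(self) -> np.ndarray:
        """Chance-centred effect matrix (AUC - 0.5) for group statistics."""
        return self.auc - 0.5


def auc(scores, labels) -> float:
    """Rank-based AUC: P(score of random positive > random negative).

    Ties contribute 1/2, so the result equals the all-pairs count
    (Mann-Whitney U / (n1*n0)) exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def time_resolved_decode(
    epochs_a: Epochs | np.ndarray,
    epochs_b: Epochs | np.ndarray,
    n_folds: int = 30,
    seed: int = 0,
    C: float = 1.0,
    pool_predictions: bool = False,
) -> np.ndarray:
    """Per-timepoint cross-validated AUC between two trial sets.

    Inputs are Epochs or bare (trials, channels, samples) arrays.  For
    each timepoint, trials are split into ``n_folds`` stratified folds
    (shuffled with ``seed``); each fold is scored once as the test set by
    a logistic-regression classifier fitted to the rest, with feature
    standardization fitted on the training folds only.  By default the
    fold AUCs are averaged; ``pool_predictions`` instead pools all
    held-out decision values into a single AUC per timepoint.
    """
    xa = epochs_a.data if isinstance(epochs_a, Epochs) else np.asarray(epochs_a)
    xb = epochs_b.data if isinstance(epochs_b, Epochs) else np.asarray(epochs_b)
    if xa.shape[1:] != xb.shape[1:]:
        raise ValueError("both conditions need identical channel/sample axes")
    n_a, n_b = xa.shape[0], xb.shape[0]
    if min(n_a, n_b) < n_folds:
        raise ValueError(
            f"need at least n_folds={n_folds} trials per condition, got {n_a}/{n_b}"
        )
    X = np.concatenate([xa, xb])  # trials x channels x samples
    y = np.concatenate([np.ones(n_a, dtype=int), np.zeros(n_b, dtype=int)])
    n_samples = X.shape[2]
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(cv.split(np.zeros(len(y)), y))

    out = np.empty(n_samples)
    for t in range(n_samples):
        Xt = X[:, :, t]
        fold_aucs = []
        pooled_scores, pooled_labels = [], []
        for train, test in splits:
            scaler = StandardScaler().fit(Xt[train])
            clf = LogisticRegression(C=C, max_iter=1000)
            clf.fit(scaler.transform(Xt[train]), y[train])
            s = clf.decision_function(scaler.transform(Xt[test]))
            if pool_predictions:
                pooled_scores.append(s)
                pooled_labels.append(y[test])
            else:
                fold_aucs.append(auc(s, y[test]))
        if pool_predictions:
            out[t] = auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
        else:
            out[t] = float(np.mean(fold_aucs))
    return out


DEFAULT_PAIRS = (("famous", "scrambled"), ("unfamiliar", "scrambled"), ("famous", "unfamiliar"))


def decode_pairs(
    imf_epochs: dict[int | None, list[Epochs]],
    pairs=DEFAULT_PAIRS,
    n_folds: int = 30,
    seed: int = 0,
    C: float = 1.0,
    feature_space: str = "sensors",
) -> list[DecodingResult]:
    """Decode every condition pair for every IMF (and the raw signal).

    ``imf_epochs`` maps IMF index (1-based; ``None`` for the
    undecomposed signal) to a list of per-participant Epochs.  Pairs
    with a missing condition label are skipped with a warning.  Seeds
    are offset per (imf, pair, participant) so folds are independent but
    reproducible.
    """
    results = []
    for imf_idx, participants in imf_epochs.items():
        for pi, pair in enumerate(pairs):
            cond_a, cond_b = pair
            rows, times = [], None
            skip = False
            for p, ep in enumerate(participants):
                present = set(ep.labels)
                if cond_a not in present or cond_b not in present:
                    logger.warning(
                        "participant %d lacks label(s) for pair %s, pair skipped", p, pair
                    )
                    skip = True
                    break
                sub_seed = (seed + 1009 * p + 101 * pi + 13 * (imf_idx or 0)) % (2**31)
                rows.append(
                    time_resolved_decode(
                        ep.select(cond_a), ep.select(cond_b), n_folds, sub_seed, C
                    )
                )
                times = ep.times
            if skip or not rows:
                continue
            results.append(
                DecodingResult(
                    auc=np.vstack(rows),
                    pair=pair,
                    feature_space=feature_space,
                    imf=imf_idx,
                    n_folds=n_folds,
                    seed=seed,
                    times=times,
                )
            )
    return results
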