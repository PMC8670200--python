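"""Classifier evaluation against experimental labels.

A gene-score classifier predicts "phosphorylated" when the gene score clears
a threshold.  Genes present in the experimental reference are the positives;
everything else in the universe is negative.  The operating threshold is the
maximizer of the Youden statistic J = tpr - fpr on the ROC curve, stabilized
by averaging over random subsamples of the scored universe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .refsets import MISSING_SCORE, GeneScoreTable, ReferenceSet

log = logging.getLogger(__name__)

#: marker for a metric whose denominator is zero
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(predicted: ReferenceSet, positives: ReferenceSet,
                     universe: ReferenceSet) -> ConfusionCounts:
    """tp / fp / tn / fn of a predicted set against labelled positives.

    Both ``predicted`` and ``positives`` must be contained in the universe.
    """
    for name, s in (("predicted", predicted), ("positives", positives)):
        outside = s.members - universe.members
        if outside:
            raise ValueError(
                f"{name} set not contained in universe; offending ids: "
                f"{sorted(outside)[:10]}{'...' if len(outside) > 10 else ''}")
    tp = len(predicted.members & positives.members)
    fp = len(predicted.members - positives.members)
    fn = len(positives.members - predicted.members)
    tn = len(universe.members - (predicted.members | positives.members))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else UNDEFINED


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """tpr/fpr/sensitivity/specificity/precision; NaN marks a 0/0 case."""
    tpr = _ratio(c.tp, c.tp + c.fn)
    return {
        "tpr": tpr,
        "fpr": _ratio(c.fp, c.fp + c.tn),
        "sensitivity": tpr,
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "precision": _ratio(c.tp, c.tp + c.fp),
    }


@dataclass
class RocCurve:
    """ROC sweep over score thresholds, highest threshold first.

    The first point is the sentinel above the maximum score (nothing
    predicted, tpr = fpr = 0) and the last is the predict-everything closure
    (threshold recorded as -1.0, tpr = fpr = 1), so the trapezoid AUC spans
    the full unit square even when some genes carry the -1 missing flag.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    #: candidate cutoffs = the unique valid scores (sentinel/closure excluded)
    score_thresholds: np.ndarray = field(default_factory=lambda: np.array([]))


def _score_label_arrays(scores: GeneScoreTable, positives: ReferenceSet,
                        universe: ReferenceSet) -> tuple[np.ndarray, np.ndarray]:
    genes = sorted(universe.members)
    # genome genes missing from the score table behave as unscored (-1)
    s = np.array([scores.scores.get(g, MISSING_SCORE) for g in genes])
    y = np.array([g in positives.members for g in genes], dtype=bool)
    return s, y


def roc_curve(scores: GeneScoreTable, positives: ReferenceSet,
              universe: ReferenceSet) -> RocCurve:
    """ROC curve of the gene-score classifier.

    Candidate thresholds are the unique valid scores observed (>=-inclusive
    prediction); genes flagged -1 are negative at every score threshold.
    """
    s, y = _score_label_arrays(scores, positives, universe)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative gene")
    valid = s != MISSING_SCORE
    cand = np.unique(s[valid])[::-1]  # descending
    if cand.size == 0:
        raise ValueError("no valid scores: every gene carries the -1 missing flag")
    # cumulative tp/fp as the threshold walks down the unique scores
    order = np.argsort(-s[valid], kind="stable")
    sv, yv = s[valid][order], y[valid][order]
    tp_cum = np.cumsum(yv)
    fp_cum = np.cumsum(~yv)
    # index of the last gene with score >= each candidate threshold
    last = np.searchsorted(-sv, -cand, side="right") - 1
    tpr_mid = tp_cum[last] / n_pos
    fpr_mid = fp_cum[last] / n_neg
    thresholds = np.concatenate(([cand[0] + 1.0], cand, [-1.0]))
    tpr = np.concatenate(([0.0], tpr_mid, [1.0]))
    fpr = np.concatenate(([0.0], fpr_mid, [1.0]))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                    score_thresholds=cand)


def optimal_threshold(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J = tpr - fpr; ties go to the largest cutoff.

    Only genuine score cutoffs are candidates, so a flat classifier returns
    its single score (J = 0) rather than the sentinel.
    """
    mask = np.isin(roc.thresholds, roc.score_thresholds)
    j = roc.tpr[mask] - roc.fpr[mask]
    cand = roc.thresholds[mask]
    # thresholds descend, so the first exact optimum is the largest cutoff
    return float(cand[np.argmax(j == j.max())])


def youden_threshold(scores: GeneScoreTable, positives: ReferenceSet,
                     universe: ReferenceSet) -> float:
    return optimal_threshold(roc_curve(scores, positives, universe))


def resampled_threshold(scores: GeneScoreTable, positives: ReferenceSet,
                        universe: ReferenceSet, n_rep: int = 5000,
                        frac: float = 0.30, seed: int = 0) -> dict:
    """Mean Youden threshold over random subsamples of the universe.

    Each replicate draws ``floor(frac * |universe|)`` genes without
    replacement and recomputes the Youden-optimal threshold on the
    subsample.  Replicates lacking either class are redrawn (count logged) so
    the number of replicates stays fixed.  Fully reproducible given ``seed``.
    """
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0,1), got {frac}")
    genes = sorted(universe.members)
    s = np.array([scores.scores.get(g, MISSING_SCORE) for g in genes])
    y = np.array([g in positives.members for g in genes], dtype=bool)
    n_draw = math.floor(frac * len(genes))
    if n_draw < 2:
        raise ValueError("subsample too small; increase frac or the universe")
    rng = np.random.default_rng(seed)
    per_rep = np.empty(n_rep)
    n_redrawn = 0
    for i in range(n_rep):
        while True:
            idx = rng.choice(len(genes), size=n_draw, replace=False)
            ys = y[idx]
            if ys.any() and not ys.all():
                break
            n_redrawn += 1
        sub_scores = GeneScoreTable({genes[j]: s[j] for j in idx})
        sub_universe = ReferenceSet("sub", frozenset(genes[j] for j in idx))
        sub_pos = ReferenceSet("pos", frozenset(g for g in sub_universe if g in positives))
        per_rep[i] = optimal_threshold(roc_curve(sub_scores, sub_pos, sub_universe))
    if n_redrawn:
        log.info("redrew %d single-class resamples", n_redrawn)
    return {
        "mean_threshold": float(per_rep.mean()),
        "sd_threshold": float(per_rep.std(ddof=1)) if n_rep > 1 else 0.0,
        "quantiles": {q: float(np.quantile(per_rep, q))
                      for q in (0.05, 0.25, 0.5, 0.75, 0.95)},
        "per_rep_thresholds": per_rep,
        "n_rep": n_rep,
        "frac": frac,
        "seed": seed,
        "n_redrawn": n_redrawn,
    }
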