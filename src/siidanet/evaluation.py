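"""Goodness-of-fit assessment for relational models.

Model adequacy is judged by four network statistics computed on the
grand-mean-centred relational matrix: the standard deviations of ego (row)
and alter (column) means, the dyadic correlation between the two directions
of each dyad, and a standardized third-moment measure of triadic
dependence. A fitted model is scored by the root-mean-square error between
each statistic's posterior-predictive distribution and its observed value,
plus tie-classification performance (F1 and accuracy) of the posterior mean
tie probabilities. Models are ranked by mean rank across the four RMSEs,
with ties broken by F1 and then by parameter count (fewest wins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GOFStats",
    "ModelAssessment",
    "gof_statistics",
    "gof_rmse",
    "classification_scores",
    "rank_models",
]

GOF_NAMES = ("sd_ego_means", "sd_alter_means", "dyadic_correlation", "triadic_dependence")


@dataclass(frozen=True)
class GOFStats:
    sd_ego_means: float
    sd_alter_means: float
    dyadic_correlation: float
    triadic_dependence: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in GOF_NAMES])


def gof_statistics(matrix: np.ndarray) -> GOFStats:
    """Four relational goodness-of-fit statistics of a square matrix.

    The matrix is centred at its off-diagonal grand mean to give residuals
    e. Then:

    * ``sd_ego_means``: sd of the row means of e (heterogeneity of senders);
    * ``sd_alter_means``: sd of the column means of e (of receivers);
    * ``dyadic_correlation``: Pearson correlation of (e_ij, e_ji) over
      unordered dyads;
    * ``triadic_dependence``: sum over ordered triples of distinct nodes of
      e_ij * e_jk * e_ik, normalized by the triple count times sd(e)^3.

    The diagonal is structurally missing and excluded everywhere.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n) or n < 3:
        raise ValueError("matrix must be square with at least 3 nodes")
    off = ~np.eye(n, dtype=bool)
    e = m - m[off].mean()
    e = np.where(off, e, 0.0)

    row_means = e.sum(axis=1) / (n - 1)
    col_means = e.sum(axis=0) / (n - 1)
    sd_ego = float(np.std(row_means, ddof=1))
    sd_alter = float(np.std(col_means, ddof=1))

    sd_e = float(np.std(e[off], ddof=1))
    if sd_e == 0.0:
        raise ValueError(
            "all-constant relational matrix: dyadic and triadic statistics are undefined"
        )
    iu = np.triu_indices(n, k=1)
    upper = e[iu]
    lower = e[(iu[1], iu[0])]
    su, sl = np.std(upper), np.std(lower)
    if su == 0.0 or sl == 0.0:
        raise ValueError("zero-variance triangle: dyadic correlation undefined")
    dyad_cor = float(np.corrcoef(upper, lower)[0, 1])

    triple_sum = float(np.sum((e @ e) * e))  # sum_{i,j,k distinct} e_ij e_jk e_ik
    n_triples = n * (n - 1) * (n - 2)
    triad = triple_sum / (n_triples * sd_e**3)

    return GOFStats(sd_ego, sd_alter, dyad_cor, triad)


def gof_rmse(observed: GOFStats, predictive: Sequence[GOFStats]) -> dict[str, float]:
    """RMSE of each statistic's posterior-predictive draws around its
    observed value: sqrt(mean_t (s_t - s_obs)^2)."""
    if len(predictive) < 1:
        raise ValueError("need at least one posterior-predictive draw")
    obs = observed.as_array()
    draws = np.stack([p.as_array() for p in predictive])
    rmse = np.sqrt(np.mean((draws - obs) ** 2, axis=0))
    return dict(zip(GOF_NAMES, rmse.tolist()))


def classification_scores(
    tie_probabilities: np.ndarray,
    observed: np.ndarray,
    threshold: float = 0.5,
) -> dict[str, float]:
    """F1 and accuracy of thresholded tie probabilities against the
    observed binary matrix, diagonal excluded.

    With no predicted and no observed positives, F1 is defined as 0 with a
    warning (precision and recall are both degenerate).
    """
    p = np.asarray(tie_probabilities, dtype=float)
    y = np.asarray(observed, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probability and outcome matrices must share a shape")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("tie probabilities must lie in [0, 1]")
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    pred = p[off] > threshold
    obs = y[off] > 0.5
    tp = int(np.sum(pred & obs))
    fp = int(np.sum(pred & ~obs))
    fn = int(np.sum(~pred & obs))
    tn = int(np.sum(~pred & ~obs))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    if tp == 0 and (fp + fn) == 0:
        warnings.warn(
            "no predicted and no observed ties: F1 defined as 0", RuntimeWarning
        )
        f1 = 0.0
    elif tp == 0:
        f1 = 0.0
        if fn > 0 and fp == 0:
            warnings.warn("no predicted positives: F1 is 0", RuntimeWarning)
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall)
    return {"f1": f1, "accuracy": accuracy, "tp": tp, "fp": fp, "fn": fn, "tn": tn}


@dataclass(frozen=True)
class ModelAssessment:
    """One model's scores for ranking: four GOF RMSEs, F1, accuracy and the
    number of fitted fixed-effect parameters."""

    name: str
    rmse: dict
    f1: float
    accuracy: float
    n_parameters: int


def rank_models(assessments: Sequence[ModelAssessment]) -> list[dict]:
    """Rank models by mean rank across the four RMSE statistics.

    Lower RMSE is better. Ties on mean rank are broken by higher F1, then
    by fewer parameters (the simplest adequate model wins). Returns a list
    of dicts ordered best-first with the selected model flagged.
    """
    if len(assessments) < 2:
        raise ValueError("need at least two models to rank")
    k = len(assessments)
    mean_ranks = np.zeros(k)
    for stat in GOF_NAMES:
        vals = np.array([a.rmse[stat] for a in assessments])
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(k)
        ranks[order] = np.arange(1, k + 1)
        # average ranks over exact ties
        for v in np.unique(vals):
            mask = vals == v
            if mask.sum() > 1:
                ranks[mask] = ranks[mask].mean()
        mean_ranks += ranks / len(GOF_NAMES)
    keyed = sorted(
        range(k),
        key=lambda i: (mean_ranks[i], -assessments[i].f1, assessments[i].n_parameters),
    )
    out = []
    for pos, i in enumerate(keyed):
        a = assessments[i]
        out.append(
            {
                "name": a.name,
                "mean_rank": float(mean_ranks[i]),
                "rmse": dict(a.rmse),
                "f1": a.f1,
                "accuracy": a.accuracy,
                "n_parameters": a.n_parameters,
                "selected": pos == 0,
            }
        )
    return out
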