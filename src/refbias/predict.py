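"""Predicting biased sites from real (truth-free) data.

On real reads only assignment balance (AB) and the mapping qualities of
the overlapping reads are available. Biased sites pair extreme AB with
low average MAPQ, so the two features are combined into a ranking score
either multiplicatively,

    score_mul = (mean_MAPQ - MAPQ_max)/MAPQ_max * AB,

or additively,

    score_add = (mean_MAPQ - MAPQ_max)/MAPQ_max * 1.5 + AB.

Lower scores rank as more likely biased; that orientation is fixed here
(``flip_orientation`` inverts it for ALT-skew investigations). Before
scoring, sites whose evidence is dominated by "other" alleles -- a
signature of missing or unphased variants rather than of bias -- are
filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc, average_precision_score, precision_recall_curve, roc_curve

from .assign import SiteEvidence

__all__ = [
    "PredictConfig",
    "SitePrediction",
    "filter_affected",
    "prediction_score",
    "evaluate_ranking",
]


@dataclass
class PredictConfig:
    mapq_max: int = 42  # 60 for aligners whose MAPQ scale tops out at 60
    add_weight: float = 1.5
    affected_other_frac: float = 0.9
    affected_other_frac_one_absent: float = 0.4
    flip_orientation: bool = False

    def __post_init__(self) -> None:
        if self.mapq_max <= 0:
            raise ValueError("mapq_max must be positive")
        for t in (self.affected_other_frac, self.affected_other_frac_one_absent):
            if not 0 < t < 1:
                raise ValueError("affected-site thresholds must be in (0, 1)")


@dataclass
class SitePrediction:
    chrom: str
    pos: int
    mean_mapq: float
    AB: Optional[float]
    score_mul: Optional[float]
    score_add: Optional[float]
    label: Optional[str] = None  # balanced | biased


def filter_affected(evidence: SiteEvidence, config: Optional[PredictConfig] = None) -> bool:
    """True when a site is likely a phasing/representation artifact.

    Affected sites have >90% "other" reads, or one HET allele entirely
    absent with >40% "other" reads. Zero-coverage sites are affected.
    """
    config = config or PredictConfig()
    total = evidence.n_overlapping
    if total == 0:
        return True
    other_frac = evidence.n_other / total
    if other_frac > config.affected_other_frac:
        return True
    if (evidence.n_ref == 0 or evidence.n_alt == 0) and (
        other_frac > config.affected_other_frac_one_absent
    ):
        return True
    return False


def prediction_score(
    mean_mapq: float,
    ab: Optional[float],
    mode: str = "mul",
    config: Optional[PredictConfig] = None,
) -> Optional[float]:
    """Combined bias score; None when AB is undefined."""
    config = config or PredictConfig()
    if ab is None:
        return None
    if not 0 <= mean_mapq <= config.mapq_max:
        raise ValueError(f"mean_mapq {mean_mapq} outside [0, {config.mapq_max}]")
    mapq_term = (mean_mapq - config.mapq_max) / config.mapq_max
    if mode == "mul":
        score = mapq_term * ab
    elif mode == "add":
        score = mapq_term * config.add_weight + ab
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    return -score if config.flip_orientation else score


def evaluate_ranking(
    scores: Sequence[float], labels: Sequence[str]
) -> dict[str, np.ndarray | float]:
    """ROC and PR curves for a biased/balanced ranking.

    Lower scores mean "more likely biased", so -score is used as the
    decision function with "biased" the positive class. ROC area is
    trapezoidal; PR area is the step-wise average precision (trapezoids
    on a PR curve are ill-defined under tied recalls). Tied scores cross
    thresholds simultaneously.
    """
    y = np.asarray([1 if lab == "biased" else 0 for lab in labels])
    s = -np.asarray(scores, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("evaluation needs at least one site of each label")
    fpr, tpr, _ = roc_curve(y, s)
    precision, recall, _ = precision_recall_curve(y, s)
    return {
        "fpr": fpr,
        "tpr": tpr,
        "auc": float(auc(fpr, tpr)),
        "precision": precision,
        "recall": recall,
        "auprc": float(average_precision_score(y, s)),
    }
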