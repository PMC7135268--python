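"""ROC/AUC performance assessment and across-shuffle summaries.

The AUC is computed as the rank-based Mann-Whitney statistic — the
probability that a randomly chosen bad-outcome case is scored above a
randomly chosen good-outcome case, with ties counted one half — which
equals the trapezoidal area under the ROC curve. Repeated-shuffle results
are summarized by the median and interquartile range per model and
partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ShuffleResult", "roc_auc", "summarize_performance"]


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC with the tie convention (ties count 1/2)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    rank_sum_pos = ranks[y == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class ShuffleResult:
    """Outcome of one shuffle: tuned models, AUCs, raw importances."""

    shuffle: int
    seed: int
    hyperparams: dict = field(default_factory=dict)   # family -> config
    train_auc: dict = field(default_factory=dict)     # family -> AUC
    test_auc: dict = field(default_factory=dict)      # family -> AUC
    importance: dict = field(default_factory=dict)    # family -> raw vector

    def __post_init__(self):
        for d in (self.train_auc, self.test_auc):
            for fam, auc in d.items():
                if not 0.0 <= auc <= 1.0:
                    raise ValueError(f"AUC out of [0,1] for {fam}: {auc}")


def summarize_performance(results: list[ShuffleResult]) -> pd.DataFrame:
    """Median AUC and IQR per model family and partition over shuffles.

    Quantiles use linear interpolation between order statistics.
    """
    if not results:
        raise ValueError("no shuffle results to summarize")
    families = list(results[0].test_auc)
    rows = []
    for fam in families:
        for partition, attr in (("train", "train_auc"), ("test", "test_auc")):
            aucs = np.array([getattr(r, attr)[fam] for r in results])
            q1, med, q3 = np.percentile(aucs, [25, 50, 75])
            rows.append(
                dict(model=fam, partition=partition,
                     median_auc=float(med), iqr=float(q3 - q1),
                     n_shuffles=len(aucs))
            )
    return pd.DataFrame(rows)
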