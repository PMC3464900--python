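"""Ranking-based gene-discovery evaluation.

Treatment-response candidates are ranked by a fold-change statistic (maximum
over timepoints, or the value at a fixed timepoint such as the 26-hour peak of
cold-response regulons) or by distance in a PCA score plot, then scored
against a gold-standard gene list with an ROC walk.  The headline summary is
the recall at the rank where cumulative true positives equal cumulative false
positives — only genes above that line are considered biologically relevant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.decomposition import PCA

from .preprocess import ExpressionMatrix

__all__ = [
    "FoldChangeMatrix",
    "RankedList",
    "RocResult",
    "ZTestResult",
    "fold_change",
    "rank_genes",
    "roc",
    "ztest_pvalues",
    "pca_distance_rank",
]


@dataclass
class FoldChangeMatrix:
    """Per-gene, per-timepoint log fold change (treatment minus control)."""

    gene_ids: list[str]
    grid_times_h: np.ndarray
    fc: np.ndarray

    def __post_init__(self) -> None:
        self.grid_times_h = np.asarray(self.grid_times_h, dtype=float)
        self.fc = np.asarray(self.fc, dtype=float)
        if self.fc.shape != (len(self.gene_ids), self.grid_times_h.size):
            raise ValueError("fc shape does not match gene/time dimensions")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fc, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.grid_times_h,
        )


@dataclass
class RankedList:
    """Genes ordered by a descending statistic; ties keep input order."""

    gene_ids: list[str]
    statistic: np.ndarray
    statistic_name: str

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        if np.any(np.diff(self.statistic) > 1e-12):
            raise ValueError("statistic must be non-increasing down the list")


@dataclass
class RocResult:
    """Cumulative TP/FP walk down a ranked list against a gold-standard set."""

    tp: np.ndarray
    fp: np.ndarray
    gold_size: int
    recall_at_tp_eq_fp: float


@dataclass
class ZTestResult:
    """Across-gene z-scores and one-sided upper-tail p-values."""

    gene_ids: list[str]
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float


def fold_change(
    control: ExpressionMatrix, treatment: ExpressionMatrix
) -> FoldChangeMatrix:
    """Log fold change: treatment log value minus control log value, per point."""
    if control.gene_ids != treatment.gene_ids:
        raise ValueError("control and treatment gene lists differ")
    if control.timepoints_h.size != treatment.timepoints_h.size or not np.allclose(
        control.timepoints_h, treatment.timepoints_h
    ):
        raise ValueError("control and treatment time grids differ")
    return FoldChangeMatrix(
        list(control.gene_ids),
        control.timepoints_h.copy(),
        treatment.values - control.values,
    )


def rank_genes(
    fcm: FoldChangeMatrix, statistic: str = "max_fc", at_time_h: float | None = None
) -> RankedList:
    """Rank genes by maximum fold change or by fold change at a fixed time.

    ``statistic`` is ``"max_fc"`` or ``"fc_at_time"`` (requires ``at_time_h``
    on the grid).  Ties are broken by input gene order (stable sort).
    """
    if statistic == "max_fc":
        values = fcm.fc.max(axis=1)
        name = "max_fc"
    elif statistic == "fc_at_time":
        if at_time_h is None:
            raise ValueError("fc_at_time requires at_time_h")
        hits = np.nonzero(np.isclose(fcm.grid_times_h, at_time_h))[0]
        if hits.size == 0:
            raise ValueError(f"time {at_time_h} h is not on the grid")
        values = fcm.fc[:, hits[0]]
        name = f"fc_at_{at_time_h:g}h"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    order = np.argsort(-values, kind="stable")
    return RankedList(
        [fcm.gene_ids[i] for i in order], values[order], name
    )


def roc(rl: RankedList, gold: set[str]) -> RocResult:
    """Walk the ranked list, counting cumulative true and false positives.

    ``recall_at_tp_eq_fp`` is TP / |gold| at the first rank where TP equals FP
    with both positive.  If the counts never meet at positive values, the
    recall at the last rank where TP > FP is reported (0 if there is none).
    """
    gold = set(gold)
    if not gold:
        raise ValueError("gold-standard set is empty")
    missing = gold - set(rl.gene_ids)
    if missing:
        raise ValueError(f"gold genes absent from ranking: {sorted(missing)[:5]}")
    hits = np.array([g in gold for g in rl.gene_ids])
    tp = np.cumsum(hits)
    fp = np.cumsum(~hits)
    eq = np.nonzero((tp == fp) & (tp > 0))[0]
    if eq.size:
        recall = tp[eq[0]] / len(gold)
    else:
        above = np.nonzero(tp > fp)[0]
        recall = tp[above[-1]] / len(gold) if above.size else 0.0
    return RocResult(tp, fp, len(gold), float(recall))


def ztest_pvalues(rl: RankedList, alpha: float = 0.05) -> ZTestResult:
    """Across-gene Z-test: standardize the statistic, upper-tail p-values."""
    if rl.statistic.size < 3:
        raise ValueError("need at least 3 genes for a Z-test")
    sd = rl.statistic.std(ddof=1)
    if sd == 0:
        raise ValueError("statistic has zero variance")
    z = (rl.statistic - rl.statistic.mean()) / sd
    p = norm.sf(z)
    return ZTestResult(list(rl.gene_ids), z, p, p <= alpha, alpha)


def pca_distance_rank(
    m: ExpressionMatrix | FoldChangeMatrix, corner: str = "bottom-left"
) -> RankedList:
    """Rank genes by Euclidean distance from a corner of the PC1/PC2 plot.

    Genes far from the bulk of the scatter in the configured corner direction
    are the strongest responders.  ``corner`` is one of ``"bottom-left"``,
    ``"bottom-right"``, ``"top-left"``, ``"top-right"``, taken over the score
    ranges of the first two principal components.
    """
    values = m.fc if isinstance(m, FoldChangeMatrix) else m.values
    gene_ids = list(m.gene_ids)
    if len(gene_ids) < 3:
        raise ValueError("need at least 3 genes for PCA")
    scores = PCA(n_components=2).fit_transform(values)
    if not np.all(np.isfinite(scores)) or np.allclose(scores.std(axis=0), 0):
        raise ValueError("degenerate input: PCA scores are rank-deficient")
    vert, horiz = corner.split("-")
    x = scores[:, 0].min() if horiz == "left" else scores[:, 0].max()
    y = scores[:, 1].min() if vert == "bottom" else scores[:, 1].max()
    dist = np.hypot(scores[:, 0] - x, scores[:, 1] - y)
    order = np.argsort(-dist, kind="stable")
    return RankedList([gene_ids[i] for i in order], dist[order], "pca_distance")
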