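"""Performance metrics and cross-validation protocols.

Implements the four standard binary-classification metrics —
sensitivity (Sn), specificity (Sp), accuracy (Acc) and Matthews
correlation coefficient (MCC) — in the N+/N- error-count
parameterisation, plus ROC/AUC from decision values, and the protocols
used to assess the predictor: jackknife (leave-one-out), stratified
k-fold CV, a sweep over the maximum pairwise distance d, and an
independent-dataset test.

Protocol convention: C and gamma are fixed once (e.g. grid-searched on
the full set) and reused in every jackknife round. That mirrors common
practice in this literature but lets selection information leak into
the resampling estimate; :func:`jackknife` exposes ``nested_grid`` to
re-run the grid search inside every round instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import EncodingConfig, encode_batch
from .io_fasta import LabeledDataset
from .model import TrainedModel, grid_search, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Class totals and error counts of a binary prediction.

    ``n_plus``/``n_minus`` are the true class sizes; ``fn`` is the
    number of positives predicted negative and ``fp`` the number of
    negatives predicted positive.
    """

    n_plus: int
    n_minus: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if not (0 <= self.fn <= self.n_plus and 0 <= self.fp <= self.n_minus):
            raise ValueError(
                f"inconsistent counts: n+={self.n_plus}, n-={self.n_minus}, "
                f"fn={self.fn}, fp={self.fp}"
            )

    @property
    def tp(self) -> int:
        return self.n_plus - self.fn

    @property
    def tn(self) -> int:
        return self.n_minus - self.fp

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        if yt.shape != yp.shape:
            raise ValueError("y_true and y_pred lengths differ")
        return cls(
            n_plus=int(np.sum(yt == +1)),
            n_minus=int(np.sum(yt == -1)),
            fn=int(np.sum((yt == +1) & (yp == -1))),
            fp=int(np.sum((yt == -1) & (yp == +1))),
        )


@dataclass
class MetricsReport:
    """Sn/Sp/Acc/MCC (and AUC when decision values were available).

    ``mcc`` is ``None`` with ``mcc_defined=False`` when the Matthews
    denominator vanishes (a degenerate confusion table); it is reported
    as undefined rather than coerced to 0.
    """

    sn: float
    sp: float
    acc: float
    mcc: float | None
    counts: ConfusionCounts
    mcc_defined: bool = True
    auc: float | None = None

    def to_row(self, **extra) -> dict:
        """Flatten to a dict suitable for a one-row report table."""
        row = dict(extra)
        row.update(
            Sn=self.sn, Sp=self.sp, Acc=self.acc,
            MCC=self.mcc if self.mcc_defined else float("nan"),
            AUC=self.auc if self.auc is not None else float("nan"),
        )
        return row


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sn/Sp/Acc/MCC from error counts.

    Sn = 1 - fn/N+, Sp = 1 - fp/N-, Acc = fraction correct overall, and
    MCC by the standard Matthews formula. Boundary behaviour: no false
    negatives gives Sn = 1; a perfect prediction gives MCC = 1; total
    disagreement gives MCC = -1; half of each class wrong gives MCC = 0.
    """
    n = counts.n_plus + counts.n_minus
    if n == 0:
        raise ValueError("empty prediction set")
    sn = 1.0 - counts.fn / counts.n_plus if counts.n_plus else float("nan")
    sp = 1.0 - counts.fp / counts.n_minus if counts.n_minus else float("nan")
    acc = (counts.tp + counts.tn) / n
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=None,
                             counts=counts, mcc_defined=False)
    mcc = (tp * tn - fp * fn) / denom
    return MetricsReport(sn=sn, sp=sp, acc=acc, mcc=mcc, counts=counts)


def roc_auc(
    decision_values: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC curve and AUC from a threshold sweep over decision values.

    Returns ``(points, auc)`` where ``points`` is an array of
    (1 - Sp, Sn) pairs from (0, 0) to (1, 1), one step per distinct
    decision value; AUC is the trapezoid area, with tied scores
    contributing half credit so that AUC equals the normalized
    Mann-Whitney rank statistic P(score+ > score-) + P(tie)/2.
    """
    dv = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if dv.shape != y.shape:
        raise ValueError("decision_values and labels lengths differ")
    n_pos = int(np.sum(y == +1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes to be present")

    order = np.argsort(-dv, kind="mergesort")
    dv_sorted, y_sorted = dv[order], y[order]
    # group ties: one ROC vertex per distinct threshold
    distinct = np.nonzero(np.diff(dv_sorted))[0]
    block_ends = np.r_[distinct, dv_sorted.size - 1]
    tps = np.cumsum(y_sorted == +1)[block_ends]
    fps = np.cumsum(y_sorted == -1)[block_ends]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def _pooled_report(
    y_true: np.ndarray, y_pred: np.ndarray, dv: np.ndarray
) -> MetricsReport:
    report = compute_metrics(ConfusionCounts.from_predictions(y_true, y_pred))
    _, report.auc = roc_auc(dv, y_true)
    return report


def jackknife(
    dataset: LabeledDataset,
    config: EncodingConfig,
    C: float,
    gamma: float,
    nested_grid: dict | None = None,
) -> MetricsReport:
    """Leave-one-out test: each protein is predicted by a model trained
    on all the others; metrics pool the N held-out predictions.

    With ``nested_grid`` (keys ``C_grid``, ``gamma_grid``, ``folds``,
    ``seed``), the hyperparameters are re-selected inside every round —
    slower, but free of selection leakage.
    """
    dataset.check_two_classes()
    if dataset.n_positive < 2 or dataset.n_negative < 2:
        raise ValueError("jackknife requires >= 2 members per class")
    X, _ = encode_batch(dataset.records, config)
    y = np.asarray(dataset.labels, dtype=int)
    n = len(y)
    preds = np.empty(n, dtype=int)
    dv = np.empty(n, dtype=float)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            C_i, gamma_i = C, gamma
            if nested_grid is not None:
                res = grid_search(X[mask], y[mask], **nested_grid)
                C_i, gamma_i = res.best_C, res.best_gamma
            m = train(X[mask], y[mask], C=C_i, gamma=gamma_i)
        except Exception as e:
            raise type(e)(f"jackknife round {i} ({dataset.records[i].id}): {e}") from e
        finally:
            mask[i] = True
        preds[i], dv[i] = m.predict(X[i])
        logger.debug("jackknife round %d/%d done", i + 1, n)
    logger.info("jackknife: %d training rounds completed", n)
    return _pooled_report(y, preds, dv)


def kfold_cv(
    dataset: LabeledDataset,
    config: EncodingConfig,
    C: float,
    gamma: float,
    k: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold CV; metrics pool the held-out predictions.

    Fold assignment is deterministic given ``seed``; stratification
    keeps class ratios within one sample per fold. ``k`` equal to the
    dataset size reduces to the jackknife protocol (leave-one-out
    splits, since stratification is impossible there).
    """
    dataset.check_two_classes()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    X, _ = encode_batch(dataset.records, config)
    y = np.asarray(dataset.labels, dtype=int)
    n = len(y)
    if k == n:
        idx = np.arange(n)
        splits = [(np.delete(idx, i), idx[i : i + 1]) for i in range(n)]
    else:
        minority = min(dataset.n_positive, dataset.n_negative)
        if k > minority:
            raise ValueError(f"k={k} exceeds the minority class size {minority}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    preds = np.empty(len(y), dtype=int)
    dv = np.empty(len(y), dtype=float)
    for train_idx, test_idx in splits:
        m = train(X[train_idx], y[train_idx], C=C, gamma=gamma)
        preds[test_idx], dv[test_idx] = m.predict_batch(X[test_idx])
    return _pooled_report(y, preds, dv)


def sweep_distance(
    dataset: LabeledDataset,
    alphabet,
    d_values: Sequence[int],
    C: float,
    gamma: float,
    k: int = 5,
    seed: int = 0,
    normalization: str = "per_stratum",
) -> tuple[pd.DataFrame, int]:
    """CV accuracy as a function of the maximum pairwise distance d.

    Runs one k-fold CV per value of d and returns the (d, Acc, ...)
    table plus the accuracy-maximising d (first maximum on ties).
    """
    if len(d_values) == 0:
        raise ValueError("d_values must be non-empty")
    rows = []
    for d in d_values:
        config = EncodingConfig(alphabet=alphabet, d_max=int(d),
                                normalization=normalization)
        rep = kfold_cv(dataset, config, C=C, gamma=gamma, k=k, seed=seed)
        rows.append(rep.to_row(d=int(d)))
    table = pd.DataFrame(rows)
    best_d = int(table.loc[table["Acc"].idxmax(), "d"])
    return table, best_d


def independent_test(
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    config: EncodingConfig,
    C: float,
    gamma: float,
) -> MetricsReport:
    """Train once on ``train_set``, evaluate on ``test_set``.

    Overlapping record ids between the two sets are allowed but warned
    about (the metrics then partly measure resubstitution).
    """
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    overlap = sorted(
        {r.id for r in train_set.records} & {r.id for r in test_set.records}
    )
    if overlap:
        warnings.warn(
            "train and test sets share %d id(s): %s"
            % (len(overlap), ", ".join(overlap[:10])),
            stacklevel=2,
        )
    X_tr, _ = encode_batch(train_set.records, config)
    m = train(X_tr, train_set.labels, C=C, gamma=gamma, config=config)
    X_te, _ = encode_batch(test_set.records, config)
    y_te = np.asarray(test_set.labels, dtype=int)
    preds, dv = m.predict_batch(X_te)
    return _pooled_report(y_te, preds, dv)


def write_report_tsv(rows: Sequence[dict], path) -> None:
    """Write protocol-run rows (profile, d, C, gamma, Sn, Sp, Acc, MCC,
    AUC, ...) as a TSV table."""
    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)


def write_roc_tsv(points: np.ndarray, path) -> None:
    """Write ROC vertices as a two-column (fpr, tpr) TSV."""
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(
        path, sep="\t", index=False
    )
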