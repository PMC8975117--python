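"""Classification and clinician-agreement metrics.

For the discrete output: accuracy, confusion matrix and macro one-vs-rest
AUC.  For the continuous output: the absolute-error distribution (CDF and
0.25-wide histogram), Pearson r, RMSE, ICC(2,1) (two-way random effects,
absolute agreement, single measure) and Bland-Altman bias with 95% limits
of agreement against the mean clinician score.  Inter-rater agreement is
the pairwise Pearson correlation between raters — the index the automatic
score is compared against.

For models without a continuous score the one-vs-rest AUC uses the
negative distance of the predicted class from each class as a coarse
surrogate score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
import yaml
from scipy import stats
from sklearn.metrics import accuracy_score, confusion_matrix, roc_auc_score

logger = logging.getLogger(__name__)

CDF_THRESHOLDS = (0.0, 0.5, 1.0, 2.0)
HISTOGRAM_BIN_WIDTH = 0.25
CLASSES = (0, 1, 2, 3)


@dataclass
class EvaluationReport:
    """All metrics for one model under LOSO."""

    model_kind: str
    accuracy: float
    auc_macro: Optional[float]
    confusion: np.ndarray
    error_cdf: Optional[dict[float, float]] = None
    histogram: Optional[tuple[np.ndarray, np.ndarray]] = None
    pearson_r: Optional[float] = None
    rmse: Optional[float] = None
    icc: Optional[float] = None
    bland_altman: Optional[tuple[float, float, float]] = None
    interrater_range: Optional[tuple[float, float]] = None

    def to_yaml(self, path) -> None:
        payload = {
            "model_kind": self.model_kind,
            "accuracy": float(self.accuracy),
            "auc_macro": None if self.auc_macro is None else float(self.auc_macro),
            "confusion": self.confusion.astype(int).tolist(),
            "error_cdf": None if self.error_cdf is None else
                {float(k): float(v) for k, v in self.error_cdf.items()},
            "pearson_r": _opt(self.pearson_r),
            "rmse": _opt(self.rmse),
            "icc": _opt(self.icc),
            "bland_altman": None if self.bland_altman is None else
                [float(v) for v in self.bland_altman],
            "interrater_range": None if self.interrater_range is None else
                [float(v) for v in self.interrater_range],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def _opt(v):
    return None if v is None else float(v)


def _class_scores(values: np.ndarray, classes: Sequence[int]) -> np.ndarray:
    """Per-class ranking scores from a scalar severity value: -|v - k|."""
    return -np.abs(values[:, None] - np.asarray(classes)[None, :])


def classification_metrics(pred_labels: Sequence[int], true_labels: Sequence[int],
                           continuous: Optional[Sequence[float]] = None,
                           classes: Sequence[int] = CLASSES):
    """Accuracy, confusion matrix and macro one-vs-rest AUC.

    AUC ranks instances by the continuous score when available, otherwise
    by the predicted-class indicator distance; with a single class present
    in the truth AUC is undefined and reported as None.
    """
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if len(pred) != len(true):
        raise ValueError("prediction/label length mismatch")
    acc = float(accuracy_score(true, pred))
    conf = confusion_matrix(true, pred, labels=list(classes))
    present = np.unique(true)
    if len(present) < 2:
        logger.warning("single-class test set: AUC undefined")
        return acc, conf, None
    values = np.asarray(continuous, dtype=float) if continuous is not None \
        else pred.astype(float)
    scores = _class_scores(values, classes)
    # macro-average over classes present in the truth
    aucs = []
    for k, cls in enumerate(classes):
        y = (true == cls).astype(int)
        if y.min() == y.max():
            continue
        aucs.append(roc_auc_score(y, scores[:, k]))
    auc = float(np.mean(aucs)) if aucs else None
    return acc, conf, auc


def error_distribution(continuous: Sequence[float], mean_clinician: Sequence[float],
                       thresholds: Sequence[float] = CDF_THRESHOLDS):
    """Absolute-error CDF at the given thresholds and a 0.25-wide histogram."""
    x = np.asarray(continuous, dtype=float)
    y = np.asarray(mean_clinician, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch between scores and targets")
    err = np.abs(x - y)
    cdf = {float(thr): float(np.mean(err <= thr)) for thr in thresholds}
    top = max(HISTOGRAM_BIN_WIDTH, np.ceil(err.max() / HISTOGRAM_BIN_WIDTH) * HISTOGRAM_BIN_WIDTH)
    edges = np.arange(0.0, top + HISTOGRAM_BIN_WIDTH / 2, HISTOGRAM_BIN_WIDTH)
    counts, edges = np.histogram(err, bins=edges)
    return cdf, (counts, edges)


def icc_2_1(a: Sequence[float], b: Sequence[float]) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    df = pd.DataFrame({
        "targets": np.tile(np.arange(n), 2),
        "raters": np.repeat(["A", "B"], n),
        "score": np.concatenate([a, b]),
    })
    res = pg.intraclass_corr(data=df, targets="targets", raters="raters",
                             ratings="score")
    # the absolute-agreement single-measure row: labelled ICC2 or ICC(A,1)
    mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
    return float(res.loc[mask, "ICC"].iloc[0])


def agreement_metrics(continuous: Sequence[float], mean_clinician: Sequence[float]):
    """Pearson r, RMSE, ICC(2,1) and Bland-Altman (bias, lower, upper).

    Limits of agreement are bias +- 1.96 * SD(differences).  With a
    zero-variance input the correlation-based metrics are undefined and
    returned as None.
    """
    x = np.asarray(continuous, dtype=float)
    y = np.asarray(mean_clinician, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    diff = x - y
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    ba = (bias, bias - 1.96 * sd, bias + 1.96 * sd)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance input: r and ICC undefined")
        return None, rmse, None, ba
    r = float(stats.pearsonr(x, y)[0])
    icc = icc_2_1(x, y)
    return r, rmse, icc, ba


def interrater_agreement(ratings: pd.DataFrame):
    """Pairwise Pearson correlation between raters over shared recordings.

    ``ratings``: one row per recording, one column per rater; NaN marks a
    missing rating.  Returns (pairwise matrix, (min, max) over valid pairs).
    A rater pair with a constant column is reported as NaN.
    """
    cols = list(ratings.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 raters")
    if len(ratings) < 3:
        raise ValueError("need at least 3 recordings")
    mat = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    vals = []
    for i, ci in enumerate(cols):
        mat.loc[ci, ci] = 1.0
        for cj in cols[i + 1:]:
            pair = ratings[[ci, cj]].dropna()
            if len(pair) < 3 or np.ptp(pair[ci]) == 0 or np.ptp(pair[cj]) == 0:
                logger.warning("rater pair (%s, %s) has no valid correlation", ci, cj)
                continue
            r = float(stats.pearsonr(pair[ci], pair[cj])[0])
            mat.loc[ci, cj] = mat.loc[cj, ci] = r
            vals.append(r)
    rng = (float(np.min(vals)), float(np.max(vals))) if vals else (np.nan, np.nan)
    return mat, rng


def evaluate_predictions(preds: pd.DataFrame, labels: Sequence[int],
                         mean_scores: Sequence[float],
                         ratings: Optional[pd.DataFrame] = None,
                         model_kind: str = "ann") -> EvaluationReport:
    """Build the full report from a LOSO prediction frame."""
    cont = preds["continuous_score"].to_numpy(dtype=float) \
        if preds["continuous_score"].notna().any() else None
    acc, conf, auc = classification_metrics(preds["label"], labels, continuous=cont)
    report = EvaluationReport(model_kind=model_kind, accuracy=acc,
                              auc_macro=auc, confusion=conf)
    if cont is not None:
        cdf, hist = error_distribution(cont, mean_scores)
        r, rmse, icc, ba = agreement_metrics(cont, mean_scores)
        report.error_cdf = cdf
        report.histogram = hist
        report.pearson_r = r
        report.rmse = rmse
        report.icc = icc
        report.bland_altman = ba
    if ratings is not None:
        _, report.interrater_range = interrater_agreement(ratings)
    return report


def plot_error_histogram(report: EvaluationReport, path) -> None:
    """Histogram of |continuous - mean clinician| errors, 0.25-wide bins."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, edges = report.histogram
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           edgecolor="black", color="#4878d0")
    ax.set_xlabel("|continuous score − mean clinician score|")
    ax.set_ylabel("recordings")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bland_altman(continuous: Sequence[float], mean_clinician: Sequence[float],
                      path) -> None:
    """Bland-Altman plot: difference vs mean, with bias and 95% limits."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(continuous, dtype=float)
    y = np.asarray(mean_clinician, dtype=float)
    diff = x - y
    mean = (x + y) / 2.0
    bias = diff.mean()
    sd = diff.std(ddof=1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(mean, diff, s=14, alpha=0.7)
    for v, style in ((bias, "-"), (bias - 1.96 * sd, "--"), (bias + 1.96 * sd, "--")):
        ax.axhline(v, linestyle=style, color="crimson", linewidth=1)
    ax.set_xlabel("mean of method and clinicians")
    ax.set_ylabel("difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
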