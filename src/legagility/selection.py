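"""Correlation-ranked, gap-thresholded feature selection.

Features are ranked by the absolute Pearson correlation of each feature
with the continuous target (the mean rater score); features below the 0.4
floor — conventionally "weak" correlation — are discarded.  The three
largest drops between adjacent ranked |r| values define three candidate
thresholds (C1, C2, C3 in rank order); the candidate subsets are the
ranking prefixes ending just above each gap.  Each candidate feeds a roster
of classifiers under leave-one-subject-out validation and the subset with
the highest mean accuracy wins (ties to the smaller subset).  Finally a
redundancy rule drops the lower-ranked member of any feature pair more
correlated with each other than either is with the target.

Gaps are measured on the full ranking (the way they appear on a ranked
correlation plot), and candidate prefixes are truncated to the survivors
above the floor — so the drop that straddles the floor can select the full
surviving set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .models import ModelSpec, loso_accuracy

logger = logging.getLogger(__name__)

DEFAULT_FLOOR = 0.4
DEFAULT_ROSTER = ("svm", "knn", "dt")


@dataclass
class SelectionResult:
    """Outcome of the full selection pipeline."""

    ranking: list[str]                   # features by descending |r|
    r_values: dict[str, float]           # signed Pearson r per feature
    floor: float
    gaps: list[int]                      # prefix lengths at C1 <= C2 <= C3
    candidate_subsets: list[list[str]]
    chosen: list[str]
    chosen_accuracy: Optional[float]
    redundancy_dropped: list[str] = field(default_factory=list)

    def to_yaml(self, path) -> None:
        payload = {
            "floor": self.floor,
            "ranking": self.ranking,
            "r_values": {k: float(v) for k, v in self.r_values.items()},
            "gaps": self.gaps,
            "candidate_subsets": self.candidate_subsets,
            "chosen": self.chosen,
            "chosen_accuracy": self.chosen_accuracy,
            "redundancy_dropped": self.redundancy_dropped,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(ranking=d["ranking"], r_values=d["r_values"], floor=d["floor"],
                   gaps=d["gaps"], candidate_subsets=d["candidate_subsets"],
                   chosen=d["chosen"], chosen_accuracy=d.get("chosen_accuracy"),
                   redundancy_dropped=d.get("redundancy_dropped", []))


def rank_features(table: pd.DataFrame, target: Sequence[float]) -> pd.DataFrame:
    """Rank features by descending |Pearson r| with the target.

    Constant features get r = 0; a constant target is an error.  Returns a
    frame with columns ``feature, r, abs_r`` in rank order.
    """
    target = np.asarray(target, dtype=float)
    if len(table) < 3:
        raise ValueError("need at least 3 recordings to rank features")
    if np.ptp(target) == 0:
        raise ValueError("constant target: correlations undefined")
    rows = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        r = 0.0 if np.ptp(x) == 0 else float(stats.pearsonr(x, target)[0])
        rows.append({"feature": col, "r": r, "abs_r": abs(r)})
    ranked = pd.DataFrame(rows).sort_values(
        ["abs_r", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranked


def candidate_subsets(ranking: pd.DataFrame, floor: float = DEFAULT_FLOOR
                      ) -> tuple[list[list[str]], list[int]]:
    """The three gap-defined prefix subsets above the correlation floor.

    Returns (subsets ordered C1 within C2 within C3, prefix lengths).  With
    fewer than 4 survivors the single all-survivors subset is returned with
    a warning.
    """
    abs_r = ranking["abs_r"].to_numpy()
    names = ranking["feature"].tolist()
    n_surv = int(np.sum(abs_r >= floor))
    if n_surv == 0:
        logger.warning("no feature reaches the %.2f floor", floor)
        return [], []
    if n_surv < 4:
        logger.warning("only %d features above the floor; single candidate", n_surv)
        return [names[:n_surv]], [n_surv]
    drops = -np.diff(abs_r)  # drop after position i (0-based), full ranking
    valid = [i for i in range(len(drops)) if i + 1 <= n_surv and drops[i] > 0]
    if not valid:
        logger.warning("no gaps in the ranking; single all-survivors candidate")
        return [names[:n_surv]], [n_surv]
    # three largest drops; ties resolve toward the earlier (lower-ranked) drop
    order = sorted(valid, key=lambda i: (-drops[i], i))[:3]
    lengths = sorted({min(i + 1, n_surv) for i in order})
    return [names[:k] for k in lengths], lengths


def choose_subset(
    candidates: Sequence[Sequence[str]],
    table: pd.DataFrame,
    subjects: Sequence[str],
    labels: Sequence[int],
    roster: Sequence[str] = DEFAULT_ROSTER,
    seed: int = 0,
) -> tuple[list[str], float]:
    """Pick the candidate with the highest mean LOSO accuracy over the
    model roster; ties go to the smaller subset."""
    if not candidates:
        raise ValueError("no candidate subsets")
    best: tuple[float, int, list[str]] | None = None
    for cand in candidates:
        cand = list(cand)
        accs = []
        for kind in roster:
            try:
                accs.append(loso_accuracy(ModelSpec(kind), table[cand], subjects,
                                          labels, seed=seed))
            except Exception as exc:  # pragma: no cover - defensive
                logger.warning("candidate %s failed for %s: %s", cand, kind, exc)
        if not accs:
            continue
        mean_acc = float(np.mean(accs))
        key = (mean_acc, -len(cand))
        if best is None or key > (best[0], best[1]):
            best = (mean_acc, -len(cand), cand)
    if best is None:
        raise RuntimeError("every candidate subset failed model evaluation")
    return best[2], best[0]


def redundancy_filter(subset: Sequence[str], table: pd.DataFrame,
                      target: Sequence[float]) -> tuple[list[str], list[str]]:
    """Drop lower-ranked members of pairs more correlated with each other
    than either is with the target; repeat until stable."""
    subset = list(subset)
    target = np.asarray(target, dtype=float)
    dropped: list[str] = []
    r_target = {f: abs(float(stats.pearsonr(table[f], target)[0]))
                if np.ptp(table[f].to_numpy()) > 0 else 0.0 for f in subset}
    changed = True
    while changed and len(subset) >= 2:
        changed = False
        for i in range(len(subset)):
            for j in range(i + 1, len(subset)):
                fi, fj = subset[i], subset[j]
                rij = abs(float(stats.pearsonr(table[fi], table[fj])[0]))
                if rij > max(r_target[fi], r_target[fj]):
                    # fj is lower-ranked (subset is in rank order)
                    subset.remove(fj)
                    dropped.append(fj)
                    changed = True
                    break
            if changed:
                break
    return subset, dropped


def select_features(
    table: pd.DataFrame,
    target: Sequence[float],
    subjects: Sequence[str],
    labels: Sequence[int],
    floor: float = DEFAULT_FLOOR,
    roster: Sequence[str] = DEFAULT_ROSTER,
    seed: int = 0,
) -> SelectionResult:
    """Full pipeline: rank -> floor -> gap candidates -> accuracy choice ->
    redundancy filter.  Deterministic given data and seed."""
    ranking = rank_features(table, target)
    candidates, lengths = candidate_subsets(ranking, floor)
    if not candidates:
        return SelectionResult(ranking=ranking["feature"].tolist(),
                               r_values=dict(zip(ranking["feature"], ranking["r"])),
                               floor=floor, gaps=[], candidate_subsets=[],
                               chosen=[], chosen_accuracy=None)
    if len(candidates) == 1:
        chosen, acc = list(candidates[0]), None
        if len(chosen) >= 1:
            acc = None
    else:
        chosen, acc = choose_subset(candidates, table, subjects, labels,
                                    roster=roster, seed=seed)
    kept, dropped = redundancy_filter(chosen, table, target)
    return SelectionResult(
        ranking=ranking["feature"].tolist(),
        r_values=dict(zip(ranking["feature"], ranking["r"])),
        floor=floor,
        gaps=lengths,
        candidate_subsets=[list(c) for c in candidates],
        chosen=kept,
        chosen_accuracy=acc,
        redundancy_dropped=dropped,
    )
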