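"""Classifier evaluation, Welch's t-test, case-level splitting, marker overlap.

ROC curves are empirical with trapezoidal AUC, which coincides with the
Mann–Whitney probability P(score_pos > score_neg) + P(tie)/2.  Train/test
splits are stratified by group at the *case* (patient) level so that
multi-timepoint samples of one patient can never straddle the partition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from cfmhl.io import Group, PathLike, SampleMeta
from cfmhl.screen import MarkerSet, ScoreVector

__all__ = [
    "RocResult",
    "SplitPlan",
    "intersect_markers",
    "roc_auc",
    "sens_spec_at",
    "split_cases",
    "welch_t",
]


@dataclass
class RocResult:
    """Empirical ROC curve with its AUC and optional operating point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    n_excluded: int = 0
    operating_point: tuple[float, float, float] | None = None  # (cutoff, sens, spec)

    def write(self, path: PathLike) -> None:
        path = Path(path)
        frame = pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )
        frame.to_csv(path, sep="\t", index=False)
        summary = {
            "auc": self.auc,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_excluded": self.n_excluded,
            "operating_point": self.operating_point,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(summary, indent=2) + "\n", encoding="utf-8"
        )


def _scores_labels(
    scores: ScoreVector | Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, int]:
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    keep = np.isfinite(s)
    return s[keep], y[keep], int((~keep).sum())


def roc_auc(
    scores: ScoreVector | Sequence[float],
    labels: Sequence[bool],
    cutoff: float | None = None,
) -> RocResult:
    """Empirical ROC with trapezoidal AUC; missing scores excluded and counted.

    When ``cutoff`` is given the sensitivity/specificity at that cutoff
    (positive iff score >= cutoff) are attached as the operating point.
    """
    s, y, n_excluded = _scores_labels(scores, labels)
    if y.all() or not y.any():
        raise ValueError("both classes must be represented")
    fpr, tpr, thresholds = _sk_roc_curve(y.astype(int), s, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    op = None
    if cutoff is not None:
        sens, spec = sens_spec_at(s, y, cutoff)
        op = (float(cutoff), sens, spec)
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=area,
        n_pos=int(y.sum()),
        n_neg=int((~y).sum()),
        n_excluded=n_excluded,
        operating_point=op,
    )


def sens_spec_at(
    scores: ScoreVector | Sequence[float], labels: Sequence[bool], cutoff: float
) -> tuple[float, float]:
    """(sensitivity, specificity) calling positive iff score >= cutoff.

    Missing scores are excluded; an absent class makes the corresponding
    rate NaN (undefined) rather than raising.
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s, y, _ = _scores_labels(scores, labels)
    pred = s >= cutoff
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    sens = float((pred & y).sum() / n_pos) if n_pos else float("nan")
    spec = float((~pred & ~y).sum() / n_neg) if n_neg else float("nan")
    return sens, spec


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Uses the Satterthwaite degrees of freedom.  When both samples have
    zero variance and equal means the statistic is defined as 0 with
    p = 1 (the df is then degenerate and unused).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint case-level train/test partition (samples follow their case)."""

    train_cases: tuple[str, ...]
    test_cases: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_cases) & set(self.test_cases):
            raise ValueError("train and test case ids must be disjoint")

    def train_samples(self, meta: Sequence[SampleMeta]) -> list[str]:
        cases = set(self.train_cases)
        return [m.sample_id for m in meta if m.case_id in cases]

    def test_samples(self, meta: Sequence[SampleMeta]) -> list[str]:
        cases = set(self.test_cases)
        return [m.sample_id for m in meta if m.case_id in cases]


def split_cases(
    meta: Sequence[SampleMeta],
    train_fraction_per_group: float,
    seed: int,
) -> SplitPlan:
    """Stratified random train/test split at the case level.

    Within each group the number of training cases is
    ``floor(n * fraction + 0.5)`` (half-up rounding).  A group with a
    single case sends it to training with a warning.  The same seed always
    yields the same plan.
    """
    if not 0 < train_fraction_per_group < 1:
        raise ValueError(
            f"train fraction must be in (0, 1), got {train_fraction_per_group}"
        )
    by_group: dict[Group, list[str]] = {}
    seen: set[str] = set()
    for m in meta:
        if m.case_id not in seen:
            seen.add(m.case_id)
            by_group.setdefault(m.group, []).append(m.case_id)

    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for group in sorted(by_group, key=lambda g: g.value):
        cases = sorted(by_group[group])
        if len(cases) == 1:
            warnings.warn(
                f"group {group.value} has a single case; assigned to training",
                stacklevel=2,
            )
            train.extend(cases)
            continue
        n_train = math.floor(len(cases) * train_fraction_per_group + 0.5)
        order = rng.permutation(len(cases))
        train.extend(cases[i] for i in order[:n_train])
        test.extend(cases[i] for i in order[n_train:])
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)), seed)


def intersect_markers(a: MarkerSet, b: MarkerSet) -> list[str]:
    """Sorted block ids present in both marker sets."""
    return sorted(set(a.block_ids) & set(b.block_ids))
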