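"""Threshold-based methylation marker screens and aggregate-score classifiers.

Two screens operate on a uMHL matrix:

* the **AP screen** selects blocks hypermethylated (uMHL < 0.1) in more
  than half of healthy training samples yet demethylated to some degree
  (uMHL >= 0.1) in more than 40% of diseased training samples — sample
  level, because draws from the same patient are compared to healthy
  draws individually;
* the **SAP screen** works at the case (patient) level across each
  patient's multi-timepoint samples: a mild-AP case passes when its
  maximal uMHL stays below 0.7 and its mean below 0.5, a severe-AP case
  passes when its minimal uMHL stays above 0.3 and its mean above 0.5,
  and a block is selected when more than 65% of cases on both sides pass.

Selected markers are summarized per sample by the arithmetic mean of their
uMHL values (the aggregate score), thresholded at a fixed cutoff to call a
sample positive.  ``choose_cutoff`` picks the Youden-optimal threshold on
training scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cfmhl.metrics import UmhlMatrix

__all__ = [
    "MarkerSet",
    "ScoreVector",
    "aggregate_score",
    "choose_cutoff",
    "classify",
    "screen_ap_markers",
    "screen_sap_markers",
]


@dataclass(frozen=True)
class MarkerSet:
    """An ordered marker selection plus the screen parameters that produced it."""

    block_ids: tuple[str, ...]
    screen: str  # "AP" or "SAP"
    params: dict = field(default_factory=dict, hash=False, compare=False)
    provenance: tuple[str, ...] = ()  # training sample ids

    def __post_init__(self) -> None:
        if len(set(self.block_ids)) != len(self.block_ids):
            raise ValueError("marker block_ids must be unique")
        if self.screen not in ("AP", "SAP"):
            raise ValueError(f"screen must be 'AP' or 'SAP', got {self.screen!r}")

    def __len__(self) -> int:
        return len(self.block_ids)


@dataclass
class ScoreVector:
    """Per-sample aggregate marker scores in [0, 1], NaN = not scorable."""

    sample_ids: list[str]
    scores: np.ndarray
    marker_set: MarkerSet | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids),):
            raise ValueError("scores length must match sample_ids")

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids)


def _check_ids(matrix: UmhlMatrix, ids: Sequence[str], name: str) -> list[str]:
    ids = list(ids)
    if not ids:
        raise ValueError(f"{name} sample ids must be non-empty")
    missing = set(ids) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"{name} ids not in matrix: {sorted(missing)[:5]}")
    return ids


def screen_ap_markers(
    matrix: UmhlMatrix,
    healthy_ids: Sequence[str],
    ap_ids: Sequence[str],
    hypo_cut: float = 0.1,
    healthy_frac: float = 0.5,
    ap_frac: float = 0.4,
) -> MarkerSet:
    """Select blocks separating healthy from diseased plasma at the sample level.

    A block is selected iff strictly more than ``healthy_frac`` of healthy
    samples (with non-missing values) have uMHL < ``hypo_cut`` AND strictly
    more than ``ap_frac`` of diseased samples have uMHL >= ``hypo_cut``.
    Blocks missing in every sample of either group are never selected.
    """
    healthy_ids = _check_ids(matrix, healthy_ids, "healthy")
    ap_ids = _check_ids(matrix, ap_ids, "AP")
    if set(healthy_ids) & set(ap_ids):
        raise ValueError("healthy and AP sample ids overlap")

    h = matrix.values.loc[healthy_ids]
    a = matrix.values.loc[ap_ids]
    h_n = h.notna().sum(axis=0)
    a_n = a.notna().sum(axis=0)
    with np.errstate(invalid="ignore"):
        h_hypo = (h < hypo_cut).sum(axis=0) / h_n
        a_hyper = (a >= hypo_cut).sum(axis=0) / a_n
    selected = (h_n > 0) & (a_n > 0) & (h_hypo > healthy_frac) & (a_hyper > ap_frac)
    block_ids = tuple(matrix.values.columns[selected])
    return MarkerSet(
        block_ids,
        screen="AP",
        params={
            "hypo_cut": hypo_cut,
            "healthy_frac": healthy_frac,
            "ap_frac": ap_frac,
            "metric": matrix.metric,
        },
        provenance=tuple(healthy_ids) + tuple(ap_ids),
    )


def screen_sap_markers(
    matrix: UmhlMatrix,
    map_case_samples: Mapping[str, Sequence[str]],
    sap_case_samples: Mapping[str, Sequence[str]],
    map_max_cut: float = 0.7,
    map_mean_cut: float = 0.5,
    sap_min_cut: float = 0.3,
    sap_mean_cut: float = 0.5,
    case_frac: float = 0.65,
) -> MarkerSet:
    """Select blocks separating mild from severe AP at the case level.

    For each block and case the max, min and mean uMHL across the case's
    non-missing samples are computed; a MAP case passes iff
    ``max < map_max_cut and mean < map_mean_cut``, an SAP case iff
    ``min > sap_min_cut and mean > sap_mean_cut``.  A block is selected
    iff strictly more than ``case_frac`` of evaluable cases pass on BOTH
    sides.  Cases with no non-missing value for a block are not evaluable
    for it and do not enter the fractions.
    """
    if not map_case_samples or not sap_case_samples:
        raise ValueError("both case maps must be non-empty")
    if set(map_case_samples) & set(sap_case_samples):
        raise ValueError("case ids overlap between MAP and SAP groups")

    def _case_pass_fraction(
        case_samples: Mapping[str, Sequence[str]], side: str
    ) -> pd.Series:
        n_pass = pd.Series(0, index=matrix.values.columns, dtype=float)
        n_eval = pd.Series(0, index=matrix.values.columns, dtype=float)
        for case_id, sids in case_samples.items():
            sids = _check_ids(matrix, sids, f"case {case_id}")
            sub = matrix.values.loc[sids]
            evaluable = sub.notna().any(axis=0)
            cmax, cmin, cmean = sub.max(axis=0), sub.min(axis=0), sub.mean(axis=0)
            if side == "MAP":
                passed = (cmax < map_max_cut) & (cmean < map_mean_cut)
            else:
                passed = (cmin > sap_min_cut) & (cmean > sap_mean_cut)
            n_pass += (passed & evaluable).astype(float)
            n_eval += evaluable.astype(float)
        with np.errstate(invalid="ignore"):
            return n_pass / n_eval.replace(0, np.nan)

    map_frac = _case_pass_fraction(map_case_samples, "MAP")
    sap_frac = _case_pass_fraction(sap_case_samples, "SAP")
    selected = (map_frac > case_frac) & (sap_frac > case_frac)
    selected = selected.fillna(False)
    block_ids = tuple(matrix.values.columns[selected])
    provenance = tuple(
        s for case in (*map_case_samples.values(), *sap_case_samples.values()) for s in case
    )
    return MarkerSet(
        block_ids,
        screen="SAP",
        params={
            "map_max_cut": map_max_cut,
            "map_mean_cut": map_mean_cut,
            "sap_min_cut": sap_min_cut,
            "sap_mean_cut": sap_mean_cut,
            "case_frac": case_frac,
            "metric": matrix.metric,
        },
        provenance=provenance,
    )


def aggregate_score(
    matrix: UmhlMatrix,
    marker_set: MarkerSet,
    min_covered_fraction: float = 0.5,
) -> ScoreVector:
    """Arithmetic mean of non-missing uMHL over marker blocks, per sample.

    Samples covering fewer than ``min_covered_fraction`` of the markers get
    a missing score rather than an average over a thin slice.
    """
    if len(marker_set) == 0:
        raise ValueError("marker_set must be non-empty")
    missing_cols = set(marker_set.block_ids) - set(matrix.block_ids)
    if missing_cols:
        raise ValueError(f"markers not in matrix: {sorted(missing_cols)[:5]}")
    sub = matrix.values.loc[:, list(marker_set.block_ids)]
    covered = sub.notna().mean(axis=1)
    scores = sub.mean(axis=1)
    scores[covered < min_covered_fraction] = np.nan
    return ScoreVector(list(matrix.sample_ids), scores.to_numpy(), marker_set)


def classify(scores: ScoreVector, cutoff: float) -> pd.Series:
    """Label samples positive iff score >= cutoff; missing scores stay unclassified.

    Returns a pandas Series of nullable booleans indexed by sample id
    (pd.NA = unclassified).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    labels = pd.Series(pd.NA, index=scores.sample_ids, dtype="boolean")
    finite = np.isfinite(scores.scores)
    labels[finite] = scores.scores[finite] >= cutoff
    return labels


def choose_cutoff(
    scores: ScoreVector | np.ndarray,
    labels: Sequence[bool],
    method: str = "YOUDEN",
) -> float:
    """Score threshold maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are midpoints between adjacent distinct scores;
    ties in J are broken toward higher specificity (higher cutoff).
    """
    if method != "YOUDEN":
        raise ValueError(f"unknown method {method!r}")
    s = scores.scores if isinstance(scores, ScoreVector) else np.asarray(scores, float)
    y = np.asarray(labels, dtype=bool)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    if y.all() or not y.any():
        raise ValueError("both classes must be represented")
    distinct = np.unique(s)
    if distinct.size == 1:
        warnings.warn("all scores identical; Youden index is 0", stacklevel=2)
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2
    n_pos, n_neg = y.sum(), (~y).sum()
    best_j, best_cut = -np.inf, candidates[0]
    for cut in candidates:
        sens = (s[y] >= cut).sum() / n_pos
        spec = (s[~y] < cut).sum() / n_neg
        j = sens + spec - 1
        if j >= best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and cut > best_cut):
            best_j, best_cut = j, float(cut)
    return best_cut
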