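"""Haplotype-level methylation metrics over methylation haplotype blocks.

The unmethylated haplotype load (uMHL) of one block in one sample is a
length-weighted average of the fractions of fully unmethylated contiguous
CpG substrings among all substrings of each length:

    uMHL = sum_i w_i * P(UMH_i) / sum_i w_i,    w_i = i ** weight_exponent

where ``P(UMH_i)`` is the count-weighted fraction of all contiguous
length-``i`` windows of the observed haplotype patterns that are entirely
``U``.  With the default cubic weights (``weight_exponent = 3``) long runs
of unmethylated CpGs on a single molecule dominate the score, which is what
makes the metric sensitive to coordinated (haplotype-level) demethylation
rather than to scattered single-CpG changes.  MHL is the mirror image
(fully ``M`` substrings) and AMF is the plain per-CpG methylated fraction.

Lengths at which no substring is observed (patterns shorter than ``i``)
contribute to neither the numerator nor the denominator, so shallow
coverage is not penalized for unobservable lengths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cfmhl.io import HaplotypeRecord, MhbRegion, PathLike, ValidationError

__all__ = [
    "UmhlMatrix",
    "build_matrix",
    "compute_amf",
    "compute_mhl",
    "compute_umhl",
    "filter_blocks",
    "read_matrix",
    "write_matrix",
]


def _substring_fractions(
    records: Sequence[HaplotypeRecord], target: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-length counts of fully-``target`` substrings and of all substrings.

    Returns ``(hits, totals)`` indexed by length-1 for lengths 1..l_max.
    A run of ``r`` consecutive target calls contains ``r - i + 1`` fully-
    target windows of length ``i``; every pattern of length ``k`` contains
    ``k - i + 1`` windows of length ``i``.  All counts are weighted by the
    record's read count.
    """
    l_max = max(len(r.pattern) for r in records)
    hits = np.zeros(l_max, dtype=float)
    totals = np.zeros(l_max, dtype=float)
    for rec in records:
        k = len(rec.pattern)
        totals[:k] += rec.count * np.arange(k, 0, -1)
        # run-length scan of consecutive target calls
        run = 0
        for ch in rec.pattern + "\0":
            if ch == target:
                run += 1
            else:
                if run:
                    hits[:run] += rec.count * np.arange(run, 0, -1)
                run = 0
    return hits, totals


def _haplotype_load(
    records: Sequence[HaplotypeRecord], target: str, weight_exponent: float
) -> float:
    if weight_exponent < 0:
        raise ValueError(f"weight_exponent must be >= 0, got {weight_exponent}")
    if not records:
        return float("nan")
    hits, totals = _substring_fractions(records, target)
    observed = totals > 0
    lengths = np.arange(1, len(totals) + 1, dtype=float)[observed]
    weights = lengths**weight_exponent
    p = hits[observed] / totals[observed]
    return float(np.dot(weights, p) / weights.sum())


def compute_umhl(
    records: Sequence[HaplotypeRecord], weight_exponent: float = 3.0
) -> float:
    """Unmethylated haplotype load of one block; NaN when no records."""
    return _haplotype_load(records, "U", weight_exponent)


def compute_mhl(
    records: Sequence[HaplotypeRecord], weight_exponent: float = 3.0
) -> float:
    """Methylated haplotype load: :func:`compute_umhl` with M and U swapped."""
    return _haplotype_load(records, "M", weight_exponent)


def compute_amf(records: Sequence[HaplotypeRecord]) -> float:
    """Average methylation frequency: count-weighted fraction of M calls."""
    if not records:
        return float("nan")
    m_calls = sum(r.count * r.pattern.count("M") for r in records)
    all_calls = sum(r.count * len(r.pattern) for r in records)
    return m_calls / all_calls


_METRIC_FUNCS = {
    "UMHL": compute_umhl,
    "MHL": compute_mhl,
    "AMF": lambda records, weight_exponent=3.0: compute_amf(records),
}


@dataclass
class UmhlMatrix:
    """Samples x blocks matrix of a haplotype metric with explicit missingness.

    ``values`` is a :class:`pandas.DataFrame` (rows = samples, columns =
    blocks, NaN = missing); every non-missing entry lies in [0, 1].
    """

    values: pd.DataFrame
    metric: str = "UMHL"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in _METRIC_FUNCS:
            raise ValueError(f"unknown metric {self.metric!r}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("metric values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def block_ids(self) -> list[str]:
        return list(self.values.columns)


def build_matrix(
    samples: Mapping[str, Mapping[str, Sequence[HaplotypeRecord]]],
    panel: Sequence[MhbRegion],
    metric: str = "UMHL",
    min_reads: int = 3,
    weight_exponent: float = 3.0,
) -> UmhlMatrix:
    """Assemble the coverage-filtered samples x blocks metric matrix.

    Cell (s, b) carries the metric over sample s's records for block b when
    the total read count reaches ``min_reads``, otherwise it is missing.
    A sample referencing a block id absent from the panel is a validation
    error: the panel defines the universe of blocks.
    """
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    func = _METRIC_FUNCS[metric]
    block_ids = [r.block_id for r in panel]
    known = set(block_ids)
    rows = {}
    for sample_id, table in samples.items():
        unknown = set(table) - known
        if unknown:
            raise ValidationError(
                f"sample {sample_id!r} references unknown block ids: {sorted(unknown)[:5]}"
            )
        row = np.full(len(block_ids), np.nan)
        for j, bid in enumerate(block_ids):
            records = table.get(bid, ())
            if records and sum(r.count for r in records) >= min_reads:
                row[j] = func(records, weight_exponent=weight_exponent)
        rows[sample_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=block_ids)
    frame = frame.loc[list(samples)]
    return UmhlMatrix(
        frame,
        metric=metric,
        params={"min_reads": min_reads, "weight_exponent": weight_exponent},
    )


def filter_blocks(matrix: UmhlMatrix, min_sample_fraction: float = 0.8) -> UmhlMatrix:
    """Keep blocks non-missing in at least ``min_sample_fraction`` of samples.

    Ties (coverage fraction exactly at the threshold) are kept; column
    order is preserved.
    """
    if not 0 < min_sample_fraction <= 1:
        raise ValueError(
            f"min_sample_fraction must be in (0, 1], got {min_sample_fraction}"
        )
    frac_covered = matrix.values.notna().mean(axis=0)
    keep = frac_covered[frac_covered >= min_sample_fraction].index
    params = dict(matrix.params, min_sample_fraction=min_sample_fraction)
    return UmhlMatrix(matrix.values.loc[:, keep], metric=matrix.metric, params=params)


def write_matrix(matrix: UmhlMatrix, path: PathLike) -> None:
    """Serialize as TSV (empty cell = missing) plus a JSON params sidecar."""
    path = Path(path)
    # repr round-trips doubles exactly; pandas' default str() may not
    matrix.values.to_csv(
        path, sep="\t", index_label="sample_id", na_rep="", float_format=lambda v: repr(float(v))
    )
    sidecar = {"metric": matrix.metric, "params": matrix.params}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8"
    )


def read_matrix(path: PathLike) -> UmhlMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="sample_id", float_precision="round_trip")
    frame.index = frame.index.astype(str)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    metric, params = "UMHL", {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        metric = sidecar.get("metric", "UMHL")
        params = sidecar.get("params", {})
    return UmhlMatrix(frame, metric=metric, params=params)
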