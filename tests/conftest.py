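"""Shared fixtures: independent brute-force oracles and small cohorts."""

from __future__ import annotations

from collections import defaultdict
from fractions import Fraction

import numpy as np
import pytest

from cfmhl import CohortConfig, generate_cohort, generate_worked_example
from cfmhl.io import HaplotypeRecord


def brute_force_haplotype_load(records, target: str, weight_exponent: int = 3) -> Fraction:
    """Materialize every contiguous substring of every read explicitly.

    Exact-rational reference implementation of the haplotype-load metrics,
    independent of the package's run-length computation.
    """
    subs: dict[int, list[str]] = defaultdict(list)
    for rec in records:
        for _ in range(rec.count):
            p = rec.pattern
            for i in range(1, len(p) + 1):
                for j in range(len(p) - i + 1):
                    subs[i].append(p[j : j + i])
    num, den = Fraction(0), Fraction(0)
    for i, windows in subs.items():
        frac = Fraction(sum(1 for w in windows if set(w) == {target}), len(windows))
        num += Fraction(i**weight_exponent) * frac
        den += Fraction(i**weight_exponent)
    return num / den


def flip_records(records):
    """Swap M and U calls in every record."""
    table = str.maketrans("MU", "UM")
    return [
        HaplotypeRecord(r.block_id, r.pattern.translate(table), r.count, r.offset)
        for r in records
    ]


def random_record_sets(rng: np.random.Generator, n_sets: int, max_cpgs: int = 6, max_reads: int = 20):
    """Random haplotype sets for oracle-equivalence sweeps."""
    sets = []
    for _ in range(n_sets):
        n_patterns = int(rng.integers(1, 6))
        records = []
        reads_left = max_reads
        for _ in range(n_patterns):
            if reads_left <= 0:
                break
            length = int(rng.integers(1, max_cpgs + 1))
            pattern = "".join(rng.choice(list("MU"), size=length))
            count = int(rng.integers(1, min(6, reads_left + 1)))
            reads_left -= count
            records.append(HaplotypeRecord("b", pattern, count))
        sets.append(records)
    return sets


@pytest.fixture(scope="session")
def umhl_oracle():
    return brute_force_haplotype_load


@pytest.fixture(scope="session")
def worked_example():
    return generate_worked_example()


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort: enough structure for end-to-end checks, seconds to build."""
    config = CohortConfig(
        n_healthy_cases=8,
        n_map_cases=6,
        n_sap_cases=10,
        n_blocks=300,
        n_planted_ap=25,
        n_planted_sap=15,
        seed=42,
    )
    return generate_cohort(config)
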