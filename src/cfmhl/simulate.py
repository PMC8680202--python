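"""Synthetic cfDNA methylation cohorts with planted diagnostic structure.

The generator emulates the statistical shape of a three-group plasma
methylation study: healthy controls plus mild (MAP) and severe (SAP)
acute pancreatitis patients, each patient sampled at several days after
admission.  For every (sample, block) cell a per-molecule unmethylation
propensity is drawn from a Beta distribution centered on the group rate
(planted marker blocks) or on the background rate (null blocks); reads
are then drawn with *within-read correlation*: with probability ``rho`` a
molecule is coherent (all CpGs share one call), otherwise calls are
independent.  Coherence matters because the haplotype-load metrics weight
long runs of identical calls — independent calls would understate the
haplotype signal the screens look for.

Clinical biomarkers are generated for the curated 12-test panel at its
published per-test scale (location = cohort mean, support truncated to
the published min/max) with a severity shift whose *sign* follows the
published model coefficient (positive coefficient → higher in SAP), plus
a configurable number of uninformative noise tests.  Missing clinical
cells are masked completely at random.

Everything is reproducible from the config seed, byte-identically across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from cfmhl.io import (
    ClinicalTable,
    Group,
    HaplotypeRecord,
    MhbRegion,
    PathLike,
    SampleMeta,
    write_clinical_table,
    write_haplotype_table,
    write_mhb_panel,
    write_sample_meta,
)
from cfmhl.models import _TABLE1_ROWS

__all__ = ["CohortConfig", "CohortTruth", "SimulatedCohort", "generate_cohort", "generate_worked_example"]

_SAMPLE_DAYS = (1, 3, 7, 14, 21)


@dataclass
class CohortConfig:
    """Generator parameters; defaults mirror the study's cohort structure.

    Rates are mean per-CpG unmethylation propensities by group:
    ``ap_marker_rates`` applies at planted AP blocks (healthy, MAP, SAP),
    ``sap_marker_rates`` at planted SAP blocks (MAP, SAP; healthy samples
    sit at the background rate there).  ``propensity_concentration`` is
    the Beta concentration of per-(sample, block) propensities around the
    group rate; ``read_correlation`` is the probability that a molecule
    is fully coherent.
    """

    n_healthy_cases: int = 12
    n_map_cases: int = 9
    n_sap_cases: int = 22
    samples_per_case: tuple[int, int] = (2, 3)  # inclusive range, patients only
    n_blocks: int = 2000
    n_planted_ap: int = 100
    n_planted_sap: int = 60
    cpg_per_block: tuple[int, int] = (4, 8)  # inclusive range
    reads_per_block_mean: float = 25.0
    reads_dispersion: float = 3.0  # negative-binomial shape; smaller = more spread
    low_coverage_block_fraction: float = 0.05
    low_coverage_mean: float = 1.5
    ap_marker_rates: tuple[float, float, float] = (0.03, 0.35, 0.35)
    sap_marker_rates: tuple[float, float] = (0.25, 0.75)
    background_unmeth_rate: float = 0.05
    propensity_concentration: float = 30.0
    read_correlation: float = 0.9
    n_noise_tests: int = 45
    clinical_effect_scale: float = 1.0
    missing_clinical_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_healthy_cases, self.n_map_cases, self.n_sap_cases) < 0:
            raise ValueError("case counts must be >= 0")
        if self.n_planted_ap + self.n_planted_sap > self.n_blocks:
            raise ValueError("more planted marker blocks than total blocks")
        rates = (*self.ap_marker_rates, *self.sap_marker_rates, self.background_unmeth_rate)
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.read_correlation <= 1:
            raise ValueError("read_correlation must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort, for recovery checks."""

    planted_ap_block_ids: tuple[str, ...]
    planted_sap_block_ids: tuple[str, ...]
    sample_groups: dict[str, Group]
    clinical_effects: dict[str, float]  # per-test SAP shift actually applied


@dataclass
class SimulatedCohort:
    """A generated cohort in the package's native containers."""

    panel: list[MhbRegion]
    haplotype_tables: dict[str, dict[str, list[HaplotypeRecord]]]
    clinical: ClinicalTable
    meta: list[SampleMeta]
    truth: CohortTruth

    def write(self, outdir: PathLike) -> None:
        """Emit the cohort in the package's file formats under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_mhb_panel(self.panel, outdir / "panel.bed")
        write_clinical_table(self.clinical, outdir / "clinical.tsv")
        write_sample_meta(self.meta, outdir / "samples.tsv")
        hapdir = outdir / "haplotypes"
        hapdir.mkdir(exist_ok=True)
        for sample_id, table in self.haplotype_tables.items():
            write_haplotype_table(table, hapdir / f"{sample_id}.tsv")


def _draw_cell_records(
    rng: np.random.Generator,
    block_id: str,
    n_cpgs: int,
    n_reads: int,
    propensity: float,
    rho: float,
) -> list[HaplotypeRecord]:
    """Draw one cell's reads as bitmask integers (bit set = U call)."""
    if n_reads == 0:
        return []
    coherent = rng.random(n_reads) < rho
    masks = np.zeros(n_reads, dtype=np.int64)
    n_coh = int(coherent.sum())
    if n_coh:
        all_u = rng.random(n_coh) < propensity
        masks[coherent] = np.where(all_u, (1 << n_cpgs) - 1, 0)
    n_free = n_reads - n_coh
    if n_free:
        calls = rng.random((n_free, n_cpgs)) < propensity
        masks[~coherent] = calls @ (1 << np.arange(n_cpgs, dtype=np.int64))
    uniq, counts = np.unique(masks, return_counts=True)
    records = []
    for mask, count in zip(uniq, counts):
        pattern = "".join("U" if mask >> i & 1 else "M" for i in range(n_cpgs))
        records.append(HaplotypeRecord(block_id, pattern, int(count)))
    return records


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full cohort (panel, reads, clinical table, metadata, truth)."""
    rng = np.random.default_rng(config.seed)

    # --- sample roster -----------------------------------------------------
    meta: list[SampleMeta] = []
    case_specs = (
        [("H", Group.HEALTHY)] * config.n_healthy_cases
        + [("M", Group.MAP)] * config.n_map_cases
        + [("S", Group.SAP)] * config.n_sap_cases
    )
    counters = {"H": 0, "M": 0, "S": 0}
    for prefix, group in case_specs:
        counters[prefix] += 1
        case_id = f"{prefix}{counters[prefix]:03d}"
        if group is Group.HEALTHY:
            meta.append(SampleMeta(f"{case_id}_d0", case_id, group, 0))
            continue
        lo, hi = config.samples_per_case
        n_samples = int(rng.integers(lo, hi + 1))
        for day in _SAMPLE_DAYS[:n_samples]:
            meta.append(SampleMeta(f"{case_id}_d{day}", case_id, group, day))

    # --- MHB panel ---------------------------------------------------------
    panel: list[MhbRegion] = []
    pos = 1000
    lo, hi = config.cpg_per_block
    n_cpgs_per_block = rng.integers(lo, hi + 1, size=config.n_blocks)
    for b, n_cpgs in enumerate(n_cpgs_per_block):
        gaps = rng.integers(10, 60, size=int(n_cpgs))
        cpgs = pos + 20 + np.cumsum(gaps)
        start, end = pos, int(cpgs[-1]) + 30
        panel.append(
            MhbRegion(f"mhb{b:05d}", "chrS", start, end, tuple(int(c) for c in cpgs))
        )
        pos = end + int(rng.integers(200, 800))

    block_ids = [r.block_id for r in panel]
    planted_idx = rng.choice(
        config.n_blocks, size=config.n_planted_ap + config.n_planted_sap, replace=False
    )
    ap_idx = set(planted_idx[: config.n_planted_ap].tolist())
    sap_idx = set(planted_idx[config.n_planted_ap :].tolist())
    low_cov = rng.random(config.n_blocks) < config.low_coverage_block_fraction

    h_ap, m_ap, s_ap = config.ap_marker_rates
    m_sap, s_sap = config.sap_marker_rates
    bg = config.background_unmeth_rate

    def _group_rate(block_index: int, group: Group) -> float:
        if block_index in ap_idx:
            return {Group.HEALTHY: h_ap, Group.MAP: m_ap, Group.SAP: s_ap}[group]
        if block_index in sap_idx:
            return {Group.HEALTHY: bg, Group.MAP: m_sap, Group.SAP: s_sap}[group]
        return bg

    # --- haplotype reads ---------------------------------------------------
    kappa = config.propensity_concentration
    nb_shape = config.reads_dispersion
    tables: dict[str, dict[str, list[HaplotypeRecord]]] = {}
    for m in meta:
        table: dict[str, list[HaplotypeRecord]] = {}
        for b, region in enumerate(panel):
            mean_reads = config.low_coverage_mean if low_cov[b] else config.reads_per_block_mean
            n_reads = int(rng.negative_binomial(nb_shape, nb_shape / (nb_shape + mean_reads)))
            if n_reads == 0:
                continue
            mu = _group_rate(b, m.group)
            a = max(mu * kappa, 1e-6)
            bpar = max((1 - mu) * kappa, 1e-6)
            propensity = float(rng.beta(a, bpar))
            records = _draw_cell_records(
                rng, region.block_id, region.n_cpgs, n_reads, propensity, config.read_correlation
            )
            if records:
                table[region.block_id] = records
        tables[m.sample_id] = table

    # --- clinical table ----------------------------------------------------
    sample_ids = [m.sample_id for m in meta]
    groups = {m.sample_id: m.group for m in meta}
    test_names: list[str] = []
    units: dict[str, str] = {}
    columns: list[np.ndarray] = []
    effects: dict[str, float] = {}
    is_sap = np.array([groups[s] is Group.SAP for s in sample_ids])

    for name, unit, mean, lo_v, hi_v, coef in _TABLE1_ROWS:
        sd = (hi_v - lo_v) / 6.0
        shift = np.sign(coef) * config.clinical_effect_scale * sd
        locs = np.where(is_sap, mean + shift, mean)
        a, b = (lo_v - locs) / sd, (hi_v - locs) / sd
        col = sps.truncnorm.rvs(a, b, loc=locs, scale=sd, random_state=rng)
        test_names.append(name)
        units[name] = unit
        columns.append(col)
        effects[name] = float(shift)
    for j in range(config.n_noise_tests):
        name = f"noise_test_{j:02d}"
        scale = float(10 ** rng.uniform(-1, 2))
        col = rng.normal(scale, scale / 4, size=len(sample_ids))
        test_names.append(name)
        units[name] = "a.u."
        columns.append(col)
        effects[name] = 0.0

    values = np.column_stack(columns)
    mask = rng.random(values.shape) < config.missing_clinical_fraction
    values[mask] = np.nan
    clinical = ClinicalTable(sample_ids, test_names, values, units)

    truth = CohortTruth(
        planted_ap_block_ids=tuple(block_ids[i] for i in sorted(ap_idx)),
        planted_sap_block_ids=tuple(block_ids[i] for i in sorted(sap_idx)),
        sample_groups=groups,
        clinical_effects=effects,
    )
    return SimulatedCohort(panel, tables, clinical, meta, truth)


def generate_worked_example() -> SimulatedCohort:
    """A deterministic 6-sample, 8-block toy cohort with exact-rational metrics.

    Patterns are hand-chosen so the haplotype metrics are simple fractions
    (e.g. block ``toy_mix`` holds two UU and two MM molecules, uMHL = 1/2);
    used in unit tests and the documentation's worked example.  No random
    numbers are involved: regeneration is always identical.
    """
    cpgs = {
        2: (110, 130),
        3: (110, 130, 150),
    }
    panel = [
        MhbRegion("toy_mix", "chrT", 100, 200, tuple(p + 0 for p in cpgs[2])),
        MhbRegion("toy_mu", "chrT", 300, 400, tuple(p + 200 for p in cpgs[2])),
        MhbRegion("toy_all_m", "chrT", 500, 600, tuple(p + 400 for p in cpgs[3])),
        MhbRegion("toy_all_u", "chrT", 700, 800, tuple(p + 600 for p in cpgs[3])),
        MhbRegion("toy_half", "chrT", 900, 1000, tuple(p + 800 for p in cpgs[2])),
        MhbRegion("toy_long", "chrT", 1100, 1200, tuple(p + 1000 for p in cpgs[3])),
        MhbRegion("toy_sparse", "chrT", 1300, 1400, tuple(p + 1200 for p in cpgs[2])),
        MhbRegion("toy_const", "chrT", 1500, 1600, tuple(p + 1400 for p in cpgs[2])),
    ]

    def _records(sample_kind: str) -> dict[str, list[HaplotypeRecord]]:
        # "low" samples lean methylated, "high" samples lean unmethylated
        high = sample_kind == "high"
        table = {
            "toy_mix": [HaplotypeRecord("toy_mix", "UU", 2), HaplotypeRecord("toy_mix", "MM", 2)],
            "toy_mu": [HaplotypeRecord("toy_mu", "MU", 1), HaplotypeRecord("toy_mu", "MM", 2)],
            "toy_all_m": [HaplotypeRecord("toy_all_m", "MMM", 5)],
            "toy_all_u": [HaplotypeRecord("toy_all_u", "UUU", 5)],
            "toy_half": [
                HaplotypeRecord("toy_half", "UU" if high else "MM", 3),
                HaplotypeRecord("toy_half", "UM", 1),
            ],
            "toy_long": [
                HaplotypeRecord("toy_long", "UUU" if high else "MMM", 4),
                HaplotypeRecord("toy_long", "MUM", 2),
            ],
            # below the default min_reads=3 coverage threshold
            "toy_sparse": [HaplotypeRecord("toy_sparse", "MU", 2)],
            "toy_const": [HaplotypeRecord("toy_const", "MM", 4)],
        }
        return table

    meta = [
        SampleMeta("ex_h1_d0", "ex_h1", Group.HEALTHY, 0),
        SampleMeta("ex_h2_d0", "ex_h2", Group.HEALTHY, 0),
        SampleMeta("ex_m1_d1", "ex_m1", Group.MAP, 1),
        SampleMeta("ex_m1_d3", "ex_m1", Group.MAP, 3),
        SampleMeta("ex_s1_d1", "ex_s1", Group.SAP, 1),
        SampleMeta("ex_s1_d3", "ex_s1", Group.SAP, 3),
    ]
    kinds = {
        "ex_h1_d0": "low",
        "ex_h2_d0": "low",
        "ex_m1_d1": "low",
        "ex_m1_d3": "low",
        "ex_s1_d1": "high",
        "ex_s1_d3": "high",
    }
    tables = {m.sample_id: _records(kinds[m.sample_id]) for m in meta}

    sample_ids = [m.sample_id for m in meta]
    names = ["Urea nitrogen", "Red blood cell count"]
    units = {"Urea nitrogen": "mmol/L", "Red blood cell count": "10^12/L"}
    values = np.array(
        [
            [5.0, 4.5],
            [5.5, 4.4],
            [6.0, 4.2],
            [6.5, 4.3],
            [12.0, 3.1],
            [13.0, 3.0],
        ]
    )
    clinical = ClinicalTable(sample_ids, names, values, units)
    truth = CohortTruth(
        planted_ap_block_ids=("toy_half", "toy_long"),
        planted_sap_block_ids=("toy_half", "toy_long"),
        sample_groups={m.sample_id: m.group for m in meta},
        clinical_effects={"Urea nitrogen": 6.5, "Red blood cell count": -1.3},
    )
    return SimulatedCohort(panel, tables, clinical, meta, truth)
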