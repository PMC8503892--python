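"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators mirror the three data sources of the analysis:

* :func:`simulate_microarray_cohort` — a labelled multi-entity expression
  matrix (e.g. RELA-fusion-positive ependymomas among ATRT/HGG/medulloblastoma
  samples) with group-specific marker probes planted at a known fold-change,
  standing in for public microarray cohorts.
* :func:`simulate_nanostring_run` — a batch of nCounter lanes with positive
  controls on a geometric concentration ladder, housekeeping genes, and
  group-elevated signature genes, all scaled by a per-lane lognormal
  technical factor; counts are negative binomial.
* :func:`simulate_survival` — clinical records with exponential event times
  from stated monthly hazards and uniform administrative censoring,
  emulating the posterior-fossa survival contrast.

All generators are pure functions of (design, seed): the same design yields
the same data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ClinicalRecord, ExpressionMatrix, RccLane, RccRecord

__all__ = [
    "CohortDesign",
    "NanoDesign",
    "SurvivalDesign",
    "SurvivalGroup",
    "simulate_microarray_cohort",
    "simulate_nanostring_run",
    "simulate_survival",
    "POSITIVE_CONTROL_LADDER",
]

#: Expected positive-control counts: the conventional six-point geometric
#: ladder of relative concentrations 128, 32, 8, 2, 0.5, 0.125, scaled x100.
POSITIVE_CONTROL_LADDER = (12800.0, 3200.0, 800.0, 200.0, 50.0, 12.5)

DEFAULT_HK_GENES = ("ACTB", "GAPDH", "TBP")


@dataclass
class CohortDesign:
    """Design of a labelled multi-entity expression cohort.

    ``marker_plan`` plants probes: ``(probe_id, target_entity, fold_change)``
    gives the probe an expected linear-scale mean ``fold_change`` times the
    baseline in samples of ``target_entity`` only.  ``noise_sd`` is the
    per-value Gaussian noise on the log2 scale (multiplicative lognormal on
    the linear scale).
    """

    entities: Sequence[tuple[str, int]]
    n_probes: int
    marker_plan: Sequence[tuple[str, str, float]] = ()
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        names = [e[0] for e in self.entities]
        if len(set(names)) != len(names):
            raise ValueError("entity names must be unique")
        for probe, entity, fold in self.marker_plan:
            if fold <= 1:
                raise ValueError(f"marker {probe!r}: fold_change must exceed 1")
            if entity not in names:
                raise ValueError(f"marker {probe!r}: unknown entity {entity!r}")
        if self.baseline_log2_sd <= 0:
            raise ValueError("baseline_log2_sd must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def probe_id(self, i: int) -> str:
        return f"PROBE_{i + 1:04d}"


def simulate_microarray_cohort(design: CohortDesign) -> ExpressionMatrix:
    """Linear-scale matrix with planted group markers; deterministic per seed."""
    import pandas as pd

    rng = np.random.default_rng(design.seed)
    probes = [design.probe_id(i) for i in range(design.n_probes)]
    probe_index = {p: i for i, p in enumerate(probes)}
    samples: list[str] = []
    labels: dict[str, str] = {}
    for name, n in design.entities:
        for j in range(n):
            sid = f"{name}_{j + 1:03d}"
            samples.append(sid)
            labels[sid] = name

    baseline = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd,
                          size=design.n_probes)
    log2 = np.tile(baseline[:, None], (1, len(samples)))
    for probe, entity, fold in design.marker_plan:
        if probe not in probe_index:
            raise ValueError(f"marker probe {probe!r} not on the array "
                             f"(n_probes={design.n_probes})")
        row = probe_index[probe]
        cols = [k for k, s in enumerate(samples) if labels[s] == entity]
        log2[row, cols] += math.log2(fold)
    if design.noise_sd > 0:
        log2 = log2 + rng.normal(0.0, design.noise_sd, size=log2.shape)

    data = pd.DataFrame(2.0 ** log2, index=probes, columns=samples)
    return ExpressionMatrix(data, scale="linear", labels=labels)


@dataclass
class NanoDesign:
    """Design of a synthetic nCounter run.

    Each group's lanes have the genes of ``signature_sets[group]`` elevated
    ``signature_fold``-fold over ``baseline_mean``.  Per lane, a lognormal
    technical factor (sd ``lane_scale_sd`` on the natural-log scale)
    multiplies every expected count; counts are negative binomial with the
    given ``dispersion`` (NB size parameter; ``inf`` -> Poisson, ``None`` ->
    deterministic rounded means, the zero-noise limit).
    """

    groups: Sequence[tuple[str, int]]
    signature_sets: dict[str, Sequence[str]]
    signature_fold: float = 6.0
    hk_genes: Sequence[str] = DEFAULT_HK_GENES
    positive_control_targets: Sequence[float] = POSITIVE_CONTROL_LADDER
    lane_scale_sd: float = 0.25
    dispersion: Optional[float] = 20.0
    baseline_mean: float = 200.0
    hk_mean: float = 1500.0
    neg_mean: float = 4.0
    n_negative: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g[0] for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        hk = set(self.hk_genes)
        for group, genes in self.signature_sets.items():
            if hk & set(genes):
                raise ValueError(f"group {group!r}: signature genes overlap housekeeping")
        for name in names:
            if name not in self.signature_sets:
                raise ValueError(f"group {name!r} has no signature set")
        if self.signature_fold < 1:
            raise ValueError("signature_fold must be >= 1 (1 = null, no group signal)")
        if self.lane_scale_sd < 0:
            raise ValueError("lane_scale_sd must be non-negative")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def endogenous_genes(self) -> list[str]:
        genes: list[str] = []
        for _, gs in sorted(self.signature_sets.items()):
            for g in gs:
                if g not in genes:
                    genes.append(g)
        return genes


def _draw_counts(rng: np.random.Generator, means: np.ndarray,
                 dispersion: Optional[float]) -> np.ndarray:
    if dispersion is None:
        return np.rint(means).astype(int)
    if math.isinf(dispersion):
        return rng.poisson(means).astype(int)
    p = dispersion / (dispersion + means)
    return rng.negative_binomial(dispersion, p).astype(int)


def simulate_nanostring_run(design: NanoDesign) -> list[RccLane]:
    """One RCC lane per sample; deterministic per seed."""
    rng = np.random.default_rng(design.seed)
    endo = design.endogenous_genes
    lanes: list[RccLane] = []
    lane_no = 0
    for group, n_lanes in design.groups:
        sig = set(design.signature_sets[group])
        for j in range(n_lanes):
            lane_no += 1
            factor = float(np.exp(rng.normal(0.0, design.lane_scale_sd))) \
                if design.lane_scale_sd > 0 else 1.0
            records: list[RccRecord] = []
            pos_means = np.asarray(design.positive_control_targets) * factor
            pos_counts = _draw_counts(rng, pos_means, design.dispersion)
            for i, c in enumerate(pos_counts):
                conc = design.positive_control_targets[i]
                records.append(RccRecord(
                    "Positive", f"POS_{chr(ord('A') + i)}({conc:g})",
                    f"ERCC_POS_{i}", int(c)))
            neg_means = np.full(design.n_negative, design.neg_mean) * factor
            neg_counts = _draw_counts(rng, neg_means, design.dispersion)
            for i, c in enumerate(neg_counts):
                records.append(RccRecord(
                    "Negative", f"NEG_{chr(ord('A') + i)}(0)",
                    f"ERCC_NEG_{i}", int(c)))
            hk_means = np.full(len(design.hk_genes), design.hk_mean) * factor
            hk_counts = _draw_counts(rng, hk_means, design.dispersion)
            for gene, c in zip(design.hk_genes, hk_counts):
                records.append(RccRecord("Housekeeping", gene, f"NM_{gene}", int(c)))
            endo_means = np.array([
                design.baseline_mean * (design.signature_fold if g in sig else 1.0)
                for g in endo
            ]) * factor
            endo_counts = _draw_counts(rng, endo_means, design.dispersion)
            for gene, c in zip(endo, endo_counts):
                records.append(RccRecord("Endogenous", gene, f"NM_{gene}", int(c)))

            sample = f"{group}_{j + 1:02d}"
            lanes.append(RccLane(
                lane_id=str(lane_no),
                sample_name=sample,
                records=records,
                attributes={"FileVersion": "1.7",
                            "Sample_Attributes.Owner": "epnsig-synthetic",
                            "Lane_Attributes.CartridgeID": "SYN1"},
            ))
    return lanes


@dataclass
class SurvivalGroup:
    name: str
    n: int
    monthly_hazard_death: float
    monthly_hazard_progression: float = 0.0
    age_mean: float = 5.0
    age_sd: float = 2.0


@dataclass
class SurvivalDesign:
    """Exponential event times with uniform administrative censoring."""

    groups: Sequence[SurvivalGroup]
    censor_window_months: tuple[float, float] = (24.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.censor_window_months
        if lo <= 0 or hi < lo:
            raise ValueError("censoring window must be positive and ordered")
        for g in self.groups:
            for h in (g.monthly_hazard_death, g.monthly_hazard_progression):
                if not math.isfinite(h) or h < 0:
                    raise ValueError(f"group {g.name!r}: hazards must be finite and >= 0")


def _exp_times(rng: np.random.Generator, hazard: float, n: int) -> np.ndarray:
    if hazard == 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / hazard, size=n)


def simulate_survival(design: SurvivalDesign) -> list[ClinicalRecord]:
    """Clinical records under the designed hazards; deterministic per seed."""
    rng = np.random.default_rng(design.seed)
    lo, hi = design.censor_window_months
    records: list[ClinicalRecord] = []
    for g in design.groups:
        t_death = _exp_times(rng, g.monthly_hazard_death, g.n)
        t_prog = _exp_times(rng, g.monthly_hazard_progression, g.n)
        censor = rng.uniform(lo, hi, size=g.n)
        ages = np.clip(rng.normal(g.age_mean, g.age_sd, size=g.n), 0.1, None)
        sexes = rng.choice(["M", "F"], size=g.n)
        for i in range(g.n):
            death = bool(t_death[i] <= censor[i])
            time = float(min(t_death[i], censor[i]))
            first_prog = min(t_prog[i], t_death[i])
            progressed = bool(first_prog <= censor[i]) and math.isfinite(first_prog)
            t_pfs = float(min(first_prog, censor[i]))
            records.append(ClinicalRecord(
                patient_id=f"{g.name}_{i + 1:03d}",
                age_years=float(ages[i]),
                sex=str(sexes[i]),
                group_label=g.name,
                fusion_call=None,
                time_months=time,
                event_death=death,
                event_progression=progressed,
                time_progression_months=t_pfs,
            ))
    return records
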