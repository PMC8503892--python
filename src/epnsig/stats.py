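"""Downstream clinical statistics for the classified cohorts.

Covers the association between the RELA+ expression signature and the
ZFTA-RELA fusion call (two-sided Fisher's exact test on a 2x2 table),
Kaplan-Meier overall / progression-free survival with log-rank group
comparisons, two-sample t-tests (e.g. on age between PFA and PFB), and the
counting rules derived from the clinical table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .io import ClinicalRecord

__all__ = [
    "ContingencyTable2x2",
    "KmCurve",
    "fisher_exact_two_sided",
    "km_estimate",
    "logrank_test",
    "survivor_count",
    "fusion_concordance",
    "two_sample_ttest",
]


@dataclass
class ContingencyTable2x2:
    """Counts with rows = signature class and columns = fusion status."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class KmCurve:
    """Product-limit survival estimate on an event-time grid (months)."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival estimates must be non-increasing")

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: the sum of hypergeometric point
    probabilities (margins fixed) no larger than the observed table's
    (minimum-likelihood convention)."""
    if table.n == 0:
        return 1.0
    _, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def _endpoint_times(records: Iterable[ClinicalRecord], endpoint: str):
    """(durations, events) for OS or PFS, skipping unknown follow-up times."""
    durations: list[float] = []
    events: list[bool] = []
    for r in records:
        if endpoint == "OS":
            if r.time_months is None:
                continue
            durations.append(r.time_months)
            events.append(r.event_death)
        elif endpoint == "PFS":
            # first of progression or death; otherwise censored at follow-up
            if r.event_progression and r.time_progression_months is not None:
                durations.append(r.time_progression_months)
                events.append(True)
            elif r.time_months is None:
                continue
            else:
                durations.append(r.time_months)
                events.append(r.event_death)
        else:
            raise ValueError(f"unknown endpoint {endpoint!r}")
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=bool)


def km_estimate(records: Sequence[ClinicalRecord], endpoint: str = "OS") -> KmCurve:
    """Kaplan-Meier product-limit estimate for OS or PFS."""
    from lifelines import KaplanMeierFitter

    durations, events = _endpoint_times(records, endpoint)
    if durations.size == 0:
        raise ValueError("no records with a known follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([np.sum(durations >= t) for t in grid], dtype=int)
    return KmCurve(times=grid, survival=surv, at_risk=at_risk,
                   n_events=int(events.sum()))


def logrank_test(
    records: Sequence[ClinicalRecord],
    group_field: str = "group_label",
    endpoint: str = "OS",
) -> tuple[float, float]:
    """Mantel-Haenszel log-rank test across groups: (chi2, p)."""
    from lifelines.statistics import multivariate_logrank_test

    durations_all: list[float] = []
    events_all: list[bool] = []
    groups_all: list[str] = []
    by_group: dict[str, list[ClinicalRecord]] = {}
    for r in records:
        by_group.setdefault(getattr(r, group_field), []).append(r)
    if len(by_group) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    for g, recs in by_group.items():
        durations, events = _endpoint_times(recs, endpoint)
        durations_all.extend(durations)
        events_all.extend(events)
        groups_all.extend([g] * len(durations))
    if not any(events_all):
        raise ValueError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(
        np.asarray(durations_all), np.asarray(groups_all), np.asarray(events_all)
    )
    return float(res.test_statistic), float(res.p_value)


def survivor_count(records: Sequence[ClinicalRecord], group_label: str,
                   min_months: float) -> int:
    """Patients of ``group_label`` known to have survived >= ``min_months``.

    Counts patients alive with follow-up of at least ``min_months`` as well
    as those who died at or after ``min_months``; patients with shorter
    follow-up or an unknown death time cannot be verified and are not
    counted.  ``min_months <= 0`` returns the group size.
    """
    groups = {r.group_label for r in records}
    if group_label not in groups:
        raise ValueError(f"unknown group {group_label!r}; have {sorted(groups)}")
    members = [r for r in records if r.group_label == group_label]
    if min_months <= 0:
        return len(members)
    return sum(
        1 for r in members
        if r.time_months is not None and r.time_months >= min_months
    )


def fusion_concordance(
    records: Sequence[ClinicalRecord],
    positive_label: str = "RELA+",
    negative_label: str = "NC",
    fusion: str = "ZFTA-RELA",
) -> ContingencyTable2x2:
    """2x2 of signature class vs fusion detection.

    Rows are the signature-positive and not-classified samples (all other
    groups excluded); columns are whether the named fusion was detected.
    A different detected fusion (e.g. ZFTA-MAML2) counts as "not detected".
    """
    a = b = c = d = 0
    for r in records:
        detected = r.fusion_call == fusion
        if r.group_label == positive_label:
            a += detected
            b += not detected
        elif r.group_label == negative_label:
            c += detected
            d += not detected
    return ContingencyTable2x2(a, b, c, d)


def two_sample_ttest(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided equal-variance Student t-test p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    import warnings

    with warnings.catch_warnings():
        # degenerate zero-variance inputs are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):
        # zero pooled variance: identical means -> no evidence; else certain
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(p)
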