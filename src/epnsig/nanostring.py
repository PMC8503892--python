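"""Technical and biological normalization of nCounter lane batches.

The two-step scheme mirrors the instrument vendor's default processing:

1. **Positive-control (technical) normalization** — each lane is scaled by
   ``(batch mean of per-lane geometric means of the positive controls) /
   (this lane's geometric mean)``, equalizing the control geometric means
   across lanes and removing per-lane hybridization/scanning efficiency.
2. **Housekeeping (biological) normalization** — the same geometric-mean
   scaling using the housekeeping genes (default ACTB, GAPDH, TBP), removing
   differences in RNA input/quality.  Endogenous genes are then
   log2-transformed with pseudocount 1; control and housekeeping records are
   dropped from the output matrix.

Lanes whose scaling factor falls outside conventional QC bounds are flagged
but never dropped.  Background subtraction from the negative controls
(mean + 2*SD) is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import RccLane

__all__ = [
    "CountsBatch",
    "NormalizedCounts",
    "positive_control_normalize",
    "housekeeping_normalize",
    "normalize_lanes",
]

#: Flag-not-drop QC bounds on the technical (positive-control) factor.
TECH_FACTOR_BOUNDS = (0.3, 3.0)
#: Conventional bounds on the housekeeping (content) factor.
BIO_FACTOR_BOUNDS = (0.1, 10.0)


@dataclass
class CountsBatch:
    """Technically normalized counts for a lane batch.

    ``data`` is indexed by ``(code_class, gene)`` with one column per lane
    (sample name); ``tech_factors`` holds the per-lane scaling applied.
    """

    data: pd.DataFrame
    tech_factors: pd.Series
    qc_flags: dict[str, set[str]]

    def class_counts(self, code_class: str) -> pd.DataFrame:
        return self.data.loc[code_class]


@dataclass
class NormalizedCounts:
    """Log2 endogenous matrix (genes x samples) after both normalizations."""

    data: pd.DataFrame
    tech_factors: pd.Series
    bio_factors: pd.Series
    qc_flags: dict[str, set[str]]

    def __post_init__(self) -> None:
        if (self.tech_factors <= 0).any() or (self.bio_factors <= 0).any():
            raise ValueError("normalization factors must be strictly positive")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("normalized matrix contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def gene_names(self) -> list[str]:
        return list(self.data.index)


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _lanes_to_frame(lanes: Sequence[RccLane]) -> pd.DataFrame:
    """Stack lanes into a (code_class, gene) x sample frame.

    Lanes must share one codeset; sample names are made unique by suffixing
    duplicates with the lane id.
    """
    if not lanes:
        raise ValueError("empty lane batch")
    keys = [(r.code_class, r.gene_name) for r in lanes[0].records]
    keyset = set(keys)
    columns: dict[str, list[int]] = {}
    names: list[str] = []
    seen: set[str] = set()
    for lane in lanes:
        lane_keys = {(r.code_class, r.gene_name) for r in lane.records}
        if lane_keys != keyset:
            raise ValueError(
                f"lane {lane.lane_id!r} ({lane.sample_name!r}) disagrees with the "
                "batch codeset"
            )
        if not lane.normalization_eligible:
            raise ValueError(
                f"lane {lane.lane_id!r} lacks positive-control or housekeeping records"
            )
        name = lane.sample_name or lane.lane_id
        if name in seen:
            name = f"{name}.{lane.lane_id}"
        seen.add(name)
        names.append(name)
        lookup = {(r.code_class, r.gene_name): r.count for r in lane.records}
        columns[name] = [lookup[k] for k in keys]
    index = pd.MultiIndex.from_tuples(keys, names=["code_class", "gene"])
    return pd.DataFrame(columns, index=index, dtype=float)[names]


def positive_control_normalize(lanes: Sequence[RccLane]) -> CountsBatch:
    """Scale every lane so positive-control geometric means are equal.

    A lane with a zero positive-control count is flagged
    ``zero_positive_control`` and its geometric mean computed from the
    nonzero controls only; factors outside ``TECH_FACTOR_BOUNDS`` flag the
    lane ``tech_factor_out_of_range``.
    """
    frame = _lanes_to_frame(lanes)
    pos = frame.loc["Positive"]
    if pos.shape[0] < 2:
        raise ValueError("need >= 2 positive-control records per lane")
    qc_flags: dict[str, set[str]] = {s: set() for s in frame.columns}
    geo = {}
    for sample in frame.columns:
        vals = pos[sample].to_numpy()
        if (vals == 0).any():
            qc_flags[sample].add("zero_positive_control")
            vals = vals[vals > 0]
            if vals.size == 0:
                raise ValueError(f"lane {sample!r}: all positive controls are zero")
        geo[sample] = _geometric_mean(vals)
    target = float(np.mean(list(geo.values())))
    factors = pd.Series({s: target / g for s, g in geo.items()})
    lo, hi = TECH_FACTOR_BOUNDS
    for sample, f in factors.items():
        if not (lo <= f <= hi):
            qc_flags[sample].add("tech_factor_out_of_range")
    return CountsBatch(data=frame * factors, tech_factors=factors, qc_flags=qc_flags)


def housekeeping_normalize(
    batch: CountsBatch,
    hk_genes: Sequence[str] = ("ACTB", "GAPDH", "TBP"),
    subtract_background: bool = False,
) -> NormalizedCounts:
    """Housekeeping geometric-mean scaling, then log2(x+1) of endogenous genes.

    ``subtract_background=True`` first subtracts each lane's negative-control
    background estimate (mean + 2*SD), clipping at zero.
    """
    frame = batch.data.copy()
    qc_flags = {s: set(f) for s, f in batch.qc_flags.items()}

    if subtract_background:
        if "Negative" not in frame.index.get_level_values(0):
            raise ValueError("no negative-control records for background subtraction")
        neg = frame.loc["Negative"]
        background = neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)
        frame = (frame - background).clip(lower=0.0)

    try:
        hk = frame.loc[("Housekeeping", list(hk_genes)), :]
    except KeyError:
        hk = None
    if hk is None or hk.shape[0] != len(hk_genes):
        present = set(frame.loc["Housekeeping"].index) \
            if "Housekeeping" in frame.index.get_level_values(0) else set()
        missing = [g for g in hk_genes if g not in present]
        raise ValueError(f"housekeeping genes {missing} absent from the codeset")
    for sample in frame.columns:
        vals = hk[sample].to_numpy()
        if (vals <= 0).any():
            raise ValueError(
                f"lane {sample!r}: non-positive housekeeping count; cannot normalize"
            )

    geo = {s: _geometric_mean(hk[s].to_numpy()) for s in frame.columns}
    target = float(np.mean(list(geo.values())))
    bio_factors = pd.Series({s: target / g for s, g in geo.items()})
    lo, hi = BIO_FACTOR_BOUNDS
    for sample, f in bio_factors.items():
        if not (lo <= f <= hi):
            qc_flags[sample].add("bio_factor_out_of_range")

    scaled = frame * bio_factors
    endo = scaled.loc["Endogenous"]
    log2 = np.log2(endo + 1.0)
    return NormalizedCounts(
        data=log2,
        tech_factors=batch.tech_factors.reindex(log2.columns),
        bio_factors=bio_factors.reindex(log2.columns),
        qc_flags=qc_flags,
    )


def normalize_lanes(
    lanes: Sequence[RccLane],
    hk_genes: Sequence[str] = ("ACTB", "GAPDH", "TBP"),
    subtract_background: bool = False,
) -> NormalizedCounts:
    """Convenience composition of the two normalization steps."""
    return housekeeping_normalize(
        positive_control_normalize(lanes),
        hk_genes=hk_genes,
        subtract_background=subtract_background,
    )
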