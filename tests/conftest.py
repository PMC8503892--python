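import numpy as np
import pandas as pd
import pytest

from epnsig.io import RccLane, RccRecord


def make_lane(lane_id="1", sample="S1", pos=(1000, 500, 100), hk=(2000, 1500, 1000),
              endo=None, neg=(5, 3), hk_genes=("ACTB", "GAPDH", "TBP")):
    """Small hand-built RCC lane for normalization tests."""
    if endo is None:
        endo = {"RELA": 800, "ELL3": 400, "FBP2": 200}
    records = []
    for i, c in enumerate(pos):
        records.append(RccRecord("Positive", f"POS_{chr(65 + i)}", f"P{i}", int(c)))
    for i, c in enumerate(neg):
        records.append(RccRecord("Negative", f"NEG_{chr(65 + i)}", f"N{i}", int(c)))
    for g, c in zip(hk_genes, hk):
        records.append(RccRecord("Housekeeping", g, f"HK_{g}", int(c)))
    for g, c in endo.items():
        records.append(RccRecord("Endogenous", g, f"E_{g}", int(c)))
    return RccLane(lane_id=lane_id, sample_name=sample, records=records,
                   attributes={"FileVersion": "1.7"})


def scale_lane(lane: RccLane, factor: int) -> RccLane:
    """Integer-rescale every count of a lane (new sample name)."""
    return RccLane(
        lane_id=lane.lane_id + "x",
        sample_name=lane.sample_name + "x",
        records=[r._replace(count=r.count * factor) for r in lane.records],
        attributes=dict(lane.attributes),
    )


@pytest.fixture
def frame_pf():
    """Tiny posterior-fossa-like log2 matrix with clear PFA/PFB structure."""
    genes = ["LAMA2", "ALDH1L1", "SLC6A13", "IGSF1", "CXorf67",
             "NELL2", "DNAH1", "CEP83", "C9orf72", "NXNL2"]
    rng = np.random.default_rng(42)
    cols = {}
    for i in range(6):
        cols[f"A{i}"] = np.r_[np.full(5, 10.0), np.full(5, 6.0)] + rng.normal(0, 0.1, 10)
    for i in range(3):
        cols[f"B{i}"] = np.r_[np.full(5, 6.0), np.full(5, 10.0)] + rng.normal(0, 0.1, 10)
    return pd.DataFrame(cols, index=genes)
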