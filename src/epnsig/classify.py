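"""Molecular-group assignment from signature-gene expression.

Supratentorial tumours are assigned RELA+ / YAP1+ / NC by average-linkage
hierarchical clustering (Euclidean distance on log2 values) anchored by
reference samples of known fusion status; posterior-fossa tumours are split
into PFA / PFB (with outlier detection), PFA into PFA1 / PFA2 on a four-gene
panel, and the whole PF cohort is stratified by the two-gene NELL2 / LAMA2
expression status.

A sample's *signature score* for a group is the mean, over the group's
panel genes, of the per-gene z-score computed across the analysis batch.
Positive/negative calls on one-dimensional scores use a two-cluster
variance-minimizing split (no fixed count threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .io import ExpressionMatrix
from .nanostring import NormalizedCounts

__all__ = [
    "SignaturePanel",
    "GroupAssignment",
    "DendrogramCut",
    "cluster_samples",
    "assign_by_reference",
    "assign_pf",
    "assign_pfa_subgroup",
    "classify_nell2_lama2",
    "split_1d",
]

#: Final marker-gene panels after probe QC (DRD1 and ANGPTL6 removed:
#: uniform-low and nonspecific hybridization respectively).
SUPRATENTORIAL_PANEL = {
    "RELA+": ("RELA", "ELL3", "FBP2", "PCP4L1", "MYO3A"),
    "YAP1+": ("MRAP", "IGF1", "CAPS", "WWC1"),
}
POSTERIOR_FOSSA_PANEL = {
    "PFA": ("LAMA2", "ALDH1L1", "SLC6A13", "IGSF1", "CXorf67"),
    "PFB": ("NELL2", "DNAH1", "CEP83", "C9orf72", "NXNL2"),
}
PFA_SUBGROUP_PANEL = {
    "PFA1": ("SKAP2", "WIF1"),
    "PFA2": ("EN2", "CNPY1"),
}


@dataclass
class SignaturePanel:
    """Group -> signature-gene map; genes must be unique within a panel.

    The six-gene CNS HGNET-MN1 signature is not part of the defaults and
    must be supplied by the user (``SignaturePanel({"MN1": (...)})``).
    """

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        self.groups = {g: tuple(genes) for g, genes in self.groups.items()}
        seen: dict[str, str] = {}
        for group, genes in self.groups.items():
            if not genes:
                raise ValueError(f"group {group!r} has an empty signature set")
            for gene in genes:
                if gene in seen:
                    raise ValueError(
                        f"gene {gene!r} appears in both {seen[gene]!r} and {group!r}"
                    )
                seen[gene] = group

    @classmethod
    def supratentorial(cls) -> "SignaturePanel":
        return cls(dict(SUPRATENTORIAL_PANEL))

    @classmethod
    def posterior_fossa(cls) -> "SignaturePanel":
        return cls(dict(POSTERIOR_FOSSA_PANEL))

    @classmethod
    def pfa_subgroups(cls) -> "SignaturePanel":
        return cls(dict(PFA_SUBGROUP_PANEL))

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        for genes in self.groups.values():
            out.extend(genes)
        return out


@dataclass
class GroupAssignment:
    """Per-sample molecular label with its score and supporting evidence."""

    sample_id: str
    label: str
    score: float
    evidence: str = "score-rule"


@dataclass
class DendrogramCut:
    """Average-linkage merge tree over a sample set."""

    sample_ids: tuple[str, ...]
    linkage: np.ndarray
    method: str = "average"
    metric: str = "euclidean"

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (1..k) at ``k`` clusters."""
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def cophenetic(self) -> np.ndarray:
        """Square cophenetic-distance matrix (merge height of each pair's LCA)."""
        from scipy.spatial.distance import squareform
        return squareform(hierarchy.cophenet(self.linkage))


Matrix = Union[ExpressionMatrix, NormalizedCounts, pd.DataFrame]


def _as_frame(matrix: Matrix) -> pd.DataFrame:
    if isinstance(matrix, pd.DataFrame):
        return matrix
    return matrix.data


def _zscores(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across the batch (constant genes get z = 0)."""
    mu = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=0).replace(0.0, np.inf)
    return frame.sub(mu, axis=0).div(sd, axis=0)


def _signature_scores(frame: pd.DataFrame, panel: SignaturePanel) -> pd.DataFrame:
    """groups x samples mean-z signature scores."""
    z = _zscores(frame)
    return pd.DataFrame(
        {g: z.loc[list(genes)].mean(axis=0) for g, genes in panel.groups.items()}
    ).T


def cluster_samples(matrix: Matrix, genes: Sequence[str]) -> DendrogramCut:
    """Average-linkage tree on Euclidean distances over the gene subset."""
    frame = _as_frame(matrix)
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")
    if frame.shape[1] < 2:
        raise ValueError("need >= 2 samples to cluster")
    X = frame.loc[list(genes)].T.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    return DendrogramCut(sample_ids=tuple(frame.columns), linkage=Z)


def _cluster_members(labels: np.ndarray, sample_ids: Sequence[str]) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for sid, lab in zip(sample_ids, labels):
        out.setdefault(int(lab), []).append(sid)
    return out


def assign_by_reference(
    cut: DendrogramCut,
    matrix: Matrix,
    references: Mapping[str, str],
    panel: Optional[SignaturePanel] = None,
    k: Optional[int] = None,
    z_min: float = 2.0,
) -> list[GroupAssignment]:
    """Label samples by co-clustering with molecularly verified references.

    The tree is cut into ``k`` clusters (default: number of distinct
    reference groups + 2, leaving room for an unclassified cluster and a
    possible singleton).  A cluster containing references of exactly one
    group takes that group's label; if references of different groups fall
    into one cluster, ``k`` is increased until they separate (identical
    conflicting references raise).  An unreferenced cluster whose best
    signature score reaches ``z_min`` for a group with no reference in the
    batch takes that label (the rare-group case); any other unreferenced
    cluster adopts the label of the cophenetically nearest referenced
    cluster.
    """
    if panel is None:
        panel = SignaturePanel.supratentorial()
    if not references:
        raise ValueError("need at least one reference sample")
    frame = _as_frame(matrix)
    unknown = set(references) - set(cut.sample_ids)
    if unknown:
        raise ValueError(f"reference samples not in the batch: {sorted(unknown)}")
    ref_groups = sorted(set(references.values()))
    n = len(cut.sample_ids)
    if k is None:
        k = min(len(ref_groups) + 2, n)

    labels = None
    for kk in range(k, n + 1):
        candidate = cut.cut(kk)
        members = _cluster_members(candidate, cut.sample_ids)
        conflict = any(
            len({references[s] for s in mem if s in references}) > 1
            for mem in members.values()
        )
        if not conflict:
            labels = candidate
            break
    if labels is None:
        raise ValueError(
            "references of different groups co-cluster at every cut; "
            "review the signature panel"
        )

    members = _cluster_members(labels, cut.sample_ids)
    scores = _signature_scores(frame, panel)
    coph = cut.cophenetic()
    pos = {s: i for i, s in enumerate(cut.sample_ids)}

    cluster_label: dict[int, str] = {}
    cluster_evidence: dict[int, str] = {}
    referenced: list[int] = []
    for cid, mem in members.items():
        refs_here = [s for s in mem if s in references]
        if refs_here:
            cluster_label[cid] = references[refs_here[0]]
            cluster_evidence[cid] = "co-clustered with " + ",".join(refs_here)
            referenced.append(cid)

    unref_groups = [g for g in panel.groups if g not in ref_groups]
    for cid, mem in members.items():
        if cid in cluster_label:
            continue
        mean_scores = scores[mem].mean(axis=1)
        best_unref = None
        if unref_groups:
            best_unref = mean_scores.loc[unref_groups].idxmax()
        if best_unref is not None and mean_scores[best_unref] >= z_min:
            cluster_label[cid] = best_unref
            cluster_evidence[cid] = "score-rule"
            continue
        # adopt the nearest referenced cluster's label (cophenetic distance)
        best_cid, best_d = None, np.inf
        for rcid in referenced:
            d = min(coph[pos[a], pos[b]] for a in mem for b in members[rcid])
            if d < best_d:
                best_cid, best_d = rcid, d
        if best_cid is None:
            cluster_label[cid] = "NC"
            cluster_evidence[cid] = "score-rule"
        else:
            cluster_label[cid] = cluster_label[best_cid]
            cluster_evidence[cid] = f"nearest reference cluster ({cluster_evidence[best_cid]})"

    out: list[GroupAssignment] = []
    for sid in cut.sample_ids:
        cid = int(labels[pos[sid]])
        group = cluster_label[cid]
        score = float(scores.loc[group, sid]) if group in scores.index else float("nan")
        out.append(GroupAssignment(sid, group, score, cluster_evidence[cid]))
    return out


def split_1d(values: Sequence[float]) -> tuple[np.ndarray, float]:
    """Two-cluster variance-minimizing partition of a 1-D array.

    Returns a boolean high-cluster mask and the midpoint threshold.  Raises
    on constant input (no split exists).
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("cannot split constant values")
    order = np.argsort(x, kind="stable")
    s = x[order]
    n = len(s)
    csum = np.cumsum(s)
    csq = np.cumsum(s ** 2)
    best_i, best_ss = 0, np.inf
    for i in range(1, n):  # low cluster = s[:i]
        if s[i] == s[i - 1]:
            continue  # ties must not straddle the boundary
        ss_low = csq[i - 1] - csum[i - 1] ** 2 / i
        ss_high = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        ss = ss_low + ss_high
        if ss < best_ss - 1e-12:
            best_i, best_ss = i, ss
    threshold = (s[best_i - 1] + s[best_i]) / 2.0
    mask = x > threshold
    return mask, float(threshold)


def assign_pf(
    matrix: Matrix,
    panel: Optional[SignaturePanel] = None,
) -> list[GroupAssignment]:
    """PFA / PFB assignment with outlier detection.

    Samples sitting in the low cluster of *both* signature scores (two-gene
    1-D splits of the mean log2 signature expression) carry neither
    signature and are labelled ``outlier`` before clustering; the remaining
    samples are cut into two average-linkage clusters over the ten panel
    genes, and each cluster is labelled by its mean PFA-vs-PFB z-score
    differential.
    """
    if panel is None:
        panel = SignaturePanel.posterior_fossa()
    groups = list(panel.groups)
    if len(groups) != 2:
        raise ValueError("assign_pf needs a two-group panel")
    ga, gb = groups
    frame = _as_frame(matrix)
    if frame.shape[1] < 3:
        raise ValueError("need >= 3 samples for PF assignment")
    missing = [g for g in panel.all_genes if g not in frame.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")

    values = frame.loc[panel.all_genes]
    if np.ptp(values.to_numpy()) == 0:
        warnings.warn("degenerate all-equal matrix: every sample labelled outlier")
        return [GroupAssignment(s, "outlier", 0.0) for s in frame.columns]

    raw_scores = {
        g: values.loc[list(genes)].mean(axis=0) for g, genes in panel.groups.items()
    }
    high: dict[str, np.ndarray] = {}
    for g in groups:
        try:
            high[g], _ = split_1d(raw_scores[g].to_numpy())
        except ValueError:
            high[g] = np.ones(frame.shape[1], dtype=bool)
    is_outlier = ~high[ga] & ~high[gb]
    outliers = [s for s, o in zip(frame.columns, is_outlier) if o]
    kept = [s for s in frame.columns if s not in outliers]

    z = _signature_scores(frame, panel)
    out: dict[str, GroupAssignment] = {
        s: GroupAssignment(s, "outlier", float(z[s].max()), "score-rule")
        for s in outliers
    }
    if len(kept) >= 2:
        cut = cluster_samples(frame[kept], panel.all_genes)
        labels = cut.cut(2)
        members = _cluster_members(labels, kept)
        zk = _signature_scores(frame[kept], panel)
        diff = {cid: float((zk.loc[ga, mem] - zk.loc[gb, mem]).mean())
                for cid, mem in members.items()}
        a_cluster = max(diff, key=lambda c: diff[c])
        for cid, mem in members.items():
            lab = ga if cid == a_cluster else gb
            for s in mem:
                out[s] = GroupAssignment(s, lab, float(zk.loc[lab, s]),
                                         "2-cluster cut")
    elif kept:
        s = kept[0]
        lab = ga if z.loc[ga, s] >= z.loc[gb, s] else gb
        out[s] = GroupAssignment(s, lab, float(z.loc[lab, s]))
    return [out[s] for s in frame.columns]


def assign_pfa_subgroup(
    matrix: Matrix,
    panel: Optional[SignaturePanel] = None,
) -> list[GroupAssignment]:
    """PFA1 / PFA2 sub-assignment of PFA-labelled samples (four-gene panel)."""
    if panel is None:
        panel = SignaturePanel.pfa_subgroups()
    groups = list(panel.groups)
    if len(groups) != 2:
        raise ValueError("assign_pfa_subgroup needs a two-group panel")
    ga, gb = groups
    frame = _as_frame(matrix)
    if frame.shape[1] < 3:
        warnings.warn("fewer than 3 PFA samples: subgrouping refused")
        return [GroupAssignment(s, "PFA", float("nan"), "too few samples")
                for s in frame.columns]
    missing = [g for g in panel.all_genes if g not in frame.index]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")
    sub = frame.loc[panel.all_genes]
    if np.ptp(sub.to_numpy()) == 0:
        warnings.warn("subgroup genes carry no signal: samples stay PFA")
        return [GroupAssignment(s, "PFA", float("nan"), "flat subgroup genes")
                for s in frame.columns]

    cut = cluster_samples(frame, panel.all_genes)
    labels = cut.cut(2)
    members = _cluster_members(labels, cut.sample_ids)
    z = _signature_scores(frame, panel)
    diff = {cid: float((z.loc[ga, mem] - z.loc[gb, mem]).mean())
            for cid, mem in members.items()}
    a_cluster = max(diff, key=lambda c: diff[c])
    out: dict[str, GroupAssignment] = {}
    for cid, mem in members.items():
        lab = ga if cid == a_cluster else gb
        for s in mem:
            out[s] = GroupAssignment(s, lab, float(z.loc[lab, s]), "2-cluster cut")
    return [out[s] for s in frame.columns]


def classify_nell2_lama2(
    matrix: Matrix, genes: tuple[str, str] = ("NELL2", "LAMA2")
) -> list[GroupAssignment]:
    """Two-gene expression trichotomy of the PF cohort.

    Each gene's log2 values are dichotomized by the two-cluster
    variance-minimizing split; the labels compose to NELL2+/LAMA2-,
    NELL2+/LAMA2+ and NELL2-/LAMA2+, with the doubly negative combination
    mapped to ``outlier``.
    """
    g1, g2 = genes
    frame = _as_frame(matrix)
    for g in genes:
        if g not in frame.index:
            raise ValueError(f"gene {g!r} absent from the matrix")
    v1 = frame.loc[g1].to_numpy(dtype=float)
    v2 = frame.loc[g2].to_numpy(dtype=float)
    for g, v in ((g1, v1), (g2, v2)):
        if np.ptp(v) == 0:
            raise ValueError(f"gene {g!r} has all-equal values; no split exists")
    hi1, _ = split_1d(v1)
    hi2, _ = split_1d(v2)
    z = _zscores(frame.loc[[g1, g2]])
    out: list[GroupAssignment] = []
    for i, sid in enumerate(frame.columns):
        if hi1[i] and not hi2[i]:
            label = f"{g1}+/{g2}-"
        elif hi1[i] and hi2[i]:
            label = f"{g1}+/{g2}+"
        elif hi2[i]:
            label = f"{g1}-/{g2}+"
        else:
            label = "outlier"
        score = float(z.iloc[:, i].mean())
        out.append(GroupAssignment(sid, label, score, "two-gene split"))
    return out
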