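import numpy as np
import pandas as pd
import pytest

from epnsig.classify import (SignaturePanel, assign_by_reference, assign_pf,
                             assign_pfa_subgroup, classify_nell2_lama2,
                             cluster_samples, split_1d)
from epnsig.nanostring import normalize_lanes
from epnsig.simulate import NanoDesign, simulate_nanostring_run

ST = SignaturePanel.supratentorial().groups
PF = SignaturePanel.posterior_fossa().groups
SUB = SignaturePanel.pfa_subgroups().groups


def pf_norm(n_pfa=42, n_pfb=7, n_flat=1, fold=6.0, seed=3, **kwargs):
    sets = {"PFA": PF["PFA"], "PFB": PF["PFB"]}
    groups = [("PFA", n_pfa), ("PFB", n_pfb)]
    if n_flat:
        sets["FLAT"] = ()
        groups.append(("FLAT", n_flat))
    design = NanoDesign(groups=groups, signature_sets=sets,
                        signature_fold=fold, seed=seed, **kwargs)
    return normalize_lanes(simulate_nanostring_run(design))


class TestSignaturePanel:
    def test_defaults_match_final_gene_lists(self):
        panel = SignaturePanel.supratentorial()
        assert panel.groups["RELA+"] == ("RELA", "ELL3", "FBP2", "PCP4L1", "MYO3A")
        assert panel.groups["YAP1+"] == ("MRAP", "IGF1", "CAPS", "WWC1")
        # probes failing hybridization QC are not in the panels
        assert "DRD1" not in panel.all_genes and "ANGPTL6" not in panel.all_genes

    def test_shared_gene_rejected(self):
        with pytest.raises(ValueError, match="appears in both"):
            SignaturePanel({"A": ("G1",), "B": ("G1", "G2")})


class TestClusterSamples:
    def test_identical_samples_merge_at_height_zero(self):
        frame = pd.DataFrame({"S1": [1.0, 2.0], "S2": [1.0, 2.0], "S3": [5.0, 9.0]},
                             index=["g1", "g2"])
        cut = cluster_samples(frame, ["g1", "g2"])
        assert cut.linkage[0, 2] == 0.0
        assert set(np.where(cut.cut(2) == cut.cut(2)[0])[0]) == {0, 1}

    def test_closest_pair_merges_first_and_heights_monotone(self):
        frame = pd.DataFrame({"S1": [0.0], "S2": [1.0], "S3": [10.0]}, index=["g"])
        cut = cluster_samples(frame, ["g"])
        first = set(cut.linkage[0, :2].astype(int))
        assert first == {0, 1}
        heights = cut.linkage[:, 2]
        assert np.all(np.diff(heights) >= 0)

    def test_missing_gene_listed(self, frame_pf):
        with pytest.raises(ValueError, match="NOPE"):
            cluster_samples(frame_pf, ["LAMA2", "NOPE"])


class TestSplit1d:
    def test_bimodal_split(self):
        mask, thr = split_1d([4.0, 4.2, 3.9, 10.0, 10.3])
        assert mask.tolist() == [False, False, False, True, True]
        assert 4.2 < thr < 10.0

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            split_1d([2.0, 2.0, 2.0])


class TestAssignByReference:
    def test_references_only_each_labels_own_cluster(self):
        frame = pd.DataFrame(
            {"refP": np.r_[np.full(5, 10.0), np.full(4, 5.0)],
             "refN": np.full(9, 5.0)},
            index=list(ST["RELA+"]) + list(ST["YAP1+"]))
        cut = cluster_samples(frame, list(frame.index))
        out = assign_by_reference(cut, frame, {"refP": "RELA+", "refN": "NC"}, k=2)
        labels = {a.sample_id: a.label for a in out}
        assert labels == {"refP": "RELA+", "refN": "NC"}

    def test_synthetic_batch_recovery(self):
        """10 RELA-like + 6 flat + 1 YAP1-like lanes plus two references
        recover 10 RELA+, 6 NC (+ the NC reference) and 1 YAP1+."""
        sets = {"RELA": ST["RELA+"], "YAP1": ST["YAP1+"], "NCQ": (),
                "REFP": ST["RELA+"], "REFN": ()}
        design = NanoDesign(
            groups=[("RELA", 10), ("NCQ", 6), ("YAP1", 1), ("REFP", 1), ("REFN", 1)],
            signature_sets=sets, signature_fold=6.0, seed=17)
        norm = normalize_lanes(simulate_nanostring_run(design))
        panel = SignaturePanel.supratentorial()
        cut = cluster_samples(norm, panel.all_genes)
        out = assign_by_reference(cut, norm, {"REFP_01": "RELA+", "REFN_01": "NC"},
                                  panel)
        expected = {"RELA": "RELA+", "NCQ": "NC", "YAP1": "YAP1+",
                    "REFP": "RELA+", "REFN": "NC"}
        for a in out:
            assert a.label == expected[a.sample_id.rsplit("_", 1)[0]], a

    def test_reference_samples_keep_their_group(self):
        norm = pf_norm(5, 3, 0, seed=23)
        panel = SignaturePanel.posterior_fossa()
        cut = cluster_samples(norm, panel.all_genes)
        refs = {"PFA_01": "PFA", "PFB_01": "PFB"}
        out = assign_by_reference(cut, norm, refs, panel)
        labels = {a.sample_id: a.label for a in out}
        assert labels["PFA_01"] == "PFA" and labels["PFB_01"] == "PFB"

    def test_all_flat_queries_are_nc(self):
        """Signature-less lanes cluster with the fusion-negative reference."""
        # zero-lane group keeps the YAP1 genes on the codeset
        sets = {"NCQ": (), "REFP": ST["RELA+"], "REFN": (), "Y0": ST["YAP1+"]}
        design = NanoDesign(groups=[("NCQ", 8), ("REFP", 1), ("REFN", 1), ("Y0", 0)],
                            signature_sets=sets, signature_fold=6.0, seed=29)
        norm = normalize_lanes(simulate_nanostring_run(design))
        panel = SignaturePanel.supratentorial()
        cut = cluster_samples(norm, panel.all_genes)
        out = assign_by_reference(cut, norm, {"REFP_01": "RELA+", "REFN_01": "NC"},
                                  panel)
        for a in out:
            if a.sample_id.startswith("NCQ"):
                assert a.label == "NC"

    def test_unknown_reference_rejected(self, frame_pf):
        cut = cluster_samples(frame_pf, list(frame_pf.index))
        with pytest.raises(ValueError, match="not in the batch"):
            assign_by_reference(cut, frame_pf, {"ghost": "PFA"})


class TestAssignPf:
    def test_recovery_42_7_1(self):
        norm = pf_norm()
        out = assign_pf(norm)
        counts = pd.Series([a.label for a in out]).value_counts()
        assert counts["PFA"] == 42 and counts["PFB"] == 7 and counts["outlier"] == 1
        for a in out:
            planted = a.sample_id.rsplit("_", 1)[0]
            assert a.label == {"PFA": "PFA", "PFB": "PFB", "FLAT": "outlier"}[planted]

    def test_signature_swap_swaps_labels(self, frame_pf):
        out1 = {a.sample_id: a.label for a in assign_pf(frame_pf)}
        swapped = SignaturePanel({"PFA": PF["PFB"], "PFB": PF["PFA"]})
        out2 = {a.sample_id: a.label for a in assign_pf(frame_pf, swapped)}
        flip = {"PFA": "PFB", "PFB": "PFA", "outlier": "outlier"}
        assert out2 == {s: flip[l] for s, l in out1.items()}

    def test_single_pfb_among_pfa_still_pfb(self):
        norm = pf_norm(12, 1, 0, seed=31)
        out = {a.sample_id: a.label for a in assign_pf(norm)}
        assert out["PFB_01"] == "PFB"
        assert all(l == "PFA" for s, l in out.items() if s.startswith("PFA"))

    def test_degenerate_matrix_all_outlier(self):
        frame = pd.DataFrame(5.0, index=list(PF["PFA"] + PF["PFB"]),
                             columns=["S1", "S2", "S3"])
        with pytest.warns(UserWarning, match="degenerate"):
            out = assign_pf(frame)
        assert all(a.label == "outlier" for a in out)

    def test_sample_order_invariance(self, frame_pf):
        out1 = {a.sample_id: a.label for a in assign_pf(frame_pf)}
        shuffled = frame_pf[list(frame_pf.columns[::-1])]
        out2 = {a.sample_id: a.label for a in assign_pf(shuffled)}
        assert out1 == out2


class TestAssignPfaSubgroup:
    def _norm(self, n1=33, n2=9, seed=5):
        sets = {"PFA1": tuple(PF["PFA"]) + SUB["PFA1"],
                "PFA2": tuple(PF["PFA"]) + SUB["PFA2"]}
        design = NanoDesign(groups=[("PFA1", n1), ("PFA2", n2)],
                            signature_sets=sets, seed=seed)
        return normalize_lanes(simulate_nanostring_run(design))

    def test_recovery_33_9(self):
        out = assign_pfa_subgroup(self._norm())
        assert sum(a.label == "PFA1" for a in out) == 33
        assert sum(a.label == "PFA2" for a in out) == 9
        for a in out:
            assert a.label == a.sample_id.rsplit("_", 1)[0]

    def test_gene_set_swap_swaps_labels(self):
        norm = self._norm(8, 4, seed=7)
        out1 = {a.sample_id: a.label for a in assign_pfa_subgroup(norm)}
        swapped = SignaturePanel({"PFA1": SUB["PFA2"], "PFA2": SUB["PFA1"]})
        out2 = {a.sample_id: a.label for a in assign_pfa_subgroup(norm, swapped)}
        flip = {"PFA1": "PFA2", "PFA2": "PFA1"}
        assert out2 == {s: flip[l] for s, l in out1.items()}

    def test_flat_subgroup_genes_stay_pfa(self):
        genes = list(SUB["PFA1"] + SUB["PFA2"])
        frame = pd.DataFrame(
            np.r_[np.full((4, 5), 6.0), np.random.default_rng(0).normal(8, 1, (2, 5))],
            index=genes + ["LAMA2", "IGSF1"],
            columns=[f"S{i}" for i in range(5)])
        with pytest.warns(UserWarning, match="stay PFA"):
            out = assign_pfa_subgroup(frame)
        assert all(a.label == "PFA" for a in out)

    def test_too_few_samples_stay_pfa(self, frame_pf):
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = assign_pfa_subgroup(frame_pf.iloc[:, :2])
        assert all(a.label == "PFA" for a in out)


class TestNell2Lama2:
    def test_planted_bimodality_trichotomy(self):
        cols = {}
        for i in range(3):
            cols[f"BB_{i}"] = [10.0 + 0.1 * i, 4.0]   # NELL2 high only
        for i in range(4):
            cols[f"AA_{i}"] = [4.0 + 0.1 * i, 10.0]   # LAMA2 high only
        for i in range(2):
            cols[f"DP_{i}"] = [10.0, 10.0 + 0.1 * i]  # both
        frame = pd.DataFrame(cols, index=["NELL2", "LAMA2"])
        out = {a.sample_id: a.label for a in classify_nell2_lama2(frame)}
        assert all(out[f"BB_{i}"] == "NELL2+/LAMA2-" for i in range(3))
        assert all(out[f"AA_{i}"] == "NELL2-/LAMA2+" for i in range(4))
        assert all(out[f"DP_{i}"] == "NELL2+/LAMA2+" for i in range(2))

    def test_double_negative_is_outlier(self):
        frame = pd.DataFrame({"S1": [10.0, 4.0], "S2": [4.0, 10.0],
                              "S3": [4.0, 4.0]}, index=["NELL2", "LAMA2"])
        out = {a.sample_id: a.label for a in classify_nell2_lama2(frame)}
        assert out["S3"] == "outlier"
        assert out["S1"] == "NELL2+/LAMA2-"

    def test_constant_gene_rejected(self):
        frame = pd.DataFrame({"S1": [5.0, 4.0], "S2": [5.0, 10.0]},
                              index=["NELL2", "LAMA2"])
        with pytest.raises(ValueError, match="NELL2"):
            classify_nell2_lama2(frame)

    def test_pfb_lanes_are_nell2_pos_lama2_neg(self):
        norm = pf_norm(10, 5, 0, seed=19)
        pf_labels = {a.sample_id: a.label for a in assign_pf(norm)}
        nl_labels = {a.sample_id: a.label for a in classify_nell2_lama2(norm)}
        pfb = {s for s, l in pf_labels.items() if l == "PFB"}
        nell_pos = {s for s, l in nl_labels.items() if l == "NELL2+/LAMA2-"}
        assert pfb == nell_pos
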