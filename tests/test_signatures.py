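from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from sigcollapse import (Signature, SignatureSet, assemble_signatures,
                         extend_mirna_signature, mirna_signatures,
                         network_correlated_component, spearman)
from sigcollapse import mi_study
from sigcollapse.io_formats import InteractionNetwork, TargetMap
from sigcollapse.signatures import read_signature_set, write_signature_set

from conftest import factor_matrix


class TestSpearman:
    def test_identity_and_reversal(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x).rho == 1.0
        assert spearman(x, x).p == 0.0
        assert spearman(x, x[::-1]).rho == -1.0

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])

    def test_rejection_decisions_match_exact_permutation_distribution(self):
        """At n=5 the t-approximate p must reach the same accept/reject call
        as the exact permutation distribution of rho over all 120 orderings."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(40):
            y = rng.permutation(x) + 0.01 * rng.standard_normal(5)
            rec = spearman(x, y)
            # exact two-sided permutation p of |rho|
            rhos = [spearman(x, np.array(perm)).rho for perm in permutations(y)]
            p_exact = float(np.mean(np.abs(rhos) >= abs(rec.rho) - 1e-12))
            if abs(p_exact - 0.05) > 0.04:  # skip knife-edge cases
                assert (rec.p < 0.05) == (p_exact < 0.05)
                checked += 1
        assert checked >= 15


class TestMirnaSignatures:
    def _degs(self, genes):
        return pd.DataFrame({"direction": ["up"] * len(genes)}, index=genes)

    def test_worked_example_six_member_signature(self):
        # three strongly positive targets, two negative, mirroring the
        # published MIR21 co-expression pattern
        m = factor_matrix({
            "MIR21": (1.0, 0.05), "BCL6": (1.0, 0.1), "CCR1": (1.0, 0.1),
            "SGK1": (1.0, 0.1), "PDGFD": (-0.8, 0.3), "TGFBR3": (-0.8, 0.3),
            "MAFB": (0.0, 1.0),
        })
        degs = self._degs(["MIR21", "BCL6", "CCR1", "SGK1", "PDGFD", "TGFBR3"])
        targets = TargetMap({"MIR21": frozenset(
            {"BCL6", "CCR1", "PDGFD", "SGK1", "TGFBR3"})})
        sigs = mirna_signatures(degs, targets, m)
        assert len(sigs) == 1
        sig = sigs[0]
        assert sig.anchor == "MIR21" and sig.members[0] == "MIR21"
        assert set(sig.members) == {"MIR21", "BCL6", "CCR1", "SGK1",
                                    "PDGFD", "TGFBR3"}
        assert sig.provenance["correlations"]["BCL6"]["rho"] > 0.9
        assert sig.provenance["correlations"]["PDGFD"]["rho"] < -0.6

    def test_mirna_without_deg_targets_yields_nothing(self):
        m = factor_matrix({"MIR21": (1.0, 0.1), "BCL6": (1.0, 0.1)})
        degs = self._degs(["MIR21"])
        targets = TargetMap({"MIR21": frozenset({"BCL6"})})
        assert mirna_signatures(degs, targets, m) == []

    def test_mirna_absent_from_matrix_skipped_with_warning(self, caplog):
        m = factor_matrix({"BCL6": (1.0, 0.1), "X": (0.0, 1.0)})
        degs = self._degs(["MIR21", "BCL6"])
        targets = TargetMap({"MIR21": frozenset({"BCL6"})})
        import logging
        with caplog.at_level(logging.WARNING):
            assert mirna_signatures(degs, targets, m) == []
        assert any("MIR21" in r.message for r in caplog.records)

    def test_uncorrelated_block_yields_no_signature_under_null(self):
        # loading 0: the target is pure noise relative to the miRNA
        misses = 0
        for seed in range(40):
            m = factor_matrix({"MIRX": (1.0, 0.1), "TGT": (0.0, 1.0)},
                              n=20, seed=seed)
            sigs = mirna_signatures(self._degs(["MIRX", "TGT"]),
                                    TargetMap({"MIRX": frozenset({"TGT"})}), m)
            misses += (sigs == [])
        assert misses >= 36  # ~alpha=0.05 false-positive rate


class TestExtendMirnaSignature:
    def _base(self):
        m = factor_matrix({
            "MIR21": (1.0, 0.05), "CCR1": (1.0, 0.1), "FCGR1A": (0.9, 0.2),
            "FCGR1B": (0.9, 0.2), "FPR1": (0.8, 0.3), "S100A12": (0.8, 0.3),
            "HLA-DQB1": (0.0, 1.0),
        })
        sig = Signature("MIR21", "mirna", ("MIR21", "CCR1"), anchor="MIR21")
        return sig, m

    def test_correlated_candidates_appended(self):
        sig, m = self._base()
        out = extend_mirna_signature(
            sig, ["FCGR1A", "FCGR1B", "FPR1", "S100A12"], m)
        assert set(out.members) == {"MIR21", "CCR1", "FCGR1A", "FCGR1B",
                                    "FPR1", "S100A12"}

    def test_uncorrelated_candidate_rejected(self):
        sig, m = self._base()
        out = extend_mirna_signature(sig, ["HLA-DQB1"], m)
        assert out.members == sig.members

    def test_idempotent_on_existing_member(self):
        sig, m = self._base()
        out = extend_mirna_signature(sig, ["CCR1"], m)
        assert out.members == sig.members


class TestNetworkCorrelatedComponent:
    def _mi_matrix(self, seed=5):
        groups = {g: (0.9, 0.3) for g in mi_study.NEUTROPHIL_DEGS}
        for g in mi_study.NEUTROPHIL_ISOLATED:
            groups[g] = (0.0, 1.0)
        return factor_matrix(groups, n=12, seed=seed)

    def test_worked_example_ten_gene_signature(self):
        net = InteractionNetwork.from_pairs(mi_study.NEUTROPHIL_EDGES)
        sig = network_correlated_component(list(mi_study.NEUTROPHIL_DEGS), net,
                                           self._mi_matrix(),
                                           name="NeutrophilDegranulation")
        assert sig is not None
        assert len(sig.members) == 10
        assert set(sig.members) == set(mi_study.NEUTROPHIL_DEGS) - set(
            mi_study.NEUTROPHIL_ISOLATED)
        assert sig.provenance["isolated"] == sorted(mi_study.NEUTROPHIL_ISOLATED)

    def test_edgeless_network_yields_nothing(self):
        net = InteractionNetwork.from_pairs([("X", "Y")])
        sig = network_correlated_component(["CD14", "TLR2"], net, self._mi_matrix())
        assert sig is None

    def test_largest_component_tie_broken_lexicographically(self):
        m = factor_matrix({g: (0.9, 0.2) for g in "ABCDXY"}, n=12)
        net = InteractionNetwork.from_pairs([("X", "Y"), ("A", "B")])
        sig = network_correlated_component(["A", "B", "X", "Y"], net, m)
        assert set(sig.members) == {"A", "B"}


class TestAssembleSignatures:
    def _published_inputs(self):
        mir21 = Signature("MIR21", "mirna",
                          ("MIR21", "BCL6", "CCR1", "PDGFD", "SGK1", "TGFBR3",
                           "FCGR1A", "FCGR1B", "FPR1", "S100A12"), anchor="MIR21")
        mir223 = Signature("MIR223", "mirna", ("MIR223", "MAFB"), anchor="MIR223")
        neut = Signature("NeutrophilDegranulation", "pathway_network",
                         ("BST1", "C3AR1", "CD14", "CLEC4D", "CR1", "FPR1",
                          "FPR2", "S100A12", "SLC11A1", "TLR2"))
        immuno = Signature("Immunoregulatory", "pathway_network",
                           ("KIR2DL1", "KIR2DL3", "KLRB1", "KLRC1", "KLRD1",
                            "KLRF1"))
        cytokine = Signature("CytokineSignaling", "pathway_network",
                             ("CCR1", "FCGR1A", "FCGR1B", "FPR1", "S100A12"))
        return ["ADAP2", "KLRB1"], [mir21, mir223], [immuno, neut, cytokine]

    def test_published_layout_five_signatures_29_slots(self):
        individual, mirna, pathway = self._published_inputs()
        out = assemble_signatures(individual, mirna, pathway)
        assert len(out) == 5
        assert out.slot_counts() == (1, 6, 10, 2, 10)
        assert out.n_slots == 29
        assert out.signatures[0].name == "ADAP2"
        klrb1 = out.get("Immunoregulatory")
        assert klrb1.anchor == "KLRB1" and klrb1.members[0] == "KLRB1"
        # the cytokine component is fully inside the extended MIR21 signature
        with pytest.raises(KeyError):
            out.get("CytokineSignaling")

    def test_slot_total_equals_sum_of_sizes(self):
        individual, mirna, pathway = self._published_inputs()
        out = assemble_signatures(individual, mirna, pathway)
        assert out.n_slots == sum(len(s) for s in out)

    def test_without_individuals_or_mirnas_only_pathways_remain(self):
        p = Signature("P", "pathway_network", ("A", "B"))
        out = assemble_signatures([], [], [p])
        assert [s.name for s in out] == ["P"]

    def test_members_outside_universe_rejected(self):
        p = Signature("P", "pathway_network", ("A", "B"))
        with pytest.raises(ValueError, match="universe"):
            assemble_signatures([], [], [p], deg_universe={"A"})


class TestSerialization:
    def test_gmt_and_provenance_roundtrip(self, tmp_path):
        sig = Signature("MIR21", "mirna", ("MIR21", "BCL6"), anchor="MIR21",
                        provenance={"correlations": {"BCL6": {"rho": 0.95, "p": 0.001}}})
        sigs = SignatureSet((sig, Signature("ADAP2", "individual", ("ADAP2",),
                                            anchor="ADAP2")))
        write_signature_set(sigs, tmp_path / "s.gmt", tmp_path / "s.json")
        back = read_signature_set(tmp_path / "s.gmt", tmp_path / "s.json")
        assert [s.name for s in back] == ["MIR21", "ADAP2"]
        assert back.get("MIR21").anchor == "MIR21"
        assert back.get("MIR21").members == ("MIR21", "BCL6")
        assert back.get("MIR21").provenance["correlations"]["BCL6"]["rho"] == 0.95
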