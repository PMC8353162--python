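import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_nm, uniform_composition
from oracles import assign_bruteforce
from sctube.classify import (
    UNASSIGNED,
    BinaryMatrix,
    assign_broad_type,
    assign_subtype,
    binarize_expression,
    classify_pns,
    two_step_classify,
)
from sctube.knowledge import KnowledgeMatrix
from sctube.scoring import normalize_log
from sctube.simulate import SimulationParams, simulate_counts


def binary_from_profiles(km, profiles):
    """BinaryMatrix for cells defined by explicit positive-gene sets."""
    genes = pd.Index(km.marker_genes)
    values = np.zeros((len(genes), len(profiles)), dtype=np.uint8)
    for j, positive in enumerate(profiles):
        for g in positive:
            values[genes.get_loc(g), j] = 1
    cells = pd.Index([f"c{j}" for j in range(len(profiles))])
    return BinaryMatrix(values, genes, cells, pd.Series(0.5, index=genes))


class TestBinarize:
    def test_separated_modes(self):
        nm = make_nm(np.array([[0.0, 0.0, 5.0, 5.0]]), genes=["g0"])
        bm = binarize_expression(nm, ["g0"], min_positive_frac=0.0)
        np.testing.assert_array_equal(bm.values[0], [0, 0, 1, 1])

    def test_all_zero_gene(self):
        nm = make_nm(np.zeros((1, 10)), genes=["g0"])
        bm = binarize_expression(nm, ["g0"])
        assert bm.values.sum() == 0

    def test_rare_positive_gene_zeroed(self):
        values = np.zeros((1, 200))
        values[0, 0] = 5.0
        nm = make_nm(values, genes=["g0"])
        bm = binarize_expression(nm, ["g0"], min_positive_frac=0.01)
        assert bm.values.sum() == 0

    def test_missing_genes_warn(self):
        nm = make_nm(np.ones((1, 4)), genes=["g0"])
        with pytest.warns(UserWarning, match="absent"):
            bm = binarize_expression(nm, ["g0", "ghost"])
        assert "ghost" not in bm.genes
        assert not bm.row("ghost").any()  # treated as all-zero

    def test_empty_marker_list_errors(self):
        nm = make_nm(np.ones((1, 4)))
        with pytest.raises(ValueError, match="empty"):
            binarize_expression(nm, [])

    def test_unknown_method_errors(self):
        nm = make_nm(np.ones((1, 4)))
        with pytest.raises(ValueError, match="method"):
            binarize_expression(nm, ["g0"], method="kmeans17")

    def test_bimodal_nb_mixture_recovers_truth(self, km):
        # mu_off ambient vs mu_on signal: >=98% per-gene agreement
        params = SimulationParams(mu_on=20.0, mu_off=0.1, seed=33)
        comp = uniform_composition(km, n_cells=2000)
        cm, anno = simulate_counts(km, comp, params)
        nm = normalize_log(cm)
        bm = binarize_expression(nm, ["SOX2", "OLIG2", "ELAVL3", "PAX3"])
        from sctube.simulate import _on_genes, default_contaminant_programs

        programs = default_contaminant_programs()
        on_sets = {t: set(_on_genes(km, programs, t)) for t in anno["truth_type"].unique()}
        for gene in ["SOX2", "OLIG2", "ELAVL3", "PAX3"]:
            truth = anno["truth_type"].map(lambda t: gene in on_sets[t]).to_numpy()
            assert (bm.row(gene) == truth).mean() >= 0.98


class TestBroadType:
    def test_argmax(self):
        scores = pd.DataFrame(
            {"neural_progenitor": [0.8, -0.2], "mesoderm": [-0.1, 0.4]}, index=["c1", "c2"]
        )
        labels = assign_broad_type(scores)
        assert labels.tolist() == ["neural_progenitor", "mesoderm"]

    def test_below_min_score_is_other(self):
        scores = pd.DataFrame({"a": [-0.5], "b": [-0.1]}, index=["c1"])
        assert assign_broad_type(scores, min_score=0.0).iloc[0] == "other"

    def test_tie_is_other(self):
        scores = pd.DataFrame({"a": [0.4], "b": [0.4]}, index=["c1"])
        assert assign_broad_type(scores).iloc[0] == "other"

    def test_mixed_tissue_recovery(self, noisy_dataset, km):
        cm, anno = noisy_dataset
        _, log = two_step_classify(cm, km)
        # recovery measured through the full first step
        asg, _ = two_step_classify(cm, km)
        neural_truth = anno["truth_tissue"] == "neural"
        correct = (asg["tissue"] == "neural") == neural_truth
        assert correct.mean() >= 0.95


class TestAssignSubtype:
    def test_pmn_profile(self, km):
        bm = binary_from_profiles(km, [{"SOX2", "OLIG2", "NKX6-1"}])
        out = assign_subtype(bm, km)
        assert out["subtype"].iloc[0] == "pMN"
        assert out["n_mismatches"].iloc[0] == 0
        assert out["score"].iloc[0] == 1.0

    def test_no_match_unassigned(self, km):
        bm = binary_from_profiles(km, [{"SOX2", "LMX1A", "OLIG2", "DBX1"}])
        assert assign_subtype(bm, km)["subtype"].iloc[0] == UNASSIGNED

    def test_tie_unassigned(self, km):
        # equidistant from pMN (lacks OLIG2) and p3 (lacks NKX2-2) at mm=1
        bm = binary_from_profiles(km, [{"SOX2", "NKX6-1"}])
        out = assign_subtype(bm, km, max_mismatch=1)
        assert out["subtype"].iloc[0] == UNASSIGNED

    def test_empty_km_errors(self, km):
        bm = binary_from_profiles(km, [{"SOX2"}])
        empty = km.subset([])
        with pytest.raises(ValueError):
            assign_subtype(bm, empty)

    def test_noise_free_all_types_recovered(self, km):
        profiles = [set(km.required(t)) for t in km.types]
        bm = binary_from_profiles(km, profiles)
        out = assign_subtype(bm, km)
        assert out["subtype"].tolist() == list(km.types)

    def test_monotone_in_max_mismatch(self, km):
        rng = np.random.default_rng(0)
        genes = pd.Index(km.marker_genes)
        values = (rng.random((len(genes), 300)) < 0.2).astype(np.uint8)
        bm = BinaryMatrix(values, genes, [f"c{i}" for i in range(300)], pd.Series(0.5, index=genes))
        counts = []
        for mm in range(4):
            out = assign_subtype(bm, km, max_mismatch=mm)
            counts.append(int((out["subtype"] != UNASSIGNED).sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_row_order_invariance(self, km):
        rng = np.random.default_rng(1)
        genes = pd.Index(km.marker_genes)
        values = (rng.random((len(genes), 200)) < 0.25).astype(np.uint8)
        bm = BinaryMatrix(values, genes, [f"c{i}" for i in range(200)], pd.Series(0.5, index=genes))
        out1 = assign_subtype(bm, km, max_mismatch=2)
        perm = list(rng.permutation(km.types))
        out2 = assign_subtype(bm, km.subset(perm), max_mismatch=2)
        assert (out1["subtype"] == out2["subtype"]).all()

    def test_bruteforce_equivalence(self, km):
        rng = np.random.default_rng(7)
        genes = pd.Index(km.marker_genes[:40])
        values = (rng.random((len(genes), 50)) < 0.3).astype(np.uint8)
        cells = pd.Index([f"c{i}" for i in range(50)])
        bm = BinaryMatrix(values, genes, cells, pd.Series(0.5, index=genes))
        for mm in (0, 1, 2):
            ours = assign_subtype(bm, km, max_mismatch=mm)["subtype"].tolist()
            frame = pd.DataFrame(values, index=genes, columns=cells)
            oracle = assign_bruteforce(frame, km, max_mismatch=mm)
            assert ours == oracle

    def test_deterministic(self, km):
        rng = np.random.default_rng(9)
        genes = pd.Index(km.marker_genes)
        values = (rng.random((len(genes), 100)) < 0.2).astype(np.uint8)
        bm = BinaryMatrix(values, genes, [f"c{i}" for i in range(100)], pd.Series(0.5, index=genes))
        out1 = assign_subtype(bm, km)
        out2 = assign_subtype(bm, km)
        pd.testing.assert_frame_equal(out1, out2)


class TestClassifyPns:
    def test_progenitor_rule(self, km):
        bm = binary_from_profiles(km, [{"SOX10", "SOX2"}, {"SOX10"}])
        out = classify_pns(bm, km)
        assert out["subtype"].tolist() == ["pns_progenitor", "pns_progenitor"]

    def test_precursor_rule(self, km):
        bm = binary_from_profiles(km, [{"NEUROG1"}, {"NEUROD1"}, {"NEUROG2", "SOX10"}])
        out = classify_pns(bm, km)
        assert out["subtype"].tolist() == ["pns_precursor"] * 3

    def test_postmitotic_subtype_refinement(self, km):
        bm = binary_from_profiles(
            km,
            [
                {"ELAVL3", "SIX1", "NTRK3", "RUNX3"},   # proprioceptor
                {"ELAVL3", "SIX1", "NTRK2", "MAF"},     # mechanoreceptor
                {"ELAVL3", "SIX1"},                     # unrefined postmitotic
            ],
        )
        out = classify_pns(bm, km)
        assert out["subtype"].tolist() == ["proprioceptor", "mechanoreceptor", "pns_neuron"]
        assert (out["stage"] == "pns_neuron").all()

    def test_no_pns_rows_errors(self, km):
        cns = km.subset(km.types_of_class("progenitor"))
        bm = binary_from_profiles(km, [{"SOX10"}])
        with pytest.raises(ValueError, match="PNS"):
            classify_pns(bm, cns)


class TestTwoStep:
    def test_noise_free_full_recovery(self, km, noise_free_dataset):
        cm, anno = noise_free_dataset
        asg, log = two_step_classify(cm, km)
        neural = (anno["truth_tissue"] == "neural").to_numpy()
        assert (asg.loc[neural, "subtype"] == anno.loc[neural, "truth_type"]).all()

    def test_default_noise_recovery_bound(self, km, noisy_dataset):
        # regression bound measured once against generator truth
        cm, anno = noisy_dataset
        asg, _ = two_step_classify(cm, km)
        neural = (anno["truth_tissue"] == "neural").to_numpy()
        recovery = (asg.loc[neural, "subtype"] == anno.loc[neural, "truth_type"]).mean()
        assert recovery >= 0.90

    def test_non_neural_cells_get_no_subtype(self, km, noisy_dataset):
        cm, anno = noisy_dataset
        asg, _ = two_step_classify(cm, km)
        non_neural = asg["tissue"] != "neural"
        assert (asg.loc[non_neural, "subtype"] == "").all()

    def test_log_counts_consistent(self, km, noise_free_dataset):
        cm, _ = noise_free_dataset
        _, log = two_step_classify(cm, km)
        assert log["n_cells"] == cm.shape[1]
        assert log["n_neural"] <= log["n_cells"]
        assert log["n_assigned"] <= log["n_neural"]


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(1, 60))
def test_property_bruteforce_equivalence_random_instances(seed, n_cells):
    km = _km_cached()
    rng = np.random.default_rng(seed)
    genes = pd.Index(km.marker_genes)
    values = (rng.random((len(genes), n_cells)) < rng.uniform(0.05, 0.5)).astype(np.uint8)
    cells = pd.Index([f"c{i}" for i in range(n_cells)])
    bm = BinaryMatrix(values, genes, cells, pd.Series(0.5, index=genes))
    ours = assign_subtype(bm, km, max_mismatch=1)["subtype"].tolist()
    frame = pd.DataFrame(values, index=genes, columns=cells)
    assert ours == assign_bruteforce(frame, km, max_mismatch=1)


_KM_CACHE = {}


def _km_cached():
    if "km" not in _KM_CACHE:
        from sctube.knowledge import default_knowledge_matrix

        _KM_CACHE["km"] = default_knowledge_matrix()
    return _KM_CACHE["km"]
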