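import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import uniform_composition
from sctube.knowledge import default_knowledge_matrix
from sctube.simulate import (
    SimulationParams,
    StageComposition,
    concat_datasets,
    default_timecourse_preset,
    expected_profile,
    simulate_bulk_timecourse,
    simulate_counts,
    simulate_ortholog_pair,
    simulate_timecourse,
)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mu_on": 1.0, "mu_off": 2.0},
            {"mu_on": 5.0, "mu_off": -0.1},
            {"dispersion": 0.0},
            {"mito_frac_mean": 1.0},
            {"mito_frac_mean": -0.2},
            {"depth_sigma": -1.0},
            {"n_housekeeping": -1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationParams(**kwargs)

    def test_composition_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            StageComposition("s", {"a": 0.5, "b": 0.4}, 10)
        with pytest.raises(ValueError, match="positive"):
            StageComposition("s", {"a": 1.0}, 0)
        with pytest.raises(ValueError):
            StageComposition("s", {"a": 1.5, "b": -0.5}, 10)


class TestSimulateCounts:
    def test_deterministic_under_seed(self, km):
        comp = uniform_composition(km, n_cells=200)
        params = SimulationParams(seed=5)
        cm1, anno1 = simulate_counts(km, comp, params)
        cm2, anno2 = simulate_counts(km, comp, params)
        assert (cm1.counts != cm2.counts).nnz == 0
        pd.testing.assert_frame_equal(anno1, anno2)

    def test_different_seed_differs(self, km):
        comp = uniform_composition(km, n_cells=200)
        cm1, _ = simulate_counts(km, comp, SimulationParams(seed=5))
        cm2, _ = simulate_counts(km, comp, SimulationParams(seed=6))
        assert (cm1.counts != cm2.counts).nnz > 0

    def test_unknown_type_label_raises(self, km):
        comp = StageComposition("s", {"unobtainium": 1.0}, 10)
        with pytest.raises(KeyError, match="unobtainium"):
            simulate_counts(km, comp, SimulationParams())

    def test_noise_free_cells_express_exactly_required(self, km, noise_free_dataset):
        from sctube.simulate import _on_genes, default_contaminant_programs

        cm, anno = noise_free_dataset
        programs = default_contaminant_programs()
        frame = cm.to_frame()
        signal = [g for g in cm.genes if not g.startswith(("HK", "MT-")) and g != "SRY"]
        rng = np.random.default_rng(0)
        for barcode in rng.choice(cm.cells, 40, replace=False):
            truth = anno.loc[barcode, "truth_type"]
            on = set(_on_genes(km, programs, truth))
            col = frame.loc[signal, barcode]
            assert set(col.index[col > 0]) == on

    def test_nb_mean_within_5pct(self, km):
        # analytic NB mean of a required marker is mu_on * E[depth] = mu_on
        params = SimulationParams(mu_on=10.0, seed=9)
        comp = StageComposition("s", {"pMN": 0.5, "p3": 0.5}, 5000)
        cm, anno = simulate_counts(km, comp, params)
        olig2 = cm.to_frame().loc["OLIG2"]
        pmn_cells = anno.index[anno["truth_type"] == "pMN"]
        emp = olig2[pmn_cells].mean()
        assert abs(emp - 10.0) / 10.0 < 0.05

    def test_nb_variance_within_tolerance(self, km):
        # Var = mu + mu^2/theta, inflated by the depth multiplier:
        # Var_total = E[Var|d] + Var(mu*d) with lognormal mean-1 depth
        params = SimulationParams(mu_on=10.0, dispersion=8.0, depth_sigma=0.3, seed=9)
        comp = StageComposition("s", {"pMN": 1.0}, 5000)
        cm, _ = simulate_counts(km, comp, params)
        olig2 = cm.to_frame().loc["OLIG2"]
        mu, theta, sigma = 10.0, 8.0, 0.3
        vd = math.exp(sigma**2) - 1  # variance of the mean-1 depth
        ed2 = 1 + vd
        expected_var = mu + (mu**2 / theta) * ed2 + mu**2 * vd
        assert abs(olig2.var() - expected_var) / expected_var < 0.1

    def test_truth_proportions_multinomial(self, km):
        props = {"pMN": 0.5, "p3": 0.3, "dp1": 0.2}
        comp = StageComposition("s", props, 5000)
        _, anno = simulate_counts(km, comp, SimulationParams(seed=4))
        observed = anno["truth_type"].value_counts()
        f_obs = [observed.get(t, 0) for t in props]
        f_exp = [p * 5000 for p in props.values()]
        assert stats.chisquare(f_obs, f_exp).pvalue > 0.01

    def test_mito_fraction_targets_mean(self, km):
        from sctube.counts_io import compute_qc

        comp = uniform_composition(km, n_cells=2000)
        cm, _ = simulate_counts(km, comp, SimulationParams(mito_frac_mean=0.05, seed=3))
        qc = compute_qc(cm)
        assert abs(qc["mito_frac"].mean() - 0.05) / 0.05 < 0.2

    def test_sry_only_in_male_samples(self, km):
        male = uniform_composition(km, n_cells=300, sex="male")
        female = uniform_composition(km, n_cells=300, sex="female")
        cm_m, _ = simulate_counts(km, male, SimulationParams(seed=1))
        cm_f, _ = simulate_counts(km, female, SimulationParams(seed=1))
        assert cm_m.gene_vector("SRY").sum() > 0
        assert cm_f.gene_vector("SRY").sum() == 0

    def test_poisson_limit_matches_poisson_stats(self, km):
        params = SimulationParams(mu_on=20.0, dispersion=math.inf, depth_sigma=0.0, seed=2)
        comp = StageComposition("s", {"pMN": 1.0}, 5000)
        cm, _ = simulate_counts(km, comp, params)
        olig2 = cm.to_frame().loc["OLIG2"]
        assert abs(olig2.mean() - 20) / 20 < 0.05
        assert abs(olig2.var() - 20) / 20 < 0.1  # Poisson: var == mean


class TestTimecourse:
    def test_empty_stage_list_raises(self, km):
        with pytest.raises(ValueError, match="empty"):
            simulate_timecourse([], SimulationParams(), km)

    def test_one_dataset_per_stage(self, km):
        stages = default_timecourse_preset(km, n_cells=100)
        out = simulate_timecourse(stages, SimulationParams(seed=0), km)
        assert len(out) == 4
        assert [a["stage"].iloc[0] for _, a in out] == ["CS12", "CS14", "CS17", "CS19"]

    def test_preset_neuron_share_strictly_increases(self, km):
        neurons = set(km.types_of_class("neuron"))
        stages = default_timecourse_preset(km)
        shares = [
            sum(v for t, v in comp.type_proportions.items() if t in neurons)
            for comp in stages
        ]
        assert all(b > a for a, b in zip(shares, shares[1:]))

    def test_repeated_composition_gives_identical_expectations(self, km):
        comp = uniform_composition(km, n_cells=100)
        stages = [comp, comp, comp]
        out = simulate_timecourse(stages, SimulationParams(seed=1), km)
        assert len(out) == 3
        # expectations identical by construction; realisations differ by sub-seed
        assert (out[0][0].counts != out[1][0].counts).nnz > 0

    def test_recovered_composition_within_multinomial_error(self, km):
        stages = default_timecourse_preset(km, n_cells=5000)
        out = simulate_timecourse(stages, SimulationParams(seed=12), km)
        for comp, (_, anno) in zip(stages, out):
            observed = anno["truth_type"].value_counts()
            types = list(comp.type_proportions)
            f_obs = np.array([observed.get(t, 0) for t in types], dtype=float)
            f_exp = np.array([comp.type_proportions[t] * comp.n_cells for t in types])
            f_exp *= f_obs.sum() / f_exp.sum()
            assert stats.chisquare(f_obs, f_exp).pvalue > 0.01

    def test_concat_requires_shared_genes(self, km):
        stages = default_timecourse_preset(km, n_cells=50)
        out = simulate_timecourse(stages, SimulationParams(seed=0), km)
        cm, anno = concat_datasets(out)
        assert cm.shape[1] == sum(o[0].shape[1] for o in out)
        assert len(anno) == cm.shape[1]


class TestOrthologPair:
    def test_noise_zero_all_one_to_one(self, km):
        comp = uniform_composition(km, n_cells=50)
        pair = simulate_ortholog_pair(km, comp, comp, 0.0, SimulationParams(seed=3))
        assert len(pair.pairs) == len(pair.true_one_to_one)
        assert pair.pairs["gene_a"].is_unique and pair.pairs["gene_b"].is_unique

    def test_noise_fraction_bookkeeping(self, km):
        from sctube.compare import map_orthologs

        comp = uniform_composition(km, n_cells=50)
        pair = simulate_ortholog_pair(km, comp, comp, 0.2, SimulationParams(seed=3))
        retained = map_orthologs(pair.pairs)
        truth = set(map(tuple, pair.true_one_to_one.to_numpy()))
        assert set(map(tuple, retained.to_numpy())) == truth

    def test_disjoint_namespaces(self, km):
        comp = uniform_composition(km, n_cells=50)
        pair = simulate_ortholog_pair(km, comp, comp, 0.0, SimulationParams(seed=3))
        assert not set(pair.counts_a.genes) & set(pair.counts_b.genes)

    def test_invalid_noise_rejected(self, km):
        comp = uniform_composition(km, n_cells=10)
        with pytest.raises(ValueError, match="ortholog_noise"):
            simulate_ortholog_pair(km, comp, comp, 1.5, SimulationParams())

    def test_same_type_profiles_correlate_highest(self, km):
        # qualitative cross-species claim, on a small synthetic pair
        from sctube.compare import cross_correlate, map_orthologs, mean_profiles
        from sctube.scoring import normalize_log

        types = ["pMN", "p3", "dp1", "MN", "dI1"]
        props = {t: 0.2 for t in types}
        comp = StageComposition("s", props, 1000)
        pair = simulate_ortholog_pair(
            km, comp, comp, 0.0, SimulationParams(seed=8, n_type_markers=4)
        )
        omap = map_orthologs(pair.pairs)
        prof_a, _ = mean_profiles(normalize_log(pair.counts_a), pair.anno_a["truth_type"])
        prof_b, _ = mean_profiles(normalize_log(pair.counts_b), pair.anno_b["truth_type"])
        tf_a = [g for g in prof_a.columns if g.startswith("TF-") or g in km.marker_genes]
        corr = cross_correlate(prof_a[tf_a], prof_b, omap)
        assert (corr.idxmax(axis=1) == corr.index).all()


class TestBulkTimecourse:
    def test_day0_equals_pure_progenitor_pseudobulk(self, km):
        params = SimulationParams(seed=0)
        bulk = simulate_bulk_timecourse(km, None, 5, params)
        prog = pd.concat(
            [expected_profile(km, t, params) for t in ["p0", "p1", "p2", "pMN", "p3"]],
            axis=1,
        ).mean(axis=1)
        pd.testing.assert_series_equal(bulk["day_0"], prog, check_names=False)

    def test_reproducible(self, km):
        params = SimulationParams(seed=7)
        pd.testing.assert_frame_equal(
            simulate_bulk_timecourse(km, None, 6, params),
            simulate_bulk_timecourse(km, None, 6, params),
        )

    def test_requires_two_days(self, km):
        with pytest.raises(ValueError):
            simulate_bulk_timecourse(km, None, 1, SimulationParams())

    def test_staging_alignment_by_construction(self, km):
        # the designed alignment: later in vivo stages match later days
        from sctube.compare import staging_correlation
        from sctube.scoring import normalize_log
        from sctube.simulate import varying_genes

        stages = default_timecourse_preset(km, n_cells=800)
        out = simulate_timecourse(stages, SimulationParams(seed=5), km)
        cm, truth = concat_datasets(out)
        nm = normalize_log(cm)
        ventral = ["p0", "p1", "p2", "pMN", "p3", "V0", "V1", "V2", "MN", "V3"]
        mask = truth["truth_type"].isin(ventral).to_numpy()
        nm_v = nm.subset_cells(cm.cells[mask])
        stage_of = truth.loc[mask, "stage"]
        pseudo = {
            s: nm_v.subset_cells(nm_v.cells[(stage_of == s).to_numpy()]).values.mean(axis=1)
            for s in stage_of.unique()
        }
        pseudobulk = pd.DataFrame(pseudo, index=nm_v.genes)
        bulk = simulate_bulk_timecourse(km, None, 8, SimulationParams(seed=5))
        genes = [g for g in varying_genes(km) if g in bulk.index]
        corr = staging_correlation(pseudobulk, bulk, genes)
        best_day = corr.idxmax(axis=1).str.replace("day_", "").astype(int)
        assert best_day.is_monotonic_increasing
        assert best_day.iloc[0] < best_day.iloc[-1]
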