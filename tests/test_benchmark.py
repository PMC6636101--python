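"""Gene-network benchmark: structure, sampling, datasets, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foldreg import benchmark as bm
from foldreg.ode_core import Condition, simulate


class TestNetworkStructure:
    def test_kinetic_parameter_census(self):
        config = bm.default_config()
        census = bm.parameter_census(config)
        assert census == {"ribosomal": 6, "synthesis": 6, "degradation": 1,
                          "km": 8, "hill": 8}
        assert sum(census.values()) == 29
        model = bm.build_network_model(config)
        assert model.n_params == 29
        assert model.n_states == 12  # 6 mRNA + 6 protein

    def test_three_gene_reduction_census(self):
        config = bm.three_gene_config()
        assert sum(bm.parameter_census(config).values()) == 15
        assert bm.build_network_model(config).n_states == 6

    def test_wrong_edge_count_rejected(self):
        config = bm.default_config()
        broken = bm.GeneNetworkConfig(genes=config.genes,
                                      edges=config.edges[:7], required_edges=8)
        with pytest.raises(ValueError, match="edges"):
            bm.build_network_model(broken)

    def test_single_gene_network_matches_hand_written_rates(self):
        """One self-repressing gene against a hand-coded Hill right-hand side."""
        config = bm.GeneNetworkConfig(genes=("g1",), edges=(("g1", "g1", "-"),))
        model = bm.build_network_model(config)
        cm = model.compiled()
        rng = np.random.default_rng(8)
        p = {n: rng.uniform(0.2, 3.0) for n in model.param_names}
        pv = np.array([p[n] for n in model.param_names])
        u = np.ones(3)
        for _ in range(10):
            m, P = rng.uniform(0.01, 5.0, 2)
            dm = p["syn_g1"] / (1 + (P / p["km_g1_g1"]) ** p["h_g1_g1"]) \
                - p["deg_mrna"] * m
            dP = p["rbs_g1"] * m - P
            out = cm._f(np.array([m, P]), pv, u)
            assert np.allclose(out, [dm, dP], rtol=1e-12)

    def test_all_synthesis_off_keeps_states_at_zero(self):
        model = bm.build_network_model(bm.three_gene_config())
        cond = Condition(inputs={f"ktr_{g}": 0.0 for g in ("g1", "g2", "g3")})
        traj = simulate(model, np.zeros(model.n_params), cond,
                        np.linspace(0, 5, 6))
        assert np.allclose(traj.x, 0.0, atol=1e-12)


class TestPerturbationCatalogue:
    def test_has_exactly_18_setups(self):
        cat = bm.perturbation_catalogue(bm.default_config())
        assert len(cat) == 18
        assert len(set(cat)) == 18
        kinds = {p.kind for p in cat}
        assert kinds == {"knockout", "degradation_x5", "synthesis_x2"}


class TestGroundTruthSampling:
    def test_specific_subset_is_one_third(self):
        config = bm.default_config()
        truth = bm.sample_ground_truth(config, seed=1)
        assert len(truth.specific) == 10  # round(29 / 3)

    def test_hill_folds_respect_range(self):
        config = bm.default_config()
        for seed in range(30):
            truth = bm.sample_ground_truth(config, seed=seed)
            for name in bm.hill_param_names(config):
                val = 10 ** (truth.ref_log10[name] + truth.r_log10[name])
                assert 1.0 - 1e-9 <= val <= 4.0 + 1e-9

    def test_hill_fold_admissibility_filter(self):
        assert bm.admissible_hill_folds(4.0) == [0.25, 0.5]
        assert bm.admissible_hill_folds(1.0) == [2.0, 4.0]
        assert 2.0 not in bm.admissible_hill_folds(3.0)

    def test_seed_determinism(self):
        config = bm.default_config()
        t1 = bm.sample_ground_truth(config, seed=42)
        t2 = bm.sample_ground_truth(config, seed=42)
        assert t1.specific == t2.specific
        assert t1.r_log10 == t2.r_log10

    def test_nonhill_fold_frequencies_uniform(self):
        """Over many draws every fold value from the stated six-element set
        appears, with empirical frequencies uniform within binomial 3 sigma."""
        config = bm.default_config()
        rng = np.random.default_rng(123)
        counts = {}
        total = 0
        hill = set(bm.hill_param_names(config))
        for _ in range(1000):
            truth = bm.sample_ground_truth(config, rng=rng)
            for name in truth.specific:
                if name not in hill:
                    fold = round(10 ** truth.r_log10[name], 6)
                    counts[fold] = counts.get(fold, 0) + 1
                    total += 1
        assert set(counts) == {0.1, 0.2, 0.5, 2.0, 5.0, 10.0}
        p = 1.0 / 6.0
        sigma = np.sqrt(total * p * (1 - p))
        for fold, n in counts.items():
            assert abs(n - total * p) < 3 * sigma, fold


class TestDesignSampling:
    def test_observation_modes_and_point_counts(self):
        config = bm.default_config()
        seen = set()
        for seed in range(40):
            design = bm.sample_design(config, seed=seed)
            seen.add(design.mode)
            if design.mode == "mrna":
                assert len(design.observables) == 6
                assert design.n_points == 21  # 6 x 21 = 126 points/condition
            else:
                assert len(design.observables) == 2
                assert design.n_points == 41  # 2 x 41 = 82 points/condition
        assert seen == {"mrna", "protein"}

    def test_base_condition_always_present(self):
        for seed in range(10):
            design = bm.sample_design(bm.three_gene_config(), seed=seed)
            assert "base" in design.conditions


@pytest.fixture(scope="module")
def run_noise_free():
    return bm.generate_run(bm.three_gene_config(), seed=5,
                           noise=bm.NoiseConfig(scale=0.0))


class TestSimulatedDatasets:
    def test_zero_noise_measurements_equal_simulation(self, run_noise_free):
        run = run_noise_free
        names = run.model.param_names
        ref = np.array([run.truth.ref_log10[n] for n in names])
        r = run.truth.r_vector(names)
        times = np.sort(run.measurements.df["time"].unique())
        obs_idx = [run.model.state_names.index(o) for o in run.design.observables]
        for (cid, ct), sub in run.measurements.df.groupby(["conditionId", "cellType"]):
            logp = ref + (r if ct == 1 else 0.0)
            traj = simulate(run.model, logp, run.design.conditions[cid], times)
            for _, row in sub.iterrows():
                ti = np.searchsorted(times, row.time)
                oi = obs_idx[run.design.observables.index(row.observableId)]
                assert row.measurement == pytest.approx(traj.x[ti, oi],
                                                        rel=1e-6, abs=1e-9)

    def test_identical_cell_types_without_fold_changes(self):
        run = bm.generate_run(bm.three_gene_config(), seed=6,
                              noise=bm.NoiseConfig(scale=0.0), forced_truth={})
        df = run.measurements.df
        piv = df.pivot_table(index=["observableId", "conditionId", "time"],
                             columns="cellType", values="measurement")
        assert np.allclose(piv[0], piv[1], rtol=1e-9)

    def test_residual_z_scores_are_standard_normal(self):
        """(measurement - signal) / sd over >= 1000 points passes a KS test."""
        run = bm.generate_run(bm.three_gene_config(), seed=9)
        clean = bm.generate_run(bm.three_gene_config(), seed=9,
                                noise=bm.NoiseConfig(scale=0.0))
        z = ((run.measurements.df["measurement"].to_numpy()
              - clean.measurements.df["measurement"].to_numpy())
             / run.measurements.df["sd"].to_numpy())
        assert z.size >= 500
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_reproducible_from_seed(self):
        a = bm.generate_run(bm.three_gene_config(), seed=11)
        b = bm.generate_run(bm.three_gene_config(), seed=11)
        pd.testing.assert_frame_equal(a.measurements.df, b.measurements.df)
        assert a.truth.specific == b.truth.specific


class TestClassification:
    names = [f"p{i}" for i in range(29)]

    def _truth(self, n_pos):
        spec = tuple(self.names[:n_pos])
        r = {n: (1.0 if n in spec else 0.0) for n in self.names}
        return bm.GroundTruth(ref_log10={n: 0.0 for n in self.names},
                              specific=spec, r_log10=r)

    def test_perfect_prediction(self):
        truth = self._truth(10)
        m = bm.classify(set(truth.specific), truth, self.names)
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_specificity_19_of_22(self):
        truth = self._truth(7)  # 22 negatives
        pred = set(truth.specific) | set(self.names[7:10])  # 3 false positives
        m = bm.classify(pred, truth, self.names)
        assert m.specificity == pytest.approx(19 / 22)
        assert m.specificity == pytest.approx(0.864, abs=5e-4)

    def test_all_negative_predictor(self):
        truth = self._truth(10)
        m = bm.classify(set(), truth, self.names)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.accuracy == pytest.approx(19 / 29)

    def test_counts_sum_to_universe(self):
        truth = self._truth(10)
        m = bm.classify(set(self.names[5:12]), truth, self.names)
        assert m.total == 29


class TestStudySummary:
    def _metrics(self):
        rows = []
        sens = {"l1": [0.6, 0.8, 0.7], "lq": [0.6, 0.7, 0.8]}
        spec = {"l1": [0.5, 0.6, 0.7], "lq": [0.8, 0.9, 0.7]}
        for run in range(3):
            for meth in ("l1", "lq"):
                rows.append({"run": run, "method": meth,
                             "sensitivity": sens[meth][run],
                             "specificity": spec[meth][run],
                             "accuracy": 0.5 * (sens[meth][run] + spec[meth][run])})
        return pd.DataFrame(rows)

    def test_paired_deltas_match_hand_computation(self):
        summary, per_method, level = bm.summarize_study(
            self._metrics(), pairs=(("l1", "lq"),), n_comparisons=12)
        row = summary.iloc[0]
        d_spec = np.array([0.3, 0.3, 0.0])
        assert row["delta_specificity"] == pytest.approx(d_spec.mean())
        t_expect = stats.ttest_rel([0.8, 0.9, 0.7], [0.5, 0.6, 0.7]).pvalue
        assert row["p_specificity"] == pytest.approx(t_expect)

    def test_bonferroni_level_is_5_percent_over_12(self):
        _, _, level = bm.summarize_study(self._metrics(),
                                         pairs=(("l1", "lq"),), n_comparisons=12)
        assert level == pytest.approx(0.05 / 12)
        assert level == pytest.approx(0.0042, abs=2e-4)

    def test_method_compared_to_itself_is_null(self):
        summary, _, _ = bm.summarize_study(self._metrics(),
                                           pairs=(("l1", "l1"),))
        row = summary.iloc[0]
        assert row["delta_specificity"] == 0.0
        assert not row["sig_specificity"]


class TestDeformationScan:
    def test_zero_deformation_reproduces_l1(self):
        from conftest import QuadraticProblem
        A = np.array([[4.0, 1.5], [1.5, 2.0]])
        mu = np.array([0.9, 0.05])
        prob = QuadraticProblem(A, mu, n_ref=0, c=1.0)
        grid = np.logspace(-2, 1.5, 9)
        df = bm.deformation_scan(prob, "lq", d_grid=[0.0, 0.3], lam_grid=grid,
                                 seed=0, names=["r0", "r1"])
        from foldreg.penalties import PenaltySpec
        from foldreg.regpath import scan_lambda
        l1_path = scan_lambda(prob, PenaltySpec("l1"), lam_grid=grid, seed=0,
                              n_starts=2)
        row0 = df[df["deformation"] == 0.0].iloc[0]
        l1_nonzero = tuple(f"r{i}" for i in range(2) if i not in l1_path.final_zero)
        assert row0["nonzero"] == l1_nonzero
        assert row0["lambda_star"] == pytest.approx(l1_path.lam_star)
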