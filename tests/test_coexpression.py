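"""Co-expression stage: adjacency, TOM, modules, eigengenes, trait table."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import _oracles
from epitopescan import (
    IntensityMatrix,
    SimulationConfig,
    adjacency_matrix,
    detect_modules,
    filter_case_elevated,
    fit_coexpression,
    module_eigengene,
    module_trait_correlation,
    pick_soft_threshold,
    simulate_array,
    simulate_trait_coupled_modules,
    tom_similarity,
)


class TestCaseElevatedFilter:
    def _matrix(self, values, md):
        return IntensityMatrix(
            values, [f"p{i}" for i in range(values.shape[0])], md.sample_ids
        )

    def test_null_retains_about_half(self, small_library):
        lib, _ = small_library
        retained = []
        for seed in range(10):
            mat, md, _ = simulate_array(lib, SimulationConfig(seed=seed, n_epitopes=0))
            retained.append(filter_case_elevated(mat, md).mean())
        # ties are measure-zero: P(case median > control median) = 1/2
        assert 0.4 < np.mean(retained) < 0.6

    def test_all_elevated_retains_all(self, small_library):
        lib, _ = small_library
        mat, md, _ = simulate_array(lib, SimulationConfig(seed=3, n_epitopes=0))
        v = mat.values.copy()
        cases = [mat.sample_ids.index(s) for s in md.case_ids]
        v[:, cases] *= 10
        mat = IntensityMatrix(v, mat.peptide_ids, mat.sample_ids)
        assert filter_case_elevated(mat, md).all()

    def test_mean_and_median_disagree_on_skew(self, small_library):
        lib, _ = small_library
        mat, md, _ = simulate_array(lib, SimulationConfig(seed=4, n_epitopes=0))
        v = mat.values.copy()
        cases = [mat.sample_ids.index(s) for s in md.case_ids]
        ctrls = [mat.sample_ids.index(s) for s in md.control_ids]
        # peptide 0: all case values slightly below controls, one huge outlier
        v[0, :] = 100.0
        v[0, cases] = 90.0
        v[0, cases[0]] = 1e7
        mat = IntensityMatrix(v, mat.peptide_ids, mat.sample_ids)
        assert filter_case_elevated(mat, md, stat="mean")[0]
        assert not filter_case_elevated(mat, md, stat="median")[0]


class TestAdjacencyAndTom:
    def test_adjacency_closed_forms(self):
        t = np.linspace(0, 1, 20)
        x = np.vstack([t, 2 * t + 1])  # perfectly correlated pair
        a = adjacency_matrix(x, beta=7)
        assert a[0, 1] == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        y = rng.standard_normal((6, 40))
        a = adjacency_matrix(y, beta=6)
        c = np.corrcoef(y)
        assert a[1, 2] == pytest.approx(abs(c[1, 2]) ** 6)
        assert np.allclose(a, a.T, atol=1e-12)
        # 0.5^6 closed form on a constructed correlation
        assert 0.5**6 == pytest.approx(0.015625)

    def test_zero_variance_rejected(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency_matrix(x, beta=6)

    def test_tom_clique_and_hand_example(self):
        assert np.allclose(tom_similarity(np.ones((3, 3))), 1.0)
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 1.0
        tom = tom_similarity(a)
        assert tom[0, 1] == pytest.approx(1.0)
        assert tom[0, 2] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_tom_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        c = rng.uniform(0, 1, size=(n, n))
        a = (c + c.T) / 2
        np.fill_diagonal(a, 1.0)
        np.testing.assert_allclose(tom_similarity(a), _oracles.tom_oracle(a), atol=1e-12)

    def test_tom_range_and_symmetry(self):
        rng = np.random.default_rng(99)
        a = rng.uniform(0, 1, size=(40, 40))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert tom.min() >= 0 and tom.max() <= 1
        assert np.allclose(tom, tom.T, atol=1e-12)


class TestSoftThreshold:
    def test_modular_data_reaches_target(self):
        m, _, _ = simulate_trait_coupled_modules(SimulationConfig(seed=0))
        beta, table = pick_soft_threshold(np.log(m.values))
        assert table.loc[table.power == beta, "fit_r2"].iloc[0] >= 0.9
        # recovery holds across the conventional moderate powers
        m2, _, truth = simulate_trait_coupled_modules(SimulationConfig(seed=1, n_modules=2))
        for b in (6, 8):
            labels = detect_modules(tom_similarity(adjacency_matrix(np.log(m2.values), b)))
            assert adjusted_rand_score(truth.labels, labels) >= 0.85

    def test_pure_noise_warning_path(self, caplog):
        x = np.random.default_rng(3).standard_normal((60, 10))
        with caplog.at_level("WARNING"):
            beta, table = pick_soft_threshold(x)
        assert (table["fit_r2"] < 0.9).all()
        assert any("no power reaches" in r.message for r in caplog.records)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="3 samples"):
            pick_soft_threshold(np.random.default_rng(0).standard_normal((10, 2)))
        with pytest.raises(ValueError, match="too few"):
            pick_soft_threshold(np.random.default_rng(0).standard_normal((2, 10)))


class TestModuleDetection:
    def _block_tom(self, sizes, within=0.6, between=0.01, seed=0):
        n = sum(sizes)
        rng = np.random.default_rng(seed)
        tom = np.full((n, n), between) + rng.uniform(0, 0.005, size=(n, n))
        tom = (tom + tom.T) / 2
        pos = 0
        for s in sizes:
            tom[pos : pos + s, pos : pos + s] = within + rng.uniform(0, 0.01)
            pos += s
        np.fill_diagonal(tom, 1.0)
        return np.clip(tom, 0, 1)

    def test_two_planted_modules_recovered(self):
        for seed in range(10):
            m, _, truth = simulate_trait_coupled_modules(
                SimulationConfig(seed=seed, n_modules=2)
            )
            model, _ = fit_coexpression(m, beta=6, prefilter_stat=None)
            assert adjusted_rand_score(truth.labels, model.labels) >= 0.9
            assert model.labels.max() == 2

    def test_pure_noise_yields_no_modules(self):
        found = 0
        for seed in range(30):
            x = np.random.default_rng(2000 + seed).standard_normal((50, 50))
            labels = detect_modules(tom_similarity(adjacency_matrix(x, 6)), min_size=30)
            found += labels.max() > 0
        assert found <= 3  # >= 90% of seeds produce no module

    def test_min_size_boundary(self):
        # a coherent cluster of 29 stays unassigned; 30 becomes a module
        labels29 = detect_modules(self._block_tom([29, 25]), min_size=30)
        assert labels29.max() == 0
        labels30 = detect_modules(self._block_tom([30, 25]), min_size=30)
        assert (labels30[:30] == 1).all() and (labels30[30:] == 0).all()

    def test_fewer_peptides_than_min_size(self, caplog):
        with caplog.at_level("WARNING"):
            labels = detect_modules(np.eye(5), min_size=30)
        assert (labels == 0).all()


class TestEigengenes:
    def test_identical_peptides_give_their_profile(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        x = np.tile(profile, (6, 1))
        me = module_eigengene(x, np.ones(6, dtype=int))["ME1"].to_numpy()
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(me / np.linalg.norm(me), z / np.linalg.norm(z), atol=1e-9)

    def test_pca_optimality_against_random_projections(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((20, 30)) + rng.standard_normal(30) * 2
        me = module_eigengene(x, np.ones(20, dtype=int))["ME1"].to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        var_me = np.var(z.T @ (z @ me) / np.linalg.norm(z @ me))
        explained = np.linalg.norm(z @ me) ** 2
        for _ in range(100):
            w = rng.standard_normal(x.shape[1])
            w /= np.linalg.norm(w)
            assert np.linalg.norm(z @ w) ** 2 <= explained + 1e-9

    def test_orientation_rule_is_sign_invariant(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(1, 0.3, size=(10, 15))
        me1 = module_eigengene(x, np.ones(10, dtype=int))["ME1"]
        me2 = module_eigengene(-x, np.ones(10, dtype=int))["ME1"]
        np.testing.assert_allclose(me1, -me2, atol=1e-9)
        # and the eigengene correlates positively with the mean profile
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        assert np.corrcoef(me1, z.mean(0))[0, 1] > 0

    def test_single_peptide_module(self):
        x = np.vstack([np.arange(8.0), np.ones(8)])
        me = module_eigengene(x, np.array([1, 0]))["ME1"].to_numpy()
        z = (np.arange(8.0) - 3.5) / np.arange(8.0).std()
        np.testing.assert_allclose(me / np.linalg.norm(me), z / np.linalg.norm(z), atol=1e-9)


class TestModuleTraitTable:
    def test_coupled_module_tops_table(self):
        hits = 0
        for seed in range(25):
            m, traits, truth = simulate_trait_coupled_modules(SimulationConfig(seed=seed))
            model, table = fit_coexpression(m, traits=traits, beta=6, prefilter_stat=None)
            if table is None or table["rho"].isna().all():
                continue
            best = table.loc[table["rho"].abs().idxmax()]
            mod = int(best["module"][2:])
            coupled = np.mean(truth.labels[model.labels == mod] == 1) > 0.5
            hits += coupled and best["p_adj"] < 0.05
        assert hits >= 24

    def test_permuted_traits_rarely_significant(self):
        sig = 0
        for seed in range(20):
            m, traits, truth = simulate_trait_coupled_modules(SimulationConfig(seed=seed))
            rng = np.random.default_rng(seed)
            traits = traits.assign(
                proteinuria_T12=rng.permutation(traits["proteinuria_T12"].to_numpy())
            )
            model, table = fit_coexpression(m, traits=traits, beta=6, prefilter_stat=None)
            if table is not None and (table["p_adj"].dropna() < 0.05).any():
                sig += 1
        assert sig <= 2  # >= 95% of seeds show nothing after BH

    def test_trait_equal_to_eigengene_and_degenerate_traits(self):
        m, _, truth = simulate_trait_coupled_modules(SimulationConfig(seed=2))
        mes = module_eigengene(np.log(m.values), truth.labels)
        traits = pd.DataFrame(
            {
                "self": mes["ME1"],
                "constant": np.ones(len(mes)),
                "sparse": [np.nan] * (len(mes) - 2) + [1.0, 2.0],
            }
        )
        table = module_trait_correlation(mes, traits)
        row = table[(table.module == "ME1") & (table.trait == "self")].iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert (table.loc[table.trait == "constant", "note"] == "constant trait").all()
        assert (table.loc[table.trait == "sparse", "note"] == "fewer than 3 pairs").all()
        ok = table.dropna(subset=["p"])
        assert (ok["p_adj"] >= ok["p"] - 1e-15).all()

    def test_bh_monotone_in_rank(self):
        m, traits, _ = simulate_trait_coupled_modules(SimulationConfig(seed=6))
        _, table = fit_coexpression(m, traits=traits, beta=6, prefilter_stat=None)
        t = table.dropna(subset=["p"]).sort_values("p")
        assert (np.diff(t["p_adj"]) >= -1e-15).all()
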