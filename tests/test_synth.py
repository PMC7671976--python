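import numpy as np
import pandas as pd
import pytest

import deraml as d
from deraml.kernels import KernelBank, KernelDefinition
from deraml.variants import Variant, WILD_TYPE

from conftest import random_variant_set


class TestStudyDesignConfig:
    def test_default_shape_matches_study(self):
        cfg = d.StudyDesignConfig()
        assert cfg.n_positions == 24
        assert cfg.singles_total == 69
        assert cfg.n_combos == 62
        assert sum(cfg.per_position_multiplicities) == 69
        assert len(cfg.per_position_multiplicities) == 24
        assert sorted(set(cfg.per_position_multiplicities)) == [2, 3]

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            d.StudyDesignConfig(per_position_multiplicities=(1,) * 24)
        with pytest.raises(ValueError, match="1..19"):
            d.StudyDesignConfig(n_positions=2, singles_total=40,
                                per_position_multiplicities=(20, 20))
        with pytest.raises(ValueError, match="noise_sd"):
            d.StudyDesignConfig(noise_sd=-0.1)
        with pytest.raises(ValueError, match="replicates"):
            d.StudyDesignConfig(n_replicates=0)


class TestMutationLibrary:
    def test_counts_and_validity(self):
        graph = d.generate_toy_structure(100, seed=6)
        cfg = d.StudyDesignConfig(seed=6)
        library = d.generate_mutation_library(cfg, graph)
        assert len(library) == 69
        assert len({m.position for m in library}) == 24
        assert len(set(library)) == 69
        for m in library:
            assert graph.amino_acid_at(m.position) == m.wt
            assert m.mut != m.wt

    def test_deterministic(self):
        graph = d.generate_toy_structure(80, seed=7)
        cfg = d.StudyDesignConfig(seed=7)
        a = d.generate_mutation_library(cfg, graph)
        b = d.generate_mutation_library(cfg, graph)
        assert a == b

    def test_too_many_positions_rejected(self):
        graph = d.generate_toy_structure(10, seed=0)
        with pytest.raises(ValueError, match="positions"):
            d.generate_mutation_library(d.StudyDesignConfig(), graph)


class TestCombinationVariants:
    def test_sizes_positions_and_membership(self):
        graph = d.generate_toy_structure(100, seed=8)
        library = d.generate_mutation_library(d.StudyDesignConfig(seed=8), graph)
        combos = d.generate_combination_variants(library, 62, seed=9)
        assert len(combos) == 62
        assert len({str(v) for v in combos}) == 62
        lib_set = set(library)
        for v in combos:
            assert len(v) in (2, 3)
            assert len({m.position for m in v}) == len(v)
            assert all(m in lib_set for m in v)
        sizes = np.array([len(v) for v in combos])
        assert (sizes == 2).sum() > (sizes == 3).sum()  # ~70/30 mix

    def test_impossible_request_rejected(self):
        graph = d.generate_toy_structure(30, seed=0)
        cfg = d.StudyDesignConfig(n_positions=2, singles_total=2, n_combos=0, seed=0)
        library = d.generate_mutation_library(cfg, graph)
        with pytest.raises(ValueError, match="distinct combinations"):
            d.generate_combination_variants(library, 100, seed=0)


@pytest.fixture(scope="module")
def oracle(small_bank):
    rng = np.random.default_rng(30)
    weights = {s: rng.dirichlet(np.ones(len(small_bank))) for s in ("DRP", "ACET")}
    return d.SpecificityOracle(small_bank, weights, seed=30)


class TestSpecificityOracle:
    def test_wild_type_maps_to_one(self, oracle):
        vals = oracle.values([WILD_TYPE])
        for s in oracle.substrates:
            assert vals[s][0] == 1.0

    def test_values_nonnegative_and_consistent_across_queries(self, oracle, small_graph):
        rng = np.random.default_rng(31)
        vs = random_variant_set(small_graph, 20, rng, include_wt=True)
        first = oracle.values(vs)
        # re-query in a different order, interleaved with new variants
        probe = random_variant_set(small_graph, 30, rng, include_wt=True)
        oracle.values(probe)
        second = oracle.values(list(reversed(vs)))
        for s in oracle.substrates:
            assert np.all(first[s] >= 0.0)
            np.testing.assert_array_equal(second[s], first[s][::-1])

    def test_same_seed_same_landscape(self, small_graph, small_bank):
        w = {"DRP": np.full(len(small_bank), 1.0 / len(small_bank))}
        rng = np.random.default_rng(32)
        vs = random_variant_set(small_graph, 10, rng)
        a = d.SpecificityOracle(small_bank, w, seed=5).values(vs)["DRP"]
        b = d.SpecificityOracle(small_bank, w, seed=5).values(vs)["DRP"]
        np.testing.assert_array_equal(a, b)
        c = d.SpecificityOracle(small_bank, w, seed=6).values(vs)["DRP"]
        assert not np.array_equal(a, c)

    def test_off_simplex_weights_rejected(self, small_bank):
        with pytest.raises(ValueError, match="simplex"):
            d.SpecificityOracle(small_bank, {"DRP": [0.5] * len(small_bank)}, seed=0)

    def test_zero_signal_is_flat_landscape(self, small_graph, small_bank):
        w = {"DRP": np.eye(len(small_bank))[0]}
        oracle = d.SpecificityOracle(small_bank, w, seed=0, signal_sd=0.0)
        rng = np.random.default_rng(33)
        vs = random_variant_set(small_graph, 5, rng, include_wt=True)
        np.testing.assert_array_equal(oracle.values(vs)["DRP"], 1.0)


class TestAdditiveLandscape:
    def test_effects_add_and_clip(self):
        land = d.AdditiveSpecificityLandscape(
            {"DRP": {"A5V": -0.8, "G9S": -0.4}, "ACET": {"A5V": 0.3, "G9S": 0.2}})
        vs = [WILD_TYPE, Variant.parse("A5V"), Variant.parse("A5V/G9S")]
        vals = land.values(vs)
        np.testing.assert_allclose(vals["DRP"], [1.0, 0.2, 0.0])  # 1-1.2 clips to 0
        np.testing.assert_allclose(vals["ACET"], [1.0, 1.3, 1.5])

    def test_planted_screening_landscape(self):
        graph = d.generate_toy_structure(100, seed=9)
        library = d.generate_mutation_library(d.StudyDesignConfig(seed=9), graph)
        land, planted = d.plant_screening_landscape(library, seed=9)
        assert len(planted) == 10  # C(5, 3) designated triples
        vals = land.values(planted)
        # each triple gains 3 x 0.5 on ACET and loses all DRP activity
        np.testing.assert_allclose(vals["ACET"], 2.5)
        np.testing.assert_allclose(vals["DRP"], 0.0)
        np.testing.assert_allclose(vals["DR"], 0.0, atol=1e-12)
        singles = [Variant([m]) for m in library]
        background = land.values(singles)
        assert np.mean(background["DRP"]) < 1.0  # mildly deleterious on average


class TestSimulateMeasurements:
    def test_noiseless_records_equal_oracle(self, small_graph, small_bank):
        rng = np.random.default_rng(34)
        vs = random_variant_set(small_graph, 12, rng, include_wt=True)
        w = {"DRP": np.eye(len(small_bank))[1]}
        oracle = d.SpecificityOracle(small_bank, w, seed=3)
        records = d.simulate_measurements(vs, oracle, noise_sd=0.0, seed=0)
        truth = oracle.values(vs)["DRP"]
        got = records.set_index("variant")["relative_activity"]
        for v, t in zip(vs, truth):
            assert got[str(v)] == pytest.approx(t, abs=1e-12)
        assert set(records["round"]) <= {1, 2}
        assert (records.loc[records.variant == "WT", "round"] == 1).all()

    def test_noise_sd_is_calibrated(self):
        # 10^4 replicates of one variant: the empirical sd of the noise
        # matches the requested level within a few percent
        land = d.AdditiveSpecificityLandscape({"DRP": {"A5V": 0.0}})
        records = d.simulate_measurements(
            [Variant.parse("A5V")], land, noise_sd=0.1, seed=0, n_replicates=10_000)
        vals = records["relative_activity"].to_numpy()
        assert len(vals) == 10_000
        assert vals.std() == pytest.approx(0.1, rel=0.05)
        assert vals.mean() == pytest.approx(1.0, abs=0.01)
        assert np.all(vals >= 0.0)

    def test_input_validation(self, small_bank):
        land = d.AdditiveSpecificityLandscape({"DRP": {}})
        with pytest.raises(ValueError, match="nonempty"):
            d.simulate_measurements([], land, noise_sd=0.1, seed=0)
        with pytest.raises(ValueError, match="noise_sd"):
            d.simulate_measurements([WILD_TYPE], land, noise_sd=-1.0, seed=0)


class TestBuildStudyDataset:
    def test_counts_and_schema(self):
        ds = d.build_study_dataset(d.StudyDesignConfig(seed=1), n_residues=80)
        assert len(ds.library) == 69
        assert len(ds.singles) == 69
        assert len(ds.combos) == 62
        assert len(ds.variants) == 131
        assert len(ds.records) == 131 * 3  # three substrates, one replicate
        assert set(ds.records.columns) == {
            "variant", "substrate", "relative_activity", "round", "replicate"}
        assert set(ds.records["substrate"]) == {"DRP", "DR", "ACET"}
        singles_rounds = ds.records[ds.records.variant.isin(
            [str(v) for v in ds.singles])]["round"]
        assert (singles_rounds == 1).all()
        combos_rounds = ds.records[ds.records.variant.isin(
            [str(v) for v in ds.combos])]["round"]
        assert (combos_rounds == 2).all()

    def test_deterministic_in_seed(self):
        a = d.build_study_dataset(d.StudyDesignConfig(seed=2), n_residues=60)
        b = d.build_study_dataset(d.StudyDesignConfig(seed=2), n_residues=60)
        pd.testing.assert_frame_equal(a.records, b.records)
        c = d.build_study_dataset(d.StudyDesignConfig(seed=3), n_residues=60)
        assert not a.records.equals(c.records)

    def test_activity_csv_roundtrip(self, tmp_path):
        ds = d.build_study_dataset(d.StudyDesignConfig(seed=4), n_residues=60)
        path = tmp_path / "records.csv"
        d.write_activity_csv(ds.records, path, seed=4)
        assert path.read_text().startswith("# seed: 4\n")
        back = d.read_activity_csv(path)
        pd.testing.assert_frame_equal(back, ds.records.reset_index(drop=True))


class TestAbsorbanceSimulation:
    def test_trace_shape_and_bounds(self):
        assay = d.AssayParameters(n_points=51, noise_sd=0.01)
        trace = d.simulate_absorbance_trace(80.0, assay, seed=1)
        assert len(trace) == 51
        assert np.all(trace.a340 >= 0.0)
        assert np.all(np.diff(trace.time_s) > 0)

    def test_initial_slope_matches_beer_lambert(self):
        # dA/dt(0) = -eps * l * v0; compare against the first finite difference
        assay = d.AssayParameters(n_points=1001)
        trace = d.simulate_absorbance_trace(100.0, assay)
        v0 = 100.0 * assay.enzyme_conc_uM * 1e-6  # M/min
        expected = assay.epsilon * assay.path_cm * v0  # AU/min
        dt_min = (trace.time_s[1] - trace.time_s[0]) / 60.0
        slope = (trace.a340[0] - trace.a340[1]) / dt_min
        assert slope == pytest.approx(expected, rel=1e-3)

    def test_adaptive_duration_keeps_window_linear(self):
        # default duration ends near 10% NADH consumption; slow reactions
        # hit the 600 s cap instead and consume even less
        for activity in (100.0, 1000.0):
            trace = d.simulate_absorbance_trace(activity)
            assert trace.a340[-1] == pytest.approx(0.9, rel=1e-6)
        slow = d.simulate_absorbance_trace(10.0)
        assert slow.time_s[-1] == 600.0
        assert slow.a340[-1] > 0.9

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            d.simulate_absorbance_trace(-1.0)


class TestToyStructure:
    def test_geometry_constraints(self):
        g = d.generate_toy_structure(60, seed=10)
        coords = np.asarray(g.coordinates)
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8, atol=1e-9)
        from scipy.spatial.distance import pdist
        d_nonadjacent = pdist(coords)
        # non-bonded pairs keep the excluded-volume separation
        n = len(coords)
        idx = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        nonadj = np.abs(idx[:, 0] - idx[:, 1]) > 1
        assert d_nonadjacent[nonadj].min() >= 3.5 - 1e-9

    def test_contact_density_is_protein_like(self):
        g = d.generate_toy_structure(100, seed=12)
        mean_degree = 2 * len(g.edges) / len(g)
        assert 2.0 <= mean_degree <= 20.0
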