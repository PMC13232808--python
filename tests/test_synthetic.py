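"""Virtual landscapes and species: known-truth generators."""

import numpy as np
import pytest

from nichekit import (Response, ScenarioDelta, apply_scenario,
                      define_virtual_species, generate_landscape, make_fixture,
                      range_change, binarize, sample_occurrences,
                      true_suitability, truth_binary, truth_change)
from nichekit.errors import SamplingError, SpecificationError

from conftest import make_stack


class TestLandscape:
    def test_same_seed_identical(self):
        a = generate_landscape(20, 20, 3, seed=4)
        b = generate_landscape(20, 20, 3, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_standardized_layers(self):
        stack = generate_landscape(30, 30, 4, seed=1)
        np.testing.assert_allclose(stack.values.mean(axis=(1, 2)), 0.0, atol=1e-10)
        np.testing.assert_allclose(stack.values.std(axis=(1, 2)), 1.0, atol=1e-10)

    def test_distinct_layers_nearly_uncorrelated(self):
        stack = generate_landscape(100, 100, 2, autocorr_range=2, seed=9)
        r = np.corrcoef(stack.values.reshape(2, -1))[0, 1]
        assert abs(r) < 0.1

    def test_gradient_layer_increases_southward(self):
        stack = generate_landscape(60, 60, 2, seed=2, gradients={"env1": 3.0})
        col_means = stack.layer("env1").mean(axis=1)
        assert col_means[-1] > col_means[0]  # south edge (last row) higher

    def test_too_small_dimensions_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(4, 40, 1)


class TestVirtualSpecies:
    def test_optimum_cell_has_unit_suitability(self):
        stack = generate_landscape(20, 20, 2, seed=3)
        vs = define_virtual_species(stack, {"env1": Response(0.0, 0.5)})
        # the rescaling guarantees max 1 at the cell nearest the joint optimum
        assert np.nanmax(vs.truth.values) == pytest.approx(1.0)

    def test_far_from_optimum_is_negligible(self):
        vals = np.zeros((8, 8)); vals[0, 0] = 5.0  # 5 breadths away at breadth 1
        stack = make_stack({"env1": vals})
        vs = define_virtual_species(stack, {"env1": Response(0.0, 1.0)})
        assert vs.truth.values[0, 0] < np.exp(-12)

    def test_truth_matches_elementwise_formula(self):
        stack = generate_landscape(15, 15, 2, seed=6)
        opt, br = 0.3, 0.4
        vs = define_virtual_species(stack, {"env1": Response(opt, br),
                                            "env2": Response(0.0, 1.0)})
        raw = (np.exp(-((stack.layer("env1") - opt) ** 2) / (2 * br**2))
               * np.exp(-(stack.layer("env2") ** 2) / 2.0))
        np.testing.assert_allclose(vs.truth.values, raw / raw.max())

    def test_logistic_link_hits_prevalence_target(self):
        stack = generate_landscape(40, 40, 2, seed=7)
        vs = define_virtual_species(stack, {"env1": Response(0, weight=2.0)},
                                    link="logistic_additive", prevalence_target=0.2)
        assert np.nanmean(vs.truth.values) == pytest.approx(0.2, abs=1e-6)

    def test_empty_response_rejected(self):
        stack = generate_landscape(10, 10, 1, seed=0)
        with pytest.raises(SpecificationError):
            define_virtual_species(stack, {})

    def test_unknown_variable_rejected(self):
        stack = generate_landscape(10, 10, 1, seed=0)
        with pytest.raises(SpecificationError):
            define_virtual_species(stack, {"nope": Response(0)})


@pytest.fixture(scope="module")
def specialist_vs():
    stack = generate_landscape(50, 50, 3, seed=8)
    return define_virtual_species(stack, {"env1": Response(0.5, 0.3)})


class TestSampling:
    @pytest.fixture
    def vs(self, specialist_vs):
        return specialist_vs

    def test_deterministic(self, vs):
        a = sample_occurrences(vs, 100, seed=5)
        b = sample_occurrences(vs, 100, seed=5)
        np.testing.assert_array_equal(a.points, b.points)

    def test_zero_suitability_cells_never_sampled(self):
        vals = np.zeros((10, 10)); vals[:2, :] = 2.0
        stack = make_stack({"env1": vals})
        # breadth 0.05: cells at 0 underflow to exactly zero suitability
        vs = define_virtual_species(stack, {"env1": Response(2.0, 0.05)})
        assert (vs.truth.values == 0).sum() == 80
        occ = sample_occurrences(vs, 15, seed=1)
        truth_at = vs.truth.values[occ.cell_indices[:, 0], occ.cell_indices[:, 1]]
        assert (truth_at > 0).all()

    def test_sampled_cells_richer_than_average(self, vs):
        occ = sample_occurrences(vs, 200, seed=2)
        t = vs.truth.values
        sampled = t[occ.cell_indices[:, 0], occ.cell_indices[:, 1]]
        assert sampled.mean() > np.nanmean(t)

    def test_occurrence_density_monotone_over_suitability_deciles(self, vs):
        occ = sample_occurrences(vs, 800, seed=3)
        t = vs.truth.values.ravel()
        chosen = np.zeros(t.size, bool)
        chosen[occ.cell_indices[:, 0] * 50 + occ.cell_indices[:, 1]] = True
        deciles = np.quantile(t, np.linspace(0, 1, 11))
        dens = []
        for lo, hi in zip(deciles[:-1], deciles[1:]):
            sel = (t >= lo) & (t < hi if hi < deciles[-1] else t <= hi)
            dens.append(chosen[sel].mean())
        # allow small wobble in the middle, require a clear monotone trend
        from scipy.stats import spearmanr
        assert dens[-1] > dens[0]
        assert spearmanr(np.arange(10), dens).statistic > 0.7

    def test_demand_exceeding_positive_cells_raises(self):
        vals = np.full((10, 10), -50.0); vals[0, :3] = 0.0
        stack = make_stack({"env1": vals})
        vs = define_virtual_species(stack, {"env1": Response(0.0, 0.1)})
        with pytest.raises(SamplingError):
            sample_occurrences(vs, 50, seed=1)


class TestScenario:
    def test_zero_delta_is_identity(self, small_stack):
        out = apply_scenario(small_stack, ScenarioDelta({"v1": 0.0}, "null"))
        np.testing.assert_array_equal(out.values, small_stack.values)

    def test_double_application_equals_double_shift(self, small_stack):
        d1 = ScenarioDelta({"v1": 0.7}, "a")
        d2 = ScenarioDelta({"v1": 1.4}, "b")
        twice = apply_scenario(apply_scenario(small_stack, d1), d1)
        once = apply_scenario(small_stack, d2)
        np.testing.assert_allclose(twice.values, once.values)

    def test_shift_relocates_truth_maximum(self):
        stack = generate_landscape(40, 40, 2, seed=12)
        vs = define_virtual_species(stack, {"env1": Response(0.5, 0.2)})
        shifted = apply_scenario(stack, ScenarioDelta({"env1": 0.4}, "warm"))
        t2 = true_suitability(vs, shifted)
        # new optimum sits where original env1 = 0.1
        r, c = np.unravel_index(np.nanargmax(t2.values), t2.values.shape)
        assert abs(stack.layer("env1")[r, c] - 0.1) < 0.05

    def test_unknown_variable_rejected(self, small_stack):
        with pytest.raises(SpecificationError):
            apply_scenario(small_stack, ScenarioDelta({"zz": 1.0}, "x"))


class TestTruthChange:
    def test_no_change_when_future_equals_baseline(self):
        stack = generate_landscape(20, 20, 1, seed=13)
        vs = define_virtual_species(stack, {"env1": Response(0, 0.5)})
        assert truth_change(vs, stack, stack, 0.5).rci == 0.0

    def test_complete_loss_by_construction(self):
        stack = generate_landscape(20, 20, 1, seed=14)
        vs = define_virtual_species(stack, {"env1": Response(0, 0.3)})
        wiped = apply_scenario(stack, ScenarioDelta({"env1": 100.0}, "doom"))
        assert truth_change(vs, stack, wiped, 0.5).rci == pytest.approx(-100.0)

    def test_hand_constructed_6x6_counts(self):
        vals = np.full((6, 6), 10.0)
        vals[0, :4] = 0.0           # baseline suitable: 4 cells
        stack = make_stack({"env1": vals}, cell_size=1000.0)
        vs = define_virtual_species(stack, {"env1": Response(0.0, 1.0)})
        fut_vals = np.full((6, 6), 10.0)
        fut_vals[0, :2] = 0.0       # keep 2 of the 4
        fut_vals[5, :3] = 0.0       # gain 3 new cells
        fut = make_stack({"env1": fut_vals}, cell_size=1000.0)
        summary = truth_change(vs, stack, fut, 0.5)
        assert summary.rci == pytest.approx((3 - 2) / 4 * 100)
        est_base = truth_binary(vs, stack, 0.5)
        assert est_base.values.sum() == 4


class TestFixture:
    def test_fixture_writes_complete_worked_example(self, tmp_path):
        manifest = make_fixture(tmp_path, seed=1, n_rows=40, n_cols=40, n_vars=3,
                                species_counts={"a": 60, "b": 25},
                                scenario_shifts={"ssp585": 1.0})
        assert len(manifest["baseline"]) == 3
        assert set(manifest["scenarios"]) == {"ssp585"}
        assert (tmp_path / "occurrences.csv").exists()
        import pandas as pd
        occ = pd.read_csv(manifest["occurrences"])
        assert set(occ["species"]) == {"a", "b"}
        assert occ["species"].value_counts()["a"] == 60
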