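import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opdpipe.errors import (
    MissingDataError,
    ModelDomainError,
    UndefinedVolumeFractionError,
)
from opdpipe.stages import OocyteStage
from opdpipe.stereology import (
    GRID_A,
    GRID_B,
    FieldCount,
    ShrinkageModel,
    compare_correction_models,
    component_fractions,
    correct_shrinkage,
    select_grid,
    shape_factor,
    stabilization_curve,
    volume_based_diameter,
    volume_fraction,
)


def fc(field_id, hits, n_points=None, female_id="F1"):
    n = n_points if n_points is not None else sum(hits.values())
    return FieldCount(field_id=field_id, n_points=n, hits=hits, female_id=female_id)


class TestFieldCount:
    def test_hits_must_sum_to_points(self):
        with pytest.raises(ValueError):
            FieldCount("f1", 10, {"VTO": 3})

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            FieldCount("f1", 3, {"NOT_A_THING": 3})

    def test_valid_points_excludes_empty_and_outside(self):
        count = fc("f1", {"VTO": 90, "TISSUE": 150, "EMPTY": 40, "OUTSIDE": 20})
        assert count.n_points == 300
        assert count.valid_points == 240


class TestVolumeFraction:
    def test_worked_example(self):
        count = fc("f1", {"VTO": 90, "TISSUE": 150, "EMPTY": 40, "OUTSIDE": 20})
        assert volume_fraction([count], OocyteStage.VTO) == pytest.approx(90 / 240)

    def test_full_coverage(self):
        count = fc("f1", {"CAO": 370})
        assert volume_fraction([count], "CAO") == 1.0

    def test_pooled_ratio_of_sums_not_mean_of_ratios(self):
        a = fc("f1", {"VTO": 10, "TISSUE": 10})  # 0.5 of 20 valid
        b = fc("f2", {"VTO": 10, "TISSUE": 90})  # 0.1 of 100 valid
        pooled = volume_fraction([a, b], "VTO")
        assert pooled == pytest.approx(20 / 120)
        assert pooled != pytest.approx(0.3)  # the mean of per-field ratios

    def test_zero_valid_points(self):
        count = fc("f1", {"EMPTY": 300, "OUTSIDE": 70})
        with pytest.raises(UndefinedVolumeFractionError):
            volume_fraction([count], "VTO")

    def test_no_fields(self):
        with pytest.raises(MissingDataError):
            volume_fraction([], "VTO")

    def test_fraction_accounting_modes(self):
        count = fc("f1", {"VTO": 90, "TISSUE": 150, "EMPTY": 40, "OUTSIDE": 20})
        raw = component_fractions([count], over_raw=True)
        assert sum(raw.values()) == pytest.approx(1.0)
        valid = component_fractions([count])
        assert sum(valid.values()) == pytest.approx(1.0)
        assert "EMPTY" not in valid


class TestStabilization:
    def test_constant_series(self):
        res = stabilization_curve([5.0, 5.0, 5.0, 5.0])
        assert np.allclose(res.deviations, 0.0)
        assert res.stable_n == 1

    def test_two_point_hand_computation(self):
        res = stabilization_curve([0.0, 1.0])
        assert res.deviations[0] == pytest.approx(1.0)
        assert res.deviations[1] == 0.0
        assert res.stable_n == 2

    def test_final_deviation_always_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            vals = rng.uniform(0.1, 1.0, size=rng.integers(1, 20))
            assert stabilization_curve(vals).deviations[-1] == pytest.approx(0.0)

    def test_zero_mean_undefined(self):
        with pytest.raises(ModelDomainError):
            stabilization_curve([-1.0, 1.0])

    @given(
        st.lists(st.floats(0.01, 100.0), min_size=2, max_size=30),
        st.floats(0.001, 1000.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_scale_invariance(self, values, factor):
        base = stabilization_curve(values).deviations
        scaled = stabilization_curve([v * factor for v in values]).deviations
        assert np.allclose(base, scaled, rtol=1e-8, atol=1e-10)


class TestShapeAndDiameter:
    def test_shape_factor_examples(self, measurements_factory):
        m = measurements_factory(
            [
                ("F1", "VTO", 130.0, 100.0, True),
                ("F1", "VTO", 120.0, 100.0, True),
                ("F1", "VTO", 500.0, 100.0, False),  # not through nucleus: excluded
            ]
        )
        assert shape_factor(m, OocyteStage.VTO, "F1") == pytest.approx(1.25)

    def test_spheres_give_unity(self, measurements_factory):
        m = measurements_factory([("F1", "CAO", 100.0, 100.0, True)] * 3)
        assert shape_factor(m, "CAO", "F1") == 1.0

    def test_missing_stage_warns_nan(self, measurements_factory):
        m = measurements_factory([("F1", "CAO", 100.0, 100.0, True)])
        with pytest.warns(UserWarning):
            assert np.isnan(shape_factor(m, "VTO", "F1"))

    def test_odv_equal_diameters(self, measurements_factory):
        m = measurements_factory([("F1", "CAO", 100.0, 100.0, True)] * 3)
        assert volume_based_diameter(m, "CAO", "F1") == pytest.approx(100.0)

    def test_odv_hand_arithmetic(self, measurements_factory):
        m = measurements_factory(
            [
                ("F1", "CAO", 80.0, 80.0, True),
                ("F1", "CAO", 100.0, 100.0, True),
                ("F1", "CAO", 120.0, 120.0, True),
            ]
        )
        expected = (1_080_000.0) ** (1.0 / 3.0)  # ~102.60
        assert volume_based_diameter(m, "CAO", "F1") == pytest.approx(expected)
        assert expected == pytest.approx(102.60, abs=0.01)

    def test_single_oocyte(self, measurements_factory):
        m = measurements_factory([("F1", "VTO", 120.0, 100.0, True)])
        assert volume_based_diameter(m, "VTO", "F1") == pytest.approx(110.0)

    def test_odv_at_least_arithmetic_mean(self, measurements_factory):
        rng = np.random.default_rng(8)
        od = rng.uniform(50, 300, size=12)
        m = measurements_factory([("F1", "VTO", d, d, True) for d in od])
        assert volume_based_diameter(m, "VTO", "F1") >= od.mean() - 1e-9

    @given(st.lists(st.floats(10.0, 500.0), min_size=2, max_size=15), st.floats(1.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_odv_monotone_in_any_diameter(self, diams, bump):
        def odv(values):
            return float(np.cbrt(np.mean(np.array(values) ** 3)))

        bumped = list(diams)
        bumped[0] += bump
        assert odv(bumped) >= odv(diams)


class TestShrinkage:
    def test_identity(self):
        assert correct_shrinkage(100.0, ShrinkageModel("identity")) == 100.0

    def test_multiplicative(self):
        model = ShrinkageModel("multiplicative", (1.25,))
        assert correct_shrinkage(80.0, model) == pytest.approx(100.0)

    def test_round_trip_inverse(self):
        shrink = ShrinkageModel("multiplicative", (0.8,))
        correction = shrink.inverse()
        assert correction.apply(shrink.apply(123.4)) == pytest.approx(123.4)

    def test_linear_inverse(self):
        model = ShrinkageModel("linear", (5.0, 1.1))
        inv = model.inverse()
        assert inv.apply(model.apply(77.0)) == pytest.approx(77.0)

    def test_negative_output_is_domain_error(self):
        model = ShrinkageModel("linear", (-500.0, 1.0))
        with pytest.raises(ModelDomainError):
            correct_shrinkage(100.0, model)

    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            ShrinkageModel("exponential", (1.0,))


class TestCompareCorrectionModels:
    @staticmethod
    def _vto_inputs(n=6, shrink=0.8, seed=4):
        """Females with known true diameters, observed in shrunken form."""
        from opdpipe.opd_engine import oocyte_number, opd

        rng = np.random.default_rng(seed)
        rows, ref = [], {}
        for i in range(n):
            true_od = rng.uniform(250, 350)
            vv = rng.uniform(0.1, 0.3)
            gwf = rng.uniform(10, 40)
            rows.append(
                {
                    "female_id": f"F{i}",
                    "Vv": vv,
                    "k": 1.0,
                    "ODv_um": true_od * shrink,  # embedded (shrunken) diameter
                    "rho": 1.072,
                    "GWf_g": gwf,
                }
            )
            ref[f"F{i}"] = oocyte_number(opd(vv, 1.0, true_od, 1.072), gwf)
        return pd.DataFrame(rows), ref

    def test_true_inverse_ranked_first(self):
        inputs, ref = self._vto_inputs(shrink=0.8)
        models = [
            ShrinkageModel("identity", name="none"),
            ShrinkageModel("multiplicative", (1.0 / 0.8,), name="true"),
            ShrinkageModel("multiplicative", (1.5,), name="over"),
        ]
        ranked = compare_correction_models(models, inputs, ref)
        assert ranked.iloc[0]["model"] == "true"
        assert ranked.iloc[0]["mean_abs_rel_dev"] < 1e-9

    def test_single_model_trivially_best(self):
        inputs, ref = self._vto_inputs()
        ranked = compare_correction_models([ShrinkageModel("identity", name="only")], inputs, ref)
        assert list(ranked["model"]) == ["only"]

    def test_tie_broken_by_input_order(self):
        inputs, ref = self._vto_inputs()
        twins = [
            ShrinkageModel("multiplicative", (1.1,), name="first"),
            ShrinkageModel("multiplicative", (1.1,), name="second"),
        ]
        ranked = compare_correction_models(twins, inputs, ref)
        assert ranked.iloc[0]["model"] == "first"

    def test_empty_overlap_errors(self):
        inputs, _ = self._vto_inputs()
        with pytest.raises(MissingDataError):
            compare_correction_models([ShrinkageModel("identity")], inputs, {"ZZ": 1.0})


class TestSelectGrid:
    def test_identical_estimates_pick_sparser(self):
        est = [0.1, 0.2, 0.3]
        assert select_grid(GRID_A, GRID_B, est, est) is GRID_A

    def test_disagreement_picks_denser(self):
        a = [0.05, 0.06, 0.05]
        b = [0.10, 0.11, 0.10]
        assert select_grid(GRID_A, GRID_B, a, b) is GRID_B

    def test_grid_b_definition(self):
        assert GRID_B.n_points == 370
        assert GRID_B.probe_line_length_um == pytest.approx(65.7)
        assert GRID_A.n_points == 240
        assert GRID_A.probe_line_length_um == pytest.approx(77.1)

    def test_unpaired_inputs_error(self):
        with pytest.raises(MissingDataError):
            select_grid(GRID_A, GRID_B, [0.1, 0.2], [0.1])

    def test_small_particle_simulation_prefers_denser_grid(self):
        """Sparse grids scatter more on small scattered particles; the paired
        differences then exceed tolerance and the dense grid is kept."""
        from opdpipe.stages import OocyteStage
        from opdpipe.stereology import volume_fraction as vf
        from opdpipe.synthetic import (
            SectionFieldSpec,
            StagePopulationSpec,
            count_grid_hits,
            render_fields,
            simulate_population,
        )

        pop = simulate_population(
            [StagePopulationSpec(OocyteStage.PVO1, 5.0e6, 16.0, 0.05)],
            0.002,
            1.061,
            seed=21,
        )
        fields = render_fields(
            pop, SectionFieldSpec(400.0, 400.0, 4.0, 6, 0.0), seed=22
        )
        est_a = [
            vf([count_grid_hits(f, GRID_A, seed=100 + i)], "PVO1")
            for i, f in enumerate(fields)
        ]
        est_b = [
            vf([count_grid_hits(f, GRID_B, seed=200 + i)], "PVO1")
            for i, f in enumerate(fields)
        ]
        chosen = select_grid(GRID_A, GRID_B, est_a, est_b, tolerance=0.05)
        assert chosen is GRID_B
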