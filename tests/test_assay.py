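"""ΔCNP arithmetic, IUPAC blank statistics, OFF/ON calls, dose response."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diracsense.assay import (AssayStep, classify, delta_cnp, dose_response,
                              evaluate_assay, limit_of_detection,
                              limit_of_identification, platform_lod, relative_shift)
from diracsense.cnp import CNPFitResult
from diracsense.simulate import ScenarioConfig, make_assay

# ΔCNP values of a representative three-replicate sensing campaign (mV),
# by concentration; '/' cells of the published-style table are absent.
SENSING_TABLE = {
    1e-19: [-49, -66],
    1e-18: [-58],
    1e-17: [-62, -28],
    1e-16: [-59, -50, -33],
    1e-13: [-48, -52],
    1e-10: [-70, -93],
}


def result(v_cnp_mv: float, sd_mv: float = 11.0) -> CNPFitResult:
    return CNPFitResult.from_values(v_cnp_mv * 1e-3, sd_mv * 1e-3)


class TestDeltaCNP:
    def test_baseline_335_to_286_gives_minus_49(self):
        shift = delta_cnp(result(335), result(286))
        assert shift.value == pytest.approx(-49.0, abs=1e-9)

    def test_quadrature_sd(self):
        shift = delta_cnp(result(335, 11), result(286, 11))
        assert shift.sd == pytest.approx(math.hypot(11, 11), abs=0.01)  # ≈15.6

    def test_identical_fits_give_zero(self):
        assert delta_cnp(result(300), result(300)).value == 0.0

    def test_antisymmetric(self):
        a, b = result(335), result(286)
        assert delta_cnp(a, b).value == -delta_cnp(b, a).value

    def test_unconverged_rejected(self):
        bad = CNPFitResult.from_values(0.3, 0.011, converged=False)
        with pytest.raises(ValueError, match="converge"):
            delta_cnp(bad, result(286))


class TestBlankStatistics:
    def test_zero_variance_blanks(self):
        stats = limit_of_detection([14.0, 14.0, 14.0])
        assert stats.lod == pytest.approx(14.0)
        assert stats.sigma == 0.0

    def test_mean_14_sd_11_gives_47(self):
        # two blanks with mean magnitude 14 and sample sd 11
        x = 11.0 / math.sqrt(2.0)
        stats = limit_of_detection([14.0 - x, 14.0 + x])
        assert stats.mu_n == pytest.approx(14.0)
        assert stats.sigma == pytest.approx(11.0)
        assert stats.lod == pytest.approx(47.0)

    def test_single_blank_rejected(self):
        with pytest.raises(ValueError):
            limit_of_detection([14.0])

    def test_loi_six_sigma_convention(self):
        x = 11.0 / math.sqrt(2.0)
        blanks = [x, -x]  # sample sd exactly 11
        assert limit_of_identification(blanks, pure_sigma=True) == pytest.approx(66.0)
        assert limit_of_identification(blanks) == pytest.approx(x + 66.0)

    def test_loi_zero_variance(self):
        assert limit_of_identification([5.0, 5.0]) == pytest.approx(5.0)

    def test_loi_at_least_lod(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            blanks = rng.normal(0, 11, 3)
            stats = limit_of_detection(blanks)
            assert stats.loi >= stats.lod

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8), st.integers(0, 7))
    def test_permutation_invariant(self, blanks, rot):
        rotated = blanks[rot % len(blanks):] + blanks[:rot % len(blanks)]
        assert limit_of_detection(rotated).lod == pytest.approx(
            limit_of_detection(blanks).lod, rel=1e-12, abs=1e-12)

    def test_monotone_in_dispersion(self):
        tight = limit_of_detection([-5.0, 2.0, 5.0])
        wide = limit_of_detection([-10.0, 4.0, 10.0])
        assert wide.lod > tight.lod

    def test_platform_lod_for_11mv_noise(self):
        # σ√(2/π) + 3σ at σ = 11 mV
        assert platform_lod(11.0) == pytest.approx(41.77, abs=0.01)


class TestClassify:
    @pytest.mark.parametrize("delta,lod,expected", [
        (-55.0, 25.0, "ON"),      # single-molecule sensing shift
        (-10.0, 25.0, "OFF"),
        (25.0, 25.0, "OFF"),      # tie → OFF (strict inequality)
        (30.0, 25.0, "ON"),       # magnitude, not sign
    ])
    def test_calls(self, delta, lod, expected):
        assert classify(delta, lod) == expected

    def test_negative_lod_rejected(self):
        with pytest.raises(ValueError):
            classify(-55.0, -1.0)


class TestRelativeShift:
    def test_sixteen_percent_shift(self):
        out = relative_shift(335.0, 280.0)
        assert out["abs_over_baseline"] == pytest.approx(55.0 / 335.0 * 100, abs=0.01)

    def test_literal_over_sensing_convention(self):
        out = relative_shift(335.0, 286.0)
        assert out["over_sensing"] == pytest.approx((286 - 335) / 286 * 100, abs=0.01)
        assert out["abs_over_baseline"] == pytest.approx(49 / 335 * 100, abs=0.01)

    def test_no_shift(self):
        assert relative_shift(300.0, 300.0)["abs_over_baseline"] == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            relative_shift(0.0, 286.0)


class TestDoseResponse:
    def test_two_replicate_mean(self):
        table = dose_response({1e-19: [-49.0, -66.0]})
        assert table.loc[0, "mean_delta_cnp"] == pytest.approx(-57.5)

    def test_single_replicate_sd_flagged(self):
        table = dose_response({1e-10: [7.0]})
        assert table.loc[0, "mean_delta_cnp"] == 7.0
        assert not table.loc[0, "sd_defined"]
        assert np.isnan(table.loc[0, "sd_delta_cnp"])

    def test_grand_mean_of_sensing_campaign(self):
        values = [v for col in SENSING_TABLE.values() for v in col]
        assert np.mean(values) == pytest.approx(-55.7, abs=0.1)

    def test_missing_cells_skipped(self):
        table = dose_response(SENSING_TABLE)
        assert len(table) == 6
        assert table["n"].tolist() == [2, 1, 2, 3, 2, 2]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dose_response({1e-19: []})


class TestEvaluateAssay:
    def steps_from_simulation(self, seed=20250121):
        sim = make_assay(ScenarioConfig(seed=seed))
        return [AssayStep(label=s.label, fit=sim.cnp_readout(s), analyte=s.analyte,
                          concentration=s.concentration, replicate_id=s.replicate_id)
                for s in sim.steps]

    def test_default_assay_calls_with_platform_lod(self):
        """Every sensing dose reads ON and every non-binder OFF against the
        platform LOD of the 11 mV blank-noise level."""
        res = evaluate_assay(self.steps_from_simulation(), lod=platform_lod(11.0))
        sensing = res.steps[res.steps.label == "sensing"]
        controls = res.steps[res.steps.label == "negative_control"]
        assert (sensing.call == "ON").all()
        assert (controls.call == "OFF").all()

    def test_blank_statistics_reported(self):
        res = evaluate_assay(self.steps_from_simulation())
        assert res.blank_stats.n_blanks == 3
        assert res.lod == res.blank_stats.lod

    def test_missing_baseline_rejected(self):
        steps = [s for s in self.steps_from_simulation() if s.label != "baseline"]
        with pytest.raises(ValueError, match="baseline"):
            evaluate_assay(steps)

    def test_duplicate_baseline_rejected(self):
        steps = self.steps_from_simulation()
        steps.append(steps[0])
        with pytest.raises(ValueError, match="two baselines"):
            evaluate_assay(steps)

    def test_dose_response_covers_all_concentrations(self):
        res = evaluate_assay(self.steps_from_simulation(), lod=platform_lod(11.0))
        assert len(res.dose_response) == 6
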