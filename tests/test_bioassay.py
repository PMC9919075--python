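"""Inhibition rate, 4PL IC50 fitting, MIC reading and endpoint assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectrum_effect import (
    DILUTION_SERIES_MG_ML,
    AbsorbanceQuadruple,
    MICPlate,
    build_activity_table,
    fit_four_pl,
    gen_dose_response,
    gen_mic_plate,
    inhibition_rate,
    read_mic,
    summarize_ic50,
    zone_summary,
)
from spectrum_effect.bioassay import format_mean_sd
from spectrum_effect.datasets import stream_rng


class TestInhibitionRate:
    def test_limits(self):
        # sample signal equals the enzyme control -> no inhibition
        assert inhibition_rate(AbsorbanceQuadruple(1.2, 0.2, 1.1, 0.1)) == pytest.approx(0.0)
        # sample signal fully suppressed -> 100%
        assert inhibition_rate(AbsorbanceQuadruple(0.3, 0.3, 1.1, 0.1)) == pytest.approx(100.0)

    def test_negative_rate_is_legal(self):
        # colour interference: (Asa-Asc) = 1.5 * (Aea-Aec) -> -50%
        q = AbsorbanceQuadruple(1.6, 0.1, 1.1, 0.1)
        assert inhibition_rate(q) == pytest.approx(-50.0)

    def test_dead_enzyme_control_raises(self):
        with pytest.raises(ValueError):
            inhibition_rate(AbsorbanceQuadruple(1.0, 0.1, 0.5, 0.5))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-0.5, 0.5), st.floats(0.1, 2.0), st.floats(0.0, 1.0),
           st.floats(0.2, 1.5))
    def test_affine_invariance(self, shift, asa, asc, span):
        q = AbsorbanceQuadruple(asa, asc, asc + span, asc)
        shifted = AbsorbanceQuadruple(asa + shift, asc + shift, asc + span + shift,
                                      asc + shift)
        assert inhibition_rate(q) == pytest.approx(inhibition_rate(shifted), abs=1e-9)


class TestFourPL:
    def test_noiseless_roundtrip(self):
        df = gen_dose_response(ic50=100, hill=1, bottom=0, top=100, noise_sd=0,
                               replicates=1)
        fit = fit_four_pl(df["concentration"], df["inhibition_pct"])
        assert fit.converged
        assert fit.ic50 == pytest.approx(100, rel=1e-4)

    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 4.0])
    def test_all_parameters_recovered_across_hill_slopes(self, hill):
        df = gen_dose_response(ic50=80, hill=hill, bottom=5, top=95, noise_sd=0,
                               concentrations=(5, 10, 20, 40, 80, 160, 320, 640, 1280),
                               replicates=1)
        fit = fit_four_pl(df["concentration"], df["inhibition_pct"])
        assert fit.ic50 == pytest.approx(80, rel=1e-3)
        assert fit.hill == pytest.approx(hill, rel=1e-3)
        assert fit.bottom == pytest.approx(5, abs=0.1)
        assert fit.top == pytest.approx(95, abs=0.1)

    def test_flat_curve_flagged(self):
        fit = fit_four_pl([10, 20, 40, 80], [50.0, 50.0, 50.0, 50.0])
        assert not fit.converged
        assert fit.degenerate
        assert math.isnan(fit.ic50)

    def test_too_few_concentrations_raise(self):
        with pytest.raises(ValueError):
            fit_four_pl([10, 20, 30], [1, 2, 3])

    def test_low_response_curve_is_degenerate(self):
        # fewer than 3 rates above 10%: no meaningful midpoint
        fit = fit_four_pl([10, 20, 40, 80, 160], [1, 2, 3, 5, 12])
        assert fit.degenerate and not fit.converged

    def test_noisy_median_relative_error_under_5pct(self):
        """Pooled triplicate fits at 2% assay noise recover IC50 to
        better than 5% median relative error."""
        errs = []
        for seed in range(200):
            df = gen_dose_response(ic50=100, hill=1, bottom=0, top=100,
                                   noise_sd=2.0, seed=seed)
            fit = fit_four_pl(df["concentration"], df["inhibition_pct"])
            if fit.converged:
                errs.append(abs(fit.ic50 - 100) / 100)
        assert len(errs) >= 190
        assert np.median(errs) < 0.05


class TestIC50Summary:
    def test_hand_arithmetic(self):
        fits = [fit_four_pl_like(60), fit_four_pl_like(65), fit_four_pl_like(70)]
        s = summarize_ic50(fits)
        assert s["mean"] == pytest.approx(65)
        assert s["sd"] == pytest.approx(5)

    def test_single_replicate_mean_only(self):
        s = summarize_ic50([fit_four_pl_like(42.0)])
        assert s["mean"] == pytest.approx(42.0)
        assert math.isnan(s["sd"])

    def test_all_nonconverged_reported_missing(self):
        bad = fit_four_pl_like(50.0)
        bad.converged = False
        s = summarize_ic50([bad, bad])
        assert s["missing"] and s["n"] == 0


def fit_four_pl_like(ic50):
    from spectrum_effect import FourPLFit

    return FourPLFit(bottom=0, top=100, ic50=ic50, hill=1, rss=0, converged=True)


class TestMIC:
    def test_paper_series_readout(self):
        plate = MICPlate(growth=[False] * 5 + [True] * 4)
        assert read_mic(plate).value == pytest.approx(0.20)
        assert read_mic(plate).censored == ""

    def test_censoring(self):
        assert str(read_mic(MICPlate(growth=[True] * 9))) == ">3.12"
        low = read_mic(MICPlate(growth=[False] * 9))
        assert low.censored == "<" and low.value == pytest.approx(0.0125)

    def test_control_failure_raises(self):
        with pytest.raises(ValueError, match="positive control"):
            read_mic(MICPlate(growth=[True] * 9, positive_control_growth=False))
        with pytest.raises(ValueError, match="negative control"):
            read_mic(MICPlate(growth=[True] * 9, negative_control_growth=True))

    def test_non_monotone_pattern_raises(self):
        with pytest.raises(ValueError, match="non-monotone"):
            read_mic(MICPlate(growth=[False, True, False] + [True] * 6))

    def test_generator_roundtrip_identity(self):
        rng = stream_rng(0, "mic-test")
        for _ in range(50):
            true_mic = float(rng.choice(DILUTION_SERIES_MG_ML))
            plate = MICPlate(growth=gen_mic_plate(true_mic, DILUTION_SERIES_MG_ML))
            got = read_mic(plate)
            if true_mic == min(DILUTION_SERIES_MG_ML):
                # lowest dilution clears everything below it too: censored
                assert got.censored == "<" or got.value == pytest.approx(true_mic)
            else:
                assert got.censored == ""
                assert got.value == pytest.approx(true_mic)


class TestZoneAndAssembly:
    def test_zone_summary_hand_arithmetic(self):
        mean, sd = zone_summary([9.0, 9.8, 10.0])
        assert mean == pytest.approx(9.6, abs=1e-12)
        assert sd == pytest.approx(0.5291502622, abs=1e-9)
        assert format_mean_sd(9.78, 0.72) == "9.78 ± 0.72"

    def test_identical_replicates_zero_sd(self):
        assert zone_summary([10.0, 10.0, 10.0])[1] == 0.0

    def test_activity_table_masks_missing_endpoints(self):
        # two samples lack the amylase endpoint, as on an interference-hit panel
        zone = {f"S{i}": 8.0 + i for i in range(1, 11)}
        amylase = {f"S{i}": 200.0 + i for i in range(1, 11) if i not in (6, 7)}
        table = build_activity_table(
            {"zone_mm": zone, "amylase_ic50": amylase},
            {"zone_mm": "higher_is_active", "amylase_ic50": "lower_is_active"},
        )
        assert table.values.shape == (10, 2)
        assert table.values["amylase_ic50"].isna().sum() == 2
        assert table.direction["amylase_ic50"] == "lower_is_active"

    def test_activity_table_io_roundtrip(self, tmp_path):
        from spectrum_effect import ActivityTable

        zone = {"S1": 9.78, "S2": 9.41}
        t = build_activity_table({"zone_mm": zone}, {"zone_mm": "higher_is_active"})
        p = tmp_path / "act.tsv"
        t.write(p)
        back = ActivityTable.read(p)
        assert back.direction == t.direction
        np.testing.assert_allclose(back.values, t.values)

    def test_empty_input_gives_empty_table(self):
        t = build_activity_table({}, {})
        assert t.values.empty
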