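"""Precision/trueness arithmetic, interference checks, report assembly."""

import numpy as np
import pytest

from hairetg import (
    QCSeries,
    assemble_report,
    fit_calibration,
    interference_check,
    precision_trueness,
)
from hairetg.errors import HairEtgError, InsufficientDataError
from hairetg.fixtures import load_fixture
from hairetg.limits import LodResult, METHOD_SNR
from hairetg.simulate import (
    CalibrationSimSpec,
    GaussianPeak,
    QCSimSpec,
    TraceSpec,
    simulate_calibration,
    simulate_qc,
    simulate_traces,
)
from hairetg.util import round_half_up
from hairetg.validation import SCOPE_INTER_DAY, SCOPE_INTRA_DAY


def qc_series_from_frame(df):
    return QCSeries(
        nominal=float(df["nominal_pg_per_mg"].iloc[0]),
        measurements=[
            (float(r.value_pg_per_mg), str(r.day), str(r.operator)) for r in df.itertuples()
        ],
    )


class TestPrecisionTrueness:
    def test_all_equal_to_nominal(self):
        series = QCSeries(30.0, [(30.0, "d1", "o"), (30.0, "d1", "o"), (30.0, "d1", "o")])
        res = precision_trueness(series, SCOPE_INTRA_DAY)
        assert res.rsd_percent == 0.0 and res.bias_percent == 0.0

    def test_inter_day_pools_all_measurements(self):
        df = simulate_qc(QCSimSpec(nominal=30.0, cv=0.08, n_days=3, replicates_per_day=3, seed=1))
        res = precision_trueness(qc_series_from_frame(df), SCOPE_INTER_DAY)
        assert res.n == 9
        vals = df["value_pg_per_mg"].to_numpy()
        assert res.mean == pytest.approx(vals.mean())
        assert res.sd == pytest.approx(vals.std(ddof=1))

    def test_printed_rounding_matches_convention(self):
        # inter-day summary mean 27.8, sd 2.7 at nominal 30 prints RSD 10%, bias 7.3%
        series = QCSeries(30.0, [(25.1, "d1", "o"), (27.8, "d2", "o"), (30.5, "d3", "o")])
        res = precision_trueness(series, SCOPE_INTER_DAY)
        assert round_half_up(100 * res.sd / res.mean, 0) == 10.0
        assert round_half_up(abs(res.bias_percent), 1) == 7.3

    def test_loq_level_bias_rounds_to_six_percent(self):
        # six replicates averaging 5.66 pg/mg at nominal 6: |bias| -> 6%
        vals = [5.66] * 6
        series = QCSeries(6.0, [(v, "d1", "o") for v in vals])
        res = precision_trueness(series, SCOPE_INTRA_DAY)
        assert round_half_up(abs(res.bias_percent), 0) == 6.0

    def test_scope_grouping_errors(self):
        multi = QCSeries(30.0, [(30.0, "d1", "o"), (31.0, "d2", "o"), (29.0, "d2", "o")])
        with pytest.raises(InsufficientDataError):
            precision_trueness(multi, SCOPE_INTRA_DAY)  # ambiguous day
        single = QCSeries(30.0, [(30.0, "d1", "o"), (31.0, "d1", "o"), (29.0, "d1", "o")])
        with pytest.raises(InsufficientDataError):
            precision_trueness(single, SCOPE_INTER_DAY)

    def test_estimated_rsd_converges_to_generating_cv(self):
        df = simulate_qc(QCSimSpec(nominal=30.0, cv=0.10, n_days=1, replicates_per_day=1000, seed=6))
        res = precision_trueness(qc_series_from_frame(df), SCOPE_INTRA_DAY, day="0")
        assert res.rsd_percent == pytest.approx(10.0, abs=1.0)
        assert res.bias_percent == pytest.approx(0.0, abs=1.5)


@pytest.fixture()
def cal_fit():
    return fit_calibration(
        simulate_calibration(CalibrationSimSpec(slope=0.01, noise_param=0.0))
    )


def blank_run(quant_height=0.0, qual_height=0.0, is_height=1000.0, seed=0):
    peaks = [GaussianPeak("is", 30.0, is_height, 2.0)]
    if quant_height > 0:
        peaks.append(GaussianPeak("quant", 30.0, quant_height, 2.0))
    spec = TraceSpec(
        transitions=["quant", "is", "qual"],
        duration=60,
        peaks=peaks,
        baseline_level=0.0,
        interference=GaussianPeak("qual", 30.0, qual_height, 2.0) if qual_height > 0 else None,
        seed=seed,
    )
    return simulate_traces(spec)


class TestInterference:
    def test_zero_signal_blanks_pass(self, cal_fit):
        verdict = interference_check(
            [blank_run()], cal_fit, lod=4.0,
            quantifier_id="quant", internal_standard_id="is", window=(20.0, 40.0),
        )
        assert verdict.passed
        assert verdict.apparent_concentrations == [0.0]

    def test_quantifier_window_peak_fails(self, cal_fit):
        # forward model: apparent 10 pg/mg needs ratio 0.10, i.e. analyte
        # peak height 10% of the IS height
        run = blank_run(quant_height=100.0, is_height=1000.0)
        verdict = interference_check(
            [run], cal_fit, lod=4.0,
            quantifier_id="quant", internal_standard_id="is", window=(20.0, 40.0),
        )
        assert not verdict.passed
        assert verdict.apparent_concentrations[0] == pytest.approx(10.0, rel=0.05)

    def test_qualifier_only_interference_passes_with_warning(self, cal_fit):
        run = blank_run(qual_height=500.0)
        verdict = interference_check(
            [run], cal_fit, lod=4.0,
            quantifier_id="quant", internal_standard_id="is", window=(20.0, 40.0),
            qualifier_ids=["qual"],
        )
        assert verdict.passed
        assert any("qual" in w for w in verdict.warnings)

    def test_missing_quantifier_trace_raises(self, cal_fit):
        run = {k: v for k, v in blank_run().items() if k != "quant"}
        with pytest.raises(HairEtgError):
            interference_check(
                [run], cal_fit, lod=4.0,
                quantifier_id="quant", internal_standard_id="is", window=(20.0, 40.0),
            )


class TestAssembleReport:
    def make_components(self, cal_fit):
        from hairetg import CalibrationModel

        table = simulate_calibration(CalibrationSimSpec(slope=0.01, noise_param=0.005, seed=2))
        res = CalibrationModel(table).fit()
        qc = [
            precision_trueness(
                qc_series_from_frame(
                    simulate_qc(QCSimSpec(nominal=nom, cv=0.08, seed=int(nom)))
                ),
                SCOPE_INTER_DAY,
            )
            for nom in (20.0, 30.0, 60.0)
        ]
        return res.calibration, res.linearity, qc

    def test_all_passing_components_pass(self, cal_fit):
        calibration, linearity, qc = self.make_components(cal_fit)
        report = assemble_report(
            calibration=calibration,
            linearity=linearity,
            lod_results=[LodResult(METHOD_SNR, 4.0)],
            loq=6.0,
            qc=qc,
        )
        assert report.overall_pass
        assert report.to_dict()["loq_pg_per_mg"] == 6.0
        assert "PASS" in report.summary()

    def test_undefined_loq_fails_with_reason(self, cal_fit):
        calibration, linearity, qc = self.make_components(cal_fit)
        report = assemble_report(calibration=calibration, linearity=linearity, loq=None, qc=qc)
        assert not report.overall_pass
        assert any("LOQ" in r for r in report.reasons)

    def test_missing_calibration_named(self):
        with pytest.raises(HairEtgError, match="calibration"):
            assemble_report(calibration=None)

    def test_report_internal_consistency(self, cal_fit):
        calibration, linearity, qc = self.make_components(cal_fit)
        report = assemble_report(calibration=calibration, linearity=linearity, loq=6.0, qc=qc)
        for r in report.qc:
            assert r.rsd_percent == pytest.approx(100 * r.sd / r.mean)
            assert r.bias_percent == pytest.approx(100 * (r.mean - r.nominal) / r.nominal)


def test_printed_validation_summaries_within_limits():
    """The packaged inter-day validation rows all sit inside the 15% RSD /
    20% bias acceptance window."""
    df = load_fixture("validation_table4")
    inter = df[df["scope"] == "inter_day"]
    assert (inter["rsd_percent_printed"] <= 15).all()
    assert (inter["bias_percent_printed"].abs() <= 20).all()
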