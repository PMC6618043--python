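import numpy as np
import pytest

from imsmetry import (
    ArrivalTimeDistribution,
    CcsResult,
    MeasurandRecord,
    atd_to_ccsd,
    ccsd_to_atd,
    find_centroid,
    format_notation,
    validate_report,
)
from imsmetry.errors import (
    DomainError,
    FormattingError,
    NoPeakError,
    ValidationError,
)
from imsmetry.synthetic import make_atd


class TestAtdContainer:
    def test_axis_must_be_monotone(self):
        with pytest.raises(DomainError):
            ArrivalTimeDistribution(axis=[1.0, 1.0, 2.0], intensity=[1, 2, 3])

    def test_axis_kind_must_name_what_was_measured(self):
        with pytest.raises(DomainError):
            ArrivalTimeDistribution(axis=[1.0, 2.0], intensity=[1, 2],
                                    axis_kind="drift time")

    def test_negative_intensity_rejected(self):
        with pytest.raises(DomainError):
            ArrivalTimeDistribution(axis=[1.0, 2.0], intensity=[1, -2])


class TestCentroid:
    def test_symmetric_gaussian_all_methods_agree(self):
        atd, truth = make_atd(centroid=10e-3, fwhm=1e-3, n_points=600, seed=1)
        bin_w = atd.axis[1] - atd.axis[0]
        for method in ("apex", "gaussian_fit", "weighted_mean"):
            peak = find_centroid(atd, method=method)
            assert peak.centroid == pytest.approx(truth["centroid"], abs=2 * bin_w)
        peak = find_centroid(atd, method="apex")
        assert peak.fwhm == pytest.approx(1e-3, rel=0.02)

    def test_apex_tie_broken_toward_lower_axis_and_flagged(self):
        atd = ArrivalTimeDistribution(axis=[1.0, 2.0, 3.0, 4.0],
                                      intensity=[1.0, 5.0, 5.0, 1.0])
        peak = find_centroid(atd, method="apex")
        assert peak.centroid == 2.0
        assert peak.diagnostics["apex_tie"]

    def test_skewed_peak_apex_below_weighted_mean(self):
        atd, truth = make_atd(centroid=10e-3, fwhm=1e-3, n_points=800, seed=2,
                              tail_tau=1.5e-3)
        apex = find_centroid(atd, method="apex").centroid
        wmean = find_centroid(atd, method="weighted_mean").centroid
        assert apex < wmean
        # oracle: brute-force evaluation on the same samples
        assert apex == atd.axis[np.argmax(atd.intensity)]
        assert wmean == pytest.approx(
            float(np.sum(atd.axis * atd.intensity) / np.sum(atd.intensity)),
            rel=1e-12)

    def test_flat_window_is_no_peak(self):
        atd = ArrivalTimeDistribution(axis=np.linspace(0, 1, 10),
                                      intensity=np.ones(10))
        with pytest.raises(NoPeakError):
            find_centroid(atd, method="apex")

    def test_two_conformers_resolved_when_well_separated(self):
        atd, _ = make_atd(centroid=10e-3, fwhm=1e-3, n_points=1200, seed=3,
                          second_peak=(14e-3, 1e-3, 800.0))
        p1 = find_centroid(atd, method="apex", window=(7e-3, 12e-3))
        p2 = find_centroid(atd, method="apex", window=(12e-3, 17e-3))
        assert p1.centroid == pytest.approx(10e-3, abs=5e-5)
        assert p2.centroid == pytest.approx(14e-3, abs=5e-5)


class TestCcsd:
    def _atd(self):
        # odd point count puts the peak on a sample (no apex tie)
        atd, _ = make_atd(centroid=8e-3, fwhm=0.8e-3, n_points=301, seed=4)
        return atd

    def test_intensity_conserved_under_linear_transform(self):
        atd = self._atd()
        ccsd = atd_to_ccsd(atd, lambda t: 3.2e4 * (t - 2e-4))
        assert ccsd.total_intensity() == pytest.approx(atd.total_intensity(),
                                                       rel=1e-12)

    def test_intensity_conserved_under_power_transform(self):
        atd = self._atd()
        ccsd = atd_to_ccsd(atd, lambda t: 1.8e4 * t**0.5)
        assert ccsd.total_intensity() == pytest.approx(atd.total_intensity(),
                                                       rel=1e-9)

    def test_round_trip_reproduces_original_bins(self):
        atd = self._atd()
        ccsd = atd_to_ccsd(atd, lambda t: 3.2e4 * (t - 2e-4))
        back = ccsd_to_atd(ccsd)
        assert np.allclose(back.axis, atd.axis)
        assert np.allclose(back.intensity, atd.intensity)

    def test_centroid_transforms_consistently(self):
        atd = self._atd()
        transform = lambda t: 3.2e4 * (t - 2e-4)
        ccsd = atd_to_ccsd(atd, transform)
        apex_t = find_centroid(atd, method="apex").centroid
        apex_c = find_centroid(ccsd, method="apex").centroid
        assert apex_c == pytest.approx(float(transform(np.array([apex_t]))[0]),
                                       rel=1e-9)

    def test_mixed_charges_refused(self):
        with pytest.raises(DomainError):
            atd_to_ccsd(self._atd(), lambda t: 1e4 * t, charge_states=(1, 2))

    def test_output_labeled_apparent(self):
        ccsd = atd_to_ccsd(self._atd(), lambda t: 1e4 * t)
        assert ccsd.metadata["label"] == "apparent CCSD"
        assert ccsd.axis_kind == "ccs"


class TestNotation:
    def test_primary_drift_tube_helium(self):
        ccs = CcsResult(value=205.0, gas="He", method="DT", primary=True)
        assert format_notation(ccs) == "^DT,1ry^CCS_He"

    def test_with_temperature(self):
        ccs = CcsResult(value=205.0, gas="He", method="DT", primary=True,
                        temperature=298.0)
        assert format_notation(ccs, include_temperature=True) == "^DT,1ry^CCS_He,298"

    def test_calibrated_crossover(self):
        ccs = CcsResult(value=300.0, gas="N2", method="TW", primary=False,
                        calibration_gas="He")
        assert format_notation(ccs) == "^TW^CCS_N2->He"

    def test_same_gas_calibration_no_crossover(self):
        ccs = CcsResult(value=300.0, gas="N2", method="TW", primary=False,
                        calibration_gas="N2")
        assert format_notation(ccs) == "^TW^CCS_N2"

    def test_secondary_without_provenance_rejected(self):
        ccs = CcsResult(value=300.0, gas="N2", method="TW", primary=False)
        with pytest.raises(FormattingError):
            format_notation(ccs)

    def test_injective_over_provenance_tuples(self):
        variants = [
            CcsResult(value=1.0, gas="He", method="DT", primary=True),
            CcsResult(value=1.0, gas="He", method="DT", primary=False),
            CcsResult(value=1.0, gas="N2", method="DT", primary=True),
            CcsResult(value=1.0, gas="N2", method="TW", primary=False,
                      calibration_gas="He"),
            CcsResult(value=1.0, gas="N2", method="TW", primary=False,
                      calibration_gas="N2"),
            CcsResult(value=1.0, gas="N2", method="TIMS", primary=False,
                      calibration_gas="N2"),
        ]
        rendered = [format_notation(c) for c in variants]
        assert len(set(rendered)) == len(rendered)


class TestValidation:
    def _full_dtims(self):
        return MeasurandRecord(fields={
            "sample_preparation": "10 uM in 100 mM NH4OAc",
            "ionization": "nano-ESI positive",
            "gas_identity": "N2", "gas_purity": "99.999%",
            "temperature": 298.0, "instrument_model": "in-house tube",
            "mz_selection_range": [500, 2000], "mz_extraction_range": [980, 1020],
            "pressure": 530.0, "drift_length": 0.78,
            "drift_voltages": [600, 2000], "e_over_n": 8.5,
            "isotopologue_scope": "monoisotopic",
        })

    def test_complete_record_passes(self):
        report = validate_report(self._full_dtims(), "dtims")
        assert report["passed"] and report["findings"] == []

    def test_missing_twims_wave_velocity_fails(self):
        rec = self._full_dtims()
        rec.fields.update({"wave_height": 40.0, "pressures": {"He": 180, "N2": 320},
                           "calibrant_list": ["polyalanine"]})
        report = validate_report(rec, "twims")
        fields = [f["field"] for f in report["findings"]]
        assert not report["passed"] and "wave_velocity" in fields

    def test_faims_peak_to_peak_amplitude_rejected(self):
        rec = MeasurandRecord(fields={"dispersion_voltage_peak_to_peak": 8000.0})
        report = validate_report(rec, "faims")
        reasons = " ".join(f["reason"] for f in report["findings"])
        assert "zero-to-peak" in reasons

    def test_findings_monotone_in_fields(self):
        rec = MeasurandRecord(fields={})
        before = {f["field"] for f in validate_report(rec, "dtims")["findings"]}
        rec.fields["temperature"] = 296.0
        after = {f["field"] for f in validate_report(rec, "dtims")["findings"]}
        assert after == before - {"temperature"}

    def test_empty_record_never_passes(self):
        assert not validate_report(MeasurandRecord(fields={}), "tims")["passed"]

    def test_unknown_platform(self):
        with pytest.raises(ValidationError):
            validate_report(MeasurandRecord(fields={}), "orbitrap")
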