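"""Cooling-curve inversion, case aggregation and error statistics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermopmi.pmi import (MeasurementRecord, ReconstructionError,
                           bin_by_delta_t, reconstruct_case, reconstruct_pmi,
                           summarize_errors)
from thermopmi.thermo import CoolingCurve


def linear_curve(site="chest", t_end=10.0, t0=37.0, slope=-1.0, n=601):
    t = np.linspace(0.0, t_end, n)
    return CoolingCurve(site, (), t, t0 + slope * t)


class TestReconstructPMI:
    def test_round_trip_on_every_sample(self, sphere_case):
        curve = sphere_case["curve"]
        for i in range(0, len(curve.times_h), 37):
            est = reconstruct_pmi(curve, float(curve.temps_C[i]))
            assert est.pmi_h == curve.times_h[i]
            assert est.min_residual_C == 0.0

    def test_interpolates_between_samples(self):
        curve = linear_curve()
        est = reconstruct_pmi(curve, 37.0 - 3.141)
        assert est.pmi_h == pytest.approx(3.141, abs=1e-9)
        assert est.status == "ok"

    def test_measured_above_curve_maximum_is_out_of_range(self):
        curve = linear_curve()
        est = reconstruct_pmi(curve, 42.0, tolerance_C=0.5)
        assert est.status == "out_of_range"
        assert est.pmi_h == 0.0

    def test_tie_resolves_to_earliest_time(self):
        curve = CoolingCurve("chest", (), np.array([0.0, 1.0, 2.0, 3.0]),
                             np.array([30.0, 25.0, 25.0, 20.0]))
        est = reconstruct_pmi(curve, 25.0)
        assert est.pmi_h == 1.0

    def test_flat_tail_flagged_near_equilibrium(self):
        t = np.linspace(0, 20, 1201)
        temps = 20.0 + 17.0 * np.exp(-t / 2.0)
        curve = CoolingCurve("chest", (), t, temps)
        est = reconstruct_pmi(curve, float(curve(18.0)))
        assert est.status == "near_equilibrium"
        est_early = reconstruct_pmi(curve, float(curve(1.0)))
        assert est_early.status == "ok"


class TestReconstructCase:
    @staticmethod
    def _records(pmis, clock="2021-03-01T12:00", curve=None):
        curve = curve or linear_curve()
        return [MeasurementRecord("chest", pd.Timestamp(clock),
                                  float(curve(p)), 20.0) for p in pmis]

    def test_hand_median_and_mad(self):
        curves = {"chest": linear_curve()}
        case = reconstruct_case(curves, self._records([4.0, 5.0, 6.0]))
        assert case.median_pmi_h == pytest.approx(5.0, abs=1e-9)
        assert case.mad_h == pytest.approx(1.0, abs=1e-9)

    def test_single_record(self):
        curves = {"chest": linear_curve()}
        case = reconstruct_case(curves, self._records([7.25]))
        assert case.median_pmi_h == pytest.approx(7.25, abs=1e-9)
        assert case.mad_h == 0.0

    def test_clock_referencing_across_measurement_times(self):
        # Two measurements of the same death taken an hour apart must agree
        # on the time of death.
        curve = linear_curve()
        recs = [
            MeasurementRecord("chest", pd.Timestamp("2021-03-01T10:00"),
                              float(curve(4.0)), 20.0),
            MeasurementRecord("chest", pd.Timestamp("2021-03-01T11:00"),
                              float(curve(5.0)), 20.0),
        ]
        case = reconstruct_case({"chest": curve}, recs)
        assert case.median_pmi_h == pytest.approx(5.0, abs=1e-6)
        assert case.time_of_death == pd.Timestamp("2021-03-01T06:00")
        assert case.mad_h == pytest.approx(0.0, abs=1e-6)

    def test_permutation_invariance(self):
        curves = {"chest": linear_curve()}
        recs = self._records([2.0, 9.0, 4.5, 7.0])
        a = reconstruct_case(curves, recs)
        b = reconstruct_case(curves, list(reversed(recs)))
        assert a.median_pmi_h == b.median_pmi_h
        assert a.mad_h == b.mad_h
        assert a.time_of_death == b.time_of_death

    def test_all_out_of_range_raises(self):
        curves = {"chest": linear_curve(t_end=5.0)}
        recs = [MeasurementRecord("chest", pd.Timestamp("2021-03-01"),
                                  50.0, 20.0)]
        with pytest.raises(ReconstructionError, match="out of range"):
            reconstruct_case(curves, recs)

    def test_missing_curve_site_raises(self):
        with pytest.raises(ReconstructionError, match="abdomen"):
            reconstruct_case(
                {"chest": linear_curve()},
                [MeasurementRecord("abdomen", pd.Timestamp("2021-03-01"),
                                   30.0, 20.0)])


class TestSummarizeErrors:
    def test_perfect_reconstruction(self):
        out = summarize_errors([("chest", 5.0, 5.0), ("thigh", 8.0, 8.0)])
        assert out.pooled_mean_h == 0.0
        assert out.pooled_fraction_within_2p8h == 1.0

    def test_hand_mean_and_sample_sd(self):
        out = summarize_errors([("chest", 6.0, 5.0), ("chest", 4.0, 5.0)])
        assert out.pooled_mean_h == 0.0
        assert out.pooled_sd_h == pytest.approx(np.sqrt(2.0))

    def test_recovery_sd_consistent_with_noise_over_slope(self, recovery_case):
        # sigma_PMI ~ sigma_T / |dT/dt|: the pooled error spread should be
        # within a factor 2 of the propagated sensor noise for well-
        # conditioned samples (dT >= 5 deg C).
        curves = recovery_case.result.curves_by_site()
        triples, predicted = [], []
        for rec, (_, tr) in zip(recovery_case.records,
                                recovery_case.truth.iterrows()):
            if rec.delta_t_C < 5.0:
                continue
            est = reconstruct_pmi(curves[rec.site], rec.skin_temp_C)
            triples.append((rec.site, est.pmi_h, tr.true_pmi_h))
            predicted.append(0.2 / abs(est.slope_C_per_h))
        out = summarize_errors(triples)
        pred = float(np.median(predicted))
        assert pred / 2 <= out.pooled_sd_h <= pred * 2
        assert abs(out.pooled_mean_h) < 1.0


class TestBinByDeltaT:
    def test_single_bin_pools_everything(self):
        bins = bin_by_delta_t([(3.0, 0.5), (3.5, -0.5)], bin_width_C=5.0)
        assert len(bins) == 1
        assert bins[0].n == 2
        assert bins[0].mean_dpmi_h == 0.0

    def test_edge_value_goes_to_upper_bin(self):
        bins = bin_by_delta_t([(5.0, 1.0), (4.999, 2.0)], bin_width_C=5.0)
        assert [b.n for b in bins] == [1, 1]
        assert bins[1].lo_C == 5.0
        assert bins[1].members_h[0] == 1.0

    def test_every_member_in_exactly_one_bin(self):
        rng = np.random.default_rng(3)
        data = [(float(dt), float(d)) for dt, d in
                zip(rng.uniform(-2, 20, 100), rng.normal(0, 1, 100))]
        bins = bin_by_delta_t(data, bin_width_C=2.5)
        assert sum(b.n for b in bins) == 100

    def test_recovery_error_grows_towards_equilibrium(self, recovery_case):
        # Mirror of the dT-dependence analysis: reconstruction error in the
        # smallest dT band exceeds that of well-separated samples.
        curves = recovery_case.result.curves_by_site()
        pairs = []
        for rec, (_, tr) in zip(recovery_case.records,
                                recovery_case.truth.iterrows()):
            est = reconstruct_pmi(curves[rec.site], rec.skin_temp_C)
            pairs.append((rec.delta_t_C, est.pmi_h - tr.true_pmi_h))
        bins = bin_by_delta_t(pairs, bin_width_C=2.0)
        low = [b for b in bins if b.hi_C <= 2.0]
        high = [b for b in bins if b.lo_C >= 4.0]
        worst_low = max(abs(b.mean_dpmi_h) for b in low)
        best_high = min(abs(b.mean_dpmi_h) for b in high)
        assert worst_low > best_high


@given(st.lists(st.floats(min_value=0.5, max_value=9.5), min_size=2,
                max_size=8))
def test_case_median_within_member_range(pmis):
    """The case median PMI always lies inside the span of member PMIs."""
    curve = linear_curve()
    recs = [MeasurementRecord("chest", pd.Timestamp("2021-03-01T12:00"),
                              float(curve(p)), 20.0) for p in pmis]
    case = reconstruct_case({"chest": curve}, recs)
    assert min(pmis) - 1e-6 <= case.median_pmi_h <= max(pmis) + 1e-6
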