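import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phenolatency as ph
from phenolatency.between_season import (
    SeasonSeries,
    SeasonSummary,
    equilibrate,
    next_cohort,
)


class TestNextCohort:
    def test_extinction_absorbing(self, semel_params):
        assert next_cohort(0.0, 0.0, 0.0, semel_params) == 0.0

    def test_printed_map_value(self, semel_params):
        p = semel_params.replace(phi=1.0)
        got = next_cohort(1e6, 0.0, 0.0, p)
        assert got == pytest.approx(200 * 1e6 / (1 + 100), rel=1e-12)
        assert got == pytest.approx(1.9802e6, rel=1e-4)

    def test_fecundity_retention(self, semel_params):
        # ever-infected hosts reproduce at a fraction phi but crowd fully
        p = semel_params.replace(phi=0.5)
        got = next_cohort(1e6, 0.0, 1e6, p)
        assert got == pytest.approx(200 * (1e6 + 0.5e6) / (1 + 1e-4 * 2e6))

    def test_iteroparous_counts_infectious(self, itero_params):
        p = itero_params.replace(phi=0.5)
        got = next_cohort(1e6, 2e5, 1e5, p)
        expected = 200 * (1e6 + 0.5 * 2e5 + 0.5 * 1e5) / (1 + 1e-4 * 1.3e6)
        assert got == pytest.approx(expected)

    def test_fixed_cohort_mode(self, semel_params):
        p = semel_params.replace(demography_mode="fixed-cohort")
        assert next_cohort(123.0, 0.0, 456.0, p) == p.s_hat_const

    def test_negative_inputs_rejected(self, semel_params):
        with pytest.raises(ValueError):
            next_cohort(-1.0, 0.0, 0.0, semel_params)

    @given(s=st.floats(0, 1e9), ds=st.floats(1.0, 1e8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_saturating(self, s, ds):
        p = ph.default_parameters("semelparous")
        assert next_cohort(s + ds, 0.0, 0.0, p) > next_cohort(s, 0.0, 0.0, p)
        assert next_cohort(s, 0.0, 0.0, p) <= p.sigma / p.rho


class TestDiseaseFreeFixedPoint:
    def test_closed_form(self, semel_params):
        k = ph.disease_free_cohort_factor(semel_params)
        assert k == pytest.approx(0.41795, abs=1e-5)
        assert ph.disease_free_fixed_point(semel_params) == pytest.approx(
            1.976e6, rel=1e-3
        )

    def test_iterating_map_reaches_closed_form(self, semel_params):
        """No parasites: seasons drive s_hat to the Beverton-Holt fixed
        point from any positive start (global stability)."""
        target = ph.disease_free_fixed_point(semel_params)
        rng = np.random.default_rng(7)
        for s0 in rng.uniform(1e3, 5e7, size=5):
            state = ph.SeasonState(0, float(s0), np.array([0.0]))
            series, _ = ph.run_seasons(state, np.array([1.0]), semel_params, 200)
            assert series.final.s_hat == pytest.approx(target, rel=1e-3)

    def test_host_extinction_when_fecundity_too_low(self, semel_params):
        p = semel_params.replace(sigma=2.0)  # sigma * k < 1
        assert ph.disease_free_fixed_point(p) == 0.0


class TestRunSeasons:
    def test_transmission_free_strain_decays_and_goes_extinct(self, semel_params):
        p = semel_params.replace(beta=0.0)
        state = ph.SeasonState(0, 1e7, np.array([50.0]))
        series, _ = ph.run_seasons(state, np.array([1.0]), p, 5)
        first = series.summaries[0]
        assert first.v_T[0] / first.v_hat[0] == pytest.approx(
            np.exp(-p.delta * p.T), rel=1e-6
        )
        # 50 * exp(-4) < 1, so the strain is removed at the next boundary
        assert series.v_hat[1:, 0].max() == 0.0

    def test_equilibration_semelparous_monocyclic(self, semel_params):
        """The tau=2.8 resident reaches an ecological fixed point."""
        state, info = equilibrate(np.array([2.8]), semel_params)
        assert info["converged"] and not info["extinct"]
        assert info["residual"] < 1e-6
        # regression values for the attractor (package's own numbers)
        assert state.strain_densities[0] == pytest.approx(3.309e7, rel=1e-2)
        assert state.s_hat == pytest.approx(9.928e5, rel=1e-2)

    def test_cost_free_infection_recovers_disease_free_host_demography(
        self, semel_params
    ):
        """phi=1 with equal death rates: infection carries no demographic
        cost, so the host settles within a fraction of a percent of the
        disease-free fixed point (the residual gap is the latent cohort at
        season end, which the recruitment map does not see)."""
        p = semel_params.replace(phi=1.0)
        state, info = equilibrate(np.array([2.8]), p)
        assert info["converged"]
        assert state.s_hat == pytest.approx(
            ph.disease_free_fixed_point(p), rel=5e-3
        )


def _series_from_vhat(vhat):
    summaries = [
        SeasonSummary(
            season=i, s_hat=1.0, s_T=1.0, r_T=0.0, i_T=0.0,
            v_hat=np.array([v]), v_T=np.array([v]),
        )
        for i, v in enumerate(vhat)
    ]
    return SeasonSeries(
        taus=np.array([1.0]),
        summaries=summaries,
        params=ph.default_parameters("semelparous"),
    )


class TestAttractorClassification:
    def test_constant_series_is_fixed_point(self):
        series = _series_from_vhat(np.full(450, 3.14))
        report = ph.classify_attractor(series, burn_in=400)
        assert report.kind == "fixed-point"
        assert report.residual == 0.0

    def test_two_cycle_detected_with_period(self):
        series = _series_from_vhat(np.tile([1.0, 2.0], 250))
        report = ph.classify_attractor(series, burn_in=400)
        assert report.kind == "cycle"
        assert report.period == 2

    def test_short_series_rejected(self):
        series = _series_from_vhat(np.ones(100))
        with pytest.raises(ValueError):
            ph.classify_attractor(series, burn_in=400)

    def test_report_serializes(self):
        series = _series_from_vhat(np.full(450, 2.0))
        text = ph.classify_attractor(series, burn_in=400).to_json()
        assert '"fixed-point"' in text


class TestExport:
    def test_season_series_frame(self, semel_params):
        state = ph.SeasonState(0, 1e6, np.array([1e5, 2e5]))
        series, _ = ph.run_seasons(state, np.array([1.0, 2.0]), semel_params, 3)
        df = series.to_frame()
        assert len(df) == 3 * 2
        assert {"season", "strain_id", "tau", "s_hat", "v_hat", "v_T"} <= set(df.columns)
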