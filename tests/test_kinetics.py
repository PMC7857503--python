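"""Stopped-flow kinetic fitting and rate-constant derivation."""

import math

import numpy as np
import pytest

from lipbind.errors import (
    AlignmentError,
    InsufficientDataError,
    NonPositiveRateError,
)
from lipbind.kinetics import (
    KineticTrace,
    association_rate_constant,
    average_replicate_traces,
    fit_association,
    fit_dissociation,
    normalize_trace,
)
from lipbind.synthetic import simulate_kinetic_trace, simulate_replicate_traces
from lipbind.titration import PartitioningInputs


def stopped_flow_inputs(accessible=37.5):
    return PartitioningInputs(accessible_lipid=accessible)


class TestAveraging:
    def test_identical_traces_idempotent(self):
        tr, _ = simulate_kinetic_trace("association", rates=[30.0], noise_sd=0.0)
        avg = average_replicate_traces([tr, tr])
        assert np.allclose(avg.signal, tr.signal)
        assert avg.n_replicates_averaged == 2

    def test_symmetric_noise_cancels(self):
        tr, _ = simulate_kinetic_trace("association", rates=[30.0], noise_sd=0.0)
        eps = np.sin(np.arange(tr.time.size))
        up = tr.with_signal(tr.signal + eps)
        down = tr.with_signal(tr.signal - eps)
        avg = average_replicate_traces([up, down])
        assert np.allclose(avg.signal, tr.signal, atol=1e-12)

    def test_variance_reduction_eight_replicates(self):
        """Averaging n=8 replicates reduces noise variance ~ sigma^2/8."""
        sigma = 0.05
        ratios = []
        for seed in range(50):
            traces, truth = simulate_replicate_traces(
                8, seed=seed * 100, model="association", rates=[30.0],
                noise_sd=sigma, duration=0.3, dt=1e-3,
            )
            avg = average_replicate_traces(traces)
            resid = avg.signal - truth.values["clean_signal"]
            ratios.append(np.var(resid) / sigma**2)
        assert abs(np.mean(ratios) - 1 / 8) < 0.3 / 8

    def test_mismatched_time_base_rejected(self):
        a, _ = simulate_kinetic_trace("association", duration=0.1)
        b, _ = simulate_kinetic_trace("association", duration=0.1, dt=2e-3)
        with pytest.raises(AlignmentError):
            average_replicate_traces([a, b])

    def test_dead_time_is_max(self):
        a, _ = simulate_kinetic_trace("association", dead_time=1.4e-3)
        b, _ = simulate_kinetic_trace("association", dead_time=2.0e-3)
        assert average_replicate_traces([a, b]).dead_time == 2.0e-3


class TestAssociation:
    def test_noiseless_round_trip(self):
        tr, _ = simulate_kinetic_trace(
            "association", rates=[30.0], amplitudes=[1.0], noise_sd=0.0
        )
        fit = fit_association(tr)
        assert fit.k_obs == pytest.approx(30.0, rel=1e-3)
        assert fit.delta_f_max == pytest.approx(1.0, rel=1e-3)

    def test_closed_form_identities(self):
        tr, _ = simulate_kinetic_trace("association", rates=[30.0], noise_sd=0.0)
        fit = fit_association(tr)
        t1 = 1.0 / fit.k_obs
        assert fit.predict([t1])[0] - fit.offset_c == pytest.approx(
            fit.delta_f_max * (1 - math.exp(-1)), rel=1e-9
        )
        t_half = math.log(2) / fit.k_obs
        assert fit.predict([t_half])[0] - fit.offset_c == pytest.approx(
            fit.delta_f_max / 2, rel=1e-9
        )

    def test_dead_time_points_ignored(self):
        tr, _ = simulate_kinetic_trace(
            "association", rates=[30.0], noise_sd=0.0, dead_time=5e-3
        )
        corrupted = tr.signal.copy()
        corrupted[tr.time < tr.dead_time] = 99.0
        fit_clean = fit_association(tr)
        fit_corrupt = fit_association(tr.with_signal(corrupted))
        assert fit_corrupt.k_obs == pytest.approx(fit_clean.k_obs, rel=1e-12)


class TestDissociation:
    def test_noiseless_biexponential_round_trip(self):
        tr, _ = simulate_kinetic_trace(
            "dissociation", rates=[1.0, 0.14], amplitudes=[0.35, 0.65],
            duration=30.0, dt=0.01, noise_sd=0.0,
        )
        fit = fit_dissociation(tr, model="double")
        assert fit.rates[0] == pytest.approx(1.0, rel=5e-3)
        assert fit.rates[1] == pytest.approx(0.14, rel=5e-3)
        assert fit.amplitude_fractions[0] == pytest.approx(35.0, rel=5e-3)
        assert fit.amplitude_fractions[1] == pytest.approx(65.0, rel=5e-3)

    def test_amplitude_fractions_sum_to_100(self):
        tr, _ = simulate_kinetic_trace(
            "dissociation", rates=[2.0, 0.3], amplitudes=[0.4, 0.6],
            duration=20.0, dt=0.01, noise_sd=0.01,
        )
        fit = fit_dissociation(tr, model="double")
        assert sum(fit.amplitude_fractions) == pytest.approx(100.0, abs=1e-6)

    def test_auto_selects_single_on_single_data(self):
        for seed in range(10):
            tr, _ = simulate_kinetic_trace(
                "dissociation", rates=[1.0], amplitudes=[1.0],
                duration=10.0, dt=0.01, noise_sd=0.0, seed=seed,
            )
            assert fit_dissociation(tr, model="auto").model == "single"

    def test_auto_selects_double_on_biexponential_data(self):
        hits = 0
        for seed in range(20):
            tr, _ = simulate_kinetic_trace(
                "dissociation", rates=[1.0, 0.14], amplitudes=[0.35, 0.65],
                duration=30.0, dt=0.01, noise_sd=0.01, seed=seed,
            )
            hits += fit_dissociation(tr, model="auto").model == "double"
        assert hits >= 19

    def test_rates_fast_first(self):
        tr, _ = simulate_kinetic_trace(
            "dissociation", rates=[0.2, 3.0], amplitudes=[0.5, 0.5],
            duration=20.0, dt=0.01, noise_sd=0.0,
        )
        fit = fit_dissociation(tr, model="double")
        assert fit.rates[0] > fit.rates[1]

    def test_too_short_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_dissociation(
                KineticTrace(time=np.arange(5) * 0.01 + 0.01,
                             signal=np.exp(-np.arange(5.0)), dead_time=0.0)
            )


class TestRateConstant:
    def test_printed_worked_value(self):
        """k_obs=30/s, fast k_off=1.0/s, 37.5 uM accessible lipid after
        1:1 mixing -> k_on,x = 43e6 at 2 s.f."""
        res = association_rate_constant(30.0, 1.0, stopped_flow_inputs())
        assert res.kon_x == pytest.approx(42.92e6, rel=1e-3)
        assert round(res.kon_x / 1e6) == 43

    def test_zero_koff_limit(self):
        inputs = stopped_flow_inputs()
        res = association_rate_constant(30.0, 0.0, inputs)
        assert res.kon_x == pytest.approx(
            30.0 * inputs.water_molarity * 1e6 / inputs.accessible_lipid
        )

    def test_unit_ratio(self):
        inputs = PartitioningInputs(water_molarity=1e-6 * 40.0, accessible_lipid=40.0)
        res = association_rate_constant(30.0, 1.0, inputs)
        assert res.kon_x == pytest.approx(29.0)

    def test_linearity_and_lipid_scaling(self):
        a = association_rate_constant(10.0, 1.0, stopped_flow_inputs()).kon_x
        b = association_rate_constant(19.0, 1.0, stopped_flow_inputs()).kon_x
        c = association_rate_constant(28.0, 1.0, stopped_flow_inputs()).kon_x
        assert c - b == pytest.approx(b - a, rel=1e-9)
        half = association_rate_constant(10.0, 1.0, stopped_flow_inputs(75.0)).kon_x
        assert half == pytest.approx(a / 2, rel=1e-12)

    def test_kobs_below_koff_rejected(self):
        with pytest.raises(NonPositiveRateError):
            association_rate_constant(1.0, 2.0, stopped_flow_inputs())


class TestNormalisation:
    def test_normalised_dissociation_extrapolates_to_one(self):
        tr, _ = simulate_kinetic_trace(
            "dissociation", rates=[1.0, 0.14], amplitudes=[0.7, 1.3],
            offset=0.2, duration=30.0, dt=0.01, noise_sd=0.0,
        )
        fit = fit_dissociation(tr, model="double")
        norm = normalize_trace(tr, fit)
        assert norm.signal[0] == pytest.approx(1.0, abs=1e-3)

    def test_refit_after_normalisation_same_rates(self):
        tr, _ = simulate_kinetic_trace(
            "dissociation", rates=[1.0, 0.14], amplitudes=[0.35, 0.65],
            offset=0.1, duration=30.0, dt=0.01, noise_sd=0.0,
        )
        fit = fit_dissociation(tr, model="double")
        refit = fit_dissociation(normalize_trace(tr, fit), model="double")
        assert refit.rates[0] == pytest.approx(fit.rates[0], rel=1e-6)
        assert refit.rates[1] == pytest.approx(fit.rates[1], rel=1e-6)
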