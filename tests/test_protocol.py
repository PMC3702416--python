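"""The viability protocol: simulation, classification, bootstrap, objective."""

import numpy as np
import pytest

from phenofit.model import SimulationTrace
from phenofit.parameters import StrainSpec
from phenofit.protocol import (
    INDETERMINATE,
    INVIABLE,
    VIABLE,
    PhenotypeCall,
    ProtocolSettings,
    check_event_order,
    classify_viability,
    evaluate_objective,
    simulate_strain,
    wt_bootstrap,
)


def _trace(sizes, blew_up=False, nonfinite=False):
    sizes = np.asarray(sizes, dtype=float)
    times = 50.0 * (1 + np.arange(len(sizes)))
    return SimulationTrace(
        division_times=times,
        division_sizes=sizes,
        blew_up=blew_up,
        nonfinite=nonfinite,
        t_end=2000.0,
        final_state=np.zeros(3),
    )


class TestClassification:
    def test_blowup_is_inviable(self, protocol_settings):
        call = classify_viability(_trace([], blew_up=True), protocol_settings)
        assert call == PhenotypeCall(INVIABLE, "mass_blowup")

    def test_blowup_short_circuits_division_history(self, protocol_settings):
        # many converged divisions, but the trace ended in blow-up
        call = classify_viability(_trace([2.0, 2.0, 2.0, 2.0], blew_up=True), protocol_settings)
        assert call.call == INVIABLE

    def test_converged_sizes_within_5pct_are_viable(self, protocol_settings):
        call = classify_viability(_trace([2.2, 2.00, 2.02, 1.98]), protocol_settings)
        assert call == PhenotypeCall(VIABLE, "size_converged")

    def test_alternating_sizes_are_period_doubling(self, protocol_settings):
        call = classify_viability(_trace([2.4, 2.0, 2.4, 2.0]), protocol_settings)
        assert call == PhenotypeCall(INDETERMINATE, "period_doubling")

    def test_too_few_divisions_indeterminate(self, protocol_settings):
        call = classify_viability(_trace([2.0, 2.0]), protocol_settings)
        assert call == PhenotypeCall(INDETERMINATE, "insufficient_divisions")

    def test_nonfinite_is_inviable_with_diagnostic(self, protocol_settings):
        call = classify_viability(_trace([], nonfinite=True), protocol_settings)
        assert call == PhenotypeCall(INVIABLE, "numerical_failure")

    def test_tolerance_is_relative_to_earlier_size(self, protocol_settings):
        # 4.9% relative deviation passes, 5.1% fails: the denominator is the
        # earlier division's size
        assert classify_viability(_trace([2.0, 2.0, 2.098]), protocol_settings).call == VIABLE
        assert classify_viability(_trace([2.0, 2.0, 2.102]), protocol_settings).call != VIABLE

    def test_indeterminate_matches_no_observed_phenotype(self):
        call = PhenotypeCall(INDETERMINATE, "period_doubling")
        assert not call.matches(VIABLE) and not call.matches(INVIABLE)


class TestSimulateStrain:
    def test_zero_growth_keeps_mass_constant(self, clock_model, protocol_settings):
        params = clock_model.wt_params.with_updates({"g": 0.0, "f": 1.0})
        trace = simulate_strain(
            clock_model, params, clock_model.initial_state(params.values), protocol_settings
        )
        assert not trace.blew_up
        assert clock_model.mass_of(trace.final_state) == pytest.approx(1.0)
        assert np.allclose(trace.division_sizes, 1.0)

    def test_mass_limit_stops_early_with_blowup_flag(self, clock_model):
        # strong growth with no mass partition: blow-up before 3 divisions
        params = clock_model.wt_params.with_updates({"g": 0.1, "f": 1.0})
        settings = ProtocolSettings()
        trace = simulate_strain(
            clock_model, params, clock_model.initial_state(params.values), settings
        )
        assert trace.blew_up
        assert trace.t_end < settings.horizon
        assert trace.n_divisions < 3

    def test_clock_division_times_are_exact(self, clock_model, protocol_settings):
        params = clock_model.wt_params
        trace = simulate_strain(
            clock_model, params, clock_model.initial_state(params.values), protocol_settings
        )
        # u0 = 40 crosses period/2 = 25 at t = 15, then every 50 min
        expected = 15.0 + 50.0 * np.arange(trace.n_divisions)
        assert np.allclose(trace.division_times, expected, atol=protocol_settings.dt)
        assert classify_viability(trace, protocol_settings).call == VIABLE


class TestBootstrap:
    def test_deterministic(self, toy, protocol_settings):
        model, wt = toy
        call1, ics1 = wt_bootstrap(model, wt, protocol_settings)
        call2, ics2 = wt_bootstrap(model, wt, protocol_settings)
        assert call1 == call2
        assert np.array_equal(ics1, ics2)

    def test_newborn_ics_differ_from_input_ics(self, toy, protocol_settings):
        model, wt = toy
        call, ics = wt_bootstrap(model, wt, protocol_settings)
        assert call.call == VIABLE
        assert not np.allclose(ics, model.initial_state(wt.values))

    def test_inviable_wt_returns_default_ics(self, toy, protocol_settings):
        model, wt = toy
        dead = wt.with_updates({"ks_x": 0.0, "ka_x": 0.0})
        call, ics = wt_bootstrap(model, dead, protocol_settings)
        assert call.call != VIABLE
        assert np.array_equal(ics, model.default_ics)

    def test_configured_default_ics_override(self, toy):
        model, wt = toy
        custom = np.array([0.01, 0.5, 2.5])
        settings = ProtocolSettings(default_ics=custom)
        dead = wt.with_updates({"ks_x": 0.0, "ka_x": 0.0})
        _, ics = wt_bootstrap(model, dead, settings)
        assert np.array_equal(ics, custom)


class TestObjective:
    def test_perfect_score_at_ground_truth(self, toy, protocol_settings):
        model, wt = toy
        res = evaluate_objective(model, wt, protocol_settings)
        assert res.objective == len(model.strains)
        assert all(b == 1 for b in res.bits.values())

    def test_flipping_observed_label_flips_bit(self, toy, protocol_settings):
        model, wt = toy
        flipped = [
            StrainSpec(
                s.strain_id,
                INVIABLE if s.observed == VIABLE else VIABLE,
                s.transformations,
            )
            for s in model.strains
        ]
        model2 = type(model)(panel=flipped)
        res = evaluate_objective(model2, wt, protocol_settings)
        assert res.objective == 0

    def test_objective_invariant_to_strain_order(self, toy, protocol_settings):
        model, wt = toy
        reversed_model = type(model)(panel=list(reversed(model.strains)))
        a = evaluate_objective(model, wt, protocol_settings)
        b = evaluate_objective(reversed_model, wt, protocol_settings)
        assert a.objective == b.objective
        assert a.bits == b.bits

    def test_selection_subset_restricts_sum(self, toy, protocol_settings):
        model, wt = toy
        ids = [s.strain_id for s in model.strains][:5]
        res = evaluate_objective(model, wt, protocol_settings, selection=ids)
        assert res.objective == 5  # ground truth captures everything
        assert len(res.bits) == len(model.strains)  # full bits still reported

    def test_objective_bounded(self, toy, protocol_settings):
        model, wt = toy
        bad = wt.with_updates({"ka_x": 0.0})
        res = evaluate_objective(model, bad, protocol_settings)
        assert 0 <= res.objective <= len(model.strains)

    def test_empty_strain_table_rejected(self, toy, protocol_settings):
        model, wt = toy
        empty = type(model)(panel=[])
        with pytest.raises(ValueError):
            evaluate_objective(empty, wt, protocol_settings)


class TestEventOrder:
    def _trace_with_events(self, events):
        return SimulationTrace(
            division_times=np.asarray(events.get("division", [])),
            division_sizes=np.asarray(events.get("division", [])),
            blew_up=False,
            nonfinite=False,
            t_end=2000.0,
            final_state=np.zeros(3),
            event_times={k: np.asarray(v, dtype=float) for k, v in events.items()},
        )

    def test_sorted_events_ok(self):
        trace = self._trace_with_events(
            {"start": [10.0, 110.0], "division": [50.0, 150.0]}
        )
        ok, violations = check_event_order(trace, ["start", "division"])
        assert ok and violations == []

    def test_swapped_events_single_violation(self):
        trace = self._trace_with_events(
            {"start": [60.0, 110.0], "division": [50.0, 150.0]}
        )
        ok, violations = check_event_order(trace, ["start", "division"])
        assert not ok
        assert len(violations) == 1

    def test_missing_event_reported(self):
        trace = self._trace_with_events({"division": [50.0]})
        ok, violations = check_event_order(trace, ["start", "division"])
        assert not ok
        assert any("missing" in v for v in violations)

    def test_toy_wt_order_holds_every_cycle(self, toy, protocol_settings):
        model, wt = toy
        trace = simulate_strain(
            model, wt, model.initial_state(wt.values), protocol_settings
        )
        ok, violations = check_event_order(trace, ["start", "division"])
        assert ok, violations


def test_fast_and_generic_paths_agree(toy, protocol_settings):
    model, wt = toy
    ics = model.initial_state(wt.values)
    fast = simulate_strain(model, wt, ics, protocol_settings)
    generic = simulate_strain(model, wt, ics, ProtocolSettings(use_fast_path=False))
    assert fast.n_divisions == generic.n_divisions
    assert np.allclose(fast.division_times, generic.division_times, atol=1e-9)
    assert np.allclose(fast.division_sizes, generic.division_sizes, rtol=1e-12)
    assert np.allclose(fast.post_division_state, generic.post_division_state, rtol=1e-12)
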