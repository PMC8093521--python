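import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsim import (
    CAP,
    ConfigurationError,
    PulseTrain,
    ValidationError,
    check_conservation,
    check_refractory_exclusion,
    in_transit_count,
    resolve_convergence,
    simulate,
)
from capsim.collisions import oracle_simulate

from conftest import DT, VELOCITY, chain_model, convergence_model, grid_poisson_inputs, random_network

L = 1e-3
TOL = 1e-5


def _arrivals(times):
    return [(CAP(f"i{k}", t, L), t) for k, t in enumerate(times)]


class TestResolveConvergence:
    def test_in_phase_pair_fuses_to_single_cap(self):
        survivors, records = resolve_convergence(_arrivals([0.010, 0.010]), L, TOL)
        assert [t for _c, t in survivors] == [0.010]
        assert [r.outcome for r in records] == ["fused"]
        assert len(records[0].participants) == 2
        assert records[0].survivor == "i0"

    def test_late_third_annulled_by_refractory(self):
        survivors, records = resolve_convergence(
            _arrivals([0.010, 0.010, 0.0105]), L, TOL
        )
        assert [t for _c, t in survivors] == [0.010]
        assert [r.outcome for r in records] == ["fused", "annulled"]
        annulled = records[1]
        assert annulled.participants == ("i2",)
        assert annulled.survivor is None
        assert annulled.blocking == "i0"

    def test_post_refractory_third_passes(self):
        survivors, records = resolve_convergence(
            _arrivals([0.010, 0.010, 0.0112]), L, TOL
        )
        assert [t for _c, t in survivors] == [0.010, 0.0112]
        assert [r.outcome for r in records] == ["fused", "passed"]

    def test_arrival_exactly_at_window_end_passes(self):
        # the refractory window is half-open: membrane that has just
        # recovered has no effect
        survivors, records = resolve_convergence(_arrivals([0.010, 0.011]), L, TOL)
        assert [r.outcome for r in records] == ["passed", "passed"]
        assert len(survivors) == 2

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValidationError):
            resolve_convergence(_arrivals([0.02, 0.01]), L, TOL)

    def test_tolerance_must_be_below_refractory(self):
        with pytest.raises(ConfigurationError):
            resolve_convergence(_arrivals([0.01]), L, fusion_tolerance=L)

    @settings(max_examples=60, deadline=None)
    @given(
        gaps=st.lists(
            st.floats(min_value=1e-6, max_value=5e-3, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_conservation_and_refractory_exclusion(self, gaps):
        """Every arrival is accounted for exactly once and survivors are
        separated by at least the refractory period."""
        times = np.cumsum(gaps)
        survivors, records = resolve_convergence(_arrivals(times), L, TOL)
        participants = [p for r in records for p in r.participants]
        assert sorted(participants) == sorted(f"i{k}" for k in range(len(times)))
        n_fused_absorbed = sum(len(r.participants) - 1 for r in records if r.outcome == "fused")
        n_annulled = sum(1 for r in records if r.outcome == "annulled")
        assert len(survivors) + n_annulled + n_fused_absorbed == len(times)
        st_times = [t for _c, t in survivors]
        assert all(b - a >= L - 1e-12 for a, b in zip(st_times, st_times[1:]))


class TestSimulate:
    def test_chain_is_pure_delay(self):
        model = chain_model(total_latency=0.02)
        res = simulate(model, {"src": PulseTrain("src", [0.0])}, t_end=1.0)
        assert res.output_trains["out"].times == pytest.approx((0.02,))
        check_conservation(res, model)

    def test_identical_branches_fuse_to_one_shifted_train(self):
        model = convergence_model(n_sources=2, branch_latency=5e-3, relay_latency=2e-3)
        times = [0.0, 0.01, 0.02, 0.05]
        inputs = {s: PulseTrain(s, times) for s in ("s0", "s1")}
        res = simulate(model, inputs, t_end=1.0)
        expected = tuple(t + 7e-3 for t in times)
        assert res.output_trains["out"].times == pytest.approx(expected)
        assert all(
            r.outcome == "fused" for r in res.collisions if r.node == "m"
        )

    def test_fan_out_duplicates_quantum_on_all_outgoing(self):
        from capsim import NetworkModel, NetworkNode, Neurite

        nodes = [
            NetworkNode("s", "source"),
            NetworkNode("m", "convergence"),
            NetworkNode("k1", "sink"),
            NetworkNode("k2", "sink"),
        ]
        neurites = [
            Neurite("s->m", "s", "m", 0.003, 0.3),
            Neurite("m->k1", "m", "k1", 0.003, 0.3),
            Neurite("m->k2", "m", "k2", 0.006, 0.3),
        ]
        model = NetworkModel(nodes, neurites)
        res = simulate(model, {"s": PulseTrain("s", [0.0])}, t_end=1.0)
        assert res.output_trains["k1"].times == pytest.approx((0.02,))
        assert res.output_trains["k2"].times == pytest.approx((0.03,))

    def test_invalid_network_rejected(self):
        from capsim import NetworkModel, NetworkNode, Neurite

        model = NetworkModel(
            [NetworkNode("s", "source")],
            [Neurite("s->ghost", "s", "ghost", 1.0, 1.0)],
        )
        with pytest.raises(ValidationError):
            simulate(model, {}, t_end=1.0)

    def test_refractory_violating_inputs_rejected(self):
        model = chain_model()
        with pytest.raises(ValidationError):
            simulate(model, {"src": PulseTrain("src", [0.0, 1e-4])}, t_end=1.0)

    def test_determinism_bit_identical_records(self, rng):
        model = random_network(rng)
        inputs = grid_poisson_inputs(model, rng, rate=150.0, t_end=0.05)
        r1 = simulate(model, inputs, 0.05)
        r2 = simulate(model, inputs, 0.05)
        assert r1.collisions == r2.collisions
        assert r1.output_trains == r2.output_trains

    def test_causality_no_output_before_total_latency(self, rng):
        """Every output threshold lags some input threshold by at least the
        shortest route latency."""
        from capsim.core import latency

        model = random_network(rng)
        inputs = grid_poisson_inputs(model, rng, rate=150.0, t_end=0.05)
        res = simulate(model, inputs, 0.05)
        min_lat = min(latency(e) for e in model.neurites)
        first_in = min(
            (tr.times[0] for tr in inputs.values() if tr.times), default=None
        )
        for train in res.output_trains.values():
            for t in train.times:
                assert t >= first_in + min_lat - 1e-12

    def test_monotone_gating_extra_train_preserves_earlier_outputs(self):
        """Adding an input train never disturbs outputs earlier than the new
        train's first possible arrival, and never compresses intervals
        below the refractory period."""
        model = convergence_model(n_sources=2, branch_latency=5e-3, relay_latency=2e-3)
        base = {"s0": PulseTrain("s0", [0.0, 0.01, 0.03]), "s1": PulseTrain("s1", [])}
        extra_first = 0.02
        extended = {
            "s0": base["s0"],
            "s1": PulseTrain("s1", [extra_first, 0.04]),
        }
        res_a = simulate(model, base, 1.0)
        res_b = simulate(model, extended, 1.0)
        horizon = extra_first + 7e-3  # new train cannot reach the sink before this
        early_a = [t for t in res_a.output_trains["out"].times if t < horizon]
        early_b = [t for t in res_b.output_trains["out"].times if t < horizon]
        assert early_a == early_b
        check_refractory_exclusion(res_b, model)


class TestInTransit:
    def test_zero_before_first_entry(self):
        model = chain_model(total_latency=0.02)
        res = simulate(model, {"src": PulseTrain("src", [0.5])}, t_end=1.0)
        assert in_transit_count(res, "src->out", 0.25) == 0
        assert in_transit_count(res, "src->out", 0.51) == 1

    def test_steady_periodic_drive_fills_lambda_caps(self):
        # edge spanning 3 periods at 100 Hz holds 3 CAPs in steady state,
        # 6 when the drive frequency doubles to 200 Hz
        from capsim.generators import periodic_train

        for f, expected in ((100.0, 3), (200.0, 6)):
            model = chain_model(total_latency=3 / 100.0, refractory=1e-3)
            train = periodic_train(f, 0.0, 1.0, 1e-3, location="src")
            res = simulate(model, {"src": train}, t_end=1.0)
            assert in_transit_count(res, "src->out", 0.5 + 0.5 / f) == expected

    def test_unknown_neurite_rejected(self):
        model = chain_model()
        res = simulate(model, {"src": PulseTrain("src", [0.0])}, t_end=1.0)
        with pytest.raises(ValidationError):
            in_transit_count(res, "nope", 0.5)
        with pytest.raises(ValidationError):
            in_transit_count(res, "src->out", 2.0)

    def test_transit_log_counts_match_point_queries(self):
        model = chain_model(total_latency=0.02)
        res = simulate(model, {"src": PulseTrain("src", [0.0, 0.01, 0.05])}, t_end=1.0)
        for t, count in res.transit_log("src->out"):
            assert in_transit_count(res, "src->out", t) == count


class TestOracle:
    def test_no_collision_chain_matches_event_driven(self):
        model = chain_model(total_latency=0.002)
        train = PulseTrain("src", [0.0, 0.005, 0.011])
        res = simulate(model, {"src": train}, 0.05)
        ora = oracle_simulate(model, {"src": train}, 0.05, dt=DT)
        assert ora.output_trains["out"].times == pytest.approx(
            res.output_trains["out"].times, abs=DT
        )

    def test_annulment_scenario_drops_late_threshold(self):
        # two in-phase branches fuse; a third threshold 0.5 ms later on one
        # branch is annulled and never reaches the sink
        model = convergence_model(n_sources=3, branch_latency=2e-3, relay_latency=1e-3)
        inputs = {
            "s0": PulseTrain("s0", [0.010]),
            "s1": PulseTrain("s1", [0.010]),
            "s2": PulseTrain("s2", [0.0105]),
        }
        res = simulate(model, inputs, 0.05)
        ora = oracle_simulate(model, inputs, 0.05, dt=DT)
        assert len(res.output_trains["out"]) == 1
        assert ora.output_trains["out"].times == pytest.approx(
            res.output_trains["out"].times, abs=DT
        )

    def test_dt_too_coarse_rejected(self):
        model = chain_model()
        with pytest.raises(ConfigurationError):
            oracle_simulate(model, {}, 0.05, dt=1e-5, fusion_tolerance=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_networks_agree_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        model = random_network(rng)
        inputs = grid_poisson_inputs(model, rng, rate=150.0, t_end=0.05)
        res = simulate(model, inputs, 0.05)
        ora = oracle_simulate(model, inputs, 0.05, dt=DT)
        check_conservation(res, model)
        check_refractory_exclusion(res, model)
        for sink, train in res.output_trains.items():
            other = ora.output_trains[sink].times
            assert len(other) == len(train.times)
            assert other == pytest.approx(train.times, abs=DT)
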