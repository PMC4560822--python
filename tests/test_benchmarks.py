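"""Benchmark generators: protocols, conservation laws, truth oracles."""

import itertools

import numpy as np
import pytest
from scipy.integrate import odeint

from phenodyn.benchmarks import (
    BenchmarkConfig,
    GLYCOLYSIS_OBSERVED,
    build_glycolysis_model,
    build_phospho_network,
    draw_phospho_rates,
    generate_glycolysis_data,
    generate_gravity_data,
    generate_phospho_data,
    glycolysis_sampling_ranges,
    simple_phospho_model,
)
from phenodyn import glycolysis_constants as glyco


class TestGravityGenerator:
    def test_protocol_counts(self):
        data, _ = generate_gravity_data(BenchmarkConfig.gravity(N=150, seed=0))
        assert len(data.conditions) == 150
        assert all(len(c.records) == 1 for c in data.conditions)
        assert data.N == 150

    def test_noiseless_records_equal_oracle(self):
        cfg = BenchmarkConfig.gravity(N=10, seed=1, noise_frac=0.0)
        data, oracle = generate_gravity_data(cfg)
        for cond in data.conditions:
            r0 = float(np.asarray(cond.inputs)[0])
            rec = cond.records[0]
            truth = float(oracle.trajectory(r0, [rec.time])[0])
            assert rec.value == pytest.approx(truth, rel=1e-8)

    def test_circular_release_stays_put(self):
        _, oracle = generate_gravity_data(BenchmarkConfig.gravity(N=1, seed=0))
        rc = oracle.circular_radius
        traj = oracle.trajectory(rc, np.linspace(0.1, 5.0, 20))
        np.testing.assert_allclose(traj, rc, rtol=1e-6)

    def test_release_range_straddles_both_orbit_types(self):
        cfg = BenchmarkConfig.gravity(N=40, seed=2)
        data, oracle = generate_gravity_data(cfg)
        r0s = [float(np.asarray(c.inputs)[0]) for c in data.conditions]
        bound = [oracle.is_bound(r) for r in r0s]
        assert any(bound) and not all(bound)
        lo, hi = cfg.extra["r0_range"]
        assert lo < oracle.circular_radius < hi

    def test_seed_determinism(self):
        d1, _ = generate_gravity_data(BenchmarkConfig.gravity(N=5, seed=9))
        d2, _ = generate_gravity_data(BenchmarkConfig.gravity(N=5, seed=9))
        assert [c.records for c in d1.conditions] == [c.records for c in d2.conditions]


def phospho_observable_bookkeeping(network, V, times):
    """Independent brute-force oracle: dict-of-microstates rate equations."""
    states = list(itertools.product((0, 1), repeat=network.n_sites))

    def rhs(x, t):
        conc = dict(zip(states, x))
        dx = dict.fromkeys(states, 0.0)
        for s in states:
            for site in range(network.n_sites):
                direction = -1 if s[site] else +1
                target = list(s)
                target[site] = 1 - target[site]
                target = tuple(target)
                cfg = []
                if site > 0:
                    cfg.append(s[site - 1])
                if site < network.n_sites - 1:
                    cfg.append(s[site + 1])
                Vr, K = network.rate_params[(site, direction, tuple(cfg))]
                if site == 1 and direction == +1 and site + 1 < network.n_sites \
                        and s[site + 1] == 1:
                    Vr = V
                flux = Vr * conc[s] / (K + conc[s])
                dx[s] -= flux
                dx[target] += flux
        return [dx[s] for s in states]

    x0 = [0.0] * len(states)
    x0[states.index((0,) * network.n_sites)] = 1.0
    teval = np.concatenate([[0.0], times]) if times[0] > 0 else times
    sol = odeint(rhs, x0, teval, rtol=1e-9, atol=1e-11)
    occ = np.array([sum(s) for s in states], float)
    return sol[-len(times):] @ occ


class TestPhosphoNetwork:
    def test_single_site_has_two_states(self):
        net = build_phospho_network(1, draw_phospho_rates(1, seed=0))
        assert net.n_equations == 2
        assert len(net._src) == 2  # one flip each way

    def test_five_sites_give_32_equations(self):
        net = build_phospho_network(5)
        assert net.n_equations == 32

    def test_total_concentration_conserved(self):
        net = build_phospho_network(3, draw_phospho_rates(3, seed=1))
        x0 = net.initial_state()
        sol = odeint(lambda x, t: net.rhs(x, 2.0), x0,
                     np.linspace(0, 5, 50), rtol=1e-10, atol=1e-12)
        totals = sol.sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-9)

    def test_observable_matches_bookkeeping_oracle(self):
        net = build_phospho_network(3, draw_phospho_rates(3, seed=2))
        times = np.array([0.5, 1.0, 4.0])
        got = net.observable(3.3, times)
        want = phospho_observable_bookkeeping(net, 3.3, times)
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_observable_bounded_by_site_count(self):
        net = build_phospho_network(5)
        obs = net.observable(50.0, np.linspace(0.5, 50.0, 30))
        assert np.all(obs <= 5.0 + 1e-9)
        assert obs[-1] > 0.0


class TestPhosphoData:
    def test_time_zero_observable_is_zero(self):
        net = build_phospho_network(5)
        assert net.observable(1.0, np.array([0.0]))[0] == 0.0

    def test_record_counts_and_determinism(self):
        cfg = BenchmarkConfig.phosphorylation(N=40, seed=3)
        d1, _ = generate_phospho_data(cfg)
        d2, _ = generate_phospho_data(cfg)
        assert d1.N == 40
        assert [c.records for c in d1.conditions] == [c.records for c in d2.conditions]

    def test_sigma_floor_is_positive_at_zero_value(self):
        data, _ = generate_phospho_data(BenchmarkConfig.phosphorylation(N=30, seed=4))
        assert all(r.sigma > 0 for c in data.conditions for r in c.records)


class TestSimplePhosphoModel:
    def test_time_zero_gives_offset(self):
        f = simple_phospho_model([3.0, 1.0, 0.5, 2.0, 0.25])
        assert f(0.0, 5.0) == pytest.approx(0.25)

    def test_double_saturation_limit(self):
        A, c = 3.0, 0.25
        f = simple_phospho_model([A, 1.0, 0.5, 2.0, c])
        assert f(1e6, 1e6) == pytest.approx(A + c)

    def test_exactly_five_parameters(self):
        with pytest.raises(ValueError):
            simple_phospho_model([1.0, 2.0, 3.0, 4.0])


class TestGlycolysis:
    def test_seven_species_sixteen_parameters(self):
        model = build_glycolysis_model()
        assert model.n_species == 7
        assert model.n_parameters == 16
        assert set(model.params) == set(glyco.PARAMETERS)

    def test_sustained_oscillations_near_one_minute(self):
        model = build_glycolysis_model()
        assert model.oscillation_period() == pytest.approx(1.0, rel=0.2)

    def test_data_protocol(self):
        cfg = BenchmarkConfig.glycolysis(N=40, seed=5)
        data, model = generate_glycolysis_data(cfg)
        assert len(data.conditions) == 40
        assert all(len(c.records) == 3 for c in data.conditions)
        assert data.observed_names == list(GLYCOLYSIS_OBSERVED)
        # all three records of a condition share one measurement time
        for c in data.conditions:
            assert len({r.time for r in c.records}) == 1

    def test_noiseless_time_zero_records_equal_initial_conditions(self):
        cfg = BenchmarkConfig.glycolysis(N=5, seed=6, noise_frac=0.0)
        cfg.t_max = 0.0  # degenerate protocol: measure at release
        data, model = generate_glycolysis_data(cfg)
        for cond in data.conditions:
            for j, rec in enumerate(cond.records):
                assert rec.value == pytest.approx(cond.observed_x0[j], rel=1e-9)

    def test_range_scaling_doubles_half_width(self):
        r1 = glycolysis_sampling_ranges(1.0)
        r2 = glycolysis_sampling_ranges(2.0)
        w1 = r1[:, 1] - r1[:, 0]
        w2 = r2[:, 1] - r2[:, 0]
        # clipping at zero may shorten the lower side, never the upper
        assert np.all(w2 >= w1)
        np.testing.assert_allclose(r2[:, 1] - r1[:, 1], w1 / 2, rtol=1e-9)
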