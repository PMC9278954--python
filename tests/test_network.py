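"""Recurrent network: wiring statistics, determinism, conductance and
release-probability invariants, manipulation semantics and the
inhibition/gain properties (scaled networks)."""

import dataclasses

import numpy as np
import pytest

from crhnet import (GABA_PARAMS_DEFAULT, ManipulationEvent,
                    ManipulationSchedule, NetworkConfig, PVNNetwork,
                    simulate_poisson_driven_neuron)
from crhnet.network import adaptation_decay, logistic_recovery


def _scaled(n, seed=7, **kw):
    cfg = NetworkConfig().scaled(n, n)
    return dataclasses.replace(cfg, seed=seed, **kw)


class TestBuild:
    def test_zero_connection_probability_zero_synapses(self):
        cfg = dataclasses.replace(NetworkConfig(n_crh=50, n_gaba=50),
                                  conn_prob_crh_to_gaba=0.0,
                                  conn_prob_gaba_to_crh=0.0)
        net = PVNNetwork(cfg)
        assert net.n_crh_to_gaba_synapses == 0
        assert net.n_gaba_to_crh_synapses == 0

    def test_synapse_count_within_binomial_bound(self):
        net = PVNNetwork(NetworkConfig(seed=1))
        expect = 500 * 500 * 0.02
        sd = np.sqrt(500 * 500 * 0.02 * 0.98)
        assert abs(net.n_gaba_to_crh_synapses - expect) < 4 * sd
        assert abs(net.n_crh_to_gaba_synapses - expect) < 4 * sd

    def test_baseline_release_probabilities_in_range(self):
        net = PVNNetwork(NetworkConfig(seed=2))
        assert np.all(net.p_release >= 0.9) and np.all(net.p_release <= 1.0)

    def test_adaptation_b_drawn_in_range(self):
        net = PVNNetwork(NetworkConfig(seed=3))
        assert np.all(net.crh_b >= 5.0) and np.all(net.crh_b <= 18.0)

    def test_build_deterministic_under_seed(self):
        a = PVNNetwork(NetworkConfig(seed=4))
        b = PVNNetwork(NetworkConfig(seed=4))
        assert np.array_equal(a.gc_targets, b.gc_targets)
        assert np.array_equal(a.p_release, b.p_release)
        assert np.array_equal(a.crh_b, b.crh_b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_crh=0)
        with pytest.raises(ValueError):
            NetworkConfig(gaba_pr_range=(0.5, 0.2))
        with pytest.raises(ValueError):
            NetworkConfig(conn_prob_gaba_to_crh=1.5)

    def test_scaled_preserves_in_degree(self):
        cfg = NetworkConfig().scaled(100, 100)
        assert cfg.conn_prob_gaba_to_crh == pytest.approx(0.1)
        assert cfg.n_crh == 100


class TestSimulate:
    def test_raster_bit_exact_under_seed(self):
        net = PVNNetwork(_scaled(40))
        a = net.simulate(10.0, seed=5)
        b = net.simulate(10.0, seed=5)
        for ta, tb in zip(a.crh_trains + a.gaba_trains,
                          b.crh_trains + b.gaba_trains):
            assert np.array_equal(ta.times, tb.times)

    def test_spike_times_strictly_increasing(self):
        sim = PVNNetwork(_scaled(40)).simulate(10.0, seed=6)
        for tr in sim.crh_trains:
            assert np.all(np.diff(tr.times) > 0)

    def test_quiescent_without_drive(self):
        # homogeneous population: heterogeneous draws may include
        # intrinsically tonic cells, so pin every neuron to the mean set
        sd0 = {k: 0.0 for k in NetworkConfig().crh_params_sd}
        cfg = dataclasses.replace(_scaled(20), epsp_rate=0.0, crh_params_sd=sd0)
        sim = PVNNetwork(cfg).simulate(5.0, seed=1)
        assert sum(len(tr) for tr in sim.crh_trains + sim.gaba_trains) == 0

    def test_conductances_recorded_nonnegative_and_decaying(self):
        sim = PVNNetwork(_scaled(40)).simulate(5.0, record=[0], seed=8)
        trc = sim.traces[0]
        assert np.all(trc.g_e >= 0) and np.all(trc.g_i >= 0)
        # between increments the conductance is multiplied by exp(-dt/tau)
        dec = np.exp(-0.1 / 12.5)
        dge = trc.g_e[1:] - trc.g_e[:-1] * dec
        assert np.all(dge > -1e-12)  # only upward jumps break pure decay

    def test_schedule_event_outside_span_rejected(self):
        net = PVNNetwork(_scaled(20))
        sched = ManipulationSchedule.pr_drop(50.0)
        with pytest.raises(ValueError):
            net.simulate(10.0, schedule=sched)

    def test_epsp_rate_step_increases_drive(self):
        net = PVNNetwork(_scaled(60))
        sched = ManipulationSchedule.epsp_step(15.0, 90.0)
        sim = net.simulate(30.0, schedule=sched, seed=9)
        pre = sim.crh_rates(2.0, 15.0).mean()
        post = sim.crh_rates(15.0, 30.0).mean()
        assert post > pre

    def test_isolated_limit_matches_single_neuron_oracle(self):
        """With w_i = 0, CRH units behave like isolated Poisson-driven
        neurons (population mean rate compared to an independently coded
        single-neuron simulation)."""
        syn = dataclasses.replace(NetworkConfig().synapse, w_i=0.0)
        cfg = dataclasses.replace(_scaled(50), synapse=syn)
        net = PVNNetwork(cfg)
        sim = net.simulate(30.0, seed=10)
        net_rate = sim.crh_rates(0.0).mean()
        iso = [simulate_poisson_driven_neuron(p, syn, 30.0, 30.0, b=b, seed=k)
               for k, (p, b) in enumerate(zip(net.crh_params, net.crh_b))]
        iso_rate = np.mean([tr.rate for tr in iso])
        assert net_rate == pytest.approx(iso_rate, rel=0.1)

    def test_rate_non_increasing_in_inhibitory_weight(self):
        rates = []
        for w_i in (0.0, 1.65, 3.3):
            syn = dataclasses.replace(NetworkConfig().synapse, w_i=w_i)
            cfg = dataclasses.replace(_scaled(80), synapse=syn)
            sim = PVNNetwork(cfg).simulate(40.0, seed=11)
            rates.append(sim.crh_rates(5.0).mean())
        assert rates[0] >= rates[1] >= rates[2]

    def test_gain_gating_direction(self):
        """The 30->60 Hz rate increase is larger without recurrent
        inhibition than with it."""
        deltas = {}
        for label, extra in (("with", {}),
                             ("without", dict(gaba_pr_range=(0.01, 0.2),
                                              adaptation_b_range=(36.0, 50.0)))):
            r = {}
            for rate in (30.0, 60.0):
                cfg = dataclasses.replace(_scaled(80), epsp_rate=rate, **extra)
                sim = PVNNetwork(cfg).simulate(40.0, seed=12)
                r[rate] = sim.crh_rates(5.0).mean()
            deltas[label] = r[60.0] - r[30.0]
        assert deltas["without"] > deltas["with"]


class TestManipulations:
    def test_pr_drop_redraws_in_range_and_recovers(self):
        """After a transient drop, release probabilities recover toward 1 by
        the logistic law."""
        assert logistic_recovery(0.1, 0.0, 80.0) == pytest.approx(0.1)
        mid = logistic_recovery(0.1, 80.0, 80.0)
        assert 0.1 < mid < 1.0
        # closed form: logit grows linearly at rate 1/tau_p
        expect = 1.0 / (1.0 + 9.0 * np.exp(-1.0))
        assert mid == pytest.approx(expect)
        assert logistic_recovery(1.0, 1e9, 80.0) == 1.0

    def test_adaptation_trigger_no_change_when_target_equals_current(self):
        net = PVNNetwork(_scaled(40, seed=13))
        ev = ManipulationEvent(5.0, "trigger_adaptation_increase",
                               {"range": (36.0, 50.0)})
        sched = ManipulationSchedule([ev])
        sim = net.simulate(10.0, schedule=sched, seed=13)
        base = net.simulate(10.0, seed=13)
        # identical until the trigger, diverging after
        pre_a = [tr.times[tr.times < 5.0] for tr in sim.crh_trains]
        pre_b = [tr.times[tr.times < 5.0] for tr in base.crh_trains]
        for x, y in zip(pre_a, pre_b):
            assert np.array_equal(x, y)

    def test_adaptation_increment_decays_within_5pct_after_3_tau(self):
        assert adaptation_decay(33.0, 3 * 40.0, 40.0) < 0.05 * 33.0

    def test_unknown_action_rejected(self):
        with pytest.raises(ValueError):
            ManipulationEvent(0.0, "explode", {})

    def test_event_times_must_be_sorted(self):
        with pytest.raises(ValueError):
            ManipulationSchedule([
                ManipulationEvent(5.0, "set_epsp_rate", {"rate": 60.0}),
                ManipulationEvent(1.0, "set_epsp_rate", {"rate": 30.0})])
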