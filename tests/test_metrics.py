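"""Spike-train analytics: hand-traced burst examples, brute-force oracles,
distribution binning rules and the log-ISI earth mover's distance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crhnet import (BurstCriterion, SpikeTrain, burst_length_distribution,
                    burst_prob_vs_preceding_silence,
                    burst_prob_vs_proceeding_silence, burst_vs_total_rate,
                    detect_bursts, firing_rate_timecourse, ibi_distribution,
                    isi_sequence, light_response_test, log_isi_emd,
                    network_fit_distance, psth, running_average,
                    silence_by_event_length)
from conftest import random_train


def brute_force_bursts(times, start_max=0.006, cont_max=0.020, prec_min=0.025):
    """Independent per-spike state machine implementing the stated burst
    criterion; oracle for detect_bursts."""
    n = len(times)
    assigned = [None] * n
    bursts = []
    for i in range(n - 1):
        if assigned[i] is not None:
            continue
        preceding = float("inf") if i == 0 else times[i] - times[i - 1]
        if times[i + 1] - times[i] < start_max and preceding > prec_min:
            members = [i, i + 1]
            j = i + 1
            while j + 1 < n and times[j + 1] - times[j] < cont_max:
                members.append(j + 1)
                j += 1
            for m in members:
                assigned[m] = len(bursts)
            bursts.append((members[0], len(members)))
    ss = [i for i in range(n) if assigned[i] is None]
    return bursts, ss


def w1_oracle(x, y):
    """Wasserstein-1 between empirical samples via the |CDF difference|
    integral on the merged support."""
    x = np.sort(x)
    y = np.sort(y)
    z = np.sort(np.concatenate([x, y]))
    total = 0.0
    for a, b in zip(z[:-1], z[1:]):
        fx = np.searchsorted(x, a, side="right") / x.size
        fy = np.searchsorted(y, a, side="right") / y.size
        total += abs(fx - fy) * (b - a)
    return total


class TestDetectBursts:
    def test_hand_traced_burst_of_four(self):
        tr = SpikeTrain(times=np.array([0.100, 0.104, 0.112, 0.125, 0.900]))
        ann = detect_bursts(tr)
        assert ann.bursts == [(0, 4)]
        assert list(ann.ss_indices) == [4]

    def test_empty_train(self):
        ann = detect_bursts(SpikeTrain(times=np.array([])))
        assert ann.n_bursts == 0 and ann.ss_indices.size == 0

    def test_7ms_initial_isi_is_not_a_burst(self):
        ann = detect_bursts(SpikeTrain(times=np.array([0.100, 0.107])))
        assert ann.n_bursts == 0 and ann.ss_indices.size == 2

    def test_short_preceding_isi_blocks_burst_start(self):
        # second pair has a 10 ms preceding ISI (< 25 ms): no new burst
        tr = SpikeTrain(times=np.array([0.100, 0.130, 0.140, 0.144]))
        ann = detect_bursts(tr)
        assert ann.n_bursts == 0

    def test_first_spike_may_start_a_burst(self):
        ann = detect_bursts(SpikeTrain(times=np.array([0.001, 0.005, 1.0])))
        assert ann.bursts == [(0, 2)]

    def test_matches_brute_force_on_1000_random_trains(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            tr = random_train(rng)
            ann = detect_bursts(tr)
            ob, oss = brute_force_bursts(list(tr.times))
            assert ann.bursts == ob
            assert list(ann.ss_indices) == oss

    def test_every_spike_classified_exactly_once(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tr = random_train(rng)
            ann = detect_bursts(tr)
            mask = ann.burst_member_mask()
            assert mask.sum() + ann.ss_indices.size == len(tr)
            assert not np.any(mask[ann.ss_indices])

    def test_lowering_start_isi_only_reduces_burst_count(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            tr = random_train(rng)
            loose = detect_bursts(tr, BurstCriterion(start_isi_max=0.006))
            tight = detect_bursts(tr, BurstCriterion(start_isi_max=0.003))
            assert tight.n_bursts <= loose.n_bursts

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain(times=np.array([0.2, 0.1]))


class TestDistributions:
    def test_ibi_binning_labels_by_upper_limit(self):
        # two bursts whose end-to-start gap is 1.75 s -> 1.8 s-labeled bin
        tr = SpikeTrain(times=np.array([0.100, 0.103, 0.106,
                                        1.856, 1.859]))
        ann = detect_bursts(tr)
        assert ann.n_bursts == 2
        labels, probs = ibi_distribution(tr, ann)
        assert probs.sum() == pytest.approx(1.0)
        assert labels[np.argmax(probs)] == pytest.approx(1.8)

    def test_no_bursts_empty_ibi(self):
        tr = SpikeTrain(times=np.array([0.1, 0.5, 1.2]))
        labels, probs = ibi_distribution(tr, detect_bursts(tr))
        assert labels.size == 0 and probs.size == 0

    def test_burst_length_distribution_probabilities(self):
        tr = SpikeTrain(times=np.array([0.100, 0.104, 0.500, 0.504, 0.512,
                                        2.000]))
        ann = detect_bursts(tr)
        lengths, probs = burst_length_distribution(ann)
        assert list(lengths) == [2, 3]
        assert probs == pytest.approx([0.5, 0.5])

    def test_isi_sequence(self):
        tr = SpikeTrain(times=np.array([0.1, 0.3, 0.6]))
        assert isi_sequence(tr) == pytest.approx([0.2, 0.3])


class TestSilenceAnalyses:
    def test_burst_prob_matches_exhaustive_count(self):
        # hand-built 6-spike train; enumerate by hand:
        # times:      0.1   0.7   0.704  0.76  1.46  1.462
        # preceding:       0.6   0.004  0.056  0.70  0.002
        # proceeding:      0.004 0.056  0.70   0.002
        # spikes with both ISIs: indices 1..4
        tr = SpikeTrain(times=np.array([0.1, 0.7, 0.704, 0.76, 1.46, 1.462]))
        labels, probs, ns = burst_prob_vs_preceding_silence(tr)
        table = dict(zip(labels, probs))
        # preceding 0.6 s -> bin 1.0 (500 ms-wide bins above 0.5): burst (isi 4 ms)
        assert table[1.0] == pytest.approx(1.0)
        # preceding 4 ms -> bin 0.01: next isi 56 ms, not burst
        idx = int(np.argmin(np.abs(labels - 0.01)))
        assert probs[idx] == 0.0
        # preceding 0.7 -> bin 1.0 counted with the 0.6 one; both burst
        assert ns[list(labels).index(1.0)] == 2

    def test_no_burst_range_isis_all_zero(self):
        tr = SpikeTrain(times=np.arange(50) * 0.1)
        _, probs, _ = burst_prob_vs_preceding_silence(tr)
        assert np.all(probs == 0.0)
        _, probs2, _ = burst_prob_vs_proceeding_silence(tr)
        assert np.all(probs2 == 0.0)

    def test_silence_by_event_length_hand_built(self):
        # one 2-spike burst flanked by singles
        tr = SpikeTrain(times=np.array([0.1, 1.1, 1.104, 1.8]))
        ann = detect_bursts(tr)
        out = silence_by_event_length(tr, ann)
        pre2, post2 = out[2]
        assert pre2 == pytest.approx(1.0)
        assert post2 == pytest.approx(0.696)
        pre1, post1 = out[1]
        # two singles: first has no preceding interval, second precedes burst
        assert pre1 == pytest.approx(0.696)
        assert post1 == pytest.approx(1.0)

    def test_empty_train_all_nan(self):
        out = silence_by_event_length(SpikeTrain(times=np.array([])),
                                      detect_bursts(SpikeTrain(times=np.array([]))))
        assert all(np.isnan(v[0]) and np.isnan(v[1]) for v in out.values())


class TestRates:
    def test_constant_one_hz_train(self):
        tr = SpikeTrain(times=np.arange(100) + 0.5, t_start=0, t_stop=100)
        centers, rates = firing_rate_timecourse(tr, bin_s=10)
        assert rates == pytest.approx(np.ones(10))

    def test_running_average_of_constant_is_constant(self):
        assert running_average(np.full(20, 3.0)) == pytest.approx(np.full(20, 3.0))

    def test_running_average_truncated_edges(self):
        r = running_average(np.array([1.0, 2, 3, 4, 5, 6, 7]), window=5)
        assert r[0] == pytest.approx(np.mean([1, 2, 3]))
        assert r[1] == pytest.approx(np.mean([1, 2, 3, 4]))
        assert r[3] == pytest.approx(np.mean([2, 3, 4, 5, 6]))
        assert r[-1] == pytest.approx(np.mean([5, 6, 7]))

    def test_burst_vs_total_rate_no_bursts(self):
        tr = SpikeTrain(times=np.arange(0.25, 60, 0.5), t_start=0, t_stop=60)
        cls, tot = burst_vs_total_rate(tr, detect_bursts(tr))
        assert np.all(cls == 0.0)
        assert tot == pytest.approx(np.full(6, 2.0))

    def test_burst_vs_total_rate_classes(self):
        # 3 bursts in one 10 s bin -> class 0.3; 7 bursts -> capped at 0.6
        times = []
        for k in range(3):
            times += [k * 2.0, k * 2.0 + 0.004]
        for k in range(7):
            times += [10.5 + k * 1.0, 10.5 + k * 1.0 + 0.004]
        tr = SpikeTrain(times=np.array(times), t_start=0, t_stop=20)
        cls, _ = burst_vs_total_rate(tr, detect_bursts(tr))
        assert cls[0] == pytest.approx(0.3)
        assert cls[1] == pytest.approx(0.6)


class TestOptoAnalysis:
    def test_zero_spikes_not_responsive(self):
        tr = SpikeTrain(times=np.array([]), t_stop=60)
        res = light_response_test(tr, np.arange(1, 26, 2.0))
        assert not res.responsive
        assert (res.prob_pre, res.prob_post) == (0.0, 0.0)

    def test_reliable_short_latency_unit_is_responsive(self):
        onsets = np.arange(1, 51, 2.0)
        tr = SpikeTrain(times=onsets + 0.007, t_stop=52)
        res = light_response_test(tr, onsets)
        assert res.responsive
        assert res.prob_post == 1.0 and res.prob_pre == 0.0

    def test_window_is_20_ms(self):
        onsets = np.array([1.0, 3.0, 5.0])
        # spikes 25 ms after onset: outside the 20 ms response window
        tr = SpikeTrain(times=onsets + 0.025, t_stop=6)
        res = light_response_test(tr, onsets)
        assert res.prob_post == 0.0

    def test_psth_counts(self):
        onsets = np.array([1.0, 2.0, 4.0])
        tr = SpikeTrain(times=onsets + 0.012, t_stop=5)
        edges, rate = psth(tr, onsets, window=(-0.05, 0.05), bin_s=0.01)
        k = np.searchsorted(edges, 0.012, side="right") - 1
        assert rate[k] == pytest.approx(1.0 / 0.01)
        assert rate[:k].sum() == 0.0


class TestLogIsiEmd:
    def test_identical_trains_zero(self):
        tr = SpikeTrain(times=np.array([0.1, 0.2, 0.4, 0.8]))
        assert log_isi_emd(tr, tr) == 0.0

    def test_point_masses_closed_form(self):
        a = SpikeTrain(times=np.arange(5) * 0.01)
        b = SpikeTrain(times=np.arange(5) * 0.1)
        assert log_isi_emd(a, b) == pytest.approx(1.0)  # |log10 0.01 - log10 0.1|

    def test_matches_cdf_integral_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            a = random_train(rng)
            b = random_train(rng)
            got = log_isi_emd(a, b)
            want = w1_oracle(np.log10(isi_sequence(a)), np.log10(isi_sequence(b)))
            assert got == pytest.approx(want, abs=1e-10)

    def test_metric_axioms_on_samples(self):
        rng = np.random.default_rng(7)
        trains = [random_train(rng) for _ in range(6)]
        for x in trains:
            assert log_isi_emd(x, x) == 0.0
        for x in trains:
            for y in trains:
                assert log_isi_emd(x, y) == pytest.approx(log_isi_emd(y, x))
        for x, y, z in zip(trains, trains[1:], trains[2:]):
            assert log_isi_emd(x, z) <= log_isi_emd(x, y) + log_isi_emd(y, z) + 1e-12

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            log_isi_emd(SpikeTrain(times=np.array([0.1])),
                        SpikeTrain(times=np.array([0.1, 0.2, 0.3])))

    def test_network_fit_distance_excludes_degenerate_units(self):
        ref = SpikeTrain(times=np.cumsum(np.full(20, 0.1)))
        trains = [SpikeTrain(times=np.array([0.5])),  # <2 spikes: excluded
                  ref,
                  SpikeTrain(times=np.cumsum(np.full(10, 0.2)))]
        total, used = network_fit_distance(trains, ref)
        assert used == 2
        assert total == pytest.approx(log_isi_emd(trains[2], ref))

    def test_network_fit_distance_keeps_smallest(self):
        ref = SpikeTrain(times=np.cumsum(np.full(20, 0.1)))
        near = SpikeTrain(times=np.cumsum(np.full(20, 0.11)))
        far = SpikeTrain(times=np.cumsum(np.full(20, 1.0)))
        total, used = network_fit_distance([near, far], ref, n_smallest=1)
        assert used == 1
        assert total == pytest.approx(log_isi_emd(near, ref))


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_burst_ss_conservation_property(seed):
    """Burst members + single spikes account for every spike exactly once."""
    tr = random_train(np.random.default_rng(seed))
    ann = detect_bursts(tr)
    n_burst_spikes = sum(l for _, l in ann.bursts)
    assert n_burst_spikes + ann.ss_indices.size == len(tr)
    assert all(l >= 2 for _, l in ann.bursts)
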