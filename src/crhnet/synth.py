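"""Seeded synthetic inputs with the statistical structure of the in vivo
recordings: rhythmic-brief-burst / single-spiking (RB/SS) spike trains,
step-protocol patch recordings from a known ground-truth AdEx neuron, and
opto-tagging sessions.

The RB/SS generator is a two-state renewal process, deliberately independent
of the network model so that generator and analyzer can test each other
without circularity.  In the RB state, bursts of 2-6 spikes (intraburst ISIs
of a few ms with multiplicative adaptation) are separated by gamma-distributed
interburst intervals calibrated to 1.8 +/- 0.6 s; in the SS state the unit
fires as a gamma renewal process (shape > 1, so burst-range ISIs are rare).
State dwell times are exponential and a transition never splits a burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adex import AdExParams, NeuronState, StepProtocol, simulate_adex
from .metrics import SpikeTrain

__all__ = [
    "RbSsGeneratorParams",
    "OptoSessionParams",
    "LabeledTrain",
    "OptoSession",
    "SweepRecording",
    "StepProtocolRecording",
    "generate_rb_ss_train",
    "generate_patch_recording",
    "generate_opto_session",
]


@dataclass(frozen=True)
class RbSsGeneratorParams:
    #: probability of burst lengths 2..6 (mean 3.1 spikes at the default)
    burst_len_probs: tuple = (0.25, 0.45, 0.25, 0.04, 0.01)
    intraburst_isi_start: float = 0.004  # s, first intraburst ISI
    intraburst_isi_growth: float = 1.3  # multiplicative ISI adaptation per spike
    ibi_mean: float = 1.8  # s
    ibi_sd: float = 0.6  # s
    ss_rate: float = 10.0  # Hz
    ss_shape: float = 2.0  # gamma renewal shape of the SS state
    state_dwell_mean: float = 60.0  # s
    start_in_rb: bool = True
    seed: int = 0

    def __post_init__(self):
        p = np.asarray(self.burst_len_probs, float)
        if p.size != 5 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("burst_len_probs must be 5 non-negative values summing to 1")
        if min(self.intraburst_isi_start, self.ibi_mean, self.ibi_sd,
               self.state_dwell_mean) <= 0:
            raise ValueError("time constants must be positive")
        if self.intraburst_isi_growth <= 1.0:
            raise ValueError("intraburst_isi_growth must exceed 1")
        if self.ss_rate < 0:
            raise ValueError("ss_rate must be non-negative")
        # longest burst (6 spikes) must keep every intraburst ISI below 20 ms
        if self.intraburst_isi_start * self.intraburst_isi_growth ** 4 >= 0.020:
            raise ValueError("intraburst ISIs would leave the burst range")


@dataclass(frozen=True)
class OptoSessionParams:
    n_trials: int = 25
    pulse_width: float = 0.005  # s
    trial_interval: float = 2.0  # s between pulse onsets
    response_latency_mean: float = 0.0072  # s
    response_latency_sd: float = 0.0026  # s
    response_prob: float = 0.9
    background_rate: float = 3.0  # Hz
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.response_prob <= 1:
            raise ValueError("response_prob must lie in [0, 1]")
        if self.response_latency_mean <= 0:
            raise ValueError("response_latency_mean must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


@dataclass
class LabeledTrain:
    """A synthetic spike train with its ground-truth labels."""

    train: SpikeTrain
    is_burst_spike: np.ndarray  # bool per spike (burst member xor SS)
    true_bursts: list  # (start_time_s, n_spikes) per generated burst
    state_intervals: list  # (t0, t1, "RB"|"SS")


def generate_rb_ss_train(params: RbSsGeneratorParams, duration: float,
                         unit_id: str = "synth") -> LabeledTrain:
    """Generate a two-state RB/SS spike train of the given duration (s).

    Every spike carries exactly one ground-truth label (burst member or SS);
    bursts that would cross the end of the recording are not emitted, so all
    labeled bursts are complete.  Identical (params, duration) give identical
    output.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    rng = np.random.default_rng(params.seed)
    ibi_shape = (params.ibi_mean / params.ibi_sd) ** 2
    ibi_scale = params.ibi_sd ** 2 / params.ibi_mean
    lengths = np.arange(2, 7)

    times: list[float] = []
    labels: list[bool] = []
    bursts: list[tuple] = []
    intervals: list[tuple] = []

    t = 0.0
    state = "RB" if params.start_in_rb else "SS"
    while t < duration:
        dwell = rng.exponential(params.state_dwell_mean)
        t_end = min(t + dwell, duration)
        intervals.append((t, t_end, state))
        if state == "RB":
            cursor = t
            while True:
                gap = rng.gamma(ibi_shape, ibi_scale)
                start = cursor + gap
                if start >= t_end:
                    break
                n = int(rng.choice(lengths, p=params.burst_len_probs))
                isi = params.intraburst_isi_start
                spikes = [start]
                for _ in range(n - 1):
                    spikes.append(spikes[-1] + isi)
                    isi *= params.intraburst_isi_growth
                if spikes[-1] >= duration:
                    break  # never emit a truncated burst
                times.extend(spikes)
                labels.extend([True] * n)
                bursts.append((start, n))
                cursor = spikes[-1]
        else:
            if params.ss_rate > 0:
                scale = 1.0 / (params.ss_rate * params.ss_shape)
                cursor = t + rng.gamma(params.ss_shape, scale)
                while cursor < t_end:
                    if not times or cursor > times[-1]:
                        times.append(cursor)
                        labels.append(False)
                    cursor += rng.gamma(params.ss_shape, scale)
        t = t_end
        state = "SS" if state == "RB" else "RB"

    times_arr = np.array(times)
    labels_arr = np.array(labels, bool)
    order = np.argsort(times_arr, kind="stable")
    times_arr = times_arr[order]
    labels_arr = labels_arr[order]
    train = SpikeTrain(times=times_arr, t_start=0.0, t_stop=duration,
                       unit_id=unit_id)
    return LabeledTrain(train=train, is_burst_spike=labels_arr,
                        true_bursts=bursts, state_intervals=intervals)


@dataclass
class SweepRecording:
    """One current-clamp sweep: time (s), voltage (mV), current (pA)."""

    dt: float  # ms
    voltage: np.ndarray  # mV
    current: np.ndarray  # pA

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt  # ms

    def spike_times(self, threshold_mv: float = -10.0) -> np.ndarray:
        """Upward threshold crossings, in ms."""
        v = self.voltage
        crossings = np.flatnonzero((v[:-1] < threshold_mv) & (v[1:] >= threshold_mv))
        return (crossings + 1) * self.dt


@dataclass
class StepProtocolRecording:
    """A multi-sweep step-protocol recording used by the fitting penalty."""

    protocol: StepProtocol
    sweeps: list  # of SweepRecording

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


def generate_patch_recording(true_params: AdExParams,
                             protocol: StepProtocol | None = None,
                             noise_sd: float = 0.5, seed: int = 0,
                             ) -> StepProtocolRecording:
    """Simulate the step protocol on a ground-truth AdEx neuron and add
    i.i.d. Gaussian observation noise (mV) to the voltage.

    The noise is observation-only — it never enters the dynamics — so the
    noiseless trajectory remains an exact fitting target.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if protocol is None:
        protocol = StepProtocol.patch_default()
    if protocol.n_sweeps < 1:
        raise ValueError("protocol needs at least one sweep")
    rng = np.random.default_rng(seed)
    sweeps = []
    for k in range(protocol.n_sweeps):
        I = protocol.sweep_current(k)
        tr = simulate_adex(true_params, I, protocol.dt,
                           NeuronState(v=true_params.E_L, w=0.0))
        v = tr.v + (rng.normal(0.0, noise_sd, tr.v.size) if noise_sd > 0 else 0.0)
        sweeps.append(SweepRecording(dt=protocol.dt, voltage=v, current=I))
    return StepProtocolRecording(protocol=protocol, sweeps=sweeps)


@dataclass
class OptoSession:
    """A synthetic opto-tagging session: one unit plus light-pulse onsets."""

    train: SpikeTrain
    pulse_onsets: np.ndarray
    pulse_width: float
    evoked_times: np.ndarray  # ground-truth light-evoked spikes


def generate_opto_session(params: OptoSessionParams) -> OptoSession:
    """Simulate a tagging session: background Poisson spiking plus, with
    probability ``response_prob`` per trial, one short-latency evoked spike
    after each light onset."""
    rng = np.random.default_rng(params.seed)
    onsets = (1.0 + np.arange(params.n_trials) * params.trial_interval)
    t_stop = onsets[-1] + params.trial_interval
    n_bg = rng.poisson(params.background_rate * t_stop)
    spikes = list(rng.uniform(0.0, t_stop, n_bg))
    evoked = []
    for o in onsets:
        if rng.uniform() < params.response_prob:
            lat = -1.0
            while lat <= 0.0005:  # latency strictly positive
                lat = rng.normal(params.response_latency_mean,
                                 params.response_latency_sd)
            evoked.append(o + lat)
    spikes.extend(evoked)
    spikes = np.unique(np.asarray(spikes, float))
    train = SpikeTrain(times=spikes, t_start=0.0, t_stop=t_stop, unit_id="opto")
    return OptoSession(train=train, pulse_onsets=onsets,
                       pulse_width=params.pulse_width,
                       evoked_times=np.asarray(evoked))
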