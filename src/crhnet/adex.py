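"""Adaptive exponential integrate-and-fire (AdEx) neuron model.

The membrane potential ``v`` (mV) and adaptation current ``w`` (pA) evolve as

    C dv/dt = g_L (E_L - v) + g_L * Delta_T * exp((v - V_T) / Delta_T)
              + g_e (E_e - v) + g_i (E_i - v) - w + I(t)
    tau_w dw/dt = a (v - E_L) - w

with a spike emitted when ``v`` crosses ``spike_cutoff``, followed by the
reset ``v -> V_R``, ``w -> w + b``.  Units are the electrophysiologist's
convention throughout: pF, nS, mV, ms, pA (so pA/pF = mV/ms).

The model is the single-neuron building block of the recurrent PVN network
(:mod:`crhnet.network`) and the object fitted to current-clamp step
recordings (:mod:`crhnet.fitting`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

__all__ = [
    "AdExParams",
    "NeuronState",
    "StepProtocol",
    "FICurve",
    "AdExTrace",
    "CRH_PARAMS_MEAN",
    "CRH_PARAMS_SD",
    "simulate_adex",
    "fi_curve",
    "subthreshold_mse",
    "sample_population",
]

_EXP_ARG_CAP = 30.0  # caps the exponential term; crossings are caught by spike_cutoff


@dataclass(frozen=True)
class AdExParams:
    """The nine AdEx constants plus the numerical spike-detection ceiling.

    ``spike_cutoff`` defaults to ``V_T + 5 * Delta_T``; any upward crossing of
    it counts as a spike.  ``tau_m = C / g_L`` is derived, never stored.
    """

    C: float  # pF
    g_L: float  # nS
    E_L: float  # mV
    Delta_T: float  # mV
    V_T: float  # mV
    V_R: float  # mV
    tau_w: float  # ms
    a: float  # nS
    b: float  # pA
    spike_cutoff: float | None = None  # mV

    def __post_init__(self):
        if self.C <= 0 or self.g_L <= 0 or self.Delta_T <= 0 or self.tau_w <= 0:
            raise ValueError("C, g_L, Delta_T and tau_w must be positive")
        if self.b < 0:
            raise ValueError("spike-triggered adaptation b must be non-negative")
        if self.spike_cutoff is None:
            object.__setattr__(self, "spike_cutoff", self.V_T + 5.0 * self.Delta_T)
        if not self.V_R < self.spike_cutoff:
            raise ValueError("V_R must lie below spike_cutoff")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L

    def with_(self, **kw) -> "AdExParams":
        return replace(self, **kw)


#: Population mean of the CRH-neuron parameter fits (ex vivo patch-clamp, n=33).
CRH_PARAMS_MEAN = AdExParams(
    C=22.0, g_L=0.9, E_L=-67.9, Delta_T=12.1, V_T=-47.2, V_R=-58.8,
    tau_w=98.2, a=0.082, b=17.9,
)

#: Population standard deviation of the same fits, field for field.
CRH_PARAMS_SD = dict(
    C=2.6, g_L=0.19, E_L=2.9, Delta_T=2.0, V_T=6.5, V_R=2.5,
    tau_w=54.3, a=0.13, b=9.8,
)


@dataclass
class NeuronState:
    v: float  # mV
    w: float  # pA


@dataclass(frozen=True)
class StepProtocol:
    """A multi-sweep piecewise-constant current-injection protocol.

    ``sweeps[k]`` is a list of ``(amplitude_pA, duration_ms)`` segments.
    """

    sweeps: tuple
    dt: float = 0.05  # ms

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for sweep in self.sweeps:
            for _, dur in sweep:
                if dur <= 0:
                    raise ValueError("segment durations must be positive")

    @classmethod
    def patch_default(cls, n_sweeps: int = 14, dt: float = 0.05,
                      baseline_ms: float = 100.0, hyper_pA: float = -20.0,
                      hyper_ms: float = 200.0, gap_ms: float = 100.0,
                      step_increment_pA: float = 10.0, step_ms: float = 500.0,
                      tail_ms: float = 100.0) -> "StepProtocol":
        """The standard patch protocol: a -20 pA / 200 ms hyperpolarizing pulse
        followed by a depolarizing step growing in 10 pA increments (500 ms),
        14 sweeps by default."""
        sweeps = []
        for k in range(1, n_sweeps + 1):
            sweeps.append((
                (0.0, baseline_ms),
                (hyper_pA, hyper_ms),
                (0.0, gap_ms),
                (k * step_increment_pA, step_ms),
                (0.0, tail_ms),
            ))
        return cls(sweeps=tuple(sweeps), dt=dt)

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_duration(self, k: int) -> float:
        return sum(dur for _, dur in self.sweeps[k])

    def sweep_current(self, k: int, dt: float | None = None) -> np.ndarray:
        """Sampled injected current (pA) for sweep ``k``."""
        dt = self.dt if dt is None else dt
        parts = []
        for amp, dur in self.sweeps[k]:
            parts.append(np.full(int(round(dur / dt)), amp))
        return np.concatenate(parts)

    def depolarizing_segment(self, k: int) -> tuple[float, float, float]:
        """(t_start_ms, t_end_ms, amplitude_pA) of the largest-amplitude segment."""
        t = 0.0
        best = (0.0, 0.0, -np.inf)
        for amp, dur in self.sweeps[k]:
            if amp > best[2]:
                best = (t, t + dur, amp)
            t += dur
        return best

    def step_amplitudes(self) -> np.ndarray:
        return np.array([self.depolarizing_segment(k)[2] for k in range(self.n_sweeps)])


@dataclass
class FICurve:
    """Firing rate (Hz) as a function of injected step current (pA)."""

    currents: np.ndarray
    rates: np.ndarray

    def __post_init__(self):
        self.currents = np.asarray(self.currents, float)
        self.rates = np.asarray(self.rates, float)
        if self.currents.shape != self.rates.shape:
            raise ValueError("currents and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class AdExTrace:
    """Result of a single-neuron simulation."""

    dt: float  # ms
    v: np.ndarray  # mV
    w: np.ndarray  # pA
    spike_times: np.ndarray  # ms

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.v.size) * self.dt


@njit(cache=True)
def _adex_kernel(I, dt, C, gL, EL, DT, VT, VR, tauw, a, b, cutoff, v0, w0):
    n = I.size
    v_tr = np.empty(n)
    w_tr = np.empty(n)
    spikes = np.empty(n, np.int64)
    n_sp = 0
    v = v0
    w = w0
    ok = True
    for i in range(n):
        v_tr[i] = v
        w_tr[i] = w
        arg = (v - VT) / DT
        if arg > _EXP_ARG_CAP:
            arg = _EXP_ARG_CAP
        dv = (gL * (EL - v) + gL * DT * np.exp(arg)
              + I[i] - w) / C
        dw = (a * (v - EL) - w) / tauw
        v = v + dt * dv
        w = w + dt * dw
        if not (np.isfinite(v) and np.isfinite(w)):
            ok = False
            break
        if v >= cutoff:
            v = VR
            w = w + b
            spikes[n_sp] = i + 1
            n_sp += 1
    return v_tr, w_tr, spikes[:n_sp], ok


def simulate_adex(params: AdExParams, injected, dt: float,
                  initial: NeuronState | None = None) -> AdExTrace:
    """Forward-Euler integration of the AdEx equations under an injected
    current.

    Parameters
    ----------
    injected : array_like
        Injected current in pA sampled at ``dt``; its length sets the
        simulated span.
    dt : float
        Integration step in ms (0.025 ms is the single-neuron fitting
        default, 0.1 ms the network default).
    initial : NeuronState, optional
        Initial (v, w); defaults to (E_L, 0).

    Returns
    -------
    AdExTrace with the voltage/adaptation traces and spike times (ms).
    On each spike v resets to V_R and w is incremented by b.

    Raises
    ------
    FloatingPointError if the state diverges (never a silent NaN).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    I = np.ascontiguousarray(injected, dtype=float)
    if initial is None:
        initial = NeuronState(v=params.E_L, w=0.0)
    v_tr, w_tr, spikes, ok = _adex_kernel(
        I, dt, params.C, params.g_L, params.E_L, params.Delta_T, params.V_T,
        params.V_R, params.tau_w, params.a, params.b, params.spike_cutoff,
        initial.v, initial.w)
    if not ok:
        raise FloatingPointError("AdEx integration diverged (non-finite state)")
    return AdExTrace(dt=dt, v=v_tr, w=w_tr, spike_times=spikes * dt)


def fi_curve(params: AdExParams, protocol: StepProtocol,
             dt: float | None = None) -> FICurve:
    """Firing rate vs injected current over a step protocol.

    The rate of each sweep is the spike count inside the depolarizing
    segment divided by that segment's duration.
    """
    dt = protocol.dt if dt is None else dt
    currents = []
    rates = []
    for k in range(protocol.n_sweeps):
        tr = simulate_adex(params, protocol.sweep_current(k, dt), dt)
        t0, t1, amp = protocol.depolarizing_segment(k)
        n = np.count_nonzero((tr.spike_times >= t0) & (tr.spike_times < t1))
        currents.append(amp)
        rates.append(n / ((t1 - t0) * 1e-3))
    return FICurve(np.array(currents), np.array(rates))


def subthreshold_mse(model_v: np.ndarray, reference_v: np.ndarray, dt: float,
                     reference_spike_times: Sequence[float] = (),
                     spike_mask_window: float = 8.0) -> float:
    """Mean squared voltage error (mV^2) over subthreshold samples.

    Samples within ``spike_mask_window`` ms of a reference spike are excluded,
    so the comparison is restricted to the subthreshold trajectory.
    Traces must share the time base (same dt and length).
    """
    model_v = np.asarray(model_v, float)
    reference_v = np.asarray(reference_v, float)
    if model_v.shape != reference_v.shape:
        raise ValueError("traces must share a common time base")
    keep = np.ones(model_v.size, bool)
    half = spike_mask_window
    t = np.arange(model_v.size) * dt
    for ts in reference_spike_times:
        keep &= ~((t >= ts - half) & (t <= ts + half))
    if not np.any(keep):
        return 0.0
    d = model_v[keep] - reference_v[keep]
    return float(np.mean(d * d))


def sample_population(mean_params: AdExParams, sd_params: dict, n: int,
                      seed: int | np.random.Generator = 0) -> list[AdExParams]:
    """Draw a heterogeneous neuron population.

    Each parameter is drawn independently Gaussian(mean, sd) and redrawn until
    the invariants hold: C, g_L, Delta_T, tau_w > 0; b >= 0; V_R < V_T
    (a reset above threshold would spike indefinitely); a > -g_L (keeps the
    subthreshold fixed point stable).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fields = ["C", "g_L", "E_L", "Delta_T", "V_T", "V_R", "tau_w", "a", "b"]
    out = []
    for _ in range(n):
        for _attempt in range(10_000):
            draw = {f: rng.normal(getattr(mean_params, f), sd_params.get(f, 0.0))
                    for f in fields}
            if (draw["C"] > 0 and draw["g_L"] > 0 and draw["Delta_T"] > 0
                    and draw["tau_w"] > 0 and draw["b"] >= 0
                    and draw["V_R"] < draw["V_T"]
                    and draw["a"] > -draw["g_L"]):
                out.append(AdExParams(**draw))
                break
        else:  # pragma: no cover - pathological sd choices only
            raise RuntimeError("rejection sampling failed to satisfy invariants")
    return out
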