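"""Network clamp: extract the summed synaptic + adaptation current a model
neuron receives inside the network and turn it into an injectable stimulus
waveform.

The extracted current at each 100 µs step is

    I(t) = g_e(t) (E_e - v(t)) + g_i(t) (E_i - v(t)) - w(t)

The leak current g_L (E_L - v) is deliberately excluded — the biological
neuron on the receiving end expresses its leak intrinsically.  The waveform
can be capped at +/- 200 pA (pointwise clipping, which preserves event
timings by construction) and truncated to test the necessity of the
preceding network input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .adex import AdExParams, NeuronState, simulate_adex
from .network import StateTrace

__all__ = [
    "CurrentWaveform",
    "extract_network_current",
    "cap_current",
    "truncate_preceding",
    "truncation_family",
    "export_waveform",
    "read_waveform",
    "export_episodic",
    "replay_waveform",
    "closed_loop_spike_match",
]


@dataclass
class CurrentWaveform:
    """Time-stamped injected-current series at a fixed step (100 µs default)."""

    samples: np.ndarray  # pA
    dt: float = 1e-4  # s
    t0: float = 0.0  # s

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


def extract_network_current(trace: StateTrace) -> CurrentWaveform:
    """Network current received by a tagged neuron, from its recorded
    per-step state (g_e, g_i, v, w).  Leak excluded."""
    syn = trace.synapse
    I = (trace.g_e * (syn.E_e - trace.v)
         + trace.g_i * (syn.E_i - trace.v)
         - trace.w)
    return CurrentWaveform(samples=I, dt=trace.dt)


def cap_current(waveform: CurrentWaveform, limit_pA: float = 200.0) -> CurrentWaveform:
    """Clip samples to [-limit, +limit] pA; sample count, dt and event
    timings are unchanged."""
    if limit_pA <= 0:
        raise ValueError("limit must be positive")
    return replace(waveform, samples=np.clip(waveform.samples, -limit_pA, limit_pA))


def truncate_preceding(waveform: CurrentWaveform, keep_window_s: float,
                       event_time_s: float) -> CurrentWaveform:
    """Zero all samples earlier than ``event_time - keep_window`` (the
    truncated-current control: only the final ``keep_window`` of input before
    an event survives)."""
    if not waveform.t0 <= event_time_s <= waveform.t0 + waveform.duration:
        raise ValueError("event time outside the waveform span")
    if keep_window_s > waveform.duration:
        raise ValueError("keep window exceeds the waveform span")
    cut = event_time_s - keep_window_s
    out = waveform.samples.copy()
    out[waveform.t < cut] = 0.0
    return replace(waveform, samples=out)


def truncation_family(waveform: CurrentWaveform, event_time_s: float,
                      keep_windows_s=(0.05, 0.1, 0.2, 0.4, 0.8)) -> dict:
    """Family of truncated controls with increasing amounts of preserved
    preceding input — the stimulus set for a shortest-evoked-ISI curve.

    Returns ``{keep_window_s: CurrentWaveform}``.
    """
    return {w: truncate_preceding(waveform, w, event_time_s)
            for w in keep_windows_s}


def export_waveform(waveform: CurrentWaveform, path) -> None:
    """Write the canonical two-column text stimulus (time_s, current_pA).

    Round-trips bit-exact through :func:`read_waveform`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# network-clamp stimulus; dt_s={waveform.dt!r} t0_s={waveform.t0!r}\n")
        fh.write("time_s\tcurrent_pA\n")
        for t, x in zip(waveform.t, waveform.samples):
            fh.write(f"{float(t)!r}\t{float(x)!r}\n")


def read_waveform(path) -> CurrentWaveform:
    path = Path(path)
    dt, t0 = 1e-4, 0.0
    samples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("dt_s="):
                        dt = float(tok[5:])
                    elif tok.startswith("t0_s="):
                        t0 = float(tok[5:])
                continue
            if not line or line.startswith("time_s"):
                continue
            samples.append(float(line.split("\t")[1]))
    return CurrentWaveform(samples=np.array(samples), dt=dt, t0=t0)


def export_episodic(waveform: CurrentWaveform, path, sweep_length_s: float | None = None,
                    name: str = "netclamp") -> None:
    """Episodic text stimulus table (one column per sweep) for import into
    patch-clamp acquisition software."""
    path = Path(path)
    n = waveform.samples.size
    per = n if sweep_length_s is None else int(round(sweep_length_s / waveform.dt))
    per = max(per, 1)
    n_sweeps = max(1, int(np.ceil(n / per)))
    with open(path, "w") as fh:
        fh.write(f'"{name}"\tepisodic stimulus\tdt_ms={waveform.dt * 1e3:g}\n')
        fh.write("\t".join([f"sweep_{k}_pA" for k in range(n_sweeps)]) + "\n")
        for row in range(per):
            cells = []
            for k in range(n_sweeps):
                i = k * per + row
                cells.append(f"{waveform.samples[i]:.6f}" if i < n else "")
            fh.write("\t".join(cells) + "\n")


def replay_waveform(waveform: CurrentWaveform, params: AdExParams,
                    v0: float | None = None):
    """Inject a waveform into an isolated AdEx neuron.

    The extracted current already contains the network neuron's adaptation
    current -w(t), so the playback neuron's own adaptation is disabled
    (a = 0, b = 0); its leak is kept, mirroring the intrinsic leak of a
    biological neuron.  Returns the :class:`~crhnet.adex.AdExTrace` (times
    in ms).
    """
    playback = params.with_(a=0.0, b=0.0)
    v0 = params.E_L if v0 is None else v0
    return simulate_adex(playback, waveform.samples, waveform.dt * 1e3,
                         NeuronState(v=v0, w=0.0))


def closed_loop_spike_match(trace: StateTrace, network_spike_times_s,
                            tol_s: float = 1e-3, capped: bool = False) -> dict:
    """Closed-loop check: replay the (optionally capped) extracted current
    into a matched isolated neuron and score how many in-network spikes are
    reproduced within ``tol_s``.

    ``network_spike_times_s`` are the tagged neuron's spike times from the
    network run.  Returns a dict with both spike-time arrays and the matched
    fraction.
    """
    wf = extract_network_current(trace)
    if capped:
        wf = cap_current(wf)
    tr = replay_waveform(wf, trace.params, v0=trace.v[0])
    replay_s = tr.spike_times * 1e-3
    net_s = np.asarray(network_spike_times_s, float)
    matched = 0
    for t in net_s:
        if replay_s.size and np.min(np.abs(replay_s - t)) <= tol_s:
            matched += 1
    frac = matched / net_s.size if net_s.size else 1.0
    return {"network_spikes_s": net_s, "replay_spikes_s": replay_s,
            "match_fraction": frac}
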