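"""Recurrent excitatory-inhibitory spiking network of the paraventricular
nucleus: 500 CRH (AdEx, heterogeneous, ex vivo-fitted) and 500 GABA neurons.

Wiring and transmission:

* CRH -> GABA: sparse (2 %) projection through a slow alpha synapse
  (tau_CRH ~ 233 ms, weight w_CRH) standing in for metabotropic CRHR1
  excitation.  On a presynaptic spike the auxiliary variable jumps
  ``y -> y + w_CRH``; the conductance follows
  ``tau d[CRH]/dt = y - [CRH]``, ``tau dy/dt = -y``.
* GABA -> CRH: sparse (2 %) fast conductance synapse (tau_i, w_i, E_i) with
  stochastic release: each presynaptic spike releases with per-synapse
  probability p.  A manipulation can re-draw p inside a range; after a
  *transient* drop, p recovers toward 1 by the slow logistic law
  ``dp/dt = p (1 - p) / tau_p`` (tau_p = 80 s).  An optional depression mode
  (``release_depression=True``) additionally resets p -> 0.1 after every
  successful release.
* External drive: each CRH neuron receives an independent homogeneous
  Poisson train of fast EPSPs (rate ``epsp_rate``, instantaneous rise
  ``g_e -> g_e + w_e``, exponential decay tau_e).  GABA neurons receive no
  external drive.
* Spike-triggered adaptation: each CRH neuron's b is drawn uniformly from
  ``adaptation_b_range``; a triggered increase jumps b by ``b_inc`` which
  decays back with tau_br = 40 s.

Integration is forward Euler at dt = 0.1 ms (conductance decays use their
exact exponential update).  All randomness is reproducible from the seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .adex import AdExParams, CRH_PARAMS_MEAN, CRH_PARAMS_SD, sample_population
from .metrics import SpikeTrain

__all__ = [
    "SynapseParams",
    "NetworkConfig",
    "ManipulationEvent",
    "ManipulationSchedule",
    "PVNNetwork",
    "NetworkSimulation",
    "StateTrace",
    "GABA_PARAMS_DEFAULT",
    "build_network",
    "simulate_poisson_driven_neuron",
    "adaptation_decay",
    "logistic_recovery",
]


@dataclass(frozen=True)
class SynapseParams:
    E_e: float = 0.0  # mV
    E_i: float = -80.0  # mV
    tau_e: float = 12.5  # ms
    tau_i: float = 20.4  # ms
    tau_CRH: float = 232.6  # ms
    w_e: float = 3.9  # nS
    w_i: float = 3.3  # nS
    w_CRH: float = 0.005  # nS
    tau_p: float = 80.0  # s, release-probability recovery
    tau_br: float = 40.0  # s, adaptation-increment decay

    def __post_init__(self):
        if min(self.tau_e, self.tau_i, self.tau_CRH, self.tau_p, self.tau_br) <= 0:
            raise ValueError("all synaptic time constants must be positive")
        if min(self.w_e, self.w_i, self.w_CRH) < 0:
            raise ValueError("synaptic weights must be non-negative")


#: Default tonic-spiking interneuron parameter set for the GABA population
#: (no spike-triggered adaptation, b = 0).  Its rest sits a few mV below
#: threshold so that the pA-scale slow CRH drive (w_CRH = 0.005 nS at 2 %
#: connectivity) modulates firing; the shallow reset lets the cell re-fire
#: quickly while driven, and the small subthreshold adaptation (a, tau_w)
#: makes inhibitory episodes self-limiting.  Calibrated once against the
#: baseline rhythmic-bursting regime of the fitted network, then frozen;
#: any tonic-spiking set of comparable rheobase is admissible.
GABA_PARAMS_DEFAULT = AdExParams(
    C=30.0, g_L=1.0, E_L=-52.8, Delta_T=2.0, V_T=-50.0, V_R=-51.5,
    tau_w=500.0, a=0.2, b=0.0,
)


@dataclass(frozen=True)
class NetworkConfig:
    n_crh: int = 500
    n_gaba: int = 500
    conn_prob_crh_to_gaba: float = 0.02
    conn_prob_gaba_to_crh: float = 0.02
    epsp_rate: float = 30.0  # Hz
    gaba_pr_range: tuple = (0.9, 1.0)
    adaptation_b_range: tuple = (5.0, 18.0)  # pA
    synapse: SynapseParams = SynapseParams()
    gaba_params: AdExParams = GABA_PARAMS_DEFAULT
    #: optional per-field Gaussian spread of the GABA population (same
    #: convention as crh_params_sd); zero spread = identical interneurons
    gaba_params_sd: dict | None = None
    crh_params_mean: AdExParams = CRH_PARAMS_MEAN
    crh_params_sd: dict = field(default_factory=lambda: dict(CRH_PARAMS_SD))
    release_depression: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_crh <= 0 or self.n_gaba <= 0:
            raise ValueError("population counts must be positive")
        for p in (self.conn_prob_crh_to_gaba, self.conn_prob_gaba_to_crh):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must lie in [0, 1]")
        for lo, hi in (self.gaba_pr_range, self.adaptation_b_range):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo <= hi)")
        if not 0.0 < self.gaba_pr_range[0] <= 1.0 or self.gaba_pr_range[1] > 1.0:
            raise ValueError("gaba_pr_range must lie in (0, 1]")
        if self.epsp_rate < 0:
            raise ValueError("epsp_rate must be non-negative")

    def scaled(self, n_crh: int, n_gaba: int) -> "NetworkConfig":
        """Smaller network with the expected synaptic in-degree preserved
        (connection probabilities rescaled by the population ratio)."""
        return replace(
            self, n_crh=n_crh, n_gaba=n_gaba,
            conn_prob_crh_to_gaba=min(1.0, self.conn_prob_crh_to_gaba
                                      * self.n_crh / n_crh),
            conn_prob_gaba_to_crh=min(1.0, self.conn_prob_gaba_to_crh
                                      * self.n_gaba / n_gaba),
        )


@dataclass(frozen=True)
class ManipulationEvent:
    time: float  # s
    action: str  # set_gaba_pr_range | trigger_adaptation_increase |
    #              set_adaptation_range | set_epsp_rate
    payload: dict

    _ACTIONS = ("set_gaba_pr_range", "trigger_adaptation_increase",
                "set_adaptation_range", "set_epsp_rate")

    def __post_init__(self):
        if self.action not in self._ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")


@dataclass
class ManipulationSchedule:
    events: list

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")

    @classmethod
    def pr_drop(cls, time: float, pr_range=(0.01, 0.2), transient: bool = True):
        return cls([ManipulationEvent(time, "set_gaba_pr_range",
                                      {"range": tuple(pr_range),
                                       "transient": transient})])

    @classmethod
    def pr_drop_with_adaptation(cls, time: float, pr_range=(0.01, 0.2),
                                b_range=(36.0, 50.0), transient: bool = True):
        return cls([
            ManipulationEvent(time, "set_gaba_pr_range",
                              {"range": tuple(pr_range), "transient": transient}),
            ManipulationEvent(time, "trigger_adaptation_increase",
                              {"range": tuple(b_range)}),
        ])

    @classmethod
    def epsp_step(cls, time: float, rate: float = 60.0):
        return cls([ManipulationEvent(time, "set_epsp_rate", {"rate": rate})])


def logistic_recovery(p0: float, elapsed_s: float, tau_p: float) -> float:
    """Closed-form solution of dp/dt = p (1 - p) / tau_p from p0."""
    if p0 >= 1.0:
        return 1.0
    p0 = max(p0, 1e-9)
    return 1.0 / (1.0 + (1.0 / p0 - 1.0) * np.exp(-elapsed_s / tau_p))


def adaptation_decay(b_inc0: float, elapsed_s: float, tau_br: float) -> float:
    """Exponential decay of a triggered adaptation increment (pA)."""
    return b_inc0 * np.exp(-elapsed_s / tau_br)


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True)
def _net_kernel(n_steps, step0, dt,
                v, w, ge, gi, crh_g, crh_y,
                C, gL, EL, DT, VT, VR, tauw, a_, cutoff, b_base, b_inc,
                n_crh, n_gaba,
                cg_indptr, cg_targets, gc_indptr, gc_targets,
                p0, p_t0, p_rec,
                Ee, Ei, we, wi, wcrh,
                dec_e, dec_i, dec_crh, dec_br, alpha_h, tau_p_s,
                epsp_prob, release_depression,
                sp_step, sp_unit, n_sp_in,
                tagged_idx, tag_v, tag_w, tag_ge, tag_gi):
    n = n_crh + n_gaba
    n_sp = n_sp_in
    cap = sp_step.size
    n_tag = tagged_idx.size
    _EXPCAP = 30.0
    for s in range(n_steps):
        # external Poisson EPSPs onto CRH neurons
        for i in range(n_crh):
            if np.random.random() < epsp_prob:
                ge[i] += we
        # tagged-state recording: exactly the values entering this step's
        # membrane update (so network-clamp replay is faithful)
        for k in range(n_tag):
            i = tagged_idx[k]
            tag_v[k, step0 + s] = v[i]
            tag_w[k, step0 + s] = w[i]
            tag_ge[k, step0 + s] = ge[i]
            tag_gi[k, step0 + s] = gi[i]
        # membrane + adaptation update (forward Euler)
        for i in range(n):
            if i < n_crh:
                gexc = ge[i]
            else:
                gexc = crh_g[i - n_crh]
            arg = (v[i] - VT[i]) / DT[i]
            if arg > _EXPCAP:
                arg = _EXPCAP
            dv = (gL[i] * (EL[i] - v[i]) + gL[i] * DT[i] * np.exp(arg)
                  + gexc * (Ee - v[i]) + gi[i] * (Ei - v[i]) - w[i]) / C[i]
            dw = (a_[i] * (v[i] - EL[i]) - w[i]) / tauw[i]
            v[i] = v[i] + dt * dv
            w[i] = w[i] + dt * dw
        # conductance decay (exact exponential update)
        for i in range(n):
            ge[i] *= dec_e
            gi[i] *= dec_i
        for j in range(n_gaba):
            crh_g[j] = dec_crh * (crh_g[j] + crh_y[j] * alpha_h)
            crh_y[j] *= dec_crh
        for i in range(n_crh):
            b_inc[i] *= dec_br
        # spike detection, reset, propagation
        t_s = (step0 + s + 1) * dt * 1e-3
        for i in range(n):
            if v[i] >= cutoff[i]:
                v[i] = VR[i]
                w[i] += b_base[i] + b_inc[i]
                if n_sp >= cap:
                    return n_sp, 2  # spike buffer overflow
                sp_step[n_sp] = step0 + s + 1
                sp_unit[n_sp] = i
                n_sp += 1
                if i < n_crh:
                    for q in range(cg_indptr[i], cg_indptr[i + 1]):
                        crh_y[cg_targets[q]] += wcrh
                else:
                    j = i - n_crh
                    for q in range(gc_indptr[j], gc_indptr[j + 1]):
                        p = p0[q]
                        if p_rec[q] == 1 and p < 1.0:
                            pp = p if p > 1e-9 else 1e-9
                            p = 1.0 / (1.0 + (1.0 / pp - 1.0)
                                       * np.exp(-(t_s - p_t0[q]) / tau_p_s))
                        if np.random.random() < p:
                            gi[gc_targets[q]] += wi
                            if release_depression == 1:
                                p0[q] = 0.1
                                p_t0[q] = t_s
                                p_rec[q] = 1
            elif not v[i] == v[i]:  # NaN guard: never fail silently
                return n_sp, 1
    return n_sp, 0


@dataclass
class StateTrace:
    """Per-step state record of one tagged CRH neuron (used by the
    network-clamp extraction)."""

    neuron_index: int
    dt: float  # s
    v: np.ndarray  # mV
    w: np.ndarray  # pA
    g_e: np.ndarray  # nS
    g_i: np.ndarray  # nS
    params: AdExParams
    synapse: SynapseParams


class NetworkSimulation:
    """Result bundle of one network run: per-neuron spike trains plus
    optional tagged-state traces."""

    def __init__(self, config, dt_ms, duration, crh_trains, gaba_trains,
                 traces, seed, schedule=None):
        self.config = config
        self.dt_ms = dt_ms
        self.duration = duration
        self.crh_trains: list[SpikeTrain] = crh_trains
        self.gaba_trains: list[SpikeTrain] = gaba_trains
        self.traces: dict[int, StateTrace] = traces
        self.seed = seed
        self.schedule = schedule

    def crh_rates(self, t_min: float = 0.0, t_max: float | None = None) -> np.ndarray:
        """Per-CRH-neuron firing rate (Hz) over [t_min, t_max]."""
        t_max = self.duration if t_max is None else t_max
        span = t_max - t_min
        return np.array([np.count_nonzero((tr.times >= t_min) & (tr.times < t_max))
                         / span for tr in self.crh_trains])

    def crh_burst_rates(self, criterion=None, t_min: float = 0.0,
                        t_max: float | None = None) -> np.ndarray:
        """Per-CRH-neuron burst rate (bursts/s) under the ISI criterion."""
        from .metrics import BurstCriterion, detect_bursts
        criterion = criterion or BurstCriterion()
        t_max = self.duration if t_max is None else t_max
        span = t_max - t_min
        out = np.empty(len(self.crh_trains))
        for k, tr in enumerate(self.crh_trains):
            sel = tr.times[(tr.times >= t_min) & (tr.times < t_max)]
            sub = SpikeTrain(times=sel, t_start=t_min, t_stop=t_max,
                             unit_id=tr.unit_id)
            out[k] = detect_bursts(sub, criterion).n_bursts / span
        return out

    def summary(self, t_min: float = 0.0) -> dict:
        """Population summary over [t_min, end]: mean/SD firing and burst
        rates of the CRH population and the mean GABA rate."""
        rates = self.crh_rates(t_min)
        brates = self.crh_burst_rates(t_min=t_min)
        g_span = self.duration - t_min
        g = np.array([np.count_nonzero(tr.times >= t_min) / g_span
                      for tr in self.gaba_trains])
        return {
            "crh_rate_mean_hz": float(rates.mean()),
            "crh_rate_sd_hz": float(rates.std()),
            "crh_burst_rate_mean_per_s": float(brates.mean()),
            "crh_burst_rate_sd_per_s": float(brates.std()),
            "gaba_rate_mean_hz": float(g.mean()),
            "duration_s": float(self.duration),
            "n_crh": len(self.crh_trains),
            "n_gaba": len(self.gaba_trains),
        }


class PVNNetwork:
    """The built network: neuron populations, connectivity, per-synapse
    release probabilities and the per-neuron adaptation increments.

    Construction is deterministic under ``config.seed``.  Use
    :meth:`simulate` to run it; each call starts from the resting initial
    condition (v = E_L, w = 0, conductances 0, p at its built values).
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        syn = config.synapse

        crh = sample_population(config.crh_params_mean, config.crh_params_sd,
                                config.n_crh, rng)
        lo, hi = config.adaptation_b_range
        self.crh_b = rng.uniform(lo, hi, config.n_crh)
        self.crh_params = crh

        if config.gaba_params_sd:
            gaba = sample_population(config.gaba_params, config.gaba_params_sd,
                                     config.n_gaba, rng)
        else:
            gaba = [config.gaba_params] * config.n_gaba
        self.gaba_params_population = gaba

        n = config.n_crh + config.n_gaba
        self._par = {}
        for name in ("C", "g_L", "E_L", "Delta_T", "V_T", "V_R", "tau_w", "a",
                     "spike_cutoff"):
            vals = [getattr(p, name) for p in crh]
            vals += [getattr(p, name) for p in gaba]
            self._par[name] = np.array(vals, float)
        self.b_base = np.concatenate([self.crh_b, np.zeros(config.n_gaba)])

        # connectivity (Bernoulli, CSR layout)
        m_cg = rng.random((config.n_crh, config.n_gaba)) < config.conn_prob_crh_to_gaba
        m_gc = rng.random((config.n_gaba, config.n_crh)) < config.conn_prob_gaba_to_crh
        self.cg_indptr, self.cg_targets = _to_csr(m_cg)
        self.gc_indptr, self.gc_targets = _to_csr(m_gc)
        plo, phi = config.gaba_pr_range
        self.p_release = rng.uniform(plo, phi, self.gc_targets.size)

    @property
    def n_gaba_to_crh_synapses(self) -> int:
        return self.gc_targets.size

    @property
    def n_crh_to_gaba_synapses(self) -> int:
        return self.cg_targets.size

    def simulate(self, duration: float, schedule: ManipulationSchedule | None = None,
                 record: Sequence[int] = (), dt: float = 0.1,
                 seed: int | None = None, override_E_L: dict | None = None,
                 max_rate_hz: float = 120.0) -> NetworkSimulation:
        """Run the network for ``duration`` seconds.

        Parameters
        ----------
        schedule : ManipulationSchedule, optional
            Timed manipulations (release-probability ranges, adaptation
            triggers, EPSP-rate steps) applied at their event times.
        record : sequence of int
            CRH neuron indices whose (v, w, g_e, g_i) are recorded every
            step (needed for network-clamp extraction).
        dt : float
            Euler step in ms (0.1 default).
        seed : int, optional
            Simulation seed (Poisson drive + stochastic release); defaults
            to ``config.seed + 1``.
        override_E_L : dict, optional
            Per-CRH-neuron resting-potential overrides (e.g. clamping a
            tagged neuron to the mean ex vivo rest before extraction).
        max_rate_hz : float
            Sizing bound for the spike buffer; a run producing more spikes
            than this mean rate fails loudly rather than truncating.
        """
        if duration <= 0:
            raise ValueError("duration must be positive")
        cfg = self.config
        syn = cfg.synapse
        n = cfg.n_crh + cfg.n_gaba
        seed = cfg.seed + 1 if seed is None else seed
        events = list(schedule.events) if schedule is not None else []
        for e in events:
            if not 0.0 <= e.time <= duration:
                raise ValueError("schedule event outside the simulated span")

        par = {k: a.copy() for k, a in self._par.items()}
        if override_E_L:
            for idx, el in override_E_L.items():
                par["E_L"][idx] = el
        v = par["E_L"].copy()
        w = np.zeros(n)
        ge = np.zeros(n)
        gi = np.zeros(n)
        crh_g = np.zeros(cfg.n_gaba)
        crh_y = np.zeros(cfg.n_gaba)
        b_base = self.b_base.copy()
        b_inc = np.zeros(n)
        p0 = self.p_release.copy()
        p_t0 = np.zeros(p0.size)
        p_rec = np.zeros(p0.size, np.uint8)
        epsp_rate = cfg.epsp_rate

        n_steps_total = int(round(duration * 1000.0 / dt))
        cap = int(n * duration * max_rate_hz) + 1000
        sp_step = np.empty(cap, np.int64)
        sp_unit = np.empty(cap, np.int32)
        tagged = np.array(sorted(record), np.int64)
        tag_v = np.zeros((tagged.size, n_steps_total))
        tag_w = np.zeros((tagged.size, n_steps_total))
        tag_ge = np.zeros((tagged.size, n_steps_total))
        tag_gi = np.zeros((tagged.size, n_steps_total))

        dec_e = np.exp(-dt / syn.tau_e)
        dec_i = np.exp(-dt / syn.tau_i)
        dec_crh = np.exp(-dt / syn.tau_CRH)
        alpha_h = dt / syn.tau_CRH
        dec_br = np.exp(-dt * 1e-3 / syn.tau_br)

        _seed_kernel(seed % (2 ** 31))
        host_rng = np.random.default_rng((seed + 7919) % (2 ** 31))

        # chunk the run at schedule-event boundaries
        boundaries = sorted({int(round(e.time * 1000.0 / dt)) for e in events})
        boundaries = [b for b in boundaries if 0 < b <= n_steps_total]
        chunk_edges = [0] + boundaries + [n_steps_total]
        ev_by_step = {}
        for e in events:
            ev_by_step.setdefault(int(round(e.time * 1000.0 / dt)), []).append(e)

        n_sp = 0
        for e in ev_by_step.get(0, []):
            epsp_rate = _apply_event(e, host_rng, b_base, b_inc, p0, p_t0,
                                     p_rec, cfg, 0.0, epsp_rate)
        for c0, c1 in zip(chunk_edges[:-1], chunk_edges[1:]):
            if c1 > c0:
                n_sp, status = _net_kernel(
                    c1 - c0, c0, dt,
                    v, w, ge, gi, crh_g, crh_y,
                    par["C"], par["g_L"], par["E_L"], par["Delta_T"],
                    par["V_T"], par["V_R"], par["tau_w"], par["a"],
                    par["spike_cutoff"], b_base, b_inc,
                    cfg.n_crh, cfg.n_gaba,
                    self.cg_indptr, self.cg_targets,
                    self.gc_indptr, self.gc_targets,
                    p0, p_t0, p_rec,
                    syn.E_e, syn.E_i, syn.w_e, syn.w_i, syn.w_CRH,
                    dec_e, dec_i, dec_crh, dec_br, alpha_h, syn.tau_p,
                    epsp_rate * dt * 1e-3,
                    1 if cfg.release_depression else 0,
                    sp_step, sp_unit, n_sp,
                    tagged, tag_v, tag_w, tag_ge, tag_gi)
                if status == 1:
                    raise FloatingPointError("network integration diverged")
                if status == 2:
                    raise RuntimeError(
                        "spike buffer overflow; raise max_rate_hz")
            for e in ev_by_step.get(c1, []):
                epsp_rate = _apply_event(e, host_rng, b_base, b_inc, p0, p_t0,
                                         p_rec, cfg, c1 * dt * 1e-3, epsp_rate)

        t_spk = sp_step[:n_sp] * dt * 1e-3
        u_spk = sp_unit[:n_sp]
        crh_trains, gaba_trains = [], []
        for i in range(n):
            ts = t_spk[u_spk == i]
            tr = SpikeTrain(times=np.minimum(ts, duration), t_start=0.0,
                            t_stop=duration,
                            unit_id=(f"crh_{i}" if i < cfg.n_crh
                                     else f"gaba_{i - cfg.n_crh}"))
            (crh_trains if i < cfg.n_crh else gaba_trains).append(tr)

        traces = {}
        for k, idx in enumerate(tagged):
            traces[int(idx)] = StateTrace(
                neuron_index=int(idx), dt=dt * 1e-3,
                v=tag_v[k], w=tag_w[k], g_e=tag_ge[k], g_i=tag_gi[k],
                params=AdExParams(
                    C=par["C"][idx], g_L=par["g_L"][idx], E_L=par["E_L"][idx],
                    Delta_T=par["Delta_T"][idx], V_T=par["V_T"][idx],
                    V_R=par["V_R"][idx], tau_w=par["tau_w"][idx],
                    a=par["a"][idx], b=0.0,
                    spike_cutoff=par["spike_cutoff"][idx]),
                synapse=syn)
        return NetworkSimulation(cfg, dt, duration, crh_trains, gaba_trains,
                                 traces, seed, schedule)


def _apply_event(e: ManipulationEvent, rng, b_base, b_inc, p0, p_t0, p_rec,
                 cfg: NetworkConfig, t_s: float, epsp_rate: float) -> float:
    if e.action == "set_gaba_pr_range":
        lo, hi = e.payload["range"]
        p_now = rng.uniform(lo, hi, p0.size)
        p0[:] = p_now
        p_t0[:] = t_s
        p_rec[:] = 1 if e.payload.get("transient", True) else 0
    elif e.action == "trigger_adaptation_increase":
        lo, hi = e.payload["range"]
        target = rng.uniform(lo, hi, cfg.n_crh)
        b_inc[:cfg.n_crh] = target - b_base[:cfg.n_crh]
    elif e.action == "set_adaptation_range":
        lo, hi = e.payload["range"]
        b_base[:cfg.n_crh] = rng.uniform(lo, hi, cfg.n_crh)
        b_inc[:cfg.n_crh] = 0.0
    elif e.action == "set_epsp_rate":
        return float(e.payload["rate"])
    return epsp_rate


def _to_csr(mask: np.ndarray):
    indptr = np.zeros(mask.shape[0] + 1, np.int64)
    targets = []
    for i in range(mask.shape[0]):
        idx = np.flatnonzero(mask[i])
        targets.append(idx)
        indptr[i + 1] = indptr[i] + idx.size
    if targets:
        tg = np.concatenate(targets).astype(np.int64)
    else:
        tg = np.zeros(0, np.int64)
    return indptr, tg


def build_network(config: NetworkConfig) -> PVNNetwork:
    """Functional alias for :class:`PVNNetwork` construction."""
    return PVNNetwork(config)


@njit(cache=True)
def _poisson_neuron_kernel(n_steps, dt, C, gL, EL, DT, VT, VR, tauw, a, b,
                           cutoff, Ee, we, dec_e, epsp_prob):
    v = EL
    w = 0.0
    ge = 0.0
    spikes = np.empty(n_steps, np.int64)
    n_sp = 0
    for s in range(n_steps):
        if np.random.random() < epsp_prob:
            ge += we
        arg = (v - VT) / DT
        if arg > 30.0:
            arg = 30.0
        dv = (gL * (EL - v) + gL * DT * np.exp(arg) + ge * (Ee - v) - w) / C
        dw = (a * (v - EL) - w) / tauw
        v += dt * dv
        w += dt * dw
        ge *= dec_e
        if v >= cutoff:
            v = VR
            w += b
            spikes[n_sp] = s + 1
            n_sp += 1
    return spikes[:n_sp]


def simulate_poisson_driven_neuron(params: AdExParams, synapse: SynapseParams,
                                   epsp_rate: float, duration: float,
                                   b: float | None = None, dt: float = 0.1,
                                   seed: int = 0) -> SpikeTrain:
    """A single conductance-based AdEx neuron under independent Poisson EPSP
    drive — the isolated-neuron reference for the network's
    inhibition-removed limit."""
    n_steps = int(round(duration * 1000.0 / dt))
    _seed_kernel(seed % (2 ** 31))
    sp = _poisson_neuron_kernel(
        n_steps, dt, params.C, params.g_L, params.E_L, params.Delta_T,
        params.V_T, params.V_R, params.tau_w, params.a,
        params.b if b is None else b, params.spike_cutoff,
        synapse.E_e, synapse.w_e, np.exp(-dt / synapse.tau_e),
        epsp_rate * dt * 1e-3)
    return SpikeTrain(times=np.minimum(sp * dt * 1e-3, duration),
                      t_start=0.0, t_stop=duration, unit_id="isolated")
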