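"""End-to-end scenario orchestration: simulate -> analyze -> export, with
seeded runs, manifests and figure-style tabular outputs.

Scenarios
---------
``baseline``        stationary network at the fitted operating point.
``pr-drop``         transient GABA release-probability drop at the switch time.
``pr-drop-adapt``   the drop combined with the adaptation-current increase
                    (the RB -> SS state switch).
``epsp-step``       EPSP drive step 30 -> 60 Hz at the switch time.
``gain``            2x2 stationary design: EPSP 30/60 Hz x recurrent
                    inhibition intact/removed(+adaptation increase), four
                    mean rates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as cio
from .adex import CRH_PARAMS_MEAN, StepProtocol
from .metrics import BurstCriterion, SpikeTrain, detect_bursts
from .network import ManipulationSchedule, NetworkConfig, PVNNetwork
from .synth import (OptoSessionParams, RbSsGeneratorParams,
                    generate_opto_session, generate_patch_recording,
                    generate_rb_ss_train)

__all__ = ["ScenarioConfig", "run_scenario", "make_fixtures", "SCENARIOS",
           "gain_experiment", "state_switch_experiment"]

log = logging.getLogger("crhnet")

SCENARIOS = ("baseline", "pr-drop", "pr-drop-adapt", "epsp-step", "gain")

#: Manipulation ranges of the disinhibition switch.
PR_DROP_RANGE = (0.01, 0.2)
ADAPT_INCREASE_RANGE = (36.0, 50.0)
EPSP_STEP_RATE = 60.0


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "baseline"
    network: NetworkConfig = NetworkConfig()
    duration: float = 100.0  # s
    switch_time: float = 50.0  # s, for the switching scenarios
    seed: int = 0
    warmup: float = 10.0  # s excluded from summaries
    out_dir: str | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.warmup >= self.duration:
            # short diagnostic runs: keep a usable analysis window
            object.__setattr__(self, "warmup", self.duration / 2.0)


def _schedule_for(cfg: ScenarioConfig) -> ManipulationSchedule | None:
    t = cfg.switch_time
    if cfg.scenario == "baseline":
        return None
    if cfg.scenario == "pr-drop":
        return ManipulationSchedule.pr_drop(t, PR_DROP_RANGE)
    if cfg.scenario == "pr-drop-adapt":
        return ManipulationSchedule.pr_drop_with_adaptation(
            t, PR_DROP_RANGE, ADAPT_INCREASE_RANGE)
    if cfg.scenario == "epsp-step":
        return ManipulationSchedule.epsp_step(t, EPSP_STEP_RATE)
    return None


def gain_experiment(network_config: NetworkConfig, duration: float = 100.0,
                    seed: int = 0, warmup: float = 10.0,
                    epsp_rates=(30.0, 60.0)) -> dict:
    """The 2x2 gain-gating experiment: mean CRH firing rate at 30 and 60 Hz
    EPSP drive, with recurrent inhibition intact vs removed (release
    probability dropped to [0.01, 0.2] with the adaptation current raised to
    [36, 50] pA).  Each condition is a stationary run.

    Returns a dict with the four mean rates (Hz) and the per-condition
    per-neuron rates.
    """
    conditions = {}
    rates = {}
    for inhibition in ("intact", "removed"):
        for r in epsp_rates:
            cfg = replace(network_config, epsp_rate=float(r))
            if inhibition == "removed":
                cfg = replace(cfg, gaba_pr_range=PR_DROP_RANGE,
                              adaptation_b_range=ADAPT_INCREASE_RANGE)
            sim = PVNNetwork(cfg).simulate(duration, seed=seed)
            key = f"{inhibition}_{int(r)}hz"
            per = sim.crh_rates(t_min=warmup)
            conditions[key] = per
            rates[key] = float(per.mean())
    d_intact = rates[f"intact_{int(epsp_rates[1])}hz"] \
        - rates[f"intact_{int(epsp_rates[0])}hz"]
    d_removed = rates[f"removed_{int(epsp_rates[1])}hz"] \
        - rates[f"removed_{int(epsp_rates[0])}hz"]
    return {"mean_rates_hz": rates, "per_neuron_rates": conditions,
            "delta_intact_hz": d_intact, "delta_removed_hz": d_removed}


def state_switch_experiment(network_config: NetworkConfig,
                            switch_time: float = 200.0,
                            post_duration: float = 100.0, seed: int = 0,
                            criterion: BurstCriterion = BurstCriterion()) -> dict:
    """RB -> SS switch: transient release-probability drop plus adaptation
    increase at ``switch_time``; per-neuron total/burst/SS rates before and
    after.  Mirrors the paired before/after comparison of the in vivo
    analysis."""
    duration = switch_time + post_duration
    sched = ManipulationSchedule.pr_drop_with_adaptation(
        switch_time, PR_DROP_RANGE, ADAPT_INCREASE_RANGE)
    sim = PVNNetwork(network_config).simulate(duration, schedule=sched, seed=seed)
    out = {"pre": [], "post": []}
    for tr in sim.crh_trains:
        for phase, (t0, t1) in (("pre", (0.0, switch_time)),
                                ("post", (switch_time, duration))):
            sel = tr.times[(tr.times >= t0) & (tr.times < t1)]
            sub = SpikeTrain(times=sel, t_start=t0, t_stop=t1)
            ann = detect_bursts(sub, criterion)
            span = t1 - t0
            out[phase].append({
                "total_hz": len(sub) / span,
                "bursts_per_s": ann.n_bursts / span,
                "ss_hz": ann.ss_indices.size / span,
            })
    summary = {}
    for phase in ("pre", "post"):
        for key in ("total_hz", "bursts_per_s", "ss_hz"):
            summary[f"{phase}_{key}_mean"] = float(
                np.mean([d[key] for d in out[phase]]))
    return {"per_neuron": out, "summary": summary, "simulation": sim}


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Run a scenario end to end; if ``cfg.out_dir`` is set, write rasters,
    analytics tables, a summary JSON and a manifest.  Deterministic under
    ``cfg.seed``."""
    t_wall = time.time()
    doc = dataclasses.asdict(cfg)
    doc.pop("out_dir", None)  # the config hash identifies the science, not paths
    doc["network"]["crh_params_mean"] = cio.adex_params_to_dict(
        cfg.network.crh_params_mean)
    doc["network"]["gaba_params"] = cio.adex_params_to_dict(
        cfg.network.gaba_params)
    doc["network"]["synapse"] = dataclasses.asdict(cfg.network.synapse)

    log.info("scenario %s: n=%d+%d, %.0f s, seed %d", cfg.scenario,
             cfg.network.n_crh, cfg.network.n_gaba, cfg.duration, cfg.seed)
    if cfg.scenario == "gain":
        res = gain_experiment(cfg.network, cfg.duration, cfg.seed, cfg.warmup)
        summary = {"scenario": "gain", **res["mean_rates_hz"],
                   "delta_intact_hz": res["delta_intact_hz"],
                   "delta_removed_hz": res["delta_removed_hz"]}
        bundle = {"summary": summary, "gain": res}
    else:
        sched = _schedule_for(cfg)
        sim = PVNNetwork(cfg.network).simulate(cfg.duration, schedule=sched,
                                               seed=cfg.seed)
        summary = {"scenario": cfg.scenario, **sim.summary(t_min=cfg.warmup)}
        if sched is not None:
            post = sim.crh_rates(t_min=cfg.switch_time).mean()
            pre = sim.crh_rates(t_min=cfg.warmup,
                                t_max=cfg.switch_time).mean()
            summary["crh_rate_pre_switch_hz"] = float(pre)
            summary["crh_rate_post_switch_hz"] = float(post)
        bundle = {"summary": summary, "simulation": sim}
    summary["wall_time_s"] = round(time.time() - t_wall, 2)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "simulation" in bundle:
            sim = bundle["simulation"]
            cio.write_spike_trains(
                sim.crh_trains + sim.gaba_trains, out / "raster.tsv",
                populations=["CRH"] * len(sim.crh_trains)
                + ["GABA"] * len(sim.gaba_trains))
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        cio.write_manifest(out / "manifest.json", doc, cfg.seed,
                           {"scenario": cfg.scenario})
    return bundle


def make_fixtures(seed: int = 0, out_dir="fixtures") -> dict:
    """Small bundled test dataset: a labeled RB/SS train, a compact synthetic
    patch recording and a tiny network raster.  Byte-identical under a fixed
    seed; loads through all package readers."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    labeled = generate_rb_ss_train(RbSsGeneratorParams(seed=seed), duration=120.0)
    cio.write_spike_trains([labeled.train], out / "rb_ss_train.tsv")
    cio.write_labels(labeled, out / "rb_ss_labels.json")

    protocol = StepProtocol.patch_default(n_sweeps=5, dt=0.2)
    rec = generate_patch_recording(CRH_PARAMS_MEAN, protocol, noise_sd=0.5,
                                   seed=seed + 1)
    cio.write_recording(rec, out / "patch_recording")

    net = PVNNetwork(replace(NetworkConfig().scaled(25, 25), seed=seed + 2))
    sim = net.simulate(20.0, seed=seed + 3)
    cio.write_spike_trains(sim.crh_trains + sim.gaba_trains,
                           out / "network_raster.tsv",
                           populations=["CRH"] * 25 + ["GABA"] * 25)

    opto = generate_opto_session(OptoSessionParams(seed=seed + 4))
    cio.write_spike_trains([opto.train], out / "opto_train.tsv")
    np.savetxt(out / "opto_onsets.tsv", opto.pulse_onsets, header="onset_s",
               comments="")
    cio.write_manifest(out / "manifest.json", {"seed": seed}, seed,
                       {"kind": "fixtures"})
    return {"dir": str(out)}
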