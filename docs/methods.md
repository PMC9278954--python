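# Methods

`crhnet` models the firing-state dynamics of corticotropin-releasing-hormone
(CRH) neurons of the paraventricular hypothalamus (PVN): rhythmic brief
bursts (RB) under baseline conditions, continuous single spiking (SS) under
stress-like disinhibition, and the recurrent inhibitory circuit that
switches between them.  This note documents the model equations, the
parameter choices, the synthetic-data generators, the fitting machinery, the
numerical conventions, and the known limitations.

## 1. Single-neuron model

Each neuron is an adaptive exponential integrate-and-fire (AdEx) unit:

    C dv/dt   = g_L (E_L - v) + g_L Δ_T exp((v - V_T)/Δ_T)
                + g_e (E_e - v) + g_i (E_i - v) - w + I(t)
    τ_w dw/dt = a (v - E_L) - w

with reset `v → V_R`, `w → w + b` when `v` crosses the numerical ceiling
`spike_cutoff = V_T + 5 Δ_T` (the source dataset never states a detection
voltage; any crossing that far up the exponential upswing is unambiguous).
Units are pF, nS, mV, ms, pA throughout, so `pA/pF = mV/ms`.

The CRH population parameters (means and SDs) are the ex vivo patch-clamp
fits shipped as `CRH_PARAMS_MEAN` / `CRH_PARAMS_SD`: C = 22.0 ± 2.6 pF,
g_L = 0.9 ± 0.19 nS, E_L = −67.9 ± 2.9 mV, Δ_T = 12.1 ± 2.0 mV,
V_T = −47.2 ± 6.5 mV, V_R = −58.8 ± 2.5 mV, τ_w = 98.2 ± 54.3 ms,
a = 0.082 ± 0.13 nS, b = 17.9 ± 9.8 pA.

`sample_population` draws each parameter independently Gaussian(mean, SD)
and redraws until the invariants hold (positive C, g_L, Δ_T, τ_w; b ≥ 0;
V_R < V_T so a reset cannot land above threshold; a > −g_L so the
subthreshold fixed point stays stable).  Independent draws are a modelling
choice: the underlying per-cell fits are surely correlated across
parameters, so independent sampling widens the excitability spread of the
population relative to the cells it summarises (see §8).

Integration is explicit (forward) Euler — dt = 0.1 ms in the network,
0.1–0.025 ms for single-neuron work — with conductance decays applied as
exact exponential factors.  A ten-times-finer reference integration bounds
the first-spike timing error below 1 ms on step inputs (tested), and the
exponential term is clamped at exp(30) so an escaping trajectory is caught
by the cutoff rather than overflowing; a non-finite state raises, never
propagates.

## 2. Network model

500 CRH neurons (heterogeneous, as above, spike-triggered adaptation b drawn
uniformly from the baseline range [5, 18] pA) and 500 GABA interneurons.

* **CRH → GABA** (2 % Bernoulli connectivity): slow alpha synapse standing
  in for metabotropic CRHR1 excitation.  On a presynaptic spike the
  auxiliary variable jumps `y → y + w_CRH`; the conductance follows
  `τ_CRH d[CRH]/dt = y − [CRH]`, `τ_CRH dy/dt = −y` with τ_CRH = 232.6 ms,
  w_CRH = 0.005 nS.
* **GABA → CRH** (2 %): fast conductance synapse, w_i = 3.3 nS,
  τ_i = 20.4 ms, E_i = −80 mV, with stochastic release: each presynaptic
  spike releases with per-synapse probability p.  At baseline p is drawn
  from [0.9, 1.0]; a disinhibition manipulation re-draws it in a lower
  range (the stress-switch uses [0.01, 0.2]).  After a *transient* drop, p
  recovers toward 1 along the logistic law `dp/dt = p(1 − p)/τ_p`,
  τ_p = 80 s (solved in closed form between release events).  An optional
  depression mode resets p → 0.1 after every successful release; it is off
  by default because with τ_p = 80 s such depression would pin every active
  synapse near p ≈ 0.1 within seconds, erasing the distinction between the
  baseline and disinhibited conditions that the model exists to study.
* **External drive**: each CRH neuron receives an independent homogeneous
  Poisson train of fast EPSPs (30 Hz baseline; 60 Hz in the gain
  experiment), each event incrementing g_e by w_e = 3.9 nS with
  τ_e = 12.5 ms decay.  GABA neurons receive no external drive.
* **Adaptation switch**: `trigger_adaptation_increase` jumps each CRH
  neuron's b to a uniform draw in the target range (e.g. [36, 50] pA); the
  increment decays back with τ_br = 40 s.  The sustained variant
  (`set_adaptation_range`) holds the new range, which is how the
  four-condition gain experiment is run (each condition is stationary).

Event delivery is same-step with no axonal delays.  Initial conditions:
v = E_L per neuron, w = 0, all conductances 0.  All randomness (population
draws, wiring, Poisson drive, release) descends from two integer seeds
(build seed, simulation seed); rasters are bit-identical under fixed seeds.

### The GABA interneuron parameter set

The interneuron population is deliberately generic — tonic spiking, fast
membrane, no spike-triggered adaptation — because the slow CRH drive it
receives is tiny: w_CRH = 0.005 nS at ten expected inputs per cell yields
only ~1–3 pA of mean drive, so the shipped set must have a pA-scale
rheobase for the recurrent loop to operate at all.  The default is

    C = 30 pF, g_L = 1 nS, E_L = −52.8 mV, Δ_T = 2 mV, V_T = −50 mV,
    V_R = −51.5 mV, a = 0.2 nS, τ_w = 500 ms, b = 0

i.e. rest a few mV below threshold, a shallow reset (fast re-firing while
the cell is driven), and a small subthreshold adaptation that makes
inhibitory episodes self-limiting.  The set was calibrated once, as part of
model construction, against the baseline RB regime the fitted network is
reported to occupy (low mean rate with ~2 s interburst rhythm and 2–6-spike
bursts) and then frozen; any tonic-spiking set with comparable rheobase and
kinetics is admissible and can be passed through `NetworkConfig`.
`gaba_params_sd` optionally spreads the population, although in our hands
interneuron heterogeneity lowers both rates and rhythmicity (the excitable
tail inhibits tonically).

## 3. Spike-train analytics

Bursts: a burst starts at a spike whose next ISI is < 6 ms and whose
preceding ISI exceeds 25 ms (the recording start counts as an infinite
preceding interval), and extends while ISIs stay < 20 ms; everything else
is a single spike.  Each burst counts as one event for rate purposes.
Derived tables follow the in vivo conventions: IBI distributions in 100 ms
bins labeled by the upper bin limit (IBI measured from burst end to next
burst start), burst-length distributions, preceding/proceeding-silence
analyses binned 10 ms below 500 ms and 500 ms above, firing-rate time
courses in 10 s bins with a five-bin running average (truncated at the
edges), burst-rate-vs-total-rate tables with classes 0, 0.1 … ≥ 0.6
bursts/s, and PSTH / light-response testing (paired two-sided t-test on
spike counts in the 20 ms windows before and after light onset, α = 0.05,
with event probabilities as the fraction of trials containing a spike).

The spike-train distance is the Wasserstein-1 (earth mover's) distance
between empirical distributions of log10(ISI), computed exactly on samples
(no binning; the value is base-10-dependent and documented as such).  Units
with fewer than two spikes have no ISI distribution and are excluded.  The
network-level objective sums the 100 smallest per-unit distances to a
reference train.

## 4. Synthetic data

The RB/SS generator is a two-state renewal process, independent of the
network model so generator and analyzer can test each other without
circularity.  RB state: gamma-distributed interburst gaps (mean 1.8 s,
SD 0.6 s), burst lengths 2–6 with probabilities (0.25, 0.45, 0.25, 0.04,
0.01) (mean 3.1 spikes), intraburst ISIs starting at 4 ms and growing 1.3×
per spike (frequency adaptation within the burst, all ISIs < 20 ms).
SS state: gamma renewal with shape 2 at 10 Hz (burst-range ISIs rare by
construction).  Dwell times in each state are exponential with mean 60 s
and a transition never splits a burst.  Defaults reproduce the in vivo
calibration bands (detected burst length 2.6–3.6 spikes, IBI 1.2–2.4 s)
across seeds.

Patch recordings: the 14-sweep step protocol (−20 pA for 200 ms, then a
depolarizing step of 10·k pA for 500 ms, k = 1…14) simulated on a known
AdEx ground truth plus i.i.d. Gaussian observation noise (0.5 mV default);
the noise never enters the dynamics, so the noiseless trajectory remains an
exact recovery target.  Opto sessions: background Poisson spiking plus one
short-latency evoked spike per light pulse with probability
`response_prob` (latency 7.2 ± 2.6 ms, 25 pulses of 5 ms).

What the generators do *not* emulate: spike sorting and unit contamination,
electrode drift, correlated (non-renewal) SS firing, bursty non-stationary
background in opto sessions, and any within-burst spike-amplitude
structure.  Tests passing on synthetic data therefore validate the
analytics and the fitting contracts, not in vivo data handling.

## 5. Single-neuron fitting

The penalty is `subthreshold MSE + F-I log-MSE`: the mean squared voltage
error over samples outside ±8 ms windows around reference spikes, averaged
over sweeps, plus the mean squared difference of log10(rate + 1 Hz) over
the F-I curve (the +1 Hz floor admits zero-rate sweeps).  Fits are
discarded when the subthreshold root-MSE exceeds 5 mV or the F-I root-MSE
exceeds 10 Hz; the thresholds are applied on the root-MSE scale and both
raw values are always reported.

The search is a coarse-screen + evolutionary-refinement contract.  The
screen draws a Sobol sample of the 9-parameter space (256 points),
restricts it by F-I similarity (best quarter), refines each survivor's
passive parameters (C, g_L, E_L, a) against the noise-averaged
pre-depolarization segment — which is identical across sweeps and purely
subthreshold, so averaging the 14 sweeps cuts the noise ~3.7× — and ranks
the restricted subset by the full objective.  The evolutionary stage runs
differential evolution (54-member population seeded from the refined
screen plus fresh random members, sharp mutation, two independent restarts,
final local polish; deterministic under the seed), after which the winner's
passive parameters are re-pinned on the pre-depolarization segment and its
spiking parameters (Δ_T, V_T, V_R, τ_w, b) re-fitted around them; the
corrected candidate is adopted only if it improves the objective.
Internally the optimizer minimises a gate-normalised combination
(subthreshold MSE / 25 mV² + (F-I RMSE / 10 Hz)² + F-I log-MSE) so that
neither term swamps the other; the reported penalty remains the plain sum.
On synthetic recordings with 0.5 mV observation noise this recovers C, g_L
and E_L within ~10 % and τ_w, b within ~5–30 % across seeds; the
subthreshold conductance a is only weakly identified against g_L at
|a| ≈ 0.08 nS (their sum is what static subthreshold data constrain).

Network-synapse fitting follows the same pattern one level up: candidates
for (w_e, w_i, τ_e, τ_i, τ_CRH, EPSP rate) are scored by simulating the
network twice — baseline adaptation against a bursting reference, increased
adaptation against a tonic reference (50 s each by default) — and summing
the two spike-train distances; differential evolution over a configurable
budget returns the best candidate and a monotone best-so-far trace.

## 6. Network clamp

For a tagged CRH neuron the per-step state (v, w, g_e, g_i) is recorded at
exactly the values entering the membrane update, and the injectable current
is

    I(t) = g_e(t)(E_e − v(t)) + g_i(t)(E_i − v(t)) − w(t)

at 100 µs resolution.  The leak is excluded (a biological neuron supplies
its own), and the extraction convention clamps the tagged neuron's rest to
the mean ex vivo resting potential (−67.9 mV).  Replaying the uncapped
waveform into an isolated AdEx neuron with the same parameters — adaptation
disabled, because −w(t) is already inside I(t) — reproduces ≥ 95 % of the
in-network spike times within 1 ms (tested; the residual mismatch is
floating-point association order, not physics).  Capping clips the summed
trace pointwise to ±200 pA, which preserves event timings by construction;
the per-event alternative was rejected because it would reshape the
waveform between events.  The truncation control zeroes everything earlier
than a chosen window before an event, for testing whether the preceding
network input is necessary for burst generation.  Waveforms export as
two-column text (bit-exact round trip) and as an episodic stimulus table.

## 7. Problem sizes and measurement conventions

Reported quantities are computed at the sizes the analyses were designed
for: the baseline burst rate on the full 500 + 500 network over 200 s and
3 seeds (full span, since burst detection needs long records and the
initial transient contributes bursts exactly as any other epoch); condition
means of the gain experiment over 100 s after a 10 s settling window,
3 seeds, full size; integration dt 0.1 ms everywhere in the network.
Scaled networks used in the test suite preserve the expected synaptic
in-degree (connection probability rescaled with population size).

## 8. Known limitations

* **Heterogeneity model.**  Independent Gaussian parameter draws produce a
  wider excitability spread than the correlated per-cell fits they
  summarise: many units are near-silent or tonic, and only a minority
  (~16 % in our baseline simulations) bursts above 0.1 bursts/s, whereas
  in vivo a majority of bursting-classified units does.  The
  population-mean burst rate at the baseline operating point
  (~0.10 bursts/s) accordingly sits at the low edge of the
  0.1456 ± 0.05 bursts/s band the acceptance analysis checks, not at its
  centre.
* **Burst abolition under disinhibition.**  With the printed adaptation
  switch range ([36, 50] pA) and Poisson EPSP drive (w_e = 3.9 nS at
  30 Hz), drive fluctuations alone keep producing occasional burst-range
  ISI pairs after disinhibition; in this implementation the switch raises
  total and SS rates robustly but does not push the detected burst rate
  toward zero (that requires b ≳ 70 pA here).  The discrepancy points at
  the input statistics: a smoother drive (smaller, more frequent EPSPs at
  equal mean conductance) would suppress fluctuation bursts while leaving
  the rate targets intact.
* The circuit omits external inhibition onto CRH neurons, any external
  drive to the GABA population, and glutamatergic CRH→GABA
  co-transmission; GABA kinetics are a calibrated stand-in, not a fitted
  population.
* Euler at dt = 0.1 ms slightly biases spike times of the fastest
  intraburst intervals; the fine-step oracle bounds this below 1 ms for
  the first spike and the acceptance analytics operate at ≥ 1 ms
  granularity.
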