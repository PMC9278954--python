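"""Spike-train analytics: burst detection, interval statistics, silence
analyses, firing-rate time courses, optogenetic-tagging tests and the
log-ISI earth mover's distance.

Burst criterion (in vivo convention): a burst is a series of two or more
spikes whose initial ISI is < 6 ms, extended while subsequent ISIs stay
< 20 ms, and whose first spike is preceded by an ISI > 25 ms (the recording
start counts as an infinite preceding ISI).  Every spike not in a burst is a
single spike (SS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SpikeTrain",
    "BurstCriterion",
    "BurstAnnotation",
    "detect_bursts",
    "isi_sequence",
    "ibi_distribution",
    "burst_length_distribution",
    "burst_prob_vs_preceding_silence",
    "burst_prob_vs_proceeding_silence",
    "silence_by_event_length",
    "firing_rate_timecourse",
    "running_average",
    "burst_vs_total_rate",
    "psth",
    "light_response_test",
    "log_isi_emd",
    "network_fit_distance",
]


@dataclass
class SpikeTrain:
    """Ordered spike times (s) of one unit over a recording span."""

    times: np.ndarray
    t_start: float = 0.0
    t_stop: float | None = None
    unit_id: str = "unit"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-D array")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.t_stop is None:
            self.t_stop = float(self.times[-1]) if self.times.size else self.t_start
        if self.times.size and (self.times[0] < self.t_start
                                or self.times[-1] > self.t_stop):
            raise ValueError("spike times must lie within the recording span")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    @property
    def rate(self) -> float:
        """Mean firing rate (Hz) over the span."""
        return len(self) / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class BurstCriterion:
    start_isi_max: float = 0.006  # s
    continue_isi_max: float = 0.020  # s
    preceding_isi_min: float = 0.025  # s

    def __post_init__(self):
        if not self.start_isi_max < self.continue_isi_max:
            raise ValueError("start_isi_max must be below continue_isi_max")


@dataclass
class BurstAnnotation:
    """Bursts as (start index, length in spikes); remaining spikes are SS."""

    bursts: list  # of (start_index, length)
    ss_indices: np.ndarray
    n_spikes: int

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def burst_lengths(self) -> np.ndarray:
        return np.array([l for _, l in self.bursts], int)

    def burst_member_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_spikes, bool)
        for s, l in self.bursts:
            mask[s:s + l] = True
        return mask

    def burst_rate(self, duration: float) -> float:
        """Bursts per second; each burst counts once regardless of length."""
        return self.n_bursts / duration if duration > 0 else 0.0


def detect_bursts(train: SpikeTrain,
                  criterion: BurstCriterion = BurstCriterion()) -> BurstAnnotation:
    """Classify every spike as burst member or single spike.

    A burst starts at spike i iff ISI(i -> i+1) < start_isi_max and the
    preceding ISI exceeds preceding_isi_min (infinite at the recording
    start); it extends while ISIs stay < continue_isi_max.
    """
    t = train.times
    n = t.size
    bursts = []
    in_burst = np.zeros(n, bool)
    i = 0
    while i < n - 1:
        isi_next = t[i + 1] - t[i]
        preceding = np.inf if i == 0 else t[i] - t[i - 1]
        if isi_next < criterion.start_isi_max and preceding > criterion.preceding_isi_min:
            j = i + 1
            while j + 1 < n and t[j + 1] - t[j] < criterion.continue_isi_max:
                j += 1
            bursts.append((i, j - i + 1))
            in_burst[i:j + 1] = True
            i = j + 1
        else:
            i += 1
    return BurstAnnotation(bursts=bursts, ss_indices=np.flatnonzero(~in_burst),
                           n_spikes=n)


def isi_sequence(train: SpikeTrain) -> np.ndarray:
    """Interspike intervals in seconds."""
    return np.diff(train.times)


def ibi_distribution(train: SpikeTrain, annotation: BurstAnnotation,
                     bin_s: float = 0.1):
    """Interburst-interval distribution (default 100 ms bins, labeled by the
    upper limit of the bin).

    The IBI is measured from the last spike of one burst to the first spike
    of the next.  Returns ``(bin_upper_labels_s, probability)``; empty arrays
    when fewer than two bursts exist.
    """
    if annotation.n_bursts < 2:
        return np.array([]), np.array([])
    t = train.times
    ends = np.array([t[s + l - 1] for s, l in annotation.bursts])
    starts = np.array([t[s] for s, _ in annotation.bursts])
    ibis = starts[1:] - ends[:-1]
    n_bins = int(np.ceil(ibis.max() / bin_s)) or 1
    counts, _ = np.histogram(ibis, bins=np.arange(n_bins + 1) * bin_s)
    labels = (np.arange(n_bins) + 1) * bin_s
    return labels, counts / counts.sum()


def burst_length_distribution(annotation: BurstAnnotation):
    """Probability distribution over burst lengths (spikes per burst).

    Returns ``(lengths, probability)``.
    """
    if annotation.n_bursts == 0:
        return np.array([], int), np.array([])
    lengths = annotation.burst_lengths
    uniq = np.arange(2, lengths.max() + 1)
    counts = np.array([(lengths == u).sum() for u in uniq])
    return uniq, counts / counts.sum()


def _silence_bins(max_s: float):
    """Preceding/proceeding silence bins: 10 ms wide below 500 ms, 500 ms
    wide at and above 500 ms."""
    edges = list(np.arange(0.0, 0.5 + 1e-12, 0.01))
    top = 0.5
    while top < max_s:
        top += 0.5
        edges.append(top)
    return np.array(edges)


def burst_prob_vs_preceding_silence(train: SpikeTrain,
                                    criterion: BurstCriterion = BurstCriterion()):
    """Probability that a spike initiates burst-range firing (proceeding
    ISI < start_isi_max) as a function of its preceding ISI.

    Returns a record array ``(bin_upper_s, probability, n)`` over occupied
    bins.  Needs at least three spikes (one spike with both ISIs defined).
    """
    isi = isi_sequence(train)
    if isi.size < 2:
        return np.array([]), np.array([]), np.array([], int)
    preceding = isi[:-1]
    proceeding = isi[1:]
    return _binned_probability(preceding, proceeding < criterion.start_isi_max)


def burst_prob_vs_proceeding_silence(train: SpikeTrain,
                                     criterion: BurstCriterion = BurstCriterion()):
    """Probability of burst-range firing (preceding ISI < continue_isi_max)
    as a function of the proceeding ISI (the symmetric analysis)."""
    isi = isi_sequence(train)
    if isi.size < 2:
        return np.array([]), np.array([]), np.array([], int)
    preceding = isi[:-1]
    proceeding = isi[1:]
    return _binned_probability(proceeding, preceding < criterion.continue_isi_max)


def _binned_probability(x, flag):
    edges = _silence_bins(float(x.max()) if x.size else 0.5)
    idx = np.digitize(x, edges) - 1
    labels, probs, ns = [], [], []
    for k in range(edges.size - 1):
        sel = idx == k
        m = int(sel.sum())
        if m == 0:
            continue
        labels.append(edges[k + 1])
        probs.append(float(flag[sel].mean()))
        ns.append(m)
    return np.array(labels), np.array(probs), np.array(ns, int)


def silence_by_event_length(train: SpikeTrain, annotation: BurstAnnotation):
    """Mean preceding and proceeding silence per event-length class.

    Events are bursts plus single spikes (length-1 events); classes are
    {1, 2, 3, >=4}.  The preceding silence of an event is the interval from
    the previous spike to its first spike; the proceeding silence runs from
    its last spike to the next spike.  Events at the recording boundaries
    lack the corresponding interval and are excluded from that side.

    Returns ``{class: (mean_preceding_s, mean_proceeding_s)}`` with NaN
    where no interval is defined.
    """
    t = train.times
    events = [(s, l) for s, l in annotation.bursts]
    events += [(int(i), 1) for i in annotation.ss_indices]
    events.sort()
    pre = {1: [], 2: [], 3: [], 4: []}
    post = {1: [], 2: [], 3: [], 4: []}
    for s, l in events:
        cls = min(l, 4)
        if s > 0:
            pre[cls].append(t[s] - t[s - 1])
        last = s + l - 1
        if last < t.size - 1:
            post[cls].append(t[last + 1] - t[last])
    out = {}
    for cls in (1, 2, 3, 4):
        mp = float(np.mean(pre[cls])) if pre[cls] else np.nan
        mq = float(np.mean(post[cls])) if post[cls] else np.nan
        out[cls] = (mp, mq)
    return out


def firing_rate_timecourse(train: SpikeTrain, bin_s: float = 10.0):
    """Spike rate (Hz) in consecutive bins over the recording span.

    Returns ``(bin_centers_s, rates_hz)``.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = max(1, int(np.ceil(train.duration / bin_s)))
    edges = train.t_start + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(train.times, bins=edges)
    return (edges[:-1] + edges[1:]) / 2.0, counts / bin_s


def running_average(rates: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving average over ``window`` consecutive bins; edge bins use the
    available neighbors only (truncated window)."""
    rates = np.asarray(rates, float)
    kernel = np.ones(window)
    num = np.convolve(rates, kernel, mode="same")
    den = np.convolve(np.ones_like(rates), kernel, mode="same")
    return num / den


def burst_vs_total_rate(train: SpikeTrain, annotation: BurstAnnotation,
                        bin_s: float = 10.0):
    """Per-time-bin (burst-rate class, total spike rate) pairs.

    Burst-rate classes are 0, 0.1, ..., 0.5, and >=0.6 bursts/s (the class is
    the bin's burst rate rounded to the 0.1 grid, capped at 0.6).

    Returns ``(classes, total_rates_hz)`` with one entry per time bin.
    """
    t = train.times
    starts = np.array([t[s] for s, _ in annotation.bursts]) if annotation.n_bursts \
        else np.array([])
    n_bins = max(1, int(np.ceil(train.duration / bin_s)))
    edges = train.t_start + np.arange(n_bins + 1) * bin_s
    total, _ = np.histogram(t, bins=edges)
    bursts, _ = np.histogram(starts, bins=edges)
    classes = np.minimum(np.round(bursts / bin_s, 1), 0.6)
    return classes, total / bin_s


def psth(train: SpikeTrain, event_times, window=(-0.1, 0.1), bin_s: float = 0.005):
    """Peristimulus time histogram around event onsets.

    Returns ``(bin_edges_s, rate_hz)`` where the rate is the trial-averaged
    spike rate in each bin.
    """
    event_times = np.asarray(event_times, float)
    edges = np.arange(window[0], window[1] + bin_s / 2, bin_s)
    counts = np.zeros(edges.size - 1)
    for ev in event_times:
        rel = train.times - ev
        sel = rel[(rel >= window[0]) & (rel < window[1])]
        c, _ = np.histogram(sel, bins=edges)
        counts += c
    n = max(1, event_times.size)
    return edges, counts / (n * bin_s)


@dataclass
class LightResponse:
    responsive: bool
    p_value: float
    prob_pre: float  # fraction of trials with >=1 spike in the pre window
    prob_post: float
    mean_pre: float  # mean spike count per trial, pre window
    mean_post: float


def light_response_test(train: SpikeTrain, pulse_onsets,
                        window_s: float = 0.02, alpha: float = 0.05) -> LightResponse:
    """Opto-tagging test: is the unit driven by the light pulses?

    Spike counts in the 20 ms window before each pulse onset are compared to
    the 20 ms window after by a trial-by-trial two-sided paired t-test; the
    unit is responsive iff the test is significant at ``alpha`` with a
    post-onset increase.  Event probabilities are the fraction of trials with
    at least one spike in the window.
    """
    onsets = np.asarray(pulse_onsets, float)
    pre = np.array([np.count_nonzero((train.times >= o - window_s)
                                     & (train.times < o)) for o in onsets])
    post = np.array([np.count_nonzero((train.times >= o)
                                      & (train.times < o + window_s)) for o in onsets])
    prob_pre = float((pre > 0).mean()) if onsets.size else 0.0
    prob_post = float((post > 0).mean()) if onsets.size else 0.0
    diff = post - pre
    if onsets.size < 2 or np.all(diff == diff[0]) and diff[0] == 0:
        p = 1.0
    else:
        with np.errstate(all="ignore"):
            p = float(stats.ttest_rel(post, pre).pvalue)
        if np.isnan(p):
            p = 1.0
    responsive = bool(p < alpha and post.mean() > pre.mean())
    return LightResponse(responsive, p, prob_pre, prob_post,
                         float(pre.mean()) if onsets.size else 0.0,
                         float(post.mean()) if onsets.size else 0.0)


def log_isi_emd(train_a: SpikeTrain, train_b: SpikeTrain) -> float:
    """Wasserstein-1 (earth mover's) distance between the log10-scaled ISI
    distributions of two trains.

    Computed exactly on the empirical samples (no binning).  Both trains need
    at least two spikes; otherwise the distance is undefined.
    """
    ia = isi_sequence(train_a)
    ib = isi_sequence(train_b)
    if ia.size < 1 or ib.size < 1:
        raise ValueError("log_isi_emd needs trains with at least 2 spikes")
    return float(stats.wasserstein_distance(np.log10(ia), np.log10(ib)))


def network_fit_distance(simulated_trains, reference: SpikeTrain,
                         n_smallest: int = 100) -> tuple[float, int]:
    """Fitting objective: sum of the smallest ``n_smallest`` log-ISI EMDs
    between simulated units and a reference train.

    Units with fewer than two spikes have no ISI distribution and are
    excluded.  Returns ``(total_distance, n_units_used)``.
    """
    dists = []
    for tr in simulated_trains:
        if len(tr) < 2:
            continue
        dists.append(log_isi_emd(tr, reference))
    dists.sort()
    used = dists[:n_smallest]
    if not used:
        return float("inf"), 0
    return float(sum(used)), len(used)
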