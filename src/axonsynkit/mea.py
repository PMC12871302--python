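"""Multi-electrode-array spike, burst and network-burst analysis.

Raw extracellular voltage is band-limited (2nd-order 100 Hz high-pass,
4th-order 3.5 kHz low-pass Butterworth, 50 Hz notch, all zero-phase),
spikes are detected at +/-5 robust SDs of the baseline noise, and per-well
activity is summarised as: active electrodes (>10 spikes/min), mean firing
rate over active electrodes, bursts (spikes recurring within 50 ms,
terminated by >100 ms of silence) and network bursts (bursts concurrent on
at least 4 of the 12 electrodes).

The two burst constants conflict for inter-spike gaps in (50, 100] ms: a
burst here is *seeded* by a pair of spikes at most 50 ms apart and then
*continues* through any gap of at most 100 ms, terminating at the first
longer gap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthetic import SpikeTrain, WellRecording

__all__ = [
    "Burst",
    "NetworkBurst",
    "WellSummary",
    "filter_cascade_sos",
    "filter_trace",
    "detect_spikes",
    "robust_noise_sd",
    "active_electrodes",
    "mean_firing_rate",
    "detect_bursts",
    "detect_network_bursts",
    "summarize_well",
    "well_from_traces",
]

HP_ORDER, HP_HZ = 2, 100.0
LP_ORDER, LP_HZ = 4, 3500.0
NOTCH_HZ, NOTCH_Q = 50.0, 30.0


@dataclass
class Burst:
    electrode_id: int
    t_start: float
    t_end: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class NetworkBurst:
    t_start: float
    t_end: float
    electrode_ids: frozenset

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass
class WellSummary:
    well_id: str
    div: int
    n_active: int
    mfr: float              # spikes/s, mean over active electrodes
    burst_freq: float       # bursts/min over active electrodes
    burst_dur_mean: float   # s
    nb_freq: float          # network bursts/min
    nb_dur_mean: float      # s


# ---------------------------------------------------------------------------
# filtering and spike detection
# ---------------------------------------------------------------------------

def filter_cascade_sos(fs_hz: float) -> np.ndarray:
    """Second-order sections of the HP + LP + notch cascade."""
    if fs_hz <= 2 * LP_HZ:
        raise ValueError(f"sampling rate {fs_hz} too low for a {LP_HZ} Hz low-pass")
    hp = signal.butter(HP_ORDER, HP_HZ, btype="highpass", fs=fs_hz, output="sos")
    lp = signal.butter(LP_ORDER, LP_HZ, btype="lowpass", fs=fs_hz, output="sos")
    b, a = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=fs_hz)
    notch = signal.tf2sos(b, a)
    return np.vstack([hp, lp, notch])


def filter_trace(trace: np.ndarray, fs_hz: float) -> np.ndarray:
    """Zero-phase band-limiting of one voltage trace; preserves length."""
    sos = filter_cascade_sos(fs_hz)
    return signal.sosfiltfilt(sos, np.asarray(trace, dtype=np.float64))


def robust_noise_sd(trace: np.ndarray) -> float:
    """Baseline noise SD, estimated as median(|x|)/0.6745 (spike-robust)."""
    return float(np.median(np.abs(trace)) / 0.6745)


def detect_spikes(trace: np.ndarray, fs_hz: float, k_sd: float = 5.0,
                  refractory_s: float = 1e-3) -> np.ndarray:
    """Spike times from a filtered trace by +/- k_sd threshold crossing.

    Each supra-threshold excursion (either polarity) yields one spike at
    its extremum sample; detections within the refractory dead time of the
    previous spike are suppressed.
    """
    x = np.asarray(trace)
    sd = robust_noise_sd(x)
    if sd == 0:
        warnings.warn("constant trace: noise SD is 0, no spikes detected")
        return np.empty(0)
    thr = k_sd * sd
    above = np.abs(x) > thr
    if not above.any():
        return np.empty(0)
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [x.size]])
    peaks = np.array([s + np.argmax(np.abs(x[s:e])) for s, e in zip(starts, ends)])
    times = peaks / fs_hz
    dead = refractory_s
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= dead:
            kept.append(t)
    return np.asarray(kept)


def well_from_traces(traces: list[np.ndarray], fs_hz: float, duration_s: float,
                     well_id: str = "well", div: int = 0,
                     prefiltered: bool = False) -> WellRecording:
    """Run the filter + spike-detection front end on raw traces."""
    trains = []
    for e, tr in enumerate(traces):
        y = tr if prefiltered else filter_trace(tr, fs_hz)
        t = detect_spikes(y, fs_hz)
        t = t[(t >= 0) & (t < duration_s)]
        trains.append(SpikeTrain(electrode_id=e, spike_times=t,
                                 duration_s=duration_s))
    return WellRecording(well_id=well_id, div=div, electrodes=trains,
                         fs_hz=fs_hz, duration_s=duration_s)


# ---------------------------------------------------------------------------
# activity metrics
# ---------------------------------------------------------------------------

def active_electrodes(well: WellRecording,
                      min_rate_per_min: float = 10.0) -> set[int]:
    """Electrodes firing strictly more than ``min_rate_per_min`` spikes/min."""
    out = set()
    for tr in well.electrodes:
        if tr.spike_times.size / (well.duration_s / 60.0) > min_rate_per_min:
            out.add(tr.electrode_id)
    return out


def mean_firing_rate(well: WellRecording,
                     min_rate_per_min: float = 10.0) -> float:
    """Mean of per-electrode firing rates over active electrodes (spikes/s).

    0 (with a warning) when no electrode is active.
    """
    act = active_electrodes(well, min_rate_per_min)
    if not act:
        warnings.warn(f"well {well.well_id}: no active electrode, MFR set to 0")
        return 0.0
    rates = [tr.rate_hz for tr in well.electrodes if tr.electrode_id in act]
    return float(np.mean(rates))


def detect_bursts(train: SpikeTrain, isi_join_s: float = 0.05,
                  quiet_s: float = 0.1, min_spikes: int = 3) -> list[Burst]:
    """Bursts on one electrode by the seed-and-extend rule.

    A burst is seeded by two spikes at most ``isi_join_s`` apart, continues
    through gaps up to ``quiet_s``, and terminates at the first longer gap;
    candidates with fewer than ``min_spikes`` spikes are dropped.  Bursts
    never overlap and each spike belongs to at most one burst.
    """
    t = train.spike_times
    bursts: list[Burst] = []
    i, n = 0, t.size
    while i < n - 1:
        if t[i + 1] - t[i] <= isi_join_s:        # seed
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= quiet_s:
                j += 1
            if j - i + 1 >= min_spikes:
                bursts.append(Burst(electrode_id=train.electrode_id,
                                    t_start=float(t[i]), t_end=float(t[j]),
                                    n_spikes=j - i + 1))
            i = j + 1
        else:
            i += 1
    return bursts


def detect_network_bursts(bursts_by_electrode: dict[int, list[Burst]],
                          min_electrodes: int = 4) -> list[NetworkBurst]:
    """Maximal spans with bursts concurrently on >= ``min_electrodes`` electrodes.

    Event sweep over the union of burst intervals; the participating set of
    a network burst is every electrode bursting at some point of the span.
    """
    events: list[tuple[float, int, int]] = []  # (time, +1/-1, electrode)
    for e, bl in bursts_by_electrode.items():
        for b in bl:
            events.append((b.t_start, +1, e))
            events.append((b.t_end, -1, e))
    if not events:
        return []
    # starts before ends at equal times so touching intervals count together
    events.sort(key=lambda ev: (ev[0], -ev[1]))
    out: list[NetworkBurst] = []
    depth: dict[int, int] = {}
    span_start = None
    members: set[int] = set()
    for t, kind, e in events:
        n_before = sum(1 for v in depth.values() if v > 0)
        depth[e] = depth.get(e, 0) + kind
        n_after = sum(1 for v in depth.values() if v > 0)
        if span_start is None and n_after >= min_electrodes:
            span_start = t
            members = {el for el, v in depth.items() if v > 0}
        elif span_start is not None:
            members.update(el for el, v in depth.items() if v > 0)
            if n_after < min_electrodes and n_before >= min_electrodes:
                out.append(NetworkBurst(t_start=span_start, t_end=t,
                                        electrode_ids=frozenset(members)))
                span_start = None
                members = set()
    return out


def summarize_well(well: WellRecording, isi_join_s: float = 0.05,
                   quiet_s: float = 0.1, min_spikes: int = 3,
                   min_electrodes: int = 4,
                   min_rate_per_min: float = 10.0) -> WellSummary:
    """Assemble the per-well activity summary.

    Burst frequency is the total burst count over active electrodes per
    minute of recording; network-burst frequency is per well.
    """
    act = active_electrodes(well, min_rate_per_min)
    mfr = mean_firing_rate(well, min_rate_per_min)
    bursts_by_e = {
        tr.electrode_id: detect_bursts(tr, isi_join_s, quiet_s, min_spikes)
        for tr in well.electrodes
    }
    act_bursts = [b for e, bl in bursts_by_e.items() if e in act for b in bl]
    nbs = detect_network_bursts(bursts_by_e, min_electrodes)
    minutes = well.duration_s / 60.0
    return WellSummary(
        well_id=well.well_id,
        div=well.div,
        n_active=len(act),
        mfr=mfr,
        burst_freq=len(act_bursts) / minutes,
        burst_dur_mean=float(np.mean([b.duration_s for b in act_bursts]))
        if act_bursts else 0.0,
        nb_freq=len(nbs) / minutes,
        nb_dur_mean=float(np.mean([nb.duration_s for nb in nbs])) if nbs else 0.0,
    )
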