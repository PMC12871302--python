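"""Ground-truth synthetic data for every pipeline stage.

Five input classes are emulated, each with genotype-dependent parameters
(:mod:`axonsynkit.config`):

* SVP transport kymographs — piecewise-constant-velocity cargo tracks
  rendered into a space-time intensity grid;
* microtubule comet movies — stationary SVP+ site bands plus slow comet
  streaks with a configurable site-association probability;
* multi-electrode-array wells — 12 spike trains with burst and
  network-burst structure, optionally rendered to raw voltage traces;
* qPCR Ct tables built by inverting the ddCt relation;
* 3-D synapse puncta fields with a known apposed fraction.

Every generator is a pure function of its parameters and a seed, and every
generated object carries the ground-truth labels needed to score a
downstream detector (track directions and peak speeds, comet association
flags, network-event participant sets, apposition pairs).

The generators reproduce summary statistics only; no motor biophysics,
microtubule chemistry or membrane trafficking is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    COMET_DT_S,
    MEA_DURATION_S,
    MEA_FS_HZ,
    N_ELECTRODES,
    PX_UM,
    SVP_DT_S,
    GenotypeParams,
)

__all__ = [
    "Track",
    "Kymograph",
    "SvpSite",
    "CometEvent",
    "SpikeTrain",
    "WellRecording",
    "gen_svp_tracks",
    "render_kymograph",
    "gen_comet_site_axon",
    "render_comet_kymograph",
    "gen_mea_recording",
    "render_spike_trace",
    "gen_ct_table",
    "gen_synapse_field",
    "render_puncta_stack",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """One moving cargo: a polyline of (time s, position um) inflection points."""

    axon_id: str
    points: list[tuple[float, float]]
    intensity: float = 1.0
    origin: str = "generated"
    # ground truth, populated by the generator only
    truth_direction: str | None = None
    truth_peak_speed: float | None = None

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a track needs at least 2 points")
        t = np.asarray([p[0] for p in self.points])
        if np.any(np.diff(t) <= 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=float)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.points], dtype=float)

    @property
    def net_displacement_um(self) -> float:
        return self.points[-1][1] - self.points[0][1]


@dataclass
class Kymograph:
    """Space-time intensity grid with physical calibration.

    Rows are time (``dt_s`` apart), columns space (``px_um`` apart).
    """

    values: np.ndarray
    px_um: float
    dt_s: float
    length_um: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.px_um <= 0 or self.dt_s <= 0:
            raise ValueError("calibration must be positive")
        n_rows, n_cols = self.values.shape
        if abs(n_cols * self.px_um - self.length_um) > self.px_um:
            raise ValueError("grid width inconsistent with length_um")
        if abs(n_rows * self.dt_s - self.duration_s) > self.dt_s:
            raise ValueError("grid height inconsistent with duration_s")


@dataclass
class SvpSite:
    """Stationary SVP accumulation along an axon."""

    axon_id: str
    centroid_um: float
    extent_um: float
    mean_intensity: float = 1.0

    def __post_init__(self) -> None:
        if self.extent_um <= 0:
            raise ValueError("extent_um must be > 0")


@dataclass
class CometEvent:
    """A growing microtubule plus-end traced as a straight streak."""

    axon_id: str
    start: tuple[float, float]  # (time s, position um)
    end: tuple[float, float]
    truth_assoc: bool | None = None

    def __post_init__(self) -> None:
        if self.end[0] <= self.start[0]:
            raise ValueError("comet end time must exceed start time")

    @property
    def velocity(self) -> float:
        return (self.end[1] - self.start[1]) / (self.end[0] - self.start[0])

    @property
    def span_um(self) -> tuple[float, float]:
        lo, hi = sorted((self.start[1], self.end[1]))
        return lo, hi


@dataclass
class SpikeTrain:
    electrode_id: int
    spike_times: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0 or t[-1] >= self.duration_s):
            raise ValueError("spike times must be strictly increasing in [0, duration)")
        self.spike_times = t

    @property
    def rate_hz(self) -> float:
        return self.spike_times.size / self.duration_s


@dataclass
class WellRecording:
    """One MEA well: 12 electrodes, optional raw voltage traces."""

    well_id: str
    div: int
    electrodes: list[SpikeTrain]
    fs_hz: float = MEA_FS_HZ
    duration_s: float = MEA_DURATION_S
    traces: list[np.ndarray] | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.electrodes) != N_ELECTRODES:
            raise ValueError(f"a well has exactly {N_ELECTRODES} electrodes")


# ---------------------------------------------------------------------------
# SVP transport (kymograph mode, 5 fps)
# ---------------------------------------------------------------------------

#: segments slower than this are pauses, um/s
PAUSE_SPEED_UM_S = 0.05
#: probability that a track pauses once mid-run
PAUSE_PROB = 0.3
#: relative SD of the designated per-axon top speeds
_TOP_SPEED_CV = 0.08
#: baseline motile-cargo brightness, AU
_TRACK_BASE_INTENSITY = 500.0


def _draw_track_speeds(rng: np.random.Generator, n: int, vmax: float) -> np.ndarray:
    """Speeds for ``n`` same-direction tracks of one axon.

    Five tracks are designated speed leaders with peak speeds drawn around
    the preset mean, so the per-axon mean of the five fastest segment speeds
    is an unbiased estimate of ``vmax``; the remaining tracks stay strictly
    below the slowest leader.
    """
    if n == 0:
        return np.empty(0)
    k = min(n, 5)
    tops = rng.normal(vmax, _TOP_SPEED_CV * vmax, size=k)
    tops = np.clip(tops, 0.3 * vmax, None)
    if n <= 5:
        speeds = tops
    else:
        ceiling = min(0.95 * tops.min(), 0.8 * vmax)
        rest = rng.uniform(0.45 * vmax, max(ceiling, 0.46 * vmax), size=n - k)
        speeds = np.concatenate([tops, rest])
    rng.shuffle(speeds)
    return speeds


def _build_track(rng: np.random.Generator, axon_id: str, sign: int, speed: float,
                 t0: float, duration_s: float, length_um: float,
                 intensity: float) -> Track:
    """Piecewise-constant-velocity polyline entering the window at ``t0``.

    Anterograde tracks (sign +1) enter at position 0, retrograde at the
    distal end.  With probability ``PAUSE_PROB`` the run is interrupted by
    one pause; the post-pause run moves at 0.75x the peak speed so that the
    peak segment stays the track's fastest.
    """
    x0 = 0.0 if sign > 0 else length_um
    pts = [(t0, x0)]
    t, x = t0, x0
    remaining = length_um
    paused = rng.random() < PAUSE_PROB
    # distance covered at peak speed before any pause
    first_frac = rng.uniform(0.35, 0.75) if paused else 1.0

    def advance(v: float, dist: float) -> None:
        nonlocal t, x, remaining
        dist = min(dist, remaining)
        if dist <= 0 or t >= duration_s:
            return
        dt = dist / v
        if t + dt > duration_s:  # clipped by movie end
            dt = duration_s - t
            dist = v * dt
        t, x, remaining = t + dt, x + sign * dist, remaining - dist
        pts.append((t, x))

    advance(speed, first_frac * length_um)
    if paused and t < duration_s and remaining > 0:
        pause_d = rng.uniform(1.0, 4.0)
        drift = rng.uniform(0.0, PAUSE_SPEED_UM_S)
        end = min(t + pause_d, duration_s)
        if end > t:
            pts.append((end, x + sign * drift * (end - t)))
            t, x = pts[-1]
        advance(0.75 * speed, remaining)
    if len(pts) < 2:  # entered in the very last frame; give it a stub
        pts.append((min(t0 + 0.2, duration_s + 0.2), x0 + sign * 0.2 * speed))
    return Track(
        axon_id=axon_id,
        points=pts,
        intensity=intensity,
        truth_direction="anterograde" if sign > 0 else "retrograde",
        truth_peak_speed=speed,
    )


def gen_svp_tracks(params: GenotypeParams, n_axons: int, duration_s: float,
                   length_um: float, seed: int) -> dict[str, list[Track]]:
    """Generate SVP cargo tracks, grouped by axon.

    Per axon and direction the track count is Poisson with mean
    ``flux * duration/60``; motile intensities are log-normal scaled by the
    genotype's ``intensity_scale``.
    """
    if duration_s <= 0 or length_um <= 0:
        raise ValueError("duration_s and length_um must be > 0")
    rng = np.random.default_rng(seed)
    axons: dict[str, list[Track]] = {}
    for i in range(n_axons):
        axon_id = f"axon{i:03d}"
        tracks: list[Track] = []
        for sign, flux, vmax in (
            (+1, params.antero_flux, params.antero_vmax_mean),
            (-1, params.retro_flux, params.retro_vmax_mean),
        ):
            n = rng.poisson(flux * duration_s / 60.0) if flux > 0 else 0
            speeds = _draw_track_speeds(rng, n, vmax)
            t0s = np.sort(rng.uniform(0.0, duration_s, size=n))
            for t0, v in zip(t0s, speeds):
                inten = rng.lognormal(
                    math.log(_TRACK_BASE_INTENSITY * params.intensity_scale), 0.3
                )
                tracks.append(
                    _build_track(rng, axon_id, sign, v, t0, duration_s,
                                 length_um, inten)
                )
        axons[axon_id] = tracks
    return axons


# ---------------------------------------------------------------------------
# kymograph rendering
# ---------------------------------------------------------------------------

def _paint_path(signal: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                intensity: float) -> None:
    """Paint an anti-aliased 3-px-wide path; overlaps keep the max value."""
    n_cols = signal.shape[1]
    for off in (-1, 0, 1):
        cc = np.round(cols).astype(int) + off
        ok = (cc >= 0) & (cc < n_cols)
        # triangular kernel of half-width 1.5 px around the subpixel centre
        w = np.clip(1.0 - np.abs(cc - cols) / 1.5, 0.0, 1.0) * intensity
        np.maximum.at(signal, (rows[ok], cc[ok]), w[ok])


def render_kymograph(tracks: list[Track], length_um: float, duration_s: float,
                     px_um: float = PX_UM, dt_s: float = SVP_DT_S,
                     noise_sd: float = 0.0, bg: float = 100.0,
                     seed: int = 0, sites: list[SvpSite] | None = None) -> Kymograph:
    """Render tracks (and optional stationary site bands) into a kymograph.

    Each track becomes a 3-pixel-wide anti-aliased streak of its intensity
    over a constant background with Gaussian read noise; sites become
    vertical bands.  Track portions outside the spatial span are clipped.
    """
    if px_um <= 0 or dt_s <= 0:
        raise ValueError("calibration must be positive")
    n_rows = int(round(duration_s / dt_s))
    n_cols = int(round(length_um / px_um))
    rng = np.random.default_rng(seed)
    signal = np.zeros((n_rows, n_cols))

    row_t = (np.arange(n_rows) + 0.5) * dt_s
    for tr in tracks:
        t, x = tr.times, tr.positions
        inside = (row_t >= t[0]) & (row_t <= t[-1])
        if not inside.any():
            continue
        rows = np.nonzero(inside)[0]
        xs = np.interp(row_t[rows], t, x)
        cols = xs / px_um
        ok = (cols >= 0) & (cols < n_cols)
        _paint_path(signal, rows[ok], cols[ok], tr.intensity)

    for s in sites or []:
        lo = max(int((s.centroid_um - s.extent_um / 2) / px_um), 0)
        hi = min(int(math.ceil((s.centroid_um + s.extent_um / 2) / px_um)), n_cols)
        if hi > lo:
            band = np.full((n_rows, hi - lo), s.mean_intensity)
            signal[:, lo:hi] = np.maximum(signal[:, lo:hi], band)

    values = signal + bg
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return Kymograph(values=values, px_um=px_um, dt_s=dt_s,
                     length_um=n_cols * px_um, duration_s=n_rows * dt_s)


# ---------------------------------------------------------------------------
# microtubule comets and SVP+ sites (comet mode, 1 s per row)
# ---------------------------------------------------------------------------

#: minimum separation between generated site centroids, um (hard-core process)
_SITE_MIN_SEP_UM = 3.0
_SITE_BASE_INTENSITY = 400.0
#: association window used by the generator, um
ASSOC_WINDOW_UM = 10.0


def _place_sites(rng: np.random.Generator, n: int, length_um: float) -> np.ndarray:
    """Uniform site centroids with a 3 um hard-core minimum separation."""
    pos: list[float] = []
    margin = 1.5
    for _ in range(n):
        for _attempt in range(200):
            x = rng.uniform(margin, length_um - margin)
            if all(abs(x - p) >= _SITE_MIN_SEP_UM for p in pos):
                pos.append(x)
                break
        else:  # axon saturated; accept overlap rather than dropping the site
            pos.append(rng.uniform(margin, length_um - margin))
    return np.asarray(pos)


def gen_comet_site_axon(params: GenotypeParams, length_um: float,
                        duration_s: float, seed: int,
                        axon_id: str = "axon000") -> tuple[list[SvpSite], list[CometEvent]]:
    """Stationary SVP+ sites plus comet events for one axon.

    Site count is Poisson(site_density * length/10); comet count is
    Poisson(comet_rate * length * duration/60).  A fraction ``assoc_prob``
    of comets initiates within 10 um of a site centroid, the rest start
    uniformly; comet growth speeds are Normal(0.1, 0.02) um/s truncated
    positive.  With no sites, all comets are placed uniformly.
    """
    if length_um <= 0 or duration_s <= 0:
        raise ValueError("length_um and duration_s must be > 0")
    rng = np.random.default_rng(seed)

    n_sites = rng.poisson(params.site_density * length_um / 10.0)
    centroids = _place_sites(rng, n_sites, length_um)
    sites = [
        SvpSite(axon_id=axon_id, centroid_um=c,
                extent_um=rng.uniform(1.0, 2.0),
                mean_intensity=rng.lognormal(math.log(_SITE_BASE_INTENSITY), 0.2))
        for c in centroids
    ]

    n_comets = rng.poisson(params.comet_rate * length_um * duration_s / 60.0)
    comets: list[CometEvent] = []
    for _ in range(n_comets):
        assoc = bool(n_sites > 0 and rng.random() < params.assoc_prob)
        if assoc:
            c = centroids[rng.integers(n_sites)]
            x0 = float(np.clip(c + rng.uniform(-0.95, 0.95) * ASSOC_WINDOW_UM,
                               0.0, length_um))
        else:
            x0 = rng.uniform(0.0, length_um)
        v = max(rng.normal(0.10, 0.02), 0.01)
        sign = 1 if rng.random() < 0.8 else -1  # most comets grow anterogradely
        dur = rng.uniform(20.0, 60.0)
        t0 = rng.uniform(0.0, max(duration_s - dur, 1.0))
        t1 = min(t0 + dur, duration_s)
        x1 = float(np.clip(x0 + sign * v * (t1 - t0), 0.0, length_um))
        comets.append(CometEvent(axon_id=axon_id, start=(t0, x0), end=(t1, x1),
                                 truth_assoc=assoc))
    return sites, comets


def render_comet_kymograph(sites: list[SvpSite], comets: list[CometEvent],
                           length_um: float, duration_s: float,
                           px_um: float = PX_UM, dt_s: float = COMET_DT_S,
                           noise_sd: float = 8.0, bg: float = 100.0,
                           seed: int = 0) -> Kymograph:
    """Comet-mode kymograph: persistent site bands plus faint comet streaks."""
    streaks = [
        Track(axon_id=c.axon_id, points=[c.start, c.end],
              intensity=0.5 * _SITE_BASE_INTENSITY, origin="generated")
        for c in comets
    ]
    return render_kymograph(streaks, length_um, duration_s, px_um=px_um,
                            dt_s=dt_s, noise_sd=noise_sd, bg=bg, seed=seed,
                            sites=sites)


# ---------------------------------------------------------------------------
# MEA wells
# ---------------------------------------------------------------------------

#: mean within-burst inter-spike interval, s
_BURST_ISI_MEAN_S = 0.020
#: denser spiking inside network-burst events, s
_NETBURST_ISI_MEAN_S = 0.015
#: network events recruit at least half of the array
_NETBURST_MIN_ELECTRODES = 6
_NETBURST_JITTER_S = 0.020
#: extracellular noise SD, uV; spike amplitude is 10x this
MEA_NOISE_SD_UV = 5.0
SPIKE_AMPLITUDE_SD = 10.0


def _burst_spikes(rng: np.random.Generator, t0: float, n: int, isi_mean: float) -> np.ndarray:
    isis = rng.exponential(isi_mean, size=max(n - 1, 0))
    return t0 + np.concatenate([[0.0], np.cumsum(isis)])


def gen_mea_recording(params: GenotypeParams, div: int = 21,
                      duration_s: float = MEA_DURATION_S, seed: int = 0,
                      with_traces: bool = False,
                      well_id: str = "well00") -> WellRecording:
    """One synthetic MEA well.

    Per electrode: homogeneous Poisson background at ``mfr_base`` plus burst
    epochs (Poisson onsets at ``burst_rate``; sizes 3 + Geometric(1/2);
    within-burst ISIs exponential, mean 20 ms).  Network events at
    ``netburst_rate`` recruit 6-12 electrodes with <=20 ms onset jitter and
    denser spiking.  With ``with_traces`` the spikes are rendered as biphasic
    1 ms templates (amplitude 10x the noise SD) on Gaussian noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    per_el: list[list[np.ndarray]] = [[] for _ in range(N_ELECTRODES)]
    truth: dict = {"bursts": [], "network_events": []}

    for e in range(N_ELECTRODES):
        n_bg = rng.poisson(params.mfr_base * duration_s)
        per_el[e].append(np.sort(rng.uniform(0.0, duration_s, size=n_bg)))
        n_b = rng.poisson(params.burst_rate * duration_s / 60.0)
        for t0 in rng.uniform(0.0, duration_s, size=n_b):
            n_sp = 3 + int(rng.geometric(0.5))
            sp = _burst_spikes(rng, t0, n_sp, _BURST_ISI_MEAN_S)
            per_el[e].append(sp)
            truth["bursts"].append({"electrode": e, "t_start": float(t0),
                                    "n_spikes": n_sp})

    n_nb = rng.poisson(params.netburst_rate * duration_s / 60.0)
    for t0 in np.sort(rng.uniform(0.0, max(duration_s - 1.0, 1.0), size=n_nb)):
        k = int(rng.integers(_NETBURST_MIN_ELECTRODES, N_ELECTRODES + 1))
        members = rng.choice(N_ELECTRODES, size=k, replace=False)
        for e in members:
            jitter = rng.uniform(0.0, _NETBURST_JITTER_S)
            n_sp = 5 + int(rng.geometric(0.5))
            sp = _burst_spikes(rng, t0 + jitter, n_sp, _NETBURST_ISI_MEAN_S)
            per_el[int(e)].append(sp)
        truth["network_events"].append({"t_start": float(t0),
                                        "electrodes": sorted(int(e) for e in members)})

    trains = []
    for e in range(N_ELECTRODES):
        t = np.sort(np.concatenate(per_el[e])) if per_el[e] else np.empty(0)
        t = t[(t >= 0) & (t < duration_s)]
        if t.size:  # enforce strict ordering for coincident samples
            keep = np.concatenate([[True], np.diff(t) > 1e-6])
            t = t[keep]
        trains.append(SpikeTrain(electrode_id=e, spike_times=t,
                                 duration_s=duration_s))

    traces = None
    if with_traces:
        traces = [
            render_spike_trace(tr.spike_times, duration_s, MEA_FS_HZ,
                               noise_sd=MEA_NOISE_SD_UV,
                               seed=int(rng.integers(2**31)))
            for tr in trains
        ]
    return WellRecording(well_id=well_id, div=div, electrodes=trains,
                         fs_hz=MEA_FS_HZ, duration_s=duration_s,
                         traces=traces, truth=truth)


def spike_template(fs_hz: float, amplitude: float) -> np.ndarray:
    """Biphasic 1 ms extracellular spike template (negative phase first)."""
    n = max(int(round(1e-3 * fs_hz)), 4)
    t = np.arange(n) / n
    return -amplitude * np.sin(2 * np.pi * t) * np.exp(-2.5 * t)


def render_spike_trace(spike_times: np.ndarray, duration_s: float,
                       fs_hz: float, noise_sd: float = MEA_NOISE_SD_UV,
                       seed: int = 0) -> np.ndarray:
    """Render a spike train onto Gaussian noise as float32 voltage, uV."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    trace = rng.normal(0.0, noise_sd, size=n).astype(np.float32)
    tmpl = spike_template(fs_hz, SPIKE_AMPLITUDE_SD * noise_sd).astype(np.float32)
    idx = np.round(np.asarray(spike_times) * fs_hz).astype(int)
    for i in idx:
        j = min(i + tmpl.size, n)
        if i < n:
            trace[i:j] += tmpl[: j - i]
    return trace


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def gen_ct_table(rel_expr: dict[str, float], ct_ref: float = 20.0,
                 ct_housekeeping: float = 15.0, noise_sd: float = 0.0,
                 n_reps: int = 3, seed: int = 0,
                 target_gene: str = "KIF1A",
                 housekeeping_gene: str = "GAPDH",
                 reference_genotype: str = "WT") -> pd.DataFrame:
    """Tidy Ct table built by inverting the ddCt relation.

    For genotype g the target Ct is ``ct_ref - log2(rel_expr[g])`` plus
    Gaussian noise; the housekeeping gene sits at ``ct_housekeeping`` for
    every sample.  The reference genotype must have rel_expr 1.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if any(v <= 0 for v in rel_expr.values()):
        raise ValueError("rel_expr values must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for g, r in rel_expr.items():
        for rep in range(n_reps):
            sample = f"{g}_rep{rep}"
            ct_t = ct_ref - math.log2(r) + rng.normal(0.0, noise_sd)
            ct_h = ct_housekeeping + rng.normal(0.0, noise_sd)
            rows.append((sample, g, target_gene, ct_t, f"rep{rep}"))
            rows.append((sample, g, housekeeping_gene, ct_h, f"rep{rep}"))
    return pd.DataFrame(rows, columns=["sample_id", "genotype", "gene", "ct",
                                       "replicate_id"])


# ---------------------------------------------------------------------------
# synapse puncta fields
# ---------------------------------------------------------------------------

PRE_SIZE_UM = (0.2, 2.5)
POST_SIZE_UM = (0.06, 2.0)


def gen_synapse_field(n_pre: int, apposed_frac: float,
                      map2_area_um2: float = 2000.0,
                      max_gap_um: float = 0.5, seed: int = 0,
                      lone_post_frac: float = 0.3) -> dict:
    """Pre/post puncta field with exactly ``floor(apposed_frac * n_pre)`` pairs.

    Pre puncta are laid out on a field of the given MAP2 area with pairwise
    spacing > 2 * max_gap_um (so greedy matching is provably optimal);
    apposed partners sit at a centroid gap <= max_gap_um, lone post puncta
    at > 3 * max_gap_um from every pre punctum.
    """
    if not 0.0 <= apposed_frac <= 1.0:
        raise ValueError("apposed_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    side = math.sqrt(map2_area_um2)
    min_sep = 2.5 * max_gap_um + 2.6  # keeps puncta (diam <= 2.5) well apart

    pre_xy: list[np.ndarray] = []
    for _ in range(n_pre):
        for _attempt in range(500):
            p = rng.uniform(2.0, side - 2.0, size=2)
            if all(np.linalg.norm(p - q) > min_sep for q in pre_xy):
                pre_xy.append(p)
                break
        else:
            pre_xy.append(rng.uniform(2.0, side - 2.0, size=2))
    pre_xy_a = np.asarray(pre_xy) if pre_xy else np.empty((0, 2))
    pre_z = rng.uniform(0.5, 2.5, size=n_pre)
    pre_xyz = np.column_stack([pre_xy_a, pre_z]) if n_pre else np.empty((0, 3))

    n_pair = int(math.floor(apposed_frac * n_pre))
    paired = rng.choice(n_pre, size=n_pair, replace=False) if n_pair else np.empty(0, int)
    post_xyz, pairs = [], []
    for i in paired:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.uniform(0.05, 0.9 * max_gap_um)
        post_xyz.append(pre_xyz[i] + r * u)
        pairs.append((int(i), len(post_xyz) - 1))
    n_lone = int(round(lone_post_frac * n_pre))
    for _ in range(n_lone):
        for _attempt in range(500):
            p = np.append(rng.uniform(0.0, side, size=2),
                          rng.uniform(0.5, 2.5))
            if pre_xyz.size == 0 or np.min(
                np.linalg.norm(pre_xyz - p, axis=1)) > 3.0 * max_gap_um:
                post_xyz.append(p)
                break

    pre = pd.DataFrame({
        "channel": "pre",
        "x_um": pre_xyz[:, 0] if n_pre else [],
        "y_um": pre_xyz[:, 1] if n_pre else [],
        "z_um": pre_xyz[:, 2] if n_pre else [],
        "equiv_diameter_um": rng.uniform(*PRE_SIZE_UM, size=n_pre),
        "mean_intensity": rng.uniform(400.0, 600.0, size=n_pre),
    })
    pa = np.asarray(post_xyz) if post_xyz else np.empty((0, 3))
    post = pd.DataFrame({
        "channel": "post",
        "x_um": pa[:, 0] if len(pa) else [],
        "y_um": pa[:, 1] if len(pa) else [],
        "z_um": pa[:, 2] if len(pa) else [],
        "equiv_diameter_um": rng.uniform(*POST_SIZE_UM, size=len(pa)),
        "mean_intensity": rng.uniform(400.0, 600.0, size=len(pa)),
    })
    return {"pre": pre, "post": post, "map2_area_um2": map2_area_um2,
            "truth_pairs": pairs}


def render_puncta_stack(puncta: pd.DataFrame, shape: tuple[int, int, int],
                        cal_um_px: float, z_step_um: float = 0.4,
                        bg: float = 0.0, noise_sd: float = 0.0,
                        seed: int = 0) -> np.ndarray:
    """Paint puncta as solid ellipsoids of their mean intensity into a z-stack.

    ``shape`` is (z, y, x); xy calibration ``cal_um_px``, z spacing
    ``z_step_um``.  Used for detector round-trip tests.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    stack = np.full(shape, bg, dtype=float)
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    for _, p in puncta.iterrows():
        r_um = p.equiv_diameter_um / 2.0
        d2 = (((xx * cal_um_px) - p.x_um) ** 2
              + ((yy * cal_um_px) - p.y_um) ** 2
              + ((zz * z_step_um) - p.z_um) ** 2)
        stack = np.where(d2 <= r_um ** 2,
                         np.maximum(stack, p.mean_intensity), stack)
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=shape)
    return stack
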