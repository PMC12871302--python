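"""Kymograph tracing and SVP transport metrics.

A kymograph is a space-time image of one axon: motile cargo appears as
sloped streaks, stationary material as vertical bands.  This module
replaces the manual ImageJ tracing workflow with an automatic tracer
(row-wise peak detection, predictive nearest-neighbour linking,
Douglas-Peucker simplification to inflection points) and computes the
standard transport read-outs:

* direction class — net displacement beyond 10 um, anterograde vs retrograde;
* flux — motile cargos per minute per direction;
* maximum velocity — per-axon mean of the five fastest segment speeds;
* motile intensity — background-subtracted peak brightness of a cargo as it
  enters the field.

Anterograde is the direction of increasing spatial coordinate; readers of
external kymographs must flip the axis if their acquisition ran the other
way.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Kymograph, Track

__all__ = [
    "TransportSummary",
    "trace_tracks",
    "classify_track",
    "segment_velocities",
    "max_velocity",
    "flux",
    "motile_intensity",
    "flux_ratio",
    "summarize_axon",
    "robust_background",
    "ANTEROGRADE",
    "RETROGRADE",
    "NON_MOTILE",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"
NON_MOTILE = "non_motile"

#: MAD -> Gaussian SD scale
_MAD_SCALE = 1.4826
#: segment speeds below this are pauses and excluded from the top-k pool, um/s
PAUSE_SPEED_UM_S = 0.1


@dataclass
class TransportSummary:
    """Per-axon transport metrics."""

    axon_id: str
    antero_flux: float
    retro_flux: float
    antero_vmax: float
    retro_vmax: float
    motile_intensities: list[float] = field(default_factory=list)

    @property
    def flux_ratio(self) -> float:
        return flux_ratio(self.antero_flux, self.retro_flux)


def robust_background(values: np.ndarray, k: float = 3.0) -> float:
    """Background level as median + k robust SDs (scaled MAD)."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + k * _MAD_SCALE * mad


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def _row_detections(kymo: Kymograph, thr: float) -> list[np.ndarray]:
    """Per-row sub-pixel positions (px) of local maxima above ``thr``."""
    v = kymo.values
    above = v > thr
    left = np.empty_like(v)
    right = np.empty_like(v)
    left[:, 1:], left[:, 0] = v[:, :-1], -np.inf
    right[:, :-1], right[:, -1] = v[:, 1:], -np.inf
    peaks = above & (v >= left) & (v > right)
    out = []
    for r in range(v.shape[0]):
        cols = np.nonzero(peaks[r])[0]
        # intensity-weighted sub-pixel refinement over +-1 px
        pos = []
        for c in cols:
            lo, hi = max(c - 1, 0), min(c + 2, v.shape[1])
            w = np.clip(v[r, lo:hi] - thr, 0.0, None)
            pos.append(float(np.average(np.arange(lo, hi), weights=w))
                       if w.sum() > 0 else float(c))
        out.append(np.asarray(pos))
    return out


class _Candidate:
    __slots__ = ("rows", "cols", "virtual", "vel", "misses", "n_virtual")

    def __init__(self, row: int, col: float):
        self.rows = [row]
        self.cols = [col]
        self.virtual = [False]
        self.vel = 0.0  # px per row
        self.misses = 0
        self.n_virtual = 0  # consecutive coasted rows

    def predict(self, row: int) -> float:
        return self.cols[-1] + self.vel * (row - self.rows[-1])

    def add(self, row: int, col: float) -> None:
        dr = row - self.rows[-1]
        v_new = (col - self.cols[-1]) / dr
        self.vel = v_new if len(self.rows) == 1 else 0.5 * self.vel + 0.5 * v_new
        self.rows.append(row)
        self.cols.append(col)
        self.virtual.append(False)
        self.misses = 0
        self.n_virtual = 0

    def coast(self, row: int) -> None:
        """Extend along the prediction through an occlusion (no detection)."""
        pred = self.predict(row)
        self.rows.append(row)
        self.cols.append(pred)
        self.virtual.append(True)
        self.misses = 0
        self.n_virtual += 1

    def finalize(self) -> tuple[np.ndarray, np.ndarray]:
        """Real and leading/trailing-trimmed coasted points."""
        v = np.asarray(self.virtual)
        real = np.nonzero(~v)[0]
        lo, hi = real[0], real[-1] + 1
        return (np.asarray(self.rows[lo:hi], dtype=float),
                np.asarray(self.cols[lo:hi], dtype=float))


def _end_slope(c: _Candidate, head: bool, n: int = 6) -> float:
    rows = np.asarray(c.rows[:n] if head else c.rows[-n:], dtype=float)
    cols = np.asarray(c.cols[:n] if head else c.cols[-n:], dtype=float)
    if rows.size < 2:
        return c.vel
    return float(np.polyfit(rows, cols, 1)[0])


def _stitch_fragments(cands: list[_Candidate], max_gap_rows: int = 25,
                      max_dvel: float = 2.0) -> list[_Candidate]:
    """Rejoin track fragments split by occlusions.

    A fragment pair is stitched when the second starts shortly after the
    first ends, on the first's constant-velocity extrapolation, with a
    compatible slope.  Greedy, nearest-deviation-first, one-to-one.
    """
    cands = sorted(cands, key=lambda c: c.rows[0])
    links = []
    for i, a in enumerate(cands):
        va = _end_slope(a, head=False)
        for j, b in enumerate(cands):
            gap = b.rows[0] - a.rows[-1]
            if not 0 < gap <= max_gap_rows:
                continue
            dev = abs(a.cols[-1] + va * gap - b.cols[0])
            max_dev = min(4.0 + 1.0 * gap, 15.0)
            if dev <= max_dev and abs(va - _end_slope(b, head=True)) <= max_dvel:
                links.append((dev, i, j))
    links.sort(key=lambda t: t[0])
    succ: dict[int, int] = {}
    pred: dict[int, int] = {}
    for _, i, j in links:
        if i in succ or j in pred:
            continue
        succ[i] = j
        pred[j] = i
    out = []
    for i, c in enumerate(cands):
        if i in pred:
            continue
        k = i
        while k in succ:
            nxt = cands[succ[k]]
            c.rows.extend(nxt.rows)
            c.cols.extend(nxt.cols)
            c.virtual.extend(nxt.virtual)
            k = succ[k]
        out.append(c)
    return out


def _douglas_peucker(rows: np.ndarray, cols: np.ndarray, tol: float) -> np.ndarray:
    """Indices of the polyline simplified to inflection points."""
    keep = np.zeros(rows.size, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, rows.size - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        dr, dc = rows[j] - rows[i], cols[j] - cols[i]
        norm = np.hypot(dr, dc)
        d = np.abs(dc * (rows[i + 1:j] - rows[i])
                   - dr * (cols[i + 1:j] - cols[i])) / norm
        k = int(np.argmax(d))
        if d[k] > tol:
            m = i + 1 + k
            keep[m] = True
            stack.extend([(i, m), (m, j)])
    return np.nonzero(keep)[0]


def trace_tracks(kymo: Kymograph, min_len_um: float = 3.0,
                 max_step_um: float = 6.0, max_gap_rows: int = 2,
                 dp_tol_px: float = 1.0, min_rows: int = 3) -> list[Track]:
    """Trace motile tracks from a calibrated kymograph.

    Pipeline: per-row local maxima above the robust background
    (median + 3 robust SDs), nearest-neighbour linking against a
    constant-velocity prediction with a per-step displacement limit, gap
    closing across up to ``max_gap_rows`` missed rows, Douglas-Peucker
    simplification (tolerance 1 px) to inflection points.  Paths spanning
    less than ``min_len_um`` — stationary bands included — are discarded.
    """
    if not isinstance(kymo, Kymograph):
        raise ValueError("trace_tracks needs a calibrated Kymograph")
    thr = robust_background(kymo.values)
    dets = _row_detections(kymo, thr)
    max_step_px = max_step_um / kymo.px_um
    # once a velocity estimate exists, detections must stay close to the
    # constant-velocity prediction; fresh candidates get the full step limit
    on_path_px = 1.5
    tight_px = 3.0  # px/row deviation from prediction once a velocity exists
    contest_px = 4.0          # two streaks this close are unresolvable (3-px width)
    max_coast_rows = 12       # longest tolerated occlusion

    active: list[_Candidate] = []
    done: list[_Candidate] = []
    for r, cols in enumerate(dets):
        taken = np.zeros(cols.size, dtype=bool)
        preds = [c.predict(r) for c in active]
        contested = [
            any(abs(q - p) <= contest_px for k, q in enumerate(preds) if k != i)
            for i, p in enumerate(preds)
        ]
        # globally nearest-first claims: the track closest to a detection wins
        claims = []
        for i, c in enumerate(active):
            gap = r - c.rows[-1]
            last = c.cols[-1]
            for j in range(cols.size):
                d_pred = abs(cols[j] - preds[i])
                if len(c.rows) < 2:
                    # velocity still unknown: bound by the per-step limit,
                    # but never wider than a plausible single-row run
                    ok = d_pred <= min(max_step_px, 8.0) * gap
                elif abs(c.vel) >= 1.0:
                    # moving: follow the prediction, or brake into a pause
                    ok = (d_pred <= tight_px * gap
                          or abs(cols[j] - last) <= tight_px)
                else:
                    # paused / stationary: allow a run to resume at speed
                    ok = abs(cols[j] - last) <= 8.0 * gap
                if ok:
                    claims.append((d_pred, i, j))
        claims.sort(key=lambda t: t[0])
        assigned = [False] * len(active)
        for d, i, j in claims:
            if assigned[i] or taken[j]:
                continue
            c = active[i]
            if d > on_path_px and contested[i]:
                continue  # ambiguous crossing: coast instead of grabbing
            if len(c.rows) >= 3 and abs(c.vel) > 0.8:
                gap = r - c.rows[-1]
                v_implied = (cols[j] - c.cols[-1]) / gap
                if c.vel * v_implied < 0 and abs(v_implied) > 0.8:
                    continue  # a different streak moving the other way
            c.add(r, float(cols[j]))
            taken[j] = True
            assigned[i] = True
        survivors = []
        for i, c in enumerate(active):
            if assigned[i]:
                survivors.append(c)
                continue
            if contested[i] and len(c.rows) >= 3 and c.n_virtual < max_coast_rows:
                c.coast(r)
                survivors.append(c)
                continue
            c.misses = r - c.rows[-1]
            if c.misses > max_gap_rows:
                done.append(c)
            else:
                survivors.append(c)
        active = survivors
        # unclaimed detections spawn candidates, but never right on top of
        # an existing track (crossing residue)
        for j in np.nonzero(~taken)[0]:
            col = float(cols[j])
            if all(abs(p - col) > contest_px for p in preds):
                active.append(_Candidate(r, col))
    done.extend(active)

    done = _stitch_fragments(done)

    # streak brightness validation: genuine cargo sits well above the noise
    med = float(np.median(kymo.values))
    sigma = float(np.median(np.abs(kymo.values - med))) * _MAD_SCALE
    min_track_intensity = med + 8.0 * sigma

    tracks = []
    for c in done:
        rows, cols = c.finalize()
        if rows.size < min_rows:
            continue
        if (cols.max() - cols.min()) * kymo.px_um < min_len_um:
            continue
        samp = kymo.values[rows.astype(int),
                           np.clip(np.round(cols).astype(int), 0,
                                   kymo.values.shape[1] - 1)]
        if float(np.median(samp)) < min_track_intensity:
            continue
        idx = _douglas_peucker(rows, cols, dp_tol_px)
        pts = [((rows[i] + 0.5) * kymo.dt_s, cols[i] * kymo.px_um)
               for i in idx]
        tracks.append(Track(axon_id="traced", points=pts, origin="traced"))
    return tracks


# ---------------------------------------------------------------------------
# transport metrics
# ---------------------------------------------------------------------------

def classify_track(track: Track, min_net_um: float = 10.0) -> str:
    """Direction class by net displacement (strictly greater than the cutoff)."""
    net = track.net_displacement_um
    if net > min_net_um:
        return ANTEROGRADE
    if net < -min_net_um:
        return RETROGRADE
    return NON_MOTILE


def segment_velocities(track: Track) -> np.ndarray:
    """Unsigned speed (um/s) of each inter-inflection segment."""
    t, x = track.times, track.positions
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("repeated or decreasing timestamps")
    return np.abs(np.diff(x)) / dt


def max_velocity(tracks: list[Track], direction: str, k: int = 5,
                 min_net_um: float = 10.0,
                 pause_speed: float = PAUSE_SPEED_UM_S) -> float:
    """Per-axon 'maximum velocity': mean of the k fastest segment speeds.

    Speeds are pooled over every track classified in ``direction``; pause
    segments (below ``pause_speed``) are excluded.  With fewer than k
    speeds the mean of all is returned with a warning; with no motile track
    the value is undefined (NaN, with a warning) — never zero.
    """
    pool: list[float] = []
    for tr in tracks:
        if classify_track(tr, min_net_um) == direction:
            s = segment_velocities(tr)
            pool.extend(s[s >= pause_speed])
    if not pool:
        warnings.warn(f"no motile {direction} track: maximum velocity undefined")
        return float("nan")
    speeds = np.sort(np.asarray(pool))[::-1]
    if speeds.size < k:
        warnings.warn(f"only {speeds.size} segment speeds (< k={k}); using all")
        return float(speeds.mean())
    return float(speeds[:k].mean())


def flux(tracks: list[Track], direction: str, duration_s: float,
         min_net_um: float = 10.0) -> float:
    """Motile cargos per minute in one direction (each track counted once)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = sum(1 for tr in tracks if classify_track(tr, min_net_um) == direction)
    return n / (duration_s / 60.0)


def motile_intensity(kymo: Kymograph, track: Track,
                     exclude_halfwidth_px: int = 5) -> float:
    """Background-subtracted peak brightness of a cargo entering the field.

    Maximum pixel value in a 3x3 window at the track's first point, minus
    the local background (median of the first occupied row outside a window
    around the track).
    """
    t0 = track.points[0][0]
    n_rows, n_cols = kymo.values.shape
    # first rendered row at or after the track's entry, and the track's
    # interpolated position at that row time
    r = max(int(math.ceil(t0 / kymo.dt_s - 0.5)), 0)
    r = min(r, n_rows - 1)
    x0 = float(np.interp((r + 0.5) * kymo.dt_s, track.times, track.positions))
    c = int(round(x0 / kymo.px_um))
    if not (0 <= c < n_cols) or not (0 <= r < n_rows):
        raise ValueError("track first point outside the kymograph grid")
    r0, r1 = max(r - 1, 0), min(r + 2, n_rows)
    c0, c1 = max(c - 1, 0), min(c + 2, n_cols)
    peak = float(kymo.values[r0:r1, c0:c1].max())
    row = kymo.values[r]
    mask = np.ones(n_cols, dtype=bool)
    mask[max(c - exclude_halfwidth_px, 0):c + exclude_halfwidth_px + 1] = False
    bg = float(np.median(row[mask])) if mask.any() else float(np.median(row))
    return peak - bg


def flux_ratio(antero_flux: float, retro_flux: float) -> float:
    """Retrograde / anterograde flux; undefined (NaN) when anterograde is 0."""
    if antero_flux == 0:
        warnings.warn("anterograde flux is 0: flux ratio undefined")
        return float("nan")
    return retro_flux / antero_flux


def summarize_axon(tracks: list[Track], duration_s: float, axon_id: str = "",
                   kymo: Kymograph | None = None, k: int = 5) -> TransportSummary:
    """Assemble the per-axon TransportSummary from traced (or given) tracks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a_v = max_velocity(tracks, ANTEROGRADE, k=k)
        r_v = max_velocity(tracks, RETROGRADE, k=k)
    intens = []
    if kymo is not None:
        for tr in tracks:
            if classify_track(tr) == ANTEROGRADE:
                try:
                    intens.append(motile_intensity(kymo, tr))
                except ValueError:
                    pass
    return TransportSummary(
        axon_id=axon_id,
        antero_flux=flux(tracks, ANTEROGRADE, duration_s),
        retro_flux=flux(tracks, RETROGRADE, duration_s),
        antero_vmax=a_v,
        retro_vmax=r_v,
        motile_intensities=intens,
    )


def summaries_to_frame(summaries: list[TransportSummary]) -> pd.DataFrame:
    """Tidy per-axon table of transport metrics."""
    return pd.DataFrame(
        {
            "axon_id": [s.axon_id for s in summaries],
            "antero_flux_per_min": [s.antero_flux for s in summaries],
            "retro_flux_per_min": [s.retro_flux for s in summaries],
            "antero_vmax_um_s": [s.antero_vmax for s in summaries],
            "retro_vmax_um_s": [s.retro_vmax for s in summaries],
            "mean_motile_intensity": [
                float(np.mean(s.motile_intensities)) if s.motile_intensities
                else float("nan")
                for s in summaries
            ],
        }
    )
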