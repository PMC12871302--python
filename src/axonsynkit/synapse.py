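"""Synapse puncta detection, apposition matching and intensity masks.

Pre- and postsynaptic puncta (synapsin / PSD-95 style channels) are
segmented from 3-D stacks with a channel-specific size window (pre
0.2-2.5 um, post 0.06-2 um equivalent diameter) and a final threshold of
two-thirds of the mean puncta intensity.  Apposed pairs are pre/post
puncta whose centroids lie within a small gap (default 0.5 um), matched
one-to-one; synapse density normalises the matched count to the
MAP2-positive somatodendritic area.  Intensity read-outs for soma and
heterologous-synapse analyses (top-percent masks, ROI means) live here
too.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import chi2
from skimage import draw, measure
from skimage.filters import threshold_otsu

__all__ = [
    "SIZE_WINDOWS_UM",
    "detect_puncta",
    "match_appositions",
    "apposed_percent",
    "synapse_density",
    "chi_square_independence",
    "top_percent_mask_intensity",
    "roi_mean_intensity",
]

#: channel-specific equivalent-diameter windows, um
SIZE_WINDOWS_UM = {"pre": (0.2, 2.5), "post": (0.06, 2.0)}


def _components(stack: np.ndarray, thr: float, cal_um_px: float,
                z_step_um: float) -> pd.DataFrame:
    labels = measure.label(stack > thr)
    props = measure.regionprops(labels, intensity_image=stack)
    voxel_um3 = cal_um_px * cal_um_px * z_step_um
    rows = []
    for p in props:
        vol = p.area * voxel_um3
        d = (6.0 * vol / np.pi) ** (1.0 / 3.0)
        cz, cy, cx = p.centroid
        rows.append((cx * cal_um_px, cy * cal_um_px, cz * z_step_um, d,
                     float(p.mean_intensity)))
    return pd.DataFrame(rows, columns=["x_um", "y_um", "z_um",
                                       "equiv_diameter_um", "mean_intensity"])


def detect_puncta(stack: np.ndarray, channel: str, cal_um_px: float,
                  z_step_um: float = 0.4) -> pd.DataFrame:
    """Detect puncta in a (z, y, x) stack for one synaptic channel.

    Otsu-seeded connected components give a provisional puncta set; the
    final threshold is two-thirds of the mean puncta intensity, and the
    resulting components are filtered to the channel's equivalent-diameter
    window.
    """
    if channel not in SIZE_WINDOWS_UM:
        raise ValueError(f"channel must be one of {sorted(SIZE_WINDOWS_UM)}")
    stack = np.asarray(stack, dtype=float)
    cols = ["channel", "x_um", "y_um", "z_um", "equiv_diameter_um",
            "mean_intensity"]
    if stack.size == 0 or np.ptp(stack) == 0:
        return pd.DataFrame(columns=cols)
    provisional = _components(stack, threshold_otsu(stack), cal_um_px, z_step_um)
    if provisional.empty:
        return pd.DataFrame(columns=cols)
    thr = (2.0 / 3.0) * float(provisional.mean_intensity.mean())
    final = _components(stack, thr, cal_um_px, z_step_um)
    lo, hi = SIZE_WINDOWS_UM[channel]
    final = final[(final.equiv_diameter_um >= lo)
                  & (final.equiv_diameter_um <= hi)].reset_index(drop=True)
    final.insert(0, "channel", channel)
    return final


def match_appositions(pre: pd.DataFrame, post: pd.DataFrame,
                      max_gap_um: float = 0.5) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-neighbour matching of pre to post puncta.

    Candidate pairs with centroid gap <= ``max_gap_um`` are accepted in
    order of increasing distance (ties by lower pre then post index); each
    punctum is matched at most once.  Returns (pre_index, post_index)
    positional pairs.
    """
    if len(pre) == 0 or len(post) == 0:
        return []
    a = pre[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    b = post[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    d = cdist(a, b)
    ii, jj = np.nonzero(d <= max_gap_um)
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_pre: set[int] = set()
    used_post: set[int] = set()
    pairs = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_pre or j in used_post:
            continue
        pairs.append((i, j))
        used_pre.add(i)
        used_post.add(j)
    return pairs


def apposed_percent(n_matched: int, n_pre: int) -> float:
    """Percentage of presynaptic puncta with a postsynaptic partner."""
    if n_pre <= 0:
        raise ValueError("n_pre must be > 0")
    return 100.0 * n_matched / n_pre


def synapse_density(n_matched: int, map2_area_um2: float) -> float:
    """Matched synapses per um^2 of MAP2-positive area."""
    if map2_area_um2 <= 0:
        raise ValueError("map2_area_um2 must be > 0: density undefined")
    return n_matched / map2_area_um2


def chi_square_independence(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a 2 x k contingency table.

    Rows are apposed vs lone presynaptic puncta, columns genotypes.
    Expected counts come from the row/column margins; returns
    (statistic, df, p) with p from the upper chi-square tail.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("counts must be a 2-D contingency table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValueError("zero margin in contingency table")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(chi2.sf(stat, df))
    return stat, df, p


def top_percent_mask_intensity(image: np.ndarray, pct: float) -> float:
    """Mean original intensity within the top-``pct``-percent intensity mask.

    The mask keeps pixels above the (100 - pct)th percentile, mirroring the
    8-bit object masks used for heterologous-synapse intensity (top 3% for
    synaptophysin, 2% for synaptobrevin-2).  A constant image masks every
    pixel, with a warning.
    """
    if not 0 < pct < 100:
        raise ValueError("pct must be in (0, 100)")
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        warnings.warn("constant image: top-percent mask covers everything")
        return float(img.mean())
    thr = np.percentile(img, 100.0 - pct)
    return float(img[img > thr].mean())


def roi_mean_intensity(sum_projection: np.ndarray,
                       roi_polygon: np.ndarray) -> float:
    """Mean pixel value inside a polygonal ROI of a sum projection.

    ``roi_polygon`` is an (n, 2) array of (row, col) vertices, e.g. a
    somatodendritic outline drawn on the MAP2 channel.
    """
    img = np.asarray(sum_projection, dtype=float)
    poly = np.asarray(roi_polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3:
        raise ValueError("roi_polygon needs at least 3 (row, col) vertices")
    rr, cc = draw.polygon(poly[:, 0], poly[:, 1], shape=img.shape)
    if rr.size == 0:
        raise ValueError("empty ROI")
    return float(img[rr, cc].mean())
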