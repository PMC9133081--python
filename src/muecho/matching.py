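"""Matching EMG-derived firing patterns to tissue-velocity components.

For each motor unit the firing pattern is convolved with a 50 ms positive
half-sine to form its *train of displacement velocities*.  The train is
cross-correlated with every temporal independent component of every ROI
within a +/-20 ms lag window; the per-ROI maxima form a 19 x 19 correlation
map.  The map is thresholded at cc > 0.5, the best 8-connected cluster is
selected (largest; ties broken by mean correlation), the cluster's
sign-aligned spatial components are overlap-added into the unit's
displacement map (whose |value|-weighted centroid localizes the unit in mm),
and the cluster-mean temporal component is spike-triggered averaged into the
unit's velocity profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .population import FiringPattern, MuscleGeometry
from .stica import DecompositionSet

__all__ = [
    "DisplacementTrain",
    "CorrelationMap",
    "MUIdentification",
    "displacement_train",
    "correlate_rois",
    "segment_map",
    "displacement_area",
    "velocity_profile",
    "identify_mu",
    "save_identifications_h5",
    "save_heatmap_png",
]

WAVE_MS = 50.0
MAX_LAG_MS = 20.0
CC_THRESHOLD = 0.5
STA_WINDOW_S = (-0.025, 0.175)
MIN_STA_SPIKES = 20


@dataclass(frozen=True)
class DisplacementTrain:
    """Synthetic train of MU displacement velocities at frame resolution."""

    mu_id: int
    samples: np.ndarray
    fps: float


@dataclass
class CorrelationMap:
    """Per-ROI best match of one displacement train.

    ``peak_cc`` stores the sign-aligned (non-negative) peak correlation;
    ``sign`` records the flip to apply to the paired spatial/temporal
    component; ``best_lag`` is in frames (positive = component delayed
    relative to the train).
    """

    mu_id: int
    peak_cc: np.ndarray  # (n_rows, n_cols)
    best_component: np.ndarray  # int, -1 where the ROI had no components
    best_lag: np.ndarray  # int frames
    sign: np.ndarray  # +/-1
    fps: float


@dataclass
class MUIdentification:
    """Full identification of one MU in the velocity movie."""

    mu_id: int
    matched: bool
    cluster: set[tuple[int, int]]
    correlation_map: CorrelationMap
    displacement_map: np.ndarray | None
    us_centroid_mm: tuple[float, float] | None  # (x, depth)
    profile_mean: np.ndarray | None
    profile_sd: np.ndarray | None
    profile_lags_s: np.ndarray | None
    mean_cluster_cc: float


def _half_sine(fps: float, duration_ms: float = WAVE_MS) -> np.ndarray:
    m = int(round(duration_ms / 1000.0 * fps)) - 1
    return np.sin(np.pi * np.arange(m + 1) / m)


def displacement_train(fp: FiringPattern, fps: float, duration_s: float) -> DisplacementTrain:
    """Convolve the spike indicator with the 50 ms positive half-sine (peak 1)."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    n = int(round(duration_s * fps))
    t = fp.spike_times_s
    if t.size and (t.min() < 0 or t.max() * fps >= n):
        raise ValueError("spike times outside the recording duration")
    idx = np.minimum(np.round(t * fps).astype(int), n - 1)
    s = np.zeros(n)
    np.add.at(s, idx, 1.0)
    samples = np.convolve(s, _half_sine(fps))[:n]
    return DisplacementTrain(mu_id=fp.mu_id, samples=samples, fps=fps)


def _shifted_matrix(z: np.ndarray, max_lag: int) -> np.ndarray:
    """Rows are the zero-padded train shifted by lag -L..+L (z[t - lag])."""
    n = z.size
    out = np.zeros((2 * max_lag + 1, n), dtype=np.float32)
    for k, lag in enumerate(range(-max_lag, max_lag + 1)):
        if lag >= 0:
            out[k, lag:] = z[: n - lag]
        else:
            out[k, :lag] = z[-lag:]
    return out


def correlate_rois(
    train: DisplacementTrain,
    decomps: DecompositionSet,
    max_lag_ms: float = MAX_LAG_MS,
) -> CorrelationMap:
    """Best component/lag per ROI by normalized cross-correlation.

    For every ROI the component and lag (within +/- ``max_lag_ms``) with the
    greatest |cc| is kept; the stored peak is sign-aligned (>= 0) and the
    flip recorded for downstream use of the paired components.
    """
    if abs(train.fps - decomps.fps) > 1e-9:
        raise ValueError("train and decompositions have different frame rates")
    T = decomps.n_frames
    if train.samples.size != T:
        raise ValueError("train length does not match component length")
    sd = train.samples.std()
    if sd == 0:
        z = np.zeros(T, dtype=np.float32)
    else:
        z = ((train.samples - train.samples.mean()) / sd).astype(np.float32)
    max_lag = int(round(max_lag_ms / 1000.0 * train.fps))
    shifted = _shifted_matrix(z, max_lag)  # (2L+1, T)
    comps, owners = decomps.stacked_temporal()
    n_rows, n_cols = decomps.grid.grid_shape
    peak = np.zeros((n_rows, n_cols))
    best_comp = np.full((n_rows, n_cols), -1, dtype=int)
    best_lag = np.zeros((n_rows, n_cols), dtype=int)
    sign = np.ones((n_rows, n_cols), dtype=int)
    if comps.size:
        cc = (comps @ shifted.T) / np.float32(T)  # (n_total, 2L+1)
        flat_best = np.abs(cc).argmax(axis=1)
        cc_best = cc[np.arange(cc.shape[0]), flat_best]
        # components are stacked grouped by ROI: reduce each group with argmax
        roi_lin = owners[:, 0] * n_cols + owners[:, 1]
        bounds = np.flatnonzero(np.diff(roi_lin)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [roi_lin.size]])
        for s0, s1 in zip(starts, stops):
            n = s0 + int(np.abs(cc_best[s0:s1]).argmax())
            i, j, c = owners[n]
            peak[i, j] = abs(cc_best[n])
            best_comp[i, j] = c
            best_lag[i, j] = flat_best[n] - max_lag
            sign[i, j] = 1 if cc_best[n] >= 0 else -1
    return CorrelationMap(
        mu_id=train.mu_id,
        peak_cc=peak,
        best_component=best_comp,
        best_lag=best_lag,
        sign=sign,
        fps=train.fps,
    )


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def segment_map(cmap: CorrelationMap, threshold: float = CC_THRESHOLD) -> set[tuple[int, int]]:
    """Threshold at cc > ``threshold`` and pick the best 8-connected cluster.

    Clusters are ranked by size, ties broken by mean correlation.  An empty
    result is a valid "no identification" for the unit.
    """
    mask = cmap.peak_cc > threshold
    labels, n_lab = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    if n_lab == 0:
        return set()
    best: tuple[int, float] | None = None
    best_lab = 0
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        key = (int(sel.sum()), float(cmap.peak_cc[sel].mean()))
        if best is None or key > best:
            best, best_lab = key, lab
    ii, jj = np.nonzero(labels == best_lab)
    return {(int(i), int(j)) for i, j in zip(ii, jj)}


def displacement_area(
    cluster: set[tuple[int, int]],
    decomps: DecompositionSet,
    cmap: CorrelationMap,
    geometry: MuscleGeometry,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Overlap-add the cluster's sign-aligned spatial components; centroid in mm.

    The summed canvas is normalized by the per-pixel count of covering cluster
    ROIs, so a pixel's weight does not depend on how many overlapping ROIs the
    5 px tiling happens to place over it.  The centroid is the |value|-weighted
    mean pixel position of the map, converted with the geometry's mm/px.
    """
    if not cluster:
        raise ValueError("empty cluster")
    rows, cols = geometry.image_px
    canvas = np.zeros((rows, cols))
    coverage = np.zeros((rows, cols))
    p = decomps.grid.roi_px
    for (i, j) in cluster:
        d = decomps[(i, j)]
        c = cmap.best_component[i, j]
        if c < 0:
            continue
        r0, c0 = d.origin
        canvas[r0 : r0 + p, c0 : c0 + p] += cmap.sign[i, j] * d.spatial[c]
        coverage[r0 : r0 + p, c0 : c0 + p] += 1.0
    canvas /= np.maximum(coverage, 1.0)
    w = np.abs(canvas)
    total = w.sum()
    if total == 0:
        raise ValueError("displacement map is identically zero")
    mmpx = geometry.mm_per_px
    r_idx, c_idx = np.mgrid[0:rows, 0:cols]
    depth = float((w * (r_idx + 0.5)).sum() / total) * mmpx
    x = float((w * (c_idx + 0.5)).sum() / total) * mmpx
    return canvas, (x, depth)


def velocity_profile(
    cluster: set[tuple[int, int]],
    decomps: DecompositionSet,
    cmap: CorrelationMap,
    fp: FiringPattern,
    window_s: tuple[float, float] = STA_WINDOW_S,
    min_spikes: int = MIN_STA_SPIKES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike-triggered average of the cluster-mean temporal component.

    Returns ``(mean, sd, lags_s)`` over the window around each usable spike
    (spikes whose full window lies inside the recording).
    """
    if not cluster:
        raise ValueError("empty cluster")
    fps = decomps.fps
    T = decomps.n_frames
    tc = np.zeros(T)
    n_used = 0
    for (i, j) in cluster:
        d = decomps[(i, j)]
        c = cmap.best_component[i, j]
        if c < 0:
            continue
        tc += cmap.sign[i, j] * d.temporal[c]
        n_used += 1
    if n_used == 0:
        raise ValueError("cluster has no usable components")
    tc /= n_used
    lo = int(round(window_s[0] * fps))
    hi = int(round(window_s[1] * fps))
    idx = np.round(fp.spike_times_s * fps).astype(int)
    usable = idx[(idx + lo >= 0) & (idx + hi < T)]
    if usable.size < min_spikes:
        raise ValueError(
            f"only {usable.size} spikes with a full STA window (need >= {min_spikes})"
        )
    segs = np.stack([tc[k + lo : k + hi + 1] for k in usable])
    lags = np.arange(lo, hi + 1) / fps
    return segs.mean(axis=0), segs.std(axis=0, ddof=0), lags


def save_identifications_h5(path, idents: Sequence["MUIdentification"]) -> None:
    """Per-MU results in one HDF5 file: displacement map, centroid, profile."""
    import h5py

    with h5py.File(path, "w") as f:
        for ident in idents:
            g = f.create_group(f"mu/{ident.mu_id}")
            g.attrs["matched"] = ident.matched
            g.attrs["mean_cluster_cc"] = ident.mean_cluster_cc
            g.create_dataset("correlation_map", data=ident.correlation_map.peak_cc)
            if not ident.matched:
                continue
            g.attrs["centroid_x_mm"], g.attrs["centroid_depth_mm"] = ident.us_centroid_mm
            g.create_dataset("displacement_map", data=ident.displacement_map)
            g.create_dataset("cluster", data=np.array(sorted(ident.cluster)))
            if ident.profile_mean is not None:
                g.create_dataset("profile_mean", data=ident.profile_mean)
                g.create_dataset("profile_sd", data=ident.profile_sd)
                g.create_dataset("profile_lags_s", data=ident.profile_lags_s)


def save_heatmap_png(path, ident: "MUIdentification", geometry: MuscleGeometry) -> None:
    """Displacement-area heatmap with the centroid marked (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not ident.matched:
        raise ValueError("cannot plot an unmatched identification")
    fov_d, fov_x = geometry.field_of_view_mm
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    im = ax.imshow(
        np.abs(ident.displacement_map), extent=(0, fov_x, fov_d, 0), cmap="hot"
    )
    ax.plot(*ident.us_centroid_mm, "c+", markersize=12, markeredgewidth=2)
    ax.set_xlabel("medio-lateral (mm)")
    ax.set_ylabel("depth (mm)")
    ax.set_title(f"MU {ident.mu_id} displacement area")
    fig.colorbar(im, ax=ax, label="|summed spatial component|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def identify_mu(
    fp: FiringPattern,
    decomps: DecompositionSet,
    geometry: MuscleGeometry,
    max_lag_ms: float = MAX_LAG_MS,
    threshold: float = CC_THRESHOLD,
    sta_window_s: tuple[float, float] = STA_WINDOW_S,
    min_sta_spikes: int = MIN_STA_SPIKES,
) -> MUIdentification:
    """Run the full identification chain for one firing pattern."""
    duration_s = decomps.n_frames / decomps.fps
    train = displacement_train(fp, decomps.fps, duration_s)
    cmap = correlate_rois(train, decomps, max_lag_ms=max_lag_ms)
    cluster = segment_map(cmap, threshold=threshold)
    if not cluster:
        return MUIdentification(
            mu_id=fp.mu_id,
            matched=False,
            cluster=set(),
            correlation_map=cmap,
            displacement_map=None,
            us_centroid_mm=None,
            profile_mean=None,
            profile_sd=None,
            profile_lags_s=None,
            mean_cluster_cc=0.0,
        )
    dmap, centroid = displacement_area(cluster, decomps, cmap, geometry)
    try:
        mean, sd, lags = velocity_profile(
            cluster, decomps, cmap, fp, window_s=sta_window_s, min_spikes=min_sta_spikes
        )
    except ValueError:
        mean = sd = lags = None
    cc_vals = [cmap.peak_cc[i, j] for (i, j) in cluster]
    return MUIdentification(
        mu_id=fp.mu_id,
        matched=True,
        cluster=cluster,
        correlation_map=cmap,
        displacement_map=dmap,
        us_centroid_mm=centroid,
        profile_mean=mean,
        profile_sd=sd,
        profile_lags_s=lags,
        mean_cluster_cc=float(np.mean(cc_vals)),
    )
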