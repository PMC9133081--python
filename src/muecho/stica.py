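"""Sliding-ROI singular value decomposition + spatio-temporal ICA.

The conditioned tissue-velocity movie is analysed in overlapping regions of
interest (ROIs) of 12 x 12 mm (38 px) slid in 1.6 mm (5 px) steps, which
tiles a 128 px axis with exactly 19 positions.  Each ROI movie (pixels x
time) is reduced with a truncated SVD (50 components) and the retained
subspace is rotated with a spatio-temporal ICA: a single orthogonal rotation
of the whitened temporal principal components whose contrast mixes temporal
and spatial non-Gaussianity with weight ``alpha`` (``alpha = 1`` reduces to
plain temporal FastICA; the default 0.5 weighs both equally, Stone-style).
Temporal components are zero-mean, unit-variance and mutually uncorrelated;
each is paired with the spatial image that reconstructs the ROI movie.
Component signs are arbitrary at this stage and resolved downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from sklearn.utils.extmath import randomized_svd

from ._seeds import child_seed
from .tvs_sim import TissueVelocitySequence

__all__ = [
    "ROIGrid",
    "ROIDecomposition",
    "DecompositionSet",
    "build_roi_grid",
    "decompose_roi",
    "decompose_all",
    "save_decompositions",
    "load_decompositions",
]

ROI_PX = 38
STEP_PX = 5
N_COMPONENTS = 50

#: Relative singular-value floor below which components are treated as null.
#: Directions this far below the leading one (1e-6 in variance) are numerical
#: noise; whitening would amplify them into unstable ICA directions.
SV_RTOL = 1e-3


@dataclass(frozen=True)
class ROIGrid:
    """Origins (top-left corners) of the sliding ROIs over the image."""

    roi_px: int
    step_px: int
    row_origins: tuple[int, ...]
    col_origins: tuple[int, ...]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (len(self.row_origins), len(self.col_origins))

    @property
    def origins(self) -> list[tuple[int, int]]:
        return [(r, c) for r in self.row_origins for c in self.col_origins]

    def origin(self, i: int, j: int) -> tuple[int, int]:
        return (self.row_origins[i], self.col_origins[j])


def _axis_origins(size: int, roi: int, step: int) -> tuple[int, ...]:
    if size < roi:
        raise ValueError(f"image axis ({size} px) smaller than one ROI ({roi} px)")
    last = size - roi
    origins = list(range(0, last + 1, step))
    if origins[-1] != last:  # clamp a final ROI to the image edge
        origins.append(last)
    return tuple(origins)


def build_roi_grid(
    image_shape: tuple[int, int], roi_px: int = ROI_PX, step_px: int = STEP_PX
) -> ROIGrid:
    """ROI origins for an image; 128 px / 38 px ROI / 5 px step gives 19 x 19."""
    rows, cols = image_shape
    return ROIGrid(
        roi_px=roi_px,
        step_px=step_px,
        row_origins=_axis_origins(rows, roi_px, step_px),
        col_origins=_axis_origins(cols, roi_px, step_px),
    )


@dataclass
class ROIDecomposition:
    """Paired spatial/temporal components of one ROI.

    ``spatial`` is (k, roi, roi), ``temporal`` is (k, T) with zero-mean,
    unit-variance rows; ``spatial[i]``'s outer product with ``temporal[i]``
    sums over i to the (centred) ROI movie.
    """

    roi_index: tuple[int, int]
    origin: tuple[int, int]
    spatial: np.ndarray
    temporal: np.ndarray
    singular_values: np.ndarray
    converged: bool = True
    degenerate: bool = False

    @property
    def n_components(self) -> int:
        return int(self.temporal.shape[0])


def _stica_rotation(
    z_temporal: np.ndarray,
    z_spatial: np.ndarray,
    alpha: float,
    seed: int,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> tuple[np.ndarray, bool]:
    """Orthogonal un-mixing rotation maximizing a tanh negentropy contrast.

    ``z_temporal`` (k x T) and ``z_spatial`` (k x P) are the whitened temporal
    and spatial bases of the retained subspace; the contrast gradient is the
    ``alpha``-weighted sum of the FastICA updates computed on each.  Symmetric
    decorrelation keeps the rotation orthonormal at every step.
    """
    k = z_temporal.shape[0]
    if k == 1:
        return np.ones((1, 1)), True

    def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
        s, u = np.linalg.eigh(w @ w.T)
        return (u / np.sqrt(np.maximum(s, 1e-12))) @ u.T @ w

    rng = np.random.default_rng(seed)
    w = _sym_decorrelate(rng.standard_normal((k, k)))

    def _update(w: np.ndarray, z: np.ndarray) -> np.ndarray:
        y = np.tanh(w @ z)
        return (y @ z.T) / z.shape[1] - np.mean(1.0 - y**2, axis=1)[:, None] * w

    for _ in range(max_iter):
        w_new = np.zeros_like(w)
        if alpha > 0:
            w_new += alpha * _update(w, z_temporal)
        if alpha < 1:
            w_new += (1.0 - alpha) * _update(w, z_spatial)
        w_new = _sym_decorrelate(w_new)
        lim = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", w_new, w)) - 1.0)))
        w = w_new
        if lim < tol:
            return w, True
    return w, False


def decompose_roi(
    tvs: TissueVelocitySequence,
    roi_index: tuple[int, int],
    grid: ROIGrid,
    n_components: int = N_COMPONENTS,
    seed: int = 0,
    alpha: float = 0.5,
    ica_tol: float = 1e-4,
    ica_max_iter: int = 200,
) -> ROIDecomposition:
    """Truncated SVD + stICA of one ROI movie.

    Rank-deficient ROIs return fewer than ``n_components`` components; an
    all-zero ROI is flagged ``degenerate`` with zero components.
    """
    i, j = roi_index
    r0, c0 = grid.origin(i, j)
    p = grid.roi_px
    patch = tvs.frames[:, r0 : r0 + p, c0 : c0 + p]
    T = patch.shape[0]
    if T <= n_components:
        raise ValueError("sequence shorter than the requested number of components")
    x = patch.reshape(T, p * p).T.astype(np.float32)  # pixels x time
    x = x - x.mean(axis=1, keepdims=True)
    scale = float(np.abs(x).max()) if x.size else 0.0
    if scale == 0.0 or not np.isfinite(scale):
        return ROIDecomposition(
            roi_index=roi_index,
            origin=(r0, c0),
            spatial=np.zeros((0, p, p), dtype=np.float32),
            temporal=np.zeros((0, T), dtype=np.float32),
            singular_values=np.zeros(0),
            degenerate=True,
        )
    k_req = min(n_components, p * p, T - 1)
    u, s, vt = randomized_svd(
        x, n_components=k_req, n_oversamples=10, n_iter=2, random_state=child_seed(seed, i, j, 0)
    )
    keep = s > SV_RTOL * s[0]
    u, s, vt = u[:, keep], s[keep], vt[keep]
    k = s.size
    z_t = np.sqrt(T) * vt  # whitened temporal PCs (unit variance rows)
    z_s = np.sqrt(p * p) * u.T  # orthonormal spatial basis, unit second moment
    w, converged = _stica_rotation(
        z_t, z_s, alpha=alpha, seed=child_seed(seed, i, j, 1), tol=ica_tol, max_iter=ica_max_iter
    )
    temporal = (w @ z_t).astype(np.float32)
    spatial_flat = ((u * (s / np.sqrt(T))) @ w.T).T  # k x pixels
    spatial = spatial_flat.reshape(k, p, p).astype(np.float32)
    return ROIDecomposition(
        roi_index=roi_index,
        origin=(r0, c0),
        spatial=spatial,
        temporal=temporal,
        singular_values=s,
        converged=converged,
    )


@dataclass
class DecompositionSet:
    """All ROI decompositions of one contraction, indexed by grid position."""

    grid: ROIGrid
    fps: float
    mm_per_px: float
    items: dict[tuple[int, int], ROIDecomposition]

    @property
    def n_frames(self) -> int:
        for d in self.items.values():
            if d.n_components:
                return int(d.temporal.shape[1])
        return 0

    def __getitem__(self, idx: tuple[int, int]) -> ROIDecomposition:
        return self.items[idx]

    def stacked_temporal(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenate temporal components over ROIs.

        Returns ``(components, owners)`` where ``components`` is (n_total, T)
        and ``owners`` is an (n_total, 3) int array of (i, j, component index).
        """
        comps, owners = [], []
        for (i, j), d in sorted(self.items.items()):
            for c in range(d.n_components):
                comps.append(d.temporal[c])
                owners.append((i, j, c))
        if not comps:
            return np.zeros((0, self.n_frames), np.float32), np.zeros((0, 3), int)
        return np.asarray(comps, dtype=np.float32), np.asarray(owners, dtype=int)


def decompose_all(
    tvs: TissueVelocitySequence,
    grid: ROIGrid | None = None,
    n_components: int = N_COMPONENTS,
    seed: int = 0,
    alpha: float = 0.5,
    ica_tol: float = 1e-4,
    ica_max_iter: int = 200,
    progress: bool = False,
) -> DecompositionSet:
    """Decompose every ROI of the grid (cacheable with :func:`save_decompositions`)."""
    if grid is None:
        grid = build_roi_grid(tvs.frames.shape[1:])
    items: dict[tuple[int, int], ROIDecomposition] = {}
    n_rows, n_cols = grid.grid_shape
    for i in range(n_rows):
        for j in range(n_cols):
            items[(i, j)] = decompose_roi(
                tvs,
                (i, j),
                grid,
                n_components=n_components,
                seed=seed,
                alpha=alpha,
                ica_tol=ica_tol,
                ica_max_iter=ica_max_iter,
            )
        if progress:
            print(f"  decomposed ROI row {i + 1}/{n_rows}", flush=True)
    return DecompositionSet(grid=grid, fps=tvs.fps, mm_per_px=tvs.mm_per_px, items=items)


def save_decompositions(path: str | Path, dset: DecompositionSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fps"] = dset.fps
        f.attrs["mm_per_px"] = dset.mm_per_px
        f.attrs["roi_px"] = dset.grid.roi_px
        f.attrs["step_px"] = dset.grid.step_px
        f.attrs["row_origins"] = list(dset.grid.row_origins)
        f.attrs["col_origins"] = list(dset.grid.col_origins)
        for (i, j), d in dset.items.items():
            g = f.create_group(f"roi/{i}_{j}")
            g.create_dataset("spatial", data=d.spatial)
            g.create_dataset("temporal", data=d.temporal)
            g.create_dataset("singvals", data=d.singular_values)
            g.attrs["origin"] = list(d.origin)
            g.attrs["converged"] = d.converged
            g.attrs["degenerate"] = d.degenerate


def load_decompositions(path: str | Path) -> DecompositionSet:
    with h5py.File(path, "r") as f:
        grid = ROIGrid(
            roi_px=int(f.attrs["roi_px"]),
            step_px=int(f.attrs["step_px"]),
            row_origins=tuple(int(v) for v in f.attrs["row_origins"]),
            col_origins=tuple(int(v) for v in f.attrs["col_origins"]),
        )
        items = {}
        for key, g in f["roi"].items():
            i, j = (int(v) for v in key.split("_"))
            items[(i, j)] = ROIDecomposition(
                roi_index=(i, j),
                origin=tuple(int(v) for v in g.attrs["origin"]),
                spatial=g["spatial"][...],
                temporal=g["temporal"][...],
                singular_values=g["singvals"][...],
                converged=bool(g.attrs["converged"]),
                degenerate=bool(g.attrs["degenerate"]),
            )
        return DecompositionSet(
            grid=grid, fps=float(f.attrs["fps"]), mm_per_px=float(f.attrs["mm_per_px"]), items=items
        )
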