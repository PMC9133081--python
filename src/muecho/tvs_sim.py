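"""Forward simulation of interferential tissue-velocity image sequences.

Each motor-unit discharge produces a stereotyped axial tissue-velocity twitch:
a 50 ms positive (contraction) half-sine lobe followed by a 100 ms negative
(relaxation) half-sine lobe at half the peak amplitude, so that the velocity
integrates to zero and the tissue returns to rest.  The twitch amplitude
scales quadratically with territory area, and velocity is transmitted
passively outside the territory with an exponential decay in distance
(unit gain inside the disc; ~37% of the centre velocity at twice the
territory radius).  The interferential sequence is the linear superposition
of every active unit's space-time response driven by its spike train.

Frames are axial velocity (positive = toward the probe, i.e. superficial) on
the imaging grid, by default 128 x 128 px over 40 x 40 mm at 1024 fps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .population import FiringPattern, MotorUnit, MuscleGeometry

__all__ = [
    "TwitchVelocityProfile",
    "TissueVelocitySequence",
    "make_twitch_profile",
    "spatial_decay_factor",
    "mu_velocity_field",
    "simulate_tvs",
    "save_tvs",
    "load_tvs",
]

#: Largest simulated territory area (mm**2); normalizes the quadratic gain law.
AREA_MAX_MM2 = 44.0

#: Peak axial velocity (mm/s) of the largest unit at its territory centre.
PEAK_VELOCITY_MM_S = 5.0

CONTRACTION_MS = 50.0
RELAXATION_MS = 100.0


@dataclass(frozen=True)
class TwitchVelocityProfile:
    """Normalized per-discharge velocity profile (peak of the positive lobe = 1)."""

    samples: np.ndarray
    fps: float

    @property
    def n_pos_samples(self) -> int:
        """Samples spanning the positive lobe (zero endpoints included)."""
        return int(round(CONTRACTION_MS / 1000.0 * self.fps))

    @property
    def t_contraction_ms(self) -> float:
        return 1000.0 * (self.n_pos_samples - 1) / self.fps

    @property
    def t_relaxation_ms(self) -> float:
        return 2.0 * self.t_contraction_ms

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fps


@dataclass
class TissueVelocitySequence:
    """Axial-velocity movie: ``frames`` is (time, rows, cols) in mm/s."""

    frames: np.ndarray
    fps: float
    mm_per_px: float
    t0: float = 0.0
    flagged: np.ndarray | None = None  # optional per-pixel aliasing/clip mask

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.frames.shape)  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def make_twitch_profile(fps: float) -> TwitchVelocityProfile:
    """Build the per-discharge twitch velocity profile at frame rate ``fps``.

    The positive lobe spans ``round(0.05 * fps)`` samples (51 at 1024 fps,
    zero endpoints included); the negative lobe has twice as many intervals at
    half amplitude, so the continuous-time waveform integrates exactly to zero.
    """
    if fps < 200:
        raise ValueError("fps must be >= 200 to resolve the 50 ms contraction lobe")
    m = int(round(CONTRACTION_MS / 1000.0 * fps)) - 1  # intervals in the + lobe
    pos = np.sin(np.pi * np.arange(m + 1) / m)
    n_neg = 2 * m
    neg = -0.5 * np.sin(np.pi * np.arange(1, n_neg + 1) / n_neg)
    samples = np.concatenate([pos, neg])
    samples /= samples.max()  # exact peak 1 also when n_pos is odd
    return TwitchVelocityProfile(samples=samples, fps=float(fps))


def spatial_decay_factor(
    distance_mm: float | np.ndarray, radius_mm: float
) -> float | np.ndarray:
    """Passive-transmission gain vs distance from the territory centre.

    Unit gain inside the territory; exponential decay with space constant equal
    to the radius outside, so the gain at twice the radius is ``exp(-1)`` (~37%
    of the centre value).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    d = np.asarray(distance_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.where(d <= radius_mm, 1.0, np.exp(-(d - radius_mm) / radius_mm))
    return float(out) if np.isscalar(distance_mm) else out


def mu_velocity_field(
    mu: MotorUnit, geometry: MuscleGeometry
) -> tuple[np.ndarray, float]:
    """Spatial gain map (rows x cols) and scalar amplitude gain of one MU.

    The per-pixel gain is ``(area / area_max)**2`` (quadratic area scaling)
    times the exponential passive-transmission decay from the territory
    centre; the unit's space-time response is the outer product of this map
    with the twitch profile.
    """
    rows, cols = geometry.image_px
    fov_d, fov_x = geometry.field_of_view_mm
    x_mu, d_mu = mu.center_mm
    if not (0 <= x_mu <= fov_x and 0 <= d_mu <= fov_d):
        raise ValueError("motor unit lies outside the field of view")
    mmpx = geometry.mm_per_px
    depth = (np.arange(rows) + 0.5) * mmpx
    x = (np.arange(cols) + 0.5) * mmpx
    dist = np.hypot(depth[:, None] - d_mu, x[None, :] - x_mu)
    amp_gain = (mu.area_mm2 / AREA_MAX_MM2) ** 2
    return amp_gain * spatial_decay_factor(dist, mu.radius_mm), amp_gain


def _spike_indicator(fp: FiringPattern, fps: float, n_frames: int) -> np.ndarray:
    t = fp.spike_times_s
    if t.size and (t.min() < 0 or t.max() * fps >= n_frames):
        raise ValueError(f"MU {fp.mu_id}: spike times outside the simulated duration")
    idx = np.minimum(np.round(t * fps).astype(int), n_frames - 1)
    s = np.zeros(n_frames, dtype=np.float32)
    np.add.at(s, idx, 1.0)
    return s


def simulate_tvs(
    population_active: Sequence[MotorUnit],
    firings: Sequence[FiringPattern],
    geometry: MuscleGeometry,
    twitch: TwitchVelocityProfile,
    duration_s: float,
    peak_velocity_mm_s: float = PEAK_VELOCITY_MM_S,
) -> TissueVelocitySequence:
    """Superpose every active MU's twitch response into one velocity movie.

    ``firings`` must carry exactly the ids of ``population_active``.  Each
    unit's frame-rate spike indicator is convolved with the twitch and
    multiplied by its spatial gain map; units sum linearly.
    """
    fps = twitch.fps
    n_frames = int(round(duration_s * fps))
    rows, cols = geometry.image_px
    ids_pop = {mu.id for mu in population_active}
    ids_fir = {fp.mu_id for fp in firings}
    if ids_pop != ids_fir:
        raise ValueError("mismatched MU ids between population and firing patterns")
    frames = np.zeros((n_frames, rows, cols), dtype=np.float32)
    if not population_active:
        return TissueVelocitySequence(frames=frames, fps=fps, mm_per_px=geometry.mm_per_px)
    by_id = {fp.mu_id: fp for fp in firings}
    gains = np.empty((len(population_active), rows * cols), dtype=np.float32)
    drives = np.empty((n_frames, len(population_active)), dtype=np.float32)
    w = twitch.samples.astype(np.float32)
    for k, mu in enumerate(population_active):
        gmap, _ = mu_velocity_field(mu, geometry)
        gains[k] = gmap.ravel()
        s = _spike_indicator(by_id[mu.id], fps, n_frames)
        drives[:, k] = np.convolve(s, w)[:n_frames]
    frames = (drives @ gains).reshape(n_frames, rows, cols)
    frames *= np.float32(peak_velocity_mm_s)
    return TissueVelocitySequence(frames=frames, fps=fps, mm_per_px=geometry.mm_per_px)


def save_tvs(
    path: str | Path,
    tvs: TissueVelocitySequence,
    population_path: str | None = None,
    firings_path: str | None = None,
) -> None:
    """Write a velocity movie to HDF5 (dataset ``velocity`` + metadata attrs)."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("velocity", data=tvs.frames.astype(np.float32))
        d.attrs["fps"] = tvs.fps
        d.attrs["mm_per_px"] = tvs.mm_per_px
        d.attrs["t0"] = tvs.t0
        if population_path:
            d.attrs["population_path"] = population_path
        if firings_path:
            d.attrs["firings_path"] = firings_path


def load_tvs(path: str | Path) -> TissueVelocitySequence:
    with h5py.File(path, "r") as f:
        d = f["velocity"]
        return TissueVelocitySequence(
            frames=d[...],
            fps=float(d.attrs["fps"]),
            mm_per_px=float(d.attrs["mm_per_px"]),
            t0=float(d.attrs.get("t0", 0.0)),
        )
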