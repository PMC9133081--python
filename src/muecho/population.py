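"""Simulated motor-unit populations, recruitment and firing patterns.

The simulated muscle is an elliptical cross-section (598 mm**2, biceps
brachii-like) lying under a 1 mm skin and 2.5 mm subcutaneous layer, imaged
over a 40 x 40 mm field of view on a 128 x 128 pixel grid.  Motor-unit (MU)
territories are circular discs placed uniformly at random inside the ellipse
(whole disc inside the muscle).  Territory areas follow a truncated
exponential over 5-44 mm**2, so small units are far more numerous than large
ones, mirroring the classical skewed MU size distribution.  Recruitment is
size-ordered: a contraction level activates the ``n`` smallest units, which
makes lower-level active sets nested inside higher-level ones.

Firing statistics: mean discharge rate is assigned linearly with recruitment
rank from 15 pps (first recruited) down to 8 pps (last recruited); inter-spike
intervals are Gaussian with a 15% coefficient of variation, truncated at half
the mean interval.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seeds import rng_from

__all__ = [
    "MuscleGeometry",
    "MotorUnit",
    "FiringPattern",
    "ContractionPlan",
    "CONTRACTION_LEVELS",
    "generate_population",
    "recruit",
    "generate_firing_pattern",
    "generate_firing_patterns",
    "validate_firing_pattern",
    "save_population_csv",
    "load_population_csv",
    "save_firings_json",
    "load_firings_json",
    "firings_to_long_csv",
]

#: Area bounds of simulated MU territories (mm**2).
AREA_RANGE_MM2 = (5.0, 44.0)

#: Fibre count bounds per MU and the nominal fibre density (fibres / mm**2).
FIBER_RANGE = (150, 1500)
FIBER_DENSITY_PER_MM2 = 135.0

#: Discharge-rate bounds (pulses per second) across the recruitment order.
RATE_RANGE_PPS = (8.0, 15.0)

#: Coefficient of variation of the inter-spike interval.
ISI_COV = 0.15


@dataclass(frozen=True)
class MuscleGeometry:
    """Imaging geometry and elliptical muscle cross-section.

    Coordinates are in millimetres in the ultrasound image frame:
    ``x`` runs medio-lateral across the image columns, ``depth`` runs from the
    skin surface (row 0) downward.
    """

    field_of_view_mm: tuple[float, float] = (40.0, 40.0)  # (depth, width)
    image_px: tuple[int, int] = (128, 128)  # (rows, cols)
    skin_thickness_mm: float = 1.0
    subcutaneous_thickness_mm: float = 2.5
    muscle_csa_mm2: float = 598.0
    semi_axis_x_mm: float = 18.0

    @property
    def mm_per_px(self) -> float:
        return self.field_of_view_mm[1] / self.image_px[1]

    @property
    def semi_axis_depth_mm(self) -> float:
        """Depth semi-axis derived so the ellipse area equals the muscle CSA."""
        return self.muscle_csa_mm2 / (math.pi * self.semi_axis_x_mm)

    @property
    def muscle_top_mm(self) -> float:
        return self.skin_thickness_mm + self.subcutaneous_thickness_mm

    @property
    def ellipse_center_mm(self) -> tuple[float, float]:
        """(x, depth) of the ellipse centre."""
        return (self.field_of_view_mm[1] / 2.0, self.muscle_top_mm + self.semi_axis_depth_mm)

    def validate(self) -> None:
        a, b = self.semi_axis_x_mm, self.semi_axis_depth_mm
        cx, cd = self.ellipse_center_mm
        if a <= 0 or b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if cx - a < 0 or cx + a > self.field_of_view_mm[1]:
            raise ValueError("muscle ellipse exceeds the field of view laterally")
        if cd + b > self.field_of_view_mm[0]:
            raise ValueError("muscle ellipse exceeds the field of view in depth")
        if abs(math.pi * a * b - self.muscle_csa_mm2) > 0.01 * self.muscle_csa_mm2:
            raise ValueError("ellipse area inconsistent with muscle CSA")

    def contains_disc(self, x_mm: float, depth_mm: float, radius_mm: float) -> bool:
        """True if the disc lies entirely inside the muscle ellipse.

        Uses the conservative shrunken-ellipse criterion (semi-axes reduced by
        the disc radius), exact here because territory radii are well below the
        minimal radius of curvature of the boundary.
        """
        a = self.semi_axis_x_mm - radius_mm
        b = self.semi_axis_depth_mm - radius_mm
        if a <= 0 or b <= 0:
            return False
        cx, cd = self.ellipse_center_mm
        return ((x_mm - cx) / a) ** 2 + ((depth_mm - cd) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class MotorUnit:
    """A single motor unit: circular territory plus firing-rate assignment."""

    id: int
    center_mm: tuple[float, float]  # (x medio-lateral, depth)
    radius_mm: float
    n_fibers: int
    mean_rate_pps: float

    @property
    def area_mm2(self) -> float:
        return math.pi * self.radius_mm**2


@dataclass(frozen=True)
class FiringPattern:
    """Ordered spike times of one motor unit."""

    mu_id: int
    spike_times_s: np.ndarray
    mean_rate_pps: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_times_s", np.asarray(self.spike_times_s, dtype=float))

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def isi_cov(self) -> float:
        """Sample coefficient of variation of the inter-spike intervals."""
        isi = np.diff(self.spike_times_s)
        if isi.size < 2:
            return float("nan")
        return float(np.std(isi, ddof=1) / np.mean(isi))


@dataclass(frozen=True)
class ContractionPlan:
    level_id: int
    n_active_mus: int
    pct_mvc: float
    duration_s: float = 10.0


#: The five simulated contraction levels: (active MU count, %MVC).
CONTRACTION_LEVELS: tuple[ContractionPlan, ...] = tuple(
    ContractionPlan(level_id=i + 1, n_active_mus=n, pct_mvc=p)
    for i, (n, p) in enumerate([(32, 3), (50, 5), (74, 7), (106, 10), (138, 20)])
)


def _sample_area_mm2(rng: np.random.Generator, scale_mm2: float = 10.0) -> float:
    """Truncated-exponential territory area on [5, 44] mm**2 (many small, few large)."""
    lo, hi = AREA_RANGE_MM2
    u = rng.random()
    return lo - scale_mm2 * math.log1p(-u * (1.0 - math.exp(-(hi - lo) / scale_mm2)))


def generate_population(
    geometry: MuscleGeometry,
    n_mus: int = 200,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[MotorUnit]:
    """Generate ``n_mus`` motor units with territories inside the muscle ellipse.

    Centres are uniform over the ellipse; candidate placements whose disc would
    cross the muscle boundary are rejected and redrawn.  Overlap between
    territories is allowed.  Mean discharge rates are assigned by area rank
    (smallest unit: 15 pps, largest: 8 pps, linear in rank), anticipating
    size-ordered recruitment.

    Raises
    ------
    ValueError
        If ``n_mus < 1``, the geometry is invalid, or a territory cannot be
        placed within ``max_attempts`` rejection-sampling attempts.
    """
    if n_mus < 1:
        raise ValueError("n_mus must be >= 1")
    geometry.validate()
    rng = rng_from(seed)
    a, b = geometry.semi_axis_x_mm, geometry.semi_axis_depth_mm
    cx, cd = geometry.ellipse_center_mm

    units: list[tuple[float, float, float]] = []  # (x, depth, radius)
    for _ in range(n_mus):
        area = _sample_area_mm2(rng)
        radius = math.sqrt(area / math.pi)
        for attempt in range(max_attempts):
            # uniform point in the ellipse via uniform disc scaling
            r = math.sqrt(rng.random())
            th = rng.uniform(0.0, 2.0 * math.pi)
            x = cx + a * r * math.cos(th)
            d = cd + b * r * math.sin(th)
            if geometry.contains_disc(x, d, radius):
                units.append((x, d, radius))
                break
        else:
            raise ValueError(
                f"could not place a territory of radius {radius:.2f} mm inside the "
                f"muscle ellipse after {max_attempts} attempts"
            )

    # rate by area rank: smallest area -> 15 pps, largest -> 8 pps
    order = np.argsort([math.pi * u[2] ** 2 for u in units], kind="stable")
    rank_of = np.empty(n_mus, dtype=int)
    rank_of[order] = np.arange(n_mus)
    hi, lo = RATE_RANGE_PPS[1], RATE_RANGE_PPS[0]
    out = []
    for i, (x, d, radius) in enumerate(units):
        area = math.pi * radius**2
        n_fib = int(np.clip(round(area * FIBER_DENSITY_PER_MM2), *FIBER_RANGE))
        rate = hi if n_mus == 1 else hi - (hi - lo) * rank_of[i] / (n_mus - 1)
        out.append(
            MotorUnit(
                id=i, center_mm=(x, d), radius_mm=radius, n_fibers=n_fib, mean_rate_pps=float(rate)
            )
        )
    return out


def recruit(population: Sequence[MotorUnit], plan: ContractionPlan) -> list[MotorUnit]:
    """Size-ordered recruitment: the ``plan.n_active_mus`` smallest-area units.

    Because selection is a prefix of the fixed area ordering, the active set of
    a lower contraction level is a subset of every higher level's.
    """
    if plan.n_active_mus > len(population):
        raise ValueError(
            f"plan requires {plan.n_active_mus} active MUs but population has {len(population)}"
        )
    ordered = sorted(population, key=lambda mu: (mu.area_mm2, mu.id))
    return ordered[: plan.n_active_mus]


def generate_firing_pattern(mu: MotorUnit, duration_s: float, seed: int = 0) -> FiringPattern:
    """Draw a spike train for one MU over ``[0, duration_s)``.

    ISIs are Gaussian with mean ``1/rate`` and SD ``0.15/rate`` (15% CoV),
    truncated below at half the mean interval; the first spike is placed at a
    uniform phase within one mean interval.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    rng = rng_from(seed, mu.id)
    mean_isi = 1.0 / mu.mean_rate_pps
    sd = ISI_COV * mean_isi
    t = rng.uniform(0.0, mean_isi)
    spikes = []
    while t < duration_s:
        spikes.append(t)
        isi = rng.normal(mean_isi, sd)
        while isi < 0.5 * mean_isi:
            isi = rng.normal(mean_isi, sd)
        t += isi
    return FiringPattern(mu_id=mu.id, spike_times_s=np.array(spikes), mean_rate_pps=mu.mean_rate_pps)


def generate_firing_patterns(
    active: Sequence[MotorUnit], duration_s: float, seed: int = 0
) -> list[FiringPattern]:
    """Independent firing patterns for a recruited set of MUs."""
    return [generate_firing_pattern(mu, duration_s, seed=seed) for mu in active]


def validate_firing_pattern(
    fp: FiringPattern,
    window_s: tuple[float, float],
    min_spikes: int = 20,
    max_isi_cov_pct: float = 30.0,
) -> tuple[bool, str]:
    """Accept/reject a firing pattern for analysis within a time window.

    Rejection mirrors standard decomposition quality control: fewer than 20
    firings in the window, or an ISI coefficient of variation above 30%.
    Returns ``(accepted, reason)`` with ``reason == "ok"`` on acceptance.
    """
    w0, w1 = window_s
    if not w1 > w0:
        raise ValueError("empty validation window")
    t = fp.spike_times_s
    in_win = t[(t >= w0) & (t < w1)]
    if in_win.size < min_spikes:
        return False, "too few firings"
    isi = np.diff(in_win)
    cov_pct = 100.0 * np.std(isi, ddof=1) / np.mean(isi)
    if cov_pct > max_isi_cov_pct:
        return False, "irregular"
    return True, "ok"


# ---------------------------------------------------------------------------
# file interfaces


def save_population_csv(path: str | Path, population: Iterable[MotorUnit]) -> None:
    rows = [
        {
            "mu_id": mu.id,
            "x_mm": mu.center_mm[0],
            "depth_mm": mu.center_mm[1],
            "radius_mm": mu.radius_mm,
            "area_mm2": mu.area_mm2,
            "n_fibers": mu.n_fibers,
            "mean_rate_pps": mu.mean_rate_pps,
        }
        for mu in population
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_population_csv(path: str | Path) -> list[MotorUnit]:
    df = pd.read_csv(path)
    return [
        MotorUnit(
            id=int(r.mu_id),
            center_mm=(float(r.x_mm), float(r.depth_mm)),
            radius_mm=float(r.radius_mm),
            n_fibers=int(r.n_fibers),
            mean_rate_pps=float(r.mean_rate_pps),
        )
        for r in df.itertuples()
    ]


def save_firings_json(path: str | Path, firings: Iterable[FiringPattern]) -> None:
    payload = {str(fp.mu_id): fp.spike_times_s.tolist() for fp in firings}
    Path(path).write_text(json.dumps(payload))


def load_firings_json(path: str | Path, rates: dict[int, float] | None = None) -> list[FiringPattern]:
    payload = json.loads(Path(path).read_text())
    out = []
    for k, times in payload.items():
        times = np.asarray(times, dtype=float)
        rate = (rates or {}).get(int(k))
        if rate is None:
            span = times[-1] - times[0] if times.size > 1 else 1.0
            rate = (times.size - 1) / span if span > 0 else float("nan")
        out.append(FiringPattern(mu_id=int(k), spike_times_s=times, mean_rate_pps=float(rate)))
    return sorted(out, key=lambda fp: fp.mu_id)


def firings_to_long_csv(path: str | Path, firings: Iterable[FiringPattern]) -> None:
    """Long-format alternative: one (mu_id, spike_time_s) row per firing."""
    rows = [
        {"mu_id": fp.mu_id, "spike_time_s": t} for fp in firings for t in fp.spike_times_s
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
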