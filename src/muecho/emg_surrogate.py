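"""Surrogate MUAP amplitude distributions over an 8 x 8 electrode grid.

Downstream analysis consumes only the centroid of each motor unit's action
potential amplitude distribution across the grid.  Instead of a full
anisotropic volume-conductor simulation, the surface amplitude at each
electrode is modelled as an exponential decay of the unit's fibre count with
the 3-D electrode-to-territory-centre distance.  This preserves the property
the analysis relies on: deeper units produce flatter (more diffuse) surface
distributions, superficial units sharply peaked ones, and the medio-lateral
centroid tracks the territory's medio-lateral position.

Grid convention: 8 rows x 8 columns at 10 mm inter-electrode distance, the
columns running along the fibres (out of the imaging plane) and the rows
spanning the medio-lateral direction; the ultrasound plane passes midway
between rows 4 and 5, and the grid is centred on the image's medio-lateral
axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .population import MotorUnit

__all__ = [
    "ElectrodeGrid",
    "MUAPAmplitudeDistribution",
    "surrogate_amplitudes",
    "amplitude_centroid",
    "save_amplitudes_csv",
]

#: Transverse-decay space constant of the surrogate amplitude model (mm).
LAMBDA_T_MM = 8.0


@dataclass(frozen=True)
class ElectrodeGrid:
    n_rows: int = 8
    n_cols: int = 8
    ied_mm: float = 10.0
    center_x_mm: float = 20.0  # aligned with the image medio-lateral centre

    def positions_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) of every electrode on the skin plane.

        ``x`` is medio-lateral (shared with the image frame), ``y`` runs along
        the fibres with 0 at the ultrasound plane (between rows 4 and 5).
        Returned arrays are flattened row-major, length ``n_rows * n_cols``.
        """
        x_line = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.ied_mm + self.center_x_mm
        y_line = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.ied_mm
        y, x = np.meshgrid(y_line, x_line, indexing="ij")
        return x.ravel(), y.ravel()


@dataclass(frozen=True)
class MUAPAmplitudeDistribution:
    mu_id: int
    amplitudes: np.ndarray  # (n_rows * n_cols,), arbitrary units, >= 0
    grid: ElectrodeGrid

    @property
    def emg_centroid_mm(self) -> tuple[float, float]:
        return amplitude_centroid(self)


def surrogate_amplitudes(
    mu: MotorUnit, grid: ElectrodeGrid | None = None, lambda_t_mm: float = LAMBDA_T_MM
) -> MUAPAmplitudeDistribution:
    """Amplitude at each electrode: ``n_fibers * exp(-d / lambda_t)``.

    ``d`` is the 3-D distance from the electrode (on the skin plane) to the
    territory centre; the unit's depth coordinate already includes the skin
    and subcutaneous layers, so no extra offset is applied.
    """
    grid = grid or ElectrodeGrid()
    ex, ey = grid.positions_mm()
    x_mu, depth_mu = mu.center_mm
    d = np.sqrt((ex - x_mu) ** 2 + ey**2 + depth_mu**2)
    amps = mu.n_fibers * np.exp(-d / lambda_t_mm)
    return MUAPAmplitudeDistribution(mu_id=mu.id, amplitudes=amps, grid=grid)


def amplitude_centroid(dist: MUAPAmplitudeDistribution) -> tuple[float, float]:
    """Amplitude-weighted mean electrode position, (x mm, y mm)."""
    total = dist.amplitudes.sum()
    if total <= 0:
        raise ValueError("all-zero amplitude distribution")
    ex, ey = dist.grid.positions_mm()
    return (
        float((dist.amplitudes * ex).sum() / total),
        float((dist.amplitudes * ey).sum() / total),
    )


def save_amplitudes_csv(path: str | Path, dists: Iterable[MUAPAmplitudeDistribution]) -> None:
    rows = []
    for d in dists:
        cx, cy = d.emg_centroid_mm
        row = {"mu_id": d.mu_id}
        row.update({f"amp_{k:02d}": a for k, a in enumerate(d.amplitudes)})
        row.update({"centroid_x_mm": cx, "centroid_y_mm": cy})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
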