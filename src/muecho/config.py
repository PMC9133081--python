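"""TOML study configuration.

A config file can override any of the study defaults; all keys are optional.

```toml
[geometry]
muscle_csa_mm2 = 598.0
semi_axis_x_mm = 18.0
skin_thickness_mm = 1.0
subcutaneous_thickness_mm = 2.5

[study]
n_mus = 200
duration_s = 10.0
fps = 1024.0
n_components = 50
ica_alpha = 0.5
cc_threshold = 0.5
max_lag_ms = 20.0
lambda_t_mm = 8.0
seed = 0

[[levels]]          # optional; defaults to the five standard levels
level_id = 1
n_active_mus = 32
pct_mvc = 3.0
```
"""

from __future__ import annotations

import tomllib
from dataclasses import fields, replace
from pathlib import Path

from .pipeline import StudyConfig
from .population import ContractionPlan, MuscleGeometry

__all__ = ["load_config"]


def load_config(path: str | Path) -> tuple[StudyConfig, int]:
    """Read a TOML file into a :class:`StudyConfig`; returns (config, seed)."""
    data = tomllib.loads(Path(path).read_text())
    geo_kwargs = data.get("geometry", {})
    allowed = {f.name for f in fields(MuscleGeometry)}
    bad = set(geo_kwargs) - allowed
    if bad:
        raise ValueError(f"unknown geometry keys: {sorted(bad)}")
    geometry = MuscleGeometry(**geo_kwargs)
    geometry.validate()

    study = dict(data.get("study", {}))
    seed = int(study.pop("seed", 0))
    cfg = StudyConfig(geometry=geometry)
    allowed = {f.name for f in fields(StudyConfig)}
    bad = set(study) - allowed
    if bad:
        raise ValueError(f"unknown study keys: {sorted(bad)}")
    cfg = replace(cfg, **study)

    if "levels" in data:
        plans = tuple(
            ContractionPlan(
                level_id=int(lv["level_id"]),
                n_active_mus=int(lv["n_active_mus"]),
                pct_mvc=float(lv["pct_mvc"]),
                duration_s=float(lv.get("duration_s", cfg.duration_s)),
            )
            for lv in data["levels"]
        )
        cfg = replace(cfg, levels=plans)
    return cfg, seed
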