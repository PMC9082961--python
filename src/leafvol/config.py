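"""Experiment configuration: one YAML-round-trippable record of every knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["ExperimentConfig"]


@dataclass
class ExperimentConfig:
    """All generator, measurement and resampling parameters of one run.

    Defaults mirror the bench conditions: 14 specimens spanning 60-3500 mm^2,
    mean lamina thickness 0.25 mm (CV 12 %), midrib worth 2-8 % of total
    volume, a 0.001 g balance, 0.01 mm micrometer noise, water at 22 deg C,
    scans at the standard office-scanner resolutions with 1200 dpi as the
    reference.
    """

    seed: int = 0
    n_specimens: int = 14
    area_range_mm2: tuple[float, float] = (60.0, 3500.0)
    thickness_mean_mm: float = 0.25
    thickness_cv: float = 0.12
    #: within-leaf base/middle/tip thickness relative to the leaf mean;
    #: (1, 1, 1) gives a flat lamina for identity checks
    thickness_taper: tuple[float, float, float] = (1.2, 1.0, 0.8)
    midrib_fraction_range: tuple[float, float] = (0.02, 0.08)
    midrib_mismatch: float = 0.2

    temp_c: float = 22.0
    retainer_volume_mm3: float = 2000.0
    retainer_weight_g: float = 20.0
    balance_resolution_g: float = 0.001
    weighing_noise_sd_g: float = 0.0
    thickness_scheme: str = "every_2cm"
    thickness_noise_sd_mm: float = 0.01

    dpis: tuple[float, ...] = (200.0, 300.0, 400.0, 600.0, 800.0, 1000.0, 1200.0)
    reference_dpi: float = 1200.0

    pile_group_size: int = 7
    n_piles: int = 100
    thickness_population_n: int = 35
    thickness_group_k: int = 5
    thickness_n_groups: int = 100

    outdir: str = "leafvol_out"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        for key in ("area_range_mm2", "midrib_fraction_range", "dpis",
                    "thickness_taper"):
            data[key] = list(data[key])
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("area_range_mm2", "midrib_fraction_range", "dpis",
                    "thickness_taper"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
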