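"""Hydrostatic leaf volumetry and the volumetric leaf-area estimator.

Two weighing protocols are supported:

* **Suspension technique** — the sample hangs fully submerged from a holder
  above a beaker standing on a balance; the balance reading equals the weight
  of displaced water, so volume = reading / water density.  The retainer
  (clip + hook + submerged line) is measured first and subtracted.
* **Specific Gravity Bench (SGB)** — the sample sits in a cage hanging from a
  load cell and is immersed by raising the water container; volume follows
  from the dry and underwater weights of the cage and sample.

Volumetric leaf area (VLA) is the measured leaf volume divided by the mean
lamina thickness, optionally after subtracting a modelled midrib volume
(cylinder for cut pieces, cone for complete leaves).

Units: volumes mm^3, lengths/thicknesses mm, weights g, temperatures deg C,
densities g/mm^3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SuspensionRecord",
    "SGBRecord",
    "VolumeResult",
    "BubbleError",
    "water_density",
    "retainer_volume",
    "leaf_volume_suspension",
    "leaf_volume_sgb",
    "midrib_volume",
    "volumetric_leaf_area",
    "aggregate_replicates",
]

# Water density vs temperature, g/cm^3, 15-30 degC at 0.5 degC steps
# (standard-atmosphere liquid water reference values, Kell formulation).
_DENSITY_GRID_C = np.arange(15.0, 30.01, 0.5)
_DENSITY_GRID_G_CM3 = np.array([
    0.999100, 0.999023, 0.998943, 0.998860, 0.998775, 0.998687, 0.998596,
    0.998502, 0.998405, 0.998306, 0.998204, 0.998100, 0.997992, 0.997883,
    0.997771, 0.997656, 0.997538, 0.997419, 0.997297, 0.997172, 0.997045,
    0.996915, 0.996784, 0.996650, 0.996513, 0.996374, 0.996234, 0.996090,
    0.995945, 0.995797, 0.995647,
])

TEMP_RANGE_C = (float(_DENSITY_GRID_C[0]), float(_DENSITY_GRID_C[-1]))


class BubbleError(ValueError):
    """A computed volume is negative beyond measurement tolerance.

    The classic cause in practice is an air bubble trapped on the retainer
    during the reference weighing, inflating the retainer volume.
    """


def water_density(temp_c: float) -> float:
    """Density of pure water at ``temp_c`` in g/mm^3.

    Linear interpolation on the embedded 15-30 degC reference grid; no
    extrapolation is performed.
    """
    t = float(temp_c)
    if not (TEMP_RANGE_C[0] <= t <= TEMP_RANGE_C[1]):
        raise ValueError(
            f"temperature {t} degC outside density table range {TEMP_RANGE_C}"
        )
    rho_g_cm3 = float(np.interp(t, _DENSITY_GRID_C, _DENSITY_GRID_G_CM3))
    return rho_g_cm3 / 1000.0  # g/cm^3 -> g/mm^3


@dataclass(frozen=True)
class SuspensionRecord:
    """One replicate of a suspension weighing.

    ``dw_r`` is the balance change on immersing the empty retainer, ``dw_t``
    the change with the leaf sample attached, both in grams.
    """

    dw_r: float
    dw_t: float
    temp_c: float
    replicate: int = 0

    def __post_init__(self) -> None:
        water_density(self.temp_c)  # range check
        if self.dw_r <= 0:
            raise ValueError("retainer reading dw_r must be positive")


@dataclass(frozen=True)
class SGBRecord:
    """One replicate of a Specific Gravity Bench weighing.

    ``w_r1`` dry retainer weight in air, ``w_l1`` dry leaf pile in air,
    ``w_t2`` underwater weight of the immersed set, ``w_r2`` (optional)
    underwater weight of the empty retainer; all in grams.
    """

    w_r1: float
    w_l1: float
    w_t2: float
    temp_c: float
    w_r2: float | None = None
    replicate: int = 0

    def __post_init__(self) -> None:
        water_density(self.temp_c)
        if self.w_r1 <= 0 or self.w_l1 < 0:
            raise ValueError("dry weights must be non-negative (w_r1 positive)")
        if self.w_r2 is not None and self.w_r2 >= self.w_r1:
            raise ValueError("w_r2 must be below w_r1 (buoyancy)")


@dataclass(frozen=True)
class VolumeResult:
    """Volumes of a measured sample, mm^3."""

    v_r: float
    v_t: float
    v_l: float
    v_m: float = 0.0

    @property
    def v_l_excl(self) -> float:
        """Leaf volume with the midrib model volume removed."""
        return self.v_l - self.v_m


def retainer_volume(dw_r: float, temp_c: float) -> float:
    """Retainer volume V_r = dW_r / rho_T in mm^3."""
    if dw_r <= 0:
        raise ValueError("dw_r must be positive")
    return dw_r / water_density(temp_c)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, int]:
    """Mean of replicate volumes after a median-anchored outlier rejection.

    A replicate is discarded when it deviates from the median by more than
    three times the median absolute deviation of the set — the occasional
    bubble-inflated reading sticks out by far more than balance noise.
    Returns ``(mean, n_used)``.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicates")
    if vals.size == 1:
        return float(vals[0]), 1
    med = np.median(vals)
    spread = np.median(np.abs(vals - med))
    keep = np.abs(vals - med) <= 3.0 * spread
    if not keep.any():  # degenerate: keep the median itself
        keep = np.abs(vals - med) == np.abs(vals - med).min()
    return float(vals[keep].mean()), int(keep.sum())


def _check_negative(v_l: float, tolerance_mm3: float) -> float:
    if v_l >= 0:
        return v_l
    if v_l >= -tolerance_mm3:
        warnings.warn(
            f"computed volume {v_l:.3f} mm^3 slightly negative; clamped to 0",
            stacklevel=3,
        )
        return 0.0
    raise BubbleError(
        f"computed leaf volume {v_l:.3f} mm^3 is negative beyond the "
        f"rounding tolerance ({tolerance_mm3} mm^3); check for bubbles"
    )


def leaf_volume_suspension(
    records: SuspensionRecord | Iterable[SuspensionRecord],
    v_r: float,
    *,
    tolerance_mm3: float = 1.0,
) -> tuple[float, int]:
    """Leaf volume V_l = dW_t / rho_T - V_r, aggregated over replicates.

    ``v_r`` is the previously determined retainer volume (mm^3).  Returns
    ``(volume_mm3, n_replicates_used)``.
    """
    if isinstance(records, SuspensionRecord):
        records = [records]
    if v_r < 0:
        raise ValueError("v_r must be non-negative")
    per_rep = [r.dw_t / water_density(r.temp_c) - v_r for r in records]
    v_l, n_used = aggregate_replicates(per_rep)
    return _check_negative(v_l, tolerance_mm3), n_used


def leaf_volume_sgb(
    records: SGBRecord | Iterable[SGBRecord],
    v_r: float,
    *,
    w_r2_tolerance_g: float = 0.01,
    tolerance_mm3: float = 1.0,
) -> tuple[float, int]:
    """Leaf volume from SGB records, aggregated over replicates.

    The immersed set (cage + leaf) displaces V_r + V_l of water, so the
    load cell reads ``W_T2 = W_l1 + W_r1 - (V_l + V_r) rho_T``.  When
    ``w_r2`` is recorded, the net underwater leaf weight W_l2 = W_T2 - W_r2
    gives V_l = (W_l1 - W_T2 + W_r2)/rho_T; the recorded ``w_r2`` must be
    consistent with ``w_r1 - V_r * rho_T`` within ``w_r2_tolerance_g``.
    Without ``w_r2`` the equivalent form
    V_l = (W_l1 + W_r1 - W_T2 - V_r rho_T)/rho_T is used.
    """
    if isinstance(records, SGBRecord):
        records = [records]
    if v_r < 0:
        raise ValueError("v_r must be non-negative")
    per_rep = []
    for r in records:
        rho = water_density(r.temp_c)
        if r.w_r2 is not None:
            expected = r.w_r1 - v_r * rho
            if abs(r.w_r2 - expected) > w_r2_tolerance_g:
                raise ValueError(
                    f"w_r2={r.w_r2} inconsistent with w_r1 - V_r*rho "
                    f"({expected:.4f} g)"
                )
            per_rep.append((r.w_l1 - r.w_t2 + r.w_r2) / rho)
        else:
            per_rep.append((r.w_l1 + r.w_r1 - r.w_t2 - v_r * rho) / rho)
    v_l, n_used = aggregate_replicates(per_rep)
    return _check_negative(v_l, tolerance_mm3), n_used


def midrib_volume(length_mm: float, t_bm: float, model: str) -> float:
    """Midrib volume from sample length and basal midrib diameter.

    ``model='cylinder'`` (cut pieces): L * pi * (T_bm/2)^2.
    ``model='cone'`` (complete leaves, midrib tapering to nothing): one third
    of the cylinder.
    """
    if length_mm <= 0:
        raise ValueError("length must be positive")
    if t_bm <= 0:
        raise ValueError("basal midrib diameter must be positive")
    cyl = length_mm * math.pi * (t_bm / 2.0) ** 2
    if model == "cylinder":
        return cyl
    if model == "cone":
        return cyl / 3.0
    raise ValueError(f"unknown midrib model {model!r}; use 'cylinder' or 'cone'")


def volumetric_leaf_area(v_l: float, t_l: float, v_m: float = 0.0) -> float:
    """VLA = (V_l - V_m) / T_l in mm^2.

    ``t_l`` is the mean lamina thickness of the sample; pass ``v_m > 0`` to
    exclude a modelled midrib volume.
    """
    if v_l <= 0:
        raise ValueError("v_l must be positive")
    if t_l <= 0:
        raise ValueError("mean thickness t_l must be positive")
    if not 0 <= v_m < v_l:
        raise ValueError("v_m must satisfy 0 <= v_m < v_l")
    return (v_l - v_m) / t_l
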