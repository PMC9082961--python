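"""Synthetic wheat-leaf populations with exact geometric ground truth.

A leaf is modelled as a flat lamina whose half-width and thickness vary along
the leaf axis, plus a midrib running the length of the blade:

* width profile ``w(x) = W * (4 u (1 - u))**a`` with ``u = x/L`` — maximum
  width mid-leaf; the default exponent ``a = 0.5`` gives a lanceolate
  outline.  Rectangular and triangular profiles are available for degenerate
  test geometries.
* lamina thickness: linear interpolation through base / middle / tip values,
  matching the three-point micrometer scheme used in the field.
* midrib: an add-on volume equal to the cylinder (cut pieces) or cone
  (complete leaves) model built from the basal midrib diameter, times an
  optional model-mismatch factor that emulates how far a real midrib departs
  from the idealised solid.

Specimens may be complete leaves or pieces cut from a leaf (an interval
``[x0, x1]`` of the axis).  True area and volume come from adaptive
quadrature and serve as the ground-truth oracle for both measurement paths.

All randomness flows from explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize

from .volumetry import SGBRecord, SuspensionRecord, midrib_volume, water_density

__all__ = [
    "LeafShapeParams",
    "LeafSpecimen",
    "PopulationParams",
    "ScanImage",
    "sample_population",
    "sample_study_set",
    "true_area",
    "true_volume",
    "mean_thickness",
    "render_scan",
    "simulate_suspension_weighing",
    "simulate_sgb_weighing",
]

MM_PER_INCH = 25.4

#: ratios applied to the sampled mean lamina thickness to form the
#: base/middle/tip triple (base thicker than tip, mean preserved)
_TAPER_BASE, _TAPER_MID, _TAPER_TIP = 1.2, 1.0, 0.8
#: midrib diameter taper along the leaf, relative to its basal diameter
_MIDRIB_TIP_FRACTION = 0.5


@dataclass(frozen=True)
class LeafShapeParams:
    """Parametric geometry of one whole leaf."""

    length_mm: float
    max_width_mm: float
    thickness_base_mm: float
    thickness_middle_mm: float
    thickness_tip_mm: float
    midrib_base_mm: float
    midrib_middle_mm: float
    midrib_tip_mm: float
    width_exponent: float = 0.5
    width_mode: str = "lanceolate"  # lanceolate | rectangular | triangular
    is_complete_leaf: bool = True

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.max_width_mm <= 0:
            raise ValueError("length and width must be positive")
        for t in (self.thickness_base_mm, self.thickness_middle_mm,
                  self.thickness_tip_mm, self.midrib_base_mm,
                  self.midrib_middle_mm, self.midrib_tip_mm):
            if t <= 0:
                raise ValueError("all thicknesses/diameters must be positive")
        if self.thickness_base_mm < self.thickness_tip_mm:
            raise ValueError("lamina must taper toward the tip (base >= tip)")
        if self.midrib_base_mm < self.thickness_base_mm:
            raise ValueError("basal midrib diameter must be >= basal lamina thickness")
        if self.width_mode not in ("lanceolate", "rectangular", "triangular"):
            raise ValueError(f"unknown width_mode {self.width_mode!r}")

    # -- profiles along the axis (x in mm from the leaf base) ---------------

    def width(self, x):
        """Blade width at axial position x (vectorised)."""
        u = np.clip(np.asarray(x, dtype=float) / self.length_mm, 0.0, 1.0)
        if self.width_mode == "rectangular":
            return np.full_like(u, self.max_width_mm)
        if self.width_mode == "triangular":
            return self.max_width_mm * (1.0 - u)
        base = 4.0 * u * (1.0 - u)
        if self.width_exponent == 0.5:  # default outline; sqrt is much cheaper
            return self.max_width_mm * np.sqrt(base)
        return self.max_width_mm * base ** self.width_exponent

    def lamina_thickness(self, x):
        """Lamina thickness at axial position x (piecewise linear)."""
        xs = np.asarray(x, dtype=float)
        knots = [0.0, self.length_mm / 2.0, self.length_mm]
        vals = [self.thickness_base_mm, self.thickness_middle_mm,
                self.thickness_tip_mm]
        return np.interp(xs, knots, vals)

    def midrib_diameter(self, x):
        xs = np.asarray(x, dtype=float)
        knots = [0.0, self.length_mm / 2.0, self.length_mm]
        vals = [self.midrib_base_mm, self.midrib_middle_mm, self.midrib_tip_mm]
        return np.interp(xs, knots, vals)


@dataclass(frozen=True)
class LeafSpecimen:
    """A measurable sample: a complete leaf or a piece cut from one.

    ``piece_interval`` is the sampled stretch of the leaf axis in mm;
    ``midrib_mismatch`` multiplies the idealised midrib add-on volume to
    emulate the model error seen on real leaves (1.0 = the model is exact).
    """

    shape: LeafShapeParams
    piece_interval: tuple[float, float] = (0.0, -1.0)  # sentinel: full leaf
    specimen_id: str = ""
    midrib_mismatch: float = 1.0

    def __post_init__(self) -> None:
        x0, x1 = self.piece_interval
        if x1 < 0:  # full-leaf sentinel
            object.__setattr__(self, "piece_interval", (0.0, self.shape.length_mm))
            x0, x1 = self.piece_interval
        if not (0.0 <= x0 < x1 <= self.shape.length_mm + 1e-9):
            raise ValueError(f"piece interval {self.piece_interval} outside [0, L]")
        if self.midrib_mismatch <= 0:
            raise ValueError("midrib_mismatch must be positive")

    @property
    def length_mm(self) -> float:
        x0, x1 = self.piece_interval
        return x1 - x0

    @property
    def is_complete_leaf(self) -> bool:
        x0, x1 = self.piece_interval
        return (self.shape.is_complete_leaf and x0 == 0.0
                and abs(x1 - self.shape.length_mm) < 1e-9)

    @property
    def midrib_model(self) -> str:
        """Default midrib solid: cone for complete leaves, else cylinder."""
        return "cone" if self.is_complete_leaf else "cylinder"

    @property
    def basal_midrib_diameter_mm(self) -> float:
        return float(self.shape.midrib_diameter(self.piece_interval[0]))


def _quad(f: Callable, a: float, b: float) -> float:
    val, _ = integrate.quad(f, a, b, epsrel=1e-8, epsabs=1e-12, limit=200)
    return val


def true_area(specimen: LeafSpecimen) -> float:
    """Ground-truth planform area of the specimen in mm^2 (adaptive quadrature)."""
    x0, x1 = specimen.piece_interval
    return _quad(lambda x: float(specimen.shape.width(x)), x0, x1)


def lamina_volume(specimen: LeafSpecimen) -> float:
    """Ground-truth lamina (blade-only) volume in mm^3."""
    x0, x1 = specimen.piece_interval
    s = specimen.shape
    return _quad(lambda x: float(s.width(x)) * float(s.lamina_thickness(x)), x0, x1)


def midrib_addon_volume(specimen: LeafSpecimen, *, apply_mismatch: bool = True) -> float:
    """The specimen's midrib volume: the cylinder/cone model, optionally
    scaled by the specimen's model-mismatch factor (the *true* midrib)."""
    v = midrib_volume(specimen.length_mm, specimen.basal_midrib_diameter_mm,
                      specimen.midrib_model)
    return v * specimen.midrib_mismatch if apply_mismatch else v


def true_volume(specimen: LeafSpecimen, include_midrib: bool = True) -> float:
    """Ground-truth specimen volume in mm^3."""
    v = lamina_volume(specimen)
    if include_midrib:
        v += midrib_addon_volume(specimen)
    return v


def mean_thickness(
    specimen: LeafSpecimen,
    scheme: str = "three_point",
    *,
    noise_sd_mm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> float:
    """Mean lamina thickness by one of the field sampling schemes.

    ``three_point``: readings at the base, middle and tip of the sample.
    ``every_2cm``: readings at 2 cm spacing along the sample (a single
    mid-sample reading for pieces shorter than 2 cm).
    ``middle_only``: one reading at mid-sample.

    ``noise_sd_mm`` adds independent Gaussian micrometer reading error.
    """
    x0, x1 = specimen.piece_interval
    if scheme == "three_point":
        pts = np.array([x0, (x0 + x1) / 2.0, x1])
    elif scheme == "every_2cm":
        n = int((x1 - x0) // 20.0)
        if n < 1:
            pts = np.array([(x0 + x1) / 2.0])
        else:
            # centred readings of consecutive 2 cm stretches
            pts = x0 + 20.0 * np.arange(n) + 10.0
    elif scheme == "middle_only":
        pts = np.array([(x0 + x1) / 2.0])
    else:
        raise ValueError(f"unknown thickness sampling scheme {scheme!r}")
    readings = specimen.shape.lamina_thickness(pts)
    if noise_sd_mm > 0:
        if rng is None:
            rng = np.random.default_rng()
        readings = readings + rng.normal(0.0, noise_sd_mm, size=readings.shape)
    return float(np.mean(readings))


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

#: dimension order used throughout the copula sampler
_DIMENSIONS = ("length", "width", "thickness_base", "thickness_middle",
               "thickness_tip", "midrib_base", "midrib_middle", "midrib_tip")

#: default means — a mid-tillering wheat canopy (mm); CVs from seasonal
#: surveys of the same dimensions (fractions, not %)
_DEFAULT_MEANS = {
    "length": 175.0, "width": 12.0,
    "thickness_base": 0.30, "thickness_middle": 0.25, "thickness_tip": 0.20,
    "midrib_base": 0.80, "midrib_middle": 0.60, "midrib_tip": 0.40,
}
_DEFAULT_CVS = {
    "length": 0.210, "width": 0.193,
    "thickness_base": 0.153, "thickness_middle": 0.129, "thickness_tip": 0.145,
    "midrib_base": 0.236, "midrib_middle": 0.143, "midrib_tip": 0.125,
}


@dataclass(frozen=True)
class PopulationParams:
    """Marginal means/CVs and a common correlation for leaf dimensions.

    Marginals are log-normal (positive support, right skew typical of size
    traits); dependence is a Gaussian copula with a single equicorrelation
    knob.  CV = 0 collapses a marginal to its mean.
    """

    n: int
    seed: int
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    cvs: dict = field(default_factory=lambda: dict(_DEFAULT_CVS))
    correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for d in _DIMENSIONS:
            if self.means.get(d, 0.0) <= 0:
                raise ValueError(f"mean for {d} must be positive")
            if self.cvs.get(d, 0.0) < 0:
                raise ValueError(f"CV for {d} must be non-negative")
        if not -0.1 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [-0.1, 1)")


def _lognormal_from_mean_cv(z: np.ndarray, mean: float, cv: float) -> np.ndarray:
    """Map standard-normal draws to a log-normal with given mean and CV."""
    if cv == 0.0:
        return np.full_like(z, mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return np.exp(mu + math.sqrt(sigma2) * z)


def sample_population(params: PopulationParams) -> list[LeafSpecimen]:
    """Draw ``params.n`` complete leaves; deterministic per seed."""
    rng = np.random.default_rng(params.seed)
    k = len(_DIMENSIONS)
    cov = np.full((k, k), params.correlation)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((params.n, k)) @ chol.T
    draws = {
        d: _lognormal_from_mean_cv(z[:, i], params.means[d], params.cvs.get(d, 0.0))
        for i, d in enumerate(_DIMENSIONS)
    }
    specimens = []
    for i in range(params.n):
        tb, tm, tt = (draws["thickness_base"][i], draws["thickness_middle"][i],
                      draws["thickness_tip"][i])
        if tb < tt:  # enforce the taper invariant; rare under default CVs
            tb, tt = tt, tb
        mb = max(draws["midrib_base"][i], tb)
        shape = LeafShapeParams(
            length_mm=float(draws["length"][i]),
            max_width_mm=float(draws["width"][i]),
            thickness_base_mm=float(tb),
            thickness_middle_mm=float(tm),
            thickness_tip_mm=float(tt),
            midrib_base_mm=float(mb),
            midrib_middle_mm=float(min(draws["midrib_middle"][i], mb)),
            midrib_tip_mm=float(min(draws["midrib_tip"][i], mb)),
        )
        specimens.append(LeafSpecimen(shape=shape, specimen_id=f"leaf{i:04d}"))
    return specimens


def _width_shape_integral(exponent: float) -> float:
    """Integral of (4u(1-u))**a over [0,1]; pi/4 for the default a=0.5."""
    return _quad(lambda u: (4.0 * u * (1.0 - u)) ** exponent, 0.0, 1.0)


def _solve_piece_interval(shape: LeafShapeParams, target_area: float,
                          rng: np.random.Generator) -> tuple[float, float]:
    """Find an interval of the leaf whose blade area equals ``target_area``."""
    L = shape.length_mm
    total = _quad(lambda x: float(shape.width(x)), 0.0, L)
    if target_area >= total:
        return (0.0, L)
    # anchor the piece at a random start, growing toward the tip
    x0_max = 0.4 * L
    x0 = float(rng.uniform(0.0, x0_max))

    def area_to(x1: float) -> float:
        return _quad(lambda x: float(shape.width(x)), x0, x1)

    if area_to(L) < target_area:  # not enough blade left of the tip
        x0 = 0.0
    x1 = optimize.brentq(lambda x: area_to(x) - target_area, x0 + 1e-6, L,
                         xtol=1e-9)
    return (x0, float(x1))


def sample_study_set(
    n: int = 14,
    *,
    seed: int,
    area_range_mm2: tuple[float, float] = (60.0, 3500.0),
    thickness_mean_mm: float = 0.25,
    thickness_cv: float = 0.12,
    midrib_fraction_range: tuple[float, float] = (0.02, 0.08),
    midrib_mismatch: float = 0.2,
    aspect_ratio_mean: float = 15.0,
    full_leaf_area_mm2: float = 1000.0,
    thickness_taper: tuple[float, float, float] = (_TAPER_BASE, _TAPER_MID,
                                                   _TAPER_TIP),
) -> list[LeafSpecimen]:
    """Generate the bench's specimen set: pieces and full leaves spanning a
    wide area range with known ground truth.

    Target areas are stratified log-uniform over ``area_range_mm2`` so every
    draw spans the full range.  Samples with target area below
    ``full_leaf_area_mm2`` are cut as pieces from a larger parent leaf (the
    small-sample regime); the rest are complete leaves.  Each specimen's
    midrib add-on is sized to a fraction of total volume drawn uniformly
    from ``midrib_fraction_range``, then perturbed by a multiplicative
    model-mismatch factor uniform in ``1 +/- midrib_mismatch``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = area_range_mm2
    # stratified log-uniform target areas
    edges = np.linspace(math.log(lo), math.log(hi), n + 1)
    targets = np.exp(rng.uniform(edges[:-1], edges[1:]))
    rng.shuffle(targets)

    c_a = _width_shape_integral(0.5)  # lanceolate area factor, = pi/4
    specimens = []
    for i, target in enumerate(targets):
        t_mean = float(_lognormal_from_mean_cv(
            rng.standard_normal(1), thickness_mean_mm, thickness_cv)[0])
        tb, tm, tt = (r * t_mean for r in thickness_taper)
        aspect = float(rng.normal(aspect_ratio_mean, 2.0))
        aspect = max(aspect, 5.0)

        if target >= full_leaf_area_mm2:
            W = math.sqrt(target / (c_a * aspect))
            L = aspect * W
            if L > 300.0:  # cap at the longest wheat leaves; widen instead
                L = 300.0
                W = target / (c_a * L)
            interval = None
        else:
            parent_area = float(rng.uniform(1200.0, 2500.0))
            W = math.sqrt(parent_area / (c_a * aspect))
            L = aspect * W
            interval = "piece"

        frac = float(rng.uniform(*midrib_fraction_range))
        mismatch = float(rng.uniform(1.0 - midrib_mismatch, 1.0 + midrib_mismatch))

        # provisional shape (unit midrib) to locate the piece, then size the
        # midrib so the add-on hits the requested share of total volume
        provisional = LeafShapeParams(
            length_mm=L, max_width_mm=W,
            thickness_base_mm=tb, thickness_middle_mm=tm, thickness_tip_mm=tt,
            midrib_base_mm=max(1.0, tb), midrib_middle_mm=max(0.75, tb),
            midrib_tip_mm=0.5,
        )
        if interval is None:
            x0, x1 = 0.0, L
        else:
            x0, x1 = _solve_piece_interval(provisional, target, rng)
        piece_len = x1 - x0
        spec_tmp = LeafSpecimen(shape=provisional, piece_interval=(x0, x1))
        v_lam = lamina_volume(spec_tmp)
        v_m_target = frac / (1.0 - frac) * v_lam
        model = spec_tmp.midrib_model
        divisor = 3.0 if model == "cone" else 1.0
        d_at_x0 = 2.0 * math.sqrt(divisor * v_m_target / (math.pi * piece_len))
        # back out the whole-leaf basal diameter from the linear midrib taper
        rel = 1.0 - (1.0 - _MIDRIB_TIP_FRACTION) * (x0 / L)
        d_base = max(d_at_x0 / rel, tb)
        shape = LeafShapeParams(
            length_mm=L, max_width_mm=W,
            thickness_base_mm=tb, thickness_middle_mm=tm, thickness_tip_mm=tt,
            midrib_base_mm=d_base,
            midrib_middle_mm=d_base * (1.0 + _MIDRIB_TIP_FRACTION) / 2.0,
            midrib_tip_mm=d_base * _MIDRIB_TIP_FRACTION,
        )
        specimens.append(LeafSpecimen(
            shape=shape, piece_interval=(x0, x1),
            specimen_id=f"sample{i:03d}", midrib_mismatch=mismatch,
        ))
    return specimens


# ---------------------------------------------------------------------------
# scan rendering
# ---------------------------------------------------------------------------


@dataclass
class ScanImage:
    """A rendered flat-bed scan of one specimen.

    ``mask`` is the binary foreground raster (True = leaf) or, in grayscale
    mode, ``rgb`` holds an 8-bit image on white background.
    """

    mask: np.ndarray
    dpi: float
    specimen_id: str = ""
    rgb: np.ndarray | None = None

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


_LEAF_RGB = np.array([70, 128, 45], dtype=float)  # wheat-leaf green


def render_scan(
    specimen: LeafSpecimen,
    dpi: float,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    rotation_deg: float | None = None,
    offset_px: tuple[float, float] | None = None,
    max_rotation_deg: float = 2.0,
    canvas_mm: tuple[float, float] = (350.0, 500.0),
    mode: str = "binary",
    row_chunk: int = 512,
) -> ScanImage:
    """Rasterise a specimen as a flat-bed scan at ``dpi``.

    The specimen lands on the (virtual) platen at a seeded sub-pixel offset
    and a small random rotation, as a hand-placed leaf would; pass explicit
    ``rotation_deg`` / ``offset_px`` to pin the placement.  Foreground is
    decided by a pixel-centre-in-silhouette test (no anti-aliasing).
    ``mode='grayscale'`` additionally returns an RGB image of the leaf on a
    white background for exercising the segmentation path.
    """
    if not 50.0 <= dpi <= 2400.0:
        raise ValueError("dpi must lie in [50, 2400]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if rotation_deg is None:
        rotation_deg = float(rng.uniform(-max_rotation_deg, max_rotation_deg))
    if offset_px is None:
        offset_px = (float(rng.uniform(0.0, 1.0)), float(rng.uniform(0.0, 1.0)))

    pitch = MM_PER_INCH / dpi
    x0, x1 = specimen.piece_interval
    half_w = specimen.shape.max_width_mm / 2.0
    theta = math.radians(rotation_deg)
    c, s = math.cos(theta), math.sin(theta)

    # scanner-frame bounding box of the rotated leaf rectangle hull
    corners = np.array([[x0, -half_w], [x0, half_w], [x1, -half_w], [x1, half_w]])
    rot = np.array([[c, -s], [s, c]])
    sc = corners @ rot.T
    span_x = sc[:, 0].max() - sc[:, 0].min()
    span_y = sc[:, 1].max() - sc[:, 1].min()
    if span_x > canvas_mm[1] or span_y > canvas_mm[0]:
        raise ValueError(
            f"specimen spans {span_x:.0f} x {span_y:.0f} mm, larger than the "
            f"canvas {canvas_mm} mm"
        )
    origin_x = sc[:, 0].min() - (1.0 + offset_px[0]) * pitch
    origin_y = sc[:, 1].min() - (1.0 + offset_px[1]) * pitch
    ncols = int(math.ceil(span_x / pitch)) + 3
    nrows = int(math.ceil(span_y / pitch)) + 3

    mask = np.zeros((nrows, ncols), dtype=bool)
    xs = origin_x + (np.arange(ncols) + 0.5) * pitch
    shape = specimen.shape
    fast_lanceolate = (shape.width_mode == "lanceolate"
                       and shape.width_exponent == 0.5)
    for r0 in range(0, nrows, row_chunk):
        r1 = min(r0 + row_chunk, nrows)
        ys = origin_y + (np.arange(r0, r1) + 0.5) * pitch
        # inverse-rotate pixel centres into the leaf frame
        xf = c * xs[None, :] + s * ys[:, None]
        yf = -s * xs[None, :] + c * ys[:, None]
        inside = (xf >= x0) & (xf <= x1)
        if fast_lanceolate:
            # |y| <= (W/2) sqrt(4u(1-u))  <=>  y^2 <= W^2 u (1-u),
            # and the right side is negative outside the blade
            u = xf * (1.0 / shape.length_mm)
            inside &= yf * yf <= shape.max_width_mm**2 * u * (1.0 - u)
        else:
            idx = np.nonzero(inside)
            if idx[0].size:
                w_half = 0.5 * shape.width(xf[idx])
                inside[idx] = np.abs(yf[idx]) <= w_half
        mask[r0:r1] = inside

    rgb = None
    if mode == "grayscale":
        rgb = np.full((nrows, ncols, 3), 255.0)
        rgb[mask] = _LEAF_RGB
        rgb += rng.normal(0.0, 2.0, size=rgb.shape)
        rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    elif mode != "binary":
        raise ValueError(f"unknown render mode {mode!r}")
    return ScanImage(mask=mask, dpi=dpi, specimen_id=specimen.specimen_id, rgb=rgb)


# ---------------------------------------------------------------------------
# weighing simulation
# ---------------------------------------------------------------------------


def _round_to(value: float, resolution: float) -> float:
    if resolution <= 0:
        return value
    return round(value / resolution) * resolution


def simulate_suspension_weighing(
    v_true_mm3: float,
    temp_c: float,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    retainer_volume_mm3: float = 2000.0,
    n_replicates: int | None = None,
    noise_sd_g: float = 0.0,
    resolution_g: float = 0.001,
) -> list[SuspensionRecord]:
    """Simulate suspension weighings of a sample of known volume.

    The balance change equals the weight of displaced water
    (``volume * rho_T``) plus Gaussian noise, quantised to the balance
    resolution.  Returns one record per replicate (2-3 by default, as the
    bench protocol repeats readings to catch bubbles).
    """
    if v_true_mm3 <= 0:
        raise ValueError("v_true must be positive")
    rho = water_density(temp_c)
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_replicates is None:
        n_replicates = int(rng.integers(2, 4))
    records = []
    for rep in range(n_replicates):
        dw_r = retainer_volume_mm3 * rho + rng.normal(0.0, noise_sd_g)
        dw_t = (retainer_volume_mm3 + v_true_mm3) * rho + rng.normal(0.0, noise_sd_g)
        records.append(SuspensionRecord(
            dw_r=_round_to(dw_r, resolution_g),
            dw_t=_round_to(dw_t, resolution_g),
            temp_c=temp_c, replicate=rep,
        ))
    return records


def simulate_sgb_weighing(
    v_true_mm3: float,
    w_dry_g: float,
    temp_c: float,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    retainer_w_r1_g: float = 20.0,
    retainer_volume_mm3: float = 2000.0,
    n_replicates: int | None = None,
    noise_sd_g: float = 0.0,
    resolution_g: float = 0.001,
    record_w_r2: bool = False,
) -> list[SGBRecord]:
    """Simulate Specific-Gravity-Bench weighings of a sample of known volume.

    The load cell under water reads the dry weight of the immersed set minus
    the buoyancy of its displaced water:
    ``W_T2 = W_dry + W_r1 - (V_true + V_r) * rho_T``.
    """
    if v_true_mm3 <= 0:
        raise ValueError("v_true must be positive")
    if w_dry_g <= 0:
        raise ValueError("w_dry must be positive")
    rho = water_density(temp_c)
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_replicates is None:
        n_replicates = int(rng.integers(2, 4))
    records = []
    for rep in range(n_replicates):
        w_l1 = w_dry_g + rng.normal(0.0, noise_sd_g)
        w_t2 = (w_dry_g + retainer_w_r1_g
                - (v_true_mm3 + retainer_volume_mm3) * rho
                + rng.normal(0.0, noise_sd_g))
        w_r2 = None
        if record_w_r2:
            w_r2 = _round_to(retainer_w_r1_g - retainer_volume_mm3 * rho,
                             resolution_g)
        records.append(SGBRecord(
            w_r1=retainer_w_r1_g,
            w_l1=_round_to(w_l1, resolution_g),
            w_t2=_round_to(w_t2, resolution_g),
            temp_c=temp_c, w_r2=w_r2, replicate=rep,
        ))
    return records
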