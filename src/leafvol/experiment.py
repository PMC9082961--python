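"""End-to-end simulated experiments: the bench runs behind the CLI and the
reproduction scripts.

Each function generates its own specimens from an explicit seed, pushes them
through the measurement pipelines (simulated weighing -> volumetry; rendered
scan -> optical area) and returns tidy tables plus agreement summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthesis, volumetry
from .agreement import AgreementReport, agreement_report, pearson
from .optical import optical_area, resolution_study
from .resampling import ThicknessSamplingResult, thickness_sampling_experiment
from .synthesis import LeafSpecimen

__all__ = [
    "measure_specimens",
    "vla_ola_experiment",
    "resolution_experiment",
    "thickness_experiment",
    "volume_area_correlation",
]

_DEFAULTS = dict(
    temp_c=22.0,
    retainer_volume_mm3=2000.0,
    balance_resolution_g=0.001,
    weighing_noise_sd_g=0.0,
    thickness_scheme="every_2cm",
    thickness_noise_sd_mm=0.01,
    dpi=1200.0,
)


def measure_specimens(
    specimens: list[LeafSpecimen],
    *,
    seed: int,
    temp_c: float = 22.0,
    retainer_volume_mm3: float = 2000.0,
    balance_resolution_g: float = 0.001,
    weighing_noise_sd_g: float = 0.0,
    thickness_scheme: str = "every_2cm",
    thickness_noise_sd_mm: float = 0.01,
    dpi: float = 1200.0,
    render: bool = True,
) -> pd.DataFrame:
    """Run the full simulated measurement of each specimen.

    Per specimen: simulate suspension weighings of its true volume (midrib
    included), recover the leaf volume through the volumetric equations
    using the retainer volume estimated from the same records, sample its
    mean thickness with micrometer noise, model its midrib volume, and —
    when ``render`` is on — measure its optical area from a seeded scan.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in specimens:
        v_true = synthesis.true_volume(spec, include_midrib=True)
        records = synthesis.simulate_suspension_weighing(
            v_true, temp_c, rng=rng,
            retainer_volume_mm3=retainer_volume_mm3,
            noise_sd_g=weighing_noise_sd_g,
            resolution_g=balance_resolution_g,
        )
        rho = volumetry.water_density(temp_c)
        v_r_est, _ = volumetry.aggregate_replicates(
            [r.dw_r / rho for r in records])
        v_l, n_used = volumetry.leaf_volume_suspension(records, v_r_est)
        t_l = synthesis.mean_thickness(
            spec, thickness_scheme, noise_sd_mm=thickness_noise_sd_mm, rng=rng)
        v_m = synthesis.midrib_addon_volume(spec, apply_mismatch=False)
        row = {
            "specimen_id": spec.specimen_id,
            "true_area": synthesis.true_area(spec),
            "true_volume": v_true,
            "v_r": v_r_est,
            "v_l": v_l,
            "v_m": v_m,
            "v_l_excl": v_l - v_m,
            "t_l": t_l,
            "n_replicates_used": n_used,
            "vla_incl": volumetry.volumetric_leaf_area(v_l, t_l),
            "vla_excl": volumetry.volumetric_leaf_area(v_l, t_l, v_m),
        }
        if render:
            img = synthesis.render_scan(spec, dpi, rng=rng)
            res = optical_area(img)
            row["sp"] = res.pixel_count
            row["dpi"] = dpi
            row["ola"] = res.ola_mm2
        rows.append(row)
    return pd.DataFrame(rows)


def vla_ola_experiment(
    seed: int, *, n: int = 14, **overrides
) -> tuple[pd.DataFrame, AgreementReport, AgreementReport]:
    """VLA vs OLA agreement on one simulated specimen set.

    Returns the per-specimen table and the agreement of VLA against OLA
    with the midrib volume included and excluded.
    """
    params = {**_DEFAULTS, **overrides}
    specimens = synthesis.sample_study_set(n, seed=seed)
    df = measure_specimens(specimens, seed=seed + 1, **params)
    rep_incl = agreement_report(df["ola"], df["vla_incl"])
    rep_excl = agreement_report(df["ola"], df["vla_excl"])
    return df, rep_incl, rep_excl


def resolution_experiment(
    seed: int, *, n: int = 14,
    dpis: tuple[float, ...] = (200.0, 300.0, 400.0, 600.0, 800.0, 1000.0, 1200.0),
    reference_dpi: float = 1200.0,
) -> pd.DataFrame:
    """Optical-area agreement across scan resolutions for one specimen set."""
    specimens = synthesis.sample_study_set(n, seed=seed)
    return resolution_study(specimens, dpis, reference_dpi, seed=seed + 1)


def thickness_experiment(
    seed: int, *, population_n: int = 35, mean_mm: float = 0.25, cv: float = 0.12,
    k: int = 5, n_groups: int = 100,
) -> ThicknessSamplingResult:
    """The thickness-sampling error experiment on a log-normal population."""
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv * cv)
    pop = np.exp(np.log(mean_mm) - sigma2 / 2.0
                 + np.sqrt(sigma2) * rng.standard_normal(population_n))
    return thickness_sampling_experiment(pop, k=k, n_groups=n_groups,
                                         seed=seed + 1)


def volume_area_correlation(
    seed: int, *, n: int = 14, thickness_cv: float = 0.05, dpi: float = 1200.0,
) -> tuple[float, float]:
    """Pearson r between true leaf volume and optical area for a
    within-harvest sample (little thickness variation among pieces).

    Returns ``(r_incl, r_excl)`` for volume with and without the midrib.
    """
    specimens = synthesis.sample_study_set(n, seed=seed,
                                           thickness_cv=thickness_cv)
    rng = np.random.default_rng(seed + 1)
    v_incl, v_excl, olas = [], [], []
    for spec in specimens:
        v_incl.append(synthesis.true_volume(spec, include_midrib=True))
        v_excl.append(synthesis.true_volume(spec, include_midrib=False))
        olas.append(optical_area(synthesis.render_scan(spec, dpi, rng=rng)).ola_mm2)
    return pearson(v_incl, olas), pearson(v_excl, olas)
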