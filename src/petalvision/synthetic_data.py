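"""Synthetic petal spectra, petal areas and hourly O₃ series.

The generator emulates anthocyanin-type petals: a reflectance trough near
550 nm (anthocyanin absorption), a UV bump near 380 nm, and a steep rise
beyond ~650 nm to a NIR plateau — so the anthocyanin reflectance index is
positive and the trough/peak structure the analysis expects is present.

Treatment effects mirror an OTC ozone-fumigation design:

* overall reflectance scaling increasing CFA → NFA → FU+ (bleaching under
  exposure);
* an extra anthocyanin-trough deepening (higher ARI) in ambient-level
  ozone (NFA), the non-linear pigment response;
* petal-area multipliers below 1 under exposure (defaults 0.802 for NFA
  and 0.750 for FU+, i.e. 19.8% and 25% mean-area reductions vs CFA);
* the chamber-less AMB treatment mirrors NFA (no chamber effect on petal
  traits), so AMB-vs-NFA comparisons are null by construction.

Plant-to-plant variation enters additively on the spectrum scale and
multiplicatively (lognormal) on petal area; petal-level area noise is
lognormal with a fixed coefficient of variation.  Every random stream is
derived from one dataset seed with per-plant substreams, so outputs are
byte-identical across runs and stable when only one treatment's
configuration changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet, make_grid

__all__ = [
    "SpectrumModelParams",
    "TreatmentEffects",
    "SimConfig",
    "simulate_petal_spectrum",
    "simulate_dataset",
    "simulate_o3_series",
    "expected_clean_spectrum",
    "expected_ari",
    "expected_aot40",
]


@dataclass(frozen=True)
class SpectrumModelParams:
    """Shape parameters of the noise-free petal reflectance model.

    R(λ) = scale · [base(λ) − depth·G(λ; 550, width) + uv_amp·G(λ; 380, uv_width)]

    where base(λ) ramps from ``baseline`` to ``nir_plateau`` across the
    red edge and G is a unit-height Gaussian.  Units: reflectance
    fraction (white = 1), wavelengths nm.
    """

    baseline: float = 0.45
    anthocyanin_center_nm: float = 550.0
    anthocyanin_width_nm: float = 60.0
    anthocyanin_depth: float = 0.25
    uv_center_nm: float = 380.0
    uv_width_nm: float = 25.0
    uv_amplitude: float = 0.06
    nir_plateau: float = 0.85
    red_edge_nm: float = 680.0
    red_edge_width_nm: float = 30.0
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.anthocyanin_depth < 1.0:
            raise ValueError("anthocyanin depth must be in [0, 1)")
        if self.baseline <= 0 or self.nir_plateau <= 0:
            raise ValueError("reflectance levels must be positive")


@dataclass(frozen=True)
class TreatmentEffects:
    """Per-treatment effect sizes calibrated to the OTC study conditions."""

    reflectance_scale: dict = field(
        default_factory=lambda: {"CFA": 1.00, "NFA": 1.08, "FU+": 1.15, "AMB": 1.08}
    )
    ari_depth_shift: dict = field(
        default_factory=lambda: {"CFA": 0.0, "NFA": 0.06, "FU+": 0.0, "AMB": 0.06}
    )
    area_multiplier: dict = field(
        default_factory=lambda: {"CFA": 1.000, "NFA": 0.802, "FU+": 0.750, "AMB": 0.802}
    )
    plant_sd: float = 0.05
    base_area_cm2: float = 0.40
    area_cv: float = 0.25

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.reflectance_scale.values()):
            raise ValueError("reflectance scales must be positive")
        if any(v <= 0 for v in self.area_multiplier.values()):
            raise ValueError("area multipliers must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Design of a simulated dataset (defaults mirror the field design:
    four treatments, two plants each, nine petals per plant, 3 nm grid)."""

    treatments: tuple = ("CFA", "NFA", "FU+", "AMB")
    plants_per_treatment: int = 2
    petals_per_plant: int = 9
    grid_lo_nm: float = 325.0
    grid_hi_nm: float = 1075.0
    grid_step_nm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plants_per_treatment < 1 or self.petals_per_plant < 1:
            raise ValueError("counts must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return make_grid(self.grid_lo_nm, self.grid_hi_nm, self.grid_step_nm)


def _gauss(lam, center, width):
    return np.exp(-0.5 * ((lam - center) / width) ** 2)


def expected_clean_spectrum(
    grid_nm,
    params: SpectrumModelParams,
    effects: TreatmentEffects,
    treatment: str,
    plant_scale_offset: float = 0.0,
) -> np.ndarray:
    """Noise-free generator reflectance (closed form, before clipping)."""
    lam = np.asarray(grid_nm, dtype=float)
    base = params.baseline + (params.nir_plateau - params.baseline) / (
        1.0 + np.exp(-(lam - params.red_edge_nm) / params.red_edge_width_nm)
    )
    depth = params.anthocyanin_depth + effects.ari_depth_shift[treatment]
    shape = (
        base
        - depth * _gauss(lam, params.anthocyanin_center_nm, params.anthocyanin_width_nm)
        + params.uv_amplitude * _gauss(lam, params.uv_center_nm, params.uv_width_nm)
    )
    scale = effects.reflectance_scale[treatment] + plant_scale_offset
    return scale * shape


def expected_ari(
    params: SpectrumModelParams, effects: TreatmentEffects, treatment: str
) -> float:
    """Closed-form ARI implied by the noise-free generator ordinates."""
    r550, r700, r800 = expected_clean_spectrum(
        np.array([550.0, 700.0, 800.0]), params, effects, treatment
    )
    return (r800 / r550) - (r800 / r700)


def simulate_petal_spectrum(
    params: SpectrumModelParams,
    effects: TreatmentEffects,
    treatment: str,
    plant_scale_offset: float,
    rng: np.random.Generator,
    grid_nm=None,
    meta: dict | None = None,
) -> Spectrum:
    """One noisy petal spectrum; guarantees a 550 nm trough and R800 > R550.

    Raises if the parameter combination drives the clean reflectance
    non-positive on more than 1% of the grid (clipping would then distort
    the shape instead of trimming rare noise excursions).
    """
    lam = np.asarray(
        make_grid(325.0, 1075.0, 3.0) if grid_nm is None else grid_nm, dtype=float
    )
    clean = expected_clean_spectrum(lam, params, effects, treatment, plant_scale_offset)
    if np.mean(clean <= 0) > 0.01:
        raise ValueError(
            "parameters drive reflectance non-positive on more than 1% of the grid"
        )
    noisy = clean + rng.normal(0.0, params.noise_sd, size=lam.size)
    r = np.clip(noisy, 1e-6, 1.0)
    return Spectrum(lam, r, dict(meta or {}, treatment=treatment))


def simulate_dataset(
    config: SimConfig,
    params: SpectrumModelParams | None = None,
    effects: TreatmentEffects | None = None,
):
    """Simulate a full petal dataset: spectra plus metadata/areas table.

    Returns ``(SpectrumSet, DataFrame)`` where the table has columns
    ``petal_id, plant_id, treatment, area_cm2``.  Per-plant RNG substreams
    are seeded as (seed, treatment index, plant index), making output
    fully reproducible and insensitive to the order of other plants.
    """
    params = params or SpectrumModelParams()
    effects = effects or TreatmentEffects()
    grid = config.grid
    sigma_area = math.sqrt(math.log(1.0 + effects.area_cv**2))
    spectra, rows = [], []
    for t_idx, treatment in enumerate(config.treatments):
        for p_idx in range(config.plants_per_treatment):
            rng = np.random.default_rng([config.seed, t_idx, p_idx])
            plant_id = f"{treatment}-p{p_idx + 1}"
            plant_scale = rng.normal(0.0, effects.plant_sd)
            plant_area = math.exp(rng.normal(0.0, effects.plant_sd))
            for f_idx in range(config.petals_per_plant):
                petal_id = f"{plant_id}-f{f_idx + 1}"
                sp = simulate_petal_spectrum(
                    params,
                    effects,
                    treatment,
                    plant_scale,
                    rng,
                    grid,
                    meta={"petal_id": petal_id, "plant_id": plant_id},
                )
                # lognormal area noise, mean-one (areas are positive, right-skewed)
                noise = math.exp(rng.normal(-0.5 * sigma_area**2, sigma_area))
                area = (
                    effects.base_area_cm2
                    * effects.area_multiplier[treatment]
                    * plant_area
                    * noise
                )
                sp.meta["area_cm2"] = area
                spectra.append(sp)
                rows.append(
                    {
                        "petal_id": petal_id,
                        "plant_id": plant_id,
                        "treatment": treatment,
                        "area_cm2": area,
                    }
                )
    return SpectrumSet(spectra, grid), pd.DataFrame(rows)


# --------------------------------------------------------------------------
# hourly ozone series


def _diurnal_profile() -> np.ndarray:
    """Unit diurnal shape: zero at night, sine bump peaking early afternoon."""
    h = np.arange(24)
    return np.clip(np.sin(math.pi * (h - 6.0) / 14.0), 0.0, None)


def simulate_o3_series(
    days: int,
    window_mean_target: float,
    shape: str = "diurnal",
    noise_sd: float = 0.0,
    seed: int | None = None,
    start: str = "2019-04-03",
) -> pd.Series:
    """Hourly O₃ series whose 07-15 h mean equals ``window_mean_target``.

    ``shape="diurnal"`` scales a day-time sine profile so the daylight
    window mean hits the target exactly (closed-form scaling);
    ``shape="constant"`` holds the target value around the clock.
    Optional Gaussian noise is clipped at zero.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    if window_mean_target < 0:
        raise ValueError("window mean target must be non-negative")
    idx = pd.date_range(start=start, periods=24 * days, freq="h")
    if shape == "constant":
        values = np.full(24 * days, float(window_mean_target))
    elif shape == "diurnal":
        prof = _diurnal_profile()
        win = prof[7:15]
        values = np.tile(window_mean_target * prof / win.mean(), days)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, values.size), 0.0, None)
    return pd.Series(values, index=idx, name="o3_nl_l")


def expected_aot40(
    days: int, window_mean_target: float, shape: str = "diurnal", threshold: float = 40.0
) -> float:
    """Closed-form AOT40 of the noise-free generator series."""
    if shape == "constant":
        hourly = np.full(8, window_mean_target)
    else:
        prof = _diurnal_profile()
        win = prof[7:15]
        hourly = window_mean_target * win / win.mean()
    return float(days * np.clip(hourly - threshold, 0.0, None).sum())
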