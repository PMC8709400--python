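"""Insect color-space models: quantum catches, von Kries adaptation, and
bee hexagon / fly categorical / butterfly tetrahedral loci.

The chain for every guild is the same.  For each photoreceptor i the raw
quantum catch of a stimulus R(λ) under illuminant I(λ) is

    Q_i = ∫ R(λ) S_i(λ) I(λ) dλ        (trapezoidal on the working grid)

with S_i the receptor sensitivity.  Receptors adapt to the background
(green foliage here), which von Kries normalization expresses as
q_i = Q_i / Q_i(background): a petal spectrally identical to foliage has
q_i = 1 on every receptor and sits at the achromatic point of every
space.  Guild-specific opponent mappings then place each petal:

* bee — hyperbolic transduction E = q/(q+1) on three receptors, mapped to
  the 2-D color hexagon (distance from centre < 1 always);
* fly — categorical space from two opponent pairs, colors = quadrants;
* butterfly — catches of four receptors normalized to sum 1, plotted in a
  regular tetrahedron (centroid = achromatic).

Receptor sensitivities are generated from the Govardovskii A1 pigment
template parameterized only by λmax, so the whole model is configurable
from `defaults.yaml` without bundled instrument curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from ._illuminants import d65_quanta, green_leaf_reflectance
from .spectra import Spectrum, SpectrumSet, make_grid

__all__ = [
    "load_default_config",
    "PhotoreceptorSensitivity",
    "VisualSystemSpec",
    "QuantumCatchSet",
    "HexagonLocus",
    "CategoricalLocus",
    "TetrahedronLocus",
    "pigment_template",
    "build_visual_system",
    "quantum_catch",
    "von_kries",
    "catch_set",
    "bee_hexagon",
    "fly_categorical",
    "butterfly_tetrahedron",
    "luminance",
    "loci_table",
]

GUILDS = ("bee", "fly", "butterfly")


def load_default_config() -> dict:
    """Packaged visual-model configuration (λmax values, label maps...)."""
    with resources.files("petalvision").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class PhotoreceptorSensitivity:
    """Peak-normalized spectral sensitivity S(λ) of one receptor class."""

    name: str
    lambda_max_nm: float
    grid_nm: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        self.grid_nm = np.asarray(self.grid_nm, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        if np.any(~np.isfinite(self.sensitivity)) or np.any(self.sensitivity < 0):
            raise ValueError("sensitivity must be finite and non-negative")
        if not math.isclose(float(self.sensitivity.max()), 1.0, rel_tol=1e-9):
            raise ValueError("sensitivity must be peak-normalized to 1")


def pigment_template(lambda_max_nm: float, grid_nm) -> np.ndarray:
    """A1 visual-pigment absorbance template (Govardovskii et al. form).

    α-band::

        S_α(λ) = 1 / (exp[A(a − x)] + exp[B(b − x)] + exp[C(c − x)] + D)

    with x = λmax/λ, A=69.7, B=28, C=−14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459·exp[−(λmax − 300)²/11940]; plus a Gaussian β-band
    with amplitude 0.26 at λ = 189 + 0.315·λmax and width −40.5 + 0.195·λmax.
    The sum is peak-normalized.  Valid for 300 ≤ λmax ≤ 700 nm.
    """
    if not 300.0 <= lambda_max_nm <= 700.0:
        raise ValueError(f"λmax={lambda_max_nm:g} nm outside 300-700 nm")
    lam = np.asarray(grid_nm, dtype=float)
    x = lambda_max_nm / lam
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max_nm - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max_nm
    width_beta = -40.5 + 0.195 * lambda_max_nm
    beta = 0.26 * np.exp(-(((lam - lam_beta) / width_beta) ** 2))
    s = alpha + beta
    return s / s.max()


@dataclass
class VisualSystemSpec:
    """A pollinator guild's receptor set plus viewing conditions.

    ``illuminant`` is relative quanta (D65 by default), ``background`` the
    adapting reflectance (green foliage), both sampled on ``grid_nm``.
    """

    guild: str
    receptors: list
    illuminant: np.ndarray
    background: np.ndarray
    grid_nm: np.ndarray
    luminance_receptor: str
    config: dict

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"unknown guild {self.guild!r}")
        expected = {"bee": 3, "fly": 4, "butterfly": 4}[self.guild]
        if len(self.receptors) != expected:
            raise ValueError(
                f"{self.guild} model needs {expected} receptors, got {len(self.receptors)}"
            )
        if np.any(np.asarray(self.illuminant) <= 0) or np.any(
            np.asarray(self.background) <= 0
        ):
            raise ValueError("illuminant and background must be strictly positive")
        names = [r.name for r in self.receptors]
        if self.luminance_receptor not in names:
            raise ValueError(
                f"luminance receptor {self.luminance_receptor!r} not in {names}"
            )

    @property
    def receptor_names(self) -> list:
        return [r.name for r in self.receptors]


def build_visual_system(
    guild: str,
    grid_nm=None,
    config: dict | None = None,
) -> VisualSystemSpec:
    """Assemble the default visual model of a guild on a 1 nm working grid.

    All inputs are trimmed to the configured range (325-700 nm by default):
    insect photoreceptors do not extend into the NIR, so the long petal
    spectra are cut before catch integration.
    """
    cfg = config or load_default_config()
    if guild not in cfg["guilds"]:
        raise ValueError(f"unknown guild {guild!r}; configured: {list(cfg['guilds'])}")
    lo, hi = cfg.get("trim_nm", [325, 700])
    if grid_nm is None:
        grid_nm = make_grid(float(lo), float(hi))
    grid_nm = np.asarray(grid_nm, dtype=float)
    gcfg = cfg["guilds"][guild]
    receptors = [
        PhotoreceptorSensitivity(
            name, float(lmax), grid_nm, pigment_template(float(lmax), grid_nm)
        )
        for name, lmax in gcfg["receptors"].items()
    ]
    # longest-wavelength receptor carries the achromatic (luminance) channel
    lum = gcfg.get("luminance_receptor") or max(
        receptors, key=lambda r: r.lambda_max_nm
    ).name
    return VisualSystemSpec(
        guild=guild,
        receptors=receptors,
        illuminant=d65_quanta(grid_nm),
        background=green_leaf_reflectance(grid_nm),
        grid_nm=grid_nm,
        luminance_receptor=lum,
        config=cfg,
    )


def quantum_catch(reflectance, sensitivity, illuminant, grid_nm) -> float:
    """Q = ∫ R·S·I dλ by the trapezoid rule on a common grid."""
    r = np.asarray(reflectance, dtype=float)
    s = np.asarray(sensitivity, dtype=float)
    i = np.asarray(illuminant, dtype=float)
    g = np.asarray(grid_nm, dtype=float)
    if not (len(r) == len(s) == len(i) == len(g)):
        raise ValueError("reflectance, sensitivity, illuminant and grid lengths differ")
    return float(np.trapezoid(r * s * i, g))


def von_kries(q_stimulus: float, q_background: float) -> float:
    """Adapted catch q = Q_stimulus / Q_background (background must be > 0)."""
    if q_background <= 0:
        raise ValueError("background quantum catch must be positive")
    return q_stimulus / q_background


@dataclass
class QuantumCatchSet:
    """Raw catches Q, adapted catches q, and bee excitations E per receptor."""

    petal_id: str | None
    raw: dict
    adapted: dict
    excitation: dict  # E = q/(q+1); meaningful for the bee model

    def __post_init__(self) -> None:
        for name, q in self.adapted.items():
            if q <= 0:
                raise ValueError(f"non-positive adapted catch for receptor {name!r}")


def catch_set(spectrum: Spectrum, system: VisualSystemSpec) -> QuantumCatchSet:
    """Quantum catches of one petal under a guild's visual model.

    The petal spectrum is interpolated onto the system grid (it must cover
    it) and every receptor's catch is computed for petal and background.
    """
    if spectrum.lo_nm > system.grid_nm[0] or spectrum.hi_nm < system.grid_nm[-1]:
        raise ValueError(
            f"petal {spectrum.petal_id!r} spans {spectrum.lo_nm:g}-"
            f"{spectrum.hi_nm:g} nm, not covering the model grid "
            f"{system.grid_nm[0]:g}-{system.grid_nm[-1]:g} nm"
        )
    r = np.interp(system.grid_nm, spectrum.wavelengths_nm, spectrum.reflectance)
    raw, adapted, excitation = {}, {}, {}
    for rec in system.receptors:
        q_s = quantum_catch(r, rec.sensitivity, system.illuminant, system.grid_nm)
        q_b = quantum_catch(
            system.background, rec.sensitivity, system.illuminant, system.grid_nm
        )
        if q_s <= 0:
            raise ValueError(
                f"petal {spectrum.petal_id!r}: zero quantum catch on {rec.name!r}"
            )
        raw[rec.name] = q_s
        adapted[rec.name] = von_kries(q_s, q_b)
        excitation[rec.name] = adapted[rec.name] / (adapted[rec.name] + 1.0)
    return QuantumCatchSet(spectrum.petal_id, raw, adapted, excitation)


# --------------------------------------------------------------------------
# guild-specific loci


@dataclass(frozen=True)
class HexagonLocus:
    petal_id: str | None
    x: float
    y: float
    sector: str


@dataclass(frozen=True)
class CategoricalLocus:
    petal_id: str | None
    cx: float
    cy: float
    category: str  # one of the four quadrant names, or "boundary"


@dataclass(frozen=True)
class TetrahedronLocus:
    petal_id: str | None
    relative: dict  # receptor -> relative catch, sums to 1
    x: float
    y: float
    z: float


_DEFAULT_SECTORS = ["Green", "Blue-Green", "Blue", "UV-Blue", "UV", "UV-Green"]


def bee_hexagon(
    q_uv: float,
    q_blue: float,
    q_green: float,
    sector_labels=None,
    petal_id=None,
) -> HexagonLocus:
    """Color-hexagon locus from three adapted catches.

    E = q/(q+1) per receptor, then x = (√3/2)(E_G − E_UV),
    y = E_B − (E_UV + E_G)/2.  With 0 < E < 1 the locus always lies inside
    the unit hexagon.  The sector is the 60° wedge containing the angular
    position (labels configurable; achromatic center reported as such).
    """
    for q in (q_uv, q_blue, q_green):
        if q <= 0:
            raise ValueError("adapted catches must be positive")
    e_uv, e_b, e_g = (q / (q + 1.0) for q in (q_uv, q_blue, q_green))
    x = (math.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    labels = sector_labels or _DEFAULT_SECTORS
    if abs(x) < 1e-12 and abs(y) < 1e-12:
        sector = "achromatic"
    else:
        theta = math.degrees(math.atan2(y, x))
        sector = labels[int(((theta + 60.0) % 360.0) // 60.0)]
    return HexagonLocus(petal_id, x, y, sector)


_DEFAULT_FLY_MAP = {
    "+,+": "Fly UV",
    "-,+": "Fly Purple",
    "-,-": "Fly Blue",
    "+,-": "Fly Yellow",
}


def fly_categorical(
    q_r7p: float,
    q_r7y: float,
    q_r8p: float,
    q_r8y: float,
    quadrant_map: dict | None = None,
    petal_id=None,
) -> CategoricalLocus:
    """Categorical fly locus from the two R7−R8 opponent differences.

    cx = q(R7p) − q(R8p), cy = q(R7y) − q(R8y).  The color category is a
    pure sign pattern; a coordinate exactly at 0 is labelled "boundary"
    rather than being assigned to a quadrant.
    """
    for q in (q_r7p, q_r7y, q_r8p, q_r8y):
        if q <= 0:
            raise ValueError("adapted catches must be positive")
    cx = q_r7p - q_r8p
    cy = q_r7y - q_r8y
    if cx == 0.0 or cy == 0.0:
        category = "boundary"
    else:
        key = f"{'+' if cx > 0 else '-'},{'+' if cy > 0 else '-'}"
        category = (quadrant_map or _DEFAULT_FLY_MAP)[key]
    return CategoricalLocus(petal_id, cx, cy, category)


_DEFAULT_VERTICES = {
    "u": np.array([0.0, 0.0, 1.0]),
    "s": np.array([2.0 * math.sqrt(2.0) / 3.0, 0.0, -1.0 / 3.0]),
    "m": np.array([-math.sqrt(2.0) / 3.0, math.sqrt(2.0 / 3.0), -1.0 / 3.0]),
    "l": np.array([-math.sqrt(2.0) / 3.0, -math.sqrt(2.0 / 3.0), -1.0 / 3.0]),
}


def butterfly_tetrahedron(
    q_u: float,
    q_s: float,
    q_m: float,
    q_l: float,
    vertices: dict | None = None,
    petal_id=None,
) -> TetrahedronLocus:
    """Tetrahedral locus: catches normalized to sum 1, then vertex-weighted.

    Vertices form a regular tetrahedron with unit circumradius and centroid
    at the origin, one vertex per receptor (u "up").  Equal catches map to
    the centroid; a pure single-receptor stimulus maps to its vertex.
    """
    qs = {"u": q_u, "s": q_s, "m": q_m, "l": q_l}
    total = sum(qs.values())
    if total <= 0 or any(q < 0 for q in qs.values()):
        raise ValueError("catches must be non-negative with a positive sum")
    rel = {k: q / total for k, q in qs.items()}
    verts = vertices or _DEFAULT_VERTICES
    xyz = sum(rel[k] * np.asarray(verts[k], dtype=float) for k in rel)
    return TetrahedronLocus(petal_id, rel, float(xyz[0]), float(xyz[1]), float(xyz[2]))


def luminance(catches: QuantumCatchSet, system: VisualSystemSpec) -> float:
    """Achromatic signal: adapted catch of the longest-wavelength receptor."""
    name = system.luminance_receptor
    if name not in catches.adapted:
        raise ValueError(f"receptor {name!r} missing from the catch set")
    return catches.adapted[name]


def loci_table(sset: SpectrumSet, system: VisualSystemSpec) -> pd.DataFrame:
    """Per-petal color loci of a whole spectrum set under one guild's model.

    Columns depend on the guild: hexagon (x, y, sector), categorical
    (cx, cy, category) or tetrahedral (u, s, m, l, x, y, z); the adapted
    catches and the luminance channel are always included.
    """
    cfg = system.config
    rows = []
    for sp in sset:
        cs = catch_set(sp, system)
        row = {
            "petal_id": sp.petal_id,
            "plant_id": sp.meta.get("plant_id"),
            "treatment": sp.meta.get("treatment"),
        }
        q = cs.adapted
        for name, val in q.items():
            row[f"q_{name}"] = val
        if system.guild == "bee":
            locus = bee_hexagon(
                q["uv"], q["blue"], q["green"],
                sector_labels=cfg.get("hexagon_sectors"),
                petal_id=sp.petal_id,
            )
            row.update(x=locus.x, y=locus.y, sector=locus.sector)
        elif system.guild == "fly":
            locus = fly_categorical(
                q["r7p"], q["r7y"], q["r8p"], q["r8y"],
                quadrant_map=cfg.get("fly_quadrants"),
                petal_id=sp.petal_id,
            )
            row.update(cx=locus.cx, cy=locus.cy, category=locus.category)
        else:
            verts = cfg.get("tetrahedron_vertices")
            if verts is not None:
                verts = {k: np.asarray(v, dtype=float) for k, v in verts.items()}
            locus = butterfly_tetrahedron(
                q["u"], q["s"], q["m"], q["l"], vertices=verts, petal_id=sp.petal_id
            )
            row.update(
                u=locus.relative["u"], s=locus.relative["s"],
                m=locus.relative["m"], l=locus.relative["l"],
                x=locus.x, y=locus.y, z=locus.z,
            )
        row["luminance"] = luminance(cs, system)
        rows.append(row)
    return pd.DataFrame(rows)
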