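"""Anthocyanin reflectance index (ARI) and point-wavelength reflectances.

ARI = (R800 / R550) - (R800 / R700), with R(λ) the relative reflectance
at λ nm.  Anthocyanins absorb near 550 nm, so higher pigment content
depresses R550 and raises the index; the R700 term corrects for
chlorophyll and scattering.  The index is invariant to a common scaling
of the whole spectrum (ratios cancel), which makes it robust to
illumination geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet, max_peak_height

__all__ = ["PigmentIndexResult", "reflectance_at", "ari", "index_table"]


@dataclass(frozen=True)
class PigmentIndexResult:
    petal_id: str | None
    ari: float
    r550: float
    r700: float
    r800: float


class UndefinedIndexError(ValueError):
    """ARI is undefined for this petal (zero reflectance in a ratio term)."""


def reflectance_at(spectrum: Spectrum, lambda_nm: float) -> float:
    """Interpolated R(λ); exact when λ is on the grid, error outside it."""
    if lambda_nm < spectrum.lo_nm or lambda_nm > spectrum.hi_nm:
        raise ValueError(
            f"λ={lambda_nm:g} nm outside spectrum range "
            f"{spectrum.lo_nm:g}-{spectrum.hi_nm:g} nm"
        )
    return float(np.interp(lambda_nm, spectrum.wavelengths_nm, spectrum.reflectance))


def ari(spectrum: Spectrum, band_halfwidth_nm: float = 0.0) -> PigmentIndexResult:
    """Anthocyanin reflectance index of one petal spectrum.

    By default the three ordinates are point reflectances at exactly
    550/700/800 nm (after 1 nm resampling upstream).  A ±``band_halfwidth_nm``
    band mean around each ordinate is available for noisy spectra; it is
    off (0) by default because the index is defined on point wavelengths.
    """

    def _r(lam: float) -> float:
        if band_halfwidth_nm <= 0:
            return reflectance_at(spectrum, lam)
        lo = max(lam - band_halfwidth_nm, spectrum.lo_nm)
        hi = min(lam + band_halfwidth_nm, spectrum.hi_nm)
        mask = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm <= hi)
        return float(np.mean(spectrum.reflectance[mask]))

    r550, r700, r800 = _r(550.0), _r(700.0), _r(800.0)
    if r550 <= 0 or r700 <= 0:
        raise UndefinedIndexError(
            f"petal {spectrum.petal_id!r}: ARI undefined "
            f"(R550={r550:g}, R700={r700:g})"
        )
    value = (r800 / r550) - (r800 / r700)
    return PigmentIndexResult(spectrum.petal_id, value, r550, r700, r800)


def index_table(
    sset: SpectrumSet,
    peak_window=(325.0, 600.0),
    band_halfwidth_nm: float = 0.0,
) -> pd.DataFrame:
    """Per-petal table of ARI, its ordinates and the peak-height metric.

    Petals with an undefined ARI are reported with NaN and a note rather
    than silently dropped.
    """
    rows = []
    for sp in sset:
        row = {
            "petal_id": sp.petal_id,
            "plant_id": sp.meta.get("plant_id"),
            "treatment": sp.meta.get("treatment"),
        }
        try:
            res = ari(sp, band_halfwidth_nm)
            row.update(ari=res.ari, r550=res.r550, r700=res.r700, r800=res.r800, note="")
        except UndefinedIndexError as exc:
            row.update(ari=np.nan, r550=np.nan, r700=np.nan, r800=np.nan, note=str(exc))
        if sp.lo_nm <= peak_window[0] and sp.hi_nm >= peak_window[1]:
            pk = max_peak_height(sp, peak_window)
            row["peak_height_325_600"] = pk.height
            row["peak_wavelength"] = pk.wavelength_nm
        rows.append(row)
    return pd.DataFrame(rows)
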