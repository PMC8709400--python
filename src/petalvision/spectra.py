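"""Petal reflectance spectra: containers, IO, resampling and peak metrics.

Spectra are relative reflectance against a white standard (white = 1.0).
Field spectroradiometers commonly report percent; the CSV reader converts
at the boundary so everything downstream works on a single internal unit.

Instruments like the FieldSpec deliver ~3 nm native resolution over
325-1075 nm; pigment indices address exact wavelengths (550/700/800 nm),
so spectra are linearly resampled onto a 1 nm grid before index work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TREATMENTS = ("AMB", "CFA", "NFA", "FU+")

__all__ = [
    "TREATMENTS",
    "Spectrum",
    "SpectrumSet",
    "PeakResult",
    "read_spectra_csv",
    "write_spectra_csv",
    "resample",
    "trim",
    "average_spectra",
    "max_peak_height",
    "boxcar_smooth",
    "make_grid",
]


@dataclass
class Spectrum:
    """One petal's relative reflectance on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    reflectance
        Relative reflectance (unitless fraction, white reference = 1.0),
        same length as ``wavelengths_nm``, finite and non-negative.
    meta
        Optional per-petal metadata: ``petal_id``, ``plant_id``,
        ``treatment`` (one of AMB/CFA/NFA/FU+) and ``area_cm2``.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths_nm.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if len(self.wavelengths_nm) != len(self.reflectance):
            raise ValueError(
                f"length mismatch: {len(self.wavelengths_nm)} wavelengths vs "
                f"{len(self.reflectance)} reflectance values"
            )
        if len(self.wavelengths_nm) == 0:
            raise ValueError("empty spectrum")
        dl = np.diff(self.wavelengths_nm)
        if np.any(dl <= 0):
            i = int(np.argmax(dl <= 0))
            raise ValueError(
                "wavelengths not strictly increasing at sample "
                f"{i + 1} (λ={self.wavelengths_nm[i + 1]:g} after "
                f"λ={self.wavelengths_nm[i]:g})"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite reflectance values")
        if np.any(self.reflectance < 0):
            raise ValueError("negative reflectance values")
        tr = self.meta.get("treatment")
        if tr is not None and tr not in TREATMENTS:
            raise ValueError(f"unknown treatment {tr!r}; expected one of {TREATMENTS}")

    @property
    def petal_id(self) -> str | None:
        return self.meta.get("petal_id")

    @property
    def lo_nm(self) -> float:
        return float(self.wavelengths_nm[0])

    @property
    def hi_nm(self) -> float:
        return float(self.wavelengths_nm[-1])

    def copy_with(self, wavelengths_nm=None, reflectance=None) -> "Spectrum":
        return Spectrum(
            self.wavelengths_nm if wavelengths_nm is None else wavelengths_nm,
            self.reflectance if reflectance is None else reflectance,
            dict(self.meta),
        )


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one wavelength grid.

    Petal ids must be unique; the shared grid makes matrix operations
    (multivariate statistics, color modelling) well-defined.
    """

    spectra: list
    grid_nm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("SpectrumSet needs at least one spectrum")
        if self.grid_nm is None:
            self.grid_nm = self.spectra[0].wavelengths_nm
        self.grid_nm = np.asarray(self.grid_nm, dtype=float)
        for sp in self.spectra:
            if len(sp.wavelengths_nm) != len(self.grid_nm) or not np.allclose(
                sp.wavelengths_nm, self.grid_nm
            ):
                raise ValueError(
                    f"spectrum {sp.petal_id!r} is not on the shared grid"
                )
        ids = [sp.petal_id for sp in self.spectra]
        if None in ids:
            raise ValueError("every spectrum in a set needs a petal_id")
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValueError(f"duplicate petal ids: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, petal_id: str) -> Spectrum:
        for sp in self.spectra:
            if sp.petal_id == petal_id:
                return sp
        raise KeyError(petal_id)

    @property
    def petal_ids(self) -> list:
        return [sp.petal_id for sp in self.spectra]

    def to_matrix(self) -> pd.DataFrame:
        """Petals x wavelengths reflectance matrix (index = petal ids)."""
        return pd.DataFrame(
            np.vstack([sp.reflectance for sp in self.spectra]),
            index=self.petal_ids,
            columns=self.grid_nm,
        )

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.spectra:
            row = {"petal_id": sp.petal_id}
            for k in ("plant_id", "treatment", "area_cm2"):
                if k in sp.meta:
                    row[k] = sp.meta[k]
            rows.append(row)
        return pd.DataFrame(rows)

    def map(self, fn) -> "SpectrumSet":
        """Apply ``fn`` to every spectrum; result must share one grid."""
        out = [fn(sp) for sp in self.spectra]
        return SpectrumSet(out, out[0].wavelengths_nm)


@dataclass(frozen=True)
class PeakResult:
    height: float
    wavelength_nm: float


def make_grid(lo_nm: float, hi_nm: float, step_nm: float = 1.0) -> np.ndarray:
    """Inclusive wavelength grid from ``lo`` to ``hi`` in ``step`` nm."""
    n = int(round((hi_nm - lo_nm) / step_nm))
    return lo_nm + step_nm * np.arange(n + 1)


def _attach_metadata(spectra: list, meta: pd.DataFrame | None) -> None:
    if meta is None:
        return
    if "petal_id" not in meta.columns:
        raise ValueError("metadata table needs a petal_id column")
    meta = meta.set_index(meta["petal_id"].astype(str))
    for sp in spectra:
        pid = str(sp.meta["petal_id"])
        if pid not in meta.index:
            raise ValueError(f"no metadata row for petal {pid!r}")
        row = meta.loc[pid]
        for k in ("plant_id", "treatment", "area_cm2"):
            if k in meta.columns and not pd.isna(row[k]):
                sp.meta[k] = row[k]


def read_spectra_csv(
    path,
    *,
    percent: bool = False,
    metadata=None,
    fmt: str = "auto",
) -> SpectrumSet:
    """Read petal spectra from CSV in long or wide format.

    Long format has columns ``petal_id, wavelength_nm, reflectance``;
    wide format has a wavelength column first and one column per petal
    (header row = petal ids).  ``percent=True`` divides reflectance by
    100 on input.  ``metadata`` is an optional sidecar CSV path or
    DataFrame with columns ``petal_id, plant_id, treatment[, area_cm2]``.
    """
    df = pd.read_csv(path)
    if fmt == "auto":
        fmt = (
            "long"
            if {"petal_id", "wavelength_nm", "reflectance"} <= set(df.columns)
            else "wide"
        )
    spectra = []
    if fmt == "long":
        for pid, g in df.groupby("petal_id", sort=False):
            wl = g["wavelength_nm"].to_numpy(dtype=float)
            if np.any(np.diff(wl) <= 0):
                i = int(np.argmax(np.diff(wl) <= 0))
                raise ValueError(
                    f"petal {pid!r}: duplicate or non-monotone wavelength "
                    f"{wl[i + 1]:g} nm"
                )
            r = g["reflectance"].to_numpy(dtype=float)
            spectra.append(Spectrum(wl, r / 100.0 if percent else r, {"petal_id": str(pid)}))
    elif fmt == "wide":
        wl_col = df.columns[0]
        wl = df[wl_col].to_numpy(dtype=float)
        order = None
        if np.any(np.diff(wl) <= 0):
            raise ValueError(
                f"wavelength column {wl_col!r} is not strictly increasing "
                f"(first offending row index {int(np.argmax(np.diff(wl) <= 0)) + 1})"
            )
        for col in df.columns[1:]:
            r = df[col].to_numpy(dtype=float)
            spectra.append(Spectrum(wl, r / 100.0 if percent else r, {"petal_id": str(col)}))
        del order
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if isinstance(metadata, (str, Path)):
        metadata = pd.read_csv(metadata)
    _attach_metadata(spectra, metadata)
    # grids may differ between petals in long format; a shared-grid set is
    # only built if they match, otherwise the caller resamples first
    try:
        return SpectrumSet(spectra)
    except ValueError:
        grid = spectra[0].wavelengths_nm
        raise ValueError(
            "petals are on different wavelength grids; resample onto a "
            f"common grid (e.g. {grid[0]:g}-{grid[-1]:g} nm at 1 nm) first"
        )


def write_spectra_csv(sset: SpectrumSet, path) -> None:
    """Write a set to long-format CSV (petal_id, wavelength_nm, reflectance)."""
    frames = []
    for sp in sset:
        frames.append(
            pd.DataFrame(
                {
                    "petal_id": sp.petal_id,
                    "wavelength_nm": sp.wavelengths_nm,
                    "reflectance": sp.reflectance,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def resample(spectrum: Spectrum, grid_nm) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid_nm`` (no extrapolation).

    On-grid points are preserved exactly; a requested grid outside the
    measured range raises.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    if grid_nm[0] < spectrum.lo_nm or grid_nm[-1] > spectrum.hi_nm:
        raise ValueError(
            f"grid {grid_nm[0]:g}-{grid_nm[-1]:g} nm outside measured range "
            f"{spectrum.lo_nm:g}-{spectrum.hi_nm:g} nm"
        )
    r = np.interp(grid_nm, spectrum.wavelengths_nm, spectrum.reflectance)
    return spectrum.copy_with(wavelengths_nm=grid_nm, reflectance=r)


def trim(spectrum: Spectrum, lo_nm: float, hi_nm: float) -> Spectrum:
    """Keep samples with ``lo <= λ <= hi``; metadata preserved."""
    if lo_nm >= hi_nm:
        raise ValueError("lo_nm must be < hi_nm")
    mask = (spectrum.wavelengths_nm >= lo_nm) & (spectrum.wavelengths_nm <= hi_nm)
    if not np.any(mask):
        raise ValueError(
            f"trim window {lo_nm:g}-{hi_nm:g} nm contains no samples "
            f"(spectrum spans {spectrum.lo_nm:g}-{spectrum.hi_nm:g} nm)"
        )
    return spectrum.copy_with(
        wavelengths_nm=spectrum.wavelengths_nm[mask],
        reflectance=spectrum.reflectance[mask],
    )


def average_spectra(scans: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of repeated scans on a common grid.

    Spectroradiometer protocols average repeated scans per petal (25 is a
    typical count) to suppress shot noise.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan")
    grid = scans[0].wavelengths_nm
    for s in scans[1:]:
        if len(s.wavelengths_nm) != len(grid) or not np.allclose(s.wavelengths_nm, grid):
            raise ValueError("scans are on mismatched wavelength grids")
    mean_r = np.mean([s.reflectance for s in scans], axis=0)
    return scans[0].copy_with(reflectance=mean_r)


def max_peak_height(
    spectrum: Spectrum,
    window=(325.0, 600.0),
    baseline: str = "none",
) -> PeakResult:
    """Maximum reflectance within a wavelength window and its location.

    ``baseline="none"`` (default) returns the absolute maximum of R(λ) in
    the window.  ``baseline="window_min"`` subtracts the window minimum,
    i.e. peak height above the local trough — both conventions are in use
    for pigment peak metrics, so both are exposed.
    """
    lo, hi = window
    if lo < spectrum.lo_nm or hi > spectrum.hi_nm:
        raise ValueError(
            f"window {lo:g}-{hi:g} nm outside spectrum range "
            f"{spectrum.lo_nm:g}-{spectrum.hi_nm:g} nm"
        )
    sub = trim(spectrum, lo, hi)
    i = int(np.argmax(sub.reflectance))
    height = float(sub.reflectance[i])
    if baseline == "window_min":
        height -= float(np.min(sub.reflectance))
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return PeakResult(height=height, wavelength_nm=float(sub.wavelengths_nm[i]))


def boxcar_smooth(spectrum: Spectrum, width: int = 5) -> Spectrum:
    """Optional running-mean smoothing (odd ``width`` in samples).

    Off by default everywhere in the pipeline; provided for noisy single
    scans only.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be a positive odd integer")
    if width == 1:
        return spectrum.copy_with()
    pad = width // 2
    r = np.pad(spectrum.reflectance, pad, mode="edge")
    kernel = np.ones(width) / width
    sm = np.convolve(r, kernel, mode="valid")
    return spectrum.copy_with(reflectance=sm)
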