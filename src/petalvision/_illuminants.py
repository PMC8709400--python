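"""Illuminant and background spectra for visual modelling.

D65 is the CIE standard daylight illuminant, tabulated here at 10 nm as
relative spectral power (560 nm = 100) and converted to relative quanta
(power × λ) because photoreceptors are photon counters.

The adapting background is a smooth synthetic green-foliage reflectance:
low in the blue and red, a modest peak near 555 nm, and a red-edge rise —
the canonical shape of a healthy leaf.  It is generated from a closed
form rather than tabulated so it stays strictly positive on any grid.
"""

from __future__ import annotations

import numpy as np

# CIE standard illuminant D65, relative spectral power at 10 nm intervals.
_D65_NM = np.arange(300.0, 790.0, 10.0)
_D65_POWER = np.array([
    0.0341, 3.2945, 20.2360, 37.0535, 39.9488, 44.9117, 46.6383, 52.0891,
    49.9755, 54.6482, 82.7549, 91.4860, 93.4318, 86.6823, 104.8650,
    117.0080, 117.8120, 114.8610, 115.9230, 108.8110, 109.3540, 107.8020,
    104.7900, 107.6890, 104.4050, 104.0460, 100.0000, 96.3342, 95.7880,
    88.6856, 90.0062, 89.5991, 87.6987, 83.2886, 83.6992, 80.0268,
    80.2146, 82.2778, 78.2842, 69.7213, 71.6091, 74.3490, 61.6040,
    69.8856, 75.0870, 63.5927, 46.4182, 66.8054, 63.3828,
])


def d65_quanta(grid_nm) -> np.ndarray:
    """Relative quantum flux of D65 on ``grid_nm``, peak-normalized to 1."""
    grid_nm = np.asarray(grid_nm, dtype=float)
    if grid_nm[0] < _D65_NM[0] or grid_nm[-1] > _D65_NM[-1]:
        raise ValueError("grid outside the tabulated D65 range (300-780 nm)")
    power = np.interp(grid_nm, _D65_NM, _D65_POWER)
    quanta = power * grid_nm
    return quanta / quanta.max()


def green_leaf_reflectance(grid_nm) -> np.ndarray:
    """Synthetic green-foliage reflectance on ``grid_nm`` (fraction)."""
    lam = np.asarray(grid_nm, dtype=float)
    green_peak = 0.12 * np.exp(-0.5 * ((lam - 555.0) / 45.0) ** 2)
    red_edge = 0.45 / (1.0 + np.exp(-(lam - 705.0) / 12.0))
    return 0.03 + green_peak + red_edge
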