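"""Ozone-exposure indices and open-top-chamber (OTC) microclimate summaries.

Exposure is described by AOT40 — the accumulated hourly O₃ concentration
in excess of 40 nL L⁻¹ during the daylight fumigation window — together
with the in-window and whole-day mean concentrations.  The daylight
window is 07:00-15:00, i.e. the eight hourly records whose timestamps
start at 07..14 h.

The module also carries the published summary of a Mediterranean OTC
ozone-fumigation campaign on *Erodium paularense* (four treatments:
chamber-less ambient AMB, charcoal-filtered CFA, non-filtered NFA and
supplemented FU+), used to recompute derived quantities — charcoal
filtration efficiency, relative O₃ enrichment, and the chamber effect on
temperature, humidity, VPD and light — directly from the tabulated cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExposureSummary",
    "read_series_csv",
    "aot40",
    "window_mean",
    "daily_mean",
    "window_coverage",
    "summarize_exposure",
    "filtration_efficiency",
    "percent_difference",
    "vpd_from_t_rh",
    "CAMPAIGN_OZONE",
    "CAMPAIGN_MICROCLIMATE",
    "campaign_comparisons",
]

DAYLIGHT_WINDOW = (7, 15)  # hour-start timestamps 07:00..14:00 inclusive
AOT40_THRESHOLD = 40.0  # nL L-1


@dataclass(frozen=True)
class ExposureSummary:
    treatment: str | None
    aot40_nl_l_h: float
    mean_7_15_nl_l: float
    daily_mean_nl_l: float
    n_hours: int
    n_missing: int


def read_series_csv(path) -> pd.DataFrame:
    """Hourly series CSV with columns timestamp, o3_nl_l[, t_c, rh_pct, par_umol]."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if "o3_nl_l" not in df.columns:
        raise ValueError("series needs an o3_nl_l column")
    if (df["o3_nl_l"].dropna() < 0).any():
        raise ValueError("negative O3 concentrations")
    return df.set_index("timestamp").sort_index()


def _o3(series) -> pd.Series:
    if isinstance(series, pd.DataFrame):
        series = series["o3_nl_l"]
    if not isinstance(series.index, pd.DatetimeIndex):
        raise ValueError("series needs a DatetimeIndex of hourly timestamps")
    return series


def _in_window(s: pd.Series, window) -> pd.Series:
    lo, hi = window
    return s[(s.index.hour >= lo) & (s.index.hour < hi)]


def aot40(series, threshold: float = AOT40_THRESHOLD, window=DAYLIGHT_WINDOW) -> float:
    """Σ max(0, c − threshold) over in-window hours, in nL L⁻¹ h.

    Missing (NaN) hours are skipped; use :func:`window_coverage` to report
    how many were.  Additive over disjoint time segments by construction.
    """
    s = _in_window(_o3(series), window)
    if len(s) == 0:
        raise ValueError("no hours inside the daylight window")
    return float(np.clip(s.dropna() - threshold, 0.0, None).sum())


def window_mean(series, window=DAYLIGHT_WINDOW) -> float:
    """Arithmetic mean O₃ of in-window hourly values (nL L⁻¹)."""
    s = _in_window(_o3(series), window).dropna()
    if len(s) == 0:
        raise ValueError("no hours inside the daylight window")
    return float(s.mean())


def daily_mean(series) -> float:
    """Whole-day (0-24 h) mean O₃ concentration (nL L⁻¹)."""
    s = _o3(series).dropna()
    if len(s) == 0:
        raise ValueError("empty series")
    return float(s.mean())


def window_coverage(series, window=DAYLIGHT_WINDOW) -> dict:
    """Hours present and missing inside the daylight window (no gap-filling)."""
    s = _in_window(_o3(series), window)
    return {"n_hours": int(s.notna().sum()), "n_missing": int(s.isna().sum())}


def summarize_exposure(series, treatment: str | None = None) -> ExposureSummary:
    cov = window_coverage(series)
    return ExposureSummary(
        treatment=treatment,
        aot40_nl_l_h=aot40(series),
        mean_7_15_nl_l=window_mean(series),
        daily_mean_nl_l=daily_mean(series),
        n_hours=cov["n_hours"],
        n_missing=cov["n_missing"],
    )


def filtration_efficiency(mean_cfa: float, mean_amb: float) -> float:
    """Charcoal filtration efficiency, 100·(1 − CFA/AMB), in percent."""
    if mean_amb <= 0:
        raise ValueError("ambient mean must be positive")
    return 100.0 * (1.0 - mean_cfa / mean_amb)


def percent_difference(a: float, b: float, mode: str = "relative") -> float:
    """Difference of a vs the reference b: 100·(a/b − 1) or plain a − b."""
    if mode == "relative":
        if b == 0:
            raise ValueError("reference value is zero")
        return 100.0 * (a / b - 1.0)
    if mode == "absolute":
        return a - b
    raise ValueError(f"unknown mode {mode!r}")


def vpd_from_t_rh(t_c, rh_pct):
    """Vapour pressure deficit (kPa) from air temperature and RH.

    Magnus saturation pressure es = 0.6108·exp(17.27·T/(T+237.3));
    VPD = es·(1 − RH/100).  Apply per hourly record and average the
    result: because es is convex in T, the VPD of period-mean T and RH is
    NOT the period-mean VPD, so never back-compute one from the other.
    """
    t = np.asarray(t_c, dtype=float)
    rh = np.asarray(rh_pct, dtype=float)
    if np.any(t < -20) or np.any(t > 60):
        raise ValueError("temperature outside -20..60 °C")
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError("relative humidity outside 0..100%")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    out = es * (1.0 - rh / 100.0)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# published campaign summary (37-day fumigation, daylight-window means)

CAMPAIGN_OZONE = pd.DataFrame(
    {
        "aot40_nl_l_h": [2922.7, 23.7, 2333.2, 12121.5],
        "mean_7_15_nl_l": [41.3, 21.7, 40.1, 64.6],
        "daily_mean_nl_l": [36.0, 17.3, 35.2, 48.8],
    },
    index=pd.Index(["AMB", "CFA", "NFA", "FU+"], name="treatment"),
)

CAMPAIGN_MICROCLIMATE = pd.DataFrame(
    {
        "mean_t_c": [15.8, 19.1],
        "max_t_c": [28.6, 33.6],
        "rh_pct": [52.5, 56.5],
        "vpd_kpa": [0.78, 1.06],
        "par_umol_m2_s": [841.0, 698.2],
    },
    index=pd.Index(["ambient", "otc"], name="location"),
)


def campaign_comparisons(
    ozone: pd.DataFrame | None = None,
    microclimate: pd.DataFrame | None = None,
) -> dict:
    """Derived exposure/microclimate comparisons from campaign summary cells.

    Returns, all recomputed from the tabulated values:

    * ``filtration_efficiency_pct`` — charcoal filtration vs ambient;
    * ``nfa_vs_amb_o3_pct``, ``fu_vs_amb_o3_pct`` — relative O₃ difference
      of the chambered treatments vs ambient (7-15 h means);
    * ``otc_temp_delta_c`` — chamber warming (absolute, °C);
    * ``otc_rh_delta_pct_points`` — RH change (percentage points);
    * ``otc_vpd_pct``, ``otc_par_pct`` — relative VPD and PAR change.
    """
    oz = CAMPAIGN_OZONE if ozone is None else ozone
    mc = CAMPAIGN_MICROCLIMATE if microclimate is None else microclimate
    m = oz["mean_7_15_nl_l"]
    return {
        "filtration_efficiency_pct": filtration_efficiency(m["CFA"], m["AMB"]),
        "nfa_vs_amb_o3_pct": percent_difference(m["NFA"], m["AMB"], "relative"),
        "fu_vs_amb_o3_pct": percent_difference(m["FU+"], m["AMB"], "relative"),
        "otc_temp_delta_c": percent_difference(
            mc.loc["otc", "mean_t_c"], mc.loc["ambient", "mean_t_c"], "absolute"
        ),
        "otc_rh_delta_pct_points": percent_difference(
            mc.loc["otc", "rh_pct"], mc.loc["ambient", "rh_pct"], "absolute"
        ),
        "otc_vpd_pct": percent_difference(
            mc.loc["otc", "vpd_kpa"], mc.loc["ambient", "vpd_kpa"], "relative"
        ),
        "otc_par_pct": percent_difference(
            mc.loc["otc", "par_umol_m2_s"], mc.loc["ambient", "par_umol_m2_s"], "relative"
        ),
    }
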