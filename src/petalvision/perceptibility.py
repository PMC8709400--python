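"""Perceptibility of color differences between petals for each guild.

Discrimination criteria (chosen to give at least ~60% correct choice in
behavioural work):

* flies   — two stimuli are distinguishable iff they fall in different
  quadrants of the categorical space;
* bees    — Euclidean distance in the hexagon ≥ 0.09 units;
* butterflies — difference ≥ 0.03 on a single relative-catch axis
  (the UV receptor u by default), with an alternative Euclidean mode in
  the tetrahedron.

Treatment-level scoring asks how many treated petals are perceptibly
different from a control group.  The reference can be the control-group
centroid (default: one reference region, as when an envelope is drawn
around the control cloud) or every single control petal (strict mode);
both are exposed so the choice can be sensitivity-analysed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vision_models import CategoricalLocus, HexagonLocus, TetrahedronLocus

__all__ = [
    "PerceptibilityRule",
    "PerceptibilitySummary",
    "default_rule",
    "pair_perceptible",
    "category_fractions",
    "cross_treatment_perceptibility",
]

_RULES = ("quadrant_change", "euclidean_threshold", "axis_threshold")


@dataclass(frozen=True)
class PerceptibilityRule:
    guild: str
    rule: str
    threshold: float | None = None
    axis: str | None = None

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {_RULES}")
        if self.rule != "quadrant_change" and (
            self.threshold is None or self.threshold <= 0
        ):
            raise ValueError("threshold rules need a positive threshold")


@dataclass(frozen=True)
class PerceptibilitySummary:
    treatment_pair: tuple
    guild: str
    n_compared: int
    n_perceptible: int
    fraction: float
    mode: str = "centroid"
    per_category: dict = field(default_factory=dict)

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def default_rule(guild: str, config: dict | None = None) -> PerceptibilityRule:
    """The packaged discrimination rule for a guild."""
    if config is None:
        from .vision_models import load_default_config

        config = load_default_config()
    pcfg = config["perceptibility"][guild]
    return PerceptibilityRule(
        guild=guild,
        rule=pcfg["rule"],
        threshold=pcfg.get("threshold"),
        axis=pcfg.get("axis"),
    )


def _coords(locus, rule: PerceptibilityRule) -> np.ndarray:
    if isinstance(locus, HexagonLocus):
        return np.array([locus.x, locus.y])
    if isinstance(locus, CategoricalLocus):
        return np.array([locus.cx, locus.cy])
    if isinstance(locus, TetrahedronLocus):
        if rule.rule == "axis_threshold":
            return np.array([locus.relative[rule.axis or "u"]])
        return np.array([locus.x, locus.y, locus.z])
    raise TypeError(f"not a color locus: {locus!r}")


def pair_perceptible(locus_a, locus_b, rule: PerceptibilityRule):
    """Whether two loci of one guild differ perceptibly; returns (bool, distance).

    The distance reported is the one the rule thresholds (Euclidean for
    bees, axis difference for butterflies, opponent-plane Euclidean for
    flies, where the decision itself is categorical).
    """
    if type(locus_a) is not type(locus_b):
        raise ValueError("loci come from different color spaces")
    d = float(np.linalg.norm(_coords(locus_a, rule) - _coords(locus_b, rule)))
    if rule.rule == "quadrant_change":
        if not isinstance(locus_a, CategoricalLocus):
            raise ValueError("quadrant_change applies to categorical (fly) loci")
        return locus_a.category != locus_b.category, d
    return d >= rule.threshold, d


def category_fractions(
    loci: pd.DataFrame, by: str = "treatment"
) -> pd.DataFrame:
    """Counts and percentages of fly color categories per group.

    ``loci`` is a table with a ``category`` column (see
    :func:`petalvision.vision_models.loci_table`).  Boundary loci (a
    coordinate exactly on an axis) are counted but excluded from the
    percentage denominator.
    """
    if loci.empty:
        raise ValueError("no loci to summarize")
    if "category" not in loci.columns:
        raise ValueError("expected a 'category' column (fly loci)")
    rows = []
    for group, g in loci.groupby(by, sort=True):
        if g.empty:
            raise ValueError(f"empty group {group!r}")
        counts = g["category"].value_counts()
        n_valid = int(counts.drop(index="boundary", errors="ignore").sum())
        for cat, n in counts.items():
            rows.append(
                {
                    by: group,
                    "category": cat,
                    "count": int(n),
                    "percent": (
                        np.nan if cat == "boundary" else 100.0 * n / n_valid
                    ),
                }
            )
    return pd.DataFrame(rows)


def _frame_coords(df: pd.DataFrame, rule: PerceptibilityRule) -> np.ndarray:
    """Coordinate matrix of a loci table under a rule's metric."""
    if rule.guild == "bee":
        return df[["x", "y"]].to_numpy(dtype=float)
    if rule.guild == "fly":
        return df[["cx", "cy"]].to_numpy(dtype=float)
    if rule.rule == "axis_threshold":
        return df[[rule.axis or "u"]].to_numpy(dtype=float)
    return df[["x", "y", "z"]].to_numpy(dtype=float)


def _fly_category_of_point(point: np.ndarray, quadrant_map: dict) -> str:
    cx, cy = point
    if cx == 0.0 or cy == 0.0:
        return "boundary"
    return quadrant_map[f"{'+' if cx > 0 else '-'},{'+' if cy > 0 else '-'}"]


def cross_treatment_perceptibility(
    loci_control: pd.DataFrame,
    loci_treated: pd.DataFrame,
    rule: PerceptibilityRule,
    mode: str = "centroid",
    quadrant_map: dict | None = None,
) -> PerceptibilitySummary:
    """Fraction of treated petals perceptibly different from the control group.

    ``mode="centroid"`` (default) scores each treated petal against the
    control-group centroid; ``mode="strict"`` requires perceptibility from
    every individual control petal.  For flies the criterion is a category
    change (treated boundary loci are scored as not changed).
    """
    if loci_control.empty or loci_treated.empty:
        raise ValueError("control and treated groups must both be non-empty")
    if mode not in ("centroid", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    pair = (
        _single_treatment(loci_control),
        _single_treatment(loci_treated),
    )
    xc = _frame_coords(loci_control, rule)
    xt = _frame_coords(loci_treated, rule)

    if rule.guild == "fly" and rule.rule == "quadrant_change":
        if quadrant_map is None:
            from .vision_models import _DEFAULT_FLY_MAP

            quadrant_map = _DEFAULT_FLY_MAP
        treated_cat = loci_treated["category"].to_numpy()
        if mode == "centroid":
            ref = _fly_category_of_point(xc.mean(axis=0), quadrant_map)
            hits = (treated_cat != ref) & (treated_cat != "boundary")
        else:
            control_cat = set(loci_control["category"])
            hits = np.array(
                [c != "boundary" and c not in control_cat for c in treated_cat]
            )
    else:
        if mode == "centroid":
            dists = np.linalg.norm(xt - xc.mean(axis=0), axis=1)
        else:
            dists = np.min(
                np.linalg.norm(xt[:, None, :] - xc[None, :, :], axis=2), axis=1
            )
        hits = dists >= rule.threshold

    n = len(loci_treated)
    k = int(np.sum(hits))
    return PerceptibilitySummary(
        treatment_pair=pair,
        guild=rule.guild,
        n_compared=n,
        n_perceptible=k,
        fraction=k / n,
        mode=mode,
    )


def _single_treatment(df: pd.DataFrame) -> str:
    if "treatment" in df.columns:
        vals = sorted({str(v) for v in df["treatment"].dropna()})
        if len(vals) == 1:
            return vals[0]
        if len(vals) > 1:
            return "+".join(vals)
    return "?"
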