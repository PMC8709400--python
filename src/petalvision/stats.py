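"""Statistical procedures for treatment comparisons of petal traits.

Four tools cover the analysis plan of a small multi-treatment exposure
experiment:

* :func:`bray_curtis` + :func:`permanova` — whole-spectrum comparison:
  reflectance profiles are square-root transformed (damping the leverage
  of high-reflectance wavelengths), turned into a Bray-Curtis
  dissimilarity matrix and tested for treatment differences with
  Anderson's permutational MANOVA (pseudo-F, permutation p-value).
* :func:`oneway_anova` — one-way ANOVA / ANCOVA with the covariate
  entered first (sequential sums of squares).
* :func:`contrast_test` — single-df planned contrasts on (adjusted)
  treatment means, including orthogonal-polynomial "linear increase"
  coding for three ordered exposure levels.
* :func:`fit_random_intercept` — maximum-likelihood linear mixed model
  with a plant random intercept, profiled over the variance ratio, with
  AIC comparison against the fixed-effects-only fit and a likelihood
  ratio χ² for the treatment term.

ML (not REML) is used throughout so that AIC values are comparable
between models that differ in their fixed effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f as f_dist

__all__ = [
    "DissimilarityMatrix",
    "PermanovaResult",
    "ContrastSpec",
    "ContrastResult",
    "RandomInterceptFit",
    "bray_curtis",
    "permanova",
    "oneway_anova",
    "contrast_test",
    "named_contrast",
    "fit_random_intercept",
    "select_random_intercept",
]


# --------------------------------------------------------------------------
# dissimilarity + PERMANOVA


@dataclass
class DissimilarityMatrix:
    labels: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")


def bray_curtis(matrix, labels=None, transform: str = "sqrt") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between row profiles.

    D_ij = Σ|x_i − x_j| / Σ(x_i + x_j) after an elementwise transform.
    ``transform`` is ``"sqrt"`` (default, tames high-reflectance
    wavelengths) or ``"none"``.  Rows of all zeros have no defined
    dissimilarity and raise, naming the offending profile.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index) if labels is None else labels
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        labels = list(range(len(x))) if labels is None else list(labels)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires non-negative data")
    zero = np.where(x.sum(axis=1) == 0)[0]
    if len(zero):
        raise ValueError(f"all-zero profile for {labels[zero[0]]!r}")
    if transform == "sqrt":
        x = np.sqrt(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(labels, d)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    p_perm: float
    n_permutations: int
    seed: int | None
    method: str = "sampled"


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    """Within-group sum of squared dissimilarities, Σ_g (Σ_{i<j∈g} d²)/n_g."""
    ss_w = 0.0
    for g, n_g in enumerate(sizes):
        idx = np.where(codes == g)[0]
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    return ss_w


def _pseudo_f(d2, codes, sizes, ss_total, df_b, df_w) -> float:
    ss_w = _permanova_ss(d2, codes, sizes)
    ss_a = ss_total - ss_w
    return (ss_a / df_b) / (ss_w / df_w)


def permanova(
    dm: DissimilarityMatrix,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    method: str = "sampled",
) -> PermanovaResult:
    """Permutational MANOVA on a dissimilarity matrix (Anderson's pseudo-F).

    SS_total = Σ_{i<j} d²_ij / N and SS_within pools squared within-group
    dissimilarities; F = (SS_between/df_b)/(SS_within/df_w).  The p-value
    permutes group labels: ``method="sampled"`` draws ``n_perm`` random
    permutations and reports (1 + #{F* ≥ F}) / (1 + n_perm);
    ``method="exact"`` enumerates every distinct assignment of labels to
    samples (small designs only) and reports the exact tail fraction.
    """
    groups = np.asarray(groups)
    n = len(groups)
    if n != len(dm.labels):
        raise ValueError("groups length does not match the matrix")
    levels, codes = np.unique(groups, return_inverse=True)
    a = len(levels)
    if a < 2:
        raise ValueError("need at least two groups")
    sizes = np.bincount(codes)
    df_b, df_w = a - 1, n - a
    if df_w < 1:
        raise ValueError("no within-group degrees of freedom (singleton design)")
    d2 = dm.values ** 2
    ss_total = d2.sum() / (2.0 * n)
    f_obs = _pseudo_f(d2, codes, sizes, ss_total, df_b, df_w)

    if method == "exact":
        # distinct multiset permutations: choose positions per group
        count = 0
        hits = 0
        for perm in _multiset_permutations(codes):
            f_p = _pseudo_f(d2, perm, sizes, ss_total, df_b, df_w)
            count += 1
            if f_p >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(
            f_obs, df_b, df_w, hits / count, count, seed, method="exact"
        )
    if method != "sampled":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _pseudo_f(d2, perm, sizes, ss_total, df_b, df_w) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(f_obs, df_b, df_w, p, n_perm, seed)


def _multiset_permutations(codes: np.ndarray):
    """All distinct arrangements of a label multiset (iterator of arrays)."""
    from sympy.utilities.iterables import multiset_permutations

    counts = np.bincount(codes)
    if _multiset_count(counts) > 200_000:
        raise ValueError("design too large for exact enumeration")
    for perm in multiset_permutations(list(map(int, codes))):
        yield np.asarray(perm, dtype=int)


def _multiset_count(counts) -> int:
    total = math.factorial(int(np.sum(counts)))
    for c in counts:
        total //= math.factorial(int(c))
    return total


# --------------------------------------------------------------------------
# ANOVA / planned contrasts


def _design(groups, levels, covariate=None):
    groups = np.asarray(groups)
    cols = [np.asarray(groups == lev, dtype=float) for lev in levels]
    names = [f"mean[{lev}]" for lev in levels]
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        cols.append(cov - cov.mean())  # centred so group terms are adjusted means
        names.append("covariate")
    return np.column_stack(cols), names


def oneway_anova(y, groups, covariate=None) -> pd.DataFrame:
    """One-way ANOVA (or ANCOVA, covariate entered first) table.

    Sequential (type-I) sums of squares: the covariate is fitted before
    the group factor, matching an analysis where the nuisance variable is
    adjusted for a priori.  Returns a tidy table with terms as rows.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    n = len(y)
    terms = []
    x0 = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    df_prev = n - 1
    x = x0
    if covariate is not None:
        x = np.column_stack([x, np.asarray(covariate, dtype=float)])
        rss_cov = _rss(y, x)
        terms.append(("covariate", rss_prev - rss_cov, 1))
        rss_prev, df_prev = rss_cov, df_prev - 1
    dummies = np.column_stack(
        [np.asarray(groups == lev, dtype=float) for lev in levels[1:]]
    )
    x = np.column_stack([x, dummies])
    rss_full = _rss(y, x)
    df_group = len(levels) - 1
    terms.append(("group", rss_prev - rss_full, df_group))
    df_resid = n - x.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    mse = rss_full / df_resid
    tss = float(((y - y.mean()) ** 2).sum())
    degenerate = tss == 0.0 or mse <= 1e-12 * tss / (n - 1)
    rows = []
    for name, ss, df in terms:
        if degenerate:
            f_val, p = (np.nan, np.nan)  # 0/0: undefined, not zero
        else:
            f_val = (ss / df) / mse
            p = float(f_dist.sf(f_val, df, df_resid))
        rows.append({"term": name, "ss": ss, "df": df, "F": f_val, "p": p})
    rows.append(
        {"term": "residual", "ss": rss_full, "df": df_resid, "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def _rss(y, x) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


@dataclass(frozen=True)
class ContrastSpec:
    """A planned single-df contrast over ordered treatment levels."""

    levels: tuple
    coefficients: tuple
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.coefficients):
            raise ValueError("levels and coefficients differ in length")
        c = np.asarray(self.coefficients, dtype=float)
        if abs(c.sum()) > 1e-10:
            raise ValueError("contrast coefficients must sum to zero")
        if np.all(c == 0):
            raise ValueError("contrast coefficients cannot all be zero")


def named_contrast(name: str, levels=("CFA", "NFA", "FU+")) -> ContrastSpec:
    """Standard contrast codings for three ordered ozone levels.

    * ``linear_increase`` / ``linear_decrease`` — orthogonal polynomial
      scores (−1, 0, 1)/√2 for equally spaced levels, sign flipped for the
      decreasing hypothesis;
    * ``nfa_vs_rest`` — middle level against the mean of the outer two
      (−1, 2, −1);
    * ``control_vs_rest`` — first level against the rest (2, −1, −1).
    """
    if len(levels) != 3:
        raise ValueError("named contrasts are defined for exactly three levels")
    s = 1.0 / math.sqrt(2.0)
    table = {
        "linear_increase": (-s, 0.0, s),
        "linear_decrease": (s, 0.0, -s),
        "nfa_vs_rest": (-1.0, 2.0, -1.0),
        "control_vs_rest": (2.0, -1.0, -1.0),
    }
    if name not in table:
        raise ValueError(f"unknown contrast {name!r}; choose from {sorted(table)}")
    return ContrastSpec(tuple(levels), table[name], name)


@dataclass(frozen=True)
class ContrastResult:
    name: str
    estimate: float
    f: float
    df1: int
    df2: int
    p: float


def contrast_test(y, groups, spec: ContrastSpec, covariate=None) -> ContrastResult:
    """Single-df F test of Σ c_g · mean_g = 0 within a one-way/ANCOVA model.

    Fitted with cell-means coding via OLS; with a covariate the contrast
    applies to covariate-adjusted group means.  The F statistic equals
    t² of the estimated contrast.
    """
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    present = set(np.unique(groups))
    if set(spec.levels) != present:
        raise ValueError(
            f"contrast levels {spec.levels} do not match data groups {sorted(present)}"
        )
    x, names = _design(groups, spec.levels, covariate)
    fit = sm.OLS(y, x).fit()
    c = np.zeros(x.shape[1])
    c[: len(spec.levels)] = spec.coefficients
    ft = fit.f_test(c)
    estimate = float(np.dot(c, fit.params))
    return ContrastResult(
        name=spec.name,
        estimate=estimate,
        f=float(ft.fvalue),
        df1=1,
        df2=int(fit.df_resid),
        p=float(ft.pvalue),
    )


# --------------------------------------------------------------------------
# random-intercept mixed model (ML, profile likelihood)


@dataclass(frozen=True)
class RandomInterceptFit:
    fixed_effects: dict
    sigma2_plant: float
    sigma2_resid: float
    loglik: float
    aic: float
    n_params: int
    converged: bool = True


def _profile_loglik(lam, y, x, plant_codes, n_plants):
    """ML log-likelihood profiled over β and σ² at variance ratio λ.

    V is block diagonal with blocks I + λJ per plant; Sherman-Morrison
    gives V⁻¹z = z − (λ/(1+λn_g))·(Σz)·1 per block, and
    log|V| = Σ_g log(1 + λ n_g).
    """
    n = len(y)
    sizes = np.bincount(plant_codes, minlength=n_plants).astype(float)
    shrink = lam / (1.0 + lam * sizes)  # per plant

    def whiten_half(z):
        # returns V^{-1} z  (z may be 2-D with observations on axis 0)
        sums = np.zeros((n_plants,) + z.shape[1:])
        np.add.at(sums, plant_codes, z)
        return z - (shrink[plant_codes].reshape(-1, *([1] * (z.ndim - 1)))) * sums[plant_codes]

    viy = whiten_half(y)
    vix = whiten_half(x)
    xtvx = x.T @ vix
    xtvy = x.T @ viy
    beta = np.linalg.solve(xtvx, xtvy)
    r = y - x @ beta
    quad = float(r @ whiten_half(r))
    sigma2 = quad / n
    logdet = float(np.sum(np.log1p(lam * sizes)))
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


def fit_random_intercept(y, x, plant_ids, xatol: float = 1e-8) -> RandomInterceptFit:
    """ML fit of y = Xβ + b_plant + ε with b ~ N(0, σ²_plant).

    The likelihood is profiled down to the single variance ratio
    λ = σ²_plant/σ²_resid and maximized by bounded one-dimensional search
    (absolute tolerance ``xatol``); λ = 0 (no plant variance) is always
    evaluated explicitly so the boundary solution is found exactly.
    AIC counts fixed effects plus both variance parameters.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    plants, plant_codes = np.unique(np.asarray(plant_ids), return_inverse=True)
    if len(plants) < 2:
        raise ValueError("need at least two plants for a random intercept")
    n_plants = len(plants)

    def neg_ll(log_lam):
        return -_profile_loglik(math.exp(log_lam), y, x, plant_codes, n_plants)[0]

    res = minimize_scalar(
        neg_ll, bounds=(-12.0, 8.0), method="bounded", options={"xatol": xatol}
    )
    ll_hat, beta_hat, s2_hat = _profile_loglik(
        math.exp(res.x), y, x, plant_codes, n_plants
    )
    ll0, beta0, s20 = _profile_loglik(0.0, y, x, plant_codes, n_plants)
    if ll0 >= ll_hat:  # boundary optimum: no plant variance
        lam_hat, ll_hat, beta_hat, s2_hat = 0.0, ll0, beta0, s20
    else:
        lam_hat = math.exp(res.x)
    k = x.shape[1] + 2
    return RandomInterceptFit(
        fixed_effects={f"b{j}": float(b) for j, b in enumerate(beta_hat)},
        sigma2_plant=lam_hat * s2_hat,
        sigma2_resid=s2_hat,
        loglik=ll_hat,
        aic=2 * k - 2 * ll_hat,
        n_params=k,
        converged=bool(res.success),
    )


def fit_fixed_only(y, x) -> RandomInterceptFit:
    """ML fit of the fixed-effects-only model (σ²_plant fixed at 0)."""
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != len(y):
        x = x.T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    n = len(y)
    s2 = float(r @ r) / n
    ll = -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)
    k = x.shape[1] + 1
    return RandomInterceptFit(
        fixed_effects={f"b{j}": float(b) for j, b in enumerate(beta)},
        sigma2_plant=0.0,
        sigma2_resid=s2,
        loglik=ll,
        aic=2 * k - 2 * ll,
        n_params=k,
    )


def design_for_groups(groups, levels=None):
    """Intercept + treatment-dummy design matrix for mixed-model fits."""
    groups = np.asarray(groups)
    if levels is None:
        levels = list(pd.unique(groups))
    cols = [np.ones(len(groups))]
    for lev in levels[1:]:
        cols.append(np.asarray(groups == lev, dtype=float))
    return np.column_stack(cols)


@dataclass(frozen=True)
class ModelSelection:
    mixed: RandomInterceptFit
    fixed: RandomInterceptFit
    chosen: str  # "mixed" or "fixed"
    treatment_chi2: float | None = None
    treatment_df: int | None = None
    treatment_p: float | None = None


def select_random_intercept(y, groups, plant_ids, levels=None) -> ModelSelection:
    """Fit both candidate models, pick by AIC, and LRT the treatment term.

    The treatment χ² is a likelihood-ratio statistic comparing the chosen
    model against the same model with the treatment fixed effects removed
    (df = number of treatment dummies).
    """
    x_full = design_for_groups(groups, levels)
    x_null = x_full[:, :1]
    plants = np.asarray(plant_ids)
    treatments_of_plants = pd.DataFrame({"g": groups, "p": plants}).groupby("p")["g"].nunique()
    if (treatments_of_plants > 1).any():
        raise ValueError("plants must be nested within treatments")
    if len(np.unique(plants)) < len(np.unique(np.asarray(groups))):
        raise ValueError("fewer plants than treatments")
    mixed = fit_random_intercept(y, x_full, plants)
    fixed = fit_fixed_only(y, x_full)
    chosen = "mixed" if mixed.aic < fixed.aic else "fixed"
    if chosen == "mixed":
        null = fit_random_intercept(y, x_null, plants)
        full_ll, null_ll = mixed.loglik, null.loglik
    else:
        null = fit_fixed_only(y, x_null)
        full_ll, null_ll = fixed.loglik, null.loglik
    df = x_full.shape[1] - 1
    chi2 = max(0.0, 2.0 * (full_ll - null_ll))
    from scipy.stats import chi2 as chi2_dist

    return ModelSelection(
        mixed=mixed,
        fixed=fixed,
        chosen=chosen,
        treatment_chi2=chi2,
        treatment_df=df,
        treatment_p=float(chi2_dist.sf(chi2, df)),
    )
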