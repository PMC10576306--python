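"""Per-wavelength inferential models for calculated reflectance.

Reflectance at each analysis wavelength is modelled separately against the
experimental design — genotype group, measurement time, batch, leaf number,
leaf position — with one-way ANOVA (plus eta-squared), OLS regression, or a
random-intercept linear mixed model for repeated measurements of the same
plant.  P-values from the resulting family of ~2101 tests are adjusted with
the Benjamini-Yekutieli step-up procedure, which controls the false
discovery rate under the arbitrary dependence structure that neighbouring
wavelengths exhibit.  Maximal contiguous runs of adjusted-significant
wavelengths are reported as spectral regions.

All categorical factors use treatment (reference-level) coding; the
intercept therefore corresponds to the reference genotype measured in the
morning, in the first batch, with one leaf — the baseline condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    DesignError,
    ParameterError,
)
from .reflectance import ReflectanceSet

ALPHA = 0.05

#: reference levels giving the intercept its baseline meaning
DEFAULT_REFERENCES = {
    "genotype_group": "REF_UTWT",
    "genotype": "EV",
    "time_window": "am",
    "leaf_number": 1,
    "leaf_position": "older",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed factors, optional interactions and random intercept grouping."""

    fixed: tuple = ()
    interactions: tuple = ()  # tuples of factor names
    random: str | None = None  # grouping column for a random intercept
    references: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(self, "interactions", tuple(tuple(i) for i in self.interactions))
        for term in self.interactions:
            if any(f not in self.fixed for f in term):
                raise DesignError(f"interaction {term} involves undeclared main effects")

    @property
    def estimation(self) -> str:
        return "REML" if self.random else "OLS"

    def with_interaction(self, term) -> "ModelSpec":
        return replace(self, interactions=self.interactions + (tuple(term),))


@dataclass
class ModelResultSpectrum:
    """Per-wavelength fit summaries for one model.

    ``stats`` is indexed by wavelength (omnibus F/p, fit indices);
    ``coefficients`` is long format with Wald-t CIs per term and wavelength.
    """

    kind: str  # anova | ols | lmm
    spec: ModelSpec | None
    wavelengths: np.ndarray
    stats: pd.DataFrame
    coefficients: pd.DataFrame | None = None

    def significant_regions(self, alpha: float = ALPHA, label: str = "omnibus"):
        return significant_regions(
            self.stats["p_adj"].to_numpy(), self.wavelengths, alpha=alpha, label=label
        )


@dataclass(frozen=True)
class SignificantRegion:
    start_nm: int
    end_nm: int
    label: str
    min_p_adj: float


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _reference_level(column: str, levels: list, references: dict):
    if column in references:
        ref = references[column]
    elif column in DEFAULT_REFERENCES:
        ref = DEFAULT_REFERENCES[column]
    else:
        ref = None
    if ref is not None and ref in levels:
        return ref
    return sorted(levels, key=str)[0]


def _factor_dummies(meta: pd.DataFrame, column: str, references: dict):
    """Treatment-coded dummies for one categorical factor."""
    if column not in meta.columns:
        raise DesignError(f"metadata has no column {column!r}")
    vals = meta[column]
    levels = sorted(pd.unique(vals.dropna()), key=str)
    if len(levels) < 2:
        raise DesignError(f"factor {column!r} has {len(levels)} level(s)")
    ref = _reference_level(column, levels, references)
    cols, names = [], []
    for lev in levels:
        if lev == ref:
            continue
        cols.append((vals == lev).to_numpy(dtype=float))
        names.append(f"{column}[{lev}]")
    return np.column_stack(cols), names, ref


def design_matrix(meta: pd.DataFrame, spec: ModelSpec):
    """Full-rank design matrix with intercept, mains and interactions.

    Returns (X, names, references) where names[0] == 'Intercept'.
    """
    n = len(meta)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    refs = {}
    factor_cols: dict[str, tuple[np.ndarray, list]] = {}
    for col in spec.fixed:
        D, dn, ref = _factor_dummies(meta, col, spec.references)
        factor_cols[col] = (D, dn)
        refs[col] = ref
        blocks.append(D)
        names.extend(dn)
    for term in spec.interactions:
        Ds = [factor_cols[f][0] for f in term]
        Ns = [factor_cols[f][1] for f in term]
        # products of dummy columns across the interacting factors
        prod_cols, prod_names = Ds[0], list(Ns[0])
        for D, N in zip(Ds[1:], Ns[1:]):
            new_cols, new_names = [], []
            for i, ni in enumerate(prod_names):
                for j, nj in enumerate(N):
                    new_cols.append(prod_cols[:, i] * D[:, j])
                    new_names.append(f"{ni}:{nj}")
            prod_cols = np.column_stack(new_cols)
            prod_names = new_names
        blocks.append(prod_cols)
        names.extend(prod_names)
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name terms whose removal restores full rank
        aliased = []
        for j in range(1, X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                aliased.append(names[j])
        raise DesignError(f"design matrix rank deficient; aliased terms: {aliased}")
    return X, names, refs


# ---------------------------------------------------------------------------
# multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_by(p_raw) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    With m tests and c(m) = sum_{i=1..m} 1/i, the sorted p_(j) maps to
    min(1, min_{j' >= j} p_(j') * m * c(m) / j'), returned in input order.
    Valid under arbitrary dependence between tests.
    """
    p = np.asarray(p_raw, dtype=float)
    shape = p.shape
    p = p.ravel()
    if p.size == 0:
        return p.reshape(shape)
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise ParameterError("p-values must lie in [0, 1] with no NaN")
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m * c_m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out.reshape(shape)


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up (no dependence factor); for comparison."""
    p = np.asarray(p_raw, dtype=float).ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out.reshape(np.asarray(p_raw).shape)


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _eta_squared_ci_low(F: float, df1: int, df2: int, conf: float = 0.95) -> float:
    """Lower bound of the one-sided noncentral-F CI for eta squared.

    Finds the noncentrality at which the observed F sits at the ``conf``
    quantile; the upper bound of the interval is fixed at 1.  This follows
    the usual one-sided effect-size CI convention for ANOVA.
    """
    if not np.isfinite(F) or F <= 0:
        return 0.0
    if stats.ncf.cdf(F, df1, df2, 0.0) <= conf:
        return 0.0
    lo, hi = 0.0, 1.0
    while stats.ncf.cdf(F, df1, df2, hi) > conf:
        hi *= 2
        if hi > 1e6:
            return 1.0
    from scipy.optimize import brentq

    lam = brentq(lambda nc: stats.ncf.cdf(F, df1, df2, nc) - conf, lo, hi, xtol=1e-8)
    return float(lam / (lam + df1 + df2 + 1))


def fit_anova_spectrum(
    rs: ReflectanceSet, factor: str, eta_ci: bool = True, adjust: bool = True
) -> ModelResultSpectrum:
    """One-way ANOVA of reflectance on one factor, at every wavelength."""
    meta = rs.meta_aligned()
    if factor not in meta.columns:
        raise DesignError(f"metadata has no column {factor!r}")
    labels = meta[factor].to_numpy()
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise DesignError(f"factor {factor!r} has fewer than 2 levels")
    counts = {g: int((labels == g).sum()) for g in levels}
    small = [g for g, c in counts.items() if c < 2]
    if small:
        raise DesignError(f"levels with <2 samples: {small}")

    Y = rs.cr
    n, m = Y.shape
    grand = Y.mean(axis=0)
    ssb = np.zeros(m)
    ssw = np.zeros(m)
    for g in levels:
        rows = labels == g
        gm = Y[rows].mean(axis=0)
        ssb += rows.sum() * (gm - grand) ** 2
        ssw += ((Y[rows] - gm) ** 2).sum(axis=0)
    df1 = len(levels) - 1
    df2 = n - len(levels)
    msw = ssw / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(msw > 0, (ssb / df1) / msw, 0.0)
    sst = ssb + ssw
    eta2 = np.where(sst > 0, ssb / np.where(sst > 0, sst, 1.0), 0.0)
    p = stats.f.sf(F, df1, df2)
    p = np.where(np.isfinite(p), p, 1.0)
    stats_df = pd.DataFrame(
        {
            "F": F,
            "df1": df1,
            "df2": df2,
            "p_raw": p,
            "eta2": eta2,
            "eta2_ci_low": (
                [_eta_squared_ci_low(f, df1, df2) for f in F] if eta_ci else np.nan
            ),
            "eta2_ci_high": 1.0,
        },
        index=pd.Index(rs.wavelengths, name="wavelength"),
    )
    stats_df["p_adj"] = adjust_by(p) if adjust else p
    return ModelResultSpectrum(
        kind="anova", spec=ModelSpec(fixed=(factor,)), wavelengths=rs.wavelengths, stats=stats_df
    )


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

def _gaussian_aic(n: int, sse: np.ndarray, k_params: int) -> np.ndarray:
    """AIC of the Gaussian ML fit (matches R's lm AIC up to fp rounding)."""
    with np.errstate(divide="ignore"):
        ll = -0.5 * n * (np.log(2 * np.pi) + np.log(sse / n) + 1)
    return 2 * (k_params + 1) - 2 * ll


def fit_ols_spectrum(
    rs: ReflectanceSet, spec: ModelSpec, adjust: bool = True
) -> ModelResultSpectrum:
    """OLS of reflectance on the design, vectorized across wavelengths."""
    meta = rs.meta_aligned()
    X, names, refs = design_matrix(meta, spec)
    Y = rs.cr
    n, p = X.shape
    if n <= p:
        raise DesignError(f"{n} samples cannot identify {p} parameters")
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ Y)  # p x m
    resid = Y - X @ beta
    sse = (resid**2).sum(axis=0)
    sst = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    degenerate = sst <= 1e-20  # constant response at this wavelength
    dfe = n - p
    sigma2 = sse / dfe
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))  # p x m
    tcrit = stats.t.ppf(0.975, dfe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
        r2 = np.where(degenerate, 0.0, 1 - sse / np.where(degenerate, 1.0, sst))
    adj_r2 = np.where(degenerate, 0.0, 1 - (1 - r2) * (n - 1) / dfe)
    df_model = p - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(degenerate | (sse <= 0), 0.0, ((sst - sse) / df_model) / sigma2)
    p_omni = np.where(degenerate, 1.0, stats.f.sf(F, df_model, dfe))

    stats_df = pd.DataFrame(
        {
            "F": F,
            "df1": df_model,
            "df2": dfe,
            "p_raw": p_omni,
            "r2": r2,
            "adj_r2": adj_r2,
            "aic": _gaussian_aic(n, sse, p),
        },
        index=pd.Index(rs.wavelengths, name="wavelength"),
    )
    stats_df["p_adj"] = adjust_by(p_omni) if adjust else p_omni

    m = Y.shape[1]
    coef = pd.DataFrame(
        {
            "wavelength": np.repeat(rs.wavelengths, p),
            "term": np.tile(np.asarray(names, dtype=object), m),
            "estimate": beta.T.ravel(),
            "se": se.T.ravel(),
            "ci_low": (beta - tcrit * se).T.ravel(),
            "ci_high": (beta + tcrit * se).T.ravel(),
            "t": tvals.T.ravel(),
            "p": 2 * stats.t.sf(np.abs(tvals), dfe).T.ravel(),
        }
    )
    return ModelResultSpectrum(
        kind="ols", spec=spec, wavelengths=rs.wavelengths, stats=stats_df, coefficients=coef
    )


# ---------------------------------------------------------------------------
# linear mixed model (random intercept, REML)
# ---------------------------------------------------------------------------

def fit_lmm_spectrum(
    rs: ReflectanceSet,
    spec: ModelSpec,
    wavelengths=None,
    adjust: bool = True,
) -> ModelResultSpectrum:
    """Random-intercept mixed model per wavelength (REML via statsmodels).

    Marginal R^2 = var_fixed / (var_fixed + var_random + var_residual);
    conditional R^2 adds var_random to the numerator; var_fixed is the
    variance of the fixed-effect linear predictor.  Wald-t inference uses
    the residual-df approximation n_obs - n_fixed - n_groups + 1.  A random
    variance estimated at (or squeezed against) zero is reported with a
    boundary flag rather than treated as an error.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    if spec.random is None:
        raise DesignError("fit_lmm_spectrum requires a random intercept grouping")
    meta = rs.meta_aligned()
    if spec.random not in meta.columns:
        raise DesignError(f"metadata has no column {spec.random!r}")
    groups = meta[spec.random].to_numpy()
    n_groups = len(pd.unique(groups))
    if n_groups < 2:
        raise DesignError("random grouping needs >= 2 groups")
    X, names, refs = design_matrix(meta, spec)
    n, p = X.shape
    df_t = max(n - p - n_groups + 1, 1)
    tcrit = stats.t.ppf(0.975, df_t)

    if wavelengths is None:
        wl_idx = np.arange(len(rs.wavelengths))
    else:
        wl_idx = np.searchsorted(rs.wavelengths, np.asarray(wavelengths))
    wl_out = rs.wavelengths[wl_idx]

    rows_stats, rows_coef = [], []
    for j, wl in zip(wl_idx, wl_out):
        y = rs.cr[:, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=groups)
            try:
                fit = model.fit(reml=True, method="lbfgs")
            except Exception:
                try:
                    fit = model.fit(reml=True, method="cg")
                except Exception as exc:  # pragma: no cover - rare
                    raise ConvergenceError(
                        f"mixed model failed to converge at {wl} nm: {exc}"
                    ) from exc
        beta = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:p, :p]
        se = np.sqrt(np.diag(cov))
        var_random = float(np.asarray(fit.cov_re)[0, 0])
        var_resid = float(fit.scale)
        boundary = var_random < 1e-10 * max(var_resid, 1e-300)
        fixed_pred = X @ beta
        var_fixed = float(np.var(fixed_pred, ddof=1))
        denom = var_fixed + var_random + var_resid
        marginal = var_fixed / denom if denom > 0 else 0.0
        conditional = (var_fixed + var_random) / denom if denom > 0 else 0.0
        # omnibus Wald F on all non-intercept fixed effects
        if p > 1:
            L = np.zeros((p - 1, p))
            L[:, 1:] = np.eye(p - 1)
            est = L @ beta
            covL = L @ cov @ L.T
            try:
                Fstat = float(est @ np.linalg.solve(covL, est)) / (p - 1)
            except np.linalg.LinAlgError:
                Fstat = np.nan
            p_omni = float(stats.f.sf(Fstat, p - 1, df_t)) if np.isfinite(Fstat) else 1.0
        else:
            Fstat, p_omni = 0.0, 1.0
        rows_stats.append(
            {
                "wavelength": wl,
                "F": Fstat,
                "df1": p - 1,
                "df2": df_t,
                "p_raw": p_omni,
                "marginal_r2": marginal,
                "conditional_r2": conditional,
                "var_fixed": var_fixed,
                "var_random": var_random,
                "var_resid": var_resid,
                "boundary": boundary,
                "aic": float(fit.aic) if np.isfinite(fit.aic) else np.nan,
            }
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            tv = np.where(se > 0, beta / se, 0.0)
        for b, s_, t_, name in zip(beta, se, tv, names):
            rows_coef.append(
                {
                    "wavelength": wl,
                    "term": name,
                    "estimate": b,
                    "se": s_,
                    "ci_low": b - tcrit * s_,
                    "ci_high": b + tcrit * s_,
                    "t": t_,
                    "p": 2 * stats.t.sf(abs(t_), df_t),
                }
            )
    stats_df = pd.DataFrame(rows_stats).set_index("wavelength")
    stats_df["p_adj"] = adjust_by(stats_df["p_raw"].to_numpy()) if adjust else stats_df["p_raw"]
    return ModelResultSpectrum(
        kind="lmm",
        spec=spec,
        wavelengths=np.asarray(wl_out),
        stats=stats_df,
        coefficients=pd.DataFrame(rows_coef),
    )


# ---------------------------------------------------------------------------
# Tukey post-hoc contrasts
# ---------------------------------------------------------------------------

def tukey_posthoc(
    rs: ReflectanceSet,
    spec: ModelSpec,
    factor: str,
    wavelengths=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """All pairwise contrasts of one factor's model-based means, per wavelength.

    P-values come from the studentized-range distribution with the model's
    residual df (Tukey HSD on adjusted means).  With ``adjust=True`` each
    contrast additionally receives a Benjamini-Yekutieli adjustment across
    wavelengths, as its own family.
    """
    if factor not in spec.fixed:
        raise DesignError(f"factor {factor!r} not in model fixed effects {spec.fixed}")
    meta = rs.meta_aligned()
    X, names, refs = design_matrix(meta, spec)
    n, p = X.shape
    dfe = n - p
    levels = sorted(pd.unique(meta[factor].dropna()), key=str)
    k = len(levels)
    ref = refs[factor]

    XtX_inv = np.linalg.inv(X.T @ X)
    if wavelengths is None:
        wl_idx = np.arange(len(rs.wavelengths))
    else:
        wl_idx = np.searchsorted(rs.wavelengths, np.asarray(wavelengths))
    Y = rs.cr[:, wl_idx]
    beta = XtX_inv @ (X.T @ Y)
    sse = ((Y - X @ beta) ** 2).sum(axis=0)
    sigma2 = sse / dfe

    def level_vector(lev):
        v = np.zeros(p)
        if lev != ref:
            v[names.index(f"{factor}[{lev}]")] = 1.0
        return v

    rows = []
    for a_i in range(k):
        for b_i in range(a_i + 1, k):
            a, b = levels[a_i], levels[b_i]
            c = level_vector(a) - level_vector(b)
            est = c @ beta  # per wavelength
            se = np.sqrt((c @ XtX_inv @ c) * sigma2)
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.where(se > 0, np.abs(est) / se * np.sqrt(2.0), 0.0)
            pvals = stats.studentized_range.sf(q, k, dfe)
            pvals = np.clip(np.where(np.isfinite(pvals), pvals, 1.0), 0.0, 1.0)
            block = pd.DataFrame(
                {
                    "wavelength": rs.wavelengths[wl_idx],
                    "contrast": f"{a} - {b}",
                    "estimate": est,
                    "se": se,
                    "p_raw": pvals,
                }
            )
            block["p_adj"] = adjust_by(pvals) if adjust else pvals
            rows.append(block)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# AIC-guided forward selection
# ---------------------------------------------------------------------------

def _aic_at_probes(rs: ReflectanceSet, spec: ModelSpec, probe_idx: np.ndarray) -> np.ndarray:
    sub = ReflectanceSet(
        sample_ids=rs.sample_ids,
        wavelengths=rs.wavelengths[probe_idx],
        cr=rs.cr[:, probe_idx],
        au=rs.au[:, probe_idx],
        ru=rs.ru[:, probe_idx],
        metadata=rs.metadata,
    )
    if spec.random:
        res = fit_lmm_spectrum(sub, spec, adjust=False)
    else:
        res = fit_ols_spectrum(sub, spec, adjust=False)
    return res.stats["aic"].to_numpy()


def select_model_aic(
    rs: ReflectanceSet,
    base: ModelSpec,
    full: ModelSpec,
    probe_wavelengths,
    delta: float = -2.0,
) -> ModelSpec:
    """Forward stepwise interaction selection judged by AIC at probe wavelengths.

    Starting from the main-effects model, at each step the candidate
    interaction that improves AIC by more than ``|delta|`` at the majority
    of the probe wavelengths (typically the four wavelengths contributing
    most to the first four PCs) is added; selection stops when no candidate
    wins a majority.  With two or fewer main effects the base and full
    models are compared directly.
    """
    probe = np.asarray(probe_wavelengths)
    probe_idx = np.searchsorted(rs.wavelengths, probe)
    if not np.array_equal(rs.wavelengths[probe_idx], probe):
        raise ParameterError("probe wavelengths must lie on the analysis grid")
    majority = len(probe) / 2.0

    if len(base.fixed) <= 2 or not full.interactions:
        if not full.interactions or base.interactions == full.interactions:
            return base if not full.interactions else full
        aic_base = _aic_at_probes(rs, base, probe_idx)
        aic_full = _aic_at_probes(rs, full, probe_idx)
        wins = int(((aic_full - aic_base) < delta).sum())
        return full if wins > majority else base

    current = base
    remaining = [t for t in full.interactions if t not in current.interactions]
    aic_current = _aic_at_probes(rs, current, probe_idx)
    while remaining:
        best_term, best_wins, best_aic = None, 0, None
        for term in remaining:
            try:
                cand_aic = _aic_at_probes(rs, current.with_interaction(term), probe_idx)
            except DesignError:
                continue
            wins = int(((cand_aic - aic_current) < delta).sum())
            if wins > best_wins:
                best_term, best_wins, best_aic = term, wins, cand_aic
        if best_term is None or best_wins <= majority:
            break
        current = current.with_interaction(best_term)
        aic_current = best_aic
        remaining = [t for t in remaining if t != best_term]
    return current


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------

def significant_regions(
    p_adj, wavelengths, alpha: float = ALPHA, label: str = ""
) -> list[SignificantRegion]:
    """Maximal contiguous runs of adjusted-significant wavelengths."""
    p = np.asarray(p_adj, dtype=float)
    wl = np.asarray(wavelengths)
    sig = p < alpha
    regions = []
    i = 0
    n = len(p)
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and sig[j + 1] and wl[j + 1] == wl[j] + 1:
            j += 1
        regions.append(
            SignificantRegion(
                start_nm=int(wl[i]),
                end_nm=int(wl[j]),
                label=label,
                min_p_adj=float(p[i : j + 1].min()),
            )
        )
        i = j + 1
    return regions


def regions_table(regions: list[SignificantRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_nm": r.start_nm,
                "end_nm": r.end_nm,
                "label": r.label,
                "min_p_adj": r.min_p_adj,
            }
            for r in regions
        ]
    )
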