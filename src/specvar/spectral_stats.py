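"""Spectrally resolved descriptive statistics: CV, bootstrap envelopes, PCA.

The coefficient of variation per wavelength (sd/mean across a group's
calculated-reflectance spectra) summarizes within-group spectral variation.
When groups of unequal size are compared, the larger group is repeatedly
subsampled down to the smaller group's size and the envelope (pointwise
min/mean/max over replicates) of the resulting CV spectra is reported, so
the comparison is not confounded by sample size.

PCA here is covariance PCA on mean-centered, unscaled reflectance;
reflectance shares units across wavelengths, and correlation scaling would
inflate the noisy water-absorption bands.  The contribution of wavelength w
to component k is 100 * loading(w,k)^2 / sum_w loading(w,k)^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError
from .reflectance import ReflectanceSet


@dataclass
class CVSpectrum:
    group: object
    cv: np.ndarray  # dimensionless sd/mean; NaN where group mean <= 0
    n: int


@dataclass
class BootstrapCVEnvelope:
    group: object
    target_n: int
    reps: int
    cv_min: np.ndarray
    cv_max: np.ndarray
    cv_mean: np.ndarray
    seed: int


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # wavelengths x components
    explained_pct: np.ndarray  # per retained component, of total variance
    contributions: np.ndarray  # wavelengths x components, columns sum to 100
    center: np.ndarray
    n_components: int
    wavelengths: np.ndarray | None = None


def _cv(matrix: np.ndarray) -> np.ndarray:
    """Per-column sd/mean with the sample (n-1) sd; NaN where mean <= 0."""
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    cv = np.full_like(mean, np.nan)
    ok = mean > 0
    cv[ok] = sd[ok] / mean[ok]
    return cv


def group_cv(rs: ReflectanceSet, grouping: str) -> dict[object, CVSpectrum]:
    """CV spectrum per level of a metadata column (each level needs >= 2)."""
    meta = rs.meta_aligned()
    if grouping not in meta.columns:
        raise DesignError(f"metadata has no column {grouping!r}")
    out = {}
    labels = meta[grouping].to_numpy()
    for g in pd.unique(labels):
        rows = np.nonzero(labels == g)[0]
        if len(rows) < 2:
            raise DesignError(f"group {g!r} has {len(rows)} sample(s); CV needs >= 2")
        out[g] = CVSpectrum(group=g, cv=_cv(rs.cr[rows]), n=len(rows))
    return out


def bootstrap_cv(
    matrix: np.ndarray,
    target_n: int,
    reps: int = 100,
    seed: int = 0,
    replace: bool = False,
    group: object = None,
) -> BootstrapCVEnvelope:
    """CV envelope over repeated subsamples of size target_n.

    Subsamples are drawn without replacement by default (downscaling to a
    smaller group's size); set ``replace=True`` for a conventional bootstrap.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(matrix)
    if target_n >= n and not replace:
        raise ParameterError(f"target_n {target_n} must be < group size {n}")
    if target_n < 2:
        raise ParameterError("target_n must be >= 2")
    rng = np.random.default_rng(seed)
    cvs = np.empty((reps, matrix.shape[1]))
    for r in range(reps):
        rows = rng.choice(n, size=target_n, replace=replace)
        cvs[r] = _cv(matrix[rows])
    return BootstrapCVEnvelope(
        group=group,
        target_n=target_n,
        reps=reps,
        cv_min=np.nanmin(cvs, axis=0),
        cv_max=np.nanmax(cvs, axis=0),
        cv_mean=np.nanmean(cvs, axis=0),
        seed=seed,
    )


def pca(data, n_components: int = 8) -> PCAResult:
    """Covariance PCA of reflectance spectra via SVD of the centered matrix.

    ``data`` is a ReflectanceSet or a (samples x wavelengths) matrix.
    Component signs are fixed so each loading vector's largest-magnitude
    entry is positive, making results reproducible across SVD backends.
    """
    if isinstance(data, ReflectanceSet):
        matrix, wavelengths = data.cr, data.wavelengths
    else:
        matrix, wavelengths = np.asarray(data, dtype=float), None
    n, p = matrix.shape
    if n < 2:
        raise DesignError("PCA needs at least 2 samples")
    max_rank = min(n - 1, p)
    if n_components > max_rank:
        raise ParameterError(f"n_components {n_components} exceeds max rank {max_rank}")
    center = matrix.mean(axis=0)
    X = matrix - center
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s**2 / (n - 1)
    total = eigvals.sum()
    k = n_components
    loadings = Vt[:k].T.copy()  # wavelengths x k
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest |loading| entry positive per component
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    explained_pct = 100.0 * eigvals[:k] / total
    contributions = 100.0 * loadings**2 / (loadings**2).sum(axis=0, keepdims=True)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_pct=explained_pct,
        contributions=contributions,
        center=center,
        n_components=k,
        wavelengths=wavelengths,
    )


def top_contributing_wavelengths(
    p: PCAResult, k_components: int = 4, wavelengths: np.ndarray | None = None
) -> list[int]:
    """Distinct wavelengths contributing most to each of the first k PCs.

    Ties break toward the shorter wavelength; if a component's top wavelength
    was already taken by an earlier component, its next-highest contributor
    is used, so the result has k distinct wavelengths.
    """
    if wavelengths is None:
        wavelengths = p.wavelengths
    if wavelengths is None:
        wavelengths = np.arange(p.contributions.shape[0])
    wavelengths = np.asarray(wavelengths)
    if p.n_components < k_components:
        raise ParameterError(
            f"PCA has {p.n_components} components, {k_components} requested"
        )
    chosen: list[int] = []
    for comp in range(k_components):
        contrib = p.contributions[:, comp]
        # stable sort descending by contribution; ties keep grid (ascending nm) order
        order = np.argsort(-contrib, kind="stable")
        for idx in order:
            nm = int(wavelengths[idx])
            if nm not in chosen:
                chosen.append(nm)
                break
    return chosen
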