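"""Calculated reflectance and measurement uncertainty from leaf-clip scans.

The leaf clip measures each leaf against two backgrounds.  Writing the four
condition means as WR (bare white reference), WRL (leaf on white), BR (bare
black reference) and BRL (leaf on black), the background-corrected calculated
reflectance is

    CR = (WR * BRL - BR * WRL) / (WR - BR)

which is exact under a single-pass transmission model: if the leaf has true
reflectance R and transmittance T, then WRL = R + T^2 * WR and
BRL = R + T^2 * BR, and CR recovers R for any pair of distinct backgrounds.

The absolute uncertainty AU propagates the scan-to-scan standard deviations
STD_c of the four condition means (standard errors STD_c / sqrt(N)) through
that formula to first order, treating conditions as independent:

    AU^2 = (BR*(WRL-BRL)/(WR-BR)^2)^2 * (STD_WR/sqrt(N))^2
         + (BR/(WR-BR))^2             * (STD_WRL/sqrt(N))^2
         + (WR*(WRL-BRL)/(WR-BR)^2)^2 * (STD_BR/sqrt(N))^2
         + (WR/(WR-BR))^2             * (STD_BRL/sqrt(N))^2

and the relative uncertainty is RU = AU / CR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateBackgroundError, InsufficientDataError
from .spectra_io import ANALYSIS_GRID, CONDITIONS, ScanSet, WavelengthGrid

#: minimum admissible white-black background separation (the two references
#: differ by >> 0.5 in practice; anything near zero is an instrument fault)
DENOMINATOR_EPS = 1e-6

#: |CR| below this is treated as an unreliable divisor for RU and masked
RU_CR_FLOOR = 1e-4


@dataclass
class ConditionSummary:
    """Per-sample, per-condition mean spectrum and scan-to-scan dispersion."""

    sample_id: object
    condition: str
    mean: np.ndarray
    std: np.ndarray  # sample (n-1) standard deviation across retained scans
    n: int


@dataclass
class ReflectanceSet:
    """Calculated reflectance and uncertainties for a set of samples.

    ``cr``, ``au``, ``ru`` are (n_samples, n_wavelengths); ``ru`` is NaN where
    |CR| is below the masking floor.
    """

    sample_ids: list
    wavelengths: np.ndarray
    cr: np.ndarray
    au: np.ndarray
    ru: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id) -> int:
        return self.sample_ids.index(sample_id)

    def meta_aligned(self) -> pd.DataFrame:
        """Metadata rows aligned to sample order (raises on missing ids)."""
        return self.metadata.loc[self.sample_ids]

    def subset(self, sample_ids) -> "ReflectanceSet":
        keep = [self.sample_ids.index(s) for s in sample_ids]
        return ReflectanceSet(
            sample_ids=list(sample_ids),
            wavelengths=self.wavelengths,
            cr=self.cr[keep],
            au=self.au[keep],
            ru=self.ru[keep],
            metadata=self.metadata,
        )


def condition_means(scanset: ScanSet, sample_id) -> dict[str, ConditionSummary]:
    """Mean and sample SD across retained scans, per condition, one sample.

    Requires 3 or 4 retained scans in every condition (the nominal four
    post-first-scan scans, or three after a single outlier removal).
    """
    out: dict[str, ConditionSummary] = {}
    for cond in CONDITIONS:
        scans = scanset.scans_for(sample_id, cond)
        if len(scans) < 3:
            raise InsufficientDataError(
                f"sample {sample_id} condition {cond}: {len(scans)} retained scans (<3)"
            )
        out[cond] = ConditionSummary(
            sample_id=sample_id,
            condition=cond,
            mean=scans.mean(axis=0),
            std=scans.std(axis=0, ddof=1),
            n=len(scans),
        )
    return out


def _check_denominator(wr: np.ndarray, br: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    denom = wr - br
    bad = denom <= DENOMINATOR_EPS
    if bad.any():
        offenders = np.asarray(wavelengths)[bad][:10].tolist()
        raise DegenerateBackgroundError(
            f"white-black background separation <= {DENOMINATOR_EPS} at wavelengths {offenders}"
        )
    return denom


def calculated_reflectance(means: dict[str, ConditionSummary], wavelengths=None) -> np.ndarray:
    """CR = (WR*BRL - BR*WRL) / (WR - BR), elementwise; no clipping."""
    wr, wrl = means["WR"].mean, means["WRL"].mean
    br, brl = means["BR"].mean, means["BRL"].mean
    if wavelengths is None:
        wavelengths = np.arange(len(wr))
    denom = _check_denominator(wr, br, wavelengths)
    return (wr * brl - br * wrl) / denom


def absolute_uncertainty(means: dict[str, ConditionSummary], wavelengths=None) -> np.ndarray:
    """First-order propagated uncertainty of CR (positive square root)."""
    wr, wrl = means["WR"].mean, means["WRL"].mean
    br, brl = means["BR"].mean, means["BRL"].mean
    if wavelengths is None:
        wavelengths = np.arange(len(wr))
    denom = _check_denominator(wr, br, wavelengths)
    leaf_diff = wrl - brl
    se = {c: means[c].std / np.sqrt(means[c].n) for c in CONDITIONS}
    au2 = (
        (br * leaf_diff / denom**2) ** 2 * se["WR"] ** 2
        + (br / denom) ** 2 * se["WRL"] ** 2
        + (wr * leaf_diff / denom**2) ** 2 * se["BR"] ** 2
        + (wr / denom) ** 2 * se["BRL"] ** 2
    )
    return np.sqrt(au2)


def relative_uncertainty(au: np.ndarray, cr: np.ndarray, floor: float = RU_CR_FLOOR) -> np.ndarray:
    """RU = AU / CR, masked (NaN) where |CR| < floor rather than exploding."""
    cr = np.asarray(cr, dtype=float)
    au = np.asarray(au, dtype=float)
    ru = np.full_like(cr, np.nan)
    ok = np.abs(cr) >= floor
    ru[ok] = au[ok] / cr[ok]
    return ru


def trim_to_analysis_grid(
    wavelengths: np.ndarray, *arrays: np.ndarray, grid: WavelengthGrid = ANALYSIS_GRID
):
    """Restrict spectra to the analysis window (default 400-2500 nm).

    The shortest wavelengths (350-399 nm) have poor signal-to-noise on this
    class of instrument and are dropped before analysis.
    """
    wavelengths = np.asarray(wavelengths)
    keep = (wavelengths >= grid.start_nm) & (wavelengths <= grid.end_nm)
    trimmed = [np.asarray(a)[..., keep] for a in arrays]
    return (wavelengths[keep], *trimmed)


def compute_reflectance(
    scanset: ScanSet, trim: bool = True, sample_ids=None
) -> ReflectanceSet:
    """Condition means -> CR, AU, RU for every complete sample in a ScanSet."""
    if sample_ids is None:
        sample_ids = scanset.complete_samples()
    wl = scanset.grid.wavelengths
    crs, aus = [], []
    for sid in sample_ids:
        means = condition_means(scanset, sid)
        crs.append(calculated_reflectance(means, wl))
        aus.append(absolute_uncertainty(means, wl))
    if not sample_ids:
        raise InsufficientDataError("no complete samples to compute reflectance for")
    cr = np.vstack(crs)
    au = np.vstack(aus)
    if trim:
        wl, cr, au = trim_to_analysis_grid(wl, cr, au)
    ru = relative_uncertainty(au, cr)
    return ReflectanceSet(
        sample_ids=list(sample_ids),
        wavelengths=wl,
        cr=cr,
        au=au,
        ru=ru,
        metadata=scanset.metadata,
    )
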