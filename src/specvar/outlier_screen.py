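"""Three-step outlier screening of raw scan sets.

The screen formalizes a quality-control workflow for leaf-clip spectroscopy:

1. *Shape check* — a scan recorded under a bare-reference condition (WR, BR)
   must not look like a leaf, and a leaf-on-background scan (WRL, BRL) must
   not look like a flat reference.  Leaf-likeness is measured with a
   red-edge contrast index (v(800)-v(670)) / (v(800)+v(670)): vegetation has
   strong chlorophyll absorption at 670 nm and a NIR plateau at 800 nm, so
   leaves score high and flat references score near zero.
2. *Local Outlier Factor* — density-based outlier scores computed per
   measurement condition within each experiment, on the full spectral
   vector.  LOF compares each scan's local density with that of its
   neighbours, so genotype-driven clusters of unusual spectra are not
   penalized the way a global distance rule would penalize them.
3. *Post-reflectance check* — after calculated reflectance is available,
   samples whose CR leaves plausible physical bounds anywhere, or strays
   many robust deviations from their experiment x genotype-group median,
   are flagged; an explicit manual exclusion list is honoured verbatim.

In addition, the first scan of every condition is always dropped (signal
stabilization after clip opening), and a fixed removal policy applies: one
flagged scan in a condition drops that scan, two or more drop the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import LocalOutlierFactor

from .errors import ClassificationError, ConsistencyError, ParameterError
from .reflectance import ReflectanceSet
from .spectra_io import LEAF_CONDITIONS, REFERENCE_CONDITIONS, ScanSet

RED_EDGE_THRESHOLD = 0.3
#: Each sample contributes 4 retained scans per condition, so k = 3 makes a
#: scan's neighbourhood its own replicate cluster: replicate-scale density is
#: the right yardstick, and between-sample biological spread is not penalized.
DEFAULT_LOF_K = 3
DEFAULT_LOF_THRESHOLD = 1.5
CR_BOUNDS = (-0.02, 1.05)
MAD_MULTIPLIER = 6.0


@dataclass(frozen=True)
class OutlierFlag:
    """One flagged unit: a scan (scan_index set) or a whole sample (None)."""

    sample_id: object
    condition: str | None
    scan_index: int | None
    step: str  # shape | lof | post_reflectance | manual
    score: float | None = None
    note: str = ""


@dataclass
class FilterDecision:
    sample_id: object
    action: str  # keep | drop_scan | drop_sample
    retained: dict = field(default_factory=dict)  # condition -> sorted scan indices
    reason: str = ""


def drop_first_scans(s: ScanSet) -> ScanSet:
    """Remove scan_index 1 in every condition (stabilization scan)."""
    keep = (s.index["scan_index"] != 1).to_numpy()
    return s.subset_rows(keep)


def red_edge_index(values: np.ndarray, wavelengths: np.ndarray) -> float:
    """Normalized red-edge contrast between 800 nm and 670 nm."""
    wl = np.asarray(wavelengths)
    v670 = float(np.asarray(values)[..., int(np.searchsorted(wl, 670))])
    v800 = float(np.asarray(values)[..., int(np.searchsorted(wl, 800))])
    denom = v800 + v670
    if denom == 0:
        raise ClassificationError("red-edge index undefined: v(670) + v(800) = 0")
    return (v800 - v670) / denom


def classify_scan_shape(
    values: np.ndarray, wavelengths: np.ndarray, threshold: float = RED_EDGE_THRESHOLD
) -> str:
    """Classify a scan as leaf_like or reference_like by red-edge contrast."""
    return "leaf_like" if red_edge_index(values, wavelengths) > threshold else "reference_like"


def shape_flags(s: ScanSet, threshold: float = RED_EDGE_THRESHOLD) -> list[OutlierFlag]:
    """Flag scans whose shape class contradicts their recorded condition."""
    flags = []
    wl = s.grid.wavelengths
    for i in range(s.n_scans):
        row = s.index.iloc[i]
        idx = red_edge_index(s.values[i], wl)
        leafy = idx > threshold
        cond = row["condition"]
        if (cond in REFERENCE_CONDITIONS and leafy) or (cond in LEAF_CONDITIONS and not leafy):
            flags.append(
                OutlierFlag(
                    sample_id=row["sample_id"],
                    condition=cond,
                    scan_index=int(row["scan_index"]),
                    step="shape",
                    score=idx,
                    note=f"red-edge index {idx:.3f} inconsistent with condition {cond}",
                )
            )
    return flags


def lof_scores(X: np.ndarray, k: int) -> np.ndarray:
    """Local Outlier Factor scores (>= ~1; larger = more isolated)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ParameterError("lof_scores expects a 2-D scan matrix")
    n = len(X)
    if n < k + 1:
        raise ParameterError(f"LOF needs at least k+1={k + 1} scans, got {n}")
    lof = LocalOutlierFactor(n_neighbors=k, metric="euclidean")
    with warnings.catch_warnings():
        # duplicate scans produce infinite densities but still score correctly
        warnings.filterwarnings("ignore", message="Duplicate values")
        lof.fit(X)
    return -lof.negative_outlier_factor_


def lof_flags(
    s: ScanSet,
    k: int = DEFAULT_LOF_K,
    threshold: float = DEFAULT_LOF_THRESHOLD,
) -> list[OutlierFlag]:
    """LOF flags per measurement condition within each experiment.

    The neighbour count shrinks automatically to n-1 in small groups; groups
    with fewer than 4 scans are left unscored.
    """
    flags = []
    if len(s.metadata) and "experiment" in s.metadata.columns:
        experiment = s.index["sample_id"].map(s.metadata["experiment"]).fillna("?")
    else:
        experiment = pd.Series(["all"] * s.n_scans)
    groups = pd.DataFrame(
        {"experiment": experiment.to_numpy(), "condition": s.index["condition"].to_numpy()}
    )
    for _, rows in groups.groupby(["experiment", "condition"], sort=False).groups.items():
        rows = np.asarray(rows)
        n = len(rows)
        if n < 4:
            continue
        k_eff = min(k, n - 1)
        scores = lof_scores(s.values[rows], k_eff)
        for r, sc in zip(rows, scores):
            if sc > threshold:
                row = s.index.iloc[r]
                flags.append(
                    OutlierFlag(
                        sample_id=row["sample_id"],
                        condition=row["condition"],
                        scan_index=int(row["scan_index"]),
                        step="lof",
                        score=float(sc),
                        note=f"LOF {sc:.3f} > {threshold} (k={k_eff})",
                    )
                )
    return flags


def apply_outlier_policy(
    s: ScanSet, flags: list[OutlierFlag]
) -> tuple[ScanSet, list[FilterDecision]]:
    """Apply the scan-vs-sample removal policy to a first-scan-free ScanSet.

    Per sample and condition: no flags keeps all retained scans, exactly one
    flag drops that scan, two or more flags drop the whole sample.  Whole-
    sample flags (scan_index None) always drop the sample.
    """
    known = set(
        zip(s.index["sample_id"], s.index["condition"], s.index["scan_index"].astype(int))
    )
    sample_ids = set(s.sample_ids)
    scan_flags: dict[tuple, list[OutlierFlag]] = {}
    sample_drop: dict[object, str] = {}
    for f in flags:
        if f.sample_id not in sample_ids:
            raise ConsistencyError(f"flag references unknown sample {f.sample_id!r}")
        if f.scan_index is None:
            sample_drop.setdefault(f.sample_id, f"{f.step}: {f.note}")
            continue
        key = (f.sample_id, f.condition, int(f.scan_index))
        if key not in known:
            raise ConsistencyError(f"flag references unknown scan {key}")
        scan_flags.setdefault((f.sample_id, f.condition), []).append(f)

    decisions = []
    drop_rows = np.zeros(s.n_scans, dtype=bool)
    for sid in s.sample_ids:
        if sid in sample_drop:
            decisions.append(FilterDecision(sid, "drop_sample", reason=sample_drop[sid]))
            drop_rows |= (s.index["sample_id"] == sid).to_numpy()
            continue
        flagged_by_cond = {
            cond: sorted({int(f.scan_index) for f in fl})
            for (fsid, cond), fl in scan_flags.items()
            if fsid == sid
        }
        if any(len(fl) >= 2 for fl in flagged_by_cond.values()):
            worst = max(len(fl) for fl in flagged_by_cond.values())
            decisions.append(
                FilterDecision(sid, "drop_sample", reason=f"{worst} flagged scans in one condition")
            )
            drop_rows |= (s.index["sample_id"] == sid).to_numpy()
            continue
        action = "keep"
        for cond, fl in flagged_by_cond.items():
            action = "drop_scan"
            drop_rows |= (
                (s.index["sample_id"] == sid)
                & (s.index["condition"] == cond)
                & (s.index["scan_index"] == fl[0])
            ).to_numpy()
        retained = {
            cond: sorted(
                int(i)
                for i in s.index.loc[
                    (s.index["sample_id"] == sid)
                    & (s.index["condition"] == cond)
                    & ~drop_rows,
                    "scan_index",
                ]
            )
            for cond in s.conditions_present(sid)
        }
        if any(len(v) < 3 for v in retained.values()):
            decisions.append(
                FilterDecision(sid, "drop_sample", reason="fewer than 3 retained scans in a condition")
            )
            drop_rows |= (s.index["sample_id"] == sid).to_numpy()
            continue
        decisions.append(FilterDecision(sid, action, retained=retained))
    return s.subset_rows(~drop_rows), decisions


def post_reflectance_check(
    rs: ReflectanceSet,
    bounds: tuple[float, float] = CR_BOUNDS,
    mad_multiplier: float = MAD_MULTIPLIER,
    manual_exclusions=(),
) -> tuple[ReflectanceSet, list[OutlierFlag]]:
    """Flag and remove samples with implausible calculated reflectance.

    A sample is flagged when its CR leaves ``bounds`` at any analysis
    wavelength, or deviates more than ``mad_multiplier`` robust standard
    deviations (1.4826 * MAD) from the per-wavelength median of its
    experiment x genotype-group peers (groups of fewer than 3 samples skip
    the robust rule).  Samples on the manual exclusion list are always
    removed.
    """
    lo, hi = bounds
    flags: list[OutlierFlag] = []
    flagged: set = set()

    manual = set(manual_exclusions)
    for sid in rs.sample_ids:
        if sid in manual:
            flags.append(OutlierFlag(sid, None, None, "manual", note="manual exclusion list"))
            flagged.add(sid)

    out_lo = rs.cr < lo
    out_hi = rs.cr > hi
    for i, sid in enumerate(rs.sample_ids):
        if sid in flagged:
            continue
        bad = out_lo[i] | out_hi[i]
        if bad.any():
            nm = int(rs.wavelengths[np.argmax(bad)])
            flags.append(
                OutlierFlag(
                    sid, None, None, "post_reflectance",
                    score=float(rs.cr[i][bad][0]),
                    note=f"CR outside [{lo}, {hi}] at {nm} nm",
                )
            )
            flagged.add(sid)

    # robust within-group deviation rule
    if len(rs.metadata):
        meta = rs.metadata.reindex(rs.sample_ids)
        exp = meta.get("experiment", pd.Series("all", index=meta.index)).fillna("all")
        grp = meta.get("genotype_group", pd.Series("all", index=meta.index)).fillna("all")
        labels = list(zip(exp, grp))
    else:
        labels = [("all", "all")] * rs.n_samples
    labels = np.array([f"{a}|{b}" for a, b in labels])
    for lab in np.unique(labels):
        rows = np.nonzero(labels == lab)[0]
        if len(rows) < 3:
            continue
        block = rs.cr[rows]
        med = np.median(block, axis=0)
        # robust sd = 1.4826 * MAD (consistency constant for the normal),
        # floored so identical groups still detect shifts
        robust_sd = np.maximum(1.4826 * np.median(np.abs(block - med), axis=0), 1e-6)
        dev = np.abs(block - med) / robust_sd
        for j, i in enumerate(rows):
            sid = rs.sample_ids[i]
            if sid in flagged:
                continue
            worst = dev[j].max()
            if worst > mad_multiplier:
                nm = int(rs.wavelengths[int(np.argmax(dev[j]))])
                flags.append(
                    OutlierFlag(
                        sid, None, None, "post_reflectance",
                        score=float(worst),
                        note=f"{worst:.1f} MADs from group median at {nm} nm (group {lab})",
                    )
                )
                flagged.add(sid)

    keep = [sid for sid in rs.sample_ids if sid not in flagged]
    return rs.subset(keep), flags


@dataclass
class ScreenResult:
    scanset: ScanSet
    flags: list[OutlierFlag]
    decisions: list[FilterDecision]

    def audit_table(self) -> pd.DataFrame:
        """Audit CSV view: one row per flag plus one per sample decision."""
        rows = [
            {
                "sample_id": f.sample_id,
                "condition": f.condition,
                "scan_index": f.scan_index,
                "step": f.step,
                "score": f.score,
                "action": "",
                "note": f.note,
            }
            for f in self.flags
        ] + [
            {
                "sample_id": d.sample_id,
                "condition": None,
                "scan_index": None,
                "step": "policy",
                "score": None,
                "action": d.action,
                "note": d.reason,
            }
            for d in self.decisions
        ]
        return pd.DataFrame(rows)


def screen(
    s: ScanSet,
    lof_k: int = DEFAULT_LOF_K,
    lof_threshold: float = DEFAULT_LOF_THRESHOLD,
    shape_threshold: float = RED_EDGE_THRESHOLD,
) -> ScreenResult:
    """First-scan drop + shape check + LOF + removal policy, in order."""
    s = drop_first_scans(s)
    flags = shape_flags(s, threshold=shape_threshold)
    flags += lof_flags(s, k=lof_k, threshold=lof_threshold)
    cleaned, decisions = apply_outlier_policy(s, flags)
    return ScreenResult(scanset=cleaned, flags=flags, decisions=decisions)
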