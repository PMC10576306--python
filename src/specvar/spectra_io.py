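"""Data model and I/O for raw leaf-clip spectroradiometer scans.

A measurement session for one sample consists of 20 scans taken in four
conditions: the bare white reference (WR), the leaf pressed on the white
reference (WRL), the bare black reference (BR), and the leaf on the black
reference (BRL), five scans each.  Scans are vectors on an integer-nanometre
grid, 350-2500 nm as delivered by the instrument; analysis is restricted to
400-2500 nm downstream.

The canonical interchange format is a long CSV with columns
``sample_id, condition, scan_index, wavelength, value``; a wide dialect with
one column per wavelength is accepted for convenience.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, GridError, OutOfProtocolError

CONDITIONS = ("WR", "WRL", "BR", "BRL")
LEAF_CONDITIONS = ("WRL", "BRL")
REFERENCE_CONDITIONS = ("WR", "BR")

#: columns expected in a metadata table (besides the sample_id key)
METADATA_COLUMNS = (
    "plant_id",
    "genotype",
    "genotype_group",
    "experiment",
    "timestamp",
    "time_window",
    "batch",
    "leaf_number",
    "leaf_position",
)

GENOTYPE_GROUPS = ("REF_UTWT", "EV", "PL", "RIL", "TL")
EXPERIMENTS = ("Field_AZ", "Field_UT", "Glasshouse")

#: readings above this are flagged by validation (field instruments can exceed
#: 1 against an imperfect reference, so they are not rejected outright)
MAX_PLAUSIBLE_VALUE = 1.2


@dataclass(frozen=True)
class WavelengthGrid:
    """Integer-nanometre wavelength grid, closed interval, 1 nm step."""

    start_nm: int = 350
    end_nm: int = 2500
    step_nm: int = 1

    def __post_init__(self) -> None:
        if self.step_nm != 1:
            raise GridError(f"only 1 nm grids are supported, got step {self.step_nm}")
        if self.end_nm <= self.start_nm:
            raise GridError(f"grid end {self.end_nm} <= start {self.start_nm}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.end_nm - self.start_nm + 1

    def index_of(self, nm: int) -> int:
        if not self.start_nm <= nm <= self.end_nm:
            raise GridError(f"{nm} nm outside grid {self.start_nm}-{self.end_nm}")
        return int(nm) - self.start_nm


FULL_GRID = WavelengthGrid(350, 2500)
ANALYSIS_GRID = WavelengthGrid(400, 2500)


def assign_time_window(timestamp) -> str:
    """Bin a local clock time into the diurnal windows am / noon / pm.

    Windows partition the measurement day: am = [07:00, 12:00),
    noon = [12:00, 16:00), pm = [16:00, 20:00].  Measurements outside
    07:00-20:00 are out of protocol and raise rather than silently binning.

    ``timestamp`` may be a :class:`datetime.time`, :class:`datetime.datetime`,
    pandas timestamp, or an ``"HH:MM"`` string.
    """
    t = _as_time(timestamp)
    minutes = t.hour * 60 + t.minute
    if minutes < 7 * 60 or minutes > 20 * 60 or (minutes == 20 * 60 and (t.second or t.microsecond)):
        raise OutOfProtocolError(f"timestamp {t.isoformat()} outside 07:00-20:00 protocol")
    if minutes < 12 * 60:
        return "am"
    if minutes < 16 * 60:
        return "noon"
    return "pm"


def _as_time(timestamp) -> _dt.time:
    if isinstance(timestamp, _dt.datetime):
        return timestamp.time()
    if isinstance(timestamp, _dt.time):
        return timestamp
    if isinstance(timestamp, str):
        ts = pd.Timestamp(timestamp)
        return ts.time()
    if isinstance(timestamp, pd.Timestamp):
        return timestamp.time()
    raise TypeError(f"cannot interpret {timestamp!r} as a clock time")


@dataclass
class ScanSet:
    """Raw scans for many samples with row-aligned index and value matrix.

    ``index`` has one row per scan with columns ``sample_id``, ``condition``,
    ``scan_index``; row *i* of ``values`` is that scan's spectrum on ``grid``.
    ``metadata`` is indexed by ``sample_id``.
    """

    index: pd.DataFrame
    values: np.ndarray
    grid: WavelengthGrid = field(default_factory=lambda: FULL_GRID)
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.index = self.index.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.index):
            raise FormatError(
                f"values shape {self.values.shape} does not match {len(self.index)} index rows"
            )
        if self.values.shape[1] != self.grid.n:
            raise GridError(
                f"values have {self.values.shape[1]} wavelengths, grid has {self.grid.n}"
            )
        bad = set(self.index["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels {sorted(bad)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_scans(self) -> int:
        return len(self.index)

    @property
    def sample_ids(self) -> list:
        return list(pd.unique(self.index["sample_id"]))

    def scans_for(self, sample_id, condition: str) -> np.ndarray:
        mask = (self.index["sample_id"] == sample_id) & (self.index["condition"] == condition)
        return self.values[mask.to_numpy()]

    def subset_rows(self, mask: np.ndarray) -> "ScanSet":
        mask = np.asarray(mask, dtype=bool)
        return ScanSet(
            index=self.index.loc[mask].reset_index(drop=True),
            values=self.values[mask],
            grid=self.grid,
            metadata=self.metadata,
        )

    def drop_samples(self, sample_ids) -> "ScanSet":
        drop = set(sample_ids)
        keep = ~self.index["sample_id"].isin(drop).to_numpy()
        return self.subset_rows(keep)

    def conditions_present(self, sample_id) -> set:
        return set(self.index.loc[self.index["sample_id"] == sample_id, "condition"])

    def complete_samples(self) -> list:
        return [s for s in self.sample_ids if self.conditions_present(s) == set(CONDITIONS)]

    def incomplete_samples(self) -> list:
        return [s for s in self.sample_ids if self.conditions_present(s) != set(CONDITIONS)]


@dataclass
class ValidationReport:
    """Result of :func:`validate_scanset`; purely descriptive, never mutates."""

    incomplete_samples: list = field(default_factory=list)
    duplicate_scans: list = field(default_factory=list)  # (sample_id, condition, scan_index)
    negative_values: list = field(default_factory=list)  # (sample_id, condition, scan_index, nm)
    implausible_values: list = field(default_factory=list)  # values > MAX_PLAUSIBLE_VALUE
    missing_metadata: list = field(default_factory=list)
    inconsistent_time_windows: list = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not (
            self.incomplete_samples
            or self.duplicate_scans
            or self.negative_values
            or self.implausible_values
            or self.missing_metadata
            or self.inconsistent_time_windows
        )


def validate_scanset(s: ScanSet) -> ValidationReport:
    """Report structural problems in a ScanSet without modifying it."""
    report = ValidationReport()
    report.incomplete_samples = s.incomplete_samples()

    dup = s.index.duplicated(subset=["sample_id", "condition", "scan_index"], keep=False)
    if dup.any():
        report.duplicate_scans = [
            tuple(r) for r in s.index.loc[dup, ["sample_id", "condition", "scan_index"]].itertuples(index=False)
        ]

    wl = s.grid.wavelengths
    neg_rows, neg_cols = np.nonzero(s.values < 0)
    for r, c in zip(neg_rows, neg_cols):
        row = s.index.iloc[r]
        report.negative_values.append(
            (row["sample_id"], row["condition"], int(row["scan_index"]), int(wl[c]))
        )
    hi_rows, hi_cols = np.nonzero(s.values > MAX_PLAUSIBLE_VALUE)
    for r, c in zip(hi_rows, hi_cols):
        row = s.index.iloc[r]
        report.implausible_values.append(
            (row["sample_id"], row["condition"], int(row["scan_index"]), int(wl[c]))
        )

    if len(s.metadata):
        known = set(s.metadata.index)
        report.missing_metadata = [sid for sid in s.sample_ids if sid not in known]
        if {"timestamp", "time_window"}.issubset(s.metadata.columns):
            for sid, row in s.metadata.iterrows():
                ts, tw = row.get("timestamp"), row.get("time_window")
                if pd.isna(ts) or pd.isna(tw):
                    continue
                try:
                    derived = assign_time_window(ts)
                except (OutOfProtocolError, TypeError, ValueError):
                    report.inconsistent_time_windows.append(sid)
                    continue
                if derived != tw:
                    report.inconsistent_time_windows.append(sid)
    else:
        report.missing_metadata = list(s.sample_ids)
    return report


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ["sample_id", "condition", "scan_index", "wavelength", "value"]


def _normalize_conditions(series: pd.Series) -> pd.Series:
    norm = series.astype(str).str.strip().str.upper()
    bad = set(norm.unique()) - set(CONDITIONS)
    if bad:
        raise FormatError(f"unknown condition labels {sorted(bad)}; expected one of {CONDITIONS}")
    return norm


def _check_grid(wavelengths: np.ndarray) -> WavelengthGrid:
    wl = np.asarray(wavelengths)
    if len(wl) < 2:
        raise GridError("grid needs at least two wavelengths")
    diffs = np.diff(wl)
    if not np.all(diffs > 0):
        raise GridError("wavelength grid is not strictly increasing")
    if not np.all(diffs == 1):
        gaps = wl[:-1][diffs != 1]
        raise GridError(f"wavelength grid has gaps after {gaps[:5].tolist()} nm")
    return WavelengthGrid(int(wl[0]), int(wl[-1]))


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV keyed by sample_id; derive time_window."""
    meta = pd.read_csv(path, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise FormatError("metadata table must have a sample_id column")
    meta = meta.set_index("sample_id")
    if "leaf_number" in meta.columns:
        meta["leaf_number"] = meta["leaf_number"].fillna(1).astype(int)
    else:
        meta["leaf_number"] = 1
    if "timestamp" in meta.columns and "time_window" not in meta.columns:
        meta["time_window"] = [assign_time_window(t) for t in meta["timestamp"]]
    return meta


def read_scan_table(path, format: str = "long", metadata=None, grid: WavelengthGrid | None = None) -> ScanSet:
    """Read a scan table in the long or wide dialect into a ScanSet.

    Long: columns sample_id, condition, scan_index, wavelength, value.
    Wide: columns sample_id, condition, scan_index, then one numeric-named
    column per wavelength.  Condition labels are normalized case-insensitively.
    """
    if format not in ("long", "wide"):
        raise FormatError(f"unknown dialect {format!r}")
    df = pd.read_csv(path, dtype={"sample_id": str})
    if format == "long":
        missing = [c for c in _SCAN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"long table missing columns {missing}")
        df["condition"] = _normalize_conditions(df["condition"])
        wide = df.pivot_table(
            index=["sample_id", "condition", "scan_index"],
            columns="wavelength",
            values="value",
            sort=False,
        )
        wide = wide.reindex(columns=sorted(wide.columns))
        found = _check_grid(np.asarray(wide.columns, dtype=np.int64))
        index = wide.index.to_frame(index=False)
        values = wide.to_numpy()
    else:
        key_cols = ["sample_id", "condition", "scan_index"]
        missing = [c for c in key_cols if c not in df.columns]
        if missing:
            raise FormatError(f"wide table missing columns {missing}")
        df["condition"] = _normalize_conditions(df["condition"])
        wl_cols = [c for c in df.columns if c not in key_cols]
        try:
            wl = np.array([int(c) for c in wl_cols], dtype=np.int64)
        except ValueError as exc:
            raise FormatError(f"wide table has a non-wavelength column: {exc}") from exc
        order = np.argsort(wl)
        found = _check_grid(wl[order])
        index = df[key_cols].copy()
        values = df[np.array(wl_cols)[order]].to_numpy(dtype=np.float64)

    if grid is not None and (grid.start_nm != found.start_nm or grid.end_nm != found.end_nm):
        raise GridError(
            f"file grid {found.start_nm}-{found.end_nm} differs from declared "
            f"{grid.start_nm}-{grid.end_nm}"
        )
    if np.isnan(values).any():
        raise FormatError("scan table has missing values on the wavelength grid")

    meta = pd.DataFrame()
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    return ScanSet(index=index, values=values, grid=found, metadata=meta)


def write_scan_table(s: ScanSet, path, format: str = "long") -> None:
    """Write a ScanSet in the long or wide dialect (lossless round-trip)."""
    wl = s.grid.wavelengths
    if format == "long":
        n = s.n_scans
        out = pd.DataFrame(
            {
                "sample_id": np.repeat(s.index["sample_id"].to_numpy(), s.grid.n),
                "condition": np.repeat(s.index["condition"].to_numpy(), s.grid.n),
                "scan_index": np.repeat(s.index["scan_index"].to_numpy(), s.grid.n),
                "wavelength": np.tile(wl, n),
                "value": s.values.ravel(),
            }
        )
        out.to_csv(path, index=False)
    elif format == "wide":
        out = pd.concat(
            [s.index.reset_index(drop=True), pd.DataFrame(s.values, columns=wl)], axis=1
        )
        out.to_csv(path, index=False)
    else:
        raise FormatError(f"unknown dialect {format!r}")


def write_tidy(table: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    """Write a result table as plain CSV; refuses empty tables."""
    if table is None or len(table) == 0:
        raise FormatError("refusing to write an empty result table")
    table.to_csv(path, index=False, float_format=float_format)


def reflectance_to_tidy(rs) -> pd.DataFrame:
    """Long-format view of a ReflectanceSet: sample_id, wavelength, CR, AU, RU."""
    n_wl = len(rs.wavelengths)
    return pd.DataFrame(
        {
            "sample_id": np.repeat(np.asarray(rs.sample_ids, dtype=object), n_wl),
            "wavelength": np.tile(rs.wavelengths, len(rs.sample_ids)),
            "CR": rs.cr.ravel(),
            "AU": rs.au.ravel(),
            "RU": rs.ru.ravel(),
        }
    )
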