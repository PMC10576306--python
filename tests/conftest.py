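import numpy as np
import pandas as pd
import pytest

from specvar.reflectance import ReflectanceSet
from specvar.spectra_io import FULL_GRID, ScanSet
from specvar.synthetic_data import DesignSpec, simulate_experiment


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec(seed=42, groups={"REF_UTWT": 3, "PL": 3})


@pytest.fixture(scope="session")
def small_scanset(small_design):
    scanset, truth = simulate_experiment(small_design)
    return scanset, truth


@pytest.fixture(scope="session")
def noiseless_scanset(small_design):
    scanset, truth = simulate_experiment(small_design.noiseless())
    return scanset, truth


def make_flat_scanset(n_samples=2, level=0.5, n_scans=5, grid=FULL_GRID, metadata=None):
    """Uniform constant-valued scans: a minimal structurally valid ScanSet."""
    rows, values = [], []
    for s in range(n_samples):
        for cond in ("WR", "WRL", "BR", "BRL"):
            for k in range(1, n_scans + 1):
                rows.append((f"S{s}", cond, k))
                values.append(np.full(grid.n, level))
    index = pd.DataFrame(rows, columns=["sample_id", "condition", "scan_index"])
    meta = metadata if metadata is not None else pd.DataFrame(
        {"sample_id": [f"S{s}" for s in range(n_samples)], "experiment": "Glasshouse"}
    ).set_index("sample_id")
    return ScanSet(index=index, values=np.array(values), grid=grid, metadata=meta)


def make_reflectance_set(cr, metadata, wavelengths=None):
    """ReflectanceSet from a CR matrix with zero uncertainties."""
    cr = np.asarray(cr, dtype=float)
    if wavelengths is None:
        wavelengths = np.arange(400, 400 + cr.shape[1])
    return ReflectanceSet(
        sample_ids=list(metadata.index),
        wavelengths=np.asarray(wavelengths),
        cr=cr,
        au=np.zeros_like(cr),
        ru=np.zeros_like(cr),
        metadata=metadata,
    )
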