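"""Synthetic leaf-clip experiments with known ground truth.

The generator builds raw 20-scan measurement sets with the statistical and
physical structure the analysis pipeline assumes, so every stage can be
verified against known truth:

* a smooth leaf reflectance/transmittance template with the canonical
  vegetation features — low VIS baseline with a green peak near 550 nm, a
  logistic red edge near 700-730 nm, a NIR plateau, water-absorption dips
  near 1450 and 1940 nm, and a SWIR decline;
* additive genotype-group effect spectra (e.g. a VIS bump for natural
  variants, a SWIR shift for transgenic-like groups), plant-level random
  intercepts, batch and diurnal-time effects, and per-sample residual
  deviations, plus an optional multiplicative "brightness" factor;
* the dual-background forward model WR = B_w, BR = B_b,
  WRL = R + T^2 B_w, BRL = R + T^2 B_b under which calculated reflectance
  is exact;
* five scans per condition with a small first-scan bias (why the first scan
  is always dropped) and additive plus multiplicative scan noise;
* labelled contaminants of the three kinds the outlier screen targets:
  condition swaps, spectral spikes, and global shifts.

All randomness flows from one seed through per-sample counter-keyed
streams, so any subset of samples is reproducible independently of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .spectra_io import CONDITIONS, FULL_GRID, ScanSet, WavelengthGrid

_WINDOW_TIMES = {"am": "09:30", "noon": "14:00", "pm": "17:30"}


@dataclass
class LeafTemplate:
    """True leaf reflectance and transmittance on the full instrument grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray

    def __post_init__(self):
        r, t = self.reflectance, self.transmittance
        if (r < 0).any() or (t < 0).any() or (r + t > 1 + 1e-12).any():
            raise ParameterError("leaf template must satisfy 0 <= R, T and R + T <= 1")


def make_leaf_template(
    grid: WavelengthGrid = FULL_GRID,
    vis_base: float = 0.05,
    green_peak_amp: float = 0.06,
    green_peak_nm: float = 550.0,
    green_peak_sd: float = 35.0,
    red_edge_nm: float = 715.0,
    red_edge_width: float = 12.0,
    nir_plateau: float = 0.48,
    water_dip_1450: float = 0.35,
    water_dip_1940: float = 0.55,
    water_dip_sd: tuple = (45.0, 60.0),
    swir_decline: float = 0.25,
    transmittance_ratio: float = 0.85,
) -> LeafTemplate:
    """Construct a smooth, physically plausible leaf optical template.

    Water dips and the SWIR decline are applied multiplicatively so the
    spectrum stays positive; transmittance is a scaled copy of reflectance
    (``transmittance_ratio`` < 1/nir_plateau - 1 keeps R + T <= 1).
    """
    wl = grid.wavelengths.astype(float)
    vis = vis_base + green_peak_amp * np.exp(-0.5 * ((wl - green_peak_nm) / green_peak_sd) ** 2)
    rise = 1.0 / (1.0 + np.exp(-(wl - red_edge_nm) / red_edge_width))
    r = vis + (nir_plateau - vis) * rise
    dip = (
        water_dip_1450 * np.exp(-0.5 * ((wl - 1450.0) / water_dip_sd[0]) ** 2)
        + water_dip_1940 * np.exp(-0.5 * ((wl - 1940.0) / water_dip_sd[1]) ** 2)
        + swir_decline * np.clip((wl - 1900.0) / 600.0, 0.0, 1.0)
    )
    r = r * np.clip(1.0 - dip, 0.05, 1.0)
    t = transmittance_ratio * r
    return LeafTemplate(wavelengths=grid.wavelengths, reflectance=r, transmittance=t)


@dataclass(frozen=True)
class EffectSpec:
    """Additive effect spectrum delta(lambda) for one factor level."""

    factor: str
    level: object
    delta: np.ndarray


def window_effect(factor, level, amplitude, start_nm, end_nm, grid: WavelengthGrid = FULL_GRID):
    """Flat additive effect over a closed wavelength window."""
    wl = grid.wavelengths
    delta = np.where((wl >= start_nm) & (wl <= end_nm), float(amplitude), 0.0)
    return EffectSpec(factor=factor, level=level, delta=delta)


def gaussian_effect(factor, level, amplitude, center_nm, sd_nm, grid: WavelengthGrid = FULL_GRID):
    """Smooth Gaussian-shaped additive effect."""
    wl = grid.wavelengths.astype(float)
    delta = float(amplitude) * np.exp(-0.5 * ((wl - center_nm) / sd_nm) ** 2)
    return EffectSpec(factor=factor, level=level, delta=delta)


@dataclass
class DesignSpec:
    """Experiment layout and variance components for the generator.

    Magnitudes are additive on the reflectance-factor scale (dimensionless).
    Defaults give within-group CVs of roughly 5-20% in the VIS and a few
    percent in the NIR, and relative measurement uncertainty below 1% over
    most of the spectrum — the regime a well-operated leaf clip produces.
    """

    seed: int
    groups: dict = field(default_factory=lambda: {"REF_UTWT": 10, "PL": 10})
    group_genotype_group: dict = field(default_factory=dict)  # group -> metadata group label
    times: tuple = ("am",)
    n_batches: int = 1
    experiment: str = "Glasshouse"
    two_leaf_prob: float = 0.0
    plant_sd: float = 0.008
    batch_sd: float = 0.003
    residual_sd: float = 0.008
    brightness_sd: float = 0.03
    #: smooth leaf-to-leaf biochemical variability: pigment depth in the VIS
    #: and water-band depth in the SWIR, independent per sample, so sample
    #: spectra vary in several directions as real leaves do
    pigment_jitter_sd: float = 0.004
    water_jitter_sd: float = 0.006
    time_effects: dict = field(default_factory=lambda: {"am": 0.0, "noon": 0.004, "pm": -0.003})
    leaf_number_effect: float = 0.005
    scan_additive_sd: float = 5e-4
    scan_multiplicative_sd: float = 1e-3
    first_scan_bias: float = 0.005
    n_scans: int = 5
    background_white: float = 0.98
    background_black: float = 0.03

    def __post_init__(self):
        for name in ("plant_sd", "batch_sd", "residual_sd", "brightness_sd",
                     "scan_additive_sd", "scan_multiplicative_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.seed is None:
            raise ParameterError("a seed is mandatory")

    def noiseless(self) -> "DesignSpec":
        """Copy with every stochastic component and bias switched off."""
        from dataclasses import replace

        return replace(
            self,
            plant_sd=0.0,
            batch_sd=0.0,
            residual_sd=0.0,
            brightness_sd=0.0,
            time_effects={t: self.time_effects.get(t, 0.0) for t in self.times},
            pigment_jitter_sd=0.0,
            water_jitter_sd=0.0,
            scan_additive_sd=0.0,
            scan_multiplicative_sd=0.0,
            first_scan_bias=0.0,
        )


@dataclass
class GroundTruth:
    """What the generator actually did: truth for recovery tests."""

    template: LeafTemplate
    samples: pd.DataFrame  # one row per sample with realized effects
    true_r: np.ndarray  # n_samples x n_wavelengths, after all effects
    outlier_labels: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "condition", "scan_index", "kind"])
    )


def _sample_rng(seed: int, sample_counter: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, sample_counter)))


def simulate_experiment(
    design: DesignSpec,
    effects: tuple = (),
    template: LeafTemplate | None = None,
) -> tuple[ScanSet, GroundTruth]:
    """Generate a raw ScanSet plus ground truth for one experiment.

    Each plant contributes one sample per measurement time; each sample has
    ``n_scans`` scans in each of the four conditions.  Sample-level effects
    are flat (wavelength-constant) offsets except the named effect spectra,
    so the per-wavelength linear models downstream are correctly specified.
    """
    if template is None:
        template = make_leaf_template()
    grid = WavelengthGrid(int(template.wavelengths[0]), int(template.wavelengths[-1]))
    wl_n = grid.n
    b_w = np.full(wl_n, design.background_white)
    b_b = np.full(wl_n, design.background_black)
    t2 = template.transmittance**2

    effect_map: dict[object, np.ndarray] = {}
    for e in effects:
        effect_map.setdefault(e.level, np.zeros(wl_n))
        effect_map[e.level] = effect_map[e.level] + e.delta

    wl_f = grid.wavelengths.astype(float)
    pigment_shape = np.exp(-0.5 * ((wl_f - 550.0) / 60.0) ** 2)
    water_shape_1 = np.exp(-0.5 * ((wl_f - 1450.0) / 45.0) ** 2)
    water_shape_2 = np.exp(-0.5 * ((wl_f - 1940.0) / 60.0) ** 2)

    structure_rng = np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=(0,)))
    batch_effects = structure_rng.normal(0.0, design.batch_sd, size=max(design.n_batches, 1))

    # enumerate plants in a fixed order; draw plant intercepts from the
    # structure stream so they are shared across measurement times
    plants = []
    for group in design.groups:
        for p in range(design.groups[group]):
            plants.append((group, p + 1))
    plant_intercepts = structure_rng.normal(0.0, design.plant_sd, size=len(plants))

    index_rows, values, truth_rows, true_rs = [], [], [], []
    counter = 0
    for plant_i, (group, p) in enumerate(plants):
        plant_id = f"{group}-P{p:03d}"
        batch = (plant_i % design.n_batches) + 1 if design.n_batches else 1
        for time in design.times:
            sid = f"{design.experiment}:{plant_id}:{time}"
            rng = _sample_rng(design.seed, counter)
            counter += 1
            leaf_number = 2 if rng.random() < design.two_leaf_prob else 1
            resid = rng.normal(0.0, design.residual_sd) if design.residual_sd else 0.0
            brightness = 1.0 + (rng.normal(0.0, design.brightness_sd) if design.brightness_sd else 0.0)
            pig = rng.normal(0.0, design.pigment_jitter_sd) if design.pigment_jitter_sd else 0.0
            wat1 = rng.normal(0.0, design.water_jitter_sd) if design.water_jitter_sd else 0.0
            wat2 = rng.normal(0.0, design.water_jitter_sd) if design.water_jitter_sd else 0.0
            r = template.reflectance + effect_map.get(group, 0.0)
            r = r + plant_intercepts[plant_i] + batch_effects[batch - 1]
            r = r + design.time_effects.get(time, 0.0)
            r = r + design.leaf_number_effect * (leaf_number - 1) + resid
            r = r + pig * pigment_shape + wat1 * water_shape_1 + wat2 * water_shape_2
            r = np.clip(r * brightness, 0.0, 1.0)

            signals = {
                "WR": b_w,
                "WRL": r + t2 * b_w,
                "BR": b_b,
                "BRL": r + t2 * b_b,
            }
            for cond in CONDITIONS:
                base = signals[cond]
                for scan_idx in range(1, design.n_scans + 1):
                    v = base.copy()
                    if scan_idx == 1:
                        v = v + design.first_scan_bias
                    if design.scan_multiplicative_sd:
                        v = v * (1.0 + rng.normal(0.0, design.scan_multiplicative_sd, wl_n))
                    if design.scan_additive_sd:
                        v = v + rng.normal(0.0, design.scan_additive_sd, wl_n)
                    index_rows.append((sid, cond, scan_idx))
                    values.append(v)

            truth_rows.append(
                {
                    "sample_id": sid,
                    "plant_id": plant_id,
                    "group": group,
                    "time_window": time,
                    "batch": batch,
                    "leaf_number": leaf_number,
                    "plant_intercept": plant_intercepts[plant_i],
                    "batch_effect": batch_effects[batch - 1],
                    "residual": resid,
                    "brightness": brightness,
                    "pigment_jitter": pig,
                    "water_jitter_1450": wat1,
                    "water_jitter_1940": wat2,
                }
            )
            true_rs.append(r)

    index = pd.DataFrame(index_rows, columns=["sample_id", "condition", "scan_index"])
    truth = pd.DataFrame(truth_rows)
    metadata = pd.DataFrame(
        {
            "sample_id": truth["sample_id"],
            "plant_id": truth["plant_id"],
            "genotype": truth["group"],
            "genotype_group": truth["group"].map(
                lambda g: design.group_genotype_group.get(g, g)
            ),
            "experiment": design.experiment,
            "timestamp": truth["time_window"].map(_WINDOW_TIMES),
            "time_window": truth["time_window"],
            "batch": truth["batch"],
            "leaf_number": truth["leaf_number"],
            "leaf_position": pd.NA,
        }
    ).set_index("sample_id")

    scanset = ScanSet(index=index, values=np.vstack(values), grid=grid, metadata=metadata)
    ground_truth = GroundTruth(template=template, samples=truth, true_r=np.vstack(true_rs))
    return scanset, ground_truth


def inject_outliers(
    s: ScanSet,
    n_condition_swap: int = 0,
    n_spike: int = 0,
    n_global_shift: int = 0,
    seed: int = 0,
    spike_factor: float = 10.0,
    spike_window_nm: int = 200,
    shift: float = 0.3,
) -> tuple[ScanSet, pd.DataFrame]:
    """Contaminate a ScanSet with the three outlier kinds the screen targets.

    * ``condition_swap`` — a bare-reference scan (WR/BR, scan 2-5) is replaced
      by the same sample's leaf-on-background scan, creating the classic
      "leaf spectrum recorded as a reference" mistake;
    * ``spike`` — one leaf scan is multiplied by ``spike_factor`` over a
      random 200 nm window (detector / contact artefact);
    * ``global_shift`` — every scan of one sample is offset by ``shift``
      (wrong reference calibration), visible only after reflectance.

    Each contaminated sample hosts exactly one contamination kind, so the
    labels identify disjoint units.  Returns the contaminated set and a
    label table (sample_id, condition, scan_index, kind).
    """
    rng = np.random.default_rng(seed)
    samples = list(s.sample_ids)
    need = n_condition_swap + n_spike + n_global_shift
    if need > len(samples):
        raise ParameterError(f"{need} contaminations requested for {len(samples)} samples")
    chosen = rng.choice(len(samples), size=need, replace=False)
    swap_s = [samples[i] for i in chosen[:n_condition_swap]]
    spike_s = [samples[i] for i in chosen[n_condition_swap : n_condition_swap + n_spike]]
    shift_s = [samples[i] for i in chosen[n_condition_swap + n_spike :]]

    values = s.values.copy()
    labels = []
    idx = s.index

    def _row(sample_id, condition, scan_index):
        m = (
            (idx["sample_id"] == sample_id)
            & (idx["condition"] == condition)
            & (idx["scan_index"] == scan_index)
        ).to_numpy()
        pos = np.nonzero(m)[0]
        if len(pos) != 1:
            raise ParameterError(f"cannot locate scan {(sample_id, condition, scan_index)}")
        return int(pos[0])

    for sid in swap_s:
        cond = str(rng.choice(["WR", "BR"]))
        scan = int(rng.integers(2, 6))
        leaf_cond = "WRL" if cond == "WR" else "BRL"
        values[_row(sid, cond, scan)] = values[_row(sid, leaf_cond, scan)]
        labels.append({"sample_id": sid, "condition": cond, "scan_index": scan, "kind": "condition_swap"})

    wl = s.grid.wavelengths
    for sid in spike_s:
        cond = str(rng.choice(["WRL", "BRL"]))
        scan = int(rng.integers(2, 6))
        start = int(rng.integers(wl[0], wl[-1] - spike_window_nm))
        window = (wl >= start) & (wl < start + spike_window_nm)
        r = _row(sid, cond, scan)
        values[r] = np.where(window, values[r] * spike_factor, values[r])
        labels.append({"sample_id": sid, "condition": cond, "scan_index": scan, "kind": "spike"})

    for sid in shift_s:
        rows = (idx["sample_id"] == sid).to_numpy()
        values[rows] += shift
        labels.append({"sample_id": sid, "condition": None, "scan_index": None, "kind": "global_shift"})

    contaminated = ScanSet(index=s.index.copy(), values=values, grid=s.grid, metadata=s.metadata)
    label_df = pd.DataFrame(labels, columns=["sample_id", "condition", "scan_index", "kind"])
    return contaminated, label_df
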