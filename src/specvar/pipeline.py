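"""End-to-end orchestration: ingest -> screen -> reflectance -> stats -> models.

Stages communicate through tidy CSV files in the output directory so any
stage can be rerun or inspected independently; a JSON manifest reconciles
row counts (n_in = n_out + n_removed at every stage) and records every
removal with its reason.  All stochastic stages consume only the config
seed, so a rerun with identical config and inputs writes identical result
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import outlier_screen, spectral_stats
from .errors import DesignError, SpecvarError
from .models import (
    ModelSpec,
    fit_anova_spectrum,
    fit_lmm_spectrum,
    fit_ols_spectrum,
    regions_table,
)
from .reflectance import ReflectanceSet, compute_reflectance
from .spectra_io import read_metadata, read_scan_table, reflectance_to_tidy, write_tidy

log = logging.getLogger("specvar")

__version__ = "0.1.0"


@dataclass
class RunConfig:
    scans: str
    metadata: str
    out_dir: str
    scan_format: str = "long"
    seed: int = 0
    alpha: float = 0.05
    lof_k: int = outlier_screen.DEFAULT_LOF_K
    lof_threshold: float = outlier_screen.DEFAULT_LOF_THRESHOLD
    shape_threshold: float = outlier_screen.RED_EDGE_THRESHOLD
    manual_exclusions: tuple = ()
    cv_groupby: str | None = "genotype_group"
    pca_components: int = 4
    models: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def canonical_json(self) -> str:
        d = asdict(self)
        d["manual_exclusions"] = list(d["manual_exclusions"])
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: list = field(default_factory=list)
    removals: list = field(default_factory=list)
    written_at: str = ""

    def add_stage(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out, "n_removed": n_in - n_out})

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "stages": self.stages,
                "removals": self.removals,
                "written_at": self.written_at,
            },
            indent=2,
        )


def subset_samples(rs: ReflectanceSet, rule: dict) -> ReflectanceSet:
    """Filter samples by a metadata predicate {column: allowed values}."""
    meta = rs.meta_aligned()
    keep = np.ones(rs.n_samples, dtype=bool)
    for col, allowed in rule.items():
        if col not in meta.columns:
            raise DesignError(f"subset rule references unknown metadata column {col!r}")
        allowed = allowed if isinstance(allowed, (list, tuple, set)) else [allowed]
        keep &= meta[col].isin(list(allowed)).to_numpy()
    ids = [s for s, k in zip(rs.sample_ids, keep) if k]
    if not ids:
        raise DesignError(f"subset rule {rule} matches no samples")
    log.info("subset %s: %d of %d samples", rule, len(ids), rs.n_samples)
    return rs.subset(ids)


def paper_models_template() -> list[dict]:
    """The eight standard model analyses as config entries.

    Covers: (1) reference-genotype ANOVA across experiments; (2-3) OLS for
    the high-throughput field screen with and without genotype groups;
    (4-6) glasshouse reference / natural-variant / transgenic contrasts;
    (7-8) mixed models for the repeated-measures field experiments.
    """
    return [
        {"name": "model1_experiment_anova", "kind": "anova", "factor": "experiment",
         "subset": {"genotype_group": ["REF_UTWT"]}},
        {"name": "model2_az_full_ols", "kind": "ols",
         "fixed": ["genotype_group", "time_window", "batch", "leaf_number"],
         "subset": {"experiment": ["Field_AZ"]}},
        {"name": "model3_az_ref_ols", "kind": "ols",
         "fixed": ["time_window", "batch", "leaf_number"],
         "subset": {"experiment": ["Field_AZ"], "genotype_group": ["REF_UTWT"]}},
        {"name": "model4_gh_reference_anova", "kind": "anova", "factor": "genotype",
         "subset": {"experiment": ["Glasshouse"], "genotype_group": ["REF_UTWT", "EV"]}},
        {"name": "model5_gh_pl_anova", "kind": "anova", "factor": "genotype_group",
         "subset": {"experiment": ["Glasshouse"], "genotype_group": ["PL", "REF_UTWT"]}},
        {"name": "model6_gh_tl_ols", "kind": "ols", "fixed": ["genotype"],
         "subset": {"experiment": ["Glasshouse"], "genotype_group": ["TL", "EV"]}},
        {"name": "model7_ut_screen_lmm", "kind": "lmm",
         "fixed": ["time_window", "genotype"],
         "interactions": [["time_window", "genotype"]], "random": "plant_id",
         "subset": {"experiment": ["Field_UT"], "genotype_group": ["TL", "EV"]}},
        {"name": "model8_ut_leafpos_lmm", "kind": "lmm",
         "fixed": ["time_window", "leaf_position"], "random": "plant_id",
         "subset": {"experiment": ["Field_UT"], "genotype_group": ["REF_UTWT"]}},
    ]


def _validate_models(models: list[dict], meta: pd.DataFrame) -> None:
    for m in models:
        cols = list(m.get("fixed", [])) + ([m["factor"]] if "factor" in m else [])
        if m.get("random"):
            cols.append(m["random"])
        cols += list(m.get("subset", {}))
        missing = [c for c in cols if c not in meta.columns]
        if missing:
            raise DesignError(f"model {m.get('name')}: metadata lacks columns {missing}")


def run_model(rs: ReflectanceSet, m: dict, alpha: float, out_dir: Path) -> dict:
    """Fit one configured model and write its result tables."""
    sub = subset_samples(rs, m.get("subset", {})) if m.get("subset") else rs
    kind = m["kind"]
    if kind == "anova":
        res = fit_anova_spectrum(sub, m["factor"], eta_ci=m.get("eta_ci", False))
    elif kind == "ols":
        spec = ModelSpec(fixed=tuple(m.get("fixed", ())),
                         interactions=tuple(tuple(t) for t in m.get("interactions", ())),
                         references=m.get("references", {}))
        res = fit_ols_spectrum(sub, spec)
    elif kind == "lmm":
        spec = ModelSpec(fixed=tuple(m.get("fixed", ())),
                         interactions=tuple(tuple(t) for t in m.get("interactions", ())),
                         random=m["random"], references=m.get("references", {}))
        res = fit_lmm_spectrum(sub, spec, wavelengths=m.get("wavelengths"))
    else:
        raise DesignError(f"unknown model kind {kind!r}")
    mdir = out_dir / m["name"]
    mdir.mkdir(parents=True, exist_ok=True)
    write_tidy(res.stats.reset_index(), mdir / "stats.csv")
    if res.coefficients is not None:
        write_tidy(res.coefficients, mdir / "coefficients.csv")
    regions = res.significant_regions(alpha=alpha, label=m["name"])
    if regions:
        write_tidy(regions_table(regions), mdir / "regions.csv")
    return {"name": m["name"], "kind": kind, "n_samples": sub.n_samples,
            "n_regions": len(regions)}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order, writing result tables and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)

    try:
        meta = read_metadata(config.metadata)
        scanset = read_scan_table(config.scans, format=config.scan_format, metadata=meta)
    except SpecvarError as exc:
        raise SpecvarError(f"stage ingest: {exc}") from exc
    if config.models:
        _validate_models(config.models, meta)
    n0 = len(scanset.sample_ids)
    manifest.add_stage("ingest", n0, n0)

    try:
        screened = outlier_screen.screen(
            scanset,
            lof_k=config.lof_k,
            lof_threshold=config.lof_threshold,
            shape_threshold=config.shape_threshold,
        )
    except SpecvarError as exc:
        raise SpecvarError(f"stage screen: {exc}") from exc
    write_tidy(screened.audit_table(), out / "screen_audit.csv") if len(
        screened.audit_table()
    ) else None
    n1 = len(screened.scanset.sample_ids)
    manifest.add_stage("screen", n0, n1)
    for d in screened.decisions:
        if d.action == "drop_sample":
            manifest.removals.append({"stage": "screen", "sample_id": str(d.sample_id),
                                      "reason": d.reason})

    try:
        rs = compute_reflectance(screened.scanset)
        rs, post_flags = outlier_screen.post_reflectance_check(
            rs, manual_exclusions=config.manual_exclusions
        )
    except SpecvarError as exc:
        raise SpecvarError(f"stage reflectance: {exc}") from exc
    manifest.add_stage("reflectance", n1, rs.n_samples)
    for f in post_flags:
        manifest.removals.append({"stage": "post_reflectance", "sample_id": str(f.sample_id),
                                  "reason": f.note})
    write_tidy(reflectance_to_tidy(rs), out / "reflectance.csv")

    if config.cv_groupby and config.cv_groupby in rs.metadata.columns:
        try:
            cvs = spectral_stats.group_cv(rs, config.cv_groupby)
        except DesignError as exc:
            log.warning("CV stage skipped: %s", exc)
        else:
            rows = [
                pd.DataFrame({"group": c.group, "wavelength": rs.wavelengths, "cv": c.cv, "n": c.n})
                for c in cvs.values()
            ]
            write_tidy(pd.concat(rows, ignore_index=True), out / "cv.csv")

    if config.pca_components:
        k = min(config.pca_components, rs.n_samples - 1)
        p = spectral_stats.pca(rs, n_components=k)
        write_tidy(
            pd.DataFrame(
                {"component": np.arange(1, k + 1), "explained_pct": p.explained_pct}
            ),
            out / "pca_explained.csv",
        )
        contrib = pd.DataFrame(
            p.contributions, columns=[f"PC{i + 1}" for i in range(k)]
        )
        contrib.insert(0, "wavelength", rs.wavelengths)
        write_tidy(contrib, out / "pca_contributions.csv")
        scores = pd.DataFrame(p.scores, columns=[f"PC{i + 1}" for i in range(k)])
        scores.insert(0, "sample_id", rs.sample_ids)
        write_tidy(scores, out / "pca_scores.csv")

    model_summaries = []
    for m in config.models:
        try:
            model_summaries.append(run_model(rs, m, config.alpha, out))
        except SpecvarError as exc:
            raise SpecvarError(f"stage model {m.get('name')}: {exc}") from exc
    manifest.add_stage("models", rs.n_samples, rs.n_samples)

    manifest.written_at = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
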