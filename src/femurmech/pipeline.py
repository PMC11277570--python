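"""End-to-end cohort pipeline: generate → measure → solve → fracture → stats.

``run_cohort`` drives the whole study for one synthetic cohort: femur
geometries are built from sampled morphologies, re-measured by the
morphometry module (the measured values, not the generator inputs, enter
the statistics, as they would for real specimens), trimmed and embedded,
solved for both load cases, and classified by the fracture criterion.
The resulting cohort table feeds the correlation → PCA → regression
chain.  A manifest (seed, configuration hash, package version) makes
every run exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .errors import FemurMechError, ConfigurationError
from .fe import (
    CASE_FALL,
    CASE_STUMBLING,
    MaterialAndCriterionConfig,
    assemble_and_solve,
    configure_load_case,
)
from .fracture import FractureResult, fracture_load
from .meshing import FemurModel, build_geometry, trim_and_embed
from .morphometry import build_frame, measure
from .params import (
    PARAMETER_NAMES,
    GeneratorConfig,
    MorphologySet,
    sample_morphologies,
)
from .stats import StatsReport, run_stats_chain

__all__ = ["RunConfig", "CohortReport", "run_cohort", "report",
           "STRENGTH_COLUMNS"]

log = logging.getLogger("femurmech")

STRENGTH_COLUMNS = {CASE_STUMBLING: "F_stumbling", CASE_FALL: "F_lateral_fall"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one cohort run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    material: MaterialAndCriterionConfig = field(
        default_factory=MaterialAndCriterionConfig)
    cases: Tuple[str, ...] = (CASE_STUMBLING, CASE_FALL)
    alpha: float = 0.05
    element_order: int = 1
    out_dir: Optional[Path] = None
    write_fields: bool = False
    max_failure_fraction: float = 0.2

    def validate(self) -> None:
        self.generator.validate()
        self.material.validate()
        if not self.cases:
            raise ConfigurationError("at least one load case must be selected")
        for c in self.cases:
            if c not in STRENGTH_COLUMNS:
                raise ConfigurationError(f"unknown load case {c!r}")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.element_order not in (1, 2):
            raise ConfigurationError("element_order must be 1 or 2")

    def config_hash(self) -> str:
        payload = json.dumps({
            "generator": dataclasses.asdict(self.generator),
            "material": dataclasses.asdict(self.material),
            "cases": list(self.cases),
            "alpha": self.alpha,
            "element_order": self.element_order,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortReport:
    """All per-femur and cohort-level results of one run."""

    table: pd.DataFrame                    # measured morphology + strengths
    ground_truth: pd.DataFrame
    fracture: Dict[str, List[Optional[FractureResult]]]
    stats: Optional[StatsReport]
    failed_femurs: List[Tuple[int, str]]
    manifest: Dict[str, object]


def _process_femur(i: int, morph: MorphologySet, config: RunConfig,
                   out_dir: Optional[Path]) -> Tuple[Dict[str, float],
                                                     Dict[str, FractureResult]]:
    fm = build_geometry(morph, config.generator)
    trimmed = trim_and_embed(fm, config.material.embedding_depth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame = build_frame(trimmed)
        measured = measure(trimmed, frame)
    row = measured.as_dict()
    results: Dict[str, FractureResult] = {}
    for case in config.cases:
        lcm = configure_load_case(trimmed, case, config.material,
                                  frame=frame, ata_deg=measured.ATA)
        strain = assemble_and_solve(lcm, order=config.element_order)
        res = fracture_load(strain, config.material)
        results[case] = res
        row[STRENGTH_COLUMNS[case]] = res.load if res.load is not None \
            else np.nan
        if config.write_fields and out_dir is not None:
            from .fileio import write_vtk
            mask = np.zeros(len(trimmed.tets))
            mask[res.failing_elements] = 1.0
            write_vtk(out_dir / f"femur{i:03d}_{case}.vtk",
                      trimmed.nodes, trimmed.tets,
                      cell_data={"region": trimmed.region.astype(float),
                                 "e_max_ref": strain.e_max,
                                 "e_min_ref": strain.e_min,
                                 "failing": mask})
    return row, results


def run_cohort(config: RunConfig) -> CohortReport:
    """Run the full pipeline for one synthetic cohort."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    morphs = sample_morphologies(config.generator)
    rows: List[Dict[str, float]] = []
    fracture: Dict[str, List[Optional[FractureResult]]] = {
        c: [] for c in config.cases}
    failed: List[Tuple[int, str]] = []
    for i, morph in enumerate(morphs):
        try:
            row, results = _process_femur(i, morph, config, out_dir)
        except FemurMechError as exc:
            log.warning("femur %d failed: %s", i, exc)
            failed.append((i, str(exc)))
            for c in config.cases:
                fracture[c].append(None)
            continue
        row["femur_id"] = i
        rows.append(row)
        for c in config.cases:
            fracture[c].append(results[c])
    n = len(morphs)
    if n and len(failed) / n > config.max_failure_fraction:
        raise FemurMechError(
            f"{len(failed)}/{n} femurs failed to process; aborting run "
            f"(limit {config.max_failure_fraction:.0%})")

    columns = ["femur_id"] + list(PARAMETER_NAMES) + [
        STRENGTH_COLUMNS[c] for c in config.cases]
    table = pd.DataFrame(rows, columns=columns)
    gt = pd.DataFrame([m.as_dict() for m in morphs],
                      columns=list(PARAMETER_NAMES))
    gt.insert(0, "femur_id", np.arange(n))

    stats_report = None
    usable = table.dropna()
    if len(usable) >= 4:
        stats_report = run_stats_chain(
            usable, list(PARAMETER_NAMES),
            [STRENGTH_COLUMNS[c] for c in config.cases], alpha=config.alpha)

    manifest = {
        "package": "femurmech",
        "version": __version__,
        "seed": config.generator.seed,
        "cohort_size": config.generator.cohort_size,
        "config_hash": config.config_hash(),
        "cases": list(config.cases),
        "element_order": config.element_order,
        "edge_length_mm": config.generator.edge_length,
        "failed_femurs": [i for i, _ in failed],
    }
    rep = CohortReport(table=table, ground_truth=gt, fracture=fracture,
                       stats=stats_report, failed_femurs=failed,
                       manifest=manifest)
    if out_dir is not None:
        report(rep, out_dir)
    return rep


def _descriptive(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c != "femur_id"]
    desc = pd.DataFrame({
        "mean": table[cols].mean(),
        "SD": table[cols].std(ddof=1),
        "min": table[cols].min(),
        "max": table[cols].max(),
    })
    desc.index.name = "parameter"
    return desc


def _full_correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    from .stats import pearson_with_p
    cols = [c for c in table.columns if c != "femur_id"]
    mat = pd.DataFrame(index=cols, columns=cols, dtype=float)
    for a in cols:
        for b in cols:
            r, _ = pearson_with_p(table[a].to_numpy(), table[b].to_numpy())
            mat.loc[a, b] = r
    return mat


def report(cohort: CohortReport, out_dir) -> List[Path]:
    """Write the cohort report files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if len(cohort.table) == 0:
        raise ConfigurationError("refusing to report an empty cohort")
    written: List[Path] = []

    def _w(path: Path):
        written.append(path)
        return path

    cohort.table.to_csv(_w(out / "cohort_table.csv"), index=False,
                        float_format="%.6g")
    cohort.ground_truth.to_csv(_w(out / "ground_truth.csv"), index=False,
                               float_format="%.6g")
    _descriptive(cohort.table).to_csv(_w(out / "descriptive_stats.csv"),
                                      float_format="%.6g")
    _full_correlation_matrix(cohort.table).to_csv(
        _w(out / "correlation_matrix.csv"), float_format="%.4f")

    stats = cohort.stats
    payload: Dict[str, object] = {"pca": {}, "regression": {},
                                  "significant": {}, "skipped": {}}
    if stats is not None:
        for case, corr in stats.correlations.items():
            corr.to_csv(_w(out / f"correlations_{case}.csv"),
                        float_format="%.6g")
        payload["significant"] = stats.significant
        payload["skipped"] = {k: v for k, v in stats.pca_skip_reason.items()
                              if v}
        for case, block in stats.pca.items():
            if block is None:
                continue
            pca_tab = pd.DataFrame({
                "eigenvalue": block.eigenvalues,
                "pct_variance": block.pct_variance,
                "cum_pct_variance": block.cum_pct_variance,
            })
            pca_tab.index = np.arange(1, len(pca_tab) + 1)
            pca_tab.index.name = "PC"
            pca_tab.to_csv(_w(out / f"pca_variance_{case}.csv"),
                           float_format="%.6g")
            block.loadings.to_csv(_w(out / f"pca_loadings_{case}.csv"),
                                  float_format="%.6g")
            payload["pca"][case] = {            # type: ignore[index]
                "kmo": block.kmo,
                "bartlett_chi2": block.bartlett_chi2,
                "bartlett_df": block.bartlett_df,
                "bartlett_p": block.bartlett_p,
                "n_retained": block.n_retained,
            }
        for case, reg in stats.regression.items():
            if reg is None:
                continue
            tab = reg.coef.copy()
            tab.loc["Constant"] = [reg.intercept, reg.intercept_se,
                                   np.nan, reg.intercept_p]
            tab.to_csv(_w(out / f"regression_{case}.csv"),
                       float_format="%.6g")
            payload["regression"][case] = {     # type: ignore[index]
                "model_r": reg.model_r, "model_p": reg.model_p,
                "see": reg.see, "n": reg.n,
            }
    from .fileio import write_json
    write_json(_w(out / "stats_summary.json"), payload)
    write_json(_w(out / "manifest.json"), dict(cohort.manifest))
    return written
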