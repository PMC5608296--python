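"""Pipeline driver: correction -> testing -> calibration -> selection.

``run_array_analysis`` is the in-memory composition of the stages in the
order the study applied them; ``run_pipeline`` wraps it with file I/O and a
machine-readable run manifest recording versions, seeds, the thresholds
actually applied and per-stage counts, so a run is auditable and a repeat
under the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contamination import (ContaminationEstimate, MarkerPanel,
                            correct_contamination, estimate_contamination,
                            iel_reference_profile)
from .diffexpr import (CalibrationCurve, DEFAULT_GRID, Selection,
                       SelectionCriteria, calibrate_rq_cutoff, gene_rq_table,
                       select_genes)
from .io import (ConfigError, ExpressionMatrix, InputError, logger,
                 read_matrix, read_sample_sheet, split_case_ctrl,
                 write_matrix)


@dataclass
class PipelineConfig:
    """File paths plus every knob the pipeline stages consume."""

    iec_matrix: str | Path
    iel_matrix: str | Path
    sample_sheet: str | Path
    out_dir: str | Path
    contamination_mode: str = "fixed"   # fixed | estimate
    fraction: float = 0.10
    markers: tuple[str, ...] | None = None
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    alpha: float = 0.05
    grid: tuple[float, ...] = DEFAULT_GRID
    zero_substitute: float = 0.01
    case_group: str = "active_cd"
    ctrl_group: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contamination_mode not in ("fixed", "estimate"):
            raise ConfigError(
                f"unknown contamination mode {self.contamination_mode!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("fraction must be in [0, 1]")


@dataclass
class ArrayAnalysisResult:
    corrected_case: ExpressionMatrix
    corrected_ctrl: ExpressionMatrix
    contamination: ContaminationEstimate | None
    fraction_applied: float
    results: pd.DataFrame
    calibration: CalibrationCurve
    selection: Selection
    manifest: dict


def run_array_analysis(iec_case: ExpressionMatrix,
                       iec_ctrl: ExpressionMatrix,
                       iel_reference: pd.Series,
                       *,
                       contamination_mode: str = "fixed",
                       fraction: float = 0.10,
                       ctrl_fraction: float = 0.0,
                       panel: MarkerPanel | None = None,
                       criteria: SelectionCriteria | None = None,
                       alpha: float = 0.05,
                       grid: Sequence[float] = DEFAULT_GRID,
                       zero_substitute: float = 0.01,
                       ) -> ArrayAnalysisResult:
    """Correct, test, calibrate and select in the study's order.

    The disease-arm matrix is corrected at ``fraction`` (fixed mode, the
    default 0.10) or at the marker-panel estimate (estimate mode); the
    control arm is corrected at ``ctrl_fraction`` (default 0: the admixture
    burden sits in the actively inflamed arm).  Calibration runs on the
    expressed, upregulated subset of the gene table; selection applies the
    stated criteria literally.
    """
    criteria = criteria or SelectionCriteria(alpha=alpha)
    estimate = None
    if contamination_mode == "estimate":
        estimate = estimate_contamination(iec_case, iel_reference, panel)
        fraction = estimate.pooled_fraction
    elif contamination_mode != "fixed":
        raise ConfigError(f"unknown contamination mode {contamination_mode!r}")

    corrected_case = correct_contamination(iec_case, iel_reference, fraction)
    corrected_ctrl = (correct_contamination(iec_ctrl, iel_reference,
                                            ctrl_fraction)
                      if ctrl_fraction > 0 else iec_ctrl.copy())

    results = gene_rq_table(corrected_case, corrected_ctrl,
                            zero_substitute=zero_substitute)
    expressed_up = results[
        (results["median_case"] >= criteria.expressed_min_signal)
        & (results["rq"] >= 1.0)]
    if len(expressed_up) == 0:
        logger.warning("no expressed upregulated genes; outputs are empty")
        calibration = CalibrationCurve(
            pd.DataFrame(columns=["cutoff", "n_above", "n_significant",
                                  "frac_significant"]),
            alpha, None)
    else:
        calibration = calibrate_rq_cutoff(expressed_up, alpha=alpha, grid=grid)
    selection = select_genes(results, criteria)

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "contamination_mode": contamination_mode,
        "fraction_applied": fraction,
        "ctrl_fraction_applied": ctrl_fraction,
        "zero_substitute": zero_substitute,
        "alpha": alpha,
        "criteria": {
            "expressed_min_signal": criteria.expressed_min_signal,
            "min_signal_case": criteria.min_signal_case,
            "min_rq": criteria.min_rq,
            "alpha": criteria.alpha,
            "direction_up_only": criteria.direction_up_only,
        },
        "grid": [float(c) for c in grid],
        "chosen_cutoff": calibration.chosen_cutoff,
        "counts": {
            "genes": int(len(results)),
            "n_case": int(iec_case.signals.shape[1]),
            "n_ctrl": int(iec_ctrl.signals.shape[1]),
            "expressed_upregulated": int(len(expressed_up)),
            **{f"after_{k}": v for k, v in selection.audit.items()},
        },
    }
    return ArrayAnalysisResult(corrected_case, corrected_ctrl, estimate,
                               fraction, results, calibration, selection,
                               manifest)


def run_pipeline(config: PipelineConfig) -> ArrayAnalysisResult:
    """File-based driver: read inputs, run the analysis, write outputs.

    Writes ``corrected_case.tsv``, ``corrected_ctrl.tsv``, ``results.tsv``
    (gene table with the ``selected`` flag), ``calibration.tsv``,
    ``selected_genes.txt`` and ``manifest.json`` under ``out_dir``.  Any
    stage failure propagates with the stage name prefixed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    sheet = _stage("read", read_sample_sheet, config.sample_sheet)
    iec = _stage("read", read_matrix, config.iec_matrix, sheet)
    iel = _stage("read", read_matrix, config.iel_matrix, sheet)
    iec_case, iec_ctrl = _stage("split", split_case_ctrl, iec,
                                config.case_group, config.ctrl_group)
    iel_ref = _stage("reference", iel_reference_profile, iel)

    panel = MarkerPanel(config.markers) if config.markers else None
    result = _stage("analysis", run_array_analysis, iec_case, iec_ctrl,
                    iel_ref,
                    contamination_mode=config.contamination_mode,
                    fraction=config.fraction, panel=panel,
                    criteria=config.criteria, alpha=config.alpha,
                    grid=config.grid,
                    zero_substitute=config.zero_substitute)

    write_matrix(result.corrected_case, out / "corrected_case.tsv")
    write_matrix(result.corrected_ctrl, out / "corrected_ctrl.tsv")
    result.selection.table.to_csv(out / "results.tsv", sep="\t", index=False)
    result.calibration.curve.to_csv(out / "calibration.tsv", sep="\t",
                                    index=False)
    (out / "selected_genes.txt").write_text(
        "".join(f"{g}\n" for g in result.selection.selected))
    result.manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1,
                                                  sort_keys=True))
    if result.manifest["counts"]["after_expressed"] == 0:
        logger.warning("advisory: empty gene list after expressed filter")
    return result
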