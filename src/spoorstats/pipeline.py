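"""End-to-end orchestration: ingest or simulate, filter, summarize, estimate.

``run`` executes filter -> effort -> density matrix -> precision curves
(per species/stratum with enough spoor) -> calibrated estimate table ->
rank test, writes every table under the output directory and returns a
:class:`RunReport`. Identical config + seed produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .calibration import CalibrationModel, default_model, estimate_table, estimates_frame
from .comparison import RankTestResult, compare_land_use
from .precision import bootstrap_curve
from .spoor_metrics import (
    density_matrix,
    effort_frame,
    filter_spoor,
    inter_spoor_intervals,
)
from .survey_data import ConfigError, SurveyDataset, read_survey
from .synthetic_survey import SimulationConfig, simulate_survey

logger = logging.getLogger(__name__)

#: Minimum spoor for a precision curve (need >= 2 intervals).
MIN_SPOOR_FOR_CURVE = 3


@dataclass
class RunConfig:
    """One pipeline invocation. Set exactly one of input_dir / scenario."""

    out_dir: Path
    input_dir: Path | None = None
    scenario: SimulationConfig | None = None
    n_bootstrap: int = 1000
    seed: int = 0
    model: CalibrationModel = field(default_factory=default_model)

    def validated(self) -> "RunConfig":
        if (self.input_dir is None) == (self.scenario is None):
            raise ConfigError("set exactly one of input_dir / scenario")
        return self


@dataclass
class RunReport:
    effort: pd.DataFrame
    densities: pd.DataFrame
    estimates: pd.DataFrame
    rank_test: RankTestResult
    precision_files: dict[tuple[str, str], Path]
    insufficient: list[tuple[str, str]]
    provenance: dict

    @property
    def files(self) -> list[Path]:
        return list(self.precision_files.values())


def _config_hash(config: RunConfig) -> str:
    blob = repr(
        (
            str(config.input_dir),
            repr(config.scenario),
            config.n_bootstrap,
            config.seed,
            config.model.to_mapping(),
        )
    ).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis and write all artifacts under out_dir."""
    config.validated()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if config.input_dir is not None:
            dataset = read_survey(config.input_dir)
        else:
            dataset = simulate_survey(config.scenario, seed=config.seed)
        logger.info("loaded %d records, %d transects", len(dataset.records), len(dataset.transects))

    with _stage("filter"):
        kept = filter_spoor(dataset.records)
        logger.info("filter kept %d of %d records", len(kept), len(dataset.records))
        clean = SurveyDataset(records=kept, transects=dataset.transects, strata=dataset.strata)

    with _stage("effort"):
        effort = effort_frame(clean)
        effort.to_csv(out / "effort.csv", index=False)

    with _stage("densities"):
        matrix = density_matrix(clean)
        matrix.round(2).to_csv(out / "densities.csv")
        for lut in matrix.columns:
            for sp in matrix.index:
                n = sum(1 for r in clean.records if r.species == sp and r.lut == lut)
                if n:
                    logger.info("count %s/%s = %d", sp, lut, n)

    precision_dir = out / "precision"
    precision_dir.mkdir(exist_ok=True)
    precision_files: dict[tuple[str, str], Path] = {}
    insufficient: list[tuple[str, str]] = []
    with _stage("precision"):
        for lut in matrix.columns:
            for sp in matrix.index:
                n = sum(1 for r in clean.records if r.species == sp and r.lut == lut)
                if n == 0:
                    continue
                if n < MIN_SPOOR_FOR_CURVE:
                    insufficient.append((sp, lut))
                    logger.info("insufficient sample for precision curve: %s/%s (n=%d)", sp, lut, n)
                    continue
                intervals = inter_spoor_intervals(clean, sp, lut=lut)
                curve = bootstrap_curve(
                    intervals, n_bootstrap=config.n_bootstrap, seed=config.seed
                )
                path = precision_dir / f"{sp}_{lut}.csv"
                curve.to_frame().to_csv(path, index=False)
                precision_files[(sp, lut)] = path

    with _stage("estimates"):
        estimates = estimate_table(
            clean, model=config.model, n_bootstrap=config.n_bootstrap, seed=config.seed
        )
        est_frame = estimates_frame(estimates)
        est_frame.to_csv(out / "estimates.csv", index=False)

    with _stage("rank_test"):
        defined = [c for c in matrix.columns if matrix[c].notna().any()]
        if len(defined) >= 2:
            result = compare_land_use(matrix[defined])
        else:  # a one-stratum survey has nothing to compare
            result = RankTestResult(H=0.0, df=max(0, len(defined) - 1), p_value=1.0,
                                    group_sizes=[len(matrix.index)] * len(defined), n_ties=0)
        (out / "kw.json").write_text(
            json.dumps(
                {
                    "H": result.H,
                    "df": result.df,
                    "p_value": result.p_value,
                    "group_sizes": result.group_sizes,
                    "n_ties": result.n_ties,
                    "group_medians": matrix.median().to_dict(),
                },
                indent=2,
            )
        )

    provenance = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_bootstrap": config.n_bootstrap,
        "version": __version__,
        "n_records_raw": len(dataset.records),
        "n_records_kept": len(clean.records),
    }
    report = RunReport(
        effort=effort,
        densities=matrix,
        estimates=est_frame,
        rank_test=result,
        precision_files=precision_files,
        insufficient=insufficient,
        provenance=provenance,
    )
    _write_markdown(report, out / "report.md")
    return report


def _write_markdown(report: RunReport, path: Path) -> None:
    lines = ["# Spoor survey run report", ""]
    lines += [f"- {k}: {v}" for k, v in report.provenance.items()]
    lines += ["", "## Effort", "", report.effort.to_markdown(index=False)]
    lines += ["", "## Spoor densities (spoor/100 km)", "", report.densities.round(2).to_markdown()]
    lines += ["", "## Estimates", "", report.estimates.to_markdown(index=False)]
    lines += ["", "## Land-use comparison", "", f"{report.rank_test}"]
    if report.insufficient:
        flagged = ", ".join(f"{sp}/{lut}" for sp, lut in report.insufficient)
        lines += ["", f"Insufficient sample for precision curves: {flagged}"]
    path.write_text("\n".join(lines) + "\n")
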