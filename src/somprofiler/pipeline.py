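"""End-to-end orchestration: cohort -> SOM ensemble -> clusters -> stats.

Glues the stages together with one user-facing seed, writes every artifact
as CSV/JSON under an output directory, and records a manifest (seeds,
configuration, input hashes) so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .accelerometry import process_count_series
from .clustering import (
    ClusterSolution,
    assign_participants,
    choose_k,
    cluster_summary,
)
from .cohort import INPUT_VARIABLE_NAMES, OUTCOME_VARIABLES
from .ensemble import EnsembleResult, EnsembleSpec, run_ensemble
from .som import HexGrid, TrainedSOM, eigenvalue_ratio, map_size
from .stats import StatsReport, report, stroop_derived

__all__ = [
    "Standardizer",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "export_component_planes",
    "add_stroop_ratios",
]

logger = logging.getLogger(__name__)


class Standardizer:
    """Per-variable z-scoring with exact inverse transform.

    The profiling variables mix minutes/day, percentiles and Likert scores,
    so Euclidean distances are computed on z-scores; codebooks and
    component planes are reported back on native scales.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0  # constant columns pass through unscaled
        self.scale_ = scale
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scale_ + self.mean_


@dataclass
class PipelineConfig:
    output_dir: str | Path
    seed: int = 0
    cohort_csv: str | Path | None = None  # None -> simulate the study cohort
    counts_csv: str | Path | None = None  # optional raw count series
    simulate_iqr_factor: float = 1.0
    input_variables: tuple[str, ...] = INPUT_VARIABLE_NAMES
    grid: tuple[int, int] | None = None  # None -> auto-sized
    ensemble: EnsembleSpec | None = None  # None -> study-scale spec
    k_min: int = 2
    k_max: int = 10
    restarts: int = 100
    alpha: float = 0.05
    standardize: bool = True


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    ensemble: EnsembleResult
    som: TrainedSOM
    solution: ClusterSolution
    summary: pd.DataFrame
    stats: StatsReport
    manifest: dict


def add_stroop_ratios(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the four Stroop efficacy ratio columns when sources exist."""
    needed = [
        "stroop_dot_time",
        "stroop_word_time",
        "stroop_color_time",
        "stroop_dot_resp",
        "stroop_word_resp",
        "stroop_color_resp",
    ]
    if not all(c in cohort.columns for c in needed):
        return cohort
    out = cohort.copy()
    dt, wt, dr, wr = stroop_derived(
        out["stroop_dot_time"],
        out["stroop_word_time"],
        out["stroop_color_time"],
        out["stroop_dot_resp"],
        out["stroop_word_resp"],
        out["stroop_color_resp"],
    )
    out["stroop_dot_time_eff"] = dt
    out["stroop_word_time_eff"] = wt
    out["stroop_dot_resp_eff"] = dr
    out["stroop_word_resp_eff"] = wr
    return out


def export_component_planes(
    som: TrainedSOM, standardizer: Standardizer | None = None
) -> dict[str, np.ndarray]:
    """One height x width matrix per variable on its native scale."""
    weights = som.weights
    if standardizer is not None:
        weights = standardizer.inverse_transform(weights)
    names = som.variable_names or tuple(
        f"var{i}" for i in range(weights.shape[1])
    )
    h, w = som.grid.height, som.grid.width
    return {name: weights[:, i].reshape(h, w) for i, name in enumerate(names)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the complete analysis and write the output bundle.

    Stages (each logged with its timing): load or simulate the cohort,
    optionally merge accelerometer-derived MVPA, standardize, train the
    SOM ensemble and select the minimal QE x TE map, cluster the codebook
    with Davies-Bouldin selection of k, summarize clusters, and run the
    nonparametric comparisons.  Partial outputs are kept if a later stage
    fails.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "inputs": {}}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                manifest["stages"][name] = {
                    "seconds": round(dt, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    logger.error("stage %s failed after %.2fs", name, dt)
                else:
                    logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    # --- cohort -----------------------------------------------------------
    with _stage("cohort"):
        if config.cohort_csv is not None:
            path = Path(config.cohort_csv)
            cohort = pd.read_csv(path)
            manifest["inputs"]["cohort_csv"] = _sha256(path)
        else:
            from .cohort import generate_study_cohort

            cohort = generate_study_cohort(
                config.seed, iqr_factor=config.simulate_iqr_factor
            )
            manifest["inputs"]["cohort"] = "simulated"
        if config.counts_csv is not None:
            path = Path(config.counts_csv)
            counts = pd.read_csv(path)
            manifest["inputs"]["counts_csv"] = _sha256(path)
            mvpa = process_count_series(counts)
            cohort = cohort.merge(
                mvpa[["participant_id", "mvpa_min_day"]],
                on="participant_id",
                how="left",
                suffixes=("_cohort", ""),
            )
        cohort = add_stroop_ratios(cohort)
        missing = cohort[list(config.input_variables)].isna().any(axis=1)
        if missing.any():
            raise ValueError(
                f"{int(missing.sum())} rows have missing input variables; "
                "complete cases are required"
            )
        cohort.to_csv(out_dir / "cohort.csv", index=False)

    # --- standardize + grid ----------------------------------------------
    X_native = cohort[list(config.input_variables)].to_numpy(dtype=float)
    standardizer = Standardizer() if config.standardize else None
    X = standardizer.fit_transform(X_native) if standardizer else X_native
    if config.grid is not None:
        grid = HexGrid(*config.grid)
    else:
        grid = HexGrid(*map_size(X.shape[0], eigenvalue_ratio(X)))
    manifest["grid"] = [grid.height, grid.width]

    # --- ensemble ---------------------------------------------------------
    with _stage("ensemble"):
        spec = config.ensemble or EnsembleSpec(base_seed=config.seed)
        result = run_ensemble(
            X, grid, spec, variable_names=tuple(config.input_variables)
        )
        result.trace().to_csv(out_dir / "ensemble_trace.csv", index=False)
        som = result.best_som
        manifest["best_run"] = result.best_run_id
        manifest["qe"] = som.quantization_error
        manifest["te"] = som.topographic_error

    # --- clustering -------------------------------------------------------
    with _stage("clustering"):
        solution = choose_k(
            som.weights,
            k_range=range(config.k_min, config.k_max + 1),
            restarts=config.restarts,
            seed=config.seed,
        )
        solution = assign_participants(som, solution, X)
        manifest["k"] = solution.k
        pd.DataFrame(
            {
                "k": list(solution.db_trace),
                "davies_bouldin": list(solution.db_trace.values()),
            }
        ).to_csv(out_dir / "db_trace.csv", index=False)
        pd.DataFrame(
            {
                "participant_id": cohort["participant_id"],
                "cluster": solution.participant_labels,
            }
        ).to_csv(out_dir / "participant_labels.csv", index=False)
        rows, cols = np.divmod(np.arange(grid.n_units), grid.width)
        pd.DataFrame(
            {
                "neuron_row": rows,
                "neuron_col": cols,
                "cluster": solution.neuron_labels,
                "hits": solution.hits,
            }
        ).to_csv(out_dir / "neuron_labels.csv", index=False)

    # --- codebook + component planes -------------------------------------
    with _stage("export"):
        native_weights = (
            standardizer.inverse_transform(som.weights)
            if standardizer
            else som.weights
        )
        codebook = pd.DataFrame(
            native_weights, columns=list(config.input_variables)
        )
        codebook.insert(0, "neuron_row", rows)
        codebook.insert(1, "neuron_col", cols)
        codebook.to_csv(out_dir / "codebook.csv", index=False)
        planes_dir = out_dir / "component_planes"
        planes_dir.mkdir(exist_ok=True)
        for name, plane in export_component_planes(som, standardizer).items():
            pd.DataFrame(plane).to_csv(planes_dir / f"{name}.csv", index=False)

    # --- cluster summary + stats ------------------------------------------
    with _stage("stats"):
        summary = cluster_summary(
            cohort, solution, list(config.input_variables)
        )
        summary.to_csv(out_dir / "cluster_summary.csv")
        outcome_vars = [
            v.name for v in OUTCOME_VARIABLES if v.name in cohort.columns
        ]
        outcome_vars += [
            c
            for c in (
                "stroop_dot_time_eff",
                "stroop_word_time_eff",
                "stroop_dot_resp_eff",
                "stroop_word_resp_eff",
            )
            if c in cohort.columns
        ]
        stats_report = report(
            cohort,
            solution.participant_labels,
            list(config.input_variables),
            outcome_vars,
            alpha=config.alpha,
        )
        stats_report.input_tests.to_csv(out_dir / "input_kw.csv", index=False)
        stats_report.outcome_tests.to_csv(out_dir / "outcome_kw.csv", index=False)
        dunn_dir = out_dir / "dunn"
        dunn_dir.mkdir(exist_ok=True)
        for var, frame in stats_report.dunn.items():
            frame.to_csv(dunn_dir / f"{var}.csv", index=False)
        if stats_report.gender is not None:
            stats_report.gender.table.to_csv(out_dir / "gender_table.csv")
            manifest["gender_chi2"] = stats_report.gender.statistic
            manifest["gender_p"] = stats_report.gender.p
        (out_dir / "report.txt").write_text(stats_report.to_text() + "\n")

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        cohort=cohort,
        ensemble=result,
        som=som,
        solution=solution,
        summary=summary,
        stats=stats_report,
        manifest=manifest,
    )
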