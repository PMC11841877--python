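"""Ensemble training of SOM configurations and best-map selection.

The analysis trains many maps across a factorial grid of training mode
(sequential/batch) x neighborhood kernel x initialization, each repeated
with distinct seeds, and keeps the map minimizing the product of
quantization and topographic errors.  The study-scale ensemble is
100 repeats x 2 modes x 4 kernels x 2 initializations = 1600 maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .som import (
    INIT_METHODS,
    NEIGHBORHOOD_KINDS,
    TRAINING_MODES,
    HexGrid,
    TrainedSOM,
    default_schedule,
    train_som,
)

__all__ = ["EnsembleSpec", "RunRecord", "EnsembleResult", "run_ensemble", "select_best"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleSpec:
    repeats: int = 100
    modes: tuple[str, ...] = TRAINING_MODES
    neighborhoods: tuple[str, ...] = NEIGHBORHOOD_KINDS
    inits: tuple[str, ...] = INIT_METHODS
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        for m in self.modes:
            if m not in TRAINING_MODES:
                raise ValueError(f"unknown mode {m!r}")
        for k in self.neighborhoods:
            if k not in NEIGHBORHOOD_KINDS:
                raise ValueError(f"unknown neighborhood {k!r}")
        for i in self.inits:
            if i not in INIT_METHODS:
                raise ValueError(f"unknown init {i!r}")

    @property
    def total_runs(self) -> int:
        return (
            self.repeats * len(self.modes) * len(self.neighborhoods) * len(self.inits)
        )


@dataclass(frozen=True)
class RunRecord:
    run_id: int
    mode: str
    neighborhood: str
    init: str
    seed: int
    quantization_error: float
    topographic_error: float
    score: float
    status: str  # ok | failed
    reason: str = ""


@dataclass
class EnsembleResult:
    spec: EnsembleSpec
    records: list[RunRecord]
    best_run_id: int
    best_som: TrainedSOM

    def trace(self) -> pd.DataFrame:
        """Full per-run trace (including failures) as a DataFrame."""
        return pd.DataFrame(
            [
                {
                    "run_id": r.run_id,
                    "mode": r.mode,
                    "kernel": r.neighborhood,
                    "init": r.init,
                    "seed": r.seed,
                    "qe": r.quantization_error,
                    "te": r.topographic_error,
                    "score": r.score,
                    "status": r.status,
                }
                for r in self.records
            ]
        )


def _iter_configs(spec: EnsembleSpec):
    run_id = 0
    for repeat in range(spec.repeats):
        for mode in spec.modes:
            for kind in spec.neighborhoods:
                for init in spec.inits:
                    yield run_id, repeat, mode, kind, init
                    run_id += 1


def run_ensemble(
    data: np.ndarray,
    grid: HexGrid,
    spec: EnsembleSpec,
    variable_names: tuple[str, ...] | None = None,
) -> EnsembleResult:
    """Train every configured map and record its errors.

    Run seeds are derived as base_seed + run_id, so runs are independent
    of execution order and the whole ensemble is reproducible from one
    seed.  A failing run is recorded with status 'failed' and excluded
    from selection.
    """
    data = np.asarray(data, dtype=float)
    records: list[RunRecord] = []
    soms: dict[int, TrainedSOM] = {}
    for run_id, _, mode, kind, init in _iter_configs(spec):
        seed = spec.base_seed + run_id
        try:
            schedule = default_schedule(
                grid, data.shape[0], mode=mode, neighborhood=kind, init=init,
                seed=seed,
            )
            som = train_som(data, grid, schedule, variable_names=variable_names)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("run %d (%s/%s/%s) failed: %s", run_id, mode, kind, init, exc)
            records.append(
                RunRecord(run_id, mode, kind, init, seed, np.nan, np.nan, np.nan,
                          "failed", str(exc))
            )
            continue
        soms[run_id] = som
        records.append(
            RunRecord(
                run_id, mode, kind, init, seed,
                som.quantization_error, som.topographic_error, som.score, "ok",
            )
        )
    best_id = _select_best_id(records)
    return EnsembleResult(
        spec=spec, records=records, best_run_id=best_id, best_som=soms[best_id]
    )


def _select_best_id(records: list[RunRecord]) -> int:
    ok = [r for r in records if r.status == "ok"]
    if not ok:
        raise RuntimeError("all ensemble runs failed; nothing to select")
    # Minimal QE*TE; ties broken by lower QE, then by run order.
    best = min(ok, key=lambda r: (r.score, r.quantization_error, r.run_id))
    return best.run_id


def select_best(result: EnsembleResult) -> TrainedSOM:
    """The map minimizing QE x TE (ties: lower QE, then earlier run)."""
    return result.best_som
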