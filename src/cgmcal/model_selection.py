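"""Exhaustive hyperparameter grid search for the per-cluster MLP regressor.

The search enumerates the Cartesian product of seven axes — hidden-layer
architecture, initial learning rate, learning-rate schedule, activation,
iteration budget, momentum and solver — in a fixed nesting order
(architecture outermost, solver innermost).  Every candidate is trained on
the cluster's training split and scored on its held-out split; the winner
is the lexicographic minimum by (RMSE, MARD, enumeration order).  Momentum
is a full axis even for solvers that ignore it, so the default grid's
cardinality is 7*6*3*2*3*2*3 = 4536.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    MIN_SAMPLES,
    CalibratorEnsemble,
    FittedClusterModel,
    RegressorConfig,
    fit_cluster_model,
)
from .clustering import N_CLUSTERS, ClusterScheme, partition
from .evaluation import mard, relative_errors, rmse

_AXES = (
    "hidden_layer_options",
    "learning_rates",
    "learning_types",
    "activations",
    "iteration_counts",
    "momenta",
    "solvers",
)


@dataclass(frozen=True)
class HyperparameterGrid:
    """The MLP search grid; defaults are the method's declared axes."""

    hidden_layer_options: tuple = (
        (20,),
        (100,),
        (200,),
        (10, 10),
        (20, 20),
        (10, 10, 10, 10),
        (20, 20, 20, 20),
    )
    learning_rates: tuple = (0.001, 0.01, 0.05, 0.1, 0.5, 1.0)
    learning_types: tuple = ("constant", "invscaling", "adaptive")
    activations: tuple = ("tanh", "relu")
    solvers: tuple = ("lbfgs", "sgd", "adam")
    iteration_counts: tuple = (100, 500, 1000)
    momenta: tuple = (0.9, 0.99)

    def __post_init__(self) -> None:
        for axis in _AXES:
            vals = tuple(getattr(self, axis))
            object.__setattr__(self, axis, vals)
            if len(vals) == 0:
                raise ValueError(f"grid axis {axis!r} is empty")
        object.__setattr__(
            self,
            "hidden_layer_options",
            tuple(tuple(h) if isinstance(h, (list, tuple)) else (h,) for h in self.hidden_layer_options),
        )

    @property
    def cardinality(self) -> int:
        n = 1
        for axis in _AXES:
            n *= len(getattr(self, axis))
        return n

    @classmethod
    def reduced(cls) -> "HyperparameterGrid":
        """A four-candidate grid for quick runs: two small architectures
        crossed with the LBFGS and ADAM solvers."""
        return cls(
            hidden_layer_options=((20,), (10, 10)),
            learning_rates=(0.05,),
            learning_types=("adaptive",),
            activations=("relu",),
            solvers=("lbfgs", "adam"),
            iteration_counts=(1000,),
            momenta=(0.9,),
        )

    def to_dict(self) -> dict:
        return {axis: [list(v) if isinstance(v, tuple) else v for v in getattr(self, axis)]
                for axis in _AXES}

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparameterGrid":
        return cls(**{axis: tuple(d[axis]) for axis in _AXES if axis in d})


def enumerate_grid(grid: HyperparameterGrid) -> list[RegressorConfig]:
    """All candidate configs in deterministic nesting order.

    Architecture varies slowest; then learning rate, schedule, activation,
    iteration budget, momentum; solver varies fastest.
    """
    configs = []
    for hl, lr, lrt, act, it, mom, solver in itertools.product(
        grid.hidden_layer_options,
        grid.learning_rates,
        grid.learning_types,
        grid.activations,
        grid.iteration_counts,
        grid.momenta,
        grid.solvers,
    ):
        configs.append(
            RegressorConfig(
                "MLP",
                {
                    "hidden_layers": tuple(hl),
                    "learning_rate_init": lr,
                    "learning_rate_type": lrt,
                    "activation": act,
                    "max_iterations": it,
                    "momentum": mom,
                    "solver": solver,
                },
            )
        )
    return configs


class SelectionError(RuntimeError):
    """Every grid candidate failed to train; carries the candidate log."""

    def __init__(self, cluster: int, log: pd.DataFrame):
        self.cluster = cluster
        self.log = log
        super().__init__(f"cluster {cluster}: all {len(log)} candidates failed to train")


class SelectionResult(NamedTuple):
    cluster: int
    best_config: RegressorConfig | None
    best_model: FittedClusterModel | None
    best_index: int
    log: pd.DataFrame  #: one row per evaluated candidate
    fallback: bool
    held_out: pd.DataFrame | None = None  #: winner's test rows with g_p attached


def _candidate_seed(cluster: int, index: int, base_seed: int) -> int:
    # reproducible, unique per (cluster, candidate), bounded below 2**31
    return (base_seed * 7919 + cluster * 104729 + index) % (2**31 - 1)


def grid_search_cluster(
    readings: pd.DataFrame,
    grid: HyperparameterGrid,
    train_fraction: float = 0.7,
    seed: int = 0,
    goal_mard: float | None = None,
    min_samples: int = MIN_SAMPLES,
    cluster: int = -1,
) -> SelectionResult:
    """Exhaustively evaluate the grid on one cluster's fixed split.

    Every candidate trains on the same 70:30-style split (per-candidate
    estimator seeds derived from (cluster, index)); held-out corrected
    glucose is scored by absolute RMSE, MARD and signed error extrema.  The
    winner minimizes (RMSE, MARD) lexicographically, ties broken by
    enumeration order.  If ``goal_mard`` is set, the search stops at the
    first candidate at or below it.
    """
    configs = enumerate_grid(grid)
    if len(readings) < min_samples:
        warnings.warn(
            f"cluster {cluster}: {len(readings)} readings < min_samples={min_samples}; "
            "identity fallback",
            stacklevel=2,
        )
        return SelectionResult(cluster, None, None, -1, pd.DataFrame(), True)

    rows = []
    fits = []
    best_key = None
    best_index = -1
    for i, config in enumerate(configs):
        est_seed = _candidate_seed(cluster, i, seed)
        row = {"candidate": i, "config": config.describe(), "seed": est_seed}
        try:
            res = fit_cluster_model(
                readings,
                config,
                train_fraction=train_fraction,
                split_seed=seed,
                estimator_seed=est_seed,
                min_samples=min_samples,
                cluster=cluster,
            )
            g_m = res.test_readings["g_m"].to_numpy(dtype=float)
            g_r = res.test_readings["g_r"].to_numpy(dtype=float)
            g_p = np.maximum(g_m - res.test_predictions, 1.0)
            _, mx, mn = relative_errors(g_p, g_r)
            row.update(
                rmse=rmse(g_p, g_r, "absolute"),
                rmse_rel=rmse(g_p, g_r, "relative"),
                mard=mard(g_p, g_r),
                max_error=mx,
                min_error=mn,
                error=None,
            )
            fits.append(res)
        except Exception as exc:  # noqa: BLE001 — log and move on
            row.update(rmse=np.inf, rmse_rel=np.inf, mard=np.inf,
                       max_error=np.nan, min_error=np.nan, error=str(exc))
            fits.append(None)
        rows.append(row)
        if np.isfinite(row["rmse"]):
            key = (row["rmse"], row["mard"])
            if best_key is None or key < best_key:
                best_key, best_index = key, i
            if goal_mard is not None and row["mard"] <= goal_mard:
                break

    log = pd.DataFrame(rows)
    if best_index < 0:
        raise SelectionError(cluster, log)
    win = fits[best_index]
    held = win.test_readings.copy()
    held["g_p"] = np.maximum(
        held["g_m"].to_numpy(dtype=float) - win.test_predictions, 1.0
    )
    return SelectionResult(
        cluster=cluster,
        best_config=configs[best_index],
        best_model=win.model,
        best_index=best_index,
        log=log,
        fallback=False,
        held_out=held,
    )


def select_all_clusters(
    readings: pd.DataFrame,
    scheme: ClusterScheme | None = None,
    grid: HyperparameterGrid | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    goal_mard: float | None = None,
    min_samples: int = MIN_SAMPLES,
    assign_by: str = "measured",
):
    """Run the grid search per cluster and assemble the calibrator.

    Returns ``(ensemble, report, results)``: the deployable ensemble (with
    identity fallbacks for under-populated clusters), a six-row selection
    report (cluster, glucose range, size, winning hyperparameters, held-out
    RMSE/MARD), and the per-cluster :class:`SelectionResult` objects.
    """
    scheme = scheme or ClusterScheme()
    grid = grid or HyperparameterGrid()
    parts = partition(readings, scheme, assign_by=assign_by)
    models: dict[int, object] = {}
    results: list[SelectionResult] = []
    rows = []
    for k, part in enumerate(parts):
        row = {
            "cluster": k,
            "range": scheme.range_label(k),
            "n": len(part),
            "fallback": False,
            "hyperparameters": "identity (too few readings)",
            "rmse": np.nan,
            "mard": np.nan,
        }
        if len(part) < min_samples:
            warnings.warn(
                f"cluster {k}: {len(part)} readings < min_samples={min_samples}; "
                "identity fallback",
                stacklevel=2,
            )
            row["fallback"] = True
            results.append(SelectionResult(k, None, None, -1, pd.DataFrame(), True))
        else:
            sel = grid_search_cluster(
                part, grid,
                train_fraction=train_fraction, seed=seed,
                goal_mard=goal_mard, min_samples=min_samples, cluster=k,
            )
            results.append(sel)
            models[k] = sel.best_model
            best = sel.log.loc[sel.log["candidate"] == sel.best_index].iloc[0]
            row["hyperparameters"] = sel.best_config.describe()
            row["rmse"] = float(best["rmse"])
            row["mard"] = float(best["mard"])
        rows.append(row)
    ensemble = CalibratorEnsemble(
        scheme=scheme,
        models=models,
        metadata={
            "seed": seed,
            "train_fraction": train_fraction,
            "grid_cardinality": grid.cardinality,
            "selection": "lexicographic (RMSE, MARD)",
            "assign_by": assign_by,
        },
    )
    return ensemble, pd.DataFrame(rows), results
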