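"""Per-cluster error-prediction regressors and the correction step.

The calibrator never models glucose directly.  It models the *sensor error*
d_k = g_m − g_r as a function of the measured value and seven personalized
covariates, one regressor per glucose cluster, and corrects each reading as

    g_p = g_m − d_pred.

Six regressor families are supported (SVR, KNN, decision tree, random
forest, AdaBoost, MLP); the multilayer perceptron is the family the method
ultimately selects per cluster via grid search (see
:mod:`cgmcal.model_selection`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .clustering import N_CLUSTERS, ClusterScheme, assign_cluster, partition
from .synthetic import COVARIATES

#: model inputs: the measured value x1 = g_m plus the seven covariates x2..x8
FEATURE_COLUMNS = ["g_m"] + COVARIATES

FAMILIES = ("SVR", "KNN", "DT", "RF", "AdaBoost", "MLP")

#: default minimum cluster size below which the identity fallback is used
MIN_SAMPLES = 10

_MLP_KEYMAP = {
    "hidden_layers": "hidden_layer_sizes",
    "learning_rate_init": "learning_rate_init",
    "learning_rate_type": "learning_rate",
    "activation": "activation",
    "solver": "solver",
    "max_iterations": "max_iter",
    "momentum": "momentum",
}


@dataclass(frozen=True)
class RegressorConfig:
    """One regressor family plus its hyperparameters.

    For the MLP family the hyperparameter keys are the method's own axis
    names (``hidden_layers``, ``learning_rate_init``, ``learning_rate_type``,
    ``activation``, ``solver``, ``max_iterations``, ``momentum``); for the
    other families keys pass through to the scikit-learn estimator.
    """

    family: str
    hyperparameters: tuple = ()  # stored as sorted (key, value) pairs

    def __init__(self, family: str, hyperparameters: dict | tuple = ()):
        if family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
        if isinstance(hyperparameters, dict):
            hyperparameters = tuple(sorted(hyperparameters.items()))
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "hyperparameters", tuple(hyperparameters))

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)

    def build(self, seed: int = 0):
        """Instantiate the scikit-learn estimator for this config."""
        hp = self.params
        if self.family == "SVR":
            return SVR(**hp)
        if self.family == "KNN":
            return KNeighborsRegressor(**hp)
        if self.family == "DT":
            return DecisionTreeRegressor(random_state=seed, **hp)
        if self.family == "RF":
            return RandomForestRegressor(random_state=seed, **hp)
        if self.family == "AdaBoost":
            return AdaBoostRegressor(random_state=seed, **hp)
        # MLP: translate axis names, normalize categorical spellings
        kw = {}
        for key, val in hp.items():
            if key not in _MLP_KEYMAP:
                raise ValueError(f"unknown MLP hyperparameter {key!r}")
            kw[_MLP_KEYMAP[key]] = val
        if "activation" in kw:
            kw["activation"] = str(kw["activation"]).lower()
        if "solver" in kw:
            kw["solver"] = str(kw["solver"]).lower()
        if "hidden_layer_sizes" in kw:
            kw["hidden_layer_sizes"] = tuple(kw["hidden_layer_sizes"])
        return MLPRegressor(random_state=seed, **kw)

    def describe(self) -> str:
        hp = self.params
        if self.family == "MLP" and "hidden_layers" in hp:
            layers = tuple(hp["hidden_layers"])
            bits = [f"l={len(layers)}", f"i={layers[0]}"]
            for key in ("learning_rate_init", "learning_rate_type", "activation", "solver"):
                if key in hp:
                    bits.append(str(hp[key]) if isinstance(hp[key], str) else f"lr={hp[key]}")
            if "max_iterations" in hp:
                bits.append(f"t={hp['max_iterations']}")
            if "momentum" in hp:
                bits.append(f"m={hp['momentum']}")
            return f"MLP({', '.join(bits)})"
        return f"{self.family}({', '.join(f'{k}={v}' for k, v in sorted(hp.items()))})"


def default_configs() -> dict[str, RegressorConfig]:
    """Library-default hyperparameters for the six-family screen."""
    return {family: RegressorConfig(family) for family in FAMILIES}


def compute_initial_errors(readings: pd.DataFrame) -> np.ndarray:
    """Initial sensor error d_k = g_m − g_r per reading, mg/dL."""
    return readings["g_m"].to_numpy(dtype=float) - readings["g_r"].to_numpy(dtype=float)


class IdentityModel:
    """Fallback model: predicts zero error (correction is a no-op)."""

    is_identity = True

    def predict_errors(self, readings: pd.DataFrame) -> np.ndarray:
        return np.zeros(len(readings))


@dataclass
class FittedClusterModel:
    """A trained error regressor for one glucose cluster.

    Features and target are standardized on the training split; the scaler
    state is frozen here so inference applies the training-time transform
    exactly.  ``loss_curve`` holds the per-iteration training loss when the
    underlying estimator exposes one (MLP with SGD/ADAM), for SSE-style
    convergence plots.
    """

    cluster: int
    config: RegressorConfig
    scaler: StandardScaler
    y_center: float
    y_scale: float
    estimator: object
    loss_curve: list | None = None
    is_identity: bool = False

    def predict_errors(self, readings: pd.DataFrame) -> np.ndarray:
        X = self.scaler.transform(readings[FEATURE_COLUMNS].to_numpy(dtype=float))
        y_std = self.estimator.predict(X)
        return y_std * self.y_scale + self.y_center


class FitResult(NamedTuple):
    model: FittedClusterModel | IdentityModel
    test_readings: pd.DataFrame
    test_predictions: np.ndarray
    fallback: bool
    message: str | None


def fit_cluster_model(
    readings: pd.DataFrame,
    config: RegressorConfig,
    train_fraction: float = 0.7,
    split_seed: int = 0,
    estimator_seed: int | None = None,
    min_samples: int = MIN_SAMPLES,
    cluster: int = -1,
) -> FitResult:
    """Fit one cluster's error regressor on a 70:30-style split.

    Features and target are centered/scaled on the training rows only.  If
    the cluster holds fewer than ``min_samples`` readings the identity model
    is returned with a warning instead of raising.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(readings)
    if n < min_samples:
        warnings.warn(
            f"cluster {cluster}: {n} readings < min_samples={min_samples}; "
            "using identity fallback",
            stacklevel=2,
        )
        empty = readings.iloc[0:0]
        return FitResult(IdentityModel(), empty, np.zeros(0), True, "too few samples")

    idx_train, idx_test = train_test_split(
        np.arange(n), train_size=train_fraction, random_state=split_seed, shuffle=True
    )
    train = readings.iloc[idx_train]
    test = readings.iloc[idx_test]

    scaler = StandardScaler().fit(train[FEATURE_COLUMNS].to_numpy(dtype=float))
    y_train = compute_initial_errors(train)
    y_center = float(np.mean(y_train))
    y_scale = float(np.std(y_train))
    if y_scale < 1e-12:
        y_scale = 1.0

    est = config.build(seed=split_seed if estimator_seed is None else estimator_seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(scaler.transform(train[FEATURE_COLUMNS].to_numpy(dtype=float)),
                (y_train - y_center) / y_scale)

    model = FittedClusterModel(
        cluster=cluster,
        config=config,
        scaler=scaler,
        y_center=y_center,
        y_scale=y_scale,
        estimator=est,
        loss_curve=list(getattr(est, "loss_curve_", []) or []) or None,
    )
    return FitResult(model, test, model.predict_errors(test), False, None)


@dataclass
class CalibratorEnsemble:
    """The deployable calibrator: a cluster scheme plus six cluster models.

    Clusters without a trained model fall back to the identity correction.
    """

    scheme: ClusterScheme
    models: dict = field(default_factory=dict)  # cluster index -> model
    metadata: dict = field(default_factory=dict)

    def model_for(self, k: int):
        return self.models.get(k, IdentityModel())

    @property
    def fitted(self) -> bool:
        return all(
            hasattr(self.models.get(k, IdentityModel()), "predict_errors")
            for k in range(N_CLUSTERS)
        )

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "CalibratorEnsemble":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path}: not a CalibratorEnsemble archive")
        return obj

    @classmethod
    def identity(cls, scheme: ClusterScheme | None = None) -> "CalibratorEnsemble":
        return cls(scheme=scheme or ClusterScheme(), models={}, metadata={"identity": True})


def correct(readings: pd.DataFrame, ensemble: CalibratorEnsemble) -> np.ndarray:
    """Apply the calibration g_p = g_m − d_pred to every reading.

    The cluster is assigned from the *measured* value (the reference is
    unknown at deployment); the corrected value is floored at 1 mg/dL so
    downstream relative metrics stay defined.
    """
    if ensemble is None or not ensemble.fitted:
        raise RuntimeError("ensemble is not fitted")
    g_m = readings["g_m"].to_numpy(dtype=float)
    labels = assign_cluster(g_m, ensemble.scheme)
    d_pred = np.zeros(len(readings))
    for k in range(N_CLUSTERS):
        mask = labels == k
        if mask.any():
            d_pred[mask] = ensemble.model_for(k).predict_errors(readings.loc[mask])
    return np.maximum(g_m - d_pred, 1.0)


def fit_all_clusters(
    readings: pd.DataFrame,
    scheme: ClusterScheme,
    config: RegressorConfig,
    train_fraction: float = 0.7,
    seed: int = 0,
    min_samples: int = MIN_SAMPLES,
    assign_by: str = "measured",
):
    """Fit one family across all clusters; return ensemble + held-out rows.

    The held-out frame concatenates each cluster's test split with the
    corrected prediction ``g_p`` attached, which is what the family screen
    and the end-to-end reports evaluate on.
    """
    parts = partition(readings, scheme, assign_by=assign_by)
    models: dict[int, object] = {}
    held = []
    for k, part in enumerate(parts):
        res = fit_cluster_model(
            part,
            config,
            train_fraction=train_fraction,
            split_seed=seed,
            estimator_seed=seed * N_CLUSTERS + k,
            min_samples=min_samples,
            cluster=k,
        )
        if not res.fallback:
            models[k] = res.model
            out = res.test_readings.copy()
            out["g_p"] = np.maximum(
                out["g_m"].to_numpy(dtype=float) - res.test_predictions, 1.0
            )
            held.append(out)
    ensemble = CalibratorEnsemble(
        scheme=scheme,
        models=models,
        metadata={"family": config.family, "seed": seed, "train_fraction": train_fraction},
    )
    held_df = (
        pd.concat(held, ignore_index=True)
        if held
        else readings.iloc[0:0].assign(g_p=pd.Series(dtype=float))
    )
    return ensemble, held_df


def compare_model_families(
    readings: pd.DataFrame,
    scheme: ClusterScheme | None = None,
    configs: dict[str, RegressorConfig] | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    min_samples: int = MIN_SAMPLES,
) -> pd.DataFrame:
    """Screen the six regressor families through the clustered pipeline.

    Each family is trained per cluster with its default (or supplied)
    hyperparameters; held-out MARD and Clarke-zone percentages are reported,
    one row per family, sorted by MARD descending (worst first).  A family
    that fails to fit yields a row with NaN metrics and the error message.
    """
    from .evaluation import cega_summary, mard  # local import to avoid cycle

    scheme = scheme or ClusterScheme()
    configs = configs or default_configs()
    rows = []
    for family, config in configs.items():
        try:
            ensemble, held = fit_all_clusters(
                readings, scheme, config,
                train_fraction=train_fraction, seed=seed, min_samples=min_samples,
            )
            if len(held) == 0:
                est = readings["g_m"].to_numpy(dtype=float)
                ref = readings["g_r"].to_numpy(dtype=float)
            else:
                est = held["g_p"].to_numpy(dtype=float)
                ref = held["g_r"].to_numpy(dtype=float)
            zones = cega_summary(est, ref)
            row = {"family": family, "mard": mard(est, ref), "error": None}
            for zone in "ABCDE":
                row[f"zone_{zone}_pct"] = float(
                    zones.loc[zones["zone"] == zone, "percent"].iloc[0]
                )
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 — per-family failure rows
            row = {"family": family, "mard": np.nan, "error": str(exc)}
            row.update({f"zone_{z}_pct": np.nan for z in "ABCDE"})
            rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("mard", ascending=False, na_position="last").reset_index(drop=True)
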