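"""Knowledge-based glucose clusters.

Blood glucose is stratified into six fixed, clinically motivated ranges
(hypoglycemia up to critical diabetes) before any model is trained.  The
ranges reflect stages of diabetes rather than data-driven groupings: insulin
response — and therefore the sensor-error pattern — differs systematically
across them, so each range gets its own calibration model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_BOUNDARIES: tuple[float, ...] = (80.0, 115.0, 150.0, 180.0, 250.0)
DEFAULT_NAMES: tuple[str, ...] = (
    "hypoglycemia",
    "nondiabetic",
    "prediabetes",
    "diabetes",
    "severe diabetes",
    "critical diabetes",
)
N_CLUSTERS = 6


@dataclass(frozen=True)
class ClusterScheme:
    """Six half-open glucose ranges partitioning (0, inf), in mg/dL.

    ``boundaries`` are the five upper edges of clusters 0–4; each edge is
    inclusive in the lower cluster (a reading of exactly 80 mg/dL is
    hypoglycemia, 81 is nondiabetic).  Cluster 5 is everything above the
    last edge.
    """

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    names: tuple[str, ...] = DEFAULT_NAMES

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.boundaries)
        object.__setattr__(self, "boundaries", bounds)
        object.__setattr__(self, "names", tuple(self.names))
        if len(bounds) != N_CLUSTERS - 1:
            raise ValueError(
                f"boundaries: expected {N_CLUSTERS - 1} thresholds, got {len(bounds)}"
            )
        if len(self.names) != N_CLUSTERS:
            raise ValueError(f"names: expected {N_CLUSTERS} labels, got {len(self.names)}")
        arr = np.asarray(bounds)
        if not np.all(arr > 0):
            raise ValueError("boundaries: thresholds must be positive")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("boundaries: thresholds must be strictly increasing")

    @property
    def n_clusters(self) -> int:
        return N_CLUSTERS

    def range_label(self, k: int) -> str:
        """Human-readable range for cluster ``k``, e.g. ``"81-115"``."""
        b = self.boundaries
        if k == 0:
            return f"<={b[0]:g}"
        if k == N_CLUSTERS - 1:
            return f">{b[-1]:g}"
        return f"{b[k - 1]:g}<..<={b[k]:g}"

    def to_dict(self) -> dict:
        return {"boundaries": list(self.boundaries), "names": list(self.names)}

    @classmethod
    def from_dict(cls, d: dict) -> "ClusterScheme":
        return cls(boundaries=tuple(d["boundaries"]), names=tuple(d["names"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ClusterScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def assign_cluster(g, scheme: ClusterScheme | None = None):
    """Map glucose value(s) in mg/dL to cluster indices 0–5.

    Values equal to a boundary fall in the lower cluster.  Scalar input
    returns a Python int; array input returns an int array.

    Raises
    ------
    ValueError
        If any value is non-positive or non-finite.
    """
    scheme = scheme or ClusterScheme()
    arr = np.asarray(g, dtype=float)
    if arr.size == 0:
        return np.zeros(0, dtype=int)
    if not np.all(np.isfinite(arr)):
        raise ValueError("glucose values must be finite")
    if not np.all(arr > 0):
        raise ValueError("glucose values must be positive (mg/dL)")
    idx = np.searchsorted(np.asarray(scheme.boundaries), arr, side="left")
    if np.isscalar(g) or arr.ndim == 0:
        return int(idx)
    return idx.astype(int)


def partition(readings, scheme: ClusterScheme | None = None, assign_by: str = "measured"):
    """Split a readings table into six per-cluster sub-tables.

    ``assign_by="measured"`` clusters on the sensor value ``g_m`` (the only
    value available at deployment); ``"reference"`` clusters on ``g_r`` for
    experimentation.  Returns a list of six DataFrames, disjoint and jointly
    covering the input.
    """
    if assign_by not in ("measured", "reference"):
        raise ValueError(f"assign_by must be 'measured' or 'reference', got {assign_by!r}")
    scheme = scheme or ClusterScheme()
    col = "g_m" if assign_by == "measured" else "g_r"
    if len(readings) == 0:
        return [readings.iloc[0:0].copy() for _ in range(N_CLUSTERS)]
    labels = assign_cluster(readings[col].to_numpy(), scheme)
    return [readings.loc[labels == k].copy() for k in range(N_CLUSTERS)]
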