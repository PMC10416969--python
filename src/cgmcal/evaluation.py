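"""Device-agreement statistics: MARD, RMSE, error extrema, Clarke error
grid analysis (CEGA) and FDA compliance fractions.

All functions take paired arrays of estimated and reference glucose in
mg/dL.  References must be strictly positive (they are denominators of the
relative metrics).  Percentages are returned on the 0–100 scale.

Clarke zones
------------
The (reference x, estimate y) plane is split into five clinically weighted
zones: A (clinically accurate: within 20% of the reference, or both values
hypoglycemic), B (benign deviation), C (overcorrection risk), D (failure to
detect hypo-/hyperglycemia) and E (hypo- and hyperglycemia confused).  The
ordered piecewise-linear rule set below is the widely used formulation of
the 1987 grid; rule priority A, E, C, D, else B resolves boundary overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import N_CLUSTERS, ClusterScheme, assign_cluster

ZONES = ("A", "B", "C", "D", "E")


def _validate(estimates, references) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimates, dtype=float).ravel()
    ref = np.asarray(references, dtype=float).ravel()
    if est.size == 0 or ref.size == 0:
        raise ValueError("estimates/references must be non-empty")
    if est.size != ref.size:
        raise ValueError(f"length mismatch: {est.size} estimates vs {ref.size} references")
    if not (np.all(np.isfinite(est)) and np.all(np.isfinite(ref))):
        raise ValueError("estimates/references must be finite")
    if not np.all(ref > 0):
        raise ValueError("references must be > 0 mg/dL")
    return est, ref


def mard(estimates, references) -> float:
    """Mean absolute relative difference, percent.

    MARD = (100/N) * sum |g - g_r| / g_r — the field's standard one-number
    accuracy summary for glucose sensors.
    """
    est, ref = _validate(estimates, references)
    return float(np.mean(100.0 * np.abs(est - ref) / ref))


def relative_errors(estimates, references):
    """Signed per-pair relative errors in percent, plus their max and min.

    Returns ``(errors, max_error, min_error)`` with errors
    100*(g - g_r)/g_r.
    """
    est, ref = _validate(estimates, references)
    errs = 100.0 * (est - ref) / ref
    return errs, float(errs.max()), float(errs.min())


def rmse(estimates, references, mode: str = "absolute") -> float:
    """Root-mean-square error, in mg/dL (``absolute``) or percent
    (``relative``, computed on the signed relative errors)."""
    est, ref = _validate(estimates, references)
    if mode == "absolute":
        return float(np.sqrt(np.mean((est - ref) ** 2)))
    if mode == "relative":
        return float(np.sqrt(np.mean((100.0 * (est - ref) / ref) ** 2)))
    raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")


def clarke_zones(references, estimates) -> np.ndarray:
    """Clarke zone label for each (reference, estimate) pair.

    Vectorized ordered rule set with x = reference, y = estimate (mg/dL):

    * A: (x<=70 and y<=70) or 0.8x <= y <= 1.2x
    * E: (x>=180 and y<=70) or (x<=70 and y>=180)
    * C: (70<=x<=290 and y>=x+110) or (130<=x<=180 and y<=(7/5)x-182)
    * D: (x>=240 and 70<=y<=180) or (x<=175/3 and 70<=y<=180)
         or (175/3<=x<=70 and y>=(6/5)x)
    * B: everything else
    """
    y, x = _validate(estimates, references)
    if not np.all(y > 0):
        raise ValueError("estimates must be > 0 mg/dL")
    a = ((x <= 70) & (y <= 70)) | ((y >= 0.8 * x) & (y <= 1.2 * x))
    e = ((x >= 180) & (y <= 70)) | ((x <= 70) & (y >= 180))
    c = ((x >= 70) & (x <= 290) & (y >= x + 110)) | (
        (x >= 130) & (x <= 180) & (y <= (7.0 / 5.0) * x - 182)
    )
    d = (
        ((x >= 240) & (y >= 70) & (y <= 180))
        | ((x <= 175.0 / 3.0) & (y >= 70) & (y <= 180))
        | ((x >= 175.0 / 3.0) & (x <= 70) & (y >= (6.0 / 5.0) * x))
    )
    return np.select([a, e, c, d], ["A", "E", "C", "D"], default="B")


def clarke_zone(reference: float, estimate: float) -> str:
    """Zone label for a single pair; see :func:`clarke_zones`."""
    return str(clarke_zones([reference], [estimate])[0])


def cega_summary(estimates, references) -> pd.DataFrame:
    """Zone counts and percentages over all pairs, empty zones included."""
    labels = clarke_zones(references, estimates)
    n = labels.size
    counts = {z: int(np.sum(labels == z)) for z in ZONES}
    return pd.DataFrame(
        {
            "zone": list(ZONES),
            "count": [counts[z] for z in ZONES],
            "percent": [100.0 * counts[z] / n for z in ZONES],
        }
    )


def fda_compliance(estimates, references, mode: str = "adjunctive") -> float:
    """Percent of pairs meeting the FDA accuracy tier, keyed on the sensor
    value: below 100 mg/dL the absolute error must be within 20 (adjunctive)
    or 10 (nonadjunctive) mg/dL; at or above 100 mg/dL the relative error
    must be within 20% / 10%."""
    est, ref = _validate(estimates, references)
    limit = {"adjunctive": 20.0, "nonadjunctive": 10.0}.get(mode)
    if limit is None:
        raise ValueError(f"mode must be 'adjunctive' or 'nonadjunctive', got {mode!r}")
    abs_err = np.abs(est - ref)
    ok = np.where(est < 100.0, abs_err <= limit, abs_err / ref <= limit / 100.0)
    return float(100.0 * np.mean(ok))


@dataclass
class AccuracyReport:
    """One side (before or after correction) of the agreement statistics."""

    n_pairs: int
    mard: float
    rmse_abs: float
    rmse_rel: float
    max_error: float
    min_error: float
    zone_counts: dict
    zone_percent: dict
    fda_adjunctive: float
    fda_nonadjunctive: float

    def __post_init__(self) -> None:
        if sum(self.zone_counts.values()) != self.n_pairs:
            raise ValueError("zone counts must sum to n_pairs")


def accuracy_report(estimates, references) -> AccuracyReport:
    """All agreement statistics for one estimate/reference pairing."""
    est, ref = _validate(estimates, references)
    _, mx, mn = relative_errors(est, ref)
    zones = cega_summary(est, ref)
    return AccuracyReport(
        n_pairs=int(est.size),
        mard=mard(est, ref),
        rmse_abs=rmse(est, ref, "absolute"),
        rmse_rel=rmse(est, ref, "relative"),
        max_error=mx,
        min_error=mn,
        zone_counts=dict(zip(zones["zone"], zones["count"])),
        zone_percent=dict(zip(zones["zone"], zones["percent"])),
        fda_adjunctive=fda_compliance(est, ref, "adjunctive"),
        fda_nonadjunctive=fda_compliance(est, ref, "nonadjunctive"),
    )


class BeforeAfterReport:
    """Per-cluster and overall before/after accuracy tables.

    ``table`` has seven rows (clusters 0–5 plus ``all``) with initial
    (measured vs reference) and final (predicted vs reference) RMSE, MARD
    and error extrema; ``cega_before``/``cega_after`` are overall zone
    summaries.
    """

    def __init__(self, table: pd.DataFrame, cega_before: pd.DataFrame, cega_after: pd.DataFrame):
        self.table = table
        self.cega_before = cega_before
        self.cega_after = cega_after

    def to_markdown(self) -> str:
        parts = ["## Per-cluster accuracy (initial vs final)", "", self.table.round(1).to_markdown(index=False)]
        parts += ["", "## CEGA zones, measured values", "", self.cega_before.round(1).to_markdown(index=False)]
        parts += ["", "## CEGA zones, predicted values", "", self.cega_after.round(1).to_markdown(index=False)]
        return "\n".join(parts) + "\n"

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "report.csv", index=False)
        self.cega_before.to_csv(outdir / "cega_before.csv", index=False)
        self.cega_after.to_csv(outdir / "cega_after.csv", index=False)
        (outdir / "report.md").write_text(self.to_markdown())


def _metric_block(est, ref, suffix):
    if len(ref) == 0:
        return {
            f"rmse_abs_{suffix}": np.nan, f"rmse_rel_{suffix}": np.nan,
            f"mard_{suffix}": np.nan, f"max_error_{suffix}": np.nan,
            f"min_error_{suffix}": np.nan,
        }
    _, mx, mn = relative_errors(est, ref)
    return {
        f"rmse_abs_{suffix}": rmse(est, ref, "absolute"),
        f"rmse_rel_{suffix}": rmse(est, ref, "relative"),
        f"mard_{suffix}": mard(est, ref),
        f"max_error_{suffix}": mx,
        f"min_error_{suffix}": mn,
    }


def before_after_report(
    measured,
    predicted,
    references,
    scheme: ClusterScheme | None = None,
    assign_by: str = "measured",
) -> BeforeAfterReport:
    """Build the per-cluster + overall before/after comparison.

    Rows are clustered on the measured value by default (``assign_by`` may
    be ``"reference"``), so each pair occupies the same row before and after
    correction.
    """
    scheme = scheme or ClusterScheme()
    g_m, ref = _validate(measured, references)
    g_p, _ = _validate(predicted, references)
    if g_p.size != g_m.size:
        raise ValueError("measured and predicted must have equal length")
    key = g_m if assign_by == "measured" else ref
    labels = assign_cluster(key, scheme)
    rows = []
    for k in range(N_CLUSTERS):
        mask = labels == k
        row = {"cluster": str(k), "range": scheme.range_label(k), "n": int(mask.sum())}
        row.update(_metric_block(g_m[mask], ref[mask], "initial"))
        row.update(_metric_block(g_p[mask], ref[mask], "final"))
        rows.append(row)
    overall = {"cluster": "all", "range": "entire range", "n": int(g_m.size)}
    overall.update(_metric_block(g_m, ref, "initial"))
    overall.update(_metric_block(g_p, ref, "final"))
    rows.append(overall)
    return BeforeAfterReport(
        table=pd.DataFrame(rows),
        cega_before=cega_summary(g_m, ref),
        cega_after=cega_summary(g_p, ref),
    )


def plot_cega(references, estimates, path, title: str = "Clarke error grid") -> None:
    """Scatter the pairs on the Clarke grid with zone boundaries drawn,
    points colored by zone, and save to ``path`` (format by extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    est, ref = _validate(estimates, references)
    labels = clarke_zones(ref, est)
    fig, ax = plt.subplots(figsize=(6, 6))
    lim = max(400.0, float(est.max()), float(ref.max())) * 1.05
    # zone boundary segments (x = reference, y = estimate)
    segs = [
        ([0, lim], [0, lim], ":"),
        ([0, lim / 1.2], [0, lim], "-"),  # y = 1.2x
        ([0, lim], [0, 0.8 * lim], "-"),  # y = 0.8x
        ([0, 175 / 3], [70, 70], "-"),
        ([175 / 3, 70], [70, 84], "-"),  # y = (6/5)x
        ([70, 70], [84, lim], "-"),
        ([70, 290], [180, lim], "-"),  # y = x + 110
        ([70, 70], [0, 56], "-"),
        ([70, lim], [56, 56 + 0.8 * (lim - 70)], "-"),
        ([180, 180], [0, 70], "-"),
        ([180, lim], [70, 70], "-"),
        ([240, 240], [70, 180], "-"),
        ([240, lim], [180, 180], "-"),
        ([130, 180], [0, 70], "-"),  # y = (7/5)x - 182
    ]
    for xs, ys, style in segs:
        ax.plot(xs, ys, "k" + style, linewidth=0.8)
    colors = {"A": "tab:green", "B": "tab:olive", "C": "tab:orange", "D": "tab:red", "E": "tab:purple"}
    for zone in ZONES:
        mask = labels == zone
        if mask.any():
            ax.scatter(ref[mask], est[mask], s=12, c=colors[zone], label=f"zone {zone}")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("estimated glucose (mg/dL)")
    ax.set_title(title)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
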