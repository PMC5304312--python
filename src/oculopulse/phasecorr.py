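"""Phase-shift correlation analysis of tonometry features.

For each subject ``v`` and feature ``j`` the per-subject Pearson correlation

    r_v(j) = sum_k (w_kv(j) - mean) (w_kv(6) - mean)
             / sqrt( sum_k (w_kv(j) - mean)^2 * sum_k (w_kv(6) - mean)^2 )

is evaluated between the feature values and the *wrapped* pulse-phase values
``(w6 + phi) mod 360`` for every artificial phase shift ``phi`` on a grid
(default 0..350 deg, step 10 deg).  The shift maximizing r locates the
physiological lag between the finger pulse and the ocular pulse; subjects
whose scan never reaches a usable correlation magnitude are rejected as thick
errors before pooling.

Because the wrapped phase enters the correlation as a *linear* value, r(phi)
on quasi-uniform phases is antisymmetric under a 180-degree shift
(r(phi+180) = -r(phi)) and is piecewise constant between the shifts at which
an individual phase wraps past 360.  The reported extremum shift is therefore
the centre of the plateau of grid points attaining the extremum — the
unbiased choice for a plateau-structured objective (taking the smallest
qualifying shift instead would bias the recovered lag by about half a plateau
width).

The model/results pair :class:`PhaseCouplingScan` / :class:`PhaseCouplingResults`
wraps these operations for a whole cohort dataframe.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EmptyRetainedSetError, UndefinedCorrelationError
from .records import MeasurementRecord, records_to_dataframe

__all__ = [
    "pearson_r",
    "shift_phase",
    "scan_phase_shifts",
    "significance",
    "reject_outliers",
    "pooled_max_correlation",
    "circular_mean_deg",
    "cohort_summary",
    "SubjectScan",
    "PhaseCouplingScan",
    "PhaseCouplingResults",
    "OUTLIER_PRESETS",
]

#: Outlier-rejection presets on the per-subject maximum |r|:
#: "thick" drops only grossly aberrant subjects (thick errors);
#: "strict" additionally drops weakly coupled subjects.
OUTLIER_PRESETS: dict[str, float] = {"thick": 0.3, "strict": 0.55}

DEFAULT_PHI_GRID = np.arange(0.0, 360.0, 10.0)

FEATURE_COLUMNS = ["w1_ms", "w2_ms", "w3_mm", "w4_hz", "w5_mmHg"]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation from the centred cross-product sums.

    Raises
    ------
    UndefinedCorrelationError
        If either vector is constant (zero denominator).
    ValueError
        If the vectors differ in length or have fewer than 3 entries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired measurements")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
    if denom == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


def shift_phase(phases_deg: Sequence[float], phi_deg: float) -> np.ndarray:
    """Add an artificial shift to phases and wrap into [0, 360)."""
    phases = np.asarray(phases_deg, dtype=float)
    if np.any((phases < 0) | (phases >= 360)):
        raise ValueError("phases must lie in [0, 360)")
    return (phases + phi_deg) % 360.0


def significance(r: float, k: int) -> float:
    """Two-sided p-value of a correlation under Student's t with K-2 dof.

    ``|r| = 1`` returns 0 (the limit of the t statistic).
    """
    if k < 3:
        raise ValueError("need K >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(k - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=k - 2))


@dataclass
class SubjectScan:
    """r(phi) over the shift grid for one subject/feature, with extrema."""

    phi_grid_deg: np.ndarray
    r_of_phi: np.ndarray
    phi_max_deg: float
    r_max: float
    phi_min_deg: float
    r_min: float


def _plateau_center(phi: np.ndarray, r: np.ndarray, target: float) -> float:
    """Centre of the circular plateau of grid shifts attaining ``target``.

    r(phi) is constant between phase-wrap events, so the extremum is attained
    on a circularly contiguous run of grid points; a run covers the continuous
    shift interval ``[first, last + step)`` (r only changes at the next wrap
    event).  The midpoint of that interval is reported — the unbiased location
    estimate when the wrap events fall on the grid, as they do for 30-degree
    binned phases.  Among distinct tying plateaus the one starting at the
    smallest shift wins.
    """
    hit = np.isclose(r, target, rtol=0.0, atol=1e-12) & ~np.isnan(r)
    idx = np.flatnonzero(hit)
    n = phi.size
    if idx.size == n:
        return float(phi[0])
    step = float(phi[1] - phi[0]) if n > 1 else 0.0
    # rotate so that position 0 is not inside a run
    start = 0
    while hit[(start - 1) % n]:
        start += 1
    runs: list[list[int]] = []
    current: list[int] = []
    for off in range(n):
        i = (start + off) % n
        if hit[i]:
            current.append(i)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    best = min(runs, key=lambda run: phi[run[0]])
    span = (len(best) - 1) * step + step  # continuous width of the plateau
    return float((phi[best[0]] + 0.5 * span) % 360.0)


def scan_phase_shifts(
    values: Sequence[float],
    phases_deg: Sequence[float],
    phi_grid_deg: np.ndarray | None = None,
    circular: bool = False,
) -> SubjectScan:
    """Correlation of a feature with the shifted wrapped phase, per shift.

    ``circular=True`` correlates against the cosine of the shifted phase
    instead of the wrapped linear value (a circular-aware alternative mode;
    the linear mode is the default and matches the antisymmetric
    min/max-at-180-degrees structure seen on quasi-uniform phases).

    Raises
    ------
    UndefinedCorrelationError
        If the correlation is undefined at every shift.
    """
    values = np.asarray(values, dtype=float)
    phases = np.asarray(phases_deg, dtype=float)
    if phi_grid_deg is None:
        phi_grid_deg = DEFAULT_PHI_GRID
    grid = np.asarray(phi_grid_deg, dtype=float)
    r = np.full(grid.size, np.nan)
    for i, phi in enumerate(grid):
        shifted = shift_phase(phases, phi)
        x = np.cos(np.deg2rad(shifted)) if circular else shifted
        try:
            r[i] = pearson_r(values, x)
        except UndefinedCorrelationError:
            continue
    if np.all(np.isnan(r)):
        raise UndefinedCorrelationError("correlation undefined at every shift")
    r_max = float(np.nanmax(r))
    r_min = float(np.nanmin(r))
    return SubjectScan(
        phi_grid_deg=grid,
        r_of_phi=r,
        phi_max_deg=_plateau_center(grid, r, r_max),
        r_max=r_max,
        phi_min_deg=_plateau_center(grid, r, r_min),
        r_min=r_min,
    )


def reject_outliers(
    max_abs_r: Mapping[int, float], preset: str | float = "thick"
) -> tuple[list[int], pd.DataFrame]:
    """Retain subjects whose scan reaches a usable correlation magnitude.

    ``preset`` is either a named threshold ("thick" = 0.3, rejecting only
    grossly aberrant subjects; "strict" = 0.55, additionally rejecting weak
    couplings) or an explicit numeric threshold on max |r|.

    Raises
    ------
    EmptyRetainedSetError
        If every subject falls below the threshold.
    """
    threshold = OUTLIER_PRESETS[preset] if isinstance(preset, str) else float(preset)
    flags = pd.DataFrame(
        {
            "subject": list(max_abs_r.keys()),
            "max_abs_r": list(max_abs_r.values()),
        }
    )
    flags["retained"] = flags["max_abs_r"] >= threshold
    flags["reason"] = np.where(
        flags["retained"], "", f"max |r| below {threshold:g} (thick error)"
    )
    retained = flags.loc[flags["retained"], "subject"].tolist()
    if not retained:
        raise EmptyRetainedSetError("all subjects rejected as thick errors")
    return retained, flags


def pooled_max_correlation(
    extrema: pd.DataFrame, preset: str | float = "thick"
) -> dict:
    """Pooled mean/std of per-subject maximum correlations after rejection.

    ``extrema`` needs columns ``subject`` and ``r_max``.  Both std
    conventions are reported: the population (N) estimator — the default for
    this pooled group summary — and the sample (N-1) estimator.
    """
    max_abs = dict(zip(extrema["subject"], extrema["r_max"].abs()))
    retained, flags = reject_outliers(max_abs, preset)
    kept = extrema.set_index("subject").loc[retained, "r_max"].to_numpy(dtype=float)
    return {
        "retained": retained,
        "n_retained": len(retained),
        "mean": float(kept.mean()),
        "std_population": float(kept.std(ddof=0)),
        "std_sample": float(kept.std(ddof=1)) if kept.size > 1 else float("nan"),
        "flags": flags,
    }


def circular_mean_deg(angles_deg: Sequence[float]) -> float:
    """Circular mean of angles in degrees, in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.sin(a).mean(), np.cos(a).mean())) % 360.0)


# ----------------------------------------------------------- model object
class PhaseCouplingScan:
    """Phase-coupling model for a cohort of tonometry measurements.

    Parameters
    ----------
    data : DataFrame
        One row per measurement with columns ``subject``, ``measurement``,
        the feature columns (any of ``w1_ms`` ... ``w5_mmHg``) and the phase
        column ``w6_deg``.
    feature_cols : sequence of str, optional
        Features to scan; defaults to every known feature column present.
    corr_feature : str
        The feature whose scan drives outlier rejection, significance and the
        pooled summary (IOP, ``w5_mmHg``, by default — the only feature the
        coupling analysis asserts significant).
    phi_step_deg : float
        Shift-grid step (10 deg by default, finer than the 30-deg phase bins
        so the extremum is resolved).
    circular : bool
        Use the circular-aware correlation mode (off by default).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        feature_cols: Sequence[str] | None = None,
        phase_col: str = "w6_deg",
        subject_col: str = "subject",
        corr_feature: str = "w5_mmHg",
        phi_step_deg: float = 10.0,
        circular: bool = False,
    ) -> None:
        data = pd.DataFrame(data)
        if feature_cols is None:
            feature_cols = [c for c in FEATURE_COLUMNS if c in data.columns]
        missing = [c for c in (*feature_cols, phase_col, subject_col) if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if corr_feature not in feature_cols:
            raise ValueError(f"corr_feature {corr_feature!r} not among features")
        counts = data.groupby(subject_col).size()
        if (counts < 3).any():
            bad = counts[counts < 3].index.tolist()
            raise ValueError(f"subjects with fewer than 3 measurements: {bad}")
        self.data = data
        self.feature_cols = list(feature_cols)
        self.phase_col = phase_col
        self.subject_col = subject_col
        self.corr_feature = corr_feature
        self.phi_grid_deg = np.arange(0.0, 360.0, float(phi_step_deg))
        self.circular = circular

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PhaseCouplingScan":
        return cls(data, **kwargs)

    @classmethod
    def from_records(cls, records: Sequence[MeasurementRecord], **kwargs) -> "PhaseCouplingScan":
        return cls(records_to_dataframe(records), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "PhaseCouplingScan":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        outlier_preset: str | float = "thick",
        feature_std_mode: str = "sample",
        pooled_std_mode: str = "population",
    ) -> "PhaseCouplingResults":
        """Run the shift scan for every subject and feature and summarize.

        ``feature_std_mode`` selects the estimator for the per-subject feature
        table ("sample" = N-1 by default); ``pooled_std_mode`` the one for the
        pooled max-correlation summary ("population" = N by default).  Both
        estimators are always carried in the results regardless of the
        defaults chosen here.
        """
        scans: dict[int, dict[str, SubjectScan]] = {}
        rows = []
        for subject, group in self.data.groupby(self.subject_col):
            phases = group[self.phase_col].to_numpy(dtype=float)
            scans[subject] = {}
            for feat in self.feature_cols:
                try:
                    scan = scan_phase_shifts(
                        group[feat].to_numpy(dtype=float),
                        phases,
                        self.phi_grid_deg,
                        circular=self.circular,
                    )
                except UndefinedCorrelationError:
                    continue
                scans[subject][feat] = scan
                rows.append(
                    {
                        "subject": subject,
                        "feature": feat,
                        "r_min": scan.r_min,
                        "phi_min_deg": scan.phi_min_deg,
                        "r_max": scan.r_max,
                        "phi_max_deg": scan.phi_max_deg,
                        "K": len(group),
                        "p_max": significance(scan.r_max, len(group)),
                    }
                )
        extrema = pd.DataFrame(rows)
        return cohort_summary(
            self.data,
            scans,
            extrema=extrema,
            corr_feature=self.corr_feature,
            feature_cols=self.feature_cols,
            subject_col=self.subject_col,
            outlier_preset=outlier_preset,
            feature_std_mode=feature_std_mode,
            pooled_std_mode=pooled_std_mode,
            model=self,
        )


def cohort_summary(
    data: pd.DataFrame,
    scans: Mapping[int, Mapping[str, SubjectScan]],
    extrema: pd.DataFrame | None = None,
    corr_feature: str = "w5_mmHg",
    feature_cols: Sequence[str] | None = None,
    subject_col: str = "subject",
    outlier_preset: str | float = "thick",
    feature_std_mode: str = "sample",
    pooled_std_mode: str = "population",
    model: "PhaseCouplingScan | None" = None,
) -> "PhaseCouplingResults":
    """Aggregate per-subject scans into the cohort summary tables."""
    if feature_cols is None:
        feature_cols = [c for c in FEATURE_COLUMNS if c in data.columns]
    if extrema is None:
        rows = []
        for subject, per_feat in scans.items():
            k = int((data[subject_col] == subject).sum())
            for feat, scan in per_feat.items():
                rows.append(
                    {
                        "subject": subject, "feature": feat,
                        "r_min": scan.r_min, "phi_min_deg": scan.phi_min_deg,
                        "r_max": scan.r_max, "phi_max_deg": scan.phi_max_deg,
                        "K": k, "p_max": significance(scan.r_max, k),
                    }
                )
        extrema = pd.DataFrame(rows)

    ddof_feat = 1 if feature_std_mode == "sample" else 0
    stats_rows = []
    for subject, group in data.groupby(subject_col):
        row: dict = {"subject": subject, "K": len(group)}
        if "eye" in group.columns:
            row["eye"] = group["eye"].iloc[0]
        for feat in feature_cols:
            vals = group[feat].to_numpy(dtype=float)
            row[f"{feat}_mean"] = float(vals.mean())
            row[f"{feat}_std"] = float(vals.std(ddof=ddof_feat))
            row[f"{feat}_std_population"] = float(vals.std(ddof=0))
        stats_rows.append(row)
    feature_table = pd.DataFrame(stats_rows)

    corr_extrema = extrema[extrema["feature"] == corr_feature].copy()
    pooled = pooled_max_correlation(corr_extrema, outlier_preset)
    return PhaseCouplingResults(
        model=model,
        data=data,
        scans=dict(scans),
        extrema=extrema,
        feature_table=feature_table,
        corr_feature=corr_feature,
        retained=pooled["retained"],
        flags=pooled["flags"],
        pooled_r_mean=pooled["mean"],
        pooled_r_std=pooled["std_population"] if pooled_std_mode == "population" else pooled["std_sample"],
        pooled_r_std_population=pooled["std_population"],
        pooled_r_std_sample=pooled["std_sample"],
        outlier_preset=outlier_preset,
    )


@dataclass
class PhaseCouplingResults:
    """Fitted phase-coupling results for one cohort.

    Carries the per-subject scans, the Table-of-extrema, the per-subject
    feature mean/std table, the thick-error flags and the pooled
    max-correlation summary over the retained subjects.
    """

    model: PhaseCouplingScan | None
    data: pd.DataFrame
    scans: dict
    extrema: pd.DataFrame
    feature_table: pd.DataFrame
    corr_feature: str
    retained: list
    flags: pd.DataFrame
    pooled_r_mean: float
    pooled_r_std: float
    pooled_r_std_population: float
    pooled_r_std_sample: float
    outlier_preset: str | float = "thick"

    # ------------------------------------------------------------ queries
    @property
    def corr_extrema(self) -> pd.DataFrame:
        """Extrema table restricted to the coupling feature (IOP)."""
        return self.extrema[self.extrema["feature"] == self.corr_feature].reset_index(drop=True)

    @property
    def optimum_shifts_deg(self) -> pd.Series:
        """Per-subject shift of maximum correlation for the coupling feature."""
        tab = self.corr_extrema.set_index("subject")
        return tab.loc[self.retained, "phi_max_deg"]

    @property
    def mean_optimum_shift_deg(self) -> float:
        """Circular mean of the retained subjects' optimum shifts."""
        return circular_mean_deg(self.optimum_shifts_deg.to_numpy())

    @property
    def mean_r_at_optimum(self) -> float:
        """Mean retained per-subject correlation at each subject's optimum."""
        tab = self.corr_extrema.set_index("subject")
        return float(tab.loc[self.retained, "r_max"].mean())

    @property
    def max_iop_std(self) -> float:
        """Largest per-subject IOP std — the non-synchronization spread."""
        return float(self.feature_table[f"{self.corr_feature}_std"].max())

    def significance_table(self) -> pd.DataFrame:
        """Per-subject p-values at the optimum shift for the coupling feature."""
        return self.corr_extrema[["subject", "r_max", "phi_max_deg", "p_max"]]

    # ------------------------------------------------------------ summary
    def summary(self) -> str:
        """Human-readable cohort summary (feature table, extrema, pooling)."""
        buf = io.StringIO()
        n_sub = self.feature_table.shape[0]
        buf.write("Phase-coupling scan summary\n")
        buf.write("===========================\n")
        buf.write(
            f"subjects: {n_sub}   measurements: {len(self.data)}   "
            f"coupling feature: {self.corr_feature}\n"
        )
        buf.write(f"outlier preset: {self.outlier_preset}   retained: {len(self.retained)}/{n_sub}\n\n")
        buf.write("Per-subject feature means (std):\n")
        cols = ["subject"] + sum(
            [[f"{f}_mean", f"{f}_std"] for f in (self.model.feature_cols if self.model else FEATURE_COLUMNS) if f"{f}_mean" in self.feature_table],
            [],
        )
        buf.write(self.feature_table[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        buf.write("\n\nPer-subject correlation extrema (coupling feature):\n")
        buf.write(
            self.corr_extrema[["subject", "r_min", "phi_min_deg", "r_max", "phi_max_deg", "p_max"]]
            .to_string(index=False, float_format=lambda v: f"{v:.3f}")
        )
        buf.write("\n\nPooled over retained subjects:\n")
        buf.write(
            f"  max correlation: {self.pooled_r_mean:.2f} +/- {self.pooled_r_std:.2f} "
            f"(population std; sample std {self.pooled_r_std_sample:.2f})\n"
        )
        buf.write(f"  circular mean optimum shift: {self.mean_optimum_shift_deg:.1f} deg\n")
        buf.write(f"  max per-subject IOP std: {self.max_iop_std:.2f} mmHg\n")
        return buf.getvalue()

    # ------------------------------------------------------------- plots
    def plot_scan(self, feature: str | None = None, ax=None):
        """Plot r(phi) for every subject for one feature."""
        import matplotlib.pyplot as plt

        feature = feature or self.corr_feature
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for subject, per_feat in sorted(self.scans.items()):
            scan = per_feat.get(feature)
            if scan is None:
                continue
            ax.plot(scan.phi_grid_deg, scan.r_of_phi, label=f"v={subject}", alpha=0.8)
        ax.set_xlabel("phase shift phi (deg)")
        ax.set_ylabel(f"r({feature})")
        ax.set_ylim(-1.05, 1.05)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.legend(fontsize=7, ncol=2)
        return ax
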