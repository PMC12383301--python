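"""Kinetic metrics from replicate confluence traces.

The analysis turns a treated and a matched control replicate set into one
:class:`KineticProfile` per cell line x formulation x batch: the final
confluence and its spread, the treated-control divergence (in points and as
a fraction of the control), the time at which the two mean trajectories
sustainedly separate, the longest qualifying divergence run, the steepest
log-phase slope, the trapezoidal AUC, the terminal plateau window and the
intra-assay CV.  These are the quantities that drive phenotype
classification, the FSI composite and batch QC.

Conventions
-----------
* Baseline normalization (subtracting the value at the first timepoint,
  clipped at zero) and 3-point smoothing are applied only where divergence
  is assessed; final confluence, AUC and the log-phase slope are computed on
  the raw percent scale so they stay interpretable.
* Per-timepoint comparisons use Welch's unequal-variance two-tailed t-test
  on raw replicate values with no multiplicity correction: the
  classification rule counts raw p < alpha points.
* Sample statistics use the n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sstats

from .plate_io import ConfluenceTrace, ValidationError

__all__ = [
    "KineticsConfig",
    "KineticProfile",
    "PointwiseStats",
    "normalize_to_t0",
    "smooth_ma3",
    "group_mean_curve",
    "delta_vs_control",
    "pointwise_tests",
    "divergence_onset",
    "sustained_duration",
    "logphase_slope",
    "trapezoid_auc",
    "plateau_window",
    "intra_cv",
    "compute_profile",
]


@dataclass
class KineticsConfig:
    """Tunable thresholds of the kinetic analysis.

    alpha : per-timepoint significance level.
    onset_rel : relative treated-control difference that counts toward
        divergence onset (fraction of control).
    onset_run : consecutive qualifying timepoints required to declare onset.
    class_rel : relative difference defining a sustained divergence run
        (the same 20% magnitude the classifier uses).
    slope_window : width in hours of the sliding least-squares window used
        for the log-phase slope.
    plateau_tol : maximum |slope| (%/h) inside a plateau.
    plateau_min : minimum plateau length in hours.
    plateau_fit_window : points in the centered window used to estimate the
        local slope for plateau detection.
    rel_floor : lower bound (percent points) on the denominator of relative
        differences, guarding the near-zero early baseline.
    """

    alpha: float = 0.05
    onset_rel: float = 0.10
    onset_run: int = 3
    class_rel: float = 0.20
    slope_window: float = 6.0
    plateau_tol: float = 0.15
    plateau_min: float = 6.0
    plateau_fit_window: int = 7
    rel_floor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.onset_rel <= 0 or self.class_rel <= 0:
            raise ValueError("relative thresholds must be positive")
        if self.onset_run < 1:
            raise ValueError("onset_run must be >= 1")


@dataclass
class PointwiseStats:
    """Per-timepoint two-tailed p-values of the treated vs control test."""

    times: np.ndarray
    p_values: np.ndarray
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.times.shape != self.p_values.shape:
            raise ValueError("times and p_values must have the same length")
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p-values outside [0, 1]")

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


@dataclass
class KineticProfile:
    """Per-group kinetic metrics feeding classification, FSI and QC."""

    cell_line: str
    formulation_id: str | None
    production_batch: str
    final_confluence_mean: float
    final_confluence_sd: float
    control_final_mean: float
    delta_points: float
    delta_relative: float
    onset_hours: float | None
    logphase_slope: float
    auc: float
    divergence_duration: float
    plateau_window: tuple[float, float] | None
    intra_cv: float
    n_sig_points: int

    def __post_init__(self) -> None:
        if not 0 <= self.final_confluence_mean <= 100:
            raise ValueError("final confluence outside [0, 100]")
        if self.intra_cv < 0 or self.auc < 0:
            raise ValueError("intra_cv and auc must be >= 0")
        if self.onset_hours is not None and not 0 <= self.onset_hours <= 48:
            raise ValueError("onset_hours outside [0, 48]")


# ---------------------------------------------------------------------------
# trace-level transforms
# ---------------------------------------------------------------------------

def normalize_to_t0(trace: ConfluenceTrace) -> ConfluenceTrace:
    """Subtract the value at the earliest timepoint, clipping at 0."""
    if len(trace) == 0:
        raise ValidationError("empty trace has no baseline value")
    v = np.clip(trace.values - trace.values[0], 0.0, None)
    return ConfluenceTrace(trace.well_id, trace.times, v)


def _ma3(values: np.ndarray) -> np.ndarray:
    if len(values) < 3:
        raise ValueError("3-point smoothing needs at least 3 points")
    out = np.empty_like(values, dtype=float)
    out[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    out[0] = (values[0] + values[1]) / 2.0
    out[-1] = (values[-2] + values[-1]) / 2.0
    return out


def smooth_ma3(trace: ConfluenceTrace) -> ConfluenceTrace:
    """Centered 3-point moving average; endpoints use a 2-point window."""
    return ConfluenceTrace(trace.well_id, trace.times, _ma3(trace.values))


def group_mean_curve(traces: Sequence[ConfluenceTrace]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD across replicates on a shared grid."""
    if len(traces) < 2:
        raise ValidationError("need >= 2 replicates for a group mean curve")
    t0 = traces[0].times
    tol = 0.01 * traces[0].spacing
    for tr in traces[1:]:
        if len(tr.times) != len(t0) or np.any(np.abs(tr.times - t0) > tol):
            raise ValidationError(
                f"replicate {tr.well_id} is not on the shared time grid"
            )
    vals = np.vstack([tr.values for tr in traces])
    return t0, vals.mean(axis=0), vals.std(axis=0, ddof=1)


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------

def delta_vs_control(treated_final: float, control_final: float) -> tuple[float, float]:
    """Treated-control final confluence difference in points and relative."""
    if control_final <= 0:
        raise ValueError(f"control final confluence must be > 0, got {control_final}")
    dp = treated_final - control_final
    return dp, dp / control_final


def pointwise_tests(treated: np.ndarray, control: np.ndarray,
                    times: np.ndarray, alpha: float = 0.05) -> PointwiseStats:
    """Welch two-tailed t-test at every timepoint on raw replicate values.

    ``treated`` and ``control`` are (replicates x timepoints) arrays.
    Degenerate columns where both arms have zero variance get p = 1 when the
    means agree and p = 0 when they differ, by convention.
    """
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if treated.shape[0] < 2 or control.shape[0] < 2:
        raise ValidationError("need >= 2 replicates per arm for pointwise tests")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sstats.ttest_ind(treated, control, axis=0, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(treated.mean(axis=0), control.mean(axis=0))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
    return PointwiseStats(times=np.asarray(times, float), p_values=p, alpha=alpha)


def _relative_difference(treated_mean: np.ndarray, control_mean: np.ndarray,
                         rel_floor: float) -> np.ndarray:
    denom = np.maximum(np.abs(control_mean), rel_floor)
    return (treated_mean - control_mean) / denom


def _qualifying_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each maximal True run."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def divergence_onset(times: np.ndarray, treated_mean: np.ndarray,
                     control_mean: np.ndarray, pstats: PointwiseStats,
                     cfg: KineticsConfig) -> float | None:
    """Earliest time with |relative difference| >= ``onset_rel`` and
    p < alpha, sustained for >= ``onset_run`` consecutive timepoints."""
    rel = _relative_difference(treated_mean, control_mean, cfg.rel_floor)
    mask = (np.abs(rel) >= cfg.onset_rel) & pstats.significant
    for start, length in _qualifying_runs(mask):
        if length >= cfg.onset_run:
            return float(times[start])
    return None


def sustained_duration(times: np.ndarray, treated_mean: np.ndarray,
                       control_mean: np.ndarray, pstats: PointwiseStats,
                       cfg: KineticsConfig) -> float:
    """Hours spanned by the longest run of consecutive timepoints with
    |relative difference| >= ``class_rel`` and p < alpha (0 if none).

    A run of k qualifying points on an hourly grid counts as k hours.
    """
    rel = _relative_difference(treated_mean, control_mean, cfg.rel_floor)
    mask = (np.abs(rel) >= cfg.class_rel) & pstats.significant
    runs = _qualifying_runs(mask)
    if not runs:
        return 0.0
    spacing = float(np.median(np.diff(times)))
    return max(length for _, length in runs) * spacing


def logphase_slope(times: np.ndarray, values: np.ndarray,
                   cfg: KineticsConfig) -> float:
    """Maximum-magnitude least-squares slope (%/h) over sliding windows of
    ``slope_window`` hours; the sign of the winning window is preserved."""
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    spacing = float(np.median(np.diff(times)))
    w = int(round(cfg.slope_window / spacing)) + 1
    if w > len(times):
        raise ValueError(
            f"slope window of {w} points exceeds curve length {len(times)}"
        )
    w = max(w, 2)
    best = 0.0
    for i in range(len(times) - w + 1):
        s = float(np.polyfit(times[i:i + w], values[i:i + w], 1)[0])
        if abs(s) > abs(best):
            best = s
    return best


def trapezoid_auc(times: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal integral of confluence over the observed span (%.h)."""
    if len(times) < 2:
        raise ValueError("AUC needs >= 2 points")
    return float(np.trapezoid(values, times))


def _local_slopes(times: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Per-point slope of the forward-looking least-squares window.

    Forward windows keep a plateau's first point uncontaminated by the
    growth phase that precedes it; trailing points reuse the last full
    (>= 3 point) window.
    """
    n = len(times)
    out = np.empty(n)
    for i in range(n):
        lo, hi = i, min(n, i + window)
        if hi - lo < 3:
            lo, hi = max(0, n - 3), n
        out[i] = np.polyfit(times[lo:hi], values[lo:hi], 1)[0]
    return out


def plateau_window(times: np.ndarray, values: np.ndarray,
                   cfg: KineticsConfig) -> tuple[float, float] | None:
    """Longest terminal interval with local |slope| <= ``plateau_tol``,
    or None if shorter than ``plateau_min`` hours."""
    slopes = _local_slopes(np.asarray(times, float), np.asarray(values, float),
                           cfg.plateau_fit_window)
    flat = np.abs(slopes) <= cfg.plateau_tol
    i = len(flat)
    while i > 0 and flat[i - 1]:
        i -= 1
    if i == len(flat):
        return None
    start, end = float(times[i]), float(times[-1])
    if end - start < cfg.plateau_min:
        return None
    return start, end


def intra_cv(finals: Sequence[float]) -> float:
    """100 * sample SD / mean of final confluence across replicates."""
    arr = np.asarray(finals, dtype=float)
    if len(arr) < 2:
        raise ValueError("intra-assay CV needs >= 2 replicates")
    m = arr.mean()
    if m <= 0:
        raise ValueError(f"mean final confluence must be > 0, got {m}")
    return float(100.0 * arr.std(ddof=1) / m)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def compute_profile(treated: Sequence[ConfluenceTrace],
                    control: Sequence[ConfluenceTrace],
                    cfg: KineticsConfig | None = None, *,
                    cell_line: str = "", formulation_id: str | None = None,
                    production_batch: str = "") -> tuple[KineticProfile, PointwiseStats]:
    """Full kinetic profile for one treated group and its matched control."""
    cfg = cfg or KineticsConfig()
    t_times, t_mean, _ = group_mean_curve(treated)
    c_times, c_mean, _ = group_mean_curve(control)
    if len(t_times) != len(c_times) or np.any(np.abs(t_times - c_times) > 1e-6):
        raise ValidationError("treated and control grids differ")

    t_vals = np.vstack([tr.values for tr in treated])
    c_vals = np.vstack([tr.values for tr in control])
    finals_t = t_vals[:, -1]
    finals_c = c_vals[:, -1]
    final_mean = float(finals_t.mean())
    final_sd = float(finals_t.std(ddof=1))
    control_final = float(finals_c.mean())
    dp, dr = delta_vs_control(final_mean, control_final)

    pstats = pointwise_tests(t_vals, c_vals, t_times, alpha=cfg.alpha)

    # divergence is assessed on baseline-normalized, smoothed mean curves
    t0 = float(t_times[0])
    t_norm = _ma3(np.clip(t_mean - t_mean[0], 0.0, None))
    c_norm = _ma3(np.clip(c_mean - c_mean[0], 0.0, None))
    onset = divergence_onset(t_times, t_norm, c_norm, pstats, cfg)
    duration = sustained_duration(t_times, t_norm, c_norm, pstats, cfg)

    t_smooth = _ma3(t_mean)
    profile = KineticProfile(
        cell_line=cell_line,
        formulation_id=formulation_id,
        production_batch=production_batch,
        final_confluence_mean=final_mean,
        final_confluence_sd=final_sd,
        control_final_mean=control_final,
        delta_points=dp,
        delta_relative=dr,
        onset_hours=onset,
        logphase_slope=logphase_slope(t_times, t_smooth, cfg),
        auc=trapezoid_auc(t_times, t_mean),
        divergence_duration=duration,
        plateau_window=plateau_window(t_times, t_smooth, cfg),
        intra_cv=intra_cv(finals_t),
        n_sig_points=pstats.n_significant,
    )
    return profile, pstats
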