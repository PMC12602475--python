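"""Kinematic validation: flexion parametrization, cycle averaging, regression.

During passive flexion the five dependent joint motions (adduction,
internal-external rotation and the three joint translations) are functions
of the flexion angle, so experimental and simulated trajectories are
compared after re-parametrizing each motion on a common flexion grid.  The
comparison itself is an ordinary least-squares fit

    y = b0 + b1 * x

with y the experimental and x the simulated trace, reported as slope,
intercept, RMSE, adjusted R^2, the two-sided p-value of the slope test, and
Pearson's r, over a stated flexion range (by convention 7-90 deg and
7-112 deg).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import statsmodels.api as sm
from scipy.ndimage import median_filter

__all__ = [
    "MOTION_COLUMNS",
    "FlexionParametrizedCurve",
    "RegressionReport",
    "parametrize_by_flexion",
    "average_cycles",
    "linear_regress",
    "compare_nk_cm",
    "render_report_table",
]

logger = logging.getLogger(__name__)

# dependent motions, keyed by trajectory-CSV column; labels follow the
# clinical shorthand (AA adduction, IE internal-external, ML/AP/SI the
# medial-lateral, anterior-posterior, superior-inferior translations)
MOTION_COLUMNS = {
    "AA": "adduction_deg",
    "IE": "internal_rotation_deg",
    "ML": "S1_mm",
    "AP": "S2_mm",
    "SI": "S3_mm",
}


@dataclass
class FlexionParametrizedCurve:
    """One motion resampled on a uniform flexion grid, per cycle.

    ``values`` has shape (n_cycles, n_grid); NaN marks grid points a cycle
    does not cover.  ``n_excluded`` counts samples dropped by the spurious-
    point screen.
    """

    grid: np.ndarray
    values: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("flexion grid must be strictly increasing")
        self.values = np.atleast_2d(np.asarray(self.values, float))

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    @property
    def variance(self) -> np.ndarray:
        """Unbiased pointwise variance across cycles (NaN where <2 cycles)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            n = np.sum(~np.isnan(self.values), axis=0)
            v = np.nanvar(self.values, axis=0, ddof=1)
        return np.where(n >= 2, v, np.nan)


def _split_limbs(flexion: np.ndarray):
    """Indices of the ascending and descending limbs of one cycle."""
    if len(flexion) < 2:
        return [np.arange(len(flexion))]
    i_max = int(np.argmax(flexion))
    limbs = []
    if i_max >= 1:
        limbs.append(np.arange(0, i_max + 1))
    if i_max < len(flexion) - 1:
        limbs.append(np.arange(i_max, len(flexion)))
    return limbs or [np.arange(len(flexion))]


def _screen_spurious(values: np.ndarray, mad_threshold: float,
                     abs_floor: float = 0.5) -> np.ndarray:
    """Flag isolated spikes: residual from a rolling median, MAD-scaled.

    Replaces the visual inspection step of a manual pipeline.  Returns a
    boolean keep-mask.
    """
    if len(values) < 5:
        return np.ones(len(values), dtype=bool)
    trend = median_filter(values, size=5, mode="nearest")
    resid = values - trend
    mad = np.median(np.abs(resid - np.median(resid)))
    cut = max(mad_threshold * 1.4826 * mad, abs_floor)
    return np.abs(resid) <= cut


def parametrize_by_flexion(trajectory, grid, motions=None,
                           mad_threshold: float = 5.0) -> dict:
    """Resample dependent motions of each cycle onto a uniform flexion grid.

    ``trajectory`` is a trajectory DataFrame (or anything with ``.frame``),
    ``grid`` the target flexion grid in degrees.  The ascending and
    descending limbs of each cycle are resampled separately (linear
    interpolation) and pooled; samples failing the spurious-point screen are
    excluded and logged.  Raises if the grid lies outside the data range.
    """
    df = getattr(trajectory, "frame", trajectory)
    grid = np.asarray(grid, float)
    if motions is None:
        motions = dict(MOTION_COLUMNS)
    flex_all = df["flexion_deg"].to_numpy(float)
    if grid.min() < flex_all.min() - 1e-9 or grid.max() > flex_all.max() + 1e-9:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] outside data flexion range "
            f"[{flex_all.min():.2f}, {flex_all.max():.2f}]")

    cycles = sorted(df["cycle"].unique()) if "cycle" in df else [0]
    out = {}
    for label, col in motions.items():
        if col not in df.columns:
            raise KeyError(f"motion column {col!r} missing from trajectory")
        per_cycle = []
        n_excluded = 0
        for c in cycles:
            sub = df[df["cycle"] == c] if "cycle" in df else df
            flex = sub["flexion_deg"].to_numpy(float)
            val = sub[col].to_numpy(float)
            keep = _screen_spurious(val, mad_threshold)
            n_excluded += int((~keep).sum())
            limb_vals = []
            for limb in _split_limbs(flex):
                m = limb[keep[limb]]
                if len(m) < 2:
                    continue
                order = np.argsort(flex[m], kind="stable")
                fx, fv = flex[m][order], val[m][order]
                fx, uniq = np.unique(fx, return_index=True)
                fv = fv[uniq]
                if len(fx) < 2:
                    continue
                y = np.interp(grid, fx, fv, left=np.nan, right=np.nan)
                y[(grid < fx[0]) | (grid > fx[-1])] = np.nan
                limb_vals.append(y)
            if limb_vals:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    per_cycle.append(np.nanmean(np.vstack(limb_vals), axis=0))
            else:
                per_cycle.append(np.full(len(grid), np.nan))
        if n_excluded:
            logger.info("motion %s: excluded %d spurious sample(s)", label, n_excluded)
        out[label] = FlexionParametrizedCurve(grid=grid,
                                              values=np.vstack(per_cycle),
                                              n_excluded=n_excluded)
    return out


def average_cycles(curve: FlexionParametrizedCurve):
    """Pointwise mean and unbiased variance traces across cycles."""
    return curve.mean, curve.variance


@dataclass
class RegressionReport:
    """OLS comparison of an experimental trace against a simulated one."""

    b0: float
    b1: float
    rmse: float
    r2_adj: float
    p_value: float
    pearson_r: float
    n: int
    flexion_range: tuple = (None, None)
    slope_stderr: float = float("nan")

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError("Pearson r outside [-1, 1]")
        if self.rmse < 0:
            raise ValueError("negative RMSE")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flexion_range"] = list(self.flexion_range)
        return d


def linear_regress(y, x, flexion_range=None, grid=None) -> RegressionReport:
    """Fit ``y = b0 + b1 x`` by OLS and report the comparison statistics.

    ``y`` is the experimental trace, ``x`` the simulated one, on a common
    grid; if ``grid`` and ``flexion_range`` are given the fit is restricted
    to grid points inside the range.  NaN pairs are dropped.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape:
        raise ValueError("traces must share a grid")
    mask = ~(np.isnan(y) | np.isnan(x))
    if grid is not None and flexion_range is not None:
        g = np.asarray(grid, float)
        lo, hi = flexion_range
        mask &= (g >= lo - 1e-9) & (g <= hi + 1e-9)
    y, x = y[mask], x[mask]
    if len(y) < 3:
        raise ValueError(f"fewer than 3 common points (n={len(y)})")
    if np.ptp(x) == 0:
        raise ValueError("simulated trace has zero variance")

    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid = y - fit.fittedvalues
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    r = float(np.corrcoef(x, y)[0, 1]) if np.ptp(y) > 0 else 0.0
    return RegressionReport(
        b0=float(fit.params[0]), b1=float(fit.params[1]),
        rmse=rmse, r2_adj=float(fit.rsquared_adj),
        p_value=float(fit.pvalues[1]), pearson_r=r,
        n=int(len(y)),
        flexion_range=tuple(flexion_range) if flexion_range else (float(np.min(x)), float(np.max(x))),
        slope_stderr=float(fit.bse[1]))


def compare_nk_cm(experimental, simulated, ranges=((7.0, 90.0), (7.0, 112.0)),
                  grid_step: float = 0.5, both_orientations: bool = False) -> dict:
    """Pairwise regression of all five dependent motions over flexion ranges.

    ``experimental`` and ``simulated`` are trajectory DataFrames (or CSV
    paths readable by :func:`tibfem.simulate.read_trajectory_csv`).  Returns
    a nested report: motion -> "lo-hi" -> regression dict, with an ``FE``
    row (flexion regressed on itself) for completeness.
    """
    from .simulate import read_trajectory_csv

    if isinstance(experimental, (str, bytes)) or hasattr(experimental, "__fspath__"):
        experimental = read_trajectory_csv(experimental)
    if isinstance(simulated, (str, bytes)) or hasattr(simulated, "__fspath__"):
        simulated = read_trajectory_csv(simulated)

    missing = [c for c in list(MOTION_COLUMNS.values()) + ["flexion_deg", "cycle"]
               if c not in experimental.columns or c not in simulated.columns]
    if missing:
        raise KeyError(f"missing motion columns: {missing}")

    report: dict = {}
    for lo, hi in ranges:
        key = f"{lo:g}-{hi:g}"
        lo_data = max(experimental["flexion_deg"].min(), simulated["flexion_deg"].min())
        hi_data = min(experimental["flexion_deg"].max(), simulated["flexion_deg"].max())
        glo, ghi = max(lo, lo_data), min(hi, hi_data)
        grid = np.arange(glo, ghi + 1e-9, grid_step)
        exp_curves = parametrize_by_flexion(experimental, grid)
        sim_curves = parametrize_by_flexion(simulated, grid)

        fe = linear_regress(grid, grid, flexion_range=(lo, hi), grid=grid)
        report.setdefault("FE", {})[key] = fe.to_dict()
        for label in MOTION_COLUMNS:
            ye, _ = average_cycles(exp_curves[label])
            xs, _ = average_cycles(sim_curves[label])
            rep = linear_regress(ye, xs, flexion_range=(lo, hi), grid=grid)
            entry = rep.to_dict()
            if both_orientations:
                entry["reverse"] = linear_regress(xs, ye, flexion_range=(lo, hi),
                                                  grid=grid).to_dict()
            report.setdefault(label, {})[key] = entry
    return report


def render_report_table(report: dict) -> str:
    """Plain-text table of the comparison report (slope/intercept/RMSE/R2)."""
    ranges = sorted({k for v in report.values() for k in v})
    lines = []
    head = f"{'JM':<4}" + "".join(
        f"{h + ' ' + r:>16}" for h in ("slope", "intercept", "RMSE", "R2adj", "p")
        for r in ranges)
    lines.append(head)
    for motion, per_range in report.items():
        row = f"{motion:<4}"
        for quant in ("b1", "b0", "rmse", "r2_adj", "p_value"):
            for r in ranges:
                val = per_range.get(r, {}).get(quant, float("nan"))
                row += f"{val:>16.4g}"
        lines.append(row)
    return "\n".join(lines)


def save_report_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
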