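"""The Y_i estimator: stabilised D_fast and three-compartment fractions.

The estimator repeats the segmented bi-exponential fit with the fit start
moved along a grid of low b-values (default 2, 4, 7, 10, 15, 20 s/mm^2),
log-odds-transforms the resulting apparent perfusion fractions,

    Y_i = ln[(1 - PF_i) / PF_i],

and regresses Y_i on b_i.  Under a bi-exponential decay the points fall on
an exact line with slope D_fast - D_slow and intercept ln[(1-PF)/PF], so

* ``d_fast_yi = slope + d_slow`` is a pseudo-diffusion estimate weighted
  across all grid starts instead of hinging on a single fit, and
* the intercept recovers the perfusion fraction of the *bi-exponential part*
  of the signal.  Because every fit starts at b >= 2, the very fast third
  compartment (essentially fully decayed by b = 2) never enters, and the
  intercept fraction is relative to the vfast-free sub-signal,
  F_fast / (F_fast + F_slow).  Combining it with the total perfusion
  fraction F_tot (from a conventional fit anchored at b = 0) gives the
  absolute three-compartment fractions without a tri-exponential fit:

      F_fast  = (1 - F_tot) * exp(-intercept)
      F_vfast = F_tot - F_fast.

b = 0 is excluded from the line by default: the measured Y_0 sits
systematically below the line (the very fast component inflates PF_0), and
its residual is the diagnostic for the presence of that component.

The log-odds transform is only usefully linear for PF_i roughly in
(0.05, 0.4); outside that window small PF errors explode in Y.  Grid points
whose fitted PF_i leaves the window are dropped from the regression by
default (``window_policy="drop"``; ``"flag"`` retains them, matching a
fixed-grid analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DecaySignal, inverse_yi, yi_transform
from .fitting import (
    DEFAULT_BOUNDS,
    HIGHB_THRESHOLD,
    FitBounds,
    full_biex_fit,
    full_triex_fit,
    segmented_fit,
)

__all__ = [
    "YiConfig",
    "YiSeries",
    "YiRegression",
    "YiDerivedParams",
    "YiResults",
    "compute_yi_series",
    "fit_yi_line",
    "derive_params",
    "yi_pipeline",
    "YiModel",
    "DEFAULT_B_GRID",
]

#: default grid of fit-starting b-values, s/mm^2 (b = 0 deliberately absent)
DEFAULT_B_GRID = (2.0, 4.0, 7.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class YiConfig:
    """Tunable knobs of the Y_i pipeline (defaults match the standard recipe)."""

    b_grid: tuple = DEFAULT_B_GRID
    threshold: float = HIGHB_THRESHOLD
    include_threshold: bool = False
    bounds: FitBounds = DEFAULT_BOUNDS
    #: PF_i linearity window of the log-odds transform
    pf_window: tuple = (0.05, 0.4)
    #: "drop": exclude out-of-window points from the line (>=3 must survive,
    #: else all are retained); "flag": keep all points, flag only
    window_policy: str = "drop"
    #: scan-level QC floor on the line fit
    r_squared_floor: float = 0.5
    #: where F_tot comes from: segmented / full biex at b=0, or triex
    f_tot_source: str = "segmented"
    #: correct the intercept fraction for its vfast-free normalisation
    vfast_correction: bool = True
    #: QC window on the conventional PF at b=0
    pf0_window: tuple = (0.001, 0.6)


@dataclass(frozen=True)
class YiSeries:
    """Fitted (b_i, PF_i, Y_i) points sharing one high-b D_slow estimate."""

    b_grid: np.ndarray
    pf_values: np.ndarray
    y_values: np.ndarray
    d_slow: float
    qc_flags: np.ndarray  # True where the point is a usable fit

    def __len__(self) -> int:
        return self.b_grid.size


@dataclass(frozen=True)
class YiRegression:
    """OLS line through the (b_i, Y_i) points.

    ``residuals`` are actual minus predicted at every series point;
    ``fitted_mask`` marks the points the line was estimated from (their
    residuals sum to zero); the rest are extrapolated diagnostics.
    """

    slope: float
    intercept: float
    r_squared: float
    b_grid: np.ndarray
    residuals: np.ndarray
    fitted_mask: np.ndarray

    @property
    def extrapolated_residuals(self) -> dict:
        out = ~self.fitted_mask
        return dict(zip(self.b_grid[out].tolist(), self.residuals[out].tolist()))

    def predict(self, b_i) -> np.ndarray:
        return self.slope * np.asarray(b_i, dtype=float) + self.intercept


@dataclass(frozen=True)
class YiDerivedParams:
    """IVIM parameters derived from the Y_i line."""

    d_fast_yi: float      # mm^2/s
    f_fast: float
    f_tot: float
    f_vfast: float
    flags: tuple = ()

    @property
    def valid(self) -> bool:
        return not self.flags


def compute_yi_series(
    signal: DecaySignal,
    b_grid=DEFAULT_B_GRID,
    threshold: float = HIGHB_THRESHOLD,
    include_threshold: bool = False,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> YiSeries:
    """Run the segmented fit at every grid start and log-odds the PF_i.

    D_slow is taken from the b_start = 0 high-b step; because the
    mono-exponential subset does not change with the fit start, it is shared
    by every grid point.  A grid value missing from the scheme raises; a
    fit returning PF_i outside (0, 1) is flagged invalid instead.
    """
    grid = np.asarray(b_grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("b_grid must be non-empty and strictly increasing")
    for b in grid:
        if not signal.scheme.contains(b):
            raise ValueError(f"grid b-value {b} not present in acquisition scheme")

    d_slow, _ = _seg0_highb(signal, threshold, include_threshold)
    pf = np.empty(grid.size)
    ok = np.ones(grid.size, dtype=bool)
    for i, b in enumerate(grid):
        res = segmented_fit(signal, b, threshold, include_threshold, bounds)
        pf[i] = res.pf_i
        ok[i] = np.isfinite(res.pf_i) and 0.0 < res.pf_i < 1.0
    y = np.where(ok, yi_transform(np.where(ok, pf, 0.5), clip=True), np.nan)
    return YiSeries(b_grid=grid, pf_values=pf, y_values=y, d_slow=d_slow, qc_flags=ok)


def _seg0_highb(signal, threshold, include_threshold):
    from .fitting import fit_monoexp_highb

    b0 = float(signal.b_values[0])
    return fit_monoexp_highb(signal, b0, threshold, include_threshold)


def fit_yi_line(
    series: YiSeries,
    pf_window: tuple = (0.05, 0.4),
    window_policy: str = "drop",
    fit_b=None,
) -> YiRegression:
    """Unweighted OLS of Y_i on b_i.

    ``fit_b`` restricts the fit to an explicit subset of grid b-values
    (residuals at the rest are extrapolated from the line, as in the
    residual-vs-included-range diagnostics).  Otherwise the fitted subset is
    the valid points, minus out-of-window ones under the "drop" policy
    (unless fewer than 3 would survive, in which case all valid points are
    kept).  Fewer than 3 fitted points raises.
    """
    if window_policy not in ("drop", "flag"):
        raise ValueError(f"unknown window_policy {window_policy!r}")
    mask = series.qc_flags.copy()
    if fit_b is not None:
        sel = np.isin(series.b_grid, np.asarray(fit_b, dtype=float))
        mask &= sel
    elif window_policy == "drop":
        inside = (series.pf_values > pf_window[0]) & (series.pf_values < pf_window[1])
        if (mask & inside).sum() >= 3:
            mask &= inside
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 valid points for the Y_i line, have {int(mask.sum())}")

    x, y = series.b_grid[mask], series.y_values[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred_all = slope * series.b_grid + intercept
    residuals = series.y_values - pred_all
    ss_res = float(np.sum(residuals[mask] ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return YiRegression(
        slope=float(slope), intercept=float(intercept), r_squared=float(r2),
        b_grid=series.b_grid, residuals=residuals, fitted_mask=mask,
    )


def derive_params(
    reg: YiRegression,
    d_slow: float,
    f_tot: float,
    vfast_correction: bool = True,
) -> YiDerivedParams:
    """IVIM parameters from the fitted line.

    d_fast_yi = slope + d_slow.  The intercept fraction
    ``pf_eff = 1/(1+e^intercept)`` is the perfusion fraction of the
    vfast-free sub-signal; with ``vfast_correction`` (default) it is
    rescaled to an absolute compartment fraction,
    ``f_fast = (1 - f_tot) * exp(-intercept)``, which makes
    ``f_vfast = f_tot - f_fast`` an exact three-compartment decomposition.
    Without the correction f_fast is the raw inverse log-odds.

    A non-positive slope (d_fast <= d_slow, unphysical) and a negative
    f_vfast (clipped to 0) are flagged rather than raised.
    """
    if d_slow <= 0:
        raise ValueError(f"d_slow must be positive, got {d_slow}")
    if not 0.0 < f_tot < 1.0:
        raise ValueError(f"f_tot must be in (0, 1), got {f_tot}")
    flags = []
    if reg.slope <= 0:
        flags.append("nonpositive_slope")
    d_fast_yi = reg.slope + d_slow
    if vfast_correction:
        f_fast = (1.0 - f_tot) * float(np.exp(-reg.intercept))
    else:
        f_fast = float(inverse_yi(reg.intercept))
    f_vfast = f_tot - f_fast
    if f_vfast < 0:
        flags.append("negative_f_vfast")
        f_vfast = 0.0
    return YiDerivedParams(
        d_fast_yi=float(d_fast_yi), f_fast=float(f_fast), f_tot=float(f_tot),
        f_vfast=float(f_vfast), flags=tuple(flags),
    )


@dataclass(frozen=True)
class YiResults:
    """Everything the Y_i pipeline produces for one scan."""

    series: YiSeries
    regression: YiRegression
    derived: YiDerivedParams
    qc_pass: bool
    qc_reasons: tuple = ()
    #: actual-minus-predicted Y at b = 0 (extrapolated; negative when a very
    #: fast component inflates PF_0)
    residual_b0: float = np.nan
    config: YiConfig = field(default_factory=YiConfig)

    def record(self, scan_id: str = "", subject_id: str = "", session: int = 1) -> dict:
        """Flat per-scan record for tabular export."""
        return {
            "scan_id": scan_id,
            "subject_id": subject_id,
            "session": session,
            "d_slow": self.series.d_slow,
            "d_fast_yi": self.derived.d_fast_yi,
            "f_fast": self.derived.f_fast,
            "f_tot": self.derived.f_tot,
            "f_vfast": self.derived.f_vfast,
            "slope": self.regression.slope,
            "intercept": self.regression.intercept,
            "r_squared": self.regression.r_squared,
            "residual_b0": self.residual_b0,
            "n_fitted": int(self.regression.fitted_mask.sum()),
            "qc_pass": self.qc_pass,
            "qc_reasons": ";".join(self.qc_reasons),
        }

    def summary(self) -> str:
        d = self.derived
        r = self.regression
        lines = [
            "Y_i estimation",
            f"  grid (fitted) : {r.b_grid[r.fitted_mask].astype(int).tolist()} s/mm2",
            f"  slope         : {r.slope * 1e3:.3f} x1e-3 mm2/s   "
            f"intercept: {r.intercept:.4f}   R^2: {r.r_squared:.4f}",
            f"  D_slow        : {self.series.d_slow * 1e3:.3f} x1e-3 mm2/s",
            f"  D_fast (Y_i)  : {d.d_fast_yi * 1e3:.2f} x1e-3 mm2/s",
            f"  F_tot / F_fast / F_vfast : {d.f_tot:.4f} / {d.f_fast:.4f} / {d.f_vfast:.4f}",
            f"  QC pass       : {self.qc_pass}"
            + (f"  ({', '.join(self.qc_reasons)})" if self.qc_reasons else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter the (b_i, Y_i) points with the fitted line and the b=0 point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        s, r = self.series, self.regression
        ax.scatter(s.b_grid[r.fitted_mask], s.y_values[r.fitted_mask],
                   color="tab:blue", label="fitted $Y_i$")
        out = ~r.fitted_mask
        if out.any():
            ax.scatter(s.b_grid[out], s.y_values[out], facecolor="none",
                       edgecolor="tab:blue", label="excluded")
        xs = np.linspace(0, s.b_grid.max() * 1.05, 50)
        ax.plot(xs, r.predict(xs), "k--",
                label=f"slope={r.slope*1e3:.2f}e-3, $R^2$={r.r_squared:.3f}")
        if np.isfinite(self.residual_b0):
            ax.scatter([0.0], [r.intercept + self.residual_b0], marker="x",
                       color="tab:red", label="$Y_0$ (not fitted)")
        ax.set_xlabel("fit-starting $b_i$ (s/mm$^2$)")
        ax.set_ylabel("$Y_i = \\ln[(1-PF_i)/PF_i]$")
        ax.legend(fontsize=8)
        return ax


def yi_pipeline(signal: DecaySignal, config: YiConfig = YiConfig()) -> YiResults:
    """Full per-scan Y_i estimate: series, line, derived parameters, QC.

    Deterministic given the input and config.  Scan-level QC fails when the
    line's R^2 is below the configured floor, when the conventional PF at
    b = 0 leaves its plausibility window, or when any component fit fails.
    """
    series = compute_yi_series(
        signal, config.b_grid, config.threshold, config.include_threshold,
        config.bounds,
    )
    qc_reasons = []
    try:
        reg = fit_yi_line(series, config.pf_window, config.window_policy)
    except ValueError:
        qc_reasons.append("yi_line_failed")
        n = series.b_grid.size
        reg = YiRegression(
            slope=np.nan, intercept=np.nan, r_squared=0.0, b_grid=series.b_grid,
            residuals=np.full(n, np.nan), fitted_mask=np.zeros(n, dtype=bool),
        )

    # conventional anchor at the lowest acquired b (normally 0): F_tot source
    b0 = float(signal.b_values[0])
    seg0 = segmented_fit(
        signal, b0, config.threshold, config.include_threshold, config.bounds
    )
    if config.f_tot_source == "segmented":
        f_tot = seg0.pf_i
    elif config.f_tot_source == "full":
        f_tot = full_biex_fit(
            signal, b0, config.threshold, config.include_threshold, config.bounds
        ).pf_i
    elif config.f_tot_source == "triex":
        tri = full_triex_fit(signal, config.bounds)
        f_tot = tri.params.f_tot
    else:
        raise ValueError(f"unknown f_tot_source {config.f_tot_source!r}")

    lo0, hi0 = config.pf0_window
    if not (np.isfinite(f_tot) and lo0 < f_tot < hi0):
        qc_reasons.append("pf0_out_of_range")
    if np.isfinite(reg.r_squared) and reg.r_squared < config.r_squared_floor:
        qc_reasons.append("low_r_squared")
    if not series.qc_flags.all():
        qc_reasons.append("invalid_series_points")

    residual_b0 = np.nan
    if np.isfinite(reg.slope) and np.isfinite(seg0.pf_i) and 0 < seg0.pf_i < 1:
        residual_b0 = float(yi_transform(seg0.pf_i, clip=True) - reg.predict(b0))

    if qc_reasons and ("yi_line_failed" in qc_reasons or "pf0_out_of_range" in qc_reasons):
        derived = YiDerivedParams(
            d_fast_yi=np.nan, f_fast=np.nan,
            f_tot=f_tot if np.isfinite(f_tot) else np.nan, f_vfast=np.nan,
            flags=("qc_fail",),
        )
    else:
        derived = derive_params(
            reg, series.d_slow, f_tot, vfast_correction=config.vfast_correction
        )
    qc_pass = not qc_reasons
    return YiResults(
        series=series, regression=reg, derived=derived, qc_pass=qc_pass,
        qc_reasons=tuple(qc_reasons), residual_b0=residual_b0, config=config,
    )


class YiModel:
    """Y_i estimator bound to one decay signal (statsmodels-style front end)."""

    def __init__(self, signal: DecaySignal, config: YiConfig = YiConfig()):
        self.signal = signal
        self.config = config

    @classmethod
    def from_dataframe(cls, df, b_col: str = "b", signal_col: str = "signal",
                       config: YiConfig = YiConfig()):
        from .core import AcquisitionScheme

        df = df.sort_values(b_col)
        scheme = AcquisitionScheme(df[b_col].to_numpy())
        return cls(DecaySignal(scheme, df[signal_col].to_numpy()), config)

    def fit(self) -> YiResults:
        return yi_pipeline(self.signal, self.config)
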