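"""Conventional IVIM fitting baselines.

Three estimators, each runnable from an arbitrary fit-starting b-value
``b_start`` (the signal is renormalised by S(b_start), so the model keeps
its decay rates and only the apparent perfusion fraction changes):

``segmented_fit``
    The two-stage convention: an ordinary least-squares fit of ln S against
    b over the high-b subset (b above the 60 s/mm^2 threshold, where
    perfusion is assumed fully decayed) yields D_slow and, via the
    extrapolated intercept, PF_i; a one-parameter bounded nonlinear
    least-squares step then determines D_fast with the other two held fixed.

``full_biex_fit``
    All three parameters in one bounded nonlinear least-squares fit,
    deterministically initialised from the segmented result.

``full_triex_fit``
    The three-compartment model with S(0) fixed as normalisation; six free
    parameters by default (fractions renormalised to unit sum afterwards),
    or five with the sum-to-one constraint imposed.

Bounds follow reported liver ranges and enforce the rate ordering
D_slow < D_fast < D_vfast through disjoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .core import AcquisitionScheme, BiexParams, DecaySignal, TriexParams

__all__ = [
    "FitBounds",
    "BiexFitResult",
    "TriexFitResult",
    "fit_monoexp_highb",
    "fit_dfast_constrained",
    "segmented_fit",
    "full_biex_fit",
    "full_triex_fit",
    "pixelwise_map",
    "BiexModel",
    "TriexModel",
    "HIGHB_THRESHOLD",
]

#: default b-value threshold separating perfusion from pure diffusion, s/mm^2
HIGHB_THRESHOLD = 60.0

_LSQ_OPTS = dict(ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=1000)
_BOUNDARY_RTOL = 1e-6


@dataclass(frozen=True)
class FitBounds:
    """Box bounds for the nonlinear fits, mm^2/s (fractions dimensionless)."""

    d_slow: tuple = (1e-4, 3e-3)
    d_fast: tuple = (3e-3, 0.5)
    d_vfast: tuple = (0.1, 10.0)
    pf: tuple = (0.0, 1.0)


DEFAULT_BOUNDS = FitBounds()


@dataclass(frozen=True)
class BiexFitResult:
    """A two-compartment fit anchored at ``b_start``.

    ``pf_i`` is the apparent perfusion fraction at the fit start; ``sse`` the
    residual sum of squares over the fitted points (normalised signal).
    """

    b_start: float
    pf_i: float
    d_slow: float
    d_fast: float
    method: str
    sse: float
    converged: bool

    @property
    def params(self) -> BiexParams:
        return BiexParams(pf=self.pf_i, d_slow=self.d_slow, d_fast=self.d_fast)

    def predict(self, b, s_start: float = 1.0) -> np.ndarray:
        """Model signal at b-values ``b`` (>= b_start), normalised to s_start."""
        b = np.asarray(b, dtype=float)
        db = b - self.b_start
        return s_start * (
            self.pf_i * np.exp(-db * self.d_fast)
            + (1.0 - self.pf_i) * np.exp(-db * self.d_slow)
        )

    def summary(self) -> str:
        lines = [
            f"Bi-exponential IVIM fit ({self.method}), b_start = {self.b_start:g} s/mm2",
            f"  PF_i    : {self.pf_i:.4f}",
            f"  D_slow  : {self.d_slow * 1e3:.3f} x1e-3 mm2/s",
            f"  D_fast  : {self.d_fast * 1e3:.2f} x1e-3 mm2/s",
            f"  SSE     : {self.sse:.3e}   converged: {self.converged}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class TriexFitResult:
    """A three-compartment fit with S(0) fixed as normalisation."""

    params: TriexParams
    sse: float
    converged: bool
    n_free: int

    def predict(self, b, s0: float = 1.0) -> np.ndarray:
        from .core import triex_signal

        return triex_signal(self.params, s0, b)

    def summary(self) -> str:
        p = self.params
        return "\n".join([
            f"Tri-exponential IVIM fit ({self.n_free} free parameters)",
            f"  F_slow / F_fast / F_vfast : {p.f_slow:.4f} / {p.f_fast:.4f} / {p.f_vfast:.4f}",
            f"  D_slow  : {p.d_slow * 1e3:.3f} x1e-3 mm2/s",
            f"  D_fast  : {p.d_fast * 1e3:.2f} x1e-3 mm2/s",
            f"  D_vfast : {p.d_vfast:.3f} mm2/s",
            f"  SSE     : {self.sse:.3e}   converged: {self.converged}",
        ])


def _highb_mask(b: np.ndarray, threshold: float, include_threshold: bool) -> np.ndarray:
    return b >= threshold if include_threshold else b > threshold


def fit_monoexp_highb(
    signal: DecaySignal,
    b_start: float = 0.0,
    threshold: float = HIGHB_THRESHOLD,
    include_threshold: bool = False,
):
    """Log-linear high-b step of the segmented fit.

    OLS of ln S(b) on (b - b_start) over the high-b subset.  The slope gives
    -D_slow; the intercept extrapolates the slow compartment back to
    ``b_start``, so ``pf_i = 1 - exp(intercept) / S(b_start)``.

    Returns
    -------
    (d_slow, pf_i) : tuple of float
    """
    sub = signal.restrict(b_start)
    b = sub.b_values
    hi = _highb_mask(b, threshold, include_threshold)
    if hi.sum() < 3:
        raise ValueError(
            f"need >= 3 b-values above threshold {threshold}, have {int(hi.sum())}"
        )
    slope, intercept = np.polyfit(b[hi] - b_start, np.log(sub.signal[hi]), 1)
    d_slow = -float(slope)
    pf_i = 1.0 - float(np.exp(intercept)) / sub.signal[0]
    return d_slow, float(pf_i)


def fit_dfast_constrained(
    signal: DecaySignal,
    b_start: float,
    d_slow: float,
    pf_i: float,
    bounds: FitBounds = DEFAULT_BOUNDS,
    d_fast_init: float = 50e-3,
):
    """One-parameter bounded NLLSQ for D_fast with (d_slow, pf_i) fixed.

    Fits the re-anchored bi-exponential model over all b >= b_start with
    S(b_start) fixed as normalisation.  A solution pinned at a bound is
    flagged as not converged.

    Returns
    -------
    (d_fast, converged) : tuple of (float, bool)
    """
    if not 0.0 < pf_i < 1.0:
        raise ValueError(f"pf_i must be in (0, 1), got {pf_i}")
    if d_slow <= 0:
        raise ValueError(f"d_slow must be positive, got {d_slow}")
    sub = signal.restrict(b_start)
    db = sub.b_values - b_start
    s_norm = sub.signal / sub.signal[0]
    slow_part = (1.0 - pf_i) * np.exp(-db * d_slow)

    def residuals(x):
        return pf_i * np.exp(-db * x[0]) + slow_part - s_norm

    lo, hi = bounds.d_fast
    x0 = float(np.clip(d_fast_init, lo, hi))
    sol = least_squares(residuals, [x0], bounds=([lo], [hi]), **_LSQ_OPTS)
    d_fast = float(sol.x[0])
    pinned = (
        d_fast <= lo * (1 + _BOUNDARY_RTOL) or d_fast >= hi * (1 - _BOUNDARY_RTOL)
    )
    return d_fast, bool(sol.success and not pinned)


def segmented_fit(
    signal: DecaySignal,
    b_start: float = 0.0,
    threshold: float = HIGHB_THRESHOLD,
    include_threshold: bool = False,
    bounds: FitBounds = DEFAULT_BOUNDS,
    d_fast_init: float = 50e-3,
) -> BiexFitResult:
    """Two-stage segmented bi-exponential fit anchored at ``b_start``."""
    d_slow, pf_i = fit_monoexp_highb(signal, b_start, threshold, include_threshold)
    if not 0.0 < pf_i < 1.0 or d_slow <= 0:
        # no measurable perfusion pool / non-decaying signal; D_fast undefined
        return BiexFitResult(
            b_start=float(b_start), pf_i=pf_i, d_slow=d_slow, d_fast=np.nan,
            method="segmented", sse=np.nan, converged=False,
        )
    d_fast, ok = fit_dfast_constrained(
        signal, b_start, d_slow, pf_i, bounds=bounds, d_fast_init=d_fast_init
    )
    sub = signal.restrict(b_start)
    s_norm = sub.signal / sub.signal[0]
    db = sub.b_values - b_start
    model = pf_i * np.exp(-db * d_fast) + (1 - pf_i) * np.exp(-db * d_slow)
    sse = float(np.sum((model - s_norm) ** 2))
    return BiexFitResult(
        b_start=float(b_start), pf_i=pf_i, d_slow=d_slow, d_fast=d_fast,
        method="segmented", sse=sse, converged=bool(ok and d_slow > 0),
    )


def full_biex_fit(
    signal: DecaySignal,
    b_start: float = 0.0,
    threshold: float = HIGHB_THRESHOLD,
    include_threshold: bool = False,
    bounds: FitBounds = DEFAULT_BOUNDS,
) -> BiexFitResult:
    """Three-parameter bounded NLLSQ of the re-anchored bi-exponential model.

    Deterministically initialised from :func:`segmented_fit` (no random
    restarts), normalised by the measured S(b_start).
    """
    seg = segmented_fit(signal, b_start, threshold, include_threshold, bounds)
    sub = signal.restrict(b_start)
    db = sub.b_values - b_start
    s_norm = sub.signal / sub.signal[0]

    def residuals(x):
        pf, ds, df = x
        return pf * np.exp(-db * df) + (1 - pf) * np.exp(-db * ds) - s_norm

    lo = [bounds.pf[0], bounds.d_slow[0], bounds.d_fast[0]]
    hi = [bounds.pf[1], bounds.d_slow[1], bounds.d_fast[1]]
    x0 = np.array([
        np.clip(seg.pf_i if np.isfinite(seg.pf_i) else 0.2, 1e-3, 1 - 1e-3),
        np.clip(seg.d_slow, *bounds.d_slow),
        np.clip(seg.d_fast if np.isfinite(seg.d_fast) else 50e-3, *bounds.d_fast),
    ])
    x0 = np.minimum(np.maximum(x0, lo), hi)
    sol = least_squares(residuals, x0, bounds=(lo, hi), **_LSQ_OPTS)
    pf, ds, df = map(float, sol.x)
    sse = float(np.sum(sol.fun ** 2))
    pinned = df <= bounds.d_fast[0] * (1 + _BOUNDARY_RTOL) or df >= bounds.d_fast[1] * (
        1 - _BOUNDARY_RTOL
    )
    return BiexFitResult(
        b_start=float(b_start), pf_i=pf, d_slow=ds, d_fast=df,
        method="full", sse=sse, converged=bool(sol.success and not pinned and df >= ds),
    )


_TRIEX_INIT = (0.7, 0.15, 0.15, 1e-3, 50e-3, 0.5)


def full_triex_fit(
    signal: DecaySignal,
    bounds: FitBounds = DEFAULT_BOUNDS,
    constrain_sum: bool = False,
) -> TriexFitResult:
    """Tri-exponential NLLSQ with S(0) fixed as normalisation.

    By default the six parameters (three fractions, three rates) are all
    free within bounds and the fractions are renormalised to unit sum
    afterwards; with ``constrain_sum=True`` the slow fraction is eliminated
    (five free parameters, fractions sum to one by construction).
    """
    if signal.b_values[0] != 0.0:
        raise ValueError("full_triex_fit requires the scheme to include b = 0")
    b = signal.b_values
    s_norm = signal.signal / signal.signal[0]

    f0_slow, f0_fast, f0_vfast, d0_s, d0_f, d0_v = _TRIEX_INIT
    if constrain_sum:
        def residuals(x):
            ff, fv, ds, df, dv = x
            fs = 1.0 - ff - fv
            return (
                fs * np.exp(-b * ds) + ff * np.exp(-b * df) + fv * np.exp(-b * dv)
                - s_norm
            )

        lo = [0.0, 0.0, bounds.d_slow[0], bounds.d_fast[0], bounds.d_vfast[0]]
        hi = [1.0, 1.0, bounds.d_slow[1], bounds.d_fast[1], bounds.d_vfast[1]]
        x0 = [f0_fast, f0_vfast, d0_s, d0_f, d0_v]
        sol = least_squares(residuals, x0, bounds=(lo, hi), **_LSQ_OPTS)
        ff, fv, ds, df, dv = map(float, sol.x)
        fs = 1.0 - ff - fv
        n_free = 5
    else:
        def residuals(x):
            fs, ff, fv, ds, df, dv = x
            return (
                fs * np.exp(-b * ds) + ff * np.exp(-b * df) + fv * np.exp(-b * dv)
                - s_norm
            )

        lo = [0.0, 0.0, 0.0, bounds.d_slow[0], bounds.d_fast[0], bounds.d_vfast[0]]
        hi = [1.0, 1.0, 1.0, bounds.d_slow[1], bounds.d_fast[1], bounds.d_vfast[1]]
        x0 = [f0_slow, f0_fast, f0_vfast, d0_s, d0_f, d0_v]
        sol = least_squares(residuals, x0, bounds=(lo, hi), **_LSQ_OPTS)
        fs, ff, fv, ds, df, dv = map(float, sol.x)
        n_free = 6

    total = fs + ff + fv
    if total <= 0:
        return TriexFitResult(
            params=TriexParams(1.0, 0.0, 0.0, d0_s, d0_f, d0_v),
            sse=float(np.sum(sol.fun ** 2)), converged=False, n_free=n_free,
        )
    fs, ff, fv = fs / total, ff / total, fv / total
    # exact unit sum for the dataclass invariant
    fs = 1.0 - ff - fv
    ok = bool(sol.success) and ds < df < dv
    try:
        params = TriexParams(fs, ff, fv, ds, df, dv)
    except ValueError:
        # rate ordering violated at a bound; report best-found, flagged
        eps = 1e-12
        params = TriexParams(
            fs, ff, fv, ds, max(df, ds * (1 + 1e-9)), max(dv, df * (1 + 1e-9)) + eps
        )
        ok = False
    return TriexFitResult(
        params=params, sse=float(np.sum(sol.fun ** 2)), converged=ok, n_free=n_free
    )


def pixelwise_map(
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray,
    method: str = "segmented",
    **fit_kwargs,
):
    """Apply a per-voxel estimator inside a mask.

    Parameters
    ----------
    volume : ndarray, shape (X, Y, Z, n_b)
        Diffusion-weighted intensities; the 4th axis must match the scheme.
    scheme : AcquisitionScheme
    mask : ndarray, shape (X, Y, Z)
        Voxels with value > 0.5 are fitted; everything else is NaN in the
        output maps.
    method : {"segmented", "yi"}

    Returns
    -------
    dict of str -> ndarray
        3-D float maps (NaN outside the mask) plus a boolean ``qc_pass`` map.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[-1] != len(scheme):
        raise ValueError(
            f"volume must be 4-D with last axis {len(scheme)}, got {volume.shape}"
        )
    mask = np.asarray(mask)
    if mask.shape != volume.shape[:3]:
        raise ValueError(f"mask shape {mask.shape} != spatial shape {volume.shape[:3]}")
    inside = mask > 0.5

    if method == "segmented":
        keys = ["pf", "d_slow", "d_fast"]
    elif method == "yi":
        keys = ["d_fast_yi", "f_fast", "f_tot", "f_vfast", "r_squared"]
    else:
        raise ValueError(f"unknown method {method!r}")
    maps = {k: np.full(volume.shape[:3], np.nan) for k in keys}
    maps["qc_pass"] = np.zeros(volume.shape[:3], dtype=bool)

    if method == "yi":
        from .yi import YiConfig, yi_pipeline

        config = fit_kwargs.pop("config", None) or YiConfig()

    for idx in np.argwhere(inside):
        i, j, k = idx
        decay = volume[i, j, k]
        if np.any(~np.isfinite(decay)) or np.any(decay <= 0):
            continue
        sig = DecaySignal(scheme, decay)
        try:
            if method == "segmented":
                res = segmented_fit(sig, **fit_kwargs)
                maps["pf"][i, j, k] = res.pf_i
                maps["d_slow"][i, j, k] = res.d_slow
                maps["d_fast"][i, j, k] = res.d_fast
                maps["qc_pass"][i, j, k] = res.converged
            else:
                out = yi_pipeline(sig, config)
                maps["d_fast_yi"][i, j, k] = out.derived.d_fast_yi
                maps["f_fast"][i, j, k] = out.derived.f_fast
                maps["f_tot"][i, j, k] = out.derived.f_tot
                maps["f_vfast"][i, j, k] = out.derived.f_vfast
                maps["r_squared"][i, j, k] = out.regression.r_squared
                maps["qc_pass"][i, j, k] = out.qc_pass
        except (ValueError, FloatingPointError):
            continue
    return maps


class BiexModel:
    """Two-compartment IVIM model bound to one decay signal.

    statsmodels-style front end: construct with the data and fit options,
    call :meth:`fit` to obtain a :class:`BiexFitResult`.
    """

    def __init__(
        self,
        signal: DecaySignal,
        b_start: float = 0.0,
        threshold: float = HIGHB_THRESHOLD,
        include_threshold: bool = False,
        bounds: FitBounds = DEFAULT_BOUNDS,
    ):
        self.signal = signal
        self.b_start = float(b_start)
        self.threshold = float(threshold)
        self.include_threshold = include_threshold
        self.bounds = bounds

    @classmethod
    def from_dataframe(cls, df, b_col: str = "b", signal_col: str = "signal", **kw):
        """Build from a tidy (b, signal) table, e.g. one scan of a decay CSV."""
        df = df.sort_values(b_col)
        scheme = AcquisitionScheme(df[b_col].to_numpy())
        return cls(DecaySignal(scheme, df[signal_col].to_numpy()), **kw)

    def fit(self, method: str = "segmented") -> BiexFitResult:
        if method == "segmented":
            return segmented_fit(
                self.signal, self.b_start, self.threshold,
                self.include_threshold, self.bounds,
            )
        if method == "full":
            return full_biex_fit(
                self.signal, self.b_start, self.threshold,
                self.include_threshold, self.bounds,
            )
        raise ValueError(f"unknown method {method!r}")


class TriexModel:
    """Three-compartment IVIM model bound to one decay signal."""

    def __init__(
        self,
        signal: DecaySignal,
        bounds: FitBounds = DEFAULT_BOUNDS,
        constrain_sum: bool = False,
    ):
        self.signal = signal
        self.bounds = bounds
        self.constrain_sum = constrain_sum

    @classmethod
    def from_dataframe(cls, df, b_col: str = "b", signal_col: str = "signal", **kw):
        df = df.sort_values(b_col)
        scheme = AcquisitionScheme(df[b_col].to_numpy())
        return cls(DecaySignal(scheme, df[signal_col].to_numpy()), **kw)

    def fit(self) -> TriexFitResult:
        return full_triex_fit(self.signal, self.bounds, self.constrain_sum)
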