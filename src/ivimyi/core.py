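"""Closed-form IVIM signal models and the shifted-start log-odds transform.

The intravoxel incoherent motion (IVIM) framework describes the diffusion-MRI
signal decay of perfused tissue as a mixture of exponentials.  The
two-compartment (bi-exponential) model is

    S(b) = S0 * [ PF * exp(-b * D_fast) + (1 - PF) * exp(-b * D_slow) ]

with perfusion fraction ``PF`` and diffusion coefficients
``D_slow < D_fast`` (mm^2/s; ``b`` in s/mm^2).  Liver tissue additionally
shows a very fast third compartment, giving the tri-exponential
three-compartment model

    S(b) = S0 * [ F_slow * exp(-b * D_slow) + F_fast * exp(-b * D_fast)
                  + F_vfast * exp(-b * D_vfast) ].

When the bi-exponential model is re-anchored to start at a nonzero b-value
``b_i`` (normalising by ``S(b_i)`` instead of ``S0``), the decay rates are
unchanged but the apparent perfusion fraction becomes

    PF_i = PF * exp(-b_i * D_fast)
           / [ PF * exp(-b_i * D_fast) + (1 - PF) * exp(-b_i * D_slow) ]

which decreases towards zero as ``b_i`` grows.  Its log-odds

    Y_i = ln[(1 - PF_i) / PF_i] = b_i * (D_fast - D_slow) + ln[(1 - PF)/PF]

is exactly linear in ``b_i`` -- the relationship that the Y_i estimator in
:mod:`ivimyi.yi` exploits: the slope of the fitted (b_i, Y_i) line is
``D_fast - D_slow`` and its intercept recovers the perfusion fraction of the
purely bi-exponential part of the signal.

Units are fixed package-wide: b-values in s/mm^2, diffusion coefficients in
mm^2/s.  Display helpers may show coefficients in 1e-3 mm^2/s, but internal
values are never rescaled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BiexParams",
    "TriexParams",
    "AcquisitionScheme",
    "DecaySignal",
    "biex_signal",
    "triex_signal",
    "shifted_pf",
    "yi_transform",
    "inverse_yi",
    "theoretical_yi_line",
    "PF_CLIP",
]

#: clipping bounds applied to fitted perfusion fractions before the log-odds
PF_CLIP = (1e-6, 1.0 - 1e-6)


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name}: parameters must be finite, got {v!r}")


@dataclass(frozen=True)
class BiexParams:
    """Two-compartment IVIM parameters.

    Parameters
    ----------
    pf : float
        Perfusion fraction, in (0, 1).
    d_slow : float
        Molecular diffusion coefficient, mm^2/s.
    d_fast : float
        Pseudo-diffusion coefficient of the perfusion compartment, mm^2/s.
        ``d_fast == d_slow`` is tolerated (mono-exponential collapse) for
        signal evaluation but rejected by :func:`theoretical_yi_line`.
    """

    pf: float
    d_slow: float
    d_fast: float

    def __post_init__(self) -> None:
        _require_finite("BiexParams", self.pf, self.d_slow, self.d_fast)
        if not 0.0 < self.pf < 1.0:
            raise ValueError(f"pf must be in (0, 1), got {self.pf}")
        if not 0.0 < self.d_slow <= self.d_fast:
            raise ValueError(
                f"need 0 < d_slow <= d_fast, got d_slow={self.d_slow}, "
                f"d_fast={self.d_fast}"
            )


@dataclass(frozen=True)
class TriexParams:
    """Three-compartment IVIM parameters.

    Fractions must sum to one (within 1e-9) and rates must be strictly
    ordered ``d_slow < d_fast < d_vfast``.
    """

    f_slow: float
    f_fast: float
    f_vfast: float
    d_slow: float
    d_fast: float
    d_vfast: float

    _FRACTION_TOL = 1e-9

    def __post_init__(self) -> None:
        _require_finite(
            "TriexParams",
            self.f_slow, self.f_fast, self.f_vfast,
            self.d_slow, self.d_fast, self.d_vfast,
        )
        for name in ("f_slow", "f_fast", "f_vfast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.f_slow + self.f_fast + self.f_vfast
        if abs(total - 1.0) > self._FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1, got {total!r}")
        if not self.d_slow < self.d_fast < self.d_vfast:
            raise ValueError(
                "rates must satisfy d_slow < d_fast < d_vfast, got "
                f"({self.d_slow}, {self.d_fast}, {self.d_vfast})"
            )
        if self.d_slow <= 0:
            raise ValueError(f"d_slow must be positive, got {self.d_slow}")

    @property
    def f_tot(self) -> float:
        """Total perfusion fraction F_fast + F_vfast (the bi-exponential PF)."""
        return self.f_fast + self.f_vfast

    def collapse_biex(self) -> BiexParams:
        """Two-compartment view ignoring the very fast pool (requires f_vfast=0)."""
        if self.f_vfast != 0.0:
            raise ValueError("collapse_biex requires f_vfast == 0")
        return BiexParams(pf=self.f_fast, d_slow=self.d_slow, d_fast=self.d_fast)


@dataclass(frozen=True)
class AcquisitionScheme:
    """A diffusion-weighting scheme: sorted unique b-values with NSA counts.

    ``nsa`` is the number of signal averages (excitations) acquired at each
    b-value; it drives the noise averaging in :mod:`ivimyi.simulate`.
    """

    b_values: np.ndarray
    nsa: np.ndarray

    def __init__(self, b_values, nsa=None):
        b = np.asarray(b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("b_values must be a 1-D array with >= 2 entries")
        if np.any(b < 0):
            raise ValueError("b_values must be nonnegative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if nsa is None:
            n = np.ones(b.size, dtype=int)
        else:
            n = np.asarray(nsa, dtype=int)
            if n.shape != b.shape:
                raise ValueError("nsa must match b_values in length")
            if np.any(n < 1):
                raise ValueError("nsa must be >= 1")
        b.setflags(write=False)
        n.setflags(write=False)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "nsa", n)

    def __len__(self) -> int:
        return self.b_values.size

    def index_of(self, b: float) -> int:
        """Index of b-value ``b``; raises if absent."""
        hits = np.flatnonzero(np.isclose(self.b_values, b))
        if hits.size == 0:
            raise ValueError(f"b-value {b} not in scheme {self.b_values.tolist()}")
        return int(hits[0])

    def contains(self, b: float) -> bool:
        return bool(np.any(np.isclose(self.b_values, b)))


@dataclass(frozen=True)
class DecaySignal:
    """One scan's decay series: a scheme plus strictly positive intensities."""

    scheme: AcquisitionScheme
    signal: np.ndarray = field(repr=False)

    def __init__(self, scheme: AcquisitionScheme, signal):
        s = np.asarray(signal, dtype=float)
        if s.shape != scheme.b_values.shape:
            raise ValueError(
                f"signal length {s.size} does not match scheme length {len(scheme)}"
            )
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise ValueError("signal values must be finite and > 0")
        s = s.copy()
        s.setflags(write=False)
        object.__setattr__(self, "scheme", scheme)
        object.__setattr__(self, "signal", s)

    @property
    def b_values(self) -> np.ndarray:
        return self.scheme.b_values

    def at(self, b: float) -> float:
        """Signal intensity at b-value ``b``."""
        return float(self.signal[self.scheme.index_of(b)])

    def restrict(self, b_start: float) -> "DecaySignal":
        """Sub-signal on b >= b_start (b_start must be in the scheme)."""
        i = self.scheme.index_of(b_start)
        sub = AcquisitionScheme(self.b_values[i:], self.scheme.nsa[i:])
        return DecaySignal(sub, self.signal[i:])


def biex_signal(params: BiexParams, s0: float, b) -> np.ndarray:
    """Bi-exponential IVIM decay evaluated at b-values ``b``.

    Returns ``s0 * [pf*exp(-b*d_fast) + (1-pf)*exp(-b*d_slow)]``; equals
    ``s0`` at b=0.
    """
    _require_finite("biex_signal", s0)
    if s0 <= 0:
        raise ValueError(f"s0 must be positive, got {s0}")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    return s0 * (
        params.pf * np.exp(-b * params.d_fast)
        + (1.0 - params.pf) * np.exp(-b * params.d_slow)
    )


def triex_signal(params: TriexParams, s0: float, b) -> np.ndarray:
    """Tri-exponential IVIM decay evaluated at b-values ``b``."""
    _require_finite("triex_signal", s0)
    if s0 <= 0:
        raise ValueError(f"s0 must be positive, got {s0}")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    return s0 * (
        params.f_slow * np.exp(-b * params.d_slow)
        + params.f_fast * np.exp(-b * params.d_fast)
        + params.f_vfast * np.exp(-b * params.d_vfast)
    )


def shifted_pf(params: BiexParams, b_i) -> np.ndarray | float:
    """Apparent perfusion fraction when the fit is anchored at ``b_i``.

    PF_i = pf*e^(-b_i*d_fast) / [pf*e^(-b_i*d_fast) + (1-pf)*e^(-b_i*d_slow)].
    Equals ``pf`` at b_i=0 and decreases strictly towards 0 with growing b_i
    whenever d_fast > d_slow.
    """
    b_i = np.asarray(b_i, dtype=float)
    if np.any(b_i < 0):
        raise ValueError("b_i must be nonnegative")
    fast = params.pf * np.exp(-b_i * params.d_fast)
    slow = (1.0 - params.pf) * np.exp(-b_i * params.d_slow)
    out = fast / (fast + slow)
    return float(out) if out.ndim == 0 else out


def yi_transform(pf_i, clip: bool = False) -> np.ndarray | float:
    """Log-odds of the slow fraction: Y = ln[(1 - pf_i) / pf_i].

    Strictly decreasing in ``pf_i``; zero at 0.5.  With ``clip=True``
    (the policy used for noisy fitted values) ``pf_i`` is first clipped into
    ``PF_CLIP``; otherwise values outside (0, 1) raise.
    """
    p = np.asarray(pf_i, dtype=float)
    if clip:
        p = np.clip(p, *PF_CLIP)
    elif np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("pf_i must lie in (0, 1); pass clip=True for fitted values")
    out = np.log((1.0 - p) / p)
    return float(out) if out.ndim == 0 else out


def inverse_yi(y) -> np.ndarray | float:
    """Inverse of :func:`yi_transform`: pf = 1 / (1 + e^y) (a logistic)."""
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("y must be finite")
    # evaluate in a branch-stable way for large |y|
    out = np.where(y >= 0, np.exp(-y) / (1.0 + np.exp(-y)), 1.0 / (1.0 + np.exp(y)))
    return float(out) if out.ndim == 0 else out


def theoretical_yi_line(params: BiexParams, b_i):
    """Exact (slope, intercept, y-values) of the Y_i line for known parameters.

    slope = d_fast - d_slow, intercept = ln[(1-pf)/pf], y = slope*b_i +
    intercept.  Agrees with ``yi_transform(shifted_pf(params, b_i))``
    identically.  Requires d_fast > d_slow (otherwise the line degenerates to
    slope zero and the shifted fraction no longer moves).
    """
    if not params.d_fast > params.d_slow:
        raise ValueError("theoretical_yi_line requires d_fast > d_slow")
    b_i = np.asarray(b_i, dtype=float)
    if np.any(b_i < 0):
        raise ValueError("b_i must be nonnegative")
    slope = params.d_fast - params.d_slow
    intercept = float(np.log((1.0 - params.pf) / params.pf))
    return slope, intercept, slope * b_i + intercept
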