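"""Scan-rescan agreement and dispersion statistics.

The comparison statistics used to rank estimators: coefficient of variation
over all scans (sample SD / mean), within-subject standard deviation of
paired scans (wSD = sqrt(sum d_i^2 / 2n)), Bland-Altman mean difference with
1.96-SD limits of agreement, and the intraclass correlation coefficient
(two-way random effects, absolute agreement, single measurement -- ICC(2,1)
-- with the consistency variant ICC(3,1) by flag).

``method_comparison`` assembles these into the standard per-parameter,
per-method comparison table for a whole cohort, optionally adding bias and
RMSE against a simulation truth table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedMeasurements",
    "ReproReport",
    "cov",
    "wsd",
    "bland_altman",
    "icc",
    "paired_report",
    "method_comparison",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """One parameter measured twice per subject."""

    subject_ids: tuple
    value_scan1: np.ndarray
    value_scan2: np.ndarray

    def __init__(self, subject_ids, value_scan1, value_scan2):
        v1 = np.asarray(value_scan1, dtype=float)
        v2 = np.asarray(value_scan2, dtype=float)
        ids = tuple(subject_ids)
        if not (len(ids) == v1.size == v2.size):
            raise ValueError("subject_ids and both value arrays must have equal length")
        if np.any(~np.isfinite(v1)) or np.any(~np.isfinite(v2)):
            raise ValueError("paired values must be finite (apply QC filtering first)")
        object.__setattr__(self, "subject_ids", ids)
        object.__setattr__(self, "value_scan1", v1)
        object.__setattr__(self, "value_scan2", v2)

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def differences(self) -> np.ndarray:
        return self.value_scan2 - self.value_scan1


@dataclass(frozen=True)
class ReproReport:
    """Summary row of agreement statistics for one parameter/method."""

    mean: float
    cov: float
    wsd: float
    ba_difference: float
    ba_limits: tuple
    icc: float
    n_scans: int
    n_pairs: int


def cov(values) -> float:
    """Coefficient of variation: sample SD (n-1) over mean.  Mean 0 raises."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cov needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("cov undefined for zero mean")
    return float(np.std(v, ddof=1) / m)


def wsd(pairs: PairedMeasurements) -> float:
    """Within-subject SD of two scans: sqrt(sum(d_i^2) / (2 n))."""
    if len(pairs) < 1:
        raise ValueError("wsd needs at least 1 pair")
    d = pairs.differences
    return float(np.sqrt(np.sum(d ** 2) / (2 * d.size)))


def bland_altman(pairs: PairedMeasurements):
    """Mean difference and 1.96-SD limits of agreement.

    Returns
    -------
    (mean_difference, (lower_limit, upper_limit))
    """
    if len(pairs) < 2:
        raise ValueError("bland_altman needs at least 2 pairs")
    d = pairs.differences
    md = float(d.mean())
    half = 1.96 * float(np.std(d, ddof=1))
    return md, (md - half, md + half)


def icc(pairs: PairedMeasurements, variant: str = "ICC(2,1)") -> float:
    """Intraclass correlation from the two-way ANOVA mean squares.

    ``"ICC(2,1)"`` (default): two-way random effects, absolute agreement,
    single measurement.  ``"ICC(3,1)"``: two-way mixed, consistency.  A
    fully degenerate table (every value equal) is defined as 1.
    """
    if variant not in ("ICC(2,1)", "ICC(3,1)"):
        raise ValueError(f"unknown ICC variant {variant!r}")
    if len(pairs) < 3:
        raise ValueError("icc needs at least 3 pairs")
    x = np.column_stack([pairs.value_scan1, pairs.value_scan2])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )
    if msr == 0 and msc == 0 and mse == 0:
        return 1.0
    if variant == "ICC(3,1)":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def paired_report(all_values, pairs: PairedMeasurements,
                  icc_variant: str = "ICC(2,1)") -> ReproReport:
    """Full agreement summary: dispersion over scans plus paired statistics."""
    ba_md, ba_lim = bland_altman(pairs)
    return ReproReport(
        mean=float(np.mean(all_values)),
        cov=cov(all_values),
        wsd=wsd(pairs),
        ba_difference=ba_md,
        ba_limits=ba_lim,
        icc=icc(pairs, icc_variant),
        n_scans=len(np.asarray(all_values)),
        n_pairs=len(pairs),
    )


def _pairs_from_table(df: pd.DataFrame, value_col: str) -> PairedMeasurements:
    wide = df.pivot_table(index="subject_id", columns="session",
                          values=value_col, aggfunc="first")
    wide = wide.dropna()
    if not {1, 2}.issubset(set(wide.columns)):
        raise ValueError("paired statistics need sessions 1 and 2")
    return PairedMeasurements(
        wide.index.tolist(), wide[1].to_numpy(), wide[2].to_numpy()
    )


def method_comparison(
    tables: dict,
    parameters,
    truth: pd.DataFrame | None = None,
    truth_map: dict | None = None,
    icc_variant: str = "ICC(2,1)",
) -> pd.DataFrame:
    """Comparison table across estimation methods for a scan-rescan cohort.

    Parameters
    ----------
    tables : dict of str -> DataFrame
        One per-scan table per method.  Each must carry ``subject_id``,
        ``session`` and the parameter columns; every method must cover the
        same set of scans (QC-filter to a common cohort first).
    parameters : sequence of str
        Parameter columns to summarise.
    truth : DataFrame, optional
        Simulation truth per scan (``subject_id``, ``session`` plus truth
        columns); adds bias and RMSE rows.
    truth_map : dict, optional
        Maps a parameter column to its truth column when names differ
        (e.g. ``{"d_fast_yi": "d_fast"}``).

    Returns
    -------
    DataFrame with one row per (parameter, method, statistic).
    """
    if not tables:
        raise ValueError("need at least one method table")
    scan_sets = {
        m: set(zip(t["subject_id"], t["session"])) for m, t in tables.items()
    }
    ref = next(iter(scan_sets.values()))
    for m, s in scan_sets.items():
        if s != ref:
            raise ValueError(f"scan set of method {m!r} differs from the others")
    truth_map = truth_map or {}

    rows = []
    for param in parameters:
        for m, t in tables.items():
            if param not in t.columns:
                continue
            values = t[param].to_numpy(dtype=float)
            if np.any(~np.isfinite(values)):
                raise ValueError(
                    f"non-finite {param} values in method {m!r}; QC-filter first"
                )
            pairs = _pairs_from_table(t, param)
            rep = paired_report(values, pairs, icc_variant)
            stats = {
                "mean": rep.mean, "cov": rep.cov, "wsd": rep.wsd,
                "ba_difference": rep.ba_difference,
                "ba_limit_low": rep.ba_limits[0],
                "ba_limit_high": rep.ba_limits[1],
                "icc": rep.icc,
                "n_scans": rep.n_scans, "n_pairs": rep.n_pairs,
            }
            if truth is not None:
                tcol = truth_map.get(param, param)
                if tcol in truth.columns:
                    merged = t.merge(
                        truth[["subject_id", "session", tcol]],
                        on=["subject_id", "session"], suffixes=("", "_true"),
                    )
                    tv = merged[tcol + "_true"] if tcol == param else merged[tcol]
                    err = merged[param].to_numpy(dtype=float) - tv.to_numpy(dtype=float)
                    stats["bias"] = float(err.mean())
                    stats["rmse"] = float(np.sqrt(np.mean(err ** 2)))
            for stat, value in stats.items():
                rows.append({
                    "parameter": param, "method": m, "statistic": stat,
                    "value": value,
                })
    return pd.DataFrame(rows)
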