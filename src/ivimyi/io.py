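"""File formats: long-format decay CSV, NIfTI volumes, config files.

The tabular interchange format is a long CSV with columns
``subject_id, scan_id, session, b, signal`` (optional ``nsa``), one row per
(scan, b-value).  Image input is a 4-D NIfTI volume with an FSL-style
whitespace-separated ``.bval`` text file (one value per volume) and a binary
ROI mask; the ROI-mean signal per b-value forms the decay curve, with
repeated b-values (excitations stored as separate volumes) averaged and
counted as NSA.

All numeric output uses 6 significant digits and fixed column order so that
repeated runs are byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import AcquisitionScheme, DecaySignal

__all__ = [
    "ScanRecord",
    "RunConfig",
    "read_decay_csv",
    "write_decay_csv",
    "read_nifti_scan",
    "write_maps_nifti",
    "write_table",
]

_DECAY_COLUMNS = ["subject_id", "scan_id", "session", "b", "signal"]
FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class ScanRecord:
    """One scan: identifiers plus its decay series."""

    scan_id: str
    subject_id: str
    session: int
    decay: DecaySignal

    def __post_init__(self):
        if not self.scan_id or not self.subject_id:
            raise ValueError("scan_id and subject_id must be non-empty")
        if self.session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {self.session}")


@dataclass
class RunConfig:
    """Run-wide settings shared by the CLI subcommands."""

    b_grid: tuple = (2.0, 4.0, 7.0, 10.0, 15.0, 20.0)
    threshold: float = 60.0
    include_threshold: bool = False
    window_policy: str = "drop"
    pf_window: tuple = (0.05, 0.4)
    r_squared_floor: float = 0.5
    f_tot_source: str = "segmented"
    vfast_correction: bool = True
    n_subjects: int = 17
    snr: float = 100.0
    noise_kind: str = "rician"
    rel_sd: float = 0.15
    rescan_jitter: float = 0.05
    scheme_variant: str = "dataset1"
    seed: int = 0
    outdir: str = "."

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from a flat YAML/key-value file; unknown keys raise."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg

    def dump(self, path) -> None:
        import yaml

        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def yi_config(self):
        from .yi import YiConfig

        return YiConfig(
            b_grid=tuple(self.b_grid),
            threshold=self.threshold,
            include_threshold=self.include_threshold,
            pf_window=tuple(self.pf_window),
            window_policy=self.window_policy,
            r_squared_floor=self.r_squared_floor,
            f_tot_source=self.f_tot_source,
            vfast_correction=self.vfast_correction,
        )


def read_decay_csv(path) -> list[ScanRecord]:
    """Parse a long-format decay table into validated scan records.

    Rows are grouped by ``scan_id``, sorted by b within each scan.
    Duplicate b-values within a scan, nonpositive signal, or missing
    columns raise a descriptive error naming the offending row.
    """
    df = pd.read_csv(path)
    missing = [c for c in _DECAY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = df.index[~(df["signal"] > 0)]
    if len(bad):
        raise ValueError(
            f"{path}: nonpositive signal at data row {int(bad[0]) + 2} "
            f"(scan {df.loc[bad[0], 'scan_id']!r}, b={df.loc[bad[0], 'b']})"
        )
    has_nsa = "nsa" in df.columns
    records = []
    for scan_id, g in df.groupby("scan_id", sort=True):
        g = g.sort_values("b")
        b = g["b"].to_numpy(dtype=float)
        if np.any(np.diff(b) == 0):
            raise ValueError(f"{path}: duplicate b-value within scan {scan_id!r}")
        subj = g["subject_id"].iloc[0]
        session = int(g["session"].iloc[0])
        nsa = g["nsa"].to_numpy(dtype=int) if has_nsa else None
        scheme = AcquisitionScheme(b, nsa)
        records.append(ScanRecord(
            scan_id=str(scan_id), subject_id=str(subj), session=session,
            decay=DecaySignal(scheme, g["signal"].to_numpy(dtype=float)),
        ))
    return records


def write_decay_csv(records, path) -> None:
    """Inverse of :func:`read_decay_csv` (byte-stable formatting)."""
    rows = []
    for r in records:
        for b, s, n in zip(r.decay.b_values, r.decay.signal, r.decay.scheme.nsa):
            rows.append({
                "subject_id": r.subject_id, "scan_id": r.scan_id,
                "session": r.session, "b": b, "signal": s, "nsa": int(n),
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table with the package's stable float formatting."""
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_nifti_scan(
    volume_path,
    bval_path,
    mask_path,
    scan_id: str = "scan",
    subject_id: str = "subject",
    session: int = 1,
) -> ScanRecord:
    """ROI-mean decay curve from a 4-D NIfTI volume.

    The mask includes voxels with value > 0.5.  Volumes sharing a nominal
    b-value (separately stored excitations) are averaged, with the
    replicate count recorded as NSA.
    """
    import nibabel as nib

    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{volume_path}: expected a 4-D volume, got shape {data.shape}")
    bvals = np.loadtxt(str(bval_path), dtype=float).ravel()
    if bvals.size != data.shape[-1]:
        raise ValueError(
            f"{bval_path}: {bvals.size} b-values for {data.shape[-1]} volumes"
        )
    mask_img = nib.load(str(mask_path))
    mask = np.asanyarray(mask_img.dataobj) > 0.5
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"{mask_path}: mask shape {mask.shape} != spatial shape {data.shape[:3]}"
        )
    if not mask.any():
        raise ValueError(f"{mask_path}: empty mask")
    roi_means = np.array([data[..., i][mask].mean() for i in range(data.shape[-1])])

    unique_b = np.unique(bvals)
    signal = np.array([roi_means[bvals == b].mean() for b in unique_b])
    nsa = np.array([int(np.sum(bvals == b)) for b in unique_b])
    scheme = AcquisitionScheme(unique_b, nsa)
    return ScanRecord(
        scan_id=scan_id, subject_id=subject_id, session=session,
        decay=DecaySignal(scheme, signal),
    )


def write_maps_nifti(maps: dict, ref_volume_path, outdir) -> list[Path]:
    """Write each parameter map as a 3-D NIfTI next to the input's header."""
    import nibabel as nib

    ref = nib.load(str(ref_volume_path))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.items():
        img = nib.Nifti1Image(np.asarray(arr, dtype=float), ref.affine)
        out = outdir / f"{name}.nii.gz"
        nib.save(img, str(out))
        written.append(out)
    return written
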