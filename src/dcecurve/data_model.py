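"""Domain types and table I/O for DCE-MRI intensity-time-curve analysis.

The pipeline's shared vocabulary: a :class:`SignalIntensityCurve` is one
tissue specimen's region-of-interest signal S(t) sampled after contrast
injection; a :class:`SpecimenRecord` ties the specimen to a subject and a
histopathological tissue label; an :class:`AcquisitionSetting` is one cell
of the temporal-resolution x measurement-length grid; a
:class:`CurveFeatures` holds the six non-parametric curve descriptors.

All tables are plain delimiter-separated text.  Curves are long format
(one sample per row); intensities are arbitrary units and are never
rescaled implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_LABELS",
    "RESOLUTIONS_S",
    "LENGTHS_MIN",
    "NATIVE_RESOLUTION_S",
    "NATIVE_N_SAMPLES",
    "TOTAL_DURATION_S",
    "CURVE_FEATURE_NAMES",
    "QUANTITATIVE_FEATURE_NAMES",
    "SignalIntensityCurve",
    "SpecimenRecord",
    "AcquisitionSetting",
    "CurveFeatures",
    "FormatError",
    "DataError",
    "read_curves",
    "write_curves",
    "read_metadata",
    "write_metadata",
    "read_feature_table",
    "write_feature_table",
    "check_referential_integrity",
]

#: Accepted histopathological labels.  Anything else (e.g. prostatitis) is
#: rejected at load time: only cancer vs normal peripheral-zone tissue is
#: modelled.
TISSUE_LABELS = ("cancer", "normal")

#: The seven temporal resolutions of interest, seconds between acquisitions.
RESOLUTIONS_S = (1.6, 3.2, 4.8, 6.4, 8.0, 16.0, 30.4)

#: The sixteen measurement lengths of interest, minutes.
LENGTHS_MIN = (2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5,
               6.0, 6.5, 7.0, 7.5, 8.0, 10.0, 12.0, 13.0)

#: Native acquisition: one sample each 1.6 s, 513 samples, 820.8 s total.
NATIVE_RESOLUTION_S = 1.6
NATIVE_N_SAMPLES = 513
TOTAL_DURATION_S = NATIVE_RESOLUTION_S * NATIVE_N_SAMPLES  # 820.8

#: The six non-parametric descriptors, in the order they are reported.
CURVE_FEATURE_NAMES = (
    "onset_time_s",
    "rsi_pct",
    "wash_in_slope",
    "peak_intensity",
    "wash_out_pct",
    "wash_out_slope",
)

#: The four quantitative (pharmacokinetic-map) comparison features.
QUANTITATIVE_FEATURE_NAMES = (
    "blood_volume_pct",
    "transit_time_s",
    "perfusion_ml_min_cm3",
    "extravascular_volume_pct",
)


class FormatError(ValueError):
    """A file does not have the expected columns/layout."""


class DataError(ValueError):
    """A file is well-formed but its content violates an invariant."""


@dataclass(frozen=True)
class SignalIntensityCurve:
    """One specimen's sampled signal-intensity-time profile S(t).

    Parameters
    ----------
    specimen_id
        Unique specimen identifier.
    times
        Sample times in seconds, strictly increasing, first sample > 0
        (the first sample marks the end of the first acquisition interval;
        contrast injection is t = 0).
    intensities
        Signal intensities in arbitrary units, same length as ``times``,
        finite and non-negative.
    """

    specimen_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", s)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise DataError(
                f"curve {self.specimen_id!r}: times and intensities must be "
                f"1-d and of equal length (got {t.shape} vs {s.shape})")
        if t.size < 2:
            raise DataError(f"curve {self.specimen_id!r}: needs >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise DataError(
                f"curve {self.specimen_id!r}: times must be strictly increasing")
        if t[0] <= 0:
            raise DataError(f"curve {self.specimen_id!r}: first time must be > 0")
        if not (np.all(np.isfinite(s)) and np.all(s >= 0)):
            raise DataError(
                f"curve {self.specimen_id!r}: intensities must be finite and >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one tissue specimen."""

    specimen_id: str
    subject_id: str
    tissue: str
    n_roi_points: int = 2

    def __post_init__(self) -> None:
        if self.tissue not in TISSUE_LABELS:
            raise DataError(
                f"specimen {self.specimen_id!r}: unknown tissue label "
                f"{self.tissue!r} (expected one of {TISSUE_LABELS}); "
                "other labels such as prostatitis are not analysed")
        if self.n_roi_points not in (2, 3):
            raise DataError(
                f"specimen {self.specimen_id!r}: n_roi_points must be 2 or 3")


@dataclass(frozen=True)
class AcquisitionSetting:
    """One (temporal resolution, measurement length) grid cell."""

    resolution_s: float
    length_min: float

    def __post_init__(self) -> None:
        k = self.resolution_s / NATIVE_RESOLUTION_S
        if abs(k - round(k)) > 1e-9:
            raise DataError(
                f"resolution {self.resolution_s} s is not a multiple of the "
                f"native {NATIVE_RESOLUTION_S} s spacing")
        if self.length_min * 60.0 > TOTAL_DURATION_S + 1e-9:
            raise DataError(
                f"length {self.length_min} min exceeds the recorded "
                f"{TOTAL_DURATION_S} s")

    @property
    def length_s(self) -> float:
        return self.length_min * 60.0

    def label(self) -> str:
        return f"{self.length_min:g}min_{self.resolution_s:g}s"


@dataclass
class CurveFeatures:
    """The six curve descriptors plus the intermediates they derive from.

    ``valid`` is False when extraction failed (no onset, too few samples,
    degenerate peak position); ``failure_reason`` then says why and the
    unavailable fields are NaN.
    """

    specimen_id: str
    onset_time_s: float = np.nan     # T0
    baseline_intensity: float = np.nan   # S0
    peak_intensity: float = np.nan   # Sm
    time_to_peak_s: float = np.nan   # Tp
    final_intensity: float = np.nan  # Sfinal
    measurement_end_s: float = np.nan    # Tmax
    rsi_pct: float = np.nan          # 100*Sm/S0
    wash_in_slope: float = np.nan    # (Sm-S0)/(Tp-T0)
    wash_out_pct: float = np.nan     # 100*(Sfinal-Sm)/Sm
    wash_out_slope: float = np.nan   # (Sfinal-Sm)/(Tmax-Tp)
    valid: bool = True
    failure_reason: str | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_CURVE_COLUMNS = ("specimen_id", "time_s", "intensity")
_META_COLUMNS = ("specimen_id", "subject_id", "tissue")


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")


def read_curves(path, *, delimiter: str = "\t") -> list[SignalIntensityCurve]:
    """Read a long-format curve table (specimen_id, time_s, intensity).

    Rows may appear in any order; samples are sorted by time per specimen.
    Duplicate time stamps within a specimen are a data error.
    """
    df = pd.read_csv(path, sep=delimiter)
    _require_columns(df, _CURVE_COLUMNS, path)
    curves = []
    for sid, grp in df.groupby("specimen_id", sort=True):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(f"{path}: specimen {sid!r} has duplicate time stamps")
        curves.append(SignalIntensityCurve(
            specimen_id=str(sid),
            times=t,
            intensities=grp["intensity"].to_numpy(dtype=float),
        ))
    return curves


def write_curves(curves: Iterable[SignalIntensityCurve], path, *,
                 delimiter: str = "\t") -> None:
    """Write curves in long format; inverse of :func:`read_curves`."""
    frames = [
        pd.DataFrame({
            "specimen_id": c.specimen_id,
            "time_s": c.times,
            "intensity": c.intensities,
        })
        for c in curves
    ]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=list(_CURVE_COLUMNS)))
    out.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_metadata(path) -> list[SpecimenRecord]:
    """Read the specimen metadata table and enforce its invariants.

    Each specimen id must be unique and a subject may own at most one
    cancer and one normal specimen.
    """
    df = pd.read_csv(path)
    _require_columns(df, _META_COLUMNS, path)
    if df["specimen_id"].duplicated().any():
        dup = df.loc[df["specimen_id"].duplicated(), "specimen_id"].iloc[0]
        raise DataError(f"{path}: duplicate specimen_id {dup!r}")
    records = []
    for row in df.itertuples(index=False):
        records.append(SpecimenRecord(
            specimen_id=str(row.specimen_id),
            subject_id=str(row.subject_id),
            tissue=str(row.tissue),
            n_roi_points=int(getattr(row, "n_roi_points", 2)),
        ))
    per_subject = pd.DataFrame(
        {"subject_id": [r.subject_id for r in records],
         "tissue": [r.tissue for r in records]})
    counts = per_subject.value_counts()
    if (counts > 1).any():
        subj, tissue = counts.index[counts > 1][0]
        raise DataError(
            f"{path}: subject {subj!r} owns more than one {tissue} specimen")
    return records


def write_metadata(records: Iterable[SpecimenRecord], path) -> None:
    pd.DataFrame([{
        "specimen_id": r.specimen_id,
        "subject_id": r.subject_id,
        "tissue": r.tissue,
        "n_roi_points": r.n_roi_points,
    } for r in records]).to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table as CSV, round-trip stable to full precision."""
    if table["specimen_id"].duplicated().any():
        raise DataError("feature table has duplicated specimen ids")
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("specimen_id",), path)
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(bool)
    if "failure_reason" in df.columns:
        df["failure_reason"] = df["failure_reason"].astype(object).where(
            df["failure_reason"].notna(), None)
    return df


def check_referential_integrity(curves: Iterable[SignalIntensityCurve],
                                records: Iterable[SpecimenRecord]) -> None:
    """Every curve must resolve to exactly one specimen record."""
    known = {r.specimen_id for r in records}
    orphans = sorted({c.specimen_id for c in curves} - known)
    if orphans:
        raise DataError(
            "curves without a metadata record: " + ", ".join(orphans[:5])
            + ("..." if len(orphans) > 5 else ""))
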