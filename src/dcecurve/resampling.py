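"""Temporal downsampling and truncation onto the acquisition-setting grid.

Every specimen's native 1.6 s / 820.8 s curve is reduced to each of the 112
(resolution, length) combinations: decimation emulates acquiring at a
coarser rate on the same master grid, truncation emulates a shorter
measurement.  No interpolation anywhere; non-integer sample counts floor.
"""

from __future__ import annotations

import numpy as np

from .data_model import (
    LENGTHS_MIN,
    RESOLUTIONS_S,
    AcquisitionSetting,
    DataError,
    SignalIntensityCurve,
)

__all__ = [
    "DegenerateSettingError",
    "downsample",
    "truncate",
    "apply_setting",
    "grid_settings",
    "MIN_SAMPLES",
]

#: Fewest samples on which the six descriptors are attempted.
MIN_SAMPLES = 4


class DegenerateSettingError(DataError):
    """Truncation left too few samples to characterise a curve."""


def downsample(curve: SignalIntensityCurve, resolution_s: float,
               mode: str = "decimate") -> SignalIntensityCurve:
    """Reduce temporal resolution to an integer multiple of the native one.

    ``decimate`` keeps every k-th sample starting at the k-th (sample times
    become k*dt, 2k*dt, ...), exactly emulating acquisition at the coarser
    rate.  ``block_mean`` keeps the same time stamps but replaces each kept
    sample by the mean of its k-sample block, emulating a scanner that
    integrates over the longer repetition time.
    """
    dt = float(curve.times[1] - curve.times[0])
    k = resolution_s / dt
    if abs(k - round(k)) > 1e-9:
        raise DataError(
            f"resolution {resolution_s} s is not an integer multiple of the "
            f"curve spacing {dt} s")
    k = int(round(k))
    if k == 1:
        return curve
    if mode == "decimate":
        s = curve.intensities[k - 1::k]
    elif mode == "block_mean":
        n = curve.times.size // k
        s = curve.intensities[:n * k].reshape(n, k).mean(axis=1)
    else:
        raise ValueError(f"unknown downsampling mode {mode!r}")
    return SignalIntensityCurve(curve.specimen_id, curve.times[k - 1::k], s)


def truncate(curve: SignalIntensityCurve, length_min: float,
             min_samples: int = MIN_SAMPLES) -> SignalIntensityCurve:
    """Keep samples up to the measurement length (closed interval).

    A sample exactly at the boundary is retained.  Raises
    :class:`DegenerateSettingError` when fewer than ``min_samples`` remain
    (callers flag the setting as invalid rather than crash).
    """
    cutoff = length_min * 60.0 + 1e-9
    if length_min * 60.0 > curve.times[-1] + 1e-9:
        raise DataError(
            f"length {length_min} min exceeds curve duration "
            f"{curve.times[-1]:g} s")
    n = int(np.searchsorted(curve.times, cutoff, side="right"))
    if n < min_samples:
        raise DegenerateSettingError(
            f"curve {curve.specimen_id!r}: only {n} samples within "
            f"{length_min} min")
    return SignalIntensityCurve(curve.specimen_id,
                                curve.times[:n], curve.intensities[:n])


def apply_setting(curve: SignalIntensityCurve, setting: AcquisitionSetting,
                  mode: str = "decimate") -> SignalIntensityCurve:
    """Downsample then truncate to one grid cell."""
    return truncate(downsample(curve, setting.resolution_s, mode=mode),
                    setting.length_min)


def grid_settings() -> list[AcquisitionSetting]:
    """All 112 settings, lengths-major (rows of the published C-matrix)."""
    return [AcquisitionSetting(res, length)
            for length in LENGTHS_MIN for res in RESOLUTIONS_S]
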