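"""Extraction of the six non-parametric curve descriptors.

Given a (possibly resampled) signal-intensity-time curve the extractor
determines the onset of enhancement, then computes

  (1) onset time T0 [s],
  (2) relative signal intensity RSI = 100*Sm/S0 [%],
  (3) wash-in slope (Sm - S0)/(Tp - T0) [intensity/s],
  (4) peak enhancement Sm (the raw maximum intensity),
  (5) wash-out 100*(Sfinal - Sm)/Sm [%],
  (6) wash-out slope (Sfinal - Sm)/(Tmax - Tp) [intensity/s],

where the peak search for the wash-in quantities (2)-(4) is restricted, by
default, to the first minute after the onset time.  Wash-out quantities use
the last sample of the measurement.  Values (5) and (6) are signed so that
declining curves give negative wash-out, matching the published convention.

Onset detection is not specified by the source study and is therefore an
explicit, configurable rule: the baseline is every sample before 20 s, S0
its mean, and enhancement starts at the first sample opening a run of
(default 2) consecutive samples above S0 + 3*sd(baseline).  At resolutions
too coarse for two pre-20 s samples the single first sample is the baseline
and the threshold becomes a 10% relative rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    AcquisitionSetting,
    CURVE_FEATURE_NAMES,
    CurveFeatures,
    DataError,
    SignalIntensityCurve,
    SpecimenRecord,
    check_referential_integrity,
)
from .resampling import MIN_SAMPLES, DegenerateSettingError, apply_setting

__all__ = ["FeatureOptions", "OnsetEstimate", "detect_onset",
           "extract_features", "build_feature_table"]


@dataclass(frozen=True)
class FeatureOptions:
    """Tunable knobs of the descriptor extraction.

    wash_in_window_s
        Length of the peak-search window after onset; ``None`` removes the
        restriction (the sensitivity-analysis variant).
    baseline_cutoff_s
        Samples strictly before this time form the pre-contrast baseline.
    onset_z
        Threshold multiplier on the baseline standard deviation.
    onset_consecutive
        Number of consecutive supra-threshold samples required.
    onset_rel_rise
        Relative-rise threshold used when the resolution leaves fewer than
        two baseline samples (a single sample has no sd estimate).
    """

    wash_in_window_s: float | None = 60.0
    baseline_cutoff_s: float = 20.0
    onset_z: float = 3.0
    onset_consecutive: int = 2
    onset_rel_rise: float = 0.10

    def __post_init__(self) -> None:
        if self.wash_in_window_s is not None and self.wash_in_window_s <= 0:
            raise ValueError("wash_in_window_s must be > 0 or None")
        if self.onset_z <= 0 or self.onset_rel_rise <= 0:
            raise ValueError("onset thresholds must be > 0")


@dataclass(frozen=True)
class OnsetEstimate:
    t0: float
    s0: float
    n_baseline: int
    valid: bool = True
    reason: str | None = None


DEFAULT_OPTIONS = FeatureOptions()


def detect_onset(curve: SignalIntensityCurve,
                 opts: FeatureOptions = DEFAULT_OPTIONS) -> OnsetEstimate:
    """Estimate onset time T0 and pre-contrast intensity S0."""
    t, s = curve.times, curve.intensities
    n_base = int(np.searchsorted(t, opts.baseline_cutoff_s, side="left"))
    n_base = max(n_base, 1)
    if t.size < max(n_base, 2) + opts.onset_consecutive:
        return OnsetEstimate(np.nan, np.nan, n_base, False, "too_short")
    base = s[:n_base]
    s0 = float(base.mean())
    if s0 <= 0:
        return OnsetEstimate(np.nan, s0, n_base, False, "zero_baseline")
    if n_base >= 2:
        threshold = s0 + opts.onset_z * max(float(base.std(ddof=1)), 1e-12)
    else:
        threshold = s0 * (1.0 + opts.onset_rel_rise)
    above = s > threshold
    run = 0
    for i in range(n_base, t.size):
        run = run + 1 if above[i] else 0
        if run == opts.onset_consecutive:
            start = i - opts.onset_consecutive + 1
            return OnsetEstimate(float(t[start]), s0, n_base)
    return OnsetEstimate(np.nan, s0, n_base, False, "no_onset")


def extract_features(curve: SignalIntensityCurve,
                     opts: FeatureOptions = DEFAULT_OPTIONS) -> CurveFeatures:
    """Compute the six descriptors; failures yield a flagged invalid row."""
    if len(curve) < MIN_SAMPLES:
        return CurveFeatures(curve.specimen_id, valid=False,
                             failure_reason="too_short")
    onset = detect_onset(curve, opts)
    if not onset.valid:
        return CurveFeatures(curve.specimen_id, valid=False,
                             failure_reason=onset.reason)
    t, s = curve.times, curve.intensities
    t0, s0 = onset.t0, onset.s0

    if opts.wash_in_window_s is None:
        in_window = t >= t0 - 1e-9
    else:
        in_window = (t >= t0 - 1e-9) & (t <= t0 + opts.wash_in_window_s + 1e-9)
    if not np.any(in_window):
        return CurveFeatures(curve.specimen_id, onset_time_s=t0,
                             baseline_intensity=s0, valid=False,
                             failure_reason="window_empty")
    idx = np.flatnonzero(in_window)
    peak_local = int(np.argmax(s[idx]))       # earliest index on ties
    peak = idx[peak_local]
    sm, tp = float(s[peak]), float(t[peak])
    sfinal, tmax = float(s[-1]), float(t[-1])

    feats = CurveFeatures(
        curve.specimen_id,
        onset_time_s=t0,
        baseline_intensity=s0,
        peak_intensity=sm,
        time_to_peak_s=tp,
        final_intensity=sfinal,
        measurement_end_s=tmax,
        rsi_pct=100.0 * sm / s0,
    )
    degenerate = []
    if tp > t0:
        feats.wash_in_slope = (sm - s0) / (tp - t0)
    else:
        degenerate.append("wash_in")
    feats.wash_out_pct = 100.0 * (sfinal - sm) / sm
    if tp < tmax:
        feats.wash_out_slope = (sfinal - sm) / (tmax - tp)
    else:
        degenerate.append("wash_out")
    if degenerate:
        feats.valid = False
        feats.failure_reason = "degenerate_peak:" + "+".join(degenerate)
    return feats


def build_feature_table(curves: list[SignalIntensityCurve],
                        metadata: list[SpecimenRecord],
                        setting: AcquisitionSetting | None = None,
                        opts: FeatureOptions = DEFAULT_OPTIONS,
                        mode: str = "decimate") -> pd.DataFrame:
    """One descriptor row per specimen, joined with its metadata.

    If ``setting`` is given, each curve is resampled to it first; a setting
    too coarse/short for a curve yields a flagged invalid row rather than an
    error.  Invalid rows carry NaN features and are meant to be excluded
    from model fitting (columns ``valid`` / ``failure_reason``).
    """
    check_referential_integrity(curves, metadata)
    meta = {r.specimen_id: r for r in metadata}
    rows = []
    for curve in curves:
        if setting is not None:
            try:
                resampled = apply_setting(curve, setting, mode=mode)
            except DegenerateSettingError as exc:
                rows.append({**CurveFeatures(
                    curve.specimen_id, valid=False,
                    failure_reason=f"degenerate_setting:{exc}").as_dict()})
                continue
        else:
            resampled = curve
        rows.append(extract_features(resampled, opts).as_dict())
    table = pd.DataFrame(rows)
    table.insert(1, "subject_id",
                 [meta[s].subject_id for s in table["specimen_id"]])
    table.insert(2, "tissue", [meta[s].tissue for s in table["specimen_id"]])
    return table
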