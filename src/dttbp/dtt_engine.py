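"""The diastolic-transit-time blood-pressure estimator.

A single cuff reading (SBP0/DBP0) calibrates a factor m0 from the first five
beats:

    m0 = (1/5) * sum_i (PP0 / PP_s(i)) * (SBP_s(i) - DBP_s(i+1)) / DTT(i)

after which each beat's diastolic pressure follows from its DTT and relative
contractility alone:

    eDBP(i) = SBP0 - m0 * DTT(i) * (C(i)/C0)^(-1)

Because eDBP is built from intra-beat timing features that additive
low-frequency noise cannot touch, the gap between eDBP and the raw (affine
cuff-anchored) diastolic value is an empirical measurement of the baseline
wander. That per-beat offset, smoothed with a 30-point moving median, is
subtracted from the pressure-scaled signal, and corrected beat-to-beat
SBP/DBP/MAP/HR are read off the result, with a 30-point moving-median
outlier exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat_delineation import delineate_beats
from .quality_control import continuity_filter
from .waveform import WaveformRecording

__all__ = [
    "CuffCalibration",
    "CalibrationState",
    "BaselineEstimate",
    "BP_COLUMNS",
    "calibrate_m0",
    "estimate_dbp",
    "to_pressure_units",
    "moving_median",
    "baseline_offset",
    "correct_and_extract",
    "run_dtt_pipeline",
    "DTTResult",
]

#: Column schema of a beat-indexed blood-pressure series.
BP_COLUMNS = ["t", "sbp", "dbp", "map", "hr", "edbp", "excluded"]

#: Bounds on the per-beat contractility ratio C(i)/C0; limits the leverage of
#: derivative noise on eDBP. Clamping events are counted on CalibrationState.
DEFAULT_C_RATIO_CLAMP = (0.25, 4.0)


@dataclass
class CuffCalibration:
    """One oscillometric cuff reading used to anchor the estimator."""

    sbp0: float
    dbp0: float
    t_cal: float = 0.0

    def __post_init__(self) -> None:
        if not self.sbp0 > self.dbp0 > 0:
            raise ValueError(f"cuff reading must satisfy SBP0 > DBP0 > 0, got {self.sbp0}/{self.dbp0}")

    @property
    def pp0(self) -> float:
        """Cuff pulse pressure SBP0 - DBP0 in mmHg."""
        return self.sbp0 - self.dbp0


@dataclass
class CalibrationState:
    """Everything derived from the cuff reading and the calibration beats."""

    m0: float          # mmHg/s
    c0: float          # reference contractility, sensor units / s
    gain: float        # mmHg per sensor unit
    offset: float      # mmHg; raw -> pressure map is gain*x + offset
    n_cal_beats: int = 5
    n_ratio_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not (self.m0 > 0 and self.c0 > 0 and self.gain > 0):
            raise ValueError("calibration requires m0 > 0, C0 > 0, gain > 0")


@dataclass
class BaselineEstimate:
    """Per-beat empirical baseline-wander offsets in mmHg."""

    raw_offset: np.ndarray       # raw pressure-scale DBP minus eDBP, per beat
    smoothed_offset: np.ndarray  # 30-point moving median of raw_offset
    beat_t: np.ndarray           # anchor times (end-trough times), s

    def __post_init__(self) -> None:
        if not len(self.raw_offset) == len(self.smoothed_offset) == len(self.beat_t):
            raise ValueError("baseline arrays must have equal lengths")


def _first_cal_beats(beats: pd.DataFrame, n: int) -> pd.DataFrame:
    valid = beats[beats["valid"]] if "valid" in beats else beats
    if len(valid) < n:
        raise ValueError(f"calibration needs {n} valid beats, found {len(valid)}")
    cal = valid.iloc[:n]
    if np.any(cal["dtt_s"] <= 0):
        raise ValueError("calibration beat with non-positive DTT")
    if np.any(cal["pulse_amp"] <= 0):
        raise ValueError("calibration beat with non-positive pulse amplitude")
    return cal


def calibrate_m0(beats: pd.DataFrame, cuff: CuffCalibration, n: int = 5) -> CalibrationState:
    """Compute the calibration factor m0 and the raw->pressure affine map.

    m0 averages, over the first ``n`` valid beats, the cuff-scaled sensor
    pulse-pressure drop rate ``(PP0/PP_s(i)) * (SBP_s(i) - DBP_s(i+1)) / DTT(i)``
    where ``DBP_s(i+1)`` is the trough terminating beat ``i``. The affine map
    uses ``gain = PP0 / mean(PP_s)`` and anchors the mean calibration
    end-trough to DBP0, which closes the calibration identity exactly:
    eDBP of the calibration beats averages to DBP0.
    """
    if n < 1:
        raise ValueError("need at least one calibration beat")
    cal = _first_cal_beats(beats, n)
    pp0 = cuff.pp0
    terms = (pp0 / cal["pulse_amp"]) * (cal["peak_v"] - cal["end_v"]) / cal["dtt_s"]
    m0 = float(terms.mean())
    c0 = float(cal["contractility"].mean())
    gain = pp0 / float(cal["pulse_amp"].mean())
    offset = cuff.dbp0 - gain * float(cal["end_v"].mean())
    return CalibrationState(m0=m0, c0=c0, gain=gain, offset=offset, n_cal_beats=n)


def estimate_dbp(
    beats: pd.DataFrame,
    cal: CalibrationState,
    cuff: CuffCalibration,
    c_ratio_clamp: tuple[float, float] = DEFAULT_C_RATIO_CLAMP,
) -> np.ndarray:
    """Beat-to-beat estimated DBP: eDBP(i) = SBP0 - m0*DTT(i)*(C(i)/C0)^(-1).

    Beats with non-positive contractility give NaN (excluded downstream).
    The contractility ratio is clamped to ``c_ratio_clamp``; the number of
    clamped beats is recorded on ``cal.n_ratio_clamped``.
    """
    c = beats["contractility"].to_numpy(dtype=float)
    dtt = beats["dtt_s"].to_numpy(dtype=float)
    ratio = np.where(c > 0, c / cal.c0, np.nan)
    clamped = np.clip(ratio, *c_ratio_clamp)
    cal.n_ratio_clamped = int(np.sum((ratio != clamped) & np.isfinite(ratio)))
    edbp = cuff.sbp0 - cal.m0 * dtt / clamped
    edbp[~np.isfinite(ratio) | (dtt <= 0)] = np.nan
    return edbp


def to_pressure_units(rec: WaveformRecording, cal: CalibrationState) -> WaveformRecording:
    """Affine raw->pressure transform; a no-op (with a warning) on mmHg input."""
    if rec.units == "mmHg":
        warnings.warn("recording already in mmHg; returning unchanged", stacklevel=2)
        return rec.copy()
    return rec.with_samples(cal.gain * rec.samples + cal.offset, units="mmHg")


def moving_median(x, window: int = 30) -> np.ndarray:
    """Centered moving median with shrinking windows at the edges.

    The window at index ``i`` covers ``[i - (window-1)//2, i + window//2]``
    clipped to the series; for even windows the extra point sits on the
    right. Agrees exactly with a per-window sort.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    left, right = (window - 1) // 2, window // 2
    return np.array([np.median(x[max(0, i - left) : min(n, i + right + 1)]) for i in range(n)])


def baseline_offset(
    raw_dbp_mmhg, edbp, window: int = 30, beat_t=None
) -> BaselineEstimate:
    """Empirical baseline wander: raw diastolic minus estimated diastolic.

    ``raw_offset(i) = raw_dbp(i) - eDBP(i)``; the smoothed offset is its
    ``window``-point moving median. NaN eDBP beats contribute an interpolated
    raw offset so the median filter sees a complete series.
    """
    raw_dbp = np.asarray(raw_dbp_mmhg, dtype=float)
    edbp = np.asarray(edbp, dtype=float)
    if raw_dbp.shape != edbp.shape:
        raise ValueError("raw DBP and eDBP series must have equal lengths")
    raw = raw_dbp - edbp
    bad = ~np.isfinite(raw)
    if bad.any() and (~bad).any():
        idx = np.arange(raw.size)
        raw[bad] = np.interp(idx[bad], idx[~bad], raw[~bad])
    if beat_t is None:
        beat_t = np.arange(raw.size, dtype=float)
    return BaselineEstimate(
        raw_offset=raw,
        smoothed_offset=moving_median(raw, window),
        beat_t=np.asarray(beat_t, dtype=float),
    )


def correct_and_extract(
    rec_mmhg: WaveformRecording,
    beats: pd.DataFrame,
    baseline: BaselineEstimate,
    edbp=None,
    outlier_thresh_mmhg: float = 10.0,
    median_window: int = 30,
) -> pd.DataFrame:
    """Subtract the smoothed wander offset and read corrected beat-to-beat BP.

    The per-beat smoothed offsets are linearly interpolated across samples
    (anchored at the end-trough times) and subtracted; per beat,
    SBP = corrected maximum on [onset, end], DBP = corrected minimum on
    [peak, end], MAP = DBP + (SBP - DBP)/3, HR = 60/ibi. Beats whose SBP or
    DBP deviates from its own ``median_window``-point moving median by more
    than ``outlier_thresh_mmhg`` are marked excluded.
    """
    if len(beats) == 0:
        warnings.warn("no retained beats; empty BP series", stacklevel=2)
        return pd.DataFrame(columns=BP_COLUMNS)
    if len(beats) != len(baseline.raw_offset):
        raise ValueError("beat table and baseline estimate are misaligned")

    offset_per_sample = np.interp(rec_mmhg.times, baseline.beat_t, baseline.smoothed_offset)
    corrected = rec_mmhg.samples - offset_per_sample

    n = len(beats)
    sbp = np.empty(n)
    dbp = np.empty(n)
    for k, (o, p, e) in enumerate(
        beats[["onset_idx", "peak_idx", "end_idx"]].itertuples(index=False)
    ):
        sbp[k] = corrected[int(o) : int(e) + 1].max()
        dbp[k] = corrected[int(p) : int(e) + 1].min()

    ibi = beats["ibi_s"].to_numpy(dtype=float)
    bp = pd.DataFrame(
        {
            "t": beats["peak_t"].to_numpy(dtype=float),
            "sbp": sbp,
            "dbp": dbp,
            "map": dbp + (sbp - dbp) / 3.0,
            "hr": 60.0 / ibi,
            "edbp": np.full(n, np.nan) if edbp is None else np.asarray(edbp, dtype=float),
        }
    )
    dev_s = np.abs(sbp - moving_median(sbp, median_window))
    dev_d = np.abs(dbp - moving_median(dbp, median_window))
    bp["excluded"] = (dev_s > outlier_thresh_mmhg) | (dev_d > outlier_thresh_mmhg)
    if edbp is not None:
        bp.loc[~np.isfinite(bp["edbp"]), "excluded"] = True
    return bp


@dataclass
class DTTResult:
    """Bundle returned by :func:`run_dtt_pipeline`."""

    bp: pd.DataFrame                 # corrected beat-to-beat BP series
    beats: pd.DataFrame              # full delineation table
    retained_mask: np.ndarray        # which delineated beats entered the engine
    calibration: CalibrationState
    baseline: BaselineEstimate
    corrected: WaveformRecording     # wander-corrected pressure waveform


def run_dtt_pipeline(
    rec: WaveformRecording,
    cuff: CuffCalibration,
    *,
    n_cal_beats: int = 5,
    median_window: int = 30,
    outlier_thresh_mmhg: float = 10.0,
    min_hr_bpm: float = 40.0,
    max_hr_bpm: float = 180.0,
    min_run_s: float = 30.0,
    retained_mask=None,
) -> DTTResult:
    """Delineate, calibrate, estimate, correct and extract in one call.

    ``retained_mask`` (optional, aligned with the delineation table) lets a
    caller exclude beats flagged by external quality control before
    calibration.
    """
    beats = delineate_beats(rec, min_hr_bpm=min_hr_bpm, max_hr_bpm=max_hr_bpm)
    if len(beats) == 0:
        raise ValueError("no beats detected; cannot run DTT pipeline")
    mask = continuity_filter(beats, min_len_s=min_run_s) & beats["valid"].to_numpy()
    if retained_mask is not None:
        mask &= np.asarray(retained_mask, dtype=bool)
    kept = beats[mask].reset_index(drop=True)

    cal = calibrate_m0(kept, cuff, n=n_cal_beats)
    edbp = estimate_dbp(kept, cal, cuff)
    rec_p = to_pressure_units(rec, cal)
    raw_dbp = cal.gain * kept["end_v"].to_numpy(dtype=float) + cal.offset
    baseline = baseline_offset(
        raw_dbp, edbp, window=median_window, beat_t=kept["end_t"].to_numpy(dtype=float)
    )
    bp = correct_and_extract(
        rec_p, kept, baseline, edbp=edbp,
        outlier_thresh_mmhg=outlier_thresh_mmhg, median_window=median_window,
    )
    offs = np.interp(rec_p.times, baseline.beat_t, baseline.smoothed_offset)
    corrected = rec_p.with_samples(rec_p.samples - offs)
    return DTTResult(
        bp=bp, beats=beats, retained_mask=mask, calibration=cal,
        baseline=baseline, corrected=corrected,
    )
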