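"""Per-beat fiducial detection and intra-beat feature extraction.

Finds systolic peaks, diastolic troughs and dicrotic notches in a continuous
pulse recording and computes, per beat, the diastolic transit time (DTT:
systolic peak to the following diastolic trough), the waveform contractility
(maximum of the first derivative of the systolic upstroke), the sensor pulse
amplitude, and the heart rate.

A beat spans trough to trough and is indexed by its systolic peak; the trough
*terminating* beat ``i`` supplies both that beat's DTT endpoint and the
"following diastolic" value used by the calibration equation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .waveform import WaveformRecording

__all__ = ["BEAT_COLUMNS", "delineate_beats", "compute_beat_features"]

#: Column schema of a beat feature table (one row per beat, time-ordered).
BEAT_COLUMNS = [
    "onset_t",      # s, diastolic trough opening the beat
    "onset_v",      # signal value at the onset trough
    "onset_idx",
    "peak_t",       # s, systolic peak
    "peak_v",       # signal value at the peak (sensor SBP)
    "peak_idx",
    "notch_t",      # s, dicrotic notch (NaN when not detectable)
    "end_t",        # s, diastolic trough terminating the beat
    "end_v",        # signal value at the end trough (sensor DBP of the next beat)
    "end_idx",
    "dtt_s",        # peak_t -> end_t
    "contractility",  # max first derivative on the systolic upstroke, units/s
    "pulse_amp",    # peak_v - onset_v
    "ibi_s",        # end_t - onset_t (trough-to-trough beat span)
    "hr_bpm",       # 60 / ibi_s
    "valid",        # bool, all intra-beat features physical
]

# moving-average smoothing span for the derivative estimate, in seconds
_DERIV_SMOOTH_S = 0.025


def _detection_signal(rec: WaveformRecording) -> np.ndarray:
    """Zero-phase 0.5-10 Hz bandpass used only to localize candidate peaks.

    Removes baseline wander so that peak prominence thresholds are stable;
    all reported fiducial values are read from the raw signal.
    """
    hi = min(10.0, 0.45 * rec.fs)
    sos = signal.butter(2, [0.5, hi], btype="bandpass", fs=rec.fs, output="sos")
    return signal.sosfiltfilt(sos, rec.samples)


def delineate_beats(
    rec: WaveformRecording, min_hr_bpm: float = 40.0, max_hr_bpm: float = 180.0
) -> pd.DataFrame:
    """Detect beats and return a feature table (see :data:`BEAT_COLUMNS`).

    Systolic peaks are prominent local maxima of a lightly bandpassed copy of
    the signal (which suppresses wander), refined to the raw-signal argmax in
    a +/-100 ms neighbourhood; equal-height maxima resolve to the earliest
    sample. Each beat's end trough is the raw-signal minimum between its peak
    and the next; the dicrotic notch is the most prominent local minimum of
    the smoothed first derivative between peak and end trough.

    Returns an empty table (with a warning) when no beats are detectable.
    Raises ``ValueError`` on non-finite samples or recordings < 2 s.
    """
    rec.require_finite()
    if rec.duration_s < 2.0:
        raise ValueError("recording must be at least 2 s long")
    if rec.fs < 100:
        raise ValueError("delineation requires fs >= 100 Hz")
    if not 0 < min_hr_bpm < max_hr_bpm:
        raise ValueError("need 0 < min_hr_bpm < max_hr_bpm")

    x = rec.samples
    det = _detection_signal(rec)
    lo, hi = np.percentile(det, [2.5, 97.5])
    amp = hi - lo
    empty = pd.DataFrame(columns=BEAT_COLUMNS)
    if amp <= 0:
        warnings.warn("no detectable beats (flat signal)", stacklevel=2)
        return empty

    min_dist = max(1, int(round(60.0 / max_hr_bpm * rec.fs)))
    peaks, _ = signal.find_peaks(det, distance=min_dist, prominence=0.25 * amp)
    if peaks.size < 3:
        warnings.warn("no detectable beats", stacklevel=2)
        return empty

    # refine to the raw-signal maximum near each candidate
    half = int(round(0.1 * rec.fs))
    refined = []
    for p in peaks:
        a, b = max(0, p - half), min(x.size, p + half + 1)
        refined.append(a + int(np.argmax(x[a:b])))  # argmax -> earliest on ties
    peaks = np.unique(refined)
    # re-enforce the refractory distance after refinement
    keep = [0]
    for i in range(1, peaks.size):
        if peaks[i] - peaks[keep[-1]] >= min_dist:
            keep.append(i)
    peaks = peaks[keep]
    if peaks.size < 3:
        warnings.warn("no detectable beats", stacklevel=2)
        return empty

    # interior peaks have both an onset trough and an end trough
    rows = []
    max_ibi = 60.0 / min_hr_bpm
    for j in range(1, peaks.size - 1):
        p_prev, p, p_next = peaks[j - 1], peaks[j], peaks[j + 1]
        onset_idx = p_prev + int(np.argmin(x[p_prev:p]))
        end_idx = p + int(np.argmin(x[p:p_next]))
        rows.append((onset_idx, p, end_idx))
    fiducials = pd.DataFrame(rows, columns=["onset_idx", "peak_idx", "end_idx"])
    table = compute_beat_features(rec, fiducials)
    table.loc[table["ibi_s"] > max_ibi, "valid"] = False
    return table


def compute_beat_features(rec: WaveformRecording, fiducials: pd.DataFrame) -> pd.DataFrame:
    """Compute intra-beat features for given fiducial indices.

    ``fiducials`` needs integer columns ``onset_idx``, ``peak_idx``,
    ``end_idx`` (time-ordered, non-overlapping). The derivative is estimated
    by central differences after ~25 ms moving-average smoothing; raw
    differences would amplify sensor noise. Beats with non-positive DTT,
    pulse amplitude or contractility are flagged ``valid=False`` and are
    excluded downstream.
    """
    x = rec.samples
    fs = rec.fs
    w = max(1, int(round(_DERIV_SMOOTH_S * fs)))
    deriv = np.gradient(uniform_filter1d(x, size=w, mode="nearest"), 1.0 / fs)

    rows = []
    for onset_idx, peak_idx, end_idx in fiducials[["onset_idx", "peak_idx", "end_idx"]].itertuples(
        index=False
    ):
        onset_idx, peak_idx, end_idx = int(onset_idx), int(peak_idx), int(end_idx)
        onset_t = rec.t0 + onset_idx / fs
        peak_t = rec.t0 + peak_idx / fs
        end_t = rec.t0 + end_idx / fs
        dtt = end_t - peak_t
        pulse_amp = x[peak_idx] - x[onset_idx]
        c = float(np.max(deriv[onset_idx : peak_idx + 1])) if peak_idx > onset_idx else np.nan

        notch_t = np.nan
        if end_idx - peak_idx > 2:
            seg = -deriv[peak_idx + 1 : end_idx]
            mins, props = signal.find_peaks(seg, prominence=0.0)
            if mins.size:
                notch_t = rec.t0 + (peak_idx + 1 + mins[np.argmax(props["prominences"])]) / fs

        ibi = end_t - onset_t
        valid = (
            onset_idx < peak_idx < end_idx
            and dtt > 0
            and pulse_amp > 0
            and np.isfinite(c)
            and c > 0
        )
        rows.append(
            (
                onset_t, x[onset_idx], onset_idx,
                peak_t, x[peak_idx], peak_idx,
                notch_t,
                end_t, x[end_idx], end_idx,
                dtt, c, pulse_amp, ibi, 60.0 / ibi if ibi > 0 else np.nan, valid,
            )
        )
    table = pd.DataFrame(rows, columns=BEAT_COLUMNS)
    for col in ("onset_idx", "peak_idx", "end_idx"):
        table[col] = table[col].astype(int) if len(table) else table[col]
    table["valid"] = table["valid"].astype(bool) if len(table) else table["valid"]
    return table
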