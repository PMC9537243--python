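"""Segment-quality filtering and applanation-deviation detection.

Two gates are applied before BP estimation. The continuity filter keeps only
beats lying in an unbroken run of valid, contiguous beats spanning at least
30 s (short fragments carry too little context for calibration or for the
30-beat median machinery). The applanation detector compares, in 30-s
sliding windows, the time trend of mean-normalized contractility on the
study sensor against a simultaneous reference channel: a drifting contact
(applanation) pressure changes the sensor's waveform amplitude — and hence
its contractility trend — without any corresponding change on the reference,
so a statistically significant slope difference (p < alpha) flags the
window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QCReport",
    "continuity_filter",
    "slope_difference_test",
    "detect_applanation_deviation",
]


def continuity_filter(
    beats: pd.DataFrame, min_len_s: float = 30.0, max_gap_s: float = 0.5
) -> np.ndarray:
    """Boolean mask of beats in maximal contiguous valid runs >= ``min_len_s``.

    A run breaks at any invalid beat or wherever the next beat's onset trough
    is more than ``max_gap_s`` after the previous beat's end trough. A run's
    span is measured trough-to-trough (first onset to last end); runs
    shorter than ``min_len_s`` are excluded entirely.
    """
    n = len(beats)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    valid = beats["valid"].to_numpy() if "valid" in beats else np.ones(n, dtype=bool)
    onset = beats["onset_t"].to_numpy(dtype=float)
    end = beats["end_t"].to_numpy(dtype=float)

    run_start = None
    for i in range(n + 1):
        contiguous = (
            i < n
            and valid[i]
            and (run_start is None or i == run_start or onset[i] - end[i - 1] <= max_gap_s)
        )
        if contiguous:
            if run_start is None:
                run_start = i
            continue
        if run_start is not None:
            last = i - 1
            if end[last] - onset[run_start] >= min_len_s:
                mask[run_start : last + 1] = True
            run_start = None
        if i < n and valid[i]:
            run_start = i  # this beat opens a fresh run
    return mask


def slope_difference_test(t1, y1, t2, y2) -> tuple[float, float]:
    """Two-sample test for equality of regression slopes.

    Fits ``y = a + b t`` separately to each sample, pools the residual
    variance, and tests ``b1 = b2`` with a t statistic on
    ``n1 + n2 - 4`` degrees of freedom (equivalent to the interaction term
    of an ANCOVA). Returns ``(t_statistic, p_value)``.
    """
    t1, y1, t2, y2 = (np.asarray(a, dtype=float) for a in (t1, y1, t2, y2))
    n1, n2 = t1.size, t2.size
    if n1 < 3 or n2 < 3:
        raise ValueError("each sample needs at least 3 points")

    def fit(t, y):
        tc = t - t.mean()
        sxx = float(np.sum(tc**2))
        if sxx == 0:
            raise ValueError("degenerate time axis in regression window")
        b = float(np.sum(tc * (y - y.mean())) / sxx)
        resid = y - y.mean() - b * tc
        return b, sxx, float(np.sum(resid**2))

    b1, sxx1, sse1 = fit(t1, y1)
    b2, sxx2, sse2 = fit(t2, y2)
    df = n1 + n2 - 4
    s2 = (sse1 + sse2) / df
    se = np.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx2))
    if se == 0:
        return 0.0, 1.0
    t_stat = (b1 - b2) / se
    return float(t_stat), float(2.0 * stats.t.sf(abs(t_stat), df))


@dataclass
class QCReport:
    """Windowed applanation-deviation report plus the resulting beat mask."""

    windows: pd.DataFrame         # t_start, t_end, n_pairs, p_value, flagged, skipped
    retained_mask: np.ndarray     # per sensor beat; False inside flagged windows
    alpha: float
    criteria_log: str = field(default="")

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "n_windows": int(len(self.windows)),
            "n_flagged": int(self.windows["flagged"].sum()) if len(self.windows) else 0,
            "n_beats_retained": int(self.retained_mask.sum()),
            "n_beats_total": int(self.retained_mask.size),
            "criteria_log": self.criteria_log,
            "windows": self.windows.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def detect_applanation_deviation(
    sensor_beats: pd.DataFrame,
    ref_beats: pd.DataFrame,
    window_s: float = 30.0,
    step_s: float = 5.0,
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> QCReport:
    """Flag windows where the sensor's contractility trend departs from the reference.

    Sensor beats are paired with the nearest-in-time reference beat (within
    half the sensor's median inter-beat interval). In each ``window_s``
    sliding window (step ``step_s``), each channel's contractility series is
    normalized by its own window mean and regressed on time; the window is
    flagged when the slope-difference test rejects at ``alpha``. Windows with
    fewer than ``min_pairs`` paired beats are skipped (recorded, never
    flagged). The retained mask excludes sensor beats inside any flagged
    window. This test is intrinsically pairwise: without a reference channel
    it is not evaluable (handled by the pipeline, which reports it skipped).
    """
    if len(sensor_beats) == 0 or len(ref_beats) == 0:
        raise ValueError("both beat tables must be non-empty")
    s_t = sensor_beats["peak_t"].to_numpy(dtype=float)
    s_c = sensor_beats["contractility"].to_numpy(dtype=float)
    r_t = ref_beats["peak_t"].to_numpy(dtype=float)
    r_c = ref_beats["contractility"].to_numpy(dtype=float)

    tol = 0.5 * float(np.median(np.diff(s_t))) if s_t.size > 1 else 0.5
    j = np.clip(np.searchsorted(r_t, s_t), 1, r_t.size - 1)
    j = np.where(np.abs(r_t[j] - s_t) < np.abs(r_t[j - 1] - s_t), j, j - 1)
    paired = np.abs(r_t[j] - s_t) <= tol

    t0, t1 = float(s_t.min()), float(s_t.max())
    starts = np.arange(t0, max(t0, t1 - window_s) + 1e-9, step_s)
    rows = []
    flagged_spans = []
    n_skipped = 0
    for ws in starts:
        we = ws + window_s
        in_w = paired & (s_t >= ws) & (s_t < we)
        n = int(in_w.sum())
        if n < min_pairs:
            n_skipped += 1
            rows.append((ws, we, n, np.nan, False, True))
            continue
        ts = s_t[in_w]
        ys = s_c[in_w]
        yr = r_c[j[in_w]]
        ys_n = ys / ys.mean()
        yr_n = yr / yr.mean()
        _, p = slope_difference_test(ts, ys_n, r_t[j[in_w]], yr_n)
        flag = p < alpha
        if flag:
            flagged_spans.append((ws, we))
        rows.append((ws, we, n, p, flag, False))

    windows = pd.DataFrame(
        rows, columns=["t_start", "t_end", "n_pairs", "p_value", "flagged", "skipped"]
    )
    retained = np.ones(s_t.size, dtype=bool)
    for ws, we in flagged_spans:
        retained &= ~((s_t >= ws) & (s_t < we))
    log = (
        f"{len(windows)} windows of {window_s:.0f}s (step {step_s:.0f}s); "
        f"{len(flagged_spans)} flagged at alpha={alpha}; {n_skipped} skipped (<{min_pairs} pairs); "
        f"{int((~retained).sum())}/{retained.size} sensor beats excluded"
    )
    return QCReport(windows=windows, retained_mask=retained, alpha=alpha, criteria_log=log)
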