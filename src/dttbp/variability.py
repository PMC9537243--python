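"""Beat-to-beat blood-pressure variability (BPV) indices.

Three complementary indices are computed over non-overlapping 30-beat
windows, separately for SBP and DBP:

* SD — sample standard deviation, the global fluctuation about the mean;
* COV — SD normalized by the window mean (reported as a fraction);
* ARV — average real variability, the mean absolute difference between
  adjacent beats, which unlike SD is sensitive to temporal ordering.

Windows whose BP range (max - min) exceeds a labile threshold (10 mmHg by
default) are flagged and omitted from the recording-level averages: large
swings — e.g. from vasoactive drug boluses — would otherwise dominate the
variability summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BPVReport", "window_indices", "compute_bpv"]


@dataclass
class BPVReport:
    """Windowed BPV indices plus recording-level means of non-labile windows."""

    windows: pd.DataFrame  # series, t_start, t_end, n_beats, sd, cov, arv, excluded_labile
    summary: dict          # per series: mean_sd, mean_cov, mean_arv, n_windows, n_labile

    def window_sds(self, series: str = "sbp", include_labile: bool = False) -> np.ndarray:
        w = self.windows[self.windows["series"] == series]
        if not include_labile:
            w = w[~w["excluded_labile"]]
        return w["sd"].to_numpy(dtype=float)


def window_indices(values: np.ndarray, t: np.ndarray, window_beats: int) -> tuple:
    """Per-window SD / COV / ARV / range over consecutive complete windows."""
    n_win = values.size // window_beats
    rows = []
    for k in range(n_win):
        v = values[k * window_beats : (k + 1) * window_beats]
        tw = t[k * window_beats : (k + 1) * window_beats]
        sd = float(np.std(v, ddof=1))
        mean = float(np.mean(v))
        rows.append(
            {
                "t_start": float(tw[0]),
                "t_end": float(tw[-1]),
                "n_beats": window_beats,
                "sd": sd,
                "cov": sd / mean if mean != 0 else np.nan,
                "arv": float(np.mean(np.abs(np.diff(v)))),
                "range": float(v.max() - v.min()),
            }
        )
    return rows


def compute_bpv(
    bp: pd.DataFrame,
    window_beats: int = 30,
    labile_range_mmhg: float = 10.0,
    series: tuple = ("sbp", "dbp"),
) -> BPVReport:
    """Windowed BPV for a beat-indexed BP series.

    Only non-excluded beats enter; windows are consecutive, non-overlapping
    and complete (a trailing partial window is dropped). The labile exclusion
    is applied per series: an SBP window is judged by its SBP range, a DBP
    window by its DBP range. Returns an empty report (with a warning) when
    fewer than one full window of beats is available.
    """
    if window_beats < 2:
        raise ValueError("window_beats must be >= 2")
    ok = bp[~bp["excluded"]] if "excluded" in bp else bp
    all_rows = []
    summary = {}
    for s in series:
        values = ok[s].to_numpy(dtype=float)
        t = ok["t"].to_numpy(dtype=float) if "t" in ok else np.arange(values.size, dtype=float)
        rows = window_indices(values, t, window_beats)
        for r in rows:
            r["series"] = s
            r["excluded_labile"] = r.pop("range") > labile_range_mmhg
        all_rows.extend(rows)
        kept = [r for r in rows if not r["excluded_labile"]]
        summary[s] = {
            "mean_sd": float(np.mean([r["sd"] for r in kept])) if kept else np.nan,
            "mean_cov": float(np.mean([r["cov"] for r in kept])) if kept else np.nan,
            "mean_arv": float(np.mean([r["arv"] for r in kept])) if kept else np.nan,
            "n_windows": len(rows),
            "n_labile": len(rows) - len(kept),
        }
    if not all_rows:
        warnings.warn("fewer beats than one full window; empty BPV report", stacklevel=2)
    cols = ["series", "t_start", "t_end", "n_beats", "sd", "cov", "arv", "excluded_labile"]
    windows = pd.DataFrame(all_rows, columns=cols)
    return BPVReport(windows=windows, summary=summary)
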