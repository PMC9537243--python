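"""Method-agreement statistics between an estimated and a reference BP series.

Beats are paired by nearest time within a tolerance, after which per-parameter
(SBP/DBP/MAP/HR) agreement is summarized by Pearson correlation, Bland-Altman
mean bias with 68% (1 SD) and 95% (1.96 SD) limits of agreement, percent
errors, and the AAMI/ISO 81060-2 acceptance rule (|mean bias| <= 5 mmHg and
SD of differences < 8 mmHg). A Brown-Forsythe test compares the dispersion of
two sets of BPV window statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AAMI_BIAS_LIMIT_MMHG",
    "AAMI_SD_LIMIT_MMHG",
    "ParamAgreement",
    "AgreementReport",
    "pair_series",
    "percent_error_series",
    "bland_altman_pearson",
    "bpv_equivalence_test",
]

AAMI_BIAS_LIMIT_MMHG = 5.0
AAMI_SD_LIMIT_MMHG = 8.0

_DEFAULT_PARAMS = ("sbp", "dbp", "map", "hr")


def pair_series(
    est: pd.DataFrame, ref: pd.DataFrame, max_lag_s: float = 0.5
) -> pd.DataFrame:
    """Match each estimated beat to the nearest reference beat within ``max_lag_s``.

    Excluded beats (per each table's ``excluded`` column, if present) are
    dropped first; unmatched estimated beats are dropped and counted in the
    ``n_dropped`` attribute of the returned frame. The default tolerance of
    0.5 s is half the nominal one-second synchronization precision of clock-
    aligned devices, which avoids cross-beat matches at heart rates above 60.
    Raises ``ValueError`` when no pairs survive.
    """
    e = est[~est["excluded"]] if "excluded" in est else est
    r = ref[~ref["excluded"]] if "excluded" in ref else ref
    if len(e) == 0 or len(r) == 0:
        raise ValueError("no usable beats to pair")
    et = e["t"].to_numpy(dtype=float)
    rt = r["t"].to_numpy(dtype=float)
    j = np.clip(np.searchsorted(rt, et), 1, rt.size - 1)
    j = np.where(np.abs(rt[j] - et) < np.abs(rt[j - 1] - et), j, j - 1)
    lag = et - rt[j]
    ok = np.abs(lag) <= max_lag_s
    if not ok.any():
        raise ValueError("zero pairs within the lag tolerance")

    data = {"t": et[ok], "lag_s": lag[ok]}
    for p in _DEFAULT_PARAMS:
        if p in e.columns and p in r.columns:
            data[f"est_{p}"] = e[p].to_numpy(dtype=float)[ok]
            data[f"ref_{p}"] = r[p].to_numpy(dtype=float)[j[ok]]
    pairs = pd.DataFrame(data)
    pairs.attrs["n_dropped"] = int((~ok).sum())
    return pairs


def percent_error_series(pairs: pd.DataFrame, params=("sbp", "dbp", "map")) -> pd.DataFrame:
    """Per-beat absolute percent error ``100 |est - ref| / ref`` per parameter.

    Beats with non-positive reference values are skipped (NaN).
    """
    out = {"t": pairs["t"].to_numpy()}
    for p in params:
        est = pairs[f"est_{p}"].to_numpy(dtype=float)
        ref = pairs[f"ref_{p}"].to_numpy(dtype=float)
        ok = ref > 0
        err = np.full(ref.size, np.nan)
        err[ok] = 100.0 * np.abs(est[ok] - ref[ok]) / ref[ok]
        out[p] = err
    return pd.DataFrame(out)


@dataclass
class ParamAgreement:
    n: int
    mean_bias: float
    sd_diff: float
    loa_68: tuple
    loa_95: tuple
    pearson_r: float
    r_evaluable: bool
    aami_pass: bool
    mean_pct_error: float
    sd_pct_error: float


@dataclass
class AgreementReport:
    """Bland-Altman / Pearson / AAMI summary per BP parameter."""

    n_pairs: int
    params: dict = field(default_factory=dict)  # name -> ParamAgreement

    def to_json(self, path=None) -> str:
        payload = {"n_pairs": self.n_pairs, "params": {k: vars(v) for k, v in self.params.items()}}
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def bland_altman_pearson(pairs: pd.DataFrame, params=_DEFAULT_PARAMS) -> AgreementReport:
    """Agreement statistics on a paired table from :func:`pair_series`.

    Differences are est - ref (the sign convention is a documented choice;
    swapping the inputs negates the bias and leaves everything else intact).
    With zero variance in either series the correlation is reported as not
    evaluable (NaN) rather than raising.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    report = AgreementReport(n_pairs=len(pairs))
    for p in params:
        if f"est_{p}" not in pairs.columns:
            continue
        est = pairs[f"est_{p}"].to_numpy(dtype=float)
        ref = pairs[f"ref_{p}"].to_numpy(dtype=float)
        d = est - ref
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        if np.std(est) > 0 and np.std(ref) > 0:
            r = float(stats.pearsonr(est, ref).statistic)
            r_ok = True
        else:
            r, r_ok = math.nan, False
        pct = np.where(ref > 0, 100.0 * np.abs(d) / ref, np.nan)
        report.params[p] = ParamAgreement(
            n=d.size,
            mean_bias=bias,
            sd_diff=sd,
            loa_68=(bias - sd, bias + sd),
            loa_95=(bias - 1.96 * sd, bias + 1.96 * sd),
            pearson_r=r,
            r_evaluable=r_ok,
            aami_pass=bool(abs(bias) <= AAMI_BIAS_LIMIT_MMHG and sd < AAMI_SD_LIMIT_MMHG),
            mean_pct_error=float(np.nanmean(pct)),
            sd_pct_error=float(np.nanstd(pct, ddof=1)),
        )
    return report


def bpv_equivalence_test(bpv_a, bpv_b, alpha: float = 0.05) -> dict:
    """Brown-Forsythe test for equal dispersion of two sets of window statistics.

    Levene's test with median centering; returns
    ``{"statistic", "p_value", "different"}``. Two degenerate all-equal
    groups are reported as not different with p = 1.
    """
    a = np.asarray(bpv_a, dtype=float)
    b = np.asarray(bpv_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 windows")
    if np.all(a == a[0]) and np.all(b == b[0]):
        return {"statistic": 0.0, "p_value": 1.0, "different": False}
    stat, p = stats.levene(a, b, center="median")
    return {"statistic": float(stat), "p_value": float(p), "different": bool(p < alpha)}
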