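import numpy as np
import pandas as pd
import pytest

from dttbp import CuffCalibration, SimConfig, simulate_recording


@pytest.fixture(scope="session")
def clean_sim():
    """Stationary, drift- and noise-free 60 s recording at HR 60, 120/80."""
    cfg = SimConfig(
        duration_s=60.0, fs=250.0, hr_bpm=60.0, sbp_mmHg=120.0, dbp_mmHg=80.0,
        hrv_sd_s=0.0, bpv_sd_mmHg=0.0, resp_amp_mmHg=0.0, wander=None,
        sensor={"gain": 1.0, "offset": 0.0, "noise_sd": 0.0}, seed=1,
    )
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """120 s recording with generator-default jitter, fluctuations and wander."""
    cfg = SimConfig(duration_s=120.0, fs=250.0, hr_bpm=72.0,
                    sbp_mmHg=125.0, dbp_mmHg=78.0, seed=7)
    return simulate_recording(cfg)


@pytest.fixture
def cuff_120_80():
    return CuffCalibration(sbp0=120.0, dbp0=80.0)


def make_beat_table(
    n=6, peak_v=3.0, trough_v=1.0, dtt=0.7, contractility=10.0, ibi=1.0, t0=0.5
):
    """A synthetic beat feature table of identical beats (sensor units)."""
    rows = []
    for i in range(n):
        onset_t = t0 + i * ibi
        peak_t = onset_t + (ibi - dtt)
        end_t = onset_t + ibi
        rows.append({
            "onset_t": onset_t, "onset_v": trough_v, "onset_idx": int(onset_t * 250),
            "peak_t": peak_t, "peak_v": peak_v, "peak_idx": int(peak_t * 250),
            "notch_t": np.nan,
            "end_t": end_t, "end_v": trough_v, "end_idx": int(end_t * 250),
            "dtt_s": dtt, "contractility": contractility,
            "pulse_amp": peak_v - trough_v, "ibi_s": ibi, "hr_bpm": 60.0 / ibi,
            "valid": True,
        })
    return pd.DataFrame(rows)


@pytest.fixture
def identical_beats():
    return make_beat_table()
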