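"""Synthetic pulse-waveform generator with known beat-to-beat ground truth.

Generates quasi-periodic arterial-pulse-like recordings — systolic peak,
dicrotic notch, diastolic trough per beat — riding on slow hemodynamic
trajectories, with stochastic low-frequency baseline wander, impulse / step /
cyclic motion artifacts, and an affine sensor transform with additive noise.
Every beat's true SBP/DBP/MAP/HR is recorded so that downstream estimators
can be scored against ground truth.

The generated morphology honours the intra-beat model used by the DTT
estimator: each beat's systolic-peak-to-trough interval (DTT) is coupled to
its end-diastolic pressure through ``DTT = (SBP_anchor - DBP) / m * c_rel``,
where ``c_rel`` is the beat's relative contractility. This makes the
simulator the idealized physiology the estimator assumes, which is what a
pipeline validation needs (see docs/methods.md for what this does and does
not demonstrate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .waveform import WaveformRecording

__all__ = [
    "TrajectoryEvent",
    "Trajectory",
    "WanderSpec",
    "ArtifactEvent",
    "SensorSpec",
    "SimConfig",
    "GroundTruth",
    "simulate_recording",
    "inject_baseline_wander",
    "inject_motion_artifacts",
    "sensor_transform",
]

# Beat-template shape constants. Timing constants are fractions of the
# *nominal* beat period (the recording's initial 60/HR), not of each beat's
# own length: systolic ejection time is set by the ventricle and does not
# stretch with the diastolic pause, so inter-beat jitter must not change the
# upstroke width (and hence the contractility) of otherwise equal beats.
# The systolic peak sits early in the beat; the diastolic trough is an
# interior, strict minimum at peak + DTT, followed by a shallow late-
# diastolic rise into the next upstroke. The strict V-shaped trough keeps the
# detected trough position stable under drift and noise.
_SYSTOLIC_WIDTH_FRAC = 0.10   # sigma of the systolic Gaussian lobe
_DICROTIC_WIDTH_FRAC = 0.09   # sigma of the dicrotic lobe
_DICROTIC_AMP = 0.22          # dicrotic lobe height relative to systolic
_DICROTIC_DELAY_FRAC = 0.40   # dicrotic lobe centre, as a fraction of DTT past the peak
_PEAK_POS_FRAC = 0.16         # systolic peak position after the upstroke onset
_MIN_DTT_FRAC = 0.22          # lower clamp on DTT, fraction of nominal period
_MIN_TAIL_FRAC = 0.05         # minimum late-diastolic tail after the trough
_RISE_FRAC = 0.10             # late-diastolic rise, fraction of reference pulse pressure
_TROUGH_DEAD_FRAC = 0.05      # pulse-shape dead zone around the trough
_TROUGH_FEATHER_FRAC = 0.12   # feather width back to full pulse shape


@dataclass
class TrajectoryEvent:
    """Additive modifier on a hemodynamic trajectory.

    kind ``ramp``: linear change of ``delta`` between ``t_start`` and ``t_end``.
    kind ``step``: instantaneous change of ``delta`` at ``t_start``.
    kind ``sine``: sinusoid of amplitude ``delta`` and frequency ``freq_hz``.
    """

    kind: str
    delta: float
    t_start: float = 0.0
    t_end: float | None = None
    freq_hz: float | None = None
    phase: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "ramp":
            if self.t_end is None or self.t_end <= self.t_start:
                raise ValueError("ramp requires t_end > t_start")
            u = np.clip((t - self.t_start) / (self.t_end - self.t_start), 0.0, 1.0)
            return self.delta * u
        if self.kind == "step":
            return self.delta * (t >= self.t_start)
        if self.kind == "sine":
            if not self.freq_hz:
                raise ValueError("sine requires freq_hz")
            return self.delta * np.sin(2 * np.pi * self.freq_hz * t + self.phase)
        raise ValueError(f"unknown trajectory event kind {self.kind!r}")


@dataclass
class Trajectory:
    """A constant baseline plus a sum of :class:`TrajectoryEvent` modifiers."""

    base: float
    events: list[TrajectoryEvent] = field(default_factory=list)

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.base, dtype=float)
        for ev in self.events:
            out = out + ev(t)
        return out


def _as_trajectory(spec) -> Trajectory:
    if isinstance(spec, Trajectory):
        return spec
    if isinstance(spec, (int, float)):
        return Trajectory(base=float(spec))
    if isinstance(spec, dict):
        events = [TrajectoryEvent(**e) for e in spec.get("events", [])]
        return Trajectory(base=float(spec["base"]), events=events)
    raise TypeError(f"cannot interpret trajectory spec {spec!r}")


@dataclass
class WanderSpec:
    """Stochastic low-frequency baseline-wander model.

    ``random_walk``: a Gaussian random walk updated at ``1/(2 corner_freq_hz)``
    intervals, smoothly interpolated to the sample grid and rescaled so the
    realized trace has standard deviation ``amplitude`` (sensor units).
    ``sum_of_sinusoids``: eight sinusoids with random phases and frequencies
    log-spaced below the corner, 1/f-weighted, rescaled the same way.
    """

    model: str = "random_walk"
    amplitude: float = 5.0
    corner_freq_hz: float = 0.2

    def __post_init__(self) -> None:
        if self.model not in ("random_walk", "sum_of_sinusoids"):
            raise ValueError(f"unknown wander model {self.model!r}")
        if self.amplitude < 0:
            raise ValueError("wander amplitude must be >= 0")
        if self.corner_freq_hz <= 0:
            raise ValueError("corner_freq_hz must be > 0")


@dataclass
class ArtifactEvent:
    """A motion artifact: raised-cosine impulse, persistent step, or cyclic."""

    t_start: float
    kind: str
    magnitude: float
    duration_s: float = 1.0
    freq_hz: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("impulse", "step", "cyclic"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.t_start < 0:
            raise ValueError("artifact t_start must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("artifact duration_s must be > 0")
        if self.kind == "cyclic" and not self.freq_hz:
            raise ValueError("cyclic artifact requires freq_hz")


@dataclass
class SensorSpec:
    """Affine raw-transducer model: out = gain * mmHg + offset + noise."""

    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("sensor gain must be > 0")
        if self.noise_sd < 0:
            raise ValueError("sensor noise_sd must be >= 0")


@dataclass
class SimConfig:
    """Full specification of one synthetic recording.

    Defaults describe a 20-minute decent-quality radial recording: HR 70 bpm
    with 20 ms inter-beat jitter, 120/80 mmHg, per-beat AR(1) pressure
    fluctuation of 2 mmHg SD plus a 1.5 mmHg respiratory oscillation at
    0.25 Hz, random-walk wander of 5 sensor-units SD (roughly 11% of pulse
    amplitude), unit sensor gain and 0.1-unit sensor noise.
    """

    duration_s: float = 1200.0
    fs: float = 250.0
    hr_bpm: object = 70.0
    sbp_mmHg: object = 120.0
    dbp_mmHg: object = 80.0
    hrv_sd_s: float = 0.02
    bpv_sd_mmHg: float = 2.0
    resp_amp_mmHg: float = 1.5
    resp_freq_hz: float = 0.25
    dtt_frac: float = 0.55
    wander: WanderSpec | None = field(default_factory=WanderSpec)
    artifacts: list[ArtifactEvent] = field(default_factory=list)
    sensor: SensorSpec = field(default_factory=SensorSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fs < 100:
            raise ValueError("fs must be >= 100 Hz")
        if not 0.1 <= self.dtt_frac <= 0.8:
            raise ValueError("dtt_frac must lie in [0.1, 0.8]")
        self.hr_bpm = _as_trajectory(self.hr_bpm)
        self.sbp_mmHg = _as_trajectory(self.sbp_mmHg)
        self.dbp_mmHg = _as_trajectory(self.dbp_mmHg)
        if isinstance(self.wander, dict):
            self.wander = WanderSpec(**self.wander)
        if isinstance(self.sensor, dict):
            self.sensor = SensorSpec(**self.sensor)
        self.artifacts = [
            a if isinstance(a, ArtifactEvent) else ArtifactEvent(**a)
            for a in self.artifacts
        ]
        # reject any crossing of the pressure trajectories up front
        grid = np.arange(0.0, self.duration_s + 0.25, 0.25)
        sbp, dbp = self.sbp_mmHg(grid), self.dbp_mmHg(grid)
        if np.any(sbp <= dbp):
            t_bad = grid[np.argmax(sbp <= dbp)]
            raise ValueError(
                f"invalid trajectories: SBP <= DBP at t={t_bad:.2f} s "
                f"({sbp[np.argmax(sbp <= dbp)]:.1f} <= {dbp[np.argmax(sbp <= dbp)]:.1f} mmHg)"
            )


@dataclass
class GroundTruth:
    """Per-beat truth for a simulated recording.

    ``dbp[i]`` is the value of the diastolic trough *terminating* beat ``i``
    (the trough that the DTT of beat ``i`` runs to), matching the estimator's
    beat convention. ``wander_trace`` is the injected per-sample baseline
    offset in sensor units (zeros when no wander was requested).
    """

    onset_t: np.ndarray
    peak_t: np.ndarray
    end_t: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    hr: np.ndarray
    wander_trace: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.peak_t)
        for name in ("onset_t", "end_t", "sbp", "dbp", "map", "hr"):
            if len(getattr(self, name)) != n:
                raise ValueError("ground-truth arrays have inconsistent lengths")
        if np.any((self.map <= self.dbp) | (self.map >= self.sbp)):
            raise ValueError("ground truth violates DBP < MAP < SBP")

    @property
    def n_beats(self) -> int:
        return len(self.peak_t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "onset_t": self.onset_t,
                "peak_t": self.peak_t,
                "end_t": self.end_t,
                "sbp": self.sbp,
                "dbp": self.dbp,
                "map": self.map,
                "hr": self.hr,
            }
        )


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage sub-seeds, kept below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def _beat_shape(
    tau: np.ndarray,
    L: float,
    p: float,
    tau_tr: float,
    dtt: float,
    s1: float,
    s2: float,
    ibi0: float,
) -> np.ndarray:
    """Unit pulse shape on [0, L): non-negative, ~1 at the systolic peak,
    exactly zero in a dead zone around the trough time ``tau_tr``.

    Two Gaussian lobes (systolic at ``p``, dicrotic between peak and trough)
    minus the piecewise-linear interpolant of their values at the onset,
    trough and end nodes, clipped at zero and feathered to zero around the
    trough so the underlying diastolic baseline alone defines the trough.
    """
    c2 = p + _DICROTIC_DELAY_FRAC * dtt

    def g(x):
        x = np.asarray(x, dtype=float)
        return np.exp(-0.5 * ((x - p) / s1) ** 2) + _DICROTIC_AMP * np.exp(
            -0.5 * ((x - c2) / s2) ** 2
        )

    nodes = np.array([0.0, tau_tr, L])
    out = g(tau) - np.interp(tau, nodes, g(nodes))
    out = np.clip(out, 0.0, None)
    dead = _TROUGH_DEAD_FRAC * ibi0
    feather = _TROUGH_FEATHER_FRAC * ibi0
    w = np.clip((np.abs(tau - tau_tr) - dead) / max(feather - dead, 1e-9), 0.0, 1.0)
    return out * w


def _diastolic_baseline(
    tau: np.ndarray, L: float, tau_tr: float, v0: float, v_tr: float, rise: float
) -> np.ndarray:
    """Piecewise-linear diastolic baseline: decays from ``v0`` to a strict
    V-shaped minimum ``v_tr`` at the trough, then rises by ``rise`` into the
    next onset. The kink keeps the trough slope well above typical wander
    slopes, so the detected trough position is stable under drift — the same
    property the end-diastolic corner of a real arterial waveform has."""
    down = v_tr + (v0 - v_tr) * (tau_tr - tau) / tau_tr
    up = v_tr + rise * (tau - tau_tr) / max(L - tau_tr, 1e-9)
    return np.where(tau < tau_tr, down, up)


def simulate_recording(config: SimConfig) -> tuple[WaveformRecording, GroundTruth]:
    """Generate one synthetic recording and its beat-to-beat ground truth.

    Returns the recording *after* the sensor transform, baseline wander and
    motion artifacts configured in ``config`` (units flag ``"sensor"``), plus
    a :class:`GroundTruth` whose pressures describe the clean underlying
    waveform in mmHg. Identical configs (including seed) give bit-identical
    output.
    """
    seeds = _child_seeds(config.seed, 4)
    rng = np.random.default_rng(seeds[0])
    fs = config.fs
    n_samples = int(round(config.duration_s * fs))

    # --- beat boundaries -------------------------------------------------
    boundaries = [0.0]
    t = 0.0
    while t < config.duration_s + 2.0:  # one spare beat past the end
        hr_t = float(config.hr_bpm(t))
        if hr_t <= 0:
            raise ValueError(f"heart-rate trajectory non-positive at t={t:.1f}s")
        ibi = 60.0 / hr_t + (rng.normal(0.0, config.hrv_sd_s) if config.hrv_sd_s > 0 else 0.0)
        ibi = float(np.clip(ibi, 0.3, 2.0))
        t += ibi
        boundaries.append(t)
    bnd = np.asarray(boundaries)
    nb = len(bnd) - 1

    # --- per-beat true pressures -----------------------------------------
    # AR(1) beat-to-beat fluctuation shared (scaled) between DBP and SBP,
    # plus a respiratory oscillation evaluated at the beat boundary times.
    rho = 0.8
    eps_sd = config.bpv_sd_mmHg * math.sqrt(1.0 - rho**2)
    fluct = np.zeros(nb + 1)
    if config.bpv_sd_mmHg > 0:
        fluct[0] = rng.normal(0.0, config.bpv_sd_mmHg)
        for k in range(1, nb + 1):
            fluct[k] = rho * fluct[k - 1] + rng.normal(0.0, eps_sd)
    resp = (
        config.resp_amp_mmHg * np.sin(2 * np.pi * config.resp_freq_hz * bnd)
        if config.resp_amp_mmHg > 0
        else np.zeros(nb + 1)
    )

    dbp_bnd = config.dbp_mmHg(bnd) + fluct + resp
    sbp_extra = (
        rng.normal(0.0, 0.5 * config.bpv_sd_mmHg, size=nb) if config.bpv_sd_mmHg > 0 else np.zeros(nb)
    )
    t_peak_nominal = 0.5 * (bnd[:-1] + bnd[1:])
    sbp_beat = config.sbp_mmHg(t_peak_nominal) + 1.2 * fluct[1:] + resp[1:] + sbp_extra

    if np.any(sbp_beat - dbp_bnd[1:] < 5.0) or np.any(sbp_beat - dbp_bnd[:-1] < 5.0):
        raise ValueError("invalid trajectories: pulse pressure collapsed below 5 mmHg")

    # --- DTT coupling (the physiology the estimator assumes) --------------
    s_anchor = float(config.sbp_mmHg(np.array(0.0)))
    dbp0 = float(config.dbp_mmHg(np.array(0.0)))
    ibi0 = 60.0 / float(config.hr_bpm(np.array(0.0)))
    pp_ref = s_anchor - dbp0
    m_sim = pp_ref / (config.dtt_frac * ibi0)  # mmHg per second
    sigma_sys = _SYSTOLIC_WIDTH_FRAC * ibi0    # fixed upstroke width, seconds
    sigma_dic = _DICROTIC_WIDTH_FRAC * ibi0
    rise = _RISE_FRAC * pp_ref                 # late-diastolic rise, mmHg

    samples = np.empty(int(round((bnd[-1]) * fs)) + 1)
    samples.fill(np.nan)
    onset_t = np.empty(nb)
    peak_t = np.empty(nb)
    end_t = np.empty(nb)
    sbp_true = np.empty(nb)
    dbp_true = np.empty(nb)
    hr_true = np.empty(nb)
    ok = np.zeros(nb, dtype=bool)

    for i in range(nb):
        t_a, t_b = bnd[i], bnd[i + 1]
        L = t_b - t_a
        d_tr = dbp_bnd[i + 1]         # this beat's trough (end-diastolic) value
        # onset value: continuous with the previous tail, but floored so the
        # diastolic baseline always decays strictly into the trough even when
        # DBP jumps up beat to beat (otherwise the trough position degenerates)
        v0 = max(dbp_bnd[i] + rise, d_tr + 0.4 * rise)
        s_i = sbp_beat[i]
        pp_i = s_i - d_tr
        # relative contractility of the template: max upstroke slope scales
        # with pulse amplitude at fixed upstroke width
        c_rel = pp_i / pp_ref
        p = min(_PEAK_POS_FRAC * ibi0, 0.3 * L)
        dtt = (s_anchor - d_tr) / m_sim * c_rel
        lo = _MIN_DTT_FRAC * ibi0
        hi = L - p - _MIN_TAIL_FRAC * ibi0
        dtt = float(np.clip(dtt, lo, hi)) if hi > lo else 0.5 * (L - p)
        tau_tr = p + dtt

        k0 = int(math.ceil(t_a * fs - 1e-9))
        k1 = int(math.ceil(t_b * fs - 1e-9)) - 1
        if k1 - k0 < 5:
            continue
        tau = np.arange(k0, k1 + 1) / fs - t_a
        base = _diastolic_baseline(tau, L, tau_tr, v0, d_tr, rise)
        shape = _beat_shape(tau, L, p, tau_tr, dtt, sigma_sys, sigma_dic, ibi0)
        j0 = int(np.argmax(shape))
        if shape[j0] <= 0:
            continue
        amp = (s_i - base[j0]) / shape[j0]
        value = base + amp * shape
        samples[k0 : k1 + 1] = value

        j = int(np.argmax(value))
        if j + 1 >= value.size:
            continue
        k_tr = j + 1 + int(np.argmin(value[j + 1 :]))
        peak_t[i] = (k0 + j) / fs
        end_t[i] = (k0 + k_tr) / fs
        onset_t[i] = end_t[i - 1] if i > 0 and ok[i - 1] else t_a
        sbp_true[i] = value[j]
        dbp_true[i] = value[k_tr]
        hr_true[i] = 60.0 / L
        ok[i] = True

    samples = samples[:n_samples]
    if np.any(np.isnan(samples)):  # beats shorter than one sample, should not happen
        samples = np.nan_to_num(samples, nan=float(dbp_bnd[0]))

    keep = ok & (end_t <= config.duration_s + 1e-9)
    truth = GroundTruth(
        onset_t=onset_t[keep],
        peak_t=peak_t[keep],
        end_t=end_t[keep],
        sbp=sbp_true[keep],
        dbp=dbp_true[keep],
        map=dbp_true[keep] + (sbp_true[keep] - dbp_true[keep]) / 3.0,
        hr=hr_true[keep],
        wander_trace=np.zeros(n_samples),
    )

    clean = WaveformRecording(samples, fs=fs, channel="cap", units="mmHg")
    rec = sensor_transform(
        clean, config.sensor.gain, config.sensor.offset, config.sensor.noise_sd, seed=seeds[1]
    )
    if config.wander is not None and config.wander.amplitude > 0:
        rec, trace = inject_baseline_wander(rec, config.wander, seed=seeds[2])
        truth.wander_trace = trace
    if config.artifacts:
        rec = inject_motion_artifacts(rec, config.artifacts, seed=seeds[3])
    return rec, truth


def inject_baseline_wander(
    rec: WaveformRecording, wander_spec: WanderSpec | dict, seed: int = 0
) -> tuple[WaveformRecording, np.ndarray]:
    """Add a low-frequency stochastic offset trace; return (recording, trace).

    The trace's spectral content is concentrated below the model's corner
    frequency and its realized standard deviation equals ``amplitude``.
    Output minus input equals the returned trace exactly.
    """
    if isinstance(wander_spec, dict):
        wander_spec = WanderSpec(**wander_spec)
    n = rec.n_samples
    if wander_spec.amplitude == 0 or n == 0:
        return rec.copy(), np.zeros(n)

    rng = np.random.default_rng(seed)
    duration = n / rec.fs
    if wander_spec.model == "random_walk":
        dt_c = 1.0 / (2.0 * wander_spec.corner_freq_hz)
        n_c = max(int(math.ceil(duration / dt_c)) + 3, 4)
        knots_t = np.arange(n_c) * dt_c - dt_c  # one knot before t=0 for interpolation
        walk = np.cumsum(rng.standard_normal(n_c))
        interp = PchipInterpolator(knots_t, walk)
        trace = interp(np.arange(n) / rec.fs)
    else:  # sum_of_sinusoids
        k = 8
        freqs = np.geomspace(wander_spec.corner_freq_hz / 20.0, wander_spec.corner_freq_hz, k)
        phases = rng.uniform(0.0, 2 * np.pi, size=k)
        amps = 1.0 / freqs
        tt = np.arange(n) / rec.fs
        trace = np.sum(
            amps[:, None] * np.sin(2 * np.pi * freqs[:, None] * tt[None, :] + phases[:, None]),
            axis=0,
        )
    trace = trace - trace.mean()
    sd = trace.std()
    if sd > 0:
        trace *= wander_spec.amplitude / sd
    return rec.with_samples(rec.samples + trace), trace


def inject_motion_artifacts(
    rec: WaveformRecording, events: Sequence[ArtifactEvent], seed: int = 0
) -> WaveformRecording:
    """Superimpose motion artifacts; samples outside all events are unchanged.

    impulse: raised-cosine (Hann) transient peaking at ``magnitude``.
    step: persistent offset of ``magnitude`` from ``t_start`` onward.
    cyclic: additive sinusoid of amplitude ``magnitude`` over the event span.

    The ``seed`` parameter is accepted for interface symmetry; all three
    artifact kinds are currently deterministic functions of their event.
    """
    del seed
    t_end_rec = rec.t0 + rec.duration_s
    out = rec.samples.copy()
    tt = rec.times
    for ev in events:
        if ev.t_start > t_end_rec:
            raise ValueError(f"artifact at t={ev.t_start}s starts beyond recording end")
        if ev.kind != "step" and ev.t_start + ev.duration_s > t_end_rec + 1e-9:
            raise ValueError(f"artifact at t={ev.t_start}s extends beyond recording end")
        if ev.kind == "impulse":
            u = (tt - ev.t_start) / ev.duration_s
            m = (u >= 0) & (u <= 1)
            out[m] += ev.magnitude * 0.5 * (1.0 - np.cos(2 * np.pi * u[m]))
        elif ev.kind == "step":
            out[tt >= ev.t_start] += ev.magnitude
        else:  # cyclic
            m = (tt >= ev.t_start) & (tt <= ev.t_start + ev.duration_s)
            out[m] += ev.magnitude * np.sin(2 * np.pi * ev.freq_hz * (tt[m] - ev.t_start))
    return rec.with_samples(out)


def sensor_transform(
    rec: WaveformRecording,
    gain: float,
    offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> WaveformRecording:
    """Affine transducer model ``out = gain*in + offset + N(0, noise_sd)``.

    The output's unit flag is set to ``"sensor"`` (arbitrary units needing
    cuff calibration), regardless of the input units.
    """
    if gain <= 0:
        raise ValueError("sensor gain must be > 0")
    out = gain * rec.samples + offset
    if noise_sd > 0:
        out = out + np.random.default_rng(seed).normal(0.0, noise_sd, size=out.size)
    return rec.with_samples(out, units="sensor")
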