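"""Quartz crystal microbalance signal processing.

A QCM reports adsorbed mass as a drop in resonance frequency; for thin
rigid films the Sauerbrey relation is linear, and here the instrument's
sensitivity constant C = 17.7 ng Hz^-1 cm^-2 converts directly:

    delta_m [ng/cm^2] = -C * delta_f [Hz]

The processing chain mirrors standard sensorgram evaluation: moving-average
noise filtering and baseline correction, capture slopes from 30-s window
means taken just before the onset of the frequency drop and again 5 min
later, a linear sensitivity fit of capture slope vs analyte concentration,
rinse-phase dissociation rates normalized by the captured amount, and
regeneration recovery across capture cycles.  A synthesizer converts a
simulated surface-binding time course into a frequency trace (Sauerbrey
inverted, plus drift and noise) so the whole chain is testable end to end
without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import linregress

from .transport import SensorResponse

__all__ = [
    "SAUERBREY_CONSTANT",
    "THROMBIN_MOLAR_MASS",
    "QcmTrace",
    "SensitivityCurve",
    "sauerbrey_mass",
    "smooth_and_baseline",
    "capture_slope",
    "detect_onset",
    "sensitivity_fit",
    "dissociation_rate",
    "regeneration_recovery",
    "synthesize_qcm",
]

SAUERBREY_CONSTANT = 17.7  # ng Hz^-1 cm^-2 (5 MHz AT-cut crystal)
THROMBIN_MOLAR_MASS = 36.7e3  # g/mol, human alpha-thrombin


@dataclass(frozen=True)
class QcmTrace:
    """Frequency-vs-time series with optional phase annotations.

    ``phases`` maps phase names (e.g. "baseline", "capture", "rinse") to
    (start_s, end_s) intervals.
    """

    times: np.ndarray  # s
    frequency: np.ndarray  # Hz
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.frequency, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "frequency", f)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and frequency must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    def window_mean(self, t0: float, t1: float) -> float:
        mask = (self.times >= t0) & (self.times <= t1)
        if not mask.any():
            raise ValueError(f"no samples in window [{t0}, {t1}] s")
        return float(np.mean(self.frequency[mask]))


@dataclass(frozen=True)
class SensitivityCurve:
    concentrations: np.ndarray  # M
    capture_slopes: np.ndarray  # Hz/min
    in_range: np.ndarray  # bool, points used for the linear fit
    sensitivity: float  # Hz/min per M
    intercept: float
    r_squared: float


def sauerbrey_mass(delta_f: float | np.ndarray, constant: float = SAUERBREY_CONSTANT):
    """Areal mass change (ng/cm^2) from a frequency shift: dm = -C * df."""
    return -constant * np.asarray(delta_f, dtype=float) + 0.0


def smooth_and_baseline(
    trace: QcmTrace,
    window: int = 100,
    baseline_interval: tuple[float, float] | None = None,
) -> QcmTrace:
    """Centered moving average plus baseline subtraction.

    The baseline is the mean of the smoothed trace over a user-marked
    pre-capture interval (or the trace's "baseline" phase annotation) and
    is subtracted from the whole trace.  ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(trace.times)
    if window > n:
        raise ValueError(f"window {window} longer than trace ({n} samples)")
    if window == 1:
        f = trace.frequency.copy()
    else:
        kernel = np.ones(window) / window
        # normalize by actual kernel coverage near the edges
        f = np.convolve(trace.frequency, kernel, mode="same")
        norm = np.convolve(np.ones(n), kernel, mode="same")
        f = f / norm
    out = QcmTrace(trace.times, f, dict(trace.phases))
    if baseline_interval is None:
        baseline_interval = trace.phases.get("baseline")
    if baseline_interval is not None:
        base = out.window_mean(*baseline_interval)
        out = QcmTrace(out.times, out.frequency - base, dict(out.phases))
    return out


def capture_slope(
    trace: QcmTrace,
    onset: float,
    response_window: float = 300.0,
    avg_window: float = 30.0,
) -> float:
    """Capture slope in Hz/min from window means around the onset.

    Frequency is averaged over ``avg_window`` seconds ending at the onset
    and again over the ``avg_window`` ending at onset + response_window
    (5 min by default); the slope is their difference per minute.  Adding a
    constant to the whole trace leaves the result unchanged.
    """
    f_before = trace.window_mean(onset - avg_window, onset)
    f_after = trace.window_mean(
        onset + response_window - avg_window, onset + response_window
    )
    return (f_after - f_before) / (response_window / 60.0)


def detect_onset(
    trace: QcmTrace,
    baseline_interval: tuple[float, float],
    n_sigma: float = 3.0,
) -> float:
    """First time the trace drops ``n_sigma`` noise-SDs below its baseline.

    An automated alternative to manually annotated phase boundaries.
    """
    mask = (trace.times >= baseline_interval[0]) & (trace.times <= baseline_interval[1])
    if mask.sum() < 2:
        raise ValueError("baseline interval too short")
    base = float(np.mean(trace.frequency[mask]))
    noise = float(np.std(trace.frequency[mask]))
    after = trace.times > baseline_interval[1]
    drop = after & (trace.frequency < base - n_sigma * max(noise, 1e-12))
    idx = np.flatnonzero(drop)
    if len(idx) == 0:
        raise ValueError("no onset detected")
    return float(trace.times[idx[0]])


def sensitivity_fit(
    points: Sequence[tuple[float, float]],
    linear_range: tuple[float, float] | None = None,
) -> SensitivityCurve:
    """OLS fit of capture slope vs concentration over the linear range.

    ``points`` are (concentration_M, capture_slope_Hz_per_min) pairs.
    Points outside ``linear_range`` are flagged (sub-LOQ below it) and
    excluded from the fit; at least three in-range points are required.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (concentration, slope) pairs")
    c, s = pts[:, 0], pts[:, 1]
    if linear_range is None:
        in_range = np.ones(len(c), dtype=bool)
    else:
        in_range = (c >= linear_range[0]) & (c <= linear_range[1])
    if in_range.sum() < 3:
        raise ValueError("need at least 3 points in the linear range")
    res = linregress(c[in_range], s[in_range])
    return SensitivityCurve(
        c, s, in_range, float(res.slope), float(res.intercept),
        float(res.rvalue**2),
    )


def dissociation_rate(
    trace: QcmTrace,
    rinse_start: float | None = None,
    window: float = 300.0,
) -> float:
    """Normalized dissociation rate over the first 5 min of rinsing.

    Linear-regression slope of the frequency over [rinse_start,
    rinse_start + window], divided by the total captured frequency shift at
    the end of the capture phase (so units are fraction of captured signal
    per second).  Requires a "rinse" phase annotation (or explicit
    ``rinse_start``) and a "capture" annotation for normalization.
    """
    if rinse_start is None:
        if "rinse" not in trace.phases:
            raise ValueError("no rinse phase annotated and no rinse_start given")
        rinse_start = trace.phases["rinse"][0]
    if "capture" not in trace.phases:
        raise ValueError("capture phase annotation required for normalization")
    cap0, cap1 = trace.phases["capture"]
    captured = trace.window_mean(cap0 - 30.0, cap0) - trace.window_mean(
        cap1 - 30.0, cap1
    )
    if captured <= 0:
        raise ValueError("no captured signal to normalize against")
    mask = (trace.times >= rinse_start) & (trace.times <= rinse_start + window)
    if mask.sum() < 2:
        raise ValueError("rinse window not covered by trace")
    slope = linregress(trace.times[mask], trace.frequency[mask]).slope
    return float(slope / captured)


def regeneration_recovery(first_capture_df: float, second_capture_df: float) -> float:
    """Recovery (%) = second-cycle capture shift / first-cycle shift * 100."""
    if first_capture_df == 0:
        raise ValueError("first-cycle capture is zero: recovery undefined")
    return float(second_capture_df / first_capture_df * 100.0)


def synthesize_qcm(
    response: SensorResponse,
    molar_mass: float = THROMBIN_MOLAR_MASS,
    noise_sd: float = 0.0,
    drift: float = 0.0,
    rng: np.random.Generator | None = None,
    constant: float = SAUERBREY_CONSTANT,
    baseline_s: float = 0.0,
) -> QcmTrace:
    """Convert a simulated surface-binding time course to a QCM trace.

    The bound density B (mol/m^2) becomes an areal mass B * M (converted to
    ng/cm^2), then a frequency shift through the inverted Sauerbrey
    relation; a linear drift (Hz/min) and Gaussian noise are added.  A
    quiet ``baseline_s`` stretch (buffer equilibration before the analyte
    arrives) can be prepended; phase annotations mark baseline, capture and
    rinse so the analysis chain finds its windows.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    mass_ng_cm2 = response.B * molar_mass * 1e5  # mol/m^2 * g/mol -> ng/cm^2
    df_signal = -mass_ng_cm2 / constant
    if baseline_s > 0:
        step = float(np.median(np.diff(response.times)))
        t_pre = np.arange(0.0, baseline_s, step)
        t = np.concatenate([t_pre, response.times + baseline_s])
        df_signal = np.concatenate([np.zeros(len(t_pre)), df_signal])
    else:
        t = response.times
    f = df_signal + drift * t / 60.0
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        f = f + rng.normal(0.0, noise_sd, len(t))
    onset = baseline_s
    phases = {
        "baseline": (0.0, float(onset)),
        "capture": (float(onset), float(onset + response.scenario.t_assoc)),
        "rinse": (float(onset + response.scenario.t_assoc), float(t[-1])),
    }
    return QcmTrace(t, f, phases)
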