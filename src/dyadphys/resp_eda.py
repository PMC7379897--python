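"""Respiration-rhythm and electrodermal parameters.

Respiration (4 parameters): the belt trace is zero-phase band-pass filtered
between 0.05 and 0.5 Hz; instantaneous breathing rate comes from successive
rising zero-crossings (intervals shorter than 0.5 s are treated as artifacts
and removed).  ``resp_MF``/``resp_HF`` are Fourier band powers of the
filtered trace in 0.07-0.14 / 0.15-0.5 Hz, normalised by its total power.

EDA (4 parameters): skin conductance is split into a tonic level (SCL) and a
phasic response component (SCR) by non-negative deconvolution against a
bi-exponential (Bateman) kernel; both components are integrated over 10-s
non-overlapping windows and summarised by mean and standard deviation.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d, percentile_filter
from scipy.signal import butter, lfilter, periodogram, sosfiltfilt

from .errors import DataError, InsufficientDataError

__all__ = [
    "breathing_rate_series",
    "resp_features",
    "decompose_eda",
    "eda_features",
    "bateman_filter",
    "RESP_COLUMNS",
    "EDA_COLUMNS",
]

RESP_COLUMNS = ("resp_mean", "resp_std", "resp_MF", "resp_HF")
EDA_COLUMNS = ("iscl_mean", "iscl_std", "iscr_mean", "iscr_std")

RESP_BAND = (0.05, 0.5)
MF_BAND = (0.07, 0.14)
HF_BAND = (0.15, 0.5)
MIN_BREATH_INTERVAL_S = 0.5


def _bandpass(trace: np.ndarray, fs: float) -> np.ndarray:
    sos = butter(4, RESP_BAND, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, trace)


def _rising_crossings(x: np.ndarray, fs: float) -> np.ndarray:
    """Sub-sample times (s) where x crosses zero from below."""
    below = x[:-1] < 0.0
    above = x[1:] >= 0.0
    idx = np.nonzero(below & above)[0]
    # linear interpolation inside the crossing sample
    frac = -x[idx] / (x[idx + 1] - x[idx])
    return (idx + frac) / fs


def breathing_rate_series(trace: np.ndarray, fs: float) -> np.ndarray:
    """Instantaneous breathing rates (Hz) from rising zero-crossings.

    Raises :class:`InsufficientDataError` when fewer than two crossings
    survive, or when every interval falls under the 0.5-s artifact rule.
    """
    trace = np.asarray(trace, dtype=float)
    if fs < 2.0:
        raise DataError(f"fs={fs} Hz too low for respiration analysis")
    if trace.size / fs < 20.0:
        raise InsufficientDataError("respiration trace shorter than 20 s")
    if not np.all(np.isfinite(trace)):
        raise DataError("respiration trace contains non-finite samples")
    filt = _bandpass(trace, fs)
    crossings = _rising_crossings(filt, fs)
    if crossings.size < 2:
        raise InsufficientDataError("fewer than 2 rising zero-crossings")
    intervals = np.diff(crossings)
    intervals = intervals[intervals > MIN_BREATH_INTERVAL_S]
    if intervals.size < 2:
        raise InsufficientDataError(
            "fewer than 2 breath intervals survive the 0.5 s artifact rule")
    return 1.0 / intervals


def resp_features(trace: np.ndarray, fs: float) -> dict:
    """The four respiration parameters (Table-2-shaped row)."""
    rates = breathing_rate_series(trace, fs)
    filt = _bandpass(np.asarray(trace, dtype=float), fs)
    freqs, pxx = periodogram(filt, fs=fs, window="boxcar", detrend=False)
    total = float(np.sum(pxx))
    if total <= 0.0:
        mf = hf = 0.0
    else:
        mf = float(np.sum(pxx[(freqs >= MF_BAND[0]) & (freqs <= MF_BAND[1])])) / total
        hf = float(np.sum(pxx[(freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])])) / total
    return {
        "resp_mean": float(np.mean(rates)),
        "resp_std": float(np.std(rates)),
        "resp_MF": mf,
        "resp_HF": hf,
    }


# --- EDA -------------------------------------------------------------------

def bateman_filter(fs: float, tau1: float = 0.75, tau2: float = 2.0) -> tuple:
    """Discrete Bateman kernel as an IIR filter (b, a).

    The kernel h[n] = p2^(n+1) - p1^(n+1), p_i = exp(-1/(fs*tau_i)), has the
    rational transfer function (p2-p1) / ((1-p1 z^-1)(1-p2 z^-1)); driving it
    with an impulse train of SCR event amplitudes produces the phasic trace,
    and the inverse filter performs exact deconvolution.  The kernel area
    (time-integral per unit amplitude) is returned for calibration.
    """
    p1 = np.exp(-1.0 / (fs * tau1))
    p2 = np.exp(-1.0 / (fs * tau2))
    b = np.array([p2 - p1])
    a = np.array([1.0, -(p1 + p2), p1 * p2])
    area = (p2 / (1.0 - p2) - p1 / (1.0 - p1)) / fs
    return b, a, area


def scr_from_driver(driver: np.ndarray, fs: float, tau1: float = 0.75,
                    tau2: float = 2.0) -> np.ndarray:
    """Convolve a (non-negative) driver with the Bateman kernel."""
    b, a, _ = bateman_filter(fs, tau1, tau2)
    return lfilter(b, a, np.asarray(driver, dtype=float))


def _tonic_baseline(trace: np.ndarray, fs: float, window_s: float = 10.0) -> np.ndarray:
    """Slow baseline: rolling low percentile followed by Gaussian smoothing."""
    size = max(3, int(round(window_s * fs)) | 1)
    base = percentile_filter(trace, percentile=10, size=size, mode="nearest")
    return gaussian_filter1d(base, sigma=max(1.0, 2.0 * fs), mode="nearest")


def decompose_eda(trace: np.ndarray, fs: float, tau1: float = 0.75,
                  tau2: float = 2.0) -> tuple:
    """Split a conductance trace into tonic (SCL) and phasic (SCR) parts.

    A slow baseline is subtracted, the remainder is deconvolved exactly
    against the Bateman kernel, the resulting driver is clipped at zero and
    re-convolved; this guarantees scr >= 0.  The tonic part is defined as
    ``trace - scr`` so that additivity holds to machine precision.
    """
    trace = np.asarray(trace, dtype=float)
    if fs < 2.0:
        raise DataError(f"fs={fs} Hz too low for EDA analysis")
    if not np.all(np.isfinite(trace)):
        raise DataError("EDA trace contains non-finite samples")
    tonic0 = _tonic_baseline(trace, fs)
    phasic0 = trace - tonic0
    b, a, _ = bateman_filter(fs, tau1, tau2)
    driver = lfilter(a, b, phasic0)  # exact inverse filter
    driver = np.clip(driver, 0.0, None)
    scr = lfilter(b, a, driver)
    scl = trace - scr
    return scl, scr


def _window_integrals(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Trapezoidal integrals over non-overlapping windows.

    Windows share their boundary sample; the very last window re-uses the
    final sample as a flat one-sample extension so that every window spans
    exactly ``window_s`` seconds (a constant c integrates to window_s * c).
    Partial trailing windows are dropped.
    """
    spw = int(round(window_s * fs))
    n_win = int(x.size // spw)
    padded = np.append(x, x[-1])
    out = np.empty(n_win)
    for w in range(n_win):
        seg = padded[w * spw:(w + 1) * spw + 1]
        out[w] = np.trapezoid(seg, dx=1.0 / fs)
    return out


def eda_features(trace: np.ndarray, fs: float, window_s: float = 10.0) -> dict:
    """The four EDA parameters: windowed integrals of SCL and SCR."""
    trace = np.asarray(trace, dtype=float)
    if trace.size / fs < 2 * window_s:
        raise InsufficientDataError("EDA trace shorter than two integration windows")
    scl, scr = decompose_eda(trace, fs)
    iscl = _window_integrals(scl, fs, window_s)
    iscr = _window_integrals(scr, fs, window_s)
    return {
        "iscl_mean": float(np.mean(iscl)),
        "iscl_std": float(np.std(iscl)),
        "iscr_mean": float(np.mean(iscr)),
        "iscr_std": float(np.std(iscr)),
    }
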