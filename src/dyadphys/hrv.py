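"""Heart-rate-variability parameters computed from a normal-to-normal interval series.

The 15 parameters fall into three groups:

* time domain: ``ecg_mean``, ``ecg_SDNN``, ``ecg_RMSSD``, ``ecg_NN50``,
  ``ecg_pNN50``
* Poincaré geometry: ``ecg_SD1``, ``ecg_SD2``, ``ecg_r_RR``
* frequency domain (AR/Burg spectrum of the interpolated tachogram):
  ``ecg_VLF``, ``ecg_LF``, ``ecg_HF``, ``ecg_tot_pwr``, ``ecg_LF_HF``,
  ``ecg_LFnu``, ``ecg_HFnu``

Conventions (documented because the literature is inconsistent):

* Variances are population variances (divide by n).  Under this convention
  ``SD1 == RMSSD / sqrt(2)`` holds exactly, because SD1 is computed from the
  second moment of successive differences about zero (dispersion about the
  line of identity), not about their mean.
* ``pNN50`` uses the number of successive pairs (n - 1) as denominator.
* Normalised band powers divide by (total power - VLF).
* Undefined ratios (``r_RR`` on a constant series, ``LF/HF`` with zero HF
  power) are reported as ``nan`` — an explicit sentinel, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from .errors import DataError, InsufficientDataError

__all__ = [
    "NNSeries",
    "SpectralConfig",
    "time_domain_hrv",
    "poincare_hrv",
    "frequency_domain_hrv",
    "hrv_features",
    "HRV_COLUMNS",
]

HRV_COLUMNS = (
    "ecg_mean",
    "ecg_SDNN",
    "ecg_RMSSD",
    "ecg_NN50",
    "ecg_pNN50",
    "ecg_SD1",
    "ecg_SD2",
    "ecg_r_RR",
    "ecg_VLF",
    "ecg_LF",
    "ecg_HF",
    "ecg_tot_pwr",
    "ecg_LF_HF",
    "ecg_LFnu",
    "ecg_HFnu",
)


@dataclass(frozen=True)
class NNSeries:
    """Ordered normal-to-normal intervals.

    Attributes
    ----------
    intervals : ndarray
        Interval durations in milliseconds, all > 0.
    times : ndarray
        Onset time of each interval in seconds (time of the R peak that
        opens the interval), strictly increasing.
    """

    intervals: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        tt = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "times", tt)
        if iv.ndim != 1 or tt.ndim != 1 or iv.size != tt.size:
            raise DataError("intervals and times must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(iv)) and np.all(np.isfinite(tt))):
            raise DataError("NN series contains non-finite values")
        if np.any(iv <= 0):
            raise DataError("all NN intervals must be positive")
        if np.any(np.diff(tt) <= 0):
            raise DataError("NN onset times must be strictly increasing")

    @classmethod
    def from_rpeaks(cls, rpeaks_s: np.ndarray) -> "NNSeries":
        """Build the series from R-peak event times (seconds)."""
        r = np.asarray(rpeaks_s, dtype=float)
        if r.ndim != 1 or r.size < 2:
            raise InsufficientDataError("need at least 2 R peaks")
        if np.any(np.diff(r) <= 0):
            raise DataError("R-peak times must be strictly increasing")
        return cls(intervals=np.diff(r) * 1000.0, times=r[:-1])

    @property
    def end_times(self) -> np.ndarray:
        """Time of the beat closing each interval (seconds)."""
        return self.times + self.intervals / 1000.0

    @property
    def span(self) -> float:
        """Seconds covered from first to last beat."""
        return float(self.end_times[-1] - self.times[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return int(self.intervals.size)


@dataclass(frozen=True)
class SpectralConfig:
    """Settings for the AR band-power estimate."""

    fs_interp: float = 4.0          # tachogram resampling rate, Hz
    ar_order: int = 16              # Burg model order
    n_freq: int = 2048              # PSD evaluation grid size
    vlf_band: tuple = (0.009, 0.04)
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.4)
    min_span: float = 60.0          # seconds of data required


def time_domain_hrv(nn: NNSeries, nn50_threshold_ms: float = 50.0) -> dict:
    """Mean, SDNN, RMSSD, NN50 and pNN50.

    NN50 counts successive pairs differing by strictly more than the
    threshold; pNN50 divides by the number of successive pairs.
    """
    iv = nn.intervals
    if iv.size < 3:
        raise InsufficientDataError("time-domain HRV requires >= 3 intervals")
    d = np.diff(iv)
    nn50 = int(np.sum(np.abs(d) > nn50_threshold_ms))
    return {
        "ecg_mean": float(np.mean(iv)),
        "ecg_SDNN": float(np.std(iv)),  # population convention
        "ecg_RMSSD": float(np.sqrt(np.mean(d**2))),
        "ecg_NN50": nn50,
        "ecg_pNN50": nn50 / d.size,
    }


def poincare_hrv(nn: NNSeries) -> dict:
    """SD1, SD2 and the lag-one autocorrelation r_RR of the Poincaré plot.

    SD1^2 is half the second moment of successive differences (dispersion
    perpendicular to the line of identity), SD2^2 = 2 Var(NN) - SD1^2 with
    population variance; hence SD1 == RMSSD/sqrt(2) identically.
    """
    iv = nn.intervals
    if iv.size < 3:
        raise InsufficientDataError("Poincaré HRV requires >= 3 intervals")
    x, y = iv[:-1], iv[1:]
    d = y - x
    sd1_sq = 0.5 * float(np.mean(d**2))
    sd2_sq = 2.0 * float(np.var(iv)) - sd1_sq
    sd2_sq = max(sd2_sq, 0.0)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        r_rr = float("nan")  # undefined on (near-)constant series
    else:
        r_rr = float(np.corrcoef(x, y)[0, 1])
    return {
        "ecg_SD1": float(np.sqrt(sd1_sq)),
        "ecg_SD2": float(np.sqrt(sd2_sq)),
        "ecg_r_RR": r_rr,
    }


def _burg(x: np.ndarray, order: int) -> tuple:
    """Burg AR coefficient estimate.

    Returns ``(a, e)`` with prediction polynomial A(z) = 1 + sum a_k z^-k and
    driving-noise variance ``e``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order >= n:
        raise InsufficientDataError(f"AR order {order} requires > {order} samples")
    a = np.zeros(order)
    e = float(x @ x) / n
    f = x[1:].astype(float)
    b = x[:-1].astype(float)
    for m in range(order):
        den = float(f @ f + b @ b)
        k = -2.0 * float(f @ b) / den if den > 0.0 else 0.0
        if m == 0:
            a[0] = k
        else:
            a[:m] = a[:m] + k * a[:m][::-1]
            a[m] = k
        e *= 1.0 - k * k
        if m < order - 1:
            f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return a, e


def _ar_psd(a: np.ndarray, e: float, fs: float, freqs: np.ndarray) -> np.ndarray:
    """One-sided AR power spectral density on the given frequency grid."""
    k = np.arange(1, a.size + 1)
    z = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)
    denom = np.abs(1.0 + z @ a) ** 2
    with np.errstate(divide="ignore"):
        psd = 2.0 * e / fs / denom
    return psd


def frequency_domain_hrv(nn: NNSeries, spec: SpectralConfig | None = None) -> dict:
    """Band powers of the evenly resampled, mean-detrended tachogram.

    The NN series is cubically interpolated onto a regular grid, the AR
    spectrum is estimated with the Burg method and integrated over the VLF,
    LF and HF bands.  ``tot_pwr`` is the sum of the three band powers;
    normalised units divide by ``tot_pwr - VLF``.

    Note: trials barely longer than the VLF period give a low-confidence
    VLF estimate; it is computed regardless (flag it downstream if needed).
    """
    spec = spec or SpectralConfig()
    if nn.span < spec.min_span:
        raise InsufficientDataError(
            f"NN span {nn.span:.1f}s < {spec.min_span:.0f}s required for spectra"
        )
    t = nn.end_times
    order = min(spec.ar_order, max(2, int((nn.span * spec.fs_interp) // 3)))
    grid = np.arange(t[0], t[-1], 1.0 / spec.fs_interp)
    if grid.size <= order + 1:
        raise InsufficientDataError("too few tachogram samples for AR fit")
    kind = "cubic" if t.size >= 4 else "linear"
    tach = interp1d(t, nn.intervals, kind=kind, assume_sorted=True)(grid)
    tach = tach - tach.mean()
    a, e = _burg(tach, order)
    freqs = np.linspace(0.0, spec.fs_interp / 2.0, spec.n_freq)
    psd = _ar_psd(a, e, spec.fs_interp, freqs)

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*spec.vlf_band)
    lf = band_power(*spec.lf_band)
    hf = band_power(*spec.hf_band)
    tot = vlf + lf + hf
    denom = tot - vlf
    lf_hf = lf / hf if hf > 0.0 else float("nan")
    lfnu = lf / denom if denom > 0.0 else float("nan")
    hfnu = hf / denom if denom > 0.0 else float("nan")
    return {
        "ecg_VLF": vlf,
        "ecg_LF": lf,
        "ecg_HF": hf,
        "ecg_tot_pwr": tot,
        "ecg_LF_HF": lf_hf,
        "ecg_LFnu": lfnu,
        "ecg_HFnu": hfnu,
    }


def hrv_features(nn: NNSeries, spec: SpectralConfig | None = None) -> dict:
    """All 15 HRV parameters in canonical column order."""
    out = {}
    out.update(time_domain_hrv(nn))
    out.update(poincare_hrv(nn))
    out.update(frequency_domain_hrv(nn, spec))
    return {k: out[k] for k in HRV_COLUMNS}
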