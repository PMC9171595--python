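"""Window-level accelerometer signal quantities.

The wrist signal is reduced to the magnitude of the triaxial acceleration
vector, cut into non-overlapping 10-second windows, and summarized per window
by its mean absolute deviation (MAD) — the energy proxy the whole analysis is
built on — plus seven classification features (mean, median, variance,
skewness, kurtosis, peak frequency, peak power) and a thresholded hand
displacement.

Magnitude is computed on raw axes, gravity included: MAD is invariant to the
constant ~9.81 m/s^2 offset, so no high-pass filter is applied. Moments are
population (biased) estimators; the spectrum is a plain periodogram of the
mean-subtracted magnitude without tapering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import periodogram

from .errors import IntegrityError, UndefinedWindowError

#: Default window length (s) and displacement MAD threshold (m/s^2).
DEFAULT_WINDOW_S = 10.0
DEFAULT_DISPLACEMENT_THETA = 0.02


@dataclass(frozen=True)
class WindowFeatures:
    """Time- and frequency-domain summary of one window's magnitude samples."""

    mean: float
    median: float
    variance: float
    skewness: float
    kurtosis: float
    peak_frequency: float
    peak_power: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.mean,
                self.median,
                self.variance,
                self.skewness,
                self.kurtosis,
                self.peak_frequency,
                self.peak_power,
            ]
        )


#: Column order of the feature vector exposed to the classifier (MAD first).
FEATURE_ORDER: tuple[str, ...] = (
    "mad",
    "mean",
    "median",
    "variance",
    "skewness",
    "kurtosis",
    "peak_frequency",
    "peak_power",
)


@dataclass
class SensorWindow:
    """One fixed-length window of magnitude samples.

    ``worn`` is False when fewer than 80% of the expected samples are present;
    unworn windows carry no features and are excluded from energy accounting.
    """

    start_s: float
    duration_s: float
    n_samples: int
    samples: np.ndarray
    worn: bool
    mad: Optional[float] = None
    features: Optional[WindowFeatures] = None
    patient_id: Optional[str] = None
    day_index: Optional[int] = None


def magnitude(ax: Sequence[float], ay: Sequence[float], az: Sequence[float]) -> np.ndarray:
    """Euclidean magnitude of the acceleration vector, sample-wise.

    Raises IntegrityError if the axis sequences differ in length.
    """
    ax = np.asarray(ax, dtype=float)
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    if not (ax.shape == ay.shape == az.shape):
        raise IntegrityError(
            f"axis length mismatch: {ax.shape}, {ay.shape}, {az.shape}"
        )
    return np.sqrt(ax * ax + ay * ay + az * az)


def mad(samples: Sequence[float]) -> float:
    """Mean absolute deviation of magnitude samples about their mean.

    This is the energy-expenditure proxy: (1/N) * sum |m_i - mean(m)|.
    Requires at least two samples.
    """
    m = np.asarray(samples, dtype=float)
    if m.size < 2:
        raise UndefinedWindowError(f"MAD undefined on {m.size} sample(s)")
    return float(np.mean(np.abs(m - m.mean())))


def window_features(samples: Sequence[float], sample_rate_hz: float) -> WindowFeatures:
    """The seven classification features of one worn window.

    Moments use population (biased) normalization; kurtosis is the raw
    standardized fourth moment (3 for a Gaussian). Peak frequency and power
    are the argmax and max of the periodogram of the mean-subtracted signal;
    a constant window has zero peak power at frequency zero.
    """
    m = np.asarray(samples, dtype=float)
    if m.size < 8:
        raise UndefinedWindowError(f"features undefined on {m.size} sample(s)")
    mu = m.mean()
    centered = m - mu
    var = float(np.mean(centered**2))
    if var > 0.0:
        sd = np.sqrt(var)
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / var**2)
    else:
        skew = 0.0
        kurt = 0.0
    freqs, power = periodogram(centered, fs=sample_rate_hz, window="boxcar")
    k = int(np.argmax(power))
    peak_power = float(power[k])
    peak_frequency = float(freqs[k]) if peak_power > 0.0 else 0.0
    return WindowFeatures(
        mean=float(mu),
        median=float(np.median(m)),
        variance=var,
        skewness=skew,
        kurtosis=kurt,
        peak_frequency=peak_frequency,
        peak_power=peak_power,
    )


def displacement(
    window_mad: float,
    theta: float = DEFAULT_DISPLACEMENT_THETA,
    duration_s: float = DEFAULT_WINDOW_S,
) -> float:
    """Thresholded hand displacement over one window, in meters.

    Zero below the MAD threshold theta (default 0.02 m/s^2); otherwise the
    constant-acceleration kinematic proxy (1/2) * MAD * T^2. The proxy treats
    the window MAD as a sustained acceleration scale; it is a relative
    movement index, not a literal distance.
    """
    if window_mad < theta:
        return 0.0
    return 0.5 * window_mad * duration_s**2


def window_stream(
    t_s: Sequence[float],
    m: Sequence[float],
    sample_rate_hz: float,
    duration_s: float = DEFAULT_WINDOW_S,
    compute_features: bool = True,
    worn_fraction: float = 0.8,
    partial_keep_fraction: float = 0.5,
) -> list[SensorWindow]:
    """Cut a magnitude series into non-overlapping, left-aligned windows.

    Windows are half-open [k*T, (k+1)*T) anchored at t=0 (seconds from wear
    start). A trailing partial window is kept when it holds at least 50% of a
    full window's expected samples, and dropped otherwise. A window is worn
    when at least 80% of expected samples are present; only worn windows get
    MAD and features.
    """
    t = np.asarray(t_s, dtype=float)
    m = np.asarray(m, dtype=float)
    if t.shape != m.shape:
        raise IntegrityError(f"time/magnitude length mismatch: {t.shape} vs {m.shape}")
    if t.size == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise IntegrityError("timestamps must be strictly increasing")

    expected_full = sample_rate_hz * duration_s
    t_end = t[-1]
    n_windows = int(np.floor(t_end / duration_s)) + 1
    idx = np.floor(t / duration_s).astype(int)

    out: list[SensorWindow] = []
    for k in range(n_windows):
        sel = idx == k
        samples = m[sel]
        n = int(samples.size)
        is_trailing = k == n_windows - 1
        if is_trailing and n < partial_keep_fraction * expected_full:
            continue
        worn = n >= worn_fraction * expected_full
        w = SensorWindow(
            start_s=k * duration_s,
            duration_s=duration_s,
            n_samples=n,
            samples=samples,
            worn=worn,
        )
        if worn and n >= 2:
            w.mad = mad(samples)
            if compute_features and n >= 8:
                w.features = window_features(samples, sample_rate_hz)
        out.append(w)
    return out
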