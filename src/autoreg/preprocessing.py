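"""Signal conditioning for beat-to-beat hemodynamic recordings.

Raw blood pressure (BP) and cerebral blood flow velocity (CBFV) waveforms
are reduced to the uniform series the downstream analyses consume:

1. zero-phase low-pass filtering of the raw waveforms,
2. beat-to-beat averaging over cardiac cycles,
3. cubic interpolation of the beat series onto a uniform grid (0.2 s),
4. re-interpolation onto a 0.5 s grid (2 Hz) for the SVR models,
5. amplitude normalization to [0, 1] for kernel regression.

Two uniform products coexist on purpose: a 5 Hz physical-unit series used
by transfer function analysis (512 samples span 102.4 s exactly at 5 Hz)
and a 2 Hz normalized series used by the dynamic SVR models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate as _interp
from scipy import signal as _sig

__all__ = [
    "UniformSignal",
    "BeatSeries",
    "DataError",
    "ParameterError",
    "zero_phase_lowpass",
    "beat_average",
    "resample_uniform",
    "decimate_to",
    "normalize01",
    "denormalize01",
]


class DataError(ValueError):
    """Raised when input data violate a structural requirement."""


class ParameterError(ValueError):
    """Raised when an operation is called with inconsistent parameters."""


@dataclass
class UniformSignal:
    """Evenly sampled physiological series.

    Parameters
    ----------
    values : ndarray
        Sample values in ``unit``.
    rate : float
        Sampling rate in Hz; must be positive.
    unit : str
        Physical unit, e.g. ``"mmHg"`` or ``"cm/s"``.
    t0 : float
        Time of the first sample in seconds from recording start.
    """

    values: np.ndarray
    rate: float
    unit: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise DataError("signal must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise DataError(f"non-finite sample at index {bad}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        """Span from first to last sample in seconds."""
        return (self.values.size - 1) / self.rate

    def with_values(self, values: np.ndarray) -> "UniformSignal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class BeatSeries:
    """One mean value per cardiac cycle.

    ``beat_times`` mark cycle onsets (seconds, strictly increasing);
    ``beat_means`` hold the within-cycle signal average assigned to the
    cycle onset.
    """

    beat_times: np.ndarray
    beat_means: np.ndarray
    unit: str = ""
    ibi_bounds: tuple[float, float] = (0.3, 2.0)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.beat_means = np.asarray(self.beat_means, dtype=float)
        if self.beat_times.size != self.beat_means.size:
            raise DataError("beat_times and beat_means must have equal length")
        if self.beat_times.size < 2:
            raise DataError("need at least 2 beats")
        ibi = np.diff(self.beat_times)
        if np.any(ibi <= 0):
            raise DataError("beat_times must be strictly increasing")
        lo, hi = self.ibi_bounds
        if np.any(ibi < lo) or np.any(ibi > hi):
            warnings.warn(
                f"inter-beat intervals outside [{lo}, {hi}] s present", stacklevel=2
            )

    def __len__(self) -> int:
        return self.beat_times.size


def zero_phase_lowpass(
    sig: UniformSignal, order: int = 8, cutoff: float = 20.0
) -> UniformSignal:
    """Forward-backward Butterworth low-pass filter.

    Applying the filter in both directions cancels its phase response, so
    filtered features stay time-aligned with the raw waveform; the
    effective magnitude response is the squared one-pass response.

    Parameters
    ----------
    sig : UniformSignal
    order : int
        One-pass Butterworth order (default 8).
    cutoff : float
        Cut-off frequency in Hz; must be below Nyquist.
    """
    nyq = sig.rate / 2.0
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    sos = _sig.butter(order, cutoff, btype="low", fs=sig.rate, output="sos")
    filtered = _sig.sosfiltfilt(sos, sig.values)
    return sig.with_values(filtered)


def beat_average(sig: UniformSignal, beat_times: np.ndarray) -> BeatSeries:
    """Average a waveform over cardiac cycles.

    The mean over ``[t_i, t_{i+1})`` is assigned to beat time ``t_i``; the
    last marker only closes the final interval.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        raise DataError("need at least 2 beat markers")
    if np.any(np.diff(beat_times) <= 0):
        raise DataError("beat markers must be strictly increasing")
    t = sig.times
    if beat_times[0] < t[0] - 1e-9 or beat_times[-1] > t[-1] + 1.0 / sig.rate:
        raise DataError("beat markers fall outside the signal span")

    idx = np.searchsorted(t, beat_times - 1e-12)
    means = np.empty(beat_times.size - 1)
    for k in range(means.size):
        lo, hi = idx[k], idx[k + 1]
        if hi <= lo:
            raise DataError(f"beat interval {k} contains no samples")
        means[k] = sig.values[lo:hi].mean()
    return BeatSeries(beat_times[:-1], means, unit=sig.unit)


def resample_uniform(
    beats: BeatSeries, dt: float = 0.2, poly_order: int = 3
) -> UniformSignal:
    """Interpolate a beat series onto a uniform grid.

    A spline of degree ``poly_order`` (cubic by default) passes through
    the beat means; the output grid starts at the first beat and never
    extrapolates past the last one.
    """
    if len(beats) < poly_order + 1:
        raise DataError(
            f"need at least {poly_order + 1} beats for order-{poly_order} interpolation"
        )
    t0, t_end = beats.beat_times[0], beats.beat_times[-1]
    n = int(np.floor((t_end - t0) / dt)) + 1
    grid = t0 + dt * np.arange(n)
    spline = _interp.make_interp_spline(beats.beat_times, beats.beat_means, k=poly_order)
    return UniformSignal(spline(grid), rate=1.0 / dt, unit=beats.unit, t0=t0)


def decimate_to(sig: UniformSignal, target_rate: float = 2.0) -> UniformSignal:
    """Keep every ``rate/target_rate``-th sample.

    Assumes the anti-alias low-pass has already been applied upstream.
    The ratio must be an integer; for non-integer ratios (e.g. 5 Hz to
    2 Hz) re-interpolate the beat series directly with
    :func:`resample_uniform` at the target step instead.
    """
    ratio = sig.rate / target_rate
    r = round(ratio)
    if abs(ratio - r) > 1e-9 or r < 1:
        raise ParameterError(
            f"rate ratio {sig.rate}/{target_rate} = {ratio:g} is not an integer; "
            "re-interpolate onto the target grid instead"
        )
    return UniformSignal(sig.values[::r], rate=target_rate, unit=sig.unit, t0=sig.t0)


def normalize01(sig: UniformSignal) -> tuple[UniformSignal, tuple[float, float]]:
    """Affine map of the amplitude onto [0, 1].

    Returns the normalized signal together with ``(min, max)`` so that
    model predictions can be mapped back to physical units — and so the
    same constants can be reused on a validation segment without leaking
    its range into training.
    """
    lo = float(sig.values.min())
    hi = float(sig.values.max())
    if hi <= lo:
        raise DataError("constant signal: [0, 1] scaling undefined")
    scaled = (sig.values - lo) / (hi - lo)
    return replace(sig, values=scaled, unit=""), (lo, hi)


def denormalize01(values: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Invert :func:`normalize01` given its ``(min, max)`` constants."""
    lo, hi = bounds
    return np.asarray(values) * (hi - lo) + lo
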