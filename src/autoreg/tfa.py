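"""Transfer function analysis (TFA) of the pressure-flow relationship.

Welch-averaged auto- and cross-spectra of BP (input) and CBFV (output)
give the frequency response H(f) = S_pv / S_pp, reported as gain |H|,
phase arg H and magnitude-squared coherence. Estimates are averaged over
the very-low-frequency (VLF, 0.02-0.07 Hz) and low-frequency (LF,
0.07-0.2 Hz) bands where autoregulation acts as a high-pass filter:
efficient regulation shows low VLF gain and a positive phase lead of
CBFV over BP. Band estimates are only trusted when coherence clears the
level expected of incoherent noise, 1 - alpha**(1/(L-1)) for L averaged
windows.

The 5 Hz physical-unit series are analyzed with 512-sample (102.4 s)
Hann-windowed segments at 50% overlap, linearly detrended per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .preprocessing import DataError, ParameterError, UniformSignal

__all__ = [
    "BANDS",
    "SpectralEstimate",
    "BandSummary",
    "welch_transfer",
    "band_average",
    "coherence_criterion",
]

#: Canonical band edges in Hz; inclusion is half-open [lo, hi).
BANDS: dict[str, tuple[float, float]] = {
    "VLF": (0.02, 0.07),
    "LF": (0.07, 0.2),
}


@dataclass
class SpectralEstimate:
    """Welch transfer function estimate on the resolved frequency axis."""

    freqs: np.ndarray  # Hz, ascending
    gain: np.ndarray  # |H|, output-unit per input-unit
    phase: np.ndarray  # arg H, radians (wrapped; unwrap per band)
    coherence: np.ndarray  # magnitude-squared, in [0, 1]
    n_windows: int
    gain_unit: str = "cm/s/mmHg"


@dataclass
class BandSummary:
    band: str
    lo: float
    hi: float
    mean_gain: float
    mean_phase: float
    mean_coherence: float
    n_bins: int
    accepted: bool | None = None
    coherence_threshold: float | None = None


def _count_windows(n: int, seg_len: int, overlap: float) -> int:
    step = int(round(seg_len * (1.0 - overlap)))
    if step <= 0:
        raise ParameterError("overlap too large")
    return 1 + (n - seg_len) // step


def welch_transfer(
    p: UniformSignal,
    v: UniformSignal,
    seg_len: int = 512,
    overlap: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Estimate gain, phase and coherence of the BP -> CBFV system.

    Auto-spectra S_pp, S_vv and the cross-spectrum S_pv are averaged over
    Hann-windowed, linearly detrended segments of ``seg_len`` samples at
    the given overlap; H = S_pv / S_pp. The cross-spectrum convention is
    conj(P) * V, so a CBFV that lags BP has negative phase and a pure
    delay of tau seconds has phase -2*pi*f*tau.
    """
    if p.rate != v.rate or len(p) != len(v):
        raise ParameterError("input and output must share rate and length")
    if len(p) < seg_len:
        raise DataError(f"need at least {seg_len} samples, got {len(p)}")
    n_win = _count_windows(len(p), seg_len, overlap)
    if n_win < 2:
        raise DataError("fewer than 2 windows: coherence undefined")

    noverlap = int(round(seg_len * overlap))
    kw = dict(
        fs=p.rate,
        window=window,
        nperseg=seg_len,
        noverlap=noverlap,
        detrend="linear",
        scaling="density",
    )
    f, s_pp = _sig.welch(p.values, **kw)
    _, s_vv = _sig.welch(v.values, **kw)
    _, s_pv = _sig.csd(p.values, v.values, **kw)

    h = s_pv / s_pp
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(s_pv) ** 2 / (s_pp * s_vv)
    coh = np.clip(np.nan_to_num(coh), 0.0, 1.0)
    return SpectralEstimate(
        freqs=f,
        gain=np.abs(h),
        phase=np.angle(h),
        coherence=coh,
        n_windows=n_win,
        gain_unit=f"{v.unit}/{p.unit}" if p.unit and v.unit else "",
    )


def _band_slice(est: SpectralEstimate, lo: float, hi: float) -> np.ndarray:
    mask = (est.freqs >= lo) & (est.freqs < hi)
    if not np.any(mask):
        raise ParameterError(f"no frequency bins inside [{lo}, {hi}) Hz")
    return mask


def band_average(est: SpectralEstimate, band: str | tuple[float, float]) -> BandSummary:
    """Arithmetic mean of gain, phase and coherence over a band.

    Bins are included when their center frequency lies in [lo, hi).
    Phase is unwrapped across the band bins before averaging so a branch
    cut inside the band cannot bias the mean.
    """
    if isinstance(band, str):
        lo, hi = BANDS[band]
        name = band
    else:
        lo, hi = band
        name = f"[{lo},{hi})"
    mask = _band_slice(est, lo, hi)
    phase = np.unwrap(est.phase[mask]) if mask.sum() > 1 else est.phase[mask]
    return BandSummary(
        band=name,
        lo=lo,
        hi=hi,
        mean_gain=float(est.gain[mask].mean()),
        mean_phase=float(phase.mean()),
        mean_coherence=float(est.coherence[mask].mean()),
        n_bins=int(mask.sum()),
    )


def coherence_criterion(
    est: SpectralEstimate,
    band: str | tuple[float, float],
    alpha: float = 0.05,
) -> BandSummary:
    """Apply the coherence acceptance rule to a band summary.

    For L averaged windows the (1 - alpha) critical value of the
    magnitude-squared coherence of two incoherent signals is
    1 - alpha**(1/(L-1)); the band is accepted when its mean coherence
    reaches that level. Overlapped windows are counted as independent,
    the common practical convention.
    """
    if est.n_windows < 2:
        raise DataError("need at least 2 windows")
    summary = band_average(est, band)
    threshold = 1.0 - alpha ** (1.0 / (est.n_windows - 1))
    summary.coherence_threshold = float(threshold)
    summary.accepted = bool(summary.mean_coherence >= threshold)
    return summary
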