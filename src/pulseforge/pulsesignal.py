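"""Pulse-wave post-processing and heart-rate evaluation.

Everything downstream of a predicted blood-volume-pulse wave lives here:
zero-phase band-pass filtering, periodogram estimation, spectral-peak
heart-rate readout, the rPPG signal-to-noise ratio, the five evaluation
metrics (MAE, RMSE, MAPE, Pearson ρ, SNR) with Bland–Altman agreement
statistics, and the classical GREEN baseline used as a sanity reference.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .clipio import FrameClip

__all__ = [
    "SpectrumEstimate", "BlandAltman", "MetricReport",
    "bandpass", "power_spectrum", "estimate_hr", "snr_db",
    "hr_metrics", "green_baseline", "DEFAULT_BAND", "HR_NFFT",
]

DEFAULT_BAND = (0.6, 3.3)   # Hz, 36-198 BPM
HR_NFFT = 512               # zero-padded grid for the HR readout


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray
    power: np.ndarray
    method: str = "periodogram"

    def peak_frequency(self, band: tuple[float, float] | None = None) -> float:
        f, p = self.freqs, self.power
        if band is not None:
            sel = (f >= band[0]) & (f <= band[1])
            if not sel.any():
                raise ValueError(f"band {band} is empty on the spectral grid")
            f, p = f[sel], p[sel]
        if p.max() <= 0:
            raise ValueError("zero in-band power: spectral peak undefined")
        return float(f[int(np.argmax(p))])   # argmax takes the lowest tied bin


@dataclass
class BlandAltman:
    bias: float
    loa_low: float
    loa_high: float
    sd: float


@dataclass
class MetricReport:
    mae: float
    rmse: float
    mape: float
    rho: float          # NaN when undefined (constant references or n < 2)
    snr: float          # NaN when no per-clip SNR values were supplied
    bland_altman: BlandAltman
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:
        ba = self.bland_altman
        return (f"MAE {self.mae:.2f} | RMSE {self.rmse:.2f} | MAPE {self.mape:.2f}% | "
                f"rho {self.rho:.3f} | SNR {self.snr:.2f} dB | "
                f"bias {ba.bias:.2f} [{ba.loa_low:.2f}, {ba.loa_high:.2f}] | n={self.n}")


def _check_band(band, fps):
    lo, hi = band
    if not 0 < lo < hi < fps / 2:
        raise ValueError(f"band {band} Hz invalid for fps {fps}")


def bandpass(wave, fps: float, band: tuple[float, float] = DEFAULT_BAND,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward, SOS form)."""
    _check_band(band, fps)
    wave = np.asarray(wave, np.float64).ravel()
    # remove mean and linear trend first: both are outside the passband, and
    # on short windows they otherwise drive edge transients of the
    # forward-backward IIR filter that can dominate the output spectrum
    wave = sps.detrend(wave, type="linear")
    sos = sps.butter(order, band, btype="bandpass", fs=fps, output="sos")
    padlen = min(3 * (2 * order + 1), wave.size - 1)
    return sps.sosfiltfilt(sos, wave, padlen=padlen)


def power_spectrum(wave, fps: float, n_fft: int | None = None,
                   window: str = "boxcar") -> SpectrumEstimate:
    """One-sided periodogram (rectangular window by default, Parseval-scaled
    density).  ``window="hann"`` tames spectral leakage for off-grid tones."""
    wave = np.asarray(wave, np.float64).ravel()
    if wave.size < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    n_fft = n_fft or wave.size
    freqs, power = sps.periodogram(wave, fs=fps, nfft=max(n_fft, wave.size),
                                   window=window, detrend=False)
    return SpectrumEstimate(freqs=freqs, power=power, method=f"periodogram/{window}")


def estimate_hr(wave, fps: float, band: tuple[float, float] = DEFAULT_BAND,
                n_fft: int = HR_NFFT) -> float:
    """Heart rate in BPM: 60x the in-band periodogram peak frequency.

    The spectrum is zero-padded to ``n_fft`` bins so the readout grid is
    finer than the raw clip-length resolution; ties break toward the lower
    frequency.
    """
    _check_band(band, fps)
    wave = np.asarray(wave, np.float64).ravel()
    spec = power_spectrum(wave - wave.mean(), fps, n_fft=n_fft)
    return 60.0 * spec.peak_frequency(band)


def snr_db(wave, ref_hr: float, fps: float,
           band: tuple[float, float] = DEFAULT_BAND, half_width: float = 0.1,
           n_fft: int = HR_NFFT) -> float:
    """rPPG signal-to-noise ratio in dB.

    Power within ±``half_width`` Hz of the reference fundamental f = HR/60
    and of its first harmonic 2f, over the remaining power inside ``band``.
    """
    f0 = ref_hr / 60.0
    if not band[0] <= f0 <= band[1]:
        raise ValueError(f"reference HR {ref_hr} BPM outside band {band}")
    wave = np.asarray(wave, np.float64).ravel()
    # Hann window: off-grid tones keep their power inside the +-0.1 Hz
    # signal windows instead of leaking across the whole band
    spec = power_spectrum(wave - wave.mean(), fps, n_fft=n_fft, window="hann")
    f, p = spec.freqs, spec.power
    inband = (f >= band[0]) & (f <= band[1])
    sig = (np.abs(f - f0) <= half_width) | (np.abs(f - 2 * f0) <= half_width)
    sig &= inband
    p_sig = p[sig].sum()
    p_noise = p[inband & ~sig].sum()
    if p_noise <= 0:
        p_noise = np.finfo(float).tiny
    if p_sig <= 0:
        p_sig = np.finfo(float).tiny
    return float(10.0 * np.log10(p_sig / p_noise))


def hr_metrics(pred, ref, snr_values=None) -> MetricReport:
    """The five paper metrics plus Bland–Altman agreement over HR pairs.

    MAE = mean |Δ|, RMSE = sqrt(mean Δ²), MAPE = 100·mean |Δ|/ref,
    ρ = Pearson(pred, ref), bias = mean Δ, LoA = bias ± 1.96·SD(Δ)
    with Δ = pred − ref.  ``snr_values`` (optional, per clip) are averaged
    into the report's SNR field.
    """
    pred = np.asarray(pred, np.float64).ravel()
    ref = np.asarray(ref, np.float64).ravel()
    if pred.size != ref.size:
        raise ValueError(f"length mismatch: {pred.size} vs {ref.size}")
    if pred.size == 0:
        raise ValueError("need at least one HR pair")
    if (ref == 0).any():
        raise ValueError("reference HR of 0 BPM: MAPE undefined")
    delta = pred - ref
    mae = float(np.mean(np.abs(delta)))
    rmse = float(np.sqrt(np.mean(delta ** 2)))
    mape = float(100.0 * np.mean(np.abs(delta) / np.abs(ref)))
    if pred.size >= 2 and np.std(ref) > 0 and np.std(pred) > 0:
        rho = float(np.corrcoef(pred, ref)[0, 1])
    else:
        rho = float("nan")
    sd = float(np.std(delta, ddof=0))
    bias = float(np.mean(delta))
    ba = BlandAltman(bias=bias, loa_low=bias - 1.96 * sd,
                     loa_high=bias + 1.96 * sd, sd=sd)
    snr = float(np.mean(snr_values)) if snr_values is not None and len(snr_values) else float("nan")
    return MetricReport(mae=mae, rmse=rmse, mape=mape, rho=rho, snr=snr,
                        bland_altman=ba, n=int(pred.size))


def green_baseline(clip: FrameClip, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Classical GREEN pulse trace: per-frame spatial mean of the green
    channel, band-pass filtered."""
    if clip.frames.shape[1] != 3:
        raise ValueError("GREEN baseline needs a 3-channel clip")
    trace = clip.frames[:, 1].mean(axis=(1, 2))
    return bandpass(trace, clip.fps, band)
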