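"""Gamma-oscillation analysis of two-channel extracellular recordings.

Carbachol-induced slice oscillations (nominally 10 kHz sampling) are
mean-subtracted and band-pass filtered 8-100 Hz, power spectra are
estimated by Welch averaging with the peak restricted to the 18-50 Hz
gamma band, drug effects are expressed as within-experiment normalized
peak Vrms power, and synchrony between the deep and superficial channels
is measured by FFT cross-correlation with a signed millisecond lag.

Sign convention: a positive lag means the deep channel leads the
superficial channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.fft import fft, ifft, next_fast_len

__all__ = [
    "LfpRecording",
    "SpectrumResult",
    "XcorrResult",
    "GAMMA_BAND_HZ",
    "read_recording_csv",
    "write_recording_csv",
    "preprocess",
    "power_spectrum",
    "normalized_peak_power",
    "xcorr_fft",
    "xcorr_windowed",
]

GAMMA_BAND_HZ = (18.0, 50.0)
FILTER_BAND_HZ = (8.0, 100.0)


@dataclass
class LfpRecording:
    """Paired deep/superficial voltage series from one experiment."""

    channel_deep: np.ndarray
    channel_superficial: np.ndarray
    sampling_rate_hz: float = 10_000.0
    condition: str = "CCh"            # "CCh" baseline or "+WIN"
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        self.channel_deep = np.asarray(self.channel_deep, dtype=float)
        self.channel_superficial = np.asarray(self.channel_superficial, dtype=float)
        if len(self.channel_deep) != len(self.channel_superficial):
            raise ValueError("channels differ in length")


@dataclass
class SpectrumResult:
    freqs_hz: np.ndarray
    power: np.ndarray                 # Vrms^2 per bin (Welch 'spectrum' scaling)
    peak_freq_hz: float
    peak_power_vrms: float
    experiment_id: str | None = None


@dataclass
class XcorrResult:
    lags_ms: np.ndarray
    values: np.ndarray                # correlation, arbitrary units
    max_value: float
    lag_at_max_ms: float
    window: str = "full"


def write_recording_csv(rec: LfpRecording, path) -> None:
    """Two-channel CSV with a '#'-comment header (rate, condition, roles)."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rec.sampling_rate_hz}\n")
        fh.write(f"# condition={rec.condition}\n")
        fh.write(f"# experiment_id={rec.experiment_id or ''}\n")
        fh.write("deep,superficial\n")
        np.savetxt(
            fh,
            np.column_stack([rec.channel_deep, rec.channel_superficial]),
            fmt="%.9g", delimiter=",",
        )


def read_recording_csv(path) -> LfpRecording:
    header: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
    import pandas as pd

    data = pd.read_csv(path, comment="#")
    return LfpRecording(
        channel_deep=data["deep"].to_numpy(dtype=float),
        channel_superficial=data["superficial"].to_numpy(dtype=float),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        condition=header.get("condition", "CCh"),
        experiment_id=header.get("experiment_id") or None,
    )


def preprocess(
    x: np.ndarray,
    fs: float,
    band_hz: tuple = FILTER_BAND_HZ,
    order: int = 4,
) -> np.ndarray:
    """Mean subtraction then zero-phase Butterworth band-pass (8-100 Hz).

    The filter is applied forward-backward (zero phase) so the later lag
    estimates are not biased by filter delay.
    """
    if fs <= 200:
        raise ValueError("sampling rate must exceed 200 Hz")
    x = np.asarray(x, dtype=float)
    settle = int(3 * fs / band_hz[0])
    if len(x) < settle:
        raise ValueError(
            f"signal too short to filter: {len(x)} samples < {settle} "
            f"(3x settling length at {band_hz[0]} Hz)"
        )
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x - x.mean())


def power_spectrum(
    x: np.ndarray,
    fs: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    band_hz: tuple = GAMMA_BAND_HZ,
    experiment_id: str | None = None,
) -> SpectrumResult:
    """Welch averaged-periodogram estimate with the peak in the gamma band.

    Hann window, 1-s segments with 50% overlap by default (1 Hz resolution
    over the 18-50 Hz band).  ``power`` is in Vrms^2 per bin so the peak
    amplitude reports as Vrms.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if len(x) < 2 * nperseg:
        raise ValueError("signal shorter than two Welch segments")
    freqs, pxx = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), scaling="spectrum",
    )
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("no frequency bins inside the requested band")
    k = np.flatnonzero(in_band)[np.argmax(pxx[in_band])]
    return SpectrumResult(
        freqs_hz=freqs,
        power=pxx,
        peak_freq_hz=float(freqs[k]),
        peak_power_vrms=float(np.sqrt(pxx[k])),
        experiment_id=experiment_id,
    )


def normalized_peak_power(pre: SpectrumResult, post: SpectrumResult) -> float:
    """Within-experiment normalized peak power: post Vrms / pre Vrms.

    The peak bin is located in the pre (baseline) spectrum and the same
    frequency is read out in the post spectrum; spectra must come from the
    same experiment.
    """
    if pre.experiment_id != post.experiment_id:
        raise ValueError(
            f"spectra from different experiments: {pre.experiment_id!r} vs {post.experiment_id!r}"
        )
    if len(pre.freqs_hz) != len(post.freqs_hz) or not np.allclose(pre.freqs_hz, post.freqs_hz):
        raise ValueError("spectra on different frequency grids")
    k = int(np.argmin(np.abs(pre.freqs_hz - pre.peak_freq_hz)))
    return float(np.sqrt(post.power[k]) / np.sqrt(pre.power[k]))


def xcorr_fft(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    max_lag_ms: float = 25.0,
    circular: bool = False,
) -> XcorrResult:
    """Cross-correlation via the frequency domain, peak within |lag| <= max.

    ``x`` is the deep channel and ``y`` the superficial channel; positive
    lag at the peak means the deep channel leads.  Zero padding gives
    linear (non-wrapping) correlation by default; ``circular=True``
    switches to strict circular correlation.  Exact peak ties resolve to
    the smallest |lag|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    max_lag = int(round(max_lag_ms * fs / 1e3))
    if max_lag >= n:
        raise ValueError("max lag exceeds the signal length")
    nfft = n if circular else next_fast_len(2 * n - 1)
    # c[k] = sum_n y[n] x[n-k]: peak at positive k when y is a delayed copy
    # of x, i.e. when the deep channel leads.
    c = ifft(fft(y, nfft) * np.conj(fft(x, nfft))).real
    values = np.concatenate([c[nfft - max_lag:], c[: max_lag + 1]])
    lags_ms = np.arange(-max_lag, max_lag + 1) / fs * 1e3
    peak = values.max()
    ties = np.flatnonzero(values == peak)
    best = ties[np.argmin(np.abs(lags_ms[ties]))]
    return XcorrResult(
        lags_ms=lags_ms,
        values=values,
        max_value=float(peak),
        lag_at_max_ms=float(lags_ms[best]),
        window="circular" if circular else "linear",
    )


def xcorr_windowed(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    max_lag_ms: float = 25.0,
) -> XcorrResult:
    """Cross-correlation averaged over consecutive windows of the recording.

    The correlation curves of non-overlapping ``window_s`` windows are
    averaged before the peak is taken, mirroring analysis on 1-s samples of
    an ongoing oscillation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    w = int(round(window_s * fs))
    n_win = len(x) // w
    if n_win < 1:
        raise ValueError("recording shorter than one analysis window")
    acc = None
    for i in range(n_win):
        r = xcorr_fft(x[i * w:(i + 1) * w], y[i * w:(i + 1) * w], fs, max_lag_ms)
        acc = r.values if acc is None else acc + r.values
    values = acc / n_win
    peak = values.max()
    ties = np.flatnonzero(values == peak)
    best = ties[np.argmin(np.abs(r.lags_ms[ties]))]
    return XcorrResult(
        lags_ms=r.lags_ms,
        values=values,
        max_value=float(peak),
        lag_at_max_ms=float(r.lags_ms[best]),
        window=f"{n_win} x {window_s:g} s",
    )
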