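"""Intrinsic-property extraction and synaptic-pharmacology outcomes.

Current-clamp sweeps yield the eight features used for physiological
clustering (resting membrane potential, sag index, input resistance, spike
threshold/amplitude/AHP, adaptation ratio, firing rate at twice threshold
current).  Voltage-clamp event series yield the wash-in percent-of-baseline
statistic, its inclusion rule, and the feedforward inhibition:excitation
ratio with monosynaptic subtraction.

Conventions (configurable where noted): spike threshold is the membrane
voltage at the first upward crossing of dV/dt >= 20 mV/ms; AHP is measured
as a positive magnitude, threshold minus the minimum within 20 ms of the
peak; the adaptation ratio is the last inter-spike interval over the first;
sag steady state is the mean of the last 20% of the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sweep",
    "IntrinsicProfile",
    "WashinSeries",
    "FeedforwardResult",
    "read_sweep_csv",
    "write_sweep_csv",
    "resting_membrane_potential",
    "sag_index",
    "input_resistance",
    "spike_train_features",
    "series_resistance_qc",
    "washin_percent_of_baseline",
    "washin_inclusion",
    "ie_ratio",
]


@dataclass
class Sweep:
    """One acquisition sweep with its stimulus description.

    ``samples`` are mV in current clamp (pA in voltage clamp);
    ``stim_amplitude`` is the step amplitude in pA (current clamp).
    """

    samples: np.ndarray
    sampling_rate_hz: float
    stim_onset_s: float
    stim_offset_s: float
    stim_amplitude: float
    units: str = "mV"
    holding: float | None = None
    sweep_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sweep contains non-finite samples")
        dur = len(self.samples) / self.sampling_rate_hz
        if not (0 <= self.stim_onset_s < self.stim_offset_s <= dur + 1e-9):
            raise ValueError("stimulus window must lie within the record")

    def _idx(self, t: float) -> int:
        return int(round(t * self.sampling_rate_hz))

    @property
    def baseline(self) -> np.ndarray:
        return self.samples[: self._idx(self.stim_onset_s)]

    @property
    def during_step(self) -> np.ndarray:
        return self.samples[self._idx(self.stim_onset_s): self._idx(self.stim_offset_s)]


@dataclass
class IntrinsicProfile:
    """The eight features entering physiological clustering (NaN = unmeasured)."""

    rmp_mV: float = float("nan")
    sag_index: float = float("nan")
    rin_MOhm: float = float("nan")
    spike_threshold_mV: float = float("nan")
    spike_amplitude_mV: float = float("nan")
    ahp_mV: float = float("nan")
    adaptation_ratio: float = float("nan")
    f_2x_Hz: float = float("nan")


def write_sweep_csv(sweep: Sweep, path) -> None:
    """One sample column with a '#'-comment sidecar header."""
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={sweep.sampling_rate_hz}\n")
        fh.write(f"# units={sweep.units}\n")
        fh.write(f"# stim_onset_s={sweep.stim_onset_s}\n")
        fh.write(f"# stim_offset_s={sweep.stim_offset_s}\n")
        fh.write(f"# stim_amplitude={sweep.stim_amplitude}\n")
        fh.write("sample\n")
        np.savetxt(fh, sweep.samples, fmt="%.9g")


def read_sweep_csv(path) -> Sweep:
    header: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = val.strip()
    import pandas as pd

    samples = pd.read_csv(path, comment="#")["sample"].to_numpy(dtype=float)
    return Sweep(
        samples=np.atleast_1d(samples),
        sampling_rate_hz=float(header["sampling_rate_hz"]),
        stim_onset_s=float(header["stim_onset_s"]),
        stim_offset_s=float(header["stim_offset_s"]),
        stim_amplitude=float(header["stim_amplitude"]),
        units=header.get("units", "mV"),
    )


def resting_membrane_potential(sweep: Sweep, min_baseline_s: float = 0.1) -> float:
    """Mean of the pre-stimulus zero-current baseline (>= 100 ms required)."""
    if sweep.stim_onset_s < min_baseline_s:
        raise ValueError(
            f"need a >= {min_baseline_s * 1e3:.0f} ms zero-current baseline before the step"
        )
    return float(sweep.baseline.mean())


def sag_index(sweep: Sweep, steady_frac: float = 0.2) -> float:
    """Sag index of a hyperpolarizing step: dV_ss / dV_peak, in (0, 1].

    dV_peak = baseline - minimum during the step; dV_ss = baseline - mean of
    the last ``steady_frac`` of the step.  Values closer to 1 mean less sag;
    a pure RC response gives 1.  Clipped at 1 against numerical noise.
    """
    if sweep.stim_amplitude >= 0:
        raise ValueError("sag index requires a hyperpolarizing (negative) step")
    base = float(sweep.baseline.mean())
    step = sweep.during_step
    n_ss = max(1, int(round(steady_frac * len(step))))
    dv_peak = base - float(step.min())
    dv_ss = base - float(step[-n_ss:].mean())
    if dv_peak <= 0:
        raise ValueError("no hyperpolarizing deflection found during the step")
    return min(1.0, dv_ss / dv_peak)


def input_resistance(sweeps, steady_frac: float = 0.2) -> float:
    """Input resistance in MOhm from steady-state dV vs dI.

    Least-squares slope through the origin over the supplied hyperpolarizing
    steps; a single sweep reduces to dV/dI.
    """
    sweeps = [sweeps] if isinstance(sweeps, Sweep) else list(sweeps)
    if not sweeps:
        raise ValueError("need at least one sweep")
    dv, di = [], []
    for sw in sweeps:
        if sw.stim_amplitude == 0:
            raise ValueError("zero step amplitude")
        base = float(sw.baseline.mean())
        step = sw.during_step
        n_ss = max(1, int(round(steady_frac * len(step))))
        dv.append(float(step[-n_ss:].mean()) - base)   # mV
        di.append(sw.stim_amplitude)                    # pA
    dv, di = np.array(dv), np.array(di)
    slope = float(np.sum(dv * di) / np.sum(di * di))    # mV/pA = GOhm
    return slope * 1e3


def _detect_spikes(v: np.ndarray, fs: float, dvdt_thresh: float, refractory_ms: float = 2.0):
    """Spike onsets by dV/dt threshold crossing.

    Returns (threshold_indices, peak_indices); the threshold index is the
    sample *before* the first backward difference reaching the criterion,
    i.e. the last sample on the subthreshold side.
    """
    dt_ms = 1e3 / fs
    dvdt = np.diff(v) / dt_ms                           # mV/ms, dvdt[i] = slope into i+1
    above = dvdt >= dvdt_thresh
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    onsets = onsets[onsets > 0]
    refr = int(round(refractory_ms / dt_ms))
    kept: list[int] = []
    for i in onsets:
        if not kept or i - kept[-1] > refr:
            kept.append(int(i))
    peaks = []
    for j, i in enumerate(kept):
        stop = kept[j + 1] if j + 1 < len(kept) else len(v)
        peaks.append(i + int(np.argmax(v[i:stop])))
    return kept, peaks


def spike_train_features(
    sweep: Sweep,
    rheobase_pA: float | None = None,
    dvdt_thresh: float = 20.0,
    ahp_window_ms: float = 20.0,
) -> IntrinsicProfile:
    """Spike features from the sweep at twice rheobase current.

    threshold = V at the first dV/dt crossing (first spike reported);
    amplitude = peak - threshold; AHP = threshold - post-peak minimum
    (positive magnitude); adaptation = last ISI / first ISI; f_2x = spike
    count / step duration.  Fewer than one spike leaves all features NaN;
    fewer than two leaves the adaptation ratio NaN.
    """
    fs = sweep.sampling_rate_hz
    lo, hi = sweep._idx(sweep.stim_onset_s), sweep._idx(sweep.stim_offset_s)
    v = sweep.samples
    all_onsets, all_peaks = _detect_spikes(v, fs, dvdt_thresh)
    in_step = [(i, p) for i, p in zip(all_onsets, all_peaks) if lo <= i < hi]
    onsets = [i for i, _ in in_step]
    peaks = [p for _, p in in_step]
    prof = IntrinsicProfile()
    step_dur = (hi - lo) / fs
    prof.f_2x_Hz = len(onsets) / step_dur
    if not onsets:
        return prof
    i0, p0 = onsets[0], peaks[0]
    thr = float(v[i0])
    prof.spike_threshold_mV = thr
    prof.spike_amplitude_mV = float(v[p0]) - thr
    w = int(round(ahp_window_ms * fs / 1e3))
    prof.ahp_mV = thr - float(v[p0 + 1: p0 + 1 + w].min()) if p0 + 1 < len(v) else float("nan")
    if len(peaks) >= 2:
        isis = np.diff(np.array(peaks)) / fs
        prof.adaptation_ratio = float(isis[-1] / isis[0])
    return prof


def series_resistance_qc(sr_values, max_change_pct: float = 30.0):
    """Series-resistance stability rule: fail when (max-min)/min exceeds 30%.

    Returns (passed: bool, percent_change: float).
    """
    sr = np.asarray(list(sr_values), dtype=float)
    if len(sr) < 2:
        raise ValueError("need >= 2 series-resistance measurements")
    if np.any(sr <= 0):
        raise ValueError("non-positive series resistance")
    pct = float((sr.max() - sr.min()) / sr.min() * 100.0)
    return pct <= max_change_pct, pct


@dataclass
class WashinSeries:
    """Evoked-event amplitude time course around a drug wash-in.

    Times are minutes relative to drug onset (0); amplitudes are positive
    magnitudes in pA.  The assay window follows the quantification
    convention of reading out 10-12 min after application (inclusive).
    """

    event_times_min: np.ndarray
    amplitudes_pA: np.ndarray
    baseline_window_min: tuple = (-5.0, 0.0)
    assay_window_min: tuple = (10.0, 12.0)
    drug_label: str = ""
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.event_times_min = np.asarray(self.event_times_min, dtype=float)
        self.amplitudes_pA = np.asarray(self.amplitudes_pA, dtype=float)
        if len(self.event_times_min) != len(self.amplitudes_pA):
            raise ValueError("times and amplitudes differ in length")
        if np.any(self.amplitudes_pA < 0):
            raise ValueError("amplitudes must be magnitudes (>= 0)")
        if self.baseline_window_min[1] > 0:
            raise ValueError("baseline window must precede drug onset (t = 0)")

    def _window(self, lo: float, hi: float) -> np.ndarray:
        m = (self.event_times_min >= lo) & (self.event_times_min <= hi)
        return self.amplitudes_pA[m]


def washin_percent_of_baseline(series: WashinSeries, min_events: int = 3) -> float:
    """Post-drug amplitude as percent of baseline.

    100 x mean(amplitudes in the assay window) / mean(baseline amplitudes).
    """
    base = series._window(*series.baseline_window_min)
    assay = series._window(*series.assay_window_min)
    if len(base) < min_events or len(assay) < min_events:
        raise ValueError(
            f"need >= {min_events} events in each window "
            f"(got {len(base)} baseline, {len(assay)} assay)"
        )
    return 100.0 * float(assay.mean()) / float(base.mean())


def washin_inclusion(series: WashinSeries, min_reduction_pct: float = 30.0) -> bool:
    """Inclusion rule: the experiment counts only if the drug reduced events
    by at least ``min_reduction_pct`` (the boundary itself is included)."""
    return washin_percent_of_baseline(series) <= 100.0 - min_reduction_pct


@dataclass
class FeedforwardResult:
    epsc_amp_pA: float
    ipsc_total_pA: float
    ipsc_mono_pA: float | None
    ie_ratio: float = field(init=False)

    def __post_init__(self) -> None:
        mono = self.ipsc_mono_pA
        if self.epsc_amp_pA <= 0:
            raise ValueError("EPSC amplitude must be positive")
        if min(self.ipsc_total_pA, mono if mono is not None else 0.0) < 0:
            raise ValueError("amplitudes must be magnitudes (>= 0)")
        if mono is not None and mono > self.ipsc_total_pA:
            raise ValueError("monosynaptic IPSC exceeds total IPSC")
        disyn = self.ipsc_total_pA - (mono or 0.0)
        self.ie_ratio = disyn / self.epsc_amp_pA


def ie_ratio(
    epsc_amp: float, ipsc_total: float, ipsc_mono: float | None = None
) -> FeedforwardResult:
    """Feedforward inhibition:excitation ratio.

    The disynaptic IPSC is the total minus the monosynaptic component
    measured after glutamate blockade; when no monosynaptic measurement
    exists (the pooled CA3-stimulation case) the total is used directly.
    """
    return FeedforwardResult(epsc_amp, ipsc_total, ipsc_mono)
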