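"""Spike-phase locking (SPL) and spike-triggered average (STA) LFP.

The SPL index is the resultant vector length of the unit phasors of spike
phases relative to a band-limited oscillation: 0 for spikes spread
homogeneously over phases, 1 for spikes at a single phase.  The STA is the
mean z-scored LFP within +/-100 ms of each spike, with a slope statistic
|V_peak - V_trough| / |t_peak - t_trough| measured on the falling flank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.signal import butter, filtfilt, hilbert

from .spectral import BETA_BAND

__all__ = [
    "SpikePhaseSet",
    "STAWaveform",
    "band_phase",
    "spike_phases",
    "spl_index",
    "spike_triggered_average",
]

FloatArray = NDArray[np.float64]

STA_WINDOW_MS = 100.0


@dataclass
class SpikePhaseSet:
    phases: FloatArray              # radians in [-pi, pi], one per spike
    band: tuple[float, float]       # Hz

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if len(self.phases) and np.any(np.abs(self.phases) > np.pi + 1e-9):
            raise ValueError("phases must lie in [-pi, pi]")


@dataclass
class STAWaveform:
    lags: FloatArray                # ms, -100..+100
    waveform: FloatArray            # mean z-scored LFP
    n_spikes: int
    slope: float                    # |Vpeak - Vtrough| / |tpeak - ttrough|
    clear_peak: bool                # False when excluded by the peak criterion


def band_phase(lfp: FloatArray, fs: float,
               band: tuple[float, float] = BETA_BAND,
               order: int = 3) -> FloatArray:
    """Instantaneous Hilbert phase of the band-filtered signal (zero-phase
    Butterworth band-pass)."""
    x = np.asarray(lfp, dtype=float)
    b, a = butter(order, [band[0] / (fs / 2), band[1] / (fs / 2)],
                  btype="band")
    xf = filtfilt(b, a, x - x.mean())
    return np.angle(hilbert(xf))


def spike_phases(spike_times: FloatArray, phase: FloatArray, fs: float,
                 band: tuple[float, float] = BETA_BAND) -> SpikePhaseSet:
    """Oscillation phase at each spike time.

    ``phase`` is the wrapped Hilbert phase of the band-limited LFP sampled
    at ``fs``; spike times (ms) are mapped to phases by linear interpolation
    of the unwrapped phase and re-wrapped, so millisecond spike times work
    with 1 kHz LFP.  Spikes outside the LFP support raise.
    """
    t = np.asarray(spike_times, dtype=float)
    lfp_t = np.arange(len(phase)) * 1000.0 / fs
    if len(t) and (t.min() < lfp_t[0] or t.max() > lfp_t[-1]):
        raise ValueError("spike outside the LFP time support")
    unwrapped = np.unwrap(np.asarray(phase, dtype=float))
    ph = np.interp(t, lfp_t, unwrapped)
    return SpikePhaseSet(np.angle(np.exp(1j * ph)), band)


def spl_index(phases: SpikePhaseSet | FloatArray) -> tuple[float, float]:
    """Spike-phase-locking index: (resultant length, circular mean angle).

    The resultant length of the unit phasors lies in [0, 1]; 1 means all
    spikes at one phase, 0 a perfectly balanced phase distribution.
    """
    ph = phases.phases if isinstance(phases, SpikePhaseSet) else \
        np.asarray(phases, dtype=float)
    if len(ph) == 0:
        raise ValueError("SPL undefined without spikes")
    z = np.exp(1j * ph).mean()
    return float(np.abs(z)), float(np.angle(z))


def spike_triggered_average(lfp_trials, spike_trials, fs: float,
                            window_ms: float = STA_WINDOW_MS,
                            peak_criterion: float = 2.0,
                            tail_ms: float = 75.0) -> STAWaveform:
    """Spike-triggered average of the z-scored LFP with its slope statistic.

    For each trial the LFP samples within ``window_ms`` of any spike are
    z-scored (per trial, across the timepoints entering the STA), spike-
    aligned segments are averaged within the trial, and trial STAs averaged.
    Only spikes with the full +/-window context contribute.  The slope is
    |V_peak - V_trough| / |t_peak - t_trough| between the global extrema of
    the mean waveform (the falling flank of the oscillation the spike rides).
    Waveforms whose peak-to-trough amplitude is below ``peak_criterion``
    times the standard deviation of the waveform tails (|lag| > ``tail_ms``)
    are flagged as lacking a clear peak (``clear_peak=False``), mirroring the
    exclusion of low-contrast STAs.
    """
    w = int(round(window_ms * fs / 1000.0))
    lags = np.arange(-w, w + 1) * 1000.0 / fs
    trial_stas = []
    n_spikes = 0
    for lfp, spikes in zip(lfp_trials, spike_trials):
        x = np.asarray(lfp, dtype=float)
        st = np.asarray(spikes, dtype=float)
        centers = np.round(st * fs / 1000.0).astype(int)
        centers = centers[(centers - w >= 0) & (centers + w < len(x))]
        if len(centers) == 0:
            continue
        # z-score across the timepoints within the window of any spike
        mask = np.zeros(len(x), dtype=bool)
        for c in centers:
            mask[c - w:c + w + 1] = True
        mu, sd = x[mask].mean(), x[mask].std()
        if sd == 0:
            continue
        z = (x - mu) / sd
        segs = np.stack([z[c - w:c + w + 1] for c in centers])
        trial_stas.append(segs.mean(axis=0))
        n_spikes += len(centers)
    if n_spikes == 0:
        raise ValueError("no spikes with full STA context")
    wave = np.mean(trial_stas, axis=0)

    i_peak = int(np.argmax(wave))
    i_trough = int(np.argmin(wave))
    dt = abs(lags[i_peak] - lags[i_trough])
    slope = abs(wave[i_peak] - wave[i_trough]) / dt if dt > 0 else np.nan
    tails = wave[np.abs(lags) > tail_ms]
    clear = bool(wave[i_peak] - wave[i_trough]
                 > peak_criterion * tails.std()) if len(tails) > 2 else True
    return STAWaveform(lags=lags, waveform=wave, n_spikes=n_spikes,
                       slope=float(slope), clear_peak=clear)
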