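"""LFP spectral analysis: multitaper power spectra and beta-band measures.

Power spectral densities use the multitaper method with 3 DPSS (Slepian)
tapers (time-bandwidth product NW = 2), computed per trial and averaged.
Population-style statistics operate on min-max normalized spectra; the beta
band is 14-22 Hz throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.signal.windows import dpss
from scipy.stats import pearsonr

from .synthetic import TrialSet

__all__ = [
    "PowerSpectrum",
    "BETA_BAND",
    "DELAY_WINDOW",
    "multitaper_psd",
    "normalize_and_bandpower",
    "peak_frequency",
    "subsample_freq_rate",
]

FloatArray = NDArray[np.float64]

BETA_BAND = (14.0, 22.0)
#: default analysis window: last 700 ms of the delay epoch (ms, in-trial)
DELAY_WINDOW = (1100.0, 1800.0)


@dataclass
class PowerSpectrum:
    freqs: FloatArray               # Hz
    power: FloatArray               # a.u./Hz (raw) or [0,1] (minmax)
    n_tapers: int = 3
    normalization: str = "raw"      # "raw" | "minmax"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.normalization == "raw" and np.any(self.power < 0):
            raise ValueError("raw power must be nonnegative")


def _mt_psd_single(x: FloatArray, fs: float, tapers: FloatArray,
                   eigvals: FloatArray, nfft: int) -> FloatArray:
    x = x - x.mean()
    spec = np.fft.rfft(tapers * x[None, :], n=nfft, axis=1)
    psd = (np.abs(spec) ** 2) / fs
    # one-sided: double all bins except DC (and Nyquist if present)
    psd[:, 1:] *= 2.0
    if nfft % 2 == 0:
        psd[:, -1] /= 2.0
    return np.average(psd, axis=0, weights=eigvals)


def multitaper_psd(trials, fs: float | None = None,
                   window: tuple[float, float] = DELAY_WINDOW,
                   n_tapers: int = 3, nw: float = 2.0,
                   nfft: int | None = None) -> PowerSpectrum:
    """Trial-averaged multitaper PSD of an LFP window.

    ``trials`` is a :class:`~phasecode.synthetic.TrialSet`, a list of
    :class:`~phasecode.synthetic.LFPTrace`, or a 2-D array (trials x time,
    requires ``fs``).  The window (ms) is cut from each trial; it must span
    at least two cycles of the lowest beta-band frequency.  Spectra are
    eigenvalue-weighted over ``n_tapers`` DPSS tapers, zero-padded to
    ``nfft`` (default: 4x the window length rounded up to a power of two,
    for sub-bin peak localization) and averaged across trials.
    """
    if isinstance(trials, TrialSet):
        fs = trials.trials[0].lfp.fs
        segs = [tr.lfp.samples for tr in trials]
    elif hasattr(trials, "ndim"):
        if fs is None:
            raise ValueError("fs required for array input")
        segs = list(np.atleast_2d(np.asarray(trials, dtype=float)))
    else:
        segs = [tr.samples for tr in trials]
        fs = fs or trials[0].fs
    if len(segs) == 0:
        raise ValueError("need at least one trial")

    i0 = int(round(window[0] * fs / 1000.0))
    i1 = int(round(window[1] * fs / 1000.0))
    length = i1 - i0
    min_len = int(2 * fs / BETA_BAND[0])
    if length < min_len:
        raise ValueError(
            f"window of {length} samples is shorter than two cycles of "
            f"{BETA_BAND[0]} Hz ({min_len} samples)")
    if nfft is None:
        nfft = int(2 ** np.ceil(np.log2(4 * length)))
    tapers, eigvals = dpss(length, nw, n_tapers, return_ratios=True)
    psds = []
    for s in segs:
        if len(s) < i1:
            raise ValueError("trial shorter than the analysis window")
        psds.append(_mt_psd_single(np.asarray(s[i0:i1], dtype=float), fs,
                                   tapers, eigvals, nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return PowerSpectrum(freqs=freqs, power=np.mean(psds, axis=0),
                         n_tapers=n_tapers, normalization="raw")


def normalize_and_bandpower(spec: PowerSpectrum,
                            band: tuple[float, float] = BETA_BAND
                            ) -> tuple[PowerSpectrum, float]:
    """Min-max normalize a spectrum and return the mean power in ``band``.

    Normalization maps the minimum to 0 and maximum to 1 ((X-min)/(max-min));
    band power is the mean of the normalized power over ``band`` inclusive.
    """
    lo, hi = spec.power.min(), spec.power.max()
    if hi <= lo:
        raise ValueError("constant spectrum cannot be min-max normalized")
    norm = (spec.power - lo) / (hi - lo)
    out = PowerSpectrum(spec.freqs, norm, spec.n_tapers, "minmax")
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    if not sel.any():
        raise ValueError("band contains no frequency bins")
    return out, float(norm[sel].mean())


def peak_frequency(spec: PowerSpectrum,
                   band: tuple[float, float] = BETA_BAND) -> float:
    """Frequency of maximum power within ``band``; ties break low."""
    sel = np.where((spec.freqs >= band[0]) & (spec.freqs <= band[1]))[0]
    if len(sel) == 0:
        raise ValueError("band contains no frequency bins")
    p = spec.power[sel]
    return float(spec.freqs[sel[np.argmax(p)]])   # argmax: first max = lowest


def subsample_freq_rate(trials: TrialSet, n_subsamples: int = 100,
                        fraction: float = 0.5, seed: int = 0,
                        window: tuple[float, float] = DELAY_WINDOW,
                        band: tuple[float, float] = BETA_BAND):
    """Peak-frequency / normalized-rate pairs over trial subsamples.

    Draws ``n_subsamples`` random subsets of ``fraction`` of the trials
    (without replacement within each subsample), and for each computes the
    beta peak frequency of the subsample-average spectrum and the mean
    delay-window firing rate normalized by the across-all-trials mean.
    Returns ``(pairs, r, p)`` with ``pairs`` an (n_subsamples, 2) array.
    """
    n = len(trials)
    if n < 10:
        raise ValueError("need at least 10 trials")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    k = int(round(fraction * n))
    if k >= n:
        raise ValueError("fraction leaves no trial variability; every "
                         "subsample would be identical")
    rng = np.random.default_rng(seed)
    fs = trials.trials[0].lfp.fs

    win_len_s = (window[1] - window[0]) / 1000.0
    rates = np.array([
        np.sum((tr.spikes.times >= window[0])
               & (tr.spikes.times < window[1])) / win_len_s
        for tr in trials])
    mean_rate = rates.mean()
    if mean_rate == 0:
        raise ValueError("no spikes in the analysis window")

    pairs = np.empty((n_subsamples, 2))
    for s in range(n_subsamples):
        idx = rng.choice(n, size=k, replace=False)
        sub = TrialSet([trials.trials[i] for i in idx])
        spec = multitaper_psd(sub, window=window)
        pairs[s, 0] = peak_frequency(spec, band)
        pairs[s, 1] = rates[idx].mean() / mean_rate
    if np.std(pairs[:, 0]) == 0 or np.std(pairs[:, 1]) == 0:
        raise ValueError("zero variance across subsamples")
    r, p = pearsonr(pairs[:, 0], pairs[:, 1])
    return pairs, float(r), float(p)
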