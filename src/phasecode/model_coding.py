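"""Phase-code and rate-code information measures for neural field runs.

The LFP proxy of a field simulation is segmented into oscillation cycles via
its Hilbert phase.  For every cycle and every decoding location ``theta`` the
cycle yields

* a spike-count (rate-code) distribution: Poisson with mean ``lambda_theta T``
  where ``lambda_theta`` is the cycle-averaged rate at that location, and
* a phase-code density ``q_theta(phi)`` obtained from the rate waveform by the
  change of variables ``t = g(phi)`` between time and Hilbert phase,
  ``q_theta(phi) = u(theta, g(phi)) g'(phi) / (lambda_theta T)``.

Two summary statistics compare the codes at the default decoding locations
``theta = pi/2`` (the stimulated orientation) and ``pi/4``: the information
gain (KL divergence, nats) between the two locations' distributions, and the
two-stimulus mutual information (Jensen-Shannon divergence, bits).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.signal import hilbert
from scipy.stats import linregress, pearsonr, poisson

from .field_model import FieldParams, FieldTrace, InputSpec, simulate_field

__all__ = [
    "CycleSet",
    "PhaseDensity",
    "CountDensity",
    "extract_cycles",
    "phase_density",
    "count_density",
    "kl_info_gain",
    "stim_mutual_info",
    "cycle_information",
    "wm_contrast_sweep",
    "frequency_decile_info",
    "freq_rate_correlation",
]

FloatArray = NDArray[np.float64]

DEFAULT_LOCATIONS = (np.pi / 2.0, np.pi / 4.0)
DENSITY_FLOOR = 1e-12


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------

@dataclass
class PhaseDensity:
    """Normalized phase density q(phi) on a uniform grid over [-pi, pi]."""

    phi: FloatArray
    q: FloatArray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if np.any(self.q < 0):
            raise ValueError("phase density must be nonnegative")

    def integral(self) -> float:
        return float(np.trapezoid(self.q, self.phi))

    def normalized(self) -> "PhaseDensity":
        z = self.integral()
        if z <= 0:
            raise ValueError("cannot normalize a zero density")
        return PhaseDensity(self.phi, self.q / z)


@dataclass
class CountDensity:
    """Truncated Poisson spike-count distribution p(n), n = 0..n_max."""

    p: FloatArray
    mean: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("count probabilities must be nonnegative")

    @property
    def n(self) -> NDArray[np.int_]:
        return np.arange(len(self.p))


def count_density(lam: float, T: float, n_max: int | None = None,
                  tail: float = 1e-9) -> CountDensity:
    """Poisson count distribution for rate ``lam`` (Hz) over window ``T`` (ms).

    The support is truncated at ``n_max`` chosen so the discarded tail mass is
    below ``tail`` (default 1e-9).
    """
    if lam < 0:
        raise ValueError("rate must be >= 0")
    mu = lam * T / 1000.0
    if n_max is None:
        n_max = int(poisson.ppf(1.0 - tail * 1e-3, mu)) + 2 if mu > 0 else 0
    n = np.arange(n_max + 1)
    p = poisson.pmf(n, mu)
    if 1.0 - p.sum() > tail:
        raise ValueError("truncation tail exceeds tolerance; raise n_max")
    return CountDensity(p=p, mean=mu)


# --------------------------------------------------------------------------
# cycle extraction
# --------------------------------------------------------------------------

@dataclass
class CycleSet:
    """Per-cycle records from one field simulation.

    ``phase_rate[i, j]`` holds the rate waveform of decoding location ``j``
    resampled onto the common phase grid ``phi`` for cycle ``i``, and
    ``dgdphi`` the corresponding time-per-phase Jacobian ``g'(phi)`` (ms/rad).
    """

    start: FloatArray             # ms
    end: FloatArray               # ms
    period: FloatArray            # ms
    freq: FloatArray              # Hz, = 1000 / period
    locations: FloatArray         # decoding thetas
    mean_rate: FloatArray         # (n_cycles, n_loc) Hz
    mean_lfp: FloatArray          # (n_cycles,) cycle-mean of the LFP proxy
    amplitude: FloatArray         # (n_cycles,) peak-to-trough LFP amplitude
    phi: FloatArray               # phase grid over [-pi, pi]
    phase_rate: FloatArray        # (n_cycles, n_loc, n_phi)
    dgdphi: FloatArray            # (n_cycles, n_phi)
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.period)

    def subset(self, idx) -> "CycleSet":
        idx = np.asarray(idx)
        return CycleSet(self.start[idx], self.end[idx], self.period[idx],
                        self.freq[idx], self.locations, self.mean_rate[idx],
                        self.mean_lfp[idx], self.amplitude[idx], self.phi,
                        self.phase_rate[idx], self.dgdphi[idx],
                        dict(self.meta))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("start", "end", "period", "freq", "locations",
                         "mean_rate", "mean_lfp", "amplitude", "phi",
                         "phase_rate", "dgdphi"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path) -> "CycleSet":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in
                  ("start", "end", "period", "freq", "locations",
                   "mean_rate", "mean_lfp", "amplitude", "phi",
                   "phase_rate", "dgdphi")}
        return cls(**kw)


def _location_columns(trace: FieldTrace, locations) -> NDArray[np.int_]:
    """Nearest orientation-grid column for each decoding location."""
    theta = trace.theta
    return np.array([int(np.argmin(np.abs(np.angle(
        np.exp(2j * (theta - loc))) / 2.0))) for loc in locations])


def extract_cycles(trace: FieldTrace, locations=DEFAULT_LOCATIONS,
                   n_phi: int = 256, min_period: float = 20.0,
                   max_period: float = 120.0) -> CycleSet:
    """Segment the LFP proxy into oscillation cycles via its Hilbert phase.

    Cycle boundaries sit at the -pi -> pi wrap of the Hilbert phase of the
    mean-removed LFP proxy.  For every cycle and decoding location the rate
    waveform is resampled onto a fixed phase grid by inverting the (locally
    monotone) unwrapped phase, giving the change-of-variables function
    ``g(phi)`` and its derivative.  Cycles with implausible periods (outside
    ``[min_period, max_period]`` ms) are dropped; at least two phase wraps
    are required.
    """
    lfp = trace.lfp - trace.lfp.mean()
    if np.ptp(lfp) == 0:
        raise ValueError("constant LFP proxy has no oscillation cycles")
    phase = np.unwrap(np.angle(hilbert(lfp)))
    t = trace.time
    # boundaries: unwrapped phase crossing odd multiples of pi
    k_lo = int(np.ceil((phase[0] - np.pi) / (2 * np.pi)))
    k_hi = int(np.floor((phase[-1] - np.pi) / (2 * np.pi)))
    if k_hi - k_lo < 1:
        raise ValueError("fewer than two phase wraps in trace")
    targets = np.pi + 2 * np.pi * np.arange(k_lo, k_hi + 1)
    # phase is not strictly monotone sample-to-sample under noise; use the
    # running maximum for a well-defined inverse
    mono = np.maximum.accumulate(phase)
    bound_t = np.interp(targets, mono, t)

    cols = _location_columns(trace, locations)
    phi_grid = np.linspace(-np.pi, np.pi, n_phi)

    starts, ends, periods = [], [], []
    mean_rate, mean_lfp, amplitude, phase_rate, dgdphi = [], [], [], [], []
    for b0, b1, k in zip(bound_t[:-1], bound_t[1:],
                         range(k_lo, k_hi)):
        T = b1 - b0
        if not (min_period <= T <= max_period):
            continue
        sel = (t >= b0) & (t <= b1)
        if sel.sum() < 8:
            continue
        # invert g: times at which phase passes each phi on the grid
        targ = phi_grid + 2 * np.pi * k + 2 * np.pi   # wrap k -> next cycle
        g = np.interp(targ, mono, t)
        dg = np.gradient(g, phi_grid)
        rates = np.empty((len(cols), n_phi))
        means = np.empty(len(cols))
        for j, c in enumerate(cols):
            u_loc = trace.u[:, c]
            rates[j] = np.interp(g, t, u_loc)
            means[j] = float(np.mean(u_loc[sel]))
        starts.append(b0)
        ends.append(b1)
        periods.append(T)
        mean_rate.append(means)
        mean_lfp.append(float(np.mean(trace.lfp[sel])))
        amplitude.append(float(np.ptp(trace.lfp[sel])))
        phase_rate.append(rates)
        dgdphi.append(dg)

    if len(periods) < 1:
        raise ValueError("no valid oscillation cycles found")
    periods = np.asarray(periods)
    return CycleSet(start=np.asarray(starts), end=np.asarray(ends),
                    period=periods, freq=1000.0 / periods,
                    locations=np.asarray(locations, dtype=float),
                    mean_rate=np.asarray(mean_rate),
                    mean_lfp=np.asarray(mean_lfp),
                    amplitude=np.asarray(amplitude),
                    phi=phi_grid, phase_rate=np.asarray(phase_rate),
                    dgdphi=np.asarray(dgdphi))


def phase_density(cycles: CycleSet, cycle: int, location: int) -> PhaseDensity:
    """Phase-code density of one cycle at one decoding location.

    Applies ``q(phi) = u(theta, g(phi)) g'(phi) / (lambda T)`` and
    renormalizes on the discrete grid (the continuum identity integrates to
    one exactly; the grid version is renormalized to hold to 1e-6).
    """
    lam = cycles.mean_rate[cycle, location]
    if lam <= 0:
        raise ValueError("phase density undefined for zero mean rate")
    T = cycles.period[cycle]
    q = cycles.phase_rate[cycle, location] * cycles.dgdphi[cycle] / (lam * T)
    return PhaseDensity(cycles.phi, np.clip(q, 0.0, None)).normalized()


# --------------------------------------------------------------------------
# divergences
# --------------------------------------------------------------------------

def _kl_discrete(pa, pb, weights, strict: bool) -> float:
    pa = np.asarray(pa, dtype=float)
    pb = np.asarray(pb, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("distributions must share a support")
    active = pa > DENSITY_FLOOR
    if strict and np.any(pb[active] == 0.0):
        raise ZeroDivisionError(
            "second distribution is zero where the first has mass: "
            "KL divergence is infinite")
    if np.any(pb[active] < DENSITY_FLOOR):
        warnings.warn("density floored at 1e-12 in KL divergence",
                      RuntimeWarning, stacklevel=3)
    pa_ = np.clip(pa, DENSITY_FLOOR, None)
    pb_ = np.clip(pb, DENSITY_FLOOR, None)
    integrand = np.where(active, pa * np.log(pa_ / pb_), 0.0)
    return float(np.sum(integrand * weights))


def kl_info_gain(dist_a, dist_b, strict: bool = False) -> float:
    """Kullback-Leibler divergence D(a || b) in nats (the information gain).

    Accepts a pair of :class:`PhaseDensity` (integrated over phase) or
    :class:`CountDensity` (summed over counts).  Densities are floored at
    1e-12 with a warning; pass ``strict=True`` to raise on an infinite
    divergence instead.
    """
    if isinstance(dist_a, PhaseDensity) and isinstance(dist_b, PhaseDensity):
        if not np.allclose(dist_a.phi, dist_b.phi):
            raise ValueError("phase grids differ")
        w = np.gradient(dist_a.phi)
        return _kl_discrete(dist_a.q, dist_b.q, w, strict)
    if isinstance(dist_a, CountDensity) and isinstance(dist_b, CountDensity):
        n = max(len(dist_a.p), len(dist_b.p))
        pa = np.pad(dist_a.p, (0, n - len(dist_a.p)))
        pb = np.pad(dist_b.p, (0, n - len(dist_b.p)))
        return _kl_discrete(pa, pb, np.ones(n), strict)
    raise TypeError("dist_a and dist_b must both be PhaseDensity or both "
                    "CountDensity")


def stim_mutual_info(dist_1, dist_2) -> float:
    """Two-stimulus mutual information in bits (Jensen-Shannon divergence).

    For two equiprobable stimuli with response distributions q1 and q2, the
    stimulus-response mutual information equals
    ``0.5 D(q1 || m) + 0.5 D(q2 || m)`` with ``m`` the equal mixture, taken
    in log base 2; it is bounded by 1 bit.
    """
    ln2 = np.log(2.0)
    if isinstance(dist_1, PhaseDensity):
        m = PhaseDensity(dist_1.phi, 0.5 * (dist_1.q + dist_2.q))
    else:
        n = max(len(dist_1.p), len(dist_2.p))
        p1 = np.pad(dist_1.p, (0, n - len(dist_1.p)))
        p2 = np.pad(dist_2.p, (0, n - len(dist_2.p)))
        dist_1 = CountDensity(p1, dist_1.mean)
        dist_2 = CountDensity(p2, dist_2.mean)
        m = CountDensity(0.5 * (p1 + p2), 0.5 * (dist_1.mean + dist_2.mean))
    mi = 0.5 * kl_info_gain(dist_1, m) + 0.5 * kl_info_gain(dist_2, m)
    return mi / ln2


# --------------------------------------------------------------------------
# per-cycle information and sweeps
# --------------------------------------------------------------------------

def cycle_information(cycles: CycleSet, cycle: int,
                      direction: str = "as-printed") -> dict:
    """Phase/rate information gain (nats) and MI (bits) for one cycle.

    The information gain compares the decoding locations ``locations[1]``
    (pi/4 by default) against ``locations[0]`` (pi/2): IG = D(q_pi4 || q_pi2).
    ``direction='reversed'`` swaps the arguments.
    """
    a, b = (1, 0) if direction == "as-printed" else (0, 1)
    q_a = phase_density(cycles, cycle, a)
    q_b = phase_density(cycles, cycle, b)
    T = cycles.period[cycle]
    p_a = count_density(cycles.mean_rate[cycle, a], T)
    p_b = count_density(cycles.mean_rate[cycle, b], T)
    return {
        "phase_ig": kl_info_gain(q_a, q_b),
        "rate_ig": kl_info_gain(p_a, p_b),
        "phase_mi": stim_mutual_info(q_a, q_b),
        "rate_mi": stim_mutual_info(p_a, p_b),
    }


def _cycle_table(cycles: CycleSet) -> pd.DataFrame:
    rows = []
    for i in range(len(cycles)):
        try:
            info = cycle_information(cycles, i)
        except ValueError:
            continue
        info["freq"] = cycles.freq[i]
        info["mean_rate"] = cycles.mean_lfp[i]
        rows.append(info)
    return pd.DataFrame(rows)


def wm_contrast_sweep(params: FieldParams | None = None,
                      wm_levels=(0, 1, 2, 3), contrast: int = 2,
                      duration: float = 6000.0, seed: int = 0,
                      min_cycles: int = 20) -> pd.DataFrame:
    """Mean phase/rate information per working-memory level (Fig-4C-style).

    Simulates the tuned field at each WM level with the stimulus fixed at
    ``contrast``, segments cycles, and averages per-cycle information.
    Columns: ``wm_level, contrast, phase_ig, rate_ig, phase_mi, rate_mi,
    mean_freq, mean_rate, n_cycles``.
    """
    params = params or FieldParams()
    rows = []
    for b in wm_levels:
        trace = simulate_field(params, InputSpec(a=contrast, b=b),
                               duration=duration, seed=seed + 101 * b)
        cyc = extract_cycles(trace.after_transient())
        if len(cyc) < min_cycles:
            raise ValueError(
                f"only {len(cyc)} cycles at WM level {b}; extend duration")
        tab = _cycle_table(cyc)
        rows.append({
            "wm_level": b, "contrast": contrast,
            "phase_ig": tab["phase_ig"].mean(),
            "rate_ig": tab["rate_ig"].mean(),
            "phase_mi": tab["phase_mi"].mean(),
            "rate_mi": tab["rate_mi"].mean(),
            "mean_freq": tab["freq"].mean(),
            "mean_rate": tab["mean_rate"].mean(),
            "n_cycles": len(tab),
        })
    return pd.DataFrame(rows)


def frequency_decile_info(cycles_by_contrast: dict[int, CycleSet],
                          n_deciles: int = 10,
                          min_cycles: int = 100) -> pd.DataFrame:
    """Decile analysis: information versus oscillation frequency (Fig-4D-style).

    Cycles within each contrast level are split into frequency deciles
    (equal-count bins).  Returns one row per (contrast, decile) with mean
    phase/rate information, plus per-contrast slope statistics from a linear
    regression of per-cycle information on decile index (model utility
    t-test) stored in ``DataFrame.attrs['trends']``.
    """
    rows = []
    trends = {}
    for a, cyc in sorted(cycles_by_contrast.items()):
        if len(cyc) < min_cycles:
            raise ValueError(
                f"contrast {a}: need >= {min_cycles} cycles, got {len(cyc)}")
        tab = _cycle_table(cyc)
        edges = np.quantile(tab["freq"], np.linspace(0, 1, n_deciles + 1))
        dec = np.clip(np.searchsorted(edges, tab["freq"], side="right") - 1,
                      0, n_deciles - 1)
        tab = tab.assign(decile=dec)
        counts = tab.groupby("decile").size()
        if (counts == 0).any() or len(counts) < n_deciles:
            raise ValueError(f"contrast {a}: empty frequency decile")
        for d, sub in tab.groupby("decile"):
            rows.append({
                "contrast": a, "decile": int(d),
                "phase_ig": sub["phase_ig"].mean(),
                "rate_ig": sub["rate_ig"].mean(),
                "mean_freq": sub["freq"].mean(),
                "mean_rate": sub["mean_rate"].mean(),
                "n_cycles": len(sub),
            })
        res_p = linregress(tab["decile"], tab["phase_ig"])
        res_r = linregress(tab["decile"], tab["rate_ig"])
        trends[a] = {"phase_slope": res_p.slope, "phase_p": res_p.pvalue,
                     "rate_slope": res_r.slope, "rate_p": res_r.pvalue}
    out = pd.DataFrame(rows)
    out.attrs["trends"] = trends
    return out


def freq_rate_correlation(cycles: CycleSet, min_cycles: int = 50,
                          amp_quantile: float = 0.25) -> tuple[float, float]:
    """Pearson r (and slope-test p) between cycle frequency and mean e-rate.

    Under slow noisy working-memory drive, fluctuations that push the network
    deeper past the oscillation threshold raise frequency and rate together,
    so r is strongly positive.  Cycles in the lowest ``amp_quantile`` of
    peak-to-trough amplitude are excluded: the Hilbert phase (hence the
    period estimate) is unreliable when the oscillation nearly vanishes.
    """
    if len(cycles) < min_cycles:
        raise ValueError(f"need >= {min_cycles} cycles, got {len(cycles)}")
    keep = cycles.amplitude >= np.quantile(cycles.amplitude, amp_quantile)
    f = cycles.freq[keep]
    r_ = cycles.mean_lfp[keep]
    if np.std(f) == 0 or np.std(r_) == 0:
        raise ValueError("zero variance in frequency or rate")
    r, p = pearsonr(f, r_)
    return float(r), float(p)
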