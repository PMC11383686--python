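"""Excitatory/inhibitory neural field on a ring of orientation columns.

The model describes a hypercolumn-like population indexed by preferred
orientation ``theta`` on the half-circle ``[0, pi)``.  Excitatory activity
``u(theta, t)`` and inhibitory activity ``v(theta, t)`` evolve according to

    tau_e du/dt = -u + f_sigma( W * (wee u - wei v) + I_e )
    tau_i dv/dt = -v + f_sigma( W * (wie u - wii v) + I_i )

where ``*`` is circular convolution with a pi-periodic von Mises kernel and
``f_sigma`` is the firing-rate transfer function of a noisy leaky
integrate-and-fire neuron (inverse mean first-passage time plus a refractory
period; the Siegert formula).  External input is the sum of a baseline, an
orientation-tuned stimulus drive (contrast level ``a``), a spatially uniform
working-memory drive (level ``b``), and a slow Ornstein-Uhlenbeck process
shared by all columns.

The operating point is placed just above a supercritical Hopf bifurcation so
that the uniform drive elicits a network oscillation whose frequency at onset
lies in the beta band (18-20 Hz).  The spatial mean of ``u`` serves as an LFP
proxy for all downstream phase analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import json
import numpy as np
from numpy.typing import NDArray
from scipy.integrate import quad
from scipy.optimize import brentq, fsolve
from scipy.special import erfcx, i0

__all__ = [
    "LIFParams",
    "FieldParams",
    "InputSpec",
    "FieldTrace",
    "fi_curve",
    "weight_kernel",
    "stimulus_profile",
    "ou_path",
    "fixed_point",
    "jacobian_eigenvalues",
    "tune_to_hopf",
    "hopf_frequency",
    "simulate_field",
]

FloatArray = NDArray[np.float64]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters behind the F-I transfer function.

    Units: voltages in mV, time in ms, currents in nA, capacitance in nF
    (so that ``tau_m = C/gl`` is in ms).  With the defaults, exactly 1 nA of
    steady current brings the noise-free membrane to threshold
    (``gl = 1 nA / 15 mV``) and the membrane time constant is 15 ms.
    """

    C: float = 1.0            # nF
    gl: float = 1.0 / 15.0    # uS  (fixes 1 nA -> 15 mV = threshold distance)
    Vl: float = -65.0         # mV, leak = reset
    Vt: float = -50.0         # mV, spike threshold
    t_ref: float = 5.0        # ms, absolute refractory period
    sigma: float = 1.4142135623730951   # nA sqrt(ms), white-noise amplitude

    def __post_init__(self) -> None:
        if not (self.Vt > self.Vl):
            raise ValueError("threshold Vt must exceed leak/reset Vl")
        if self.t_ref < 0:
            raise ValueError("refractory period must be >= 0")
        if self.gl <= 0 or self.C <= 0:
            raise ValueError("gl and C must be positive")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/gl in ms."""
        return self.C / self.gl

    @property
    def sigma_v(self) -> float:
        """Stationary membrane-voltage s.d. (mV) of the subthreshold process."""
        return self.sigma / np.sqrt(2.0 * self.gl * self.C)


@dataclass(frozen=True)
class FieldParams:
    """Neural field parameters.

    The default values were produced by the documented tuning procedure
    (linear-stability bisection to the Hopf threshold, then adjustment of
    ``tau_e``/``tau_i`` so the onset frequency sits at 18-20 Hz); they are not
    taken from any published table.  ``Ie0``/``Ii0`` place the resting network
    marginally above the Hopf threshold, so that even at WM level 0 a weak
    beta oscillation exists and each working-memory increment deepens it.
    """

    tau_e: float = 5.6        # ms
    tau_i: float = 11.2       # ms
    wee: float = 0.26         # nA per Hz
    wei: float = 0.26         # nA per Hz
    wie: float = 0.28         # nA per Hz
    wii: float = 0.10         # nA per Hz
    kappa: float = 6.0        # connectivity concentration
    n_theta: int = 64         # grid points over [0, pi)
    Ie0: float = 0.138        # nA baseline to e-cells (just above Hopf)
    Ii0: float = -0.012       # nA baseline to i-cells
    sigma0: float = 1.4142135623730951    # F-I noise at zero contrast
    delta_sigma: float = 0.014142135623730951  # F-I noise per contrast level
    delta_stim: float = 0.012 # nA stimulus-current increment per contrast level
    delta_wm: float = 0.008   # nA uniform WM-current increment per WM level
    tau_z: float = 50.0       # ms, OU correlation time
    sigma_z: float = 0.02     # nA, OU stationary s.d.
    lif: LIFParams = field(default_factory=LIFParams)

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0 or self.tau_z <= 0:
            raise ValueError("time constants must be positive")
        if min(self.wee, self.wei, self.wie, self.wii) < 0:
            raise ValueError("connection weights must be >= 0")
        if self.n_theta < 16:
            raise ValueError("need at least 16 orientation grid points")
        if self.kappa < 0:
            raise ValueError("kernel concentration kappa must be >= 0")

    @property
    def theta(self) -> FloatArray:
        return np.linspace(0.0, np.pi, self.n_theta, endpoint=False)

    def replace(self, **kw) -> "FieldParams":
        d = asdict(self)
        lif = d.pop("lif")
        d.update({k: v for k, v in kw.items() if k != "lif"})
        return FieldParams(lif=kw.get("lif", LIFParams(**lif)), **d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FieldParams":
        with open(path) as fh:
            d = json.load(fh)
        lif = LIFParams(**d.pop("lif")) if "lif" in d else LIFParams()
        return cls(lif=lif, **d)


@dataclass(frozen=True)
class InputSpec:
    """External drive: contrast level ``a``, WM level ``b``, stimulus angle."""

    a: int = 0                    # contrast level 0..3
    b: int = 1                    # working-memory level 0..3
    theta0: float = np.pi / 2.0   # stimulus orientation (vertical by default)
    kappa_s: float = 1.5          # stimulus tuning concentration

    def __post_init__(self) -> None:
        if self.a not in (0, 1, 2, 3) or self.b not in (0, 1, 2, 3):
            raise ValueError("contrast a and WM b must be integers in 0..3")
        if not (0.0 <= self.theta0 < np.pi):
            raise ValueError("theta0 must lie in [0, pi)")
        if self.kappa_s < 0:
            raise ValueError("kappa_s must be >= 0")


@dataclass
class FieldTrace:
    """One simulation run: activity over (time x orientation) plus LFP proxy.

    ``lfp`` is defined as the orientation-mean of the excitatory rate at every
    recorded sample.  ``transient`` marks the initial stretch (ms) the caller
    should discard before analysis.
    """

    time: FloatArray              # ms, uniform step
    u: FloatArray                 # (n_t, n_theta) e-rate, Hz
    v: FloatArray                 # (n_t, n_theta) i-rate, Hz
    lfp: FloatArray               # (n_t,) orientation-mean of u
    y: FloatArray                 # (n_t,) realized OU path, nA
    theta: FloatArray             # orientation grid
    dt: float                     # recorded sampling step, ms
    transient: float = 500.0      # suggested transient to discard, ms
    params: FieldParams | None = None
    inputs: InputSpec | None = None
    seed: int | None = None

    def after_transient(self) -> "FieldTrace":
        m = self.time >= (self.time[0] + self.transient)
        return FieldTrace(self.time[m], self.u[m], self.v[m], self.lfp[m],
                          self.y[m], self.theta, self.dt, 0.0,
                          self.params, self.inputs, self.seed)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("time", "u", "v", "lfp", "y", "theta"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["dt"] = self.dt
            f.attrs["transient"] = self.transient
            if self.seed is not None:
                f.attrs["seed"] = self.seed
            if self.params is not None:
                f.attrs["params_json"] = json.dumps(asdict(self.params))
            if self.inputs is not None:
                f.attrs["inputs_json"] = json.dumps(asdict(self.inputs))

    @classmethod
    def from_hdf5(cls, path) -> "FieldTrace":
        import h5py

        with h5py.File(path, "r") as f:
            kw = {name: f[name][...] for name in
                  ("time", "u", "v", "lfp", "y", "theta")}
            kw["dt"] = float(f.attrs["dt"])
            kw["transient"] = float(f.attrs.get("transient", 0.0))
            if "seed" in f.attrs:
                kw["seed"] = int(f.attrs["seed"])
            if "params_json" in f.attrs:
                d = json.loads(f.attrs["params_json"])
                lif = LIFParams(**d.pop("lif"))
                kw["params"] = FieldParams(lif=lif, **d)
            if "inputs_json" in f.attrs:
                kw["inputs"] = InputSpec(**json.loads(f.attrs["inputs_json"]))
        return cls(**kw)


# --------------------------------------------------------------------------
# transfer function (Siegert formula)
# --------------------------------------------------------------------------

def _siegert_rate(I: float, lif: LIFParams) -> float:
    """Firing rate (Hz) of a white-noise-driven LIF neuron at mean current I."""
    mu = lif.Vl + I / lif.gl          # asymptotic mean voltage, mV
    if lif.sigma == 0.0:
        # deterministic limit: threshold crossing only if mu exceeds Vt
        if mu <= lif.Vt:
            return 0.0
        T = lif.tau_m * np.log((mu - lif.Vl) / (mu - lif.Vt))
        return 1000.0 / (lif.t_ref + T)
    # Siegert bounds are scaled by sigma_B = sigma/sqrt(gl C), which is
    # sqrt(2) times the stationary membrane s.d.
    s = np.sqrt(2.0) * lif.sigma_v
    lo = (lif.Vl - mu) / s
    hi = (lif.Vt - mu) / s
    if hi > 25.0:
        # mean voltage so far below threshold that exp(hi^2) overflows;
        # the first-passage time exceeds ~1e270 ms
        return 0.0
    # integrand exp(x^2)(1 + erf x) written overflow-safe as erfcx(-x)
    val, _ = quad(lambda x: erfcx(-x), lo, hi, epsabs=0.0, epsrel=1e-10,
                  limit=200)
    T = lif.tau_m * np.sqrt(np.pi) * val
    return 1000.0 / (lif.t_ref + T)


def fi_curve(I, lif: LIFParams | None = None):
    """F-I curve: steady firing rate (Hz) versus input current (nA).

    The rate is the inverse mean first-passage time of a leaky
    integrate-and-fire neuron driven by Gaussian white current noise of
    amplitude ``lif.sigma`` (Siegert formula), plus a 5 ms refractory period.
    Increasing ``sigma`` smooths the curve and lowers its gain; ``sigma = 0``
    gives the deterministic piecewise rate.  Output is monotone
    non-decreasing in ``I`` and bounded by ``1000/t_ref`` Hz.
    """
    if lif is None:
        lif = LIFParams()
    arr = np.asarray(I, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input current must be finite")
    out = np.vectorize(lambda x: _siegert_rate(x, lif))(arr)
    return float(out) if np.ndim(I) == 0 else out


class _FITable:
    """Tabulated F-I curve for fast lookup inside the integrator."""

    def __init__(self, lif: LIFParams, I_min: float = -10.0,
                 I_max: float = 40.0, n: int = 4001):
        self.grid = np.linspace(I_min, I_max, n)
        self.rates = fi_curve(self.grid, lif)
        self.lif = lif

    def __call__(self, I: FloatArray) -> FloatArray:
        return np.interp(I, self.grid, self.rates)


def fi_slope(I: float, lif: LIFParams, h: float = 1e-4) -> float:
    """Numerical derivative dF/dI (Hz per nA) of the Siegert F-I curve."""
    return (_siegert_rate(I + h, lif) - _siegert_rate(I - h, lif)) / (2 * h)


# --------------------------------------------------------------------------
# spatial structure and inputs
# --------------------------------------------------------------------------

def weight_kernel(kappa: float, theta: FloatArray) -> FloatArray:
    """pi-periodic von Mises connectivity kernel, normalized to unit mass.

    ``W(theta) = exp(kappa cos 2 theta) / (pi I0(kappa))``; the factor 2 makes
    the kernel pi-periodic on the half-circle orientation domain.  ``kappa=0``
    gives the uniform kernel ``1/pi``.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    theta = np.asarray(theta, dtype=float)
    return np.exp(kappa * np.cos(2.0 * theta)) / (np.pi * i0(kappa))


def stimulus_profile(spec: InputSpec, theta: FloatArray) -> FloatArray:
    """Orientation-tuned stimulus drive, peak-normalized to 1 at ``theta0``.

    ``S(theta) = exp(kappa_s (cos 2(theta - theta0) - 1))``.
    """
    theta = np.asarray(theta, dtype=float)
    return np.exp(spec.kappa_s * (np.cos(2.0 * (theta - spec.theta0)) - 1.0))


def ou_path(tau_z: float, sigma_z: float, dt: float, n_samples: int,
            seed: int | np.random.Generator) -> FloatArray:
    """Exact-discretization Ornstein-Uhlenbeck path.

    The process ``tau_z dy = -y dt + sigma_z sqrt(2 tau_z) dW`` has zero mean,
    stationary standard deviation ``sigma_z`` and autocorrelation time
    ``tau_z``.  The initial value is drawn from the stationary law, and the
    exponential (exact) update avoids time-step bias.
    """
    if tau_z <= 0 or dt <= 0:
        raise ValueError("tau_z and dt must be positive")
    if sigma_z < 0:
        raise ValueError("sigma_z must be >= 0")
    if dt >= tau_z:
        raise ValueError("dt must be smaller than tau_z for a valid path")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if sigma_z == 0.0:
        return np.zeros(n_samples)
    rho = np.exp(-dt / tau_z)
    innov_sd = sigma_z * np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal(n_samples)
    y = np.empty(n_samples)
    y[0] = sigma_z * eps[0]
    for k in range(1, n_samples):
        y[k] = rho * y[k - 1] + innov_sd * eps[k]
    return y


# --------------------------------------------------------------------------
# fixed point, linear stability, Hopf tuning
# --------------------------------------------------------------------------

def fixed_point(params: FieldParams, I_extra: float = 0.0,
                sigma: float | None = None) -> tuple[float, float]:
    """Spatially uniform fixed point (u0, v0) under uniform extra current.

    ``sigma`` defaults to the zero-contrast F-I noise ``params.sigma0``, the
    same transfer function the simulator uses at contrast level 0.
    """
    if sigma is None:
        sigma = params.sigma0
    lif = LIFParams(**{**asdict(params.lif), "sigma": sigma})

    def eqs(x):
        u, v = x
        fe = _siegert_rate(params.wee * u - params.wei * v
                           + params.Ie0 + I_extra, lif)
        fi_ = _siegert_rate(params.wie * u - params.wii * v
                            + params.Ii0 + I_extra, lif)
        return [fe - u, fi_ - v]

    sol, info, ier, _ = fsolve(eqs, x0=[10.0, 10.0], full_output=True)
    if ier != 1:
        # retry from a quiescent start
        sol, info, ier, msg = fsolve(eqs, x0=[0.5, 0.5], full_output=True)
        if ier != 1:
            raise RuntimeError(f"fixed-point solve failed: {msg}")
    return float(sol[0]), float(sol[1])


def jacobian_eigenvalues(params: FieldParams, I_extra: float = 0.0,
                         sigma: float | None = None,
                         mode: int = 0) -> NDArray[np.complex128]:
    """Eigenvalues (1/ms) of the linearization about the uniform fixed point.

    ``mode`` selects the spatial Fourier mode of the perturbation; the kernel
    enters through its Fourier coefficient, which is 1 for the uniform mode.
    """
    if sigma is None:
        sigma = params.sigma0
    lif = LIFParams(**{**asdict(params.lif), "sigma": sigma})
    u0, v0 = fixed_point(params, I_extra, sigma)
    Ie = params.wee * u0 - params.wei * v0 + params.Ie0 + I_extra
    Ii = params.wie * u0 - params.wii * v0 + params.Ii0 + I_extra
    ge = fi_slope(Ie, lif)
    gi = fi_slope(Ii, lif)
    theta = params.theta
    W = weight_kernel(params.kappa, theta)
    # Fourier coefficient of the normalized kernel for this mode
    wk = float(np.real(np.sum(W * np.exp(-2j * mode * theta))
                       * (np.pi / params.n_theta)))
    J = np.array([
        [(-1.0 + ge * params.wee * wk) / params.tau_e,
         (-ge * params.wei * wk) / params.tau_e],
        [(gi * params.wie * wk) / params.tau_i,
         (-1.0 - gi * params.wii * wk) / params.tau_i],
    ])
    return np.linalg.eigvals(J)


def tune_to_hopf(params: FieldParams, I_lo: float = -0.6, I_hi: float = 0.6,
                 tol_frac: float = 1e-4, n_scan: int = 49) -> float:
    """Uniform current threshold I* at which the fixed point loses stability.

    Scans the added uniform current for the first sign change of the leading
    Jacobian eigenvalue's real part, then bisects it to ``tol_frac`` of the
    search interval.  Just below I* the network decays to its fixed point;
    just above, a small-amplitude oscillation grows continuously from zero
    (supercritical Hopf).  The oscillatory regime is an interval: strong
    enough uniform drive restabilizes the fixed point, so the scan keeps the
    lower (onset) crossing.  Raises if no crossing is found, reporting the
    stability profile for diagnosis.
    """
    def lead_re(I):
        return float(np.max(np.real(jacobian_eigenvalues(params, I))))

    grid = np.linspace(I_lo, I_hi, n_scan)
    vals = []
    for g in grid:
        try:
            vals.append(lead_re(g))
        except RuntimeError:
            vals.append(np.nan)
    vals = np.asarray(vals)
    xtol = tol_frac * (I_hi - I_lo)
    for i in range(len(grid) - 1):
        if vals[i] < 0 and vals[i + 1] > 0:
            return float(brentq(lead_re, grid[i], grid[i + 1], xtol=xtol))
    profile = ", ".join(f"I={g:+.3f}: {v:+.5f}" for g, v in
                        zip(grid[::4], vals[::4]))
    raise RuntimeError(
        "no Hopf crossing found in [%g, %g]; Re(lambda) profile: %s"
        % (I_lo, I_hi, profile))


def hopf_frequency(params: FieldParams, I_extra: float) -> float:
    """Oscillation frequency (Hz) from the imaginary part at the fixed point."""
    lam = jacobian_eigenvalues(params, I_extra)
    w = float(np.max(np.abs(np.imag(lam))))
    return 1000.0 * w / (2.0 * np.pi)


# --------------------------------------------------------------------------
# integration
# --------------------------------------------------------------------------

def simulate_field(params: FieldParams, inputs: InputSpec,
                   duration: float = 5000.0, dt: float = 0.1,
                   seed: int = 0, record_stride: int = 5,
                   transient: float = 500.0) -> FieldTrace:
    """Integrate the field equations and return the recorded trace.

    Explicit Euler on the rate equations at step ``dt`` (ms); the shared OU
    input is advanced with its exact exponential update.  The F-I noise
    parameter used is ``sigma0 + a * delta_sigma`` (input fluctuations grow
    with contrast).  Recording keeps every ``record_stride``-th sample.  The
    returned trace flags the suggested transient; discarding it is the
    caller's responsibility.
    """
    n_steps = int(round(duration / dt))
    if n_steps < 10:
        raise ValueError("duration must cover many time steps")
    theta = params.theta
    sigma = params.sigma0 + inputs.a * params.delta_sigma
    lif = LIFParams(**{**asdict(params.lif), "sigma": sigma})
    f = _FITable(lif)

    W = weight_kernel(params.kappa, theta)
    Wf = np.fft.rfft(W) * (np.pi / params.n_theta)   # kernel in Fourier space

    S = stimulus_profile(inputs, theta)
    Ie_base = params.Ie0 + inputs.a * params.delta_stim * S \
        + inputs.b * params.delta_wm
    Ii_base = params.Ii0 + inputs.a * params.delta_stim * S \
        + inputs.b * params.delta_wm

    rng = np.random.default_rng(seed)
    y = ou_path(params.tau_z, params.sigma_z, dt, n_steps + 1, rng)

    u = np.full(params.n_theta, 1.0)
    v = np.full(params.n_theta, 1.0)
    n_rec = n_steps // record_stride + 1
    u_rec = np.empty((n_rec, params.n_theta))
    v_rec = np.empty((n_rec, params.n_theta))
    y_rec = np.empty(n_rec)
    t_rec = np.empty(n_rec)

    def record(i_rec, t, uu, vv, yy):
        u_rec[i_rec] = uu
        v_rec[i_rec] = vv
        y_rec[i_rec] = yy
        t_rec[i_rec] = t

    record(0, 0.0, u, v, y[0])
    i_rec = 1
    ae, ai = dt / params.tau_e, dt / params.tau_i
    for k in range(1, n_steps + 1):
        drive = np.fft.irfft(np.fft.rfft(params.wee * u - params.wei * v)
                             * Wf, n=params.n_theta)
        drive_i = np.fft.irfft(np.fft.rfft(params.wie * u - params.wii * v)
                               * Wf, n=params.n_theta)
        u = u + ae * (-u + f(drive + Ie_base + y[k - 1]))
        v = v + ai * (-v + f(drive_i + Ii_base + y[k - 1]))
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise FloatingPointError(
                f"field integration diverged at t = {k * dt:.2f} ms")
        if k % record_stride == 0:
            record(i_rec, k * dt, u, v, y[k])
            i_rec += 1

    u_rec = np.clip(u_rec, 0.0, None)
    v_rec = np.clip(v_rec, 0.0, None)
    lfp = u_rec.mean(axis=1)
    return FieldTrace(time=t_rec[:i_rec], u=u_rec[:i_rec], v=v_rec[:i_rec],
                      lfp=lfp[:i_rec], y=y_rec[:i_rec], theta=theta,
                      dt=dt * record_stride, transient=transient,
                      params=params, inputs=inputs, seed=seed)
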