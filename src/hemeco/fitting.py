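"""Nonlinear fitting primitives for kinetic traces and spectro-temporal data.

Covers the transient analyses used throughout the pipeline: multi-exponential
fitting of single-wavelength traces (stopped-flow binding, ligand
replacement), hyperbolic fitting of k_obs versus [CO], first-order decays
(heme transfer to apo-myoglobin), and global multi-exponential analysis of
wavelength x delay matrices in terms of decay-associated spectra (DAS).

All fitters are deterministic pure functions of their inputs: candidate
lifetimes come from a fixed log-spaced multi-start grid, the linear
amplitudes are solved exactly at each candidate by variable projection, and
the best start is refined by trust-region least squares in log-lifetime
space (which enforces positivity).  Equal-SSR ties break toward the
lexicographically smallest lifetime vector.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

from .kinetics import ObservedRatePoint

__all__ = [
    "KineticTrace",
    "MultiExpFit",
    "SpectroTemporalMatrix",
    "DASComponent",
    "GlobalDASFit",
    "FirstOrderFit",
    "KobsFit",
    "GeminateSummary",
    "FitError",
    "fit_multiexp",
    "select_n_phases",
    "fit_kobs_curve",
    "fit_first_order",
    "global_das_fit",
    "geminate_summary",
]


class FitError(RuntimeError):
    """Raised when a fit fails to converge from every start."""


@dataclass(frozen=True)
class KineticTrace:
    """A time-resolved signal at a single wavelength."""

    times: np.ndarray
    signal: np.ndarray
    time_unit: str = "s"  # "s" or "ps"
    wavelength: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or t.size != y.size:
            raise ValueError("times and signal must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("times and signal must be finite")

    def to_csv(self, path) -> None:
        from .io import write_xy_csv

        write_xy_csv(path, self.times, self.signal, f"time_{self.time_unit}", "signal")


@dataclass(frozen=True)
class MultiExpFit:
    """Result of a multi-exponential fit: offset + sum_i amp_i exp(-t/tau_i).

    Lifetimes are sorted ascending; amplitudes are signed (bleach and induced
    absorption have opposite signs in transient spectra).
    """

    lifetimes: tuple[float, ...]
    amplitudes: tuple[float, ...]
    offset: float
    ssr: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if any(tau <= 0 for tau in self.lifetimes):
            raise ValueError("lifetimes must be positive")
        if list(self.lifetimes) != sorted(self.lifetimes):
            raise ValueError("lifetimes must be sorted ascending")

    @property
    def n_phases(self) -> int:
        return len(self.lifetimes)

    @property
    def fractional_amplitudes(self) -> tuple[float, ...]:
        """|amp_i| / sum_j |amp_j| over the decaying phases (sums to 1)."""
        mags = np.abs(self.amplitudes)
        total = mags.sum()
        if total == 0:
            return tuple(0.0 for _ in mags)
        return tuple(mags / total)

    def rates(self) -> tuple[float, ...]:
        return tuple(1.0 / tau for tau in self.lifetimes)

    def predict(self, times) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        out = np.full_like(t, self.offset)
        for a, tau in zip(self.amplitudes, self.lifetimes):
            out += a * np.exp(-t / tau)
        return out


@dataclass(frozen=True)
class SpectroTemporalMatrix:
    """Transient-absorption data: delta-A on a delay (ps) x wavelength (nm) grid."""

    delays: np.ndarray  # ps, strictly increasing
    wavelengths: np.ndarray  # nm, strictly increasing
    delta_a: np.ndarray  # shape (n_delays, n_wavelengths)

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        w = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.delta_a, dtype=float)
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "delta_a", m)
        if np.any(np.diff(d) <= 0) or np.any(np.diff(w) <= 0):
            raise ValueError("delay and wavelength grids must be strictly increasing")
        if m.shape != (d.size, w.size):
            raise ValueError("delta_a shape must be (n_delays, n_wavelengths)")

    def trace_at(self, wavelength: float) -> KineticTrace:
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return KineticTrace(
            times=self.delays,
            signal=self.delta_a[:, idx],
            time_unit="ps",
            wavelength=float(self.wavelengths[idx]),
        )

    def to_csv(self, path) -> None:
        from .io import write_matrix_csv

        write_matrix_csv(path, self.delays, self.wavelengths, self.delta_a)


@dataclass(frozen=True)
class DASComponent:
    """One shared lifetime and its decay-associated spectrum."""

    lifetime: float  # ps; inf for a non-decaying component
    spectrum: np.ndarray  # delta-A amplitude per wavelength

    def __post_init__(self) -> None:
        if not self.lifetime > 0:
            raise ValueError("lifetime must be positive")
        object.__setattr__(self, "spectrum", np.asarray(self.spectrum, dtype=float))


@dataclass(frozen=True)
class GlobalDASFit:
    """Global multi-exponential fit of a spectro-temporal matrix."""

    components: tuple[DASComponent, ...]  # decaying, lifetime-ascending
    nondecaying: DASComponent | None
    ssr: float
    converged: bool

    @property
    def lifetimes(self) -> tuple[float, ...]:
        return tuple(c.lifetime for c in self.components)


@dataclass(frozen=True)
class FirstOrderFit:
    """Single-exponential fit: offset + amplitude * exp(-rate * t)."""

    rate: float  # s^-1 (or 1/time-unit of the trace)
    amplitude: float
    offset: float
    ssr: float
    converged: bool
    rate_stderr: float = np.inf


@dataclass(frozen=True)
class KobsFit:
    """Hyperbolic fit k_obs = k1 * c / (K + c) of observed rates vs [CO]."""

    k1: float  # s^-1, limiting rate
    half_sat: float  # uM, K = k_m1/k2
    k_co: float  # uM^-1 s^-1, initial slope k1/K
    k1_stderr: float
    half_sat_stderr: float
    k_co_stderr: float
    ssr: float


@dataclass(frozen=True)
class GeminateSummary:
    """Fractional phase amplitudes and the geminate rebinding yield."""

    fractional_amplitudes: tuple[float, ...]  # decaying phases
    long_lived_fraction: float
    geminate_yield: float  # = 1 - long_lived_fraction


# ---------------------------------------------------------------------------
# variable projection machinery


def _lifetime_grid(times: np.ndarray, n_grid: int = 8) -> np.ndarray:
    dt = np.min(np.diff(times))
    span = times[-1] - times[0]
    return np.geomspace(2.0 * dt, 2.0 * span, n_grid)


def _design(times: np.ndarray, taus: np.ndarray, fit_offset: bool) -> np.ndarray:
    # absolute time: amplitudes mean "extrapolated to t = 0", which is the
    # convention for photodissociation transients whose grid starts after 0
    cols = np.exp(-times[:, None] / np.asarray(taus, dtype=float)[None, :])
    if fit_offset:
        cols = np.column_stack([cols, np.ones_like(times)])
    return cols


def _vp_solve(times, Y, taus, fit_offset):
    """Solve linear amplitudes for fixed lifetimes; return (coeffs, resid, ssr)."""
    A = _design(times, np.asarray(taus, dtype=float), fit_offset)
    coeffs, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coeffs
    return coeffs, resid, float(np.sum(resid**2))


def _starts(times: np.ndarray, n_phases: int, max_starts: int = 64):
    grid = _lifetime_grid(times)
    combos = list(itertools.combinations(grid, n_phases))
    if len(combos) > max_starts:
        idx = np.linspace(0, len(combos) - 1, max_starts).round().astype(int)
        combos = [combos[i] for i in idx]
    return combos


def _refine_lifetimes(times, Y, taus0, fit_offset):
    """Refine lifetimes in log-space with amplitudes projected out."""

    def resid_fn(log_taus):
        _, resid, _ = _vp_solve(times, Y, np.exp(log_taus), fit_offset)
        return np.ravel(resid)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = least_squares(resid_fn, np.log(np.asarray(taus0)), method="lm", max_nfev=400)
    taus = np.exp(res.x)
    _, _, ssr = _vp_solve(times, Y, taus, fit_offset)
    return taus, ssr, bool(res.status > 0)


def _best_lifetimes(times, Y, n_phases, fit_offset):
    """Multi-start VP fit shared by single-trace and global fitters."""
    scored = []
    for taus0 in _starts(times, n_phases):
        _, _, ssr = _vp_solve(times, Y, taus0, fit_offset)
        scored.append((ssr, taus0))
    scored.sort(key=lambda s: (s[0], s[1]))
    candidates = []
    for _, taus0 in scored[:3]:  # refine the 3 best grid starts
        taus, ssr, ok = _refine_lifetimes(times, Y, taus0, fit_offset)
        if np.all(np.isfinite(taus)) and np.isfinite(ssr):
            candidates.append((ssr, tuple(np.sort(taus)), ok))
    if not candidates:
        raise FitError(f"multi-exponential fit with {n_phases} phases failed from all starts")
    candidates.sort(key=lambda c: (c[0], c[1]))
    ssr, taus, ok = candidates[0]
    return np.array(taus), ssr, ok


# ---------------------------------------------------------------------------
# public fitters


def fit_multiexp(trace: KineticTrace, n_phases: int, fit_offset: bool = True) -> MultiExpFit:
    """Least-squares multi-exponential fit of a kinetic trace.

    Fits signal(t) = offset + sum_i amp_i * exp(-(t - t0)/tau_i) with
    1 <= n_phases <= 4.  Deterministic: multi-start from a fixed log-spaced
    lifetime grid, variable projection for the amplitudes, best start
    refined.  Raises :class:`FitError` if no start converges.
    """
    if not 1 <= n_phases <= 4:
        raise ValueError("n_phases must be between 1 and 4")
    n_params = 2 * n_phases + (1 if fit_offset else 0)
    if trace.times.size < 5 * (2 * n_phases + 1):
        raise ValueError(
            f"need at least {5 * (2 * n_phases + 1)} points for {n_phases} phases, "
            f"got {trace.times.size}"
        )
    t, y = trace.times, trace.signal
    taus, ssr, ok = _best_lifetimes(t, y, n_phases, fit_offset)
    coeffs, _, ssr = _vp_solve(t, y, taus, fit_offset)
    amps = coeffs[:n_phases]
    offset = float(coeffs[n_phases]) if fit_offset else 0.0
    order = np.argsort(taus)
    return MultiExpFit(
        lifetimes=tuple(float(v) for v in taus[order]),
        amplitudes=tuple(float(v) for v in amps[order]),
        offset=offset,
        ssr=float(ssr),
        converged=ok,
        n_points=t.size,
    )


def select_n_phases(trace: KineticTrace, max_n: int = 4, alpha: float = 0.05) -> int:
    """Smallest number of exponential phases justified by an F-test.

    Fits n and n+1 phases; returns the smallest n for which adding a phase
    does not significantly (at ``alpha``) reduce the residual sum of squares.
    Ties break toward smaller n.
    """
    if max_n > 4:
        raise ValueError("max_n must be <= 4")
    energy = float(np.sum(trace.signal**2))
    fits = {}

    def _fit(n):
        if n not in fits:
            fits[n] = fit_multiexp(trace, n)
        return fits[n]

    for n in range(1, max_n):
        f_n, f_n1 = _fit(n), _fit(n + 1)
        if f_n.ssr <= 1e-12 * max(energy, 1e-300):
            return n  # already at numerical noise floor
        n_pts = trace.times.size
        p1 = 2 * (n + 1) + 1
        df2 = n_pts - p1
        if f_n1.ssr <= 0 or df2 <= 0:
            continue
        f_stat = ((f_n.ssr - f_n1.ssr) / 2.0) / (f_n1.ssr / df2)
        p_value = stats.f.sf(max(f_stat, 0.0), 2, df2)
        if p_value >= alpha:
            return n
    return max_n


def fit_kobs_curve(points: list[ObservedRatePoint]) -> KobsFit:
    """Fit the hyperbolic rate law k_obs = k1*c/(K + c) to observed rates.

    Initialization is deterministic: k1 starts at 1.2x the largest observed
    rate and K at the concentration whose rate is nearest half-maximum.
    Returns the composite on-rate kCO = k1/K (the initial slope) with
    delta-method standard error.  When the data only cover the linear regime
    (all c << K), k1 and K are individually unidentifiable: their standard
    errors blow up while kCO stays determined.
    """
    c = np.array([p.co_conc for p in points], dtype=float)
    k = np.array([p.k_obs for p in points], dtype=float)
    w = np.array([1.0 if p.weight is None else p.weight for p in points], dtype=float)
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct CO concentrations")

    def model(conc, k1, K):
        return k1 * conc / (K + conc)

    k1_0 = 1.2 * k.max()
    K_0 = float(c[np.argmin(np.abs(k - 0.5 * k.max()))])
    K_0 = max(K_0, np.min(c[c > 0]) if np.any(c > 0) else 1.0)
    sigma = 1.0 / np.sqrt(w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            model, c, k, p0=[k1_0, K_0], sigma=sigma, absolute_sigma=False, maxfev=20000
        )
    k1, K = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov))
    kco = k1 / K
    # first-order error propagation for the ratio, including covariance
    var_kco = (
        pcov[0, 0] / K**2
        + (k1**2 / K**4) * pcov[1, 1]
        - 2.0 * (k1 / K**3) * pcov[0, 1]
    )
    ssr = float(np.sum(w * (k - model(c, *popt)) ** 2))
    return KobsFit(
        k1=k1,
        half_sat=K,
        k_co=kco,
        k1_stderr=float(se[0]),
        half_sat_stderr=float(se[1]),
        k_co_stderr=float(np.sqrt(max(var_kco, 0.0))),
        ssr=ssr,
    )


def fit_first_order(trace: KineticTrace, fit_offset: bool = True) -> FirstOrderFit:
    """Fit a single-exponential decay offset + amp * exp(-rate * t).

    Warns when the record spans fewer than 2 time constants of the fitted
    rate or has fewer than 8 points; a flat trace yields a fit flagged
    non-distinguishable from rate 0 (rate_stderr >= rate).
    """
    if trace.times.size < 8:
        warnings.warn("fewer than 8 points for a first-order fit", stacklevel=2)
    t_, y_ = trace.times, trace.signal
    taus, _, _ = _best_lifetimes(t_, y_, 1, fit_offset)
    coeffs, _, ssr0 = _vp_solve(t_, y_, taus, fit_offset)
    me_amp = float(coeffs[0])
    me_offset = float(coeffs[1]) if fit_offset else 0.0
    tau = float(taus[0])

    if fit_offset:
        def model(t, off, amp, rate):
            return off + amp * np.exp(-rate * t)

        p0 = [me_offset, me_amp, 1.0 / tau]
    else:
        def model(t, amp, rate):
            return amp * np.exp(-rate * t)

        p0 = [me_amp, 1.0 / tau]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(model, t_, y_, p0=p0, maxfev=20000)
        rate = float(abs(popt[-1]))
        rate_se = float(np.sqrt(abs(pcov[-1, -1])))
        ssr = float(np.sum((y_ - model(t_, *popt)) ** 2))
        fit = FirstOrderFit(
            rate=max(rate, np.finfo(float).tiny),
            amplitude=float(popt[-2]),
            offset=float(popt[0]) if fit_offset else 0.0,
            ssr=ssr,
            converged=True,
            rate_stderr=rate_se,
        )
    except RuntimeError:
        fit = FirstOrderFit(
            rate=1.0 / tau,
            amplitude=me_amp,
            offset=me_offset,
            ssr=ssr0,
            converged=False,
        )
    span = trace.times[-1] - trace.times[0]
    if span * fit.rate < 2.0:
        warnings.warn(
            "trace spans fewer than 2 time constants of the fitted rate; "
            "the rate may be poorly determined",
            stacklevel=2,
        )
    return fit


def global_das_fit(
    matrix: SpectroTemporalMatrix,
    n_phases: int,
    include_nondecaying: bool = False,
) -> GlobalDASFit:
    """Global multi-exponential analysis with shared lifetimes.

    Lifetimes are common to all wavelengths; the per-wavelength amplitudes
    (the decay-associated spectra) are the exact solution of the linear
    subproblem at each candidate lifetime set (variable projection).  An
    optional non-decaying component absorbs a long-lived population that
    does not relax within the probed delay window.
    """
    if matrix.wavelengths.size < 3:
        raise ValueError("need at least 3 wavelengths for a global fit")
    if matrix.delays.size < 10:
        raise ValueError("need at least 10 delay points for a global fit")
    if n_phases >= matrix.delays.size:
        raise ValueError("n_phases must be smaller than the number of delays")
    t = matrix.delays
    Y = matrix.delta_a
    taus, ssr, ok = _best_lifetimes(t, Y, n_phases, include_nondecaying)
    coeffs, _, ssr = _vp_solve(t, Y, taus, include_nondecaying)
    order = np.argsort(taus)
    comps = tuple(
        DASComponent(lifetime=float(taus[i]), spectrum=coeffs[i]) for i in order
    )
    nondecaying = (
        DASComponent(lifetime=np.inf, spectrum=coeffs[n_phases])
        if include_nondecaying
        else None
    )
    return GlobalDASFit(components=comps, nondecaying=nondecaying, ssr=float(ssr), converged=ok)


def geminate_summary(fit: MultiExpFit | GlobalDASFit) -> GeminateSummary:
    """Fractional phase amplitudes and geminate rebinding yield.

    The yield is the summed fractional amplitude of the decaying phases --
    the fraction of photodissociated CO that rebinds within the probed
    window -- and equals 1 minus the long-lived (escaped/non-decaying)
    fraction.  For a trace fit the fitted offset plays the long-lived role;
    for a global fit each component is weighted by the Euclidean norm of its
    decay-associated spectrum.
    """
    if isinstance(fit, MultiExpFit):
        if not fit.converged:
            raise ValueError("cannot summarize a non-converged fit")
        weights = np.abs(np.asarray(fit.amplitudes))
        long_w = abs(fit.offset)
    elif isinstance(fit, GlobalDASFit):
        if not fit.converged:
            raise ValueError("cannot summarize a non-converged fit")
        weights = np.array([np.linalg.norm(c.spectrum) for c in fit.components])
        long_w = np.linalg.norm(fit.nondecaying.spectrum) if fit.nondecaying is not None else 0.0
    else:
        raise TypeError("fit must be a MultiExpFit or GlobalDASFit")
    total = weights.sum() + long_w
    if total == 0:
        raise ValueError("all amplitudes are zero")
    fracs = tuple(float(v) for v in weights / total)
    long_frac = float(long_w / total)
    return GeminateSummary(
        fractional_amplitudes=fracs,
        long_lived_fraction=long_frac,
        geminate_yield=1.0 - long_frac,
    )
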