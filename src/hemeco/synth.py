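"""Seeded synthetic-data generators for every modality the pipeline fits.

Emulated instruments: UV-vis absorption spectrophotometer (titration
series), stopped-flow spectrometer (420 nm binding transients),
femtosecond transient-absorption setup (wavelength x delay matrices),
Raman/IR spectrometer (Gaussian bands on a wavenumber axis), and a patch-
clamp amplifier (multi-channel current records, 10 kHz sampling, 2 kHz
single-pole low-pass).

Every generator is a pure function of its parameters and the noise model's
seed: identical calls produce identical arrays.  Noise is additive Gaussian,
either absolute or relative to the peak of the clean signal.  Spectral bands
are Gaussian in the wavelength/wavenumber coordinate (a documented
simplification; real Soret bands are asymmetric in energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .channels import DEFAULT_UNITARY_CURRENT_PA, ChannelTrace
from .fitting import KineticTrace, SpectroTemporalMatrix
from .kinetics import ThreeStateRates, simulate_three_state
from .raman import GaussianBand, gaussian_profile
from .titration import morrison_bound_fraction

__all__ = [
    "Spectrum",
    "SpectralBand",
    "SpectralTemplate",
    "NoiseModel",
    "HemeStockConstants",
    "TEMPLATES",
    "DEFAULT_EPSILONS_420",
    "default_das_shape",
    "gen_titration_series",
    "gen_stopped_flow",
    "gen_exponential_trace",
    "gen_ultrafast",
    "gen_vibrational_spectrum",
    "gen_patch_trace",
]


@dataclass(frozen=True)
class Spectrum:
    """A spectrum on a 1-D axis (nm for UV-vis, cm^-1 for vibrational)."""

    axis: np.ndarray
    values: np.ndarray
    axis_name: str = "wavelength_nm"

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "axis", a)
        object.__setattr__(self, "values", v)
        if a.size != v.size:
            raise ValueError("axis and values must have equal length")

    def to_csv(self, path) -> None:
        from .io import write_xy_csv

        write_xy_csv(path, self.axis, self.values, self.axis_name, "value")


@dataclass(frozen=True)
class SpectralBand:
    center: float  # nm
    fwhm: float  # nm
    amplitude: float  # AU per uM chromophore

    def __post_init__(self) -> None:
        if self.fwhm <= 0 or self.amplitude < 0:
            raise ValueError("FWHM must be positive and amplitude non-negative")


@dataclass(frozen=True)
class SpectralTemplate:
    """Absorption spectrum of one heme species as a sum of Gaussian bands."""

    species: str
    bands: tuple[SpectralBand, ...]
    baseline: float = 0.0  # AU per uM

    def __post_init__(self) -> None:
        for b in self.bands:
            if not 300.0 <= b.center <= 800.0:
                raise ValueError(f"band center {b.center} nm outside 300-800 nm")

    def epsilon(self, wavelengths) -> np.ndarray:
        """Absorbance per uM chromophore on the given wavelength grid."""
        wl = np.asarray(wavelengths, dtype=float)
        out = np.full_like(wl, self.baseline)
        for b in self.bands:
            out = out + gaussian_profile(wl, b.center, b.fwhm, b.amplitude)
        return out


#: Species catalogue.  Soret maxima and Q-band positions follow the
#: experimentally characterized forms of the heme-SUR2A complex: ferric
#: (Soret ~413 nm), ferrous 6-coordinate (split Soret 425 nm with a 390 nm
#: shoulder, Q at 531/559 nm), ferrous-CO (sharp Soret 420 nm, Q at
#: 540/569 nm), ferrous-NO (~418 nm), plus free-heme variants with broader,
#: blue-shifted Soret bands (free hemin epsilon 58.4 mM^-1 cm^-1 at 385 nm).
TEMPLATES: dict[str, SpectralTemplate] = {
    "ferric": SpectralTemplate(
        "ferric",
        (
            SpectralBand(413.0, 28.0, 0.100),
            SpectralBand(535.0, 45.0, 0.010),
        ),
    ),
    "ferrous6c": SpectralTemplate(
        "ferrous6c",
        (
            SpectralBand(425.0, 16.0, 0.085),
            SpectralBand(390.0, 30.0, 0.040),
            SpectralBand(531.0, 16.0, 0.012),
            SpectralBand(559.0, 16.0, 0.014),
        ),
    ),
    "ferrousCO": SpectralTemplate(
        "ferrousCO",
        (
            SpectralBand(420.0, 11.0, 0.115),
            SpectralBand(540.0, 16.0, 0.012),
            SpectralBand(569.0, 16.0, 0.011),
        ),
    ),
    "ferrousNO": SpectralTemplate(
        "ferrousNO",
        (
            SpectralBand(418.0, 14.0, 0.095),
            SpectralBand(545.0, 20.0, 0.011),
            SpectralBand(573.0, 20.0, 0.010),
        ),
    ),
    "free_hemin": SpectralTemplate(
        "free_hemin",
        (
            SpectralBand(385.0, 55.0, 0.0584),
            SpectralBand(610.0, 60.0, 0.004),
        ),
    ),
    "free_hemeCO": SpectralTemplate(
        "free_hemeCO",
        (
            SpectralBand(406.0, 20.0, 0.090),
            SpectralBand(537.0, 25.0, 0.010),
        ),
    ),
}

#: Absorbance per uM at 420 nm for the three kinetic species, evaluated from
#: the templates (6c is read off the red edge of its 425 nm Soret band).
DEFAULT_EPSILONS_420: dict[str, float] = {
    "6c": float(TEMPLATES["ferrous6c"].epsilon(np.array([420.0]))[0]),
    "5c": 0.055,  # transient 5-coordinate species, not directly observed
    "CO": float(TEMPLATES["ferrousCO"].epsilon(np.array([420.0]))[0]),
}


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise, absolute or relative to the clean-signal peak."""

    sigma: float
    relative: bool = False
    seed: int = 0
    kind: str = "additive-gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "additive-gaussian":
            raise ValueError("only additive-gaussian noise is supported")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Add noise; for relative mode sigma scales the max |clean| value."""
        if self.sigma == 0:
            return np.array(clean, dtype=float)
        scale = self.sigma * (np.max(np.abs(clean)) if self.relative else 1.0)
        if rng is None:
            rng = self.rng()
        return np.asarray(clean, dtype=float) + rng.normal(0.0, scale, np.shape(clean))


NO_NOISE = NoiseModel(sigma=0.0)


@dataclass(frozen=True)
class HemeStockConstants:
    """Constants used to standardize heme and CO stock solutions."""

    epsilon_385: float = 58.4  # mM^-1 cm^-1, hemin quantification wavelength
    co_saturated_conc: float = 1000.0  # uM, CO-saturated buffer


def gen_titration_series(
    kd: float,
    p_total: float,
    ligand_concs,
    bound_template: SpectralTemplate,
    free_template: SpectralTemplate,
    noise: NoiseModel = NO_NOISE,
    wavelength_grid: np.ndarray | None = None,
) -> list[Spectrum]:
    """Spectra recorded after stepwise ligand additions to a protein cuvette.

    The bound fraction at each point follows the exact quadratic
    mass-balance (ligand depletion included, no free~total approximation);
    each spectrum is p_total * (fb * eps_bound + (1 - fb) * eps_free) plus
    noise.  Cuvette dilution is neglected.
    """
    if p_total <= 0:
        raise ValueError("protein total must be positive")
    lc = np.asarray(ligand_concs, dtype=float)
    if np.any(lc < 0) or np.any(np.diff(lc) < 0):
        raise ValueError("ligand concentrations must be non-negative and non-decreasing")
    wl = (
        np.arange(350.0, 700.0 + 1e-9, 1.0)
        if wavelength_grid is None
        else np.asarray(wavelength_grid, dtype=float)
    )
    eps_b = bound_template.epsilon(wl)
    eps_f = free_template.epsilon(wl)
    fb = morrison_bound_fraction(p_total, lc, kd)
    clean = p_total * (fb[:, None] * eps_b[None, :] + (1.0 - fb[:, None]) * eps_f[None, :])
    rng = noise.rng()
    scale = np.max(np.abs(clean))
    out = []
    for row in clean:
        if noise.sigma == 0:
            vals = row
        else:
            sigma = noise.sigma * scale if noise.relative else noise.sigma
            vals = row + rng.normal(0.0, sigma, row.shape)
        out.append(Spectrum(axis=wl, values=vals))
    return out


def gen_stopped_flow(
    rates: ThreeStateRates,
    co_conc: float,
    heme_conc: float = 2.0,
    epsilons: dict[str, float] | None = None,
    duration: float = 1.0,
    n_points: int = 1000,
    noise: NoiseModel = NO_NOISE,
) -> KineticTrace:
    """420 nm stopped-flow absorbance transient of CO binding.

    Simulates the three-state system from a pure 6c start and projects the
    state fractions through per-species absorbances (AU per uM at the
    monitoring wavelength).  Warns when [CO] < 10x the heme concentration.
    """
    eps = DEFAULT_EPSILONS_420 if epsilons is None else epsilons
    t = np.linspace(0.0, duration, n_points)
    # strictly increasing grid from 0; trajectory start = mixing dead point
    traj = simulate_three_state(rates, co_conc, (1.0, 0.0, 0.0), t, heme_conc=heme_conc)
    clean = heme_conc * (
        eps["6c"] * traj.fractions[:, 0]
        + eps["5c"] * traj.fractions[:, 1]
        + eps["CO"] * traj.fractions[:, 2]
    )
    return KineticTrace(times=t, signal=noise.apply(clean), time_unit="s", wavelength=420.0)


def gen_exponential_trace(
    rate: float,
    amplitude: float,
    offset: float,
    duration: float,
    n_points: int,
    noise: NoiseModel = NO_NOISE,
    time_unit: str = "s",
    wavelength: float | None = None,
) -> KineticTrace:
    """Single-exponential absorbance trace offset + amplitude * exp(-rate*t).

    Plumbing shared by the apo-myoglobin heme-transfer and NO-replacement
    decay simulations.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    t = np.linspace(0.0, duration, n_points)
    clean = offset + amplitude * np.exp(-rate * t)
    return KineticTrace(
        times=t, signal=noise.apply(clean), time_unit=time_unit, wavelength=wavelength
    )


def default_das_shape(wavelengths) -> np.ndarray:
    """Canonical 5c-minus-CO difference spectrum near the Soret band.

    Induced absorption of the photoproduct (~437 nm) minus the bleach of the
    CO complex (~420 nm); all geminate phases share this shape because they
    interconvert the same two species.
    """
    wl = np.asarray(wavelengths, dtype=float)
    return gaussian_profile(wl, 437.0, 14.0, 1.0) - gaussian_profile(wl, 420.0, 12.0, 1.2)


def gen_ultrafast(
    phases: list[tuple[float, float]] | None = None,
    das_shapes: np.ndarray | None = None,
    delay_grid: np.ndarray | None = None,
    wavelength_grid: np.ndarray | None = None,
    long_lived_fraction: float = 0.10,
    long_lived_shape: np.ndarray | None = None,
    noise: NoiseModel = NO_NOISE,
) -> SpectroTemporalMatrix:
    """Transient-absorption matrix after CO photodissociation.

    delta_A(t, lambda) = sum_i amp_i * das_i(lambda) * exp(-t / tau_i)
                         + long_lived_fraction * das_long(lambda)  + noise.

    Defaults emulate the measured geminate-recombination kinetics: decaying
    phases of 22 ps (14%), 150 ps (26%) and 2.5 ns (50%) plus a 10%
    long-lived (escaped-CO) population, probed on a 60-point logarithmic
    delay grid from 10 ps to 4 ns across 20 wavelengths in the Soret region.
    Fractional amplitudes plus the long-lived fraction must sum to 1.
    """
    if phases is None:
        phases = [(22.0, 0.14), (150.0, 0.26), (2500.0, 0.50)]
    total = sum(a for _, a in phases) + long_lived_fraction
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"phase amplitudes + long-lived fraction must sum to 1, got {total}")
    t = (
        np.geomspace(10.0, 4000.0, 60)
        if delay_grid is None
        else np.asarray(delay_grid, dtype=float)
    )
    wl = (
        np.linspace(400.0, 460.0, 20)
        if wavelength_grid is None
        else np.asarray(wavelength_grid, dtype=float)
    )
    shared = default_das_shape(wl)
    shapes = (
        np.tile(shared, (len(phases), 1))
        if das_shapes is None
        else np.asarray(das_shapes, dtype=float)
    )
    if shapes.shape != (len(phases), wl.size):
        raise ValueError("das_shapes must have shape (n_phases, n_wavelengths)")
    long_shape = shared if long_lived_shape is None else np.asarray(long_lived_shape, float)
    clean = long_lived_fraction * long_shape[None, :] * np.ones((t.size, 1))
    for (tau, amp), shape in zip(phases, shapes):
        clean = clean + amp * np.exp(-t / tau)[:, None] * shape[None, :]
    return SpectroTemporalMatrix(delays=t, wavelengths=wl, delta_a=noise.apply(clean))


def gen_vibrational_spectrum(
    bands: list[GaussianBand],
    window: tuple[float, float],
    baseline_slope: float = 0.0,
    baseline_intercept: float = 0.0,
    noise: NoiseModel = NO_NOISE,
    step: float = 1.0,
) -> Spectrum:
    """Raman/IR spectrum: Gaussian bands on a linear baseline, 1 cm^-1 grid."""
    lo, hi = window
    for b in bands:
        if not lo <= b.center <= hi:
            raise ValueError(f"band center {b.center} outside window {window}")
    x = np.arange(lo, hi + step / 2, step)
    clean = baseline_intercept + baseline_slope * x
    for b in bands:
        clean = clean + b.profile(x)
    return Spectrum(axis=x, values=noise.apply(clean), axis_name="wavenumber_cm1")


def _two_state_dwells(rng, open_rate, close_rate, duration, start_open):
    """Alternating exponential dwell times covering at least `duration`.

    Drawn in blocks for speed: even-index dwells belong to the starting
    state, odd-index dwells to the other.
    """
    rate_first = close_rate if start_open else open_rate
    rate_second = open_rate if start_open else close_rate
    mean_cycle = 1.0 / rate_first + 1.0 / rate_second
    dwells = np.empty(0)
    while dwells.sum() <= duration:
        n_cycles = max(16, int(1.5 * (duration - dwells.sum()) / mean_cycle) + 1)
        block = np.empty(2 * n_cycles)
        block[0::2] = rng.exponential(1.0 / rate_first, n_cycles)
        block[1::2] = rng.exponential(1.0 / rate_second, n_cycles)
        dwells = np.concatenate([dwells, block])
    return dwells


def gen_patch_trace(
    true_popen: float,
    n_channels: int = 5,
    unitary_current: float = DEFAULT_UNITARY_CURRENT_PA,
    open_rate: float | None = None,
    close_rate: float | None = None,
    sampling_rate: float = 10_000.0,
    duration: float = 120.0,
    filter_cutoff: float = 2000.0,
    noise: NoiseModel = NoiseModel(sigma=0.5, seed=0),
) -> ChannelTrace:
    """Simulated multi-channel inside-out patch current record.

    Each channel is an independent two-state Markov process with exponential
    dwell times; open channels each pass ``unitary_current`` pA.  The summed
    current is low-pass filtered (single pole at ``filter_cutoff``) and
    Gaussian noise is added.  Defaults: 10 kHz sampling, 2 kHz filter,
    120 s record, 5.46 pA unitary current (78 pS x 70 mV).

    If only one of open_rate/close_rate is given the other is derived from
    ``true_popen``; by default the mean open time is 20 ms (close_rate
    50 s^-1).  Supplying both requires consistency with ``true_popen``.
    """
    if not 0.0 <= true_popen < 1.0:
        raise ValueError("true_popen must lie in [0, 1)")
    if close_rate is None and open_rate is None:
        close_rate = 50.0
    if open_rate is None:
        open_rate = close_rate * true_popen / (1.0 - true_popen)
    elif close_rate is None:
        close_rate = open_rate * (1.0 - true_popen) / true_popen if true_popen > 0 else np.inf
    else:
        implied = open_rate / (open_rate + close_rate)
        if abs(implied - true_popen) > 1e-6:
            raise ValueError(
                f"open/close rates imply Popen {implied:.4f}, inconsistent with {true_popen}"
            )

    n_samples = int(round(duration * sampling_rate))
    sample_times = np.arange(n_samples) / sampling_rate
    rng = noise.rng()
    total_open = np.zeros(n_samples)
    for _ in range(n_channels):
        if open_rate == 0.0:
            continue
        start_open = bool(rng.random() < true_popen)
        dwells = _two_state_dwells(rng, open_rate, close_rate, duration, start_open)
        edges = np.cumsum(dwells)
        interval = np.searchsorted(edges, sample_times, side="right")
        is_open = (interval % 2 == 0) if start_open else (interval % 2 == 1)
        total_open += is_open

    clean = total_open * unitary_current
    if filter_cutoff is not None and filter_cutoff > 0:
        dt = 1.0 / sampling_rate
        rc = 1.0 / (2.0 * np.pi * filter_cutoff)
        a = dt / (rc + dt)
        clean = lfilter([a], [1.0, -(1.0 - a)], clean, zi=[clean[0] * (1.0 - a)])[0]
    current = clean if noise.sigma == 0 else clean + rng.normal(0.0, noise.sigma, n_samples)
    return ChannelTrace(
        sampling_rate=sampling_rate,
        current=current,
        unitary_current=unitary_current,
        n_channels=n_channels,
    )
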