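"""End-to-end simulate -> fit -> cross-validate workflows.

The headline internal-consistency check mirrors the experimental logic:
stopped-flow transients across a [CO] grid give the k_obs hyperbola and
hence kCO; an NO-replacement decay gives k_m2; their ratio is the kinetic
Kd, which is compared with the equilibrium Kd from a Morrison titration.
Further workflows cover the ultrafast geminate analysis, Raman
deconvolution, titration alone, and patch Popen estimation.

Every stochastic stage derives its seed deterministically from the run
seed, so identical configurations produce identical JSON reports.
Timestamps appear only in log files, never in reports.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import channels, fitting, kinetics, raman, synth, titration
from .io import sha256_digest, write_json_report

__all__ = [
    "PipelineError",
    "RunConfig",
    "CrossValidationReport",
    "default_config",
    "run_kinetic_workflow",
    "run_ultrafast_workflow",
    "run_raman_workflow",
    "run_titration_workflow",
    "run_patch_workflow",
]


class PipelineError(RuntimeError):
    """A workflow stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One workflow run: name, module parameters, seed, output directory."""

    workflow: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"workflow": self.workflow, "seed": self.seed, "outdir": self.outdir,
             "params": self.params},
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        payload = yaml.safe_load(text)
        return cls(
            workflow=payload["workflow"],
            params=payload.get("params") or {},
            seed=int(payload.get("seed", 0)),
            outdir=payload.get("outdir"),
        )


@dataclass(frozen=True)
class CrossValidationReport:
    """Kinetic vs equilibrium dissociation-constant cross-check."""

    kd_kinetic: float  # uM, k_m2 / kCO
    kd_kinetic_stderr: float  # first-order (delta-method) propagation
    kd_equilibrium: float  # uM, Morrison titration
    kd_equilibrium_stderr: float
    agreement_ratio: float  # kd_equilibrium / kd_kinetic
    details: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kd_kinetic <= 0 or self.kd_equilibrium <= 0:
            raise ValueError("both dissociation constants must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# experimental defaults: 2 uM protein in the flow, CO grid up to the 1 mM
# saturated-stock ceiling, 3 uM protein titrations, 120 s patch records
_DEFAULTS: dict[str, dict] = {
    "kinetic": {
        "rates": {"k1": 25.0, "k_m1": 5000.0, "k2": 54.0, "k_m2": 0.05},
        "heme_conc": 2.0,
        "co_grid": [float(c) for c in np.geomspace(25.0, 800.0, 8)],
        "n_phases": 1,
        "stopped_flow_noise": 0.003,
        "replacement": {
            "duration": 120.0,
            "n_points": 600,
            "amplitude": 0.25,
            "offset": 0.35,
            "noise": 0.003,
        },
        "titration": {
            "kd": 0.6,
            "p_total": 3.0,
            "ligand_concs": [float(c) for c in np.linspace(0.0, 10.0, 10)],
            "noise": 0.02,
        },
    },
    "ultrafast": {
        "phases": [[22.0, 0.14], [150.0, 0.26], [2500.0, 0.50]],
        "long_lived_fraction": 0.10,
        "noise": 0.02,
        "n_phases": 3,
    },
    "raman": {
        "protein_center": 494.0,
        "free_center": 525.0,
        "fwhm": 20.0,
        "area_fractions": [0.85, 0.15],
        "window": [450.0, 600.0],
        "noise": 0.01,
        "pair": {"nu_feco": 494.0, "nu_co": 1965.0},
    },
    "titration": {
        "kd": 0.6,
        "p_total": 3.0,
        "ligand_concs": [float(c) for c in np.linspace(0.0, 10.0, 10)],
        "noise": 0.02,
        "model": "morrison",
        "wavelength": 420.0,
    },
    "patch": {
        "true_popen": 0.303,
        "n_channels": 5,
        "duration": 120.0,
        "noise": 0.5,
    },
}


def default_config(workflow: str, seed: int = 0, outdir: str | None = None) -> RunConfig:
    if workflow not in _DEFAULTS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {sorted(_DEFAULTS)}")
    import copy

    return RunConfig(workflow=workflow, params=copy.deepcopy(_DEFAULTS[workflow]),
                     seed=seed, outdir=outdir)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in (np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF)]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage label."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def _outpath(config: RunConfig, name: str) -> Path | None:
    if config.outdir is None:
        return None
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


def _log(config: RunConfig, lines: list[str]) -> None:
    path = _outpath(config, f"{config.workflow}.log")
    if path is not None:
        stamp = time.strftime("%Y-%m-%d %H:%M:%S")
        path.write_text("\n".join([f"# {config.workflow} run at {stamp}"] + lines) + "\n")


def run_kinetic_workflow(config: RunConfig) -> CrossValidationReport:
    """Full kinetic cross-validation: kobs grid + replacement + titration."""
    p = config.params
    digests: dict[str, str] = {}
    log: list[str] = [f"seed = {config.seed}", f"params = {p}"]

    with _stage("rates"):
        rates = kinetics.ThreeStateRates(**p["rates"])
    seeds = _stage_seeds(config.seed, len(p["co_grid"]) + 2)

    with _stage("stopped_flow"):
        points = []
        for i, co in enumerate(p["co_grid"]):
            k_true = kinetics.kobs_hyperbolic(rates, co)
            trace = synth.gen_stopped_flow(
                rates,
                co_conc=co,
                heme_conc=p["heme_conc"],
                duration=6.0 / k_true,
                n_points=500,
                noise=synth.NoiseModel(sigma=p["stopped_flow_noise"], seed=seeds[i]),
            )
            fit = fitting.fit_multiexp(trace, n_phases=p["n_phases"])
            k_obs = 1.0 / min(fit.lifetimes)  # first (fastest) phase
            points.append(kinetics.ObservedRatePoint(co_conc=co, k_obs=k_obs))
            path = _outpath(config, f"stopped_flow_{co:g}uM.csv")
            if path is not None:
                trace.to_csv(path)
                digests[path.name] = sha256_digest(path)
            log.append(f"[CO] = {co:g} uM -> k_obs = {k_obs:.4g} s^-1")

    with _stage("kobs_fit"):
        kfit = fitting.fit_kobs_curve(points)
        log.append(f"k1 = {kfit.k1:.4g} s^-1, kCO = {kfit.k_co:.4g} uM^-1 s^-1")

    with _stage("replacement"):
        rep = p.get("replacement")
        if rep is None:
            raise PipelineError(
                "stage 'replacement' failed: configuration lacks the replacement-trace "
                "stage required to determine k_m2"
            )
        rate_true = kinetics.replacement_observed_rate(rates)
        rep_trace = synth.gen_exponential_trace(
            rate=rate_true,
            amplitude=rep["amplitude"],
            offset=rep["offset"],
            duration=rep["duration"],
            n_points=rep["n_points"],
            noise=synth.NoiseModel(sigma=rep["noise"], seed=seeds[-2]),
            wavelength=420.0,
        )
        rep_fit = fitting.fit_first_order(rep_trace)
        if not rep_fit.converged:
            raise PipelineError("stage 'replacement' failed: first-order fit did not converge")
        path = _outpath(config, "replacement_420nm.csv")
        if path is not None:
            rep_trace.to_csv(path)
            digests[path.name] = sha256_digest(path)
        log.append(f"k_m2 = {rep_fit.rate:.4g} s^-1")

    with _stage("titration"):
        tit = p["titration"]
        spectra = synth.gen_titration_series(
            kd=tit["kd"],
            p_total=tit["p_total"],
            ligand_concs=np.asarray(tit["ligand_concs"]),
            bound_template=synth.TEMPLATES["ferrousCO"],
            free_template=synth.TEMPLATES["ferrous6c"],
            noise=synth.NoiseModel(sigma=tit["noise"], relative=True, seed=seeds[-1]),
        )
        iso = titration.extract_isotherm(
            spectra, tit["ligand_concs"], wavelength=420.0, protein_total=tit["p_total"]
        )
        iso_fit = titration.fit_isotherm(iso, model="morrison")
        path = _outpath(config, "titration_isotherm.csv")
        if path is not None:
            iso.to_csv(path)
            digests[path.name] = sha256_digest(path)
        log.append(f"Kd_equilibrium = {iso_fit.kd:.4g} uM")

    with _stage("cross_validation"):
        kd_kin = rep_fit.rate / kfit.k_co
        # delta method: var(a/b) ~ (1/b)^2 var(a) + (a/b^2)^2 var(b)
        var = (rep_fit.rate_stderr / kfit.k_co) ** 2 + (
            rep_fit.rate / kfit.k_co**2
        ) ** 2 * kfit.k_co_stderr**2
        report = CrossValidationReport(
            kd_kinetic=kd_kin,
            kd_kinetic_stderr=float(np.sqrt(var)),
            kd_equilibrium=iso_fit.kd,
            kd_equilibrium_stderr=iso_fit.kd_stderr,
            agreement_ratio=iso_fit.kd / kd_kin,
            details={
                "k1": kfit.k1,
                "k1_stderr": kfit.k1_stderr,
                "k_co": kfit.k_co,
                "k_co_stderr": kfit.k_co_stderr,
                "half_sat_uM": kfit.half_sat,
                "k_m2": rep_fit.rate,
                "k_m2_stderr": rep_fit.rate_stderr,
                "k_obs_points": [[pt.co_conc, pt.k_obs] for pt in points],
                "titration_model": iso_fit.model,
            },
            input_digests=digests,
        )
    path = _outpath(config, "crossval_report.json")
    if path is not None:
        write_json_report(path, report.to_dict())
    _log(config, log)
    return report


def run_ultrafast_workflow(config: RunConfig) -> dict:
    """Geminate recombination: generate matrix -> global DAS fit -> summary."""
    p = config.params
    digests: dict[str, str] = {}
    (seed,) = _stage_seeds(config.seed, 1)
    with _stage("generate_matrix"):
        matrix = synth.gen_ultrafast(
            phases=[tuple(ph) for ph in p["phases"]],
            long_lived_fraction=p["long_lived_fraction"],
            noise=synth.NoiseModel(sigma=p["noise"], relative=True, seed=seed),
        )
        path = _outpath(config, "ultrafast_matrix.csv")
        if path is not None:
            matrix.to_csv(path)
            digests[path.name] = sha256_digest(path)
    with _stage("global_das_fit"):
        fit = fitting.global_das_fit(matrix, n_phases=p["n_phases"], include_nondecaying=True)
    with _stage("geminate_summary"):
        summary = fitting.geminate_summary(fit)
    report = {
        "lifetimes_ps": list(fit.lifetimes),
        "fractional_amplitudes": list(summary.fractional_amplitudes),
        "long_lived_fraction": summary.long_lived_fraction,
        "geminate_yield": summary.geminate_yield,
        "lifetime_span_ratio": max(fit.lifetimes) / min(fit.lifetimes),
        "ssr": fit.ssr,
        "input_digests": digests,
    }
    path = _outpath(config, "ultrafast_report.json")
    if path is not None:
        write_json_report(path, report)
    _log(config, [f"seed = {config.seed}", f"lifetimes = {report['lifetimes_ps']}"])
    return report


def run_raman_workflow(config: RunConfig) -> dict:
    """Two-band Fe-CO window deconvolution plus backbonding classification."""
    p = config.params
    digests: dict[str, str] = {}
    (seed,) = _stage_seeds(config.seed, 1)
    with _stage("generate_spectrum"):
        area_p, area_f = p["area_fractions"]
        # equal widths: amplitude ratio equals area ratio
        bands = [
            raman.GaussianBand(p["protein_center"], p["fwhm"], area_p),
            raman.GaussianBand(p["free_center"], p["fwhm"], area_f),
        ]
        spectrum = synth.gen_vibrational_spectrum(
            bands,
            window=tuple(p["window"]),
            noise=synth.NoiseModel(sigma=p["noise"], relative=True, seed=seed),
        )
        path = _outpath(config, "raman_feco_window.csv")
        if path is not None:
            spectrum.to_csv(path)
            digests[path.name] = sha256_digest(path)
    with _stage("deconvolve"):
        deconv = raman.deconvolve_bands(
            spectrum.axis, spectrum.values, window=tuple(p["window"]), n_bands=2
        )
        frac = raman.fraction_protein_bound(
            deconv, protein_center=p["protein_center"], free_center=p["free_center"]
        )
    with _stage("classify"):
        pair = raman.VibrationalPair(
            nu_feco=p["pair"]["nu_feco"], nu_co=p["pair"]["nu_co"], label="sample"
        )
        label, distances = raman.classify_backbonding(pair, raman.load_reference_lines())
    report = {
        "fraction_protein_bound": frac,
        "bands": [
            {"center": b.center, "fwhm": b.fwhm, "area": b.area} for b in deconv.bands
        ],
        "classification": label,
        "distances_cm1": distances,
        "input_digests": digests,
    }
    path = _outpath(config, "raman_report.json")
    if path is not None:
        write_json_report(path, report)
    _log(config, [f"seed = {config.seed}", f"fraction bound = {frac:.4f}"])
    return report


def run_titration_workflow(config: RunConfig) -> dict:
    p = config.params
    digests: dict[str, str] = {}
    (seed,) = _stage_seeds(config.seed, 1)
    with _stage("generate_titration"):
        spectra = synth.gen_titration_series(
            kd=p["kd"],
            p_total=p["p_total"],
            ligand_concs=np.asarray(p["ligand_concs"]),
            bound_template=synth.TEMPLATES["ferrousCO"],
            free_template=synth.TEMPLATES["ferrous6c"],
            noise=synth.NoiseModel(sigma=p["noise"], relative=True, seed=seed),
        )
    with _stage("extract_isotherm"):
        iso = titration.extract_isotherm(
            spectra, p["ligand_concs"], wavelength=p["wavelength"], protein_total=p["p_total"]
        )
        path = _outpath(config, "titration_isotherm.csv")
        if path is not None:
            iso.to_csv(path)
            digests[path.name] = sha256_digest(path)
    with _stage("fit_isotherm"):
        fit = titration.fit_isotherm(iso, model=p["model"])
    report = {
        "kd_uM": fit.kd,
        "kd_stderr": fit.kd_stderr,
        "model": fit.model,
        "rmax": fit.rmax,
        "ssr": fit.ssr,
        "input_digests": digests,
    }
    path = _outpath(config, "titration_report.json")
    if path is not None:
        write_json_report(path, report)
    _log(config, [f"seed = {config.seed}", f"Kd = {fit.kd:.4g} uM ({fit.model})"])
    return report


def run_patch_workflow(config: RunConfig) -> dict:
    p = config.params
    digests: dict[str, str] = {}
    (seed,) = _stage_seeds(config.seed, 1)
    with _stage("generate_patch"):
        trace = synth.gen_patch_trace(
            true_popen=p["true_popen"],
            n_channels=p["n_channels"],
            duration=p["duration"],
            noise=synth.NoiseModel(sigma=p["noise"], seed=seed),
        )
        path = _outpath(config, "patch_trace.csv")
        if path is not None:
            trace.to_csv(path)
            digests[path.name] = sha256_digest(path)
    with _stage("idealize"):
        stats = channels.idealize_popen(trace, n_channels=p["n_channels"])
    report = {
        "popen": stats.popen,
        "npo": stats.npo,
        "n_channels": stats.n_channels,
        "level_occupancy": list(stats.level_occupancy),
        "input_digests": digests,
    }
    path = _outpath(config, "patch_report.json")
    if path is not None:
        write_json_report(path, report)
    _log(config, [f"seed = {config.seed}", f"Popen = {stats.popen:.4f}"])
    return report


_WORKFLOWS = {
    "kinetic": run_kinetic_workflow,
    "ultrafast": run_ultrafast_workflow,
    "raman": run_raman_workflow,
    "titration": run_titration_workflow,
    "patch": run_patch_workflow,
}


def run_workflow(config: RunConfig):
    try:
        fn = _WORKFLOWS[config.workflow]
    except KeyError:
        raise ValueError(f"unknown workflow {config.workflow!r}") from None
    return fn(config)
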