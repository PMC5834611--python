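"""Equilibrium binding analysis from spectrophotometric titrations.

A titration adds ligand stepwise to a cuvette of protein and records a
spectrum after each addition.  The response at an analysis wavelength versus
total ligand forms a binding isotherm.  Two models are fitted:

* hyperbolic, R = Rmax * L / (L + Kd), valid when ligand depletion is
  negligible (protein concentration << Kd), using total ligand for free;
* Morrison (quadratic), R = Rmax * fb with the exact mass-balance bound
  fraction

      fb = (P + L + Kd - sqrt((P + L + Kd)^2 - 4 P L)) / (2 P),

  required for tight-binding ligands where Kd is comparable to the protein
  concentration (the CO case).

The minus root of the quadratic is always the physical one: the plus root
exceeds 1 for any positive P, L, Kd.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingIsotherm",
    "IsothermFit",
    "morrison_bound_fraction",
    "extract_isotherm",
    "fit_isotherm",
]


def morrison_bound_fraction(p_total, ligand_total, kd):
    """Exact quadratic mass-balance bound fraction [PL]/P_total.

    Valid for any non-negative P, L, Kd; monotone non-decreasing in L and
    always within [0, 1].
    """
    p = np.asarray(p_total, dtype=float)
    lig = np.asarray(ligand_total, dtype=float)
    if np.any(p <= 0):
        raise ValueError("protein total must be positive")
    if np.any(lig < 0) or np.any(np.asarray(kd) < 0):
        raise ValueError("ligand and Kd must be non-negative")
    s = p + lig + kd
    disc = s * s - 4.0 * p * lig
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p)
    return np.clip(fb, 0.0, 1.0)


@dataclass(frozen=True)
class BindingIsotherm:
    """Equilibrium response versus total ligand concentration."""

    ligand_concs: np.ndarray  # uM, total added ligand, ascending
    response: np.ndarray  # delta-A at the analysis wavelength, AU
    protein_total: float | None = None  # uM, required for Morrison fitting
    wavelength: float | None = None  # nm

    def __post_init__(self) -> None:
        lc = np.asarray(self.ligand_concs, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "ligand_concs", lc)
        object.__setattr__(self, "response", r)
        if lc.ndim != 1 or lc.size != r.size:
            raise ValueError("ligand_concs and response must be equal-length 1-D")
        if np.any(lc < 0) or np.any(np.diff(lc) < 0):
            raise ValueError("ligand_concs must be non-negative and ascending")
        if not np.all(np.isfinite(r)):
            raise ValueError("response must be finite")

    def to_csv(self, path) -> None:
        from .io import write_xy_csv

        write_xy_csv(path, self.ligand_concs, self.response, "conc_uM", "dA")


@dataclass(frozen=True)
class IsothermFit:
    """Fitted dissociation constant and response amplitude."""

    model: str  # "hyperbolic" | "morrison"
    kd: float  # uM
    rmax: float  # AU
    kd_stderr: float
    ssr: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("fitted Kd must be positive")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def extract_isotherm(
    spectra,
    ligand_concs,
    wavelength: float,
    reference_wavelength: float | None = None,
    protein_total: float | None = None,
) -> BindingIsotherm:
    """Build a binding isotherm from a titration series of spectra.

    The response at each ligand point is A(lambda) minus A(lambda) of the
    zero-ligand spectrum; if ``reference_wavelength`` is given the reading is
    the difference A(lambda) - A(lambda_ref) before baselining (emulating a
    difference titration).  The analysis wavelength snaps to the nearest
    grid point with a warning if off-grid.

    ``spectra`` is a sequence of objects with ``axis`` (nm) and ``values``
    (AU) arrays on a common grid, ordered to match ``ligand_concs``; the
    series must include a zero-ligand spectrum.
    """
    ligand_concs = np.asarray(ligand_concs, dtype=float)
    if len(spectra) != ligand_concs.size:
        raise ValueError("one spectrum per ligand concentration required")
    if not np.any(ligand_concs == 0):
        raise ValueError("titration series must include a zero-ligand spectrum")
    axis = np.asarray(spectra[0].axis, dtype=float)
    for s in spectra[1:]:
        if not np.array_equal(np.asarray(s.axis, dtype=float), axis):
            raise ValueError("all spectra must share the same wavelength axis")

    def _reading(spec, wl):
        idx = int(np.argmin(np.abs(axis - wl)))
        if abs(axis[idx] - wl) > 1e-9:
            warnings.warn(
                f"wavelength {wl} nm off-grid; snapped to {axis[idx]} nm", stacklevel=3
            )
        return float(np.asarray(spec.values)[idx])

    raw = np.array(
        [
            _reading(s, wavelength)
            - (_reading(s, reference_wavelength) if reference_wavelength is not None else 0.0)
            for s in spectra
        ]
    )
    zero_idx = int(np.flatnonzero(ligand_concs == 0)[0])
    response = raw - raw[zero_idx]
    order = np.argsort(ligand_concs, kind="stable")
    return BindingIsotherm(
        ligand_concs=ligand_concs[order],
        response=response[order],
        protein_total=protein_total,
        wavelength=wavelength,
    )


def _fit_hyperbolic(lc, resp):
    def model(L, rmax, kd):
        return rmax * L / (L + kd)

    span = resp[-1] - resp[0]
    scale = span if abs(span) > 0 else (np.max(np.abs(resp)) or 1.0)
    half = np.argmin(np.abs(resp - 0.5 * scale))
    kd0 = max(lc[half], lc[lc > 0].min() if np.any(lc > 0) else 1.0)
    popt, pcov = curve_fit(model, lc, resp, p0=[scale, kd0], maxfev=20000)
    ssr = float(np.sum((resp - model(lc, *popt)) ** 2))
    return popt, pcov, ssr


def fit_isotherm(iso: BindingIsotherm, model: str = "auto") -> IsothermFit:
    """Fit Kd and Rmax to a binding isotherm.

    ``model='auto'`` first fits the hyperbola and switches to the Morrison
    quadratic when the fitted Kd is below 10x the protein concentration,
    i.e. when ligand depletion is non-negligible.
    """
    if model not in ("auto", "hyperbolic", "morrison"):
        raise ValueError(f"unknown model {model!r}")
    lc, resp = iso.ligand_concs, iso.response
    if lc.size < 5:
        raise ValueError("at least 5 titration points required")

    if model in ("auto", "hyperbolic"):
        popt, pcov, ssr = _fit_hyperbolic(lc, resp)
        if model == "hyperbolic" or iso.protein_total is None or popt[1] >= 10.0 * iso.protein_total:
            if model == "auto" and iso.protein_total is None:
                warnings.warn(
                    "auto model selection without protein_total: using hyperbolic",
                    stacklevel=2,
                )
            return IsothermFit(
                model="hyperbolic",
                kd=float(popt[1]),
                rmax=float(popt[0]),
                kd_stderr=float(np.sqrt(pcov[1, 1])),
                ssr=ssr,
            )

    if iso.protein_total is None:
        raise ValueError("Morrison fitting requires the protein total concentration")
    p = iso.protein_total

    def model_fn(L, rmax, kd):
        return rmax * morrison_bound_fraction(p, L, kd)

    span = resp[-1] - resp[0]
    scale = span if abs(span) > 0 else (np.max(np.abs(resp)) or 1.0)
    half = np.argmin(np.abs(resp - 0.5 * scale))
    kd0 = max(lc[half], 1e-3)
    popt, pcov = curve_fit(
        model_fn, lc, resp, p0=[scale, kd0], bounds=([-np.inf, 1e-12], [np.inf, np.inf]), maxfev=20000
    )
    ssr = float(np.sum((resp - model_fn(lc, *popt)) ** 2))
    return IsothermFit(
        model="morrison",
        kd=float(popt[1]),
        rmax=float(popt[0]),
        kd_stderr=float(np.sqrt(pcov[1, 1])),
        ssr=ssr,
    )
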