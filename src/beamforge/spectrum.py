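"""Photon energy spectrum and the one-parameter slope tuning.

The beam model represents the spectrum as a binned distribution g(E) and
adjusts it with a single slope s applied around the mean energy of the
initial spectrum:

    g_s(E) = g0(E) * (1 + s * (E - <E>_g0))

Positive s hardens the beam (shifts weight above the mean), negative s
softens it; the total probability is conserved for every admissible s, and
the mean energy shifts by exactly s * Var_g0(E).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .types import BeamDataError, PDDCurve

__all__ = [
    "EnergySpectrum",
    "tune_spectrum",
    "mean_energy",
    "fit_spectrum_slope",
    "default_spectrum_6mv",
]


@dataclass(frozen=True)
class EnergySpectrum:
    """Binned photon energy distribution.

    energy_mev are strictly increasing bin centers; weight sums to one.
    slope records the tuning applied relative to the initial spectrum.
    """

    energy_mev: np.ndarray
    weight: np.ndarray
    slope: float = 0.0

    def __post_init__(self):
        e = np.asarray(self.energy_mev, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        if e.ndim != 1 or e.shape != w.shape or e.size == 0:
            raise BeamDataError("spectrum needs matching 1-D energy/weight arrays")
        if np.any(np.diff(e) <= 0):
            raise BeamDataError("energy bins must be strictly increasing")
        if np.any(w < 0):
            raise BeamDataError("spectrum weights must be >= 0")
        total = w.sum()
        if abs(total - 1.0) > 1e-9:
            w = w / total
        object.__setattr__(self, "energy_mev", e)
        object.__setattr__(self, "weight", w)

    @property
    def n_bins(self) -> int:
        return self.energy_mev.size

    def variance(self) -> float:
        m = mean_energy(self)
        return float(np.sum(self.weight * (self.energy_mev - m) ** 2))


def mean_energy(g: EnergySpectrum) -> float:
    """Spectrum-weighted mean energy <E>_g in MeV."""
    return float(np.sum(g.energy_mev * g.weight))


def tune_spectrum(g0: EnergySpectrum, s: float) -> EnergySpectrum:
    """Apply the slope adjustment g_s(E) = g0(E) (1 + s (E - <E>_g0)).

    Raises a domain error if the multiplicative factor would go
    non-positive in any bin carrying weight.
    """
    ebar = mean_energy(g0)
    factor = 1.0 + s * (g0.energy_mev - ebar)
    bad = (factor <= 0) & (g0.weight > 0)
    if np.any(bad):
        e_bad = g0.energy_mev[bad][0]
        raise BeamDataError(
            f"slope s={s:g} makes the spectrum non-positive at E={e_bad:g} MeV"
        )
    w = g0.weight * factor
    return EnergySpectrum(g0.energy_mev, w, slope=g0.slope + s)


def slope_bounds(g0: EnergySpectrum, margin: float = 0.9) -> tuple:
    """Admissible slope interval keeping 1 + s(E - Ebar) positive.

    margin < 1 shrinks the open interval to a safely closed one.
    """
    ebar = mean_energy(g0)
    dev = g0.energy_mev[g0.weight > 0] - ebar
    lo = -margin / dev.max() if dev.max() > 0 else -np.inf
    hi = -margin / dev.min() if dev.min() < 0 else np.inf
    return float(lo), float(hi)


def fit_spectrum_slope(
    pdd_meas: PDDCurve,
    forward,
    g0: EnergySpectrum,
    bounds: tuple = (-0.12, 0.25),
    xatol: float = 1e-3,
    min_depth_cm: float = 0.0,
    free_scale: bool = False,
    nuisance: np.ndarray | None = None,
) -> float:
    """Find the slope minimizing the squared PDD mismatch for the reference field.

    ``forward(gs)`` must return the calculated PDD values (percent, max 100)
    on the depth grid of ``pdd_meas``. The objective is the trapezoidal
    discretization of the integral of (D(gs, z) - PDD_meas(z))^2 over depth,
    minimized by bounded scalar search (the objective is smooth in s because
    the dose is linear in the spectrum weights).

    ``min_depth_cm`` restricts the match to depths beyond it. The
    commissioning workflow passes the electron-contamination range here:
    the buildup discrepancy is attributed to electron contamination
    (fitted in the next step), and letting the spectrum chase it biases
    the slope. ``free_scale`` additionally minimizes over a closed-form
    multiplicative amplitude, making the fit a pure shape match: the
    measured PDD's maximum contains the electron component, so a
    photon-only model differs from it by a uniform scale in the fit
    region, which must not be charged to the slope.
    """
    lo_adm, hi_adm = slope_bounds(g0)
    lo = max(bounds[0], lo_adm)
    hi = min(bounds[1], hi_adm)
    if not lo < hi:
        raise BeamDataError("empty admissible slope interval")
    sel = pdd_meas.depth_cm >= min_depth_cm - 1e-9
    if sel.sum() < 2:
        raise BeamDataError("not enough depth samples beyond min_depth_cm")
    z = pdd_meas.depth_cm[sel]
    target = pdd_meas.value[sel]
    nui = None
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[1] != pdd_meas.value.size:
            raise BeamDataError("nuisance curves must live on the measured grid")
        nui = nuisance[:, sel]

    def objective(s: float) -> float:
        calc = np.asarray(forward(tune_spectrum(g0, s)), dtype=float)
        if calc.shape != pdd_meas.value.shape or np.any(~np.isfinite(calc)):
            raise RuntimeError("forward model returned an invalid PDD")
        c = calc[sel]
        if nui is not None:
            # jointly fit the model amplitude and the nuisance coefficients
            # (linear least squares); the residual carries the spectral
            # shape only
            design = np.vstack([c, nui]).T
            coef, *_ = np.linalg.lstsq(design, target, rcond=None)
            c = design @ coef
        elif free_scale:
            denom = float(np.dot(c, c))
            a = float(np.dot(c, target)) / denom if denom > 0 else 1.0
            c = a * c
        return float(np.trapezoid((c - target) ** 2, z))

    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    return float(res.x)


def load_spectrum_csv(path) -> EnergySpectrum:
    """Read a two-column (MeV, weight) CSV spectrum table."""
    rows = []
    for ln in open(path).read().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split(",")
        try:
            rows.append([float(parts[0]), float(parts[1])])
        except ValueError:
            continue  # header row
    arr = np.asarray(rows, dtype=float)
    return EnergySpectrum(arr[:, 0], arr[:, 1])


def default_spectrum_6mv() -> EnergySpectrum:
    """The packaged generic 6 MV initial spectrum g0."""
    ref = importlib.resources.files("beamforge.data") / "spectrum_6mv.csv"
    with importlib.resources.as_file(ref) as path:
        return load_spectrum_csv(path)
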