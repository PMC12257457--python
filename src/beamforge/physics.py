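"""Water interaction data for the simplified transport engine.

The engine transports particles in a water-like medium with density scaling
only. Photon interactions are Compton scattering (Klein-Nishina),
photoelectric absorption and pair production; electrons follow the
continuous slowing down approximation (CSDA). Photoelectric and pair
coefficients come from packaged tables; the incoherent (Compton)
coefficient is evaluated from the Klein-Nishina total cross section so that
attenuation and angular sampling are mutually consistent. Coherent
scattering is neglected.

All lookups used inside the numba kernels are pre-tabulated on a uniform
log-energy grid so the kernels only do linear interpolation.
"""

from __future__ import annotations

import importlib.resources

import numpy as np

__all__ = [
    "ELECTRON_REST_MEV",
    "kn_total_cross_section",
    "kn_mean_scatter_fraction",
    "mu_total",
    "mu_en_transfer",
    "stopping_power",
    "csda_range",
    "energy_from_residual_range",
    "momentum_mev",
    "photon_lut",
    "electron_lut",
]

ELECTRON_REST_MEV = 0.511
ELECTRONS_PER_GRAM_WATER = 3.3428e23
_R_E_CM = 2.8179403e-13  # classical electron radius
PAIR_THRESHOLD_MEV = 2.0 * ELECTRON_REST_MEV


def _load_csv(name: str) -> np.ndarray:
    ref = importlib.resources.files("beamforge.data") / name
    with importlib.resources.as_file(ref) as path:
        lines = [
            ln
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    return np.array(
        [[float(v) for v in ln.split(",")] for ln in lines[1:]]
    )


def kn_total_cross_section(energy_mev) -> np.ndarray:
    """Klein-Nishina total cross section per electron (cm^2)."""
    k = np.asarray(energy_mev, dtype=float) / ELECTRON_REST_MEV
    t = 2.0 * np.pi * _R_E_CM**2
    term1 = (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log1p(2 * k) / k)
    term2 = np.log1p(2 * k) / (2 * k)
    term3 = -(1 + 3 * k) / (1 + 2 * k) ** 2
    return t * (term1 + term2 + term3)


def kn_mean_scatter_fraction(energy_mev, n_theta: int = 2001) -> np.ndarray:
    """Mean fraction of the photon energy kept by the scattered photon.

    Numerical average of E'/E over the Klein-Nishina angular distribution;
    1 minus this is the mean fraction transferred to the Compton electron.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    k = e[:, None] / ELECTRON_REST_MEV
    theta = np.linspace(0.0, np.pi, n_theta)[None, :]
    ratio = 1.0 / (1.0 + k * (1.0 - np.cos(theta)))  # E'/E
    dsigma = 0.5 * ratio**2 * (ratio + 1.0 / ratio - np.sin(theta) ** 2)
    w = dsigma * np.sin(theta)
    num = np.trapezoid(w * ratio, theta, axis=1)
    den = np.trapezoid(w, theta, axis=1)
    out = num / den
    return out if np.ndim(energy_mev) else float(out[0])


# ---------------------------------------------------------------------------
# Photon lookup tables on a uniform log-energy grid
# ---------------------------------------------------------------------------

_N_LUT = 256
_E_MIN, _E_MAX = 0.01, 10.0
_LOG_E0 = np.log(_E_MIN)
_DLOG = (np.log(_E_MAX) - _LOG_E0) / (_N_LUT - 1)
_EGRID = np.exp(_LOG_E0 + _DLOG * np.arange(_N_LUT))

_xs = _load_csv("water_photon_xs.csv")
_MU_PE = np.interp(np.log(_EGRID), np.log(_xs[:, 0]), _xs[:, 1])
_MU_PAIR = np.interp(_EGRID, _xs[:, 0], _xs[:, 2])
_MU_PAIR[_EGRID < PAIR_THRESHOLD_MEV] = 0.0
_MU_INC = ELECTRONS_PER_GRAM_WATER * kn_total_cross_section(_EGRID)
_MU_TOT = _MU_PE + _MU_PAIR + _MU_INC

_F_SCATTER = kn_mean_scatter_fraction(_EGRID)
# mean energy transferred to charged particles per collision, MeV
_TBAR = (
    _MU_INC * _EGRID * (1.0 - _F_SCATTER)
    + _MU_PE * _EGRID
    + _MU_PAIR * np.maximum(_EGRID - PAIR_THRESHOLD_MEV, 0.0)
) / _MU_TOT


def _lut_interp(table: np.ndarray, energy_mev) -> np.ndarray:
    e = np.clip(np.asarray(energy_mev, dtype=float), _E_MIN, _E_MAX)
    x = (np.log(e) - _LOG_E0) / _DLOG
    i = np.clip(x.astype(int), 0, _N_LUT - 2)
    f = x - i
    out = table[i] * (1 - f) + table[i + 1] * f
    return out if np.ndim(energy_mev) else float(out)


def mu_total(energy_mev):
    """Total mass attenuation coefficient of water (cm^2/g), no coherent."""
    return _lut_interp(_MU_TOT, energy_mev)


def mu_en_transfer(energy_mev):
    """Mass energy-transfer-like coefficient: mu_tot * Tbar / E (cm^2/g)."""
    e = np.asarray(energy_mev, dtype=float)
    return _lut_interp(_MU_TOT * _TBAR / _EGRID, e)


def mean_transfer_energy(energy_mev):
    """Mean energy transferred to charged particles per collision (MeV)."""
    return _lut_interp(_TBAR, energy_mev)


def photon_lut():
    """Arrays consumed by the numba kernels.

    Returns (log_e0, dlog, mu_tot, p_inc, p_pe, tbar). Branching
    probabilities are cumulative: interaction type is Compton if
    xi < p_inc, photoelectric if xi < p_inc + p_pe, else pair.
    """
    p_inc = _MU_INC / _MU_TOT
    p_pe = _MU_PE / _MU_TOT
    return (
        float(_LOG_E0),
        float(_DLOG),
        _MU_TOT.copy(),
        p_inc.copy(),
        p_pe.copy(),
        _TBAR.copy(),
    )


# ---------------------------------------------------------------------------
# Electron stopping power and CSDA range
# ---------------------------------------------------------------------------

_estar = _load_csv("water_estar.csv")
_S_LUT = np.interp(np.log(_EGRID), np.log(_estar[:, 0]), _estar[:, 1])

# CSDA range by integrating 1/S from the lowest tabulated energy; residual
# range below that is approximated by E/S there (sub-cutoff in any case).
_RANGE_LUT = np.empty(_N_LUT)
_RANGE_LUT[0] = _EGRID[0] / _S_LUT[0]
for _i in range(1, _N_LUT):
    _RANGE_LUT[_i] = _RANGE_LUT[_i - 1] + np.trapezoid(
        1.0 / _S_LUT[_i - 1 : _i + 1], _EGRID[_i - 1 : _i + 1]
    )


def stopping_power(energy_mev):
    """Total mass stopping power of water (MeV cm^2/g)."""
    return _lut_interp(_S_LUT, energy_mev)


def csda_range(energy_mev):
    """CSDA range in water (g/cm^2), consistent with stopping_power."""
    return _lut_interp(_RANGE_LUT, energy_mev)


def energy_from_residual_range(range_gcm2):
    """Inverse of csda_range (MeV), clipped to the tabulated domain."""
    r = np.clip(np.asarray(range_gcm2, dtype=float), _RANGE_LUT[0], _RANGE_LUT[-1])
    out = np.interp(r, _RANGE_LUT, _EGRID)
    return out if np.ndim(range_gcm2) else float(out)


def electron_lut():
    """(log_e0, dlog, stopping_power, csda_range, energy_grid) for kernels."""
    return float(_LOG_E0), float(_DLOG), _S_LUT.copy(), _RANGE_LUT.copy(), _EGRID.copy()


def momentum_mev(kinetic_mev):
    """Relativistic momentum times c, in MeV, for an electron."""
    t = np.asarray(kinetic_mev, dtype=float)
    out = np.sqrt(t * t + 2.0 * t * ELECTRON_REST_MEV)
    return out if np.ndim(kinetic_mev) else float(out)
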