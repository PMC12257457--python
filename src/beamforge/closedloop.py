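"""Closed-loop commissioning study on the synthetic golden machine.

Generates golden beam data, commissions a model from it, recalculates the
beam data from the commissioned model and scores the agreement: 1-D gamma
pass rates of PDDs and cross-profiles, output-factor deviations, and
parameter recovery errors. This is the package's end-to-end validation
and the routine behind the acceptance results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .commissioning import BeamModel, commission
from .evaluation import gamma_index_curves
from .forward import WaterForwardModel
from .synthetic import GoldenMachine, generate_beam_data, generate_reference_curves
from .transport import EngineConfig
from .types import PDDCurve

__all__ = ["ClosedLoopResult", "run_closed_loop"]

PDD_FIELDS_CM = (5.0, 10.0, 20.0)
PROFILE_DEPTHS_CM = (1.5, 5.0, 10.0)
OF_FIELDS_CM = (3.0, 5.0, 10.0, 20.0)


@dataclass
class ClosedLoopResult:
    machine: GoldenMachine
    model: BeamModel
    s_true: float
    s_hat: float
    we_true: float
    we_hat: float
    gamma_pass_rates: dict = field(default_factory=dict)
    avg_gamma_pass_rate: float = 0.0
    of_reference: dict = field(default_factory=dict)
    of_model: dict = field(default_factory=dict)
    max_of_dev_percent: float = 0.0
    max_pdd_dev_percent: float = 0.0  # beyond the buildup region
    kernel_roundtrip_max_err: float = 0.0


def _model_pdd(fwd, model, field_cm, g0):
    """PDD recalculated from a commissioned model (photon + weighted electron).

    Seeds are tag-derived, matching the golden generator's calculations
    for the same field (common random numbers).
    """
    basis, z = fwd.pdd_basis(
        field_cm, g0, oas=model.oas, kernel=model.kernel,
        seed=fwd.seed_for(f"basis-{field_cm:g}"),
    )
    dx = fwd.pdd_from_basis(basis, z, model.spectrum)
    dose_e = fwd.electron_dose(field_cm, model.spectrum, oas=model.oas,
                               kernel=model.kernel,
                               seed=fwd.seed_for(f"de-{field_cm:g}"))
    de = fwd.pdd_curve(dose_e)
    total = dx / dx.max() + model.electron_weight * de.value / de.value.max()
    return PDDCurve(z, 100.0 * total / total.max())


def run_closed_loop(
    seed: int = 1,
    config: EngineConfig | None = None,
    machine: GoldenMachine | None = None,
    gamma_dd: float = 2.0,
    gamma_dta_mm: float = 2.0,
    gamma_threshold: float = 10.0,
) -> ClosedLoopResult:
    """Full golden-machine commissioning loop with the default study conditions."""
    config = config if config is not None else EngineConfig(seed=seed)
    gm = machine if machine is not None else GoldenMachine(seed=seed)
    fwd = WaterForwardModel(gm.meta, config)

    beam_data = generate_beam_data(gm, config, forward=fwd)
    refs = generate_reference_curves(gm, config, forward=fwd,
                                     pdd_fields_cm=PDD_FIELDS_CM,
                                     profile_depths_cm=PROFILE_DEPTHS_CM)
    model = commission(beam_data, config, forward=fwd)

    res = ClosedLoopResult(
        machine=gm, model=model,
        s_true=gm.s_star, s_hat=float(model.provenance["slope"]),
        we_true=gm.we_star, we_hat=model.electron_weight,
    )

    # --- recalculate PDDs and profiles from the commissioned model
    from .spectrum import default_spectrum_6mv

    g0 = default_spectrum_6mv()
    d_max_ref = refs["d_max_cm"]
    model_doses = {}
    max_pdd_dev = 0.0
    for i, f in enumerate(PDD_FIELDS_CM):
        calc = _model_pdd(fwd, model, float(f), g0)
        model_doses[f] = fwd.photon_dose(
            float(f), model.spectrum, oas=model.oas, kernel=model.kernel,
            seed=fwd.seed_for(f"full-{f:g}"),
        )
        ref = refs["pdd"][float(f)]
        g = gamma_index_curves(
            ref.depth_cm, ref.value, calc.depth_cm, calc.value,
            dd_percent=gamma_dd, dta_mm=gamma_dta_mm,
            threshold_percent=gamma_threshold,
        )
        res.gamma_pass_rates[f"pdd_{f:g}cm"] = g.pass_rate
        beyond = ref.depth_cm > d_max_ref + 1e-9
        dev = np.max(np.abs(calc.value[beyond] - ref.value[beyond]))
        max_pdd_dev = max(max_pdd_dev, float(dev))
    res.max_pdd_dev_percent = max_pdd_dev

    dose10 = model_doses[10.0]
    norm = fwd.central_dose(dose10, d_max_ref)
    for d in PROFILE_DEPTHS_CM:
        calc_prof = fwd.cross_profile(dose10, float(d), norm)
        ref_prof = refs["profile"][float(d)]
        g = gamma_index_curves(
            ref_prof.offset_cm, ref_prof.value,
            calc_prof.offset_cm, calc_prof.value,
            dd_percent=gamma_dd, dta_mm=gamma_dta_mm,
            threshold_percent=gamma_threshold,
        )
        res.gamma_pass_rates[f"profile_{d:g}cm"] = g.pass_rate
    res.avg_gamma_pass_rate = float(np.mean(list(res.gamma_pass_rates.values())))

    # --- output factors recomputed from the model
    d_ref = gm.meta.d_ref_cm
    doses_of = {}
    for f in OF_FIELDS_CM:
        if f in model_doses:
            doses_of[f] = fwd.central_dose(model_doses[f], d_ref)
        else:
            dose_f = fwd.photon_dose(float(f), model.spectrum, oas=model.oas,
                                     kernel=model.kernel,
                                     seed=fwd.seed_for(f"full-{f:g}"))
            doses_of[f] = fwd.central_dose(dose_f, d_ref)
    d10 = doses_of[10.0]
    max_dev = 0.0
    for f in OF_FIELDS_CM:
        of_model = doses_of[f] / d10
        of_ref = beam_data.scp_table.at(float(f))
        res.of_model[f] = of_model
        res.of_reference[f] = of_ref
        max_dev = max(max_dev, abs(of_model - of_ref) * 100.0)
    res.max_of_dev_percent = float(max_dev)

    # --- kernel self-consistency (defining integral round-trip)
    from .oas_kernel import sc_roundtrip

    sc = model.provenance["sc_square"]
    errs = []
    for f_str, want in sc.items():
        f = float(f_str)
        got = sc_roundtrip(model.kernel, model.oas, f)
        errs.append(abs(got - want) / want)
    res.kernel_roundtrip_max_err = float(max(errs))
    return res
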