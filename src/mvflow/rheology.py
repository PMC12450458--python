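"""Empirical blood rheology.

Effective viscosity laws (in vitro, in vivo, and in vivo with endothelial
surface layer), the mean-corpuscular-volume diameter adjustment used when
applying human-derived laws to mouse networks, Poiseuille hydraulic
conductance, the Fahraeus tube/discharge hematocrit relation, and the
logit phase-separation law governing the red-blood-cell flux split at a
diverging bifurcation.

All three viscosity laws reduce to the plasma value (relative viscosity 1)
as the discharge hematocrit goes to zero, and all take the vessel diameter
in micrometres.  They were fitted on human blood; for mouse networks the
diameter is rescaled by the cube root of the ratio of mean corpuscular
volumes before the law is evaluated (mouse red cells are roughly half the
human volume, so a mouse vessel behaves like a proportionally wider human
one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: unit conversions: 1 mmHg = 133.322 Pa, 1 cP = 1e-3 Pa s
MMHG_TO_PA = 133.322
CP_TO_PA_S = 1e-3

LAWS = ("IN_VITRO", "IN_VIVO", "ESL")


@dataclass
class ViscosityModel:
    """Which empirical law to use and its parameters.

    plasma_viscosity is in cP; MCV values in fL.  ``mcv_adjust`` switches on
    the cube-root diameter rescaling from ``mcv_actual`` (the modelled
    species) to ``mcv_reference`` (the species the law was fitted on).
    """

    law: str = "IN_VITRO"
    plasma_viscosity: float = 1.2
    mcv_adjust: bool = False
    mcv_reference: float = 92.0
    mcv_actual: float = 45.0

    def __post_init__(self) -> None:
        if self.law not in LAWS:
            raise ValueError(f"law must be one of {LAWS}, got {self.law!r}")
        if self.plasma_viscosity <= 0:
            raise ValueError("plasma viscosity must be positive")
        if self.mcv_reference <= 0 or self.mcv_actual <= 0:
            raise ValueError("MCV values must be positive")


def mcv_effective_diameter(diameter, model: ViscosityModel):
    """Diameter fed into the viscosity law after MCV adjustment.

    Cube-root volume scaling: d_eff = d * (MCV_ref / MCV_actual)^(1/3) when
    the adjustment is enabled, identity otherwise.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if not model.mcv_adjust:
        return d if d.ndim else float(d)
    out = d * (model.mcv_reference / model.mcv_actual) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def _eta_45_vitro(d):
    # relative viscosity of blood at discharge hematocrit 0.45 (in vitro fit)
    return 220.0 * np.exp(-1.3 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)


def _shape_exponent(d):
    # hematocrit-dependence shape exponent C(d) shared by the laws
    return (0.8 + np.exp(-0.075 * d)) * (-1.0 + 1.0 / (1.0 + 1e-11 * d**12)) + 1.0 / (
        1.0 + 1e-11 * d**12
    )


def _vitro(d, h):
    eta45 = _eta_45_vitro(d)
    c = _shape_exponent(d)
    return 1.0 + (eta45 - 1.0) * ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0)


def _eta_45_vivo(d):
    # relative viscosity at 0.45 from the in-vivo fit
    return 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d**0.645)


def _vivo(d, h):
    # hematocrit-dependent part of the in-vivo fit; the outer (d/(d-1.1))^2
    # wall factor is a lumen-narrowing conductance factor and is folded into
    # the conductance-equivalent effective viscosity, not the relative law
    eta45 = _eta_45_vivo(d)
    c = _shape_exponent(d)
    wall = (d / (d - 1.1)) ** 2
    return 1.0 + (eta45 - 1.0) * ((1.0 - h) ** c - 1.0) / ((1.0 - 0.45) ** c - 1.0) * wall


def esl_width(d):
    """Effective endothelial-surface-layer width (um) as a function of diameter."""
    d = np.asarray(d, dtype=float)
    d_off, d_crit = 2.4, 10.5
    d50, e_amp, e_width, e_peak, w_max = 100.0, 1.1, 0.03, 0.6, 2.6
    w_as = np.where(d > d_off, w_max * (d - d_off) / (d + d50 - 2 * d_off), 0.0)
    w_peak = np.where(
        d <= d_off,
        0.0,
        np.where(
            d <= d_crit,
            e_amp * (d - d_off) / (d_crit - d_off),
            e_amp * np.exp(-e_width * (d - d_crit)),
        ),
    )
    w = w_as + w_peak * e_peak
    # the layer never occupies more than (almost) the whole lumen
    return np.minimum(w, 0.45 * d)


def esl_effective_diameter(d):
    """Flow-relevant (ESL-reduced) diameter d_eff = d - 2 w(d)."""
    d = np.asarray(d, dtype=float)
    out = d - 2.0 * esl_width(d)
    return out if out.ndim else float(out)


def _esl(d, h):
    # in-vitro law evaluated at the ESL-reduced (flow-relevant) diameter
    deff = d - 2.0 * esl_width(d)
    return _vitro(deff, h)


def relative_viscosity(diameter, discharge_hematocrit, model: ViscosityModel):
    """Relative apparent viscosity (dimensionless, multiplies plasma viscosity).

    ``diameter`` is the physical vessel diameter in um; the MCV adjustment
    (if enabled) is applied internally before the law is evaluated.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(discharge_hematocrit, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if np.any((h < 0) | (h > 1)):
        raise ValueError("discharge hematocrit must lie in [0, 1]")
    d = np.asarray(mcv_effective_diameter(d, model), dtype=float)
    if model.law == "IN_VITRO":
        out = _vitro(d, h)
    elif model.law == "IN_VIVO":
        out = _vivo(d, h)
    else:
        out = _esl(d, h)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def effective_viscosity(diameter, discharge_hematocrit, model: ViscosityModel):
    """Conductance-equivalent effective viscosity in cP.

    Plasma viscosity times the relative law; for the ESL law the additional
    (d/d_eff)^4 factor refers the resistance of the ESL-narrowed lumen back
    to the physical diameter used in the Poiseuille conductance, so
    ``hydraulic_conductance(d, L, effective_viscosity(...))`` is the
    conductance of the narrowed lumen.  The physical diameter stays the
    one stored in the data model.
    """
    rel = np.asarray(relative_viscosity(diameter, discharge_hematocrit, model), dtype=float)
    if model.law == "ESL":
        d = np.asarray(mcv_effective_diameter(diameter, model), dtype=float)
        deff = d - 2.0 * esl_width(d)
        rel = rel * (d / deff) ** 4
    elif model.law == "IN_VIVO":
        d = np.asarray(mcv_effective_diameter(diameter, model), dtype=float)
        rel = rel * (d / (d - 1.1)) ** 2
    out = model.plasma_viscosity * rel
    return out if out.ndim else float(out)


def hydraulic_conductance(diameter, length, effective_viscosity_cp):
    """Poiseuille conductance G = pi d^4 / (128 mu L) in um^3 s^-1 mmHg^-1.

    With d, L in um and mu in cP, q = G * dp gives um^3/s for dp in mmHg.
    """
    d = np.asarray(diameter, dtype=float)
    L = np.asarray(length, dtype=float)
    mu = np.asarray(effective_viscosity_cp, dtype=float)
    if np.any(d <= 0) or np.any(L <= 0) or np.any(mu <= 0):
        raise ValueError("diameter, length, and viscosity must be positive")
    out = math.pi * d**4 * MMHG_TO_PA / (128.0 * mu * CP_TO_PA_S * L)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def tube_hematocrit(diameter, discharge_hematocrit):
    """Tube hematocrit H_T from discharge hematocrit H_D (Fahraeus relation).

    H_T / H_D = H_D + (1 - H_D) (1 + 1.7 e^{-0.415 d} - 0.6 e^{-0.011 d}),
    the in-vitro fit; used to convert bulk to red-blood-cell velocity.
    """
    d = np.asarray(diameter, dtype=float)
    h = np.asarray(discharge_hematocrit, dtype=float)
    ratio = h + (1.0 - h) * (1.0 + 1.7 * np.exp(-0.415 * d) - 0.6 * np.exp(-0.011 * d))
    out = np.asarray(h * ratio)
    return out if out.ndim else float(out)


def phase_separation_coefficients(parent_diameter, daughter_a_diameter,
                                  daughter_b_diameter, parent_hd):
    """(A, B, X0) of the logit split law for daughter a.

    A = -6.96 ln(d_a/d_b)/d_p, B = 1 + 6.98 (1 - H_D)/d_p, X0 = 0.4/d_p,
    diameters in um, H_D the parent discharge hematocrit.
    """
    dp = float(parent_diameter)
    a = -6.96 * math.log(daughter_a_diameter / daughter_b_diameter) / dp
    b = 1.0 + 6.98 * (1.0 - parent_hd) / dp
    x0 = 0.4 / dp
    return a, b, x0


def phase_separation_split(flow_fraction, parent_diameter, daughter_a_diameter,
                           daughter_b_diameter, parent_hd):
    """RBC-flux fraction FQ_E entering daughter a, given its blood-flow
    fraction FQ_B of the parent flow.

    Below the plasma-skimming threshold X0 the daughter receives pure plasma
    (FQ_E = 0); above 1 - X0 it receives the entire red-cell flux.  In
    between, logit(FQ_E) = A + B logit((FQ_B - X0)/(1 - 2 X0)).
    """
    fqb = float(flow_fraction)
    if not 0.0 <= fqb <= 1.0:
        raise ValueError("flow fraction must lie in [0, 1]")
    if parent_hd <= 0 or parent_hd > 1:
        raise ValueError("parent discharge hematocrit must lie in (0, 1]")
    a, b, x0 = phase_separation_coefficients(
        parent_diameter, daughter_a_diameter, daughter_b_diameter, parent_hd
    )
    if fqb <= x0:
        return 0.0
    if fqb >= 1.0 - x0:
        return 1.0
    x = (fqb - x0) / (1.0 - 2.0 * x0)
    logit = a + b * math.log(x / (1.0 - x))
    return 1.0 / (1.0 + math.exp(-logit))
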