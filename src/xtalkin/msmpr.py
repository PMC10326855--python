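"""Steady-state MSMPR design relations for cubic crystals.

At steady state a mixed-suspension mixed-product-removal (MSMPR)
crystallizer with size-independent growth has the exponential population
density n(L) = n0 * exp(-L / (G * tau)), with n0 the nuclei population
density (number per volume per size), G the linear growth rate and tau
the mean residence time.  Closing the moments for cubic crystals
(volume shape factor k_v = 1) gives

    d43 = 4 * G * tau               (volume-weighted mean size)
    phi = 6 * k_v * n0 * (G*tau)^4  (solids volume fraction)
    B   = n0 * G                    (nucleation rate per volume)

which invert to the design relations used here:

    G = d43 / (4 * tau)
    B = phi * G / (6 * k_v * (G*tau)^4)

All internal arithmetic is SI (m, s); public values use the process
units G in um/min and B in particles/(mL min).
"""

from __future__ import annotations

from dataclasses import dataclass

from xtalkin.core import PowerLawFit, evaluate_power_law, invert_power_law
from xtalkin.errors import InvalidArgumentError

#: Volume shape factor; 1 for cubes. Spheres would use pi/6.
SHAPE_FACTOR_KV = 1.0

# unit conversions between SI and process units
M_PER_S_TO_UM_PER_MIN = 1e6 * 60.0  # m/s -> um/min
PER_M3_S_TO_PER_ML_MIN = 60.0 / 1e6  # 1/(m^3 s) -> 1/(mL min)


@dataclass
class MSMPRDesign:
    """A steady-state MSMPR design point and its required kinetics.

    phi is the solids volume fraction (dimensionless), d43 the
    volume-weighted mean size in metres, tau the residence time in
    seconds; B and G are the kinetics required to realise them, in
    particles/(mL min) and um/min.  n0 (particles per m^3 per m) is the
    intermediate nuclei population density.
    """

    phi: float
    d43_m: float
    tau_s: float
    B_per_mL_min: float
    G_um_per_min: float
    n0_per_m4: float


def msmpr_required_rates(phi: float, d43_m: float, tau_s: float) -> MSMPRDesign:
    """Kinetic rates (B, G) required for a target MSMPR product.

    Given the solids volume fraction, volume-weighted mean size (m) and
    residence time (s), returns the design with G = d43/(4 tau) and
    B = n0 * G where n0 = phi / (6 k_v (G tau)^4), converted to
    particles/(mL min) and um/min.
    """
    if phi <= 0 or d43_m <= 0 or tau_s <= 0:
        raise InvalidArgumentError("phi, d43 and tau must all be positive")
    G_si = d43_m / (4.0 * tau_s)  # m/s
    Gtau = G_si * tau_s  # m
    n0 = phi / (6.0 * SHAPE_FACTOR_KV * Gtau**4)  # 1/m^4
    B_si = n0 * G_si  # 1/(m^3 s)
    return MSMPRDesign(
        phi=phi,
        d43_m=d43_m,
        tau_s=tau_s,
        B_per_mL_min=B_si * PER_M3_S_TO_PER_ML_MIN,
        G_um_per_min=G_si * M_PER_S_TO_UM_PER_MIN,
        n0_per_m4=n0,
    )


def msmpr_forward(
    B_per_mL_min: float, G_um_per_min: float, tau_s: float
) -> tuple[float, float]:
    """Product (phi, d43_m) realised by kinetics (B, G) at residence time tau.

    The inverse of :func:`msmpr_required_rates`: d43 = 4 G tau and
    phi = 6 k_v n0 (G tau)^4 with n0 = B / G.  Round-trips with the
    required-rates map to floating-point precision.
    """
    if B_per_mL_min <= 0 or G_um_per_min <= 0 or tau_s <= 0:
        raise InvalidArgumentError("B, G and tau must all be positive")
    G_si = G_um_per_min / M_PER_S_TO_UM_PER_MIN  # m/s
    B_si = B_per_mL_min / PER_M3_S_TO_PER_ML_MIN  # 1/(m^3 s)
    n0 = B_si / G_si
    Gtau = G_si * tau_s
    phi = 6.0 * SHAPE_FACTOR_KV * n0 * Gtau**4
    d43_m = 4.0 * Gtau
    return phi, d43_m


def operating_point(
    design: MSMPRDesign,
    growth_fit: PowerLawFit,
    secondary_fit: PowerLawFit,
) -> dict:
    """Map the required growth rate to an operating supersaturation.

    Inverts the growth power law at the design G to find S_required,
    evaluates the secondary-nucleation power law there (B per single
    seed in the experimental vial), and reports it next to the MSMPR
    B requirement.  The two B values are on different bases (per-seed
    experimental vs per-suspension-volume MSMPR) and are labelled so.
    """
    S_required = invert_power_law(growth_fit, design.G_um_per_min)
    B_available = float(evaluate_power_law(secondary_fit, S_required))
    return {
        "S_required": S_required,
        "G_required_um_per_min": design.G_um_per_min,
        "B_required_msmpr_per_mL_min": design.B_per_mL_min,
        "B_available_per_seed_per_mL_min": B_available,
        "B_ratio_available_to_required": B_available / design.B_per_mL_min,
    }
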