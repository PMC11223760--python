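"""Unit conventions used throughout the package.

One fixed convention, applied everywhere:

* per-particle element masses in attograms (ag)
* particle diameters in nanometres (nm)
* bulk densities in g/cm^3
* dissolved (ionic) concentrations in µg/L (== ng/mL)
* sample intake flow in mL/min, dwell/acquisition times in seconds
* tissue-basis concentrations in ng/g (mass) and particles/g (number)

All conversions between these live here so that the calibration algebra in
:mod:`spq.calibrate` and the concentration formulas in :mod:`spq.quantify`
stay free of magic numbers.
"""

import math

AG_PER_NG = 1e9
AG_PER_UG = 1e12

#: ag of analyte delivered per dwell, per (µg/L concentration) x (mL/min flow)
#: x (s dwell time), at transport efficiency 1.  1 µg/L == 1e9 ag/mL and
#: 1 mL/min == 1/60 mL/s, hence 1e9/60.
MASS_FLUX_AG = 1e9 / 60.0


def flow_ml_per_s(flow_ml_per_min: float) -> float:
    """Convert a sample intake flow from mL/min to mL/s."""
    return flow_ml_per_min / 60.0


def sphere_mass_ag(diameter_nm: float, density_g_cm3: float) -> float:
    """Mass (ag) of a solid sphere of the given diameter and bulk density.

    1 nm^3 of material at 1 g/cm^3 weighs 1e-21 g = 1e-3 ag.
    """
    return density_g_cm3 * math.pi * diameter_nm**3 / 6.0 * 1e-3


def sphere_diameter_nm(mass_ag, density_g_cm3: float):
    """Diameter (nm) of a solid sphere of the given mass and bulk density.

    Inverse of :func:`sphere_mass_ag`; accepts scalars or numpy arrays.
    """
    return (6.0e3 * mass_ag / (math.pi * density_g_cm3)) ** (1.0 / 3.0)
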