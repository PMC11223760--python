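"""Calibration: ionic response, transport efficiency, and mass/size conversion.

SP-ICP-MS quantification rests on two calibrations.  An *ionic* calibration
relates the steady-state signal of dissolved standards to their concentration
(ordinary least squares through the standard points).  A *particle* calibration
ties the integrated signal of individual particle events to particle mass.
The two are linked by the transport efficiency η — the fraction of nebulised
sample that actually reaches the plasma — which here is determined by the
particle *size* method: a reference nanoparticle of certified diameter (hence
certified element mass) is measured, the mode of its event-intensity
distribution is located by kernel density estimation, and η is chosen so that
this mode maps onto the certified mass.

With the ionic slope ``f`` (counts/dwell per µg/L), intake flow ``q`` (mL/min),
dwell time ``t_d`` (s) and the unit factor ``u`` = 1e9/60 (ag per
µg/L·mL/min·s), the detector response per attogram of element at the plasma is

    S = f / (η · q · t_d · u)   [counts per ag]

so that a reference particle of element mass ``m_ref`` produces a mode
intensity ``I = S · m_ref``, giving  η = f · m_ref / (I · q · t_d · u).
Per-event masses follow as ``m = net_area / S`` and mass-equivalent spherical
diameters from the compound density and element mass fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .units import MASS_FLUX_AG, sphere_diameter_nm, sphere_mass_ag

__all__ = [
    "ElementSpec",
    "IonicCalibration",
    "TransportEfficiency",
    "CalibrationError",
    "GOLD",
    "TIO2",
    "CUO",
    "CR2O3",
    "fit_ionic_calibration",
    "kde_mode",
    "transport_efficiency_size_method",
    "sensitivity_counts_per_ag",
    "event_mass",
    "mass_to_diameter",
    "diameter_to_mass",
]


class CalibrationError(ValueError):
    """Raised when a calibration is degenerate or physically implausible."""


@dataclass(frozen=True)
class ElementSpec:
    """Element/compound description for mass–diameter conversion.

    Parameters
    ----------
    element : str
        Element symbol, e.g. ``"Au"``.
    isotope : int
        Measured isotope mass number, e.g. 197.
    compound : str
        Particle compound, e.g. ``"Au"`` or ``"TiO2"``.
    density : float
        Bulk density of the particle compound in g/cm^3.
    element_mass_fraction : float
        Mass fraction w of the measured element in the compound, in (0, 1].
    """

    element: str
    isotope: int
    compound: str
    density: float
    element_mass_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise ValueError(f"density must be > 0, got {self.density}")
        if not (0 < self.element_mass_fraction <= 1):
            raise ValueError(
                "element_mass_fraction must be in (0, 1], got "
                f"{self.element_mass_fraction}"
            )


# Common particle compounds, with bulk densities and element mass fractions.
GOLD = ElementSpec("Au", 197, "Au", density=19.32, element_mass_fraction=1.0)
TIO2 = ElementSpec("Ti", 48, "TiO2", density=4.17, element_mass_fraction=0.5995)
CUO = ElementSpec("Cu", 63, "CuO", density=6.31, element_mass_fraction=0.7989)
CR2O3 = ElementSpec("Cr", 52, "Cr2O3", density=5.22, element_mass_fraction=0.6842)


@dataclass(frozen=True)
class IonicCalibration:
    """OLS calibration line of dissolved-standard signal vs concentration.

    ``slope`` is in counts/dwell per (µg/L); ``flow_rate`` is the sample
    intake in mL/min and ``dwell_time`` the dwell length in seconds — both are
    carried here because every signal→mass conversion needs them.
    """

    slope: float
    intercept: float
    r_squared: float
    concentrations: tuple = ()
    mean_signals: tuple = ()
    flow_rate: float = 0.346
    dwell_time: float = 1e-4

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")
        if not (self.flow_rate > 0 and self.dwell_time > 0):
            raise ValueError("flow_rate and dwell_time must be > 0")


@dataclass(frozen=True)
class TransportEfficiency:
    """Transport efficiency η determined by the particle size method."""

    eta: float
    method: str = "particle size"
    reference_diameter: float = float("nan")
    kde_mode_intensity: float = float("nan")

    def __post_init__(self) -> None:
        if not (0 < self.eta < 1):
            raise CalibrationError(f"transport efficiency must be in (0, 1), got {self.eta}")


def fit_ionic_calibration(
    points,
    flow_rate: float = 0.346,
    dwell_time: float = 1e-4,
) -> IonicCalibration:
    """Fit the ionic response line by unweighted ordinary least squares.

    Parameters
    ----------
    points : sequence of (concentration µg/L, mean signal counts/dwell)
        At least two points with distinct concentrations.
    flow_rate, dwell_time :
        Sample intake (mL/min) and dwell time (s), stored on the result.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise CalibrationError("need at least two (concentration, signal) points")
    conc, sig = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 2:
        raise CalibrationError("all calibration concentrations are identical")
    res = stats.linregress(conc, sig)
    return IonicCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        concentrations=tuple(conc),
        mean_signals=tuple(sig),
        flow_rate=flow_rate,
        dwell_time=dwell_time,
    )


def kde_mode(values, n_grid: int = 2048, bw_method: str | float = "silverman") -> float:
    """Mode of a Gaussian kernel density estimate of event intensities.

    The density is evaluated on ``n_grid`` points spanning [0, 1.2·max] and
    the argmax returned.  Degenerate samples (zero spread) return the common
    value directly.

    Parameters
    ----------
    values : array-like
        Event intensities; at least 10 values required.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError(f"kde_mode needs >= 10 values, got {x.size}")
    if np.ptp(x) == 0:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    grid = np.linspace(0.0, 1.2 * x.max(), n_grid)
    return float(grid[np.argmax(kde(grid))])


def transport_efficiency_size_method(
    cal: IonicCalibration,
    mode_intensity: float,
    reference_diameter: float,
    spec: ElementSpec,
) -> TransportEfficiency:
    """Transport efficiency from a reference particle of certified diameter.

    η is the value for which the KDE-mode event intensity equals the detector
    response to the reference particle's certified element mass (see module
    docstring for the algebra).  Values outside (0, 1) indicate an
    inconsistent calibration and raise :class:`CalibrationError`.
    """
    if not (mode_intensity > 0):
        raise CalibrationError(f"mode intensity must be > 0, got {mode_intensity}")
    if not (reference_diameter > 0):
        raise CalibrationError("reference diameter must be > 0")
    m_ref = diameter_to_mass(reference_diameter, spec)
    eta = cal.slope * m_ref / (mode_intensity * cal.flow_rate * cal.dwell_time * MASS_FLUX_AG)
    # TransportEfficiency.__post_init__ enforces 0 < eta < 1
    return TransportEfficiency(
        eta=float(eta),
        reference_diameter=float(reference_diameter),
        kde_mode_intensity=float(mode_intensity),
    )


def sensitivity_counts_per_ag(cal: IonicCalibration, eta: TransportEfficiency) -> float:
    """Detector response S (counts per ag of element at the plasma)."""
    return cal.slope / (eta.eta * cal.flow_rate * cal.dwell_time * MASS_FLUX_AG)


def event_mass(net_area, cal: IonicCalibration, eta: TransportEfficiency):
    """Element mass (ag) of an event with the given net peak area (counts).

    Linear in ``net_area``; accepts scalars or arrays.
    """
    area = np.asarray(net_area, dtype=float)
    if np.any(area < 0):
        raise ValueError("net_area must be >= 0")
    m = area / sensitivity_counts_per_ag(cal, eta)
    return float(m) if np.isscalar(net_area) else m


def diameter_to_mass(diameter_nm, spec: ElementSpec):
    """Element mass (ag) of a spherical particle of the given diameter (nm)."""
    return sphere_mass_ag(diameter_nm, spec.density) * spec.element_mass_fraction


def mass_to_diameter(element_mass_ag, spec: ElementSpec):
    """Mass-equivalent spherical diameter (nm) for an element mass (ag).

    The element mass is first scaled to compound mass through the element
    mass fraction, then converted with the compound's bulk density.
    """
    m = np.asarray(element_mass_ag, dtype=float)
    if np.any(m < 0):
        raise ValueError("element mass must be >= 0")
    d = sphere_diameter_nm(m / spec.element_mass_fraction, spec.density)
    return float(d) if np.isscalar(element_mass_ag) else d
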