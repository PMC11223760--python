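"""Tissue-basis quantification: number/mass concentration and size summary.

During an acquisition of length ``t_acq`` at intake flow ``q``, the volume of
suspension that actually reaches the plasma is ``eta * q * t_acq``; each
detected event therefore represents ``1 / (eta * q * t_acq)`` particles per mL
of the measured suspension, and the dilution factor ``D`` (mL of suspension
per g of original tissue) converts to the tissue basis:

    C_N = n_events / (eta * q * t_acq) * D          [particles / g]
    C_m = sum(m_i)  / (eta * q * t_acq) * D         [ng / g]

Mean diameter is the arithmetic mean of the per-event mass-equivalent
diameters (not the diameter of the mean mass).  Events below the harmonized
per-particle mass threshold should be censored (:func:`spq.detect.censor_events`)
before calling any summary here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibrate import ElementSpec, TransportEfficiency, mass_to_diameter
from .units import AG_PER_NG, flow_ml_per_s

__all__ = [
    "SampleDescriptor",
    "QuantResult",
    "number_concentration",
    "mass_concentration",
    "size_summary",
    "quantify_sample",
    "CoincidenceWarning",
]


class CoincidenceWarning(UserWarning):
    """Raised when a concentration exceeds the coincidence working range."""


@dataclass(frozen=True)
class SampleDescriptor:
    """Dilution and acquisition context of one measured aliquot.

    ``dilution_factor`` is the total dilution from the reporting basis to the
    measured suspension (e.g. 500 for tissue diluted 500-fold, or 6000 with
    the extra 12-fold step); ``flow_rate`` in mL/min; ``acquisition_time`` in
    seconds; ``basis`` names the reporting denominator.
    """

    dilution_factor: float = 500.0
    flow_rate: float = 0.346
    acquisition_time: float = 120.0
    basis: str = "per g tissue"

    def __post_init__(self) -> None:
        if not (self.dilution_factor >= 1):
            raise ValueError("dilution_factor must be >= 1")
        if not (self.flow_rate > 0 and self.acquisition_time > 0):
            raise ValueError("flow_rate and acquisition_time must be > 0")

    @property
    def analyzed_volume_ml(self) -> float:
        """Suspension volume nebulised during the acquisition (mL)."""
        return flow_ml_per_s(self.flow_rate) * self.acquisition_time


@dataclass
class QuantResult:
    """Quantification summary of one sample."""

    number_conc: float
    mass_conc: float
    mean_diameter: float
    n_events: int
    size_distribution: dict = field(default_factory=dict)
    basis: str = "per g tissue"


def number_concentration(
    n_events: int, eta: TransportEfficiency, sample: SampleDescriptor
) -> float:
    """Particle number concentration on the reporting basis (particles/g)."""
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    return n_events / (eta.eta * sample.analyzed_volume_ml) * sample.dilution_factor


def mass_concentration(
    event_masses_ag, eta: TransportEfficiency, sample: SampleDescriptor
) -> float:
    """Particle mass concentration on the reporting basis (ng/g)."""
    total_ag = float(np.sum(np.asarray(event_masses_ag, dtype=float)))
    return (
        total_ag / AG_PER_NG / (eta.eta * sample.analyzed_volume_ml) * sample.dilution_factor
    )


def size_summary(diameters_nm, n_grid: int = 512) -> dict:
    """Arithmetic mean diameter plus a density summary for plotting/export.

    Returns a dict with ``mean``, ``n``, ``quantiles`` (5/25/50/75/95%), and —
    when at least 10 events with nonzero spread are present — a Gaussian-KDE
    ``grid``/``density`` pair.  With no events, ``mean`` is NaN and
    ``undefined`` is set.
    """
    d = np.asarray(diameters_nm, dtype=float)
    if d.size == 0:
        return {"mean": float("nan"), "n": 0, "undefined": True}
    out = {
        "mean": float(np.mean(d)),
        "n": int(d.size),
        "quantiles": {
            str(q): float(np.percentile(d, q)) for q in (5, 25, 50, 75, 95)
        },
    }
    if d.size >= 10 and np.ptp(d) > 0:
        from scipy import stats

        kde = stats.gaussian_kde(d)
        grid = np.linspace(0.0, 1.2 * d.max(), n_grid)
        out["grid"] = grid
        out["density"] = kde(grid)
    return out


def quantify_sample(
    event_masses_ag,
    eta: TransportEfficiency,
    sample: SampleDescriptor,
    element_spec: ElementSpec,
    coincidence_bound: float | None = None,
) -> QuantResult:
    """Full quantification of one (already censored) event-mass table.

    If ``coincidence_bound`` (particles/g, from
    :func:`spq.limits.coincidence_upper_range`) is given and the estimated
    number concentration exceeds it, a :class:`CoincidenceWarning` is issued —
    no coincidence correction is applied; the bound marks the end of the
    working range.
    """
    masses = np.asarray(event_masses_ag, dtype=float)
    n = int(masses.size)
    c_n = number_concentration(n, eta, sample)
    c_m = mass_concentration(masses, eta, sample)
    diameters = mass_to_diameter(masses, element_spec) if n else np.zeros(0)
    dist = size_summary(diameters)
    if coincidence_bound is not None and c_n > coincidence_bound:
        warnings.warn(
            f"number concentration {c_n:.3g} exceeds the coincidence working-range "
            f"bound {coincidence_bound:.3g} {sample.basis}; results may be biased low",
            CoincidenceWarning,
            stacklevel=2,
        )
    return QuantResult(
        number_conc=c_n,
        mass_conc=c_m,
        mean_diameter=dist["mean"],
        n_events=n,
        size_distribution=dist,
        basis=sample.basis,
    )
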