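"""Detection limits and working range.

Four quantities bound the method:

* **Per-particle size/mass LOD** — a Currie-style critical value.  The
  per-dwell threshold fixes the false-positive rate; a particle whose peak
  apex sits exactly at the threshold is missed half the time, so the critical
  net area of a triangular peak of base width ``tau`` and height ``h`` (the
  threshold above background, in counts) is ``(tau / t_d) * h / 2``.
  Converted through the calibration this gives the mass LOD, and through the
  spherical-diameter relation the size LOD, both with a 50% false-negative
  probability at the limit itself.
* **Mass-concentration LOD** — pooled mean of procedural-blank mass
  concentrations plus 3 standard deviations.
* **Number-concentration LOD** — upper bound of an exact (Garwood,
  chi-square) two-sided 99.7% Poisson confidence interval on the pooled mean
  blank event count, converted to particles/g.
* **Upper working range** — the number concentration at which 5% of
  particles have another arrival within +/- one peak width, from exponential
  inter-arrival times: ``lambda_max = -ln(1 - alpha) / (2 * tau)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy import stats

from .calibrate import (
    ElementSpec,
    IonicCalibration,
    TransportEfficiency,
    event_mass,
    mass_to_diameter,
)
from .quantify import SampleDescriptor, number_concentration

__all__ = [
    "LimitsReport",
    "size_lod",
    "mass_conc_lod",
    "number_conc_lod",
    "poisson_upper_limit",
    "coincidence_upper_range",
    "pool_daily_limits",
]


@dataclass
class LimitsReport:
    """Detection limits and working-range bounds for one run or pooled days."""

    mass_lod_per_particle: float
    size_lod: float
    mass_conc_lod: float | None = None
    number_conc_lod: float | None = None
    upper_number_conc: float | None = None
    assumptions: dict = field(default_factory=dict)


def size_lod(
    threshold_counts: float,
    local_background: float,
    tau: float,
    cal: IonicCalibration,
    eta: TransportEfficiency,
    spec: ElementSpec,
) -> tuple[float, float]:
    """Per-particle mass (ag) and size (nm) detection limit.

    Assumes a triangular peak of full base width ``tau`` (s) whose apex
    equals the intensity threshold, i.e. height ``threshold_counts -
    local_background`` net counts.  The returned limits carry a 50%
    false-negative probability: a particle of exactly this mass exceeds its
    own expected area only half the time.
    """
    if not (tau > 0):
        raise ValueError("tau must be > 0")
    h = float(threshold_counts) - float(local_background)
    if h < 0:
        raise ValueError("threshold must not be below the local background")
    critical_area = (tau / cal.dwell_time) * h / 2.0
    m = event_mass(critical_area, cal, eta)
    return m, mass_to_diameter(m, spec)


def mass_conc_lod(blank_mass_concs) -> float:
    """Mass-concentration LOD: pooled blank mean + 3 standard deviations.

    ``blank_mass_concs`` are per-replicate procedural-blank mass
    concentrations (ng/g); at least two values are required.  The sample
    standard deviation (ddof=1) is used.
    """
    x = np.asarray(blank_mass_concs, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 blank values")
    return float(np.mean(x) + 3.0 * np.std(x, ddof=1))


def poisson_upper_limit(mean_count: float, coverage: float = 0.997) -> float:
    """Garwood (chi-square) upper bound of a central Poisson CI on a count.

    For an observed count ``n`` the two-sided central interval at the given
    coverage has upper limit ``chi2.ppf(1 - (1-coverage)/2, 2n + 2) / 2``;
    non-integer pooled means are handled through the continuous chi-square
    degrees of freedom.
    """
    if mean_count < 0:
        raise ValueError("mean_count must be >= 0")
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    alpha = 1.0 - coverage
    return float(stats.chi2.ppf(1.0 - alpha / 2.0, 2.0 * mean_count + 2.0) / 2.0)


def number_conc_lod(
    blank_counts,
    eta: TransportEfficiency,
    sample: SampleDescriptor,
    coverage: float = 0.997,
) -> float:
    """Number-concentration LOD from procedural-blank event counts.

    The pooled mean blank event count is bounded above by an exact 99.7%
    (two-sided central) Poisson interval and the bound converted to
    particles/g through the usual number-concentration formula.
    """
    counts = np.asarray(blank_counts, dtype=float)
    if counts.size < 1:
        raise ValueError("need >= 1 blank")
    upper = poisson_upper_limit(float(np.mean(counts)), coverage)
    return upper / (eta.eta * sample.analyzed_volume_ml) * sample.dilution_factor


def coincidence_upper_range(
    tau: float,
    eta: TransportEfficiency,
    sample: SampleDescriptor,
    alpha: float = 0.05,
) -> float:
    """Upper working-range number concentration at ``alpha`` coincidence.

    With exponential inter-arrival times at rate ``lambda``, the probability
    that a particle has another arrival within +/- ``tau`` of its own is
    ``1 - exp(-2 * lambda * tau)``; setting this to ``alpha`` gives the
    maximum arrival rate ``-ln(1 - alpha) / (2 * tau)``, converted to
    particles/g.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if not (tau > 0):
        raise ValueError("tau must be > 0")
    lambda_max = -log(1.0 - alpha) / (2.0 * tau)
    n_max = lambda_max * sample.acquisition_time
    return number_concentration(n_max, eta, sample)


def pool_daily_limits(daily_reports) -> LimitsReport:
    """Pool per-day limits into one conservative report (max across days)."""
    reports = list(daily_reports)
    if not reports:
        raise ValueError("no daily reports")

    def _max(attr):
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return max(vals) if vals else None

    return LimitsReport(
        mass_lod_per_particle=_max("mass_lod_per_particle"),
        size_lod=_max("size_lod"),
        mass_conc_lod=_max("mass_conc_lod"),
        number_conc_lod=_max("number_conc_lod"),
        upper_number_conc=_max("upper_number_conc"),
        assumptions={"pooling": "max across days", "n_days": len(reports)},
    )
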