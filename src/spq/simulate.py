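"""Synthetic SP-ICP-MS trace generator with known ground truth.

Emulates the stochastic structure of a dwell-resolved single-element trace:

* Poisson background counts with mean ``background_mean`` per dwell;
* particle arrivals as a homogeneous Poisson process (exponential
  inter-arrival times at rate ``particle_rate``);
* per-particle element masses from a point-mass or lognormal diameter
  distribution, converted through the compound density and mass fraction;
* finite-width particle peaks: a particle of element mass ``m`` deposits an
  expected ``counts_per_ag * m`` counts, spread over a triangular (default)
  or Gaussian template of full base width ``peak_width``, discretised by
  integrating the template over dwell boundaries;
* detector counting statistics: each dwell's count is one Poisson draw with
  mean = background + summed peak contributions, so overlapping (coincident)
  arrivals superpose naturally.

The generator does not model nebulisation physics, ionic-cloud expansion,
detector dead time, or matrix suppression; transport efficiency enters only
through the detector sensitivity ``counts_per_ag`` (see :mod:`spq.calibrate`
for how sensitivity, transport efficiency and the ionic slope are related).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .calibrate import GOLD, ElementSpec, diameter_to_mass
from .detect import DwellTrace
from .units import AG_PER_NG

__all__ = [
    "SizeDistribution",
    "SimulationSpec",
    "GroundTruth",
    "simulate_trace",
    "nominal_number_concentration",
]


@dataclass(frozen=True)
class SizeDistribution:
    """Particle diameter distribution: point mass or lognormal.

    For ``kind="point"`` every particle has diameter ``median`` (nm); for
    ``kind="lognormal"`` diameters are lognormal with the given median (nm)
    and geometric standard deviation ``gsd`` (> 1).
    """

    kind: str = "point"
    median: float = 60.0
    gsd: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "lognormal"):
            raise ValueError(f"unknown size distribution kind {self.kind!r}")
        if not (self.median > 0):
            raise ValueError("median diameter must be > 0")
        if self.kind == "lognormal" and not (self.gsd > 1):
            raise ValueError("lognormal gsd must be > 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.median)
        return self.median * np.exp(rng.normal(0.0, math.log(self.gsd), n))


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic acquisition.

    Parameters
    ----------
    background_mean : float
        Expected background counts per dwell (>= 0).
    dwell_time : float
        Seconds per dwell; default 100 µs (600 000 dwells per minute).
    duration : float
        Acquisition length in seconds.
    particle_rate : float
        Detected-particle arrivals per second (>= 0).
    peak_width : float
        Full base width of a particle peak in seconds; default 500 µs.
    peak_shape : str
        ``"triangular"`` (default) or ``"gaussian"``.
    size_distribution : SizeDistribution
    element_spec : ElementSpec
    counts_per_ag : float
        Detector response S per attogram of element reaching the plasma.
    seed : int
        Governs arrivals, sizes and counting noise.
    """

    background_mean: float = 0.2
    dwell_time: float = 1e-4
    duration: float = 60.0
    particle_rate: float = 0.0
    peak_width: float = 500e-6
    peak_shape: str = "triangular"
    size_distribution: SizeDistribution = field(default_factory=SizeDistribution)
    element_spec: ElementSpec = GOLD
    counts_per_ag: float = 0.14
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_mean", "dwell_time", "duration", "particle_rate",
                     "peak_width", "counts_per_ag"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.dwell_time == 0 or self.duration == 0:
            raise ValueError("dwell_time and duration must be > 0")
        if not (self.peak_width < self.duration):
            raise ValueError("peak_width must be smaller than duration")
        if self.peak_shape not in ("triangular", "gaussian"):
            raise ValueError(f"unknown peak shape {self.peak_shape!r}")


@dataclass
class GroundTruth:
    """Known truth of a simulated trace, for closing the loop in tests."""

    event_times: np.ndarray
    event_masses: np.ndarray
    realized_background: float

    def __post_init__(self) -> None:
        if len(self.event_times) != len(self.event_masses):
            raise ValueError("event_times and event_masses must have equal length")


def _triangular_cdf(t: np.ndarray, width: float) -> np.ndarray:
    """CDF of a unit-area triangle on [0, width] with apex at width/2."""
    u = np.clip(t / width, 0.0, 1.0)
    return np.where(u < 0.5, 2 * u**2, 1 - 2 * (1 - u) ** 2)


def _peak_weights(arrival: float, spec: SimulationSpec, n_dwells: int):
    """Per-dwell fractions of one particle's expected counts.

    Returns (first dwell index, weight array); weights integrate the peak
    template over dwell boundaries.  Peaks truncated by the end of the
    acquisition lose the truncated fraction.
    """
    t_d = spec.dwell_time
    if spec.peak_shape == "triangular":
        lo, hi = arrival, arrival + spec.peak_width
    else:  # gaussian, base width taken as +/- 2 sigma
        sigma = spec.peak_width / 4.0
        lo, hi = arrival - 2 * sigma, arrival + spec.peak_width / 2 + 2 * sigma
    i0 = max(int(math.floor(lo / t_d)), 0)
    i1 = min(int(math.ceil(hi / t_d)), n_dwells)
    if i1 <= i0:
        return i0, np.zeros(0)
    edges = np.arange(i0, i1 + 1) * t_d
    if spec.peak_shape == "triangular":
        cdf = _triangular_cdf(edges - arrival, spec.peak_width)
    else:
        sigma = spec.peak_width / 4.0
        cdf = stats.norm.cdf(edges, loc=arrival + spec.peak_width / 2, scale=sigma)
    return i0, np.diff(cdf)


def simulate_trace(spec: SimulationSpec) -> tuple[DwellTrace, GroundTruth]:
    """Generate one synthetic dwell trace and its ground truth.

    Arrival times are drawn as cumulative exponential(``particle_rate``)
    inter-arrival gaps; each dwell's count is Poisson with mean equal to the
    background plus the summed per-dwell expected contributions of all
    overlapping peaks.
    """
    rng = np.random.default_rng(spec.seed)
    n_dwells = int(math.ceil(spec.duration / spec.dwell_time))
    expected = np.full(n_dwells, float(spec.background_mean))

    if spec.particle_rate > 0:
        # draw exponential gaps in blocks until past the end of the acquisition
        times = []
        t = 0.0
        block = max(int(spec.particle_rate * spec.duration * 1.5) + 10, 64)
        while True:
            gaps = rng.exponential(1.0 / spec.particle_rate, block)
            for g in gaps:
                t += g
                if t >= spec.duration:
                    break
                times.append(t)
            if t >= spec.duration:
                break
        times = np.asarray(times)
    else:
        times = np.zeros(0)

    diameters = spec.size_distribution.sample(times.size, rng)
    masses = np.asarray(diameter_to_mass(diameters, spec.element_spec), dtype=float)
    for arrival, m in zip(times, masses):
        i0, w = _peak_weights(arrival, spec, n_dwells)
        expected[i0 : i0 + w.size] += spec.counts_per_ag * m * w

    counts = rng.poisson(expected)
    trace = DwellTrace(
        counts=counts,
        dwell_time=spec.dwell_time,
        element_label=f"{spec.element_spec.isotope}{spec.element_spec.element}",
        acquisition_id=f"sim-{spec.seed}",
    )
    truth = GroundTruth(
        event_times=times,
        event_masses=masses,
        realized_background=float(spec.background_mean),
    )
    return trace, truth


def nominal_number_concentration(
    mass_conc_ng_g: float, diameter_nm: float, spec: ElementSpec
) -> float:
    """Particles per gram implied by an element mass concentration and size.

    Divides the element mass concentration (ng analyte per g tissue) by the
    per-particle element mass of a sphere of the given diameter.  Used to
    design spike levels with known particle-number truth.
    """
    if not (diameter_nm > 0):
        raise ValueError("diameter must be > 0")
    if mass_conc_ng_g < 0:
        raise ValueError("mass concentration must be >= 0")
    m_particle_ng = diameter_to_mass(diameter_nm, spec) / AG_PER_NG
    return mass_conc_ng_g / m_particle_ng
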