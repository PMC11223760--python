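"""Particle detection in dwell-resolved count traces.

Particles transiting the plasma produce short bursts of counts on top of a
low, slowly varying background that is well described as Poisson.  Detection
is a per-dwell hypothesis test: a dwell is a candidate particle signal when
its count exceeds the smallest integer ``k`` whose Poisson CDF at the local
background mean reaches ``1 - fp_budget / dwells_per_minute`` — by default
``1 - 0.05/600000``, i.e. a 95% probability of a whole minute of background
containing no false positive.

Because particle dwells contaminate any naive background estimate, the local
background mean is a *filtered* rolling mean: dwells currently flagged as
particle signal are excluded and the flag/estimate pair is iterated to a
fixed point.  Flagged runs of dwells (with short gaps merged, since one
particle peak can straddle dwell boundaries) become events, each integrated
over its extent with a rolling-median background subtraction.  The rolling
median is robust to the particle spikes themselves but the integer median of
low-mean Poisson data is nearly uninformative (it is 0 for any mean below
ln 2), so below a median of 1 the subtraction falls back to the filtered
rolling mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DwellTrace",
    "ThresholdPolicy",
    "DetectionResult",
    "rolling_background",
    "poisson_threshold",
    "detect_events",
    "harmonize_mass_thresholds",
    "censor_events",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ["acquisition_id", "start", "end", "apex", "net_area", "background"]


@dataclass
class DwellTrace:
    """A dwell-resolved single-element count trace.

    Attributes
    ----------
    counts : numpy.ndarray of int
        Non-negative counts per dwell.
    dwell_time : float
        Dwell length in seconds.
    element_label : str
        Element/isotope label, e.g. ``"197Au"``.
    acquisition_id : str
        Identifier carried into event tables.
    """

    counts: np.ndarray
    dwell_time: float = 1e-4
    element_label: str = ""
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(c.dtype, np.integer):
            rounded = np.rint(c)
            if not np.allclose(c, rounded, atol=1e-9):
                raise ValueError("counts must be integers")
            c = rounded.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        if not (self.dwell_time > 0):
            raise ValueError("dwell_time must be > 0")
        self.counts = c.astype(np.int64)

    def __len__(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        """Acquisition length in seconds."""
        return self.counts.size * self.dwell_time


@dataclass(frozen=True)
class ThresholdPolicy:
    """False-positive budget for the per-dwell Poisson threshold.

    ``per_dwell_rate`` is the CDF level ``1 - fp_budget_per_minute /
    dwells_per_minute`` at which the inverse Poisson CDF is evaluated.
    """

    fp_budget_per_minute: float = 0.05
    dwells_per_minute: int = 600_000

    def __post_init__(self) -> None:
        if not (0 < self.fp_budget_per_minute < 1):
            raise ValueError("fp_budget_per_minute must be in (0, 1)")
        if self.dwells_per_minute < 1:
            raise ValueError("dwells_per_minute must be >= 1")

    @property
    def per_dwell_rate(self) -> float:
        return 1.0 - self.fp_budget_per_minute / self.dwells_per_minute


@dataclass
class DetectionResult:
    """Output of :func:`detect_events`.

    Attributes
    ----------
    events : pandas.DataFrame
        One row per event with columns ``acquisition_id, start, end, apex,
        net_area, background`` (0-based, half-open dwell intervals).
    mean_background : float
        Trace-wide mean of the filtered rolling background (counts/dwell).
    threshold : float
        Trace-wide median of the final per-dwell integer thresholds.
    thresholds : numpy.ndarray
        Final per-dwell integer thresholds.
    converged : bool
        Whether the flag/background iteration reached a fixed point.
    n_iterations : int
    """

    events: pd.DataFrame
    mean_background: float
    threshold: float
    thresholds: np.ndarray
    converged: bool
    n_iterations: int


def rolling_background(trace: DwellTrace, window: int = 1001, exclusions=None):
    """Local background estimates for thresholding and for subtraction.

    Returns two aligned per-dwell series:

    * the *filtered rolling mean* over non-excluded dwells — used as the
      Poisson mean for thresholding;
    * the *rolling median with low-count correction* — used for background
      subtraction during peak integration (median where >= 1, filtered mean
      below; see module docstring).

    Edges are handled by shrinking the window.  Dwells whose entire window is
    excluded fall back to the trace-wide estimate.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    n = len(trace)
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    x = trace.counts.astype(float)
    if exclusions is not None:
        excl = np.asarray(exclusions, dtype=bool)
        if excl.shape != x.shape:
            raise ValueError("exclusion mask must match trace length")
        x = np.where(excl, np.nan, x)
    s = pd.Series(x)
    mean = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    med = s.rolling(window, center=True, min_periods=1).median().to_numpy()
    # all-excluded windows: fall back to global statistics of kept dwells
    if np.any(np.isnan(mean)):
        global_mean = np.nanmean(x) if np.any(np.isfinite(x)) else 0.0
        mean = np.where(np.isnan(mean), global_mean, mean)
        med = np.where(np.isnan(med), global_mean, med)
    subtract = np.where(med >= 1.0, med, mean)
    return mean, subtract


def poisson_threshold(local_mean, policy: ThresholdPolicy = ThresholdPolicy()):
    """Integer detection threshold(s) for the given local background mean(s).

    Smallest integer ``k`` with ``PoissonCDF(k; local_mean) >=
    policy.per_dwell_rate``; a dwell is a candidate detection iff its count is
    strictly greater than ``k``, which bounds the per-dwell false-positive
    probability by ``fp_budget / dwells_per_minute`` exactly.
    """
    mu = np.asarray(local_mean, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu < 0):
        raise ValueError("local_mean must be finite and >= 0")
    k = stats.poisson.ppf(policy.per_dwell_rate, mu)
    k = np.where(mu == 0, 0.0, k)
    if np.isscalar(local_mean):
        return int(k)
    return k.astype(np.int64)


def _threshold_lookup(mu: np.ndarray, policy: ThresholdPolicy) -> np.ndarray:
    """Vectorized thresholds via unique-value caching (ppf is the hot path)."""
    uniq, inv = np.unique(np.round(mu, 9), return_inverse=True)
    return poisson_threshold(uniq, policy)[inv]


def _flagged_runs(flagged: np.ndarray, max_gap: int):
    """Contiguous flagged runs, merging runs separated by <= max_gap dwells."""
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def detect_events(
    trace: DwellTrace,
    policy: ThresholdPolicy = ThresholdPolicy(),
    window: int = 1001,
    peak_width: float = 500e-6,
    max_iterations: int = 10,
) -> DetectionResult:
    """Detect and integrate particle events in a dwell trace.

    The filtered rolling mean, per-dwell thresholds and the flagged-dwell set
    are iterated to a fixed point (at most ``max_iterations`` passes), then
    contiguous flagged dwells — with sub-threshold gaps of up to
    ``ceil(peak_width / dwell_time)`` dwells merged — are integrated with
    rolling-median background subtraction.

    Parameters
    ----------
    trace : DwellTrace
    policy : ThresholdPolicy
        False-positive budget for the per-dwell threshold.
    window : int
        Odd rolling-statistics window length in dwells.
    peak_width : float
        Expected full base width of a particle peak in seconds; sets the
        gap-merging distance.
    """
    n = len(trace)
    window = min(window, n if n % 2 == 1 else n - 1)
    if window < 3:
        raise ValueError("trace too short for rolling background estimation")
    counts = trace.counts
    flagged = np.zeros(n, dtype=bool)
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        mean_bg, _ = rolling_background(trace, window, exclusions=flagged)
        thresholds = _threshold_lookup(mean_bg, policy)
        new_flagged = counts > thresholds
        if np.array_equal(new_flagged, flagged):
            converged = True
            break
        flagged = new_flagged
    if not converged:
        warnings.warn(
            f"detection did not reach a fixed point in {max_iterations} "
            f"iterations on acquisition '{trace.acquisition_id}'",
            RuntimeWarning,
            stacklevel=2,
        )
    mean_bg, subtract_bg = rolling_background(trace, window, exclusions=flagged)
    thresholds = _threshold_lookup(mean_bg, policy)

    max_gap = int(np.ceil(peak_width / trace.dwell_time))
    # extend each extent by one peak width per side: sub-threshold peak tails
    # carry real signal, and background subtraction keeps the padding unbiased
    runs = [
        (max(0, s - max_gap), min(n, e + max_gap))
        for s, e in _flagged_runs(flagged, max_gap)
    ]
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    rows = []
    for start, end in merged:
        gross = counts[start:end].astype(float)
        local_bg = subtract_bg[start:end]
        net = max(float(np.sum(gross - local_bg)), 0.0)
        rows.append(
            {
                "acquisition_id": trace.acquisition_id,
                "start": start,
                "end": end,
                "apex": int(counts[start:end].max()),
                "net_area": net,
                "background": float(np.mean(local_bg)),
            }
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return DetectionResult(
        events=events,
        mean_background=float(np.mean(mean_bg)),
        threshold=float(np.median(thresholds)),
        thresholds=thresholds,
        converged=converged,
        n_iterations=iterations,
    )


def harmonize_mass_thresholds(mass_thresholds, policy: str = "highest") -> float:
    """Common per-particle mass threshold across runs.

    Multi-run comparisons need a shared false-negative floor: each run has its
    own mass detection threshold (its count threshold divided by its
    sensitivity), and a single common value is applied to all.  ``policy``
    selects the ``"highest"`` (unbiased comparison across runs: no run keeps
    events another run could not have seen) or ``"lowest"`` (maximum
    sensitivity with matched false-negative rates) threshold.
    """
    thresholds = [float(t) for t in mass_thresholds]
    if not thresholds:
        raise ValueError("no run thresholds given")
    if policy == "highest":
        return max(thresholds)
    if policy == "lowest":
        return min(thresholds)
    raise ValueError(f"unknown policy {policy!r}; use 'highest' or 'lowest'")


def censor_events(event_masses, mass_threshold: float) -> np.ndarray:
    """Boolean mask of events at or above the harmonized mass threshold."""
    m = np.asarray(event_masses, dtype=float)
    return m >= mass_threshold
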