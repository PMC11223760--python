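"""Method-validation statistics.

Covers the four validation calculations a single-lab study needs:

* **recovery** — measured value as percent of a reference value;
* **z-score** — proficiency-test score (result − assigned) / sigma_PT;
* **anova_precision** — repeatability and intermediate precision from a
  days × replicates design by one-way ANOVA variance decomposition:
  ``s_r^2 = MS_within`` and ``s_between^2 = max(0, (MS_between − MS_within) /
  n_0)`` with ``n_0`` the effective per-group size for unbalanced designs;
  ``s_IP^2 = s_r^2 + s_between^2``.  When ``MS_between < MS_within`` the
  between-day component is clamped to zero, a flag is set, and the *total*
  RSD (SD of all values over the grand mean) is reported as the fallback;
* **mc_uncertainty** — type-B bottom-up measurement uncertainty by Monte
  Carlo propagation of a component budget through a measurand function, with
  an expanded uncertainty at coverage factor ``k`` (default 2, ~95%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "ReplicateDesign",
    "PrecisionResult",
    "UncertaintyComponent",
    "UncertaintyBudget",
    "UncertaintyResult",
    "recovery",
    "z_score",
    "anova_precision",
    "mc_uncertainty",
]


def recovery(measured: float, reference: float) -> float:
    """Recovery in percent: 100 · measured / reference.

    Report rounded to integer percent; the exact value is returned.
    """
    if reference == 0:
        raise ZeroDivisionError("reference value must be nonzero")
    return 100.0 * measured / reference


def z_score(result: float, assigned_value: float, sigma_pt: float) -> float:
    """Proficiency-test z-score: (result − assigned) / sigma_PT."""
    if not (sigma_pt > 0):
        raise ValueError("sigma_pt must be > 0")
    return (result - assigned_value) / sigma_pt


@dataclass
class ReplicateDesign:
    """Measurand values grouped by day (possibly unbalanced)."""

    values: np.ndarray
    day_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.day_labels = np.asarray(self.day_labels)
        if self.values.shape != self.day_labels.shape or self.values.ndim != 1:
            raise ValueError("values and day_labels must be equal-length 1-D arrays")

    def groups(self) -> list[np.ndarray]:
        return [self.values[self.day_labels == d] for d in np.unique(self.day_labels)]


@dataclass
class PrecisionResult:
    """Repeatability / intermediate-precision decomposition (RSDs in %)."""

    rsd_repeatability: float
    rsd_intermediate: float
    total_rsd: float
    between_day_variance: float
    within_day_variance: float
    clamped: bool
    grand_mean: float
    n_days: int


def anova_precision(design: ReplicateDesign) -> PrecisionResult:
    """One-way ANOVA precision decomposition (see module docstring).

    Requires at least 2 days with at least 2 replicates on some day.
    """
    groups = [g for g in design.groups() if g.size > 0]
    p = len(groups)
    if p < 2:
        raise ValueError("need >= 2 days")
    n_i = np.array([g.size for g in groups], dtype=float)
    big_n = n_i.sum()
    if big_n - p < 1:
        raise ValueError("need replication within days (N - p >= 1)")
    grand_mean = float(np.concatenate(groups).mean())
    group_means = np.array([g.mean() for g in groups])
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ss_between = float((n_i * (group_means - grand_mean) ** 2).sum())
    ms_within = ss_within / (big_n - p)
    ms_between = ss_between / (p - 1)
    # effective per-group size; reduces to n for balanced designs
    n0 = (big_n - (n_i**2).sum() / big_n) / (p - 1)

    s_r2 = ms_within
    clamped = ms_between < ms_within
    s_b2 = max(0.0, (ms_between - ms_within) / n0)
    s_ip2 = s_r2 + s_b2
    all_values = np.concatenate(groups)
    total_sd = float(np.std(all_values, ddof=1))
    if grand_mean == 0:
        raise ValueError("grand mean is zero; RSDs undefined")
    return PrecisionResult(
        rsd_repeatability=100.0 * np.sqrt(s_r2) / abs(grand_mean),
        rsd_intermediate=100.0 * np.sqrt(s_ip2) / abs(grand_mean),
        total_rsd=100.0 * total_sd / abs(grand_mean),
        between_day_variance=s_b2,
        within_day_variance=s_r2,
        clamped=bool(clamped),
        grand_mean=grand_mean,
        n_days=p,
    )


@dataclass(frozen=True)
class UncertaintyComponent:
    """One input quantity of the uncertainty budget.

    ``dist`` is one of ``"normal"`` (params: mean, sd), ``"uniform"``
    (params: low, high), ``"triangular"`` (params: low, mode, high) or
    ``"poisson"`` (params: mean — counting statistics, rescaled to keep the
    nominal value at ``mean``).
    """

    name: str
    dist: str
    params: tuple

    def nominal(self) -> float:
        if self.dist == "normal":
            return self.params[0]
        if self.dist == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        if self.dist == "triangular":
            return self.params[1]
        if self.dist == "poisson":
            return self.params[0]
        raise ValueError(f"unknown distribution {self.dist!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "normal":
            return rng.normal(self.params[0], self.params[1], n)
        if self.dist == "uniform":
            return rng.uniform(self.params[0], self.params[1], n)
        if self.dist == "triangular":
            return rng.triangular(self.params[0], self.params[1], self.params[2], n)
        if self.dist == "poisson":
            return rng.poisson(self.params[0], n).astype(float)
        raise ValueError(f"unknown distribution {self.dist!r}")


@dataclass
class UncertaintyBudget:
    """Component list + measurand function for Monte Carlo propagation.

    ``measurand`` maps a dict of (component name → array of draws) to the
    measurand value, vectorised over draws.
    """

    components: list
    measurand: Callable[[dict], np.ndarray]
    n_draws: int = 100_000
    seed: int = 0
    coverage_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.n_draws < 10_000:
            raise ValueError("n_draws must be >= 10^4")
        if not (self.coverage_factor > 0):
            raise ValueError("coverage factor must be > 0")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")


@dataclass
class UncertaintyResult:
    """Monte Carlo uncertainty: relative standard/expanded U and shares."""

    value: float
    rel_standard_uncertainty_pct: float
    expanded_uncertainty_pct: float
    coverage_factor: float
    component_shares: dict
    n_draws: int


def mc_uncertainty(budget: UncertaintyBudget) -> UncertaintyResult:
    """Propagate the budget through the measurand by Monte Carlo.

    All components are drawn jointly (independently) and the measurand
    evaluated per draw; the relative standard uncertainty is the SD of the
    measurand over the absolute mean, and the expanded uncertainty multiplies
    by the coverage factor.  Component variance shares are estimated by
    re-evaluating with one component varying and the others held at their
    nominal values.
    """
    if not budget.components:
        raise ValueError("budget has no components")
    rng = np.random.default_rng(budget.seed)
    n = budget.n_draws
    draws = {c.name: c.draw(n, rng) for c in budget.components}
    y = np.asarray(budget.measurand(draws), dtype=float)
    mean_y = float(np.mean(y))
    if mean_y == 0:
        raise ValueError("measurand mean is zero; relative uncertainty undefined")
    u_rel = float(np.std(y, ddof=1)) / abs(mean_y)

    nominal = {c.name: np.full(n, c.nominal()) for c in budget.components}
    variances = {}
    for c in budget.components:
        one = dict(nominal)
        one[c.name] = draws[c.name]
        variances[c.name] = float(np.var(np.asarray(budget.measurand(one), dtype=float), ddof=1))
    total = sum(variances.values())
    shares = {
        k: (v / total if total > 0 else 0.0) for k, v in variances.items()
    }
    return UncertaintyResult(
        value=mean_y,
        rel_standard_uncertainty_pct=100.0 * u_rel,
        expanded_uncertainty_pct=100.0 * u_rel * budget.coverage_factor,
        coverage_factor=budget.coverage_factor,
        component_shares=shares,
        n_draws=n,
    )
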