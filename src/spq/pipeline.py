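"""Batch pipeline: detect → calibrate → quantify → limits from one config.

The run configuration is a YAML/JSON mapping with these sections (defaults in
parentheses):

.. code-block:: yaml

    seed: 1                      # recorded in reports; stages are deterministic
    output_dir: out
    acquisition: {dwell_time: 1.0e-4, flow_rate: 0.346}
    element: {element: Au, isotope: 197, compound: Au,
              density: 19.32, element_mass_fraction: 1.0}
    threshold: {fp_budget_per_minute: 0.05, dwells_per_minute: 600000}
    detection: {window: 1001, peak_width: 5.0e-4, harmonize_policy: highest}
    calibration:
      ionic_standards:           # mean_signal in counts/dwell, or a trace file
        - {concentration: 0.5, mean_signal: 2.61}
      reference: {trace: ref.csv, diameter: 60.0}
    samples:
      - {trace: sample1.csv, label: spike30, dilution_factor: 500}
    blanks:                      # optional; enables concentration LODs
      - {trace: blank1.csv, dilution_factor: 500}

Each stage failure is re-raised as :class:`PipelineError` tagged with the
stage name.  All intermediate artifacts (event tables, calibration, per-sample
quantification, limits, summary) are written under ``output_dir``; given the
same configuration the byte content of every report is reproducible.
"""

from __future__ import annotations

from contextlib import contextmanager
from pathlib import Path

import numpy as np

from . import io as spio
from .calibrate import (
    ElementSpec,
    fit_ionic_calibration,
    kde_mode,
    sensitivity_counts_per_ag,
    transport_efficiency_size_method,
)
from .detect import (
    ThresholdPolicy,
    censor_events,
    detect_events,
    harmonize_mass_thresholds,
)
from .calibrate import event_mass, mass_to_diameter
from .limits import (
    LimitsReport,
    coincidence_upper_range,
    mass_conc_lod,
    number_conc_lod,
    size_lod,
)
from .quantify import SampleDescriptor, quantify_sample

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, str(exc)) from exc


def _element_from_config(cfg: dict) -> ElementSpec:
    e = cfg.get("element", {})
    return ElementSpec(
        element=e.get("element", "Au"),
        isotope=int(e.get("isotope", 197)),
        compound=e.get("compound", e.get("element", "Au")),
        density=float(e.get("density", 19.32)),
        element_mass_fraction=float(e.get("element_mass_fraction", 1.0)),
    )


def run_pipeline(config) -> dict:
    """Execute the full pipeline for one run configuration.

    ``config`` is a mapping (see module docstring) or a path to a YAML/JSON
    file.  Returns the summary report dict that is also written to
    ``output_dir/summary.json``.
    """
    if not isinstance(config, dict):
        config = spio.load_config(config)
    base = Path(config.get("base_dir", "."))
    out_dir = Path(config.get("output_dir", "out"))

    acq = config.get("acquisition", {})
    dwell_time = float(acq.get("dwell_time", 1e-4))
    flow_rate = float(acq.get("flow_rate", 0.346))
    det = config.get("detection", {})
    window = int(det.get("window", 1001))
    peak_width = float(det.get("peak_width", 500e-6))
    harmonize_policy = det.get("harmonize_policy", "highest")
    thr = config.get("threshold", {})
    policy = ThresholdPolicy(
        fp_budget_per_minute=float(thr.get("fp_budget_per_minute", 0.05)),
        dwells_per_minute=int(thr.get("dwells_per_minute", 600_000)),
    )
    element = _element_from_config(config)

    samples = config.get("samples", [])
    if not samples:
        raise PipelineError("config", "empty sample list")
    cal_cfg = config.get("calibration")
    if not cal_cfg:
        raise PipelineError("config", "missing calibration section")
    out_dir.mkdir(parents=True, exist_ok=True)

    def _read(entry_path):
        return spio.read_trace(base / entry_path, dwell_time=dwell_time)

    # --- calibrate ---------------------------------------------------------
    with _stage("calibrate"):
        points = []
        for std in cal_cfg["ionic_standards"]:
            if "mean_signal" in std:
                signal = float(std["mean_signal"])
            else:
                signal = float(np.mean(_read(std["trace"]).counts))
            points.append((float(std["concentration"]), signal))
        cal = fit_ionic_calibration(points, flow_rate=flow_rate, dwell_time=dwell_time)

        ref_cfg = cal_cfg["reference"]
        ref_trace = _read(ref_cfg["trace"])
        ref_det = detect_events(ref_trace, policy, window=window, peak_width=peak_width)
        if len(ref_det.events) < 10:
            raise PipelineError(
                "calibrate",
                f"only {len(ref_det.events)} reference events; need >= 10 for the KDE mode",
            )
        mode = kde_mode(ref_det.events["net_area"].to_numpy())
        eta = transport_efficiency_size_method(
            cal, mode, float(ref_cfg["diameter"]), element
        )
        calibration_report = {
            "ionic": {
                "slope": cal.slope,
                "intercept": cal.intercept,
                "r_squared": cal.r_squared,
            },
            "transport_efficiency": eta.eta,
            "kde_mode_intensity": mode,
            "reference_diameter": float(ref_cfg["diameter"]),
            "sensitivity_counts_per_ag": sensitivity_counts_per_ag(cal, eta),
        }
        spio.write_json_report(out_dir / "calibration.json", calibration_report)

    # --- detect ------------------------------------------------------------
    with _stage("detect"):
        detections = []
        for entry in samples:
            trace = _read(entry["trace"])
            res = detect_events(trace, policy, window=window, peak_width=peak_width)
            detections.append((entry, trace, res))
            label = entry.get("label", trace.acquisition_id)
            spio.write_event_table(out_dir / f"events_{label}.csv", res.events)

    # --- limits (per-particle, needed for censoring) -----------------------
    with _stage("limits"):
        per_run_lods = []
        for entry, trace, res in detections:
            m_lod, _ = size_lod(
                res.threshold, res.mean_background, peak_width, cal, eta, element
            )
            per_run_lods.append(m_lod)
        common_mass_threshold = harmonize_mass_thresholds(
            per_run_lods, policy=harmonize_policy
        )

    # --- quantify ----------------------------------------------------------
    with _stage("quantify"):
        sample_reports = {}
        for entry, trace, res in detections:
            sample = SampleDescriptor(
                dilution_factor=float(entry.get("dilution_factor", 500.0)),
                flow_rate=flow_rate,
                acquisition_time=trace.duration,
            )
            masses = event_mass(res.events["net_area"].to_numpy(), cal, eta)
            kept = masses[censor_events(masses, common_mass_threshold)]
            bound = coincidence_upper_range(peak_width, eta, sample)
            q = quantify_sample(kept, eta, sample, element, coincidence_bound=bound)
            label = entry.get("label", trace.acquisition_id)
            dist = {
                k: v
                for k, v in q.size_distribution.items()
                if k in ("mean", "n", "quantiles")
            }
            sample_reports[label] = {
                "number_conc": q.number_conc,
                "mass_conc": q.mass_conc,
                "mean_diameter": q.mean_diameter,
                "n_events": q.n_events,
                "coincidence_bound": bound,
                "size_distribution": dist,
            }
            spio.write_json_report(out_dir / f"quant_{label}.json", sample_reports[label])

    # --- limits (concentration, from blanks) -------------------------------
    with _stage("limits"):
        blanks = config.get("blanks", [])
        blank_mass_concs, blank_counts = [], []
        blank_sample = None
        for entry in blanks:
            trace = _read(entry["trace"])
            res = detect_events(trace, policy, window=window, peak_width=peak_width)
            blank_sample = SampleDescriptor(
                dilution_factor=float(entry.get("dilution_factor", 500.0)),
                flow_rate=flow_rate,
                acquisition_time=trace.duration,
            )
            masses = event_mass(res.events["net_area"].to_numpy(), cal, eta)
            kept = masses[censor_events(masses, common_mass_threshold)]
            q = quantify_sample(kept, eta, blank_sample, element)
            blank_mass_concs.append(q.mass_conc)
            blank_counts.append(q.n_events)

        first_sample = SampleDescriptor(
            dilution_factor=float(samples[0].get("dilution_factor", 500.0)),
            flow_rate=flow_rate,
            acquisition_time=detections[0][1].duration,
        )
        report = LimitsReport(
            mass_lod_per_particle=common_mass_threshold,
            size_lod=mass_to_diameter(common_mass_threshold, element),
            mass_conc_lod=(
                mass_conc_lod(blank_mass_concs) if len(blank_mass_concs) >= 2 else None
            ),
            number_conc_lod=(
                number_conc_lod(blank_counts, eta, blank_sample)
                if blank_counts
                else None
            ),
            upper_number_conc=coincidence_upper_range(peak_width, eta, first_sample),
            assumptions={
                "tau": peak_width,
                "alpha_coincidence": 0.05,
                "harmonize_policy": harmonize_policy,
            },
        )
        spio.write_json_report(out_dir / "limits.json", report)

    summary = {
        "seed": config.get("seed"),
        "element": element.element,
        "calibration": calibration_report,
        "samples": sample_reports,
        "limits": spio._to_jsonable(report),
    }
    spio.write_json_report(out_dir / "summary.json", summary)
    return summary
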