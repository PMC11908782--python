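"""End-to-end runs: stack (or traces) -> flags -> indices -> tonotopy -> maps.

Two entry points:

* :func:`process_stack` follows the movie path — Gaussian filtering,
  ROI/neuropil extraction, neuropil correction, dF/f.
* :func:`process_traces` follows the trace path for pre-extracted
  fluorescence (including the synthetic generator's output): neuropil
  correction, dF/f, then the same temporal Gaussian the movie path
  applies to the stack.

Both feed :func:`analyze` which segments trials, flags responsive
cell x combo pairs, and derives tuning.  :func:`run_pipeline` wires
everything together and writes tidy CSV tables, a JSON run manifest
and PNG maps, deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .extraction import (
    DEFAULT_NEUROPIL_COEFFICIENT,
    DffTraces,
    RawTraces,
    RoiSet,
    compute_dff,
    extract_signals,
    gaussian_filter_stack,
    load_rois,
    neuropil_correct,
    smooth_traces,
)
from .reporting import CLASS_PALETTE, frequency_palette, render_map
from .responses import (
    DEFAULT_POST_WINDOW_S,
    RESPONSIVE_THRESHOLD,
    ResponseTable,
    TrialTensor,
    TuningRecord,
    flag_responsive,
    receptive_field_sum,
    segment_trials,
)
from .stimuli import StimulusSchedule, read_schedule
from .synthetic import SyntheticExperiment
from .tonotopy import AXIS_PRESETS, bin_geometric, fit_tonotopy, project_distance

__all__ = ["AnalysisResult", "process_stack", "process_traces", "analyze", "run_pipeline"]


@dataclass
class AnalysisResult:
    """Everything one grid run produces, ready for serialization."""

    tensor: TrialTensor
    responses: ResponseTable
    tuning: TuningRecord
    params: dict

    def response_frame(self) -> pd.DataFrame:
        return self.responses.table

    def tuning_frame(self) -> pd.DataFrame:
        df = self.tuning.best.rename("best_freq_hz").to_frame()
        df["rfs_total"] = self.tuning.rfs_total
        for lv in self.tuning.rfs_by_level.columns:
            df[f"rfs_{lv:g}dB"] = self.tuning.rfs_by_level[lv]
        df.index.name = "cell_id"
        return df.reset_index()


def process_stack(
    stack: np.ndarray,
    rois: RoiSet,
    frame_rate_hz: float = 29.9,
    sigma_xy_px: float = 1.0,
    sigma_t_frames: float = 2.0,
    neuropil_coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT,
    baseline_method: str = "percentile_trend",
) -> DffTraces:
    """Movie path: filter, extract, neuropil-correct, normalize."""
    filtered = gaussian_filter_stack(stack, sigma_xy_px, sigma_t_frames)
    raw = extract_signals(filtered, rois, frame_rate_hz=frame_rate_hz)
    corrected = neuropil_correct(raw, neuropil_coefficient)
    return compute_dff(corrected, frame_rate_hz, raw.cell_ids, baseline_method)


def process_traces(
    raw: RawTraces,
    sigma_t_frames: float = 2.0,
    neuropil_coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT,
    baseline_method: str = "percentile_trend",
) -> DffTraces:
    """Trace path: neuropil-correct, normalize, temporally smooth."""
    corrected = neuropil_correct(raw, neuropil_coefficient)
    dff = compute_dff(corrected, raw.frame_rate_hz, raw.cell_ids, baseline_method)
    dff.dff = smooth_traces(dff.dff, sigma_t_frames)
    return dff


def process_experiment(
    experiment: SyntheticExperiment,
    sigma_t_frames: float = 2.0,
    neuropil_coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT,
    baseline_method: str = "percentile_trend",
) -> DffTraces:
    """Trace path applied to a synthetic experiment's recordings."""
    raw = RawTraces(
        experiment.traces,
        experiment.neuropil_traces,
        experiment.frame_rate_hz,
        [c.cell_id for c in experiment.cells],
    )
    return process_traces(raw, sigma_t_frames, neuropil_coefficient, baseline_method)


def analyze(
    dff: DffTraces,
    schedule: StimulusSchedule,
    threshold: float = RESPONSIVE_THRESHOLD,
    pre_s: float = 0.0,
    post_s: float = DEFAULT_POST_WINDOW_S,
    extra_runs=None,
) -> AnalysisResult:
    """Segment, flag, and summarize tuning for one grid."""
    tensor = segment_trials(dff, schedule, pre_s=pre_s, post_s=post_s, extra_runs=extra_runs)
    responses = flag_responsive(tensor, threshold=threshold)
    tuning = receptive_field_sum(responses)
    params = {
        "threshold": threshold,
        "pre_s": pre_s,
        "post_s": post_s,
        "window_s": tensor.window_s,
        "n_repeats": tensor.n_repeats,
        "frame_rate_hz": tensor.frame_rate_hz,
    }
    return AnalysisResult(tensor, responses, tuning, params)


def run_pipeline(
    stack_path,
    rois_path,
    schedule_path,
    out_dir,
    frame_rate_hz: float = 29.9,
    pixel_size_um: float = 1.0,
    sigma_xy_px: float = 1.0,
    sigma_t_frames: float = 2.0,
    neuropil_coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT,
    threshold: float = RESPONSIVE_THRESHOLD,
    pre_s: float = 0.0,
    post_s: float = DEFAULT_POST_WINDOW_S,
    tonotopy_axis: str = "rostromedial_caudolateral",
) -> dict:
    """File-to-file run: extraction -> flagging -> tuning -> tonotopy -> maps.

    Writes ``responses.csv``, ``tuning.csv``, ``tonotopy.json``,
    ``map_btf.png`` (+ color key) and ``manifest.json`` under
    ``out_dir``; returns the manifest dict.  Output is byte-identical
    across runs on identical inputs.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = tifffile.imread(stack_path)
    rois = load_rois(rois_path, stack.shape[1:], pixel_size_um)
    schedule = read_schedule(schedule_path)
    dff = process_stack(
        stack, rois, frame_rate_hz, sigma_xy_px, sigma_t_frames, neuropil_coefficient
    )
    result = analyze(dff, schedule, threshold=threshold, pre_s=pre_s, post_s=post_s)

    result.response_frame().to_csv(out / "responses.csv", index=False, lineterminator="\n")
    tuning = result.tuning_frame()
    tuning.to_csv(out / "tuning.csv", index=False, lineterminator="\n")

    # tonotopy along the requested preset axis, on cells with a defined BTF
    cents = rois.centroids_um()
    tuned = tuning.dropna(subset=["best_freq_hz"])
    tono_report: dict = {"axis": tonotopy_axis, "fitted": False}
    if len(tuned) >= 3:
        pts = np.array([cents[c] for c in tuned["cell_id"]])
        axis = AXIS_PRESETS[tonotopy_axis]
        dist = project_distance(pts, axis)
        binned = bin_geometric(dist, tuned["best_freq_hz"].to_numpy())
        if len(binned) >= 3:
            fit = fit_tonotopy(binned, axis)
            tono_report = {
                "axis": tonotopy_axis,
                "fitted": True,
                "n_bins": len(binned),
                "r2_linear": fit.r2_linear,
                "r2_quadratic": fit.r2_quadratic,
                "coef_linear": list(fit.coef_linear),
                "bins": binned.to_dict(orient="list"),
            }
    with open(out / "tonotopy.json", "w") as fh:
        json.dump(tono_report, fh, indent=1, sort_keys=True)

    grid_freqs = schedule.grid.freqs_hz
    palette = frequency_palette([f for f in grid_freqs if f > 0] or list(grid_freqs))
    values = {
        row.cell_id: row.best_freq_hz
        for row in tuned.itertuples()
        if format(row.best_freq_hz, "g") in palette
    }
    cell_map = render_map(rois, values, palette)
    cell_map.save(out / "map_btf.png")

    manifest = {
        "version": __version__,
        "inputs": {
            "stack": str(stack_path),
            "rois": str(rois_path),
            "schedule": str(schedule_path),
        },
        "params": {
            "frame_rate_hz": frame_rate_hz,
            "pixel_size_um": pixel_size_um,
            "sigma_xy_px": sigma_xy_px,
            "sigma_t_frames": sigma_t_frames,
            "neuropil_coefficient": neuropil_coefficient,
            "threshold": threshold,
            "pre_s": pre_s,
            "post_s": post_s,
            "tonotopy_axis": tonotopy_axis,
        },
        "n_cells": len(rois),
        "n_trials": schedule.n_trials,
        "n_responsive_cells": int(result.responses.any_responsive().sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
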