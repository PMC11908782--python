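"""Ground-truthed synthetic two-photon experiments.

Real inferior-colliculus movies are not redistributable, so every
stage of the pipeline is exercised against simulations with known
ground truth.  The generator emulates the statistical structure the
analysis assumes:

* stimulus-locked calcium transients with red-GECI-like kinetics
  (difference of exponentials, 50 ms rise / 700 ms decay),
* per-cell Gaussian tuning in log2 frequency over the tone or AM grid,
  with amplitude growing linearly with sound level above threshold,
* onset, offset, or onset+offset response timing,
* multiplicative photobleaching (single exponential), additive
  Gaussian noise, and neuropil contamination mixed in at a known
  coefficient,
* a spatial layout with module/matrix compartment labels and an
  implantable tonotopic gradient along a chosen axis,
* spontaneous transients as a Poisson process, for event-detection
  tests.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .extraction import RoiSet
from .stimuli import StimulusGrid, StimulusSchedule, StimulusType

__all__ = [
    "GroundTruthCell",
    "SyntheticExperiment",
    "generate_cells",
    "simulate_traces",
    "render_movie",
    "transient_kernel",
    "DEFAULT_FRAME_RATE_HZ",
    "DEFAULT_BASELINE_F",
    "DEFAULT_NOISE_SD",
    "DEFAULT_RESPONSE_AMP",
    "DEFAULT_TUNING_BW_OCT",
]

DEFAULT_FRAME_RATE_HZ = 29.9
#: Resting fluorescence per cell (arbitrary units).
DEFAULT_BASELINE_F = 100.0
#: Additive per-frame noise SD (a.u.); 5% of baseline.
DEFAULT_NOISE_SD = 5.0
#: Peak evoked dF/f at the preferred stimulus and maximum level.
DEFAULT_RESPONSE_AMP = 0.6
#: Gaussian tuning bandwidth (octaves, SD of the log2-frequency tuning curve).
DEFAULT_TUNING_BW_OCT = 0.7
#: Transient kinetics (seconds): fast rise, slower decay.
RISE_TAU_S = 0.05
DECAY_TAU_S = 0.7
#: Spontaneous transient rate (Hz) for nonresponsive-cell recordings.
DEFAULT_SPONT_RATE_HZ = 0.05


@dataclass(frozen=True)
class GroundTruthCell:
    """True response phenotype of one simulated neuron."""

    cell_id: str
    centroid_um: tuple[float, float]
    compartment: str = "matrix"  # "module" or "matrix"
    true_btf_hz: float = 10000.0
    true_bmf_hz: float = 8.0
    response_amp: float = DEFAULT_RESPONSE_AMP
    tuning_bw_oct: float = DEFAULT_TUNING_BW_OCT
    response_timing: str = "onset"  # onset | offset | onset_offset
    modality: str = "aud_only"  # aud_only | som_only | aud_som
    bimodal_gain: float = 1.0
    responsive: bool = True
    threshold_db: float = 40.0

    def __post_init__(self) -> None:
        if self.response_amp < 0:
            raise ValueError("response_amp must be >= 0")
        if self.tuning_bw_oct <= 0:
            raise ValueError("tuning_bw_oct must be > 0")
        if self.bimodal_gain < 0:
            raise ValueError("bimodal_gain must be >= 0")


@dataclass
class SyntheticExperiment:
    """Simulated recording: traces plus everything needed to grade results."""

    cells: list[GroundTruthCell]
    schedule: StimulusSchedule
    frame_rate_hz: float
    traces: np.ndarray  # (frames, cells), a.u.
    neuropil_traces: np.ndarray  # (frames, cells), a.u.
    baseline_f: float
    bleach_tau_s: float | None
    noise_sd: float
    neuropil_mix: float
    seed: int

    @property
    def n_frames(self) -> int:
        return self.traces.shape[0]

    def ground_truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "x_um": c.centroid_um[0],
                "y_um": c.centroid_um[1],
                "compartment": c.compartment,
                "true_btf_hz": c.true_btf_hz,
                "true_bmf_hz": c.true_bmf_hz,
                "response_amp": c.response_amp,
                "tuning_bw_oct": c.tuning_bw_oct,
                "response_timing": c.response_timing,
                "modality": c.modality,
                "bimodal_gain": c.bimodal_gain,
                "responsive": c.responsive,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows)


def transient_kernel(frame_rate_hz: float, rise_tau_s: float = RISE_TAU_S,
                     decay_tau_s: float = DECAY_TAU_S, duration_s: float = 4.0) -> np.ndarray:
    """Difference-of-exponentials calcium transient, normalized to peak 1."""
    t = np.arange(int(round(duration_s * frame_rate_hz))) / frame_rate_hz
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


def _tuning_factor(freq_hz: float, best_hz: float, bw_oct: float) -> float:
    """Gaussian tuning in log2 frequency; 0 Hz rows pass through at 1."""
    if freq_hz <= 0 or best_hz <= 0:
        return 1.0
    d_oct = math.log2(freq_hz / best_hz)
    return math.exp(-0.5 * (d_oct / bw_oct) ** 2)


def _level_factor(level_db: float, threshold_db: float, max_db: float) -> float:
    """Linear growth from threshold to the loudest level presented."""
    if max_db <= threshold_db:
        return 1.0 if level_db >= threshold_db else 0.0
    return float(np.clip((level_db - threshold_db) / (max_db - threshold_db), 0.0, 1.0))


def generate_cells(
    n: int,
    layout: str = "gradient",
    axis_angle_deg: float = 0.0,
    gradient_span_oct: float = 3.0,
    module_fraction: float = 0.25,
    field_um: float = 500.0,
    grid_freqs_hz: tuple[float, ...] | None = None,
    am_rates_hz: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0),
    btf_jitter_oct: float = 0.25,
    responsive_fraction: float = 0.8,
    seed: int = 0,
) -> list[GroundTruthCell]:
    """Lay out cells and assign response phenotypes.

    ``layout='gradient'`` implants a tonotopic gradient: log2 of the
    true best tone frequency increases linearly with the cell's
    projection on the axis at ``axis_angle_deg``, spanning
    ``gradient_span_oct`` octaves across the field, plus per-cell
    jitter.  ``layout='random'`` draws best frequencies uniformly from
    the tone grid.  Module/matrix compartments are assigned by
    spatially contiguous blobs with expected area ``module_fraction``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= module_fraction <= 1.0:
        raise ValueError("module_fraction must be in [0, 1]")
    if layout not in ("gradient", "random"):
        raise ValueError(f"unknown layout {layout!r}")
    rng = np.random.default_rng(seed)
    if grid_freqs_hz is None:
        grid_freqs_hz = tuple(5000.0 * 2 ** (0.5 * k) for k in range(7))
    f_lo, f_hi = grid_freqs_hz[0], grid_freqs_hz[-1]
    xy = rng.uniform(0.0, field_um, size=(n, 2))

    # module blobs: a few seeded disks whose total expected area matches the fraction
    n_blobs = max(1, int(round(field_um / 150.0)) ** 2 // 2)
    blob_r = field_um * math.sqrt(module_fraction / (n_blobs * math.pi))
    blob_centers = rng.uniform(0.0, field_um, size=(n_blobs, 2))
    d2 = ((xy[:, None, :] - blob_centers[None, :, :]) ** 2).sum(axis=2)
    in_module = (d2 < blob_r**2).any(axis=1)

    theta = math.radians(axis_angle_deg)
    axis = np.array([math.cos(theta), math.sin(theta)])
    proj = xy @ axis
    span = proj.max() - proj.min() if n > 1 else 1.0

    cells: list[GroundTruthCell] = []
    for i in range(n):
        if layout == "gradient":
            frac = (proj[i] - proj.min()) / span if span > 0 else 0.0
            log_f = math.log2(f_lo) + frac * gradient_span_oct
            log_f += rng.normal(0.0, btf_jitter_oct)
            btf = float(np.clip(2.0**log_f, f_lo, f_hi))
        else:
            btf = float(rng.choice(grid_freqs_hz))
        bmf = float(rng.choice(am_rates_hz))
        responsive = bool(rng.uniform() < responsive_fraction)
        timing = rng.choice(["onset", "offset", "onset_offset"], p=[0.7, 0.15, 0.15])
        cells.append(
            GroundTruthCell(
                cell_id=f"cell{i:04d}",
                centroid_um=(float(xy[i, 0]), float(xy[i, 1])),
                compartment="module" if in_module[i] else "matrix",
                true_btf_hz=btf,
                true_bmf_hz=bmf,
                response_amp=float(rng.uniform(0.8, 1.2) * DEFAULT_RESPONSE_AMP),
                response_timing=str(timing),
                responsive=responsive,
            )
        )
    return cells


def _evoked_amplitude(cell: GroundTruthCell, stype: str, level_db: float,
                      freq_hz: float, max_level_db: float) -> float:
    """Peak dF/f evoked in ``cell`` by one stimulus presentation."""
    if not cell.responsive:
        return 0.0
    aud = stype in (
        StimulusType.PURE_TONE.value,
        StimulusType.AM_NOISE.value,
        StimulusType.UNMOD_NOISE.value,
        StimulusType.BIMODAL.value,
    )
    som = stype in (StimulusType.SOMATOSENSORY.value, StimulusType.BIMODAL.value)
    amp = 0.0
    if aud and cell.modality in ("aud_only", "aud_som"):
        if stype == StimulusType.PURE_TONE.value:
            tune = _tuning_factor(freq_hz, cell.true_btf_hz, cell.tuning_bw_oct)
        elif stype == StimulusType.AM_NOISE.value and freq_hz > 0:
            tune = _tuning_factor(freq_hz, cell.true_bmf_hz, cell.tuning_bw_oct)
        else:  # unmodulated noise, or the 0 Hz AM row
            tune = 0.6  # broadband drive relative to the preferred stimulus
        a = cell.response_amp * tune * _level_factor(level_db, cell.threshold_db, max_level_db)
        if stype == StimulusType.BIMODAL.value:
            a *= cell.bimodal_gain
        amp += a
    if som and cell.modality in ("som_only", "aud_som") and stype != StimulusType.BIMODAL.value:
        amp += cell.response_amp * 0.8
    return amp


def simulate_traces(
    cells: list[GroundTruthCell],
    schedule: StimulusSchedule,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    baseline_f: float = DEFAULT_BASELINE_F,
    bleach_tau_s: float | None = 600.0,
    noise_sd: float = DEFAULT_NOISE_SD,
    neuropil_mix: float = 0.4,
    pad_s: float = 3.0,
    spont_rate_hz: float = 0.0,
    seed: int = 0,
) -> SyntheticExperiment:
    """Simulate per-cell fluorescence for one scheduled run.

    recorded = bleach(t) * (F0 + F0 * sum(transients)) + mix * neuropil(t) + noise

    The neuropil signal is a shared slowly varying background (smoothed
    noise around ``0.5 * F0``), also bleaching; the same series is
    returned as the "measured" neuropil so that subtracting
    ``mix * neuropil`` recovers the somatic signal exactly.  Offset
    cells emit transients at stimulus offset; bimodal presentations
    scale the auditory amplitude by each cell's ``bimodal_gain``.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if schedule.n_trials == 0:
        raise ValueError("schedule is empty")
    rng = np.random.default_rng(seed)
    n_frames = int(round((schedule.total_duration_s + pad_s) * frame_rate_hz))
    n_cells = len(cells)
    t = np.arange(n_frames) / frame_rate_hz
    kernel = transient_kernel(frame_rate_hz)
    bleach = np.exp(-t / bleach_tau_s) if bleach_tau_s else np.ones_like(t)

    # shared slow neuropil background: heavily smoothed white noise, strictly positive
    from scipy.ndimage import gaussian_filter1d

    base_np = 0.5 * baseline_f
    wander = gaussian_filter1d(rng.normal(0.0, 1.0, n_frames), sigma=2.0 * frame_rate_hz, mode="reflect")
    sd = wander.std()
    if sd > 0:
        wander = wander / sd * (0.05 * base_np)
    neuropil_clean = (base_np + wander) * bleach

    trials = schedule.trials()
    duration_s = schedule.grid.duration_ms / 1000.0
    max_level = max(schedule.grid.levels_db)

    signal = np.zeros((n_frames, n_cells))
    for j, cell in enumerate(cells):
        drive = np.zeros(n_frames)
        for row in trials.itertuples():
            amp = _evoked_amplitude(cell, row.stimulus_type, row.level_db, row.freq_hz, max_level)
            if amp <= 0:
                continue
            events = []
            if cell.response_timing in ("onset", "onset_offset"):
                events.append((row.onset_s, amp))
            if cell.response_timing in ("offset", "onset_offset"):
                events.append((row.onset_s + duration_s, amp))
            for when, a in events:
                idx = int(round(when * frame_rate_hz))
                if idx < n_frames:
                    seg = min(kernel.size, n_frames - idx)
                    drive[idx : idx + seg] += a * kernel[:seg]
        if spont_rate_hz > 0:
            n_ev = rng.poisson(spont_rate_hz * n_frames / frame_rate_hz)
            for idx in rng.integers(0, n_frames, size=n_ev):
                seg = min(kernel.size, n_frames - idx)
                amp = cell.response_amp * rng.uniform(0.5, 1.5)
                drive[idx : idx + seg] += amp * kernel[:seg]
        signal[:, j] = bleach * baseline_f * (1.0 + drive)

    noise = rng.normal(0.0, noise_sd, size=(n_frames, n_cells)) if noise_sd > 0 else 0.0
    np_noise = rng.normal(0.0, noise_sd, size=(n_frames, n_cells)) if noise_sd > 0 else 0.0
    traces = signal + neuropil_mix * neuropil_clean[:, None] + noise
    neuropil_traces = neuropil_clean[:, None] + np.zeros((n_frames, n_cells)) + np_noise
    return SyntheticExperiment(
        cells=list(cells),
        schedule=schedule,
        frame_rate_hz=frame_rate_hz,
        traces=traces,
        neuropil_traces=neuropil_traces,
        baseline_f=baseline_f,
        bleach_tau_s=bleach_tau_s,
        noise_sd=noise_sd,
        neuropil_mix=neuropil_mix,
        seed=seed,
    )


def render_movie(
    experiment: SyntheticExperiment,
    image_size_px: int = 256,
    cell_radius_px: int = 6,
    pixel_size_um: float = 2.0,
    background: str = "neuropil",
    seed: int = 0,
) -> tuple[np.ndarray, RoiSet]:
    """Paint each cell's trace onto disk ROIs over a neuropil background.

    Returns a float (frames, H, W) stack and the matching RoiSet.
    Somata are placed by rejection sampling with no overlap (a margin
    of one radius); placement failure after 1000 attempts per cell
    raises.  Background pixels carry the shared neuropil series (or 0
    with ``background='zero'``).
    """
    n_cells = len(experiment.cells)
    rng = np.random.default_rng(seed)
    margin = 2 * cell_radius_px + 2
    centers: list[tuple[int, int]] = []
    for _ in range(n_cells):
        for attempt in range(1000):
            r = rng.integers(margin, image_size_px - margin)
            c = rng.integers(margin, image_size_px - margin)
            if all((r - r0) ** 2 + (c - c0) ** 2 >= (2 * cell_radius_px + 2) ** 2 for r0, c0 in centers):
                centers.append((int(r), int(c)))
                break
        else:
            raise RuntimeError("could not place non-overlapping cells in 1000 attempts")

    yy, xx = np.ogrid[:image_size_px, :image_size_px]
    masks = {}
    for cell, (r0, c0) in zip(experiment.cells, centers):
        masks[cell.cell_id] = (yy - r0) ** 2 + (xx - c0) ** 2 <= cell_radius_px**2
    rois = RoiSet(masks, (image_size_px, image_size_px), pixel_size_um)

    n_frames = experiment.n_frames
    if background == "neuropil":
        bg = experiment.neuropil_traces.mean(axis=1)
    elif background == "zero":
        bg = np.zeros(n_frames)
    else:
        raise ValueError(f"unknown background {background!r}")
    stack = bg[:, None, None] * np.ones((1, image_size_px, image_size_px))
    for j, cell in enumerate(experiment.cells):
        mask = masks[cell.cell_id]
        stack[:, mask] = experiment.traces[:, j][:, None]
    return stack, rois
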