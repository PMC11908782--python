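"""From motion-corrected stacks and ROI masks to neuropil-corrected dF/F.

The extraction chain mirrors standard soma-trace processing for
two-photon movies: Gaussian smoothing of the stack (spatial then
temporal), per-ROI mean fluorescence, a surrounding-neuropil mean from
an annulus grown to about four times the ROI area, subtraction of a
scaled neuropil signal (coefficient 0.4), and normalization to a
bleaching-corrected baseline:

    dF/f(t) = (F(t) - F0(t)) / F0(t)

where F0(t) is a fitted photobleaching trend (by default a linear fit
to the running 10th-percentile envelope of the trace).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from . import imagej_roi
from .imagej_roi import RoiGeometry, RoiFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "RoiSet",
    "RawTraces",
    "DffTraces",
    "load_rois",
    "rois_from_label_image",
    "gaussian_filter_stack",
    "extract_signals",
    "neuropil_correct",
    "compute_dff",
    "smooth_traces",
    "DEFAULT_NEUROPIL_COEFFICIENT",
    "DEFAULT_NEUROPIL_AREA_FACTOR",
]

#: Fraction of the surrounding-tissue signal subtracted from each soma trace.
DEFAULT_NEUROPIL_COEFFICIENT = 0.4
#: The neuropil annulus is grown until its area reaches this multiple of the ROI area.
DEFAULT_NEUROPIL_AREA_FACTOR = 4.0


class ExtractionError(RuntimeError):
    pass


@dataclass
class RoiSet:
    """Pixel masks for a set of cells within one field of view.

    ``masks`` maps cell_id -> boolean image of the ROI; ``compartments``
    carries optional module/matrix labels from the GFP channel.
    """

    masks: dict[str, np.ndarray]
    image_shape: tuple[int, int]
    pixel_size_um: float = 1.0
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, mask in self.masks.items():
            if mask.shape != tuple(self.image_shape):
                raise ValueError(f"mask {cid} shape {mask.shape} != image {self.image_shape}")
            if not mask.any():
                raise ValueError(f"mask {cid} is empty")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.masks)

    def __len__(self) -> int:
        return len(self.masks)

    def centroids_um(self) -> dict[str, tuple[float, float]]:
        """Centroid (x, y) of each mask in micrometres."""
        out = {}
        for cid, mask in self.masks.items():
            rows, cols = np.nonzero(mask)
            out[cid] = (cols.mean() * self.pixel_size_um, rows.mean() * self.pixel_size_um)
        return out

    def mean_radius_px(self) -> float:
        """Equivalent-circle radius averaged over all ROIs (pixels)."""
        areas = np.array([m.sum() for m in self.masks.values()], dtype=float)
        return float(np.mean(np.sqrt(areas / np.pi)))


@dataclass
class RawTraces:
    """Per-cell mean fluorescence with its companion neuropil signal."""

    cell: np.ndarray  # (frames, cells)
    neuropil: np.ndarray  # (frames, cells)
    frame_rate_hz: float
    cell_ids: list[str]

    def __post_init__(self) -> None:
        if self.cell.shape != self.neuropil.shape:
            raise ValueError("cell and neuropil trace matrices must have identical shape")
        if self.cell.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not (np.isfinite(self.cell).all() and np.isfinite(self.neuropil).all()):
            raise ValueError("non-finite fluorescence values")


@dataclass
class DffTraces:
    """Fractional fluorescence change per cell at a fixed frame rate."""

    dff: np.ndarray  # (frames, cells)
    frame_rate_hz: float
    cell_ids: list[str]
    baseline_method: str = "percentile_trend"

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def n_cells(self) -> int:
        return self.dff.shape[1]


def _rasterize(roi: RoiGeometry, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if roi.roi_type == imagej_roi.RECT:
        rr, cc = np.meshgrid(
            np.arange(roi.top, roi.bottom), np.arange(roi.left, roi.right), indexing="ij"
        )
        rr, cc = rr.ravel(), cc.ravel()
    elif roi.roi_type == imagej_roi.OVAL:
        r_c = (roi.top + roi.bottom - 1) / 2.0
        c_c = (roi.left + roi.right - 1) / 2.0
        rr, cc = skdraw.ellipse(r_c, c_c, roi.height / 2.0, roi.width / 2.0)
    else:  # polygon / freehand
        rr, cc = skdraw.polygon(roi.ys, roi.xs)
    inside = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    if not inside.all():
        logger.warning("ROI %s extends beyond image bounds; clipped", roi.name)
    mask[rr[inside], cc[inside]] = True
    return mask


def load_rois(
    path,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    compartments: dict[str, str] | None = None,
) -> RoiSet:
    """Load an ImageJ ``RoiSet.zip`` archive into pixel masks.

    Oval/rectangle/polygon outlines are rasterized; masks falling
    partly outside the image are clipped with a warning.
    """
    rois = imagej_roi.read_roi_zip(path)
    masks: dict[str, np.ndarray] = {}
    for roi in rois:
        mask = _rasterize(roi, image_shape)
        if not mask.any():
            raise RoiFormatError(f"ROI {roi.name} rasterizes to an empty mask")
        masks[roi.name] = mask
    return RoiSet(masks, image_shape, pixel_size_um, compartments or {})


def rois_from_label_image(labels: np.ndarray, pixel_size_um: float = 1.0) -> RoiSet:
    """Build a RoiSet from a labeled mask image (0 = background)."""
    masks = {
        f"cell{int(lab):04d}": labels == lab for lab in np.unique(labels) if lab != 0
    }
    if not masks:
        raise RoiFormatError("label image contains no nonzero labels")
    return RoiSet(masks, labels.shape, pixel_size_um)


def gaussian_filter_stack(
    stack: np.ndarray, sigma_xy_px: float = 1.0, sigma_t_frames: float = 2.0
) -> np.ndarray:
    """Separable Gaussian smoothing of a (frames, rows, cols) stack.

    Spatial smoothing first (sigma 1 px for surface fields of view,
    2 px for microprism views), then a temporal Gaussian of sigma 2
    frames.  A sigma of 0 disables that axis.  Temporal edges use
    reflection padding.
    """
    if sigma_xy_px < 0 or sigma_t_frames < 0:
        raise ValueError("sigmas must be >= 0")
    out = np.asarray(stack, dtype=float)
    if sigma_xy_px > 0:
        out = ndimage.gaussian_filter(out, sigma=(0.0, sigma_xy_px, sigma_xy_px), mode="reflect")
    if sigma_t_frames > 0:
        out = ndimage.gaussian_filter1d(out, sigma=sigma_t_frames, axis=0, mode="reflect")
    return out


def smooth_traces(traces: np.ndarray, sigma_t_frames: float = 2.0) -> np.ndarray:
    """Temporal Gaussian smoothing for trace matrices (frames x cells).

    Used when the pipeline starts from pre-extracted traces rather
    than a pixel stack, so that trace-level analysis sees the same
    temporal filtering the stack path applies.
    """
    if sigma_t_frames < 0:
        raise ValueError("sigma must be >= 0")
    if sigma_t_frames == 0:
        return np.asarray(traces, dtype=float)
    return ndimage.gaussian_filter1d(np.asarray(traces, dtype=float), sigma=sigma_t_frames, axis=0, mode="reflect")


def _neuropil_mask(
    mask: np.ndarray, all_cells: np.ndarray, area_factor: float
) -> np.ndarray:
    """Grow an annulus around ``mask`` until it reaches the target area.

    Iterative binary dilation, excluding every cell's pixels, stopping
    once the annulus area is >= area_factor x ROI area.
    """
    target = area_factor * mask.sum()
    grown = mask.copy()
    for _ in range(max(mask.shape)):
        grown = ndimage.binary_dilation(grown)
        annulus = grown & ~all_cells
        if annulus.sum() >= target:
            return annulus
    annulus = grown & ~all_cells
    if not annulus.any():
        return annulus
    return annulus


def extract_signals(
    stack: np.ndarray,
    rois: RoiSet,
    neuropil_area_factor: float = DEFAULT_NEUROPIL_AREA_FACTOR,
    frame_rate_hz: float = 29.9,
) -> RawTraces:
    """Mean ROI fluorescence per frame plus a surrounding-neuropil mean.

    The neuropil mask is an annulus dilated from each ROI until its
    area is roughly ``neuropil_area_factor`` times the ROI area,
    excluding all cell masks.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.shape[1:] != tuple(rois.image_shape):
        raise ValueError(f"stack frames {stack.shape[1:]} != ROI image {rois.image_shape}")
    all_cells = np.zeros(rois.image_shape, dtype=bool)
    for m in rois.masks.values():
        all_cells |= m
    flat = stack.reshape(stack.shape[0], -1)
    cell_traces, np_traces = [], []
    for cid, mask in rois.masks.items():
        annulus = _neuropil_mask(mask, all_cells, neuropil_area_factor)
        if not annulus.any():
            raise ExtractionError(f"empty neuropil annulus for cell {cid}")
        cell_traces.append(flat[:, mask.ravel()].mean(axis=1))
        np_traces.append(flat[:, annulus.ravel()].mean(axis=1))
    return RawTraces(
        np.column_stack(cell_traces),
        np.column_stack(np_traces),
        frame_rate_hz,
        rois.cell_ids,
    )


def neuropil_correct(
    raw: RawTraces, coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT
) -> np.ndarray:
    """Subtract a scaled neuropil signal: corrected = cell - c * neuropil."""
    if not 0.0 <= coefficient <= 1.0:
        raise ValueError("neuropil coefficient must be in [0, 1]")
    return raw.cell - coefficient * raw.neuropil


def dff_from_baseline(trace: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """dF/f against an explicitly supplied baseline: (F - F0) / F0."""
    trace = np.asarray(trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be strictly positive")
    return (trace - baseline) / baseline


def _percentile_envelope(trace: np.ndarray, window: int, q: float) -> np.ndarray:
    pad = window // 2
    padded = np.pad(trace, pad, mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, window)[: trace.size]
    return np.percentile(view, q, axis=1)


def compute_dff(
    corrected: np.ndarray,
    frame_rate_hz: float,
    cell_ids: list[str] | None = None,
    baseline_method: str = "percentile_trend",
    envelope_window_s: float = 10.0,
    envelope_percentile: float = 10.0,
) -> DffTraces:
    """Normalize traces to a fitted photobleaching baseline.

    ``percentile_trend`` (default) fits a line to the running
    low-percentile envelope of each trace, tracking slow bleaching
    while ignoring transients; ``linear_trend`` fits the trace itself.
    The fitted line is the baseline F0(t) in (F - F0)/F0.
    """
    corrected = np.asarray(corrected, dtype=float)
    n_frames, n_cells = corrected.shape
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if cell_ids is None:
        cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    t = np.arange(n_frames, dtype=float)
    window = max(3, min(n_frames, int(round(envelope_window_s * frame_rate_hz))))
    dff = np.empty_like(corrected)
    bad: list[str] = []
    for j in range(n_cells):
        trace = corrected[:, j]
        if baseline_method == "linear_trend":
            target = trace
        elif baseline_method == "percentile_trend":
            target = _percentile_envelope(trace, window, envelope_percentile)
        else:
            raise ValueError(f"unknown baseline_method {baseline_method!r}")
        slope, intercept = np.polyfit(t, target, 1)
        baseline = slope * t + intercept
        if np.any(baseline <= 0):
            bad.append(cell_ids[j])
            dff[:, j] = np.nan
            continue
        dff[:, j] = (trace - baseline) / baseline
    if bad:
        raise ValueError(f"non-positive fitted baseline for cells: {bad}")
    return DffTraces(dff, frame_rate_hz, list(cell_ids), baseline_method)
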