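"""Pseudocolor cell maps, population summaries, and flagging validation.

Maps follow the original rendering style: a blank canvas on which
every cell is a filled circle of uniform radius (the mean ROI radius),
colored by the quantity displayed, with a JSON-serializable color key.
Validation compares correlation scores against reference labels with
an exact empirical ROC (every distinct score is a cut) and confusion
metrics at a stated threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .extraction import RoiSet

__all__ = [
    "CellMap",
    "ValidationReport",
    "render_map",
    "cumulative_distribution",
    "population_summary",
    "roc_validation",
    "frequency_palette",
    "CLASS_PALETTE",
]


class PaletteError(KeyError):
    pass


#: Default categorical palette; avoids red-green pairings.
CLASS_PALETTE: dict[str, tuple[int, int, int]] = {
    "onset": (31, 119, 180),  # blue
    "offset": (44, 160, 44),  # green
    "onset_offset": (255, 127, 14),  # orange
    "suppressed": (148, 103, 189),  # purple
    "enhanced": (255, 127, 14),
    "unchanged": (127, 127, 127),
    "tone_sel": (31, 119, 180),
    "noise_sel": (255, 127, 14),
    "non_sel": (148, 103, 189),
    "aud_sel": (31, 119, 180),
    "som_sel": (255, 127, 14),
    "aud_som_nonsel": (148, 103, 189),
    "module": (31, 119, 180),
    "matrix": (255, 215, 0),
    "unresponsive": (200, 200, 200),
    "none": (200, 200, 200),
}


@dataclass
class CellMap:
    """A rendered pseudocolor map plus its color key."""

    image: Image.Image
    color_key: dict[str, tuple[int, int, int]]
    radius_px: float
    value_name: str

    def save(self, path) -> None:
        self.image.save(path, format="PNG")
        sidecar = str(path) + ".key.json"
        with open(sidecar, "w") as fh:
            json.dump({k: list(v) for k, v in self.color_key.items()}, fh, indent=1, sort_keys=True)


@dataclass
class ValidationReport:
    """ROC curve plus confusion metrics at one operating threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else np.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else np.nan

    def summary(self) -> str:
        return (
            f"ROC AUC {self.auc:.3f}; at threshold {self.threshold:g}: "
            f"sensitivity {100 * self.sensitivity:.0f}%, specificity {100 * self.specificity:.0f}%, "
            f"PPV {100 * self.ppv:.0f}%, NPV {100 * self.npv:.0f}%"
        )


def frequency_palette(freqs_hz, cmap_name: str = "viridis") -> dict[str, tuple[int, int, int]]:
    """Map each grid frequency to a fixed color along a colormap."""
    from matplotlib import colormaps

    cmap = colormaps[cmap_name]
    freqs = sorted(set(float(f) for f in freqs_hz))
    out = {}
    for i, f in enumerate(freqs):
        frac = i / max(1, len(freqs) - 1)
        r, g, b, _ = cmap(frac)
        out[f"{f:g}"] = (int(round(255 * r)), int(round(255 * g)), int(round(255 * b)))
    return out


def render_map(
    rois: RoiSet,
    values: dict[str, object],
    palette: dict[str, tuple[int, int, int]],
    background=(0, 0, 0),
    scale: float = 1.0,
) -> CellMap:
    """Draw one uniform-radius circle per cell, filled by its value.

    ``values`` maps cell_id to a category or frequency; every distinct
    value must have a palette entry (keys are ``str(value)`` with
    floats formatted by ``format(v, 'g')``).  Rendering is fully
    deterministic.
    """
    h, w = rois.image_shape
    img = Image.new("RGB", (int(w * scale), int(h * scale)), background)
    drawer = ImageDraw.Draw(img)
    radius = rois.mean_radius_px() * scale
    centroids = rois.centroids_um()
    for cid in rois.cell_ids:
        if cid not in values:
            continue
        key = _value_key(values[cid])
        if key not in palette:
            raise PaletteError(f"no palette entry for value {key!r} (cell {cid})")
        x_um, y_um = centroids[cid]
        x = x_um / rois.pixel_size_um * scale
        y = y_um / rois.pixel_size_um * scale
        drawer.ellipse([x - radius, y - radius, x + radius, y + radius], fill=palette[key])
    used = {_value_key(v) for v in values.values()}
    return CellMap(img, {k: palette[k] for k in sorted(used)}, radius, "value")


def _value_key(v) -> str:
    if isinstance(v, (float, np.floating, int, np.integer)):
        return format(float(v), "g")
    return str(v)


def cumulative_distribution(btfs_hz) -> pd.DataFrame:
    """Empirical CDF of best frequencies over the grid frequencies.

    Returns one row per distinct frequency with the fraction of cells
    whose best frequency is <= that frequency; reaches 1 at the top.
    """
    vals = np.asarray([b for b in np.asarray(btfs_hz, dtype=float) if np.isfinite(b)])
    if vals.size == 0:
        raise ValueError("no finite best frequencies")
    freqs = np.unique(vals)
    frac = np.searchsorted(np.sort(vals), freqs, side="right") / vals.size
    return pd.DataFrame({"freq_hz": freqs, "cumulative_fraction": frac})


def population_summary(
    classes: pd.DataFrame,
    class_column: str,
    compartment_column: str = "compartment",
    include_unresponsive: bool = False,
) -> pd.DataFrame:
    """Class counts and fractions per compartment.

    Fractions are of the responsive pool (rows whose class is not
    'unresponsive', unless ``include_unresponsive``); they sum to 1
    within each non-empty compartment.
    """
    df = classes.copy()
    if not include_unresponsive:
        df = df[df[class_column] != "unresponsive"]
    rows = []
    for comp, sub in df.groupby(compartment_column, sort=True):
        counts = sub[class_column].value_counts()
        total = counts.sum()
        for cls, n in counts.items():
            rows.append(
                {
                    "compartment": comp,
                    "class": cls,
                    "count": int(n),
                    "fraction": n / total,
                }
            )
    return pd.DataFrame(rows, columns=["compartment", "class", "count", "fraction"])


def roc_validation(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.4
) -> ValidationReport:
    """Exact empirical ROC of correlation scores against reference labels.

    Every distinct score is used as a cut (no binning); AUC by
    trapezoidal integration.  Confusion metrics are reported at the
    stated operating threshold, with "positive" meaning score strictly
    above it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("ROC undefined: labels contain a single class")
    cuts = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    pos = labels.sum()
    neg = labels.size - pos
    tpr = np.array([(labels & (scores >= c)).sum() / pos for c in cuts])
    fpr = np.array([(~labels & (scores >= c)).sum() / neg for c in cuts])
    auc = float(np.trapezoid(tpr, fpr))
    pred = scores > threshold
    tp = int((pred & labels).sum())
    fp = int((pred & ~labels).sum())
    tn = int((~pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return ValidationReport(fpr, tpr, cuts, auc, threshold, tp, fp, tn, fn)
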