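"""Quantifying tonotopic organization along anatomical axes.

Cells are referred to an axis origin; the Euclidean distance
d = sqrt((x2-x1)^2 + (y2-y1)^2) of each cell from the origin is binned
at 50 um, the geometric means of best tone frequency and of distance
are taken per bin, and ordinary least squares of degree 1 and 2 are
compared by R^2.  Because best frequencies combine multiplicatively
(geometric averaging), the default regression is on log2(BTF); a
raw-Hz option is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AxisSpec",
    "TonotopyFit",
    "project_distance",
    "bin_geometric",
    "fit_tonotopy",
    "AXIS_PRESETS",
    "DEFAULT_BIN_SIZE_UM",
]

DEFAULT_BIN_SIZE_UM = 50.0


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class AxisSpec:
    """A named anatomical axis: origin point plus unit direction."""

    name: str
    origin_um: tuple[float, float] = (0.0, 0.0)
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            raise ValueError("axis direction must be nonzero")
        object.__setattr__(self, "direction", (self.direction[0] / norm, self.direction[1] / norm))


def _axis(name: str, dx: float, dy: float) -> AxisSpec:
    return AxisSpec(name, (0.0, 0.0), (dx, dy))


#: The four lateral-cortex axes and the dorsal-cortex rostromedial->caudolateral axis.
AXIS_PRESETS: dict[str, AxisSpec] = {
    "dorsal_ventral": _axis("dorsal_ventral", 0.0, 1.0),
    "rostral_caudal": _axis("rostral_caudal", 1.0, 0.0),
    "dorsocaudal_ventrorostral": _axis("dorsocaudal_ventrorostral", -1.0, 1.0),
    "dorsorostral_ventrocaudal": _axis("dorsorostral_ventrocaudal", 1.0, 1.0),
    "rostromedial_caudolateral": _axis("rostromedial_caudolateral", 1.0, 1.0),
}


@dataclass
class TonotopyFit:
    """Linear and quadratic fits of binned geometric-mean BTF vs distance."""

    axis: AxisSpec
    bin_size_um: float
    bins: pd.DataFrame  # distance_um, btf_hz (geometric means), n_cells
    r2_linear: float
    r2_quadratic: float | None
    coef_linear: np.ndarray
    coef_quadratic: np.ndarray | None
    log2_btf: bool = True

    def summary(self) -> str:
        lines = [
            f"Tonotopy fit along {self.axis.name} ({len(self.bins)} bins of {self.bin_size_um:g} um)",
            f"  scale: {'log2(BTF)' if self.log2_btf else 'BTF (Hz)'}",
            f"  R^2 linear    = {self.r2_linear:.4f}",
        ]
        if self.r2_quadratic is not None:
            lines.append(f"  R^2 quadratic = {self.r2_quadratic:.4f}")
        return "\n".join(lines)


def project_distance(
    centroids_um: np.ndarray,
    axis: AxisSpec,
    exclude_behind: bool = True,
    method: str = "euclidean",
) -> np.ndarray:
    """Distance of each cell from the axis origin (um).

    ``method='euclidean'`` (default) is the straight-line distance
    d = sqrt((x2-x1)^2 + (y2-y1)^2), appropriate when the cells lie
    along the axis line.  ``method='projection'`` is the scalar
    projection onto the axis direction; with a common origin this is
    the only variant that distinguishes one axis direction from
    another, so axis-comparison workflows use it.  The two coincide
    for cells on the axis line.  Cells projecting behind the origin
    along the axis direction get NaN (excluded, logged) unless
    ``exclude_behind=False``.
    """
    pts = np.asarray(centroids_um, dtype=float)
    if not np.isfinite(pts).all():
        raise ValueError("centroids must be finite")
    delta = pts - np.asarray(axis.origin_um)
    if method == "euclidean":
        d = np.hypot(delta[:, 0], delta[:, 1])
    elif method == "projection":
        d = delta @ np.asarray(axis.direction)
    else:
        raise ValueError(f"unknown method {method!r}")
    if exclude_behind:
        proj = delta @ np.asarray(axis.direction)
        behind = proj < 0
        if behind.any():
            logger.info("%d cells project behind the %s origin; excluded", behind.sum(), axis.name)
            d = d.copy()
            d[behind] = np.nan
    return d


def bin_geometric(
    distances_um: np.ndarray,
    btfs_hz: np.ndarray,
    bin_size_um: float = DEFAULT_BIN_SIZE_UM,
) -> pd.DataFrame:
    """Per 50-um bin: geometric means of BTF and of distance.

    Bins are half-open [k*bin, (k+1)*bin); empty bins are absent.
    Cells at distance exactly 0 enter the geometric mean as
    ``bin lower edge + 1`` um (the geometric mean of 0 is degenerate).
    NaN distances or BTFs (excluded cells) are dropped.
    """
    d = np.asarray(distances_um, dtype=float)
    f = np.asarray(btfs_hz, dtype=float)
    if d.shape != f.shape:
        raise ValueError("distances and BTFs must have equal length")
    keep = np.isfinite(d) & np.isfinite(f)
    d, f = d[keep], f[keep]
    if np.any(f <= 0):
        raise ValueError("BTFs must be positive")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    if d.size == 0:
        return pd.DataFrame(columns=["distance_um", "btf_hz", "n_cells"])
    idx = np.floor(d / bin_size_um).astype(int)
    d_safe = d.copy()
    zero = d_safe == 0
    if zero.any():
        logger.info("%d zero distances replaced by bin edge + 1 um in geometric mean", zero.sum())
        d_safe[zero] = idx[zero] * bin_size_um + 1.0
    rows = []
    for k in sorted(set(idx)):
        sel = idx == k
        rows.append(
            {
                "distance_um": float(np.exp(np.mean(np.log(d_safe[sel])))),
                "btf_hz": float(np.exp(np.mean(np.log(f[sel])))),
                "n_cells": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    coef = np.polynomial.polynomial.polyfit(x, y, degree)
    pred = np.polynomial.polynomial.polyval(x, coef)
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def fit_tonotopy(
    binned: pd.DataFrame,
    axis: AxisSpec | None = None,
    bin_size_um: float = DEFAULT_BIN_SIZE_UM,
    log2_btf: bool = True,
) -> TonotopyFit:
    """Compare linear and quadratic OLS of geometric-mean BTF on distance.

    Needs >= 3 bins for the linear fit and >= 4 for the quadratic
    (omitted otherwise).  The quadratic nests the linear model, so
    r2_quadratic >= r2_linear whenever both are fit.
    """
    if axis is None:
        axis = AxisSpec("unspecified")
    n = len(binned)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 bins, got {n}")
    x = binned["distance_um"].to_numpy(float)
    y = binned["btf_hz"].to_numpy(float)
    if log2_btf:
        y = np.log2(y)
    coef1, r2_1 = _ols_poly(x, y, 1)
    coef2, r2_2 = (None, None)
    if n >= 4:
        coef2, r2_2 = _ols_poly(x, y, 2)
        if r2_2 < r2_1:
            # the linear model lies inside the quadratic family; under float
            # round-off the degree-2 solve can land on a marginally worse
            # point, in which case the nested solution is the minimizer
            coef2, r2_2 = np.append(coef1, 0.0), r2_1
    return TonotopyFit(
        axis=axis,
        bin_size_um=bin_size_um,
        bins=binned.reset_index(drop=True),
        r2_linear=r2_1,
        r2_quadratic=r2_2,
        coef_linear=coef1,
        coef_quadratic=coef2,
        log2_btf=log2_btf,
    )
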