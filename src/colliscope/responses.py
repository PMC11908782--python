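"""Trial segmentation, correlation-based responsiveness, and tuning.

A cell is called responsive to a stimulus combination when its dF/f
time course repeats across presentations: the mean pairwise Pearson
correlation over all trial pairs must exceed a threshold (0.6 for the
tone/AM grids; 0.4 for the somatosensory/bimodal comparisons).
Response magnitude for flagged combinations is the area under the
trial-averaged dF/f over the response window, restricted to the
excitatory (positive-going) part of the signal.  Best tone and best
modulation frequencies maximize that magnitude over flagged
combinations; the binarized receptive-field sum counts flagged
combinations per level.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import DffTraces
from .stimuli import StimulusSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "TrialTensor",
    "ResponseTable",
    "TuningRecord",
    "segment_trials",
    "trial_correlation",
    "flag_responsive",
    "response_auc",
    "best_frequency",
    "receptive_field_sum",
    "RESPONSIVE_THRESHOLD",
    "CROSS_MODAL_THRESHOLD",
    "DEFAULT_POST_WINDOW_S",
]

#: Mean inter-trial correlation above which a cell x combo is responsive.
RESPONSIVE_THRESHOLD = 0.6
#: Relaxed threshold used for somatosensory / bimodal comparisons.
CROSS_MODAL_THRESHOLD = 0.4
#: Post-stimulus extension of the response window (captures offset responses within the ISI).
DEFAULT_POST_WINDOW_S = 0.6


class SegmentationError(ValueError):
    pass


class InsufficientRepeatsError(ValueError):
    pass


@dataclass
class TrialTensor:
    """dF/f segments grouped by stimulus combination.

    ``data`` has shape (cells, combos, repeats, samples); the combo
    table carries (level_db, freq_hz) per combo row, matching the
    grid's combo ordering.
    """

    data: np.ndarray
    combo_table: pd.DataFrame
    frame_rate_hz: float
    window_s: float
    pre_s: float
    stim_duration_s: float
    cell_ids: list[str]

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    @property
    def n_combos(self) -> int:
        return self.data.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.data.shape[2]

    @property
    def n_samples(self) -> int:
        return self.data.shape[3]


@dataclass
class ResponseTable:
    """Per cell x combo responsiveness and magnitude."""

    table: pd.DataFrame  # cell_id, combo_id, level_db, freq_hz, mean_r, responsive, auc
    threshold: float
    window_s: float

    def any_responsive(self) -> pd.Series:
        return self.table.groupby("cell_id", sort=False)["responsive"].any()

    def responsive_cells(self) -> list[str]:
        flags = self.any_responsive()
        return list(flags.index[flags])


@dataclass
class TuningRecord:
    """Per-cell best frequency and receptive-field sums."""

    best: pd.Series  # cell_id -> best frequency (Hz); NaN when untuned
    rfs_by_level: pd.DataFrame  # cells x levels, flagged-combo counts
    rfs_total: pd.Series


def segment_trials(
    dff: DffTraces,
    schedule: StimulusSchedule,
    pre_s: float = 0.0,
    post_s: float = DEFAULT_POST_WINDOW_S,
    extra_runs: list[tuple[DffTraces, StimulusSchedule]] | None = None,
) -> TrialTensor:
    """Cut dF/f into stimulus-locked windows grouped by combination.

    The window spans [onset - pre_s, onset + duration + post_s]; its
    sample count is round(window_s * frame_rate).  Repeats of the same
    combination — within a run and across ``extra_runs`` of the same
    grid — are concatenated along the repeat axis.
    """
    runs = [(dff, schedule)] + list(extra_runs or [])
    grid = schedule.grid
    duration_s = grid.duration_ms / 1000.0
    window_s = pre_s + duration_s + post_s
    fr = dff.frame_rate_hz
    n_samples = int(round(window_s * fr))
    if n_samples < 2:
        raise SegmentationError("window too short for the frame rate")

    per_combo: dict[int, list[np.ndarray]] = {c: [] for c in range(grid.n_combos)}
    bad: list[tuple[int, float]] = []
    for run_dff, run_sched in runs:
        if run_sched.grid.n_combos != grid.n_combos:
            raise SegmentationError("runs use different stimulus grids")
        for trial_idx, (combo, onset) in enumerate(
            zip(run_sched.combo_ids, run_sched.onsets_s)
        ):
            start = int(round((onset - pre_s) * fr))
            stop = start + n_samples
            if start < 0 or stop > run_dff.n_frames:
                bad.append((trial_idx, onset))
                continue
            per_combo[int(combo)].append(run_dff.dff[start:stop, :].T)  # (cells, samples)
    if bad:
        raise SegmentationError(f"trial windows outside the recording: {bad}")

    n_repeats = min(len(v) for v in per_combo.values())
    if n_repeats == 0:
        raise SegmentationError("a stimulus combination has no complete trials")
    n_cells = runs[0][0].n_cells
    data = np.empty((n_cells, grid.n_combos, n_repeats, n_samples))
    for combo, segs in per_combo.items():
        for r in range(n_repeats):
            data[:, combo, r, :] = segs[r]
    return TrialTensor(
        data=data,
        combo_table=grid.combos(),
        frame_rate_hz=fr,
        window_s=window_s,
        pre_s=pre_s,
        stim_duration_s=duration_s,
        cell_ids=list(dff.cell_ids),
    )


def _mean_pairwise_pearson(trials: np.ndarray) -> float:
    """Mean Pearson r over unordered trial pairs; constant trials give r=0."""
    n = trials.shape[0]
    centered = trials - trials.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    rs = []
    for i, j in itertools.combinations(range(n), 2):
        denom = norms[i] * norms[j]
        if denom == 0:
            rs.append(0.0)  # undefined Pearson for a zero-variance trial
        else:
            rs.append(float(centered[i] @ centered[j] / denom))
    return float(np.mean(rs))


def trial_correlation(tensor: TrialTensor) -> pd.DataFrame:
    """Mean pairwise Pearson correlation per cell x combination.

    Pairs involving a zero-variance (constant) trial contribute r = 0.
    """
    if tensor.n_repeats < 2:
        raise InsufficientRepeatsError(
            f"need >= 2 repeats for correlation, got {tensor.n_repeats}"
        )
    rows = []
    for ci, cid in enumerate(tensor.cell_ids):
        for combo in range(tensor.n_combos):
            rows.append(
                {
                    "cell_id": cid,
                    "combo_id": combo,
                    "mean_r": _mean_pairwise_pearson(tensor.data[ci, combo]),
                }
            )
    r = pd.DataFrame(rows)
    return r.merge(tensor.combo_table, on="combo_id", how="left")


def response_auc(
    tensor: TrialTensor, signed: bool = False
) -> pd.DataFrame:
    """AUC of the trial-averaged dF/f over the response window.

    The default rectifies the average to its excitatory part
    (negative-going segments contribute 0); ``signed=True`` integrates
    the full signal.  Trapezoidal rule at the frame spacing; units are
    dF/f x seconds.  Any pre-stimulus samples are excluded.
    """
    dt = 1.0 / tensor.frame_rate_hz
    skip = int(round(tensor.pre_s * tensor.frame_rate_hz))
    avg = tensor.data.mean(axis=2)[:, :, skip:]  # (cells, combos, samples)
    if not signed:
        avg = np.clip(avg, 0.0, None)
    auc = np.trapezoid(avg, dx=dt, axis=2)
    rows = []
    for ci, cid in enumerate(tensor.cell_ids):
        for combo in range(tensor.n_combos):
            rows.append({"cell_id": cid, "combo_id": combo, "auc": auc[ci, combo]})
    return pd.DataFrame(rows)


def flag_responsive(
    tensor: TrialTensor,
    threshold: float = RESPONSIVE_THRESHOLD,
    signed_auc: bool = False,
) -> ResponseTable:
    """Flag cell x combo pairs whose mean inter-trial r exceeds threshold.

    Strictly greater than: r equal to the threshold does not flag.
    AUC magnitudes are reported for every pair but are meaningful only
    where flagged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    corr = trial_correlation(tensor)
    auc = response_auc(tensor, signed=signed_auc)
    table = corr.merge(auc, on=["cell_id", "combo_id"])
    table["responsive"] = table["mean_r"] > threshold
    return ResponseTable(table=table, threshold=threshold, window_s=tensor.window_s)


def best_frequency(table: ResponseTable) -> pd.Series:
    """Best frequency per cell: the flagged combo with maximal AUC.

    Ties break toward the lower frequency.  Cells with no flagged
    combination get NaN and are excluded from tuning summaries.
    """
    out = {}
    for cid, sub in table.table.groupby("cell_id", sort=False):
        flagged = sub[sub["responsive"]]
        if flagged.empty:
            out[cid] = np.nan
            continue
        best_auc = flagged["auc"].max()
        winners = flagged[flagged["auc"] == best_auc]
        if len(winners) > 1:
            logger.info("BTF tie for %s; choosing lower frequency", cid)
        out[cid] = winners["freq_hz"].min()
    return pd.Series(out, name="best_freq_hz")


def receptive_field_sum(table: ResponseTable) -> TuningRecord:
    """Binarized receptive-field sum: flagged-combination counts.

    One point per responsive frequency x level combination; the total
    over levels is the cell's RFS (larger = broader receptive field).
    """
    t = table.table
    by_level = (
        t.groupby(["cell_id", "level_db"], sort=False)["responsive"].sum().unstack("level_db")
    )
    by_level = by_level.astype(int)
    total = by_level.sum(axis=1)
    total.name = "rfs_total"
    return TuningRecord(best=best_frequency(table), rfs_by_level=by_level, rfs_total=total)
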