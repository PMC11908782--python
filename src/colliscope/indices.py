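"""Spectral/temporal modulation indices, response index, and cell classes.

SMI = (R_BTF - R_unmod) / (R_BTF + R_unmod)   in [-1, 1]
TMI = (R_BMF - R_unmod) / (R_BMF + R_unmod)   in [-1, 1]
RI  = R_bimodal / R_auditory-alone            (>1 enhanced, <1 suppressed)

where R is the excitatory-response AUC.  Indices are computed per
sound level, pairing the best tone (or best AM) response at that level
with the unmodulated-noise response at the same level (the 0 Hz row of
the AM grid).  Classification helpers map responsiveness flags onto
selectivity (tone/noise/non-selective), modality (auditory,
somatosensory, both), response timing (onset/offset/both), and the
bimodal effect (suppressed/enhanced/unchanged).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .responses import ResponseTable

logger = logging.getLogger(__name__)

__all__ = [
    "smi",
    "tmi",
    "response_index",
    "classify_ri",
    "classify_selectivity",
    "classify_modality",
    "classify_timing",
    "classify_modulated",
    "indices_by_level",
]


def _contrast(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("response magnitudes must be >= 0")
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (a - b) / np.where(total > 0, total, 1.0), np.nan)
    if np.isscalar(a) or out.ndim == 0:
        return float(out)
    return out


def smi(response_btf, response_unmod):
    """Spectral modulation index: +1 pure-tone-preferring, -1 noise-preferring.

    Undefined (NaN) when both responses are zero.
    """
    return _contrast(response_btf, response_unmod)


def tmi(response_bmf, response_unmod):
    """Temporal modulation index: +1 AM-preferring, -1 unmodulated-preferring."""
    return _contrast(response_bmf, response_unmod)


def response_index(response_bimodal, response_auditory):
    """RI: auditory response under bimodal stimulation / auditory alone.

    Requires a positive auditory-alone response; RI > 1 marks
    enhancement by simultaneous somatosensory input, RI < 1
    suppression.
    """
    response_bimodal = np.asarray(response_bimodal, dtype=float)
    response_auditory = np.asarray(response_auditory, dtype=float)
    if np.any(response_auditory <= 0):
        raise ValueError("auditory-alone response must be > 0 for RI")
    out = response_bimodal / response_auditory
    return float(out) if out.ndim == 0 else out


def classify_ri(ri: float) -> str:
    """suppressed (RI<1) / enhanced (RI>1) / unchanged (RI exactly 1)."""
    if ri < 1.0:
        return "suppressed"
    if ri > 1.0:
        return "enhanced"
    logger.info("RI exactly 1: classified unchanged")
    return "unchanged"


def classify_selectivity(tone_any: bool, noise_any: bool) -> str:
    """tone_sel / noise_sel / non_sel / unresponsive from grid flags."""
    if tone_any and noise_any:
        return "non_sel"
    if tone_any:
        return "tone_sel"
    if noise_any:
        return "noise_sel"
    return "unresponsive"


def classify_modality(aud_flag: bool, som_flag: bool) -> str:
    """aud_sel / som_sel / aud_som_nonsel / unresponsive (0.4-threshold flags)."""
    if aud_flag and som_flag:
        return "aud_som_nonsel"
    if aud_flag:
        return "aud_sel"
    if som_flag:
        return "som_sel"
    return "unresponsive"


def classify_timing(
    trial_avg: np.ndarray,
    frame_rate_hz: float,
    pre_s: float,
    stim_duration_s: float,
    offset_window_s: float = 0.6,
    k_sd: float = 3.0,
) -> str:
    """Onset / offset / onset_offset from the trial-averaged time course.

    Peaks in the stimulus window and in the post-offset window are
    each compared with k x SD of the pre-stimulus baseline.  Requires
    a pre-stimulus segment (pre_s > 0) with nonzero variance.
    """
    n_pre = int(round(pre_s * frame_rate_hz))
    if n_pre < 2:
        raise ValueError("timing classification needs a pre-stimulus baseline (pre_s > 0)")
    baseline = trial_avg[:n_pre]
    sd = baseline.std()
    if sd == 0:
        raise ValueError("degenerate (zero-variance) pre-stimulus baseline")
    mu = baseline.mean()
    n_stim = int(round(stim_duration_s * frame_rate_hz))
    n_off = int(round(offset_window_s * frame_rate_hz))
    stim_peak = trial_avg[n_pre : n_pre + n_stim].max(initial=-np.inf)
    off_peak = trial_avg[n_pre + n_stim : n_pre + n_stim + n_off].max(initial=-np.inf)
    on = stim_peak - mu > k_sd * sd
    off = off_peak - mu > k_sd * sd
    if on and off:
        return "onset_offset"
    if off:
        return "offset"
    if on:
        return "onset"
    return "none"


def classify_modulated(
    tone_table: ResponseTable, am_table: ResponseTable
) -> pd.DataFrame:
    """Per cell x level: spectrally / temporally modulated flags.

    Spectrally modulated at a level: responsive to at least one pure
    tone or to unmodulated noise (the 0 Hz AM row) at that level, and
    to no AM (>0 Hz) combination at that level.  Temporally modulated:
    responsive to at least one AM (>0 Hz) combination at that level.
    """
    tone = tone_table.table
    am = am_table.table
    tone_any = tone.groupby(["cell_id", "level_db"], sort=False)["responsive"].any()
    unmod = am[am["freq_hz"] == 0]
    unmod_any = unmod.groupby(["cell_id", "level_db"], sort=False)["responsive"].any()
    am_pos = am[am["freq_hz"] > 0]
    am_any = am_pos.groupby(["cell_id", "level_db"], sort=False)["responsive"].any()
    idx = tone_any.index.union(unmod_any.index).union(am_any.index)
    tone_any = tone_any.reindex(idx, fill_value=False)
    unmod_any = unmod_any.reindex(idx, fill_value=False)
    am_any = am_any.reindex(idx, fill_value=False)
    out = pd.DataFrame(
        {
            "spectrally_modulated": (tone_any | unmod_any) & ~am_any,
            "temporally_modulated": am_any,
        }
    ).reset_index()
    return out


def indices_by_level(
    tone_table: ResponseTable, am_table: ResponseTable
) -> pd.DataFrame:
    """SMI and TMI per cell per sound level.

    The best tone (or AM) response at a level is the maximal AUC over
    that level's flagged combinations; the reference is the
    unmodulated-noise (0 Hz AM) response at the same level, taken as
    its AUC when flagged and 0 otherwise.  Rows where both terms are
    zero or where nothing is flagged carry NaN.
    """
    tone = tone_table.table
    am = am_table.table

    def _best_per_level(tbl: pd.DataFrame) -> pd.Series:
        flagged = tbl[tbl["responsive"]]
        return flagged.groupby(["cell_id", "level_db"], sort=False)["auc"].max()

    best_tone = _best_per_level(tone[tone["freq_hz"] > 0] if (tone["freq_hz"] > 0).any() else tone)
    best_am = _best_per_level(am[am["freq_hz"] > 0])
    unmod = am[am["freq_hz"] == 0].set_index(["cell_id", "level_db"])
    unmod_resp = unmod["auc"].where(unmod["responsive"], 0.0)

    cells = am["cell_id"].unique()
    levels = sorted(am["level_db"].unique())
    rows = []
    for cid in cells:
        for lv in levels:
            r_tone = best_tone.get((cid, lv), np.nan)
            r_am = best_am.get((cid, lv), np.nan)
            r_un = unmod_resp.get((cid, lv), 0.0)
            row = {"cell_id": cid, "level_db": lv, "response_unmod": r_un}
            row["smi"] = smi(r_tone, r_un) if np.isfinite(r_tone) else np.nan
            row["tmi"] = tmi(r_am, r_un) if np.isfinite(r_am) else np.nan
            row["response_btf"] = r_tone
            row["response_bmf"] = r_am
            rows.append(row)
    return pd.DataFrame(rows)
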