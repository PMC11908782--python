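"""Stimulus grids and randomized presentation schedules.

The acoustic protocol presents every level x frequency combination of a
grid in a single randomly ordered sweep: 500 ms stimuli separated by a
600 ms inter-stimulus interval.  Pure-tone grids span a frequency range
in fixed octave steps; AM-noise grids enumerate amplitude-modulation
rates, with 0 Hz denoting unmodulated broadband noise.  Somatosensory
(whisker deflection) and bimodal (simultaneous sound + whisker) blocks
are degenerate single-combination grids repeated a fixed number of
times.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusType",
    "StimulusGrid",
    "StimulusSchedule",
    "build_tone_grid",
    "build_am_grid",
    "build_noise_grid",
    "build_unimodal_grid",
    "make_schedule",
    "write_schedule",
    "read_schedule",
    "DEFAULT_LEVELS_DB",
    "DEFAULT_TONE_RANGE_HZ",
    "DEFAULT_AM_RATES_HZ",
    "DEFAULT_DURATION_MS",
    "DEFAULT_ISI_MS",
]

#: Sound pressure levels used throughout the protocol (dB SPL).
DEFAULT_LEVELS_DB = (40.0, 50.0, 60.0, 70.0, 80.0)
#: Pure-tone carrier range (Hz); half-octave steps give seven frequencies.
DEFAULT_TONE_RANGE_HZ = (5000.0, 40000.0)
#: AM rates (Hz); 0 denotes unmodulated broadband noise.
DEFAULT_AM_RATES_HZ = (0.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0, 256.0)
DEFAULT_DURATION_MS = 500.0
DEFAULT_ISI_MS = 600.0

# include f_max when the computed step lands within 0.1% of it
_TOP_TOLERANCE = 1e-3


class StimulusType(str, enum.Enum):
    PURE_TONE = "pure_tone"
    AM_NOISE = "am_noise"
    UNMOD_NOISE = "unmod_noise"
    SOMATOSENSORY = "somatosensory"
    BIMODAL = "bimodal"


class InvalidGridError(ValueError):
    """Raised when grid parameters cannot define a valid stimulus grid."""


@dataclass(frozen=True)
class StimulusGrid:
    """A level x frequency stimulus grid of one modality.

    ``freqs_hz`` holds carrier frequencies for pure tones and AM rates
    for AM noise (0 Hz = unmodulated).  For unmodulated noise,
    somatosensory and bimodal grids it holds a single placeholder 0.
    """

    stimulus_type: StimulusType
    levels_db: tuple[float, ...]
    freqs_hz: tuple[float, ...]
    duration_ms: float = DEFAULT_DURATION_MS
    isi_ms: float = DEFAULT_ISI_MS

    def __post_init__(self) -> None:
        if len(self.levels_db) == 0:
            raise InvalidGridError("level list is empty")
        if len(self.freqs_hz) == 0:
            raise InvalidGridError("frequency list is empty")
        if np.any(np.diff(self.levels_db) <= 0):
            raise InvalidGridError("levels_db must be strictly increasing")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise InvalidGridError("frequencies must be strictly increasing")

    @property
    def n_combos(self) -> int:
        return len(self.levels_db) * len(self.freqs_hz)

    def combos(self) -> pd.DataFrame:
        """Enumerate combos as a table indexed by ``combo_id``.

        Frequency varies fastest; combo_id is the 0-based row index.
        """
        levels = np.repeat(self.levels_db, len(self.freqs_hz))
        freqs = np.tile(self.freqs_hz, len(self.levels_db))
        return pd.DataFrame(
            {
                "combo_id": np.arange(levels.size),
                "stimulus_type": self.stimulus_type.value,
                "level_db": levels,
                "freq_hz": freqs,
            }
        )

    @property
    def carrier_freqs_hz(self) -> tuple[float, ...]:
        return self.freqs_hz if self.stimulus_type is StimulusType.PURE_TONE else ()

    @property
    def mod_freqs_hz(self) -> tuple[float, ...]:
        return self.freqs_hz if self.stimulus_type is StimulusType.AM_NOISE else ()


@dataclass(frozen=True)
class StimulusSchedule:
    """An ordered presentation schedule over a grid.

    ``trials`` pairs each presentation's ``combo_id`` with its onset
    time in seconds; onsets are regular at ``duration + isi``.
    """

    grid: StimulusGrid
    combo_ids: np.ndarray  # (n_trials,) int
    onsets_s: np.ndarray  # (n_trials,) float
    n_repeats: int
    seed: int

    @property
    def n_trials(self) -> int:
        return int(self.combo_ids.size)

    @property
    def period_s(self) -> float:
        return (self.grid.duration_ms + self.grid.isi_ms) / 1000.0

    @property
    def total_duration_s(self) -> float:
        return self.n_trials * self.period_s

    def trials(self) -> pd.DataFrame:
        combos = self.grid.combos().set_index("combo_id")
        df = combos.loc[self.combo_ids].reset_index()
        df.insert(0, "trial_index", np.arange(self.n_trials))
        df.insert(2, "onset_s", self.onsets_s)
        return df


def _octave_series(f_min: float, f_max: float, step_octaves: float) -> np.ndarray:
    freqs = [f_min]
    k = 1
    while True:
        f = f_min * 2.0 ** (k * step_octaves)
        if f <= f_max or abs(f - f_max) / f_max < _TOP_TOLERANCE:
            freqs.append(min(f, f_max) if abs(f - f_max) / f_max < _TOP_TOLERANCE else f)
            k += 1
        else:
            break
    return np.asarray(freqs)


def build_tone_grid(
    f_min_hz: float = DEFAULT_TONE_RANGE_HZ[0],
    f_max_hz: float = DEFAULT_TONE_RANGE_HZ[1],
    step_octaves: float = 0.5,
    levels_db=DEFAULT_LEVELS_DB,
    duration_ms: float = DEFAULT_DURATION_MS,
    isi_ms: float = DEFAULT_ISI_MS,
) -> StimulusGrid:
    """Build a pure-tone grid with carriers in geometric octave steps.

    Frequencies are ``f_min * 2**(k*step_octaves)`` for k = 0, 1, ...
    while at or below ``f_max`` (the top of the range is included when
    the computed frequency lands within 0.1% of it, guarding against
    floating-point shortfall).  The defaults reproduce the 7-carrier,
    5-level (35 combination) tone protocol.
    """
    if f_min_hz <= 0 or f_max_hz <= 0:
        raise InvalidGridError("frequencies must be positive")
    if f_min_hz > f_max_hz:
        raise InvalidGridError("f_min_hz must not exceed f_max_hz")
    if step_octaves <= 0:
        raise InvalidGridError("step_octaves must be positive")
    freqs = _octave_series(f_min_hz, f_max_hz, step_octaves)
    return StimulusGrid(
        StimulusType.PURE_TONE, tuple(levels_db), tuple(freqs), duration_ms, isi_ms
    )


def build_am_grid(
    mod_freqs_hz=DEFAULT_AM_RATES_HZ,
    levels_db=DEFAULT_LEVELS_DB,
    duration_ms: float = DEFAULT_DURATION_MS,
    isi_ms: float = DEFAULT_ISI_MS,
) -> StimulusGrid:
    """Build an AM-noise grid; a 0 Hz rate denotes unmodulated noise.

    The defaults reproduce the 9-rate, 5-level (45 combination) AM
    protocol.
    """
    mods = tuple(float(m) for m in mod_freqs_hz)
    if len(set(mods)) != len(mods):
        raise InvalidGridError("duplicate modulation frequencies")
    if any(m < 0 for m in mods):
        raise InvalidGridError("modulation frequencies must be >= 0")
    return StimulusGrid(
        StimulusType.AM_NOISE, tuple(levels_db), tuple(sorted(mods)), duration_ms, isi_ms
    )


def build_noise_grid(
    levels_db=(80.0,),
    duration_ms: float = DEFAULT_DURATION_MS,
    isi_ms: float = DEFAULT_ISI_MS,
) -> StimulusGrid:
    """Unmodulated broadband-noise grid (one combo per level)."""
    return StimulusGrid(
        StimulusType.UNMOD_NOISE, tuple(levels_db), (0.0,), duration_ms, isi_ms
    )


def build_unimodal_grid(
    stimulus_type: StimulusType,
    level_db: float = 80.0,
    duration_ms: float = DEFAULT_DURATION_MS,
    isi_ms: float = DEFAULT_ISI_MS,
) -> StimulusGrid:
    """Single-combination grid for somatosensory or bimodal blocks."""
    if stimulus_type not in (StimulusType.SOMATOSENSORY, StimulusType.BIMODAL):
        raise InvalidGridError("unimodal grids are somatosensory or bimodal")
    return StimulusGrid(stimulus_type, (float(level_db),), (0.0,), duration_ms, isi_ms)


def make_schedule(grid: StimulusGrid, n_repeats: int = 1, seed: int = 0) -> StimulusSchedule:
    """Randomize all combo x repeat slots into one presentation order.

    A single seeded uniform permutation over all slots (no block
    structure); onset k falls at ``k * (duration + isi)``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    slots = np.tile(np.arange(grid.n_combos), n_repeats)
    rng = np.random.default_rng(seed)
    order = rng.permutation(slots.size)
    combo_ids = slots[order]
    period = (grid.duration_ms + grid.isi_ms) / 1000.0
    onsets = np.arange(combo_ids.size) * period
    return StimulusSchedule(grid, combo_ids, onsets, n_repeats, seed)


_SCHEDULE_COLUMNS = ["trial_index", "onset_s", "stimulus_type", "level_db", "freq_hz", "mod_hz"]


def write_schedule(schedule: StimulusSchedule, path) -> None:
    """Write a schedule as a lossless tabular file (TSV or CSV by suffix)."""
    df = schedule.trials()
    is_am = schedule.grid.stimulus_type is StimulusType.AM_NOISE
    zeros = np.zeros(len(df))
    carrier = zeros if is_am else df["freq_hz"].to_numpy()
    mod = df["freq_hz"].to_numpy() if is_am else zeros
    fmt = lambda col: [format(float(v), ".17g") for v in col]  # noqa: E731
    out = pd.DataFrame(
        {
            "trial_index": df["trial_index"],
            "onset_s": fmt(df["onset_s"]),
            "stimulus_type": df["stimulus_type"],
            "level_db": fmt(df["level_db"]),
            "freq_hz": fmt(carrier),
            "mod_hz": fmt(mod),
        }
    )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    out.to_csv(path, sep=sep, index=False, lineterminator="\n")


def read_schedule(path, duration_ms: float = DEFAULT_DURATION_MS, isi_ms: float = DEFAULT_ISI_MS) -> StimulusSchedule:
    """Read a schedule file written by :func:`write_schedule`.

    The grid is reconstructed from the distinct (level, frequency)
    pairs present in the file; combo identity round-trips losslessly.
    """
    with open(path) as fh:
        head = fh.readline()
    sep = "\t" if "\t" in head else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"schedule file missing columns: {sorted(missing)}")
    stype = StimulusType(df["stimulus_type"].iloc[0])
    freq_col = "mod_hz" if stype is StimulusType.AM_NOISE else "freq_hz"
    levels = tuple(sorted(df["level_db"].unique()))
    freqs = tuple(sorted(df[freq_col].unique()))
    grid = StimulusGrid(stype, levels, freqs, duration_ms, isi_ms)
    combos = grid.combos()
    lookup = {
        (row.level_db, row.freq_hz): row.combo_id for row in combos.itertuples()
    }
    df = df.sort_values("trial_index")
    combo_ids = np.array(
        [lookup[(lv, fq)] for lv, fq in zip(df["level_db"], df[freq_col])], dtype=int
    )
    onsets = df["onset_s"].to_numpy(float)
    counts = np.bincount(combo_ids, minlength=grid.n_combos)
    n_repeats = int(counts.max()) if counts.size else 0
    return StimulusSchedule(grid, combo_ids, onsets, n_repeats, seed=-1)
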