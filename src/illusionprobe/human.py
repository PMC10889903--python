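"""Illusion-strength scoring and synthetic perceptual-angle data.

In the adjustment task each participant sets the orientation of four
comparison bars to match the perceived tilt of the four bars of one
stimulus.  Illusion strength is the mean of the absolute values of those
four signed angles.  Strengths are binned into eight 0.1-degree levels
over 0-0.8 degrees; levels 1-4 (strength <= 0.4 deg) form the
"No-illusion" class C1 and levels 5-8 the "With-illusion" class C2.

The response model generates angle tables with the structure observed in
the adjustment experiment: five "quiet" hues (green, spring green, cyan,
yellow-green, yellow) stay below the 0.4-degree threshold at every
diamond width, the remaining seven hues exceed it at widths 5-8 px and
drop below it at widths 9-10 px, and every mean strength lies within
0-0.8 degrees.  Positional setting I induces clockwise (positive) tilt,
setting II counterclockwise.  The same scoring functions apply unchanged
to real angle tables read from CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stimuli import StimulusSpec
from .utils import derive_rng

__all__ = [
    "PerceptualRecord",
    "StrengthRecord",
    "ResponseModelParams",
    "QUIET_HUES",
    "default_base_table",
    "illusion_strength",
    "assign_level",
    "assign_class",
    "class_from_strength",
    "simulate_responses",
    "aggregate_strengths",
    "records_to_frame",
    "write_angle_csv",
    "read_angle_csv",
    "strengths_to_frame",
]

#: Level bin width in degrees.
LEVEL_WIDTH_DEG = 0.1

#: Number of strength levels.
N_LEVELS = 8

#: C1/C2 threshold in degrees (level 4 / level 5 boundary).
CLASS_THRESHOLD_DEG = 0.4

#: Hues whose mean perceived tilt stays below the threshold at all widths.
QUIET_HUES = frozenset({"green", "spring green", "cyan", "yellow-green", "yellow"})

#: Tolerance absorbing float noise at the bin edges (a strength within
#: 1e-9 deg of an upper edge belongs to the lower bin).
_EDGE_EPS = 1e-9


@dataclass(frozen=True)
class PerceptualRecord:
    """Four signed perceived angles for one stimulus and one participant."""

    stimulus: StimulusSpec
    participant_id: int
    angles_deg: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.angles_deg) != 4:
            raise ValueError("exactly four angles are required")
        if not all(math.isfinite(a) for a in self.angles_deg):
            raise ValueError("angles must be finite")


@dataclass(frozen=True)
class StrengthRecord:
    """Per-stimulus illusion strength with its level and class."""

    stimulus: StimulusSpec
    strength_deg: float
    level: int
    illusion_class: str

    def __post_init__(self) -> None:
        if self.strength_deg < 0:
            raise ValueError("strength must be non-negative")
        if not 1 <= self.level <= N_LEVELS:
            raise ValueError("level must be in 1..8")
        expected = "C1" if self.level <= 4 else "C2"
        if self.illusion_class != expected:
            raise ValueError("illusion_class inconsistent with level")


def illusion_strength(angles: PerceptualRecord | Sequence[float]) -> float:
    """Mean of the absolute values of the four bar angles, in degrees."""
    if isinstance(angles, PerceptualRecord):
        angles = angles.angles_deg
    vals = [float(a) for a in angles]
    if len(vals) != 4:
        raise ValueError(f"exactly four angles are required, got {len(vals)}")
    return float(np.mean(np.abs(vals)))


def assign_level(strength_deg: float) -> int:
    """Level k such that strength lies in ((k-1)*0.1, k*0.1] degrees.

    Zero maps to level 1 and strengths beyond 0.8 deg clamp to level 8.
    """
    if strength_deg < 0:
        raise ValueError("strength must be non-negative")
    k = math.floor((strength_deg - _EDGE_EPS) / LEVEL_WIDTH_DEG) + 1
    return min(max(k, 1), N_LEVELS)


def assign_class(level: int) -> str:
    """C1 ("No-illusion") for levels 1-4, C2 ("With-illusion") for 5-8."""
    if not isinstance(level, (int, np.integer)) or not 1 <= level <= N_LEVELS:
        raise ValueError(f"level must be an integer in 1..{N_LEVELS}, got {level!r}")
    return "C1" if level <= 4 else "C2"


def class_from_strength(strength_deg: float) -> str:
    return assign_class(assign_level(strength_deg))


#: Mean strength (deg) per hue at diamond widths 5..10 px.  Quiet hues sit
#: below the 0.4-degree class threshold at every width; the other seven
#: exceed it at widths 5-8 px — strongest for the smallest diamonds — and
#: fall below it at 9-10 px, mirroring the width dependence of the
#: Café-Wall family.  Hues differ in magnitude so that the grid spans all
#: eight strength levels.
_BASE_BY_HUE: dict[str, tuple[float, ...]] = {
    # quiet hues (< 0.4 deg everywhere)
    "green":        (0.08, 0.07, 0.06, 0.05, 0.04, 0.03),
    "spring green": (0.15, 0.14, 0.12, 0.11, 0.09, 0.08),
    "cyan":         (0.22, 0.20, 0.18, 0.16, 0.13, 0.11),
    "yellow-green": (0.30, 0.28, 0.26, 0.24, 0.18, 0.15),
    "yellow":       (0.38, 0.36, 0.34, 0.32, 0.24, 0.20),
    # strong hues (> 0.4 deg at widths 5-8, < 0.4 deg at 9-10)
    "red":          (0.78, 0.74, 0.70, 0.66, 0.34, 0.30),
    "orange":       (0.72, 0.68, 0.63, 0.58, 0.32, 0.28),
    "dodger blue":  (0.66, 0.62, 0.57, 0.52, 0.30, 0.26),
    "blue":         (0.60, 0.56, 0.52, 0.47, 0.28, 0.24),
    "violet":       (0.56, 0.52, 0.48, 0.45, 0.26, 0.22),
    "magenta":      (0.50, 0.47, 0.45, 0.43, 0.24, 0.20),
    "rose":         (0.46, 0.44, 0.43, 0.42, 0.22, 0.18),
}


def default_base_table(
    hues: Iterable[str] | None = None,
    widths: Iterable[int] = (5, 6, 7, 8, 9, 10),
) -> dict[tuple[str, int], float]:
    """Mean illusion strength (deg) per (hue, diamond width).

    See :data:`_BASE_BY_HUE` for the structure the defaults encode.
    """
    if hues is None:
        hues = list(_BASE_BY_HUE)
    table: dict[tuple[str, int], float] = {}
    for hue in hues:
        per_width = dict(zip((5, 6, 7, 8, 9, 10), _BASE_BY_HUE[hue]))
        for w in widths:
            table[(hue, w)] = per_width[w]
    return table


@dataclass(frozen=True)
class ResponseModelParams:
    """Parameters of the synthetic adjustment-task response model."""

    base_strength_deg: dict[tuple[str, int], float] = field(
        default_factory=default_base_table
    )
    participant_sd_deg: float = 0.1
    n_participants: int = 23
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.participant_sd_deg < 0:
            raise ValueError("participant_sd_deg must be non-negative")
        for key, v in self.base_strength_deg.items():
            if not 0.0 <= v <= 0.8:
                raise ValueError(f"base strength {v} for {key} outside [0, 0.8]")


def simulate_responses(
    grid: Sequence[StimulusSpec], params: ResponseModelParams
) -> list[PerceptualRecord]:
    """Draw synthetic perceived angles for every stimulus and participant.

    Each bar's angle is the stimulus's signed base tilt (positive for
    positional setting I, negative for II) plus independent Gaussian
    noise of sd ``participant_sd_deg``.
    """
    rng = derive_rng(params.seed, "simulate_responses")
    records: list[PerceptualRecord] = []
    for spec in grid:
        key = (spec.color.name, spec.diamond_width_px)
        if key not in params.base_strength_deg:
            raise KeyError(f"no base strength for {key}")
        sign = 1.0 if spec.positional_setting == "I" else -1.0
        mean = sign * params.base_strength_deg[key]
        for pid in range(params.n_participants):
            angles = mean + rng.normal(0.0, params.participant_sd_deg, size=4)
            records.append(
                PerceptualRecord(
                    stimulus=spec,
                    participant_id=pid,
                    angles_deg=tuple(float(a) for a in angles),
                )
            )
    return records


def aggregate_strengths(records: Sequence[PerceptualRecord]) -> list[StrengthRecord]:
    """Per-stimulus mean illusion strength across participants, binned.

    The class label is assigned from the across-participant mean
    strength, not per participant.
    """
    if not records:
        raise ValueError("no perceptual records supplied")
    by_stim: dict[str, list[PerceptualRecord]] = {}
    specs: dict[str, StimulusSpec] = {}
    for rec in records:
        sid = rec.stimulus.stimulus_id
        by_stim.setdefault(sid, []).append(rec)
        specs[sid] = rec.stimulus
    out = []
    for sid, recs in by_stim.items():
        strength = float(np.mean([illusion_strength(r) for r in recs]))
        level = assign_level(strength)
        out.append(
            StrengthRecord(
                stimulus=specs[sid],
                strength_deg=strength,
                level=level,
                illusion_class=assign_class(level),
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV interchange


def records_to_frame(records: Sequence[PerceptualRecord]) -> pd.DataFrame:
    rows = [
        {
            "stimulus_id": r.stimulus.stimulus_id,
            "participant_id": r.participant_id,
            "angle1": r.angles_deg[0],
            "angle2": r.angles_deg[1],
            "angle3": r.angles_deg[2],
            "angle4": r.angles_deg[3],
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_angle_csv(records: Sequence[PerceptualRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_angle_csv(
    path: str | Path, grid: Sequence[StimulusSpec]
) -> list[PerceptualRecord]:
    """Read an angle table, resolving stimulus ids against ``grid``."""
    lookup = {s.stimulus_id: s for s in grid}
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        sid = str(row.stimulus_id)
        if sid not in lookup:
            raise KeyError(f"stimulus id {sid!r} not in the supplied grid")
        records.append(
            PerceptualRecord(
                stimulus=lookup[sid],
                participant_id=int(row.participant_id),
                angles_deg=(
                    float(row.angle1),
                    float(row.angle2),
                    float(row.angle3),
                    float(row.angle4),
                ),
            )
        )
    return records


def strengths_to_frame(records: Sequence[StrengthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stimulus_id": r.stimulus.stimulus_id,
                "color": r.stimulus.color.name,
                "diamond_width_px": r.stimulus.diamond_width_px,
                "positional_setting": r.stimulus.positional_setting,
                "strength_deg": r.strength_deg,
                "level": r.level,
                "illusion_class": r.illusion_class,
            }
            for r in records
        ]
    )
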