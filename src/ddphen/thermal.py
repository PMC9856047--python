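"""Stage-wise degree-day requirements from constant-temperature rearing data.

Under the linear degree-day model an ectotherm reared at a constant
temperature T above its lower developmental threshold ``t_min`` accumulates
``min(T, t_max) - t_min`` degree days per day, so the thermal requirement of
a developmental stage reached after ``d`` days is simply
``(min(T, t_max) - t_min) * d``.  This module turns a table of median
days-to-stage observed at several rearing temperatures into per-stage,
inter-stage and total degree-day requirements, and averages the total over
the tested thermal gradient.

Rearing runs at ambient (fluctuating) temperature cannot be converted with
the constant-temperature formula; their realized degree-day total, computed
from the ambient temperature trace at rearing time, is accepted as a
supplied value and contributes only to the mean total requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

#: Developmental stages in order, egg-laying to adult emergence.  "hatch" is
#: the first 10% egg hatch; l1..l3 are larval instars.
STAGES: tuple[str, ...] = ("hatch", "l1", "l2", "l3", "pupa", "adult")

AMBIENT_LABEL = "AC"


class DevelopmentUndefinedError(ValueError):
    """Rearing temperature at or below the lower threshold: no development."""


class IncompleteRowError(ValueError):
    """A required stage duration is missing from the row."""


@dataclass(frozen=True)
class ThermalThresholds:
    """Lower/upper developmental temperatures (degC) and required degree days.

    Defaults are the blowfly parameterisation used throughout this package:
    a conservative lower threshold of 2 degC, an upper threshold of 28 degC,
    and a mean egg-to-adult requirement of 439 degree days.
    """

    t_min: float = 2.0
    t_max: float = 28.0
    dd_req: float = 439.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_min) and np.isfinite(self.t_max)
                and np.isfinite(self.dd_req)):
            raise ValueError("thresholds must be finite")
        if self.t_min >= self.t_max:
            raise ValueError(f"t_min ({self.t_min}) must be < t_max ({self.t_max})")
        if self.dd_req <= 0:
            raise ValueError("dd_req must be positive")


@dataclass(frozen=True)
class StageRow:
    """One rearing condition: median days from egg-laying to each stage.

    ``temperature`` is the constant rearing temperature in degC, or ``None``
    for an ambient-conditions row, in which case ``ambient_total_dd`` may
    carry the realized degree-day total to adulthood.  Missing stages are
    allowed only as a trailing gap (a rearing run abandoned after some
    stage).
    """

    temperature: Optional[float]
    days: Mapping[str, Optional[float]]
    ambient_total_dd: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        seen_missing = False
        prev = 0.0
        for stage in STAGES:
            d = self.days.get(stage)
            if d is None:
                seen_missing = True
                continue
            if seen_missing:
                raise ValueError(
                    f"row {self.name}: stage {stage!r} present after a missing "
                    "stage; gaps must be trailing")
            if not np.isfinite(d) or d <= 0:
                raise ValueError(f"row {self.name}: duration for {stage!r} must "
                                 "be positive and finite")
            # the hatch column is a first-10%-hatch time while the rest are
            # medians, so under fluctuating (ambient) rearing the ordering
            # across those two statistics can invert; only constant-T rows
            # must be monotone
            if d < prev and not self.is_ambient:
                raise ValueError(
                    f"row {self.name}: days to {stage!r} ({d}) decrease below "
                    f"the previous stage ({prev})")
            prev = d

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        return AMBIENT_LABEL if self.temperature is None else f"{self.temperature:g}C"

    @property
    def is_ambient(self) -> bool:
        return self.temperature is None

    @property
    def is_complete(self) -> bool:
        """True if the row reaches adulthood (all six stages present)."""
        return all(self.days.get(s) is not None for s in STAGES)

    def duration(self, stage: str) -> float:
        if stage not in STAGES:
            raise KeyError(f"unknown stage {stage!r}; expected one of {STAGES}")
        d = self.days.get(stage)
        if d is None:
            raise IncompleteRowError(f"row {self.name}: no duration for {stage!r}")
        return float(d)


@dataclass
class StageDurationTable:
    """Collection of :class:`StageRow` observations across a thermal gradient."""

    rows: list[StageRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def constant_rows(self) -> list[StageRow]:
        return [r for r in self.rows if not r.is_ambient]

    def complete_rows(self) -> list[StageRow]:
        return [r for r in self.rows if r.is_complete]


def _effective_above_threshold(temperature: float, thresholds: ThermalThresholds) -> float:
    """Degrees above t_min per day at a constant temperature, capped at t_max."""
    if not np.isfinite(temperature):
        raise ValueError("temperature must be finite")
    if temperature <= thresholds.t_min:
        raise DevelopmentUndefinedError(
            f"development undefined at {temperature} degC "
            f"(lower threshold {thresholds.t_min} degC)")
    return min(temperature, thresholds.t_max) - thresholds.t_min


def dd_to_stage(row: StageRow, thresholds: ThermalThresholds, stage: str) -> float:
    """Degree days from egg-laying to ``stage`` for a constant-T rearing row.

    ``(min(T, t_max) - t_min) * days_to_stage``.  For example 92.8 days to
    adult at 8 degC with a 2 degC threshold gives (8 - 2) * 92.8 = 556.8 DD.

    Raises
    ------
    DevelopmentUndefinedError
        If the rearing temperature is at or below ``t_min`` (mirrors rearing
        treatments abandoned because eggs hatched too late).
    IncompleteRowError
        If the stage duration is missing, or the row is ambient (no constant
        temperature to convert with).
    """
    if row.is_ambient:
        raise IncompleteRowError(
            f"row {row.name}: ambient rows have no constant temperature; "
            "supply ambient_total_dd instead")
    k = _effective_above_threshold(row.temperature, thresholds)
    return k * row.duration(stage)


def interstage_dd(row: StageRow, thresholds: ThermalThresholds,
                  stage_a: str, stage_b: str) -> float:
    """Degree days needed to pass from ``stage_a`` to ``stage_b``.

    ``(min(T, t_max) - t_min) * (days_b - days_a)``; e.g. at 8 degC the
    passage from the 2nd (9 d) to the 3rd (18.5 d) larval instar takes
    9.5 d, i.e. 9.5 * 6 = 57 DD.
    """
    ia, ib = STAGES.index(stage_a), STAGES.index(stage_b)
    if ia > ib:
        raise ValueError(f"stage order reversed: {stage_a!r} does not precede {stage_b!r}")
    if row.is_ambient:
        raise IncompleteRowError(f"row {row.name}: ambient rows are not convertible")
    k = _effective_above_threshold(row.temperature, thresholds)
    return k * (row.duration(stage_b) - row.duration(stage_a))


def mean_required_dd(table: StageDurationTable, thresholds: ThermalThresholds) -> float:
    """Mean total degree days to adulthood over all complete rows.

    Constant-temperature rows are converted with :func:`dd_to_stage`;
    ambient rows contribute their supplied realized total.  Rows that never
    reach adulthood (trailing gaps) are excluded.
    """
    totals: list[float] = []
    for row in table:
        if row.is_ambient:
            if row.ambient_total_dd is not None:
                totals.append(float(row.ambient_total_dd))
        elif row.is_complete:
            totals.append(dd_to_stage(row, thresholds, "adult"))
    if not totals:
        raise ValueError("no complete rows: cannot compute a mean requirement")
    return float(np.mean(totals))


@dataclass
class StageDDRequirements:
    """Per-stage and inter-stage degree-day requirements plus the mean total.

    ``per_stage[row_name][stage]`` is the cumulative DD from egg-laying;
    ``interstage[row_name][(a, b)]`` the DD between consecutive stages;
    ``mean_stage_dd[stage]`` the mean cumulative DD across complete
    constant-temperature rows; ``total_dd_adult`` the mean total including
    any supplied ambient totals.
    """

    per_stage: dict[str, dict[str, float]]
    interstage: dict[str, dict[tuple[str, str], float]]
    mean_stage_dd: dict[str, float]
    total_dd_adult: float


def fit_thermal_summary(table: StageDurationTable,
                        thresholds: ThermalThresholds) -> StageDDRequirements:
    """Full degree-day requirement summary of a rearing table.

    Row-level conversion errors are re-raised with the offending row named.
    """
    per_stage: dict[str, dict[str, float]] = {}
    inter: dict[str, dict[tuple[str, str], float]] = {}
    for row in table.constant_rows():
        stages_present = [s for s in STAGES if row.days.get(s) is not None]
        try:
            per_stage[row.name] = {s: dd_to_stage(row, thresholds, s)
                                   for s in stages_present}
            inter[row.name] = {
                (a, b): interstage_dd(row, thresholds, a, b)
                for a, b in zip(stages_present[:-1], stages_present[1:])}
        except ValueError as exc:
            raise type(exc)(f"row {row.name}: {exc}") from exc
    complete = [r.name for r in table.constant_rows() if r.is_complete]
    mean_stage = {
        s: float(np.mean([per_stage[name][s] for name in complete]))
        for s in STAGES} if complete else {}
    return StageDDRequirements(
        per_stage=per_stage,
        interstage=inter,
        mean_stage_dd=mean_stage,
        total_dd_adult=mean_required_dd(table, thresholds),
    )


def kerguelen_rearing_table() -> StageDurationTable:
    """Median days-to-stage for the Kerguelen blowfly strain.

    Constant rearing at 4, 8, 12, 16 and 20 degC plus one ambient-conditions
    (AC) run at Port-aux-Francais.  The 4 degC treatment only hatched (after
    31 days) and was abandoned, so that row carries a trailing gap and is
    excluded from requirement means.  The AC row's realized total of
    397.8 DD was computed from the ambient temperature trace at rearing time
    and is supplied as-is.
    """
    def row(temp, hatch, l1, l2, l3, pupa, adult, ambient_dd=None):
        days = dict(zip(STAGES, (hatch, l1, l2, l3, pupa, adult)))
        return StageRow(temperature=temp, days=days, ambient_total_dd=ambient_dd)

    return StageDurationTable(rows=[
        row(4.0, 31.0, None, None, None, None, None),
        row(8.0, 4.5, 6.0, 9.0, 18.5, 23.0, 92.8),
        row(12.0, 2.0, 4.0, 5.0, 7.5, 12.0, 41.5),
        row(16.0, 1.0, 3.0, 3.0, 5.0, 7.0, 29.9),
        row(20.0, 1.0, 2.0, 2.5, 4.0, 5.0, 22.6),
        row(None, 4.0, 3.0, 4.5, 10.0, 16.0, 73.0, ambient_dd=397.8),
    ])
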