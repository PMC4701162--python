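"""Reading, validation and canonical orientation of battle-record tables.

A record gives, per battle, the calendar year, the two initial force
sizes and the two casualty totals.  Canonical orientation labels the
side with the *lower* casualty ratio (casualties / initial size) as
red, so that the odds ratio ``P`` in the attrition models expresses the
per-soldier advantage of the side that got off more lightly.

The 1620–1905 span is partitioned into four warfare periods (pike and
musket, linear warfare, Napoleonic wars, American Civil War era);
model fits are run per period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Battle",
    "BattleDataset",
    "BattleValidationError",
    "BattleFormatError",
    "DEFAULT_COLUMNS",
    "PERIODS",
    "read_battles",
    "write_battles",
    "canonicalize_sides",
    "assign_period",
    "filter_period",
]

#: period id -> (label, first year, last year), inclusive bounds
PERIODS: dict[int, tuple[str, int, int]] = {
    1: ("Pike and Musket", 1620, 1701),
    2: ("Linear warfare", 1702, 1792),
    3: ("Napoleonic Wars", 1793, 1860),
    4: ("American Civil War", 1861, 1905),
}

OUT_OF_RANGE = 0

DEFAULT_COLUMNS: dict[str, str] = {
    "id": "id",
    "year": "year",
    "size_a": "size_a",
    "size_b": "size_b",
    "casualties_a": "casualties_a",
    "casualties_b": "casualties_b",
}


class BattleFormatError(ValueError):
    """The table as a whole is unusable (e.g. missing columns)."""


class BattleValidationError(ValueError):
    """One or more rows violate the battle invariants."""


@dataclass(frozen=True)
class Battle:
    """One engagement with canonical blue/red orientation.

    ``blue`` is the side with the higher casualty ratio, ``red`` the
    lower (after :func:`canonicalize_sides`).  Casualties are stored as
    reals because simulated casualties are fractional after final-step
    interpolation; historical inputs are integral.
    """

    id: str
    year: int
    size_blue: int
    size_red: int
    cas_blue: float
    cas_red: float
    swapped: bool = False

    def __post_init__(self) -> None:
        if self.size_blue <= 0 or self.size_red <= 0:
            raise BattleValidationError(f"battle {self.id}: sizes must be positive")
        if not (0 < self.cas_blue <= self.size_blue):
            raise BattleValidationError(
                f"battle {self.id}: blue casualties {self.cas_blue} outside (0, {self.size_blue}]"
            )
        if not (0 < self.cas_red <= self.size_red):
            raise BattleValidationError(
                f"battle {self.id}: red casualties {self.cas_red} outside (0, {self.size_red}]"
            )

    @property
    def ratio_blue(self) -> float:
        return self.cas_blue / self.size_blue

    @property
    def ratio_red(self) -> float:
        return self.cas_red / self.size_red

    @property
    def period(self) -> int:
        return assign_period(self.year)


def canonicalize_sides(battle: Battle) -> Battle:
    """Orient a battle so red is the side with the lower casualty ratio.

    Idempotent.  On exactly equal ratios the larger initial force
    becomes blue (a deterministic tie-break; the orientation rule is
    otherwise silent on ties).  ``swapped`` records whether the sides
    were exchanged relative to the input.
    """
    ra, rb = battle.ratio_blue, battle.ratio_red
    if ra > rb:
        return battle
    if ra == rb and battle.size_blue >= battle.size_red:
        return battle
    return replace(
        battle,
        size_blue=battle.size_red,
        size_red=battle.size_blue,
        cas_blue=battle.cas_red,
        cas_red=battle.cas_blue,
        swapped=not battle.swapped,
    )


def assign_period(year: int) -> int:
    """Map a calendar year to its warfare period (1–4), or 0 if out of range."""
    for pid, (_, lo, hi) in PERIODS.items():
        if lo <= year <= hi:
            return pid
    return OUT_OF_RANGE


@dataclass
class BattleDataset:
    """Ordered collection of canonicalized battles."""

    battles: list[Battle] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.battles)

    def __iter__(self) -> Iterator[Battle]:
        return iter(self.battles)

    def __getitem__(self, i: int) -> Battle:
        return self.battles[i]

    @property
    def periods(self) -> list[int]:
        return [b.period for b in self.battles]

    def to_frame(self) -> pd.DataFrame:
        """Table in the default column dialect (canonical orientation)."""
        return pd.DataFrame(
            {
                "id": [b.id for b in self.battles],
                "year": [b.year for b in self.battles],
                "size_a": [b.size_blue for b in self.battles],
                "size_b": [b.size_red for b in self.battles],
                "casualties_a": [b.cas_blue for b in self.battles],
                "casualties_b": [b.cas_red for b in self.battles],
            }
        )


def _battle_from_row(idx, row: Mapping, columns: Mapping[str, str]) -> Battle:
    def get(key):
        return row[columns[key]]

    year = int(get("year"))
    size_a = float(get("size_a"))
    size_b = float(get("size_b"))
    if size_a <= 0 or size_b <= 0 or size_a != int(size_a) or size_b != int(size_b):
        raise BattleValidationError(f"row {idx}: sizes must be positive integers")
    battle = Battle(
        id=str(get("id")),
        year=year,
        size_blue=int(size_a),
        size_red=int(size_b),
        cas_blue=float(get("casualties_a")),
        cas_red=float(get("casualties_b")),
    )
    return canonicalize_sides(battle)


def read_battles(
    path: "str | Path",
    columns: Mapping[str, str] | None = None,
    strict: bool = True,
) -> BattleDataset:
    """Read and validate a battle CSV into a canonicalized dataset.

    Parameters
    ----------
    path:
        CSV file with a header row; the expected columns are
        ``id, year, size_a, size_b, casualties_a, casualties_b`` by
        default and can be remapped via ``columns``.
    columns:
        Optional mapping from canonical keys to the file's header names.
    strict:
        If True (default) any invalid row aborts the read with a
        row-indexed diagnostic; if False invalid rows are skipped and
        logged, never silently dropped.

    Rows with zero or missing casualties are rejected: the fit distance
    divides by historical casualties, so zero-casualty records are not
    usable downstream.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise BattleFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: no battle rows (header only)", path)

    battles: list[Battle] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            battles.append(_battle_from_row(idx, row, colmap))
        except (BattleValidationError, ValueError, TypeError) as exc:
            msg = f"row {idx}: {exc}"
            if strict:
                raise BattleValidationError(msg) from exc
            errors.append(msg)
            logger.warning("skipping invalid battle row: %s", msg)
    if errors:
        logger.warning("%s: skipped %d invalid rows", path, len(errors))
    return BattleDataset(battles)


def write_battles(dataset: BattleDataset, path: "str | Path") -> None:
    """Write a dataset as CSV in the default column dialect."""
    dataset.to_frame().to_csv(path, index=False)


def filter_period(dataset: BattleDataset, period: int) -> BattleDataset:
    """Subset of battles whose year falls in the given period (order kept)."""
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {sorted(PERIODS)}")
    return BattleDataset([b for b in dataset if b.period == period])
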