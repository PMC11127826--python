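"""Cohort data model and delimited-text readers/writers.

A cohort is a measurements table (one row per player-semester) joined with a
roster table of elite-success flags (junior national teams 16/18/20, NHL)
and optional externally recovered adult heights.  Attrition accounting
mirrors a retrospective school-records design: players lacking a resolvable
adult height are *lost to follow-up* for maturity purposes.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import maturity as _mat

__all__ = [
    "Measurement",
    "PlayerRecord",
    "CohortSummary",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "summarise_cohort",
]

logger = logging.getLogger(__name__)

HEIGHT_RANGE = (120.0, 230.0)  # cm, plausible for adolescent/adult males
WEIGHT_RANGE = (30.0, 150.0)  # kg
DEFAULT_YEAR_SPAN = (1998, 2017)

MEASUREMENT_COLUMNS = [
    "player_id",
    "semester",
    "measurement_date",
    "height_cm",
    "weight_kg",
    "birth_date",
    "region",
    "year_of_collection",
]
ROSTER_COLUMNS = ["player_id", "team16", "team18", "team20", "nhl", "recovered_adult_height"]


class CohortValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Measurement:
    semester: int
    measurement_date: dt.date
    height_cm: float
    weight_kg: Optional[float] = None


@dataclass
class PlayerRecord:
    """One player's longitudinal measurements plus cohort and career metadata."""

    player_id: object
    measurements: list[Measurement] = field(default_factory=list)
    birth_date: Optional[dt.date] = None
    region: Optional[str] = None
    year_of_collection: Optional[int] = None
    recovered_adult_height: Optional[float] = None
    team16: bool = False
    team18: bool = False
    team20: bool = False
    nhl: bool = False

    def __post_init__(self):
        self.measurements = sorted(self.measurements, key=lambda m: m.semester)
        semesters = [m.semester for m in self.measurements]
        if len(set(semesters)) != len(semesters):
            raise CohortValidationError(
                f"duplicate semester rows for player {self.player_id!r}"
            )
        for m in self.measurements:
            if not (HEIGHT_RANGE[0] <= m.height_cm <= HEIGHT_RANGE[1]):
                raise CohortValidationError(
                    f"player {self.player_id!r} semester {m.semester}: height "
                    f"{m.height_cm:g} cm outside {HEIGHT_RANGE}"
                )
            if m.weight_kg is not None and not (
                WEIGHT_RANGE[0] <= m.weight_kg <= WEIGHT_RANGE[1]
            ):
                raise CohortValidationError(
                    f"player {self.player_id!r} semester {m.semester}: weight "
                    f"{m.weight_kg:g} kg outside {WEIGHT_RANGE}"
                )

    def baseline_measurement(self) -> Optional[Measurement]:
        """The first-semester (earliest available) measurement."""
        return self.measurements[0] if self.measurements else None

    def semester_measurement(self, semester: int) -> Optional[Measurement]:
        for m in self.measurements:
            if m.semester == semester:
                return m
        return None

    def resolve_adult_height(self) -> tuple[Optional[float], Optional[str]]:
        """Adult height: sixth-semester measurement, else recovered external value."""
        s6 = self.semester_measurement(6)
        if s6 is not None:
            return s6.height_cm, "measured_semester6"
        if self.recovered_adult_height is not None:
            return self.recovered_adult_height, "recovered_external"
        return None, None


@dataclass(frozen=True)
class CohortSummary:
    """Flowchart-style attrition counts for a cohort."""

    n_players: int
    n_complete_maturity: int
    n_lost_to_followup: int
    n_excluded_gt102: int
    n_team16: int
    n_team18: int
    n_team20: int
    n_nhl: int

    def __post_init__(self):
        counts = [
            self.n_players,
            self.n_complete_maturity,
            self.n_lost_to_followup,
            self.n_excluded_gt102,
        ]
        if any(c < 0 for c in counts):
            raise CohortValidationError("counts must be non-negative")
        if (
            self.n_complete_maturity + self.n_lost_to_followup + self.n_excluded_gt102
            > self.n_players
        ):
            raise CohortValidationError("attrition counts exceed cohort size")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _parse_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "y"}:
        return True
    if s in {"0", "false", "no", "n", ""}:
        return False
    raise CohortValidationError(f"unparseable boolean {value!r}")


def read_cohort(
    measurements_source,
    roster_source=None,
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
) -> list[PlayerRecord]:
    """Read measurements (and optionally a roster) into player records.

    One record per unique ``player_id``; roster flags default to false when
    the roster is absent or has no row for the player.  Duplicate
    (player, semester) rows are an error; roster rows for unknown players
    are skipped with a warning.
    """
    meas = pd.read_csv(
        measurements_source, dtype={"player_id": str}, float_precision="round_trip"
    )
    missing = set(MEASUREMENT_COLUMNS) - set(meas.columns)
    if missing:
        raise CohortValidationError(f"measurements table missing columns {sorted(missing)}")

    dup = meas.duplicated(subset=["player_id", "semester"], keep=False)
    if dup.any():
        ids = sorted(meas.loc[dup, "player_id"].unique())
        raise CohortValidationError(
            f"duplicate (player, semester) rows for player(s) {ids[:10]}"
        )

    records: dict[str, PlayerRecord] = {}
    for pid, grp in meas.groupby("player_id", sort=True):
        first = grp.iloc[0]
        year = int(first["year_of_collection"])
        if not (year_span[0] <= year <= year_span[1]):
            raise CohortValidationError(
                f"player {pid!r}: year_of_collection {year} outside {year_span}"
            )
        ms = [
            Measurement(
                semester=int(r.semester),
                measurement_date=_parse_date(r.measurement_date),
                height_cm=float(r.height_cm),
                weight_kg=None if pd.isna(r.weight_kg) else float(r.weight_kg),
            )
            for r in grp.itertuples()
        ]
        records[pid] = PlayerRecord(
            player_id=pid,
            measurements=ms,
            birth_date=_parse_date(first["birth_date"]),
            region=None if pd.isna(first["region"]) else str(first["region"]),
            year_of_collection=year,
        )

    if roster_source is not None:
        roster = pd.read_csv(
            roster_source, dtype={"player_id": str}, float_precision="round_trip"
        )
        missing = set(ROSTER_COLUMNS) - set(roster.columns)
        if missing:
            raise CohortValidationError(f"roster table missing columns {sorted(missing)}")
        for r in roster.itertuples():
            rec = records.get(r.player_id)
            if rec is None:
                logger.warning("roster row for unknown player %r skipped", r.player_id)
                continue
            rec.team16 = _parse_bool(r.team16)
            rec.team18 = _parse_bool(r.team18)
            rec.team20 = _parse_bool(r.team20)
            rec.nhl = _parse_bool(r.nhl)
            if not pd.isna(r.recovered_adult_height):
                rec.recovered_adult_height = float(r.recovered_adult_height)
    return [records[k] for k in sorted(records)]


def write_cohort(records, measurements_path, roster_path) -> None:
    """Write a cohort back to the two delimited files (round-trips with read)."""
    mrows, rrows = [], []
    for rec in records:
        for m in rec.measurements:
            mrows.append(
                {
                    "player_id": rec.player_id,
                    "semester": m.semester,
                    "measurement_date": m.measurement_date.isoformat()
                    if m.measurement_date
                    else "",
                    "height_cm": repr(float(m.height_cm)),
                    "weight_kg": "" if m.weight_kg is None else repr(float(m.weight_kg)),
                    "birth_date": rec.birth_date.isoformat() if rec.birth_date else "",
                    "region": "" if rec.region is None else rec.region,
                    "year_of_collection": rec.year_of_collection,
                }
            )
        rrows.append(
            {
                "player_id": rec.player_id,
                "team16": int(rec.team16),
                "team18": int(rec.team18),
                "team20": int(rec.team20),
                "nhl": int(rec.nhl),
                "recovered_adult_height": ""
                if rec.recovered_adult_height is None
                else repr(float(rec.recovered_adult_height)),
            }
        )
    pd.DataFrame(mrows, columns=MEASUREMENT_COLUMNS).to_csv(measurements_path, index=False)
    pd.DataFrame(rrows, columns=ROSTER_COLUMNS).to_csv(roster_path, index=False)


def summarise_cohort(records, estimates=None) -> CohortSummary:
    """Attrition and career counts for a cohort.

    ``estimates`` maps player ids to :class:`~somamat.maturity.MaturityEstimate`
    (a dict, or an iterable of estimates).  Players without a resolvable adult
    height count as lost to follow-up; players excluded by the >102% %AH rule
    count separately; the rest with an estimate are the complete-maturity set.
    """
    if estimates is None:
        estimates = {}
    elif not isinstance(estimates, dict):
        estimates = {e.player_id: e for e in estimates}

    n_lost = n_excluded = n_complete = 0
    for rec in records:
        adult, _ = rec.resolve_adult_height()
        if adult is None or rec.baseline_measurement() is None:
            n_lost += 1
            continue
        est = estimates.get(rec.player_id)
        if est is None:
            continue
        if est.qc_flag == _mat.QC_EXCLUDED:
            n_excluded += 1
        else:
            n_complete += 1
    return CohortSummary(
        n_players=len(records),
        n_complete_maturity=n_complete,
        n_lost_to_followup=n_lost,
        n_excluded_gt102=n_excluded,
        n_team16=sum(r.team16 for r in records),
        n_team18=sum(r.team18 for r in records),
        n_team20=sum(r.team20 for r in records),
        n_nhl=sum(r.nhl for r in records),
    )
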