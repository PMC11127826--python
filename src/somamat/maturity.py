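"""Per-player somatic maturity estimation from longitudinal heights.

The chain implemented here: percent of adult height (%AH) at baseline →
data-entry cleaning → z-score against an age-matched growth reference →
biological age by inverse lookup → age offset (biological − chronological) →
early / on-time / late categorisation by both the z-score (±0.5 SD) and the
age-offset (±0.5 y) criteria.

Cleaning rules for impossible baseline values (entry errors can make the
baseline exceed the adult height): %AH in (100, 102] is clamped to 100,
%AH > 102 is excluded as unreliable.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import pandas as pd

from .growth_reference import (
    GrowthReferenceTable,
    biological_age_from_pah,
    zscore_pah,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_io import PlayerRecord

__all__ = [
    "ClassificationConfig",
    "MaturityEstimate",
    "UnresolvableAdultHeightError",
    "percent_adult_height",
    "clean_pah",
    "chronological_age",
    "classify_z",
    "classify_offset",
    "estimate_maturity",
    "estimates_frame",
]

EARLY = "early"
ON_TIME = "on_time"
LATE = "late"

QC_OK = "ok"
QC_CLAMPED = "clamped_100"
QC_EXCLUDED = "excluded_gt102"
QC_EXTRAPOLATED_LOW = "extrapolated_low"

DAYS_PER_YEAR = 365.25


class UnresolvableAdultHeightError(ValueError):
    def __init__(self, player_id):
        self.player_id = player_id
        super().__init__(
            f"unresolvable adult height for player {player_id!r}: no sixth-semester "
            "measurement and no recovered external height"
        )


def _round1(x: float) -> float:
    return math.floor(x * 10.0 + 0.5) / 10.0


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for early / on-time / late maturity categories.

    ``z_lo``/``z_hi`` bound the on-time band on the %AH z-score scale
    (default ±0.5 SD); ``offset_lo``/``offset_hi`` bound it on the age-offset
    scale (default ±0.5 years).  With ``boundary_inclusive_on_time`` (the
    default) values exactly on a threshold classify as on-time.
    """

    z_lo: float = -0.5
    z_hi: float = 0.5
    offset_lo: float = -0.5
    offset_hi: float = 0.5
    boundary_inclusive_on_time: bool = True

    def __post_init__(self):
        if not (self.z_lo < self.z_hi and self.offset_lo < self.offset_hi):
            raise ValueError("lower threshold must be below upper threshold")


@dataclass(frozen=True)
class MaturityEstimate:
    """Derived maturity quantities for one player.

    ``pah`` and everything downstream are ``None`` when the player was
    excluded by the >102% cleaning rule (``qc_flag == 'excluded_gt102'``).
    """

    player_id: object
    pah_raw: float
    pah: Optional[float]
    z_pah: Optional[float]
    chronological_age: Optional[float]
    chronological_age_source: str  # 'birthdate' | 'cohort_default'
    biological_age: Optional[float]
    age_offset: Optional[float]
    category_z: Optional[str]
    category_offset: Optional[str]
    qc_flag: str
    adult_height_source: str  # 'measured_semester6' | 'recovered_external'


def percent_adult_height(baseline_height: float, adult_height: float) -> float:
    """Raw %AH: 100 × baseline height / adult height, unrounded."""
    if baseline_height <= 0 or adult_height <= 0:
        raise ValueError("heights must be positive")
    return 100.0 * baseline_height / adult_height


def clean_pah(pah_raw: float) -> tuple[Optional[float], str]:
    """Apply the entry-error cleaning rules to a raw %AH.

    Returns ``(pah, qc_flag)``: values ≤ 100 pass through, (100, 102] clamp
    to 100 (negative apparent shrinkage attributed to baseline measurement
    error), > 102 is excluded (``pah`` is ``None``).  Idempotent.
    """
    if pah_raw <= 0:
        raise ValueError("pah_raw must be positive")
    if pah_raw <= 100.0:
        return pah_raw, QC_OK
    if pah_raw <= 102.0:
        return 100.0, QC_CLAMPED
    return None, QC_EXCLUDED


def chronological_age(
    birth_date: Optional[dt.date],
    measurement_date: dt.date,
    cohort_default: float,
) -> tuple[float, str]:
    """Decimal age at measurement, to 0.1 years.

    Without a birth date (typical for non-elite players in school records)
    the configured cohort default is returned, flagged ``cohort_default``.
    """
    if birth_date is None:
        return cohort_default, "cohort_default"
    if measurement_date < birth_date:
        raise ValueError("measurement date precedes birth date")
    years = (measurement_date - birth_date).days / DAYS_PER_YEAR
    return _round1(years), "birthdate"


def classify_z(z: float, cfg: ClassificationConfig = ClassificationConfig()) -> str:
    return _classify(z, cfg.z_lo, cfg.z_hi, cfg.boundary_inclusive_on_time)


def classify_offset(
    age_offset: float, cfg: ClassificationConfig = ClassificationConfig()
) -> str:
    return _classify(age_offset, cfg.offset_lo, cfg.offset_hi, cfg.boundary_inclusive_on_time)


def _classify(x: float, lo: float, hi: float, inclusive: bool) -> str:
    if not math.isfinite(x):
        raise ValueError("value must be finite")
    if inclusive:
        if x > hi:
            return EARLY
        if x < lo:
            return LATE
        return ON_TIME
    if x >= hi:
        return EARLY
    if x <= lo:
        return LATE
    return ON_TIME


def estimate_maturity(
    player: "PlayerRecord",
    ref: GrowthReferenceTable,
    cfg: ClassificationConfig = ClassificationConfig(),
    cohort_default_age: float = 16.2,
) -> MaturityEstimate:
    """Run the full maturity chain for one player.

    Baseline height is the earliest-semester measurement; adult height is
    the sixth-semester measurement when present, else the externally
    recovered adult height.  Players with neither raise
    :class:`UnresolvableAdultHeightError`; players excluded by the %AH
    cleaning carry only their raw value and the exclusion flag.
    """
    baseline = player.baseline_measurement()
    if baseline is None:
        raise UnresolvableAdultHeightError(player.player_id)
    adult_height, adult_source = player.resolve_adult_height()
    if adult_height is None:
        raise UnresolvableAdultHeightError(player.player_id)

    pah_raw = percent_adult_height(baseline.height_cm, adult_height)
    pah, qc_flag = clean_pah(pah_raw)
    chron, chron_source = chronological_age(
        player.birth_date, baseline.measurement_date, cohort_default_age
    )
    if qc_flag == QC_EXCLUDED:
        return MaturityEstimate(
            player_id=player.player_id,
            pah_raw=pah_raw,
            pah=None,
            z_pah=None,
            chronological_age=chron,
            chronological_age_source=chron_source,
            biological_age=None,
            age_offset=None,
            category_z=None,
            category_offset=None,
            qc_flag=qc_flag,
            adult_height_source=adult_source,
        )

    z = zscore_pah(ref, pah, chron)
    bio_age, extrapolated = biological_age_from_pah(ref, pah, with_flag=True)
    if extrapolated and qc_flag == QC_OK:
        qc_flag = QC_EXTRAPOLATED_LOW
    # offset from the rounded ages, so it is reproducible from reported values
    offset = _round1(bio_age) - _round1(chron)
    offset = round(offset, 10)  # kill binary representation fuzz
    return MaturityEstimate(
        player_id=player.player_id,
        pah_raw=pah_raw,
        pah=pah,
        z_pah=z,
        chronological_age=chron,
        chronological_age_source=chron_source,
        biological_age=bio_age,
        age_offset=offset,
        category_z=classify_z(z, cfg),
        category_offset=classify_offset(offset, cfg),
        qc_flag=qc_flag,
        adult_height_source=adult_source,
    )


def estimates_frame(estimates) -> pd.DataFrame:
    """Tabulate estimates, one row per player (the module's output format)."""
    cols = [
        "player_id",
        "pah_raw",
        "pah",
        "z_pah",
        "chronological_age",
        "chronological_age_source",
        "biological_age",
        "age_offset",
        "category_z",
        "category_offset",
        "qc_flag",
        "adult_height_source",
    ]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in estimates], columns=cols)
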