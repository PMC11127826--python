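"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a retrospective ice-hockey
school-records cohort: individual growth trajectories driven by adult
height and a maturity-timing offset applied to a reference %AH curve,
measurement noise, data-entry errors that inflate baseline %AH above 100,
loss to follow-up of the final-semester measurement, and multi-stage elite
selection (junior teams 16/18/20, then NHL) with maturity-dependent
log-odds and a region-level random intercept.

Sign convention: a **positive** timing offset means **early** maturing —
the player attains a given %AH at a younger chronological age — so the
estimated age offset (biological − chronological age) recovers
``+timing_offset``.

Each simulated cohort is returned together with a per-player *truth table*
(latent timing offset, latent z-score of %AH, stage selection
probabilities, clamping flags) for test harnesses and parameter-recovery
studies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .cohort_io import Measurement, PlayerRecord
from .growth_reference import GrowthReferenceTable

__all__ = ["SyntheticCohortConfig", "simulate_growth", "simulate_cohort"]

SEMESTER_STEP_YEARS = 0.5
N_SEMESTERS = 6
_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All knobs of the simulator.

    Defaults describe a plausible elite-pathway cohort: adult stature
    181 ± 6.5 cm, maturity timing SD 1.0 y, baseline (first autumn
    semester) age 16.2 ± 0.3 y, 0.5 cm measurement noise.  Stage
    intercepts put the marginal selection rates near 9.8% (team 16),
    9% (teams 18/20) and ≈4% (NHL); the maturity effects on the log-odds
    scale default to +0.21 per z of %AH for team-16 selection and −0.50
    for NHL selection, with positive NHL adjustment for prior team-18/20
    membership.
    """

    n_players: int = 2000
    adult_height_mean: float = 181.0
    adult_height_sd: float = 6.5
    timing_sd: float = 1.0
    measurement_sd: float = 0.5
    baseline_age_mean: float = 16.2
    baseline_age_sd: float = 0.3
    p_birthdate_missing: float = 1.0  # among non-elite players
    p_entry_error: float = 0.05
    p_lost_followup: float = 0.5
    recovered_height_policy: str = "nhl"  # 'nhl' | 'all' | 'none'
    intercept_team16: float = -2.22
    beta_team16: float = 0.21
    intercept_team18: float = -2.31
    beta_team18_sel: float = 0.10
    intercept_team20: float = -2.31
    beta_team20_sel: float = 0.0
    intercept_nhl: float = -3.9
    beta_nhl: float = -0.50
    beta_team18: float = 1.2
    beta_team20: float = 2.5
    region_sd: float = 0.3
    n_regions: int = 12
    year_start: int = 1998
    year_end: int = 2017
    seed: int = 0

    def __post_init__(self):
        if self.n_players < 1:
            raise ValueError("n_players must be >= 1")
        for name in ("p_birthdate_missing", "p_entry_error", "p_lost_followup"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p:g}")
        for name in (
            "adult_height_sd",
            "timing_sd",
            "measurement_sd",
            "baseline_age_sd",
            "region_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.recovered_height_policy not in {"nhl", "all", "none"}:
            raise ValueError("recovered_height_policy must be 'nhl', 'all' or 'none'")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _ilogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _mean_curve(ref: GrowthReferenceTable, ages):
    return np.interp(ages, ref.age_grid, ref.mean_pah)


def simulate_growth(
    ref: GrowthReferenceTable,
    adult_height: float,
    timing_offset: float,
    ages,
    measurement_sd: float,
    rng: np.random.Generator,
):
    """Heights along a trajectory: ``adult_height × mean_pah(age + offset)/100`` plus noise.

    Positive ``timing_offset`` shifts the curve to younger ages (early
    maturing).  Shifted ages outside the reference grid are clamped to the
    grid ends; returns ``(heights, clamped)`` where ``clamped`` marks the
    affected ages.
    """
    ages = np.asarray(ages, dtype=float)
    shifted = ages + timing_offset
    clamped = (shifted < ref.age_min) | (shifted > ref.terminal_age)
    shifted = np.clip(shifted, ref.age_min, ref.terminal_age)
    heights = adult_height * _mean_curve(ref, shifted) / 100.0
    if measurement_sd > 0:
        heights = heights + rng.normal(0.0, measurement_sd, size=heights.shape)
    return heights, clamped


def _semester_dates(year: int) -> list[dt.date]:
    base = dt.date(year, 9, 1)
    return [
        base + dt.timedelta(days=round(_DAYS_PER_YEAR * SEMESTER_STEP_YEARS * k))
        for k in range(N_SEMESTERS)
    ]


def simulate_cohort(
    cfg: SyntheticCohortConfig,
    ref: GrowthReferenceTable,
    rng: np.random.Generator | None = None,
):
    """Draw a full synthetic cohort.

    Returns ``(records, truth)``: the player records as the IO layer would
    read them, and a truth table (DataFrame indexed like the records) with
    the latent quantities.  Same config and seed → identical output.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_players

    adult = rng.normal(cfg.adult_height_mean, cfg.adult_height_sd, n)
    timing = rng.normal(0.0, cfg.timing_sd, n)
    a0 = rng.normal(cfg.baseline_age_mean, cfg.baseline_age_sd, n)
    a0 = np.clip(a0, ref.age_min, ref.terminal_age)
    region = rng.integers(0, cfg.n_regions, n)
    year = rng.integers(cfg.year_start, cfg.year_end + 1, n)
    bmi = rng.normal(22.5, 1.5, n)

    # latent baseline %AH and its z against the reference
    shifted0 = a0 + timing
    clamped = (shifted0 < ref.age_min) | (shifted0 > ref.terminal_age)
    pah_latent = _mean_curve(ref, np.clip(shifted0, ref.age_min, ref.terminal_age))
    mean0 = _mean_curve(ref, a0)
    sd0 = np.interp(a0, ref.age_grid, ref.sd_pah)
    z_true = (pah_latent - mean0) / sd0

    # region random intercepts, drawn independently per selection stage
    u = {
        stage: rng.normal(0.0, cfg.region_sd, cfg.n_regions)
        for stage in ("team16", "team18", "team20", "nhl")
    }
    p16 = _ilogit(cfg.intercept_team16 + cfg.beta_team16 * z_true + u["team16"][region])
    t16 = rng.random(n) < p16
    p18 = _ilogit(cfg.intercept_team18 + cfg.beta_team18_sel * z_true + u["team18"][region])
    t18 = rng.random(n) < p18
    p20 = _ilogit(cfg.intercept_team20 + cfg.beta_team20_sel * z_true + u["team20"][region])
    t20 = rng.random(n) < p20
    pnhl = _ilogit(
        cfg.intercept_nhl
        + cfg.beta_nhl * z_true
        + cfg.beta_team18 * t18
        + cfg.beta_team20 * t20
        + u["nhl"][region]
    )
    nhl = rng.random(n) < pnhl
    elite = t16 | t18 | t20 | nhl

    lost = rng.random(n) < cfg.p_lost_followup
    entry_err = rng.random(n) < cfg.p_entry_error
    entry_pah = rng.uniform(100.2, 103.0, n)  # target raw %AH for injected errors
    birth_missing = (~elite) & (rng.random(n) < cfg.p_birthdate_missing)

    sem_ages_rel = SEMESTER_STEP_YEARS * np.arange(N_SEMESTERS)
    records: list[PlayerRecord] = []
    rows = []
    for i in range(n):
        ages = a0[i] + sem_ages_rel
        heights, _ = simulate_growth(
            ref, adult[i], timing[i], ages, cfg.measurement_sd, rng
        )
        keep = N_SEMESTERS - 1 if lost[i] else N_SEMESTERS
        recovered = None
        if lost[i] and cfg.recovered_height_policy == "all":
            recovered = adult[i]
        elif lost[i] and cfg.recovered_height_policy == "nhl" and nhl[i]:
            recovered = adult[i]

        # entry-error injection: inflate the baseline so raw %AH lands >100,
        # relative to whatever value will later resolve as adult height
        resolved_adult = heights[5] if not lost[i] else recovered
        if entry_err[i] and resolved_adult is not None:
            heights = heights.copy()
            heights[0] = resolved_adult * entry_pah[i] / 100.0

        dates = _semester_dates(int(year[i]))
        birth = None
        if not birth_missing[i]:
            birth = dates[0] - dt.timedelta(days=round(a0[i] * _DAYS_PER_YEAR))
        measurements = [
            Measurement(
                semester=k + 1,
                measurement_date=dates[k],
                height_cm=float(np.clip(heights[k], 120.0, 230.0)),
                weight_kg=float(np.clip(bmi[i] * (heights[k] / 100.0) ** 2, 30.0, 150.0)),
            )
            for k in range(keep)
        ]
        pid = f"P{i + 1:05d}"
        records.append(
            PlayerRecord(
                player_id=pid,
                measurements=measurements,
                birth_date=birth,
                region=f"R{region[i] + 1:02d}",
                year_of_collection=int(year[i]),
                recovered_adult_height=None if recovered is None else float(recovered),
                team16=bool(t16[i]),
                team18=bool(t18[i]),
                team20=bool(t20[i]),
                nhl=bool(nhl[i]),
            )
        )
        rows.append(
            {
                "player_id": pid,
                "adult_height": adult[i],
                "timing_offset": timing[i],
                "baseline_age": a0[i],
                "z_true": z_true[i],
                "pah_latent": pah_latent[i],
                "clamped": bool(clamped[i]),
                "p_team16": p16[i],
                "p_team18": p18[i],
                "p_team20": p20[i],
                "p_nhl": pnhl[i],
                "team16": bool(t16[i]),
                "team18": bool(t18[i]),
                "team20": bool(t20[i]),
                "nhl": bool(nhl[i]),
                "lost_followup": bool(lost[i]),
                "entry_error": bool(entry_err[i]),
                "region": f"R{region[i] + 1:02d}",
            }
        )
    truth = pd.DataFrame(rows).set_index("player_id")
    return records, truth
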