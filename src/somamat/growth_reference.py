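"""Age-referenced distribution of percent of adult height (%AH).

A :class:`GrowthReferenceTable` holds, on an ascending age grid, the mean and
standard deviation of %AH in a reference population of boys.  It supports the
three queries the maturity pipeline needs:

* forward lookup  — age → (mean %AH, SD %AH), linearly interpolated;
* z-score         — how many reference SDs a player's %AH sits from the
  age-matched mean;
* inverse lookup  — %AH → *biological age*, the age at which the reference
  mean %AH equals the player's %AH, reported to one decimal place.

National reference values of this kind are typically published in growth
studies and are not redistributable; :func:`synthetic_default_reference`
builds a clearly labelled synthetic stand-in from a logistic maturation
curve so the pipeline is runnable out of the box.  Any user-supplied table
with columns ``age,mean_pah,sd_pah`` can be loaded with
:func:`load_reference`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GrowthReferenceTable",
    "ReferenceValidationError",
    "AgeOutOfRangeError",
    "load_reference",
    "reference_mean_sd",
    "zscore_pah",
    "biological_age_from_pah",
    "synthetic_default_reference",
]


class ReferenceValidationError(ValueError):
    """A reference table violates a structural invariant."""


class AgeOutOfRangeError(ValueError):
    """Queried age lies outside the reference age grid."""

    def __init__(self, age: float, age_min: float, age_max: float):
        self.age = age
        self.valid_range = (age_min, age_max)
        super().__init__(
            f"age {age:g} outside reference grid [{age_min:g}, {age_max:g}]"
        )


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class GrowthReferenceTable:
    """Mean and SD of percent adult height on an ascending age grid.

    Invariants (checked at construction): strictly increasing ages,
    non-decreasing mean %AH, all SDs positive, and the mean reaches exactly
    100% at the last grid age (the *terminal age*, the age the reference
    treats as adult height).
    """

    age_grid: np.ndarray
    mean_pah: np.ndarray
    sd_pah: np.ndarray
    provenance_label: str = "unspecified"

    def __post_init__(self):
        age = np.asarray(self.age_grid, dtype=float)
        mean = np.asarray(self.mean_pah, dtype=float)
        sd = np.asarray(self.sd_pah, dtype=float)
        object.__setattr__(self, "age_grid", age)
        object.__setattr__(self, "mean_pah", mean)
        object.__setattr__(self, "sd_pah", sd)
        if age.size == 0:
            raise ReferenceValidationError("empty reference table")
        if not (age.size == mean.size == sd.size):
            raise ReferenceValidationError("age/mean/sd length mismatch")
        if not np.all(np.diff(age) > 0):
            raise ReferenceValidationError("age_grid must be strictly increasing")
        bad = np.diff(mean) < 0
        if np.any(bad):
            ages = age[1:][bad]
            raise ReferenceValidationError(
                "mean_pah must be non-decreasing; decreases at age(s) "
                + ", ".join(f"{a:g}" for a in ages[:10])
            )
        if np.any(sd <= 0):
            raise ReferenceValidationError("all sd_pah must be > 0")
        if abs(mean[-1] - 100.0) > 1e-9:
            raise ReferenceValidationError(
                f"mean_pah at the last grid age is {mean[-1]:g}, expected 100.0 "
                "(terminal age must correspond to adult height)"
            )

    @property
    def terminal_age(self) -> float:
        return float(self.age_grid[-1])

    @property
    def age_min(self) -> float:
        return float(self.age_grid[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age_grid, "mean_pah": self.mean_pah, "sd_pah": self.sd_pah}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_reference(source, provenance_label: str | None = None) -> GrowthReferenceTable:
    """Read a reference table from delimited text with header ``age,mean_pah,sd_pah``.

    ``source`` is anything :func:`pandas.read_csv` accepts (path or handle).
    """
    df = pd.read_csv(source)
    missing = {"age", "mean_pah", "sd_pah"} - set(df.columns)
    if missing:
        raise ReferenceValidationError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ReferenceValidationError("empty reference table")
    df = df.sort_values("age")
    label = provenance_label if provenance_label is not None else str(source)
    return GrowthReferenceTable(
        age_grid=df["age"].to_numpy(float),
        mean_pah=df["mean_pah"].to_numpy(float),
        sd_pah=df["sd_pah"].to_numpy(float),
        provenance_label=label,
    )


def _check_age(ref: GrowthReferenceTable, age) -> np.ndarray:
    a = np.asarray(age, dtype=float)
    if np.any(a < ref.age_min - 1e-12) or np.any(a > ref.terminal_age + 1e-12):
        bad = float(np.atleast_1d(a)[np.argmax((a < ref.age_min) | (a > ref.terminal_age))])
        raise AgeOutOfRangeError(bad, ref.age_min, ref.terminal_age)
    return a


def reference_mean_sd(ref: GrowthReferenceTable, age):
    """Interpolated (mean %AH, SD %AH) at ``age``; exact at grid points.

    Accepts scalars or arrays; raises :class:`AgeOutOfRangeError` off-grid.
    """
    a = _check_age(ref, age)
    mean = np.interp(a, ref.age_grid, ref.mean_pah)
    sd = np.interp(a, ref.age_grid, ref.sd_pah)
    if np.isscalar(age) or np.ndim(age) == 0:
        return float(mean), float(sd)
    return mean, sd


def zscore_pah(ref: GrowthReferenceTable, pah, age):
    """z = (pah − mean(age)) / sd(age) against the age-matched reference."""
    mean, sd = reference_mean_sd(ref, age)
    z = (np.asarray(pah, dtype=float) - mean) / sd
    if np.isscalar(pah) or np.ndim(pah) == 0:
        return float(z)
    return z


def biological_age_from_pah(
    ref: GrowthReferenceTable, pah: float, with_flag: bool = False
):
    """Invert the reference mean curve: the age whose mean %AH equals ``pah``.

    Inverse linear interpolation on the grid, rounded half-up to one decimal.
    ``pah == 100`` maps to the terminal age; ``pah`` below the first grid
    mean maps to the first grid age (flagged ``extrapolated_low`` when
    ``with_flag=True``).  Flat mean segments resolve to the youngest age
    attaining the value.
    """
    pah = float(pah)
    if not (0.0 < pah <= 100.0):
        raise ValueError(f"pah must be in (0, 100], got {pah:g}")
    mean = ref.mean_pah
    age = ref.age_grid
    extrapolated_low = False
    if pah <= mean[0]:
        a = float(age[0])
        extrapolated_low = bool(pah < mean[0])
    else:
        # first grid index whose mean reaches pah (youngest on flat runs)
        i = int(np.searchsorted(mean, pah, side="left"))
        if i >= mean.size:  # pah == 100 handled by terminal row; safety net
            a = float(age[-1])
        else:
            m0, m1 = mean[i - 1], mean[i]
            a0, a1 = age[i - 1], age[i]
            a = float(a1) if m1 == m0 else float(a0 + (pah - m0) / (m1 - m0) * (a1 - a0))
    a = _round_half_up(a, 1)
    if with_flag:
        return a, extrapolated_low
    return a


def synthetic_default_reference(
    age_min: float = 12.0,
    age_max: float = 18.0,
    step: float = 0.1,
    midpoint: float = 13.2,
    scale: float = 0.9,
    childhood_fraction: float = 0.70,
    timing_sd_ref: float = 0.85,
    sd_floor: float = 0.30,
) -> GrowthReferenceTable:
    """Synthetic boys' %AH reference from a logistic maturation curve.

    The mean curve is ``f(age) = c + (1 − c)·logistic((age − midpoint)/scale)``
    rescaled so it equals exactly 100% at ``age_max`` (the terminal age, by
    analogy with maturity methods that treat age 18 as adult height).  With
    the defaults the mean %AH is ≈ 85% at 13.2 y, ≈ 97% at 15 y and ≈ 99% at
    16.2 y, a plausible shape for adolescent boys around peak height velocity.

    The SD tracks the local slope of the mean curve times ``timing_sd_ref``
    (the assumed SD of maturity timing in the reference population, in
    years), floored at ``sd_floor`` so the terminal SD stays positive: if
    between-boy variation in %AH at a given age is driven mostly by timing,
    one year of timing shift moves %AH by one slope unit.

    The provenance label is ``"synthetic-default"``; it is **not** a real
    national reference and is echoed through all scientific outputs.
    """
    n = int(round((age_max - age_min) / step)) + 1
    age = age_min + step * np.arange(n)
    c = childhood_fraction

    def raw(a):
        return c + (1.0 - c) / (1.0 + np.exp(-(a - midpoint) / scale))

    norm = raw(age_max)
    mean = 100.0 * raw(age) / norm
    mean[-1] = 100.0  # exact terminal value
    g = 1.0 / (1.0 + np.exp(-(age - midpoint) / scale))
    slope = 100.0 * (1.0 - c) / scale * g * (1.0 - g) / norm  # %AH per year
    sd = np.maximum(slope * timing_sd_ref, sd_floor)
    return GrowthReferenceTable(
        age_grid=age, mean_pah=mean, sd_pah=sd, provenance_label="synthetic-default"
    )
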