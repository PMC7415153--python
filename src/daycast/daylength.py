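"""Theoretical day length (photoperiod) computation.

Day length — the number of hours between sunrise and sunset — can be
computed in advance for any location and calendar date, which is what makes
it usable for planning field trials before they are planted.  This module
implements the CBM model of Forsythe et al. (1995), the standard smooth
astronomical approximation: the solar declination is derived from a
two-term expression for the Earth's revolution angle, and daylight is the
fraction of the day during which the sun's upper limb, after atmospheric
refraction, is above the horizon (daylength coefficient p = 0.8333 degrees).

Only latitude and day-of-year enter the model; longitude shifts clock time
of sunrise, not the duration of daylight, and is deliberately ignored.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError
from .io_model import Environment

__all__ = ["SUN_ANGLE_DEG", "DayLengthSeries", "day_length",
           "series_for_environment", "cumulative_day_length"]

#: Daylength coefficient: sun's upper limb plus atmospheric refraction, degrees.
SUN_ANGLE_DEG = 0.8333


def day_length(latitude: float, day_of_year):
    """Hours of daylight at `latitude` on `day_of_year` (1..366).

    Parameters
    ----------
    latitude : float
        Degrees north (negative south), in [-90, 90].
    day_of_year : int or array-like of int
        Calendar day of year.

    Returns
    -------
    float or ndarray
        Day length in hours, clamped to [0, 24].  Polar day returns 24.0,
        polar night 0.0 (the inverse-cosine argument is clipped rather
        than raising, so simulations at extreme latitudes degrade
        gracefully).
    """
    if not -90.0 <= latitude <= 90.0:
        raise DomainError(f"latitude {latitude} outside [-90, 90]")
    j = np.asarray(day_of_year, dtype=float)
    if np.any(j < 1) or np.any(j > 366):
        raise DomainError("day_of_year must lie in [1, 366]")
    # revolution angle and solar declination (radians)
    theta = 0.2163108 + 2.0 * np.arctan(0.9671396 * np.tan(0.00860 * (j - 186.0)))
    phi = np.arcsin(0.39795 * np.cos(theta))
    lat = np.deg2rad(latitude)
    p = np.deg2rad(SUN_ANGLE_DEG)
    arg = (np.sin(p) + np.sin(lat) * np.sin(phi)) / (np.cos(lat) * np.cos(phi))
    hours = 24.0 - (24.0 / np.pi) * np.arccos(np.clip(arg, -1.0, 1.0))
    if np.isscalar(day_of_year) or np.ndim(day_of_year) == 0:
        return float(hours)
    return hours


@dataclass
class DayLengthSeries:
    """Daily day length for one environment, day 1 being the planting date.

    ``values[t - 1]`` is the day length (hours) on calendar date
    ``start_date + (t - 1) days`` for 1-based day index ``t``.
    """

    env_id: str
    start_date: dt.date
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise DomainError("a day-length series needs at least one day")
        if np.any(self.values < 0) or np.any(self.values > 24):
            raise DomainError("day-length values must lie in [0, 24]")

    def __len__(self) -> int:
        return int(self.values.size)

    def value_at(self, day_index: int) -> float:
        """Day length on 1-based day index `day_index`."""
        if not 1 <= day_index <= len(self):
            raise DomainError(
                f"day index {day_index} outside series of length {len(self)}")
        return float(self.values[day_index - 1])

    def date_at(self, day_index: int) -> dt.date:
        return self.start_date + dt.timedelta(days=day_index - 1)


def series_for_environment(env: Environment, n_days: int) -> DayLengthSeries:
    """Daily day-length series for an environment from its planting date.

    Day index 1 is the planting date itself; leap years are handled through
    the actual calendar day-of-year of each date.
    """
    if n_days < 1:
        raise DomainError("n_days must be >= 1")
    doys = np.fromiter(
        ((env.planting_date + dt.timedelta(days=i)).timetuple().tm_yday
         for i in range(n_days)),
        dtype=float, count=n_days)
    values = day_length(env.latitude, doys)
    return DayLengthSeries(env_id=env.env_id, start_date=env.planting_date,
                           values=values)


def cumulative_day_length(series: DayLengthSeries, dth: int) -> float:
    """Cumulative day length (CDL): total daylight hours from planting
    (day 1) through heading (day `dth`), inclusive."""
    if not 1 <= dth <= len(series):
        raise DomainError(
            f"dth {dth} outside series of length {len(series)}")
    return float(np.sum(series.values[:dth]))
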