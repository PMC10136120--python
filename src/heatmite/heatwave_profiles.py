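"""Diurnal heat-wave regimes applied in the incubator experiments.

Two repeating 24-h programmes are used throughout the package: a *mild*
heat wave peaking at 32.0 degC and an *extreme* one peaking at 38.0 degC,
each defined as twelve 2-hour temperature / relative-humidity steps under
long-day (16:8 L:D) photoperiod.  The extreme programme is the mild one
shifted upward by exactly 6 degC at every step.  Profiles are data
constants: the simulator consumes the regime *label*, not instantaneous
temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

__all__ = [
    "ProfileStep",
    "HeatWaveProfile",
    "REGIMES",
    "make_profile",
    "profile_mean",
    "display_round",
    "profiles_frame",
    "write_profiles_csv",
]

REGIMES = ("mild", "extreme")

# 2-hour blocks starting at 00:00.  Mild temperatures (degC), mild RH (%),
# and extreme RH (%); extreme temperature = mild + 6.0 at every block.
_START_HOURS = tuple(range(0, 24, 2))
_MILD_T = (18.0, 17.0, 16.0, 19.0, 27.0, 30.0, 32.0, 29.0, 24.0, 22.0, 19.0, 18.0)
_MILD_RH = (75.0, 80.0, 85.0, 75.0, 60.0, 50.0, 50.0, 55.0, 65.0, 70.0, 75.0, 75.0)
_EXTREME_RH = (65.0, 70.0, 75.0, 65.0, 50.0, 50.0, 50.0, 50.0, 55.0, 60.0, 65.0, 65.0)

TEMPERATURE_OFFSET_C = 6.0
PHOTOPERIOD_H = 16


@dataclass(frozen=True)
class ProfileStep:
    """One 2-hour incubator block."""

    start_hour: int
    temperature_c: float
    rh_percent: float


@dataclass(frozen=True)
class HeatWaveProfile:
    """A 24-hour diurnal regime as twelve contiguous 2-hour steps."""

    regime: str
    steps: tuple[ProfileStep, ...]
    photoperiod_h: int = PHOTOPERIOD_H

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; valid regimes: {', '.join(REGIMES)}"
            )
        if len(self.steps) != 12:
            raise ValueError("a profile must have exactly 12 two-hour steps")
        hours = tuple(s.start_hour for s in self.steps)
        if hours != _START_HOURS:
            raise ValueError("steps must cover 00:00-24:00 in 2-hour blocks without gaps")

    def to_dict(self) -> dict:
        return {
            "regime": self.regime,
            "photoperiod_h": self.photoperiod_h,
            "steps": [
                {
                    "start_hour": s.start_hour,
                    "temperature_c": s.temperature_c,
                    "rh_percent": s.rh_percent,
                }
                for s in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeatWaveProfile":
        return cls(
            regime=d["regime"],
            steps=tuple(
                ProfileStep(s["start_hour"], s["temperature_c"], s["rh_percent"])
                for s in d["steps"]
            ),
            photoperiod_h=d.get("photoperiod_h", PHOTOPERIOD_H),
        )


def make_profile(regime: str) -> HeatWaveProfile:
    """Return the 12-step diurnal profile for a regime label."""
    if regime not in REGIMES:
        raise ValueError(
            f"unknown regime {regime!r}; valid regimes: {', '.join(REGIMES)}"
        )
    if regime == "mild":
        temps, rhs = _MILD_T, _MILD_RH
    else:
        temps = tuple(t + TEMPERATURE_OFFSET_C for t in _MILD_T)
        rhs = _EXTREME_RH
    steps = tuple(
        ProfileStep(h, t, rh) for h, t, rh in zip(_START_HOURS, temps, rhs)
    )
    return HeatWaveProfile(regime=regime, steps=steps)


def profile_mean(profile: HeatWaveProfile, channel: str) -> float:
    """Unweighted arithmetic mean over the 12 steps of one channel.

    The value is returned unrounded; use :func:`display_round` for the
    one-decimal presentation convention.
    """
    if channel == "temperature":
        values = [s.temperature_c for s in profile.steps]
    elif channel == "humidity":
        values = [s.rh_percent for s in profile.steps]
    else:
        raise ValueError("channel must be 'temperature' or 'humidity'")
    return sum(values) / len(values)


def display_round(x: float, ndigits: int = 1) -> float:
    """Round half-up to `ndigits` decimals (table presentation convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def profiles_frame(profiles: Iterable[HeatWaveProfile] | None = None) -> pd.DataFrame:
    """Long-format table of one or both regimes."""
    if profiles is None:
        profiles = [make_profile(r) for r in REGIMES]
    rows = [
        {
            "regime": p.regime,
            "start_hour": s.start_hour,
            "temperature_C": s.temperature_c,
            "rh_percent": s.rh_percent,
        }
        for p in profiles
        for s in p.steps
    ]
    return pd.DataFrame(rows)


def write_profiles_csv(path, profiles: Iterable[HeatWaveProfile] | None = None) -> None:
    profiles_frame(profiles).to_csv(path, index=False)
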