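"""Egg geometry and sexing-subsample bookkeeping.

Predator eggs are ellipsoidal and measured by their semi-major axis *a*
and semi-minor axis *b* (micrometres); prey eggs are globular and
measured by their radius *r*.  Volumes follow V = (4/3) pi a b^2 for the
prolate spheroid (two equal minor axes, the only reading consistent with
measuring exactly *a* and *b*) and V = (4/3) pi r^3 for the sphere.

Only a daily subsample of eggs (default two per ovipositing female) is
reared to adulthood for sex determination; :func:`sexing_subsample`
reproduces that selection rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["EggGeometry", "egg_volume", "sexing_subsample", "subsample_daily"]


@dataclass(frozen=True)
class EggGeometry:
    """Measured axes of one egg; exactly one shape's fields populated."""

    shape: str  # "ellipsoid" | "sphere"
    semi_major_um: float | None = None
    semi_minor_um: float | None = None
    radius_um: float | None = None

    def __post_init__(self) -> None:
        if self.shape == "ellipsoid":
            a, b = self.semi_major_um, self.semi_minor_um
            if a is None or b is None or self.radius_um is not None:
                raise ValueError("ellipsoid requires semi_major_um and semi_minor_um only")
            if a <= 0 or b <= 0:
                raise ValueError("axes must be positive")
            if a < b:
                raise ValueError("semi-major axis must be >= semi-minor axis")
        elif self.shape == "sphere":
            r = self.radius_um
            if r is None or self.semi_major_um is not None or self.semi_minor_um is not None:
                raise ValueError("sphere requires radius_um only")
            if r <= 0:
                raise ValueError("radius must be positive")
        else:
            raise ValueError("shape must be 'ellipsoid' or 'sphere'")


def egg_volume(geometry: EggGeometry) -> float:
    """Egg volume in cubic micrometres from the measured axes."""
    if geometry.shape == "ellipsoid":
        return (4.0 / 3.0) * math.pi * geometry.semi_major_um * geometry.semi_minor_um**2
    return (4.0 / 3.0) * math.pi * geometry.radius_um**3


def sexing_subsample(eggs: Sequence, k: int, rng: np.random.Generator) -> list:
    """Select min(k, n) eggs uniformly without replacement from one female-day.

    When a female laid k or fewer eggs that day, all of them are used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eggs = list(eggs)
    if len(eggs) <= k:
        return eggs
    idx = rng.choice(len(eggs), size=k, replace=False)
    return [eggs[i] for i in sorted(idx)]


def subsample_daily(eggs: pd.DataFrame, k: int, rng: np.random.Generator) -> pd.DataFrame:
    """Apply the per-female-day sexing subsample to a long egg table.

    Expects columns ``female_id`` and ``day``; returns the selected rows in
    stable (female, day) order so results are reproducible under a fixed rng.
    """
    pieces = []
    for _, grp in eggs.groupby(["female_id", "day"], sort=True):
        if len(grp) <= k:
            pieces.append(grp)
        else:
            idx = rng.choice(len(grp), size=k, replace=False)
            pieces.append(grp.iloc[np.sort(idx)])
    if not pieces:
        return eggs.iloc[0:0]
    return pd.concat(pieces, axis=0)
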