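"""Closed-form morphometric estimators.

Coccolith mass follows the elliptical-slab volumetric model

    m = pi * (l/2) * (w/2) * t * d

with length ``l`` and width ``w`` the distal-shield axes (um), ``t`` the
mean thickness (um) and ``d`` the calcite density (2.71 g/cm^3); the
numeric product is directly in picograms. Population calcite
concentration is

    Ca = CD * m * N_cocco * 1e-6   [ug/L]

with cell density ``CD`` in cells/L and ``N_cocco`` coccoliths per cell.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import SummaryStat

#: Density of calcite in g/cm^3.
CALCITE_DENSITY = 2.71

#: Assumed coccoliths per coccosphere: minimum, literature mean, maximum.
COCCOLITHS_PER_CELL = (10, 23, 48)


def coccolith_mass(
    length: float, width: float, thickness: float,
    density: float = CALCITE_DENSITY,
) -> float:
    """Volumetric coccolith mass in pg (elliptical slab times density)."""
    if length <= 0 or width <= 0 or density <= 0:
        raise ValueError("length, width and density must be > 0")
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    if width > length:
        raise ValueError(
            f"width ({width}) > length ({length}): violates the "
            "distal-shield axis convention"
        )
    return math.pi * (length / 2) * (width / 2) * thickness * density


def calcite_concentration(
    cell_density: float, mean_mass: float, coccoliths_per_cell: float
) -> float:
    """Population calcite concentration in ug/L.

    ``cell_density`` in cells/L, ``mean_mass`` in pg per coccolith;
    the pg/L product is converted to ug/L.
    """
    if cell_density < 0 or mean_mass < 0 or coccoliths_per_cell < 0:
        raise ValueError("all inputs must be >= 0")
    return cell_density * mean_mass * coccoliths_per_cell * 1e-6


def calcite_table(
    cell_density: float, mean_mass: float,
    coccoliths_per_cell: Sequence[int] = COCCOLITHS_PER_CELL,
) -> dict[int, float]:
    """Calcite concentration (ug/L) for each assumed coccoliths-per-cell."""
    return {
        int(n): calcite_concentration(cell_density, mean_mass, n)
        for n in coccoliths_per_cell
    }


def ct_l_ratio(ct_left: float, ct_right: float, length: float) -> float:
    """Size-independent central-tube width to length ratio (CT:L).

    The central-tube width is measured on both sides of the central area
    along the length axis and averaged before dividing by length.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    if ct_left < 0 or ct_right < 0:
        raise ValueError("central-tube widths must be >= 0")
    return (ct_left + ct_right) / 2 / length


def aspect_ratio(length: float, width: float) -> float:
    """Distal-shield length / width (>= 1 under the axis convention)."""
    if length <= 0 or width <= 0:
        raise ValueError("length and width must be > 0")
    return length / width


def morphotype_mass_table(
    sem_stats: Mapping[str, tuple[SummaryStat, SummaryStat]],
    thickness: Mapping[str, float],
    density: float = CALCITE_DENSITY,
) -> pd.DataFrame:
    """Per-morphotype volumetric mass from SEM sizes and posterior thickness.

    ``sem_stats`` maps each morphotype to its (length, width) summary
    statistics from SEM measurements; ``thickness`` maps morphotypes to
    posterior-median mean thickness (um). A morphotype present in the SEM
    summaries but absent from the posterior is kept in the table with
    ``estimable=False`` and a NaN mass rather than silently dropped.
    """
    rows = []
    for morph, (length_stat, width_stat) in sem_stats.items():
        t = thickness.get(morph)
        estimable = t is not None and np.isfinite(t)
        rows.append({
            "morphotype": morph,
            "length_um": length_stat.mean,
            "width_um": width_stat.mean,
            "thickness_um": t if estimable else np.nan,
            "mass_pg": (
                coccolith_mass(length_stat.mean, width_stat.mean, t, density)
                if estimable else np.nan
            ),
            "estimable": estimable,
        })
    return pd.DataFrame(rows).set_index("morphotype")
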