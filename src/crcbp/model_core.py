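"""Core domain types and size-unit conversions.

The model is a two-type continuous-time branching process with immigration.
Adenoma cells (compartment ``A``) arrive from the colonic-crypt stem-cell pool
at rate ``mu1`` (cells/year), divide at ``b1`` and die at ``d1`` (per cell per
year), and convert to malignant cells (compartment ``M``) at ``mu2``; malignant
cells divide at ``b2`` and die at ``d2``.  Net growth rates are
``gamma1 = b1 - d1`` and ``gamma2 = b2 - d2``.

Endoscopist-reported lesion sizes (largest dimension, mm) are converted to
cell counts assuming a half-ellipsoid with all three semi-axes equal to half
the reported dimension and ~1e8 cells per cm^3, i.e.

    N(d) = cells_per_cm3 * (pi/12) * (d/10)^3       [d in mm]
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelParams",
    "MixtureParam",
    "Observation",
    "SizeBinSpec",
    "mm_to_cells",
    "cells_to_mm",
    "bin_from_report",
    "observations_to_frame",
    "frame_to_observations",
    "CELLS_PER_CM3",
]

#: default volumetric cell density (cells per cm^3)
CELLS_PER_CM3 = 1e8


@dataclass(frozen=True)
class ModelParams:
    """The six rates of the two-type process.

    ``gamma1``/``gamma2`` are derived, never stored independently.
    """

    mu1: float
    b1: float
    d1: float
    mu2: float
    b2: float
    d2: float
    equal_death_rates: bool = False  # d1 == d2 restriction used for real-data fits

    def __post_init__(self) -> None:
        for name in ("mu1", "b1", "d1", "mu2", "b2", "d2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v!r}")
        if self.equal_death_rates and not math.isclose(self.d1, self.d2, rel_tol=1e-12, abs_tol=0.0):
            raise ValueError("equal_death_rates set but d1 != d2")

    @property
    def gamma1(self) -> float:
        return self.b1 - self.d1

    @property
    def gamma2(self) -> float:
        return self.b2 - self.d2

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.mu1, self.b1, self.d1, self.mu2, self.b2, self.d2)


@dataclass(frozen=True)
class MixtureParam:
    """Proportion ``lam`` of the population that never develops adenoma."""

    lam: float = 0.0
    fixed: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError(f"lam must be in [0, 1], got {self.lam!r}")


@dataclass(frozen=True)
class Observation:
    """One size-binned lesion finding.

    ``lower``/``upper`` are cell counts; the bin is the half-open interval
    ``(lower, upper]``.  A zero-inclusive bin (normal colonoscopy, undetected
    cancer) is encoded with ``lower = -1`` so that 0 lies inside the bin;
    ``upper`` may be ``inf``.
    """

    compartment: str  # "A" or "M"
    age: float
    lower: float
    upper: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.compartment not in ("A", "M"):
            raise ValueError(f"compartment must be 'A' or 'M', got {self.compartment!r}")
        if self.age <= 0:
            raise ValueError("age must be > 0")
        if not (self.lower >= -1 and self.lower < self.upper):
            raise ValueError(f"need -1 <= lower < upper, got ({self.lower}, {self.upper})")
        if self.weight < 1:
            raise ValueError("weight must be >= 1")

    @property
    def contains_zero(self) -> bool:
        return self.lower < 0


@dataclass(frozen=True)
class SizeBinSpec:
    """mm-level binning convention for reported lesion sizes."""

    half_width_mm: float = 0.5
    cells_per_cm3: float = CELLS_PER_CM3

    def __post_init__(self) -> None:
        if self.half_width_mm <= 0:
            raise ValueError("half_width_mm must be > 0")


def mm_to_cells(d_mm: float, cells_per_cm3: float = CELLS_PER_CM3) -> int:
    """Cell count of a half-ellipsoid lesion of reported largest dimension ``d_mm``.

    Volume (pi/12) d^3 with d in cm; rounds half up to an integer count.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("reported size must be >= 0 mm")
    cells = np.floor(cells_per_cm3 * (math.pi / 12.0) * (d / 10.0) ** 3 + 0.5)
    if cells.ndim == 0:
        return int(cells)
    return cells.astype(np.int64)


def cells_to_mm(n_cells: float, cells_per_cm3: float = CELLS_PER_CM3) -> float:
    """Inverse of :func:`mm_to_cells` (continuous; no rounding)."""
    n = np.asarray(n_cells, dtype=float)
    if np.any(n < 0):
        raise ValueError("cell count must be >= 0")
    out = 10.0 * np.cbrt(12.0 * n / (cells_per_cm3 * math.pi))
    return float(out) if out.ndim == 0 else out


def bin_from_report(reported_mm: float, spec: SizeBinSpec | None = None) -> tuple[float, float]:
    """Cell-count bin ``(L, U]`` for an endoscopist-reported size.

    A reported 0 (normal finding) maps to the zero-inclusive bin
    ``(-1, mm_to_cells(half_width)]``.  ``reported_mm = inf`` gives the
    prevalent-case bin with ``U = inf``.
    """
    spec = spec or SizeBinSpec()
    if reported_mm < 0:
        raise ValueError("reported size must be >= 0 mm")
    if math.isinf(reported_mm):
        raise ValueError("use an explicit (L, inf) bin for open upper bounds")
    lo_mm = reported_mm - spec.half_width_mm
    hi_mm = reported_mm + spec.half_width_mm
    if lo_mm <= 0:
        return (-1.0, float(mm_to_cells(hi_mm, spec.cells_per_cm3)))
    return (
        float(mm_to_cells(lo_mm, spec.cells_per_cm3)),
        float(mm_to_cells(hi_mm, spec.cells_per_cm3)),
    )


# ---------------------------------------------------------------------------
# observation CSV round trip (columns: compartment,age_years,lower_cells,
# upper_cells,weight; `upper_cells` may be the literal "inf")

def observations_to_frame(obs: list[Observation]):
    import pandas as pd

    return pd.DataFrame(
        {
            "compartment": [o.compartment for o in obs],
            "age_years": [o.age for o in obs],
            "lower_cells": [o.lower for o in obs],
            "upper_cells": [o.upper for o in obs],
            "weight": [o.weight for o in obs],
        }
    )


def frame_to_observations(df) -> list[Observation]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Observation(
                compartment=str(row.compartment),
                age=float(row.age_years),
                lower=float(row.lower_cells),
                upper=float(row.upper_cells),
                weight=float(row.weight),
            )
        )
    return out
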