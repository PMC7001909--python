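"""Registry prevalence imputation and likelihood-ready observation assembly.

Cancer registries report incident cases I(t) and at-risk counts R(t) per age
but censor prevalent cases (previously diagnosed, removed from follow-up).
With hats denoting proportions of the (unknown) total population and the
recursion anchored at the youngest observed age,

    Rhat(t) = Rhat(t-1) - Rhat(t-1) I(t) / (R(t) + I(t)),   Rhat(t0-1) = 1
    Ihat(t) = Rhat(t-1) - Rhat(t)
    Phat(t) = 1 - Rhat(t-1)

and the absolute prevalent count is imputed from the incidence scale,

    P(t) = I(t) Phat(t) / Ihat(t).

The imputed prevalent cases enter the likelihood as weighted compartment-M
observations in the open bin above the large-size cut (default 40 mm, the
median reported growth size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import Observation, SizeBinSpec, bin_from_report, mm_to_cells

__all__ = ["RegistryTable", "PrevalenceEstimates", "impute_prevalence",
           "build_observations"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegistryTable:
    ages: np.ndarray        # contiguous integer ages
    incident: np.ndarray    # I(t)
    at_risk: np.ndarray     # R(t)

    def __post_init__(self) -> None:
        a = np.asarray(self.ages)
        if len(a) == 0:
            raise ValueError("empty registry table")
        if np.any(np.diff(a) != 1):
            raise ValueError("ages must be contiguous")
        if np.any(np.asarray(self.incident) < 0) or np.any(np.asarray(self.at_risk) < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegistryTable":
        df = df.sort_values("age")
        return cls(ages=df["age"].to_numpy(dtype=int),
                   incident=df["incident_count"].to_numpy(dtype=np.int64),
                   at_risk=df["at_risk_count"].to_numpy(dtype=np.int64))


@dataclass(frozen=True)
class PrevalenceEstimates:
    ages: np.ndarray
    r_hat: np.ndarray       # proportion still at risk after each age
    i_hat: np.ndarray       # proportion newly incident at each age
    p_hat: np.ndarray       # proportion previously diagnosed entering each age
    prevalent: np.ndarray   # imputed absolute prevalent count P(t)
    total: np.ndarray       # estimated total population T(t) = I(t)/Ihat(t)


def impute_prevalence(table: RegistryTable) -> PrevalenceEstimates:
    """Run the normalized-population recursion and impute absolute prevalence."""
    I = np.asarray(table.incident, dtype=float)
    R = np.asarray(table.at_risk, dtype=float)
    n = len(I)
    r_hat = np.empty(n)
    i_hat = np.empty(n)
    p_hat = np.empty(n)
    prev = np.zeros(n)
    total = np.full(n, np.nan)
    r_prev = 1.0  # anchored at the youngest observed age
    for j in range(n):
        denom = R[j] + I[j]
        if I[j] > 0 and denom <= 0:
            raise ValueError(f"I > 0 with R + I = 0 at age {table.ages[j]}")
        frac = I[j] / denom if denom > 0 else 0.0
        r_hat[j] = r_prev - r_prev * frac
        i_hat[j] = r_prev - r_hat[j]
        p_hat[j] = 1.0 - r_prev
        if i_hat[j] > 0:
            prev[j] = I[j] * p_hat[j] / i_hat[j]
            total[j] = I[j] / i_hat[j]
        else:
            assert I[j] == 0, "Ihat = 0 with I > 0 cannot occur"
            prev[j] = 0.0
        r_prev = r_hat[j]
    return PrevalenceEstimates(ages=np.asarray(table.ages), r_hat=r_hat,
                               i_hat=i_hat, p_hat=p_hat, prevalent=prev,
                               total=total)


def build_observations(adenoma_df: pd.DataFrame | None,
                       tumor_df: pd.DataFrame | None,
                       estimates: PrevalenceEstimates | None = None,
                       *, spec: SizeBinSpec | None = None,
                       prevalent_cut_mm: float = 40.0,
                       age_window: tuple | None = None) -> list[Observation]:
    """Assemble weighted size-binned observations.

    * adenoma_df (age, size_mm; 0 = normal finding) -> compartment-A rows;
    * tumor_df (age, size_mm) -> compartment-M rows, +-half-width mm bins;
    * imputed prevalent counts -> one weighted M row per age in the open bin
      above ``prevalent_cut_mm``.

    Rows outside ``age_window`` (lo, hi) are dropped with a logged count.
    """
    spec = spec or SizeBinSpec()
    out: list[Observation] = []
    dropped = 0

    def _keep(age: float) -> bool:
        return age_window is None or (age_window[0] <= age <= age_window[1])

    for comp, df in (("A", adenoma_df), ("M", tumor_df)):
        if df is None or len(df) == 0:
            continue
        grouped = df.groupby([df["age"].round(0).astype(int), "size_mm"]) \
                    .size().reset_index(name="count")
        for row in grouped.itertuples(index=False):
            if not _keep(float(row.age)):
                dropped += int(row.count)
                continue
            lo, hi = bin_from_report(float(row.size_mm), spec)
            out.append(Observation(compartment=comp, age=float(row.age),
                                   lower=lo, upper=hi,
                                   weight=float(row.count)))
    if estimates is not None:
        cut = float(mm_to_cells(prevalent_cut_mm, spec.cells_per_cm3))
        for age, p in zip(estimates.ages, estimates.prevalent):
            w = round(float(p))
            if w < 1 or not _keep(float(age)) or age <= 0:
                continue
            out.append(Observation(compartment="M", age=float(age),
                                   lower=cut, upper=math.inf, weight=float(w)))
    if dropped:
        logger.info("build_observations: dropped %d rows outside age window",
                    dropped)
    return out
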