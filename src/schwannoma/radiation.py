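"""Excess risk of radiation-induced malignant transformation.

A dose D of ionising radiation induces double-strand breaks at a given base
pair with probability p_DSB = k D (linear over the 0-50 Gy measurement
range), each misrepaired with probability epsilon; of these, m_TSX sites on
the tumour suppressor TSX deactivate it when misrepaired (DSB misrepair
produces indels, so the indel-sensitive count m_TSX = 0.42 n_TSX applies).
Only cells that have already lost one copy of TSX (the subpopulations
N_l + N_m = (n_TSX u + p_LOH) N of the spontaneous model) can be pushed to
malignancy, and the mutated cell must also survive the dose, with
linear-quadratic survival S(D) = exp(-alpha D - beta D^2).  The excess risk
(absolute risk difference) of a single fraction is

    E.R.(D) = (1 - exp(-k eps m_TSX (n_TSX u + p_LOH) D S(D) N))
              * exp(-(1/2) n_TSX u (n_TSX u + 2 p_LOH) N)

which rises linearly at small D (no threshold), peaks where D S(D) peaks
(~1 Gy at the default coefficients) and collapses at therapeutic doses where
cell kill dominates.  Ideally fractionated schedules (fractions within one
tumour cell cycle) behave like the single total dose; the worst case, with
full recovery between F independent fractions, replaces S(D) by S(D/F) and
grows with F.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .malignancy import (
    DEFAULT_V_SC,
    MalignancyParams,
    cell_count,
    malignancy_risk,
    volume_from_diameter,
)

__all__ = [
    "RadiationParams",
    "GrowthKinetics",
    "INDEL_SENSITIVE_FRACTION",
    "survival",
    "single_copy_loss_probability",
    "excess_risk_single_fraction",
    "excess_risk_ideal_fractionation",
    "excess_risk_fractionated_worst_case",
    "peak_risk_dose",
    "tumour_division_rate",
    "risk_surface",
]

INDEL_SENSITIVE_FRACTION = 0.42     # m_gene / n_gene = 0.74/1.74, rounded
LINEAR_DSB_VALIDITY_GY = 50.0       # measured linear range of DSB induction


@dataclass(frozen=True)
class RadiationParams:
    """Radiobiological constants for DSB induction, misrepair and survival."""

    k_dsb: float = 3.90e-7       # DSBs per Gray per base pair
    epsilon: float = 0.5         # misrepair probability per DSB (pessimistic)
    alpha_lq: float = 0.77       # linear-quadratic survival, per Gray
    beta_lq: float = 0.31        # per Gray^2
    m_tsx: float = INDEL_SENSITIVE_FRACTION * 1245.0  # indel-sensitive TSX sites

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        for name in ("k_dsb", "alpha_lq", "beta_lq", "m_tsx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_n_tsx(cls, n_tsx: float, **kwargs) -> "RadiationParams":
        return cls(m_tsx=INDEL_SENSITIVE_FRACTION * n_tsx, **kwargs)

    def with_(self, **kwargs) -> "RadiationParams":
        return replace(self, **kwargs)


def survival(D: "float | np.ndarray", params: RadiationParams) -> "float | np.ndarray":
    """Linear-quadratic clonogenic survival S(D) = exp(-alpha D - beta D^2)."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be nonnegative")
    S = np.exp(-params.alpha_lq * D - params.beta_lq * D ** 2)
    return float(S) if S.ndim == 0 else S


def single_copy_loss_probability(
    D: "float | np.ndarray", params: RadiationParams
) -> "float | np.ndarray":
    """Per-cell probability that the dose inactivates one TSX copy: k D eps m."""
    D = np.asarray(D, dtype=float)
    if np.any(D > LINEAR_DSB_VALIDITY_GY):
        warnings.warn(
            f"dose beyond the {LINEAR_DSB_VALIDITY_GY:.0f} Gy linear range of the "
            "DSB-induction measurement",
            stacklevel=2,
        )
    p = params.k_dsb * D * params.epsilon * params.m_tsx
    if np.any(p > 1.0):
        warnings.warn("per-cell loss probability clipped to 1", stacklevel=2)
        p = np.clip(p, 0.0, 1.0)
    return float(p) if np.ndim(p) == 0 else p


def _no_prior_clone_factor(N: "float | np.ndarray", mal: MalignancyParams) -> np.ndarray:
    """exp(-(1/2) n u (n u + 2 p) N): no spontaneous malignant clone already."""
    return 1.0 - malignancy_risk(N, mal)["P_total"]


def excess_risk_single_fraction(
    D: "float | np.ndarray",
    N: "float | np.ndarray",
    rad: RadiationParams,
    mal: MalignancyParams,
) -> "float | np.ndarray":
    """Excess risk of a single dose D on a tumour of N cells."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be nonnegative")
    sensitive = (mal.n_tsx * mal.u + mal.p_loh) * np.asarray(N, dtype=float)
    induced = 1.0 - np.exp(
        -rad.k_dsb * rad.epsilon * rad.m_tsx * sensitive * D * survival(D, rad)
    )
    er = induced * _no_prior_clone_factor(N, mal)
    return float(er) if np.ndim(er) == 0 else er


def excess_risk_ideal_fractionation(
    D: "float | np.ndarray",
    N: "float | np.ndarray",
    rad: RadiationParams,
    mal: MalignancyParams,
) -> "float | np.ndarray":
    """Fractions delivered within one tumour cell cycle act as one total dose."""
    return excess_risk_single_fraction(D, N, rad, mal)


def excess_risk_fractionated_worst_case(
    D: "float | np.ndarray",
    F: int,
    N: "float | np.ndarray",
    rad: RadiationParams,
    mal: MalignancyParams,
) -> "float | np.ndarray":
    """Worst-case excess risk: full tumour-cell recovery between F fractions.

    The F per-fraction risks compound independently, which collapses to the
    single-fraction formula with the survival factor evaluated at the
    per-fraction dose: S(D/F) in place of S(D).  Equals the single-fraction
    result at F = 1 and is nondecreasing in F at fixed total dose.
    """
    if int(F) != F or F < 1:
        raise ValueError("fraction count F must be a positive integer")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be nonnegative")
    sensitive = (mal.n_tsx * mal.u + mal.p_loh) * np.asarray(N, dtype=float)
    induced = 1.0 - np.exp(
        -rad.k_dsb * rad.epsilon * rad.m_tsx * sensitive * D * survival(D / F, rad)
    )
    er = induced * _no_prior_clone_factor(N, mal)
    return float(er) if np.ndim(er) == 0 else er


def peak_risk_dose(params: RadiationParams) -> float:
    """Dose maximising the single-fraction excess risk.

    The prior-clone factor is dose-independent and the induced-risk exponent
    is monotone in D S(D), so the peak sits at the maximiser of D S(D):
    the positive root of 1 - alpha D - 2 beta D^2 = 0.
    """
    a, b = params.alpha_lq, params.beta_lq
    if b == 0:
        return 1.0 / a
    return (-a + math.sqrt(a ** 2 + 8.0 * b)) / (4.0 * b)


@dataclass(frozen=True)
class GrowthKinetics:
    """Tumour-cell division kinetics implied by radial expansion speed.

    A tumour growing only at its edge advances one cell diameter
    (V_SC^(1/3)) per division, so b = c / V_SC^(1/3).
    """

    expansion_speed_mm_yr: float
    v_sc: float = DEFAULT_V_SC

    @property
    def division_rate_per_yr(self) -> float:
        return self.expansion_speed_mm_yr / self.v_sc ** (1.0 / 3.0)

    @property
    def cycle_time_days(self) -> float:
        return 365.0 / self.division_rate_per_yr


def tumour_division_rate(c_mm_yr: float, v_sc: float = DEFAULT_V_SC) -> GrowthKinetics:
    """Division rate of tumour cells from the observed expansion speed."""
    if c_mm_yr <= 0 or v_sc <= 0:
        raise ValueError("expansion speed and cell volume must be positive")
    return GrowthKinetics(expansion_speed_mm_yr=c_mm_yr, v_sc=v_sc)


def risk_surface(
    diameters_mm: np.ndarray,
    doses_gy: np.ndarray,
    rad: RadiationParams,
    mal: MalignancyParams,
    fractions: int = 1,
    worst_case: bool = False,
) -> pd.DataFrame:
    """Excess risk over a diameter x dose grid, in long format."""
    rows = []
    for d in np.asarray(diameters_mm, dtype=float):
        N = cell_count(volume_from_diameter(d), mal.f_sc, mal.v_sc)
        for dose in np.asarray(doses_gy, dtype=float):
            if worst_case and fractions > 1:
                er = excess_risk_fractionated_worst_case(dose, fractions, N, rad, mal)
            else:
                er = excess_risk_single_fraction(dose, N, rad, mal)
            rows.append(
                {
                    "diameter_mm": d,
                    "dose_gy": dose,
                    "fractions": fractions,
                    "excess_risk": er,
                }
            )
    return pd.DataFrame(rows)
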