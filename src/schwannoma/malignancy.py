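"""Two-hit malignant transformation inside a growing benign schwannoma.

Within an expanding benign tumour, single cells may lose both copies of a
hypothetical tumour suppressor TSX (not on chromosome 22): by point mutation
with probability n_TSX * u per division, or by LOH with probability p_LOH per
division.  With no cell death, growth confined to the tumour edge and
haplosufficient single-hit clones (fitness s = 0), the single-hit
subpopulations track the total cell count N exactly and all explicit time
dependence cancels:

    N_l = n_TSX u N,      N_m = p_LOH N,

    P(malignancy) = 1 - exp( -(1/2) n_TSX u (n_TSX u + 2 p_LOH) N ).

The risk is therefore simply proportional to tumour volume in the rare-event
regime, with cells counted as N = f_SC V / V_SC.  Inverting the relation at
the observed ~0.2% lifetime risk of malignant transformation for a typical
40 mm (1e10-cell) tumour yields the TSX target-size estimate n_TSX ~ 1245.

The model also predicts the fraction of malignant tumours showing "excess"
LOH at the TSX locus, f = 2 p_LOH / (2 p_LOH + n_TSX u) ~ 22%, independent of
tumour size (a consequence of neutrality) and invertible for n_TSX from a
future LOH survey.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.integrate import quad

__all__ = [
    "MalignancyParams",
    "TumourGeometry",
    "volume_from_diameter",
    "diameter_from_volume",
    "cell_count",
    "general_subclone_solution",
    "malignancy_risk",
    "risk_vs_volume",
    "estimate_n_tsx",
    "excess_loh_fraction",
    "n_tsx_from_excess_loh",
    "probability_no_loh_detected",
]

DEFAULT_LIFETIME_P = 0.002     # observed lifetime risk of malignant transformation
DEFAULT_N_CELLS_40MM = 1e10    # Schwann cells in a typical 40 mm tumour
DEFAULT_F_SC = 0.5             # Schwann-cell fraction of the tumour (range 0.3-0.5)
DEFAULT_V_SC = 1.6e-6          # Schwann cell volume, mm^3
EXCESS_LOH_VALIDITY_N = 1e12   # cells; beyond this the size-free limit degrades


@dataclass(frozen=True)
class MalignancyParams:
    """Parameters of the two-hit malignant-transformation model."""

    n_tsx: float = 1245.0
    u: float = 4.48e-10
    p_loh: float = 7.97e-8
    f_sc: float = DEFAULT_F_SC
    v_sc: float = DEFAULT_V_SC
    s_l: float = 0.0
    s_m: float = 0.0
    lifetime_p: float = DEFAULT_LIFETIME_P

    def __post_init__(self):
        if not 0.0 < self.f_sc <= 1.0:
            raise ValueError("f_sc must lie in (0, 1]")
        if self.v_sc <= 0:
            raise ValueError("v_sc must be positive")
        for name in ("n_tsx", "u", "p_loh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def with_(self, **kwargs) -> "MalignancyParams":
        return replace(self, **kwargs)


def volume_from_diameter(d_mm: "float | np.ndarray") -> "float | np.ndarray":
    """Spherical convention V = pi d^3 / 6 (mm^3)."""
    return math.pi / 6.0 * np.asarray(d_mm, dtype=float) ** 3


def diameter_from_volume(v_mm3: "float | np.ndarray") -> "float | np.ndarray":
    return (6.0 * np.asarray(v_mm3, dtype=float) / math.pi) ** (1.0 / 3.0)


def cell_count(
    volume_mm3: "float | np.ndarray", f_sc: float = DEFAULT_F_SC, v_sc: float = DEFAULT_V_SC
) -> "float | np.ndarray":
    """Schwann cells in a tumour of the given volume: N = f_SC V / V_SC."""
    return f_sc * np.asarray(volume_mm3, dtype=float) / v_sc


@dataclass(frozen=True)
class TumourGeometry:
    """Tumour size bookkeeping under the spherical convention."""

    diameter_mm: float
    f_sc: float = DEFAULT_F_SC
    v_sc: float = DEFAULT_V_SC

    @property
    def volume_mm3(self) -> float:
        return float(volume_from_diameter(self.diameter_mm))

    @property
    def n_cells(self) -> float:
        return float(cell_count(self.volume_mm3, self.f_sc, self.v_sc))


def general_subclone_solution(
    g: Callable[[float], float], params: MalignancyParams, t: float
) -> tuple[float, float, float]:
    """Mean single-hit subclone sizes (N_k, N_l, N_m) at time t for growth
    rate g(t), allowing nonzero single-hit fitnesses.

    Evaluates the quadrature solution

        N_l(t) = n_TSX u N_k(t) + s_l e^{s_l t} \\int_0^t e^{-s_l t'}
                 n_TSX u N_k(t') dt'

    (and the analogue for N_m with p_LOH, s_m).  At s_l = s_m = 0 this
    reduces exactly to N_l = n_TSX u N_k, N_m = p_LOH N_k.
    """
    if g(0.0) != 0.0:
        raise ValueError("growth rate must satisfy g(0) = 0")

    def n_k(tt: float) -> float:
        val, _ = quad(g, 0.0, tt, limit=200)
        if val < 0:
            raise ValueError("negative cumulative growth; g must be nonnegative")
        return val

    N_k = n_k(t)

    def hit_clone(rate: float, s: float) -> float:
        base = rate * N_k
        if s == 0.0:
            return base
        integral, _ = quad(lambda tp: math.exp(-s * tp) * rate * n_k(tp), 0.0, t, limit=200)
        return base + s * math.exp(s * t) * integral

    N_l = hit_clone(params.n_tsx * params.u, params.s_l)
    N_m = hit_clone(params.p_loh, params.s_m)
    return N_k, N_l, N_m


def malignancy_risk(N: "float | np.ndarray", params: MalignancyParams) -> dict[str, np.ndarray]:
    """Spontaneous malignant-transformation probabilities at N tumour cells.

    Returns the with-LOH and without-LOH routes, their exact-independence
    combination, and the rare-event linearisation; (1 - P_total) equals
    (1 - P_with)(1 - P_without) exactly in the exponential forms.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("cell count must be nonnegative")
    nu, p = params.n_tsx * params.u, params.p_loh
    p_with = 1.0 - np.exp(-nu * p * N)
    p_without = 1.0 - np.exp(-0.5 * nu ** 2 * N)
    p_total = 1.0 - np.exp(-0.5 * nu * (nu + 2.0 * p) * N)
    p_linear = 0.5 * nu * (nu + 2.0 * p) * N
    return {
        "P_with_LOH": p_with,
        "P_without_LOH": p_without,
        "P_total": p_total,
        "P_total_linearised": p_linear,
    }


def risk_vs_volume(
    params: MalignancyParams,
    diameter_mm: "float | np.ndarray | None" = None,
    volume_mm3: "float | np.ndarray | None" = None,
) -> np.ndarray:
    """P(malignancy) for a tumour of the given diameter or volume."""
    if (diameter_mm is None) == (volume_mm3 is None):
        raise ValueError("give exactly one of diameter_mm or volume_mm3")
    if volume_mm3 is None:
        volume_mm3 = volume_from_diameter(diameter_mm)
    N = cell_count(volume_mm3, params.f_sc, params.v_sc)
    return malignancy_risk(N, params)["P_total"]


def estimate_n_tsx(
    P_lifetime: "float | np.ndarray",
    N: "float | np.ndarray",
    u: "float | np.ndarray",
    p_loh: "float | np.ndarray",
) -> "float | np.ndarray":
    """TSX target size from the lifetime risk: positive root of the quadratic

        P = (1/2) n u (n u + 2 p_LOH) N
        =>  n_TSX = (p_LOH / u) ( sqrt(1 + 2 P / (p_LOH^2 N)) - 1 ).
    """
    P = np.asarray(P_lifetime, dtype=float)
    if np.any(P < 0):
        raise ValueError("lifetime probability must be nonnegative")
    N, u, p = (np.asarray(x, dtype=float) for x in (N, u, p_loh))
    if np.any(N <= 0) or np.any(u <= 0) or np.any(p <= 0):
        raise ValueError("N, u and p_LOH must be positive")
    result = p / u * (np.sqrt(1.0 + 2.0 * P / (p ** 2 * N)) - 1.0)
    return float(result) if result.ndim == 0 else result


def excess_loh_fraction(params: MalignancyParams, N: float) -> dict[str, float]:
    """Fraction of malignant transformations that carry LOH at the TSX locus.

    The exact ratio P(malignancy with LOH)/P(malignancy) and its
    N-independent small-N limit 2 p_LOH / (2 p_LOH + n_TSX u).  The limit
    being size-free implies no association between excess LOH and tumour
    size under neutrality; it is accurate for N well below ~1e12 cells.
    """
    if N >= EXCESS_LOH_VALIDITY_N:
        warnings.warn(
            f"N = {N:.3g} is at or beyond the ~{EXCESS_LOH_VALIDITY_N:.0e}-cell "
            "validity bound of the size-free limit",
            stacklevel=2,
        )
    nu, p = params.n_tsx * params.u, params.p_loh
    risks = malignancy_risk(N, params)
    exact = float(risks["P_with_LOH"] / risks["P_total"]) if N > 0 else float("nan")
    limit = 2.0 * p / (2.0 * p + nu)
    return {"exact": exact, "limit": limit}


def n_tsx_from_excess_loh(f_loh_malignant: float, u: float, p_loh: float) -> float:
    """Invert the size-free excess-LOH fraction for the TSX target size."""
    if not 0.0 < f_loh_malignant < 1.0:
        raise ValueError("excess-LOH fraction must lie strictly in (0, 1)")
    return 2.0 * p_loh / u * (1.0 - f_loh_malignant) / f_loh_malignant


def probability_no_loh_detected(f_loh_malignant: float, n_samples: int) -> float:
    """Chance a survey of n malignant samples finds no excess LOH: (1-f)^n."""
    if not 0.0 <= f_loh_malignant <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    return (1.0 - f_loh_malignant) ** n_samples
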