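"""Three-hit, all-orders initiation model for sporadic vestibular schwannoma.

Schwann precursor cells start wild type and acquire, in any order, two hits to
NF2 (point mutation and/or loss of heterozygosity on 22q) plus a third hit to
either a hypothetical oncogene GFX or to SMARCB1 in cis with the mutant NF2
allele.  The mean sizes of the ten intermediate subpopulations follow a linear
ODE system dN/dt = M N; tumours of the three terminal subtypes emerge as
independent Poisson events fed by the pre-neoplastic states.

In the rare-disease regime each subtype probability is cubic in age:

    P1 ~ (1/2) N0 n_NF2 n_GFX r_LOH u^2 b^2 t^3      (NF2m + LOH + GFX)
    P2 ~ (1/4) N0 n_NF2^2 n_GFX u^3 b^3 t^3          (NF2 double mutant + GFX)
    P3 ~ (1/4) N0 n_NF2 n_SMARCB1 r_LOH u^2 b^2 t^3  (NF2m + LOH + SMARCB1m)

and their sum is A t^3, tying the model to cumulative-incidence data.

Wiring convention: the first hit to a gene uses the full rate; any subsequent
hit that must land on one specific chromosome copy of two (the second NF2
allele, the cis-constrained SMARCB1 hit, LOH removing the wild-type homologue,
or a post-LOH single-allele mutation) carries a factor 1/2; oncogene
activation always uses the full rate.  This reconstruction is pinned by an
exact symbolic path-enumeration check against the cubic prefactors above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "IncidenceModelParams",
    "SubtypeProbabilities",
    "STATES",
    "TRANSITIONS",
    "EMISSIONS",
    "build_transition_system",
    "solve_ode",
    "closed_form_probabilities",
    "aggregate_probabilities",
    "predicted_variant_frequencies",
]

# Fitted / anatomical defaults for the sporadic-VS incidence model.
DEFAULT_N0 = 456_000.0       # precursor Schwann cells on both vestibular nerves
DEFAULT_B = 25.5             # precursor divisions per cell per year
DEFAULT_U = 4.48e-10         # errors per base pair per division
DEFAULT_N_NF2 = 135.0        # sensitive sites on NF2
DEFAULT_N_SMARCB1 = 85.0     # sensitive sites on SMARCB1
DEFAULT_N_GFX = 2002.0       # effective sensitive sites on the third-hit oncogene
DEFAULT_R_LOH = 2.03e-6      # LOH events on 22q per cell per year


@dataclass(frozen=True)
class IncidenceModelParams:
    """Parameters of the three-hit initiation model.

    Rates are per cell: ``mu_gene = n_gene * u * b`` per year, ``r_loh`` per
    year.  ``A`` is the coefficient of the cubic cumulative-incidence law.
    """

    N0: float = DEFAULT_N0
    b: float = DEFAULT_B
    u: float = DEFAULT_U
    n_nf2: float = DEFAULT_N_NF2
    n_smarcb1: float = DEFAULT_N_SMARCB1
    n_gfx: float = DEFAULT_N_GFX
    r_loh: float = DEFAULT_R_LOH

    def __post_init__(self):
        for name in ("N0", "b", "u", "n_nf2", "n_smarcb1", "n_gfx", "r_loh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def mu(self, gene: str) -> float:
        n = {"NF2": self.n_nf2, "SMARCB1": self.n_smarcb1, "GFX": self.n_gfx}[gene]
        return n * self.u * self.b

    @property
    def mu_nf2(self) -> float:
        return self.n_nf2 * self.u * self.b

    @property
    def mu_smarcb1(self) -> float:
        return self.n_smarcb1 * self.u * self.b

    @property
    def mu_gfx(self) -> float:
        return self.n_gfx * self.u * self.b

    @property
    def p_loh(self) -> float:
        """LOH probability per division."""
        return self.r_loh / self.b

    @property
    def A(self) -> float:
        """Cubic coefficient of Pr(tumour, t) = A t^3, per year^3."""
        u, b = self.u, self.b
        return (
            0.25
            * self.N0
            * self.n_nf2
            * (self.n_gfx * (2.0 * self.r_loh + self.n_nf2 * u * b) + self.n_smarcb1 * self.r_loh)
            * u ** 2
            * b ** 2
        )

    def with_(self, **kwargs) -> "IncidenceModelParams":
        return replace(self, **kwargs)


# Intermediate genotypes between wild type and neoplasia.  Chromosome-copy
# bookkeeping: a = NF2+/-, b = LOH only, c = GFX mutant only, d = SMARCB1+/-,
# e = LOH+GFX, f = NF2+/- + GFX, g = NF2+/- + LOH, h = LOH + SMARCB1+/-,
# i = NF2+/- + SMARCB1+/- (cis), j = NF2-/-.
STATES: tuple[str, ...] = ("WT", "a", "b", "c", "d", "e", "f", "g", "h", "i", "j")

# (source, destination, coefficient, rate name); coefficient 1/2 marks hits
# constrained to one specific chromosome copy.
TRANSITIONS: tuple[tuple[str, str, float, str], ...] = (
    ("WT", "a", 1.0, "mu_nf2"),
    ("WT", "b", 1.0, "r_loh"),
    ("WT", "c", 1.0, "mu_gfx"),
    ("WT", "d", 1.0, "mu_smarcb1"),
    ("a", "f", 1.0, "mu_gfx"),
    ("a", "g", 0.5, "r_loh"),
    ("a", "i", 0.5, "mu_smarcb1"),
    ("a", "j", 0.5, "mu_nf2"),
    ("b", "e", 1.0, "mu_gfx"),
    ("b", "g", 0.5, "mu_nf2"),
    ("b", "h", 0.5, "mu_smarcb1"),
    ("c", "e", 1.0, "r_loh"),
    ("c", "f", 1.0, "mu_nf2"),
    ("d", "h", 0.5, "r_loh"),
    ("d", "i", 0.5, "mu_nf2"),
)

# Terminal emissions feeding the three subtype probabilities.
EMISSIONS: dict[int, tuple[tuple[str, float, str], ...]] = {
    1: (("e", 0.5, "mu_nf2"), ("f", 0.5, "r_loh"), ("g", 1.0, "mu_gfx")),
    2: (("f", 0.5, "mu_nf2"), ("j", 1.0, "mu_gfx")),
    3: (("g", 0.5, "mu_smarcb1"), ("h", 0.5, "mu_nf2"), ("i", 0.5, "r_loh")),
}


@dataclass(frozen=True)
class SubtypeProbabilities:
    """Probabilities of the three terminal subtypes by age t (years)."""

    t: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray


def build_transition_system(params: IncidenceModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Rate matrix M (11x11, proper generator with negative diagonals) and
    emission-rate matrix E (3x11) of the mean-field system."""
    idx = {s: i for i, s in enumerate(STATES)}
    M = np.zeros((len(STATES), len(STATES)))
    for src, dst, coeff, rate in TRANSITIONS:
        r = coeff * getattr(params, rate)
        M[idx[dst], idx[src]] += r
        M[idx[src], idx[src]] -= r
    E = np.zeros((3, len(STATES)))
    for end, terms in EMISSIONS.items():
        for state, coeff, rate in terms:
            r = coeff * getattr(params, rate)
            E[end - 1, idx[state]] += r
            # emission also debits the source subpopulation
            M[idx[state], idx[state]] -= r
    return M, E


def solve_ode(
    params: IncidenceModelParams,
    ages: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-18,
) -> pd.DataFrame:
    """Numerically integrate the mean-field system over an age grid.

    Returns a DataFrame indexed by age with the eleven state populations and
    the subtype probabilities P1, P2, P3.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.ndim != 1 or np.any(ages < 0) or np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be a 1-D nonnegative strictly increasing grid")
    M, E = build_transition_system(params)

    def rhs(_t, y):
        N = y[: len(STATES)]
        P = y[len(STATES) :]
        dN = M @ N
        dP = (E @ N) * (1.0 - P)
        return np.concatenate([dN, dP])

    y0 = np.zeros(len(STATES) + 3)
    y0[0] = params.N0
    t0, t1 = 0.0, float(ages[-1]) if ages[-1] > 0 else 1.0
    t_eval = ages if ages[0] == 0.0 else np.concatenate([[0.0], ages])
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    keep = np.isin(sol.t, ages)
    data = {s: sol.y[i, keep] for i, s in enumerate(STATES)}
    for j in range(3):
        data[f"P{j + 1}"] = sol.y[len(STATES) + j, keep]
    return pd.DataFrame(data, index=pd.Index(sol.t[keep], name="age"))


def closed_form_probabilities(
    params: IncidenceModelParams, t: "float | np.ndarray"
) -> SubtypeProbabilities:
    """Cubic small-probability solutions for the three subtypes."""
    t = np.asarray(t, dtype=float)
    u, b, r = params.u, params.b, params.r_loh
    common = params.N0 * params.n_nf2 * u ** 2 * b ** 2 * t ** 3
    P1 = 0.5 * common * params.n_gfx * r
    P2 = 0.25 * params.N0 * params.n_nf2 ** 2 * params.n_gfx * u ** 3 * b ** 3 * t ** 3
    P3 = 0.25 * common * params.n_smarcb1 * r
    if np.any(P1 + P2 + P3 > 0.1):
        warnings.warn(
            "closed-form cubic solutions assume the rare-disease regime; "
            "total probability exceeds 0.1",
            stacklevel=2,
        )
    return SubtypeProbabilities(t=t, P1=P1, P2=P2, P3=P3)


def aggregate_probabilities(
    subtypes: SubtypeProbabilities, flag_tolerance: float = 1e-6
) -> dict[str, "np.ndarray | bool"]:
    """Tumour / LOH / SMARCB1 probabilities, exact-independence and small-P.

    The three subtypes arise as independent (apparently polyclonal) events, so
    exactly Pr(tumour) = 1 - (1-P1)(1-P2)(1-P3); the small-P approximation is
    the plain sum.  A flag is raised when the two differ materially.
    """
    P1, P2, P3 = subtypes.P1, subtypes.P2, subtypes.P3
    exact_tumour = 1.0 - (1.0 - P1) * (1.0 - P2) * (1.0 - P3)
    exact_loh = 1.0 - (1.0 - P1) * (1.0 - P3)
    approx_tumour = P1 + P2 + P3
    approx_loh = P1 + P3
    flag = bool(
        np.any(np.abs(exact_tumour - approx_tumour) > flag_tolerance)
        or np.any(np.abs(exact_loh - approx_loh) > flag_tolerance)
    )
    return {
        "Pr_tumour": exact_tumour,
        "Pr_tumour_approx": approx_tumour,
        "Pr_LOH_tumour": exact_loh,
        "Pr_LOH_tumour_approx": approx_loh,
        "Pr_SMARCB1_tumour": P3,
        "approximation_flag": flag,
    }


def predicted_variant_frequencies(params: IncidenceModelParams) -> dict[str, float]:
    """Age-independent predicted fractions of tumours with LOH / SMARCB1 hits.

    f_LOH = (P1+P3)/(P1+P2+P3) and f_SMARCB1 = P3/(P1+P2+P3); the cubic time
    dependence cancels, leaving ratios of the rate combinations only.
    """
    r, ub = params.r_loh, params.u * params.b
    denom = 2.0 * params.n_gfx * r + params.n_smarcb1 * r + params.n_gfx * params.n_nf2 * ub
    if denom <= 0:
        raise ValueError("all rates are zero; variant frequencies undefined")
    f_loh = (2.0 * params.n_gfx * r + params.n_smarcb1 * r) / denom
    f_smarcb1 = params.n_smarcb1 * r / denom
    return {"f_LOH": f_loh, "f_SMARCB1": f_smarcb1}
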