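"""End-to-end plug-in chain producing the headline parameter estimates.

Runs the full deterministic estimation chain from the raw variant counts
(17/23 LOH-positive, 0/32 SMARCB1-positive), the anatomical precursor count,
the division rate and the fitted cubic incidence coefficient, through to the
malignancy and radiation quantities, and optionally the bootstrap confidence
intervals.  Everything is recomputed at call time; nothing is looked up.
"""

from __future__ import annotations

from typing import Any

from .inference import (
    REFERENCE_A,
    VestibularSchwannomaModel,
)
from .malignancy import (
    DEFAULT_LIFETIME_P,
    DEFAULT_N_CELLS_40MM,
    MalignancyParams,
    estimate_n_tsx,
    excess_loh_fraction,
    malignancy_risk,
    probability_no_loh_detected,
)
from .radiation import INDEL_SENSITIVE_FRACTION

__all__ = ["plug_in_chain", "reproduce_paper"]

# Anatomical inputs for the precursor pool: two vestibular nerves of ~19,000
# axons, a ~6 mm origin zone, ~0.5 mm Schwann-cell spacing.
N_NERVES = 2
AXONS_PER_NERVE = 19_000
ORIGIN_ZONE_MM = 6.0
SC_SPACING_MM = 0.5

LOH_COUNTS = (17, 23)
SMARCB1_COUNTS = (0, 32)
LOH_SURVEY_SAMPLES = 15


def precursor_population() -> float:
    """N0 = 2 x 19,000 x (6 / 0.5) = 456,000 precursor Schwann cells."""
    return N_NERVES * AXONS_PER_NERVE * (ORIGIN_ZONE_MM / SC_SPACING_MM)


def plug_in_chain(
    A: float = REFERENCE_A,
    n_boot: int = 0,
    seed: int = 0,
    scheme: str = "indicator",
) -> dict[str, Any]:
    """Deterministic estimation chain plus downstream model quantities."""
    N0 = precursor_population()
    model = VestibularSchwannomaModel.from_counts(
        loh=LOH_COUNTS, smarcb1=SMARCB1_COUNTS, A=A, N0=N0
    )
    res = model.fit(n_boot=n_boot, seed=seed, scheme=scheme)

    mal = MalignancyParams(n_tsx=res.n_tsx, u=res.u, p_loh=res.p_loh)
    m_tsx = INDEL_SENSITIVE_FRACTION * res.n_tsx
    risks = malignancy_risk(DEFAULT_N_CELLS_40MM, mal)
    loh_frac = excess_loh_fraction(mal, DEFAULT_N_CELLS_40MM)
    f_rounded = round(loh_frac["limit"], 2)
    p_none = probability_no_loh_detected(f_rounded, LOH_SURVEY_SAMPLES)

    out: dict[str, Any] = {
        "N0": N0,
        "A": res.A,
        "f_loh": res.f_loh,
        "f_smarcb1": res.f_smarcb1,
        "n_gfx": res.n_gfx,
        "u": res.u,
        "r_loh": res.r_loh,
        "p_loh": res.p_loh,
        "n_tsx": res.n_tsx,
        "m_tsx": m_tsx,
        "P_malignancy_40mm": float(risks["P_total"]),
        "excess_loh_fraction": loh_frac["limit"],
        "p_no_loh_in_survey": p_none,
        "results": res,
    }
    return out


# Printed reference values for the comparison table (printed-value column of
# the reproduction report; never fed back into any computation).
_PRINTED = {
    "N0": (456_000.0, "cells", 0.001),
    "f_loh": (0.73, "", 0.01),
    "f_smarcb1": (0.015, "", 0.02),
    "n_gfx": (2002.0, "sites", 0.001),
    "u": (4.48e-10, "/bp/division", 0.01),
    "r_loh": (2.03e-6, "/yr", 0.01),
    "p_loh": (7.97e-8, "/division", 0.01),
    "n_tsx": (1245.0, "sites", 0.01),
    "m_tsx": (523.0, "sites", 0.01),
    "P_malignancy_40mm": (0.002, "", 0.05),
    "excess_loh_fraction": (0.22, "", 0.02),
    "p_no_loh_in_survey": (0.024, "", 0.02),
}


def reproduce_paper(
    seed: int = 1, n_boot: int = 20_000, skip_bootstrap: bool = False
) -> dict[str, Any]:
    """Recompute the headline estimates and compare to printed values.

    Returns the computed chain plus a ``comparison`` table (computed value,
    printed value, relative deviation, pass flag at the stated tolerance)
    and, unless skipped, the bootstrap confidence intervals.
    """
    chain = plug_in_chain(n_boot=0 if skip_bootstrap else n_boot, seed=seed)
    comparison = []
    for key, (printed, units, tol) in _PRINTED.items():
        computed = float(chain[key])
        rel = abs(computed - printed) / abs(printed)
        comparison.append(
            {
                "quantity": key,
                "computed": computed,
                "printed": printed,
                "units": units,
                "rel_deviation": rel,
                "tolerance": tol,
                "pass": bool(rel <= tol),
            }
        )
    chain["comparison"] = comparison
    res = chain["results"]
    if res.bootstrap is not None:
        chain["conf_int"] = {
            name: [d.ci_low, d.ci_high] for name, d in res.bootstrap.items()
        }
    return chain
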