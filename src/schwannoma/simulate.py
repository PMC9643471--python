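"""Synthetic data generators with known ground truth.

Every input the inference pipeline consumes can be generated here: a period
life table (Gompertz-Makeham survivorship), a birth cohort with cubic-in-age
schwannoma risk and competing mortality, variant-status count datasets, and
coding sequences with planted sensitive sites.  All generators are seeded and
bit-reproducible, and return their configuration alongside the data.

The cohort generator draws diagnosis ages from the hazard 3 A' t^2 (the
density of the cubic net risk A' t^3, with A' = A / attribution so that the
NF2-attributable corrected curve recovers A), death ages from the life table,
and records a diagnosis only when it precedes both death and the observation
cap.  Individuals dying before diagnosis still contribute person-time, which
matches the net-risk mortality correction used downstream.  A per-cell
stochastic simulation of the eleven-state initiation chain is also provided
as a slow cross-check of the mean-field cubic law.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .incidence import EMISSIONS, STATES, TRANSITIONS, IncidenceModelParams
from .inference import VariantCountData
from .targets import CodingSequence, GeneTargetProfile, IndelLengthDistribution, profile_gene

__all__ = [
    "generate_life_table",
    "SyntheticCohort",
    "generate_cohort",
    "cumulative_incidence",
    "generate_variant_dataset",
    "generate_sequence",
    "simulate_cell_chain",
]


def generate_life_table(
    max_age: int = 100,
    makeham_rate: float = 5e-4,
    gompertz_scale: float = 5e-5,
    gompertz_shape: float = 0.09,
) -> pd.DataFrame:
    """Gompertz-Makeham survivorship table by integer age.

    Hazard h(t) = lambda + a e^{gamma t}; survivorship
    S(t) = exp(-lambda t - (a/gamma)(e^{gamma t} - 1)).  The defaults give
    survivorship to age 80 of roughly 0.46, in the range of modern national
    life tables.
    """
    ages = np.arange(max_age + 1, dtype=float)
    surv = np.exp(
        -makeham_rate * ages
        - gompertz_scale / gompertz_shape * (np.exp(gompertz_shape * ages) - 1.0)
    )
    return pd.DataFrame({"age": ages, "survivorship": surv})


@dataclass
class SyntheticCohort:
    """Per-person records of a simulated birth cohort plus its ground truth."""

    persons: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    @property
    def diagnosed(self) -> pd.DataFrame:
        return self.persons[self.persons["diagnosed"]]

    def cumulative_incidence(self, ages: np.ndarray) -> pd.DataFrame:
        return cumulative_incidence(self.persons, ages)


def _sample_death_ages(
    life_table: pd.DataFrame, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sampling of death ages from a survivorship table."""
    ages = life_table["age"].to_numpy(dtype=float)
    surv = life_table["survivorship"].to_numpy(dtype=float)
    if surv[-1] >= 1.0:
        return np.full(n, np.inf)  # immortal table: no competing deaths
    u = rng.uniform(surv[-1], 1.0, size=n)  # condition on death within the table
    # survivorship is nonincreasing; interpolate age as a function of S
    return np.interp(u, surv[::-1], ages[::-1])


def generate_cohort(
    a_true: float = 2.26e-11,
    n_persons: int = 1_000_000,
    life_table: pd.DataFrame | None = None,
    attribution: float = 0.85,
    f_loh: float = 0.73,
    f_smarcb1: float = 0.015,
    age_cap: float = 100.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Simulate a birth cohort with cubic schwannoma risk and mortality.

    ``a_true`` is the cubic coefficient of the *NF2-attributable* net risk;
    all-cause VS diagnoses are drawn with coefficient a_true/attribution and
    each diagnosed tumour gets Bernoulli LOH / SMARCB1 status flags, so the
    full pipeline (crude incidence -> mortality correction -> truncation ->
    attribution rescale -> cubic fit) recovers ``a_true``.
    """
    if a_true < 0:
        raise ValueError("a_true must be nonnegative")
    rng = np.random.default_rng(seed)
    if life_table is None:
        life_table = generate_life_table(max_age=int(np.ceil(age_cap)))
    a_all = a_true / attribution
    # net cumulative hazard Lambda(t) = a_all t^3 -> t = (E/a_all)^(1/3), E ~ Exp(1)
    if a_all > 0:
        dx_age = (rng.exponential(1.0, size=n_persons) / a_all) ** (1.0 / 3.0)
    else:
        dx_age = np.full(n_persons, np.inf)
    death_age = _sample_death_ages(life_table, n_persons, rng)
    diagnosed = (dx_age < death_age) & (dx_age <= age_cap)
    observed_age = np.where(diagnosed, dx_age, np.minimum(death_age, age_cap))
    loh = np.zeros(n_persons, dtype=bool)
    smarcb1 = np.zeros(n_persons, dtype=bool)
    n_dx = int(diagnosed.sum())
    loh[diagnosed] = rng.uniform(size=n_dx) < f_loh
    smarcb1[diagnosed] = rng.uniform(size=n_dx) < f_smarcb1
    persons = pd.DataFrame(
        {
            "age": observed_age,
            "death_age": death_age,
            "diagnosed": diagnosed,
            "loh": loh,
            "smarcb1": smarcb1,
        }
    )
    config = {
        "a_true": a_true,
        "n_persons": n_persons,
        "attribution": attribution,
        "f_loh": f_loh,
        "f_smarcb1": f_smarcb1,
        "age_cap": age_cap,
        "seed": seed,
    }
    return SyntheticCohort(persons=persons, config=config)


def cumulative_incidence(persons: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Crude cumulative incidence by age: diagnoses so far / cohort size."""
    ages = np.asarray(ages, dtype=float)
    dx = np.sort(persons.loc[persons["diagnosed"], "age"].to_numpy())
    counts = np.searchsorted(dx, ages, side="right")
    return pd.DataFrame({"age": ages, "cum_incidence": counts / len(persons)})


def generate_variant_dataset(
    f_true: float, n: int, seed: int = 0, label: str = "variant"
) -> VariantCountData:
    """k ~ Binomial(n, f_true) positives; smoothing is applied downstream."""
    if not 0.0 <= f_true <= 1.0:
        raise ValueError("f_true must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n, f_true))
    return VariantCountData(label=label, k_positive=k, n_total=n)


def generate_sequence(
    n_codons: int = 20,
    planted_sensitive: int = 5,
    seed: int = 0,
    dist: IndelLengthDistribution | None = None,
) -> tuple[CodingSequence, GeneTargetProfile]:
    """Coding sequence with a planted substitution-sensitive count.

    The ORF is ATG, then ``planted_sensitive`` TAC codons (each one
    substitution away from both TAA and TAG, contributing exactly 2 to the
    raw multiplicity) shuffled among inert GCC codons (two or more
    substitutions from any stop), then a TAA stop.  The returned expected
    profile carries the analytic raw count 2 x planted; the deletion profile
    is computed mechanistically and should be certified against a
    brute-force oracle before use as a fixture.
    """
    if planted_sensitive < 0 or planted_sensitive > n_codons:
        raise ValueError("planted count must lie in [0, n_codons]")
    rng = np.random.default_rng(seed)
    body = ["TAC"] * planted_sensitive + ["GCC"] * (n_codons - planted_sensitive)
    rng.shuffle(body)
    bases = "ATG" + "".join(body) + "TAA"
    seq = CodingSequence(
        identifier=f"synthetic-{seed}", bases=bases, has_terminal_stop=True
    )
    profile = profile_gene(seq, dist=dist, cds_mode="annotated")
    expected_raw = 2 * planted_sensitive
    if profile.raw_substitution_multiplicity != expected_raw:
        raise AssertionError(
            "planted substitution count not realised; planting infeasible"
        )
    return seq, profile


def simulate_cell_chain(
    params: IncidenceModelParams,
    t_max: float,
    n_cells: int,
    seed: int = 0,
) -> dict[int, int]:
    """Stochastic per-cell simulation of the eleven-state initiation chain.

    Each of ``n_cells`` independent cells walks the continuous-time Markov
    chain of the initiation graph (transitions plus terminal emissions) up to
    time ``t_max``.  Returns the number of cells absorbed in each end node
    {1, 2, 3}.  A slow cross-check of the mean-field cubic law: with inflated
    rates, counts/n_cells * N0 should match the closed-form P_j.
    """
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(STATES)}
    n_states = len(STATES)
    # per-state outgoing channels: (rate, destination) with end nodes as
    # negative destinations -1, -2, -3
    channels: list[list[tuple[float, int]]] = [[] for _ in range(n_states)]
    for src, dst, coeff, rate in TRANSITIONS:
        channels[idx[src]].append((coeff * getattr(params, rate), idx[dst]))
    for end, terms in EMISSIONS.items():
        for state, coeff, rate in terms:
            channels[idx[state]].append((coeff * getattr(params, rate), -end))
    out_rate = np.array([sum(r for r, _ in ch) for ch in channels])

    state = np.zeros(n_cells, dtype=int)  # all start wild type
    time = np.zeros(n_cells)
    absorbed = np.zeros(n_cells, dtype=int)  # 0 = none, 1..3 = end node
    active = np.ones(n_cells, dtype=bool)
    # at most 3 hops to absorption, but loop defensively
    for _ in range(n_states):
        if not active.any():
            break
        rates = out_rate[state]
        movable = active & (rates > 0)
        if not movable.any():
            break
        idx_mov = np.flatnonzero(movable)
        time[idx_mov] += rng.exponential(1.0 / rates[idx_mov])
        active[idx_mov[time[idx_mov] > t_max]] = False
        movers = idx_mov[active[idx_mov]]
        # vectorised categorical draw, grouped by current state
        u = rng.uniform(size=len(movers))
        for s in np.unique(state[movers]):
            ch = channels[s]
            cum = np.cumsum([r for r, _ in ch]) / out_rate[s]
            dests = np.array([d for _, d in ch])
            sel = movers[state[movers] == s]
            pick = np.minimum(np.searchsorted(cum, u[: len(sel)]), len(dests) - 1)
            chosen = dests[pick]
            u = u[len(sel) :]
            ended = chosen < 0
            absorbed[sel[ended]] = -chosen[ended]
            active[sel[ended]] = False
            state[sel[~ended]] = chosen[~ended]
    return {j: int(np.sum(absorbed == j)) for j in (1, 2, 3)}
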