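"""Parameter inference for the three-hit schwannoma initiation model.

The estimation chain combines three observables:

1. the fraction of tumours with loss of heterozygosity on 22q, ``f_LOH``,
   and the fraction carrying pathogenic SMARCB1 variants, ``f_SMARCB1``,
   both regularised by additive smoothing with pseudocount 1/2 so that a
   zero count does not make downstream estimates diverge;
2. the cumulative incidence of sporadic vestibular schwannoma by age,
   corrected for competing mortality with a period life table, truncated at
   80 years and rescaled by the 85% of cases attributable to somatic NF2
   loss, then fitted as Pr(tumour, t) = A t^3 by nonlinear least squares;
3. the sensitive-site counts n_NF2 and n_SMARCB1 from reference sequences.

Closed forms then give the oncogene target size

    n_GFX = (1/2) n_SMARCB1 (f_LOH - f_SMARCB1) / f_SMARCB1

and the LOH rate r_LOH = [(f_LOH - f_SMARCB1)/(1 - f_LOH)] (1/2) n_NF2 u b,
which is proportional to the per-base error rate u.  Substituting both into
the cubic coefficient A makes A proportional to u^3, so u is recovered as a
unique positive cube root.  Uncertainty is propagated by bootstrap resampling
of the two small variant-count datasets (the incidence fit contributes
negligibly), with percentile 95% intervals and modal point estimates.

The chain is exposed both as plain functions and as a Model/Results pair
(`VestibularSchwannomaModel` / `VestibularSchwannomaResults`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .incidence import (
    DEFAULT_B,
    DEFAULT_N0,
    DEFAULT_N_NF2,
    DEFAULT_N_SMARCB1,
    IncidenceModelParams,
)
from .malignancy import DEFAULT_LIFETIME_P, DEFAULT_N_CELLS_40MM, estimate_n_tsx

__all__ = [
    "VariantCountData",
    "FitResult",
    "BootstrapDistribution",
    "smooth_frequency",
    "estimate_n_gfx",
    "r_loh_multiplier",
    "estimate_r_loh",
    "mortality_correct",
    "fit_cubic",
    "solve_u_from_A",
    "bootstrap_parameters",
    "histogram_mode",
    "VestibularSchwannomaModel",
    "VestibularSchwannomaResults",
]

# Reference fit constants from the original incidence analysis (external
# data, not desk-reproducible); recorded for comparison only.
REFERENCE_A = 2.26e-11
REFERENCE_SIGMA_A = 2.95e-13
REFERENCE_R_SQUARED = 0.989

DEFAULT_TRUNCATION_AGE = 80.0
DEFAULT_ATTRIBUTION = 0.85


def smooth_frequency(k: int, n: int, alpha: float = 0.5) -> float:
    """Additively smoothed proportion (k + alpha) / (n + 2 alpha).

    With the default pseudocount alpha = 1/2 this is (k + 1/2)/(n + 1),
    strictly inside (0, 1) even for k = 0 or k = n.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    return (k + alpha) / (n + 2.0 * alpha)


@dataclass(frozen=True)
class VariantCountData:
    """k positives of n tumours for a binary variant status."""

    label: str
    k_positive: int
    n_total: int
    alpha: float = 0.5

    def __post_init__(self):
        if self.n_total < 1:
            raise ValueError("n_total must be positive")
        if not 0 <= self.k_positive <= self.n_total:
            raise ValueError("k_positive must lie in [0, n_total]")

    @property
    def f_smoothed(self) -> float:
        return smooth_frequency(self.k_positive, self.n_total, self.alpha)


def estimate_n_gfx(f_loh: float, f_smarcb1: float, n_smarcb1: float) -> float:
    """Oncogene target size from the two smoothed variant frequencies."""
    if f_smarcb1 <= 0.0:
        raise ZeroDivisionError(
            "f_SMARCB1 = 0 makes n_GFX diverge; additive smoothing exists "
            "precisely to regularise a zero count before this step"
        )
    if f_loh < f_smarcb1:
        raise ValueError("f_LOH < f_SMARCB1 is inconsistent with the model")
    if not f_loh < 1.0:
        raise ValueError("f_LOH must be below 1")
    return 0.5 * n_smarcb1 * (f_loh - f_smarcb1) / f_smarcb1


def r_loh_multiplier(
    f_loh: float, f_smarcb1: float, n_nf2: float = DEFAULT_N_NF2, b: float = DEFAULT_B
) -> float:
    """Constant C (per year) such that r_LOH = C * u."""
    if not f_loh < 1.0:
        raise ValueError("f_LOH must be below 1")
    if f_loh < f_smarcb1:
        raise ValueError("f_LOH < f_SMARCB1 is inconsistent with the model")
    return (f_loh - f_smarcb1) / (1.0 - f_loh) * 0.5 * n_nf2 * b


def estimate_r_loh(
    f_loh: float,
    f_smarcb1: float,
    n_nf2: float = DEFAULT_N_NF2,
    u: float = 4.48e-10,
    b: float = DEFAULT_B,
) -> float:
    """LOH rate on 22q per cell per year."""
    return r_loh_multiplier(f_loh, f_smarcb1, n_nf2, b) * u


def mortality_correct(
    incidence: pd.DataFrame,
    life_table: pd.DataFrame,
    truncation_age: float = DEFAULT_TRUNCATION_AGE,
    attribution: float = DEFAULT_ATTRIBUTION,
) -> pd.DataFrame:
    """Net-risk mortality correction of a cumulative-incidence curve.

    Each age-specific incidence increment is divided by the survivorship at
    the midpoint of its interval (the population actually at risk), then the
    increments are re-accumulated; the curve is truncated at
    ``truncation_age`` and rescaled by the ``attribution`` fraction of cases
    attributable to somatic NF2 loss, in that order.

    ``incidence`` needs columns ``age`` and ``cum_incidence``; ``life_table``
    needs ``age`` and ``survivorship`` (monotone nonincreasing in [0, 1]).
    """
    inc = incidence.sort_values("age").reset_index(drop=True)
    lt = life_table.sort_values("age")
    if inc["age"].max() > lt["age"].max():
        raise ValueError("life table does not cover all ages in the incidence data")
    ages = inc["age"].to_numpy(dtype=float)
    cum = inc["cum_incidence"].to_numpy(dtype=float)
    increments = np.diff(cum, prepend=0.0)
    midpoints = 0.5 * (np.concatenate([[0.0], ages[:-1]]) + ages)
    surv = np.interp(
        midpoints, lt["age"].to_numpy(dtype=float), lt["survivorship"].to_numpy(dtype=float)
    )
    if np.any(surv <= 0):
        raise ValueError("zero survivorship within the incidence age range")
    corrected = np.cumsum(increments / surv)
    out = pd.DataFrame({"age": ages, "cum_incidence": corrected})
    out = out[out["age"] <= truncation_age].reset_index(drop=True)
    out["cum_incidence"] *= attribution
    return out


@dataclass(frozen=True)
class FitResult:
    """Result of the cubic incidence fit and downstream inversions."""

    A: float
    stderr_A: float
    r_squared: float
    u: float | None = None
    r_loh: float | None = None
    n_gfx: float | None = None


def fit_cubic(corrected: pd.DataFrame) -> FitResult:
    """Least-squares fit of Pr(tumour, t) = A t^3.

    The standard error of A comes from the curvature of the squared-error
    surface (the covariance returned by the nonlinear fit); R^2 is reported
    against the mean of the corrected incidences.
    """
    t = corrected["age"].to_numpy(dtype=float)
    y = corrected["cum_incidence"].to_numpy(dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 age bins to fit")
    if np.all(t == 0):
        raise ValueError("degenerate data: all ages zero")
    popt, pcov = curve_fit(lambda tt, A: A * tt ** 3, t, y, p0=[1e-11])
    A = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0]))
    resid = y - A * t ** 3
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return FitResult(A=A, stderr_A=stderr, r_squared=r2)


def _cubic_coefficient_constant(
    f_loh: float,
    f_smarcb1: float,
    N0: float,
    b: float,
    n_nf2: float,
    n_smarcb1: float,
) -> float:
    """K such that A = K u^3 once r_LOH = C u and n_GFX are substituted."""
    n_gfx = estimate_n_gfx(f_loh, f_smarcb1, n_smarcb1)
    C = r_loh_multiplier(f_loh, f_smarcb1, n_nf2, b)
    return 0.25 * N0 * n_nf2 * (n_gfx * (2.0 * C + n_nf2 * b) + n_smarcb1 * C) * b ** 2


def solve_u_from_A(
    A: float,
    N0: float = DEFAULT_N0,
    b: float = DEFAULT_B,
    n_nf2: float = DEFAULT_N_NF2,
    n_smarcb1: float = DEFAULT_N_SMARCB1,
    f_loh: float = 17.5 / 24.0,
    f_smarcb1: float = 0.5 / 33.0,
) -> float:
    """Invert the cubic coefficient relation for the per-base error rate u.

    Substituting r_LOH = C u and the closed-form n_GFX into the expression
    for A collapses it to A = K u^3 with K > 0, so u = (A/K)^(1/3) is the
    unique real positive root.
    """
    if A <= 0:
        raise ValueError("A must be positive")
    K = _cubic_coefficient_constant(f_loh, f_smarcb1, N0, b, n_nf2, n_smarcb1)
    return (A / K) ** (1.0 / 3.0)


def histogram_mode(values: np.ndarray) -> float:
    """Modal estimate: centre of the fullest Freedman-Diaconis histogram bin."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise ValueError("no values")
    if len(values) < 4 or np.ptp(values) == 0.0:
        return float(np.median(values))
    counts, edges = np.histogram(values, bins="fd")
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


@dataclass(frozen=True)
class BootstrapDistribution:
    """Percentile bootstrap distribution of one parameter."""

    name: str
    values: np.ndarray
    point: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int
    excluded_fraction: float = 0.0


def _resample_frequencies(
    data: VariantCountData, rng: np.random.Generator, n_reps: int, scheme: str
) -> np.ndarray:
    """Bootstrap replicates of the smoothed frequency for one count dataset."""
    k, n, alpha = data.k_positive, data.n_total, data.alpha
    if scheme == "indicator":
        # resample the n observed Bernoulli indicators, then re-smooth:
        # k* ~ Binomial(n, k/n), f* = (k* + alpha)/(n + 2 alpha) > 0 always
        k_star = rng.binomial(n, k / n, size=n_reps)
        return (k_star + alpha) / (n + 2.0 * alpha)
    if scheme == "pseudocount":
        # treat the regularised dataset (n indicators plus one half-weight
        # pseudo-observation) as the resampling population of n+1 items;
        # can draw f* = 0 replicates, excluded downstream
        values = np.concatenate([np.ones(k), np.zeros(n - k), [alpha]])
        draws = rng.integers(0, n + 1, size=(n_reps, n + 1))
        return values[draws].sum(axis=1) / (n + 1.0)
    raise ValueError(f"unknown bootstrap scheme {scheme!r}")


def bootstrap_parameters(
    loh: VariantCountData,
    smarcb1: VariantCountData,
    A: float = REFERENCE_A,
    n_reps: int = 20_000,
    seed: int = 0,
    scheme: str = "indicator",
    N0: float = DEFAULT_N0,
    b: float = DEFAULT_B,
    n_nf2: float = DEFAULT_N_NF2,
    n_smarcb1: float = DEFAULT_N_SMARCB1,
    sigma_A: float | None = None,
    lifetime_p: float = DEFAULT_LIFETIME_P,
    n_cells: float = DEFAULT_N_CELLS_40MM,
) -> dict[str, BootstrapDistribution]:
    """Bootstrap distributions for n_GFX, u, r_LOH and n_TSX.

    Each replicate resamples both variant datasets, re-applies additive
    smoothing, and re-runs the closed-form chain (n_GFX, the u inversion with
    A held fixed, r_LOH, p_LOH, and the malignancy target-size inversion for
    n_TSX).  Replicates with model-inconsistent draws (f_LOH <= f_SMARCB1 or
    f_SMARCB1 = 0, possible under the 'pseudocount' scheme) are excluded and
    the exclusion fraction reported.  Set ``sigma_A`` to additionally draw A
    from a normal distribution as a sensitivity analysis.
    """
    if seed is None:
        raise ValueError("seed is mandatory for a reproducible bootstrap")
    rng = np.random.default_rng(seed)
    fL = _resample_frequencies(loh, rng, n_reps, scheme)
    fS = _resample_frequencies(smarcb1, rng, n_reps, scheme)
    A_draws = np.full(n_reps, A) if sigma_A is None else rng.normal(A, sigma_A, size=n_reps)

    valid = (fS > 0.0) & (fL > fS) & (fL < 1.0) & (A_draws > 0.0)
    excluded = 1.0 - valid.mean()
    fL, fS, A_v = fL[valid], fS[valid], A_draws[valid]

    n_gfx = 0.5 * n_smarcb1 * (fL - fS) / fS
    C = (fL - fS) / (1.0 - fL) * 0.5 * n_nf2 * b
    K = 0.25 * N0 * n_nf2 * (n_gfx * (2.0 * C + n_nf2 * b) + n_smarcb1 * C) * b ** 2
    u = (A_v / K) ** (1.0 / 3.0)
    r_loh = C * u
    p_loh = r_loh / b
    n_tsx = estimate_n_tsx(lifetime_p, n_cells, u, p_loh)

    out = {}
    for name, vals in (("n_gfx", n_gfx), ("u", u), ("r_loh", r_loh), ("n_tsx", n_tsx)):
        lo, hi = np.percentile(vals, [2.5, 97.5])
        out[name] = BootstrapDistribution(
            name=name,
            values=vals,
            point=histogram_mode(vals),
            ci_low=float(lo),
            ci_high=float(hi),
            n_reps=n_reps,
            seed=seed,
            excluded_fraction=float(excluded),
        )
    return out


class VestibularSchwannomaModel:
    """Three-hit initiation model bound to its input data.

    Parameters
    ----------
    loh, smarcb1
        Variant-status counts (k positives of n tumours) for LOH on 22q and
        pathogenic SMARCB1 variants.
    incidence, life_table
        Cumulative incidence by age and a period life table (columns ``age``,
        ``cum_incidence`` / ``survivorship``).  When omitted, a fixed cubic
        coefficient ``A`` must be supplied instead.
    A
        Cubic incidence coefficient to use when no incidence data is given.

    Examples
    --------
    >>> model = VestibularSchwannomaModel.from_counts(loh=(17, 23), smarcb1=(0, 32))
    >>> res = model.fit()
    >>> round(res.n_gfx)
    2003
    """

    def __init__(
        self,
        loh: VariantCountData,
        smarcb1: VariantCountData,
        incidence: pd.DataFrame | None = None,
        life_table: pd.DataFrame | None = None,
        A: float | None = None,
        N0: float = DEFAULT_N0,
        b: float = DEFAULT_B,
        n_nf2: float = DEFAULT_N_NF2,
        n_smarcb1: float = DEFAULT_N_SMARCB1,
        truncation_age: float = DEFAULT_TRUNCATION_AGE,
        attribution: float = DEFAULT_ATTRIBUTION,
        lifetime_p: float = DEFAULT_LIFETIME_P,
        n_cells: float = DEFAULT_N_CELLS_40MM,
    ):
        if incidence is None and A is None:
            raise ValueError("provide either incidence data (with a life table) or a fixed A")
        if incidence is not None and life_table is None:
            raise ValueError("incidence data requires a life table for mortality correction")
        self.loh = loh
        self.smarcb1 = smarcb1
        self.incidence = incidence
        self.life_table = life_table
        self.A_fixed = A
        self.N0 = N0
        self.b = b
        self.n_nf2 = n_nf2
        self.n_smarcb1 = n_smarcb1
        self.truncation_age = truncation_age
        self.attribution = attribution
        self.lifetime_p = lifetime_p
        self.n_cells = n_cells

    @classmethod
    def from_counts(
        cls,
        loh: tuple[int, int] = (17, 23),
        smarcb1: tuple[int, int] = (0, 32),
        A: float = REFERENCE_A,
        **kwargs,
    ) -> "VestibularSchwannomaModel":
        """Build the model from bare (k, n) counts and a fixed A."""
        return cls(
            loh=VariantCountData("LOH-22q", *loh),
            smarcb1=VariantCountData("SMARCB1", *smarcb1),
            A=A,
            **kwargs,
        )

    @classmethod
    def from_dataframes(
        cls,
        counts: pd.DataFrame,
        incidence: pd.DataFrame,
        life_table: pd.DataFrame,
        **kwargs,
    ) -> "VestibularSchwannomaModel":
        """Build from a counts table (columns label, k, n) plus incidence data."""
        by_label = {
            str(row["label"]): VariantCountData(str(row["label"]), int(row["k"]), int(row["n"]))
            for _, row in counts.iterrows()
        }
        labels = {label.lower(): label for label in by_label}
        loh_key = next(l for l in labels if "loh" in l)
        sm_key = next(l for l in labels if "smarcb1" in l)
        return cls(
            loh=by_label[labels[loh_key]],
            smarcb1=by_label[labels[sm_key]],
            incidence=incidence,
            life_table=life_table,
            **kwargs,
        )

    def fit(
        self, n_boot: int = 0, seed: int | None = None, scheme: str = "indicator"
    ) -> "VestibularSchwannomaResults":
        """Run the full estimation chain; optionally bootstrap uncertainties."""
        if self.incidence is not None:
            corrected = mortality_correct(
                self.incidence, self.life_table, self.truncation_age, self.attribution
            )
            fit = fit_cubic(corrected)
            A, stderr_A, r2 = fit.A, fit.stderr_A, fit.r_squared
        else:
            A, stderr_A, r2 = float(self.A_fixed), float("nan"), float("nan")

        f_loh = self.loh.f_smoothed
        f_smarcb1 = self.smarcb1.f_smoothed
        n_gfx = estimate_n_gfx(f_loh, f_smarcb1, self.n_smarcb1)
        u = solve_u_from_A(A, self.N0, self.b, self.n_nf2, self.n_smarcb1, f_loh, f_smarcb1)
        r_loh = estimate_r_loh(f_loh, f_smarcb1, self.n_nf2, u, self.b)
        p_loh = r_loh / self.b
        n_tsx = estimate_n_tsx(self.lifetime_p, self.n_cells, u, p_loh)

        bootstrap = None
        if n_boot > 0:
            bootstrap = bootstrap_parameters(
                self.loh,
                self.smarcb1,
                A=A,
                n_reps=n_boot,
                seed=seed if seed is not None else 0,
                scheme=scheme,
                N0=self.N0,
                b=self.b,
                n_nf2=self.n_nf2,
                n_smarcb1=self.n_smarcb1,
                lifetime_p=self.lifetime_p,
                n_cells=self.n_cells,
            )
        return VestibularSchwannomaResults(
            model=self,
            A=A,
            stderr_A=stderr_A,
            r_squared=r2,
            f_loh=f_loh,
            f_smarcb1=f_smarcb1,
            n_gfx=n_gfx,
            u=u,
            r_loh=r_loh,
            p_loh=p_loh,
            n_tsx=n_tsx,
            bootstrap=bootstrap,
        )


@dataclass
class VestibularSchwannomaResults:
    """Fitted parameter estimates with optional bootstrap uncertainties."""

    model: VestibularSchwannomaModel
    A: float
    stderr_A: float
    r_squared: float
    f_loh: float
    f_smarcb1: float
    n_gfx: float
    u: float
    r_loh: float
    p_loh: float
    n_tsx: float
    bootstrap: dict[str, BootstrapDistribution] | None = None

    @property
    def params(self) -> dict[str, float]:
        return {
            "A": self.A,
            "f_loh": self.f_loh,
            "f_smarcb1": self.f_smarcb1,
            "n_gfx": self.n_gfx,
            "u": self.u,
            "r_loh": self.r_loh,
            "p_loh": self.p_loh,
            "n_tsx": self.n_tsx,
        }

    def incidence_params(self) -> IncidenceModelParams:
        """Parameters object for the forward incidence model."""
        m = self.model
        return IncidenceModelParams(
            N0=m.N0,
            b=m.b,
            u=self.u,
            n_nf2=m.n_nf2,
            n_smarcb1=m.n_smarcb1,
            n_gfx=self.n_gfx,
            r_loh=self.r_loh,
        )

    def conf_int(self) -> pd.DataFrame:
        """Bootstrap 95% percentile intervals (requires fit(n_boot > 0))."""
        if self.bootstrap is None:
            raise ValueError("no bootstrap was run; call fit(n_boot=..., seed=...)")
        rows = {
            name: {"point": d.point, "ci_low": d.ci_low, "ci_high": d.ci_high}
            for name, d in self.bootstrap.items()
        }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            "Vestibular schwannoma three-hit model: parameter estimates",
            "=" * 62,
            f"{'parameter':<28}{'estimate':>14}  {'95% CI':>18}",
            "-" * 62,
        ]

        def ci(name):
            if self.bootstrap and name in self.bootstrap:
                d = self.bootstrap[name]
                return f"[{d.ci_low:.3g}, {d.ci_high:.3g}]"
            return ""

        rows = [
            ("A (cubic coeff, /yr^3)", self.A, ""),
            ("f_LOH (smoothed)", self.f_loh, ""),
            ("f_SMARCB1 (smoothed)", self.f_smarcb1, ""),
            ("n_GFX (sites)", self.n_gfx, ci("n_gfx")),
            ("u (/bp/division)", self.u, ci("u")),
            ("r_LOH (/yr)", self.r_loh, ci("r_loh")),
            ("p_LOH (/division)", self.p_loh, ""),
            ("n_TSX (sites)", self.n_tsx, ci("n_tsx")),
        ]
        for name, value, interval in rows:
            lines.append(f"{name:<28}{value:>14.6g}  {interval:>18}")
        if not math.isnan(self.r_squared):
            lines.append("-" * 62)
            lines.append(f"cubic fit: sigma(A) = {self.stderr_A:.3g}, R^2 = {self.r_squared:.4f}")
        lines.append("=" * 62)
        return "\n".join(lines)
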