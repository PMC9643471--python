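# Methods

## The initiation model

Sporadic vestibular schwannoma is modelled as a three-hit process in a fixed
pool of N₀ Schwann precursor cells: two hits to *NF2* (nonsense mutation
and/or loss of heterozygosity on 22q) plus one of (a) activation of a
hypothetical oncogene *GFX* or (b) a pathogenic *SMARCB1* variant in cis
with the mutant *NF2* allele, removed together with the wild-type copies by
LOH.  Hits may occur in any order; each ordering is a path through a
directed graph of eleven genotypes ending in one of three neoplastic
subtypes (1: NF2-mutant + LOH + GFX; 2: NF2 double mutant + GFX; 3:
NF2-mutant + LOH + SMARCB1-mutant).  Mean subpopulation sizes follow the
linear system dN/dt = M·N (mean-field approximation: expectations, not the
full stochastic law), and subtype probabilities accumulate as independent
Poisson emissions from the penultimate states — independence justified by
the apparently polyclonal, multifocal growth of these tumours, which makes
subtypes non-exclusive events.

Wiring convention (validated exactly, see below): the first hit to a gene
uses the full per-cell rate (μ_gene = n_gene·u·b, or r_LOH); any later hit
constrained to one specific chromosome copy of two — the second *NF2*
allele, the cis *SMARCB1* hit, LOH that must remove the wild-type
homologue, a post-LOH single-allele mutation — carries a factor ½; oncogene
activation always uses the full μ_GFX.  *GFX* and *TSX* are taken to be off
chromosome 22.  Initiating mutations are assumed selectively neutral (no
exponential phase is seen in age-incidence), so no fitness parameters
appear in the initiation model.

In the rare-disease regime the subtype probabilities are cubic in age with
prefactors ½, ¼, ¼, and their sum is Pr(tumour, t) = A·t³.  Two independent
checks pin the graph: a symbolic enumeration of all ordered three-step
paths reproduces the cubic prefactors exactly (sympy, in the test suite),
and the numerically integrated ODE (LSODA, rtol 1e-10, atol 1e-18 — the
probabilities are O(1e-5)) agrees with the closed forms to better than 0.5%
over ages 0–100 at the default parameters.

## Target-size counting

A site is sensitive if altering it creates a premature stop codon
(TAA/TAG/TGA) on the longest open reading frame.  Substitution counting
enumerates, per internal codon, the distinct single-base changes reaching a
stop; the raw multiplicity is weighted by 1/3, the equal-rate (Jukes–Cantor)
assumption — transition/transversion-specific rates are deliberately not
modelled, as no schwannoma-specific substitution spectrum exists to fit
them.  The initiator ATG and the terminal stop are excluded (start loss is a
different mechanism; mutating an existing stop is not a nonsense gain).

Deletion counting removes [i, i+k) (0-based, half-open), re-reads the
sequence in the original frame, and counts the site if a codon overlapping
the junction — the codon containing position i, plus the following codon
when k is not a multiple of 3 — is a stop that was not a stop at that codon
index before.  Scanning the entire frameshifted tail would count nearly
every frameshift as sensitive; the junction-local rule matches the
site-local definition of sensitivity used throughout.  Two exclusions keep
the count a nonsense-gain count: deletions spanning the terminal stop, and
junction codons consisting entirely of the original terminal stop shifted
forward (an in-frame truncation, not a new stop).  Indel lengths follow a
truncated geometric law f(k) = A·q^|k| with q = 0.53 and k_max = 40 (tail
mass < 1e-9), symmetric in insertions and deletions; insertions cannot
create junction stops, so they contribute zero to the numerator of the
length average but full weight to its denominator.  The normalisation A
cancels.  The empirical shortcut m ≈ 0.74·l is provided as a cross-check.

Ambiguity codes are rejected outright so that counts are reproducible
integers.  Curated CDS records (GenBank/EMBL, join() locations honoured)
can bypass the ORF scan via `cds_mode="annotated"`.

Reference constants: n_NF2 = 135 and n_SMARCB1 = 85 are carried as the
authoritative downstream inputs.  Note an internal tension in their printed
provenance: the SMARCB1 arithmetic 143×⅓ + 37 = 85 checks out, but the
analogous NF2 line (251×⅓ + 44.27) evaluates to ≈ 127.9, not 135.  We use
135 and document rather than resolve the discrepancy; reproducing the raw
counts 251/143 requires the exact archived reference records and is out of
scope here.

## Parameter inference

Inputs and their provenance:

| parameter | default | meaning |
|-----------|---------|---------|
| N₀        | 456,000 | precursor cells: 2 nerves × 19,000 axons × (6 mm / 0.5 mm) |
| b         | 25.5 /yr | Schwann-cell division rate (7%/day proliferation) |
| α (pseudocount) | ½  | additive smoothing of variant proportions |
| A         | 2.26e-11 /yr³ | fitted cubic incidence coefficient |
| truncation age | 80 yr | old-age incidence plateau treated as artefact |
| attribution | 0.85 | fraction of VS with somatic NF2 loss |

The chain: smooth the counts (17/23 → f_LOH = 72.9%, 0/32 → f_SMARCB1 =
1.52%); n_GFX and r_LOH/u follow from the closed forms; substituting both
into A makes A = K·u³ with K > 0 collecting the known constants, so u is
the unique positive cube root.  With incidence data supplied, A is fitted
by nonlinear least squares on the mortality-corrected cumulative incidence
(increments divided by survivorship at interval midpoints, re-accumulated,
truncated at 80, rescaled by 0.85 — in that order), with the standard error
from the curvature of the squared-error surface.  The reference fit
constants A = 2.26e-11, σ(A) = 2.95e-13, R² = 0.989 derive from registry
incidence data that is not redistributable; they are recorded as constants
and the fixed-A entry point (`from_counts`) is the default.

Uncertainty is bootstrapped from the two count datasets (the A-fit
uncertainty is an order of magnitude smaller and held fixed by default; an
option propagates σ(A) as a normal draw).  Two resampling schemes are
implemented because the phrase "resampling regularised datasets" admits
two readings:

- `indicator` (default, well-posed): resample the n Bernoulli indicators
  with replacement, then re-apply smoothing — every replicate has f > 0;
- `pseudocount`: treat the regularised dataset as n+1 observations
  including the half-weight pseudocount and resample those; this can draw
  f = 0 replicates (excluded, with the exclusion fraction reported,
  ≈ (32/33)³³ ≈ 36% for the 0/32 dataset) and is the only reading we found
  that reproduces a bimodal n_GFX distribution.

Point estimates from the bootstrap are modal (centre of the fullest
Freedman–Diaconis histogram bin), matching the interpretation of the
plug-in values as modes; 95% intervals are the 2.5/97.5 percentiles.  A
replicate of n_TSX is computed from each (u, r_LOH) pair via the lifetime
malignancy-risk inversion.

## Malignant transformation

Inside a growing benign tumour, a second tumour suppressor ("TSX", not on
chromosome 22; single-oncogene and chr-22 alternatives predict near-certain
transformation and are ruled out) must lose both copies: by mutation with
probability n_TSX·u per division or LOH with probability p_LOH = r_LOH/b
per division, taken chromosome-independent for lack of better constraints.
With no cell death, growth at the tumour edge only, haplosufficient
single-hit clones (s_l = s_m = 0 default; the general-s quadrature solution
exists for sensitivity analysis and reduces continuously to the neutral
limit) and certain survival of the first malignant cell, all explicit time
dependence cancels and

P(malignancy) = 1 − exp(−½ n_TSX u (n_TSX u + 2 p_LOH) N),

linear in tumour volume in the rare-event regime.  Cells are counted as
N = f_SC·V/V_SC with f_SC = 0.5 (upper end of the observed 0.3–0.5
Schwann-cell fraction; most tumour cells are macrophages) and V_SC =
1.6e-6 mm³; tumours are treated as spheres (V = πd³/6 — the geometric
convention is a package choice, exposed as a parameter).  Inverting at the
observed ~0.2% lifetime transformation risk for a typical 40 mm (≈10¹⁰
cell) tumour gives n_TSX ≈ 1245.  The predicted excess-LOH fraction in
malignant tumours, 2p_LOH/(2p_LOH + n_TSX·u) ≈ 22%, is independent of
tumour size below ~10¹² cells (a consequence of neutrality) and is exposed
both ways: predicted from parameters, and inverted for n_TSX from a future
LOH survey.

## Radiation-induced risk

DSBs are induced linearly in dose, p_DSB = kD with k = 3.90e-7 /Gy/bp
(linear over the measured 0–50 Gy range; a warning fires beyond), each
misrepaired with ε = 0.5 — a deliberately pessimistic constant; dose-rate
dependence ε(D, Ḋ) is out of scope.  Misrepair produces indels, so the
indel-sensitive count m_TSX = 0.42·n_TSX applies.  Only cells already
carrying one TSX hit (the (n_TSX·u + p_LOH)·N sensitive subpopulation of
the spontaneous model) can be pushed to malignancy, and the hit cell must
survive, with linear-quadratic survival (α = 0.77 /Gy, β = 0.31 /Gy²).
The no-prior-clone factor equals exactly 1 − P(malignancy) of the
spontaneous model, tying the modules together.  Single-fraction excess
risk rises linearly with no threshold, peaks at the maximiser of D·S(D)
(0.79 Gy at the defaults — "around 1 Gray"), and is below 1e-9 at
therapeutic doses > 10 Gy for 5–40 mm tumours.  Ideal fractionation
(fractions within one tumour cell cycle) behaves as the single total dose;
the worst case — full recovery between F independent fractions — replaces
S(D) by S(D/F) and, at 50 Gy on a 40 mm tumour with m_TSX = 100, overtakes
the 0.2% lifetime risk at around ten fractions (F = 13 on our evaluation).

The tumour cell-cycle argument uses b ≈ c/V_SC^{1/3}: a tumour growing at
its edge advances one cell diameter per division.  With c = 1–3 mm/yr this
evaluates to 85.5–256.5 /yr (cycle 1.4–4.3 days); the range 90–272 /yr
sometimes quoted for the same inputs does not reproduce from them, and the
computed values are reported.

## Synthetic data: what it does and does not emulate

The generators supply every pipeline input with known ground truth: a
Gompertz–Makeham life table (defaults give survivorship ≈ 0.46 to age 80),
a birth cohort whose diagnosis hazard is 3A′t² (the density of the cubic
net risk, with A′ = A/0.85 so the attributable corrected curve recovers A)
competing with mortality from the life table, Bernoulli LOH/SMARCB1 flags
per diagnosed tumour, binomial variant-count datasets, and coding sequences
with planted near-stop codons (TAC) among inert ones (GCC), certified
against the brute-force enumerator.  A stochastic per-cell walk through the
full eleven-state chain is included as a cross-check that the mean-field
solution matches a genuinely stochastic population (it does, within
binomial sampling error, at inflated rates that make end states reachable
in 2×10⁵ simulated cells).

What passing these tests shows: the estimators invert the model that
generated the data, at the study's actual sample sizes (23 and 32 tumours;
~120 diagnoses per 10⁷ birth cohort).  What they do not show: robustness to
real-data features the generators omit — period and cohort effects,
diagnosis-intensity trends, misclassified LOH calls, the old-age incidence
plateau (handled only by truncation), and any genetic heterogeneity beyond
the three modelled pathways (e.g. *LZTR1*, which is deliberately out of
scope).

Problem sizes in the shipped test suite were chosen to keep the full run
around ten seconds on one core (10⁷-person cohorts, 200 recovery seeds ×
1000 bootstrap replicates, 2×10⁵ simulated cells); all are package
defaults or test-local constants that scale up unchanged.

## Numerical choices and edge cases

- Probabilities near 1e-5: ODE atol 1e-18, rtol 1e-10 (LSODA).
- The exact-independence aggregation 1 − Π(1 − P_j) and the small-P sums
  are both returned; a flag is raised when they differ by > 1e-6.
- Smoothed frequencies are strictly inside (0, 1); f_SMARCB1 = 0 raises an
  error pointing at the smoothing step rather than dividing by zero.
- Bootstrap replicates violating model consistency (f_LOH ≤ f_SMARCB1,
  f = 0 draws under the pseudocount scheme) are excluded and counted.
- Per-cell radiation loss probabilities are clipped at 1 with a warning
  (they are ≪ 1 for any gene smaller than dystrophin, but the bound is
  enforced rather than assumed).
- Deletion lengths must satisfy 1 ≤ k ≤ L−3; degenerate fits (fewer than 3
  age bins, all-zero ages) and negative doses/volumes raise errors.

## Known limitations

- Initiation treats N₀ as constant and neutral; clonal expansion of
  intermediates, germline/familial *NF2*, and *LZTR1* are not modelled.
- A single effective oncogene (*GFX*) and a single malignancy suppressor
  (*TSX*) stand in for what are likely several genes each; the large
  inferred target sizes (≈ 2000 and ≈ 1245 sites) hint at that diversity.
- The substitution model is single-rate; positional/early-truncation
  severity effects and frameshift-tail stops are ignored by design.
- The radiation model has no microdosimetry, repair kinetics, or
  heterogeneous dose fields; ε = 0.5 is an upper bound, so the computed
  excess risks are conservative.
- The lifetime cumulative incidence implied by A·80³ ≈ 1.2e-5 sits well
  below the ~1/1000 lifetime risk quoted for the disease overall; the
  fitted A is treated as authoritative for the modelled NF2-somatic
  subtype and the tension is noted, not reconciled.
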