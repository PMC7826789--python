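# Methods

This note documents the models and conventions implemented in `kinoset`,
the parameters that matter, and what the synthetic-data generators do and
do not emulate.

## Selectivity model

The substrate is a compounds × kinases matrix of percent-of-control (PoC)
values from a single-concentration binding-displacement screen (default
1 µM). The selectivity index

S₁₀ = |{k : PoC(c, k) < cutoff}| / |{k assayed}|,  cutoff = 10 PoC

is the fraction of assayed kinases inhibited by ≥ 90%. Conventions:

- **Strict comparisons everywhere.** A kinase at exactly 10 PoC is not
  active; a K_D of exactly 100 nM and an S₁₀ of exactly 0.025 both fail
  inclusion. Boundary values therefore never qualify.
- **Denominator.** Only wild-type human assays with a non-missing cell
  count. Missing cells are excluded from numerator and denominator (with a
  logged warning per affected compound): an unassayed kinase is not
  evidence of selectivity. The panel reference travels with the matrix, so
  compounds profiled on different panels (e.g. a 230-assay versus a
  401-assay panel) are scored against their own denominators.
- **Inclusion rule.** A compound passes when at least one follow-up
  K_D < 100 nM (on *any* kinase — off-target potency is deliberately
  repurposed in chemogenomic design) and S₁₀ < 0.025. An initial triage at
  S₁₀ < 0.04 decides which compounds get K_D follow-up at all.
- **Follow-up cutoff.** K_D measurement is requested for kinases below a
  configurable PoC cutoff. Both 10 and 20 PoC are used in practice; the
  default is 10 and the choice is exposed rather than resolved.

## Chemotype binning

Bins are SMARTS substructure patterns with unique integer priorities
(lower rank wins); matching is substructure containment with perceived
aromaticity and no stereochemistry, because bins describe scaffolds. A
compound matching several bins takes the highest-priority match; a
compound matching none takes the designated fallback ("other") bin, which
is always the lowest-priority entry. Duplicate priorities are a hard
error — silent tie-breaking would make assignments depend on file order.
Matching uses RDKit; the test suite independently replays every toy-set
assignment through Open Babel's SMARTS engine and an explicit priority
argmin, so the two engines cross-validate the shipped catalog.

The shipped `demo_bins.tsv` (12 scaffolds + fallback) is demonstration
data covering classic hinge binders; a production catalog (the real ones
run to ~120 bins) is user input.

## Greedy set assembly

Expert triage is encoded as a deterministic greedy algorithm. A kinase is
*covered* by a compound only through a qualifying K_D record below the
potency bound — single-concentration activity alone never earns coverage
credit. Each step selects the candidate with the largest marginal gain

gain(c) = Σ_{k ∈ qualifying(c)} w(k) · 1[bin(c) ∉ bins(k) and |bins(k)| < depth_target]

with depth_target = 2 by default (the "two chemotypes per kinase" goal) and
w(k) = 1 unless an optional publication-weight mapping in [0, 1]
down-weights well-studied kinases. Ties are broken in order by (1) fewer
exemplars of the candidate's chemotype already selected, (2) lower S₁₀,
(3) lexicographic id; assembly stops when the best gain is zero. Each step
is appended to an audit log (gains for all candidates, tie-break level
applied), so a selection can be replayed and inspected. The algorithm is
greedy by design — an auditable surrogate for manual curation, not an
optimal set-cover solver.

## Coverage accounting

Family coverage is reported per kinase subfamily (AGC, Atypical, CAMK,
CK1, CMGC, Lipid, Other, STE, TK, TKL) as covered / assayed, rounded
**half-up** to integer percent — the convention that reproduces printed
coverage tables (37.5 → 38, 66.67 → 67). A totals row sums the counts and
recomputes its percentage from the sums. Redundancy reporting splits
covered kinases by distinct-chemotype depth (≥ 2 vs exactly 1); dark-kinase
coverage is an exact symbol intersection with a user-supplied IDG list.
Kinase identity throughout is the case-sensitive gene symbol; alias
resolution is deliberately out of scope.

## Growth-rate (GR) metrics

GR corrects endpoint counts for division-time differences:

GR = 2^( log2(x/x₀) / log2(x_ctrl/x₀) ) − 1

with x₀ the count at treatment time, x the treated endpoint, x_ctrl the
same-plate vehicle endpoint. Identities: GR(x_ctrl) = 1, GR(x₀) = 0,
GR < 0 iff x < x₀; GR is scale-invariant and strictly increasing in x. A
vehicle that did not grow (x_ctrl = x₀) leaves GR undefined and raises,
matching the practice of excluding non-growing lines.

Response classes over a line panel (defaults): **inactive** if every line
has GR ≥ 0.9 (within 10% of vehicle); **broad** if ≥ 75% of lines show
GR ≤ 0.7 (a ≥ 30% decrease — "most of the lines" is not quantified in
common usage, so 0.75 is a documented, configurable choice); otherwise
**line_dependent** if any line shows such a decrease; otherwise inactive.

## Cytotoxicity

The healthy-cell fraction (vehicle-normalized) is tiered: ≥ 0.8 nontoxic,
[0.5, 0.8) reduced, [⅓, 0.5) severe, < ⅓ extreme (a > 67% decrease in cell
count). Boundaries belong to the healthier tier; the four tiers partition
[0, ∞). Per-kinase aggregation considers only kinases covered by ≥ 2
distinct chemotypes (single-chemotype kinases cannot separate on-target
toxicity from compound idiosyncrasy and are excluded, logged). Eligible
kinases get the mean healthy fraction over their inhibitors' replicate
records and a one-sided Welch t-test against the vehicle replicate
distribution, Benjamini–Hochberg corrected across kinases (flag at
q < 0.05). The test choice is a documented default — the underlying
procedure is not standardized in the field.

## Autophagic flux

Reporter GFP/RFP ratio series (each pre-normalized to its own 0 h value)
are rescaled per time point to percent of the vehicle→inducer difference:
pct(t) = 100 · (r_cmpd − r_veh) / (r_ctrl − r_veh), so vehicle-like = 0%
and inducer-like = 100%. A coinciding vehicle/inducer pair leaves the scale
undefined at that time and raises naming it. A **hit** has |pct| strictly
above 20% for at least 5 consecutive points (≈ 10 h at 2 h sampling); the
first maximal qualifying run is reported and its mean sign gives the
direction (induced vs reduced). No smoothing is applied before hit
calling. Hits are placed on a six-cell category grid — direction × a
three-way phenotype axis (proliferation reduced / appearance abnormal /
normal) — which is a documented surrogate scheme, configurable in
interpretation but deterministic and exhaustive over its inputs.

## Plate logistics

Budget arithmetic is exact mole accounting with a floor (partial assays
don't count): nanomoles in the aliquot over nanomoles per well. Plate maps
use the 384-well A1–P24 grid, controls down column 1 by convention,
compounds filled row- or column-major; layouts are pure functions of their
inputs and round-trip byte-identically through CSV.

## Synthetic-data generators

`FixtureSpec` holds one seed and per-scenario parameters; every generator
is a pure function of the spec, emitting byte-identical files on repeat
runs and writing the same formats the readers consume.

- **Profiling** (defaults: 60 compounds × 401 wild-type human kinases at
  1 µM): a mixture of selective (1–8 active kinases, S₁₀ ≤ 0.02),
  promiscuous (10–30% of the panel active) and inactive compounds. Active
  cells are drawn in [0, 9.9] and inactive cells in [15, ∞) with
  truncated-normal noise (SD 2 PoC), so planted labels survive any noise
  scale. K_D records are generated only for sub-cutoff kinases of
  triage-passing compounds, from a passing (5–80 nM) or planted-failing
  (150–900 nM) range. `expected_pass` is computed arithmetically from the
  planted parameters, never by running the pipeline under test.
- **Growth** (defaults: 17 lines, vehicle doubling 1.5–3× over the assay):
  treated counts are derived by inverting the GR formula at the planted
  class target (broad: GR 0.5 on all lines; line-dependent: GR 0.2 on 1–4
  random lines), then multiplied by log-normal noise (σ = 0.05 by default;
  0 for exact-recovery tests).
- **Flux** (48 points at 2 h spacing, starting at 2 h because the percent
  scale is undefined at the shared normalization point t = 0): vehicle
  drifts slowly near 1, the inducer control decays to 0.3; hits carry
  planted runs of amplitude ±30% and length 5–8, near-misses length-4
  runs. Baseline noise is clipped to ±10% and run noise to ±5%, keeping
  planted labels exact.

What these generators do **not** emulate: real panel noise structure
(assay-family-correlated errors, activation artifacts above 100 PoC),
compound-series structural correlation between selectivity and chemotype,
plate-position effects, or biological covariance between growth, toxicity
and flux phenotypes. Passing recovery tests therefore demonstrates the
correctness of the decision rules and their thresholds, not robustness to
real-world assay pathology.

## Numerical choices

- Percent rounding is decimal half-up (not banker's rounding).
- The budget floor adds a small relative epsilon (1e-12 of the ratio, plus
  1e-9 absolute) before flooring to protect exact ratios from float
  representation; this is far below any physical measurement precision.
- Greedy gains compare exactly (no tolerance): candidate gains are sums of
  user weights, and the tie-break cascade handles equality explicitly.
- PoC and K_D validation reject negatives/non-positives at parse time with
  row indices; readers never coerce missing to zero.

## Known limitations

- The greedy objective is a surrogate for manual curation; on adversarial
  instances it can be arbitrarily worse than an optimal cover (no ILP
  solver is provided, by design).
- Kinase symbols are matched exactly; panels using different alias
  conventions must be harmonized upstream.
- The shipped chemotype catalog is demonstrative; conclusions about
  chemotype occupancy require the user's production catalog.
- The per-kinase toxicity flag assumes approximately normal replicate
  noise; with very few replicates the Welch test is underpowered.
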