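# kinoset

Toolkit for assembling and annotating **kinase chemogenomic sets** — curated
libraries of potent, narrow-spectrum kinase inhibitors distributed for
cell-based phenotypic screening. It is aimed at chemical-biology groups who
profile donated inhibitors across large kinase assay panels, triage them by
potency and selectivity, and ship the surviving compounds as an annotated
plate set.

## What it computes

**Selectivity.** Given a compounds × kinases matrix of percent-of-control
(PoC) values at a screening concentration (0 = full inhibition, 100 = no
effect), the selectivity index

> S₁₀ = (number of wild-type human kinases with PoC < 10) / (number assayed)

summarizes how narrow a compound's activity is. Compounds with S₁₀ < 0.04
are triaged for follow-up K_D measurement on their sub-cutoff kinases, and a
compound enters the set when some K_D < 100 nM **and** S₁₀ < 0.025 (all
comparisons strict). Missing cells drop out of both numerator and
denominator — an unassayed kinase is not evidence of selectivity.

**Chemotype binning.** Each inhibitor is assigned to a hinge-binder
chemotype via priority-ordered SMARTS substructure matching (RDKit), with an
"other" bin for compounds lacking a recognizable hinge binder. A small
demonstration catalog of classic scaffolds (indazoles, oxindoles,
quinazolines, quinolines, pyrimidines, …) ships with the package; real
analyses supply their own catalog TSV.

**Set assembly.** A deterministic greedy algorithm encodes the curation
goals: maximize kinome coverage, aim for two distinct chemotypes per kinase,
and prefer under-represented chemotypes among equivalent candidates
(tie-breaks: fewer chemotype exemplars, lower S₁₀, lexicographic id). Every
step is written to an audit log. Coverage accounting reports per-subfamily
percentages (half-up integer rounding), chemotype redundancy, and overlap
with a user-supplied list of understudied "dark" kinases.

**Screen annotation.** Downstream phenotypic screens are annotated with
normalized growth-rate inhibition values
`GR = 2^(log2(x/x0)/log2(x_ctrl/x0)) − 1` (1 = vehicle-like growth, 0 =
stasis, < 0 = net loss) and a three-way response class; cytotoxicity tiers on
the vehicle-normalized healthy-cell fraction (0.8 / 0.5 / ⅓ thresholds) with
per-kinase aggregation and a one-sided test against vehicle replicates; and
autophagic-flux hit calling on GFP/RFP reporter time series (> 20%
aberration of the vehicle→inducer scale sustained over ≥ 5 consecutive time
points), followed by a six-category phenotype grid.

**Logistics.** 384-well plate maps and compound-budget arithmetic (a 1 µL
aliquot of 10 mM stock supports 100 assays at 1 µM in 100 µL wells, 200 in
50 µL wells).

All inputs a study would supply — profiling matrices, K_D tables, growth,
toxicity and flux readouts — can also be generated synthetically with
embedded ground truth (`kinoset.simulate`), so the full pipeline is testable
offline.

## Worked example

```python
from kinoset import (FixtureSpec, gen_profiles, compute_s10, decide_inclusion,
                     filter_candidates, greedy_assemble, SelectionConfig,
                     redundancy_report)

spec = FixtureSpec(seed=42, n_compounds=60)   # 401-kinase panel at 1 µM
matrix, kd, truth = gen_profiles(spec)

r = compute_s10(matrix, "CMPD0002")
print(f"CMPD0002: S10 = {r.s10:.4f} ({r.n_active}/{r.n_assayed} kinases below 10 PoC)")
d = decide_inclusion(r, [k for k in kd if k.compound == "CMPD0002"])
print("inclusion:", d.passed, "| qualifying:", d.qualifying_kinases)
```

prints

```
CMPD0002: S10 = 0.0150 (6/401 kinases below 10 PoC)
inclusion: True | qualifying: ['KIN065', 'KIN108', 'KIN199', 'KIN286', 'KIN301', 'KIN368']
```

CMPD0002 inhibits 6 of 401 assayed kinases by more than 90% (S₁₀ = 0.015 <
0.025) and holds sub-100 nM K_D values on all six, so it passes inclusion.
Filtering all 60 compounds and assembling greedily:

```python
cands = filter_candidates(matrix, kd)
sel = greedy_assemble(cands, {c.compound: "demo-bin" for c in cands},
                      SelectionConfig())
print(len(cands), "candidates ->", len(sel.compounds), "selected,",
      len(sel.covered_kinases), "kinases covered")
```

```
28 candidates -> 26 selected, 112 kinases covered
```

(Two candidates are dropped: with every compound in the same demo bin,
their qualifying kinases are already covered by that chemotype, so their
marginal gain is zero.)

The same pipeline is available from the shell:

```bash
kinoset simulate profiles --seed 42 --outdir fixtures/
kinoset score  --matrix fixtures/poc.csv --panel fixtures/panel.tsv --out s10.tsv
kinoset bin    --compounds cmpds.smi --out assignments.tsv
kinoset select --matrix fixtures/poc.csv --panel fixtures/panel.tsv \
               --kd fixtures/kd.tsv --bins assignments.tsv \
               --out set.tsv --audit audit.jsonl
kinoset coverage --panel fixtures/panel.tsv --set set.tsv --out coverage.tsv
kinoset screen gr   --growth growth.csv --out gr.tsv
kinoset screen tox  --tox tox.csv --out tox.tsv
kinoset screen flux --flux flux.csv --out flux_hits.tsv
```

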