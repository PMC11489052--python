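# cohortpbn

Cohort-specific probabilistic Boolean network analysis for disease-subtype
stratification.

Boolean models of disease pathways (e.g. mitophagy or dopamine-transcription
signalling in Parkinson's disease) describe biomolecules as ON/OFF variables
updated by logical rules. `cohortpbn` makes such models *cohort-specific*: it
derives per-miRNA effect sizes from two-group expression data, converts them
into per-node initial-state probabilities, simulates stochastic trajectories
(optionally under permanent knockout/overexpression mutations encoding a
comorbidity such as type-2 diabetes), and stratifies cohorts by comparing
endpoint trajectories with staged Dynamic Time Warping (DTW).

## The method

1. **Cohort statistics.** For each miRNA in a case/control count matrix:
   median-of-ratios normalisation, descriptive log2 fold change, a paired
   *t*-test (Welch fallback), Benjamini-Hochberg FDR, and Cohen's
   *d* = (x̄₁ − x̄₂)/s_pooled on the log2 scale. The Common-Language effect
   size CL = Φ(d/√2) is the probability that a random case observation
   exceeds a random control one under normality.
2. **Target filtering.** miRNA→gene interactions are kept when they carry
   strong evidence (level "A" in the primary resource, or ≥2 supporting
   studies) and cross-table consensus, restricted to a tissue expression
   profile; miRNAs whose fold-change sign contradicts all published reports
   are excluded.
3. **Parameterization.** Each targeted network node receives its miRNA's CL
   as initial ON-probability; comorbidity DEG tables become permanent point
   mutations (down → forced 0, up → forced 1).
4. **Simulation.** Random asynchronous updates: at each step, one uniformly
   chosen node whose rule output disagrees with its state flips (the
   embedded jump chain of a unit-rate continuous-time process). An ensemble
   of repetitions estimates per-step ON-probabilities; an exact
   state-distribution oracle and attractor enumeration (terminal SCCs of the
   asynchronous state graph) are available for small networks.
5. **Trajectory comparison.** Trajectories are split into early/mid/late
   stages; DTW scores each condition's endpoint sub-series against a
   reference (lower = more similar), and Pearson correlation of the
   per-endpoint DTW profiles flags highly concordant subgroup pairs
   (r ≥ 0.98). Piecewise-linear change-point regression locates trend shifts.

## Worked example

Parameterize a PRKN-mitophagy-shaped toy model with the SWEDD cohort's
published CL values, add a comorbidity knockout, simulate, and compare:

```python
import pandas as pd
from cohortpbn import (gen_toy_networks, build_initial_spec, deg_to_forced,
                       merge_parameterizations, InitialStateSpec,
                       simulate_ensemble, stage_dtw_table, identify_terminals)

net = gen_toy_networks("prkn_shape")
swedd = pd.DataFrame({
    "mirna": ["hsa-miR-96-5p", "hsa-miR-26a-5p", "hsa-miR-424-5p",
              "hsa-miR-15b-5p", "hsa-miR-3121-3p", "hsa-miR-26a-5p"],
    "gene": ["ATXN3", "BAG4", "FBXW7", "GABARAPL1", "TIMM17A", "ULK1"],
    "cl": [0.966761, 0.712208, 0.852718, 0.92637, 0.981296, 0.712208]})
spec, report = build_initial_spec(net, swedd)

degs = pd.DataFrame({"gene": ["VPS13C"], "direction": ["down"]})
forced, _ = deg_to_forced(net, degs)
cond = merge_parameterizations(spec, forced, labels=["SWEDD", "T2DM"])

conds = {
    "baseline": simulate_ensemble(net, InitialStateSpec({}, 0.5),
                                  None, 100, 1000, seed=7),
    "SWEDD": simulate_ensemble(net, spec, None, 100, 1000, seed=7),
    "SWEDD+T2DM": simulate_ensemble(net, cond.spec, cond.forced,
                                    100, 1000, seed=7),
}
_, outputs = identify_terminals(net)
table = stage_dtw_table(conds, reference="baseline", endpoints=outputs)
print(table.to_wide().round(3))
```

which prints

```
condition                 SWEDD  SWEDD+T2DM  baseline
stage endpoint
early Apoptosis           0.440       0.591       0.0
      Mitophagy           1.060       1.115       0.0
      PINK1_accumulation  0.570       4.498       0.0
      PRKN_ubiquitinated  1.514       1.543       0.0
late  Apoptosis           0.525       0.525       0.0
      Mitophagy           1.330       1.330       0.0
      PINK1_accumulation  0.700       5.530       0.0
      PRKN_ubiquitinated  1.855       1.855       0.0
mid   Apoptosis           0.495       0.495       0.0
      Mitophagy           1.254       1.254       0.0
      PINK1_accumulation  0.660       5.214       0.0
      PRKN_ubiquitinated  1.749       1.749       0.0
```

Each cell is the DTW distance between that condition's endpoint trajectory
and the neutral baseline (all initial probabilities 0.5, no mutations) in
that simulation stage. The SWEDD parameterization already departs from
baseline in every endpoint; knocking out VPS13C additionally perturbs
PINK1 accumulation — its DTW score jumps from 0.57 to 4.50 early and keeps
diverging — while leaving the other endpoints nearly unchanged by the late
stage. The mapped CL values themselves, e.g. P(ATXN3 ON at step 0) =
0.966761, come straight from the cohort statistics.

## Command-line interface

```bash
cohortpbn synth --scenario scenario.yaml --seed 3 --outdir data/
cohortpbn model convert --in model.xml --out model.bnet
cohortpbn model verify --model model.bnet --ref signs.tsv --report report.tsv
cohortpbn stats --counts c.tsv --samples s.tsv --interactions i.tsv --out p.tsv
cohortpbn simulate --model model.bnet --init init.tsv --steps 100 --reps 1000 \
    --seed 7 --out traj.tsv
cohortpbn compare --traj a.tsv --traj b.tsv --reference pairwise --out dtw.tsv
cohortpbn run --config run.yaml
```

`cohortpbn run` executes the full pipeline (statistics → filtering →
parameterization → simulation → staged DTW → correlation) and writes TSV
tables, a JSON manifest with content digests, and a short report into the
output directory; identical configs reproduce byte-identical outputs.

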