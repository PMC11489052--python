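# Methods

This note documents the models and procedures implemented in `cohortpbn`,
the assumptions behind them, the defaults and why they were chosen, and the
limits of what the synthetic-data tests demonstrate.

## Boolean models and formats

A model is a set of named Boolean variables, each with one update rule over
`!`, `&`, `|` and parentheses; constants `0`/`1` are allowed and, like
identity self-rules (`A, A`), mark input nodes. Rule files follow the
BoolNet convention (`targets, factors` header). SBML-qual import is a strict
Boolean subset: every qualitative species must have maximum level 1 and
every transition exactly one result-level-1 function term whose MathML uses
and/or/not and 0/1-threshold comparisons; anything else raises an
unsupported-feature error rather than degrading silently. Identifiers are
matched exactly, with no case folding or normalisation, so vocabulary
discrepancies between a model and a reference table surface in reports
instead of being hidden.

SIF export assigns edge signs by literal-occurrence parity: a regulator
appearing only un-negated in a rule is stimulatory, only negated inhibitory,
and mixed parity yields one row per sign (a sensitivity-style test confirms
the parity rule agrees with flipping the regulator in all contexts for
single-parity regulators). Structural verification compares these edges
against a signed reference table and classifies each as sign match, sign
mismatch, direction conflict (reference holds the reversed edge) or absent,
report-only.

## Stochastic simulation semantics

Updates are asynchronous single-node flips: from state *s*, the set *U(s)*
of non-forced nodes whose rule output disagrees with their value is
computed; one member of *U(s)* is chosen uniformly and flipped. States with
empty *U(s)* are fixed points and persist, so all repetitions share a common
step axis. This discrete chain is the embedded jump chain of the
continuous-time asynchronous process with unit transition rates; trajectory
probabilities are reported per iteration step, which is the natural axis for
step-indexed trajectory tables. Rate-heterogeneous simulation and
synchronous updates are out of scope.

Initial states are sampled independently per node from an ON-probability
map; forced nodes (point mutations) are pinned after sampling and excluded
from *U*, making knockouts/overexpressions permanent. Defaults are 100 steps
and 1000 repetitions per condition; a 100-repetition preset exists because
both ensemble sizes are in common use for this class of model and neither is
canonical.

Randomness is counter-based (Philox): repetition *r* reads from a dedicated
stream at offset *r*·2²⁰ of the seed's key, so (i) identical inputs give
bit-identical ensembles, and (ii) enlarging the repetition count extends an
ensemble without reshuffling earlier walks (tested by checking that the
extra walks' ON-counts are non-negative integers).

Two exact methods back-stop the sampler on networks with at most 12
non-forced nodes: full propagation of the state distribution through the
jump-chain transition matrix (the verification oracle; distributions are
clipped to [0,1] each step to scrub accumulating float round-off), and
attractor enumeration as terminal strongly-connected components of the
asynchronous transition digraph. The Monte-Carlo/oracle tolerance used
throughout is 4·√(p(1−p)/R) + 0.004 per marginal — a 4σ binomial band plus
a small absolute floor for marginals near 0 or 1.

## Effect-size chain

Counts are normalised by re-implemented median-of-ratios size factors
(geometric-mean reference over features with all-positive counts); log2 fold
change is descriptive, computed on group means with a pseudocount of 0.5.
Significance comes from a paired t-test on log2-normalised values when
pairing metadata exists (Welch otherwise), with Benjamini-Hochberg FDR
across features; the negative-binomial Wald machinery of dedicated DE tools
is deliberately not reproduced — the package is self-contained and the
paired-t path is the significance route it exposes. Zero-variance features
are flagged per-feature (NaN) rather than failing the whole table.

Cohen's d uses the pooled SD with (n−1) weights. The Common-Language effect
size is the two-independent-samples form CL = Φ(d/√2) — the probability
that a random case draw exceeds a random control draw when both are normal
with common SD; the one-sample variant Φ(d) is available behind a flag since
the literature uses both. `cl_empirical` (the tie-aware empirical
probability of superiority) is kept as an independent brute-force check and
agrees with the closed form within 0.02 at n = 10,000 per group.

## Parameterization

Each network node targeted by a profiled miRNA receives that miRNA's CL as
its initial ON-probability; multiple targeting miRNAs are combined by mean
(min/max available — the combination rule is genuinely underdetermined, so
it is configurable with the least-committal default). CL is assigned
directly by default because published parameter tables list CL values as
the node parameters verbatim; the biologically motivated alternative — a
strongly expressed repressive miRNA should *lower* its target's initial
activity — is exposed as `invert_repression` (1−CL). Unmapped genes are
reported, never dropped silently; unmapped nodes default to the
maximum-entropy value 0.5. DEG tables become forced sets (down → 0,
up → 1); conflicting duplicate directions are an error, genes absent from
the model a warning. When merged, forced values take precedence over
initial probabilities.

## Trajectory comparison

DTW is the classic dynamic program with step pattern {match, insert,
delete}, absolute-difference local cost, boundary alignment and no warping
window by default (the series are ~100 points; a Sakoe-Chiba band exists
for longer ones). Trajectories are split into contiguous equal-length
stages (remainder to the last stage), labelled early/mid/late for three
stages; boundaries can instead be taken from detected change points. The
default comparator is a neutral baseline condition (all probabilities 0.5,
no forced nodes) because per-condition scores need a fixed reference;
pairwise mode scores all unordered condition pairs — both interpretations
are implemented since the choice of comparator is a genuinely open design
point. Pearson correlation of two conditions' per-endpoint DTW vectors
carries a high-similarity flag at r ≥ 0.98.

Change-point detection is discontinuous piecewise-linear least squares: a
dynamic program over breakpoint placements (minimum segment length 3, O(1)
per-segment SSE via prefix sums) with the segment count selected by BIC,
n·log(RSS/n) + k·log n over k = 2·segments + breaks parameters. This is a
deterministic, desk-scale approximation of Bayesian multiple-change-point
regression; posterior sampling is out of scope.

## Synthetic data: what it emulates and what it does not

The generator emulates the structure of a four-cohort whole-blood miRNA
study — case-group sizes clinical 1430, prodromal 223, SWEDD 187,
parkinsonism 81, with 1:1 matched controls and optional pairing — with
negative-binomial counts (var = μ + φμ², default dispersion φ = 0.15,
typical of blood miRNA-seq), log-normal per-sample size factors (σ = 0.2),
and baseline log2 means uniform on [5, 9]. The default of 800 miRNAs
reflects the scale of a blood miRNome assay and keeps planted effects a
small fraction of features, which matters because median-of-ratios
normalisation is biased when a large one-directional fraction of features
is differential. Planted effects are calibrated against the exact NB
moments of log2(count + 0.5) (a fixed-point on the mean/variance of the
shifted distribution), so the realized Cohen's d on the analysis scale
equals the target d rather than a delta-method approximation ~4% off.
Interaction, tissue, literature and DEG tables are generated with
controlled fractions (level-A evidence, multi-study support, tissue
overlap, literature agreement) so every filter outcome is known by
construction. All streams are derived from the scenario seed via
independent keyed generators, so outputs are deterministic across runs and
platforms.

What passing synthetic tests does **not** show: real miRNA count data have
correlated features, batch structure, composition effects and
heavier-tailed dispersion than the independent-NB model; the toy Boolean
networks (including the PRKN-shaped fixture, whose internal rules are
synthetic — only its input/output node names follow the published model's
terminals) do not reproduce any published pathway's dynamics. Results on
synthetic data validate the *machinery*, not biological conclusions.

## Numerical and degenerate-input choices

- Probabilities outside [0,1], unknown node names in specs/forced sets, and
  empty groups raise immediately with the offending names.
- Exact methods refuse networks above 12 free nodes (4096 states) with an
  explicit message instead of silently thrashing.
- BH adjustment passes NaN p-values through untouched.
- Ties in `cl_empirical` count one half; ties in BIC model selection prefer
  fewer segments.
- Pipeline stages abort with the stage name and offending input; every
  output file is listed in a manifest with a SHA-256 digest.

## Problem sizes used in verification

The verification suite and `scripts/acceptance.py` use: 50 random networks
(2-8 nodes) × 20,000 repetitions against the exact oracle at steps
{1, 5, 25, 50}; 100 random networks for attractor agreement; n = 10,000 per
group for the CL closed-form/empirical comparison; 500 replicates of
n = 100/group for planted-d recovery; 2,000 null features for paired-t
calibration; 300 short pairs against the exhaustive DTW oracle and 1,000
random pairs for its metric properties; 200 seeded runs for change-point
recovery; and a 20-miRNA planted cohort at n = 80/group for the end-to-end
run. These sizes give comfortable statistical resolution for every stated
tolerance while keeping the whole suite in the tens of seconds.
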