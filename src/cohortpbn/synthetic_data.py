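"""Synthetic inputs for the whole pipeline: cohort count matrices with
planted effects, interaction/literature/DEG tables, and a catalogue of toy
Boolean networks.

The default scenario mirrors the structure of the whole-blood miRNA study
cohorts: four case groups (clinical n=1430, prodromal n=223, SWEDD n=187,
parkinsonism n=81), each with an equal-sized matched control group, and
negative-binomial sequencing counts with log-normal per-sample size factors.
Effects are planted as shifts of the log2 mean calibrated (delta method) so
that the standardized effect on the log2 scale equals the requested Cohen's
d. Everything is deterministic from the scenario seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import ExpressionMatrix
from .model_io import BooleanNetwork

__all__ = [
    "SyntheticScenario",
    "PPMI_COHORT_SIZES",
    "gen_counts",
    "gen_interactions",
    "gen_toy_networks",
    "gen_deg_table",
    "TOY_NETWORK_KINDS",
]

# Case-group sizes of the study cohorts (controls matched 1:1).
PPMI_COHORT_SIZES = {
    "clinical": 1430,
    "prodromal": 223,
    "SWEDD": 187,
    "parkinsonism": 81,
}

_LN2 = math.log(2.0)


@dataclass
class SyntheticScenario:
    """Declarative description of a synthetic study.

    ``planted_effects``: rows (mirna, cohort, d) — target Cohen's d on the
    log2 scale, applied to the case group of that cohort. ``dispersion`` is
    the NB dispersion phi (var = mu + phi mu^2). ``deg_plan`` maps gene ->
    'up'/'down' for the comorbidity DEG table.
    """

    seed: int = 0
    cohort_sizes: dict[str, int] = field(
        default_factory=lambda: dict(PPMI_COHORT_SIZES))
    n_mirnas: int = 800
    planted_effects: list[tuple[str, str, float]] = field(default_factory=list)
    dispersion: float = 0.15
    baseline_log2_mean: tuple[float, float] = (5.0, 9.0)
    size_factor_sigma: float = 0.2
    paired: bool = True
    target_map_density: float = 0.05
    frac_level_a: float = 0.6
    frac_multi_study: float = 0.5
    tissue_overlap: float = 0.8
    literature_agreement: float = 0.8
    deg_plan: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cohort, n in self.cohort_sizes.items():
            if n < 2:
                raise ValueError(f"cohort {cohort!r} needs >= 2 samples")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for m, c, d in self.planted_effects:
            if not math.isfinite(d):
                raise ValueError(f"planted d for {m!r}/{c!r} is not finite")
            if c not in self.cohort_sizes:
                raise ValueError(f"planted effect names unknown cohort {c!r}")

    def mirna_ids(self) -> list[str]:
        return [f"hsa-miR-s{i:03d}" for i in range(self.n_mirnas)]


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    # independent deterministic streams per generator function
    return np.random.default_rng([scenario.seed, stream])


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             phi: float) -> np.ndarray:
    # numpy NB(n, p): mean = n (1-p)/p  ->  n = 1/phi, p = 1/(1 + phi mean)
    n = 1.0 / phi
    p = 1.0 / (1.0 + phi * mean)
    return rng.negative_binomial(n, p)


def _log2_moments(mu: float, phi: float,
                  pseudocount: float = 0.5) -> tuple[float, float]:
    """Exact mean and variance of log2(X + pseudocount), X ~ NB(mu, phi)."""
    from scipy import stats as sps
    n = 1.0 / phi
    p = 1.0 / (1.0 + phi * mu)
    sd = math.sqrt(mu + phi * mu * mu)
    hi = int(mu + 12 * sd + 50)
    k = np.arange(hi + 1)
    pmf = sps.nbinom.pmf(k, n, p)
    vals = np.log2(k + pseudocount)
    m = float((pmf * vals).sum())
    v = float((pmf * (vals - m) ** 2).sum())
    return m, v


def _calibrated_shift(mu: float, phi: float, d: float) -> float:
    """log2 shift of the NB mean whose realized standardized effect on the
    log2(X + 0.5) scale equals d (fixed-point on exact NB moments)."""
    if d == 0.0:
        return 0.0
    m0, v0 = _log2_moments(mu, phi)
    shift = d * math.sqrt(v0)  # delta-method start
    for _ in range(4):
        m1, v1 = _log2_moments(mu * 2.0 ** shift, phi)
        target = d * math.sqrt(0.5 * (v0 + v1))
        shift += target - (m1 - m0)
    return shift


def gen_counts(scenario: SyntheticScenario) -> dict[str, ExpressionMatrix]:
    """Negative-binomial count matrices per cohort with planted effects.

    The case-group log2 mean of a planted miRNA is shifted so that the
    realized standardized effect (Cohen's d) on the log2(count + 0.5) scale
    equals the target d; the shift is calibrated against the exact negative-
    binomial moments of the log2-transformed counts.
    """
    mirnas = scenario.mirna_ids()
    base_rng = _rng(scenario, 1)
    lo, hi = scenario.baseline_log2_mean
    log2_mu = base_rng.uniform(lo, hi, size=len(mirnas))
    mu = np.power(2.0, log2_mu)
    phi = scenario.dispersion

    planted: dict[str, dict[str, float]] = {}
    for mirna, cohort, d in scenario.planted_effects:
        planted.setdefault(cohort, {})[mirna] = d

    out: dict[str, ExpressionMatrix] = {}
    for ci, (cohort, n) in enumerate(sorted(scenario.cohort_sizes.items())):
        rng = _rng(scenario, 100 + ci)
        case_ids = [f"{cohort}_case_{i:04d}" for i in range(n)]
        ctrl_ids = [f"{cohort}_ctrl_{i:04d}" for i in range(n)]
        sf = rng.lognormal(mean=0.0, sigma=scenario.size_factor_sigma,
                           size=2 * n)

        shift = np.zeros(len(mirnas))
        for j, mirna in enumerate(mirnas):
            d = planted.get(cohort, {}).get(mirna, 0.0)
            if d != 0.0:
                shift[j] = _calibrated_shift(float(mu[j]), phi, d)
        mu_case = mu * np.power(2.0, shift)

        case = _nb_draw(rng, mu_case[:, None] * sf[None, :n], phi)
        ctrl = _nb_draw(rng, mu[:, None] * sf[None, n:], phi)
        counts = pd.DataFrame(np.hstack([case, ctrl]), index=mirnas,
                              columns=case_ids + ctrl_ids)
        groups = {s: "case" for s in case_ids}
        groups.update({s: "control" for s in ctrl_ids})
        pairing = dict(zip(case_ids, ctrl_ids)) if scenario.paired else None
        out[cohort] = ExpressionMatrix(counts=counts, sample_groups=groups,
                                       pairing=pairing, cohort=cohort)
    return out


# ---------------------------------------------------------------------------
# Interaction / tissue / literature tables
# ---------------------------------------------------------------------------

def gen_interactions(scenario: SyntheticScenario,
                     genes: Sequence[str] | None = None,
                     ) -> dict:
    """Interaction tables with controlled evidence structure.

    Returns a dict with keys ``primary`` (mirna, gene, evidence_level,
    n_supporting_studies, source), ``secondary`` (list of tables), ``tissue``
    (gene list), and ``literature`` (mirna, direction). Level-A fraction,
    multi-study fraction, tissue overlap, and literature agreement with the
    planted effect signs follow the scenario's knobs, so downstream filter
    outcomes are known by construction.
    """
    rng = _rng(scenario, 2)
    mirnas = scenario.mirna_ids()
    if genes is None:
        genes = [f"GENE{i:03d}" for i in range(200)]
    genes = list(genes)

    pairs = []
    for m in mirnas:
        for g in genes:
            if rng.random() < scenario.target_map_density:
                pairs.append((m, g))
    if not pairs:
        primary = pd.DataFrame(
            columns=["mirna", "gene", "evidence_level",
                     "n_supporting_studies", "source"])
        secondary = primary.assign()
        return {"primary": primary, "secondary": [secondary],
                "tissue": [], "literature": pd.DataFrame(
                    columns=["mirna", "direction"])}

    level = np.where(rng.random(len(pairs)) < scenario.frac_level_a, "A", "B")
    studies = np.where(rng.random(len(pairs)) < scenario.frac_multi_study,
                       rng.integers(2, 6, size=len(pairs)), 1)
    primary = pd.DataFrame(
        {"mirna": [p[0] for p in pairs], "gene": [p[1] for p in pairs],
         "evidence_level": level, "n_supporting_studies": 1,
         "source": "synthetic-primary"})
    secondary = pd.DataFrame(
        {"mirna": [p[0] for p in pairs], "gene": [p[1] for p in pairs],
         "evidence_level": "NA", "n_supporting_studies": studies,
         "source": "synthetic-secondary"})

    n_tissue = int(round(scenario.tissue_overlap * len(genes)))
    tissue = sorted(rng.choice(genes, size=n_tissue, replace=False).tolist())

    planted_sign = {m: ("up" if d > 0 else "down")
                    for m, _, d in scenario.planted_effects}
    lit_rows = []
    for m, true_dir in sorted(planted_sign.items()):
        agree = rng.random() < scenario.literature_agreement
        reported = true_dir if agree else ("down" if true_dir == "up" else "up")
        lit_rows.append({"mirna": m, "direction": reported})
    literature = pd.DataFrame(lit_rows, columns=["mirna", "direction"])
    return {"primary": primary, "secondary": [secondary],
            "tissue": tissue, "literature": literature}


# ---------------------------------------------------------------------------
# Toy Boolean networks
# ---------------------------------------------------------------------------

TOY_NETWORK_KINDS = ("identity", "oscillator", "chain3", "bistable",
                     "prkn_shape", "random")

_PRKN_RULES = {
    # inputs (identity self-rules)
    "ATXN3": "ATXN3",
    "BAG4": "BAG4",
    "FBXW7": "FBXW7",
    "GABARAPL1": "GABARAPL1",
    "TIMM17A": "TIMM17A",
    "ULK1": "ULK1",
    "VPS13C": "VPS13C",
    # synthetic internal layer
    "PINK1": "TIMM17A & !BAG4",
    "PRKN": "PINK1 & !ATXN3 & !FBXW7",
    "Mito_flux": "PRKN & (ULK1 | GABARAPL1)",
    # outputs (referenced by no rule)
    "Mitophagy": "Mito_flux",
    "PRKN_ubiquitinated": "PRKN & PINK1",
    "PINK1_accumulation": "PINK1 & !VPS13C",
    "Apoptosis": "!Mito_flux | !VPS13C",
}


def gen_toy_networks(kind: str, seed: int | None = None,
                     n_nodes: int = 6) -> BooleanNetwork:
    """Deterministic fixture networks.

    ``prkn_shape`` reproduces the input/output node names of the
    PRKN-mitophagy model (the published model lists only terminals, so the
    internal rules here are synthetic). ``random`` draws a seed-determined
    network with 1-3 regulators per node.
    """
    if kind == "identity":
        return BooleanNetwork(nodes=["A"], rules={"A": "A"})
    if kind == "oscillator":
        return BooleanNetwork(nodes=["A"], rules={"A": "!A"})
    if kind == "chain3":
        return BooleanNetwork(nodes=["A", "B", "C"],
                              rules={"A": "A", "B": "A", "C": "B"})
    if kind == "bistable":
        return BooleanNetwork(nodes=["A", "B"],
                              rules={"A": "!B", "B": "!A"})
    if kind == "prkn_shape":
        return BooleanNetwork(nodes=list(_PRKN_RULES),
                              rules=dict(_PRKN_RULES),
                              metadata={"name": "prkn_shape_synthetic"})
    if kind == "random":
        if seed is None:
            raise ValueError("kind='random' requires a seed")
        rng = np.random.default_rng(seed)
        nodes = [f"N{i}" for i in range(n_nodes)]
        rules = {}
        for node in nodes:
            k = int(rng.integers(1, min(3, n_nodes) + 1))
            regs = rng.choice(nodes, size=k, replace=False)
            lits = [f"!{r}" if rng.random() < 0.5 else str(r) for r in regs]
            op = " & " if rng.random() < 0.5 else " | "
            rules[node] = op.join(lits)
        return BooleanNetwork(nodes=nodes, rules=rules,
                              metadata={"name": f"random_{seed}"})
    raise ValueError(
        f"unknown network kind {kind!r}; catalogue: {TOY_NETWORK_KINDS}")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def gen_deg_table(plan: Mapping[str, str] | SyntheticScenario) -> pd.DataFrame:
    """DEG rows (gene, direction) from a plan mapping gene -> 'up'/'down'."""
    if isinstance(plan, SyntheticScenario):
        plan = plan.deg_plan
    rows = []
    for gene, direction in plan.items():
        d = direction.lower()
        if d not in ("up", "down"):
            raise ValueError(
                f"direction for {gene!r} must be up/down, got {direction!r}")
        rows.append({"gene": gene, "direction": d})
    return pd.DataFrame(rows, columns=["gene", "direction"])
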