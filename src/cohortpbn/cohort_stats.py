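"""Differential-expression and effect-size statistics on a two-group miRNA
count matrix, miRNA-target filtering, literature-direction matching, and
hypergeometric over-representation analysis.

The statistical chain per miRNA is: median-of-ratios normalisation ->
descriptive log2 fold change -> paired t-test (Welch fallback when no pairing
is available) -> Benjamini-Hochberg FDR -> Cohen's d on the log2 scale ->
Common-Language effect size CL = Phi(d / sqrt(2)), the probability that a
random case observation exceeds a random control observation under normality.
The CL values are what parameterize the Boolean models downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "CohortProfile",
    "TargetFilterConfig",
    "size_factors",
    "log2_fold_change",
    "paired_t_test",
    "welch_t_test",
    "bh_adjust",
    "cohens_d",
    "cl_from_d",
    "cl_one_sample",
    "cl_empirical",
    "compute_cohort_profile",
    "filter_mirna_targets",
    "match_literature_direction",
    "enrich_hypergeometric",
]

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ExpressionMatrix:
    """A miRNA x sample count matrix with group labels and optional pairing.

    ``counts``: non-negative integer DataFrame (rows miRNAs, columns samples);
    ``sample_groups``: sample -> 'case' | 'control';
    ``pairing``: optional bijection case-sample -> control-sample.
    """

    counts: pd.DataFrame
    sample_groups: dict[str, str]
    pairing: dict[str, str] | None = None
    cohort: str = ""

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"unlabelled samples: {sorted(missing)}")
        bad = {g for g in self.sample_groups.values()
               if g not in ("case", "control")}
        if bad:
            raise ValueError(f"groups must be case/control, got {sorted(bad)}")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        if self.pairing is not None:
            cases = set(self.case_samples)
            controls = set(self.control_samples)
            if set(self.pairing) != cases or set(
                    self.pairing.values()) != controls:
                raise ValueError(
                    "pairing must be a bijection between the case and "
                    "control sample sets")
            if len(set(self.pairing.values())) != len(self.pairing):
                raise ValueError("pairing maps two cases to one control")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.counts.columns
                if self.sample_groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.counts.columns
                if self.sample_groups[s] == "control"]


@dataclass
class CohortProfile:
    """Per-miRNA statistics plus the miRNA -> target-gene assignments used to
    parameterize a model (one CL per miRNA, shared by all its targets)."""

    stats: pd.DataFrame  # index miRNA; log2FC, t, p_value, q_value, cohens_d, cl
    targets: pd.DataFrame  # columns miRNA, gene, plus carried annotations
    cohort: str = ""

    def __post_init__(self) -> None:
        cl = self.stats["cl"].dropna()
        if ((cl < 0) | (cl > 1)).any():
            raise ValueError("CL values must lie in [0, 1]")

    def target_cl(self) -> pd.DataFrame:
        """targets joined with each miRNA's CL (constant across its targets)."""
        out = self.targets.merge(
            self.stats[["cl"]], left_on="mirna", right_index=True, how="left")
        return out


# ---------------------------------------------------------------------------
# Normalisation and fold change
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against the geometric-mean reference,
    computed over miRNAs with all-positive counts."""
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no miRNA has all-positive counts; cannot build the "
            "geometric-mean reference")
    ref = np.exp(np.log(mat[positive]).mean(axis=1))
    ratios = mat[positive] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


def normalized_counts(mat: ExpressionMatrix) -> pd.DataFrame:
    return mat.counts / size_factors(mat.counts)


def log2_fold_change(mat: ExpressionMatrix,
                     pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Descriptive per-miRNA log2FC of normalized case vs control means."""
    if not mat.case_samples or not mat.control_samples:
        raise ValueError("both groups need at least one sample")
    norm = normalized_counts(mat)
    mean_case = norm[mat.case_samples].mean(axis=1)
    mean_ctrl = norm[mat.control_samples].mean(axis=1)
    return pd.Series(
        np.log2((mean_case + pseudocount) / (mean_ctrl + pseudocount)),
        index=mat.counts.index, name="log2FC")


# ---------------------------------------------------------------------------
# Tests and effect sizes (vectorised across features; rows are features)
# ---------------------------------------------------------------------------

def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t-test on matched observations.

    Accepts 1-D vectors or (features x pairs) matrices; zero-variance
    differences yield NaN (flagged, not raised) per feature.
    """
    scalar = np.ndim(x) == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("paired samples must have identical shape")
    n = x.shape[1]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t = np.where(sd > 0, t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return (float(t[0]), float(p[0])) if scalar else (t, p)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Welch t-test (unpaired fallback when pairing is absent)."""
    scalar = np.ndim(x) == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    res = stats.ttest_ind(x, y, axis=1, equal_var=False)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    return (float(t[0]), float(p[0])) if scalar else (t, p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    return q


def cohens_d(x: np.ndarray, y: np.ndarray) -> np.ndarray | float:
    """Standardized mean difference with pooled (n-1)-weighted SD.

    1-D inputs give a scalar; (features x samples) matrices a vector. A zero
    pooled variance yields NaN for that feature.
    """
    scalar = np.ndim(x) == 1
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    nx, ny = x.shape[1], y.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 values")
    vx = x.var(axis=1, ddof=1)
    vy = y.var(axis=1, ddof=1)
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (x.mean(axis=1) - y.mean(axis=1)) / np.sqrt(pooled)
    d = np.where(pooled > 0, d, np.nan)
    return float(d[0]) if scalar else d


def cl_from_d(d) -> np.ndarray | float:
    """Common-Language effect size Phi(d / sqrt(2)): the probability that a
    random draw from the case group exceeds one from the control group when
    both are normal with the pooled SD (two-independent-samples form)."""
    return stats.norm.cdf(np.asarray(d, dtype=float) / math.sqrt(2.0)) \
        if np.ndim(d) else float(stats.norm.cdf(d / math.sqrt(2.0)))


def cl_one_sample(d) -> np.ndarray | float:
    """One-sample CL variant Phi(d) (config alternative)."""
    return stats.norm.cdf(np.asarray(d, dtype=float)) \
        if np.ndim(d) else float(stats.norm.cdf(d))


def cl_empirical(x: Sequence[float], y: Sequence[float]) -> float:
    """Empirical probability of superiority: fraction of (x_i, y_j) pairs
    with x_i > y_j, ties counted one half. Brute-force oracle for cl_from_d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left")
    greater_or_equal = np.searchsorted(ys, x, side="right")
    ties = greater_or_equal - greater
    return float((greater.sum() + 0.5 * ties.sum()) / (x.size * y.size))


# ---------------------------------------------------------------------------
# Full per-cohort profile
# ---------------------------------------------------------------------------

def compute_cohort_profile(mat: ExpressionMatrix,
                           pseudocount: float = DEFAULT_PSEUDOCOUNT,
                           cl_variant: str = "two_sample") -> pd.DataFrame:
    """Per-miRNA statistics table: log2FC, t, p, BH q, Cohen's d, CL.

    The t-test is paired when pairing metadata is present (case and control
    columns aligned by the pairing map), Welch otherwise. Effect sizes are
    computed on log2(normalized count + pseudocount).
    """
    lfc = log2_fold_change(mat, pseudocount)
    norm = normalized_counts(mat)
    logged = np.log2(norm + pseudocount)
    if mat.pairing:
        cases = sorted(mat.pairing)
        controls = [mat.pairing[c] for c in cases]
    else:
        cases, controls = mat.case_samples, mat.control_samples
    xs = logged[cases].to_numpy()
    ys = logged[controls].to_numpy()
    if mat.pairing:
        t, p = paired_t_test(xs, ys)
    else:
        t, p = welch_t_test(xs, ys)
    d = cohens_d(xs, ys)
    cl = cl_one_sample(d) if cl_variant == "one_sample" else cl_from_d(d)
    return pd.DataFrame({
        "log2FC": lfc,
        "t": t,
        "p_value": p,
        "q_value": bh_adjust(p),
        "cohens_d": d,
        "cl": cl,
    }, index=mat.counts.index)


# ---------------------------------------------------------------------------
# Target filtering
# ---------------------------------------------------------------------------

@dataclass
class TargetFilterConfig:
    """Evidence rule for keeping a (miRNA, gene) interaction.

    A pair survives when it is level-``level_a_label`` in the primary table OR
    has >= ``min_studies`` supporting studies in a secondary table, AND (when
    ``require_consensus``) appears in at least ``consensus_min_tables`` of the
    supplied tables.
    """

    level_a_label: str = "A"
    min_studies: int = 2
    require_consensus: bool = True
    consensus_min_tables: int = 2


def filter_mirna_targets(primary: pd.DataFrame,
                         secondary: Sequence[pd.DataFrame],
                         tissue_genes: Iterable[str],
                         de_mirnas: Iterable[str],
                         config: TargetFilterConfig | None = None,
                         ) -> pd.DataFrame:
    """Filter interaction tables down to trustworthy, tissue-expressed targets
    of the differentially expressed miRNAs.

    Tables carry columns ``mirna``, ``gene`` and either ``evidence_level``
    (primary) or ``n_supporting_studies`` (secondary). Returns the surviving
    (mirna, gene) rows; an empty result is allowed.
    """
    config = config or TargetFilterConfig()
    tissue = set(tissue_genes)
    de = set(de_mirnas)

    def pair_set(df: pd.DataFrame) -> set[tuple[str, str]]:
        return set(zip(df["mirna"], df["gene"]))

    evidence_ok: set[tuple[str, str]] = set()
    prim_pairs = pair_set(primary)
    if "evidence_level" in primary.columns:
        lvl_a = primary[primary["evidence_level"] == config.level_a_label]
        evidence_ok |= pair_set(lvl_a)
    for tab in secondary:
        if "n_supporting_studies" in tab.columns:
            strong = tab[tab["n_supporting_studies"] >= config.min_studies]
            evidence_ok |= pair_set(strong)

    all_tables = [prim_pairs] + [pair_set(t) for t in secondary]
    if config.require_consensus:
        counts: dict[tuple[str, str], int] = {}
        for tab in all_tables:
            for pair in tab:
                counts[pair] = counts.get(pair, 0) + 1
        consensus = {p for p, c in counts.items()
                     if c >= config.consensus_min_tables}
        evidence_ok &= consensus

    rows = [(m, g) for (m, g) in sorted(evidence_ok)
            if m in de and g in tissue]
    return pd.DataFrame(rows, columns=["mirna", "gene"])


# ---------------------------------------------------------------------------
# Literature direction matching
# ---------------------------------------------------------------------------

def match_literature_direction(profile: pd.DataFrame,
                               literature: pd.DataFrame) -> pd.DataFrame:
    """Partition profile miRNAs by literature agreement of the log2FC sign.

    ``literature`` columns: mirna, direction ('up'/'down'); several reports
    per miRNA are allowed. A miRNA is 'matched' when at least one report
    agrees with its observed sign, 'mismatched' when reports exist but none
    agrees (such miRNAs are flagged for exclusion from further analysis),
    and 'unreviewed' when absent from the literature table.
    """
    directions = literature["direction"].str.lower()
    bad = set(directions) - {"up", "down"}
    if bad:
        raise ValueError(f"directions must be up/down, got {sorted(bad)}")
    lit = literature.assign(direction=directions).groupby("mirna")[
        "direction"].agg(set)

    records = []
    for mirna, row in profile.iterrows():
        observed = "up" if row["log2FC"] > 0 else "down"
        if mirna not in lit.index:
            status = "unreviewed"
        elif observed in lit.loc[mirna]:
            status = "matched"
        else:
            status = "mismatched"
        records.append({"mirna": mirna, "log2FC": row["log2FC"],
                        "observed": observed, "status": status,
                        "excluded": status == "mismatched"})
    columns = ["mirna", "log2FC", "observed", "status", "excluded"]
    return pd.DataFrame.from_records(records,
                                     columns=columns).set_index("mirna")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def enrich_hypergeometric(query_genes: Iterable[str],
                          gene_sets: Mapping[str, Iterable[str]],
                          universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a query gene list in
    each named set, BH-adjusted across sets, sorted by p ascending."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if query - universe:
        raise ValueError("query genes outside the universe: "
                         f"{sorted(query - universe)[:5]}")
    M, n = len(universe), len(query)
    records = []
    for name, genes in gene_sets.items():
        genes = set(genes) & universe
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), n)) if k > 0 else 1.0
        records.append({"set": name, "set_size": len(genes), "overlap": k,
                        "p_value": min(p, 1.0)})
    df = pd.DataFrame.from_records(records)
    df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
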