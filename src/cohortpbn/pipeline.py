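"""End-to-end orchestration: cohort statistics -> target filtering ->
enrichment -> model parameterization (per cohort and per cohort+comorbidity)
-> stochastic simulation -> staged DTW -> subgroup correlation, with a
machine-readable manifest and a short human-readable report.

Every stage writes plain TSV/JSON into the run directory and later stages
read only those artefacts; re-running with the same config reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (ExpressionMatrix, TargetFilterConfig,
                           compute_cohort_profile, enrich_hypergeometric,
                           filter_mirna_targets, match_literature_direction)
from .model_io import BooleanNetwork, identify_terminals, parse_bnet
from .parameterization import (build_initial_spec, deg_to_forced,
                               merge_parameterizations)
from .simulator import (DEFAULT_REPS, DEFAULT_STEPS, ForcedNodeSet,
                        InitialStateSpec, simulate_ensemble)
from .trajectory_analysis import (HIGH_SIMILARITY_THRESHOLD,
                                  correlate_dtw_profiles, stage_dtw_table)

__all__ = ["PipelineConfig", "run_pipeline", "load_expression_matrix"]


@dataclass
class PipelineConfig:
    """Declarative single-document configuration of a full run."""

    models: dict[str, str]  # model name -> .bnet path
    cohorts: dict[str, dict[str, str]]  # cohort -> {counts, samples}
    interactions_primary: str
    interactions_secondary: list[str] = field(default_factory=list)
    tissue: str = ""
    literature: str = ""
    degs: dict[str, str] = field(default_factory=dict)  # label -> DEG TSV
    gene_sets: str = ""
    outdir: str = "run"
    steps: int = DEFAULT_STEPS
    reps: int = DEFAULT_REPS
    seed: int = 0
    n_stages: int = 3
    reference: str = "baseline"  # condition name or "pairwise"
    correlation_threshold: float = HIGH_SIMILARITY_THRESHOLD
    fdr: float = 0.05
    cl_variant: str = "two_sample"
    invert_repression: bool = False
    default_p: float = 0.5
    pseudocount: float = 0.5
    combine: str = "mean"

    def __post_init__(self) -> None:
        if self.steps < 1 or self.reps < 1:
            raise ValueError("steps and reps must be >= 1")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


# ---------------------------------------------------------------------------
# Input readers (plain TSV/text)
# ---------------------------------------------------------------------------

def load_expression_matrix(counts_path: str | Path, samples_path: str | Path,
                           cohort: str = "") -> ExpressionMatrix:
    """counts: miRNA x sample TSV; samples: (sample, group[, pair_id]) TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", dtype=str)
    groups = dict(zip(sheet["sample"], sheet["group"]))
    pairing = None
    if "pair_id" in sheet.columns and sheet["pair_id"].notna().any():
        pairing = {}
        for pid, sub in sheet.groupby("pair_id"):
            case = sub[sub["group"] == "case"]["sample"]
            ctrl = sub[sub["group"] == "control"]["sample"]
            if len(case) == 1 and len(ctrl) == 1:
                pairing[case.iloc[0]] = ctrl.iloc[0]
            else:
                raise ValueError(
                    f"pair {pid!r} must hold exactly one case and one control")
    return ExpressionMatrix(counts=counts, sample_groups=groups,
                            pairing=pairing, cohort=cohort)


def _read_lines(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip()]


def _read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    return {name: set(sub["gene"]) for name, sub in df.groupby("set")}


def _condition_seed(base_seed: int, *labels: str) -> int:
    tag = zlib.crc32("/".join(labels).encode())
    return int((base_seed * 1_000_003 + tag) % (2 ** 31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = outdir / name
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, sep="\t", index=index, float_format="%.10g")
        written.append(path)
        return path

    # ---- stage 1: cohort statistics + target filtering ------------------
    stage = "cohort_stats"
    try:
        primary = pd.read_csv(config.interactions_primary, sep="\t")
        secondary = [pd.read_csv(p, sep="\t")
                     for p in config.interactions_secondary]
        tissue = _read_lines(config.tissue) if config.tissue else []
        literature = (pd.read_csv(config.literature, sep="\t")
                      if config.literature else
                      pd.DataFrame(columns=["mirna", "direction"]))

        profiles: dict[str, pd.DataFrame] = {}
        target_cls: dict[str, pd.DataFrame] = {}
        for cohort, paths in sorted(config.cohorts.items()):
            mat = load_expression_matrix(paths["counts"], paths["samples"],
                                         cohort)
            profile = compute_cohort_profile(mat, config.pseudocount,
                                             config.cl_variant)
            profiles[cohort] = profile
            emit(profile, f"stats_{cohort}.tsv", index=True)

            de = profile[profile["q_value"] < config.fdr]
            matched = match_literature_direction(de, literature)
            emit(matched, f"literature_{cohort}.tsv", index=True)
            kept = matched[~matched["excluded"]].index
            targets = filter_mirna_targets(primary, secondary, tissue, kept)
            target_cl = targets.merge(profile[["cl"]], left_on="mirna",
                                      right_index=True, how="left")
            target_cls[cohort] = target_cl
            table5 = target_cl.rename(columns={
                "mirna": "miRNA", "gene": "Gene.Symbol",
                "cl": "CL-effectsize"})
            table5.insert(0, "Cohort", cohort)
            emit(table5, f"profile_{cohort}.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 2: enrichment (optional) ---------------------------------
    stage = "enrichment"
    try:
        if config.gene_sets:
            gene_sets = _read_gene_sets(config.gene_sets)
            universe = set(primary["gene"]) | set(tissue)
            for genes in gene_sets.values():
                universe |= genes
            for cohort, tcl in sorted(target_cls.items()):
                query = set(tcl["gene"])
                if query:
                    enr = enrich_hypergeometric(query, gene_sets, universe)
                    emit(enr, f"enrichment_{cohort}.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ---- stage 3: parameterization + simulation -------------------------
    stage = "simulation"
    deg_tables = {label: pd.read_csv(path, sep="\t")
                  for label, path in sorted(config.degs.items())}
    dtw_paths: dict[str, Path] = {}
    corr_records = []
    try:
        for model_name, model_path in sorted(config.models.items()):
            net = parse_bnet(Path(model_path).read_text())
            _, outputs = identify_terminals(net)
            conditions = {}

            baseline_spec = InitialStateSpec({}, config.default_p)
            conditions["baseline"] = (baseline_spec, ForcedNodeSet())

            for cohort, tcl in sorted(target_cls.items()):
                spec, report = build_initial_spec(
                    net, tcl, config.default_p, config.invert_repression,
                    config.combine)
                conditions[cohort] = (spec, ForcedNodeSet())
                for label, degs in deg_tables.items():
                    forced, absent = deg_to_forced(net, degs)
                    cond = merge_parameterizations(spec, forced,
                                                   labels=[cohort, label])
                    conditions[cond.name] = (cond.spec, cond.forced)

            ensembles = {}
            for name, (spec, forced) in sorted(conditions.items()):
                seed = _condition_seed(config.seed, model_name, name)
                ens = simulate_ensemble(net, spec, forced, config.steps,
                                        config.reps, seed)
                ensembles[name] = ens
                path = outdir / "trajectories" / f"{model_name}_{name}.tsv"
                path.parent.mkdir(parents=True, exist_ok=True)
                ens.to_tsv(path)
                written.append(path)

            table = stage_dtw_table(ensembles, config.reference,
                                    endpoints=outputs,
                                    n_stages=config.n_stages)
            dtw_paths[model_name] = emit(table.table,
                                         f"dtw_{model_name}.tsv")

            cohort_conditions = [c for c in ensembles
                                 if c != "baseline"]
            stages = sorted(table.table["stage"].unique())
            if config.reference != "pairwise":
                for c1, c2 in itertools.combinations(cohort_conditions, 2):
                    for st in stages:
                        res = correlate_dtw_profiles(
                            table, (c1, c2), st,
                            config.correlation_threshold)
                        corr_records.append({
                            "model": model_name, "condition_a": c1,
                            "condition_b": c2, "stage": st,
                            "pearson_r": res["r"],
                            "high_similarity": res["high_similarity"]})
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if corr_records:
        emit(pd.DataFrame.from_records(corr_records), "correlations.tsv")

    # ---- manifest + report ---------------------------------------------
    manifest = {
        "tool": "cohortpbn",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "steps": config.steps, "reps": config.reps,
            "n_stages": config.n_stages, "reference": config.reference,
            "fdr": config.fdr, "cl_variant": config.cl_variant,
            "invert_repression": config.invert_repression,
            "default_p": config.default_p,
            "pseudocount": config.pseudocount, "combine": config.combine,
            "correlation_threshold": config.correlation_threshold,
        },
        "inputs": {
            "models": config.models, "cohorts": config.cohorts,
            "interactions_primary": config.interactions_primary,
            "interactions_secondary": config.interactions_secondary,
            "tissue": config.tissue, "literature": config.literature,
            "degs": config.degs, "gene_sets": config.gene_sets,
        },
        "outputs": {str(p.relative_to(outdir)): _sha256(p)
                    for p in sorted(written)},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    lines = ["# cohortpbn run report", "",
             f"seed: {config.seed}; steps: {config.steps}; "
             f"reps: {config.reps}; reference: {config.reference}", "",
             f"cohorts analysed: {', '.join(sorted(config.cohorts))}",
             f"models simulated: {', '.join(sorted(config.models))}",
             f"outputs written: {len(written)} files (see manifest.json)"]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    return outdir
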