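"""Convert cohort statistics and comorbidity DEG tables into simulator inputs.

A cohort's miRNA-target CL values become per-node initial ON-probabilities
(build_initial_spec); a comorbidity DEG table becomes a forced-node set
(knockout 0 for downregulated genes, overexpression 1 for upregulated ones);
merge_parameterizations combines both into one labelled simulation condition,
forced values taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import BooleanNetwork
from .simulator import ForcedNodeSet, InitialStateSpec

__all__ = [
    "MappingReport",
    "SimulationCondition",
    "build_initial_spec",
    "deg_to_forced",
    "merge_parameterizations",
    "validate_deg_table",
]

_COMBINERS = {"mean": np.mean, "min": np.min, "max": np.max}


@dataclass
class MappingReport:
    """Which profile target genes mapped onto network nodes (exact match)."""

    matched: list[str]
    unmatched: list[str]

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_unmatched(self) -> int:
        return len(self.unmatched)


@dataclass
class SimulationCondition:
    """A fully specified simulation input: initial spec + forced nodes +
    provenance labels (cohort, comorbidity, ...)."""

    name: str
    spec: InitialStateSpec
    forced: ForcedNodeSet
    provenance: dict = field(default_factory=dict)


def build_initial_spec(net: BooleanNetwork, target_cl: pd.DataFrame,
                       default_p: float = 0.5,
                       invert_repression: bool = False,
                       combine: str = "mean",
                       ) -> tuple[InitialStateSpec, MappingReport]:
    """Assign each targeted network node its miRNA's CL as ON-probability.

    ``target_cl`` columns: mirna, gene, cl. Genes are matched to node ids
    exactly; unmatched genes are reported, never silently dropped. Several
    miRNAs targeting one node are combined per ``combine`` (mean/min/max).
    With ``invert_repression`` the node receives 1 - CL, encoding that a more
    active repressive miRNA should lower its target's initial activity.
    """
    if combine not in _COMBINERS:
        raise ValueError(f"combine must be one of {sorted(_COMBINERS)}")
    cl = target_cl["cl"].to_numpy(dtype=float)
    if np.isnan(cl).any() or ((cl < 0) | (cl > 1)).any():
        raise ValueError("CL values must lie in [0, 1]")

    nodes = set(net.nodes)
    genes = target_cl["gene"]
    matched = sorted(set(genes) & nodes)
    unmatched = sorted(set(genes) - nodes)

    probs: dict[str, float] = {}
    grouped = target_cl[genes.isin(nodes)].groupby("gene")["cl"]
    for gene, values in grouped:
        p = float(_COMBINERS[combine](values.to_numpy(dtype=float)))
        probs[gene] = 1.0 - p if invert_repression else p
    spec = InitialStateSpec(probabilities=probs, default_probability=default_p)
    return spec, MappingReport(matched=matched, unmatched=unmatched)


def validate_deg_table(degs: pd.DataFrame) -> pd.DataFrame:
    directions = degs["direction"].str.lower()
    bad = set(directions) - {"up", "down"}
    if bad:
        raise ValueError(f"DEG directions must be up/down, got {sorted(bad)}")
    out = degs.assign(direction=directions)
    conflicts = out.groupby("gene")["direction"].nunique()
    conflicted = conflicts[conflicts > 1].index.tolist()
    if conflicted:
        raise ValueError(
            f"conflicting duplicate directions for genes: {conflicted}")
    return out.drop_duplicates(subset="gene")


def deg_to_forced(net: BooleanNetwork, degs: pd.DataFrame,
                  ) -> tuple[ForcedNodeSet, list[str]]:
    """DEG table (gene, direction) -> permanent point mutations.

    Downregulated genes are knocked out (forced 0), upregulated genes
    overexpressed (forced 1). Genes absent from the network are returned as
    the second element, not errored.
    """
    if degs.empty:
        return ForcedNodeSet(), []
    degs = validate_deg_table(degs)
    nodes = set(net.nodes)
    forced = {row.gene: (0 if row.direction == "down" else 1)
              for row in degs.itertuples() if row.gene in nodes}
    absent = sorted(g for g in degs["gene"] if g not in nodes)
    return ForcedNodeSet(forced=forced), absent


def merge_parameterizations(spec: InitialStateSpec, forced: ForcedNodeSet,
                            labels: Sequence[str] = (),
                            ) -> SimulationCondition:
    """Combine a cohort initial spec with a comorbidity forced set.

    Forced values take precedence over initial probabilities on overlapping
    nodes (the spec entry is rewritten to the forced value so the reported
    initial distribution is consistent with what is simulated).
    """
    probs = dict(spec.probabilities)
    for node, v in forced.forced.items():
        probs[node] = float(v)
    merged = InitialStateSpec(probabilities=probs,
                              default_probability=spec.default_probability)
    name = "+".join(labels) if labels else "condition"
    return SimulationCondition(name=name, spec=merged, forced=forced,
                               provenance={"labels": list(labels)})
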