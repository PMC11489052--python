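"""Stochastic simulation of probabilistic Boolean models.

States evolve by random asynchronous updates: at each step the set U of
non-forced nodes whose rule output disagrees with their current value is
computed, and exactly one member of U (chosen uniformly) is flipped; states
with empty U are fixed points and persist. This is the embedded jump chain of
a unit-rate continuous-time asynchronous process. Initial states are sampled
independently per node from per-node ON-probabilities; forced nodes (point
mutations: knockout 0, overexpression 1) are pinned after sampling and
excluded from U.

Randomness is counter-based: repetition r draws from a Philox stream at a
fixed offset, so enlarging the repetition count extends an ensemble without
reshuffling earlier repetitions, and identical (network, spec, forced,
steps, reps, seed) inputs give bit-identical ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .model_io import BooleanNetwork, identify_terminals

__all__ = [
    "InitialStateSpec",
    "ForcedNodeSet",
    "TrajectoryEnsemble",
    "Attractor",
    "StateSpaceCapError",
    "DEFAULT_STEPS",
    "DEFAULT_REPS",
    "FIGURE_PRESET_REPS",
    "sample_initial_state",
    "async_step",
    "simulate_ensemble",
    "exact_state_distribution",
    "enumerate_attractors",
    "perturbation_scan",
]

# Methods-text preset: 100 iteration steps, 1000 repetitions per condition.
DEFAULT_STEPS = 100
DEFAULT_REPS = 1000
# Figure-legend variant preset (100 repetitions).
FIGURE_PRESET_REPS = 100

_STREAM_STRIDE = 1 << 20  # draws reserved per repetition stream
EXACT_CAP = 12  # max free (non-forced) nodes for exact state-space methods


class StateSpaceCapError(ValueError):
    """Raised when an exact method would enumerate too many states."""


@dataclass
class InitialStateSpec:
    """Per-node ON-probability at step 0; unmapped nodes get the default."""

    probabilities: dict[str, float] = field(default_factory=dict)
    default_probability: float = 0.5

    def __post_init__(self) -> None:
        for node, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(
                    f"initial probability for {node!r} is {p}, outside [0, 1]")
        if not (0.0 <= self.default_probability <= 1.0):
            raise ValueError("default_probability outside [0, 1]")

    def vector(self, nodes: Sequence[str]) -> np.ndarray:
        unknown = set(self.probabilities) - set(nodes)
        if unknown:
            raise KeyError(
                f"initial-state spec names nodes absent from the network: "
                f"{sorted(unknown)}")
        return np.array([self.probabilities.get(n, self.default_probability)
                         for n in nodes], dtype=float)


@dataclass
class ForcedNodeSet:
    """Nodes pinned permanently to 0 (knockout) or 1 (overexpression)."""

    forced: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, v in self.forced.items():
            if v not in (0, 1):
                raise ValueError(f"forced value for {node!r} must be 0 or 1")

    def __bool__(self) -> bool:
        return bool(self.forced)

    def check(self, nodes: Sequence[str]) -> None:
        unknown = set(self.forced) - set(nodes)
        if unknown:
            raise KeyError(
                f"forced set names nodes absent from the network: "
                f"{sorted(unknown)}")


@dataclass
class TrajectoryEnsemble:
    """Per-step, per-node estimated ON-probability from a repetition ensemble.

    ``prob`` has shape (steps + 1, n_nodes); row 0 holds the empirical
    initial-state frequencies.
    """

    steps: int
    n_repetitions: int
    seed: int
    prob: np.ndarray
    nodes: list[str]

    def series(self, node: str) -> np.ndarray:
        return self.prob[:, self.nodes.index(node)]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (step, node, probability)."""
        steps = np.repeat(np.arange(self.steps + 1), len(self.nodes))
        return pd.DataFrame({
            "step": steps,
            "node": np.tile(self.nodes, self.steps + 1),
            "probability": self.prob.ravel(),
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, n_repetitions: int = 0,
                   seed: int = 0) -> "TrajectoryEnsemble":
        wide = df.pivot(index="step", columns="node", values="probability")
        wide = wide.sort_index()
        nodes = list(wide.columns)
        return cls(steps=int(wide.index.max()), n_repetitions=n_repetitions,
                   seed=seed, prob=wide.to_numpy(), nodes=nodes)


# ---------------------------------------------------------------------------
# Vectorised rule evaluation
# ---------------------------------------------------------------------------

def _eval_ast(ast: tuple, states: np.ndarray,
              index: Mapping[str, int]) -> np.ndarray:
    kind = ast[0]
    if kind == "var":
        return states[:, index[ast[1]]]
    if kind == "const":
        return np.full(states.shape[0], bool(ast[1]))
    if kind == "not":
        return ~_eval_ast(ast[1], states, index)
    if kind == "and":
        out = _eval_ast(ast[1], states, index)
        for child in ast[2:]:
            out = out & _eval_ast(child, states, index)
        return out
    if kind == "or":
        out = _eval_ast(ast[1], states, index)
        for child in ast[2:]:
            out = out | _eval_ast(child, states, index)
        return out
    raise ValueError(f"unknown AST node {kind!r}")


class _Engine:
    """Compiled view of a network: rule ASTs + node index, batch evaluation."""

    def __init__(self, net: BooleanNetwork,
                 forced: ForcedNodeSet | None = None):
        self.net = net
        self.nodes = list(net.nodes)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.asts = [net.ast(n) for n in self.nodes]
        forced = forced or ForcedNodeSet()
        forced.check(self.nodes)
        self.forced_idx = np.array(
            [self.index[n] for n in forced.forced], dtype=int)
        self.forced_val = np.array(
            [bool(v) for v in forced.forced.values()], dtype=bool)
        self.free_mask = np.ones(len(self.nodes), dtype=bool)
        self.free_mask[self.forced_idx] = False

    def rule_outputs(self, states: np.ndarray) -> np.ndarray:
        """states: (R, n) bool -> (R, n) bool rule outputs."""
        out = np.empty_like(states)
        for j, ast in enumerate(self.asts):
            out[:, j] = _eval_ast(ast, states, self.index)
        return out

    def flippable(self, states: np.ndarray) -> np.ndarray:
        u = self.rule_outputs(states) != states
        u[:, ~self.free_mask] = False
        return u

    def pin(self, states: np.ndarray) -> np.ndarray:
        if self.forced_idx.size:
            states[:, self.forced_idx] = self.forced_val
        return states


def _rep_uniforms(seed: int, n_reps: int, n_draws: int) -> np.ndarray:
    """(n_reps, n_draws) uniforms; repetition r always sees the same stream."""
    out = np.empty((n_reps, n_draws), dtype=float)
    for r in range(n_reps):
        bg = np.random.Philox(key=seed)
        bg = bg.advance(r * _STREAM_STRIDE)
        out[r] = np.random.Generator(bg).random(n_draws)
    return out


def _flip_one(states: np.ndarray, u: np.ndarray,
              uniforms: np.ndarray) -> None:
    """Flip one uniformly chosen flippable node per row, in place."""
    k = u.sum(axis=1)
    active = k > 0
    if not active.any():
        return
    choice = np.floor(uniforms * k).astype(int)  # k=0 rows never selected
    cum = np.cumsum(u, axis=1)
    sel = u & (cum == (choice + 1)[:, None]) & active[:, None]
    states ^= sel


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def sample_initial_state(net: BooleanNetwork, spec: InitialStateSpec,
                         rng: np.random.Generator,
                         forced: ForcedNodeSet | None = None) -> np.ndarray:
    """Sample one binary state: node v is ON with spec probability, then any
    forced nodes override the sampled values."""
    p = spec.vector(net.nodes)
    state = rng.random(len(net.nodes)) < p
    if forced:
        forced.check(net.nodes)
        for node, v in forced.forced.items():
            state[net.nodes.index(node)] = bool(v)
    return state.astype(np.uint8)


def async_step(net: BooleanNetwork, state: np.ndarray | Mapping[str, int],
               forced: ForcedNodeSet | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """One asynchronous update: flip one uniformly chosen disagreeing
    non-forced node; a fixed point is returned unchanged."""
    rng = rng if rng is not None else np.random.default_rng()
    eng = _Engine(net, forced)
    if isinstance(state, Mapping):
        arr = np.array([[bool(state[n]) for n in net.nodes]])
    else:
        arr = np.asarray(state, dtype=bool).reshape(1, -1).copy()
    u = eng.flippable(arr)
    _flip_one(arr, u, np.array([rng.random()]))
    return arr[0].astype(np.uint8)


def simulate_ensemble(net: BooleanNetwork, spec: InitialStateSpec,
                      forced: ForcedNodeSet | None = None,
                      n_steps: int = DEFAULT_STEPS,
                      n_reps: int = DEFAULT_REPS,
                      seed: int = 0) -> TrajectoryEnsemble:
    """Monte-Carlo ensemble of asynchronous random walks.

    Runs ``n_reps`` independent walks of ``n_steps`` single-node updates from
    independently sampled initial states; entry (t, v) of the result is the
    fraction of repetitions with node v ON at step t.
    """
    if n_steps < 1 or n_reps < 1:
        raise ValueError("n_steps and n_reps must be >= 1")
    eng = _Engine(net, forced)
    n_nodes = len(eng.nodes)
    p0 = spec.vector(eng.nodes)

    uniforms = _rep_uniforms(seed, n_reps, n_nodes + n_steps)
    states = uniforms[:, :n_nodes] < p0[None, :]
    eng.pin(states)

    prob = np.empty((n_steps + 1, n_nodes), dtype=float)
    prob[0] = states.mean(axis=0)
    for t in range(1, n_steps + 1):
        u = eng.flippable(states)
        _flip_one(states, u, uniforms[:, n_nodes + t - 1])
        prob[t] = states.mean(axis=0)
    return TrajectoryEnsemble(steps=n_steps, n_repetitions=n_reps, seed=seed,
                              prob=prob, nodes=list(eng.nodes))


# ---------------------------------------------------------------------------
# Exact small-network oracle
# ---------------------------------------------------------------------------

def _enumerate_states(eng: _Engine) -> tuple[np.ndarray, np.ndarray]:
    """All joint states of the free nodes (forced nodes fixed).

    Returns (states bool matrix S x n, free node index array)."""
    free = np.flatnonzero(eng.free_mask)
    m = free.size
    if m > EXACT_CAP:
        raise StateSpaceCapError(
            f"{m} non-forced nodes exceeds the exact-method cap of "
            f"{EXACT_CAP} (state space 2^{m})")
    n_states = 1 << m
    states = np.zeros((n_states, len(eng.nodes)), dtype=bool)
    for bit, j in enumerate(free):
        states[:, j] = (np.arange(n_states) >> bit) & 1
    eng.pin(states)
    return states, free


def _transition_matrix(eng: _Engine) -> tuple[sparse.csr_matrix, np.ndarray,
                                              np.ndarray]:
    """Jump-chain transition matrix over the enumerated free-node states."""
    states, free = _enumerate_states(eng)
    n_states = states.shape[0]
    u = eng.flippable(states)
    k = u.sum(axis=1)

    rows, cols, vals = [], [], []
    fixed = np.flatnonzero(k == 0)
    rows.extend(fixed)
    cols.extend(fixed)
    vals.extend([1.0] * fixed.size)
    for bit, j in enumerate(free):
        movers = np.flatnonzero(u[:, j])
        if movers.size:
            rows.extend(movers)
            cols.extend(movers ^ (1 << bit))
            vals.extend(1.0 / k[movers])
    T = sparse.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    return T, states, free


def exact_state_distribution(net: BooleanNetwork, spec: InitialStateSpec,
                             forced: ForcedNodeSet | None = None,
                             n_steps: int = DEFAULT_STEPS,
                             return_state_dists: bool = False):
    """Exact per-step node marginals by propagating the full state distribution.

    Builds the embedded jump chain (from state s each disagreeing free node
    flips with probability 1/|U(s)|; fixed points self-loop) and pushes the
    product-Bernoulli initial distribution through it. Only feasible when the
    number of non-forced nodes is at most ``EXACT_CAP``.
    """
    eng = _Engine(net, forced)
    T, states, free = _transition_matrix(eng)
    p0 = spec.vector(eng.nodes)

    # product-Bernoulli over free nodes; forced nodes are deterministic
    dist = np.ones(states.shape[0], dtype=float)
    for bit, j in enumerate(free):
        on = states[:, j]
        dist *= np.where(on, p0[j], 1.0 - p0[j])

    marginals = np.empty((n_steps + 1, len(eng.nodes)), dtype=float)
    state_f = states.astype(float)
    marginals[0] = dist @ state_f
    dists = [dist.copy()] if return_state_dists else None
    for t in range(1, n_steps + 1):
        dist = dist @ T
        np.clip(dist, 0.0, 1.0, out=dist)  # scrub float round-off
        marginals[t] = dist @ state_f
        if return_state_dists:
            dists.append(dist.copy())
    np.clip(marginals, 0.0, 1.0, out=marginals)
    if return_state_dists:
        return marginals, list(eng.nodes), dists
    return marginals, list(eng.nodes)


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

@dataclass
class Attractor:
    """A terminal SCC of the asynchronous state graph; states are tuples of
    node values in network node order."""

    states: tuple[tuple[int, ...], ...]
    is_fixed_point: bool

    def __len__(self) -> int:
        return len(self.states)


def enumerate_attractors(net: BooleanNetwork,
                         forced: ForcedNodeSet | None = None) -> list[Attractor]:
    """All attractors: terminal strongly-connected components of the
    asynchronous transition digraph (fixed points are singleton self-loops)."""
    eng = _Engine(net, forced)
    states, free = _enumerate_states(eng)
    n_states = states.shape[0]
    u = eng.flippable(states)
    k = u.sum(axis=1)

    rows, cols = [], []
    fixed = np.flatnonzero(k == 0)
    rows.extend(fixed)
    cols.extend(fixed)
    for bit, j in enumerate(free):
        movers = np.flatnonzero(u[:, j])
        rows.extend(movers)
        cols.extend(movers ^ (1 << bit))
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                            shape=(n_states, n_states))
    n_comp, labels = connected_components(adj, directed=True,
                                          connection="strong")
    # a component is terminal iff no edge leaves it
    has_exit = np.zeros(n_comp, dtype=bool)
    coo = adj.tocoo()
    exits = labels[coo.row] != labels[coo.col]
    np.logical_or.at(has_exit, labels[coo.row[exits]], True)

    attractors = []
    for comp in range(n_comp):
        if has_exit[comp]:
            continue
        members = np.flatnonzero(labels == comp)
        comp_states = tuple(tuple(int(b) for b in states[s])
                            for s in sorted(members))
        is_fp = bool(members.size == 1 and k[members[0]] == 0)
        attractors.append(Attractor(states=comp_states, is_fixed_point=is_fp))
    attractors.sort(key=lambda a: a.states)
    return attractors


# ---------------------------------------------------------------------------
# Single-node perturbation scan
# ---------------------------------------------------------------------------

def perturbation_scan(net: BooleanNetwork, spec: InitialStateSpec,
                      n_steps: int = DEFAULT_STEPS,
                      n_reps: int = DEFAULT_REPS,
                      seed: int = 0,
                      outputs: Sequence[str] | None = None) -> pd.DataFrame:
    """Force each node to 0 and to 1 in turn and report, per output node, the
    maximum absolute change in ON-probability against the unperturbed ensemble.

    Returns a long table (node, forced_to, output, max_abs_delta) with two
    rows' worth of perturbations per network node.
    """
    if outputs is None:
        outputs = identify_terminals(net)[1]
    baseline = simulate_ensemble(net, spec, None, n_steps, n_reps, seed)
    out_idx = [baseline.nodes.index(o) for o in outputs]

    records = []
    for node in net.nodes:
        for value in (0, 1):
            ens = simulate_ensemble(net, spec, ForcedNodeSet({node: value}),
                                    n_steps, n_reps, seed)
            delta = np.abs(ens.prob[:, out_idx] - baseline.prob[:, out_idx])
            for j, o in enumerate(outputs):
                records.append({"node": node, "forced_to": value,
                                "output": o,
                                "max_abs_delta": float(delta[:, j].max())})
    return pd.DataFrame.from_records(records)
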