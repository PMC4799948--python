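"""Maximally weighted connected subnetwork search.

Every node of the working PPI graph carries a weight w = -log10(p) from the
differential-expression p-value (unadjusted).  A candidate node subset is
scored as the best connected component of its induced subgraph:

    score(S) = max over components C of S:  sum_{i in C} (w_i - lambda)

where lambda is a per-node inclusion penalty.  Without the penalty the
trivial optimum is the whole graph; with lambda = -log10(0.05) a node only
pays its way when more significant than p = 0.05.  The empty set scores 0,
so a search never returns a module of net-negative evidence.

Two solvers share this objective: a genetic algorithm over per-node
bitstrings (tournament selection, uniform crossover, per-bit mutation,
elitism; connectivity is enforced at scoring time by taking the best
component, which keeps the GA provably consistent with the oracle), and an
exhaustive enumerator for small graphs that serves as the ground-truth
optimum in benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "NodeWeights",
    "GAConfig",
    "ModuleResult",
    "assign_weights",
    "score_subnetwork",
    "best_component",
    "search_ga",
    "search_exhaustive",
    "extract_seeded_module",
    "jaccard",
]

#: default per-node penalty: a node must beat p = 0.05 to pay its way
DEFAULT_LAMBDA = -math.log10(0.05)

NodeWeights = dict


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    ``mutation_rate=None`` means the 1/|nodes| per-bit default.  All
    randomness flows through ``seed``.
    """

    population_size: int = 200
    generations: int = 300
    crossover_rate: float = 0.8
    mutation_rate: float | None = None
    tournament_size: int = 3
    elitism_count: int = 2
    lambda_penalty: float = DEFAULT_LAMBDA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.elitism_count < 0 or self.elitism_count > self.population_size:
            raise ValueError("elitism_count out of range")


@dataclass(frozen=True)
class ModuleResult:
    """A scored connected module with search provenance."""

    nodes: frozenset
    score: float
    connected: bool
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "nodes": sorted(str(n) for n in self.nodes),
            "score": self.score,
            "connected": self.connected,
            "provenance": self.provenance,
        }


def assign_weights(de: pd.DataFrame, p_min: float = 1e-300) -> NodeWeights:
    """Node weights w = -log10(max(p, p_min)) from a DE table."""
    if len(de) == 0:
        raise ValueError("empty DE table")
    p = de["p"].clip(lower=p_min)
    return {str(g): float(-np.log10(v)) for g, v in p.items()}


class _WorkGraph:
    """Flat-array view of a node-weighted graph for fast component scoring."""

    def __init__(self, g: nx.Graph, w: NodeWeights, lambda_penalty: float):
        self.nodes = sorted(g.nodes, key=str)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        missing = [n for n in self.nodes if n not in w]
        if missing:
            raise ValueError(f"weights missing for nodes: {missing[:5]}")
        self.net_w = np.array([w[n] - lambda_penalty for n in self.nodes])
        eu, ev = [], []
        for u, v in g.edges:
            eu.append(self.index[u])
            ev.append(self.index[v])
        self.eu = np.asarray(eu, dtype=np.intp)
        self.ev = np.asarray(ev, dtype=np.intp)
        self.n = len(self.nodes)

    def best_component(self, sel: np.ndarray) -> tuple[float, list[int]]:
        """Best-scoring connected component of the selected node set.

        Returns (score, member indices); the empty selection scores 0 with
        an empty member list, and a non-empty selection whose best
        component is net-negative keeps its (negative) score so callers can
        compare against the empty set explicitly.
        """
        sel_idx = np.nonzero(sel)[0]
        if sel_idx.size == 0:
            return 0.0, []
        parent = np.arange(self.n)

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        if self.eu.size:
            live = sel[self.eu] & sel[self.ev]
            for k in np.nonzero(live)[0]:
                ru, rv = find(self.eu[k]), find(self.ev[k])
                if ru != rv:
                    parent[rv] = ru
        sums: dict[int, float] = {}
        members: dict[int, list[int]] = {}
        for i in sel_idx:
            r = find(i)
            sums[r] = sums.get(r, 0.0) + self.net_w[i]
            members.setdefault(r, []).append(int(i))
        best_root = max(sums, key=lambda r: (sums[r], -len(members[r])))
        return float(sums[best_root]), members[best_root]


def best_component(
    nodes, g: nx.Graph, w: NodeWeights, lambda_penalty: float = DEFAULT_LAMBDA
) -> tuple[float, frozenset]:
    """Score a node set and report its maximizing connected component."""
    nodes = set(nodes)
    unknown = nodes - set(g.nodes)
    if unknown:
        raise ValueError(f"unknown nodes: {sorted(map(str, unknown))[:5]}")
    if not nodes:
        return 0.0, frozenset()
    wg = _WorkGraph(g.subgraph(nodes), {n: w[n] for n in nodes}, lambda_penalty)
    score, idx = wg.best_component(np.ones(wg.n, dtype=bool))
    return score, frozenset(wg.nodes[i] for i in idx)


def score_subnetwork(
    nodes, g: nx.Graph, w: NodeWeights, lambda_penalty: float = DEFAULT_LAMBDA
) -> float:
    """Score = best connected component's sum of (w - lambda); empty set = 0."""
    return best_component(nodes, g, w, lambda_penalty)[0]


def _result_from(wg: _WorkGraph, score: float, idx: list[int], provenance: dict) -> ModuleResult:
    nodes = frozenset(wg.nodes[i] for i in idx)
    # tie-break against the empty set: a module of non-positive net evidence
    # is replaced by the empty module at score 0
    if score <= 0.0 and (score < 0.0 or nodes):
        return ModuleResult(frozenset(), 0.0, True, provenance)
    return ModuleResult(nodes, score, True, provenance)


def search_ga(g: nx.Graph, w: NodeWeights, cfg: GAConfig = GAConfig()) -> ModuleResult:
    """Genetic-algorithm search for the maximally weighted connected module.

    Individuals are per-node bitstrings; fitness is ``score_subnetwork``.
    Half the initial population is seeded from the above-penalty nodes plus
    their direct neighbors (jump-starting convergence without constraining
    the optimum), half is uniform random.  The best connected component seen
    in any generation is returned; runs are deterministic under a fixed
    seed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    wg = _WorkGraph(g, w, cfg.lambda_penalty)
    n = wg.n
    rng = np.random.default_rng(cfg.seed)
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n
    pop_n = cfg.population_size

    seed_mask = wg.net_w > 0
    neighbor_mask = np.zeros(n, dtype=bool)
    if wg.eu.size:
        nb = seed_mask[wg.eu] | seed_mask[wg.ev]
        neighbor_mask[wg.eu[nb]] = True
        neighbor_mask[wg.ev[nb]] = True
        neighbor_mask &= ~seed_mask
    half = pop_n // 2
    pop = np.empty((pop_n, n), dtype=bool)
    # seeded half: all above-penalty nodes plus a sparse random subset of
    # their neighbors (candidate low-weight bridges), plus bit noise; the
    # first individual is the pure thresholded set
    pop[:half] = seed_mask[None, :] | (
        neighbor_mask[None, :] & (rng.random((half, n)) < 0.05)
    )
    pop[1:half] ^= rng.random((half - 1, n)) < mut
    pop[half:] = rng.random((pop_n - half, n)) < 0.5

    def evaluate(p):
        out = np.empty(p.shape[0])
        comps = []
        for i in range(p.shape[0]):
            s, c = wg.best_component(p[i])
            out[i] = s
            comps.append(c)
        return out, comps

    fitness, comps = evaluate(pop)
    best_i = int(np.argmax(fitness))
    best_score, best_idx = fitness[best_i], comps[best_i]
    best_gen = 0
    trace = [float(best_score)]

    for gen in range(1, cfg.generations + 1):
        order = np.argsort(-fitness, kind="stable")
        new = np.empty_like(pop)
        new[: cfg.elitism_count] = pop[order[: cfg.elitism_count]]
        n_children = pop_n - cfg.elitism_count
        # tournament selection for both parent slots
        cand = rng.integers(pop_n, size=(2, n_children, cfg.tournament_size))
        winners = cand[
            np.arange(2)[:, None],
            np.arange(n_children)[None, :],
            np.argmax(fitness[cand], axis=2),
        ]
        p1 = pop[winners[0]]
        p2 = pop[winners[1]]
        do_cx = rng.random(n_children) < cfg.crossover_rate
        mix = rng.random((n_children, n)) < 0.5
        children = np.where(do_cx[:, None] & mix, p2, p1)
        children ^= rng.random((n_children, n)) < mut
        new[cfg.elitism_count:] = children
        pop = new
        fitness, comps = evaluate(pop)
        gi = int(np.argmax(fitness))
        if fitness[gi] > best_score:
            best_score, best_idx, best_gen = fitness[gi], comps[gi], gen
        trace.append(float(best_score))

    provenance = {
        "method": "ga",
        "config": asdict(cfg),
        "seed": cfg.seed,
        "generations_to_best": best_gen,
        "trace_final": trace[-1],
    }
    return _result_from(wg, float(best_score), best_idx, provenance)


def search_exhaustive(
    g: nx.Graph, w: NodeWeights, lambda_penalty: float = DEFAULT_LAMBDA
) -> ModuleResult:
    """Global optimum by enumeration of all connected induced subgraphs.

    Guarded to graphs of at most 18 nodes.  Ties are broken toward the
    smaller node set, then lexicographically, so the all-zero-weight case
    returns the empty module.
    """
    n = g.number_of_nodes()
    if n > 18:
        raise ValueError(f"graph too large for exhaustive search ({n} nodes > 18)")
    wg = _WorkGraph(g, w, lambda_penalty)
    adj = [0] * n
    for u, v in zip(wg.eu.tolist(), wg.ev.tolist()):
        adj[u] |= 1 << v
        adj[v] |= 1 << u
    netw = wg.net_w

    best_score = 0.0
    best_mask = 0
    for mask in range(1, 1 << n):
        # connectivity by bitmask BFS from the lowest selected bit
        start = mask & -mask
        reached = start
        while True:
            frontier = 0
            m = reached
            while m:
                b = m & -m
                frontier |= adj[b.bit_length() - 1]
                m ^= b
            nxt = (reached | frontier) & mask
            if nxt == reached:
                break
            reached = nxt
        if reached != mask:
            continue
        s = 0.0
        m = mask
        while m:
            b = m & -m
            s += netw[b.bit_length() - 1]
            m ^= b
        if s > best_score + 1e-12:
            best_score, best_mask = s, mask
        elif abs(s - best_score) <= 1e-12 and best_mask:
            # tie: prefer fewer nodes, then lexicographically smaller set
            cand = [wg.nodes[i] for i in range(n) if mask >> i & 1]
            cur = [wg.nodes[i] for i in range(n) if best_mask >> i & 1]
            if (len(cand), sorted(map(str, cand))) < (len(cur), sorted(map(str, cur))):
                best_mask = mask
    idx = [i for i in range(n) if best_mask >> i & 1]
    provenance = {"method": "exhaustive", "lambda_penalty": lambda_penalty}
    return _result_from(wg, best_score, idx, provenance)


def extract_seeded_module(
    result: ModuleResult,
    g: nx.Graph,
    seeds,
    radius: int = 1,
    w: NodeWeights | None = None,
    lambda_penalty: float = DEFAULT_LAMBDA,
) -> ModuleResult:
    """Delimit the part of a module within graph distance ``radius`` of seeds.

    Distances are measured inside the module's induced subgraph.  With the
    optional weights the returned score is recomputed on the extracted set;
    otherwise it is reported as NaN.
    """
    seeds = set(seeds)
    present = seeds & set(result.nodes)
    if not present:
        raise ValueError("no seed gene lies in the module")
    sub = g.subgraph(result.nodes)
    keep: set = set()
    for s in present:
        dist = nx.single_source_shortest_path_length(sub, s, cutoff=radius)
        keep.update(dist)
    kept_sub = sub.subgraph(keep)
    connected = nx.is_connected(kept_sub) if keep else True
    if w is not None:
        score, _ = best_component(keep, g, w, lambda_penalty)
    else:
        score = float("nan")
    provenance = {
        "method": "seeded_extraction",
        "parent": result.provenance.get("method"),
        "seeds": sorted(map(str, present)),
        "radius": radius,
    }
    return ModuleResult(frozenset(keep), score, connected, provenance)


def jaccard(a, b) -> float:
    """Jaccard similarity of two node sets; two empty sets score 1."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
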