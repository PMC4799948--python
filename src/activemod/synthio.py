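"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's three data sources:

* two-group log2 expression matrices with a configurable fraction of truly
  differentially expressed genes (mimicking a cancer-versus-normal
  microarray design);
* scale-free-ish protein interaction graphs with a planted connected module
  of low-p nodes, the ground truth for module-recovery benchmarks;
* paired per-patient cohort tables of two positive, rank-correlated gene
  variables across anatomical sites (arbitrary-unit qPCR-style ratios).

Every generator is a pure function of its spec and seed: identical inputs
give byte-identical outputs, and no global RNG state is touched.  Writers
emit the external text formats the pipeline reads (expression TSV, group
TSV, STRING-links TSV, long-format cohort TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "SimExpressionSpec",
    "PlantedModuleTruth",
    "SimCohortSpec",
    "gen_expression",
    "gen_ppi_with_planted_module",
    "gen_cohort_table",
    "write_string_fixture",
    "write_expression_tsv",
    "write_groups_tsv",
    "write_cohort_tsv",
]


@dataclass(frozen=True)
class SimExpressionSpec:
    """Design of a simulated two-group expression experiment."""

    n_genes: int
    n_case: int
    n_control: int
    de_fraction: float = 0.0
    effect_log2: float = 1.0
    sigma: float = 0.5
    seed: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must each be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")

    @property
    def n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))


@dataclass(frozen=True)
class PlantedModuleTruth:
    """Ground truth for a planted active module.

    ``module_weight_dist`` and ``background_weight_dist`` are (mean, sd)
    pairs of the -log10(p) node weights, recorded exactly as used.
    """

    module_nodes: frozenset
    background_weight_dist: tuple[float, float] = (0.5, 0.3)
    module_weight_dist: tuple[float, float] = (3.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_nodes", frozenset(self.module_nodes))


@dataclass(frozen=True)
class SimCohortSpec:
    """Design of a paired-site cohort of two rank-correlated gene variables."""

    n_patients: int
    sites: tuple[str, ...] = ("tumor", "adjacent", "distant")
    rho: float = 0.0
    seed: int = 0
    genes: tuple[str, str] = ("AURKA", "RACGAP1")

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if len(self.sites) == 0:
            raise ValueError("sites must be non-empty")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("site labels must be unique")
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")


def gen_expression(spec: SimExpressionSpec) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate a two-group log2 expression matrix.

    Gene baselines are Gaussian; within-group noise has SD ``sigma``.  A
    random subset of ``round(de_fraction * n_genes)`` genes receives a mean
    shift of ``effect_log2`` in the case group, with random sign per gene.

    Returns the matrix (groups labelled ``case``/``control``) and the list
    of truly differential gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    cases = [f"case{i:02d}" for i in range(spec.n_case)]
    controls = [f"ctrl{i:02d}" for i in range(spec.n_control)]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    n_samples = spec.n_case + spec.n_control
    x = baseline[:, None] + rng.normal(0.0, spec.sigma, size=(spec.n_genes, n_samples))
    de_idx = rng.choice(spec.n_genes, size=spec.n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=spec.n_de)
    x[de_idx, : spec.n_case] += signs[:, None] * spec.effect_log2
    values = pd.DataFrame(x, index=genes, columns=cases + controls)
    groups = pd.Series(
        ["case"] * spec.n_case + ["control"] * spec.n_control,
        index=cases + controls,
        name="group",
    )
    truth = sorted(genes[i] for i in de_idx)
    return ExpressionMatrix(values, groups), truth


def gen_ppi_with_planted_module(
    n_nodes: int,
    avg_degree: float,
    truth: PlantedModuleTruth,
    model: str = "preferential_attachment",
    edge_confidence: float = 1.0,
    module_extra_edge_prob: float = 0.25,
) -> tuple[nx.Graph, dict]:
    """Random PPI-like graph with a planted connected module of low-p nodes.

    The background graph is preferential-attachment (scale-free-like degree
    distribution, as in high-confidence human interactomes); set
    ``model="erdos_renyi"`` for a homogeneous control.  The module nodes are
    wired to induce a connected subgraph (random spanning tree plus extra
    edges with probability ``module_extra_edge_prob``).  Node p-values are
    derived from -log10(p) weights sampled from the truth's module and
    background normal distributions, truncated at 0.

    Returns the graph (edges carry ``confidence``) and a node -> p-value map.
    """
    module = sorted(truth.module_nodes)
    if len(module) > n_nodes:
        raise ValueError("planted module larger than graph")
    if avg_degree < 2:
        raise ValueError("avg_degree must be >= 2")
    rng = np.random.default_rng(truth.seed)
    if model == "preferential_attachment":
        m = max(1, int(round(avg_degree / 2)))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=int(rng.integers(2**31)))
    elif model == "erdos_renyi":
        p = avg_degree / max(n_nodes - 1, 1)
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown background model: {model}")
    for n in module:
        if n not in g:
            raise ValueError(f"module node {n!r} not in generated graph")
    # wire module: random spanning tree, then densify
    if len(module) >= 2:
        shuffled = list(module)
        rng.shuffle(shuffled)
        for i in range(1, len(shuffled)):
            j = int(rng.integers(i))
            g.add_edge(shuffled[i], shuffled[j])
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                if rng.random() < module_extra_edge_prob:
                    g.add_edge(module[i], module[j])
    nx.set_edge_attributes(g, edge_confidence, "confidence")
    mod_mu, mod_sd = truth.module_weight_dist
    bg_mu, bg_sd = truth.background_weight_dist
    module_set = set(module)
    pvals: dict = {}
    for n in sorted(g.nodes):
        mu, sd = (mod_mu, mod_sd) if n in module_set else (bg_mu, bg_sd)
        w = max(0.0, rng.normal(mu, sd))
        pvals[n] = 10.0 ** (-w)
    return g, pvals


def gen_cohort_table(spec: SimCohortSpec) -> pd.DataFrame:
    """Simulate a long-format cohort table of two positive gene variables.

    Per site, patient values for the two genes are drawn from a bivariate
    normal on the log scale and exponentiated (Gaussian copula with
    lognormal margins), so values are strictly positive like qPCR ratios.
    The normal-scale correlation is set to 2*sin(pi*rho/6) so that the
    population Spearman correlation equals ``rho`` exactly.

    Columns: patient, site, gene, value.
    """
    rng = np.random.default_rng(spec.seed)
    rho_pearson = 2.0 * np.sin(np.pi * spec.rho / 6.0)
    cov = np.array([[1.0, rho_pearson], [rho_pearson, 1.0]])
    chol = np.linalg.cholesky(cov)
    rows = []
    patients = [f"p{i:03d}" for i in range(spec.n_patients)]
    for site in spec.sites:
        z = rng.standard_normal(size=(spec.n_patients, 2)) @ chol.T
        vals = np.exp(z)
        for pi, patient in enumerate(patients):
            for gi, gene in enumerate(spec.genes):
                rows.append((patient, site, gene, float(vals[pi, gi])))
    return pd.DataFrame(rows, columns=["patient", "site", "gene", "value"])


def gen_linked_instance(
    expr_spec: SimExpressionSpec,
    n_nodes: int = 300,
    module_size: int = 15,
    avg_degree: float = 4.0,
) -> tuple[ExpressionMatrix, list[str], nx.Graph, frozenset]:
    """Expression matrix and PPI graph sharing gene identity.

    The graph's planted module is relabelled with truly differential gene
    ids and the background with non-differential ones, so the
    differential-expression p-values computed from the matrix make the
    planted module the high-weight region of the network — the full
    pipeline benchmark.

    Returns (matrix, de_truth, graph, module gene set).
    """
    m, de_truth = gen_expression(expr_spec)
    if module_size > len(de_truth):
        raise ValueError("module_size exceeds number of truly DE genes")
    if n_nodes > expr_spec.n_genes:
        raise ValueError("n_nodes exceeds number of genes")
    rng = np.random.default_rng(expr_spec.seed + 1)
    module_genes = list(rng.choice(de_truth, size=module_size, replace=False))
    background_pool = sorted(set(m.values.index) - set(de_truth))
    background_genes = list(
        rng.choice(background_pool, size=n_nodes - module_size, replace=False)
    )
    truth = PlantedModuleTruth(
        module_nodes=frozenset(range(module_size)), seed=expr_spec.seed + 2
    )
    g, _ = gen_ppi_with_planted_module(n_nodes, avg_degree, truth)
    labels = {i: module_genes[i] for i in range(module_size)}
    labels.update(
        {i + module_size: background_genes[i] for i in range(len(background_genes))}
    )
    g = nx.relabel_nodes(g, labels)
    return m, de_truth, g, frozenset(module_genes)


def write_string_fixture(graph: nx.Graph, path) -> None:
    """Write a graph as a STRING-links TSV.

    Header ``protein1 protein2 combined_score``; confidence written on the
    integer 0-1000 scale, so the round trip through the reader is lossless
    to 1/1000 resolution.
    """
    if graph is None:
        raise ValueError("graph must not be None")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            score = int(round(float(data.get("confidence", 1.0)) * 1000))
            fh.write(f"{u}\t{v}\t{score}\n")


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    """Genes x samples TSV, first column = gene id."""
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def write_groups_tsv(m: ExpressionMatrix, path) -> None:
    """Two-column sample-to-group TSV."""
    m.groups.rename_axis("sample").to_frame("group").to_csv(path, sep="\t")


def write_cohort_tsv(table: pd.DataFrame, path) -> None:
    """Long-format cohort TSV: patient, site, gene, value."""
    table.to_csv(path, sep="\t", index=False)
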