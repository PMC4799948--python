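"""End-to-end pipeline: preprocess -> differential expression -> network
filtering -> module search -> interactor report.

Stages run in the fixed order of the discovery procedure: present-call
filtering, quantile normalization, array outlier removal, probe collapse,
moderated-t differential expression, confidence filtering of the PPI
network, restriction to measured genes, -log10(p) weighting, GA module
search, and (optionally) an interactor-order report from a query gene.

A run emits every intermediate table plus a reproducibility manifest
(config hash, global seed, per-stage derived seeds, per-stage counts)
sufficient to re-run bit-identically.  One global seed fans out to
per-stage seeds through numpy's SeedSequence spawn-key mechanism, so any
stage can be re-run in isolation with its recorded seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, modsearch, ppi, preprocess

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

STAGE_ORDER = (
    "load",
    "filter_present",
    "normalize",
    "outliers",
    "collapse",
    "diffexp",
    "ppi",
    "weights",
    "search",
    "interactors",
)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, message: str, manifest: dict | None = None):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.manifest = manifest or {}


@dataclass
class PipelineConfig:
    expression_tsv: str
    groups_tsv: str
    edges_tsv: str
    out_dir: str
    annotation_tsv: str | None = None
    calls_tsv: str | None = None
    seed_genes: tuple[str, ...] = ()
    interactor_source: str | None = None
    min_present_fraction: float = 0.5
    min_confidence: float = 0.850
    lambda_penalty: float = modsearch.DEFAULT_LAMBDA
    p_min: float = 1e-300
    alpha: float = 0.05
    ga: modsearch.GAConfig = field(default_factory=modsearch.GAConfig)
    global_seed: int = 0
    case_label: str = "case"
    control_label: str = "control"
    drop_outliers: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ga = modsearch.GAConfig(**raw.pop("ga", {}))
        if "seed_genes" in raw:
            raw["seed_genes"] = tuple(raw["seed_genes"])
        return cls(ga=ga, **raw)

    def validate(self) -> None:
        for name in ("expression_tsv", "groups_tsv", "edges_tsv"):
            p = getattr(self, name)
            if not Path(p).exists():
                stage = "ppi" if name == "edges_tsv" else "load"
                raise PipelineError(stage, f"input file missing: {p}")
        for name in ("annotation_tsv", "calls_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("load", f"input file missing: {p}")
        if not 0 <= self.min_present_fraction <= 1:
            raise PipelineError("load", "min_present_fraction out of [0,1]")
        if not 0 <= self.min_confidence <= 1:
            raise PipelineError("ppi", "min_confidence out of [0,1]")

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["seed_genes"] = list(d["seed_genes"])
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed: SeedSequence(global_seed) spawned at the
    stage's fixed index, reduced below 2**31."""
    idx = STAGE_ORDER.index(stage)
    ss = np.random.SeedSequence(global_seed, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2**31))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_jsonable(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full discovery pipeline; returns the manifest dict.

    Outputs under ``cfg.out_dir``: filtered/normalized/collapsed expression
    TSVs, the DE table, the filtered edge list, ``module.json`` and
    ``manifest.json`` (plus ``interactors.json`` when a query is set).
    Any stage failure raises :class:`PipelineError` naming the stage, with
    the partial manifest attached.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_jsonable(),
        "config_hash": _config_hash(cfg),
        "global_seed": cfg.global_seed,
        "stage_order": list(STAGE_ORDER),
        "stage_seeds": {s: stage_seed(cfg.global_seed, s) for s in STAGE_ORDER},
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    def fail(stage: str, exc: Exception) -> PipelineError:
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=2))
        return PipelineError(stage, str(exc), manifest)

    # -- load ---------------------------------------------------------------
    try:
        values = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
        groups = pd.read_csv(cfg.groups_tsv, sep="\t", index_col=0)["group"]
        calls = None
        if cfg.calls_tsv:
            calls = pd.read_csv(cfg.calls_tsv, sep="\t", index_col=0).astype(bool)
        m = preprocess.ExpressionMatrix(values, groups, calls)
        record("load", probes=m.n_genes, samples=len(m.sample_ids))
    except PipelineError:
        raise
    except Exception as e:
        raise fail("load", e) from e

    # -- preprocessing ------------------------------------------------------
    try:
        m = preprocess.filter_present(m, cfg.min_present_fraction)
        record("filter_present", probes=m.n_genes)
        m = preprocess.quantile_normalize(m)
        record("normalize", probes=m.n_genes)
        flagged = preprocess.detect_outlier_samples(m)
        if flagged and cfg.drop_outliers:
            m = m.subset_samples([s for s in m.sample_ids if s not in flagged])
        record("outliers", flagged=list(flagged), samples=len(m.sample_ids))
        if cfg.annotation_tsv:
            ann_df = pd.read_csv(cfg.annotation_tsv, sep="\t", dtype=str)
            ann = preprocess.ProbeAnnotation(
                dict(zip(ann_df.iloc[:, 0], ann_df.iloc[:, 1]))
            )
            m = preprocess.collapse_to_genes(m, ann)
        record("collapse", genes=m.n_genes)
        from .synthio import write_expression_tsv
        write_expression_tsv(m, out / "expression.processed.tsv")
        manifest["outputs"]["expression"] = "expression.processed.tsv"
    except PipelineError:
        raise
    except Exception as e:
        raise fail("preprocess", e) from e

    # -- differential expression -------------------------------------------
    try:
        de = diffexp.fit_moderated_t(m, "auto", cfg.case_label, cfg.control_label)
        diffexp.write_de_table(de, out / "de_table.tsv")
        manifest["outputs"]["de_table"] = "de_table.tsv"
        record("diffexp", genes=len(de),
               significant_unadj=int((de["p"] < cfg.alpha).sum()))
    except Exception as e:
        raise fail("diffexp", e) from e

    # -- PPI network --------------------------------------------------------
    try:
        g = ppi.read_string_edges(cfg.edges_tsv)
        n0, e0 = g.number_of_nodes(), g.number_of_edges()
        g = ppi.filter_by_confidence(g, cfg.min_confidence)
        g = ppi.restrict_to_measured(g, set(map(str, de.index)))
        ppi.write_edge_tsv(g, out / "network.filtered.tsv")
        manifest["outputs"]["network"] = "network.filtered.tsv"
        record("ppi", nodes_before=n0, edges_before=e0,
               nodes_after=g.number_of_nodes(), edges_after=g.number_of_edges())
    except PipelineError:
        raise
    except Exception as e:
        raise fail("ppi", e) from e

    # -- weights + module search -------------------------------------------
    try:
        w = modsearch.assign_weights(de, cfg.p_min)
        record("weights", weighted_genes=len(w))
        ga_cfg = modsearch.GAConfig(
            **{**asdict(cfg.ga),
               "lambda_penalty": cfg.lambda_penalty,
               "seed": stage_seed(cfg.global_seed, "search")}
        )
        module = modsearch.search_ga(g, w, ga_cfg)
        (out / "module.json").write_text(json.dumps(module.to_dict(), indent=2))
        manifest["outputs"]["module"] = "module.json"
        record("search", module_size=len(module.nodes), score=module.score,
               generations_to_best=module.provenance["generations_to_best"])
    except Exception as e:
        raise fail("search", e) from e

    # -- interactor orders --------------------------------------------------
    if cfg.interactor_source:
        try:
            report = ppi.interaction_order(
                g, cfg.interactor_source,
                sorted(set(module.nodes) - {cfg.interactor_source}),
            )
            report.to_json(out / "interactors.json")
            manifest["outputs"]["interactors"] = "interactors.json"
            reachable = sum(1 for o in report.orders.values() if o is not None)
            record("interactors", source=cfg.interactor_source, reachable=reachable)
        except Exception as e:
            raise fail("interactors", e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
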