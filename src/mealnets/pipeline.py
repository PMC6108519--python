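"""End-to-end orchestration: recalls -> tables -> networks -> communities
-> comparison, with deterministic seeding and a checksummed run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import compare_networks
from .copula import NetworkEstimate, estimate_network
from .intake import HabitualTable, MealTable, build_habitual_table, build_meal_table, load_recalls
from .io import (
    write_centrality_tsv,
    write_communities_json,
    write_cv_json,
    write_edge_tsv,
    write_network_graphml,
)
from .linkcomm import (
    CentralityTable,
    CommunityPartition,
    EdgeGraph,
    community_centrality,
    detect_communities,
)
from .synthetic import generate_recalls, potsdam_preset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineStageError", "run_all"]


class PipelineStageError(RuntimeError):
    """Failure in a named pipeline stage, carrying the partial manifest."""

    def __init__(self, stage: str, cause: BaseException, manifest: "RunManifest"):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips through YAML unchanged."""

    source: str = "simulate"  # "simulate" or a recall CSV path
    output_dir: str = "mealnets-run"
    # simulation
    sim_seed: int = 0
    n_participants: int = 814
    target_pcor: float = 0.35
    participant_effect_sd: float = 0.7
    margin_family: str = "lognormal"
    # estimation
    method: str = "spearman"
    cv_folds: int = 10
    cv_seed: int = 0
    cv_selection_rule: str = "1se"
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01
    eigenvalue_floor: float = 1e-4
    # communities (hooks; only the defaults are implemented)
    community_similarity: str = "jaccard"
    community_tie_rule: str = "finer"
    # comparison
    sign_specific: bool = True

    def __post_init__(self) -> None:
        if self.method not in {"spearman", "kendall"}:
            raise ValueError("method must be spearman or kendall")
        if self.community_similarity != "jaccard":
            raise ValueError("only the unweighted jaccard similarity is implemented")
        if self.community_tie_rule != "finer":
            raise ValueError("only the finer-partition tie rule is implemented")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    config: dict
    version: str
    timings: dict[str, float] = field(default_factory=dict)
    summaries: dict[str, dict] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)  # relative path -> sha256

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _slug(label: str) -> str:
    return label.replace(" ", "_")


def _empty_partition(nodes: tuple[str, ...]) -> CommunityPartition:
    return CommunityPartition(edge_clusters=(), communities=(),
                              partition_density_value=0.0, cut_similarity=1.0,
                              nodes=nodes, unassigned_nodes=nodes, n_edges=0)


def analyse_table(table: MealTable | HabitualTable, config: PipelineConfig
                  ) -> tuple[NetworkEstimate, CommunityPartition, CentralityTable]:
    """SGCGM + link communities for one intake table."""
    est = estimate_network(
        table.matrix(), tuple(table.data.columns), method=config.method,
        k=config.cv_folds, seed=config.cv_seed, n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
        eigenvalue_floor=config.eigenvalue_floor,
        selection_rule=config.cv_selection_rule,
    )
    net = est.network
    if net.edges:
        graph = EdgeGraph.from_edges([(e.u, e.v) for e in net.edges])
        partition, centrality = detect_communities(graph)
    else:
        partition = _empty_partition(())
        centrality = community_centrality(partition)
    return est, partition, centrality


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all artifacts under ``config.output_dir``.

    Deterministic given the seeds in the config: a repeat run reproduces
    every output checksum.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # record the config with a neutral output path so artifacts are
    # byte-identical wherever the run directory lives
    recorded = replace(config, output_dir=".")
    manifest = RunManifest(config=asdict(recorded), version=__version__)

    def record(path: Path) -> None:
        manifest.files[str(path.relative_to(out))] = _sha256(path)

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                logger.info("stage=%s status=start", name)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    logger.error("stage=%s status=failed error=%s", name, exc)
                    raise PipelineStageError(name, exc, manifest) from exc
                logger.info("stage=%s status=done", name)

        return _Stage()

    with stage("recalls"):
        if config.source == "simulate":
            cohort, margins = potsdam_preset(
                seed=config.sim_seed, target_pcor=config.target_pcor,
                participant_effect_sd=config.participant_effect_sd,
                n_participants=config.n_participants,
                margin_family=config.margin_family,
            )
            dataset = generate_recalls(cohort, margins)
            recalls_csv = out / "recalls.csv"
            dataset.to_csv(recalls_csv)
            record(recalls_csv)
            record(out / "recalls.csv.meta.json")
        else:
            dataset = load_recalls(config.source)
        recorded.to_yaml(out / "config.yaml")
        record(out / "config.yaml")

    with stage("tables"):
        tables: dict[str, MealTable | HabitualTable] = {}
        for meal in dataset.main_meals:
            tables[meal] = build_meal_table(dataset, meal)
        tables["habitual"] = build_habitual_table(dataset)
        for name, table in tables.items():
            path = out / f"table_{_slug(name)}.tsv"
            table.to_tsv(path)
            record(path)

    networks = {}
    for name, table in tables.items():
        with stage(f"network[{name}]"):
            est, partition, centrality = analyse_table(table, config)
            networks[name] = est.network
            slug = _slug(name)
            pd.DataFrame(est.skeptic.matrix, index=est.network.nodes,
                         columns=est.network.nodes).to_csv(
                out / f"skeptic_{slug}.tsv", sep="\t", float_format="%.10g")
            write_cv_json(est.cv, out / f"cv_{slug}.json")
            pd.DataFrame(est.fit.precision, index=est.network.nodes,
                         columns=est.network.nodes).to_csv(
                out / f"precision_{slug}.tsv", sep="\t", float_format="%.10g")
            write_edge_tsv(est.network, out / f"edges_{slug}.tsv")
            write_network_graphml(est.network, out / f"network_{slug}.graphml",
                                  partition)
            write_communities_json(partition, out / f"communities_{slug}.json")
            write_centrality_tsv(centrality, out / f"centrality_{slug}.tsv")
            for suffix in ("skeptic_{}.tsv", "cv_{}.json", "precision_{}.tsv",
                           "edges_{}.tsv", "network_{}.graphml",
                           "communities_{}.json", "centrality_{}.tsv"):
                record(out / suffix.format(slug))
            manifest.summaries[name] = {
                "n_obs": table.n_obs,
                "n_edges": est.network.n_edges,
                "n_networks": len(est.network.networks),
                "n_communities": len(partition.communities),
                "lambda_star": est.cv.lambda_star,
                "central_nodes": list(centrality.central_nodes),
            }

    with stage("compare"):
        meal_nets = {m: networks[m] for m in dataset.main_meals}
        report = compare_networks(meal_nets, networks["habitual"],
                                  sign_specific=config.sign_specific)
        report.to_json(out / "overlap_report.json")
        report.to_tsv(out / "overlap_report.tsv")
        discordant_path = out / "discordant_pairs.tsv"
        lines = ["meal\tsource\ttarget"]
        for meal, pairs in report.discordant_pairs.items():
            lines += [f"{meal}\t{u}\t{v}" for u, v in pairs]
        discordant_path.write_text("\n".join(lines) + "\n")
        for f in ("overlap_report.json", "overlap_report.tsv", "discordant_pairs.tsv"):
            record(out / f)

    manifest.to_json(out / "manifest.json")
    return manifest
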