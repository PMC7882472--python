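"""End-to-end orchestration: surveys -> webs -> metrics -> model table.

``run_all`` drives the whole chain from either real input CSVs or a
synthetic study, writes every stage's outputs, and returns a
:class:`RunManifest` whose specimen accounting satisfies, exactly:

    pooled specimens = allocated (sum of all b_ij) + excluded specimens
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import assembly, community, inference, netmetrics, simulate
from .landscape import ConnectivityParams, connectivity_all, design_check, load_patches

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-level knobs; serialisable to/from YAML."""

    delta_threshold: float = 6.0
    ci_level: float = 0.95
    alpha: float = 0.001
    beta: float = 0.5
    radius: float = 2000.0
    area_scale: float = 1e4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def connectivity_params(self) -> ConnectivityParams:
        return ConnectivityParams(self.alpha, self.beta, self.radius, self.area_scale)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    inputs: dict
    config_hash: str
    row_counts: dict = field(default_factory=dict)
    pooled_specimens: int = 0
    allocated_specimens: float = 0.0
    excluded_specimens: int = 0
    exclusions_by_rule: dict = field(default_factory=dict)
    n_fragments: int = 0
    total_links: int = 0
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def run_all(
    out_dir,
    config: PipelineConfig | None = None,
    covers_path=None,
    counts_path=None,
    diet_path=None,
    design_path=None,
    patches_path=None,
    synthetic: bool = False,
    synthetic_config: simulate.SyntheticConfig | None = None,
) -> RunManifest:
    """Run every stage and write webs, metrics.csv, model_table.csv, manifest.

    With ``synthetic=True`` the input tables are generated (seeded from the
    config) and written alongside the outputs; otherwise the four input CSVs
    are required (patches.csv optional — used to compute connectivity when
    the design table lacks the column).
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if synthetic:
        study = simulate.generate_study(synthetic_config, seed=config.seed)
        input_paths = study.write(out / "inputs")
        covers_path = input_paths["covers"]
        counts_path = input_paths["counts"]
        diet_path = input_paths["diet"]
        design_path = input_paths["design"]
        patches_path = input_paths["patches"]
    if covers_path is None or counts_path is None or diet_path is None or design_path is None:
        raise community.SchemaError(
            "run_all needs covers, counts, diet and design tables (or synthetic=True)"
        )

    logger.info("stage load: reading surveys and diet table")
    surveys = community.load_surveys(covers_path, counts_path)
    diet_db = community.load_diet(diet_path)
    design = pd.read_csv(design_path, dtype={"fragment_id": str})

    if "connectivity" not in design.columns:
        if patches_path is None:
            raise community.SchemaError(
                "design table lacks a connectivity column and no patches.csv given"
            )
        logger.info("stage connectivity: computing incidence-function index")
        conn = connectivity_all(load_patches(patches_path), config.connectivity_params())
        design["connectivity"] = design["fragment_id"].map(conn)

    communities = community.fragment_communities(surveys, diet_db)

    logger.info("stage assemble: building %d quantitative webs", len(communities))
    webs = assembly.build_webs(communities, diet_db)
    edge_frames = [web.to_edge_list() for web in webs.values()]
    edges = pd.concat(edge_frames, ignore_index=True)
    edges_path = out / "webs_edge_list.csv"
    edges.to_csv(edges_path, index=False)
    webs_dir = out / "webs"
    webs_dir.mkdir(exist_ok=True)
    for fid, web in webs.items():
        web.to_matrix().to_csv(webs_dir / f"web_{fid}.csv")
        for exc in web.exclusion_log:
            logger.info("fragment %s: excluded %s (%s, %d specimens)",
                        fid, exc.taxon, exc.rule, exc.specimens)

    logger.info("stage metrics: computing weighted web indices")
    metrics = netmetrics.metrics_table(webs, diet_db)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)

    logger.info("stage fit: multimodel inference for all responses")
    table = inference.model_table(
        design, metrics,
        delta_threshold=config.delta_threshold, ci_level=config.ci_level,
    )
    table_path = out / "model_table.csv"
    table.to_csv(table_path, index=False)

    rho = design_check(design)
    rho_path = out / "design_spearman.csv"
    rho.to_csv(rho_path)

    pooled = sum(sum(c.pooled_abundance.values()) for c in communities.values())
    allocated = sum(web.B for web in webs.values())
    excluded = sum(web.excluded_specimens for web in webs.values())
    by_rule: dict[str, int] = {}
    for web in webs.values():
        for exc in web.exclusion_log:
            by_rule[exc.rule] = by_rule.get(exc.rule, 0) + exc.specimens

    manifest = RunManifest(
        inputs={
            "covers": str(covers_path), "counts": str(counts_path),
            "diet": str(diet_path), "design": str(design_path),
            "patches": str(patches_path) if patches_path else None,
        },
        config_hash=config.hash(),
        row_counts={
            "surveys": len(surveys),
            "fragments": len(communities),
            "metrics": len(metrics),
            "model_table": len(table),
        },
        pooled_specimens=int(pooled),
        allocated_specimens=float(allocated),
        excluded_specimens=int(excluded),
        exclusions_by_rule=by_rule,
        n_fragments=len(webs),
        total_links=int(sum(web.n_links for web in webs.values())),
        outputs={
            "edge_list": str(edges_path),
            "webs_dir": str(webs_dir),
            "metrics": str(metrics_path),
            "model_table": str(table_path),
            "design_spearman": str(rho_path),
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
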