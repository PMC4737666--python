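"""End-to-end orchestration: one call reproducing the full analysis workflow.

Read a connectome → graph distances → MDS(3) and Isomap(3, auto-k)
embeddings → centrality validation in anatomic/MDS/Isomap spaces →
center-distance ranking → lesion suite (random Monte-Carlo plus the targeted
schemes) → dimension sweep — collected into a JSON-serializable
:class:`RunReport`.  A single global seed is expanded into per-stage seeds by
a fixed counter scheme (``stage_seed = (seed * 1009 + stage_index) % 2**31``)
so any stage can be rerun in isolation from the recorded parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .lesion import SCHEMES
from .model import IntrinsicGeometry

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_full_pipeline", "stage_seed"]

_STAGE_INDEX = {"random_lesion": 1, "targeted_lesion": 2}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + _STAGE_INDEX[stage]) % 2**31


@dataclass
class PipelineConfig:
    dim: int = 3
    k_start: int = 3
    seed: int = 0
    fraction: float = 0.215
    trials: int = 100  # 0 disables the lesion stage
    schemes: tuple[str, ...] = ("strength", "clustering", "path_length",
                                "betweenness", "embeddedness")
    sweep_dims: tuple[int, ...] = tuple(range(1, 9))
    export_embeddings: bool = True

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("schemes", "sweep_dims"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class RunReport:
    """Machine-readable record of one full pipeline run."""

    input: dict = field(default_factory=dict)
    embeddings: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    ranking: list = field(default_factory=list)
    lesion: dict | None = None
    dimension_sweep: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    failure: dict | None = None

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True,
                          default=_jsonify) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_full_pipeline(matrix_path, nodes_path=None, config: PipelineConfig | dict | None = None,
                      out_dir=None) -> RunReport:
    """Execute every stage on one connectome and return the report.

    Stage errors propagate (annotated with the stage name) after a partial
    report with a failure marker has been written to ``out_dir`` when given.
    With ``config.trials == 0`` the lesion stage is skipped and its report
    section omitted.
    """
    if config is None:
        config = PipelineConfig()
    elif isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    report = RunReport(parameters={
        "dim": config.dim, "k_start": config.k_start, "seed": config.seed,
        "fraction": config.fraction, "trials": config.trials,
        "schemes": list(config.schemes), "sweep_dims": list(config.sweep_dims),
        "matrix_path": str(matrix_path),
        "nodes_path": str(nodes_path) if nodes_path else None,
    })

    stage = "read_inputs"
    try:
        model = IntrinsicGeometry.from_files(matrix_path, nodes_path)
        c = model.connectome
        density = float((c.weights > 0).sum() / (c.n * (c.n - 1)))
        report.input = {"n": c.n, "density": density,
                        "total_weight": float(c.weights.sum() / 2.0)}

        stage = "embedding"
        results = {}
        for method in ("mds", "isomap"):
            res = model.fit(method=method, dim=config.dim, k_start=config.k_start)
            results[method] = res
            report.embeddings[method] = {
                "dim": res.embedding.dim,
                "k_used": res.embedding.k_used,
                "residual_variance": res.residual_variance,
                "eigenvalues": list(res.embedding.eigenvalues),
                "dbar": res.dbar,
            }
            if out_dir is not None and config.export_embeddings and config.dim == 3:
                res.export_json(out_dir / f"embedding_{method}.json")

        stage = "validation"
        from .metrics import centrality_validation

        for method, res in results.items():
            v = res.validation
            report.validation[method] = {"r_squared": v.r_squared, "slope": v.slope,
                                         "intercept": v.intercept}
        if model.nodes is not None and model.nodes.anatomic_xyz is not None:
            v = centrality_validation(model.nodes.anatomic_xyz,
                                      model.nodal_path_length, space="anatomic")
            report.validation["anatomic"] = {"r_squared": v.r_squared, "slope": v.slope,
                                             "intercept": v.intercept}

        stage = "ranking"
        rank = results["isomap"].rank_table()
        report.ranking = rank.to_dict(orient="records")

        if config.trials > 0:
            stage = "lesion"
            report.lesion = {}
            dist = model.random_removal(config.fraction, config.trials,
                                        seed=stage_seed(config.seed, "random_lesion"),
                                        dim=config.dim)
            report.lesion["random"] = {
                "trials": dist.trials, "mean": dist.mean,
                "percentile_5": dist.interval[0], "percentile_95": dist.interval[1],
                "redraws": dist.redraws, "seed": dist.seed,
            }
            schemes = list(config.schemes)
            if model.nodes is not None and model.nodes.rich_club is not None \
                    and model.nodes.rich_club.any() and "rich_club" not in schemes:
                schemes.append("rich_club")
            for scheme in schemes:
                if scheme not in SCHEMES:
                    raise ValueError(f"unknown lesion scheme {scheme!r}")
                r = model.lesion(scheme, config.fraction, dim=config.dim,
                                 seed=stage_seed(config.seed, "targeted_lesion"))
                report.lesion[scheme] = {
                    "removed": list(r.removed),
                    "dbar_raw": r.dbar_raw,
                    "dbar_normalized": r.dbar_normalized,
                }

        stage = "dimension_sweep"
        sweep = model.dimension_sweep(config.sweep_dims)
        report.dimension_sweep = {"dims": list(sweep.dims), "rmse": list(sweep.rmse),
                                  "k_used": list(sweep.k_used)}
    except Exception as exc:
        report.failure = {"stage": stage, "error": str(exc)}
        if out_dir is not None:
            report.write(out_dir / "report.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if out_dir is not None:
        report.write(out_dir / "report.json")
    return report
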