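"""End-to-end wiring: score table → aggregation → Pareto analysis → reports.

One call executes the analysis half of a differential screening campaign on
an existing replicate score table: robust outlier trimming and trimmed-mean
aggregation per (ligand, condition), objective-pair assembly, dominance
enumeration with λ-support annotation, and report emission (aggregated CSV,
Pareto JSON, scatter-export CSV, run log). Per-ligand independence makes
external parallelization trivial; this runs single-process.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from . import io_formats, pareto
from .aggregate import DEFAULT_Q, aggregate as aggregate_scores, aggregated_to_frame
from .models import DomainError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    Condition labels name the two environments in the score table; θ1
    (acidic, pH 5.0 by default) is the maximized objective, θ2 (neutral,
    pH 7.4) the minimized one. Docking provenance (engine exhaustiveness
    etc.) may be carried in ``provenance`` as metadata only.
    """

    scores_path: str = ""
    out_dir: str = "."
    acidic_label: str = "acidic"
    neutral_label: str = "neutral"
    acidic_ph: float = 5.0
    neutral_ph: float = 7.4
    q: float = DEFAULT_Q
    lambda_grid: int = pareto.DEFAULT_LAMBDA_GRID
    epsilon: float = 0.0
    k_layers: int = 1
    alpha: Optional[float] = None
    neutral_max: Optional[float] = None
    top_k: int = 3
    paired: bool = False
    seed: int = 0
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.acidic_label == self.neutral_label:
            raise DomainError("condition labels must be distinct")
        if not 0.0 < self.q < 1.0:
            raise DomainError("q must be in (0, 1)")
        if self.lambda_grid < 2:
            raise DomainError("lambda_grid must be >= 2")

    @classmethod
    def from_file(cls, path: PathLike, **overrides) -> "RunConfig":
        """Load from a YAML (or JSON — a YAML subset) config file.

        Keyword overrides win over file values, so CLI flags can override
        the config.
        """
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise DomainError(f"{path}: config must be a mapping")
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise DomainError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunSummary:
    """What a pipeline run produced, with the counts the log records."""

    n_observations: int
    n_ligands: int
    n_outliers: int
    front_size: int
    outputs: dict[str, str]


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute analysis + optimization on a score table; write reports.

    Emits into ``config.out_dir``: ``aggregated.csv``, ``pareto.json``,
    ``scatter.csv`` and ``run_log.json``. Any stage failure raises
    :class:`StageError` naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        observations = io_formats.read_score_table(config.scores_path)
    except Exception as exc:
        raise StageError("read_score_table", exc) from exc

    try:
        aggregated = aggregate_scores(observations, q=config.q)
    except Exception as exc:
        raise StageError("aggregate", exc) from exc

    try:
        points = pareto.objective_pairs_from_aggregates(
            aggregated,
            acidic_label=config.acidic_label,
            neutral_label=config.neutral_label,
        )
        if not points:
            raise DomainError(
                "no ligand has scores under both conditions "
                f"({config.acidic_label!r}, {config.neutral_label!r})"
            )
        results = pareto.pareto_front(points, lambda_grid=config.lambda_grid)
        if config.alpha is not None:
            results = pareto.constrained_front(
                points, config.alpha, lambda_grid=config.lambda_grid
            )
        elif config.k_layers > 1 or config.epsilon > 0:
            mode = "layers" if config.k_layers > 1 else "additive"
            results = pareto.epsilon_front(
                points, mode=mode, k=config.k_layers, eps=config.epsilon,
                lambda_grid=config.lambda_grid,
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("pareto", exc) from exc

    try:
        agg_path = out_dir / "aggregated.csv"
        aggregated_to_frame(aggregated).to_csv(agg_path, index=False)
        report_path = out_dir / "pareto.json"
        io_formats.write_report(results, report_path)
        scatter_path = out_dir / "scatter.csv"
        pareto.results_to_frame(
            pareto.pareto_front(points, lambda_grid=config.lambda_grid)
        ).to_csv(scatter_path, index=False)
    except Exception as exc:
        raise StageError("write_report", exc) from exc

    n_outliers = sum(a.n_outliers for a in aggregated)
    front_size = sum(1 for r in results if r.on_front)
    summary = RunSummary(
        n_observations=len(observations),
        n_ligands=len(points),
        n_outliers=n_outliers,
        front_size=front_size,
        outputs={
            "aggregated": str(agg_path),
            "pareto": str(report_path),
            "scatter": str(scatter_path),
        },
    )
    log_path = out_dir / "run_log.json"
    log_payload = {
        "config": asdict(config),
        "n_observations": summary.n_observations,
        "n_ligands": summary.n_ligands,
        "n_outliers": summary.n_outliers,
        "front_size": summary.front_size,
        "outputs": summary.outputs,
    }
    log_path.write_text(json.dumps(log_payload, indent=2) + "\n", encoding="utf-8")
    summary.outputs["log"] = str(log_path)
    logger.info(
        "pipeline: %d observations, %d ligands, %d outliers removed, "
        "front size %d",
        summary.n_observations, summary.n_ligands, summary.n_outliers,
        summary.front_size,
    )
    return summary
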