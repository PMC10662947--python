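"""End-to-end orchestration from a single YAML-loadable configuration."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import SymptomTrajectoryModel, _jsonable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs; defaults are the reference study design (5 y lookback, 10:1, alpha 0.05)."""

    source: str = "registry"
    lookback_years: float = 5.0
    control_ratio: int = 10
    n_comparison_groups: int = 10
    alpha: float = 0.05
    min_support: int | None = None  # 100 registry / 20 notes when None
    trajectory_length: int = 3
    survival_split_days: float = 90.0
    follower_mode: str = "pre_only"
    seed: int = 0
    registry_path: str = "registry.tsv"
    confirmed_path: str = "cancer_registry_ids.txt"
    notes_path: str | None = None
    dictionary_path: str | None = None
    out_dir: str = "out"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.control_ratio < 1 or self.n_comparison_groups < 1:
            raise ValueError("ratios must be >= 1")
        if self.trajectory_length not in (3, 4):
            raise ValueError("trajectory_length must be 3 or 4")
        if self.source not in ("registry", "notes", "both"):
            raise ValueError("source must be registry, notes or both")
        if self.source in ("notes", "both") and not self.notes_path:
            raise ValueError("notes source needs notes_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute cohort → (text mining) → pair screen → trajectories.

    Writes all tables plus a JSON manifest per source under
    ``out_dir/<source>/``; returns the combined manifest.  Any stage error
    aborts with the stage name attached.
    """
    config.validate()
    with open(config.confirmed_path) as fh:
        confirmed = {line.strip() for line in fh if line.strip()}

    sources = ["registry", "notes"] if config.source == "both" else [config.source]
    combined: dict = {"sources": {}}
    for source in sources:
        model = SymptomTrajectoryModel.from_files(
            config.registry_path,
            confirmed,
            notes_jsonl=config.notes_path if source == "notes" else None,
            dictionary_tsv=config.dictionary_path if source == "notes" else None,
            source=source,
            lookback_years=config.lookback_years,
            control_ratio=config.control_ratio,
            n_comparison_groups=config.n_comparison_groups,
            alpha=config.alpha,
            min_support=config.min_support,
            trajectory_length=config.trajectory_length,
            survival_split_days=config.survival_split_days,
            follower_mode=config.follower_mode,
        )
        try:
            results = model.fit(seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{source} fit' failed: {exc}") from exc
        out = Path(config.out_dir) / source
        results.to_tsv(out)
        logger.info(
            "source=%s: m_effect=%s m_direction=%s edges=%s trajectories=%s",
            source,
            results.manifest["m_effect"],
            results.manifest["m_direction"],
            results.manifest["n_edges"],
            results.manifest["n_trajectories"],
        )
        combined["sources"][source] = results.manifest

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(_jsonable(combined), fh, indent=1)
    return combined
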