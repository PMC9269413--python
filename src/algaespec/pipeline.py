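"""End-to-end orchestration: generate -> extract -> screen -> train -> evaluate.

A :class:`PipelineConfig` (constructible from YAML) drives one seeded run.
The master seed deterministically derives independent per-stage seeds, so
adding a stage never perturbs earlier stages' randomness, and re-running
the same config is bit-identical except for timings (which live only in
the manifest, never in ``report.json``).

To avoid information leakage, the train/test split happens before
variable screening: the ranking and elimination trace are computed on the
training split only, and the test split is touched exactly once, at final
evaluation.  The classifier by default uses the fixed 8-variable optimal
subset ("optimal8"); set ``feature_subset: screened`` to classify on the
subset selected by the run's own elimination trace instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    GridConfig,
    SeaweedClassifier,
    SplitSpec,
    grid_search_svm,
    split_train_test,
)
from .evaluate import pca_class_representation
from .features import OPTIMAL_SUBSET_8, build_feature_table, write_feature_table
from .screening import backward_eliminate, rank_variables
from .simulate import GeneratorConfig, NoiseModel, default_counts, generate_dataset
from .spectra import SPECIES, write_spectra

__all__ = ["PipelineConfig", "run_full_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (below 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    outdir: Path = Path("algaespec_run")
    master_seed: int = 0
    n_samples: int = 382
    noise: NoiseModel = field(default_factory=NoiseModel)
    alpha: float = 0.05
    split: SplitSpec = field(default_factory=SplitSpec)
    grid: str = "coarse"  # "coarse" | "fine" | "small"
    level: str = "species"  # "species" | "phylum"
    model_kind: str = "svm"  # "svm" | "fusion"
    feature_subset: str | Sequence[str] = "optimal8"  # or "screened" or explicit list

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.level not in ("species", "phylum"):
            raise ValueError(f"level must be species|phylum, got {self.level!r}")
        if self.model_kind not in ("svm", "fusion"):
            raise ValueError(f"model_kind must be svm|fusion, got {self.model_kind!r}")
        if self.grid not in ("coarse", "fine", "small"):
            raise ValueError(f"grid must be coarse|fine|small, got {self.grid!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "noise" in raw:
            raw["noise"] = NoiseModel(**raw["noise"])
        if "split" in raw:
            raw["split"] = SplitSpec(**raw["split"])
        return cls(**raw)

    def grid_config(self) -> GridConfig:
        return getattr(GridConfig, self.grid)()

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir),
            "master_seed": self.master_seed,
            "n_samples": self.n_samples,
            "noise": vars(self.noise) | {},
            "alpha": self.alpha,
            "split": {
                "train_fraction": self.split.train_fraction,
                "stratified": self.split.stratified,
                "seed": self.split.seed,
            },
            "grid": self.grid,
            "level": self.level,
            "model_kind": self.model_kind,
            "feature_subset": (
                self.feature_subset
                if isinstance(self.feature_subset, str)
                else list(self.feature_subset)
            ),
        }


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts under ``config.outdir``, return the report."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "generate"
    try:
        t0 = time.perf_counter()
        gen = GeneratorConfig(
            counts=default_counts(config.n_samples),
            noise=config.noise,
            seed=stage_seed(config.master_seed, "generate"),
        )
        sset = generate_dataset(gen)
        write_spectra(sset, out / "spectra.csv", dialect="long_csv")
        timings[stage] = time.perf_counter() - t0

        stage = "extract"
        t0 = time.perf_counter()
        table = build_feature_table(sset)
        write_feature_table(table, out / "features.csv")
        timings[stage] = time.perf_counter() - t0

        stage = "split"
        t0 = time.perf_counter()
        split = SplitSpec(
            train_fraction=config.split.train_fraction,
            stratified=config.split.stratified,
            seed=stage_seed(config.master_seed, "split"),
        )
        train, test = split_train_test(table, split, label_col=config.level)
        timings[stage] = time.perf_counter() - t0

        stage = "screen"
        t0 = time.perf_counter()
        ranking = rank_variables(train, label_col=config.level, alpha=config.alpha)
        eval_seed = stage_seed(config.master_seed, "screen")
        small_grid = GridConfig.small()

        def subset_cv_accuracy(subset: tuple[str, ...]) -> float:
            sub = train[list(subset)].to_numpy(dtype=float)
            y = train[config.level].to_numpy()
            _, _, _, surface = grid_search_svm(sub, y, small_grid, seed=eval_seed)
            return float(surface["cv_accuracy"].max())

        trace = backward_eliminate(subset_cv_accuracy, ranking)
        _write_json(
            out / "screening.json",
            {"ranking": ranking.to_dict(), "elimination": trace.to_dict()},
        )
        timings[stage] = time.perf_counter() - t0

        stage = "train"
        t0 = time.perf_counter()
        if config.feature_subset == "optimal8":
            subset = OPTIMAL_SUBSET_8
        elif config.feature_subset == "screened":
            subset = trace.best_subset
        else:
            subset = tuple(config.feature_subset)
        model = SeaweedClassifier(
            train,
            label_col=config.level,
            feature_subset=subset,
            kind=config.model_kind,
            grid=config.grid_config(),
            seed=stage_seed(config.master_seed, "train"),
        )
        res = model.fit()
        _write_json(out / "model.json", res.to_dict())
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        report_obj = res.evaluate(test)
        pc1 = {}
        for sp in SPECIES:
            try:
                _, ev = pca_class_representation(sset, sp)
                pc1[sp] = float(ev)
            except ValueError:
                pc1[sp] = None
        # the output directory is run metadata, not part of the scientific
        # configuration; keep report.json identical across output locations
        report_config = {k: v for k, v in config.to_dict().items() if k != "outdir"}
        report = {
            "config": report_config,
            "chosen_subset": list(subset),
            "screened_best_subset": list(trace.best_subset),
            "svm_params": {"g": res.g, "c": res.c},
            "cv_accuracy_pct": res.cv_accuracy,
            "test": report_obj.to_dict(),
            "pc1_explained_pct": pc1,
            "n_train": int(len(train)),
            "n_test": int(len(test)),
        }
        _write_json(out / "report.json", report)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        logger.error("pipeline stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "algaespec_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "master_seed": config.master_seed,
        "stage_seeds": {
            s: stage_seed(config.master_seed, s)
            for s in ("generate", "split", "screen", "train")
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    _write_json(out / "manifest.json", manifest)
    return report
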