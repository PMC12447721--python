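"""One-config reproducible runs: simulate/load -> preprocess -> CV -> train ->
evaluate -> explain -> biomarker catalog, with every artifact stamped by the
config hash and seed."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    OmicsMatrix,
    ScoreSchema,
    ScoreMatrix,
    default_schema,
    read_matrix,
    read_scores,
    write_matrix,
    write_scores,
)
from .model import (
    ArchitectureSpec,
    Hyperparams,
    build_model,
    predict_scores,
    train,
)
from .evaluate import crossval_pipeline, mse_per_output
from .resampling import rus_plan, stratified_kfold
from .shapley import categorize_biomarkers, explain_all
from .simulate import SimConfig, concatenate_omics, simulate_cohort


class ConfigError(ValueError):
    """A run config failed validation before any compute."""


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    simulate: dict | None = None          # SimConfig kwargs (omics generated)
    data: dict | None = None              # paths: omics {kind: path}, scores, labels
    schema: list[dict] | None = None      # OutputSpec blocks; default 12-output
    architecture: dict = field(default_factory=dict)
    hyperparams: dict = field(default_factory=dict)
    resampling: dict = field(default_factory=lambda: {"k_folds": 5, "rus_iterations": 0})
    shap: dict = field(default_factory=lambda: {"background_size": 100, "top_k": 10, "cutoff": 0.75})
    network: dict = field(default_factory=lambda: {"threshold": 0.3})

    def validate(self) -> None:
        if self.simulate is None and self.data is None:
            raise ConfigError("config needs a 'simulate' or 'data' block")
        if self.simulate is not None and self.data is not None:
            raise ConfigError("'simulate' and 'data' blocks are mutually exclusive")
        if self.data is not None and self.schema is None:
            raise ConfigError("a 'schema' block is required when loading data")

    def schema_obj(self) -> ScoreSchema:
        return default_schema() if self.schema is None else ScoreSchema.from_dict(self.schema)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "seed": self.seed,
                "simulate": self.simulate,
                "data": self.data,
                "schema": self.schema,
                "architecture": self.architecture,
                "hyperparams": self.hyperparams,
                "resampling": self.resampling,
                "shap": self.shap,
                "network": self.network,
            },
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> tuple[OmicsMatrix, ScoreMatrix, pd.Series]:
    schema = config.schema_obj()
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = SimConfig(schema=schema, **sim_kwargs)
        omics, scores, labels, _truth = simulate_cohort(cfg)
        return concatenate_omics(omics), scores, labels
    paths = config.data
    mats = {
        kind: read_matrix(p, kind=kind) for kind, p in paths.get("omics", {}).items()
    }
    X = concatenate_omics(mats) if len(mats) > 1 else next(iter(mats.values()))
    Y = read_scores(paths["scores"], schema)
    labels = pd.read_csv(paths["labels"], sep="\t", index_col=0).iloc[:, 0]
    return X, Y, labels


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full workflow and write artifacts under ``out_dir``.

    Artifacts: resolved config, cross-validated metrics, the model trained on
    all samples, per-output attributions, and the biomarker catalog.  All
    randomness descends from ``config.seed``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
    }
    (out / "config.yaml").write_text(config.to_yaml())

    X, Y, labels = _load_inputs(config)
    schema = Y.schema
    arch = ArchitectureSpec(n_features=X.n_features, **config.architecture)
    hp = Hyperparams(seed=config.seed, **config.hyperparams)

    folds = stratified_kfold(
        labels.loc[X.sample_ids].to_numpy(), k=config.resampling.get("k_folds", 5),
        seed=config.seed,
    )
    folds.to_json(out / "folds.json")

    cv = crossval_pipeline(X, Y, labels, folds, arch=arch, hp=hp)
    metrics = {
        "binary": cv.metrics.binary.mean().to_dict(),
        "binary_sd": cv.metrics.binary.std().to_dict(),
        "per_output_mse": cv.metrics.per_output_mse.mean().to_dict(),
        **stamp,
    }
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

    n_iter = config.resampling.get("rus_iterations", 0)
    if n_iter:
        plan = rus_plan(labels.loc[X.sample_ids].to_numpy(), n_iter=n_iter, seed=config.seed)
        plan.to_json(out / "rus_plan.json")

    final = train(build_model(arch, schema, seed=config.seed), X, Y, hp)
    final.save(out / "model")

    shap_cfg = config.shap
    atts = explain_all(
        final, X,
        background_size=min(shap_cfg.get("background_size", 100), X.n_samples),
        n_coalitions=shap_cfg.get("n_coalitions"),
        seed=config.seed,
    )
    np.savez(
        out / "attributions.npz",
        **{a.output_name: a.phi for a in atts},
        features=np.array(atts[0].feature_ids),
        samples=np.array(atts[0].sample_ids),
    )
    catalog = categorize_biomarkers(
        atts, top_k=shap_cfg.get("top_k", 10), cutoff=shap_cfg.get("cutoff", 0.75)
    )
    (out / "catalog.json").write_text(json.dumps({**catalog.to_dict(), **stamp}, indent=2))

    return {"metrics": metrics, "catalog": catalog, "model_dir": str(out / "model"), **stamp}
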