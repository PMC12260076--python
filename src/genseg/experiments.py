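"""Experiment orchestration: configs, evaluation, multi-seed comparisons.

An experiment trains one or more methods (the end-to-end trilevel method,
the separate two-phase baseline, or the vanilla no-augmentation baseline)
on a dataset — either loaded from a PNG/CSV manifest or generated by the
synthetic-shape fixtures — evaluates on the in-domain test split and on any
configured out-of-domain datasets, and writes per-seed scores plus
mean ± sd summaries (the convention is three seeds) as CSV and JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augmentation import AugmentConfig, ElasticConfig
from .autodiff import Tensor, no_grad
from .fixtures import (OODShift, SegDataset, ShapeDatasetConfig,
                       generate_shape_dataset, load_dataset, make_ood_variant)
from .mlo import (MLOConfig, ModelConfig, OptimSettings, train_genseg,
                  train_separate, train_vanilla)
from .segmodel import METRICS, predict_masks

__all__ = ["RunConfig", "evaluate", "run_experiment", "load_run_config"]

_TRAINERS = {"genseg", "separate", "vanilla"}


@dataclass
class RunConfig:
    """Everything one experiment needs, loadable from YAML/JSON."""

    methods: tuple = ("genseg", "vanilla")
    metric: str = "dice"
    seeds: tuple = (0, 1, 2)
    output_dir: str = "runs/experiment"
    # dataset: either a manifest path or a fixture specification
    manifest: str | None = None
    fixture: dict = field(default_factory=lambda: {
        "shape_kind": "blob", "image_size": 32,
        "n_train": 10, "n_val": 5, "n_test": 30,
    })
    ood: dict | None = None          # OODShift fields, applied to the test split
    mlo: dict = field(default_factory=dict)        # MLOConfig overrides
    model: dict = field(default_factory=dict)      # ModelConfig overrides
    augment: dict = field(default_factory=dict)    # AugmentConfig overrides

    def validate(self):
        if self.metric not in METRICS:
            raise ValueError(f"config key 'metric': must be one of {sorted(METRICS)}")
        for m in self.methods:
            if m not in _TRAINERS:
                raise ValueError(f"config key 'methods': unknown method {m!r}")
        if self.manifest is not None and not Path(self.manifest).exists():
            raise ValueError(f"config key 'manifest': path {self.manifest} does not exist")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("methods", "seeds"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def evaluate(seg, s_params: dict, dataset: SegDataset, metric: str = "dice",
             positive_label: int = 1) -> dict:
    """Per-pair metric on argmax predictions, plus the arithmetic mean."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    metric_fn = METRICS[metric]
    imgs = Tensor(dataset.images())
    with no_grad():
        scores = seg.forward(imgs, s_params)
    preds = predict_masks(scores)
    per_pair = [metric_fn(p, m, positive_label)
                for p, m in zip(preds, dataset.masks())]
    return {"mean": float(np.mean(per_pair)), "per_pair": per_pair,
            "metric": metric, "n": len(per_pair)}


def _build_datasets(cfg: RunConfig):
    if cfg.manifest is not None:
        d_tr = load_dataset(cfg.manifest, "train")
        d_val = load_dataset(cfg.manifest, "validation")
        d_te = load_dataset(cfg.manifest, "test")
    else:
        fx = dict(cfg.fixture)
        base_seed = int(fx.pop("seed", 7))
        n_tr = int(fx.pop("n_train", 10))
        n_val = int(fx.pop("n_val", 5))
        n_te = int(fx.pop("n_test", 30))
        mk = lambda n, split, off: generate_shape_dataset(ShapeDatasetConfig(
            n=n, split=split, seed=base_seed + off, **fx))
        d_tr, d_val, d_te = mk(n_tr, "train", 0), mk(n_val, "validation", 1), mk(n_te, "test", 2)
    ood = None
    if cfg.ood:
        ood = make_ood_variant(d_te, OODShift(**cfg.ood), seed=9001)
    return d_tr, d_val, d_te, ood


def _mlo_config(cfg: RunConfig, seed: int) -> MLOConfig:
    overrides = dict(cfg.mlo)
    base = MLOConfig.toy() if overrides.pop("preset", "toy") == "toy" else MLOConfig()
    for k, v in overrides.items():
        if k.startswith("opt_"):
            setattr(base, k, OptimSettings(**v))
        else:
            setattr(base, k, v)
    base.seed = seed
    base.metric = cfg.metric
    base.validate()
    return base


def _aug_config(cfg: RunConfig) -> AugmentConfig:
    kw = dict(cfg.augment)
    if "elastic" in kw and kw["elastic"] is not None:
        kw["elastic"] = ElasticConfig(**kw["elastic"])
    for key in ("rotation_range", "enabled_ops"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    return AugmentConfig(**kw)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_experiment(config_path) -> dict:
    """Train, evaluate and report per the run config; returns the summary.

    Writes ``report.csv`` (one row per method × dataset × seed) and
    ``summary.json`` (means and standard deviations across seeds, config
    hash, seeds, package version) into the configured output directory.
    """
    cfg = load_run_config(config_path) if not isinstance(config_path, RunConfig) else config_path
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    d_tr, d_val, d_te, ood = _build_datasets(cfg)
    model_cfg = ModelConfig(image_size=d_tr[0].mask.shape[0],
                            label_count=d_tr.label_count, **cfg.model)
    aug = _aug_config(cfg)

    rows = []
    for method in cfg.methods:
        for seed in cfg.seeds:
            mlo_cfg = _mlo_config(cfg, seed)
            log = out_dir / f"{method}_seed{seed}.jsonl"
            if method == "genseg":
                state = train_genseg(d_tr, d_val, mlo_cfg, model_cfg, aug, log_path=log)
            elif method == "separate":
                state = train_separate(d_tr, d_val, mlo_cfg, model_cfg, aug, log_path=log)
            else:
                state = train_vanilla(d_tr, d_val, mlo_cfg, model_cfg, log_path=log)
            seg = state.models[2]
            best_s = state.best_s_params()
            targets = [("in_domain", d_te)] + ([("ood", ood)] if ood is not None else [])
            for ds_name, ds in targets:
                res = evaluate(seg, best_s, ds, cfg.metric)
                rows.append({"method": method, "dataset": ds_name, "seed": seed,
                             "score": res["mean"], "metric": cfg.metric,
                             "best_val": state.best_metric})
    report = pd.DataFrame(rows)
    report.to_csv(out_dir / "report.csv", index=False)

    summary = {"config_hash": _config_hash(cfg), "seeds": list(cfg.seeds),
               "version": __version__, "metric": cfg.metric, "results": {}}
    for (method, ds_name), grp in report.groupby(["method", "dataset"]):
        summary["results"][f"{method}/{ds_name}"] = {
            "mean": float(grp["score"].mean()),
            "sd": float(grp["score"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "per_seed": {int(s): float(v) for s, v in zip(grp["seed"], grp["score"])},
        }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
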