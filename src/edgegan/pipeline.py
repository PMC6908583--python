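"""End-to-end pipeline configuration and orchestration.

``RunConfig`` is a versioned YAML schema (unknown keys are errors, to
protect reproducibility); :func:`run_pipeline` executes the demo flow
simulate -> train -> classify -> evaluate on the synthetic texture classes
and writes a deterministic JSON report: re-running an identical config
reproduces identical model fingerprints and identical report bytes.

Every stochastic stage receives an explicit seed derived from the single
top-level seed in a fixed order; the derived seeds are echoed in the
report so any number in it is recomputable from the config alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cgan import DiscriminatorSpec, GeneratorSpec, TrainingConfig, train_class_model
from .classify import classify_hpf, classify_tiles
from .edges import SIGMA_PRESETS, EdgeParams
from .errors import InvalidArgumentError
from .evaluation import confusion_from_labels, f1, precision, sensitivity
from .registry import ModelRegistry, save_registry
from .synthetic import TextureClassSpec, default_specs, generate_hpf, generate_tiles
from .tiles import stack_pixels

_SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version", "seed", "out_dir", "tile_size", "edge", "metric",
    "classes", "n_train_tiles", "n_test_tiles", "hpf", "training",
    "generator", "discriminator", "log_level",
}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise InvalidArgumentError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def resolve_edge_params(edge: str | dict) -> EdgeParams:
    """Map a sigma preset name ('sigma_2' / 'sigma_5') or an explicit
    parameter mapping to EdgeParams."""
    if isinstance(edge, str):
        if edge not in SIGMA_PRESETS:
            raise InvalidArgumentError(
                f"unknown edge preset {edge!r}; choose from {sorted(SIGMA_PRESETS)}"
            )
        return SIGMA_PRESETS[edge]
    _check_keys(edge, {"sigma", "low_fraction", "high_fraction"}, "edge")
    return EdgeParams(sigma=float(edge.get("sigma", 2.0)),
                      low_fraction=float(edge.get("low_fraction", 0.1)),
                      high_fraction=float(edge.get("high_fraction", 0.2)))


@dataclass
class RunConfig:
    """Validated pipeline configuration (schema version 1)."""

    seed: int = 0
    out_dir: str = "edgegan_run"
    tile_size: int = 64
    edge: str | dict = "sigma_2"
    metric: str = "mse"
    classes: list = field(default_factory=lambda: [s.to_dict() for s in default_specs()])
    n_train_tiles: int = 200
    n_test_tiles: int = 50
    hpf: dict = field(default_factory=lambda: {"count": 10, "size": [192, 192], "n_windows": 50})
    training: dict = field(default_factory=dict)
    generator: dict = field(default_factory=dict)
    discriminator: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "top level")
        version = raw.get("schema_version", _SCHEMA_VERSION)
        if version != _SCHEMA_VERSION:
            raise InvalidArgumentError(
                f"unsupported schema_version {version!r} (expected {_SCHEMA_VERSION})"
            )
        kwargs = {k: v for k, v in raw.items() if k != "schema_version"}
        cfg = cls(**kwargs)
        cfg.resolve()  # validate eagerly, before any work
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InvalidArgumentError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def resolve(self) -> dict:
        """Materialise derived objects; raises on any invalid field."""
        edge_params = resolve_edge_params(self.edge)
        specs = [TextureClassSpec.from_dict(d) if isinstance(d, dict) else d
                 for d in self.classes]
        if len({s.name for s in specs}) != len(specs):
            raise InvalidArgumentError("class names must be unique")
        _check_keys(self.training, {"epochs", "batch_size", "learning_rate", "beta1",
                                    "lambda_mse", "lambda_adv", "noise_mode",
                                    "adversarial_form"}, "training")
        _check_keys(self.generator, {"depth", "base_filters", "dropout_rate"}, "generator")
        _check_keys(self.discriminator, {"conv_stages", "base_filters"}, "discriminator")
        _check_keys(self.hpf, {"count", "size", "n_windows"}, "hpf")
        gspec = GeneratorSpec(depth=int(self.generator.get("depth", 3)),
                              base_filters=int(self.generator.get("base_filters", 16)),
                              dropout_rate=float(self.generator.get("dropout_rate", 0.5)))
        dspec = DiscriminatorSpec(conv_stages=int(self.discriminator.get("conv_stages", 3)),
                                  base_filters=int(self.discriminator.get("base_filters", 16)))
        return {"edge_params": edge_params, "specs": specs, "gspec": gspec, "dspec": dspec}

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION, "seed": self.seed,
            "out_dir": self.out_dir, "tile_size": self.tile_size,
            "edge": self.edge, "metric": self.metric, "classes": self.classes,
            "n_train_tiles": self.n_train_tiles, "n_test_tiles": self.n_test_tiles,
            "hpf": self.hpf, "training": self.training, "generator": self.generator,
            "discriminator": self.discriminator, "log_level": self.log_level,
        }


def derive_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """Derive one child seed (< 2^31) per named stage, in a fixed order."""
    rng = np.random.default_rng(seed)
    return {name: int(rng.integers(0, 2**31 - 1)) for name in names}


def run_pipeline(cfg: RunConfig, progress=None) -> dict:
    """Run simulate -> train -> classify -> evaluate; returns the report
    dict and writes report.json, config.yaml and the model registry under
    ``cfg.out_dir``."""
    resolved = cfg.resolve()
    edge_params: EdgeParams = resolved["edge_params"]
    specs: list[TextureClassSpec] = resolved["specs"]
    gspec: GeneratorSpec = resolved["gspec"]
    dspec: DiscriminatorSpec = resolved["dspec"]
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage_names = (["train:" + s.name for s in specs]
                   + ["hpf_gen", "hpf_classify"])
    seeds = derive_seeds(cfg.seed, stage_names)

    def note(msg: str) -> None:
        if progress is not None:
            progress(msg)

    # --- simulate + train one model per class --------------------------
    registry = ModelRegistry()
    test_tiles = []
    for spec in specs:
        note(f"training class {spec.name!r}")
        n_total = cfg.n_train_tiles + cfg.n_test_tiles
        tiles = generate_tiles(spec, n_total, cfg.tile_size)
        train, test = tiles[:cfg.n_train_tiles], tiles[cfg.n_train_tiles:]
        tcfg = TrainingConfig(
            epochs=int(_cfg_get(cfg.training, "epochs", 5)),
            batch_size=int(_cfg_get(cfg.training, "batch_size", 4)),
            learning_rate=float(_cfg_get(cfg.training, "learning_rate", 1e-3)),
            beta1=float(_cfg_get(cfg.training, "beta1", 0.5)),
            lambda_mse=float(_cfg_get(cfg.training, "lambda_mse", 100.0)),
            lambda_adv=float(_cfg_get(cfg.training, "lambda_adv", 1.0)),
            seed=seeds["train:" + spec.name],
            noise_mode=str(_cfg_get(cfg.training, "noise_mode", "dropout")),
            adversarial_form=str(_cfg_get(cfg.training, "adversarial_form", "non_saturating")),
        )
        model = train_class_model(train, edge_params, gspec, dspec, tcfg)
        registry.add_class(model)
        test_tiles.extend(test)

    save_registry(registry, out / "registry")

    # --- tile-level evaluation on held-out tiles ------------------------
    note("classifying held-out tiles")
    results = classify_tiles(registry, stack_pixels(test_tiles), metric=cfg.metric)
    y_true = [t.label for t in test_tiles]
    y_pred = [r.predicted_label for r in results]
    positive = "tumor" if "tumor" in registry.labels else registry.labels[0]
    conf = confusion_from_labels(y_true, y_pred, positive)
    p, s = precision(conf), sensitivity(conf)
    tile_metrics = {
        "precision": round(p, 2), "sensitivity": round(s, 2), "f1": round(f1(p, s), 2),
        "accuracy": round(100.0 * sum(t == q for t, q in zip(y_true, y_pred)) / len(y_true), 2),
        "n_tiles": len(y_true), "positive_label": positive,
        "confusion": {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn},
    }

    # --- homogeneous synthetic HPFs + majority vote ---------------------
    note("classifying high-power fields")
    hpf_count = int(_cfg_get(cfg.hpf, "count", 10))
    hpf_size = tuple(_cfg_get(cfg.hpf, "size", [192, 192]))
    n_windows = int(_cfg_get(cfg.hpf, "n_windows", 50))
    hpf_rng = np.random.default_rng(seeds["hpf_gen"])
    vote_rng = np.random.default_rng(seeds["hpf_classify"])
    hpf_records = []
    n_correct = 0
    for i in range(hpf_count):
        spec = specs[i % len(specs)]
        field_ = generate_hpf([spec], hpf_size, seed=int(hpf_rng.integers(0, 2**31 - 1)))
        res = classify_hpf(registry, field_.pixels, n_windows=n_windows,
                           seed=int(vote_rng.integers(0, 2**31 - 1)), metric=cfg.metric)
        correct = res.predicted_label == field_.true_label
        n_correct += correct
        hpf_records.append({"true_label": field_.true_label,
                            "predicted_label": res.predicted_label,
                            "votes": res.votes, "correct": bool(correct)})
    hpf_metrics = {
        "accuracy": round(100.0 * n_correct / hpf_count, 2) if hpf_count else 0.0,
        "n_hpfs": hpf_count, "n_windows": n_windows,
    }

    report = {
        "edgegan_version": __version__,
        "config": cfg.to_dict(),
        "derived_seeds": seeds,
        "edge_params": edge_params.to_dict(),
        "fingerprints": {m.label: m.fingerprint for m in registry},
        "tile_level": tile_metrics,
        "hpf_level": {"summary": hpf_metrics, "fields": hpf_records},
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return report


def _cfg_get(d: dict, key: str, default):
    return d.get(key, default) if isinstance(d, dict) else default
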