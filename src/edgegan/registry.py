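"""The modular collection of independently trained class generators.

Adding or removing a class never touches other models — on disk each class
is a self-contained subdirectory (weights + metadata), indexed by a
top-level ``registry.yaml``, so an add is a pure directory add.  Iteration
order is lexicographic by label everywhere; downstream tie-breaking relies
on this.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import yaml

from .cgan import ClassModel, GeneratorSpec, LossBundle, TrainingConfig, compute_fingerprint
from .edges import EdgeParams
from .errors import ConflictError, InvalidArgumentError, NotFoundError, RegistryFormatError

__all__ = ["ModelRegistry", "add_class", "remove_class", "save_registry", "load_registry"]

_FORMAT_VERSION = 1


@dataclass
class ModelRegistry:
    """Ordered (lexicographic by label) map of class label -> ClassModel."""

    tile_size: int | None = None
    entries: dict[str, ClassModel] = field(default_factory=dict)
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    modified: str = ""

    def __post_init__(self) -> None:
        if not self.modified:
            self.modified = self.created

    @property
    def labels(self) -> list[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> ClassModel:
        if label not in self.entries:
            raise NotFoundError(f"no class {label!r} in registry (have {self.labels})")
        return self.entries[label]

    def __iter__(self) -> Iterator[ClassModel]:
        for label in self.labels:
            yield self.entries[label]

    def _touch(self) -> None:
        self.modified = _dt.datetime.now().isoformat(timespec="seconds")

    def add_class(self, model: ClassModel) -> "ModelRegistry":
        """Add one trained class model; existing entries are untouched."""
        if model.label in self.entries:
            raise ConflictError(f"class {model.label!r} already present")
        if self.tile_size is None:
            self.tile_size = model.tile_size
        elif model.tile_size != self.tile_size:
            raise InvalidArgumentError(
                f"tile size mismatch: registry is {self.tile_size}, model is {model.tile_size}"
            )
        self.entries[model.label] = model
        self._touch()
        return self

    def remove_class(self, label: str) -> "ModelRegistry":
        if label not in self.entries:
            raise NotFoundError(f"no class {label!r} in registry (have {self.labels})")
        del self.entries[label]
        self._touch()
        return self

    def save(self, path: str | Path) -> None:
        save_registry(self, path)


def add_class(registry: ModelRegistry, model: ClassModel) -> ModelRegistry:
    return registry.add_class(model)


def remove_class(registry: ModelRegistry, label: str) -> ModelRegistry:
    return registry.remove_class(label)


def _model_dir(root: Path, label: str) -> Path:
    return root / label


def _save_model(model: ClassModel, mdir: Path) -> None:
    mdir.mkdir(parents=True, exist_ok=True)
    np.savez(mdir / "weights.npz",
             **{f"w{i:03d}": arr for i, arr in enumerate(model.generator_weights)})
    meta = {
        "label": model.label,
        "tile_size": model.tile_size,
        "fingerprint": model.fingerprint,
        "generator_spec": model.generator_spec.to_dict(),
        "edge_params": model.edge_params.to_dict(),
        "training_config": model.training_config.to_dict(),
    }
    with open(mdir / "metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    with open(mdir / "training_log.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "d_loss", "g_adv", "g_mse", "g_total"])
        for i, rec in enumerate(model.training_log):
            writer.writerow([i, rec.d_loss, rec.g_adv, rec.g_mse, rec.g_total])


def _load_model(mdir: Path, label: str) -> ClassModel:
    meta_path = mdir / "metadata.yaml"
    weights_path = mdir / "weights.npz"
    if not meta_path.is_file():
        raise RegistryFormatError(f"class {label!r}: missing {meta_path.name}")
    if not weights_path.is_file():
        raise RegistryFormatError(f"class {label!r}: missing {weights_path.name}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    try:
        gspec = GeneratorSpec.from_dict(meta["generator_spec"])
        eparams = EdgeParams.from_dict(meta["edge_params"])
        tcfg = TrainingConfig.from_dict(meta["training_config"])
        stored_fp = meta["fingerprint"]
        tile_size = int(meta["tile_size"])
    except (KeyError, TypeError) as exc:
        raise RegistryFormatError(f"class {label!r}: malformed metadata ({exc})") from exc
    with np.load(weights_path) as npz:
        weights = [npz[k] for k in sorted(npz.files)]
    fp = compute_fingerprint(weights)
    if fp != stored_fp:
        raise RegistryFormatError(
            f"class {label!r}: weight fingerprint mismatch (file corrupt?)"
        )
    log: list[LossBundle] = []
    log_path = mdir / "training_log.csv"
    if log_path.is_file():
        with open(log_path, newline="") as fh:
            for rec in csv.DictReader(fh):
                log.append(LossBundle(d_loss=float(rec["d_loss"]), g_adv=float(rec["g_adv"]),
                                      g_mse=float(rec["g_mse"]), g_total=float(rec["g_total"])))
    return ClassModel(label=label, tile_size=tile_size, generator_spec=gspec,
                      edge_params=eparams, training_config=tcfg,
                      generator_weights=weights, training_log=log, fingerprint=fp)


def save_registry(registry: ModelRegistry, path: str | Path) -> None:
    """Write the registry: one subdirectory per class plus ``registry.yaml``."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for model in registry:
        _save_model(model, _model_dir(root, model.label))
    index = {
        "format_version": _FORMAT_VERSION,
        "tile_size": registry.tile_size,
        "classes": registry.labels,
        "created": registry.created,
        "modified": registry.modified,
    }
    with open(root / "registry.yaml", "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=True)


def load_registry(path: str | Path) -> ModelRegistry:
    """Load a registry saved by :func:`save_registry`; validates per-class
    files and weight fingerprints, naming the offending class on failure."""
    root = Path(path)
    index_path = root / "registry.yaml"
    if not index_path.is_file():
        raise RegistryFormatError(f"{root}: no registry.yaml found")
    with open(index_path) as fh:
        index = yaml.safe_load(fh)
    version = index.get("format_version")
    if version != _FORMAT_VERSION:
        raise RegistryFormatError(
            f"{root}: unsupported registry format version {version!r}"
        )
    reg = ModelRegistry(tile_size=index.get("tile_size"),
                        created=index.get("created", ""),
                        modified=index.get("modified", ""))
    for label in index.get("classes", []):
        model = _load_model(_model_dir(root, label), label)
        reg.entries[model.label] = model
    return reg
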