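"""Classification by minimum reconstruction error, and HPF majority voting.

Each class generator in the registry attempts to reconstruct the query
tile from its edge condition; the class whose reconstruction is least
dissimilar to the original wins.  MSE is the default dissimilarity and is
computed on the 0-255 intensity scale so reported errors are comparable
across configurations; SSIM and PSNR are offered as pluggable alternatives
converted to dissimilarities (1 - SSIM, and a ceiling-shifted -PSNR) so
the arg-min winner rule applies uniformly.

Region-level (high-power field) classification samples random windows from
the field, classifies each, and takes a majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .errors import InvalidArgumentError, StateError
from .registry import ModelRegistry

__all__ = ["ClassificationResult", "HPFResult", "dissimilarity",
           "classify_tile", "classify_tiles", "classify_hpf", "METRICS"]

METRICS = ("mse", "ssim", "psnr")


@dataclass
class ClassificationResult:
    """Per-class reconstruction errors and the arg-min predicted label."""

    per_class_errors: dict[str, float]
    predicted_label: str
    metric: str = "mse"
    tie_broken: bool = False


@dataclass
class HPFResult:
    """Window-level results, vote counts and the majority-vote label for
    one high-power field."""

    window_results: list[ClassificationResult]
    votes: dict[str, int]
    predicted_label: str
    n_windows: int
    tie_broken: bool = False
    corners: list[tuple[int, int]] = field(default_factory=list)


def _check_pair(original: np.ndarray, reconstruction: np.ndarray) -> None:
    if original.shape != reconstruction.shape:
        raise InvalidArgumentError(
            f"shape mismatch: {original.shape} vs {reconstruction.shape}"
        )


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))


def dissimilarity(metric: str, original: np.ndarray, reconstruction: np.ndarray) -> float:
    """Dissimilarity >= 0 between an original and its reconstruction.

    mse: mean squared difference over all pixels/channels (0-255 scale).
    ssim: 1 - SSIM.
    psnr: ceiling - PSNR, where the ceiling 10*log10(255^2 * N) is the
    largest PSNR a nonzero integer difference can attain on N samples, so
    identical images map to 0 and the ordering matches MSE.
    """
    metric = metric.lower()
    if metric not in METRICS:
        raise InvalidArgumentError(f"unknown metric {metric!r}; choose from {METRICS}")
    _check_pair(original, reconstruction)
    if metric == "mse":
        return _mse(original, reconstruction)
    if metric == "ssim":
        s = structural_similarity(original, reconstruction, channel_axis=2, data_range=255)
        return float(max(1.0 - s, 0.0))
    mse = _mse(original, reconstruction)
    ceiling = 10.0 * np.log10(255.0 ** 2 * original.size)
    if mse == 0.0:
        return 0.0
    psnr = 10.0 * np.log10(255.0 ** 2 / mse)
    return float(max(ceiling - psnr, 0.0))


def _argmin_label(errors: dict[str, float]) -> tuple[str, bool]:
    """Lexicographically smallest label attaining the minimum; flags ties."""
    best = min(errors.values())
    winners = sorted(label for label, e in errors.items() if e == best)
    return winners[0], len(winners) > 1


def classify_tiles(registry: ModelRegistry, tiles_px: np.ndarray,
                   metric: str = "mse") -> list[ClassificationResult]:
    """Classify a stack of (N, H, W, 3) uint8 tiles in one batched pass per
    class model."""
    if len(registry) == 0:
        raise StateError("cannot classify with an empty registry")
    tiles_px = np.asarray(tiles_px)
    if tiles_px.ndim != 4:
        raise InvalidArgumentError(f"expected (N, H, W, 3) tiles, got {tiles_px.shape}")
    if tiles_px.shape[1] != registry.tile_size or tiles_px.shape[2] != registry.tile_size:
        raise InvalidArgumentError(
            f"tile size {tiles_px.shape[1:3]} does not match registry "
            f"tile size {registry.tile_size}"
        )
    n = tiles_px.shape[0]
    errors: dict[str, np.ndarray] = {}
    for model in registry:  # lexicographic
        recon = model.reconstruct_batch(tiles_px)
        errors[model.label] = np.array([
            dissimilarity(metric, tiles_px[i], recon[i]) for i in range(n)
        ])
    results = []
    for i in range(n):
        per_class = {label: float(errors[label][i]) for label in registry.labels}
        label, tie = _argmin_label(per_class)
        results.append(ClassificationResult(per_class_errors=per_class,
                                            predicted_label=label,
                                            metric=metric, tie_broken=tie))
    return results


def classify_tile(registry: ModelRegistry, tile: np.ndarray,
                  metric: str = "mse") -> ClassificationResult:
    """Classify one (H, W, 3) uint8 tile by minimum reconstruction error."""
    if len(registry) == 0:
        raise StateError("cannot classify with an empty registry")
    tile = np.asarray(tile)
    if tile.ndim != 3:
        raise InvalidArgumentError(f"expected an (H, W, 3) tile, got {tile.shape}")
    per_class: dict[str, float] = {}
    for model in registry:  # lexicographic order
        recon = model.reconstruct(tile)
        per_class[model.label] = dissimilarity(metric, tile, recon)
    label, tie = _argmin_label(per_class)
    return ClassificationResult(per_class_errors=per_class, predicted_label=label,
                                metric=metric, tie_broken=tie)


def classify_hpf(registry: ModelRegistry, hpf: np.ndarray, n_windows: int = 50,
                 window_size: int | None = None, seed: int = 0,
                 metric: str = "mse") -> HPFResult:
    """Classify a high-power field by majority vote over randomly sampled
    windows.

    ``n_windows`` top-left corners are drawn uniformly with replacement
    (seeded); each window is classified by minimum reconstruction error.
    Vote ties are broken by the smaller summed dissimilarity across the
    tied label's winning windows, then lexicographically.
    """
    if len(registry) == 0:
        raise StateError("cannot classify with an empty registry")
    if n_windows < 1:
        raise InvalidArgumentError(f"n_windows must be >= 1, got {n_windows}")
    hpf = np.asarray(hpf)
    if hpf.ndim != 3 or hpf.shape[2] != 3:
        raise InvalidArgumentError(f"expected an (H, W, 3) field, got {hpf.shape}")
    w = registry.tile_size if window_size is None else window_size
    if w != registry.tile_size:
        raise InvalidArgumentError(
            f"window size {w} does not match registry tile size {registry.tile_size}"
        )
    h_max, w_max = hpf.shape[0] - w, hpf.shape[1] - w
    if h_max < 0 or w_max < 0:
        raise InvalidArgumentError(
            f"field {hpf.shape[:2]} is smaller than the {w} px window"
        )
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h_max + 1, size=n_windows)
    cols = rng.integers(0, w_max + 1, size=n_windows)
    windows = np.stack([hpf[r:r + w, c:c + w] for r, c in zip(rows, cols)])
    results = classify_tiles(registry, windows, metric=metric)

    votes = {label: 0 for label in registry.labels}
    summed: dict[str, float] = {label: 0.0 for label in registry.labels}
    for res in results:
        votes[res.predicted_label] += 1
        summed[res.predicted_label] += res.per_class_errors[res.predicted_label]
    top = max(votes.values())
    tied = sorted(label for label, v in votes.items() if v == top)
    tie = len(tied) > 1
    if tie:
        best = min(summed[label] for label in tied)
        tied = sorted(label for label in tied if summed[label] == best)
    predicted = tied[0]
    return HPFResult(window_results=results, votes=votes, predicted_label=predicted,
                     n_windows=n_windows, tie_broken=tie,
                     corners=[(int(r), int(c)) for r, c in zip(rows, cols)])
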