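"""Channel-wise Canny edge conditioning.

The conditioning input of every class generator is a 3-channel binary mask:
channel *i* is the Canny edge map of the tile's intensity channel *i*
(red, green, blue), computed on raw intensities with no colour-space
transform.  Draining colour this way leaves only structure for the
generator to reconstruct from, which is what makes reconstruction error a
class-specific signal.

Two sigma presets are shipped, ``sigma_2`` and ``sigma_5`` (Gaussian
smoothing SD in pixels).  Hysteresis thresholds are expressed as fractions
of the full 8-bit intensity scale and default to 0.1 / 0.2; they are stored
alongside sigma so a saved model always reproduces its training-time
conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny

from .errors import InvalidArgumentError

__all__ = ["EdgeParams", "EdgeCondition", "detect_edges", "condition_to_raster",
           "SIGMA_PRESETS"]


@dataclass(frozen=True)
class EdgeParams:
    """Canny parameters: smoothing sigma (px) and hysteresis thresholds.

    ``low_fraction`` / ``high_fraction`` are fractions of the full intensity
    scale (gradients of an image mapped to [0, 1]).
    """

    sigma: float = 2.0
    low_fraction: float = 0.1
    high_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidArgumentError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.low_fraction < self.high_fraction <= 1.0:
            raise InvalidArgumentError(
                "hysteresis thresholds must satisfy 0 <= low < high <= 1, got "
                f"low={self.low_fraction}, high={self.high_fraction}"
            )

    def to_dict(self) -> dict:
        return {"sigma": self.sigma, "low_fraction": self.low_fraction,
                "high_fraction": self.high_fraction}

    @classmethod
    def from_dict(cls, d: dict) -> "EdgeParams":
        return cls(sigma=float(d["sigma"]), low_fraction=float(d["low_fraction"]),
                   high_fraction=float(d["high_fraction"]))


SIGMA_PRESETS: dict[str, EdgeParams] = {
    "sigma_2": EdgeParams(sigma=2.0),
    "sigma_5": EdgeParams(sigma=5.0),
}


@dataclass(frozen=True)
class EdgeCondition:
    """A 3-channel binary edge mask aligned to its source tile.

    ``mask`` has shape (H, W, 3) with values in {0, 1}; channel *i* derives
    only from source channel *i*.
    """

    mask: np.ndarray
    params: EdgeParams
    source_shape: tuple[int, int]

    @property
    def edge_fraction(self) -> float:
        """Fraction of mask entries that are edge pixels (over all channels)."""
        return float(self.mask.mean())


def _validate_tile(tile: np.ndarray) -> None:
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise InvalidArgumentError(
            f"expected an H x W x 3 RGB tile, got shape {tile.shape}; "
            "grayscale or alpha-channel images are not converted silently"
        )
    if tile.shape[0] < 16 or tile.shape[1] < 16:
        raise InvalidArgumentError(f"tile must be at least 16 px per side, got {tile.shape[:2]}")


def detect_edges(tile: np.ndarray, params: EdgeParams) -> EdgeCondition:
    """Compute the per-channel Canny edge condition of an 8-bit RGB tile.

    Each channel is mapped to [0, 1] and run through Canny independently
    with the given sigma and hysteresis fractions.  Reflective padding is
    used during smoothing and edges on the border ring are kept.
    """
    _validate_tile(tile)
    mask = np.empty(tile.shape, dtype=np.uint8)
    for c in range(3):
        plane = tile[:, :, c].astype(np.float64) / 255.0
        mask[:, :, c] = canny(
            plane, sigma=params.sigma,
            low_threshold=params.low_fraction, high_threshold=params.high_fraction,
            mode="reflect",
        ).astype(np.uint8)
    return EdgeCondition(mask=mask, params=params, source_shape=tile.shape[:2])


def condition_to_raster(cond: EdgeCondition) -> np.ndarray:
    """Render an edge condition as an 8-bit RGB raster ({0, 255} per channel).

    A pixel that is an edge in all three channels renders white; an edge in
    a single channel renders in that channel's colour.
    """
    return (cond.mask.astype(np.uint8)) * np.uint8(255)
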