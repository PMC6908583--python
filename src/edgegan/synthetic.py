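"""Seeded synthetic H&E-like texture classes.

Real slide data is large, access-restricted, and unnecessary for exercising
the classification machinery, so this module generates labelled texture
tiles whose class identity is carried by *structure* rather than colour:
a "tumorlike" class of densely packed dark elliptical blobs (nuclei, with a
fraction rendered as rings to imitate gland lumina) and a "stromalike"
class of sparse wavy fibers on a pale background.  Because the two classes
differ in the amount and geometry of their edges, their per-channel Canny
edge maps are distinguishable even when the palettes are made identical —
the property the edge-conditioned classifier relies on.

Every generation call is a pure function of its arguments and the spec's
seed; there is no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError
from .tiles import Tile

__all__ = [
    "TextureClassSpec",
    "SyntheticHPF",
    "generate_tiles",
    "generate_hpf",
    "default_specs",
    "drained_palette",
    "TUMORLIKE",
    "STROMALIKE",
]

_RING_FRACTION = 0.25  # fraction of blobs drawn as rings (gland motif)
_SUPERSAMPLE = 3       # subpixel grid for anti-aliased blob rendering


@dataclass(frozen=True)
class TextureClassSpec:
    """Parameters of one synthetic texture class.

    nucleus_density is the expected number of blobs per 1000 px^2; palette
    is a (foreground, background) pair of RGB triplets; noise_sd is the SD
    of additive Gaussian intensity noise on the 0-255 scale.
    """

    name: str
    nucleus_density: float = 0.0
    nucleus_radius_range: tuple[float, float] = (3.0, 6.0)
    fiber_count: int = 0
    fiber_waviness: float = 0.0
    palette: tuple[tuple[int, int, int], tuple[int, int, int]] = ((70, 40, 120), (214, 188, 226))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise InvalidArgumentError("class name must be nonempty")
        if self.nucleus_density < 0 or self.fiber_count < 0 or self.fiber_waviness < 0:
            raise InvalidArgumentError("densities, counts and waviness must be >= 0")
        if self.nucleus_radius_range[0] <= 0 or self.nucleus_radius_range[1] < self.nucleus_radius_range[0]:
            raise InvalidArgumentError(f"bad radius range {self.nucleus_radius_range}")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        for color in self.palette:
            if len(color) != 3 or any(not 0 <= v <= 255 for v in color):
                raise InvalidArgumentError(f"palette entries must be RGB in [0,255], got {color}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "nucleus_density": self.nucleus_density,
            "nucleus_radius_range": list(self.nucleus_radius_range),
            "fiber_count": self.fiber_count,
            "fiber_waviness": self.fiber_waviness,
            "palette": [list(c) for c in self.palette],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TextureClassSpec":
        return cls(
            name=d["name"],
            nucleus_density=float(d.get("nucleus_density", 0.0)),
            nucleus_radius_range=tuple(d.get("nucleus_radius_range", (3.0, 6.0))),
            fiber_count=int(d.get("fiber_count", 0)),
            fiber_waviness=float(d.get("fiber_waviness", 0.0)),
            palette=tuple(tuple(c) for c in d.get("palette", ((70, 40, 120), (214, 188, 226)))),
            noise_sd=float(d.get("noise_sd", 0.0)),
            seed=int(d.get("seed", 0)),
        )


# Shipped default classes.  Foreground/background hues imitate hematoxylin
# (blue-purple nuclei on lavender) and eosin (pink fibers on pale pink);
# the exact RGB constants are arbitrary and recorded here as config.
TUMORLIKE = TextureClassSpec(
    name="tumorlike",
    nucleus_density=8.0,
    nucleus_radius_range=(3.0, 6.0),
    fiber_count=0,
    fiber_waviness=0.0,
    palette=((70, 40, 120), (214, 188, 226)),
    noise_sd=3.0,
    seed=7,
)

STROMALIKE = TextureClassSpec(
    name="stromalike",
    nucleus_density=0.4,
    nucleus_radius_range=(1.5, 3.0),
    fiber_count=4,
    fiber_waviness=0.25,
    palette=((225, 130, 170), (247, 228, 233)),
    noise_sd=3.0,
    seed=11,
)


def default_specs() -> list[TextureClassSpec]:
    return [TUMORLIKE, STROMALIKE]


@dataclass
class SyntheticHPF:
    """A synthetic high-power field: a raster larger than the tile size,
    its dominant true label, and a per-pixel map of generating class indices."""

    pixels: np.ndarray
    true_label: str
    layout: np.ndarray = field(repr=False, default=None)
    labels: Sequence[str] = ()


def _paint_blob(cov: np.ndarray, cy: float, cx: float, a: float, b: float,
                theta: float, ring: bool) -> None:
    """Max-combine the anti-aliased coverage of one (possibly hollow) ellipse."""
    h, w = cov.shape
    r = max(a, b) + 1.0
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 2, h)
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 2, w)
    if y0 >= y1 or x0 >= x1:
        return
    s = _SUPERSAMPLE
    # subpixel sample centres within each pixel of the bounding box
    ys = y0 + (np.arange((y1 - y0) * s) + 0.5) / s
    xs = x0 + (np.arange((x1 - x0) * s) + 0.5) / s
    dy = ys[:, None] - cy
    dx = xs[None, :] - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    inside = (u * u + v * v) <= 1.0
    if ring:
        ui = (dx * ct + dy * st) / (0.55 * a)
        vi = (-dx * st + dy * ct) / (0.55 * b)
        inside &= (ui * ui + vi * vi) > 1.0
    frac = inside.reshape(y1 - y0, s, x1 - x0, s).mean(axis=(1, 3))
    np.maximum(cov[y0:y1, x0:x1], frac, out=cov[y0:y1, x0:x1])


def _paint_fiber(cov: np.ndarray, rng: np.random.Generator, waviness: float) -> None:
    """Stamp an anti-aliased wavy stroke of ~2.6 px width across the canvas."""
    h, w = cov.shape
    pos = np.array([rng.uniform(0, h), rng.uniform(0, w)])
    heading = rng.uniform(0, 2 * np.pi)
    n_steps = int(1.5 * max(h, w) / 0.75)
    radius = 1.3
    win = int(np.ceil(radius)) + 1
    for _ in range(n_steps):
        heading += waviness * rng.normal()
        pos += 0.75 * np.array([np.sin(heading), np.cos(heading)])
        cy, cx = pos
        if not (-radius < cy < h + radius and -radius < cx < w + radius):
            break
        y0, y1 = max(int(cy) - win, 0), min(int(cy) + win + 1, h)
        x0, x1 = max(int(cx) - win, 0), min(int(cx) + win + 1, w)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)[:, None] + 0.5
        xx = np.arange(x0, x1)[None, :] + 0.5
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        frac = np.clip(radius + 0.5 - dist, 0.0, 1.0)
        np.maximum(cov[y0:y1, x0:x1], frac, out=cov[y0:y1, x0:x1])


def _render(spec: TextureClassSpec, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Render one texture raster of the given (H, W) shape."""
    h, w = shape
    cov = np.zeros((h, w), dtype=np.float64)
    n_blobs = rng.poisson(spec.nucleus_density * h * w / 1000.0)
    lo, hi = spec.nucleus_radius_range
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a, b = rng.uniform(lo, hi), rng.uniform(lo, hi)
        theta = rng.uniform(0, np.pi)
        ring = rng.random() < _RING_FRACTION
        _paint_blob(cov, cy, cx, a, b, theta, ring)
    for _ in range(spec.fiber_count):
        _paint_fiber(cov, rng, spec.fiber_waviness)
    fg = np.asarray(spec.palette[0], dtype=np.float64)
    bg = np.asarray(spec.palette[1], dtype=np.float64)
    img = bg[None, None, :] + cov[:, :, None] * (fg - bg)[None, None, :]
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_tiles(spec: TextureClassSpec, n: int, tile_size: int) -> list[Tile]:
    """Generate ``n`` labelled tiles of ``tile_size`` px; deterministic in
    (spec, n, tile_size)."""
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    if tile_size < 32:
        raise InvalidArgumentError(f"tile_size must be >= 32, got {tile_size}")
    rng = np.random.default_rng(spec.seed)
    return [
        Tile(pixels=_render(spec, (tile_size, tile_size), rng), label=spec.name,
             source_id=f"synthetic:{spec.name}", row=None, col=None)
        for _ in range(n)
    ]


def generate_hpf(specs: Sequence[TextureClassSpec], size: tuple[int, int],
                 layout: str | None = None, seed: int = 0) -> SyntheticHPF:
    """Generate one synthetic high-power field.

    ``layout`` is ``None`` (homogeneous fill with the first spec),
    ``"hsplit"`` (specs side by side, left to right) or ``"vsplit"``
    (stacked top to bottom).  The returned ``layout`` map holds, per pixel,
    the index of the generating spec.
    """
    if not specs:
        raise InvalidArgumentError("at least one TextureClassSpec is required")
    h, w = size
    if h < 64 or w < 64:
        raise InvalidArgumentError(f"HPF must be at least 64 px per side, got {size}")
    if layout not in (None, "hsplit", "vsplit"):
        raise InvalidArgumentError(f"unknown layout {layout!r}")

    region = np.zeros((h, w), dtype=np.intp)
    if layout == "hsplit" and len(specs) > 1:
        bounds = np.linspace(0, w, len(specs) + 1).astype(int)
        for i in range(len(specs)):
            region[:, bounds[i]:bounds[i + 1]] = i
    elif layout == "vsplit" and len(specs) > 1:
        bounds = np.linspace(0, h, len(specs) + 1).astype(int)
        for i in range(len(specs)):
            region[bounds[i]:bounds[i + 1], :] = i

    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=len(specs))
    pixels = np.zeros((h, w, 3), dtype=np.uint8)
    for i, spec in enumerate(specs):
        rendered = _render(spec, (h, w), np.random.default_rng(int(child_seeds[i])))
        sel = region == i
        pixels[sel] = rendered[sel]

    areas = [(region == i).sum() for i in range(len(specs))]
    true_label = specs[int(np.argmax(areas))].name
    return SyntheticHPF(pixels=pixels, true_label=true_label, layout=region,
                        labels=[s.name for s in specs])


def drained_palette(spec: TextureClassSpec,
                    palette=((128, 128, 128), (210, 210, 210))) -> TextureClassSpec:
    """Return a copy of ``spec`` with a shared neutral palette (colour drained)."""
    return replace(spec, palette=palette)
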