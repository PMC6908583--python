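"""Per-class conditional GAN: U-Net generator, conv discriminator, training.

One model is trained per tissue class on that class's tiles only.  The
generator maps the 3-channel Canny edge condition of a tile back to the
RGB tile; the discriminator sees (condition, image) pairs and outputs a
two-way softmax probability of the image being real.  The generator's loss
combines the non-saturating adversarial cross-entropy with a mean-squared
reconstruction term (default weights 1 and 100, the pix2pix convention).

Images are mapped to [-1, 1] inside the model and the generator output is
bounded by tanh; classification-time reconstructions are mapped back to
the 0-255 scale.  Training is bit-reproducible from the config seed, and a
trained model never reads tiles of any other class.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .edges import EdgeParams, detect_edges
from .errors import InvalidArgumentError
from .tiles import Tile, stack_pixels

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "TrainingConfig",
    "LossBundle",
    "ClassModel",
    "UNetGenerator",
    "ConvDiscriminator",
    "discriminator_loss",
    "generator_loss",
    "build_generator",
    "build_discriminator",
    "train_class_model",
    "reconstruct",
    "compute_fingerprint",
]

_EPS = 1e-7  # probability clip for log terms


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net shape: ``depth`` down/up stages, ``base_filters`` at stage 0,
    dropout in the inner decoder stages."""

    in_channels: int = 3
    out_channels: int = 3
    depth: int = 3
    base_filters: int = 16
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise InvalidArgumentError(f"depth must be >= 2, got {self.depth}")
        if self.base_filters < 8:
            raise InvalidArgumentError(f"base_filters must be >= 8, got {self.base_filters}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise InvalidArgumentError(f"dropout_rate must be in [0,1), got {self.dropout_rate}")

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "out_channels": self.out_channels,
                "depth": self.depth, "base_filters": self.base_filters,
                "dropout_rate": self.dropout_rate}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(**d)


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Conv discriminator shape: stride-2 conv stages then a dense two-way
    softmax head over the flattened features."""

    in_channels: int = 6
    conv_stages: int = 3
    base_filters: int = 16

    def __post_init__(self) -> None:
        if self.conv_stages < 2:
            raise InvalidArgumentError(f"conv_stages must be >= 2, got {self.conv_stages}")
        if self.base_filters < 8:
            raise InvalidArgumentError(f"base_filters must be >= 8, got {self.base_filters}")

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "conv_stages": self.conv_stages,
                "base_filters": self.base_filters}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscriminatorSpec":
        return cls(**d)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 5
    batch_size: int = 4
    learning_rate: float = 2e-4
    beta1: float = 0.5
    lambda_mse: float = 100.0
    lambda_adv: float = 1.0
    seed: int = 0
    noise_mode: str = "dropout"          # "dropout" | "input"
    adversarial_form: str = "non_saturating"  # | "saturating"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InvalidArgumentError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")
        if self.lambda_mse < 0 or self.lambda_adv < 0:
            raise InvalidArgumentError("loss weights must be >= 0")
        if self.lambda_mse + self.lambda_adv == 0:
            raise InvalidArgumentError("at least one loss weight must be positive")
        if self.noise_mode not in ("dropout", "input"):
            raise InvalidArgumentError(f"unknown noise_mode {self.noise_mode!r}")
        if self.adversarial_form not in ("non_saturating", "saturating"):
            raise InvalidArgumentError(f"unknown adversarial_form {self.adversarial_form!r}")

    def to_dict(self) -> dict:
        return {"epochs": self.epochs, "batch_size": self.batch_size,
                "learning_rate": self.learning_rate, "beta1": self.beta1,
                "lambda_mse": self.lambda_mse, "lambda_adv": self.lambda_adv,
                "seed": self.seed, "noise_mode": self.noise_mode,
                "adversarial_form": self.adversarial_form}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainingConfig":
        return cls(**d)


@dataclass(frozen=True)
class LossBundle:
    """One logged loss record: discriminator cross-entropy, generator
    adversarial term, reconstruction MSE, and the weighted total."""

    d_loss: float
    g_adv: float
    g_mse: float
    g_total: float


def discriminator_loss(d_real: float | np.ndarray, d_fake: float | np.ndarray) -> float:
    """Cross-entropy of the discriminator on one (real, fake) probability
    pair: -log d_real - log(1 - d_fake); array inputs are averaged."""
    d_real = np.asarray(d_real, dtype=np.float64)
    d_fake = np.asarray(d_fake, dtype=np.float64)
    if np.any(d_real < 0) or np.any(d_real > 1) or np.any(d_fake < 0) or np.any(d_fake > 1):
        raise InvalidArgumentError("discriminator probabilities must lie in [0, 1]")
    dr = np.clip(d_real, _EPS, 1.0 - _EPS)
    df = np.clip(d_fake, _EPS, 1.0 - _EPS)
    return float(np.mean(-np.log(dr)) + np.mean(-np.log(1.0 - df)))


def _adv_term(d_fake: np.ndarray, form: str) -> float:
    df = np.clip(np.asarray(d_fake, dtype=np.float64), _EPS, 1.0 - _EPS)
    if form == "saturating":
        return float(np.mean(np.log(1.0 - df)))
    return float(np.mean(-np.log(df)))


def generator_loss(d_fake: float | np.ndarray, reconstruction: np.ndarray,
                   target: np.ndarray, cfg: TrainingConfig) -> LossBundle:
    """Generator loss bundle for one batch.

    ``g_adv`` is the non-saturating -log D (or the saturating log(1-D) when
    configured); ``g_mse`` is the mean squared difference over all pixels
    and channels on the model's normalised scale.
    """
    d_fake_arr = np.asarray(d_fake, dtype=np.float64)
    if np.any(d_fake_arr < 0) or np.any(d_fake_arr > 1):
        raise InvalidArgumentError("d_fake must lie in [0, 1]")
    reconstruction = np.asarray(reconstruction, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if reconstruction.shape != target.shape:
        raise InvalidArgumentError(
            f"shape mismatch: reconstruction {reconstruction.shape} vs target {target.shape}"
        )
    g_adv = _adv_term(d_fake_arr, cfg.adversarial_form)
    g_mse = float(np.mean((reconstruction - target) ** 2))
    g_total = cfg.lambda_adv * g_adv + cfg.lambda_mse * g_mse
    return LossBundle(d_loss=0.0, g_adv=g_adv, g_mse=g_mse, g_total=g_total)


class UNetGenerator:
    """U-Net: stride-2 conv encoder, stride-2 transposed-conv decoder with
    skip connections between mirrored stages, tanh output."""

    def __init__(self, spec: GeneratorSpec, tile_size: int, rng: np.random.Generator) -> None:
        if tile_size % (2 ** spec.depth) != 0:
            raise InvalidArgumentError(
                f"tile size {tile_size} not divisible by 2^depth = {2 ** spec.depth}"
            )
        self.spec = spec
        self.tile_size = tile_size
        d, f = spec.depth, spec.base_filters
        enc_ch = [f * 2 ** i for i in range(d)]
        self.enc_conv: list[nn.Conv2d] = []
        self.enc_act: list[nn.LeakyReLU] = []
        c_in = spec.in_channels
        for c_out in enc_ch:
            self.enc_conv.append(nn.Conv2d(c_in, c_out, rng))
            self.enc_act.append(nn.LeakyReLU(0.2))
            c_in = c_out
        self.dec_conv: list[nn.ConvTranspose2d] = []
        self.dec_act: list[nn.ReLU] = []
        self.dec_drop: list[nn.Dropout] = []
        self._concat_prev_ch: list[int] = [0] * d
        prev = enc_ch[-1]
        for j in range(d):
            if j > 0:
                self._concat_prev_ch[j] = prev
                c_in = prev + enc_ch[d - 1 - j]
            else:
                c_in = prev
            c_out = enc_ch[d - 2 - j] if j < d - 1 else spec.out_channels
            self.dec_conv.append(nn.ConvTranspose2d(c_in, c_out, rng))
            if j < d - 1:
                self.dec_act.append(nn.ReLU())
                self.dec_drop.append(nn.Dropout(spec.dropout_rate, rng))
            prev = c_out
        self.out_tanh = nn.Tanh()
        self._encs: list[np.ndarray] = []

    # --- parameter plumbing -------------------------------------------------
    def layers(self) -> list[nn.Layer]:
        return [*self.enc_conv, *self.dec_conv]

    def param_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(arr for _, arr in layer.params())
        return out

    def grad_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(layer.grads())
        return out

    def set_params(self, arrays: list[np.ndarray]) -> None:
        own = self.param_arrays()
        if len(own) != len(arrays):
            raise InvalidArgumentError(
                f"expected {len(own)} weight arrays, got {len(arrays)}"
            )
        for dst, src in zip(own, arrays):
            if dst.shape != src.shape:
                raise InvalidArgumentError(
                    f"weight shape mismatch: {dst.shape} vs {src.shape}"
                )
            dst[...] = src

    def n_params(self) -> int:
        return sum(a.size for a in self.param_arrays())

    # --- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.spec.depth
        a = x
        self._encs = []
        for i in range(d):
            a = self.enc_act[i].forward(self.enc_conv[i].forward(a))
            self._encs.append(a)
        out = self._encs[-1]
        for j in range(d):
            if j > 0:
                out = np.concatenate([out, self._encs[d - 1 - j]], axis=1)
            out = self.dec_conv[j].forward(out)
            if j < d - 1:
                out = self.dec_drop[j].forward(self.dec_act[j].forward(out), train)
        return self.out_tanh.forward(out)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        genc: list[np.ndarray | None] = [None] * d
        g = self.out_tanh.backward(gy)
        for j in reversed(range(d)):
            if j < d - 1:
                g = self.dec_act[j].backward(self.dec_drop[j].backward(g))
            g = self.dec_conv[j].backward(g)
            if j > 0:
                split = self._concat_prev_ch[j]
                skip = g[:, split:]
                i = d - 1 - j
                genc[i] = skip if genc[i] is None else genc[i] + skip
                g = g[:, :split]
            else:
                genc[d - 1] = g if genc[d - 1] is None else genc[d - 1] + g
        ge = genc[d - 1]
        gx = None
        for i in reversed(range(d)):
            g = self.enc_conv[i].backward(self.enc_act[i].backward(ge))
            if i > 0:
                ge = g + (genc[i - 1] if genc[i - 1] is not None else 0.0)
            else:
                gx = g
        return gx


class ConvDiscriminator:
    """Stride-2 conv stack with leaky ReLU, flattened into a dense two-way
    softmax head (a single global real/fake classification per sample)."""

    def __init__(self, spec: DiscriminatorSpec, tile_size: int, rng: np.random.Generator) -> None:
        if tile_size % (2 ** spec.conv_stages) != 0:
            raise InvalidArgumentError(
                f"tile size {tile_size} not divisible by 2^conv_stages = {2 ** spec.conv_stages}"
            )
        self.spec = spec
        self.tile_size = tile_size
        self.convs: list[nn.Conv2d] = []
        self.acts: list[nn.LeakyReLU] = []
        c_in = spec.in_channels
        for i in range(spec.conv_stages):
            c_out = spec.base_filters * 2 ** i
            self.convs.append(nn.Conv2d(c_in, c_out, rng))
            self.acts.append(nn.LeakyReLU(0.2))
            c_in = c_out
        side = tile_size // 2 ** spec.conv_stages
        self.head = nn.Dense(c_in * side * side, 2, rng)

    def layers(self) -> list[nn.Layer]:
        return [*self.convs, self.head]

    def param_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(arr for _, arr in layer.params())
        return out

    def grad_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers():
            out.extend(layer.grads())
        return out

    def n_params(self) -> int:
        return sum(a.size for a in self.param_arrays())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Return raw logits of shape (N, 2); index 1 is the 'real' class."""
        a = x
        for conv, act in zip(self.convs, self.acts):
            a = act.forward(conv.forward(a))
        return self.head.forward(a)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False))

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        g = self.head.backward(glogits)
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            g = conv.backward(act.backward(g))
        return g


def build_generator(spec: GeneratorSpec, tile_size: int, seed: int = 0) -> UNetGenerator:
    """Build an untrained generator; identical (spec, tile_size, seed) give
    bit-identical initial parameters."""
    return UNetGenerator(spec, tile_size, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, tile_size: int, seed: int = 0) -> ConvDiscriminator:
    return ConvDiscriminator(spec, tile_size, np.random.default_rng(seed))


def compute_fingerprint(weights: list[np.ndarray]) -> str:
    """Content hash (sha256) over the serialized weight arrays."""
    h = hashlib.sha256()
    for arr in weights:
        a = np.ascontiguousarray(arr)
        h.update(str(a.dtype).encode())
        h.update(json.dumps(a.shape).encode())
        h.update(a.tobytes())
    return h.hexdigest()


@dataclass
class ClassModel:
    """One trained class generator plus everything needed to reproduce its
    conditioning and training: edge parameters, specs, config, loss log."""

    label: str
    tile_size: int
    generator_spec: GeneratorSpec
    edge_params: EdgeParams
    training_config: TrainingConfig
    generator_weights: list[np.ndarray] = field(repr=False, default_factory=list)
    training_log: list[LossBundle] = field(default_factory=list)
    fingerprint: str = ""

    def __post_init__(self) -> None:
        self._net: UNetGenerator | None = None
        if self.generator_weights and not self.fingerprint:
            self.fingerprint = compute_fingerprint(self.generator_weights)

    def _network(self) -> UNetGenerator:
        if self._net is None:
            net = build_generator(self.generator_spec, self.tile_size, seed=0)
            net.set_params(self.generator_weights)
            self._net = net
        return self._net

    def _to_condition_input(self, tiles_px: np.ndarray) -> np.ndarray:
        """(N, H, W, 3) uint8 tiles -> (N, C, H, W) generator input."""
        conds = np.stack([
            detect_edges(t, self.edge_params).mask for t in tiles_px
        ]).astype(np.float32)
        x = np.transpose(conds, (0, 3, 1, 2)) * 2.0 - 1.0
        if self.training_config.noise_mode == "input":
            # deterministic inference: the noise channel is fixed at zero
            z = np.zeros((x.shape[0], 1, x.shape[2], x.shape[3]), dtype=np.float32)
            x = np.concatenate([x, z], axis=1)
        return x

    def reconstruct_batch(self, tiles_px: np.ndarray) -> np.ndarray:
        """Reconstruct a stack of (N, H, W, 3) uint8 tiles; returns the same
        shape in uint8.  Deterministic (inference dropout disabled)."""
        if tiles_px.ndim != 4 or tiles_px.shape[1] != self.tile_size \
                or tiles_px.shape[2] != self.tile_size or tiles_px.shape[3] != 3:
            raise InvalidArgumentError(
                f"expected (N, {self.tile_size}, {self.tile_size}, 3) tiles, got {tiles_px.shape}"
            )
        x = self._to_condition_input(tiles_px)
        y = self._network().forward(x, train=False)
        out = np.transpose(y, (0, 2, 3, 1))
        return np.clip(np.rint((out + 1.0) * 127.5), 0, 255).astype(np.uint8)

    def reconstruct(self, tile: np.ndarray) -> np.ndarray:
        """Reconstruct one (H, W, 3) uint8 tile via the stored edge params."""
        if tile.ndim != 3 or tile.shape[:2] != (self.tile_size, self.tile_size):
            raise InvalidArgumentError(
                f"tile shape {tile.shape} does not match model tile size {self.tile_size}"
            )
        return self.reconstruct_batch(tile[None])[0]


def reconstruct(model: ClassModel, tile: np.ndarray) -> np.ndarray:
    """Module-level alias for :meth:`ClassModel.reconstruct`."""
    return model.reconstruct(tile)


def _onehot_grad(logits: np.ndarray, real: bool) -> np.ndarray:
    """Gradient of mean cross-entropy w.r.t. logits for label real/fake."""
    p = nn.softmax(logits)
    target = np.zeros_like(p)
    target[:, 1 if real else 0] = 1.0
    return (p - target) / logits.shape[0]


def train_class_model(tiles: list[Tile], edge_params: EdgeParams,
                      gspec: GeneratorSpec, dspec: DiscriminatorSpec,
                      cfg: TrainingConfig) -> ClassModel:
    """Train one class generator on tiles of a single class.

    Alternates one discriminator and one generator update per shuffled
    mini-batch.  Bit-reproducible given ``cfg.seed``; raises if the tile
    collection mixes labels (the single-task contract).
    """
    if not tiles:
        raise InvalidArgumentError("at least one tile is required")
    labels = {t.label for t in tiles}
    if len(labels) != 1:
        raise InvalidArgumentError(
            f"tiles must share exactly one label, got {sorted(str(l) for l in labels)}"
        )
    label = tiles[0].label
    sizes = {t.pixels.shape for t in tiles}
    if len(sizes) != 1:
        raise InvalidArgumentError(f"tiles must share one size, got {sorted(sizes)}")
    tile_size = tiles[0].size

    gspec_eff = gspec
    if cfg.noise_mode == "input":
        gspec_eff = replace(gspec, in_channels=gspec.in_channels + 1)

    pixels = stack_pixels(tiles)
    conds = np.stack([detect_edges(p, edge_params).mask for p in pixels]).astype(np.float32)
    cond_in = np.transpose(conds, (0, 3, 1, 2)) * 2.0 - 1.0     # {0,1} -> [-1,1]
    imgs = np.transpose(pixels, (0, 3, 1, 2)).astype(np.float32) / 127.5 - 1.0

    rng = np.random.default_rng(cfg.seed)
    gen = UNetGenerator(gspec_eff, tile_size, rng)
    disc = ConvDiscriminator(dspec, tile_size, rng)
    opt_g = nn.Adam(list(zip(gen.param_arrays(), gen.grad_arrays())),
                    lr=cfg.learning_rate, beta1=cfg.beta1)
    opt_d = nn.Adam(list(zip(disc.param_arrays(), disc.grad_arrays())),
                    lr=cfg.learning_rate, beta1=cfg.beta1)

    n = len(tiles)
    log: list[LossBundle] = []
    for _ in range(cfg.epochs):
        perm = rng.permutation(n)
        ep = {"d": 0.0, "adv": 0.0, "mse": 0.0, "tot": 0.0, "nb": 0}
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            y = cond_in[idx]
            x = imgs[idx]
            gin = y
            if cfg.noise_mode == "input":
                z = rng.random((len(idx), 1, tile_size, tile_size), dtype=np.float32) * 2.0 - 1.0
                gin = np.concatenate([y, z], axis=1)

            fake = gen.forward(gin, train=True)

            # --- discriminator update ----------------------------------
            opt_d.zero_grad()
            logits_r = disc.forward(np.concatenate([y, x], axis=1), train=True)
            p_real = nn.softmax(logits_r)[:, 1]
            disc.backward(_onehot_grad(logits_r, real=True))
            logits_f = disc.forward(np.concatenate([y, fake], axis=1), train=True)
            p_fake0 = nn.softmax(logits_f)[:, 1]
            disc.backward(_onehot_grad(logits_f, real=False))
            opt_d.step()
            d_loss = discriminator_loss(p_real, p_fake0)

            # --- generator update (against the updated discriminator) --
            opt_d.zero_grad()
            logits_f2 = disc.forward(np.concatenate([y, fake], axis=1), train=True)
            p_fake = nn.softmax(logits_f2)[:, 1]
            if cfg.adversarial_form == "saturating":
                glog = -_onehot_grad(logits_f2, real=False)
            else:
                glog = _onehot_grad(logits_f2, real=True)
            g_pair = disc.backward(cfg.lambda_adv * glog)
            g_fake_adv = g_pair[:, y.shape[1]:]
            g_fake_mse = 2.0 * (fake - x) / fake.size
            opt_g.zero_grad()
            gen.backward(g_fake_adv.astype(np.float32)
                         + np.float32(cfg.lambda_mse) * g_fake_mse)
            opt_g.step()
            opt_d.zero_grad()

            bundle = generator_loss(p_fake, fake, x, cfg)
            ep["d"] += d_loss
            ep["adv"] += bundle.g_adv
            ep["mse"] += bundle.g_mse
            ep["tot"] += bundle.g_total
            ep["nb"] += 1
        nb = max(ep["nb"], 1)
        log.append(LossBundle(d_loss=ep["d"] / nb, g_adv=ep["adv"] / nb,
                              g_mse=ep["mse"] / nb, g_total=ep["tot"] / nb))

    weights = [a.copy() for a in gen.param_arrays()]
    return ClassModel(
        label=label, tile_size=tile_size, generator_spec=gspec_eff,
        edge_params=edge_params, training_config=cfg,
        generator_weights=weights, training_log=log,
        fingerprint=compute_fingerprint(weights),
    )
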