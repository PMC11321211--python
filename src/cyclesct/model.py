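"""CLCGAN network components.

Two symmetric translation generators (G_SN: streaked CBCT-like domain S ->
clean CT-like domain N, and G_NS the reverse), two patch discriminators
(D_N, D_S), and per-encoder-layer two-layer MLP projection heads used by the
patch-contrastive objective.  Each generator is a fully convolutional
three-stage encoder, nine residual blocks and a three-stage decoder with
instance normalisation throughout (appropriate for batch size 1).

For the contrastive scheme, features are taken directly from the generator
encoder at sampled spatial locations: the embedding of a location on one
side (input or translated output) is the query, the same location on the
other side is its positive, and the other sampled locations provide the k
negatives.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

ENCODER_LAYERS = 3
RESIDUAL_BLOCKS = 9
DECODER_LAYERS = 3
DISCRIMINATOR_LAYERS = 4

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 1
    base_channels: int = 64
    encoder_layers: int = ENCODER_LAYERS
    residual_blocks: int = RESIDUAL_BLOCKS
    decoder_layers: int = DECODER_LAYERS
    allow_nonstandard: bool = False

    def __post_init__(self):
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        std = (self.encoder_layers == ENCODER_LAYERS
               and self.residual_blocks == RESIDUAL_BLOCKS
               and self.decoder_layers == DECODER_LAYERS)
        if not std and not self.allow_nonstandard:
            raise ValueError(
                "layer counts are fixed (3 encoder / 9 residual / 3 decoder); "
                "pass allow_nonstandard=True to override")


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 1
    base_channels: int = 64
    layers: int = DISCRIMINATOR_LAYERS

    def __post_init__(self):
        if self.layers != DISCRIMINATOR_LAYERS:
            raise ValueError("discriminator depth is fixed at 4 encoder layers")


@dataclass(frozen=True)
class ProjectionHeadSpec:
    embedding_dim: int = 256
    hidden_dim: int = 256
    layer_ids: tuple = (0, 1, 2)

    def __post_init__(self):
        if self.embedding_dim < 1 or self.hidden_dim < 1:
            raise ValueError("head dimensions must be >= 1")
        if any(l not in range(ENCODER_LAYERS) for l in self.layer_ids):
            raise ValueError(f"layer_ids must be within 0..{ENCODER_LAYERS - 1}")


class Generator(nn.Module):
    """Resnet translation generator; `encode` exposes per-stage features."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        ngf = spec.base_channels
        # encoder stage 1: 7x7 stem at full resolution
        self.enc = [
            nn.Sequential(nn.Conv2d(spec.in_channels, ngf, 7, pad=3,
                                    pad_mode="reflect", rng=rng),
                          nn.InstanceNorm2d(), nn.ReLU()),
            nn.Sequential(nn.Conv2d(ngf, ngf * 2, 3, stride=2, pad=1,
                                    pad_mode="zeros", rng=rng),
                          nn.InstanceNorm2d(), nn.ReLU()),
            nn.Sequential(nn.Conv2d(ngf * 2, ngf * 4, 3, stride=2, pad=1,
                                    pad_mode="zeros", rng=rng),
                          nn.InstanceNorm2d(), nn.ReLU()),
        ]
        self.blocks = [nn.ResnetBlock(ngf * 4, rng) for _ in range(spec.residual_blocks)]
        self.dec = [
            nn.Sequential(nn.Upsample2x(),
                          nn.Conv2d(ngf * 4, ngf * 2, 3, pad=1, pad_mode="zeros", rng=rng),
                          nn.InstanceNorm2d(), nn.ReLU()),
            nn.Sequential(nn.Upsample2x(),
                          nn.Conv2d(ngf * 2, ngf, 3, pad=1, pad_mode="zeros", rng=rng),
                          nn.InstanceNorm2d(), nn.ReLU()),
            nn.Sequential(nn.Conv2d(ngf, spec.in_channels, 7, pad=3,
                                    pad_mode="reflect", rng=rng),
                          nn.Tanh()),
        ]

    def encode(self, x: Tensor) -> list:
        feats = []
        h = x
        for stage in self.enc:
            h = stage(h)
            feats.append(h)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        h = self.encode(x)[-1]
        for blk in self.blocks:
            h = blk(h)
        for stage in self.dec:
            h = stage(h)
        return h

    def feature_channels(self, layer_ids) -> list:
        ngf = self.spec.base_channels
        dims = [ngf, ngf * 2, ngf * 4]
        return [dims[i] for i in layer_ids]


class PatchDiscriminator(nn.Module):
    """Four strided-conv encoder layers emitting a patch score map (logits).

    Deliberately *unnormalised*: instance normalisation inside the
    discriminator would cancel per-image mean/scale — i.e. exactly the
    global CT-number depression the adversarial signal must detect for the
    network to correct HU values.
    """

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        ndf = spec.base_channels
        self.net = nn.Sequential(
            nn.Conv2d(spec.in_channels, ndf, 4, stride=2, pad=1, pad_mode="zeros", rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(ndf, ndf * 2, 4, stride=2, pad=1, pad_mode="zeros", rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(ndf * 2, ndf * 4, 4, stride=2, pad=1, pad_mode="zeros", rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(ndf * 4, ndf * 8, 4, stride=1, pad=1, pad_mode="zeros", rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(ndf * 8, 1, 4, stride=1, pad=1, pad_mode="zeros", rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class ProjectionHeads(nn.Module):
    """One two-layer MLP per selected encoder layer; shared across domains."""

    def __init__(self, spec: ProjectionHeadSpec, channel_dims: list,
                 rng: np.random.Generator):
        self.spec = spec
        self.mlps = [
            nn.Sequential(nn.Linear(c, spec.hidden_dim, rng=rng), nn.ReLU(),
                          nn.Linear(spec.hidden_dim, spec.embedding_dim, rng=rng))
            for c in channel_dims
        ]

    def project(self, layer_index: int, feats: Tensor) -> Tensor:
        """(N, P, C) features -> (N, P, D) unit-norm embeddings."""
        return T.l2_normalize(self.mlps[layer_index](feats))


def build_generator(spec: GeneratorSpec, seed: int) -> Generator:
    return Generator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


def build_heads(spec: ProjectionHeadSpec, gen: Generator, seed: int) -> ProjectionHeads:
    return ProjectionHeads(spec, gen.feature_channels(spec.layer_ids),
                           np.random.default_rng(seed))


def sample_patch_locations(layer_shape, n_patches: int, seed: int) -> np.ndarray:
    """Distinct flat spatial indices on a feature map, seeded."""
    h, w = layer_shape[-2:]
    area = h * w
    if n_patches > area:
        raise ValueError(f"n_patches {n_patches} exceeds layer area {area}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(area, size=n_patches, replace=False))


def encode_and_project(generator: Generator, heads: ProjectionHeads,
                       image, layer_ids=None, locations: dict | None = None) -> dict:
    """Per-layer, per-location unit-norm embeddings of an image.

    ``locations`` maps layer id -> flat spatial indices on that layer's
    feature map; returns layer id -> (N, P, D) embedding arrays for the
    requested ``layer_ids`` (default: all layers the heads serve).
    """
    if locations is None:
        raise ValueError("locations mapping is required")
    if layer_ids is None:
        layer_ids = heads.spec.layer_ids
    bad = [l for l in layer_ids if l not in heads.spec.layer_ids]
    if bad:
        raise ValueError(f"no projection head for encoder layer(s) {bad}")
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=np.float32))
    if x.ndim == 2:
        x = Tensor(x.data[None, None])
    feats = generator.encode(x)
    out = {}
    for hi, lid in enumerate(heads.spec.layer_ids):
        if lid not in locations or lid not in layer_ids:
            continue
        f = feats[lid]
        gathered = T.gather_hw(f, np.asarray(locations[lid]))
        out[lid] = heads.project(hi, gathered)
    return out


@dataclass
class ModelBundle:
    """The full CLCGAN: both generators, both discriminators, shared heads."""

    G_SN: Generator
    G_NS: Generator
    D_N: PatchDiscriminator
    D_S: PatchDiscriminator
    heads: ProjectionHeads
    gen_spec: GeneratorSpec = field(default_factory=GeneratorSpec)
    disc_spec: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)
    head_spec: ProjectionHeadSpec = field(default_factory=ProjectionHeadSpec)

    def components(self) -> dict:
        return {"G_SN": self.G_SN, "G_NS": self.G_NS,
                "D_N": self.D_N, "D_S": self.D_S, "heads": self.heads}

    def generator_parameters(self) -> list:
        return (self.G_SN.parameters() + self.G_NS.parameters()
                + self.heads.parameters())

    def discriminator_parameters(self) -> list:
        return self.D_N.parameters() + self.D_S.parameters()

    def state_dict(self) -> dict:
        state = {}
        for name, comp in self.components().items():
            for k, v in comp.state_dict().items():
                state[f"{name}.{k}"] = v
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, comp in self.components().items():
            prefix = name + "."
            sub = {k[len(prefix):]: v for k, v in state.items() if k.startswith(prefix)}
            comp.load_state_dict(sub)


def build_bundle(gen_spec: GeneratorSpec = GeneratorSpec(),
                 disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
                 head_spec: ProjectionHeadSpec = ProjectionHeadSpec(),
                 seed: int = 0) -> ModelBundle:
    ss = np.random.SeedSequence(seed).generate_state(5)
    g_sn = build_generator(gen_spec, int(ss[0]))
    g_ns = build_generator(gen_spec, int(ss[1]))
    return ModelBundle(
        G_SN=g_sn, G_NS=g_ns,
        D_N=build_discriminator(disc_spec, int(ss[2])),
        D_S=build_discriminator(disc_spec, int(ss[3])),
        heads=build_heads(head_spec, g_sn, int(ss[4])),
        gen_spec=gen_spec, disc_spec=disc_spec, head_spec=head_spec)


def save_bundle(bundle: ModelBundle, path, extra: dict | None = None) -> None:
    """Single-file archive: all weights + the three spec records."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "gen_spec": asdict(bundle.gen_spec),
        "disc_spec": asdict(bundle.disc_spec),
        "head_spec": asdict(bundle.head_spec),
        "extra": extra or {},
    }
    arrays = {f"w::{k}": v for k, v in bundle.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_bundle(path):
    """Load a bundle archive; returns (bundle, extra-metadata dict)."""
    try:
        with np.load(path, allow_pickle=False) as z:
            if "__meta__" not in z:
                raise ValueError("not a cyclesct checkpoint (missing metadata)")
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            arrays = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
    except (OSError, ValueError, KeyError) as exc:
        raise IOError(f"could not load checkpoint {path}: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise IOError(
            f"checkpoint version {meta.get('version')} != supported {CHECKPOINT_VERSION}")
    bundle = build_bundle(GeneratorSpec(**meta["gen_spec"]),
                          DiscriminatorSpec(**meta["disc_spec"]),
                          ProjectionHeadSpec(
                              **{**meta["head_spec"],
                                 "layer_ids": tuple(meta["head_spec"]["layer_ids"])}),
                          seed=0)
    bundle.load_state_dict(arrays)
    return bundle, meta["extra"]
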