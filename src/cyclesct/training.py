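"""Training orchestration: alternating CLCGAN updates, checkpointing,
deterministic inference.

Hyperparameters follow the published recipe: Adam (lr 2e-4, beta1 0.5,
beta2 0.999), batch size 1, instance normalisation, paired random crops and
random horizontal flips, loss weights (2, 1, 1, 0.01), temperature 0.07.
Each iteration updates the discriminators first (on the current fakes,
detached) and then the generators plus projection heads on the weighted
total loss.  One root seed drives model init, data order, crops, flips and
patch sampling, making the whole trajectory bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import losses as L
from . import model as M
from .core import PhaseVolume, SlicePair
from .data import DatasetManifest, NormalizationSpec, denormalize_hu, normalize_hu, \
    paired_random_crop, paired_random_flip
from .nn import Adam
from .nn.tensor import Tensor

_SEED_MOD = 2 ** 31


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 100
    seed: int = 0
    crop_size: int = 512
    n_patches: int = 256
    k_negatives: int | None = None      # defaults to n_patches - 1 (internal negatives)
    layer_ids: tuple = (0, 1, 2)
    checkpoint_every: int = 0           # epochs; 0 disables
    output_dir: str | None = None
    max_iterations: int | None = None
    adversarial_mode: str = "nonsaturating"
    contrastive_keys: str = "paired"    # "paired": positives from the paired
                                        # real target image; "self": from the
                                        # generator's own input (unpaired style)
    base_channels: int = 64
    disc_channels: int = 64
    embedding_dim: int = 256
    hu_window: tuple = (-1000.0, 3095.0)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.k_negatives is None:
            self.k_negatives = self.n_patches - 1
        if self.k_negatives != self.n_patches - 1:
            raise ValueError(
                "negatives are the other sampled locations, so k_negatives "
                "must equal n_patches - 1")

    @classmethod
    def desk_preset(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """Desk-scale preset: 64x64 crops, small nets, ~300 iterations."""
        args = dict(crop_size=64, n_patches=64, base_channels=16,
                    disc_channels=16, embedding_dim=64, epochs=100,
                    max_iterations=300, seed=seed)
        args.update(overrides)
        return cls(**args)

    @property
    def norm_spec(self) -> NormalizationSpec:
        return NormalizationSpec(*self.hu_window)


@dataclass
class TrainState:
    epoch: int = 0
    iteration: int = 0
    loss_history: list = field(default_factory=list)
    rng_state: dict | None = None


def _build_bundle_for(config: TrainConfig) -> M.ModelBundle:
    return M.build_bundle(
        M.GeneratorSpec(base_channels=config.base_channels),
        M.DiscriminatorSpec(base_channels=config.disc_channels),
        M.ProjectionHeadSpec(embedding_dim=config.embedding_dim,
                             hidden_dim=config.embedding_dim,
                             layer_ids=tuple(config.layer_ids)),
        seed=config.seed)


def make_optimizers(bundle: M.ModelBundle, config: TrainConfig):
    opt_g = Adam(bundle.generator_parameters(), lr=config.learning_rate,
                 beta1=config.beta1, beta2=config.beta2)
    opt_d = Adam(bundle.discriminator_parameters(), lr=config.learning_rate,
                 beta1=config.beta1, beta2=config.beta2)
    return opt_g, opt_d


def _layer_shapes(crop: int, layer_ids) -> dict:
    sizes = {0: crop, 1: crop // 2, 2: crop // 4}
    return {lid: (sizes[lid], sizes[lid]) for lid in layer_ids}


def _nce_direction(gen: M.Generator, heads: M.ProjectionHeads, inp_feats: list,
                   fake: Tensor, locations: dict, tau: float):
    """PatchNCE for one direction: queries from the translated output,
    positives/negatives from the input, both through the same encoder."""
    fake_feats = gen.encode(fake)
    terms = []
    for hi, lid in enumerate(heads.spec.layer_ids):
        if lid not in locations:
            continue
        idx = locations[lid]
        from .nn import tensor as T
        q = heads.project(hi, T.gather_hw(fake_feats[lid], idx))
        k = heads.project(hi, T.gather_hw(inp_feats[lid], idx))
        terms.append(L.patch_nce_loss(q, k, tau))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def train_step(bundle: M.ModelBundle, pair: SlicePair, weights: L.LossWeights,
               config: TrainConfig, opt_g: Adam | None = None,
               opt_d: Adam | None = None, step_seed: int = 0):
    """One alternating update on a normalised slice pair.

    ``pair.ct``/``pair.cbct`` must already be on the network input scale
    [-1, 1].  Returns (bundle, LossReport); the bundle is updated in place.
    """
    if opt_g is None or opt_d is None:
        _g, _d = make_optimizers(bundle, config)
        opt_g = opt_g or _g
        opt_d = opt_d or _d
    n = Tensor(np.asarray(pair.ct, dtype=np.float32)[None, None])
    s = Tensor(np.asarray(pair.cbct, dtype=np.float32)[None, None])

    # forward passes with graph; encoder features come along for free
    fake_n, feats_s = _forward_with_features(bundle.G_SN, s)
    fake_s, feats_n = _forward_with_features(bundle.G_NS, n)

    # --- discriminator update on detached fakes ---------------------------
    d_loss = (L.discriminator_adversarial_loss(
                  bundle.D_N(n), bundle.D_N(fake_n.detach()), config.adversarial_mode)
              + L.discriminator_adversarial_loss(
                  bundle.D_S(s), bundle.D_S(fake_s.detach()), config.adversarial_mode))
    opt_d.zero_grad()
    d_loss.backward()
    opt_d.step()

    # --- generator + heads update ----------------------------------------
    l_adv = (L.generator_adversarial_loss(bundle.D_N(fake_n), config.adversarial_mode)
             + L.generator_adversarial_loss(bundle.D_S(fake_s), config.adversarial_mode))
    rec_n = bundle.G_SN(fake_s)
    rec_s = bundle.G_NS(fake_n)
    l_cyc = L.cycle_loss_t(rec_n, n) + L.cycle_loss_t(rec_s, s)
    l_freq = L.frequency_loss_t(rec_n, n) + L.frequency_loss_t(rec_s, s)

    rng = np.random.default_rng(step_seed)
    shapes = _layer_shapes(pair.ct.shape[-1], config.layer_ids)
    locations = {lid: M.sample_patch_locations(shapes[lid], config.n_patches,
                                               int(rng.integers(_SEED_MOD)))
                 for lid in config.layer_ids}
    if config.contrastive_keys == "paired":
        # positives: the paired real target image at the same locations,
        # through the same encoder the query (generated) side uses
        keys_sn = bundle.G_SN.encode(n)
        keys_ns = bundle.G_NS.encode(s)
    elif config.contrastive_keys == "self":
        # unpaired (CUT-style) fallback: keys from the generator's input
        keys_sn, keys_ns = feats_s, feats_n
    else:
        raise ValueError(f"unknown contrastive_keys {config.contrastive_keys!r}")
    l_cont = (_nce_direction(bundle.G_SN, bundle.heads, keys_sn, fake_n,
                             locations, weights.tau)
              + _nce_direction(bundle.G_NS, bundle.heads, keys_ns, fake_s,
                               locations, weights.tau)) * 0.5

    total = (l_cont * weights.lambda_contrastive + l_cyc * weights.lambda_cycle
             + l_adv * weights.lambda_adversarial + l_freq * weights.lambda_frequency)
    opt_g.zero_grad()
    total.backward()
    opt_g.step()

    report = L.total_loss(l_cont.item(), l_cyc.item(), l_adv.item(),
                          l_freq.item(), weights)
    return bundle, report


def _forward_with_features(gen: M.Generator, x: Tensor):
    feats = gen.encode(x)
    h = feats[-1]
    for blk in gen.blocks:
        h = blk(h)
    for stage in gen.dec:
        h = stage(h)
    return h, feats


def train(manifest: DatasetManifest, config: TrainConfig,
          weights: L.LossWeights = L.LossWeights(),
          resume_from=None, bundle: M.ModelBundle | None = None):
    """Full training loop with per-epoch shuffling and checkpointing.

    Returns (ModelBundle, TrainState).  A run resumed from an epoch
    checkpoint reproduces the same trajectory as an uninterrupted one.
    """
    if len(manifest) == 0:
        raise ValueError("empty dataset manifest")
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    log_fh = (out / "training_log.jsonl").open("a") if out else None

    state = TrainState()
    rng = np.random.default_rng(config.seed)
    if resume_from is not None:
        bundle, state, opt_g, opt_d = load_checkpoint(resume_from, config)
        rng = np.random.default_rng(config.seed)
        rng.bit_generator.state = state.rng_state
    else:
        if bundle is None:
            bundle = _build_bundle_for(config)
        opt_g, opt_d = make_optimizers(bundle, config)

    norm = config.norm_spec
    records = list(manifest.records)
    done = False
    for epoch in range(state.epoch, config.epochs):
        order = rng.permutation(len(records))
        for idx in order:
            rec = records[int(idx)]
            raw = manifest.load_pair(rec)
            crop_seed = int(rng.integers(_SEED_MOD))
            flip_seed = int(rng.integers(_SEED_MOD))
            step_seed = int(rng.integers(_SEED_MOD))
            pair = paired_random_crop(raw, config.crop_size, crop_seed)
            pair = paired_random_flip(pair, flip_seed)
            pair = dataclasses.replace(pair, ct=normalize_hu(pair.ct, norm),
                                       cbct=normalize_hu(pair.cbct, norm))
            bundle, report = train_step(bundle, pair, weights, config,
                                        opt_g, opt_d, step_seed=step_seed)
            state.iteration += 1
            state.loss_history.append(report)
            if log_fh:
                log_fh.write(json.dumps({"epoch": epoch, "iteration": state.iteration,
                                         **dataclasses.asdict(report)}) + "\n")
            if config.max_iterations and state.iteration >= config.max_iterations:
                done = True
                break
        state.epoch = epoch + 1
        state.rng_state = rng.bit_generator.state
        if out and config.checkpoint_every and (epoch + 1) % config.checkpoint_every == 0:
            save_checkpoint(bundle, state, opt_g, opt_d,
                            out / f"checkpoint_epoch{epoch + 1:04d}.npz")
        if done:
            break
    if log_fh:
        log_fh.close()
    if out:
        save_checkpoint(bundle, state, opt_g, opt_d, out / "checkpoint_final.npz")
    return bundle, state


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(bundle: M.ModelBundle, state: TrainState,
                    opt_g: Adam | None, opt_d: Adam | None, path) -> None:
    extra = {
        "state": {
            "epoch": state.epoch,
            "iteration": state.iteration,
            "rng_state": _jsonable(state.rng_state),
        },
        "has_optim": opt_g is not None and opt_d is not None,
    }
    arrays = {}
    hist = np.array([[r.l_cont, r.l_cyc, r.l_adv, r.l_freq, r.total]
                     for r in state.loss_history], dtype=np.float64)
    arrays["hist"] = hist.reshape(-1, 5)
    if extra["has_optim"]:
        for tag, opt in (("g", opt_g), ("d", opt_d)):
            st = opt.state()
            extra[f"opt_{tag}_t"] = st["t"]
            for i, m in enumerate(st["m"]):
                arrays[f"opt{tag}_m_{i}"] = m
            for i, v in enumerate(st["v"]):
                arrays[f"opt{tag}_v_{i}"] = v
    meta = {
        "version": M.CHECKPOINT_VERSION,
        "gen_spec": dataclasses.asdict(bundle.gen_spec),
        "disc_spec": dataclasses.asdict(bundle.disc_spec),
        "head_spec": dataclasses.asdict(bundle.head_spec),
        "extra": extra,
    }
    weights = {f"w::{k}": v for k, v in bundle.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **weights, **{f"x::{k}": v for k, v in arrays.items()})


def load_checkpoint(path, config: TrainConfig | None = None):
    """Load (bundle, state, opt_g, opt_d) from a checkpoint archive."""
    bundle, extra = _load_bundle_and_arrays(path)
    bundle, extra, arrays = bundle
    st = extra["state"]
    hist = arrays.get("hist", np.zeros((0, 5)))
    state = TrainState(
        epoch=int(st["epoch"]), iteration=int(st["iteration"]),
        loss_history=[L.LossReport(*row) for row in hist],
        rng_state=_unjsonable(st["rng_state"]))
    opt_g = opt_d = None
    if extra.get("has_optim"):
        cfg = config or TrainConfig()
        opt_g, opt_d = make_optimizers(bundle, cfg)
        for tag, opt in (("g", opt_g), ("d", opt_d)):
            n = len(opt.params)
            opt.load_state({
                "t": extra[f"opt_{tag}_t"],
                "m": [arrays[f"opt{tag}_m_{i}"] for i in range(n)],
                "v": [arrays[f"opt{tag}_v_{i}"] for i in range(n)],
            })
    return bundle, state, opt_g, opt_d


def _load_bundle_and_arrays(path):
    try:
        with np.load(path, allow_pickle=False) as z:
            if "__meta__" not in z:
                raise ValueError("missing checkpoint metadata")
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            if meta.get("version") != M.CHECKPOINT_VERSION:
                raise ValueError(
                    f"checkpoint version {meta.get('version')} != "
                    f"supported {M.CHECKPOINT_VERSION}")
            weights = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
            arrays = {k[3:]: z[k] for k in z.files if k.startswith("x::")}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise IOError(f"could not load checkpoint {path}: {exc}") from exc
    bundle = M.build_bundle(
        M.GeneratorSpec(**meta["gen_spec"]),
        M.DiscriminatorSpec(**meta["disc_spec"]),
        M.ProjectionHeadSpec(**{**meta["head_spec"],
                                "layer_ids": tuple(meta["head_spec"]["layer_ids"])}),
        seed=0)
    bundle.load_state_dict(weights)
    return (bundle, meta["extra"], arrays), meta["extra"]


def checkpoint_roundtrip(bundle: M.ModelBundle, state: TrainState, path):
    """save + load; the loaded bundle reproduces outputs bit-identically."""
    save_checkpoint(bundle, state, None, None, path)
    b2, s2, _, _ = load_checkpoint(path)
    return b2, s2


def _jsonable(rng_state):
    if rng_state is None:
        return None
    return json.loads(json.dumps(rng_state, default=int))


def _unjsonable(st):
    if st is None:
        return None
    # numpy Generator state: uint64s arrive as ints, which is acceptable
    return st


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def generate_sct(bundle: M.ModelBundle, cbct, norm: NormalizationSpec = NormalizationSpec(),
                 identity_surrogate: bool = False):
    """Slice-wise G_SN application producing a synthetic-CT volume.

    Accepts a PhaseVolume (2-D slice or 3-D stack) or a list of them
    (a 4-D set); output keeps the input geometry, modality 'sCT'.
    """
    if isinstance(cbct, (list, tuple)):
        return [generate_sct(bundle, v, norm, identity_surrogate) for v in cbct]
    vol = cbct
    if vol.modality not in ("CBCT", "sCBCT"):
        raise ValueError(f"generate_sct expects a CBCT-like input, got {vol.modality}")
    img = vol.voxels
    slices = img[None] if img.ndim == 2 else img
    out = np.empty_like(slices, dtype=np.float32)
    for i, sl in enumerate(slices):
        x = normalize_hu(sl, norm)
        if identity_surrogate:
            y = x
        else:
            y = bundle.G_SN(Tensor(x[None, None])).data[0, 0]
        out[i] = denormalize_hu(y, norm)
    result = out[0] if img.ndim == 2 else out
    return PhaseVolume(voxels=result, phase=vol.phase, spacing=vol.spacing,
                       modality="sCT", n_phases=vol.n_phases,
                       subject_id=vol.subject_id)
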