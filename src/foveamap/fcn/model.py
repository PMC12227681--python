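"""Distance-transform regression U-Net: architecture, training, inference.

The network is an encoder-decoder with no fully connected layers. Each
resolution level is a block of k sub-blocks (3x3 zero-padded convolution,
batch norm, ReLU); channel count doubles at the first sub-block of each
encoder level and halves in the decoder. Three max-pooling steps set the
receptive field to the range of cone sizes; dropout at the lowest resolution
regularizes against small training sets; 4x4/stride-2/pad-1 transposed
convolutions upsample, with skip concatenation from the same-resolution
encoder block; a final 1x1 convolution yields the single-channel predicted
distance transform at the input resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..core import ScalarMap, ValidityMask
from ..preprocess import (EROSION_ITERS_INFERENCE, PatchSet, erode_mask, stitch,
                          tile_for_inference, Patch)
from .layers import (F32, Adam, BatchNorm2D, Conv2D, ConvTranspose2D, Dropout,
                     MaxPool2x2, ReLU)


@dataclass(frozen=True)
class FCNConfig:
    in_size: int = 256
    depth: int = 3            # number of resolution decreases by pooling
    sub_blocks_k: int = 2     # sub-blocks (conv+BN+ReLU) per resolution block
    base_filters: int = 32
    dropout_p: float = 0.2    # applied at the lowest resolution
    out_channels: int = 1

    def validate(self) -> None:
        if self.in_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"in_size {self.in_size} must be divisible by 2^depth = {2 ** self.depth}"
            )
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.sub_blocks_k < 1 or self.base_filters < 1 or self.depth < 1:
            raise ValueError("depth, sub_blocks_k and base_filters must be >= 1")


@dataclass
class TrainConfig:
    loss: str = "mse"          # "mse" or "mae", on valid pixels
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 8
    epochs: int = 25
    augment: bool = True       # random flips and 90-degree rotations
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.loss not in ("mse", "mae"):
            raise ValueError("loss must be 'mse' or 'mae'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class TrainState:
    model: "UNet"
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    config: TrainConfig | None = None


def _block(c_in: int, c_out: int, k_sub: int, rng) -> list:
    layers: list = []
    c = c_in
    for _ in range(k_sub):
        layers += [Conv2D(c, c_out, k=3, rng=rng), BatchNorm2D(c_out), ReLU()]
        c = c_out
    return layers


class UNet:
    def __init__(self, cfg: FCNConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        b, d, k = cfg.base_filters, cfg.depth, cfg.sub_blocks_k

        self.enc_blocks = []
        c_in = 1
        for lvl in range(d):
            c_out = b * (2 ** lvl)
            self.enc_blocks.append(_block(c_in, c_out, k, rng))
            c_in = c_out
        self.pools = [MaxPool2x2() for _ in range(d)]
        c_bott = b * (2 ** d)
        self.bottleneck = _block(c_in, c_bott, k, rng) + [Dropout(cfg.dropout_p)]

        self.ups, self.dec_blocks = [], []
        c_in = c_bott
        for lvl in reversed(range(d)):
            c_out = b * (2 ** lvl)
            self.ups.append(ConvTranspose2D(c_in, c_out, rng=rng))
            self.dec_blocks.append(_block(2 * c_out, c_out, k, rng))
            c_in = c_out
        self.head = Conv2D(c_in, cfg.out_channels, k=1, pad=0, rng=rng)

    # -- plumbing ---------------------------------------------------------
    def all_layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        for up, blk in zip(self.ups, self.dec_blocks):
            yield up
            yield from blk
        yield self.head

    def params(self):
        out = []
        for i, layer in enumerate(self.all_layers()):
            out.extend((f"{i}.{n}", v, g) for n, v, g in layer.params())
        return out

    def n_params(self) -> int:
        return sum(v.size for _, v, _ in self.params())

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h, w = x.shape[1], x.shape[2]
        if h % (2 ** self.cfg.depth) or w % (2 ** self.cfg.depth):
            raise ValueError("input spatial size must be divisible by 2^depth")
        x = x.astype(F32)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                x = layer.forward(x, train=train, rng=rng)
            skips.append(x)
            x = pool.forward(x, train=train)
        for layer in self.bottleneck:
            x = layer.forward(x, train=train, rng=rng)
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train=train)
            x = np.concatenate([skip, x], axis=-1)
            for layer in blk:
                x = layer.forward(x, train=train, rng=rng)
        return self.head.forward(x, train=train)

    def backward(self, dy: np.ndarray) -> None:
        dx = self.head.backward(dy.astype(F32))
        dskips = [None] * len(self.enc_blocks)
        for i in reversed(range(len(self.ups))):
            for layer in reversed(self.dec_blocks[i]):
                dx = layer.backward(dx)
            lvl = len(self.enc_blocks) - 1 - i
            c_skip = self.enc_blocks[lvl][-3].c_out
            dskips[lvl] = dx[..., :c_skip]
            dx = self.ups[i].backward(np.ascontiguousarray(dx[..., c_skip:]))
        for layer in reversed(self.bottleneck):
            dx = layer.backward(dx)
        for lvl in reversed(range(len(self.enc_blocks))):
            dx = self.pools[lvl].backward(dx)
            dx = dx + dskips[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                dx = layer.backward(dx)

    # -- serialization ----------------------------------------------------
    _STATE_NAMES = ("W", "b", "gamma", "beta", "running_mean", "running_var")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.all_layers()):
            for name in self._STATE_NAMES:
                if hasattr(layer, name):
                    state[f"{i}.{name}"] = getattr(layer, name)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.all_layers()):
            for name in self._STATE_NAMES:
                if hasattr(layer, name):
                    key = f"{i}.{name}"
                    if key not in state:
                        raise ValueError(f"checkpoint is missing {key}")
                    getattr(layer, name)[...] = state[key]


def build_model(cfg: FCNConfig | None = None, seed: int = 0) -> UNet:
    """Construct the regression U-Net with He-initialized weights."""
    return UNet(cfg or FCNConfig(), seed=seed)


def save_model(model: UNet, path) -> None:
    """Single-file checkpoint: all weights + batch-norm statistics + config."""
    state = dict(model.state_dict())
    state["_config_json"] = np.frombuffer(
        json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_model(path) -> UNet:
    with np.load(path) as data:
        cfg = FCNConfig(**json.loads(bytes(data["_config_json"]).decode()))
        model = UNet(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "_config_json"})
    return model


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str):
    diff = pred - target
    n = diff.size
    if kind == "mse":
        return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / n) * diff
    return float(np.mean(np.abs(diff.astype(np.float64)))), np.sign(diff) / n


def _augment_batch(x, y, rng):
    k = int(rng.integers(4))
    if k:
        x = np.rot90(x, k=k, axes=(1, 2))
        y = np.rot90(y, k=k, axes=(1, 2))
    if rng.integers(2):
        x, y = x[:, :, ::-1], y[:, :, ::-1]
    if rng.integers(2):
        x, y = x[:, ::-1], y[:, ::-1]
    return np.ascontiguousarray(x), np.ascontiguousarray(y)


def _stack_patches(patches: PatchSet):
    xs = np.stack([p.crop for p in patches]).astype(F32)[..., None]
    if any(p.label is None for p in patches):
        raise ValueError("all patches must carry labels for training")
    ys = np.stack([p.label for p in patches]).astype(F32)[..., None]
    return xs, ys


def _eval_loss(model: UNet, x: np.ndarray, y: np.ndarray, kind: str,
               batch: int) -> float:
    tot, cnt = 0.0, 0
    for i in range(0, x.shape[0], batch):
        pred = model.forward(x[i:i + batch], train=False)
        l, _ = _loss_and_grad(pred, y[i:i + batch], kind)
        tot += l * x[i:i + batch].shape[0]
        cnt += x[i:i + batch].shape[0]
    return tot / max(cnt, 1)


def train(model: UNet, train_patches: PatchSet, val_patches: PatchSet | None,
          tcfg: TrainConfig | None = None) -> TrainState:
    """Minimize the regression loss between predicted and label distance maps.

    Deterministic given ``tcfg.seed`` (single-threaded numpy backend); returns
    per-epoch train/validation loss history of length ``epochs``.
    """
    tcfg = tcfg or TrainConfig()
    tcfg.validate()
    if len(train_patches) == 0:
        raise ValueError("empty training patch set")
    x_tr, y_tr = _stack_patches(train_patches)
    x_va = y_va = None
    if val_patches is not None and len(val_patches) > 0:
        x_va, y_va = _stack_patches(val_patches)

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.params(), lr=tcfg.lr)
    state = TrainState(model=model, config=tcfg)
    n = x_tr.shape[0]
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_cnt = 0.0, 0
        for i in range(0, n, tcfg.batch_size):
            idx = order[i:i + tcfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            if tcfg.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            pred = model.forward(xb, train=True, rng=rng)
            loss, dy = _loss_and_grad(pred, yb, tcfg.loss)
            model.backward(dy.astype(F32))
            opt.step()
            ep_loss += loss * xb.shape[0]
            ep_cnt += xb.shape[0]
        state.train_loss.append(ep_loss / ep_cnt)
        if x_va is not None:
            state.val_loss.append(_eval_loss(model, x_va, y_va, tcfg.loss,
                                             tcfg.batch_size))
    return state


def predict(model: UNet, image: np.ndarray, mask: ValidityMask | None = None,
            tile_size: int | None = None, overlap: int = 32) -> ScalarMap:
    """Predicted distance transform for a full image.

    Applies the 2-iteration inference erosion preset to the validity mask,
    tiles the image, runs forward passes, stitches tile outputs by averaging,
    and clamps the result below at zero (distances are non-negative).
    """
    image = np.asarray(image, dtype=F32)
    if mask is None:
        mask = ValidityMask(np.ones(image.shape, dtype=bool))
    mask = erode_mask(mask, EROSION_ITERS_INFERENCE)
    size = tile_size or model.cfg.in_size
    tiles = tile_for_inference(image, size=size, overlap=overlap)
    preds = []
    batch = np.stack([t.crop for t in tiles]).astype(F32)[..., None]
    bs = 8
    outs = []
    for i in range(0, batch.shape[0], bs):
        outs.append(model.forward(batch[i:i + bs], train=False)[..., 0])
    out = np.concatenate(outs, axis=0)
    for t, o in zip(tiles, out):
        preds.append(Patch(crop=np.asarray(o, dtype=float), label=None, offset=t.offset))
    stitched = stitch(PatchSet(patches=preds, size=size, padded=tiles.padded),
                      image.shape)
    stitched.data[:] = np.maximum(stitched.data, 0.0)
    stitched.valid &= mask.mask
    return stitched
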