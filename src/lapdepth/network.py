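"""Dual shared-weight encoder-decoder disparity network and training loop.

One parameter set serves both views: the left branch consumes the left
image, the right branch consumes the horizontally flipped right image and
its outputs are flipped back, so a single network learns a single disparity
chirality. The decoder emits sigmoid disparity heads at its last four
scales, scaled by max_disparity_fraction times the width at that scale, and
exposes the matching decoder feature maps for the appearance-gated
smoothness loss. At test time the finest left and (warped) right maps are
fused by averaging where the principled mask is valid.

Two encoders are provided: ``tiny`` — four stride-2 convolution blocks
(~10^5 parameters), the backbone used throughout the test suite — and
``resnet50`` — a bottleneck-residual encoder with stage layout [3, 4, 6, 3]
and a five-stage decoder (a stride-2 convolution stands in for the stem
max-pool). Training uses Adam with an epoch-indexed learning-rate schedule.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, conv2d, elu, flip_h, sigmoid, upsample2x
from .confidence import ProxyLabel
from .losses import (LossWeights, downsample_image, downsample_proxy,
                     lr_consistency_loss, neighbourhood_smoothness_loss,
                     photometric_loss, proxy_label_loss, total_loss)
from .stereo_core import DisparityMap
from .synthetic_data import StereoPair

#: Downsampling factor of each output scale, coarse to fine.
SCALE_FACTORS = (8, 4, 2, 1)


@dataclass
class ModelConfig:
    backbone: str = "tiny"
    width: int = 64
    height: int = 64
    max_disparity_fraction: float = 0.3
    channels: int = 1

    def __post_init__(self) -> None:
        if self.backbone not in ("tiny", "resnet50"):
            raise ValueError("backbone must be 'tiny' or 'resnet50'")
        div = 16 if self.backbone == "tiny" else 32
        if self.width % div or self.height % div:
            raise ValueError(f"input size must be divisible by {div}")
        if not 0 < self.max_disparity_fraction <= 0.5:
            raise ValueError("max_disparity_fraction must be in (0, 0.5]")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")


@dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 50
    lr: float = 1e-4
    lr_schedule: tuple = ((30, 0.5), (40, 0.25))  # (epoch, factor on base lr)
    seed: int = 0
    weights: LossWeights = dc_field(default_factory=LossWeights)
    max_steps: int | None = None
    checkpoint_dir: str | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class MultiScaleDisparity:
    """Per-view disparity maps at the four output scales (coarse to fine)
    plus the decoder feature map of each scale."""

    disparities: list
    features: list


# ------------------------------------------------------------ layers

class _Conv:
    def __init__(self, rng, c_in, c_out, k=3, stride=1):
        fan_in = c_in * k * k
        self.w = ad.parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                         (c_out, c_in, k, k)).astype(np.float32))
        self.b = ad.parameter(np.zeros(c_out, dtype=np.float32))
        self.stride, self.pad = stride, k // 2

    def __call__(self, x, act=True):
        # edge padding keeps a constant image constant through every layer,
        # which makes the two flip-related branches agree exactly on
        # symmetric inputs
        out = conv2d(x, self.w, self.b, stride=self.stride, padding=self.pad,
                     pad_mode="edge")
        return elu(out) if act else out

    @property
    def params(self):
        return [self.w, self.b]


class _Bottleneck:
    """1x1 -> 3x3 -> 1x1 residual block with optional projection."""

    def __init__(self, rng, c_in, c_mid, c_out, stride=1):
        self.c1 = _Conv(rng, c_in, c_mid, k=1)
        self.c2 = _Conv(rng, c_mid, c_mid, k=3, stride=stride)
        self.c3 = _Conv(rng, c_mid, c_out, k=1)
        self.proj = (_Conv(rng, c_in, c_out, k=1, stride=stride)
                     if (c_in != c_out or stride != 1) else None)

    def __call__(self, x):
        out = self.c3(self.c2(self.c1(x)), act=False)
        shortcut = self.proj(x, act=False) if self.proj is not None else x
        return elu(out + shortcut)

    @property
    def params(self):
        ps = self.c1.params + self.c2.params + self.c3.params
        return ps + (self.proj.params if self.proj is not None else [])


class DisparityNet:
    """Shared-weight encoder-decoder with four sigmoid disparity heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.channels
        if config.backbone == "tiny":
            self.encoder = [_Conv(rng, c, 16, stride=2),
                            _Conv(rng, 16, 32, stride=2),
                            _Conv(rng, 32, 64, stride=2),
                            _Conv(rng, 64, 64, stride=2)]
            skips = [64, 32, 16, 0]          # encoder channels fed per stage
            dec_ch = [32, 32, 16, 16]
            self.dec_in = [64 + skips[0], dec_ch[0] + skips[1],
                           dec_ch[1] + skips[2], dec_ch[2]]
        else:  # resnet50-style
            self.stem = [_Conv(rng, c, 64, k=7, stride=2),
                         _Conv(rng, 64, 64, k=3, stride=2)]
            self.stages = []
            spec = [(64, 256, 3, 1), (128, 512, 4, 2),
                    (256, 1024, 6, 2), (512, 2048, 3, 2)]
            c_in = 64
            for c_mid, c_out, blocks, stride in spec:
                stage = [_Bottleneck(rng, c_in, c_mid, c_out, stride)]
                stage += [_Bottleneck(rng, c_out, c_mid, c_out)
                          for _ in range(blocks - 1)]
                self.stages.append(stage)
                c_in = c_out
            skips = [1024, 512, 256, 64, 0]  # layer3, layer2, layer1, stem1
            dec_ch = [256, 128, 64, 32, 16]
            self.dec_in = [2048 + skips[0], dec_ch[0] + skips[1],
                           dec_ch[1] + skips[2], dec_ch[2] + skips[3],
                           dec_ch[3]]
        self.decoder = [_Conv(rng, ci, co)
                        for ci, co in zip(self.dec_in, dec_ch)]
        n_heads = 4
        self.heads = [_Conv(rng, dec_ch[len(dec_ch) - n_heads + i], 1)
                      for i in range(n_heads)]
        # near-zero head logits: every scale starts at mid-range disparity,
        # away from sigmoid saturation and with ~zero consistency loss
        for head in self.heads:
            head.w.data *= 0.1

    # ------------------------------------------------------------ params
    @property
    def params(self):
        ps = []
        if self.config.backbone == "tiny":
            for layer in self.encoder:
                ps += layer.params
        else:
            for layer in self.stem:
                ps += layer.params
            for stage in self.stages:
                for block in stage:
                    ps += block.params
        for layer in self.decoder + self.heads:
            ps += layer.params
        return ps

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    # ----------------------------------------------------------- forward
    def _encode(self, x):
        """Returns (bottleneck, skip list aligned with decoder stages)."""
        if self.config.backbone == "tiny":
            e1 = self.encoder[0](x)
            e2 = self.encoder[1](e1)
            e3 = self.encoder[2](e2)
            e4 = self.encoder[3](e3)
            return e4, [e3, e2, e1, None]
        s1 = self.stem[0](x)
        s2 = self.stem[1](s1)
        feats = [s2]
        for stage in self.stages:
            out = feats[-1]
            for block in stage:
                out = block(out)
            feats.append(out)
        _, l1, l2, l3, l4 = feats
        return l4, [l3, l2, l1, s1, None]

    def forward(self, x) -> MultiScaleDisparity:
        """x: NCHW Tensor/array at the configured size -> four scales."""
        x = ad.as_tensor(x)
        if x.data.ndim != 4:
            raise ValueError("input must be NCHW")
        n, c, h, w = x.data.shape
        if (c, h, w) != (self.config.channels, self.config.height,
                         self.config.width):
            raise ValueError(
                f"input {(c, h, w)} does not match the configured "
                f"{(self.config.channels, self.config.height, self.config.width)}")
        out, skips = self._encode(x)
        n_stages = len(self.decoder)
        disps, feats = [], []
        for i, (dec, skip) in enumerate(zip(self.decoder, skips)):
            up = upsample2x(out)
            out = dec(concat([up, skip]) if skip is not None else up)
            head_i = i - (n_stages - 4)
            if head_i >= 0:
                w_scale = self.config.width // SCALE_FACTORS[head_i]
                raw = self.heads[head_i](out, act=False)
                disp = sigmoid(raw) * (self.config.max_disparity_fraction
                                       * w_scale)
                disps.append(disp)
                feats.append(out)
        return MultiScaleDisparity(disps, feats)


def build_model(config: ModelConfig, seed: int = 0) -> DisparityNet:
    """Construct the shared-weight dual-branch disparity network."""
    return DisparityNet(config, seed=seed)


# ------------------------------------------------------------- forward

def _to_nchw(image: np.ndarray, channels: int) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:  # HWC
        arr = arr.transpose(2, 0, 1)[None]
    if arr.shape[1] != channels:
        if channels == 1:
            arr = arr.mean(axis=1, keepdims=True)
        else:
            arr = np.repeat(arr, channels, axis=1)
    return arr


def forward_dual(model: DisparityNet, pair,
                 ) -> tuple[MultiScaleDisparity, MultiScaleDisparity]:
    """Run both branches: left on I_l; right on the flipped I_r, outputs
    flipped back so d_r is a right-view map in its own coordinates."""
    c = model.config.channels
    left = ad.as_tensor(_to_nchw(pair.left, c))
    right = ad.as_tensor(_to_nchw(pair.right, c))
    out_l = model.forward(left)
    out_r_flipped = model.forward(flip_h(right))
    out_r = MultiScaleDisparity(
        [flip_h(d) for d in out_r_flipped.disparities],
        [flip_h(f) for f in out_r_flipped.features])
    return out_l, out_r


def _feature_plane(feat: Tensor) -> Tensor:
    """Channel-mean decoder activation, min-max normalised per image."""
    n, c, h, w = feat.data.shape
    avg_w = Tensor(np.full((1, c, 1, 1), 1.0 / c, dtype=feat.data.dtype))
    mean = conv2d(feat, avg_w)
    lo = mean.data.min(axis=(1, 2, 3), keepdims=True)
    hi = mean.data.max(axis=(1, 2, 3), keepdims=True)
    return (mean - lo) / np.maximum(hi - lo, 1e-6)


def compute_losses(model: DisparityNet, batch_pairs: StereoPair,
                   batch_proxy: np.ndarray, weights: LossWeights,
                   ) -> tuple[Tensor, dict]:
    """Total multi-scale loss for one batch.

    ``batch_pairs`` holds NCHW left/right stacks; ``batch_proxy`` is the
    full-resolution proxy stack (N, 1, H, W) with 0 outside the support.
    """
    out_l, out_r = forward_dual(model, batch_pairs)
    left = _to_nchw(batch_pairs.left, model.config.channels) \
        if np.asarray(batch_pairs.left).ndim != 4 else batch_pairs.left
    right = _to_nchw(batch_pairs.right, model.config.channels) \
        if np.asarray(batch_pairs.right).ndim != 4 else batch_pairs.right
    terms, logged = [], {}
    for s, factor in enumerate(SCALE_FACTORS):
        il = downsample_image(np.asarray(left, dtype=np.float32), factor)
        ir = downsample_image(np.asarray(right, dtype=np.float32), factor)
        d_l, d_r = out_l.disparities[s], out_r.disparities[s]
        rec_l, mask_l = ad.warp1d(ir, d_l, -1)
        rec_r, mask_r = ad.warp1d(il, d_r, +1)
        l_r = (photometric_loss(il, rec_l, mask_l, weights.alpha_ssim)
               + photometric_loss(ir, rec_r, mask_r, weights.alpha_ssim))
        l_rc = lr_consistency_loss(d_l, d_r)
        proxy_s = ProxyLabel(np.stack([
            downsample_proxy(ProxyLabel(p[0]), factor).d_tilde
            for p in batch_proxy])[:, None].astype(np.float32))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty proxy support is legal
            l_p = proxy_label_loss(d_l, d_r, proxy_s)
        f_l = _feature_plane(out_l.features[s])
        f_r = _feature_plane(out_r.features[s])
        l_s = (neighbourhood_smoothness_loss(d_l, f_l, weights.lambda_s,
                                             weights.t)
               + neighbourhood_smoothness_loss(d_r, f_r, weights.lambda_s,
                                               weights.t))
        terms.append({"r": l_r, "rc": l_rc, "p": l_p, "s": l_s})
        logged[f"L_r_s{s + 1}"] = float(l_r)
        logged[f"L_rc_s{s + 1}"] = float(l_rc)
        logged[f"L_p_s{s + 1}"] = float(l_p)
        logged[f"L_s_s{s + 1}"] = float(l_s)
    loss = total_loss(terms, weights)
    logged["L_r"] = sum(float(t["r"]) for t in terms)
    logged["L_rc"] = sum(float(t["rc"]) for t in terms)
    logged["L_p"] = sum(float(t["p"]) for t in terms)
    logged["L_s"] = sum(float(t["s"]) for t in terms)
    logged["total"] = float(loss)
    return loss, logged


# ------------------------------------------------------------- training

class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.lr = params, lr
        self.b1, self.b2, self.eps, self.t = beta1, beta2, eps, 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.grad = None


def _lr_at(base: float, schedule, epoch: int) -> float:
    lr = base
    for at_epoch, factor in sorted(schedule):
        if epoch >= at_epoch:
            lr = base * factor
    return lr


def train(model: DisparityNet, dataset, config: TrainConfig,
          ) -> tuple[DisparityNet, list[dict]]:
    """Minimise the total loss over (StereoPair, ProxyLabel) samples.

    Returns the trained model (updated in place) and a per-step history of
    every loss term. Divergence to NaN aborts with a diagnostic; a
    checkpoint is written per epoch when ``config.checkpoint_dir`` is set.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    c = model.config.channels
    lefts = np.concatenate([_to_nchw(p.left, c) for p, _ in dataset])
    rights = np.concatenate([_to_nchw(p.right, c) for p, _ in dataset])
    proxies = np.stack([np.asarray(px.d_tilde, dtype=np.float32)[None]
                        for _, px in dataset])
    n = len(dataset)
    opt = _Adam(model.params, config.lr)
    history: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        opt.lr = _lr_at(config.lr, config.lr_schedule, epoch)
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = StereoPair(left=lefts[idx], right=rights[idx])
            loss, logged = compute_losses(model, batch, proxies[idx],
                                          config.weights)
            if not np.isfinite(float(loss)):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={float(loss)}")
            loss.backward()
            opt.step()
            logged.update(step=step, epoch=epoch, lr=opt.lr)
            history.append(logged)
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                break
        if config.checkpoint_dir is not None:
            save_checkpoint(Path(config.checkpoint_dir) /
                            f"epoch_{epoch:04d}.npz", model)
        if config.max_steps is not None and step >= config.max_steps:
            break
    return model, history


def write_history_csv(path, history: list[dict]) -> None:
    cols = ["step", "epoch", "lr", "L_r", "L_rc", "L_p", "L_s", "total"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(history)


# ------------------------------------------------------------ predict

def predict(model: DisparityNet, pair) -> DisparityMap:
    """Fused left-view disparity: mean of d_l4 and d_r4 warped into the
    left view where the principled mask allows, d_l4 elsewhere."""
    out_l, out_r = forward_dual(model, pair)
    d_l4 = out_l.disparities[-1].data
    d_r4 = out_r.disparities[-1].data
    warped, mask = ad.warp1d(Tensor(d_r4), Tensor(d_l4), -1)
    fused = np.where(mask > 0, 0.5 * (d_l4 + warped.data), d_l4)
    return DisparityMap(fused[0, 0].astype(np.float64), view="left")


# --------------------------------------------------------- checkpoints

def save_checkpoint(path, model: DisparityNet) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    cfg = json.dumps(vars(model.config))
    np.savez(path, config=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> DisparityNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["config"]).decode())
        model = DisparityNet(ModelConfig(**cfg))
        for i, p in enumerate(model.params):
            p.data = data[f"param_{i}"].copy()
    return model
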