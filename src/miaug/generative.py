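"""Conditional generative augmenters: class-conditioned VAE and GAN.

Both models operate on flattened epochs with a one-hot class label appended
(at the encoder/discriminator input and at the latent/generator input) and
share the same optimizer-level hyperparameters: Adam with learning rate
0.0002, batch size 32, 50 training epochs, latent dimension 100.  Epochs are
standardized by the training set's global mean/std before training and
samples are mapped back to µV, which keeps optimization scale-free.

The networks are deliberately compact MLPs (one hidden ELU layer on each
side).  Topology is an open design choice here — only the optimizer-level
hyperparameters are fixed — and a small dense net trains stably at both
full and reduced epoch sizes; ``hidden_units`` is configurable.

Leakage rule: generators must be trained on the *training* partition only;
the evaluation layer enforces this by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .containers import SYNTHETIC_SUBJECT, EpochSet

__all__ = ["GenerativeConfig", "TrainedGenerator", "train_generator", "sample",
           "save_generator", "load_generator"]

CVAE = "CVAE"
CGAN = "CGAN"


@dataclass
class GenerativeConfig:
    kind: str = CVAE  # "CVAE" or "CGAN"
    latent_dim: int = 100
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 0.0002
    hidden_units: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in (CVAE, CGAN):
            raise ValueError(f"kind must be CVAE or CGAN, got {self.kind!r}")
        if min(self.latent_dim, self.epochs, self.batch_size, self.hidden_units) < 1:
            raise ValueError("all counts must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedGenerator:
    """Fitted generator state; sampling is allowed only for trained labels."""

    kind: str
    config: GenerativeConfig
    classes: list[str]
    data_shape: tuple[int, int]  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    loss_trace: dict[str, list[float]]
    nets: dict[str, nn.Sequential] = field(repr=False, default_factory=dict)
    norm: tuple[float, float] = (0.0, 1.0)  # (mean, std) in µV


def _onehot(indices: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((indices.size, n), dtype=nn.DTYPE)
    out[np.arange(indices.size), indices] = 1.0
    return out


def _mlp(sizes: list[int], rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for i in range(len(sizes) - 1):
        layers.append(nn.Dense(sizes[i], sizes[i + 1], rng))
        if i < len(sizes) - 2:
            layers.append(nn.ELU())
    return nn.Sequential(layers)


def train_generator(train_epochs: EpochSet, config: GenerativeConfig) -> TrainedGenerator:
    """Fit a conditional VAE or GAN on the training partition.

    Deterministic given ``config.seed``; per-epoch losses are recorded
    (reconstruction + KL for the VAE; generator and discriminator losses
    separately for the GAN).
    """
    classes = sorted(set(map(str, train_epochs.labels)))
    if not classes:
        raise ValueError("training set is empty")
    counts = {c: int(np.sum(train_epochs.labels == c)) for c in classes}
    empty = [c for c, k in counts.items() if k == 0]
    if empty:
        raise ValueError(f"no training epochs for class(es) {empty}")

    c, t = train_epochs.n_channels, train_epochs.n_samples
    dim = c * t
    mean = float(train_epochs.data.mean())
    std = float(train_epochs.data.std()) or 1.0
    x = ((train_epochs.data.reshape(-1, dim) - mean) / std).astype(nn.DTYPE)
    y = np.array([classes.index(l) for l in train_epochs.labels], dtype=int)
    onehot = _onehot(y, len(classes))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA1]))
    gen = TrainedGenerator(
        kind=config.kind, config=config, classes=classes, data_shape=(c, t),
        fs=train_epochs.fs, channel_names=list(train_epochs.channel_names),
        loss_trace={}, norm=(mean, std),
    )
    if config.kind == CVAE:
        _train_cvae(gen, x, onehot, config, rng)
    else:
        _train_cgan(gen, x, onehot, config, rng)
    return gen


# ---------------------------------------------------------------------------
# conditional VAE


def _train_cvae(gen: TrainedGenerator, x, onehot, cfg: GenerativeConfig, rng) -> None:
    dim, ncls, h, lat = x.shape[1], onehot.shape[1], cfg.hidden_units, cfg.latent_dim
    enc = _mlp([dim + ncls, h], rng)
    enc_elu = nn.ELU()
    head_mu = nn.Dense(h, lat, rng)
    head_lv = nn.Dense(h, lat, rng)
    dec = _mlp([lat + ncls, h, dim], rng)
    params = enc.all_params + head_mu.params + head_lv.params + dec.all_params
    grads = enc.all_grads + head_mu.grads + head_lv.grads + dec.all_grads
    opt = nn.Adam(params, grads, lr=cfg.learning_rate)

    n = x.shape[0]
    trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, cb = x[idx], onehot[idx]
            b = xb.shape[0]
            hpre = enc.forward(np.concatenate([xb, cb], axis=1), True, rng)
            hact = enc_elu.forward(hpre, True, rng)
            mu = head_mu.forward(hact, True, rng)
            lv = np.clip(head_lv.forward(hact, True, rng), -10.0, 10.0)
            eps = rng.standard_normal(mu.shape).astype(nn.DTYPE)
            z = mu + np.exp(0.5 * lv) * eps
            xhat = dec.forward(np.concatenate([z, cb], axis=1), True, rng)

            recon = float(np.sum((xhat - xb) ** 2) / b)
            kl = float(-0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv)) / b)
            total += (recon + kl) * b

            dxhat = (2.0 * (xhat - xb) / b).astype(nn.DTYPE)
            dzc = dec.backward(dxhat)
            dz = dzc[:, :lat]
            dmu = dz + mu / b
            dlv = dz * (0.5 * np.exp(0.5 * lv) * eps) + (0.5 * (np.exp(lv) - 1.0) / b)
            dh = head_mu.backward(dmu.astype(nn.DTYPE)) + head_lv.backward(dlv.astype(nn.DTYPE))
            enc.backward(enc_elu.backward(dh))
            opt.step()
        trace.append(total / n)
    gen.loss_trace = {"elbo": trace}
    gen.nets = {"decoder": dec}


# ---------------------------------------------------------------------------
# conditional GAN


def _train_cgan(gen: TrainedGenerator, x, onehot, cfg: GenerativeConfig, rng) -> None:
    dim, ncls, h, lat = x.shape[1], onehot.shape[1], cfg.hidden_units, cfg.latent_dim
    g_net = _mlp([lat + ncls, h, dim], rng)
    d_net = _mlp([dim + ncls, h, 1], rng)
    opt_g = nn.Adam(g_net.all_params, g_net.all_grads, lr=cfg.learning_rate, beta1=0.5)
    opt_d = nn.Adam(d_net.all_params, d_net.all_grads, lr=cfg.learning_rate, beta1=0.5)

    n = x.shape[0]
    g_trace: list[float] = []
    d_trace: list[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        g_total = d_total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, cb = x[idx], onehot[idx]
            b = xb.shape[0]
            z = rng.standard_normal((b, lat)).astype(nn.DTYPE)
            fake = g_net.forward(np.concatenate([z, cb], axis=1), True, rng)

            # --- discriminator step (real -> 1, fake -> 0)
            d_real = d_net.forward(np.concatenate([xb, cb], axis=1), True, rng)
            loss_r, dr = nn.bce_with_logits(d_real, 1.0)
            d_net.backward(dr)
            grads_real = [g.copy() for g in d_net.all_grads]
            d_fake = d_net.forward(np.concatenate([fake, cb], axis=1), True, rng)
            loss_f, df = nn.bce_with_logits(d_fake, 0.0)
            d_net.backward(df)
            for gacc, gr in zip(d_net.all_grads, grads_real):
                gacc += gr
            opt_d.step()
            d_total += (loss_r + loss_f) * b

            # --- generator step (fool the discriminator: fake -> 1)
            z = rng.standard_normal((b, lat)).astype(nn.DTYPE)
            fake = g_net.forward(np.concatenate([z, cb], axis=1), True, rng)
            d_out = d_net.forward(np.concatenate([fake, cb], axis=1), True, rng)
            loss_g, dg = nn.bce_with_logits(d_out, 1.0)
            dfake = d_net.backward(dg)[:, :dim]
            g_net.backward(dfake)
            opt_g.step()
            g_total += loss_g * b
        g_trace.append(g_total / n)
        d_trace.append(d_total / n)
    gen.loss_trace = {"generator": g_trace, "discriminator": d_trace}
    gen.nets = {"generator": g_net}


# ---------------------------------------------------------------------------
# sampling and persistence


def sample(generator: TrainedGenerator, label: str, n: int, seed: int = 0) -> EpochSet:
    """Draw ``n`` synthetic epochs of class ``label`` from a trained model."""
    if label not in generator.classes:
        raise ValueError(f"label {label!r} was not seen in training (classes: {generator.classes})")
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = generator.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB2]))
    z = rng.standard_normal((n, cfg.latent_dim)).astype(nn.DTYPE)
    cb = _onehot(np.full(n, generator.classes.index(label)), len(generator.classes))
    net = generator.nets["decoder" if generator.kind == CVAE else "generator"]
    flat = net.forward(np.concatenate([z, cb], axis=1), False, None)
    mean, std = generator.norm
    data = flat.astype(float).reshape(n, *generator.data_shape) * std + mean
    if not np.isfinite(data).all():
        raise FloatingPointError("generator produced non-finite samples")
    return EpochSet(
        data=data,
        labels=np.array([label] * n, dtype=object),
        subjects=np.array([SYNTHETIC_SUBJECT] * n, dtype=object),
        fs=generator.fs,
        channel_names=list(generator.channel_names),
    )


def save_generator(generator: TrainedGenerator, path: str | Path) -> Path:
    """Persist a trained generator (config embedded) to a single ``.npz`` file."""
    path = Path(path).with_suffix(".npz")
    arrays: dict[str, np.ndarray] = {}
    net_names = []
    for net_name, net in generator.nets.items():
        net_names.append(net_name)
        for i, p in enumerate(net.all_params):
            arrays[f"{net_name}__{i}"] = p
    meta = {
        "kind": generator.kind,
        "config": asdict(generator.config),
        "classes": generator.classes,
        "data_shape": list(generator.data_shape),
        "fs": generator.fs,
        "channel_names": generator.channel_names,
        "loss_trace": generator.loss_trace,
        "norm": list(generator.norm),
        "nets": net_names,
        "layer_sizes": {
            name: [list(p.shape) for p in net.all_params]
            for name, net in generator.nets.items()
        },
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def load_generator(path: str | Path) -> TrainedGenerator:
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        cfg = GenerativeConfig(**meta["config"])
        gen = TrainedGenerator(
            kind=meta["kind"], config=cfg, classes=meta["classes"],
            data_shape=tuple(meta["data_shape"]), fs=meta["fs"],
            channel_names=meta["channel_names"], loss_trace=meta["loss_trace"],
            norm=tuple(meta["norm"]),
        )
        rng = np.random.default_rng(0)
        dim = gen.data_shape[0] * gen.data_shape[1]
        ncls = len(gen.classes)
        for net_name in meta["nets"]:
            net = _mlp([cfg.latent_dim + ncls, cfg.hidden_units, dim], rng)
            for i, p in enumerate(net.all_params):
                p[...] = npz[f"{net_name}__{i}"]
            gen.nets[net_name] = net
    return gen
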