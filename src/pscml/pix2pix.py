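"""Scaled-down bright-field-to-fluorescence translation.

A conditional-adversarial image translator: the generator G (an
encoder-decoder with skip connections, nearest-neighbor upsampling followed
by convolution instead of transposed convolution, and instance
normalization) maps a bright-field patch to a fluorescence prediction in
[0, 1]; the patch discriminator D scores (bright-field, candidate) pairs
with a per-pixel receptive field of exactly 16x16 (verified by gradient
probing at build time). The objective is::

    G* = argmin_G max_D  lambda * L_L1(G) + L_cGAN(G, D)

with the adversarial term disabled after a configured epoch to favor
reconstruction fidelity. The desk preset (quarter-width channels, 64 px
patches, tens of epochs) is the tested CPU path; the full-scale preset
(lambda=100, 2000 epochs, 256 px patches, batch 16, lr 2e-4 with linear
decay over the second half, Adam beta1=0.5) is retained as configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from skimage.transform import resize

from pscml import nn
from pscml.well_io import WellImage

logger = logging.getLogger(__name__)


@dataclass
class TranslatorConfig:
    base_channels: int = 8
    lambda_l1: float = 100.0
    epochs: int = 30
    patches_per_epoch: int = 48
    patch_size: int = 64
    batch_size: int = 8
    lr: float = 4e-4
    beta1: float = 0.5
    beta2: float = 0.999
    lr_decay_after: int | None = None  # linear decay to 0 from this epoch on
    gan_disable_after: int | None = 15  # epoch index after which GAN loss is off
    dropout: float = 0.0  # the generator's randomness source; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_l1 <= 0:
            raise ValueError("lambda_l1 must be positive")

    @classmethod
    def paper(cls) -> "TranslatorConfig":
        """Full-scale settings (GPU scale; not exercised by the test suite)."""
        return cls(
            base_channels=64,
            lambda_l1=100.0,
            epochs=2000,
            patches_per_epoch=1260,
            patch_size=256,
            batch_size=16,
            lr=2e-4,
            lr_decay_after=1000,
            gan_disable_after=1000,
            dropout=0.5,
        )


class Generator:
    """Encoder-decoder with skip connections (two 2x downsamplings)."""

    def __init__(self, config: TranslatorConfig):
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        self.enc1 = nn.Sequential(nn.Conv2d(1, c, 3, rng=rng), nn.InstanceNorm(c), nn.ReLU())
        self.pool1 = nn.MaxPool2()
        self.enc2 = nn.Sequential(nn.Conv2d(c, 2 * c, 3, rng=rng), nn.InstanceNorm(2 * c), nn.ReLU())
        self.pool2 = nn.MaxPool2()
        self.dropout = nn.Dropout(config.dropout, seed=config.seed + 1)
        self.bottleneck = nn.Sequential(
            nn.Conv2d(2 * c, 4 * c, 3, rng=rng), nn.InstanceNorm(4 * c), nn.ReLU()
        )
        self.up1 = nn.NearestUpsample()
        self.dec1 = nn.Sequential(
            nn.Conv2d(4 * c + 2 * c, 2 * c, 3, rng=rng), nn.InstanceNorm(2 * c), nn.ReLU()
        )
        self.up2 = nn.NearestUpsample()
        self.dec2 = nn.Sequential(nn.Conv2d(2 * c + c, c, 3, rng=rng), nn.InstanceNorm(c), nn.ReLU())
        self.out = nn.Sequential(nn.Conv2d(c, 1, 3, rng=rng), nn.Sigmoid())
        self._blocks = [self.enc1, self.enc2, self.bottleneck, self.dec1, self.dec2, self.out]
        self._c = c

    @property
    def params(self):
        return [p for b in self._blocks for p in b.params]

    @property
    def grads(self):
        return [g for b in self._blocks for g in b.grads]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self.dropout.training = training
        e1 = self.enc1(x)
        e2 = self.enc2(self.pool1(e1))
        b = self.bottleneck(self.dropout(self.pool2(e2)))
        d1 = self.dec1(np.concatenate([self.up1(b), e2], axis=1))
        d2 = self.dec2(np.concatenate([self.up2(d1), e1], axis=1))
        return self.out(d2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c = self._c
        dd2 = self.out.backward(dout)
        dcat2 = self.dec2.backward(dd2)
        dup2, de1_skip = dcat2[:, : 2 * c], dcat2[:, 2 * c :]
        dd1 = self.up2.backward(dup2)
        dcat1 = self.dec1.backward(dd1)
        dup1, de2_skip = dcat1[:, : 4 * c], dcat1[:, 4 * c :]
        db = self.up1.backward(dup1)
        dp2 = self.dropout.backward(self.bottleneck.backward(db))
        de2 = self.pool2.backward(dp2) + de2_skip
        de1 = self.pool1.backward(self.enc2.backward(de2)) + de1_skip
        return self.enc1.backward(de1)


def build_discriminator(config: TranslatorConfig) -> nn.Sequential:
    """Patch discriminator whose score-map pixels see 16x16 input pixels."""
    rng = np.random.default_rng(config.seed + 7)
    c = config.base_channels
    return nn.Sequential(
        nn.Conv2d(2, c, 4, stride=2, pad=1, rng=rng), nn.LeakyReLU(),
        nn.Conv2d(c, 2 * c, 3, rng=rng), nn.LeakyReLU(),
        nn.Conv2d(2 * c, 2 * c, 3, rng=rng), nn.LeakyReLU(),
        nn.Conv2d(2 * c, 2 * c, 3, rng=rng), nn.LeakyReLU(),
        nn.Conv2d(2 * c, 1, 1, pad=0, rng=rng), nn.Sigmoid(),
    )


def measure_receptive_field(D: nn.Sequential, input_size: int = 64) -> int:
    """Empirical receptive field of the score map by gradient probing."""
    x = np.full((1, 2, input_size, input_size), 0.1)
    out = D(x)
    center = out.shape[2] // 2
    dout = np.zeros_like(out)
    dout[0, 0, center, center] = 1.0
    dx = D.backward(dout)
    support = np.abs(dx[0]).sum(axis=0) > 1e-12
    rows = np.nonzero(support.any(axis=1))[0]
    cols = np.nonzero(support.any(axis=0))[0]
    return int(max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1))


def build_translator(config: TranslatorConfig) -> tuple[Generator, nn.Sequential]:
    """Generator and discriminator; raises if the probed receptive field
    of the discriminator is not 16."""
    G = Generator(config)
    D = build_discriminator(config)
    rf = measure_receptive_field(D)
    if rf != 16:
        raise ValueError(f"discriminator receptive field is {rf}, expected 16")
    return G, D


# ---------------------------------------------------------------------------
# training


@dataclass
class LossCurves:
    l1: list[float] = field(default_factory=list)  # raw lambda * L1 per epoch
    l1_display: list[float] = field(default_factory=list)  # scaled by 1/5 for plots
    gan: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)


def _sample_patches(
    pairs: list[tuple[np.ndarray, np.ndarray]], n: int, size: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for _ in range(n):
        bx, fy = pairs[rng.integers(len(pairs))]
        r = rng.integers(0, bx.shape[0] - size + 1)
        c = rng.integers(0, bx.shape[1] - size + 1)
        xs.append(bx[r : r + size, c : c + size])
        ys.append(fy[r : r + size, c : c + size])
    return np.stack(xs)[:, None], np.stack(ys)[:, None]


def train_translator(
    pairs: list[tuple[WellImage | np.ndarray, WellImage | np.ndarray]],
    config: TranslatorConfig | None = None,
) -> tuple[Generator, nn.Sequential, LossCurves]:
    """Adversarially train the translator on paired, aligned images.

    Each epoch samples ``patches_per_epoch`` random patches from the pairs.
    The generator objective per step is exactly
    ``lambda * mean|y - G(x)| + mean log(1 - D(x, G(x)))``; after
    ``gan_disable_after`` epochs the adversarial term is zeroed and the
    discriminator is frozen. Returns the models and per-epoch loss curves
    (the L1 curve is additionally stored scaled by 1/5, the display
    convention of the training-curve plots).
    """
    config = config or TranslatorConfig()
    arrs = []
    for bx, fy in pairs:
        bxa = bx.pixels if isinstance(bx, WellImage) else np.asarray(bx, dtype=float)
        fya = fy.pixels if isinstance(fy, WellImage) else np.asarray(fy, dtype=float)
        if bxa.shape != fya.shape:
            raise ValueError("paired images must have identical shapes")
        arrs.append((bxa, fya))
    G, D = build_translator(config)
    rng = np.random.default_rng(config.seed + 13)
    optG = nn.Adam(G.params, G.grads, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    optD = nn.Adam(D.params, D.grads, lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    curves = LossCurves()
    eps = 1e-8
    for epoch in range(config.epochs):
        if config.lr_decay_after is not None and epoch >= config.lr_decay_after:
            frac = 1.0 - (epoch - config.lr_decay_after) / max(
                1, config.epochs - config.lr_decay_after
            )
            optG.lr = optD.lr = config.lr * max(0.0, frac)
        gan_on = config.gan_disable_after is None or epoch < config.gan_disable_after
        ep_l1 = ep_gan = 0.0
        n_steps = 0
        for start in range(0, config.patches_per_epoch, config.batch_size):
            nb = min(config.batch_size, config.patches_per_epoch - start)
            x, y = _sample_patches(arrs, nb, config.patch_size, rng)

            fake = G.forward(x, training=True)

            if gan_on:
                # discriminator ascent on log D(x,y) + log(1 - D(x,fake))
                real_in = np.concatenate([x, y], axis=1)
                fake_in = np.concatenate([x, fake], axis=1)
                d_real = D(real_in)
                d_loss_grad = -1.0 / (d_real + eps) / d_real.size
                D.backward(d_loss_grad)
                g_real = [g.copy() for g in D.grads]
                d_fake = D(fake_in)
                D.backward((1.0 / (1.0 - d_fake + eps)) / d_fake.size)
                for acc, g in zip(D.grads, g_real):
                    acc += g
                optD.step()

            # generator descent on lambda*L1 + log(1 - D(x, fake))
            diff = fake - y
            l1 = float(np.abs(diff).mean())
            dfake = config.lambda_l1 * np.sign(diff) / diff.size
            gan_term = 0.0
            if gan_on:
                fake_in = np.concatenate([x, fake], axis=1)
                d_fake = D(fake_in)
                gan_term = float(np.log(1.0 - d_fake + eps).mean())
                dd = (-1.0 / (1.0 - d_fake + eps)) / d_fake.size
                dfake_gan = D.backward(dd)[:, 1:2]
                dfake = dfake + dfake_gan
            G.backward(dfake)
            optG.step()

            ep_l1 += config.lambda_l1 * l1
            ep_gan += gan_term
            n_steps += 1
        curves.l1.append(ep_l1 / n_steps)
        curves.l1_display.append(ep_l1 / n_steps / 5.0)
        curves.gan.append(ep_gan / n_steps)
        curves.total.append((ep_l1 + ep_gan) / n_steps)
    return G, D, curves


# ---------------------------------------------------------------------------
# inference and evaluation


def predict_fluorescence(G: Generator, bright: WellImage | np.ndarray) -> WellImage:
    """Predicted fluorescence for a whole bright-field image.

    The image is reflect-padded to a multiple of the generator's
    downsampling factor (4), translated, and cropped back; output is a
    [0, 1] image of the input shape. Inference is deterministic (dropout
    inactive).
    """
    px = bright.pixels if isinstance(bright, WellImage) else np.asarray(bright, dtype=float)
    h, w = px.shape
    ph = (-h) % 4
    pw = (-w) % 4
    padded = np.pad(px, ((0, ph), (0, pw)), mode="reflect")
    pred = G.forward(padded[None, None], training=False)[0, 0][:h, :w]
    well_id = bright.well_id if isinstance(bright, WellImage) else ""
    return WellImage(np.clip(pred, 0, 1), well_id=well_id, channel="cTnT")


def evaluate_pixel_correlation(
    pred: WellImage | np.ndarray,
    true: WellImage | np.ndarray,
    eval_size: int = 512,
    bin_scale: float = 100.0,
    n_bins: int = 50,
) -> tuple[float, np.ndarray]:
    """Pixel-level Pearson r and joint intensity histogram.

    Both images are resized to ``eval_size`` squared; the histogram's counts
    are divided by ``bin_scale`` (frequency per 100 by default). A constant
    image makes r undefined (returned as NaN).
    """
    p = pred.pixels if isinstance(pred, WellImage) else np.asarray(pred, dtype=float)
    t = true.pixels if isinstance(true, WellImage) else np.asarray(true, dtype=float)
    p = resize(p, (eval_size, eval_size), order=1, preserve_range=True, anti_aliasing=True)
    t = resize(t, (eval_size, eval_size), order=1, preserve_range=True, anti_aliasing=True)
    hist, _, _ = np.histogram2d(t.ravel(), p.ravel(), bins=n_bins, range=[[0, 1], [0, 1]])
    hist = hist / bin_scale
    if p.std() == 0 or t.std() == 0:
        logger.warning("constant image: pixel correlation undefined")
        return float("nan"), hist
    r = float(pearsonr(p.ravel(), t.ravel())[0])
    return r, hist
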