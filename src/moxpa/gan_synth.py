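"""Minimal tabular GAN: dense generator/discriminator, adversarial loop.

The generator is a three-layer dense network (two ReLU hidden layers,
linear output, He-uniform kernel init) mapping latent standard-normal noise
to one table row; the discriminator mirrors it with a logistic-sigmoid
output scoring real (1) versus synthetic (0).  Both are trained with binary
cross-entropy and Adam; inside the combined model the discriminator's
weights are frozen.  Features are standardized to zero mean / unit variance
before training and de-standardized on sampling.

Tabular GANs are prone to mode collapse on small tables — with a discrete
label column this shows up as a single generated class.  ``sample_gan``
detects and warns about this failure mode rather than hiding it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, Network, binary_cross_entropy

__all__ = ["GanConfig", "TrainedGan", "ModeCollapseWarning",
           "generate_latent_points", "train_gan", "sample_gan"]


class ModeCollapseWarning(UserWarning):
    """Sampled table has lost diversity (e.g. a single label class)."""


@dataclass(frozen=True)
class GanConfig:
    """Architecture and training settings of the tabular GAN.

    Hidden widths are desk-scale defaults; the adversarial pathway itself
    (layer plan, activations, init, losses) is fixed.
    """

    latent_dim: int = 8
    generator_hidden: tuple[int, int] = (64, 32)
    discriminator_hidden: tuple[int, int] = (64, 32)
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epochs: int = 2000
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class TrainedGan:
    """A trained generator with the scaling needed to sample on data scale."""

    generator: Network
    discriminator: Network
    config: GanConfig
    columns: list[str]
    mean: np.ndarray
    scale: np.ndarray
    integer_columns: tuple[str, ...]
    loss_history: pd.DataFrame = field(repr=False, default=None)


def generate_latent_points(latent_dim: int, n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """``n`` standard-normal latent vectors of dimension ``latent_dim``, seeded."""
    if latent_dim < 1 or n < 1:
        raise ValueError("latent_dim and n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal((n, latent_dim))


def _build_networks(config: GanConfig, n_features: int) -> tuple[Network, Network]:
    g = Network.dense_stack(
        [config.latent_dim, *config.generator_hidden, n_features],
        ["relu", "relu", "linear"],
        seed=config.seed,
    )
    d = Network.dense_stack(
        [n_features, *config.discriminator_hidden, 1],
        ["relu", "relu", "sigmoid"],
        seed=config.seed + 1,
    )
    return g, d


def train_gan(table: pd.DataFrame, config: GanConfig = GanConfig()) -> TrainedGan:
    """Adversarial training on a numeric table; returns the best generator.

    Per epoch one discriminator update (a half-real/half-fake batch labelled
    1/0) alternates with one combined-model update (fresh noise labelled 1,
    discriminator frozen).  Losses are recorded per epoch; the generator
    snapshot with the lowest combined loss is restored at the end.  Training
    aborts with a diagnostic if a loss goes non-finite.
    """
    x = table.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    n, n_features = xs.shape
    rng = np.random.default_rng(config.seed)
    gen, disc = _build_networks(config, n_features)
    opt_d = Adam(lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    opt_g = Adam(lr=config.learning_rate, beta1=config.beta1, beta2=config.beta2)
    half = max(config.batch_size // 2, 1)
    d_losses, g_losses = [], []
    best_g_loss = np.inf
    best_weights = gen.get_weights()
    for epoch in range(config.epochs):
        # --- discriminator step: real labelled 1, synthetic labelled 0
        idx = rng.integers(0, n, size=half)
        real = xs[idx]
        fake = gen.forward(generate_latent_points(config.latent_dim, half, rng))
        batch = np.vstack([real, fake])
        labels = np.vstack([np.ones((half, 1)), np.zeros((half, 1))])
        pred = disc.forward(batch)
        d_loss = binary_cross_entropy(pred, labels)
        delta = (pred - labels) / len(batch)  # fused sigmoid + BCE gradient
        grads, _ = disc.backward(delta)
        opt_d.step(disc.parameters(), [g for pair in grads for g in pair])
        # --- combined step: generator updated through the frozen discriminator
        noise = generate_latent_points(config.latent_dim, config.batch_size, rng)
        fake = gen.forward(noise)
        pred = disc.forward(fake)
        g_loss = binary_cross_entropy(pred, np.ones((config.batch_size, 1)))
        delta = (pred - 1.0) / config.batch_size
        _, d_input_grad = disc.backward(delta)  # discriminator weights not updated
        g_grads, _ = gen.backward(d_input_grad)  # linear output: dout == delta
        opt_g.step(gen.parameters(), [g for pair in g_grads for g in pair])
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: d_loss={d_loss}, g_loss={g_loss}"
            )
        d_losses.append(d_loss)
        g_losses.append(g_loss)
        if g_loss < best_g_loss:
            best_g_loss = g_loss
            best_weights = gen.get_weights()
    gen.set_weights(best_weights)
    history = pd.DataFrame({"epoch": np.arange(config.epochs), "d_loss": d_losses, "g_loss": g_losses})
    return TrainedGan(
        generator=gen,
        discriminator=disc,
        config=config,
        columns=list(table.columns),
        mean=mean,
        scale=scale,
        integer_columns=tuple(c for c in ("Steps", "Active") if c in table.columns),
        loss_history=history,
    )


def sample_gan(model: TrainedGan, n: int, seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` rows on the original data scale (seeded, deterministic).

    Warns with :class:`ModeCollapseWarning` when a discrete label column
    comes out single-valued.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    noise = generate_latent_points(model.config.latent_dim, n, seed)
    xs = model.generator.forward(noise)
    x = xs * model.scale + model.mean
    out = pd.DataFrame(x, columns=model.columns)
    for col in model.integer_columns:
        out[col] = np.round(out[col]).astype(int)
    if "Active" in out.columns and out["Active"].nunique() == 1:
        warnings.warn(
            "generated 'Active' labels collapsed to a single class "
            "(tabular-GAN mode collapse)",
            ModeCollapseWarning,
            stacklevel=2,
        )
    return out
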