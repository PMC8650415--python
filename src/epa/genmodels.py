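"""PCM-GAN and PCM-AAE: adversarial generators of positive PCM rows.

Both models learn the distribution of *positive* training rows (601-dim:
600 features + 1 p-affinity label ≥ 6) and synthesize new ones.

PCM-GAN is a plain GAN on the data space: a generator maps Gaussian
noise straight to 601-dim rows and a discriminator separates real
positives from generated rows. Its training is notoriously unstable, so
bounded finite losses — not convergence — are all that is promised.

PCM-AAE routes the adversarial game through the latent space of an
auto-encoder. Each iteration performs three steps:

1. reconstruction — encoder/decoder minimize MSE on a positive batch;
2. discriminator — learns to tell encoder latents (real) from
   generator latents (fake), where the generator maps Gaussian noise to
   latent vectors;
3. generator — updated to fool the discriminator, pulling its output
   distribution toward the encoder's aggregated posterior.

Sampling goes noise → generator → latent → decoder → new 601-dim row.
The adversarial loss weight is annealed linearly from 0 to 1 over the
first half of training (cost annealing), and batch normalization and
dropout are applied in all auto-encoder layers, both of which stabilize
training. A trained model is judged partly by its *valid-label ratio*:
the fraction of generated labels inside [6, 11] (1 µM to 0.01 nM), which
should exceed 0.9 once training has converged.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import MLP, Adam, bce_with_logits, mse_loss
from .dataset import PCMDataset

DEFAULT_VALID_RANGE = (6.0, 11.0)


@dataclass
class AaeConfig:
    """Hyper-parameters shared by PCM-AAE and PCM-GAN training."""

    latent_dim: int = 16
    encoder_layers: list[int] = field(default_factory=lambda: [128, 64])
    decoder_layers: list[int] = field(default_factory=lambda: [64, 128])
    generator_layers: list[int] = field(default_factory=lambda: [64, 64])
    discriminator_layers: list[int] = field(default_factory=lambda: [64, 64])
    learning_rate: float = 0.01
    epochs: int = 50
    iterations: int | None = None  # overrides epochs when set
    batch_size: int = 64
    anneal_fraction: float = 0.5  # adversarial weight ramps 0→1 over this fraction
    valid_label_range: tuple[float, float] = DEFAULT_VALID_RANGE
    dropout: float = 0.1
    checkpoint_burn_in_epochs: int = 10
    max_checkpoints: int = 24
    grad_clip: float = 5.0
    seed: int = 0

    def validate(self, input_dim: int) -> None:
        if self.latent_dim >= input_dim:
            raise ValueError("latent_dim must be smaller than the input dimension")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        lo, hi = self.valid_label_range
        if lo >= hi:
            raise ValueError("valid_label_range must be increasing")


class GeneratorHandle:
    """A frozen snapshot able to sample new PCM rows deterministically.

    For the AAE the pipeline is noise → generator → latent → decoder;
    for the plain GAN the decoder is absent and the generator emits data
    rows directly.
    """

    def __init__(self, generator: MLP, decoder: MLP | None, noise_dim: int,
                 output_dim: int, tag: str = ""):
        self.generator = copy.deepcopy(generator)
        self.decoder = copy.deepcopy(decoder)
        self.noise_dim = noise_dim
        self.output_dim = output_dim
        self.tag = tag

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Draw ``n`` generated rows (features + label as last column)."""
        if n <= 0:
            raise ValueError("n must be positive")
        rng = np.random.default_rng(seed)
        z = rng.normal(size=(n, self.noise_dim))
        out = self.generator.forward(z, train=False)
        if self.decoder is not None:
            out = self.decoder.forward(out, train=False)
        return out


@dataclass
class AaeArtifacts:
    encoder: MLP
    decoder: MLP
    generator: MLP
    discriminator: MLP
    config: AaeConfig
    input_dim: int
    loss_trace: np.ndarray  # (iterations, 3): reconstruction, discriminator, generator
    checkpoints: list[GeneratorHandle]

    def final_generator(self) -> GeneratorHandle:
        return GeneratorHandle(self.generator, self.decoder,
                               self.config.latent_dim, self.input_dim, tag="final")


@dataclass
class GanArtifacts:
    generator: MLP
    discriminator: MLP
    config: AaeConfig
    input_dim: int
    loss_trace: np.ndarray  # (iterations, 2): discriminator, generator

    def final_generator(self) -> GeneratorHandle:
        return GeneratorHandle(self.generator, None,
                               self.config.latent_dim, self.input_dim, tag="final")


def _clip_grads(nets: list[MLP], max_norm: float) -> None:
    if max_norm <= 0:
        return
    total = 0.0
    for net in nets:
        for _, g in net.params():
            total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for net in nets:
            for _, g in net.params():
                g *= scale


def _iter_plan(n_rows: int, config: AaeConfig) -> tuple[int, int]:
    """Total iterations and batches per epoch for the configured run."""
    batches_per_epoch = max(1, int(np.ceil(n_rows / config.batch_size)))
    if config.iterations is not None:
        return int(config.iterations), batches_per_epoch
    return config.epochs * batches_per_epoch, batches_per_epoch


def train_pcm_aae(positives: PCMDataset, config: AaeConfig | None = None) -> AaeArtifacts:
    """Train PCM-AAE on positive rows; see the module docstring for the regime."""
    config = config or AaeConfig()
    rows = positives.rows()
    n, dim = rows.shape
    if n == 0:
        raise ValueError("positive training set is empty")
    if n < config.batch_size:
        raise ValueError("need at least one full batch of positives")
    config.validate(dim)

    rng = np.random.default_rng(config.seed)
    enc = MLP([dim, *config.encoder_layers, config.latent_dim], rng,
              batchnorm=True, dropout=config.dropout)
    dec = MLP([config.latent_dim, *config.decoder_layers, dim], rng,
              batchnorm=True, dropout=config.dropout)
    gen = MLP([config.latent_dim, *config.generator_layers, config.latent_dim], rng)
    disc = MLP([config.latent_dim, *config.discriminator_layers, 1], rng)

    opt_ae = Adam(enc.params() + dec.params(), lr=config.learning_rate)
    opt_disc = Adam(disc.params(), lr=config.learning_rate)
    opt_gen = Adam(gen.params(), lr=config.learning_rate)

    total_iters, batches_per_epoch = _iter_plan(n, config)
    burn_in = config.checkpoint_burn_in_epochs * batches_per_epoch
    anneal_len = max(1, int(config.anneal_fraction * total_iters))

    trace = np.zeros((total_iters, 3))
    checkpoints: list[GeneratorHandle] = []
    save_every = batches_per_epoch
    order = rng.permutation(n)
    pos_in_epoch = 0

    for it in range(total_iters):
        if pos_in_epoch >= batches_per_epoch:
            order = rng.permutation(n)
            pos_in_epoch = 0
        batch = rows[order[pos_in_epoch * config.batch_size:(pos_in_epoch + 1) * config.batch_size]]
        pos_in_epoch += 1
        w = min(1.0, (it + 1) / anneal_len)

        # (i) reconstruction step
        enc.zero_grad(); dec.zero_grad()
        z = enc.forward(batch, train=True)
        recon = dec.forward(z, train=True)
        recon_loss, dout = mse_loss(recon, batch)
        dz = dec.backward(dout)
        enc.backward(dz)
        _clip_grads([enc, dec], config.grad_clip)
        opt_ae.step()

        # (ii) discriminator step: encoder latents real, generator latents fake
        noise = rng.normal(size=(batch.shape[0], config.latent_dim))
        z_fake = gen.forward(noise, train=False)
        disc.zero_grad()
        logits_real = disc.forward(z, train=True)
        loss_real, dlr = bce_with_logits(logits_real, np.ones_like(logits_real))
        disc.backward(dlr)
        logits_fake = disc.forward(z_fake, train=True)
        loss_fake, dlf = bce_with_logits(logits_fake, np.zeros_like(logits_fake))
        disc.backward(dlf)
        _clip_grads([disc], config.grad_clip)
        opt_disc.step(lr_scale=w)
        disc_loss = 0.5 * (loss_real + loss_fake)

        # (iii) generator step: fool the discriminator (non-saturating)
        gen.zero_grad()
        noise = rng.normal(size=(batch.shape[0], config.latent_dim))
        z_fake = gen.forward(noise, train=True)
        logits = disc.forward(z_fake, train=True)
        gen_loss, dlg = bce_with_logits(logits, np.ones_like(logits))
        disc.zero_grad()  # discriminator is a fixed critic in this step
        dzf = disc.backward(dlg)
        disc.zero_grad()
        gen.backward(dzf)
        _clip_grads([gen], config.grad_clip)
        opt_gen.step(lr_scale=w)

        trace[it] = (recon_loss, disc_loss, gen_loss)
        if not np.all(np.isfinite(trace[it])):
            raise RuntimeError(f"training diverged at iteration {it}: losses {trace[it]}")

        if it + 1 > burn_in and (it + 1 - burn_in) % save_every == 0:
            checkpoints.append(GeneratorHandle(gen, dec, config.latent_dim, dim,
                                               tag=f"iter{it + 1}"))
            if len(checkpoints) > config.max_checkpoints:
                # thin to every other checkpoint so the kept set keeps
                # spanning the whole post-burn-in run
                checkpoints = checkpoints[1::2]
                save_every *= 2

    return AaeArtifacts(enc, dec, gen, disc, config, dim, trace, checkpoints)


def train_pcm_gan(positives: PCMDataset, config: AaeConfig | None = None) -> GanArtifacts:
    """Train PCM-GAN: generator maps noise directly to 601-dim rows.

    Finite, recorded losses are the contract; simultaneous convergence of
    generator and discriminator is not promised for this architecture.
    """
    config = config or AaeConfig()
    rows = positives.rows()
    n, dim = rows.shape
    if n == 0:
        raise ValueError("positive training set is empty")
    if n < config.batch_size:
        raise ValueError("need at least one full batch of positives")
    config.validate(dim)

    rng = np.random.default_rng(config.seed)
    gen = MLP([config.latent_dim, *config.generator_layers, dim], rng)
    disc = MLP([dim, *config.discriminator_layers, 1], rng)
    opt_gen = Adam(gen.params(), lr=config.learning_rate)
    opt_disc = Adam(disc.params(), lr=config.learning_rate)

    total_iters, batches_per_epoch = _iter_plan(n, config)
    trace = np.zeros((total_iters, 2))
    order = rng.permutation(n)
    pos_in_epoch = 0

    for it in range(total_iters):
        if pos_in_epoch >= batches_per_epoch:
            order = rng.permutation(n)
            pos_in_epoch = 0
        batch = rows[order[pos_in_epoch * config.batch_size:(pos_in_epoch + 1) * config.batch_size]]
        pos_in_epoch += 1

        noise = rng.normal(size=(batch.shape[0], config.latent_dim))
        fake = gen.forward(noise, train=False)
        disc.zero_grad()
        logits_real = disc.forward(batch, train=True)
        loss_real, dlr = bce_with_logits(logits_real, np.ones_like(logits_real))
        disc.backward(dlr)
        logits_fake = disc.forward(fake, train=True)
        loss_fake, dlf = bce_with_logits(logits_fake, np.zeros_like(logits_fake))
        disc.backward(dlf)
        _clip_grads([disc], config.grad_clip)
        opt_disc.step()

        gen.zero_grad()
        noise = rng.normal(size=(batch.shape[0], config.latent_dim))
        fake = gen.forward(noise, train=True)
        logits = disc.forward(fake, train=True)
        gen_loss, dlg = bce_with_logits(logits, np.ones_like(logits))
        disc.zero_grad()
        dfake = disc.backward(dlg)
        disc.zero_grad()
        gen.backward(dfake)
        _clip_grads([gen], config.grad_clip)
        opt_gen.step()

        trace[it] = (0.5 * (loss_real + loss_fake), gen_loss)
        if not np.all(np.isfinite(trace[it])):
            raise RuntimeError(f"training diverged at iteration {it}: losses {trace[it]}")

    return GanArtifacts(gen, disc, config, dim, trace)


def select_generators(artifacts: AaeArtifacts, m: int, skip_fraction: float = 1 / 3) -> list[GeneratorHandle]:
    """Pick ``m`` checkpoints evenly spread over the later part of training.

    The earliest ``skip_fraction`` of saved checkpoints is skipped (they
    predate distribution matching); the rest are sampled evenly so the
    ensemble sees diverse generator states.
    """
    ckpts = artifacts.checkpoints
    if not ckpts:
        raise ValueError("no checkpoints were saved during training")
    start = min(len(ckpts) - 1, int(skip_fraction * len(ckpts)))
    idx = np.linspace(start, len(ckpts) - 1, m).astype(int)
    return [ckpts[i] for i in idx]


def sample_from_aae(artifacts: AaeArtifacts, n: int, seed: int = 0) -> np.ndarray:
    """Sample ``n`` new rows through the final generator and decoder."""
    return artifacts.final_generator().sample(n, seed)


def valid_label_ratio(rows: np.ndarray, lo: float = 6.0, hi: float = 11.0) -> float:
    """Fraction of generated rows whose label (last column) lies in [lo, hi]."""
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("no rows given")
    labels = rows[:, -1]
    return float(np.mean((labels >= lo) & (labels <= hi)))


# ---------------------------------------------------------------------------
# persistence: directory of JSON metadata + per-network weight arrays
# ---------------------------------------------------------------------------

def save_aae(artifacts: AaeArtifacts, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": asdict(artifacts.config),
        "input_dim": artifacts.input_dim,
        "iterations": int(artifacts.loss_trace.shape[0]),
        "n_checkpoints": len(artifacts.checkpoints),
        "final_losses": artifacts.loss_trace[-1].tolist(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    np.savetxt(out / "loss_trace.csv", artifacts.loss_trace, delimiter=",",
               header="reconstruction,discriminator,generator", comments="")
    arrays = {}
    for name, net in (("encoder", artifacts.encoder), ("decoder", artifacts.decoder),
                      ("generator", artifacts.generator), ("discriminator", artifacts.discriminator)):
        for i, arr in enumerate(net.state_arrays()):
            arrays[f"{name}_{i}"] = arr
    for c, ckpt in enumerate(artifacts.checkpoints):
        for i, arr in enumerate(ckpt.generator.state_arrays()):
            arrays[f"ckpt{c}_gen_{i}"] = arr
        for i, arr in enumerate(ckpt.decoder.state_arrays()):
            arrays[f"ckpt{c}_dec_{i}"] = arr
    np.savez(out / "weights.npz", **arrays)


def load_aae(run_dir) -> AaeArtifacts:
    run = Path(run_dir)
    meta = json.loads((run / "meta.json").read_text())
    cfg_dict = meta["config"]
    cfg_dict["valid_label_range"] = tuple(cfg_dict["valid_label_range"])
    config = AaeConfig(**cfg_dict)
    dim = meta["input_dim"]
    rng = np.random.default_rng(0)
    enc = MLP([dim, *config.encoder_layers, config.latent_dim], rng,
              batchnorm=True, dropout=config.dropout)
    dec = MLP([config.latent_dim, *config.decoder_layers, dim], rng,
              batchnorm=True, dropout=config.dropout)
    gen = MLP([config.latent_dim, *config.generator_layers, config.latent_dim], rng)
    disc = MLP([config.latent_dim, *config.discriminator_layers, 1], rng)
    data = np.load(run / "weights.npz")
    for name, net in (("encoder", enc), ("decoder", dec),
                      ("generator", gen), ("discriminator", disc)):
        net.load_state_arrays([data[f"{name}_{i}"]
                               for i in range(len(net.state_arrays()))])
    checkpoints = []
    for c in range(meta["n_checkpoints"]):
        g = MLP([config.latent_dim, *config.generator_layers, config.latent_dim], rng)
        d = MLP([config.latent_dim, *config.decoder_layers, dim], rng,
                batchnorm=True, dropout=config.dropout)
        g.load_state_arrays([data[f"ckpt{c}_gen_{i}"] for i in range(len(g.state_arrays()))])
        d.load_state_arrays([data[f"ckpt{c}_dec_{i}"] for i in range(len(d.state_arrays()))])
        checkpoints.append(GeneratorHandle(g, d, config.latent_dim, dim, tag=f"ckpt{c}"))
    trace = np.loadtxt(run / "loss_trace.csv", delimiter=",", skiprows=1)
    return AaeArtifacts(enc, dec, gen, disc, config, dim,
                        np.atleast_2d(trace), checkpoints)
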