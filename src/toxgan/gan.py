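"""Conditional Wasserstein GAN for clinical-pathology profiles.

The generator maps a scaled condition vector c = (descriptors, dose, time)
plus an equally long Gaussian noise vector to a profile in (-1, 1)^|panel|
(tanh output). The critic scores (profile, condition) pairs. Training
alternates several critic updates per generator update; the critic is kept
approximately 1-Lipschitz with a gradient penalty on interpolates between
real and generated profiles. A log-loss objective reproducing the classic
non-saturating cGAN formulation is available as an alternative.

The generator loss additionally carries a Lipschitz-style regularizer over
the *condition* space: for a small Gaussian perturbation dc of the
condition, the ratio ||G(c+dc,z) - G(c,z)|| / ||dc|| is clamped at tau and
minimized, which encourages the generator to interpolate smoothly between
neighboring treatment conditions instead of memorizing the training grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .data import StudyDataset, StudyScalers, TreatmentCondition, fit_scaler
from .evaluation import cosine_similarity, rmse
from .nn import Tensor, concat, grad

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# architecture specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """Five-hidden-layer MLP; LeakyReLU + batch norm per hidden layer,
    tanh output. Noise dimension equals the condition dimension, so the
    input is 2*(D+2)-dimensional (3656 when D=1826)."""

    condition_dim: int
    output_dim: int = 38
    hidden: tuple[int, ...] = (4096, 2048, 1024, 256, 64)
    negative_slope: float = 0.2
    batch_norm: bool = True

    @property
    def noise_dim(self) -> int:
        return self.condition_dim

    @property
    def input_dim(self) -> int:
        return 2 * self.condition_dim


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Critic MLP over (profile, condition); LeakyReLU(0.2) and dropout 0.4
    after each hidden layer, scalar output."""

    profile_dim: int
    condition_dim: int
    hidden: tuple[int, ...] = (2048, 1024, 256, 64, 32)
    negative_slope: float = 0.2
    dropout: float = 0.4

    @property
    def input_dim(self) -> int:
        return self.profile_dim + self.condition_dim


class Generator:
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        self.linears: list[nn.Linear] = []
        self.bns: list[nn.BatchNorm1d | None] = []
        d = spec.input_dim
        for h in spec.hidden:
            self.linears.append(nn.Linear(d, h, rng))
            self.bns.append(nn.BatchNorm1d(h) if spec.batch_norm else None)
            d = h
        self.out = nn.Linear(d, spec.output_dim, rng)

    @property
    def noise_dim(self) -> int:
        return self.spec.noise_dim

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for lin, bn in zip(self.linears, self.bns):
            ps.extend(lin.params)
            if bn is not None:
                ps.extend(bn.params)
        ps.extend(self.out.params)
        return ps

    def forward(self, x: Tensor, train: bool = True) -> Tensor:
        if x.data.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"generator expects input dim {self.spec.input_dim}, got {x.data.shape[1]}"
            )
        h = x
        for lin, bn in zip(self.linears, self.bns):
            h = lin(h).leaky_relu(self.spec.negative_slope)
            if bn is not None:
                h = bn(h, train=train)
        return self.out(h).tanh()

    def infer(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode forward in plain NumPy (running BN statistics)."""
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"generator expects input dim {self.spec.input_dim}, got {x.shape[1]}"
            )
        h = x
        slope = self.spec.negative_slope
        for lin, bn in zip(self.linears, self.bns):
            h = lin.infer(h)
            h = np.where(h > 0, h, slope * h)
            if bn is not None:
                h = bn.infer(h)
        return np.tanh(self.out.infer(h))

    def get_weights(self) -> list[np.ndarray]:
        ws = [p.data.copy() for p in self.params]
        for bn in self.bns:
            if bn is not None:
                ws.append(bn.running_mean.copy())
                ws.append(bn.running_var.copy())
        return ws

    def set_weights(self, ws: Sequence[np.ndarray]) -> None:
        ps = self.params
        for p, w in zip(ps, ws[: len(ps)]):
            p.data = w.copy()
        extra = list(ws[len(ps):])
        for bn in self.bns:
            if bn is not None:
                bn.running_mean = extra.pop(0).copy()
                bn.running_var = extra.pop(0).copy()


class Critic:
    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        self.linears: list[nn.Linear] = []
        d = spec.input_dim
        for h in spec.hidden:
            self.linears.append(nn.Linear(d, h, rng))
            d = h
        self.out = nn.Linear(d, 1, rng)
        self.dropout = nn.Dropout(spec.dropout)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for lin in self.linears:
            ps.extend(lin.params)
        ps.extend(self.out.params)
        return ps

    def forward(self, x: Tensor, rng: np.random.Generator, train: bool = True) -> Tensor:
        if x.data.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"critic expects input dim {self.spec.input_dim}, got {x.data.shape[1]}"
            )
        h = x
        for lin in self.linears:
            h = lin(h).leaky_relu(self.spec.negative_slope)
            h = self.dropout(h, rng, train=train)
        return self.out(h)


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

def build_generator_input(
    condition: TreatmentCondition,
    noise: np.ndarray,
    scalers: StudyScalers,
    descriptors: np.ndarray | None = None,
) -> np.ndarray:
    """Concatenate (scaled condition, noise): order (s, d, t, z). The noise
    block is already standard normal and passes through unscaled."""
    c = condition.condition_vector(descriptors)
    c_scaled = scalers.condition.transform(c)
    noise = np.asarray(noise, dtype=float)
    if noise.shape[-1] != c_scaled.shape[-1]:
        raise ValueError(
            f"noise length {noise.shape[-1]} != condition length {c_scaled.shape[-1]}"
        )
    return np.concatenate([c_scaled, noise], axis=-1)


_LOG_EPS = 1e-7


def adversarial_losses(objective: str, d_real: Tensor, d_fake: Tensor) -> tuple[Tensor, Tensor]:
    """(discriminator/critic loss, generator loss) from raw score batches.

    ``wgan_gp``: critic loss mean(D_fake) - mean(D_real) (gradient penalty
    added by the trainer), generator loss -mean(D_fake).
    ``log_gan``: scores pass through a sigmoid; the discriminator maximizes
    log D(real) + log(1 - D(fake)) and the generator minimizes
    log(1 - D(fake)), with clamped logs for finiteness.
    """
    if d_real.data.size == 0 or d_fake.data.size == 0:
        raise ValueError("empty score batches")
    if objective == "wgan_gp":
        d_loss = d_fake.mean() - d_real.mean()
        g_loss = -d_fake.mean()
        return d_loss, g_loss
    if objective == "log_gan":
        p_real = d_real.sigmoid().maximum(_LOG_EPS).minimum(1.0 - _LOG_EPS)
        p_fake = d_fake.sigmoid().maximum(_LOG_EPS).minimum(1.0 - _LOG_EPS)
        d_loss = -(p_real.log().mean() + (1.0 - p_fake).log().mean())
        g_loss = (1.0 - p_fake).log().mean()
        return d_loss, g_loss
    raise ValueError(f"unknown objective {objective!r}")


def gradient_penalty(
    critic: Critic,
    real: np.ndarray,
    fake: np.ndarray,
    cond: np.ndarray,
    rng: np.random.Generator,
) -> tuple[Tensor, Tensor]:
    """Two-sided gradient penalty on profile interpolates, condition held
    fixed: E[(||grad_x D(x_hat | c)|| - 1)^2]. Returns (penalty, x_hat)."""
    eps = rng.random((real.shape[0], 1))
    x_hat = Tensor(eps * real + (1 - eps) * fake, requires_grad=True)
    scores = critic.forward(concat([x_hat, Tensor(cond)], axis=1), rng, train=True)
    (g,) = grad(scores.sum(), [x_hat])
    gnorm = ((g * g).sum(axis=1) + 1e-12) ** 0.5
    return ((gnorm - 1.0) ** 2.0).mean(), x_hat


def generator_regularization(
    generator: Generator,
    cond: np.ndarray,
    noise: np.ndarray,
    sigma_dc: float,
    tau: float,
    epsilon_dc: float,
    rng: np.random.Generator,
    train: bool = True,
) -> Tensor:
    """Condition-smoothness term: mean over the batch of
    min(||G(c+dc,z) - G(c,z)|| / max(||dc||, eps), tau), dc ~ N(0, sigma^2 I)
    drawn in scaled condition space over the full condition block."""
    if cond.shape[0] == 0:
        raise ValueError("empty batch")
    if sigma_dc <= 0:
        raise ValueError("sigma_dc must be > 0")
    dc = rng.normal(0.0, sigma_dc, size=cond.shape)
    g0 = generator.forward(Tensor(np.concatenate([cond, noise], axis=1)), train=train)
    g1 = generator.forward(Tensor(np.concatenate([cond + dc, noise], axis=1)), train=train)
    diff = g1 - g0
    num = ((diff * diff).sum(axis=1) + 1e-24) ** 0.5
    den = np.maximum(np.linalg.norm(dc, axis=1), epsilon_dc)
    ratio = num * Tensor(1.0 / den)
    return ratio.minimum(tau).mean()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    objective: str = "wgan_gp"  # or "log_gan"
    lambda_gr: float = 1.0
    tau: float = 10.0
    sigma_dc: float = 0.01
    epsilon_dc: float = 1e-8
    gp_weight: float = 10.0
    lr: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.9)
    batch_size: int = 128
    critic_steps: int = 5
    epochs: int = 6000
    checkpoint_every: int = 100
    seed: int = 0
    generator_hidden: tuple[int, ...] = (4096, 2048, 1024, 256, 64)
    critic_hidden: tuple[int, ...] = (2048, 1024, 256, 64, 32)
    n_target_draws: int = 100  # draws entering the checkpoint metrics

    def __post_init__(self):
        if self.lambda_gr < 0 or self.tau <= 0 or self.sigma_dc <= 0 or self.epochs < 0:
            raise ValueError("invalid training configuration")


@dataclass
class CheckpointRecord:
    epoch: int
    weights: list[np.ndarray] = field(repr=False)
    mean_cosine: float = float("nan")
    mean_rmse: float = float("nan")
    validity_rate: float = float("nan")


@dataclass
class TrainResult:
    generator: Generator
    critic: Critic
    checkpoints: list[CheckpointRecord]
    history: pd.DataFrame
    scalers: StudyScalers
    aborted: bool = False


def _training_arrays(
    dataset: StudyDataset,
    descriptors: np.ndarray,
    scalers: StudyScalers,
    compound_ids: Sequence[str],
):
    idx = {str(c): i for i, c in enumerate(compound_ids)}
    conds = dataset.conditions
    cond_scaled = np.stack(
        [
            scalers.condition.transform(
                c.condition_vector(descriptors[idx[c.compound_id]])
            )
            for c in conds
        ]
    )
    treated = dataset.records[dataset.records["group"] == "treated"]
    key_to_row = {c.key: i for i, c in enumerate(conds)}
    rec_cond = np.array(
        [
            key_to_row[(str(r.compound_id), str(r.dose_level), int(r.time_days))]
            for r in treated[["compound_id", "dose_level", "time_days"]].itertuples(index=False)
        ]
    )
    profiles = scalers.profile.transform(treated[dataset.panel.codes].to_numpy(dtype=float))
    return conds, cond_scaled, rec_cond, profiles


def train(
    dataset: StudyDataset,
    descriptors: np.ndarray,
    config: TrainConfig,
    scalers: StudyScalers | None = None,
    compound_ids: Sequence[str] | None = None,
) -> TrainResult:
    """Adversarial training on a study dataset.

    One epoch is one pass over the treated records in minibatches; each
    minibatch runs ``critic_steps`` critic updates then one generator update
    (whose loss includes the condition-smoothness term weighted by
    ``lambda_gr``). Checkpoints every ``checkpoint_every`` epochs snapshot
    the weights and score the training set with the 100-valid-draw rule.
    Deterministic for a fixed seed. A non-finite loss aborts training,
    retaining the checkpoints taken so far.
    """
    from .generation import generate_condition_profile  # local: avoids cycle

    if compound_ids is None:
        compound_ids = [str(x) for x in dataset.compounds["compound_id"]]
    descriptors = np.where(np.isfinite(descriptors), np.asarray(descriptors, float), 0.0)
    if scalers is None:
        scalers = fit_scaler(dataset, descriptors, compound_ids)

    conds, cond_scaled, rec_cond, profiles = _training_arrays(
        dataset, descriptors, scalers, compound_ids
    )
    n_records = profiles.shape[0]
    cdim = cond_scaled.shape[1]
    pdim = profiles.shape[1]

    rng = np.random.default_rng(config.seed)
    g_spec = GeneratorSpec(condition_dim=cdim, output_dim=pdim, hidden=config.generator_hidden)
    d_spec = DiscriminatorSpec(profile_dim=pdim, condition_dim=cdim, hidden=config.critic_hidden)
    G = Generator(g_spec, rng)
    C = Critic(d_spec, rng)
    opt_g = nn.Adam(G.params, lr=config.lr, betas=config.betas)
    opt_c = nn.Adam(C.params, lr=config.lr, betas=config.betas)

    desc_by_id = {str(cid): descriptors[i] for i, cid in enumerate(compound_ids)}
    real_means = {c.key: dataset.treated_values(c).mean(axis=0) for c in conds}

    def checkpoint_metrics(epoch: int) -> CheckpointRecord:
        cosines, rmses, vrates = [], [], []
        for ci, c in enumerate(conds):
            res = generate_condition_profile(
                G,
                c,
                scalers,
                n_target=config.n_target_draws,
                seed=(config.seed * 100003 + 7919 * epoch + ci) % (2**31),
                descriptors=desc_by_id[c.compound_id],
                panel=dataset.panel,
                strict=False,
            )
            vrates.append(res.n_valid / max(res.n_attempted, 1))
            if res.mean_profile is None:
                continue
            r_bar = real_means[c.key]
            cosines.append(cosine_similarity(res.mean_profile, r_bar))
            rmses.append(rmse(res.mean_profile, r_bar))
        return CheckpointRecord(
            epoch=epoch,
            weights=G.get_weights(),
            mean_cosine=float(np.mean(cosines)) if cosines else float("nan"),
            mean_rmse=float(np.mean(rmses)) if rmses else float("nan"),
            validity_rate=float(np.mean(vrates)) if vrates else 0.0,
        )

    checkpoints: list[CheckpointRecord] = []
    hist_rows = []
    steps_per_epoch = max(1, int(np.ceil(n_records / config.batch_size)))
    aborted = False

    for epoch in range(1, config.epochs + 1):
        d_losses, g_losses, reg_terms = [], [], []
        for _ in range(steps_per_epoch):
            # ---- critic updates
            for _ in range(config.critic_steps):
                idx = rng.integers(0, n_records, size=min(config.batch_size, n_records))
                real = profiles[idx]
                cond = cond_scaled[rec_cond[idx]]
                noise = rng.standard_normal((len(idx), cdim))
                fake = G.forward(
                    Tensor(np.concatenate([cond, noise], axis=1)), train=True
                ).detach()
                d_real = C.forward(concat([Tensor(real), Tensor(cond)], axis=1), rng)
                d_fake = C.forward(concat([fake, Tensor(cond)], axis=1), rng)
                d_loss, _ = adversarial_losses(config.objective, d_real, d_fake)
                if config.objective == "wgan_gp" and config.gp_weight > 0:
                    gp, _ = gradient_penalty(C, real, fake.data, cond, rng)
                    d_loss = d_loss + gp * config.gp_weight
                grads = grad(d_loss, C.params)
                opt_c.step(grads)
                d_losses.append(d_loss.item())

            # ---- generator update
            idx = rng.integers(0, n_records, size=min(config.batch_size, n_records))
            cond = cond_scaled[rec_cond[idx]]
            noise = rng.standard_normal((len(idx), cdim))
            fake = G.forward(Tensor(np.concatenate([cond, noise], axis=1)), train=True)
            scores = C.forward(concat([fake, Tensor(cond)], axis=1), rng)
            _, g_loss = adversarial_losses(config.objective, scores, scores)
            if config.objective == "wgan_gp":
                g_loss = -scores.mean()
            reg = Tensor(0.0)
            if config.lambda_gr > 0:
                reg = generator_regularization(
                    G, cond, noise, config.sigma_dc, config.tau, config.epsilon_dc, rng
                )
                g_loss = g_loss + reg * config.lambda_gr
            grads = grad(g_loss, G.params)
            opt_g.step(grads)
            g_losses.append(g_loss.item())
            reg_terms.append(reg.item())

        d_mean, g_mean = float(np.mean(d_losses)), float(np.mean(g_losses))
        hist_rows.append(
            {
                "epoch": epoch,
                "d_loss": d_mean,
                "g_loss": g_mean,
                "gr_term": float(np.mean(reg_terms)),
            }
        )
        if not (np.isfinite(d_mean) and np.isfinite(g_mean)):
            logger.error("non-finite loss at epoch %d; aborting with last checkpoint", epoch)
            aborted = True
            break
        if epoch % config.checkpoint_every == 0 or epoch == config.epochs:
            checkpoints.append(checkpoint_metrics(epoch))

    history = pd.DataFrame(hist_rows)
    return TrainResult(
        generator=G, critic=C, checkpoints=checkpoints, history=history,
        scalers=scalers, aborted=aborted,
    )


def select_checkpoint(records: Sequence[CheckpointRecord]) -> CheckpointRecord:
    """Best checkpoint: maximal mean cosine, ties broken by minimal mean
    RMSE, then by the latest epoch."""
    if not records:
        raise ValueError("no checkpoints to select from")

    def sort_key(r: CheckpointRecord):
        cos = r.mean_cosine if np.isfinite(r.mean_cosine) else -np.inf
        rm = r.mean_rmse if np.isfinite(r.mean_rmse) else np.inf
        return (-cos, rm, -r.epoch)

    return min(records, key=sort_key)
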