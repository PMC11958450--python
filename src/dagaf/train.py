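"""Step-1 constrained optimization: adversarial training inside an
augmented-Lagrangian outer loop driving the acyclicity functional to zero.

The generator reconstructs X̃ from X (no noise vector in this step; the
reconstructions are diagnostic only and are never emitted as synthetic
data). The objective per generator update is

    L = w_adv·L_adv + w_mse·L_mse + w_kld·L_kld + w_mmd·L_mmd [+ w_pnl·L_pnl]
        + λ·h(A) + (c/2)·h(A)² + λ₁‖W_L0‖₁ + λ₂‖θ‖²

with h the trace-exponential acyclicity value of the implicit adjacency.
λ and c follow the classic multiplier/penalty schedule: after each inner
phase, λ ← λ + c·h and c is multiplied by 10 whenever h failed to shrink
below a quarter of its previous value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fcm import Assumption, Critic, FcmGenerator, InverseNet
from .graphs import BinaryDag, WeightedAdjacency, postprocess_structure
from .losses import (LossBreakdown, LossWeights, kld_loss, median_bandwidth,
                     mmd_loss, mse_loss, pnl_loss, total_step1_loss,
                     wasserstein_gp)


class Adam:
    """Adaptive-moment gradient descent on a fixed list of parameters."""

    def __init__(self, params, lr=3e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass(frozen=True)
class LagrangianState:
    """Progress of the constrained optimization: multiplier, penalty, h."""

    lam: float = 0.0
    c: float = 1.0
    h_value: float = np.inf
    outer_iter: int = 0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("penalty coefficient c must be positive")
        if self.h_value < 0:
            raise ValueError("acyclicity value must be nonnegative")


def lagrangian_update(
    state: LagrangianState, h_new: float, progress_ratio: float = 0.25
) -> LagrangianState:
    """Multiplier step λ ← λ + c·h; penalty ×10 when h stalls.

    The penalty grows only when the new h exceeds ``progress_ratio``
    times the previous value (insufficient constraint progress).
    """
    if h_new < 0:
        raise ValueError("h must be nonnegative")
    lam = state.lam + state.c * h_new
    c = state.c
    if np.isfinite(state.h_value) and h_new > progress_ratio * state.h_value:
        c = 10.0 * c
    return LagrangianState(lam=lam, c=c, h_value=h_new,
                           outer_iter=state.outer_iter + 1)


@dataclass
class TrainConfig:
    """Hyperparameters of the Step-1 optimization.

    Defaults are the framework's reference settings (lr 3e-3, batch
    1000, critic weight decay 1e-6, threshold 0.3); the remaining knobs
    carry the conventions of the architectures the framework builds on
    (WGAN-GP, NOTEARS-MLP).
    """

    assumption: "Assumption | str" = Assumption.ANM
    lr: float = 3e-3
    batch: int = 1000
    epochs: int = 300          # inner epochs per outer iteration
    warm_epochs: "int | None" = None  # epochs for the first outer iteration
    k_max_iter: int = 20       # outer (augmented Lagrangian) iterations
    n_critic: int = 5
    critic_weight_decay: float = 1e-6
    threshold: float = 0.3
    h_tol: float = 1e-8
    c_max: float = 1e16
    progress_ratio: float = 0.25
    h: int = 10                # latent width of each local mechanism
    depth: int = 1
    l1: float = 0.01           # sparsity penalty on the structure layer
    l2: float = 0.01           # ridge penalty on generator parameters
    mmd_batch: int = 256       # subsample for the O(n²) MMD estimator
    center: bool = True        # subtract column means before training
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self):
        self.assumption = Assumption(self.assumption)
        for name in ("lr", "batch", "epochs", "n_critic", "k_max_iter",
                     "threshold", "h", "depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class StructureResult:
    """Learned structure plus training diagnostics."""

    weighted: WeightedAdjacency
    dag: BinaryDag
    loss_history: list
    wasserstein_trace: list
    state: LagrangianState
    config: TrainConfig
    generator: FcmGenerator
    inverse: "InverseNet | None" = None
    column_means: "np.ndarray | None" = None


def _acyclicity_tensor(gen: FcmGenerator) -> Tensor:
    A_sq = gen.squared_adjacency_tensor()
    return ad.trace_expm(A_sq) - float(gen.d)


def gradient_penalty_norms(critic: Critic, X: np.ndarray, Xt: np.ndarray,
                           rng: np.random.Generator) -> Tensor:
    """‖∇D‖ at per-sample uniform interpolates x̂ = εx + (1−ε)x̃."""
    eps = rng.uniform(size=(X.shape[0], 1))
    interp = Tensor(eps * X + (1 - eps) * Xt, requires_grad=True)
    scores = critic(interp)
    g, = ad.grad(ad.sum_(scores), [interp], create_graph=True)
    return ad.sqrt(ad.sum_(ad.square(g), axis=1) + 1e-12)


def adversarial_epoch(
    gen: FcmGenerator,
    critic: Critic,
    batches,
    weights: LossWeights,
    assumption: "Assumption | str",
    opt_gen: "Adam | None" = None,
    opt_critic: "Adam | None" = None,
    inverse: "InverseNet | None" = None,
    lam: float = 0.0,
    c: float = 0.0,
    n_critic: int = 5,
    critic_weight_decay: float = 1e-6,
    mmd_batch: int = 256,
    l1: float = 0.0,
    l2: float = 0.0,
    rng: "np.random.Generator | None" = None,
    epoch: int = 0,
) -> tuple[LossBreakdown, float]:
    """One epoch of alternating critic/generator updates over a batch stream.

    Returns the mean per-term generator loss breakdown and the epoch's
    Wasserstein estimate (mean real − mean fake critic score).
    """
    assumption = Assumption(assumption)
    weights = weights.for_assumption(assumption)
    rng = rng or np.random.default_rng(0)
    batches = list(batches)
    if not batches:
        raise ValueError("empty batch stream")
    agg = LossBreakdown()
    wass = 0.0
    mmd_bw: float | None = None
    for Xb in batches:
        Xb = np.asarray(Xb, dtype=np.float64)
        # --- critic updates -----------------------------------------
        Xt_np = gen.forward(Xb).data
        nb_rows = Xb.shape[0]
        for _ in range(n_critic if opt_critic is not None else 0):
            opt_critic.zero_grad()
            both = critic(np.vstack([Xb, Xt_np]))
            real_s, fake_s = both[:nb_rows], both[nb_rows:]
            norms = gradient_penalty_norms(critic, Xb, Xt_np, rng)
            c_loss, _ = wasserstein_gp(real_s, fake_s, norms, weights.gp_coeff)
            if critic_weight_decay > 0:
                wd = Tensor(0.0)
                for W in critic.weights:
                    wd = wd + ad.sum_(ad.square(W))
                c_loss = c_loss + critic_weight_decay * wd
            c_loss.backward()
            opt_critic.step()
        # --- generator update ---------------------------------------
        if opt_gen is not None:
            opt_gen.zero_grad()
        Xt = gen.forward(Xb)
        fake_s = critic(Xt)
        real_s_np = critic(Xb).data
        gen_adv = -ad.mean(fake_s)
        m = min(mmd_batch, Xb.shape[0])
        if mmd_bw is None:  # median heuristic, cached across the epoch
            mmd_bw = median_bandwidth(Xb[:m], Xt.data[:m])
        components = {
            "adv": gen_adv,
            "mse": mse_loss(Xb, Xt),
            "mmd": mmd_loss(Xb[:m], Xt[:m], bandwidth=mmd_bw),
        }
        if assumption is not Assumption.LINGAM:
            components["kld"] = kld_loss(Xt)
        if assumption is Assumption.PNL:
            if inverse is None:
                raise ValueError("PNL training requires an InverseNet")
            components["pnl"] = pnl_loss(inverse(Xb), Xt)
        total, bd = total_step1_loss(components, weights, assumption)
        h_t = _acyclicity_tensor(gen)
        total = total + lam * h_t + 0.5 * c * ad.square(h_t)
        if l1 > 0:
            total = total + l1 * ad.sum_(ad.abs_(gen.W1 * gen._mask))
        if l2 > 0:
            reg = Tensor(0.0)
            for p in gen.parameters():
                reg = reg + ad.sum_(ad.square(p))
            total = total + l2 * reg
        if not np.isfinite(total.item()):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch}"
            )
        if opt_gen is not None:
            total.backward()
            opt_gen.step()
        for name in ("adv", "mse", "kld", "mmd", "pnl", "total"):
            setattr(agg, name, getattr(agg, name) + getattr(bd, name))
        wass += float(real_s_np.mean() - fake_s.data.mean())
    nb = len(batches)
    for name in ("adv", "mse", "kld", "mmd", "pnl", "total"):
        setattr(agg, name, getattr(agg, name) / nb)
    return agg, wass / nb


def _batch_stream(X: np.ndarray, batch: int, rng: np.random.Generator):
    n = X.shape[0]
    idx = rng.permutation(n)
    for start in range(0, n, batch):
        sel = idx[start:start + batch]
        if len(sel) < 2:
            continue
        yield X[sel]


def train_structure(X: np.ndarray, cfg: "TrainConfig | None" = None) -> StructureResult:
    """Learn a weighted adjacency / DAG from data under the configured FCM.

    Runs ``cfg.k_max_iter`` outer augmented-Lagrangian iterations, each
    consisting of ``cfg.epochs`` adversarial epochs, then thresholds the
    implicit adjacency at ``cfg.threshold`` (residual cycles, if any,
    are repaired by dropping the weakest cycle edge).
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be an n×d matrix with n ≥ 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    n, d = X.shape
    means = X.mean(axis=0) if cfg.center else np.zeros(d)
    Xc = X - means
    batch = min(cfg.batch, n)

    gen = FcmGenerator(d, h=cfg.h, depth=cfg.depth, assumption=cfg.assumption,
                       seed=cfg.seed)
    critic = Critic(d, seed=cfg.seed + 1)
    inverse = InverseNet(d, seed=cfg.seed + 2) if cfg.assumption is Assumption.PNL else None
    gen_params = gen.parameters() + (inverse.parameters() if inverse else [])
    opt_gen = Adam(gen_params, lr=cfg.lr)
    opt_critic = Adam(critic.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1000)

    state = LagrangianState()
    loss_history: list[dict] = []
    wasserstein_trace: list[float] = []
    epoch_counter = 0
    for k in range(cfg.k_max_iter):
        # the first (nearly unconstrained) phase fits the mechanisms; it may
        # run longer than later phases, which mainly drive h down
        n_epochs = cfg.warm_epochs if (k == 0 and cfg.warm_epochs) else cfg.epochs
        for _ in range(n_epochs):
            bd, w = adversarial_epoch(
                gen, critic, _batch_stream(Xc, batch, rng), cfg.weights,
                cfg.assumption, opt_gen=opt_gen, opt_critic=opt_critic,
                inverse=inverse, lam=state.lam, c=state.c,
                n_critic=cfg.n_critic, critic_weight_decay=cfg.critic_weight_decay,
                mmd_batch=cfg.mmd_batch, l1=cfg.l1, l2=cfg.l2, rng=rng,
                epoch=epoch_counter,
            )
            loss_history.append(bd.as_dict())
            wasserstein_trace.append(w)
            epoch_counter += 1
        h_new = float(_acyclicity_tensor(gen).item())
        state = lagrangian_update(state, h_new, cfg.progress_ratio)
        if h_new <= cfg.h_tol:
            break
        if state.c > cfg.c_max:
            warnings.warn(
                f"penalty coefficient exceeded c_max={cfg.c_max:g} with "
                f"h={h_new:.3g}; returning best-so-far structure",
                RuntimeWarning,
            )
            break

    A_sq = gen.squared_adjacency_tensor().data
    weighted, dag = postprocess_structure(A_sq, cfg.threshold, enforce_acyclic=True)
    return StructureResult(
        weighted=weighted, dag=dag, loss_history=loss_history,
        wasserstein_trace=wasserstein_trace, state=state, config=cfg,
        generator=gen, inverse=inverse, column_means=means,
    )
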