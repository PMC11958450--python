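"""Step-2 causally-aware data synthesis.

The learned structure layer L0 is copied from the Step-1 generator into
a fresh generator and frozen; only the locally connected hidden layers
(the mechanisms) are trained, adversarially against a fresh critic, so
the synthesizer can match the data distribution without disturbing the
structural equations. Sampling is ancestral: noise Z_j ~ N(μ, σ²) is
drawn per node and columns are realized in a topological order of the
thresholded DAG, each mechanism seeing only its parents.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fcm import Assumption, Critic, FcmGenerator, InverseNet, Module
from .graphs import BinaryDag
from .losses import wasserstein_gp
from .train import Adam, gradient_penalty_norms


class ForwardNet(Module):
    """MLP for the forward post-nonlinearity g (PNL synthesis only).

    Step 1 learns g⁻¹; generation needs g itself, so after Step 1 this
    network is fitted by minimizing ‖g(g⁻¹(x)) − x‖² on the training data.
    Same shape family as the inverse net, near-identity initialisation.
    """

    def __init__(self, d: int, width_factor: int = 10, seed: int = 0):
        self._net = InverseNet(d, width_factor=width_factor, seed=seed)
        self.d = d

    def parameters(self):
        return self._net.parameters()

    def forward(self, X):
        return self._net.forward(X)

    __call__ = forward


@dataclass
class SynthConfig:
    lr: float = 3e-3
    batch: int = 1000
    epochs: int = 100
    n_critic: int = 5
    critic_weight_decay: float = 1e-6
    gp_coeff: float = 10.0
    noise_mu: float = 0.0
    noise_sigma: float = 1.0
    seed: int = 0


@dataclass
class GeneratorBundle:
    """Frozen-structure generator plus its adversary and noise law."""

    generator: FcmGenerator
    critic: Critic
    dag: BinaryDag
    assumption: Assumption
    noise_mu: float = 0.0
    noise_sigma: float = 1.0
    forward_g: "ForwardNet | None" = None
    inverse: "InverseNet | None" = None   # enables numeric inversion of g⁻¹
    column_means: "np.ndarray | None" = None
    wasserstein_trace: "list | None" = None

    def l0_hash(self) -> str:
        """Digest of the structure layer; must never change in Step 2."""
        return hashlib.sha256(
            np.ascontiguousarray(self.generator.W1.data).tobytes()
        ).hexdigest()


def transfer_weights(
    structure_gen: FcmGenerator,
    dag: BinaryDag,
    seed: int = 0,
    noise_mu: float = 0.0,
    noise_sigma: float = 1.0,
    column_means: "np.ndarray | None" = None,
    inverse: "InverseNet | None" = None,
) -> GeneratorBundle:
    """Copy L0 from a trained Step-1 generator into a fresh synthesizer.

    The hidden (mechanism) layers are re-initialized from ``seed``; L0 is
    loaded exactly and marked non-trainable — modifying it would change
    the structural equations the synthesis is meant to preserve.
    """
    src_cfg = structure_gen.config()
    if dag.d != structure_gen.d:
        raise ValueError(
            f"DAG dimension {dag.d} does not match generator d={structure_gen.d}"
        )
    gen = FcmGenerator(
        d=src_cfg["d"], h=src_cfg["h"], depth=src_cfg["depth"],
        assumption=src_cfg["assumption"], activation=src_cfg["activation"],
        seed=seed,
    )
    gen.W1.data = structure_gen.W1.data.copy()
    gen.W1.requires_grad = False  # frozen: excluded from every optimizer
    critic = Critic(gen.d, seed=seed + 1)
    return GeneratorBundle(
        generator=gen, critic=critic, dag=dag,
        assumption=Assumption(src_cfg["assumption"]),
        noise_mu=noise_mu, noise_sigma=noise_sigma,
        column_means=column_means, inverse=inverse,
    )


def fit_forward_g(
    bundle: GeneratorBundle,
    inverse: InverseNet,
    X: np.ndarray,
    epochs: int = 200,
    lr: float = 3e-3,
    batch: int = 1000,
    seed: int = 0,
) -> ForwardNet:
    """Fit g by reconstruction through the learned inverse: g(g⁻¹(x)) ≈ x."""
    X = np.asarray(X, dtype=np.float64)
    g = ForwardNet(bundle.generator.d, seed=seed)
    opt = Adam(g.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    X_hat = inverse.forward(X).data  # fixed targets: g maps g⁻¹(x) back to x
    n = X.shape[0]
    b = min(batch, n)
    for _ in range(epochs):
        idx = rng.permutation(n)[:b]
        opt.zero_grad()
        out = g.forward(X_hat[idx])
        loss = ad.mean(ad.square(out - Tensor(X[idx])))
        loss.backward()
        opt.step()
    bundle.forward_g = g
    return g


def _ancestral_forward(
    bundle: GeneratorBundle, Z: np.ndarray, as_tensor: bool = False
):
    """Generate samples column-by-column in topological order.

    Each mechanism sees only the columns of its thresholded-DAG parents
    (all other inputs are zeroed), so generation follows the learned
    causal factorization exactly.
    """
    gen, dag = bundle.generator, bundle.dag
    n, d = Z.shape
    cols: list = [None] * d
    zero = Tensor(np.zeros((n, 1)))
    for j in dag.topological_order():
        parents = set(dag.parents(j).tolist())
        inputs = [
            cols[k] if k in parents else zero
            for k in range(d)
        ]
        Xpart = ad.concat(inputs, axis=1)
        f_out = _node_forward(gen, Xpart, j)
        val = f_out + Tensor(Z[:, j:j + 1])
        if bundle.assumption is Assumption.PNL:
            if bundle.forward_g is not None:
                full = ad.concat(
                    [val if k == j else zero for k in range(d)], axis=1
                )
                val = bundle.forward_g(full)[:, j:j + 1]
            elif bundle.inverse is not None:
                val = Tensor(_invert_monotone(bundle.inverse, val.data, j, d))
        cols[j] = val
    out = ad.concat(cols, axis=1)
    return out if as_tensor else out.data


def _invert_monotone(inverse: InverseNet, target: np.ndarray, j: int, d: int,
                     iters: int = 60) -> np.ndarray:
    """Solve g⁻¹(x)_j = target for x_j by bisection.

    The post-nonlinearity g is invertible by assumption, so the learned
    g⁻¹ is treated as monotone in its j-th coordinate; an expanding
    bracket followed by bisection recovers g = (g⁻¹)⁻¹ pointwise. This is
    the numeric alternative to fitting a forward network.
    """
    t = target.ravel()
    n = t.shape[0]

    def eval_j(x):
        full = np.zeros((n, d))
        full[:, j] = x
        return inverse.forward(full).data[:, j]

    lo = np.full(n, -1.0)
    hi = np.full(n, 1.0)
    sign = 1.0 if eval_j(hi).mean() >= eval_j(lo).mean() else -1.0
    for _ in range(60):  # expand brackets until the target is enclosed
        flo, fhi = sign * eval_j(lo), sign * eval_j(hi)
        st = sign * t
        need_lo, need_hi = flo > st, fhi < st
        if not (need_lo.any() or need_hi.any()):
            break
        lo[need_lo] *= 2.0
        hi[need_hi] *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        below = sign * eval_j(mid) < sign * t
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return (0.5 * (lo + hi)).reshape(target.shape)


def _node_forward(gen: FcmGenerator, X: Tensor, j: int) -> Tensor:
    """Mechanism f_j applied to an n×d input, returning an n×1 column."""
    from .fcm import _act

    act = _act(gen.activation)
    W1m = gen.W1 * gen._mask
    H = act(ad.matmul(X, W1m[j]) + gen.b1[j])
    for W, b in gen.hidden:
        H = act(ad.matmul(H, W[j]) + b[j])
    return ad.matmul(H, gen.W2[j]) + gen.b2[j]


def sample(
    bundle: GeneratorBundle,
    n: int,
    seed: int = 0,
    add_means: bool = True,
) -> np.ndarray:
    """Draw n synthetic samples by ancestral sampling through the DAG."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    d = bundle.generator.d
    Z = rng.normal(bundle.noise_mu, bundle.noise_sigma, size=(n, d))
    X = _ancestral_forward(bundle, Z)
    if add_means and bundle.column_means is not None:
        X = X + bundle.column_means
    return X


def train_synthesizer(
    bundle: GeneratorBundle,
    X: np.ndarray,
    cfg: "SynthConfig | None" = None,
) -> GeneratorBundle:
    """Adversarially train the synthesizer's mechanisms against real data.

    Noise-driven: each update draws fresh Z, generates samples by
    ancestral forward passes, and optimizes the Wasserstein-GP objective.
    Only hidden-layer parameters (and the critic) change; L0 is frozen.
    """
    cfg = cfg or SynthConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != bundle.generator.d:
        raise ValueError(f"expected n×{bundle.generator.d} data, got {X.shape}")
    means = bundle.column_means if bundle.column_means is not None else np.zeros(X.shape[1])
    Xc = X - means
    gen, critic = bundle.generator, bundle.critic
    opt_gen = Adam(gen.mechanism_parameters(), lr=cfg.lr)
    opt_critic = Adam(critic.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    b = min(cfg.batch, n)
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        Xb = Xc[rng.permutation(n)[:b]]
        for _ in range(cfg.n_critic):
            Z = rng.normal(cfg.noise_mu, cfg.noise_sigma, size=(b, gen.d))
            fake = _ancestral_forward(bundle, Z)
            opt_critic.zero_grad()
            real_s = critic(Xb)
            fake_s = critic(fake)
            norms = gradient_penalty_norms(critic, Xb, fake, rng)
            c_loss, _ = wasserstein_gp(real_s, fake_s, norms, cfg.gp_coeff)
            if cfg.critic_weight_decay > 0:
                wd = Tensor(0.0)
                for W in critic.weights:
                    wd = wd + ad.sum_(ad.square(W))
                c_loss = c_loss + cfg.critic_weight_decay * wd
            if not np.isfinite(c_loss.item()):
                raise FloatingPointError(f"critic diverged at epoch {epoch}")
            c_loss.backward()
            opt_critic.step()
        Z = rng.normal(cfg.noise_mu, cfg.noise_sigma, size=(b, gen.d))
        opt_gen.zero_grad()
        fake_t = _ancestral_forward(bundle, Z, as_tensor=True)
        fake_s = critic(fake_t)
        g_loss = -ad.mean(fake_s)
        if not np.isfinite(g_loss.item()):
            raise FloatingPointError(f"generator diverged at epoch {epoch}")
        g_loss.backward()
        opt_gen.step()
        trace.append(float(critic(Xb).data.mean() - fake_s.data.mean()))
    bundle.wasserstein_trace = (bundle.wasserstein_trace or []) + trace
    return bundle
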