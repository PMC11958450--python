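"""Loss terms for structure learning (Step 1) and synthesis (Step 2).

All functions accept numpy arrays or autodiff Tensors and return Tensors,
so they can sit directly inside a training objective; call ``.item()``
for a plain float. The composite Step-1 objective is a weighted sum of

  adversarial (Wasserstein-1 with gradient penalty)  — distribution match
  MSE                                                — pointwise reconstruction
  KLD (ANM/PNL only)                                 — location prior on X̃
  MMD (RBF kernel)                                   — higher-order moments
  PNL reconstruction (PNL only)                      — ‖g⁻¹(X) − f(Pa)‖²
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .fcm import Assumption


@dataclass
class LossWeights:
    """Relative weights of the Step-1 loss terms.

    Reconstruction (and, under PNL, the inverse-reconstruction coupling)
    carries the structure-learning signal; the distributional terms
    default to 0.05, acting as weak regularizers — weighting them as
    strongly as the MSE injects enough gradient noise to flip edge
    orientations (see docs/methods.md).
    """

    w_adv: float = 0.05
    w_mse: float = 1.0
    w_kld: float = 0.05
    w_mmd: float = 0.05
    w_pnl: float = 1.0
    gp_coeff: float = 10.0

    def __post_init__(self):
        for name in ("w_adv", "w_mse", "w_kld", "w_mmd", "w_pnl", "gp_coeff"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")

    def for_assumption(self, assumption: "Assumption | str") -> "LossWeights":
        """KLD is tied to the Gaussian-noise models; it is dropped under LiNGAM."""
        a = Assumption(assumption)
        w = LossWeights(**self.__dict__)
        if a is Assumption.LINGAM:
            w.w_kld = 0.0
        if a is not Assumption.PNL:
            w.w_pnl = 0.0
        return w


def _check_finite(name: str, t: Tensor) -> None:
    if not np.all(np.isfinite(t.data)):
        raise ValueError(f"{name} contains non-finite values")


def wasserstein_gp(
    critic_real, critic_fake, grad_norms, gp_coeff: float = 10.0
) -> tuple[Tensor, Tensor]:
    """Wasserstein-1 critic/generator losses with gradient penalty.

    ``grad_norms`` are ‖∇_x̂ D(x̂)‖₂ evaluated at uniform interpolates
    x̂ = εx + (1−ε)x̃.  Returns (critic_loss, gen_loss):

      critic_loss = mean(fake) − mean(real) + gp·mean((‖∇D‖−1)²)
      gen_loss    = −mean(fake)
    """
    r, f, g = ad.astensor(critic_real), ad.astensor(critic_fake), ad.astensor(grad_norms)
    for name, t in (("critic_real", r), ("critic_fake", f), ("grad_norms", g)):
        _check_finite(name, t)
    if not (r.shape[0] == f.shape[0] == g.shape[0]):
        raise ValueError("critic scores and gradient norms must share length")
    penalty = ad.mean(ad.square(g - 1.0))
    critic_loss = ad.mean(f) - ad.mean(r) + gp_coeff * penalty
    gen_loss = -ad.mean(f)
    return critic_loss, gen_loss


def mse_loss(X, Xt) -> Tensor:
    """Reconstruction loss: (1/n) Σ_i Σ_j (X_ij − X̃_ij)²."""
    X, Xt = ad.astensor(X), ad.astensor(Xt)
    if X.shape != Xt.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xt.shape}")
    n = X.shape[0]
    return ad.sum_(ad.square(X - Xt)) * (1.0 / n)


def kld_loss(Xt, per_sample: bool = False) -> Tensor:
    """KL(N(μ,1) ‖ N(0,1)) reduced to ½ Σ μ²; a location prior on X̃.

    μ is the per-variable batch mean by default (the regularizer targets
    the generated distribution's location); ``per_sample=True`` gives the
    literal per-row reading instead.
    """
    Xt = ad.astensor(Xt)
    _check_finite("Xt", Xt)
    mu = ad.mean(Xt, axis=0) if not per_sample else ad.mean(Xt, axis=1)
    return 0.5 * ad.sum_(ad.square(mu))


def rbf_kernel(X, Y, bandwidth: float) -> Tensor:
    """k(x, y) = exp(−‖x−y‖² / (2σ²)) as an n×m Gram tensor."""
    X, Y = ad.astensor(X), ad.astensor(Y)
    xx = ad.reshape(ad.sum_(ad.square(X), axis=1), (X.shape[0], 1))
    yy = ad.reshape(ad.sum_(ad.square(Y), axis=1), (1, Y.shape[0]))
    d2 = xx + yy - 2.0 * ad.matmul(X, ad.transpose(Y))
    return ad.exp(d2 * (-0.5 / bandwidth**2))


def median_bandwidth(X: np.ndarray, Xt: np.ndarray) -> float:
    """Median-heuristic RBF bandwidth over the pooled batch."""
    Z = np.vstack([np.asarray(X, float), np.asarray(Xt, float)])
    sq = (Z * Z).sum(1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T), 0.0)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    return float(np.sqrt(max(med, 1e-12) / 2.0))


def mmd_loss(X, Xt, bandwidth: "float | None" = None) -> Tensor:
    """Maximum mean discrepancy, computed exactly as the printed estimator:

        (1/n) Σ_{i≠j} k(x_i,x_j) − (2/n) Σ_{i≠j} k(x_i,x̃_j)
                                  + (1/n) Σ_{i≠j} k(x̃_i,x̃_j)

    with an RBF kernel (median-heuristic bandwidth by default). Note the
    1/n normalisation of the i≠j sums is kept as printed rather than the
    conventional 1/(n(n−1)).
    """
    X, Xt = ad.astensor(X), ad.astensor(Xt)
    if X.shape != Xt.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Xt.shape}")
    n = X.shape[0]
    if n < 2:
        raise ValueError("MMD requires at least 2 samples (i≠j sums are empty)")
    if bandwidth is None:
        bandwidth = median_bandwidth(X.data, Xt.data)
    off = Tensor(1.0 - np.eye(n))
    kxx = ad.sum_(rbf_kernel(X, X, bandwidth) * off)
    kxy = ad.sum_(rbf_kernel(X, Xt, bandwidth) * off)
    kyy = ad.sum_(rbf_kernel(Xt, Xt, bandwidth) * off)
    return (kxx - 2.0 * kxy + kyy) * (1.0 / n)


def pnl_loss(X_hat, F_out) -> Tensor:
    """PNL residual ‖g⁻¹(X) − f(Pa)‖²: same arithmetic as ``mse_loss``."""
    return mse_loss(X_hat, F_out)


@dataclass
class LossBreakdown:
    adv: float = 0.0
    mse: float = 0.0
    kld: float = 0.0
    mmd: float = 0.0
    pnl: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict:
        return dict(adv=self.adv, mse=self.mse, kld=self.kld,
                    mmd=self.mmd, pnl=self.pnl, total=self.total)


def total_step1_loss(
    components: dict,
    weights: LossWeights,
    assumption: "Assumption | str",
) -> tuple[Tensor, LossBreakdown]:
    """Weighted sum of the Step-1 terms, with a per-term breakdown for logging.

    ``components`` maps term names ("adv", "mse", "kld", "mmd", "pnl") to
    Tensors (or floats). Supplying a KLD term under LiNGAM is an error —
    the non-Gaussian noise of that model admits no Gaussian prior.
    """
    a = Assumption(assumption)
    if a is Assumption.LINGAM and "kld" in components and weights.w_kld > 0:
        raise ValueError("KLD loss is not applicable under the LiNGAM assumption")
    if a is not Assumption.PNL and "pnl" in components and weights.w_pnl > 0:
        raise ValueError("PNL loss only applies under the PNL assumption")
    wmap = {"adv": weights.w_adv, "mse": weights.w_mse, "kld": weights.w_kld,
            "mmd": weights.w_mmd, "pnl": weights.w_pnl}
    unknown = set(components) - set(wmap)
    if unknown:
        raise ValueError(f"unknown loss components: {sorted(unknown)}")
    total = Tensor(0.0)
    bd = LossBreakdown()
    for name, term in components.items():
        t = ad.astensor(term)
        setattr(bd, name, t.item())
        total = total + wmap[name] * t
    bd.total = total.item()
    return total, bd
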