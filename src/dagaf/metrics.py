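"""Structure-recovery scoring and synthetic-data-quality diagnostics.

Structure scores use the directed-edge convention: SHD counts the edge
insertions, deletions and reversals turning the prediction into the
truth, a reversal costing 1; TPR/FDR/FPR are computed on directed edges,
so a reversed edge is simultaneously a false positive and a miss.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import BinaryDag


@dataclass(frozen=True)
class StructureScore:
    shd: int
    tpr: float
    fdr: float
    fpr: float
    n_true: int
    n_pred: int
    correct: int
    reversed_: int
    extra: int
    missing: int


def shd(pred: BinaryDag, truth: BinaryDag) -> StructureScore:
    """Structural Hamming distance and companion rates between two DAGs."""
    if pred.d != truth.d:
        raise ValueError(f"dimension mismatch: {pred.d} vs {truth.d}")
    P, T = pred.edges, truth.edges
    d = pred.d
    correct = int(np.sum((P == 1) & (T == 1)))
    rev = int(np.sum((P == 1) & (T == 0) & (T.T == 1) & (P.T == 0)))
    extra = int(np.sum((P == 1) & (T == 0))) - rev       # FP not explained by reversal
    missing = int(np.sum((P == 0) & (T == 1))) - rev     # FN not explained by reversal
    n_true = int(T.sum())
    n_pred = int(P.sum())
    fp = n_pred - correct  # directed convention: reversals count as discoveries
    fn = n_true - correct
    negatives = d * (d - 1) - n_true
    return StructureScore(
        shd=missing + extra + rev,
        tpr=correct / n_true if n_true else (1.0 if n_pred == 0 else 0.0),
        fdr=fp / n_pred if n_pred else 0.0,
        fpr=fp / negatives if negatives else 0.0,
        n_true=n_true, n_pred=n_pred, correct=correct,
        reversed_=rev, extra=extra, missing=missing,
    )


@dataclass
class QualityReport:
    """Diagnostics comparing a synthetic dataset with the real one."""

    corr_real: pd.DataFrame
    corr_synth: pd.DataFrame
    max_corr_discrepancy: float
    pca_scores: pd.DataFrame            # 2 components, labeled by origin
    marginals: dict                     # per-feature histogram overlays
    importance_real: pd.Series
    importance_synth: pd.Series

    def save(self, out_dir: "str | Path") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.corr_real.to_csv(out / "correlation_real.csv")
        self.corr_synth.to_csv(out / "correlation_synth.csv")
        self.pca_scores.to_csv(out / "pca_scores.csv", index=False)
        pd.DataFrame(
            {"real": self.importance_real, "synth": self.importance_synth}
        ).to_csv(out / "feature_importance.csv")
        rows = []
        for feat, (edges, h_real, h_synth) in self.marginals.items():
            for lo, hi, hr, hs in zip(edges[:-1], edges[1:], h_real, h_synth):
                rows.append((feat, lo, hi, hr, hs))
        pd.DataFrame(
            rows, columns=["feature", "bin_lo", "bin_hi", "density_real", "density_synth"]
        ).to_csv(out / "marginals.csv", index=False)
        self._figures(out)

    def _figures(self, out: Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, (title, corr) in zip(
            axes, [("real", self.corr_real), ("synthetic", self.corr_synth)]
        ):
            im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
            ax.set_title(f"correlation ({title})")
        fig.colorbar(im, ax=axes, shrink=0.8)
        fig.savefig(out / "correlations.png", dpi=110)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(5, 4))
        for origin, marker in (("real", "o"), ("synth", "x")):
            sub = self.pca_scores[self.pca_scores.origin == origin]
            ax.scatter(sub.pc1, sub.pc2, s=4, alpha=0.4, marker=marker, label=origin)
        ax.legend()
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.savefig(out / "pca.png", dpi=110)
        plt.close(fig)


def quality_report(
    real: np.ndarray,
    synth: np.ndarray,
    names=None,
    bins: int = 30,
    seed: int = 0,
) -> QualityReport:
    """Compare a synthetic dataset against the real one feature-by-feature.

    Produces both correlation matrices with their maximum absolute
    discrepancy, pooled 2-component PCA scores labeled by origin,
    per-feature histogram overlays, and per-feature importances from a
    seeded random-forest regressor predicting each column from the rest.
    """
    from sklearn.decomposition import PCA
    from sklearn.ensemble import RandomForestRegressor

    real = np.asarray(real, dtype=np.float64)
    synth = np.asarray(synth, dtype=np.float64)
    if real.ndim != 2 or synth.ndim != 2 or real.shape[1] != synth.shape[1]:
        raise ValueError("real and synth must be 2-D with matching column count")
    if real.shape[0] < 3 or synth.shape[0] < 3:
        raise ValueError("need at least 3 samples in each dataset")
    d = real.shape[1]
    names = list(names) if names is not None else [f"X{i}" for i in range(d)]

    corr_real = pd.DataFrame(np.corrcoef(real, rowvar=False), index=names, columns=names)
    corr_synth = pd.DataFrame(np.corrcoef(synth, rowvar=False), index=names, columns=names)
    max_disc = float(np.nanmax(np.abs(corr_real.to_numpy() - corr_synth.to_numpy())))

    pooled = np.vstack([real, synth])
    pca = PCA(n_components=2, random_state=seed)
    scores = pca.fit_transform(pooled)
    pca_scores = pd.DataFrame(scores, columns=["pc1", "pc2"])
    pca_scores["origin"] = ["real"] * len(real) + ["synth"] * len(synth)

    marginals = {}
    for i, name in enumerate(names):
        lo = min(real[:, i].min(), synth[:, i].min())
        hi = max(real[:, i].max(), synth[:, i].max())
        edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
        h_real, _ = np.histogram(real[:, i], bins=edges, density=True)
        h_synth, _ = np.histogram(synth[:, i], bins=edges, density=True)
        marginals[name] = (edges, h_real, h_synth)

    def _importance(X: np.ndarray) -> pd.Series:
        imp = np.zeros(d)
        for i in range(d):
            others = np.delete(np.arange(d), i)
            rf = RandomForestRegressor(
                n_estimators=30, max_depth=6, random_state=seed, n_jobs=1
            )
            rf.fit(X[:, others], X[:, i])
            imp[others] += rf.feature_importances_
        return pd.Series(imp / d, index=names)

    return QualityReport(
        corr_real=corr_real,
        corr_synth=corr_synth,
        max_corr_discrepancy=max_disc,
        pca_scores=pca_scores,
        marginals=marginals,
        importance_real=_importance(real),
        importance_synth=_importance(synth),
    )
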