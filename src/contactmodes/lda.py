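"""Fisher linear discriminant analysis on truncated PC scores.

LDA is used here as a coordinate transform, not a classifier: the rows of
the coefficient matrix C maximize between-class over within-class scatter
(generalized eigenproblem S_b w = lambda S_w w), giving LD scores
LD_l = sum_j PC_j * C_l^j.  Because each PC loading d^(k) is a unit vector
in contact space, the combination sum_k C_l^k d^(k) is the l-th LD loading
expressed in contact space, and can be rendered as a signed residue-residue
contact map (positive = contact formation in the class listed second,
negative = breaking) via the same back-mapping as the PCs.

Frames are treated as independent observations; autocorrelation in real
trajectories is not corrected for (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from contactmodes.pca import (
    PCABasis,
    ScoreMatrix,
    ContactDisplacementMap,
    loading_to_contact_map,
)

RIDGE_SCALE = 1e-6  # times trace(S_w)/k, applied only on numerical singularity


@dataclass
class ClassLabeling:
    """Per-frame class assignment for one labeled condition."""

    condition: str
    classes: list[str]
    assignment: np.ndarray  # (n_frames,) integer index into classes

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if len(self.classes) < 1:
            raise ValueError("need at least 1 class")
        counts = np.bincount(self.assignment, minlength=len(self.classes))
        if np.any(counts < 2):
            raise ValueError("every class needs at least 2 frames")

    @classmethod
    def from_labels(cls, condition: str, labels: list[str],
                    class_order: list[str] | None = None) -> "ClassLabeling":
        classes = class_order if class_order is not None else sorted(set(labels))
        index = {c: k for k, c in enumerate(classes)}
        return cls(condition=condition, classes=classes,
                   assignment=np.array([index[l] for l in labels]))


@dataclass
class LDAModel:
    C: np.ndarray                    # (n_discriminants, k) rows unit-norm
    n_discriminants: int
    class_means_on_LD: np.ndarray    # (n_classes, n_discriminants)
    condition: str
    classes: list[str]


@dataclass
class DensityEstimate:
    grid: np.ndarray
    densities: dict[str, np.ndarray]
    bandwidth: float


def _scatter_matrices(S: np.ndarray, y: np.ndarray, n_classes: int):
    overall = S.mean(axis=0)
    k = S.shape[1]
    Sw = np.zeros((k, k))
    Sb = np.zeros((k, k))
    for c in range(n_classes):
        Sc = S[y == c]
        mu = Sc.mean(axis=0)
        dev = Sc - mu
        Sw += dev.T @ dev
        dm = (mu - overall)[:, None]
        Sb += len(Sc) * (dm @ dm.T)
    return Sw, Sb


def fit_lda(scores: ScoreMatrix, labeling: ClassLabeling,
            n_discriminants: int | None = None) -> LDAModel:
    """Fisher LDA by the generalized eigenproblem S_b w = lambda S_w w.

    Rows of C are ordered by discriminative eigenvalue and normalized to
    unit length; the sign of each row is fixed so the class listed first in
    ``labeling.classes`` has the lower mean LD score on it.  A numerically
    singular within-class scatter is ridge-regularized with
    ``RIDGE_SCALE * trace(S_w)/k`` and a loud warning.
    """
    S = np.asarray(scores.scores, dtype=float)
    y = labeling.assignment
    if S.shape[0] != y.shape[0]:
        raise ValueError("scores and labeling cover different frame counts")
    n_classes = len(labeling.classes)
    if n_classes < 2:
        raise ValueError("discriminant analysis needs at least 2 classes")
    k = S.shape[1]
    if n_classes > k + 1:
        raise ValueError("more classes than PC dimensions + 1")
    max_ld = min(n_classes - 1, k)
    if n_discriminants is None:
        n_discriminants = max_ld
    if n_discriminants > max_ld:
        raise ValueError(f"at most {max_ld} discriminants available")

    Sw, Sb = _scatter_matrices(S, y, n_classes)
    eps = RIDGE_SCALE * np.trace(Sw) / k
    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError:
        warnings.warn(
            f"singular within-class scatter; ridge-regularizing with eps={eps:.3e}",
            stacklevel=2,
        )
        evals, evecs = scipy.linalg.eigh(Sb, Sw + eps * np.eye(k))
    order = np.argsort(evals)[::-1][:n_discriminants]
    C = evecs[:, order].T
    C /= np.linalg.norm(C, axis=1, keepdims=True)
    if not np.all(np.isfinite(C)):
        raise ValueError("non-finite discriminant coefficients")

    LD = S @ C.T
    class_means = np.stack([LD[y == c].mean(axis=0) for c in range(n_classes)])
    for l in range(n_discriminants):
        if class_means[0, l] > class_means[-1, l]:
            C[l] = -C[l]
            class_means[:, l] = -class_means[:, l]
    return LDAModel(C=C, n_discriminants=n_discriminants,
                    class_means_on_LD=class_means,
                    condition=labeling.condition, classes=list(labeling.classes))


def lda_scores(model: LDAModel, scores: ScoreMatrix) -> np.ndarray:
    """LD[f, l] = sum_j scores[f, j] * C_l^j."""
    S = np.asarray(scores.scores, dtype=float)
    if S.shape[1] != model.C.shape[1]:
        raise ValueError("score dimension does not match model coefficients")
    return S @ model.C.T


def ld_loading_in_contact_space(model: LDAModel, basis: PCABasis,
                                pair_index: list[tuple[int, int]],
                                n_residues: int, l: int = 1) -> ContactDisplacementMap:
    """Back-map LD loading l (1-based): sum_k C_l^k d^(k) as a signed map."""
    if not (1 <= l <= model.n_discriminants):
        raise ValueError("discriminant index out of range")
    k = model.C.shape[1]
    if k > basis.loadings.shape[1]:
        raise ValueError("model uses more PCs than the basis supplies")
    vec = basis.loadings[:, :k] @ model.C[l - 1]
    return loading_to_contact_map(vec, pair_index, n_residues,
                                  source=f"LD{l}_{model.condition}")


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        spread = max(abs(x).max(), 1.0) * 1e-3  # degenerate spike guard
    return 0.9 * spread * n ** (-1 / 5)


def class_score_density(ld_scores_1d: np.ndarray, labeling: ClassLabeling,
                        grid_size: int = 512) -> DensityEstimate:
    """Per-class Gaussian-kernel densities on a shared grid.

    The bandwidth is Silverman's rule on the pooled scores; the grid spans
    the pooled range padded by six bandwidths so each class density
    integrates to 1 within 1e-6 under the trapezoid rule.
    """
    x = np.asarray(ld_scores_1d, dtype=float).ravel()
    y = labeling.assignment
    if x.shape[0] != y.shape[0]:
        raise ValueError("scores and labeling cover different frame counts")
    h = _silverman_bandwidth(x)
    grid = np.linspace(x.min() - 6 * h, x.max() + 6 * h, grid_size)
    densities: dict[str, np.ndarray] = {}
    for c, name in enumerate(labeling.classes):
        xc = x[y == c]
        if xc.std() == 0:
            warnings.warn(f"class {name!r} has zero score variance "
                          "(degenerate spike)", stacklevel=2)
        z = (grid[:, None] - xc[None, :]) / h
        densities[name] = np.exp(-0.5 * z * z).sum(axis=1) / (
            xc.size * h * np.sqrt(2 * np.pi))
    return DensityEstimate(grid=grid, densities=densities, bandwidth=h)


def overlap_coefficient(density: DensityEstimate, class_a: str, class_b: str) -> float:
    """Integral of min(f_A, f_B) over the shared grid (trapezoid rule)."""
    fa, fb = density.densities[class_a], density.densities[class_b]
    if fa.shape != fb.shape:
        raise ValueError("density grids do not match")
    return float(np.trapezoid(np.minimum(fa, fb), density.grid))
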