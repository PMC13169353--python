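"""PCA over dynamic-contact coordinates.

The covariance matrix of the mean-centered frames × contacts binary matrix
is eigendecomposed; eigenvectors (loadings) are the principal components,
ordered by decreasing eigenvalue.  Frames from all conditions are pooled
and centered by the pooled mean, so for a mixture of ensembles the PCs are
collective contact coordinates rather than dynamic modes of any one run.

Scaled loadings follow the lambda convention (loading times its eigenvalue);
the more common sqrt-lambda amplitude scaling is available as an option.
Any loading or discriminant direction can be back-mapped to a signed
symmetric residue-residue contact-displacement map, where positive entries
mean contact formation along the coordinate and negative entries mean
contact breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from contactmodes.contacts import ContactTrajectory


@dataclass
class PCABasis:
    mean_vector: np.ndarray          # (D,)
    loadings: np.ndarray             # (D, D) column k = d^(k), orthonormal
    eigenvalues: np.ndarray          # (D,) non-increasing, >= 0
    D: int
    n_frames_fit: int


@dataclass
class ScoreMatrix:
    scores: np.ndarray               # (n_frames, k)
    basis_id: str = "pca"
    labels: list[dict[str, str]] | None = None


@dataclass
class ContactDisplacementMap:
    n_residues: int
    matrix: np.ndarray               # signed symmetric
    source: str = ""


def fit_contact_pca(ct: ContactTrajectory) -> PCABasis:
    """Eigendecompose the sample covariance (1/(N-1)) of the contact matrix.

    Sign convention: each loading is flipped so its largest-magnitude
    coefficient is positive.  Constant columns are allowed and contribute
    zero-eigenvalue directions.
    """
    X = np.asarray(ct.X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 frames to fit PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        col = evecs[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, k] = -col
    return PCABasis(mean_vector=mean, loadings=evecs, eigenvalues=evals,
                    D=X.shape[1], n_frames_fit=n)


def project_onto_pcs(ct: ContactTrajectory, basis: PCABasis, k: int) -> ScoreMatrix:
    """PC scores: score[f, i] = (X[f] - mean) . d^(i) for i = 1..k."""
    if ct.n_contacts != basis.D:
        raise ValueError("contact dimension does not match basis")
    if k > basis.loadings.shape[1]:
        raise ValueError("k exceeds number of loadings")
    Xc = np.asarray(ct.X, dtype=float) - basis.mean_vector
    return ScoreMatrix(scores=Xc @ basis.loadings[:, :k], labels=ct.labels)


def variance_explained(basis: PCABasis, k: int) -> float:
    """Fraction of total variance captured by the top k PCs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    total = basis.eigenvalues.sum()
    if total <= 0:
        raise ValueError("degenerate ensemble: all eigenvalues are zero")
    return float(basis.eigenvalues[:k].sum() / total)


def scaled_loading(basis: PCABasis, i: int, scale: str = "lambda") -> np.ndarray:
    """Loading i (1-based) scaled by its fluctuation amplitude.

    ``scale``: "lambda" multiplies by the eigenvalue (the printed
    convention), "sqrt-lambda" by its square root (the RMS-amplitude
    convention), "none" returns the unit loading.
    """
    if not (1 <= i <= basis.loadings.shape[1]):
        raise ValueError("loading index out of range")
    d = basis.loadings[:, i - 1]
    lam = basis.eigenvalues[i - 1]
    if scale == "lambda":
        return d * lam
    if scale == "sqrt-lambda":
        return d * np.sqrt(lam)
    if scale == "none":
        return d.copy()
    raise ValueError("scale must be one of lambda, sqrt-lambda, none")


def loading_to_contact_map(
    vector: np.ndarray,
    pair_index: list[tuple[int, int]],
    n_residues: int,
    source: str = "",
) -> ContactDisplacementMap:
    """Render a contact-space vector as a signed symmetric residue map."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(pair_index),):
        raise ValueError("vector length does not match pair index")
    M = np.zeros((n_residues, n_residues))
    for v, (i, j) in zip(vector, pair_index):
        M[i, j] = M[j, i] = v
    return ContactDisplacementMap(n_residues=n_residues, matrix=M, source=source)


def contact_map_to_vector(
    cmap: ContactDisplacementMap, pair_index: list[tuple[int, int]]
) -> np.ndarray:
    """Inverse of :func:`loading_to_contact_map` over the same pair index."""
    return np.array([cmap.matrix[i, j] for i, j in pair_index])
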