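"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as the dumbest possible reference: explicit
double loops, closed forms, or an algorithm different from the one in the
package (quaternion superposition vs Kabsch SVD, characteristic-polynomial
eigenvalues vs LAPACK).
"""

from __future__ import annotations

import numpy as np
import sympy


def brute_force_contacts(coords: np.ndarray, residue_index: np.ndarray,
                         cutoff: float, box: np.ndarray | None = None) -> np.ndarray:
    """All-pairs double-loop any-atom contact matrix."""
    n = int(residue_index.max()) + 1
    u = np.zeros((n, n), dtype=int)
    for i in range(n):
        ai = coords[residue_index == i]
        for j in range(i + 1, n):
            aj = coords[residue_index == j]
            best = np.inf
            for a in ai:
                for b in aj:
                    d = a - b
                    if box is not None:
                        d = d - box * np.round(d / box)
                    best = min(best, float(np.sqrt(np.sum(d * d))))
            u[i, j] = u[j, i] = int(best <= cutoff)
    return u


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Horn's closed-form quaternion superposition; returns the RMSD."""
    P = mobile - mobile.mean(axis=0)
    Q = reference - reference.mean(axis=0)
    Sxx = P.T @ Q
    K = np.zeros((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P * P) + np.sum(Q * Q) - 2 * lam) / len(P)
    return float(np.sqrt(max(msd, 0.0)))


def charpoly_eigenvalues(M: np.ndarray) -> np.ndarray:
    """Eigenvalues via the symbolic characteristic polynomial (D <= 6)."""
    sm = sympy.Matrix(M.tolist())
    poly = sm.charpoly()
    roots = [complex(r) for r in poly.nroots(n=30)]
    return np.sort(np.array([r.real for r in roots]))[::-1]


def gaussian_overlap(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Closed-form overlap coefficient of two equal-variance Gaussians."""
    from scipy.stats import norm
    assert sd1 == sd2
    return 2 * norm.cdf(-abs(mu2 - mu1) / (2 * sd1))
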