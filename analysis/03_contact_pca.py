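"""Contact PCA: eigen-spectrum, PC scores and back-mapped contact maps.

Fits PCA to the dynamic-contact trajectory from 02_contacts.py, reports the
variance captured by the eight dominant PCs and how well PC1 aligns with
the planted contact set, and writes the eigenvalue table, PC scores,
lambda-scaled PC1 contact map and its 3-D cylinder edge list under
results/pca/.
"""

from pathlib import Path

import numpy as np

from contactmodes import io as cio
from contactmodes import pca as cp
from contactmodes.cli import _load_contact_trajectory

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "pca"
K = 8


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    structure = cio.read_structure(ROOT / "synthetic" / "redox_structure.pdb")
    ct = _load_contact_trajectory(ROOT / "contacts")
    basis = cp.fit_contact_pca(ct)
    scores = cp.project_onto_pcs(ct, basis, K)

    frac = cp.variance_explained(basis, K)
    print(f"{ct.n_contacts} contact DOFs; top-{K} PCs explain "
          f"{100 * frac:.1f}% of the total variance")
    total = basis.eigenvalues.sum()
    cov_trace = np.asarray(ct.X, float).var(axis=0, ddof=1).sum()
    print(f"eigenvalue-sum / trace conservation: "
          f"{abs(total - cov_trace) / cov_trace:.2e} relative")

    truth_pairs, _, _ = cio.read_matrix(ROOT / "synthetic" / "redox_truth_pairs.tsv")
    planted = {(int(i) - 1, int(j) - 1) for i, j in truth_pairs.astype(int)[:12]}
    indicator = np.array([1.0 if p in planted else 0.0 for p in ct.pair_index])
    indicator /= np.linalg.norm(indicator)
    print(f"|cos(PC1, planted set)| = "
          f"{abs(basis.loadings[:, 0] @ indicator):.4f}")

    cio.write_matrix(np.column_stack([basis.eigenvalues,
                                      np.cumsum(basis.eigenvalues) / total]),
                     [f"PC{i + 1}" for i in range(basis.D)],
                     ["eigenvalue", "cumulative_variance_fraction"],
                     OUT / "eigenvalues.tsv")
    cio.write_matrix(scores.scores, list(range(scores.scores.shape[0])),
                     [f"PC{i + 1}" for i in range(K)], OUT / "pc_scores.tsv")
    cmap = cp.loading_to_contact_map(cp.scaled_loading(basis, 1, "lambda"),
                                     ct.pair_index, structure.n_residues, "PC1")
    res_labels = list(range(1, structure.n_residues + 1))
    cio.write_matrix(cmap.matrix, res_labels, res_labels,
                     OUT / "pc1_contact_map.tsv")
    cio.export_cylinder_edges(cmap, structure, OUT / "pc1_edges.tsv")


if __name__ == "__main__":
    main()
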