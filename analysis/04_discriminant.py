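"""Supervised discrimination of labeled conditions over PC scores.

Two analyses:

1. Redox contrast (from the persisted ensemble): Fisher LDA on the top-8
   PC scores separates wild-type from analog frames; reports the LD1
   class-density overlap and the fraction of the LD1 contact map's squared
   mass carried by the planted redox-sensitive contacts, and writes the
   coefficient matrix, LD scores, class densities and the signed LD1
   contact map under results/lda/.
2. Membrane-style three-class ensemble (generated in memory): one
   composition differs along the planted contacts while the other two are
   statistically identical, so LDA returns two discriminants of which only
   LD1 separates anything -- the planted "indistinguishable" pair stays
   overlapped on LD2.
"""

from pathlib import Path

import numpy as np

from contactmodes import contacts as cd
from contactmodes import io as cio
from contactmodes import lda as cl
from contactmodes import pca as cp
from contactmodes import synth
from contactmodes.cli import _load_contact_trajectory
from contactmodes.pca import contact_map_to_vector

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "lda"
K = 8


def redox() -> None:
    structure = cio.read_structure(ROOT / "synthetic" / "redox_structure.pdb")
    ct = _load_contact_trajectory(ROOT / "contacts")
    manifest = cio.read_label_manifest(ROOT / "synthetic" / "redox_frame_labels.tsv")
    labels = [manifest[str(f)]["redox"] for _, f in ct.frame_ids]
    labeling = cl.ClassLabeling.from_labels("redox", labels,
                                            class_order=["wild_type", "analog"])
    basis = cp.fit_contact_pca(ct)
    scores = cp.project_onto_pcs(ct, basis, K)
    model = cl.fit_lda(scores, labeling)
    LD = cl.lda_scores(model, scores)
    dens = cl.class_score_density(LD[:, 0], labeling)
    ovl = cl.overlap_coefficient(dens, "wild_type", "analog")

    truth_pairs, _, _ = cio.read_matrix(ROOT / "synthetic" / "redox_truth_pairs.tsv")
    planted = {(int(i) - 1, int(j) - 1) for i, j in truth_pairs.astype(int)[:12]}
    cmap = cl.ld_loading_in_contact_space(model, basis, ct.pair_index,
                                          structure.n_residues, 1)
    vec = contact_map_to_vector(cmap, ct.pair_index)
    mass = sum(v * v for v, p in zip(vec, ct.pair_index) if p in planted)
    print(f"redox: LD1 overlap = {ovl:.4f}; planted-set share of LD1 map "
          f"mass = {mass / np.sum(vec ** 2):.3f}")
    signs = {np.sign(cmap.matrix[p]) for p in planted}
    print(f"redox: planted entries share one sign = {len(signs) == 1} "
          "(negative = contacts broken going wild-type -> analog)")

    cio.write_matrix(model.C, ["LD1"], [f"PC{j + 1}" for j in range(K)],
                     OUT / "redox_coefficients.tsv")
    cio.write_matrix(LD, labels, ["LD1"], OUT / "redox_ld_scores.tsv")
    cio.write_matrix(np.column_stack([dens.grid, dens.densities["wild_type"],
                                      dens.densities["analog"]]),
                     list(range(dens.grid.size)),
                     ["grid", "wild_type", "analog"],
                     OUT / "redox_ld1_density.tsv")
    res_labels = list(range(1, structure.n_residues + 1))
    cio.write_matrix(cmap.matrix, res_labels, res_labels,
                     OUT / "redox_ld1_contact_map.tsv")
    cio.export_cylinder_edges(cmap, structure, OUT / "redox_ld1_edges.tsv")


def membrane_three_class() -> None:
    pairs = [(2 * k, 2 * k + 1) for k in range(12)]
    spec = synth.SyntheticEnsembleSpec(
        n_residues=45, atoms_per_residue=2, n_frames=0,
        modes=[([p], {"gpos": 0.8, "gneg": 0.2, "mixed": 0.2}) for p in pairs],
        flip_noise=0.01, n_background_pairs=8,
        class_frames={"gpos": 800, "gneg": 800, "mixed": 800}, seed=77)
    ens, labeling, truth = synth.generate_switching_ensemble(spec)
    states = [cd.compute_contact_state(f.coordinates, ens.structure, 4.2,
                                       box=f.box) for f in ens.frames]
    ct = cd.build_contact_trajectory(
        states, cd.select_dynamic_contacts(cd.compute_mean_contact_matrix(states)))
    basis = cp.fit_contact_pca(ct)
    scores = cp.project_onto_pcs(ct, basis, K)
    model = cl.fit_lda(scores, labeling)
    LD = cl.lda_scores(model, scores)
    d1 = cl.class_score_density(LD[:, 0], labeling)
    d2 = cl.class_score_density(LD[:, 1], labeling)
    print(f"membrane: {model.n_discriminants} discriminants for 3 classes")
    print(f"membrane: LD1 gpos-vs-gneg overlap = "
          f"{cl.overlap_coefficient(d1, 'gpos', 'gneg'):.4f} (separated)")
    print(f"membrane: LD2 gneg-vs-mixed overlap = "
          f"{cl.overlap_coefficient(d2, 'gneg', 'mixed'):.4f} "
          "(planted indistinguishable)")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    redox()
    membrane_three_class()


if __name__ == "__main__":
    main()
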