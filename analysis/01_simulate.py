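"""Generate the synthetic labeled ensembles and membrane fixtures.

Writes a redox-style two-class contact-switching ensemble (wild-type vs
reduced-analog contrast: 12 planted contacts occupied 90% vs 10% of the
time, plus background nuisance contacts and 1% flip noise) to
results/synthetic/ as a multi-model PDB with per-frame labels and ground
truth, together with the slab-crossing world, the hydrogen-bond triad
fixture and the lipid-shell fixture used by the later drivers.
"""

from pathlib import Path

import numpy as np

from contactmodes import io as cio
from contactmodes import synth

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 2026

REDOX_PAIRS = [(2 * k, 2 * k + 1) for k in range(12)]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = synth.SyntheticEnsembleSpec(
        n_residues=45, atoms_per_residue=2, n_frames=0,
        modes=[([p], {"wild_type": 0.9, "analog": 0.1}) for p in REDOX_PAIRS],
        flip_noise=0.01, n_background_pairs=8,
        class_frames={"wild_type": 1000, "analog": 1000}, seed=SEED)
    ens, labeling, truth = synth.generate_switching_ensemble(spec)
    cio.write_multimodel_pdb(ens, OUT / "redox_ensemble.pdb")
    cio.write_structure_pdb(ens.structure, OUT / "redox_structure.pdb",
                            box=ens.frames[0].box)
    cio.write_label_manifest(
        {str(f): {"redox": c} for f, c in enumerate(truth.frame_classes)},
        OUT / "redox_frame_labels.tsv")
    cio.write_matrix(np.array([[i + 1, j + 1] for i, j in truth.all_pairs]),
                     list(range(len(truth.all_pairs))), ["res_i", "res_j"],
                     OUT / "redox_truth_pairs.tsv",
                     comment="first 12 rows are the planted redox-sensitive "
                             "contacts, the rest background")
    print(f"redox ensemble: {ens.n_frames} frames, "
          f"{len(truth.all_pairs)} dynamic pairs "
          f"({len(REDOX_PAIRS)} planted, {spec.n_background_pairs} background)")

    wrapped, boxes, slab_truth = synth.generate_slab_world(
        n_particles=500, n_frames=400, box_z=60.0, slab=(22.0, 38.0),
        drift=0.3, diffusion=1.5, seed=SEED + 1)
    cio.write_matrix(wrapped, list(range(wrapped.shape[0])),
                     list(range(wrapped.shape[1])), OUT / "slab_wrapped_z.tsv")
    with open(OUT / "slab_truth_crossings.tsv", "w") as fh:
        fh.write("particle\tstart_frame\tend_frame\tdirection\n")
        for e in slab_truth.crossing_events:
            fh.write(f"{e.particle_id}\t{e.start_frame}\t{e.end_frame}\t"
                     f"{e.direction:+d}\n")
    print(f"slab world: 500 walkers, 400 frames, "
          f"{len(slab_truth.crossing_events)} true membrane crossings")

    coords, crit, hb_truth = synth.generate_hbond_fixture(
        n_triads=50, satisfied_fraction=0.4, seed=SEED + 2)
    cio.write_matrix(coords, list(range(len(coords))), ["x", "y", "z"],
                     OUT / "hbond_coordinates.tsv")
    print(f"hbond fixture: 50 triads, {len(hb_truth.satisfying_triads)} "
          "satisfy the 3.5 Å / 20° criteria by construction")

    markers, prot, lp_truth = synth.generate_lipid_shell_fixture(
        n_markers=20000, enrichment_factor=3.0, inner_radius=10.0,
        box=80.0, seed=SEED + 3)
    cio.write_matrix(markers, list(range(len(markers))), ["x", "y", "z"],
                     OUT / "lipid_markers.tsv")
    print(f"lipid fixture: {len(markers)} markers kept, planted 3x "
          "enrichment within 10 Å of the protein")


if __name__ == "__main__":
    main()
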