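"""Reading structures/trajectories and writing analysis products.

Parsing of PDB/GRO structures and DCD/XTC/multi-model-PDB trajectories is
delegated to MDAnalysis; this module converts to/from the plain containers
in :mod:`contactmodes.structure` and owns the delimited-text products
(matrices, label manifests, cylinder edge lists).

Conventions: all written residue indices are 1-based (internal storage is
0-based; conversion happens only here).  Delimited output is tab-separated
with '#'-prefixed header lines and 12-significant-digit floats; read-back
equals the original to that precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

from contactmodes.pca import ContactDisplacementMap
from contactmodes.structure import (
    Atom,
    Frame,
    StructureModel,
    TrajectoryEnsemble,
)

PS_PER_NS = 1000.0


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _structure_from_universe(u: "mda.Universe") -> StructureModel:
    if u.atoms.n_atoms == 0:
        raise ValueError("structure file contains zero atoms")
    try:
        chain_ids = u.atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chain_ids = u.atoms.segids
    try:
        elements = u.atoms.elements
    except (AttributeError, mda.exceptions.NoDataError):
        elements = [_guess_element(n) for n in u.atoms.names]
    # global 0-based residue ordinal over file order (chains concatenated)
    resi = u.atoms.resindices
    atoms = [
        Atom(atom_id=int(u.atoms.ids[k]), atom_name=str(u.atoms.names[k]),
             element=str(elements[k]), residue_index=int(resi[k]),
             residue_name=str(u.atoms.resnames[k]),
             chain_id=str(chain_ids[k]))
        for k in range(u.atoms.n_atoms)
    ]
    return StructureModel(atoms=atoms,
                          reference_coordinates=u.atoms.positions.astype(float))


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or GRO structure file into a :class:`StructureModel`.

    Atoms are kept in file order; residue indices are 0-based ordinals with
    chains concatenated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path), format=format)
    except ValueError as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    return _structure_from_universe(u)


def read_trajectory(structure: StructureModel, path: str | Path,
                    format: str | None = None, stride: int = 1,
                    stride_ns: float | None = None,
                    topology: str | Path | None = None,
                    require_box: bool = True) -> TrajectoryEnsemble:
    """Read DCD/XTC/multi-model-PDB frames, keeping every ``stride``-th one.

    Frame times are carried through from the file (ps converted to ns) when
    present, else synthesized from ``stride_ns``.  ``topology`` supplies
    the topology file for binary trajectory formats; a multi-model PDB is
    self-describing.
    """
    if stride < 1:
        raise ValueError("stride must be a positive integer")
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology is not None:
            u = mda.Universe(str(topology), str(path), format=format)
        else:
            u = mda.Universe(str(path), format=format)
    if u.atoms.n_atoms != structure.n_atoms:
        raise ValueError(
            f"topology mismatch: trajectory has {u.atoms.n_atoms} atoms, "
            f"structure has {structure.n_atoms}")
    frames: list[Frame] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # readers without dt metadata warn
        for k, ts in enumerate(u.trajectory):
            if k % stride:
                continue
            box = None
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                box = ts.dimensions[:3].astype(float)
            if box is None and require_box:
                raise ValueError("frame has no periodic box; pass "
                                 "require_box=False for non-periodic data")
            t_ns = (ts.time / PS_PER_NS if np.isfinite(ts.time) and ts.time > 0
                    else None)
            frames.append(Frame(coordinates=ts.positions.astype(float), box=box,
                                time=t_ns if t_ns is not None else 0.0))
    times = [f.time for f in frames]
    if stride_ns is not None or any(t2 <= t1 for t1, t2 in zip(times, times[1:])) \
            or (len(times) > 1 and times[0] == times[1] == 0.0):
        dt = stride_ns if stride_ns is not None else 1.0
        for k, f in enumerate(frames):
            f.time = dt * (k + 1)
    return TrajectoryEnsemble(structure=structure, frames=frames)


def write_multimodel_pdb(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB (the text trajectory dialect)."""
    path = Path(path)
    s = traj.structure
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.frames, start=1):
            if frame.box is not None:
                fh.write("CRYST1%9.3f%9.3f%9.3f  90.00  90.00  90.00 P 1           1\n"
                         % tuple(frame.box))
            fh.write(f"MODEL     {m:4d}\n")
            for k, a in enumerate(s.atoms):
                x, y, z = frame.coordinates[k]
                name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
                fh.write(
                    "ATOM  %5d %-4s %3s %1s%4d    %8.3f%8.3f%8.3f  1.00  0.00          %2s\n"
                    % (a.atom_id % 100000, name, a.residue_name[:3],
                       (a.chain_id or "A")[:1], (a.residue_index + 1) % 10000,
                       x, y, z, a.element[:2]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_structure_pdb(structure: StructureModel, path: str | Path,
                        box: np.ndarray | None = None) -> None:
    frame = Frame(coordinates=structure.reference_coordinates,
                  box=box, time=1.0)
    write_multimodel_pdb(TrajectoryEnsemble(structure=structure, frames=[frame]),
                         path)


def write_gro(structure: StructureModel, path: str | Path,
              box: np.ndarray | None = None) -> None:
    """Write the reference coordinates as a GRO file (nm units)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("synthetic structure\n")
        fh.write(f"{structure.n_atoms:5d}\n")
        for k, a in enumerate(structure.atoms):
            x, y, z = structure.reference_coordinates[k] / 10.0  # Å -> nm
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
                     % ((a.residue_index + 1) % 100000, a.residue_name[:5],
                        a.atom_name[:5], a.atom_id % 100000, x, y, z))
        b = (box / 10.0) if box is not None else np.zeros(3)
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(b))


def read_label_manifest(path: str | Path) -> dict[str, dict[str, str]]:
    """Map trajectory-id -> {condition -> class label} from a TSV manifest.

    The first column is the trajectory id; remaining header columns name
    the conditions.  Duplicate ids and missing cells are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("manifest needs an id column and >= 1 condition column")
    id_col = df.columns[0]
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate trajectory id {dup!r} in manifest")
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)].tolist()
        raise ValueError(f"missing label cell(s) in manifest rows {rows}")
    return {
        row[id_col]: {c: row[c] for c in df.columns[1:]}
        for _, row in df.iterrows()
    }


def write_label_manifest(labels: dict[str, dict[str, str]], path: str | Path) -> None:
    conditions = sorted({c for v in labels.values() for c in v})
    with open(path, "w") as fh:
        fh.write("trajectory_id\t" + "\t".join(conditions) + "\n")
        for tid, lab in labels.items():
            fh.write(tid + "\t" + "\t".join(lab[c] for c in conditions) + "\n")


def write_matrix(matrix: np.ndarray, row_labels: list, col_labels: list,
                 path: str | Path, allow_nan: bool = False,
                 comment: str | None = None) -> None:
    """Write a labeled 2-D array as TSV with 12-significant-digit floats."""
    M = np.asarray(matrix)
    if M.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if len(row_labels) != M.shape[0] or len(col_labels) != M.shape[1]:
        raise ValueError("label lengths do not match matrix dimensions")
    if not allow_nan and np.isnan(M.astype(float)).any():
        raise ValueError("matrix contains NaN entries (pass allow_nan=True "
                         "to permit them)")
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# rows x cols: %d x %d\n" % M.shape)
        fh.write("\t" + "\t".join(str(c) for c in col_labels) + "\n")
        for r in range(M.shape[0]):
            fh.write(str(row_labels[r]) + "\t"
                     + "\t".join("%.12g" % v for v in M[r]) + "\n")


def read_matrix(path: str | Path):
    """Read back a :func:`write_matrix` product -> (matrix, rows, cols)."""
    rows, data = [], []
    with open(path) as fh:
        header = None
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.rstrip("\n").split("\t")[1:]
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append(parts[0])
            data.append([float(v) for v in parts[1:]])
    return np.array(data), rows, header


def export_cylinder_edges(cmap: ContactDisplacementMap,
                          structure: StructureModel, path: str | Path) -> None:
    """Write nonzero contact-map pairs as 3-D cylinder endpoints.

    One record per pair (i < j): 1-based residue indices, representative-
    atom coordinates of each residue (alpha-carbon when present, else the
    residue geometric center) and the signed weight.  Negative weights mean
    breaking of contacts, positive weights formation.
    """
    if cmap.n_residues != structure.n_residues:
        raise ValueError("contact map dimension does not match residue count")
    reps = _representative_coordinates(structure)
    with open(path, "w") as fh:
        fh.write("# signed contact-map edges; negative = breaking, "
                 "positive = formation\n")
        fh.write("res_i\tres_j\txi\tyi\tzi\txj\tyj\tzj\tweight\n")
        n = cmap.n_residues
        for i in range(n):
            for j in range(i + 1, n):
                w = cmap.matrix[i, j]
                if w == 0:
                    continue
                xi, yi, zi = reps[i]
                xj, yj, zj = reps[j]
                fh.write("%d\t%d\t%.12g\t%.12g\t%.12g\t%.12g\t%.12g\t%.12g\t%.12g\n"
                         % (i + 1, j + 1, xi, yi, zi, xj, yj, zj, w))


def read_cylinder_edges(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _representative_coordinates(structure: StructureModel) -> np.ndarray:
    reps = np.zeros((structure.n_residues, 3))
    res = structure.residue_indices
    xyz = structure.reference_coordinates
    for r in range(structure.n_residues):
        mask = res == r
        names = [a.atom_name for a, m in zip(structure.atoms, mask) if m]
        if "CA" in names:
            k = np.flatnonzero(mask)[names.index("CA")]
            reps[r] = xyz[k]
        else:
            reps[r] = xyz[mask].mean(axis=0)
    return reps
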