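"""In-memory structure and trajectory containers.

These are deliberately plain containers: parsing of the standard formats
(PDB, GRO, DCD, XTC) is delegated to MDAnalysis in :mod:`contactmodes.io`;
everything downstream works on the arrays stored here.

Residue indices are 0-based ordinals over file order (chains concatenated,
so a two-chain 45+45-residue dimer occupies residues 0..89 and inter-chain
contacts land in the off-diagonal block).  Conversion to the 1-based
numbering used in written outputs happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Formal side-chain charges at neutral pH used for net-charge bookkeeping.
SIDECHAIN_CHARGE = {"ARG": 1, "LYS": 1, "ASP": -1, "GLU": -1, "HIS": 0}

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Mature human beta-defensin 3 peptide sequence, 45 residues, net formal
#: side-chain charge +11e.
HBD3_SEQUENCE = "GIINTLQKYYCRVRGGRCAVLSCLPKEEQIGKCSTRGRKCCRRKK"


@dataclass
class Atom:
    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str


@dataclass
class StructureModel:
    """Atoms plus reference coordinates (Å)."""

    atoms: list[Atom]
    reference_coordinates: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self) -> None:
        self.reference_coordinates = np.asarray(self.reference_coordinates, dtype=float)
        if len(self.atoms) == 0:
            raise ValueError("structure has zero atoms")
        if self.reference_coordinates.shape != (len(self.atoms), 3):
            raise ValueError("reference_coordinates shape does not match atom count")
        if not np.all(np.isfinite(self.reference_coordinates)):
            raise ValueError("non-finite reference coordinates")
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_id values are not unique")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> np.ndarray:
        """Per-atom 0-based residue ordinal."""
        return np.array([a.residue_index for a in self.atoms], dtype=int)

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices.max()) + 1

    def residue_names(self) -> list[str]:
        """One name per residue, in residue-ordinal order."""
        names: dict[int, str] = {}
        for a in self.atoms:
            names.setdefault(a.residue_index, a.residue_name)
        return [names[i] for i in range(self.n_residues)]

    def atom_selection(self, atom_names: set[str] | None = None,
                       chain_id: str | None = None,
                       residue_names: set[str] | None = None) -> np.ndarray:
        """Boolean mask over atoms matching simple name/chain filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for k, a in enumerate(self.atoms):
            if atom_names is not None and a.atom_name not in atom_names:
                mask[k] = False
            elif chain_id is not None and a.chain_id != chain_id:
                mask[k] = False
            elif residue_names is not None and a.residue_name not in residue_names:
                mask[k] = False
        return mask


def formal_sidechain_charge(structure: StructureModel) -> int:
    """Sum of formal side-chain charges (Arg, Lys = +1; Asp, Glu = -1; His = 0)."""
    return sum(SIDECHAIN_CHARGE.get(name, 0) for name in structure.residue_names())


@dataclass
class Frame:
    coordinates: np.ndarray  # (n_atoms, 3) Å
    box: np.ndarray | None   # 3 orthorhombic edge lengths, Å
    time: float              # ns

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be 3 positive edge lengths")


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of atom coordinates plus per-frame periodic box."""

    structure: StructureModel
    frames: list[Frame]
    stride_ns: float = field(default=0.0)

    def __post_init__(self) -> None:
        n = self.structure.n_atoms
        for f in self.frames:
            if f.coordinates.shape != (n, 3):
                raise ValueError("frame atom count does not match structure")
        times = [f.time for f in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")
        if self.stride_ns == 0.0 and len(times) >= 2:
            diffs = np.diff(times)
            self.stride_ns = float(np.median(diffs))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coordinates(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) array."""
        return np.stack([f.coordinates for f in self.frames])

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def parse_selection(structure: StructureModel, expression: str) -> np.ndarray:
    """Atom indices matching a simple selection expression.

    Grammar: clauses joined by ``and``; each clause is one of
    ``name N1,N2,...``, ``resname R1,...``, ``chain C1,...``, or
    ``resid a-b`` (1-based inclusive residue ordinals).  ``all`` selects
    every atom.
    """
    expr = expression.strip()
    mask = np.ones(structure.n_atoms, dtype=bool)
    if expr == "all":
        return np.flatnonzero(mask)
    for clause in expr.split(" and "):
        parts = clause.split()
        if len(parts) != 2:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        key, val = parts
        if key == "name":
            allowed = set(val.split(","))
            sub = np.array([a.atom_name in allowed for a in structure.atoms])
        elif key == "resname":
            allowed = set(val.split(","))
            sub = np.array([a.residue_name in allowed for a in structure.atoms])
        elif key == "chain":
            allowed = set(val.split(","))
            sub = np.array([a.chain_id in allowed for a in structure.atoms])
        elif key == "resid":
            lo, _, hi = val.partition("-")
            lo_i = int(lo) - 1
            hi_i = int(hi) - 1 if hi else lo_i
            sub = np.array([lo_i <= a.residue_index <= hi_i
                            for a in structure.atoms])
        else:
            raise ValueError(f"unknown selection keyword {key!r}")
        mask &= sub
    return np.flatnonzero(mask)


def synthetic_hbd3_ca_model(sequence: str = HBD3_SEQUENCE) -> StructureModel:
    """Synthetic alpha-carbon trace carrying the mature hBD-3 sequence.

    The backbone geometry is an idealized helix-like curve with ~3.8 Å
    consecutive-CA spacing; it is a synthetic stand-in for the experimental
    coordinates and is suitable only for sequence-level bookkeeping
    (residue counting, formal-charge sums) and I/O round-trip exercises.
    """
    n = len(sequence)
    t = np.arange(n)
    # generic polyproline-like spiral, ~3.8 Å rise+turn per residue
    coords = np.stack([
        4.5 * np.cos(2 * np.pi * t / 3.6),
        4.5 * np.sin(2 * np.pi * t / 3.6),
        1.5 * t,
    ], axis=1)
    atoms = [
        Atom(atom_id=i + 1, atom_name="CA", element="C", residue_index=i,
             residue_name=THREE_LETTER[aa], chain_id="A")
        for i, aa in enumerate(sequence)
    ]
    return StructureModel(atoms=atoms, reference_coordinates=coords)
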