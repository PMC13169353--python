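"""Per-frame residue-residue contact states and dynamic-contact selection.

A contact u_ij between residues i and j is formed (u_ij = 1) when any atom
of residue i lies within the distance cutoff (default 4.2 Å) of any atom of
residue j, and 0 otherwise.  Averaging over frames gives the mean contact
matrix <u>; pairs whose mean contact frequency is not strictly between the
lower and upper bounds (default 0.1 and 0.9) are considered static and
excluded.  The surviving dynamic pairs form the contact degrees of freedom
fed to PCA.

Boundary convention: contacts formed in *more than* 90% or *less than* 10%
of the frames are static, so a mean frequency exactly equal to a bound is
excluded from the dynamic set (strict inequalities).  No sequence-separation
exclusion is applied: covalently adjacent pairs have <u> near 1 and are
removed by the static filter anyway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from contactmodes.structure import StructureModel


@dataclass
class ContactState:
    """Symmetric binary contact matrix for one frame (diagonal defined 0)."""

    n_residues: int
    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if self.u.shape != (self.n_residues, self.n_residues):
            raise ValueError("contact matrix shape mismatch")


@dataclass
class MeanContactMatrix:
    n_residues: int
    mean_u: np.ndarray
    n_frames: int


@dataclass
class ContactTrajectory:
    """frames × dynamic-contacts binary matrix with its pair index list."""

    pair_index: list[tuple[int, int]]
    X: np.ndarray
    frame_ids: list[tuple[str, int]] = field(default_factory=list)
    labels: list[dict[str, str]] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.pair_index):
            raise ValueError("X columns must match pair_index length")

    @property
    def n_frames(self) -> int:
        return self.X.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.X.shape[1]


def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def _residue_blocks(structure: StructureModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Atom order sorted by residue, plus reduceat start offsets."""
    res = structure.residue_indices
    order = np.argsort(res, kind="stable")
    sorted_res = res[order]
    starts = np.searchsorted(sorted_res, np.arange(structure.n_residues))
    return order, starts, sorted_res


def compute_contact_state(
    coordinates: np.ndarray,
    structure: StructureModel,
    cutoff_A: float = 4.2,
    box: np.ndarray | None = None,
) -> ContactState:
    """Binary any-atom contact matrix of one frame.

    u[i, j] = 1 iff the minimum over atom pairs (a in residue i, b in
    residue j) of ||r_a - r_b|| is <= cutoff_A.  With ``box`` given,
    distances use the minimum-image convention under an orthorhombic box.
    All pairs i < j are evaluated; there is no sequence-separation
    exclusion.
    """
    if cutoff_A <= 0:
        raise ValueError("cutoff must be positive")
    coordinates = np.asarray(coordinates, dtype=float)
    if not np.all(np.isfinite(coordinates)):
        raise ValueError("non-finite coordinates")
    n_res = structure.n_residues
    if n_res == 0:
        raise ValueError("structure has zero residues")
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(box < 2 * cutoff_A):
            warnings.warn(
                "box edge smaller than twice the contact cutoff: "
                "minimum-image distances may be ambiguous",
                stacklevel=2,
            )

    order, starts, _ = _residue_blocks(structure)
    xyz = coordinates[order]
    diff = xyz[:, None, :] - xyz[None, :, :]
    if box is not None:
        diff = _min_image(diff, box)
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    # two-stage block-min: atoms -> residues along each axis
    m = np.minimum.reduceat(d2, starts, axis=0)
    m = np.minimum.reduceat(m, starts, axis=1)
    u = (m <= cutoff_A * cutoff_A).astype(np.int8)
    np.fill_diagonal(u, 0)
    return ContactState(n_residues=n_res, u=u)


def compute_mean_contact_matrix(states: list[ContactState]) -> MeanContactMatrix:
    """Elementwise average of contact states over frames."""
    if len(states) == 0:
        raise ValueError("need at least one contact state")
    n = states[0].n_residues
    if any(s.n_residues != n for s in states):
        raise ValueError("mixed residue counts")
    mean_u = np.mean([s.u for s in states], axis=0)
    return MeanContactMatrix(n_residues=n, mean_u=mean_u, n_frames=len(states))


def select_dynamic_contacts(
    mean: MeanContactMatrix, u_low: float = 0.1, u_high: float = 0.9
) -> list[tuple[int, int]]:
    """Pairs (i < j) with u_low < <u>_ij < u_high, sorted lexicographically.

    Boundary values are excluded: a pair formed in exactly 90% of frames is
    static under the "more than / less than" wording.
    """
    if not (0 <= u_low < u_high <= 1):
        raise ValueError("require 0 <= u_low < u_high <= 1")
    iu, ju = np.triu_indices(mean.n_residues, k=1)
    vals = mean.mean_u[iu, ju]
    keep = (vals > u_low) & (vals < u_high)
    return [(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])]


def build_contact_trajectory(
    states: list[ContactState],
    pair_index: list[tuple[int, int]],
    frame_ids: list[tuple[str, int]] | None = None,
    labels: list[dict[str, str]] | None = None,
) -> ContactTrajectory:
    """Assemble the frames × dynamic-contacts binary matrix."""
    if len(pair_index) == 0:
        raise ValueError(
            "empty dynamic pair list; widen the (u_low, u_high) bounds"
        )
    rows = np.array([p[0] for p in pair_index])
    cols = np.array([p[1] for p in pair_index])
    X = np.stack([s.u[rows, cols] for s in states]).astype(np.int8)
    if frame_ids is None:
        frame_ids = [("traj", k) for k in range(len(states))]
    if labels is not None and len(labels) != len(states):
        raise ValueError("labels must align with frames")
    return ContactTrajectory(pair_index=list(pair_index), X=X,
                             frame_ids=frame_ids, labels=labels)
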