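"""Ground-truthed synthetic inputs for every pipeline stage.

Four generators, all seed-deterministic:

* :func:`generate_switching_ensemble` — bead-resolution conformational
  ensembles whose residue-residue contacts toggle collectively under a
  small number of latent modes with class-dependent occupancies, plus
  background nuisance contacts and independent flip noise.  Contacts are
  planted *geometrically* (bead distances), so the distance kernel, cutoff
  logic and the PCA/LDA chain are exercised end to end.
* :func:`generate_slab_world` — solvated-membrane stand-in: biased random
  walkers whose continuous paths (and hence true crossing events) are
  constructed first and wrapped into the box second.
* :func:`generate_hbond_fixture` — donor-hydrogen-acceptor triads placed to
  satisfy or violate the distance/angle criteria exactly as planned.
* :func:`generate_lipid_shell_fixture` — marker positions with a controlled
  radial enrichment around a central protein bead.

No force field, thermostat or lipid chemistry is emulated — only the
statistical and geometric structure the analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from contactmodes.structure import Atom, Frame, StructureModel, TrajectoryEnsemble
from contactmodes.lda import ClassLabeling
from contactmodes.membrane import CrossingEvent, HBondCriteria, count_crossings

CONTACT_DISTANCE = 3.8   # Å nearest-atom distance when a planted contact is formed
BROKEN_DISTANCE = 8.0    # Å when broken; both sit on opposite sides of the 4.2 cutoff
ATOM_JITTER = 0.12       # Å max bead offset within a residue cluster


@dataclass
class SyntheticEnsembleSpec:
    """Layout of a contact-switching ensemble.

    ``modes`` maps each latent mode to its residue-pair contact set and a
    per-class occupancy; all planted pairs and background pairs must be
    residue-disjoint so each pair can toggle geometrically without moving
    any residue shared with another pair.
    """

    n_residues: int = 40
    atoms_per_residue: int = 3
    n_frames: int = 5000
    modes: list[tuple[list[tuple[int, int]], dict[str, float]]] = field(default_factory=list)
    flip_noise: float = 0.0
    n_background_pairs: int = 0
    conditions: dict[str, str] | None = None   # condition -> class per frame-block label
    class_frames: dict[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.flip_noise < 0.5):
            raise ValueError("flip_noise must be in [0, 0.5)")
        used: set[int] = set()
        for pairs, occ in self.modes:
            for i, j in pairs:
                if not (0 <= i < j < self.n_residues):
                    raise ValueError("planted pair out of range or unordered")
                if i in used or j in used:
                    raise ValueError(
                        "planted/background pairs must be residue-disjoint")
                used.update((i, j))
            for p in occ.values():
                if not (0 < p < 1):
                    raise ValueError("occupancies must lie in (0, 1)")
        self._used_residues = used


@dataclass
class GroundTruth:
    """Everything needed to recompute expected test values."""

    mode_states: np.ndarray | None = None          # (n_frames, n_modes) latent 0/1
    planted_pairs: list[list[tuple[int, int]]] = field(default_factory=list)
    background_pairs: list[tuple[int, int]] = field(default_factory=list)
    class_occupancies: list[dict[str, float]] = field(default_factory=list)
    contact_states: np.ndarray | None = None       # (n_frames, n_pairs) after noise
    all_pairs: list[tuple[int, int]] = field(default_factory=list)
    frame_classes: list[str] = field(default_factory=list)
    continuous_paths: np.ndarray | None = None     # slab world (n_frames, n_particles)
    crossing_events: list[CrossingEvent] = field(default_factory=list)
    satisfying_triads: list[int] = field(default_factory=list)
    enrichment_factor: float | None = None
    inner_radius: float | None = None
    expected_shell_density: np.ndarray | None = None


def _bead_structure(n_residues: int, atoms_per_residue: int,
                    rng: np.random.Generator) -> tuple[StructureModel, np.ndarray]:
    """Rigid bead clusters on a coarse grid; returns model + home centers."""
    side = int(np.ceil(n_residues ** (1 / 3)))
    spacing = 16.0
    centers = np.array([[(k % side), (k // side) % side, k // (side * side)]
                        for k in range(n_residues)], dtype=float) * spacing
    offsets = rng.uniform(-ATOM_JITTER, ATOM_JITTER, size=(n_residues, atoms_per_residue, 3))
    offsets[:, 0, :] = 0.0  # first bead sits exactly on the residue center
    atoms = []
    coords = []
    for r in range(n_residues):
        for a in range(atoms_per_residue):
            atoms.append(Atom(atom_id=r * atoms_per_residue + a + 1,
                              atom_name="CA" if a == 0 else f"C{a}",
                              element="C", residue_index=r,
                              residue_name="BEA", chain_id="A"))
            coords.append(centers[r] + offsets[r, a])
    model = StructureModel(atoms=atoms, reference_coordinates=np.array(coords))
    return model, centers


def generate_switching_ensemble(
    spec: SyntheticEnsembleSpec,
) -> tuple[TrajectoryEnsemble, ClassLabeling, GroundTruth]:
    """Labeled bead ensemble whose contacts switch under latent modes.

    Per frame, each mode's latent Bernoulli(p_class) state places that
    mode's pairs at the contact distance (state 1) or the broken distance
    (state 0); independent flip noise is applied per pair per frame;
    non-planted inter-residue distances stay >= 8 Å by grid layout, so
    recomputing contacts at 4.2 Å recovers the planted states exactly up to
    the noise flips.
    """
    rng = np.random.default_rng(spec.seed)
    model, centers = _bead_structure(spec.n_residues, spec.atoms_per_residue, rng)

    if spec.class_frames is None or len(spec.class_frames) == 0:
        class_frames = {"A": spec.n_frames}
    else:
        class_frames = dict(spec.class_frames)
    classes = list(class_frames)
    frame_classes = [c for c in classes for _ in range(class_frames[c])]
    n_frames = len(frame_classes)
    class_idx = np.array([classes.index(c) for c in frame_classes])

    # background pairs from residues untouched by any mode
    used = set(spec._used_residues)
    free = [r for r in range(spec.n_residues) if r not in used]
    if 2 * spec.n_background_pairs > len(free):
        raise ValueError("not enough free residues for background pairs; "
                         "increase n_residues")
    perm = rng.permutation(free)
    background_pairs = [tuple(sorted((int(perm[2 * k]), int(perm[2 * k + 1]))))
                        for k in range(spec.n_background_pairs)]
    background_p = rng.uniform(0.2, 0.8, size=spec.n_background_pairs)

    all_pairs: list[tuple[int, int]] = []
    pair_state = []  # per pair: (n_frames,) intended 0/1 before noise
    n_modes = len(spec.modes)
    mode_states = np.zeros((n_frames, n_modes), dtype=np.int8)
    for m, (pairs, occ) in enumerate(spec.modes):
        p_per_frame = np.array([occ[frame_classes[f]] for f in range(n_frames)])
        mode_states[:, m] = rng.random(n_frames) < p_per_frame
        for pr in pairs:
            all_pairs.append(pr)
            pair_state.append(mode_states[:, m].copy())
    for k, pr in enumerate(background_pairs):
        all_pairs.append(pr)
        pair_state.append((rng.random(n_frames) < background_p[k]).astype(np.int8))

    S = np.stack(pair_state, axis=1) if all_pairs else np.zeros((n_frames, 0), dtype=np.int8)
    if spec.flip_noise > 0 and S.size:
        flips = rng.random(S.shape) < spec.flip_noise
        S = np.where(flips, 1 - S, S)

    # realize geometry: for each dynamic pair (i, j) move residue j along the
    # i->j grid axis so the nearest-bead distance is CONTACT or BROKEN
    ref = model.reference_coordinates
    res_idx = model.residue_indices
    frames: list[Frame] = []
    box = np.array([centers.max(0)[k] + 32.0 for k in range(3)])
    partner_shift = {}
    for (i, j) in all_pairs:
        axis = centers[j] - centers[i]
        axis = axis / np.linalg.norm(axis)
        partner_shift[(i, j)] = axis
    for f in range(n_frames):
        xyz = ref.copy()
        for d, (i, j) in enumerate(all_pairs):
            dist = CONTACT_DISTANCE if S[f, d] else BROKEN_DISTANCE
            axis = partner_shift[(i, j)]
            new_center = centers[i] + axis * dist
            xyz[res_idx == j] += new_center - centers[j]
        frames.append(Frame(coordinates=xyz, box=box.copy(), time=1.2 * (f + 1)))

    ensemble = TrajectoryEnsemble(structure=model, frames=frames, stride_ns=1.2)
    labeling = ClassLabeling.from_labels("condition", frame_classes, class_order=classes)
    truth = GroundTruth(
        mode_states=mode_states,
        planted_pairs=[list(pairs) for pairs, _ in spec.modes],
        background_pairs=background_pairs,
        class_occupancies=[dict(occ) for _, occ in spec.modes],
        contact_states=S,
        all_pairs=all_pairs,
        frame_classes=frame_classes,
    )
    return ensemble, labeling, truth


def generate_slab_world(
    n_particles: int = 200,
    n_frames: int = 400,
    box_z: float = 60.0,
    slab: tuple[float, float] = (22.0, 38.0),
    drift: float = 0.0,
    diffusion: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Biased random walkers through a membrane slab, wrapped into [0, box_z).

    Continuous paths are simulated first and the true crossing events
    extracted from them; only then are coordinates wrapped.  Returns
    ``(wrapped, box_lengths, truth)`` with ``wrapped`` of shape
    (n_frames, n_particles).
    """
    if not (0 <= slab[0] < slab[1] <= box_z):
        raise ValueError("slab must lie inside the box")
    rng = np.random.default_rng(seed)
    step_scale = abs(drift) + 4 * diffusion
    if step_scale >= box_z / 2:
        raise ValueError("step size >= half box: unwrap would be ambiguous")
    x0 = rng.uniform(0.0, box_z, size=n_particles)
    steps = rng.normal(drift, diffusion, size=(n_frames - 1, n_particles))
    steps = np.clip(steps, -box_z / 2 + 1e-6, box_z / 2 - 1e-6)
    paths = np.vstack([x0, x0 + np.cumsum(steps, axis=0)])
    # true events come from the continuous paths against the periodically
    # replicated slab; the wrapped coordinates are what the analysis sees
    events = count_crossings(paths, slab[0], slab[1], box_z=box_z)
    wrapped = np.mod(paths, box_z)
    truth = GroundTruth(continuous_paths=paths, crossing_events=events)
    return wrapped, np.full(n_frames, box_z), truth


def generate_hbond_fixture(
    n_triads: int = 50,
    satisfied_fraction: float = 0.4,
    seed: int = 0,
    distance_cutoff_A: float = 3.5,
    angle_cutoff_deg: float = 20.0,
) -> tuple[np.ndarray, HBondCriteria, GroundTruth]:
    """Donor-hydrogen-acceptor triads with a planned satisfied fraction.

    Returns (coordinates, criteria, truth); atoms are laid out as
    [D0, H0, A0, D1, H1, A1, ...] with triads far apart so only the planned
    donor-acceptor pairings can bond.
    """
    if not (0 <= satisfied_fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sat = int(round(satisfied_fraction * n_triads))
    satisfied = np.zeros(n_triads, dtype=bool)
    satisfied[rng.choice(n_triads, size=n_sat, replace=False)] = True

    coords = np.zeros((3 * n_triads, 3))
    donors, acceptors = [], []
    for t in range(n_triads):
        origin = np.array([40.0 * t, 0.0, 0.0])
        u = _random_unit(rng)
        if satisfied[t]:
            d = rng.uniform(2.6, distance_cutoff_A - 0.1)
            theta = np.deg2rad(rng.uniform(0.0, angle_cutoff_deg - 2.0))
        elif rng.random() < 0.5:  # violate by distance
            d = rng.uniform(distance_cutoff_A + 0.1, distance_cutoff_A + 1.5)
            theta = np.deg2rad(rng.uniform(0.0, angle_cutoff_deg - 2.0))
        else:                     # violate by angle
            d = rng.uniform(2.6, distance_cutoff_A - 0.1)
            theta = np.deg2rad(rng.uniform(angle_cutoff_deg + 5.0, 80.0))
        D = origin
        A = origin + d * u
        h_dir = _rotate_about_random_perp(u, theta, rng)
        H = origin + 1.0 * h_dir
        coords[3 * t] = D
        coords[3 * t + 1] = H
        coords[3 * t + 2] = A
        donors.append((3 * t, 3 * t + 1))
        acceptors.append(3 * t + 2)
    criteria = HBondCriteria(donors=donors, acceptors=acceptors,
                             distance_cutoff_A=distance_cutoff_A,
                             angle_cutoff_deg=angle_cutoff_deg)
    truth = GroundTruth(satisfying_triads=[int(t) for t in np.where(satisfied)[0]])
    return coords, criteria, truth


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about_random_perp(u: np.ndarray, theta: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Unit vector at angle theta from u, azimuth random."""
    w = _random_unit(rng)
    w = w - (w @ u) * u
    w /= np.linalg.norm(w)
    return np.cos(theta) * u + np.sin(theta) * w


def generate_lipid_shell_fixture(
    n_markers: int = 2000,
    enrichment_factor: float = 3.0,
    inner_radius: float = 10.0,
    box: float = 80.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Marker positions with a planted radial enrichment around the center.

    Candidate points are sampled uniformly in the cubic box; candidates
    outside ``inner_radius`` of the central protein bead are kept with
    probability 1/enrichment, so accepted density inside / outside equals
    the enrichment factor in expectation.  Returns
    (marker_coordinates, protein_coordinates, truth).
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2)
    pts = rng.uniform(0.0, box, size=(n_markers, 3))
    r = np.linalg.norm(pts - center, axis=1)
    keep = (r <= inner_radius) | (rng.random(n_markers) < 1.0 / enrichment_factor)
    markers = pts[keep]
    rho_candidate = n_markers / box ** 3
    truth = GroundTruth(enrichment_factor=enrichment_factor,
                        inner_radius=inner_radius,
                        expected_shell_density=np.array(
                            [rho_candidate, rho_candidate / enrichment_factor]))
    return markers, center[None, :], truth
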