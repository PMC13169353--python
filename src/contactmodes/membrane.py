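"""Conventional trajectory analytics for peptide-membrane simulations.

Superposition RMSD (Kabsch), radius of gyration, protein-bilayer COM
displacement along the membrane normal, hydrogen-bond counting with the
donor-centered angle convention, PBC-aware unwrapping and water-crossing
counting, and lipid radial number density around the protein.

Hydrogen-bond convention: a bond is counted when the donor-heavy-atom to
acceptor distance is <= the distance cutoff (default 3.5 Å) AND the angle
between the donor->hydrogen and donor->acceptor vectors is <= the angle
cutoff (default 20 degrees).  This is the donor-centered definition used by
VMD; note many other packages instead require the D-H...A angle to exceed
~160 degrees, which is a different (though related) criterion.

Crossing events are detected on the unwrapped membrane-normal coordinate by
a three-state automaton (below / inside / above the slab): an event is a
complete passage from strictly below the lower bound to strictly above the
upper bound (+1) or the reverse (-1); entering the slab and retreating is
no event, and coordinates exactly on a boundary count as "inside".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class ScalarSeries:
    name: str
    times: np.ndarray   # ns
    values: np.ndarray  # Å or counts

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in series")


@dataclass
class HBondCriteria:
    donors: list[tuple[int, int]]   # (donor heavy atom index, hydrogen index)
    acceptors: list[int]
    distance_cutoff_A: float = 3.5
    angle_cutoff_deg: float = 20.0

    def __post_init__(self) -> None:
        if self.distance_cutoff_A <= 0 or self.angle_cutoff_deg <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class CrossingEvent:
    particle_id: int
    start_frame: int
    end_frame: int
    direction: int  # +1 below->above, -1 above->below

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class RadialDensityProfile:
    shell_edges: np.ndarray        # Å, strictly increasing
    number_density: np.ndarray     # count / Å^3 per shell
    selection_name: str = ""

    def __post_init__(self) -> None:
        self.shell_edges = np.asarray(self.shell_edges, dtype=float)
        self.number_density = np.asarray(self.number_density, dtype=float)
        if np.any(np.diff(self.shell_edges) <= 0):
            raise ValueError("shell edges must be strictly increasing")
        if np.any(self.number_density < 0):
            raise ValueError("densities must be non-negative")


def _min_image(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    return diff - box * np.round(diff / box)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              subset: np.ndarray | None = None):
    """Least-squares rigid superposition (Kabsch, proper rotation).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference`` over the
    subset; rmsd is over the subset after superposition, in Å.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if subset is None else np.asarray(subset)
    P = mobile[idx]
    Q = reference[idx]
    if len(P) < 3:
        raise ValueError("need at least 3 subset atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # degenerate (collinear) subsets leave the rotation underdetermined
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom subset")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(traj, reference_coordinates: np.ndarray,
                subset: np.ndarray | None = None, name: str = "rmsd") -> ScalarSeries:
    """Per-frame RMSD after aligning each frame to the reference structure.

    No chain-swap minimization is applied for multimeric systems: the atom
    correspondence is taken literally from atom order.
    """
    ref = np.asarray(reference_coordinates, dtype=float)
    values = [superpose(f.coordinates, ref, subset)[2] for f in traj.frames]
    return ScalarSeries(name=name, times=traj.times(), values=np.array(values))


def radius_of_gyration(coordinates: np.ndarray,
                       subset: np.ndarray | None = None,
                       masses: np.ndarray | None = None) -> float:
    """sqrt( sum_a w_a |r_a - r_com|^2 / sum_a w_a ), in Å."""
    xyz = np.asarray(coordinates, dtype=float)
    if subset is not None:
        xyz = xyz[np.asarray(subset)]
        if masses is not None:
            masses = np.asarray(masses)[np.asarray(subset)]
    if xyz.shape[0] == 0:
        raise ValueError("empty subset")
    w = np.ones(len(xyz)) if masses is None else np.asarray(masses, dtype=float)
    if w.sum() <= 0:
        raise ValueError("zero total weight")
    com = (w[:, None] * xyz).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((xyz - com) ** 2, axis=1)).sum() / w.sum()))


def rg_series(traj, subset: np.ndarray | None = None,
              masses: np.ndarray | None = None) -> ScalarSeries:
    values = [radius_of_gyration(f.coordinates, subset, masses) for f in traj.frames]
    return ScalarSeries(name="rg", times=traj.times(), values=np.array(values))


def com_displacement_along_normal(traj, protein_subset: np.ndarray,
                                  bilayer_subset: np.ndarray,
                                  axis: int = 2) -> ScalarSeries:
    """Per-frame (COM_protein - COM_bilayer) projected on the normal, signed."""
    p = np.asarray(protein_subset)
    b = np.asarray(bilayer_subset)
    if p.size == 0 or b.size == 0:
        raise ValueError("empty subset")
    vals = [f.coordinates[p].mean(axis=0)[axis] - f.coordinates[b].mean(axis=0)[axis]
            for f in traj.frames]
    return ScalarSeries(name="com_displacement", times=traj.times(),
                        values=np.array(vals))


def count_hbonds(coordinates: np.ndarray, criteria: HBondCriteria,
                 box: np.ndarray | None = None):
    """Count donor-centered hydrogen bonds in one frame.

    Returns ``(count, pairs)`` where pairs lists (donor heavy, hydrogen,
    acceptor) atom indices of each counted bond.  Acceptors identical to a
    donor's heavy atom or hydrogen are skipped for that donor.
    """
    xyz = np.asarray(coordinates, dtype=float)
    if box is not None:
        box = np.asarray(box, dtype=float)
    acceptors = np.asarray(criteria.acceptors, dtype=int)
    cos_cut = np.cos(np.deg2rad(criteria.angle_cutoff_deg))
    pairs = []
    for d_heavy, d_h in criteria.donors:
        dh = xyz[d_h] - xyz[d_heavy]
        if box is not None:
            dh = _min_image(dh, box)
        if np.linalg.norm(dh) >= 1.3:
            warnings.warn(f"donor {d_heavy}: hydrogen {d_h} not covalently "
                          "consistent; donor skipped", stacklevel=2)
            continue
        da = xyz[acceptors] - xyz[d_heavy]
        if box is not None:
            da = _min_image(da, box)
        dist = np.linalg.norm(da, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (da @ dh) / (dist * np.linalg.norm(dh))
        ok = (dist <= criteria.distance_cutoff_A) & (cosang >= cos_cut) & (dist > 0)
        for a in acceptors[ok]:
            if a != d_heavy and a != d_h:
                pairs.append((int(d_heavy), int(d_h), int(a)))
    return len(pairs), pairs


def unwrap_axis(wrapped: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping of 1-D coordinate series.

    ``wrapped`` is (n_frames,) or (n_frames, n_particles); ``box_lengths``
    is scalar or per-frame.  Frame-to-frame displacements are mapped to
    their minimal image and accumulated; true displacements of half a box
    or more per frame are ambiguous and resolved toward the smaller jump
    with a warning.
    """
    w = np.asarray(wrapped, dtype=float)
    squeeze = w.ndim == 1
    if squeeze:
        w = w[:, None]
    L = np.broadcast_to(np.asarray(box_lengths, dtype=float).reshape(-1, 1)
                        if np.ndim(box_lengths) else
                        np.full((w.shape[0], 1), float(box_lengths)),
                        (w.shape[0], 1))
    d = np.diff(w, axis=0)
    wraps = np.round(d / L[1:])
    if np.any(np.abs(d - wraps * L[1:]) >= L[1:] / 2 - 1e-9):
        warnings.warn("frame-to-frame displacement at or beyond half the box; "
                      "unwrap ambiguity resolved toward the smaller jump",
                      stacklevel=2)
    out = np.concatenate([w[:1], w[:1] + np.cumsum(d - wraps * L[1:], axis=0)])
    return out[:, 0] if squeeze else out


def count_crossings(unwrapped: np.ndarray, z_low, z_high,
                    box_z: float | None = None) -> list[CrossingEvent]:
    """Detect complete slab traversals on unwrapped normal coordinates.

    ``unwrapped`` is (n_frames,) for one particle or (n_frames, n_particles).
    Three-state bookkeeping per particle: a crossing requires entering the
    slab from one side and exiting on the other, with arbitrary residence
    inside; values exactly at a boundary are "inside".

    With ``box_z`` given, the slab is treated as periodically replicated
    every box length (the physical situation for a membrane in a periodic
    box): a particle that leaves through the top of the box and re-enters
    through the bottom meets the membrane again, and net crossings equal
    the particle's net displacement in units of slab images (conservation).
    Per-frame bounds arrays are only supported in the non-periodic mode.
    """
    if box_z is not None:
        return _count_crossings_periodic(unwrapped, float(z_low), float(z_high),
                                         float(box_z))
    z = np.asarray(unwrapped, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    zlo = np.broadcast_to(np.asarray(z_low, dtype=float), (z.shape[0],))
    zhi = np.broadcast_to(np.asarray(z_high, dtype=float), (z.shape[0],))
    if np.any(zlo >= zhi):
        raise ValueError("z_low must be below z_high")
    events: list[CrossingEvent] = []
    for p in range(z.shape[1]):
        side = None          # -1 below, +1 above, 0 inside; None before first outside
        entered_from = None  # side from which the slab was last entered
        entry_frame = 0
        for f, x in enumerate(z[:, p]):
            state = -1 if x < zlo[f] else (+1 if x > zhi[f] else 0)
            if state == 0:
                if side in (-1, +1):
                    entered_from, entry_frame = side, f - 1
                side = 0
                continue
            if side == 0 and entered_from is not None and state == -entered_from:
                events.append(CrossingEvent(particle_id=p, start_frame=entry_frame,
                                            end_frame=f, direction=int(state)))
            elif side is None or side == 0:
                pass
            elif state != side:
                # jumped clean across the slab within one frame step
                events.append(CrossingEvent(particle_id=p, start_frame=f - 1,
                                            end_frame=f, direction=int(state)))
            side = state
            entered_from = None
    return events


def _count_crossings_periodic(unwrapped: np.ndarray, z_low: float,
                              z_high: float, box_z: float) -> list[CrossingEvent]:
    """Slab automaton against the periodically replicated membrane.

    Image k of the slab occupies [z_low + k*box_z, z_high + k*box_z]; the
    region between images k and k+1 is "gap k".  An event is a passage from
    gap g to gap g+1 (+1) or the reverse (-1); touching a slab image and
    retreating into the same gap is no event.
    """
    if z_low >= z_high:
        raise ValueError("z_low must be below z_high")
    if z_high - z_low >= box_z:
        raise ValueError("slab must be thinner than the box")
    z = np.asarray(unwrapped, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    events: list[CrossingEvent] = []
    for p in range(z.shape[1]):
        last_gap: int | None = None
        entered_from: int | None = None
        entry_frame = 0
        inside = False
        for f, x in enumerate(z[:, p]):
            k = int(np.floor((x - z_low) / box_z))
            offset = x - k * box_z
            now_inside = offset <= z_high  # offset >= z_low by construction
            if now_inside:
                if not inside and last_gap is not None:
                    entered_from, entry_frame = last_gap, f - 1
                inside = True
                continue
            gap = k  # outside, sitting in gap k (between images k and k+1)
            if inside:
                if entered_from is not None and gap != entered_from:
                    step = 1 if gap > entered_from else -1
                    for _ in range(abs(gap - entered_from)):
                        events.append(CrossingEvent(particle_id=p,
                                                    start_frame=entry_frame,
                                                    end_frame=f,
                                                    direction=step))
            elif last_gap is not None and gap != last_gap:
                step = 1 if gap > last_gap else -1
                for _ in range(abs(gap - last_gap)):
                    events.append(CrossingEvent(particle_id=p, start_frame=f - 1,
                                                end_frame=f, direction=step))
            inside = False
            entered_from = None
            last_gap = gap
        # a gap index shift of g relative to the start implies |g| slabs passed
    return events


def count_crossings_traj(traj, water_subset: np.ndarray,
                         z_low, z_high, axis: int = 2,
                         periodic: bool = True) -> list[CrossingEvent]:
    """Crossing events for trajectory particles: unwrap the normal
    coordinate under the per-frame box, then run the slab automaton.

    Particle ids in the returned events index into ``water_subset``.
    """
    sub = np.asarray(water_subset)
    wrapped = np.stack([f.coordinates[sub, axis] for f in traj.frames])
    boxes = np.array([f.box[axis] for f in traj.frames])
    box_z = float(boxes[0]) if periodic else None
    return count_crossings(unwrap_axis(wrapped, boxes), z_low, z_high, box_z=box_z)


def lipid_radial_density(frames_coordinates: list[np.ndarray],
                         marker_subset: np.ndarray,
                         protein_subset: np.ndarray,
                         shell_edges: np.ndarray,
                         box: np.ndarray | None = None,
                         selection_name: str = "lipid") -> RadialDensityProfile:
    """Number density of lipid marker atoms in spherical shells around the protein.

    The distance of each marker is to the *nearest* protein atom (minimum
    image when ``box`` is given); per-shell counts are averaged over frames
    and divided by the spherical-shell volume.
    """
    marker_subset = np.asarray(marker_subset)
    protein_subset = np.asarray(protein_subset)
    if protein_subset.size == 0:
        raise ValueError("empty protein subset")
    if marker_subset.size == 0:
        raise ValueError("need at least one marker atom")
    edges = np.asarray(shell_edges, dtype=float)
    counts = np.zeros(len(edges) - 1)
    for xyz in frames_coordinates:
        xyz = np.asarray(xyz, dtype=float)
        diff = xyz[marker_subset][:, None, :] - xyz[protein_subset][None, :, :]
        if box is not None:
            diff = _min_image(diff, np.asarray(box, dtype=float))
        dmin = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
        counts += np.histogram(dmin, bins=edges)[0]
    counts /= len(frames_coordinates)
    volumes = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    return RadialDensityProfile(shell_edges=edges, number_density=counts / volumes,
                                selection_name=selection_name)
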