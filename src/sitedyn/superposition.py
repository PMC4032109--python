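"""Least-squares rigid-body superposition (Kabsch).

Used to remove global tumbling from trajectories before any internal-motion
analysis, and to transplant ion coordinates between structures solved in
different crystal frames. Only proper rotations (det = +1) are considered:
reflections are not physical rigid-body motions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import CongruenceError, DegeneracyError, SelectionError
from .io import Structure, Trajectory

DEFAULT_FIT_SELECTION = "*:*:N,CA,C,O"


@dataclass
class SuperpositionResult:
    """A proper rigid transform ``x' = rotation @ x + translation`` and its fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    atom_selection: list

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def _check_rank(points: np.ndarray, label: str) -> None:
    centered = points - points.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = max(svals[0], 1.0)
    if svals[1] <= 1e-8 * scale:
        raise DegeneracyError(f"{label} point set is collinear (or all-coincident)")


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               atom_selection: list | None = None) -> SuperpositionResult:
    """Proper rigid transform minimising RMSD of ``mobile`` onto ``reference``.

    Both inputs are ``(n, 3)`` coordinate arrays with ``n >= 3`` non-collinear
    points, paired row-by-row. The reported RMSD is measured after applying
    the transform.
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise CongruenceError(
            f"point sets differ in size: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    if mobile.shape[0] < 3:
        raise DegeneracyError("need at least 3 points for a unique superposition")
    _check_rank(mobile, "mobile")
    _check_rank(reference, "reference")

    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    # align_vectors solves min_R sum |a_i - R b_i|^2 over proper rotations
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        atom_selection=list(atom_selection) if atom_selection is not None else [],
    )


def _matched_indices(topology: Structure, reference: Structure, selection: str):
    """Indices of selection atoms present (by identity) in both structures."""
    sel_top = topology.select(selection)
    sel_ref = reference.select(selection)
    top_keys = topology.identity_keys()
    ref_keys = reference.identity_keys()
    ref_lookup = {ref_keys[i]: i for i in sel_ref}
    pairs = [(i, ref_lookup[top_keys[i]]) for i in sel_top if top_keys[i] in ref_lookup]
    if len(pairs) < 3:
        raise SelectionError(
            f"selection {selection!r} matched only {len(pairs)} atoms common to "
            "both structures (need >= 3)"
        )
    top_idx, ref_idx = zip(*pairs)
    return np.asarray(top_idx), np.asarray(ref_idx), [top_keys[i] for i in top_idx]


def align_frames(traj: Trajectory, reference: Structure,
                 selection: str = DEFAULT_FIT_SELECTION) -> Trajectory:
    """Rigidly fit every frame onto ``reference`` using ``selection`` atoms.

    Each frame gets its own Kabsch fit (unweighted, backbone N/CA/C/O by
    default) and the resulting transform is applied to all atoms of the
    frame. Atom identities are unchanged; the operation is idempotent.
    """
    top_idx, ref_idx, _ = _matched_indices(traj.topology, reference, selection)
    ref_coords = reference.coords[ref_idx]
    out = np.empty_like(traj.coords)
    for i in range(traj.n_frames):
        fit = kabsch_fit(traj.coords[i, top_idx], ref_coords)
        out[i] = fit.apply(traj.coords[i])
    return Trajectory(topology=traj.topology, coords=out, frame_spacing=traj.frame_spacing)


def transplant_ion(donor: Structure, acceptor: Structure, ion_id: str,
                   fit_selection: str = DEFAULT_FIT_SELECTION) -> Structure:
    """Copy an ion from ``donor`` into ``acceptor`` via rigid superposition.

    The donor is fitted onto the acceptor over ``fit_selection`` atoms common
    to both, and the donor ion position is mapped through that transform and
    appended to the acceptor as a HETATM.
    """
    ion_idx = donor.select(ion_id)
    if len(ion_idx) != 1:
        raise SelectionError(
            f"ion selection {ion_id!r} resolved to {len(ion_idx)} atoms, expected 1"
        )
    ion_idx = int(ion_idx[0])
    don_idx, acc_idx, keys = _matched_indices(donor, acceptor, fit_selection)
    fit = kabsch_fit(donor.coords[don_idx], acceptor.coords[acc_idx],
                     atom_selection=keys)
    new_pos = fit.apply(donor.coords[ion_idx][None, :])[0]

    ion_chain = donor.chain_ids[ion_idx]
    ion_resnum = int(donor.residue_numbers[ion_idx])
    # avoid identity collisions with existing acceptor atoms
    if (ion_chain, ion_resnum, donor.atom_names[ion_idx]) in set(acceptor.identity_keys()):
        ion_resnum = int(acceptor.residue_numbers.max()) + 1

    return replace(
        acceptor,
        serials=np.append(acceptor.serials, int(acceptor.serials.max()) + 1),
        atom_names=acceptor.atom_names + [donor.atom_names[ion_idx]],
        residue_names=acceptor.residue_names + [donor.residue_names[ion_idx]],
        chain_ids=acceptor.chain_ids + [ion_chain],
        residue_numbers=np.append(acceptor.residue_numbers, ion_resnum),
        coords=np.vstack([acceptor.coords, new_pos]),
        b_factors=np.append(acceptor.b_factors, donor.b_factors[ion_idx]),
        elements=acceptor.elements + [donor.elements[ion_idx]],
        het_flags=np.append(acceptor.het_flags, True),
    )
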