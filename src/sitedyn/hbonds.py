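"""Hydrogen-bond detection and occupancy over trajectories.

A bond between a donor heavy atom D (with covalently bound hydrogen H) and
an acceptor A is counted in a frame when the donor–acceptor distance is
below a cutoff (default 3.1 Å) and the geometry is near-linear (default
within 25°). Two angle conventions are available:

``donor_deviation`` (default)
    the angle at the donor between D→H and D→A; 0° for a perfectly linear
    bond.
``dha_supplement``
    180° minus the included D–H–A angle at the hydrogen; also 0° for a
    perfectly linear bond.

Occupancy for a residue pair is the fraction of frames in which ANY
donor-H/acceptor triad of the pair is bonded — carboxylates contribute both
equivalent oxygens to one pair-level number. Distances and angles are
rigid-motion invariant, so no prior alignment is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GeometryError, ParameterError
from .io import ResultTable, Structure, Trajectory, residue_label

#: backbone atom names excluded from sidechain donor/acceptor enumeration
BACKBONE_ATOMS = {
    "N", "CA", "C", "O", "OXT",
    "H", "H1", "H2", "H3", "HN", "HA", "HA2", "HA3", "HXT",
}

_COVALENT_H_CUTOFF = 1.25  # Å: H belongs to the nearest same-residue N/O within this


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (strict ``<`` at both thresholds)."""

    max_donor_acceptor_distance: float = 3.1  # Å
    max_angle_deviation: float = 25.0  # degrees
    angle_convention: str = "donor_deviation"  # or "dha_supplement"

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0 or self.max_angle_deviation <= 0:
            raise ParameterError("hydrogen-bond thresholds must be strictly positive")
        if self.angle_convention not in ("donor_deviation", "dha_supplement"):
            raise ParameterError(
                f"unknown angle convention {self.angle_convention!r}"
            )


@dataclass
class HBondRow:
    donor_residue: str
    acceptor_residue: str
    occupancy: float
    n_frames: int


@dataclass
class HBondOccupancyTable:
    rows: list[HBondRow] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_result_table(self) -> ResultTable:
        data = pd.DataFrame([
            {
                "donor": r.donor_residue,
                "acceptor": r.acceptor_residue,
                "pair": f"{r.donor_residue}-{r.acceptor_residue}",
                "occupancy": r.occupancy,
                "n_frames": r.n_frames,
            }
            for r in self.rows
        ])
        return ResultTable(data=data, metadata=dict(self.metadata))


def _resolve_residue(structure: Structure, residue) -> tuple[tuple, np.ndarray]:
    """Resolve a residue given as ``(chain, resnum)``, ``"chain:resnum"`` or int."""
    if isinstance(residue, str) and ":" in residue:
        chain, _, num = residue.partition(":")
        residue = (chain, int(num))
    if isinstance(residue, int):
        matches = [(key, idx) for key, idx in structure.residues() if key[1] == residue]
    else:
        chain, num = residue
        matches = [
            (key, idx) for key, idx in structure.residues()
            if key[0] == chain and key[1] == int(num)
        ]
    if len(matches) != 1:
        raise ParameterError(
            f"residue specifier {residue!r} matched {len(matches)} residues"
        )
    return matches[0]


def _is_hydrogen(structure: Structure, i: int) -> bool:
    el = structure.elements[i]
    if el:
        return el == "H"
    return structure.atom_names[i].lstrip("0123456789").startswith("H")


def _bound_hydrogens(structure: Structure, heavy: int, residue_idx: np.ndarray):
    pos = structure.coords[heavy]
    out = []
    for j in residue_idx:
        if int(j) == heavy or not _is_hydrogen(structure, int(j)):
            continue
        if np.linalg.norm(structure.coords[j] - pos) < _COVALENT_H_CUTOFF:
            out.append(int(j))
    return out


def enumerate_triads(structure: Structure, donor_residue, acceptor_residue,
                     include_backbone: bool = False) -> list[tuple[int, int, int]]:
    """All (D, H, A) atom-index triples between a donor and an acceptor residue.

    Donors are sidechain N/O atoms carrying at least one covalently bound
    hydrogen (assigned by distance, < 1.25 Å within the residue); acceptors
    are sidechain oxygens plus sidechain nitrogens with no bound hydrogen
    (e.g. the unprotonated His ND1/NE2). Backbone atoms participate only
    with ``include_backbone=True``. A donor-capable heavy atom with no
    resolvable hydrogen is skipped with a warning.
    """
    dkey, didx = _resolve_residue(structure, donor_residue)
    akey, aidx = _resolve_residue(structure, acceptor_residue)

    def _sidechain_ok(i: int) -> bool:
        return include_backbone or structure.atom_names[i] not in BACKBONE_ATOMS

    donors: list[tuple[int, list[int]]] = []
    for i in didx:
        i = int(i)
        el = structure.elements[i] or _guess(structure.atom_names[i])
        if el not in ("N", "O") or not _sidechain_ok(i):
            continue
        hyds = _bound_hydrogens(structure, i, didx)
        if hyds:
            donors.append((i, hyds))

    acceptors: list[int] = []
    for i in aidx:
        i = int(i)
        el = structure.elements[i] or _guess(structure.atom_names[i])
        if not _sidechain_ok(i):
            continue
        if el == "O":
            acceptors.append(i)
        elif el == "N" and not _bound_hydrogens(structure, i, aidx):
            acceptors.append(i)

    if not donors:
        warnings.warn(
            f"residue {residue_label(dkey[2], dkey[1])} has no sidechain donor "
            "with a bound hydrogen; no triads enumerated",
            stacklevel=2,
        )
    return [(d, h, a) for d, hyds in donors for h in hyds for a in acceptors]


def _guess(name: str) -> str:
    return name.lstrip("0123456789")[:1]


def _deviation_angles(d, h, a, convention: str) -> np.ndarray:
    """Angle criterion value in degrees, vectorised over leading axes."""
    dh = h - d
    dh_norm = np.linalg.norm(dh, axis=-1)
    if np.any(dh_norm < 1e-8):
        raise GeometryError("hydrogen coincides with its donor heavy atom")
    if convention == "donor_deviation":
        da = a - d
        cosang = np.sum(dh * da, axis=-1) / (dh_norm * np.linalg.norm(da, axis=-1))
        return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # dha_supplement: 180 deg minus the included angle at H
    hd = d - h
    ha = a - h
    cosang = (
        np.sum(hd * ha, axis=-1)
        / (np.linalg.norm(hd, axis=-1) * np.linalg.norm(ha, axis=-1))
    )
    return 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_in_frame(donor, hydrogen, acceptor,
                   criteria: HBondCriteria | None = None) -> bool:
    """Whether one (D, H, A) coordinate triad is bonded under the criteria."""
    criteria = criteria or HBondCriteria()
    d = np.asarray(donor, dtype=float)
    h = np.asarray(hydrogen, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    if np.linalg.norm(h - d) < 1e-8:
        raise GeometryError("hydrogen coincides with its donor heavy atom")
    if np.linalg.norm(a - d) >= criteria.max_donor_acceptor_distance:
        return False
    ang = _deviation_angles(d, h, a, criteria.angle_convention)
    return bool(ang < criteria.max_angle_deviation)


def occupancy(traj: Trajectory, donor_residue, acceptor_residue,
              criteria: HBondCriteria | None = None,
              include_backbone: bool = False) -> HBondRow:
    """Fraction of frames in which the residue pair is hydrogen bonded.

    A frame counts when ANY (D, H, A) triad of the pair satisfies the
    criteria. A pair with no triads is reported as occupancy 0 with a
    warning.
    """
    criteria = criteria or HBondCriteria()
    top = traj.topology
    dkey, _ = _resolve_residue(top, donor_residue)
    akey, _ = _resolve_residue(top, acceptor_residue)
    dlabel = residue_label(dkey[2], dkey[1])
    alabel = residue_label(akey[2], akey[1])
    triads = enumerate_triads(top, donor_residue, acceptor_residue,
                              include_backbone=include_backbone)
    if not triads:
        warnings.warn(
            f"no donor/acceptor triads for pair {dlabel}-{alabel}; occupancy 0",
            stacklevel=2,
        )
        return HBondRow(dlabel, alabel, 0.0, traj.n_frames)

    bonded = np.zeros(traj.n_frames, dtype=bool)
    for d_i, h_i, a_i in triads:
        d = traj.coords[:, d_i, :]
        h = traj.coords[:, h_i, :]
        a = traj.coords[:, a_i, :]
        dist_ok = np.linalg.norm(a - d, axis=1) < criteria.max_donor_acceptor_distance
        ang = _deviation_angles(d, h, a, criteria.angle_convention)
        bonded |= dist_ok & (ang < criteria.max_angle_deviation)
    return HBondRow(dlabel, alabel, float(bonded.mean()), traj.n_frames)


def occupancy_table(traj: Trajectory, pairs,
                    criteria: HBondCriteria | None = None,
                    include_backbone: bool = False) -> HBondOccupancyTable:
    """Occupancy rows for a list of (donor_residue, acceptor_residue) pairs."""
    criteria = criteria or HBondCriteria()
    table = HBondOccupancyTable(metadata={
        "max_donor_acceptor_distance_A": criteria.max_donor_acceptor_distance,
        "max_angle_deviation_deg": criteria.max_angle_deviation,
        "angle_convention": criteria.angle_convention,
        "n_frames": traj.n_frames,
    })
    for donor_res, acceptor_res in pairs:
        table.rows.append(
            occupancy(traj, donor_res, acceptor_res, criteria=criteria,
                      include_backbone=include_backbone)
        )
    return table
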