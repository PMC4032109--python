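"""Synthetic trajectories with known statistical ground truth.

Every analysis in the package can be validated against these generators:

* ``gen_cone_trajectory`` — a bond vector wobbling uniformly in a cone of
  semi-angle θ₀, whose order parameter is exactly
  ``S² = [cosθ₀ (1 + cosθ₀) / 2]²``;
* ``gen_two_site_trajectory`` — a two-orientation jump separated by β with
  stationary populations (p, 1−p), ``S² = 1 − 3 p (1−p) sin²β``;
* ``gen_hbond_trajectory`` — a donor/acceptor residue pair switching
  (telegraph-style) between a bonded and an unbonded geometry with
  prescribed occupancy;
* ``gen_confined_ion_trajectory`` — a single Mg²⁺ ion in a harmonic well
  (stationary per-axis Gaussian, discrete Ornstein–Uhlenbeck) inside a
  rigid scaffold, so its RMSD about the well center is √3·σ;
* ``apply_global_tumbling`` — random rigid rotation/translation per frame,
  to exercise superposition-based tumbling removal.

Scaffolds are chemically minimal ideal-geometry fragments, not physical
peptides: only the atoms each analysis consumes are guaranteed present.
Orientational sampling is i.i.d. per frame by default — the S² plateau and
H-bond occupancy depend only on the stationary distribution, not on
kinetics — with optional Markov correlation where noted. All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ParameterError
from .io import Structure, Trajectory


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic trajectory."""

    kind: str  # cone | two_site | telegraph_hbond | confined_ion | tumbling_wrapper
    parameters: dict = field(default_factory=dict)
    n_frames: int = 1000
    frame_spacing: float = 10.0  # ps
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")


# ---------------------------------------------------------------------------
# scaffold construction
# ---------------------------------------------------------------------------

def _make_structure(records) -> Structure:
    """records: iterable of (atom_name, residue_name, chain, resnum, xyz, het, element)."""
    records = list(records)
    return Structure(
        serials=np.arange(1, len(records) + 1),
        atom_names=[r[0] for r in records],
        residue_names=[r[1] for r in records],
        chain_ids=[r[2] for r in records],
        residue_numbers=np.array([r[3] for r in records]),
        coords=np.array([r[4] for r in records], dtype=float),
        b_factors=np.zeros(len(records)),
        elements=[r[6] for r in records],
        het_flags=np.array([r[5] for r in records], dtype=bool),
    )


def _asp_scaffold(n_residues: int) -> tuple[Structure, list[int], list[int]]:
    """Poly-Asp scaffold; returns (topology, CB indices, CG indices).

    Backbone N/CA/C/O and CB are static; CG is repositioned per frame by the
    orientational generators (CB→CG is the Asp symmetry-axis bond).
    """
    records = []
    cb_idx, cg_idx = [], []
    for r in range(n_residues):
        off = np.array([6.0 * r, 0.0, 0.0])
        base = [
            ("N", (0.0, 1.4, 0.0), "N"),
            ("CA", (1.2, 0.6, 0.0), "C"),
            ("C", (2.4, 1.4, 0.3), "C"),
            ("O", (2.6, 2.5, -0.2), "O"),
            ("CB", (1.3, -0.6, 1.0), "C"),
            ("CG", (1.3, -0.6, 2.52), "C"),  # placeholder; set per frame
        ]
        for name, xyz, el in base:
            if name == "CB":
                cb_idx.append(len(records))
            if name == "CG":
                cg_idx.append(len(records))
            records.append((name, "ASP", "A", r + 1, np.asarray(xyz) + off, False, el))
    return _make_structure(records), cb_idx, cg_idx


_CC_BOND = 1.52  # Å, Cβ–Cγ


def _orientation_trajectory(vectors_per_residue: list[np.ndarray],
                            frame_spacing: float) -> Trajectory:
    """Assemble a poly-Asp trajectory whose CB→CG vectors follow ``vectors``."""
    n_res = len(vectors_per_residue)
    top, cb_idx, cg_idx = _asp_scaffold(n_res)
    n_frames = vectors_per_residue[0].shape[0]
    coords = np.broadcast_to(top.coords, (n_frames, top.n_atoms, 3)).copy()
    for r in range(n_res):
        coords[:, cg_idx[r], :] = (
            top.coords[cb_idx[r]] + _CC_BOND * vectors_per_residue[r]
        )
    return Trajectory(topology=top, coords=coords, frame_spacing=frame_spacing)


# ---------------------------------------------------------------------------
# orientational generators
# ---------------------------------------------------------------------------

def cone_s2(theta0_deg: float) -> float:
    """Closed-form S² for uniform wobble in a cone of semi-angle θ₀."""
    c = np.cos(np.radians(theta0_deg))
    return float((c * (1.0 + c) / 2.0) ** 2)


def two_site_s2(beta_deg: float, p: float) -> float:
    """Closed-form S² for a two-site jump separated by β with populations (p, 1−p)."""
    s = np.sin(np.radians(beta_deg))
    return float(1.0 - 3.0 * p * (1.0 - p) * s * s)


def sample_cone_vectors(theta0_deg: float, n: int, rng) -> np.ndarray:
    """i.i.d. unit vectors uniform over the spherical cap of semi-angle θ₀ about +z."""
    if not 0.0 < theta0_deg <= 180.0:
        raise ParameterError("cone semi-angle must be in (0, 180] degrees")
    u = rng.uniform(np.cos(np.radians(theta0_deg)), 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    s = np.sqrt(np.clip(1.0 - u * u, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def gen_cone_trajectory(theta0_deg: float, n_frames: int, frame_spacing: float = 10.0,
                        seed: int = 0, n_residues: int = 1) -> tuple[Trajectory, dict]:
    """Poly-Asp trajectory whose Cβ→Cγ vectors wobble uniformly in a cone.

    Each residue gets an independent draw. Returns the trajectory and a
    truth dict carrying the analytic ``s2``.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    vectors = [sample_cone_vectors(theta0_deg, n_frames, rng) for _ in range(n_residues)]
    traj = _orientation_trajectory(vectors, frame_spacing)
    truth = {
        "kind": "cone",
        "theta0_deg": float(theta0_deg),
        "n_residues": n_residues,
        "s2_analytic": cone_s2(theta0_deg),
        "seed": seed,
    }
    return traj, truth


def _markov_states(p: float, flip_rate: float, n: int, rng) -> np.ndarray:
    """Two-state chain with stationary distribution (p, 1−p); True = state 1.

    ``flip_rate`` scales the switching probabilities (1 → i.i.d. sampling);
    the stationary distribution is (p, 1−p) for any rate in (0, 1].
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError("population p must be in [0, 1]")
    if not 0.0 < flip_rate <= 1.0:
        raise ParameterError("flip_rate must be in (0, 1]")
    if flip_rate == 1.0:
        return rng.random(n) < p
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < p
    u = rng.random(n - 1)
    p01 = flip_rate * p        # leave state 0 (towards state 1)
    p10 = flip_rate * (1 - p)  # leave state 1
    for i in range(1, n):
        if states[i - 1]:
            states[i] = u[i - 1] >= p10
        else:
            states[i] = u[i - 1] < p01
    return states


def gen_two_site_trajectory(beta_deg: float, n_frames: int, p: float = 0.5,
                            flip_rate: float = 1.0, frame_spacing: float = 10.0,
                            seed: int = 0) -> tuple[Trajectory, dict]:
    """Two-orientation jump trajectory (orientations separated by β)."""
    if not 0.0 <= beta_deg <= 180.0:
        raise ParameterError("jump angle must be in [0, 180] degrees")
    rng = np.random.default_rng(seed)
    states = _markov_states(p, flip_rate, n_frames, rng)
    beta = np.radians(beta_deg)
    mu1 = np.array([0.0, 0.0, 1.0])
    mu2 = np.array([np.sin(beta), 0.0, np.cos(beta)])
    vectors = np.where(states[:, None], mu1, mu2)
    traj = _orientation_trajectory([vectors], frame_spacing)
    truth = {
        "kind": "two_site",
        "beta_deg": float(beta_deg),
        "p": float(p),
        "flip_rate": float(flip_rate),
        "s2_analytic": two_site_s2(beta_deg, p),
        "seed": seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# hydrogen-bond telegraph generator
# ---------------------------------------------------------------------------

def _hbond_fixture_coords(bonded_distance: float, deviation_deg: float,
                          unbonded_distance: float):
    """Topology + the two acceptor-residue coordinate sets (bonded, unbonded).

    Donor: an Asn sidechain amide (ND2 at the origin, one hydrogen HD21
    along +z). Acceptor: an Asp whose OD1 sits on a ray ``deviation_deg``
    off the N–H direction, at the bonded or the unbonded distance; the rest
    of the Asp moves rigidly with it.
    """
    dev = np.radians(deviation_deg)
    u = np.array([np.sin(dev), 0.0, np.cos(dev)])  # D→A direction

    donor = [
        ("N", (-4.6, 1.6, -0.6), "N"),
        ("CA", (-3.9, 0.4, -0.6), "C"),
        ("C", (-4.6, -0.9, -0.9), "C"),
        ("O", (-5.8, -1.0, -0.7), "O"),
        ("CB", (-2.7, 0.5, 0.3), "C"),
        ("CG", (-1.5, 0.9, -0.4), "C"),
        ("OD1", (-1.5, 1.9, -1.1), "O"),
        ("ND2", (0.0, 0.0, 0.0), "N"),
        ("HD21", (0.0, 0.0, 1.01), "H"),
    ]
    od1 = bonded_distance * u
    acceptor_rel = [
        ("OD1", np.zeros(3), "O"),
        ("CG", np.array([1.1, 0.0, 0.6]), "C"),
        ("OD2", np.array([1.6, 1.0, 0.9]), "O"),
        ("CB", np.array([2.1, -1.0, 0.8]), "C"),
        ("CA", np.array([3.3, -1.8, 0.8]), "C"),
        ("N", np.array([2.9, -3.1, 0.8]), "N"),
        ("C", np.array([4.7, -1.2, 0.8]), "C"),
        ("O", np.array([5.3, -0.1, 0.8]), "O"),
    ]
    records = [(n, "ASN", "A", 1, np.asarray(x), False, e) for n, x, e in donor]
    acc_start = len(records)
    for n, rel, e in acceptor_rel:
        records.append((n, "ASP", "A", 2, od1 + rel, False, e))
    top = _make_structure(records)
    bonded_coords = top.coords.copy()
    unbonded_coords = top.coords.copy()
    shift = (unbonded_distance - bonded_distance) * u
    unbonded_coords[acc_start:] += shift
    return top, bonded_coords, unbonded_coords


def gen_hbond_trajectory(p: float, n_frames: int, frame_spacing: float = 10.0,
                         seed: int = 0, bonded_distance: float = 2.9,
                         bonded_deviation_deg: float = 5.0,
                         unbonded_distance: float = 4.5) -> tuple[Trajectory, dict]:
    """Telegraph hydrogen-bond trajectory with prescribed occupancy ``p``.

    Frames are drawn i.i.d.: bonded geometry (D–A 2.9 Å, 5° off-axis) with
    probability ``p``, otherwise an unbonded geometry (4.5 Å). The truth
    dict carries both the target and the realized occupancy.
    """
    if not 0.0 <= p <= 1.0:
        raise ParameterError("occupancy p must be in [0, 1]")
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    top, bonded_c, unbonded_c = _hbond_fixture_coords(
        bonded_distance, bonded_deviation_deg, unbonded_distance
    )
    if p == 1.0:
        states = np.ones(n_frames, dtype=bool)
    elif p == 0.0:
        states = np.zeros(n_frames, dtype=bool)
    else:
        states = rng.random(n_frames) < p
    coords = np.where(states[:, None, None], bonded_c, unbonded_c)
    traj = Trajectory(topology=top, coords=coords, frame_spacing=frame_spacing)
    truth = {
        "kind": "telegraph_hbond",
        "p": float(p),
        "realized_occupancy": float(states.mean()),
        "donor_residue": "A:1",
        "acceptor_residue": "A:2",
        "bonded_distance_A": float(bonded_distance),
        "bonded_deviation_deg": float(bonded_deviation_deg),
        "unbonded_distance_A": float(unbonded_distance),
        "seed": seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# confined-ion generator
# ---------------------------------------------------------------------------

def _ring_scaffold(center, n_residues: int = 20, radius: float = 12.0):
    records = []
    center = np.asarray(center, dtype=float)
    for r in range(n_residues):
        ang = 2.0 * np.pi * r / n_residues
        ca = center + radius * np.array([np.cos(ang), np.sin(ang), 0.0])
        for name, rel, el in [
            ("N", (-0.9, 1.0, 0.3), "N"),
            ("CA", (0.0, 0.0, 0.0), "C"),
            ("C", (1.2, 0.7, -0.4), "C"),
            ("O", (1.6, 1.8, -0.2), "O"),
        ]:
            records.append((name, "GLY", "A", r + 1, ca + np.asarray(rel), False, el))
    return records


def gen_confined_ion_trajectory(sigma: float, n_frames: int,
                                center=(0.0, 0.0, 0.0), correlation: float = 0.8,
                                frame_spacing: float = 10.0, seed: int = 0,
                                n_scaffold_residues: int = 20) -> tuple[Trajectory, dict]:
    """Rigid ring scaffold plus one Mg²⁺ ion in an isotropic harmonic well.

    The ion follows a discrete Ornstein–Uhlenbeck process per axis with
    stationary standard deviation ``sigma`` about ``center`` and lag-1
    autocorrelation ``correlation``; the scaffold is static. The stationary
    RMSD of the ion about the well center is √3·σ.
    """
    if not sigma >= 0:
        raise ParameterError("sigma must be >= 0 Å")
    if not 0.0 <= correlation < 1.0:
        raise ParameterError("correlation must be in [0, 1)")
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    records = _ring_scaffold(center, n_residues=n_scaffold_residues)
    records.append(("MG", "MG", "B", 1, center.copy(), True, "MG"))
    top = _make_structure(records)

    if sigma == 0.0:
        dev = np.zeros((n_frames, 3))
    else:
        phi = correlation
        noise = rng.standard_normal((n_frames, 3))
        dev = np.empty((n_frames, 3))
        dev[0] = sigma * noise[0]
        scale = sigma * np.sqrt(1.0 - phi * phi)
        for i in range(1, n_frames):
            dev[i] = phi * dev[i - 1] + scale * noise[i]

    coords = np.broadcast_to(top.coords, (n_frames, top.n_atoms, 3)).copy()
    coords[:, -1, :] = center + dev
    traj = Trajectory(topology=top, coords=coords, frame_spacing=frame_spacing)
    truth = {
        "kind": "confined_ion",
        "center": [float(c) for c in center],
        "sigma_A": float(sigma),
        "correlation": float(correlation),
        "rmsd_analytic_A": float(np.sqrt(3.0) * sigma),
        "ion_selection": "MG",
        "seed": seed,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# global tumbling
# ---------------------------------------------------------------------------

def apply_global_tumbling(traj: Trajectory, max_rotation_deg: float = 180.0,
                          max_translation: float = 5.0, seed: int = 0) -> Trajectory:
    """Apply an independent random rigid transform to every frame.

    Rotation angles are uniform in ``[0, max_rotation_deg]`` about uniform
    random axes; translations uniform in ``[-max_translation,
    max_translation]`` per component. Zero magnitudes reproduce the input
    exactly.
    """
    if max_rotation_deg < 0 or max_translation < 0:
        raise ParameterError("tumbling magnitudes must be >= 0")
    if max_rotation_deg == 0 and max_translation == 0:
        return Trajectory(topology=traj.topology, coords=traj.coords.copy(),
                          frame_spacing=traj.frame_spacing)
    rng = np.random.default_rng(seed)
    n = traj.n_frames
    axes = rng.standard_normal((n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.uniform(0.0, np.radians(max_rotation_deg), size=n)
    translations = rng.uniform(-max_translation, max_translation, size=(n, 3))
    out = np.empty_like(traj.coords)
    for i in range(n):
        R = Rotation.from_rotvec(axes[i] * angles[i]).as_matrix()
        out[i] = traj.coords[i] @ R.T + translations[i]
    return Trajectory(topology=traj.topology, coords=out,
                      frame_spacing=traj.frame_spacing)


# ---------------------------------------------------------------------------
# spec-driven dispatch (used by the CLI)
# ---------------------------------------------------------------------------

def generate(spec: GeneratorSpec) -> tuple[Trajectory, dict]:
    """Build the trajectory described by a :class:`GeneratorSpec`."""
    kw = dict(spec.parameters)
    common = dict(n_frames=spec.n_frames, frame_spacing=spec.frame_spacing,
                  seed=spec.seed)
    if spec.kind == "cone":
        traj, truth = gen_cone_trajectory(
            theta0_deg=kw.pop("theta0_deg"), **common, **kw)
    elif spec.kind == "two_site":
        traj, truth = gen_two_site_trajectory(
            beta_deg=kw.pop("beta_deg"), **common, **kw)
    elif spec.kind == "telegraph_hbond":
        traj, truth = gen_hbond_trajectory(p=kw.pop("p"), **common, **kw)
    elif spec.kind == "confined_ion":
        traj, truth = gen_confined_ion_trajectory(
            sigma=kw.pop("sigma"), **common, **kw)
    elif spec.kind == "tumbling_wrapper":
        inner = GeneratorSpec(
            kind=kw.pop("inner_kind"),
            parameters=kw.pop("inner_parameters", {}),
            n_frames=spec.n_frames,
            frame_spacing=spec.frame_spacing,
            seed=spec.seed,
        )
        traj, truth = generate(inner)
        traj = apply_global_tumbling(
            traj,
            max_rotation_deg=kw.pop("max_rotation_deg", 180.0),
            max_translation=kw.pop("max_translation", 5.0),
            seed=spec.seed + 1,
        )
        truth = {"kind": "tumbling_wrapper", "inner": truth}
        if kw:
            raise ParameterError(f"unused tumbling parameters: {sorted(kw)}")
    else:
        raise ParameterError(f"unknown generator kind {spec.kind!r}")
    truth.setdefault("n_frames", spec.n_frames)
    truth.setdefault("frame_spacing_ps", spec.frame_spacing)
    return traj, truth
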