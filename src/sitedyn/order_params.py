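"""Generalized order parameters (S²) for sidechain bond vectors.

The estimator is the long-time plateau of the second-rank angular
reorientational correlation function of a unit bond vector μ:

    S² = ½ (3 Σ_i Σ_j ⟨μ_i μ_j⟩² − 1),   i, j ∈ {x, y, z}

with ⟨·⟩ the plain time average over all frames of an aligned trajectory.
S² = 1 for a fully rigid bond, 0 for isotropic disorder; finite sampling can
produce values slightly outside [0, 1] but never outside [−0.5, 1].

Sidechain vectors are the symmetry-axis bonds carrying the carboxylate/amide
group whose dynamics NMR reports at the Cγ/Cδ carbons: Cβ→Cγ for Asp/Asn and
Cγ→Cδ for Glu/Gln (the "DENQ" residues). Uncertainties come from block
averaging: the trajectory is cut into contiguous blocks, S² is computed per
block, and the SEM is the sample standard deviation of the block values over
√n_blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ExtractionError, PairingError, ParameterError
from .io import ResultTable, Trajectory, residue_label

#: symmetry-axis bond per residue type: (atom_from, atom_to)
DENQ_BONDS = {
    "ASP": ("CB", "CG"),
    "ASN": ("CB", "CG"),
    "GLU": ("CG", "CD"),
    "GLN": ("CG", "CD"),
}

_LETTER_TO_RESNAMES = {
    "D": ("ASP",), "E": ("GLU",), "N": ("ASN",), "Q": ("GLN",),
}


@dataclass
class BondVectorSeries:
    """Per-frame unit vectors for one chemical bond of one residue."""

    residue_id: tuple  # (chain, residue_number, residue_name)
    bond: tuple  # (atom_from, atom_to)
    vectors: np.ndarray  # (n_frames, 3), unit norm

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def label(self) -> str:
        chain, num, name = self.residue_id
        return residue_label(name, num)


@dataclass
class OrderParameterResult:
    residue_id: tuple
    s2: float
    sem: float = float("nan")
    n_frames: int = 0
    n_blocks: int = 0

    @property
    def label(self) -> str:
        chain, num, name = self.residue_id
        return residue_label(name, num)


def residue_types_from_letters(letters: str) -> tuple[str, ...]:
    """Expand a one-letter residue-type string like ``"DENQ"`` to PDB names."""
    names: list[str] = []
    for ch in letters.upper():
        if ch not in _LETTER_TO_RESNAMES:
            raise ParameterError(f"unsupported residue letter {ch!r} (use D/E/N/Q)")
        names.extend(_LETTER_TO_RESNAMES[ch])
    return tuple(names)


def extract_bond_vectors(traj: Trajectory, residue_types: str = "DENQ",
                         residue_numbers=None) -> list[BondVectorSeries]:
    """One unit-vector series per selected DENQ residue of an aligned trajectory.

    ``residue_types`` is a one-letter subset of "DENQ"; ``residue_numbers``
    optionally restricts to specific residue numbers. A selected residue
    missing either bond atom raises :class:`ExtractionError` naming it.
    """
    wanted = set(residue_types_from_letters(residue_types))
    top = traj.topology
    out: list[BondVectorSeries] = []
    for (chain, resnum, resname), idx in top.residues():
        if resname not in wanted:
            continue
        if residue_numbers is not None and resnum not in set(residue_numbers):
            continue
        a_from, a_to = DENQ_BONDS[resname]
        names = [top.atom_names[i] for i in idx]
        try:
            i_from = idx[names.index(a_from)]
            i_to = idx[names.index(a_to)]
        except ValueError:
            raise ExtractionError(
                f"residue {resname}{resnum} (chain {chain}) lacks bond atom "
                f"{a_from}/{a_to}"
            ) from None
        vec = traj.coords[:, i_to, :] - traj.coords[:, i_from, :]
        norms = np.linalg.norm(vec, axis=1)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ExtractionError(
                f"residue {resname}{resnum}: zero-length bond vector at frame {bad[0]}"
            )
        out.append(
            BondVectorSeries(
                residue_id=(chain, resnum, resname),
                bond=(a_from, a_to),
                vectors=vec / norms[:, None],
            )
        )
    return out


def _s2_from_vectors(vectors: np.ndarray) -> float:
    # M_ij = <mu_i mu_j>; S2 = (3 tr(M^2) - 1) / 2 since M is symmetric
    M = vectors.T @ vectors / vectors.shape[0]
    return float(0.5 * (3.0 * np.sum(M * M) - 1.0))


def compute_s2(series: BondVectorSeries | np.ndarray) -> OrderParameterResult:
    """Order parameter from a unit-vector series (≥ 2 frames).

    Accepts either a :class:`BondVectorSeries` or a raw ``(n, 3)`` array.
    """
    if isinstance(series, BondVectorSeries):
        vectors = series.vectors
        residue_id = series.residue_id
    else:
        vectors = np.asarray(series, dtype=float).reshape(-1, 3)
        residue_id = ("", 0, "")
    if vectors.shape[0] < 2:
        raise ParameterError("need at least 2 frames to estimate S2")
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ParameterError("bond vectors must be unit length (tolerance 1e-6)")
    return OrderParameterResult(
        residue_id=residue_id,
        s2=_s2_from_vectors(vectors),
        n_frames=vectors.shape[0],
    )


def block_sem(series: BondVectorSeries, n_blocks: int = 10) -> OrderParameterResult:
    """S² on the full series plus a block-averaged SEM.

    The series is split into ``n_blocks`` contiguous equal blocks (remainder
    frames at the end are dropped for the block estimates only);
    ``sem = std(block S², ddof=1) / sqrt(n_blocks)``.
    """
    if n_blocks < 2:
        raise ParameterError("n_blocks must be >= 2")
    n = series.n_frames
    if n < 2 * n_blocks:
        raise ParameterError(
            f"need at least 2 frames per block ({2 * n_blocks} total), got {n}"
        )
    full = compute_s2(series)
    block_len = n // n_blocks
    block_s2 = np.array([
        _s2_from_vectors(series.vectors[k * block_len:(k + 1) * block_len])
        for k in range(n_blocks)
    ])
    sem = float(np.std(block_s2, ddof=1) / np.sqrt(n_blocks))
    return OrderParameterResult(
        residue_id=series.residue_id,
        s2=full.s2,
        sem=sem,
        n_frames=n,
        n_blocks=n_blocks,
    )


def compare_s2(a: list[OrderParameterResult], b: list[OrderParameterResult],
               z_threshold: float = 1.96) -> ResultTable:
    """Per-residue ΔS² between two conditions with a pooled-SEM significance call.

    ``ΔS² = S²_a − S²_b``; ``pooled_sem = sqrt(sem_a² + sem_b²)``; a residue
    is flagged significant iff ``|ΔS²| > z_threshold × pooled_sem``. No
    multiple-testing correction is applied.
    """
    b_by_id = {r.residue_id: r for r in b}
    if {r.residue_id for r in a} != set(b_by_id):
        raise PairingError("the two result sets cover different residues")
    rows = []
    for ra in a:
        rb = b_by_id[ra.residue_id]
        delta = ra.s2 - rb.s2
        pooled = float(np.sqrt(ra.sem ** 2 + rb.sem ** 2))
        rows.append({
            "residue": ra.label,
            "delta_s2": delta,
            "pooled_sem": pooled,
            "significant": bool(abs(delta) > z_threshold * pooled),
        })
    return ResultTable(
        data=pd.DataFrame(rows),
        metadata={"z_threshold": z_threshold},
    )


def s2_table(results: list[OrderParameterResult], metadata: dict | None = None) -> ResultTable:
    """Tabulate order-parameter results as residue / s2 / sem / n_frames."""
    rows = [
        {"residue": r.label, "s2": r.s2, "sem": r.sem, "n_frames": r.n_frames}
        for r in results
    ]
    return ResultTable(data=pd.DataFrame(rows), metadata=dict(metadata or {}))
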