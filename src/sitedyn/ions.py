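"""Positional-stability metrics for a tracked ion.

All metrics assume the trajectory has already been superposed on the protein
(global tumbling removed), so the ion's coordinates express motion relative
to the protein frame. The RMSD here is about a fixed reference position
(by default the first-frame position), not a pairwise frame-to-frame RMSD:
an ion rattling in a stable site gives a small value, an ion drifting to a
new site a large one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyInputError, ParameterError, SelectionError
from .io import Trajectory


@dataclass
class IonTrace:
    """Per-frame ion positions (Å, aligned frame) plus a reference position."""

    positions: np.ndarray  # (n_frames, 3)
    reference_position: np.ndarray | None = None  # defaults to frame 0
    frame_spacing: float = 1.0  # ps

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.positions.shape[0] < 2:
            raise EmptyInputError("an ion trace needs at least 2 frames")
        if not np.all(np.isfinite(self.positions)):
            raise ParameterError("ion positions must be finite")
        if self.reference_position is None:
            self.reference_position = self.positions[0].copy()
        else:
            self.reference_position = np.asarray(
                self.reference_position, dtype=float
            ).reshape(3)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def ion_trace_from_trajectory(traj: Trajectory, atom_selection: str,
                              reference_position=None) -> IonTrace:
    """Extract the trace of a single atom (e.g. ``"MG"``) from a trajectory."""
    idx = traj.topology.select(atom_selection)
    if len(idx) != 1:
        raise SelectionError(
            f"selection {atom_selection!r} resolved to {len(idx)} atoms, expected 1"
        )
    return IonTrace(
        positions=traj.coords[:, int(idx[0]), :],
        reference_position=reference_position,
        frame_spacing=traj.frame_spacing,
    )


def ion_rmsd(trace: IonTrace) -> float:
    """Root-mean-square deviation (Å) of the ion about its reference position."""
    d2 = np.sum((trace.positions - trace.reference_position) ** 2, axis=1)
    return float(np.sqrt(d2.mean()))


def endpoint_displacement(trace: IonTrace, head_window: int | None = None,
                          tail_window: int | None = None) -> float:
    """Distance (Å) between the mean initial and mean final ion position.

    Window defaults are 1% of the frames (minimum 1 frame) at each end,
    which damps single-frame noise while staying faithful to
    "initial vs final position".
    """
    n = trace.n_frames
    default = max(1, n // 100)
    head = default if head_window is None else int(head_window)
    tail = default if tail_window is None else int(tail_window)
    if head < 1 or tail < 1:
        raise ParameterError("endpoint windows must be >= 1 frame")
    if head + tail > n:
        raise ParameterError(
            f"windows overlap: {head} + {tail} frames > {n} total"
        )
    start = trace.positions[:head].mean(axis=0)
    end = trace.positions[n - tail:].mean(axis=0)
    return float(np.linalg.norm(end - start))


def site_distance(site_a, site_b) -> float:
    """Euclidean distance (Å) between two site positions."""
    a = np.asarray(site_a, dtype=float).reshape(3)
    b = np.asarray(site_b, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("site coordinates must be finite")
    return float(np.linalg.norm(a - b))
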