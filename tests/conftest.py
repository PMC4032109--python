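import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sitedyn.io import Structure  # noqa: E402


def make_structure(records) -> Structure:
    """Build a Structure from (name, resname, chain, resnum, xyz) records.

    Element is guessed from the atom name; append ``het=True`` as a sixth
    field for HETATM atoms.
    """
    rows = []
    for rec in records:
        name, resname, chain, resnum, xyz = rec[:5]
        het = rec[5] if len(rec) > 5 else False
        el = rec[6] if len(rec) > 6 else name.lstrip("0123456789")[:1]
        rows.append((name, resname, chain, resnum, xyz, het, el))
    return Structure(
        serials=np.arange(1, len(rows) + 1),
        atom_names=[r[0] for r in rows],
        residue_names=[r[1] for r in rows],
        chain_ids=[r[2] for r in rows],
        residue_numbers=np.array([r[3] for r in rows]),
        coords=np.array([r[4] for r in rows], dtype=float),
        b_factors=np.zeros(len(rows)),
        elements=[r[6] for r in rows],
        het_flags=np.array([r[5] for r in rows], dtype=bool),
    )


@pytest.fixture
def arg_asp_structure():
    """An Arg donor residue facing an Asp acceptor (explicit guanidinium Hs)."""
    nh = 1.01

    def h(base, direction):
        d = np.asarray(direction, dtype=float)
        return np.asarray(base) + nh * d / np.linalg.norm(d)

    ne = (1.33, 0.0, 0.0)
    nh1 = (-0.665, 1.152, 0.0)
    nh2 = (-0.665, -1.152, 0.0)
    records = [
        # ARG 10 backbone (no hydrogens) + guanidinium
        ("N", "ARG", "A", 10, (-6.0, 0.0, 0.0)),
        ("CA", "ARG", "A", 10, (-5.0, 1.0, 0.0)),
        ("C", "ARG", "A", 10, (-5.5, 2.4, 0.0)),
        ("O", "ARG", "A", 10, (-6.7, 2.6, 0.0)),
        ("CB", "ARG", "A", 10, (-3.6, 0.6, 0.0)),
        ("CZ", "ARG", "A", 10, (0.0, 0.0, 0.0)),
        ("NE", "ARG", "A", 10, ne),
        ("HE", "ARG", "A", 10, h(ne, (1.0, 1.0, 0.0))),
        ("NH1", "ARG", "A", 10, nh1),
        ("HH11", "ARG", "A", 10, h(nh1, (-0.3, 1.0, 0.0))),
        ("HH12", "ARG", "A", 10, h(nh1, (-1.0, 0.3, 0.5))),
        ("NH2", "ARG", "A", 10, nh2),
        ("HH21", "ARG", "A", 10, h(nh2, (-0.3, -1.0, 0.0))),
        ("HH22", "ARG", "A", 10, h(nh2, (-1.0, -0.3, -0.5))),
        # ASP 20
        ("N", "ASP", "A", 20, (8.0, -2.0, 0.0)),
        ("CA", "ASP", "A", 20, (7.5, -0.8, 0.0)),
        ("C", "ASP", "A", 20, (8.4, 0.4, 0.0)),
        ("O", "ASP", "A", 20, (9.6, 0.3, 0.0)),
        ("CB", "ASP", "A", 20, (6.2, -0.5, 0.2)),
        ("CG", "ASP", "A", 20, (5.4, 0.6, 0.1)),
        ("OD1", "ASP", "A", 20, (4.2, 0.4, 0.0)),
        ("OD2", "ASP", "A", 20, (5.9, 1.8, 0.1)),
    ]
    return make_structure(records)
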