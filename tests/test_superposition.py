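"""Kabsch superposition: optimality, invariances, alignment, ion transplant."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import sitedyn as sd
from sitedyn.exceptions import CongruenceError, DegeneracyError

RNG = np.random.default_rng(20240917)


def _random_transform(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    return R, t


def test_identical_sets_give_identity():
    pts = RNG.normal(size=(8, 3))
    fit = sd.kabsch_fit(pts, pts)
    assert fit.rmsd == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-10)
    assert np.linalg.det(fit.rotation) == pytest.approx(1.0)


def test_exact_recovery_of_rigid_transform():
    pts = RNG.normal(size=(12, 3))
    R, t = _random_transform(RNG)
    fit = sd.kabsch_fit(pts, pts @ R.T + t)
    assert fit.rmsd < 1e-8
    np.testing.assert_allclose(fit.rotation, R, atol=1e-8)
    np.testing.assert_allclose(fit.translation, t, atol=1e-7)


def test_beats_random_rotations():
    """Kabsch RMSD is minimal among 1000 random proper rotations (brute force)."""
    mobile = RNG.normal(size=(10, 3))
    reference = mobile + RNG.normal(scale=0.3, size=(10, 3))
    fit = sd.kabsch_fit(mobile, reference)
    mob_c = mobile - mobile.mean(0)
    ref_mean = reference.mean(0)
    for R in Rotation.random(1000, rng=np.random.default_rng(5)).as_matrix():
        moved = mob_c @ R.T + ref_mean
        rmsd = np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))
        assert fit.rmsd <= rmsd + 1e-12


@given(st.integers(0, 2 ** 31 - 1))
def test_rmsd_invariant_under_common_rigid_transform(seed):
    rng = np.random.default_rng(seed)
    mobile = rng.normal(size=(7, 3))
    reference = mobile + rng.normal(scale=0.5, size=(7, 3))
    base = sd.kabsch_fit(mobile, reference).rmsd
    R, t = _random_transform(rng)
    moved = sd.kabsch_fit(mobile @ R.T + t, reference @ R.T + t).rmsd
    assert moved == pytest.approx(base, abs=1e-8)


def test_degenerate_inputs_raise():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(DegeneracyError):
        sd.kabsch_fit(line, line + 1.0)
    with pytest.raises(DegeneracyError):
        sd.kabsch_fit(np.zeros((2, 3)), np.ones((2, 3)))
    with pytest.raises(CongruenceError):
        sd.kabsch_fit(np.zeros((4, 3)), np.zeros((5, 3)))


def test_align_recovers_tumbled_rigid_body():
    traj, _ = sd.gen_confined_ion_trajectory(0.0, 30, seed=1)  # fully rigid
    tumbled = sd.apply_global_tumbling(traj, seed=2)
    aligned = sd.align_frames(tumbled, traj.topology)
    np.testing.assert_allclose(aligned.coords,
                               np.broadcast_to(traj.topology.coords, traj.coords.shape),
                               atol=1e-6)


def test_align_is_idempotent():
    traj, _ = sd.gen_cone_trajectory(45, 40, seed=3)
    tumbled = sd.apply_global_tumbling(traj, seed=4)
    once = sd.align_frames(tumbled, traj.topology)
    twice = sd.align_frames(once, traj.topology)
    np.testing.assert_allclose(twice.coords, once.coords, atol=1e-8)


def test_alignment_restores_untumbled_s2():
    traj, _ = sd.gen_cone_trajectory(30, 4000, seed=5)
    s2_ref = sd.compute_s2(sd.extract_bond_vectors(traj)[0]).s2
    tumbled = sd.apply_global_tumbling(traj, seed=6)
    aligned = sd.align_frames(tumbled, traj.topology)
    s2_aligned = sd.compute_s2(sd.extract_bond_vectors(aligned)[0]).s2
    assert abs(s2_aligned - s2_ref) < 0.02


def _ion_structure(extra_transform=None):
    from sitedyn.synth import _asp_scaffold

    st_, _, _ = _asp_scaffold(4)
    ion = np.array([3.0, 2.0, 5.0])
    from dataclasses import replace

    st_ = replace(
        st_,
        serials=np.append(st_.serials, st_.serials.max() + 1),
        atom_names=st_.atom_names + ["MG"],
        residue_names=st_.residue_names + ["MG"],
        chain_ids=st_.chain_ids + ["B"],
        residue_numbers=np.append(st_.residue_numbers, 1),
        coords=np.vstack([st_.coords, ion]),
        b_factors=np.append(st_.b_factors, 0.0),
        elements=st_.elements + ["MG"],
        het_flags=np.append(st_.het_flags, True),
    )
    if extra_transform is not None:
        R, t = extra_transform
        st_ = st_.with_coords(st_.coords @ R.T + t)
    return st_


def test_transplant_into_self_is_noop_on_position():
    donor = _ion_structure()
    acceptor = _ion_structure()
    # remove the ion from the acceptor so identities stay unique
    keep = [i for i, n in enumerate(acceptor.atom_names) if n != "MG"]
    from dataclasses import replace

    acceptor = replace(
        acceptor,
        serials=acceptor.serials[keep],
        atom_names=[acceptor.atom_names[i] for i in keep],
        residue_names=[acceptor.residue_names[i] for i in keep],
        chain_ids=[acceptor.chain_ids[i] for i in keep],
        residue_numbers=acceptor.residue_numbers[keep],
        coords=acceptor.coords[keep],
        b_factors=acceptor.b_factors[keep],
        elements=[acceptor.elements[i] for i in keep],
        het_flags=acceptor.het_flags[keep],
    )
    out = sd.transplant_ion(donor, acceptor, "MG")
    assert out.n_atoms == acceptor.n_atoms + 1
    np.testing.assert_allclose(out.coords[-1], [3.0, 2.0, 5.0], atol=1e-10)


def test_transplant_maps_through_known_transform():
    """Ion lands at the hand-computed image of the donor ion position."""
    donor = _ion_structure()
    R, t = _random_transform(np.random.default_rng(11))
    acceptor = _ion_structure(extra_transform=(R, t))
    out = sd.transplant_ion(donor, acceptor, "B:1:MG")
    expected = R @ np.array([3.0, 2.0, 5.0]) + t
    np.testing.assert_allclose(out.coords[-1], expected, atol=1e-6)
    assert out.het_flags[-1]
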