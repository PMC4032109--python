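"""S² estimator: closed forms, invariances, block errors, condition comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import sitedyn as sd
from sitedyn.exceptions import ExtractionError, PairingError, ParameterError
from sitedyn.order_params import DENQ_BONDS
from sitedyn.synth import sample_cone_vectors

from conftest import make_structure


def brute_force_s2(vectors):
    """Independent oracle: explicit double loop over the Cartesian components."""
    n = vectors.shape[0]
    total = 0.0
    for i in range(3):
        for j in range(3):
            mean_ij = sum(vectors[k, i] * vectors[k, j] for k in range(n)) / n
            total += mean_ij ** 2
    return 0.5 * (3.0 * total - 1.0)


def test_constant_vector_is_one():
    v = np.tile([0.6, 0.0, 0.8], (50, 1))
    assert sd.compute_s2(v).s2 == pytest.approx(1.0, abs=1e-12)


def test_matches_brute_force_double_loop():
    rng = np.random.default_rng(0)
    v = rng.normal(size=(40, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    assert sd.compute_s2(v).s2 == pytest.approx(brute_force_s2(v), abs=1e-12)


def test_isotropic_limit():
    v = sample_cone_vectors(180.0, 10 ** 6, np.random.default_rng(1))
    assert sd.compute_s2(v).s2 == pytest.approx(0.0, abs=0.01)


def test_two_site_jump_closed_form():
    """Equal-population 90° jump: brute-force evaluation on the two-orientation
    ensemble gives (3cos²β+1)/4 = 0.25; the sampled estimate matches."""
    mu1 = np.array([0.0, 0.0, 1.0])
    mu2 = np.array([1.0, 0.0, 0.0])
    exact_ensemble = brute_force_s2(np.array([mu1, mu2]))  # equal weights
    assert exact_ensemble == pytest.approx(0.25, abs=1e-12)

    traj, truth = sd.gen_two_site_trajectory(90.0, 10 ** 5, p=0.5, seed=2)
    est = sd.compute_s2(sd.extract_bond_vectors(traj)[0]).s2
    assert truth["s2_analytic"] == pytest.approx(0.25)
    assert est == pytest.approx(0.25, abs=0.02)


def test_cone_closed_form_60deg():
    v = sample_cone_vectors(60.0, 10 ** 6, np.random.default_rng(3))
    assert sd.compute_s2(v).s2 == pytest.approx(0.140625, abs=0.01)


def test_cone_recovery_grid_and_monotonicity():
    angles = [10.0, 30.0, 60.0, 90.0]
    estimates = []
    for k, theta in enumerate(angles):
        v = sample_cone_vectors(theta, 10 ** 6, np.random.default_rng(10 + k))
        s2 = sd.compute_s2(v).s2
        assert s2 == pytest.approx(sd.cone_s2(theta), abs=0.01)
        estimates.append(s2)
    assert all(a > b for a, b in zip(estimates, estimates[1:]))


@given(st.integers(0, 2 ** 31 - 1))
def test_sign_flip_and_rotation_invariance(seed):
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(30, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    base = sd.compute_s2(v).s2
    flips = rng.choice([-1.0, 1.0], size=(30, 1))
    assert sd.compute_s2(v * flips).s2 == pytest.approx(base, abs=1e-12)
    R = Rotation.random(rng=rng).as_matrix()
    assert sd.compute_s2(v @ R.T).s2 == pytest.approx(base, abs=1e-10)


def test_algebraic_range():
    # antiparallel pair in a plane drives S2 to its algebraic minimum -0.5 side
    v = np.array([[1.0, 0, 0], [0, 1.0, 0]] * 10)
    s2 = sd.compute_s2(v).s2
    assert -0.5 - 1e-12 <= s2 <= 1.0 + 1e-12


def test_non_unit_vectors_rejected():
    with pytest.raises(ParameterError):
        sd.compute_s2(np.tile([0.0, 0.0, 2.0], (10, 1)))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extract_constant_bond_vector():
    records = [
        ("N", "ASP", "A", 1, (5.0, 5.0, 0.0)),
        ("CA", "ASP", "A", 1, (6.0, 5.5, 0.0)),
        ("CB", "ASP", "A", 1, (0.0, 0.0, 0.0)),
        ("CG", "ASP", "A", 1, (0.0, 0.0, 2.0)),
    ]
    top = make_structure(records)
    traj = sd.Trajectory(topology=top, coords=np.tile(top.coords, (5, 1, 1)),
                         frame_spacing=1.0)
    (series,) = sd.extract_bond_vectors(traj)
    np.testing.assert_allclose(series.vectors, np.tile([0, 0, 1.0], (5, 1)))
    assert sd.compute_s2(series).s2 == pytest.approx(1.0)


def test_gln_bond_naming_contract():
    records = [
        ("CG", "GLN", "A", 7, (0.0, 0.0, 0.0)),
        ("CD", "GLN", "A", 7, (1.5, 0.0, 0.0)),
        ("N", "GLN", "A", 7, (3.0, 2.0, 1.0)),
    ]
    top = make_structure(records)
    traj = sd.Trajectory(topology=top, coords=np.tile(top.coords, (3, 1, 1)),
                         frame_spacing=1.0)
    (series,) = sd.extract_bond_vectors(traj, residue_types="Q")
    assert series.bond == ("CG", "CD")
    assert DENQ_BONDS["GLN"] == ("CG", "CD")


def test_extract_missing_atom_names_residue():
    records = [("CB", "ASP", "A", 3, (0.0, 0.0, 0.0))]  # no CG
    top = make_structure(records)
    traj = sd.Trajectory(topology=top, coords=np.tile(top.coords, (2, 1, 1)),
                         frame_spacing=1.0)
    with pytest.raises(ExtractionError, match="ASP3"):
        sd.extract_bond_vectors(traj)


def test_cone_vectors_respect_semi_angle_bound():
    traj, _ = sd.gen_cone_trajectory(25.0, 2000, seed=8)
    (series,) = sd.extract_bond_vectors(traj)
    polar = np.degrees(np.arccos(np.clip(series.vectors[:, 2], -1, 1)))
    assert polar.max() <= 25.0 + 1e-6


# ---------------------------------------------------------------------------
# block SEM
# ---------------------------------------------------------------------------

def test_block_sem_constant_series_is_zero():
    v = np.tile([0.0, 1.0, 0.0], (100, 1))
    series = sd.BondVectorSeries(("A", 1, "ASP"), ("CB", "CG"), v)
    res = sd.block_sem(series, n_blocks=5)
    assert res.sem == pytest.approx(0.0, abs=1e-15)
    assert res.s2 == pytest.approx(1.0)


def test_block_sem_two_block_hand_formula():
    """With per-block values a and b the SEM is |a-b|/2 (sample SD over √2)."""
    block1 = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]] * 10)  # s2 = 0.25
    block2 = np.tile([0.0, 0.0, 1.0], (20, 1))  # s2 = 1
    series = sd.BondVectorSeries(("A", 1, "ASP"), ("CB", "CG"),
                                 np.vstack([block1, block2]))
    res = sd.block_sem(series, n_blocks=2)
    assert res.sem == pytest.approx(abs(0.25 - 1.0) / 2.0, abs=1e-12)
    assert res.n_blocks == 2


def test_block_sem_isotropic_consistency():
    v = sample_cone_vectors(180.0, 10 ** 5, np.random.default_rng(12))
    series = sd.BondVectorSeries(("A", 1, "ASP"), ("CB", "CG"), v)
    res = sd.block_sem(series, n_blocks=10)
    assert res.sem > 0
    assert abs(res.s2) < 3 * res.sem + 0.01


def test_block_sem_parameter_errors():
    v = np.tile([0.0, 0.0, 1.0], (10, 1))
    series = sd.BondVectorSeries(("A", 1, "ASP"), ("CB", "CG"), v)
    with pytest.raises(ParameterError):
        sd.block_sem(series, n_blocks=1)
    with pytest.raises(ParameterError):
        sd.block_sem(series, n_blocks=6)  # < 2 frames per block


# ---------------------------------------------------------------------------
# cross-condition comparison
# ---------------------------------------------------------------------------

def _results(traj, n_blocks=10):
    return [sd.block_sem(s, n_blocks=n_blocks)
            for s in sd.extract_bond_vectors(traj)]


def test_compare_identical_conditions():
    traj, _ = sd.gen_cone_trajectory(60.0, 400, seed=13, n_residues=4)
    res = _results(traj)
    table = sd.compare_s2(res, res)
    assert (table.data["delta_s2"] == 0).all()
    assert not table.data["significant"].any()


def test_compare_threshold_arithmetic():
    a = [sd.OrderParameterResult(("A", 1, "ASP"), s2=0.9, sem=0.05, n_frames=10)]
    b = [sd.OrderParameterResult(("A", 1, "ASP"), s2=0.4, sem=0.087, n_frames=10)]
    table = sd.compare_s2(a, b)
    row = table.data.iloc[0]
    assert row["delta_s2"] == pytest.approx(0.5)
    assert row["pooled_sem"] == pytest.approx(np.sqrt(0.05 ** 2 + 0.087 ** 2))
    assert bool(row["significant"])  # 0.5 > 1.96 * 0.1


def test_compare_residue_mismatch():
    a = [sd.OrderParameterResult(("A", 1, "ASP"), s2=1.0, sem=0.0)]
    b = [sd.OrderParameterResult(("A", 2, "ASP"), s2=1.0, sem=0.0)]
    with pytest.raises(PairingError):
        sd.compare_s2(a, b)


def test_null_comparison_false_positive_rate():
    """Two independent isotropic conditions over 20 residues: at the nominal
    5% level no more than 3 residues should be flagged significant."""
    ta, _ = sd.gen_cone_trajectory(180.0, 2000, seed=100, n_residues=20)
    tb, _ = sd.gen_cone_trajectory(180.0, 2000, seed=200, n_residues=20)
    table = sd.compare_s2(_results(ta), _results(tb))
    assert int(table.data["significant"].sum()) <= 3
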