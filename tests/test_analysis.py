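"""Ensemble analysis estimators against geometric and statistical oracles."""

import math

import numpy as np
import pytest

from cgdna.analysis import (
    bending_profile,
    cross_rmsd_matrix,
    end_to_end,
    essential_modes,
    persistence_length,
    rmsip,
    shape_descriptors,
    superpose_rmsd,
    writhe,
)
from cgdna.synthetic import FluctuationSpec, ideal_bdna_beads, synth_ensemble
from cgdna.topology import DuplexSequence


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def test_rmsd_zero_for_rigid_copies():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(12, 3)) * 5
    frames = np.stack(
        [base @ _random_rotation(rng).T + rng.normal(size=3) * 10 for _ in range(6)]
    )
    rmsd, mean = superpose_rmsd(frames)
    assert np.abs(rmsd).max() < 1e-10


def test_rmsd_matches_hand_computed_toy():
    """Two 3-point frames whose optimal superposition is computable by
    hand: reference an equilateral triangle, mobile the same triangle with
    one vertex pulled out by d along its in-plane symmetry axis.  The
    centred difference leaves per-point displacements of 2d/3 and d/3,
    giving RMSd = d * sqrt(6)/3 / sqrt(3)."""
    ref = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, math.sqrt(3) / 2, 0]])
    d = 0.3
    mob = ref.copy()
    mob[2, 1] += d
    # optimal rotation is identity here by symmetry (displacement along the
    # symmetry axis through the centroid)
    diff = (mob - mob.mean(axis=0)) - (ref - ref.mean(axis=0))
    expect = math.sqrt(np.mean(np.sum(diff**2, axis=1)))
    rmsd, _ = superpose_rmsd(mob[None], reference=ref)
    assert rmsd[0] == pytest.approx(expect, rel=1e-6)


def test_rmsd_never_uses_reflections():
    """A mirror image of a chiral point set must not superpose to zero."""
    rng = np.random.default_rng(1)
    base = rng.normal(size=(10, 3)) * 4
    mirror = base * np.array([1.0, 1.0, -1.0])
    rmsd, _ = superpose_rmsd(mirror[None], reference=base)
    assert rmsd[0] > 0.5


def test_rmsip_identity_and_orthogonality():
    rng = np.random.default_rng(2)
    frames = rng.normal(size=(40, 10, 3)) * 0.3 + np.arange(10)[None, :, None]
    modes = essential_modes(frames, n_modes=5)
    assert rmsip(modes, modes, n=5) == pytest.approx(1.0)
    # orthonormality of the mode vectors
    gram = modes.vectors @ modes.vectors.T
    assert np.abs(gram - np.eye(5)).max() < 1e-8
    # eigenvalues non-increasing
    assert np.all(np.diff(modes.eigenvalues) <= 1e-12)
    # modes spanning orthogonal complements overlap to zero
    from cgdna.analysis import EssentialModes

    d = 30
    a = EssentialModes(np.eye(d)[:5], np.ones(5), np.zeros((10, 3)))
    b = EssentialModes(np.eye(d)[5:10], np.ones(5), np.zeros((10, 3)))
    assert rmsip(a, b, n=5) == 0.0


def test_rmsip_random_subspace_expectation():
    """Random n-mode subspaces in dimension d: E[RMSIP^2] = n/d."""
    rng = np.random.default_rng(3)
    from cgdna.analysis import EssentialModes

    d, n, draws = 30, 5, 400
    vals = []
    for _ in range(draws):
        qa, _ = np.linalg.qr(rng.normal(size=(d, n)))
        qb, _ = np.linalg.qr(rng.normal(size=(d, n)))
        a = EssentialModes(qa.T, np.ones(n), np.zeros((d // 3, 3)))
        b = EssentialModes(qb.T, np.ones(n), np.zeros((d // 3, 3)))
        vals.append(rmsip(a, b, n=n) ** 2)
    assert np.mean(vals) == pytest.approx(n / d, rel=0.1)


def test_end_to_end_ideal_and_single_frame():
    seq = DuplexSequence("GCGCATATGCGCATATGC")
    beads = ideal_bdna_beads(seq)
    mean, sd = end_to_end(beads[None])
    assert mean == pytest.approx(17 * 3.38, rel=1e-9)  # 57.46 Å
    assert sd == 0.0


def test_persistence_length_straight_chain_is_infinite():
    seq = DuplexSequence("GCGCATATGCGCATATGCGC")
    beads = ideal_bdna_beads(seq)
    assert persistence_length(np.stack([beads, beads])) == math.inf


@pytest.fixture(scope="module")
def wlc_ensembles():
    rng = np.random.default_rng(4)
    seq = DuplexSequence("".join(rng.choice(list("ACGT"), 250)))
    short = synth_ensemble(
        seq, fluct=FluctuationSpec(persistence_length=50.0, seed=5), n_frames=400
    )
    seq2 = DuplexSequence("".join(rng.choice(list("ACGT"), 500)))
    double = synth_ensemble(
        seq2, fluct=FluctuationSpec(persistence_length=50.0, seed=6), n_frames=200
    )
    return short, double


def test_wlc_persistence_length_recovery(wlc_ensembles):
    short, _ = wlc_ensembles
    assert persistence_length(short) == pytest.approx(50.0, rel=0.10)


def test_persistence_length_is_intensive(wlc_ensembles):
    """Doubling the contour length leaves the estimate unchanged within
    sampling error."""
    short, double = wlc_ensembles
    pl_short = persistence_length(short)
    pl_double = persistence_length(double)
    assert pl_double == pytest.approx(pl_short, rel=0.15)


def test_gyration_ring_and_rod_limits():
    # ring of radius R: Rg -> R
    n = 400
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring = np.stack([50 * np.cos(th), 50 * np.sin(th), np.zeros(n)], axis=1)
    rg, aspect = shape_descriptors(ring[None])
    assert rg[0] == pytest.approx(50.0, rel=1e-3)
    # dense rod of length L: Rg -> L / sqrt(12)
    rod = np.stack([np.zeros(n), np.zeros(n), np.linspace(0, 100, n)], axis=1)
    rg, aspect = shape_descriptors(rod[None])
    assert rg[0] == pytest.approx(100 / math.sqrt(12), rel=1e-2)
    assert aspect[0] > 1e3  # rod is maximally anisotropic


def test_gyration_isotropic_cloud_aspect_near_one():
    rng = np.random.default_rng(5)
    cloud = rng.normal(size=(1, 4000, 3))
    _, aspect = shape_descriptors(cloud)
    assert aspect[0] == pytest.approx(1.0, abs=0.1)


def test_bending_profile_straight_and_ring():
    seq = DuplexSequence("GCGCATATGCGCATATGCGC")
    straight = ideal_bdna_beads(seq)
    mean, sd = bending_profile(straight[None], window=4)
    assert np.abs(mean).max() < 1e-9
    assert len(mean) == 20 - 4
    # planar ring: the chord bend at every position equals the arc angle
    # subtended by half the window on each side, w/2 * (360/n) * 2 / 2
    n, w = 90, 10
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ring_mid = np.stack([np.cos(th), np.sin(th), np.zeros(n)], axis=1) * 40
    # feed as a degenerate "duplex" by duplicating the curve as both strands
    ring_beads = np.concatenate([ring_mid, ring_mid[::-1]], axis=0)
    mean, _ = bending_profile(ring_beads[None], window=w, circular=True)
    assert mean == pytest.approx(w * 180.0 / n, rel=1e-6)


def test_bending_profile_localizes_flexible_segment():
    """A stiff synthetic chain with a floppy middle segment shows its
    bending-profile maximum inside that segment."""
    rng = np.random.default_rng(6)
    n = 120
    frames = []
    for _ in range(150):
        tilts = rng.normal(0, 0.01, size=(n - 1, 2))
        tilts[55:65] = rng.normal(0, 0.25, size=(10, 2))
        pts = np.zeros((n, 3))
        t = np.array([0.0, 0.0, 1.0])
        frame = np.eye(3)
        for s in range(n - 1):
            cx, sx = np.cos(tilts[s, 0]), np.sin(tilts[s, 0])
            cy, sy = np.cos(tilts[s, 1]), np.sin(tilts[s, 1])
            rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
            ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
            frame = frame @ rx @ ry
            pts[s + 1] = pts[s] + 3.38 * frame[:, 2]
        frames.append(np.concatenate([pts, pts[::-1]], axis=0))
    mean, _ = bending_profile(np.stack(frames), window=20)
    peak = np.argmax(mean) + 10  # profile offset by window/2
    assert 50 <= peak <= 70


def test_writhe_oracles():
    # planar circle: writhe ~ 0
    n = 80
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    circle = np.stack([np.cos(th), np.sin(th), np.zeros(n)], axis=1) * 30
    assert abs(writhe(circle)) < 1e-3

    # a closed curve with self-crossing structure: the coarse value matches
    # a 4x-refined evaluation (refinement-convergence oracle)
    def curve(m):
        t = np.linspace(0, 2 * np.pi, m, endpoint=False)
        return np.stack(
            [
                (2 + np.cos(2 * t)) * np.cos(3 * t),
                (2 + np.cos(2 * t)) * np.sin(3 * t),
                np.sin(2 * t),
            ],
            axis=1,
        ) * 10
    assert writhe(curve(120)) == pytest.approx(writhe(curve(480)), abs=5e-3)
    # rigid rotation leaves writhe unchanged
    rng = np.random.default_rng(7)
    q = _random_rotation(rng)
    assert writhe(curve(120) @ q.T) == pytest.approx(writhe(curve(120)), abs=1e-12)


def test_cross_rmsd_matrix_structure():
    rng = np.random.default_rng(8)
    family_a = rng.normal(size=(1, 15, 3)) + rng.normal(0, 0.05, size=(6, 15, 3))
    family_b = family_a[0] * np.array([1.3, 0.8, 1.1]) + rng.normal(
        0, 0.05, size=(6, 15, 3)
    )
    mat, blocks = cross_rmsd_matrix(family_a, family_b)
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 0.0)
    (a0, a1), (b0, b1) = blocks
    within = np.concatenate(
        [mat[a0:a1, a0:a1].ravel(), mat[b0:b1, b0:b1].ravel()]
    )
    between = mat[a0:a1, b0:b1].ravel()
    assert within.mean() < between.mean()


def test_estimators_invariant_under_rigid_motion(wlc_ensembles):
    short, _ = wlc_ensembles
    rng = np.random.default_rng(9)
    q = _random_rotation(rng)
    moved = short.frames @ q.T + np.array([5.0, -8.0, 11.0])
    m0, s0 = end_to_end(short)
    m1, s1 = end_to_end(moved)
    assert m1 == pytest.approx(m0, rel=1e-12)
    assert s1 == pytest.approx(s0, rel=1e-9)
    assert persistence_length(moved) == pytest.approx(
        persistence_length(short), rel=1e-9
    )
    rg0, a0 = shape_descriptors(short)
    rg1, a1 = shape_descriptors(moved)
    assert np.allclose(rg0, rg1)
    assert np.allclose(a0, a1)
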