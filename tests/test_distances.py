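"""Distance measures: superposition, GDT-TS, Q*, FlexE/MT, dispatcher.

Oracles are independent of the implementation: superposition is checked
against a rotation-grid search with local refinement, and GDT against an
exhaustive contiguous-fragment enumeration without iterative refinement.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from funnelpot.distances import (ContactMap, ElasticConfig, contact_map,
                                 flexe, gdt_ts, gdt_ts_star, measure, mt,
                                 q_star, rmsd, superpose)
from funnelpot.errors import DegenerateInputError
from funnelpot.synthetic import SynthConfig, gen_decoys

from conftest import make_chain, random_compact_chain, straight_chain


def rigid_motion(coords, angles=(0.3, -1.1, 2.0), shift=(5.0, -3.0, 8.0)):
    R = Rotation.from_euler("xyz", angles).as_matrix()
    return coords @ R.T + np.asarray(shift)


def oracle_rmsd(a, b, n_grid=12):
    """Brute-force optimal-superposition RMSD: dense Euler-angle grid with
    per-rotation optimal translation (centroid match), then Nelder-Mead
    refinement from the best grid point.  Never calls the Kabsch solution.
    """
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def cost(angles):
        R = Rotation.from_euler("xyz", angles).as_matrix()
        return np.sqrt(np.mean(np.sum((a0 - b0 @ R.T) ** 2, axis=1)))

    grid = np.linspace(-np.pi, np.pi, n_grid, endpoint=False)
    best_angles, best = None, np.inf
    for ax in grid:
        for ay in grid[: n_grid // 2]:
            for az in grid:
                v = cost((ax, ay, az))
                if v < best:
                    best, best_angles = v, (ax, ay, az)
    res = minimize(cost, best_angles, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    return min(best, res.fun)


class TestSuperpose:
    def test_identity(self):
        m = random_compact_chain(10, seed=0)
        tf, val = superpose(m, m)
        assert val == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_gives_zero(self):
        m = random_compact_chain(12, seed=1)
        moved = make_chain(rigid_motion(m.coords), seq=m.seq)
        assert rmsd(m, moved) == pytest.approx(0.0, abs=1e-6)

    def test_tetrahedron_against_grid_oracle(self):
        a = np.array([[0.0, 0, 0], [3, 0, 0], [1.5, 2.6, 0], [1.5, 0.9, 2.4]])
        b = a.copy()
        b[3] += [0.6, -0.5, 0.6]  # displace one vertex by ~1 Å
        b = rigid_motion(b)
        A = make_chain(a, seq="ACDE")
        B = make_chain(b, seq="ACDE")
        got = rmsd(A, B)
        assert got == pytest.approx(oracle_rmsd(a, b), abs=1e-3)

    def test_reflection_excluded(self):
        m = random_compact_chain(10, seed=2)
        mirrored = make_chain(m.coords * np.array([-1.0, 1.0, 1.0]),
                              seq=m.seq)
        tf, val = superpose(m, mirrored)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert val > 0.1  # a chiral fold cannot be superposed on its mirror

    def test_too_few_points(self):
        a = make_chain(np.zeros((2, 3)) + np.arange(2)[:, None] * 4)
        with pytest.raises(DegenerateInputError):
            superpose(a, a)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_rmsd_metric_properties(self, seed):
        """Symmetry and triangle inequality on random equal-length triples."""
        rng = np.random.default_rng(seed)
        pts = [make_chain(rng.normal(scale=5.0, size=(8, 3))) for _ in range(3)]
        d01, d10 = rmsd(pts[0], pts[1]), rmsd(pts[1], pts[0])
        assert d01 == pytest.approx(d10, abs=1e-8)
        d02, d12 = rmsd(pts[0], pts[2]), rmsd(pts[1], pts[2])
        assert d02 <= d01 + d12 + 1e-8


def oracle_gdt(a, b, cutoffs=(1.0, 2.0, 4.0, 8.0)):
    """Exhaustive contiguous-fragment GDT: superpose on every contiguous
    fragment of every length >= 3 and count inliers, no refinement."""
    from funnelpot.distances import _superpose_arrays
    n = a.shape[0]
    total = 0.0
    for cutoff in cutoffs:
        best = 0
        for length in range(3, n + 1):
            for start in range(0, n - length + 1):
                idx = np.arange(start, start + length)
                tf, _ = _superpose_arrays(a[idx], b[idx])
                d2 = np.sum((a - tf.apply(b)) ** 2, axis=1)
                best = max(best, int((d2 <= cutoff ** 2).sum()))
        total += best / n
    return total / len(cutoffs)


class TestGdtTs:
    def test_rigid_motion_gives_one(self):
        m = random_compact_chain(15, seed=3)
        moved = make_chain(rigid_motion(m.coords), seq=m.seq)
        assert gdt_ts(m, moved) == pytest.approx(1.0)
        assert gdt_ts_star(m, moved) == pytest.approx(0.0)

    def test_small_perturbation_still_one(self, rng):
        m = random_compact_chain(15, seed=4)
        noise = rng.uniform(-0.15, 0.15, size=m.coords.shape)
        assert np.all(np.linalg.norm(noise, axis=1) < 0.3)
        pert = make_chain(m.coords + noise, seq=m.seq)
        assert gdt_ts(m, pert) == pytest.approx(1.0)

    def test_scaled_chain_matches_exhaustive_oracle(self):
        m = random_compact_chain(20, seed=5)
        assert np.linalg.norm(
            m.coords - m.coords.mean(axis=0), axis=1).max() > 8.0
        scaled = make_chain(m.coords * 10.0, seq=m.seq)
        got = gdt_ts(m, scaled)
        want = oracle_gdt(m.coords, scaled.coords)
        assert got == pytest.approx(want, abs=0.05)

    def test_monotone_in_noise_amplitude(self):
        """GDT-TS decreases (statistically) as noise amplitude grows."""
        m = random_compact_chain(20, seed=6)
        means = []
        for sigma in (0.5, 2.0, 6.0):
            vals = []
            for s in range(5):
                rng = np.random.default_rng(100 * s + 1)
                pert = make_chain(m.coords + rng.normal(
                    scale=sigma, size=m.coords.shape), seq=m.seq)
                vals.append(gdt_ts(m, pert))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]


class TestContactMap:
    def test_two_close_residues_filtered_by_separation(self):
        m = straight_chain(2)
        cm = contact_map(m, threshold=9.0, min_sep=3)
        assert cm.count() == 0

    def test_straight_chain_threshold_9_empty(self):
        # spacing 3.8: |i-j|=3 gives 11.4 Å > 9 Å
        m = straight_chain(10)
        assert contact_map(m, threshold=9.0, min_sep=3).count() == 0

    def test_straight_chain_threshold_12_separation_3_only(self):
        # 11.4 <= 12 < 15.2: exactly the |i-j| = 3 pairs
        m = straight_chain(10)
        cm = contact_map(m, threshold=12.0, min_sep=3)
        i, j = cm.pairs
        assert np.all(j - i == 3)
        assert cm.count() == 7

    def test_min_sep_band_enforced_by_type(self):
        bad = np.zeros((5, 5), dtype=bool)
        bad[0, 1] = bad[1, 0] = True
        with pytest.raises(ValueError):
            ContactMap(n=5, contacts=bad, threshold=9.0, min_sep=3)


def q_fixture():
    """Straight chain, spacing 4 Å, threshold 12, min_sep 3: contacts are
    exactly the |i-j| = 3 pairs (distance 12).  13 residues -> 10 contacts.
    Stretching the bond between residues 5 and 6 breaks the 3 contacts
    spanning it."""
    native = straight_chain(13, spacing=4.0)
    coords = native.coords.copy()
    coords[6:, 0] += 1.0
    decoy = make_chain(coords, seq=native.seq, ident="stretched")
    return native, decoy


class TestQStar:
    def test_self_is_zero(self):
        m = random_compact_chain(20, seed=7)
        assert q_star(m, m) == 0.0

    def test_total_contact_loss(self):
        m = random_compact_chain(20, seed=8)
        stretched = make_chain(m.coords * 10.0, seq=m.seq)
        assert q_star(m, stretched) == pytest.approx(1.0)

    def test_retains_7_of_10_contacts(self):
        native, decoy = q_fixture()
        assert contact_map(native, 12.0, 3).count() == 10
        assert q_star(native, decoy, threshold=12.0, min_sep=3) == \
            pytest.approx(0.3)

    def test_gained_contacts_do_not_count(self):
        """Q* uses only the native contact set."""
        native = straight_chain(13, spacing=4.0)
        coords = native.coords.copy()
        coords[12] = coords[0] + np.array([0.0, 5.0, 0.0])  # new contact
        decoy = make_chain(coords, seq=native.seq)
        base = make_chain(native.coords.copy(), seq=native.seq)
        q_decoy = q_star(native, decoy, threshold=12.0, min_sep=3)
        # moving residue 12 breaks only its own native contact (9,12)
        assert q_decoy == pytest.approx(0.1)
        assert q_star(native, base, threshold=12.0, min_sep=3) == 0.0


class TestElastic:
    def make_single_contact_pair(self, d_decoy):
        """Two residues at native distance 5, decoy distance d_decoy; with
        min_sep=1 and threshold 9 they form the single native contact."""
        native = make_chain([[0, 0, 0], [5.0, 0, 0]], seq="AC")
        decoy = make_chain([[0, 0, 0], [d_decoy, 0.0, 0.0]], seq="AC")
        cfg = ElasticConfig(k=1.0, b=0.5, contact_threshold=9.0, min_sep=1)
        return native, decoy, cfg

    def test_self_is_zero(self):
        m = random_compact_chain(20, seed=9)
        cfg = ElasticConfig()
        assert flexe(m, m, cfg) == 0.0
        assert mt(m, m, cfg) == 0.0

    def test_flexe_closed_form_single_pair(self):
        native, decoy, cfg = self.make_single_contact_pair(6.0)
        assert flexe(native, decoy, cfg) == pytest.approx(0.5)

    def test_flexe_sign_symmetry(self):
        native, decoy, cfg = self.make_single_contact_pair(4.0)
        assert flexe(native, decoy, cfg) == pytest.approx(0.5)

    def test_mt_taylor_limit_matches_flexe(self):
        for d in (5.01, 4.99):
            native, decoy, cfg = self.make_single_contact_pair(d)
            ratio = mt(native, decoy, cfg) / flexe(native, decoy, cfg)
            assert 0.99 <= ratio <= 1.01

    def test_mt_penalizes_compression_more(self):
        native, comp, cfg = self.make_single_contact_pair(3.0)   # Δ = -2
        _, ext, _ = self.make_single_contact_pair(7.0)           # Δ = +2
        assert mt(native, comp, cfg) > mt(native, ext, cfg)

    def test_rigid_motion_invariance(self):
        m = random_compact_chain(20, seed=10)
        cfg = ElasticConfig()
        scfg = SynthConfig(n_res=20, n_decoys=4, noise_grid=[1.5], seed=11)
        decoy = gen_decoys(m, scfg).decoys[0]
        moved = make_chain(rigid_motion(decoy.coords), seq=decoy.seq)
        assert flexe(m, moved, cfg) == pytest.approx(flexe(m, decoy, cfg))
        assert mt(m, moved, cfg) == pytest.approx(mt(m, decoy, cfg))
        assert q_star(m, moved) == pytest.approx(q_star(m, decoy))

    def test_mt_nonnegative(self, rng):
        m = random_compact_chain(15, seed=12)
        for _ in range(10):
            decoy = make_chain(m.coords + rng.normal(
                scale=2.0, size=m.coords.shape), seq=m.seq)
            assert mt(m, decoy) >= 0.0


class TestMeasureDispatch:
    @pytest.mark.parametrize("which", ["RMSD", "GDT_TS_STAR", "Q_STAR",
                                       "MT", "FLEXE", "rmsd", "gdt", "q"])
    def test_self_distance_zero(self, which):
        m = random_compact_chain(12, seed=13)
        assert measure(m, m, which) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_measure(self):
        m = random_compact_chain(12, seed=13)
        with pytest.raises(ValueError, match="unknown"):
            measure(m, m, "tm_score")
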