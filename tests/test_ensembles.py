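"""Superposition and ensemble RMSD statistics against a quaternion-scan oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from duplexlens import pairwise_rmsd, representative, superpose
from duplexlens.ensembles import BACKBONE_ATOMS, select_indices, superpose_structures
from duplexlens.errors import CorrespondenceError


def oracle_rmsd(A, B, n_starts=12, seed=0):
    """Independent minimum-RMSD search: parameterize rotations by quaternion,
    polish from several random starts with a generic optimizer."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    rng = np.random.default_rng(seed)

    def cost(q):
        q = q / np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        return np.sqrt(((A @ R.T - B) ** 2).sum() / len(A))

    best = np.inf
    for _ in range(n_starts):
        q0 = rng.normal(size=4)
        res = minimize(cost, q0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestSuperpose:
    def test_self_superposition(self, rng):
        X = rng.normal(size=(30, 3))
        sp = superpose(X, X)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-8)

    def test_recovers_applied_rigid_motion(self, rng):
        X = rng.normal(size=(25, 3))
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(size=3) * 8
        sp = superpose(X, X @ R.T + t)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(sp.rotation, R, atol=1e-8)
        assert np.allclose(sp.translation, t, atol=1e-8)

    def test_matches_quaternion_scan_oracle(self, rng):
        for k in range(100):
            n = int(rng.integers(4, 12))
            A = rng.normal(size=(n, 3))
            B = A @ Rotation.random(random_state=k).as_matrix().T \
                + rng.normal(size=(n, 3)) * 0.3
            got = superpose(A, B).rmsd
            ref = oracle_rmsd(A, B, n_starts=6, seed=k)
            assert got <= ref + 1e-6
            assert got == pytest.approx(ref, abs=1e-5)

    def test_mismatched_selections_rejected(self, rng):
        with pytest.raises(CorrespondenceError):
            superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))
        with pytest.raises(CorrespondenceError):
            superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestRmsdMetricProperties:
    def test_symmetry_and_identity(self, jittered_ensemble):
        M = pairwise_rmsd(jittered_ensemble, "all-atom")
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 0.0)
        assert (M[np.triu_indices_from(M, 1)] > 0).all()

    def test_triangle_inequality_on_model_triples(self, jittered_ensemble):
        M = pairwise_rmsd(jittered_ensemble, "all-atom")
        n = M.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert M[i, j] <= M[i, k] + M[k, j] + 1e-9

    def test_invariance_under_common_rigid_motion(self, jittered_ensemble, rng):
        R = Rotation.random(random_state=9).as_matrix()
        t = rng.normal(size=3) * 10
        moved = jittered_ensemble.with_coords(
            [jittered_ensemble.coords(m) @ R.T + t
             for m in range(jittered_ensemble.n_models)])
        assert np.allclose(pairwise_rmsd(moved, "all-atom"),
                           pairwise_rmsd(jittered_ensemble, "all-atom"), atol=1e-8)


class TestEnsembleStatistics:
    def test_jittered_mean_matches_gaussian_expectation(self, jittered_ensemble):
        """iid per-coordinate jitter of scale sigma puts pairs at E[rmsd] ~ sigma*sqrt(6)."""
        M = pairwise_rmsd(jittered_ensemble, "all-atom")
        mean = M[np.triu_indices_from(M, 1)].mean()
        assert mean == pytest.approx(0.1 * np.sqrt(6.0), rel=0.10)

    def test_identical_models_have_zero_rmsd(self, ddd_helix):
        s, _ = ddd_helix
        twin = s.with_coords([s.coords(0), s.coords(0)])
        assert pairwise_rmsd(twin, "all-atom").max() == pytest.approx(0.0, abs=1e-10)

    def test_selections_differ(self, jittered_ensemble):
        i_all = select_indices(jittered_ensemble, "all-atom")
        i_heavy = select_indices(jittered_ensemble, "all-heavy")
        i_bb = select_indices(jittered_ensemble, "backbone")
        assert len(i_bb) < len(i_heavy) < len(i_all)
        names = {jittered_ensemble.atom_keys()[k][2] for k in i_bb}
        assert names <= set(BACKBONE_ATOMS)


class TestRepresentative:
    def test_mean_of_two_mirror_jitters_is_midpoint(self, ddd_helix, rng):
        s, _ = ddd_helix
        base = s.coords(0)
        d = rng.normal(size=base.shape) * 0.05
        ens = s.with_coords([base + d, base - d])
        rep = representative(ens, "mean-coordinates")
        # the pre-averaging superposition leaves a second-order residue
        assert np.abs(rep.coords(0) - base).max() < 1e-2

    def test_single_model_is_its_own_representative(self, ddd_helix):
        s, _ = ddd_helix
        for mode in ("mean-coordinates", "medoid"):
            rep = representative(s, mode)
            assert np.allclose(rep.coords(0), s.coords(0))

    def test_medoid_avoids_the_outlier(self, ddd_helix, rng):
        s, _ = ddd_helix
        base = s.coords(0)
        frames = [base + rng.normal(size=base.shape) * 0.05 for _ in range(9)]
        frames.append(base + rng.normal(size=base.shape) * 2.0)  # the outlier
        ens = s.with_coords(frames)
        med = representative(ens, "medoid")
        assert not np.allclose(med.coords(0), frames[-1])

    def test_cross_structure_superposition(self, ddd_helix, oxog4_helix):
        s1, _ = ddd_helix
        s2, _ = oxog4_helix
        sp = superpose_structures(s1, s2, "backbone")
        assert sp.rmsd < 0.5  # same helix parameters, different base at position 4
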