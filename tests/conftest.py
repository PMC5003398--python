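"""Shared fixtures and independent oracles.

The oracles here deliberately take different algorithmic routes from the
package (quaternion eigenvector superposition vs SVD Kabsch; brute-force
all-pairs contacts vs KD-tree) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

import lidmotion as lm


# ---------------------------------------------------------------------------
# oracles


def horn_quaternion_superpose(X: np.ndarray, Y: np.ndarray):
    """Horn's closed-form absolute orientation: the optimal rotation is the
    eigenvector of the 4x4 correlation matrix with the largest eigenvalue.
    Returns (R, t, rmsd) superposing Y onto X."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    A = (Y - cy).T @ (X - cx)          # 3x3 correlation
    Sxx, Sxy, Sxz = A[0]
    Syx, Syy, Syz = A[1]
    Szx, Szy, Szz = A[2]
    K = np.array([
        [Sxx + Syy + Szz, Szy - Syz,        Sxz - Szx,        Syx - Sxy],
        [Szy - Syz,       Sxx - Syy - Szz,  Sxy + Syx,        Szx + Sxz],
        [Sxz - Szx,       Sxy + Syx,       -Sxx + Syy - Szz,  Syz + Szy],
        [Syx - Sxy,       Szx + Sxz,        Syz + Szy,       -Sxx - Syy + Szz],
    ])
    w, V = np.linalg.eigh(K)
    q = V[:, np.argmax(w)]             # (w, x, y, z)
    qw, qx, qy, qz = q
    R = np.array([
        [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qz * qw), 2 * (qx * qz + qy * qw)],
        [2 * (qx * qy + qz * qw), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qx * qw)],
        [2 * (qx * qz - qy * qw), 2 * (qy * qz + qx * qw), 1 - 2 * (qx * qx + qy * qy)],
    ]).T                               # this correlation convention yields Y→X inverse
    t = cx - R @ cy
    diff = Y @ R.T + t - X
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, t, rmsd


def brute_force_contacts(s: lm.Structure, set_a, set_b, cutoff=3.5,
                         atom_scope="heavy"):
    """All-pairs O(n²) contact search; returns {(key_a, key_b): min_distance}."""
    backbone = {"N", "CA", "C", "O", "OXT"}

    def atoms_of(key):
        out = []
        for a in s.atoms:
            if (a.chain, a.res_id) != key:
                continue
            if a.element.upper() in ("H", "D"):
                continue
            if atom_scope == "sidechain_heavy" and a.name in backbone:
                continue
            out.append(a)
        return out

    result = {}
    for ka in set_a:
        aa = atoms_of(ka)
        for kb in set_b:
            bb = atoms_of(kb)
            if not aa or not bb:
                continue
            dmin = min(float(np.linalg.norm(x.xyz - y.xyz)) for x in aa for y in bb)
            if dmin <= cutoff:
                result[(ka, kb)] = dmin
    return result


def random_rigid_transform(rng: np.random.Generator) -> lm.RigidTransform:
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return lm.RigidTransform(R, t)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def scaffold():
    return lm.make_two_domain_scaffold(lm.ScaffoldSpec(n_fixed=60, n_mobile=40, seed=11))


@pytest.fixture(scope="session")
def htra2_topology():
    return lm.load_topology()


@pytest.fixture(scope="session")
def triad_topology():
    return lm.triad_truth_topology()


def interface_pivot(structure: lm.Structure, topo: lm.DomainTopology) -> np.ndarray:
    ca, keys = structure.calpha()
    mobile = np.array([topo.in_pdz(r) for _, r in keys])
    return 0.5 * (ca[mobile].mean(axis=0) + ca[~mobile].mean(axis=0))


def reference_axis(structure: lm.Structure, topo: lm.DomainTopology) -> np.ndarray:
    """Unit vector along the topology's axis_reference pair, so that positive
    schedule angles are counterclockwise (cc) under the sign convention."""
    ca, keys = structure.calpha()
    lut = {r: c for c, (_, r) in zip(ca, keys)}
    v = lut[topo.axis_reference[1]] - lut[topo.axis_reference[0]]
    return v / np.linalg.norm(v)


def rotation_trajectory(scaffold_pair, angles, noise=0.0, seed=0, axis=None):
    s, topo = scaffold_pair
    if axis is None:
        axis = reference_axis(s, topo)
    sched = lm.RotationSchedule(axis=tuple(axis), pivot=tuple(interface_pivot(s, topo)),
                                angles=tuple(angles), noise_sigma=noise, seed=seed)
    return lm.make_rotation_trajectory(s, topo, sched)
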