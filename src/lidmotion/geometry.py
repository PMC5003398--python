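"""Rigid-body superposition and RMSD.

The Kabsch algorithm computes the proper rotation R and translation t
minimizing the (optionally weighted) RMSD of ``R @ Y + t`` onto ``X``.
Reflections are corrected by flipping the smallest singular direction, so
the returned rotation always has det = +1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CorrespondenceError, GeometryError
from .structure_io import Structure

PairKey = tuple[str, int]


@dataclass(frozen=True)
class RigidTransform:
    """x' = rotation @ x + translation (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise GeometryError("rotation is improper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    pairing: list[tuple[PairKey, PairKey]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rmsd_angstrom": self.rmsd,
            "n_atoms": self.n_atoms,
            "rotation": self.transform.rotation.tolist(),
            "translation": self.transform.translation.tolist(),
            "pairing": [[list(a), list(b)] for a, b in self.pairing],
        }


def pair_common_calpha(a: Structure, b: Structure,
                       chain_map: dict[str, str] | None = None
                       ) -> list[tuple[PairKey, PairKey]]:
    """Pair residues with equal author number whose Cα is resolved in both.

    Pairing is by (chain, residue number) only — never by residue name — so
    point mutants pair with their parent structure. ``chain_map`` maps chain
    ids of ``a`` to chain ids of ``b`` (default: identical ids).
    """
    _, keys_a = a.calpha()
    _, keys_b = b.calpha()
    set_b = set(keys_b)
    if chain_map is None:
        chains_a = {ch for ch, _ in keys_a}
        chains_b = {ch for ch, _ in keys_b}
        chain_map = {ch: ch for ch in chains_a & chains_b}
        if not chain_map and len(chains_a) == 1 and len(chains_b) == 1:
            chain_map = {next(iter(chains_a)): next(iter(chains_b))}
    pairs = []
    for ch, rid in keys_a:
        if ch not in chain_map:
            continue
        key_b = (chain_map[ch], rid)
        if key_b in set_b:
            pairs.append(((ch, rid), key_b))
    pairs.sort(key=lambda p: (p[0][0], p[0][1]))
    if not pairs:
        raise CorrespondenceError(
            f"no common Cα between {a.source_id or 'A'} and {b.source_id or 'B'}")
    return pairs


def _check_points(X: np.ndarray, Y: np.ndarray, weights: np.ndarray | None):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise GeometryError(f"point sets must share shape (N,3); got {X.shape} vs {Y.shape}")
    if X.shape[0] < 3:
        raise GeometryError(f"need >= 3 points, got {X.shape[0]}")
    if weights is None:
        w = np.ones(X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (X.shape[0],) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be a non-negative N-vector with positive sum")
    return X, Y, w


def superpose_kabsch(X: np.ndarray, Y: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares superposition of Y onto X (Kabsch, SVD form)."""
    X, Y, w = _check_points(X, Y, weights)
    wn = w / w.sum()
    cx = wn @ X
    cy = wn @ Y
    Xc = X - cx
    Yc = Y - cy
    H = (Yc * wn[:, None]).T @ Xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    # degenerate geometry: all points collinear leaves the rotation underdetermined
    if S[1] < 1e-12 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear or coincident) point set")
    t = cx - R @ cy
    transform = RigidTransform(R, t)
    diff = transform.apply(Y) - X
    rmsd = float(np.sqrt(np.sum(wn * np.sum(diff**2, axis=1))))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_atoms=X.shape[0])


def superpose_structures(a: Structure, b: Structure,
                         chain_map: dict[str, str] | None = None) -> SuperpositionResult:
    """Superpose the common Cα of ``b`` onto ``a``."""
    pairs = pair_common_calpha(a, b, chain_map)
    ca_a, keys_a = a.calpha()
    ca_b, keys_b = b.calpha()
    lut_a = {k: ca_a[i] for i, k in enumerate(keys_a)}
    lut_b = {k: ca_b[i] for i, k in enumerate(keys_b)}
    X = np.array([lut_a[pa] for pa, _ in pairs])
    Y = np.array([lut_b[pb] for _, pb in pairs])
    res = superpose_kabsch(X, Y)
    res.pairing = pairs
    return res


def rmsd_no_fit(X: np.ndarray, Y: np.ndarray) -> float:
    """Root-mean-square of per-atom distances without superposition."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise GeometryError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))
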