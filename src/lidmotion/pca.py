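"""Essential dynamics: PCA of Cα trajectories.

Frames are first superposed on a common reference (frame 0, or the
iteratively refined mean structure — the default, since segmental-motion
profiles are conventionally reported against time-averaged coordinates).
The covariance of the mean-centred 3N coordinate vectors is then
diagonalized; eigenvalues λ (Å²) are reported in descending order with
their variance fractions λ_k/Σλ. Computation goes through the SVD of the
frames×3N matrix, which is algebraically equivalent to both the 3N×3N
covariance route and the frames×frames dual (Gram) route.

No mass weighting is applied (Cα only, uniform weights); eigenvalues use
the population convention (divisor = number of frames), so Σλ equals the
mean squared deviation of the frames from the mean structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, InsufficientDataError, ValidationError
from .geometry import superpose_kabsch
from .structure_io import Trajectory


@dataclass
class PCAResult:
    mean_coords: np.ndarray          # (N, 3)
    eigenvalues: np.ndarray          # (m,) descending, Å²
    eigenvectors: np.ndarray         # (m, 3N) orthonormal rows
    projections: np.ndarray          # (frames, m), Å
    res_ids: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


def align_trajectory(traj: Trajectory, reference: str = "mean_iterative",
                     selection: tuple[int, int] | None = None,
                     tol: float = 1e-6, max_iter: int = 20) -> Trajectory:
    """Least-squares superpose every frame on a reference.

    ``reference='frame0'`` aligns on the first frame; ``'mean_iterative'``
    alternates mean computation and alignment until the mean shifts by less
    than ``tol`` Å (at most ``max_iter`` rounds). ``selection`` optionally
    restricts the fit to a residue-number interval; the transform is applied
    to all atoms.
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("alignment needs at least 2 frames")
    if reference not in ("frame0", "mean_iterative"):
        raise ValidationError(f"unknown reference mode {reference!r}")
    res_ids = traj.res_ids
    if selection is None:
        fit_idx = np.arange(len(res_ids))
    else:
        lo, hi = selection
        fit_idx = np.where((res_ids >= lo) & (res_ids <= hi))[0]
        if fit_idx.size < 3:
            raise GeometryError(f"selection {selection} keeps fewer than 3 Cα")

    def align_onto(target: np.ndarray, frames: list[np.ndarray]) -> list[np.ndarray]:
        out = []
        for f in frames:
            res = superpose_kabsch(target[fit_idx], f[fit_idx])
            out.append(res.transform.apply(f))
        return out

    frames = [np.array(f) for f in traj.frames]
    if reference == "frame0":
        frames = align_onto(frames[0], frames)
    else:
        target = frames[0]
        for _ in range(max_iter):
            frames = align_onto(target, frames)
            new_mean = np.mean(frames, axis=0)
            shift = float(np.sqrt(np.mean(np.sum((new_mean - target) ** 2, axis=1))))
            target = new_mean
            if shift < tol:
                break
    return Trajectory(topology_ref=traj.topology_ref, frames=frames,
                      frame_spacing=traj.frame_spacing)


def compute_pca(traj: Trajectory) -> PCAResult:
    """PCA of an aligned Cα trajectory (SVD of the centred frame matrix)."""
    if traj.n_frames < 2:
        raise InsufficientDataError("PCA needs at least 2 frames")
    F = traj.n_frames
    X = traj.coords.reshape(F, -1)            # frames × 3N
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # drop only numerically-zero singular values (pure roundoff), so that
    # projecting on all kept modes reconstructs the frames exactly
    keep = S > (S[0] if S.size else 0.0) * 1e-12
    eigenvalues = (S**2 / F)[keep]
    Vt = Vt[keep]
    projections = Xc @ Vt.T
    return PCAResult(
        mean_coords=mean.reshape(-1, 3),
        eigenvalues=eigenvalues,
        eigenvectors=Vt,
        projections=projections,
        res_ids=traj.res_ids,
    )


def mode_square_displacements(r: PCAResult, mode: int) -> np.ndarray:
    """Per-residue squared displacement of one mode (1-based), scaled by λ.

    The values sum to λ_mode: residue j receives λ · |v_j|² where v_j is the
    mode's (x, y, z) sub-vector at residue j.
    """
    if not (1 <= mode <= r.n_modes):
        raise ValidationError(f"mode {mode} out of range 1..{r.n_modes}")
    v = r.eigenvectors[mode - 1].reshape(-1, 3)
    return r.eigenvalues[mode - 1] * np.sum(v**2, axis=1)


def reconstruct(r: PCAResult, projections: np.ndarray | None = None) -> np.ndarray:
    """Invert the projection: frames × N × 3 coordinates from mode amplitudes."""
    proj = r.projections if projections is None else np.asarray(projections)
    flat = proj @ r.eigenvectors + r.mean_coords.reshape(-1)
    return flat.reshape(proj.shape[0], -1, 3)


def scree_table(r: PCAResult, k: int = 30) -> pd.DataFrame:
    """First min(k, m) modes: eigenvalue, variance fraction, cumulative."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    m = min(k, r.n_modes)
    frac = r.variance_fractions
    return pd.DataFrame({
        "mode": np.arange(1, m + 1),
        "eigenvalue_A2": r.eigenvalues[:m],
        "variance_fraction": frac[:m],
        "cumulative_fraction": np.cumsum(frac)[:m],
    })
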