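"""Rigid-body rotation of the PDZ lid relative to the protease domain.

The analysis is a two-stage fit. For each frame, (1) the frame is
least-squares superposed onto the reference over protease-domain (PD) Cα
only, removing global motion; (2) the PD-aligned frame's PDZ Cα are
superposed onto the reference PDZ Cα. The stage-2 transform *is* the
PDZ-versus-PD motion; its residual RMSD measures internal deformation of
the lid (zero for a perfectly rigid lid).

Sign convention: the rotation axis is oriented so that its dot product
with the topology's ``axis_reference`` vector (default Cα331→Cα343,
approximating the N→C direction of PD helix α4) is non-negative. Positive
rotation about the oriented axis is labelled ``cc`` (counterclockwise for
a viewer looking down that axis with the PD C-terminal barrel in the
foreground), negative ``c``; magnitudes below the threshold (default 10°)
are ``i`` (minute irregular motion). Exactly at the threshold the label
follows the sign.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import GeometryError, ResidueLookupError, TopologyError
from .geometry import RigidTransform, superpose_kabsch
from .structure_io import DomainTopology, Trajectory

MotionLabel = str  # "cc" | "c" | "i"


@dataclass
class FrameMotion:
    frame_index: int
    signed_angle_deg: float
    axis: np.ndarray
    label: MotionLabel
    opening_distance: float
    pd_fit_rmsd: float
    pdz_internal_rmsd: float
    translation: np.ndarray

    @property
    def angle_deg(self) -> float:
        return abs(self.signed_angle_deg)


@dataclass
class MotionReport:
    frames: list[FrameMotion]
    final_label: MotionLabel
    final_angle_deg: float
    max_angle_deg: float
    max_opening: float
    opening_monotonic: bool

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": [f.frame_index for f in self.frames],
            "signed_angle_deg": [f.signed_angle_deg for f in self.frames],
            "axis_x": [f.axis[0] for f in self.frames],
            "axis_y": [f.axis[1] for f in self.frames],
            "axis_z": [f.axis[2] for f in self.frames],
            "label": [f.label for f in self.frames],
            "delta_angstrom": [f.opening_distance for f in self.frames],
        })

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.to_dataframe().to_csv(buf, sep="\t", index=False, float_format="%.6f")
        return buf.getvalue()


def _domain_indices(res_ids: np.ndarray, interval: tuple[int, int], what: str) -> np.ndarray:
    idx = np.where((res_ids >= interval[0]) & (res_ids <= interval[1]))[0]
    if idx.size < 3:
        raise GeometryError(f"fewer than 3 Cα in {what} range {interval}")
    return idx


def fit_domain_transform(frame: np.ndarray, reference: np.ndarray,
                         res_ids: np.ndarray, topo: DomainTopology
                         ) -> tuple[RigidTransform, float, float]:
    """Two-stage PD-align / PDZ-fit. Returns (PDZ-vs-PD transform,
    PD fit RMSD, PDZ internal RMSD)."""
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if frame.shape != reference.shape:
        raise GeometryError("frame and reference must share atom ordering and count")
    pd_idx = _domain_indices(res_ids, topo.pd_range, "pd")
    pdz_idx = _domain_indices(res_ids, topo.pdz_range, "pdz")
    step1 = superpose_kabsch(reference[pd_idx], frame[pd_idx])
    aligned = step1.transform.apply(frame)
    # the motion transform maps the reference PDZ onto the PD-aligned frame
    # PDZ, so its sign follows the physical displacement of the lid
    step2 = superpose_kabsch(aligned[pdz_idx], reference[pdz_idx])
    return step2.transform, step1.rmsd, step2.rmsd


def axis_reference_vector(reference: np.ndarray, res_ids: np.ndarray,
                          topo: DomainTopology) -> np.ndarray:
    """Unit vector Cα(first)→Cα(second) of the topology's axis_reference pair."""
    vecs = []
    for rid in topo.axis_reference:
        idx = np.where(res_ids == rid)[0]
        if idx.size == 0:
            raise TopologyError(f"axis_reference residue {rid} missing from coordinates")
        vecs.append(reference[idx[0]])
    v = vecs[1] - vecs[0]
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise TopologyError("axis_reference residues are coincident")
    return v / n


def signed_axis_angle(t: RigidTransform, ref_vec: np.ndarray
                      ) -> tuple[float, np.ndarray]:
    """Decompose a rotation into (signed angle in degrees, oriented unit axis).

    The axis is flipped, with the angle's sign, so that axis·ref_vec ≥ 0.
    For the identity rotation the axis defaults to ref_vec itself.
    """
    rotvec = Rotation.from_matrix(t.rotation).as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-15:
        return 0.0, np.asarray(ref_vec, dtype=float)
    axis = rotvec / angle
    sign = 1.0
    if float(axis @ ref_vec) < 0:
        axis = -axis
        sign = -1.0
    return sign * np.degrees(angle), axis


def classify_motion(t: RigidTransform, topo: DomainTopology, reference: np.ndarray,
                    res_ids: np.ndarray, threshold_deg: float = 10.0
                    ) -> tuple[MotionLabel, float, np.ndarray]:
    """Label a PDZ-vs-PD transform as cc / c / i.

    Returns (label, signed angle in degrees, oriented unit axis).
    """
    ref_vec = axis_reference_vector(reference, res_ids, topo)
    signed, axis = signed_axis_angle(t, ref_vec)
    if abs(signed) < threshold_deg:
        label = "i"
    else:
        label = "cc" if signed > 0 else "c"
    return label, signed, axis


def opening_distance(frame: np.ndarray, res_ids: np.ndarray,
                     topo: DomainTopology) -> float:
    """Instantaneous Cα–Cα distance of the opening pair (default I179–L398)."""
    pts = []
    for rid in topo.opening_pair:
        idx = np.where(res_ids == rid)[0]
        if idx.size == 0:
            raise ResidueLookupError(f"opening_pair residue {rid} missing from coordinates")
        pts.append(np.asarray(frame, dtype=float)[idx[0]])
    return float(np.linalg.norm(pts[1] - pts[0]))


def motion_report(traj: Trajectory, topo: DomainTopology,
                  reference_frame: int = 0, threshold_deg: float = 10.0) -> MotionReport:
    """Per-frame lid-motion analysis of a Cα trajectory."""
    res_ids = traj.res_ids
    reference = traj.frames[reference_frame]
    frames_out: list[FrameMotion] = []
    for i, frame in enumerate(traj.frames):
        t, pd_rmsd, pdz_rmsd = fit_domain_transform(frame, reference, res_ids, topo)
        label, signed, axis = classify_motion(t, topo, reference, res_ids, threshold_deg)
        delta = opening_distance(frame, res_ids, topo)
        frames_out.append(FrameMotion(
            frame_index=i, signed_angle_deg=signed, axis=axis, label=label,
            opening_distance=delta, pd_fit_rmsd=pd_rmsd, pdz_internal_rmsd=pdz_rmsd,
            translation=t.translation,
        ))
    deltas = [f.opening_distance for f in frames_out]
    monotonic = all(b >= a - 1e-9 for a, b in zip(deltas, deltas[1:]))
    return MotionReport(
        frames=frames_out,
        final_label=frames_out[-1].label,
        final_angle_deg=frames_out[-1].signed_angle_deg,
        max_angle_deg=max(abs(f.signed_angle_deg) for f in frames_out),
        max_opening=max(deltas),
        opening_monotonic=monotonic,
    )
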