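"""Seeded generators with known ground truth.

Three families of fixtures, all pure functions of their seeds:

* two-domain Cα scaffolds (a fixed "jug" and a mobile "lid" domain) with a
  topology describing them;
* trajectories in which the mobile domain undergoes a prescribed rotation
  about a known axis, optionally with Gaussian coordinate noise — the
  ground truth against which angle/axis recovery is validated;
* His/Asp/Ser triad fragments whose five criterion distances are sampled
  either all inside the competence bands (label ``competent``) or with at
  least one outside (label ``incompetent``).

Scaffolds are Cα-only; triad fragments carry the side-chain atoms the
competence test needs (His Nδ1/Nε2 on an idealized imidazole pentagon,
Asp Oδ1/Oδ2, Ser Oγ) at idealized-distance geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import TriadCriteria
from .errors import GeometryError, ValidationError
from .structure_io import Atom, DomainTopology, Structure, Trajectory


@dataclass(frozen=True)
class ScaffoldSpec:
    n_fixed: int = 60
    n_mobile: int = 40
    separation: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_fixed < 4 or self.n_mobile < 4:
            raise ValidationError("each domain needs at least 4 residues")
        if self.separation <= 0:
            raise ValidationError("separation must be positive")




def _ca_atom(serial: int, res_id: int, coord: np.ndarray, chain: str = "A",
             res_name: str = "ALA") -> Atom:
    return Atom(serial=serial, name="CA", element="C", res_name=res_name,
                res_id=res_id, icode="", chain=chain, coord=tuple(map(float, coord)))


def make_two_domain_scaffold(spec: ScaffoldSpec) -> tuple[Structure, DomainTopology]:
    """Deterministic two-domain Cα scaffold plus a matching topology.

    Each domain is a compact globular point cloud at protein-like density
    (well-conditioned, distinct inertia moments almost surely), so rigid
    superposition onto either domain is numerically stable.
    Fixed-domain residues are numbered 1..n_fixed, mobile-domain residues
    n_fixed+11..n_fixed+10+n_mobile; the intervening numbers play the role
    of an unresolved linker. The opening pair joins the fixed residue
    nearest the mobile centroid with the mobile residue farthest from the
    fixed centroid, emulating an interface reporter on the moving radius.
    """
    rng = np.random.default_rng(spec.seed)
    fixed = _ball_cloud(spec.n_fixed, rng)
    mobile = _ball_cloud(spec.n_mobile, rng)
    # shift the mobile domain away along a generic direction
    mobile += spec.separation * np.array([1.0, 0.3, 0.1]) / np.linalg.norm([1.0, 0.3, 0.1])

    atoms = []
    for i, c in enumerate(fixed):
        atoms.append(_ca_atom(i + 1, i + 1, c))
    mobile_start = spec.n_fixed + 11
    for i, c in enumerate(mobile):
        atoms.append(_ca_atom(spec.n_fixed + i + 1, mobile_start + i, c))
    s = Structure(atoms=atoms, source_id=f"scaffold-seed{spec.seed}", missing={"A": []})

    fixed_centroid = fixed.mean(axis=0)
    mobile_centroid = mobile.mean(axis=0)
    open_fixed = int(np.argmin(np.linalg.norm(fixed - mobile_centroid, axis=1))) + 1
    open_mobile = mobile_start + int(np.argmax(np.linalg.norm(mobile - fixed_centroid, axis=1)))
    topo = DomainTopology(
        pd_range=(1, spec.n_fixed),
        linker_range=(spec.n_fixed + 1, spec.n_fixed + 10),
        pdz_range=(mobile_start, mobile_start + spec.n_mobile - 1),
        triad=(2, 3, 4),
        opening_pair=(open_fixed, open_mobile),
        axis_reference=(1, spec.n_fixed),
    )
    return s, topo


@dataclass(frozen=True)
class RotationSchedule:
    axis: tuple[float, float, float]
    pivot: tuple[float, float, float]
    angles: tuple[float, ...]            # degrees, one per frame
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(ax)), 1.0, abs_tol=1e-8):
            raise ValidationError("axis must be a unit vector")
        if not np.all(np.isfinite(self.angles)):
            raise ValidationError("angles must be finite")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")
        if len(self.angles) < 1:
            raise ValidationError("schedule needs at least one frame")


def make_rotation_trajectory(scaffold: Structure, topo: DomainTopology,
                             schedule: RotationSchedule) -> Trajectory:
    """Frames with the mobile (pdz_range) domain rotated by the scheduled
    angle about (axis, pivot), plus i.i.d. Gaussian coordinate noise."""
    rng = np.random.default_rng(schedule.seed)
    base = np.array([a.coord for a in scaffold.atoms])
    mobile = np.array([topo.in_pdz(a.res_id) for a in scaffold.atoms])
    axis = np.asarray(schedule.axis, dtype=float)
    pivot = np.asarray(schedule.pivot, dtype=float)
    frames = []
    for ang in schedule.angles:
        coords = base.copy()
        if ang != 0.0:                  # exact no-op at 0°, bit-for-bit
            R = Rotation.from_rotvec(np.radians(ang) * axis).as_matrix()
            coords[mobile] = (coords[mobile] - pivot) @ R.T + pivot
        if schedule.noise_sigma > 0:
            coords = coords + rng.normal(0.0, schedule.noise_sigma, coords.shape)
        frames.append(coords)
    return Trajectory(topology_ref=scaffold, frames=frames)


def _ball_cloud(n: int, rng: np.random.Generator) -> np.ndarray:
    """n points quasi-uniformly filling a sphere at protein-like density
    (~one Cα per 120 Å³), deterministic given the generator state."""
    radius = 1.9 * n ** (1.0 / 3.0) * 1.6
    pts = rng.uniform(-radius, radius, (4 * n, 3))
    pts = pts[np.linalg.norm(pts, axis=1) <= radius][:n]
    while len(pts) < n:
        extra = rng.uniform(-radius, radius, (n, 3))
        extra = extra[np.linalg.norm(extra, axis=1) <= radius]
        pts = np.vstack([pts, extra])[:n]
    return pts


def make_htra2_like_monomer(seed: int = 0, separation: float = 26.0,
                            closed_angle_deg: float = -50.0,
                            topo: DomainTopology | None = None,
                            restraint_targets: dict[tuple[int, int], float] | None = None
                            ) -> Structure:
    """A synthetic Cα monomer with HtrA2 author numbering, in a closed pose.

    Synthetic stand-in for the inactive monomer: compact point clouds occupy
    the protease-domain residues (150–343) and the PDZ residues (359–458) of
    the packaged topology, with the linker absent as in the inactive-state
    crystals. The residues anchoring the packaged nine-restraint set are
    nudged (joint least squares) so that an *open* PDZ pose satisfying every
    restraint target exactly exists; the returned structure is that geometry
    with the lid rotated by ``closed_angle_deg`` about the interface into a
    closed pose. The coordinates carry no real structural information beyond
    domain compactness and restraint-target realizability.
    """
    from scipy.optimize import least_squares

    from .restraints import load_restraints
    from .structure_io import load_topology  # local import avoids a cycle at module load
    topo = topo or load_topology()
    if restraint_targets is None:
        restraint_targets = {(r.res_a, r.res_b): r.target for r in load_restraints()}
    rng = np.random.default_rng(seed)
    pd_ids = list(range(topo.pd_range[0], topo.pd_range[1] + 1))
    pdz_ids = list(range(topo.pdz_range[0], topo.pdz_range[1] + 1))
    pd_pts = _ball_cloud(len(pd_ids), rng)
    pdz_pts = _ball_cloud(len(pdz_ids), rng) * 0.85
    pdz_pts += np.array([separation, 0.0, 0.0])
    pos = {rid: p for rid, p in zip(pd_ids, pd_pts)}
    pos.update({rid: p for rid, p in zip(pdz_ids, pdz_pts)})

    # nudge the anchor residues so all restraint targets are simultaneously
    # and exactly realizable in this (open) pose
    anchors = sorted({rid for pair in restraint_targets for rid in pair})
    a_index = {rid: i for i, rid in enumerate(anchors)}
    x0 = np.concatenate([pos[rid] for rid in anchors])

    def residuals(x: np.ndarray) -> np.ndarray:
        pts = x.reshape(-1, 3)
        return np.array([
            np.linalg.norm(pts[a_index[a]] - pts[a_index[b]]) - t
            for (a, b), t in sorted(restraint_targets.items())
        ])

    sol = least_squares(residuals, x0, xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.abs(sol.fun).max() > 1e-6:
        raise GeometryError("could not realize the restraint targets "
                            f"(max residual {np.abs(sol.fun).max():.3g} Å)")
    for rid, p in zip(anchors, sol.x.reshape(-1, 3)):
        pos[rid] = p

    atoms = []
    for serial, rid in enumerate(pd_ids + pdz_ids, start=1):
        atoms.append(_ca_atom(serial, rid, pos[rid]))
    s = Structure(atoms=atoms, source_id=f"synthetic-htra2-monomer-seed{seed}",
                  missing={"A": []})
    if closed_angle_deg:
        s = open_lid(s, topo, closed_angle_deg)
    return s


def open_lid(s: Structure, topo: DomainTopology, angle_deg: float,
             axis: tuple[float, float, float] = (0.0, 0.0, 1.0)) -> Structure:
    """Rotate the PDZ (lid) rigidly about the domain-interface midpoint —
    an artificial 'opened start' for optimizer-convergence studies."""
    coords = np.array([a.coord for a in s.atoms])
    mobile = np.array([topo.in_pdz(a.res_id) for a in s.atoms])
    if mobile.sum() < 3 or (~mobile).sum() < 3:
        raise GeometryError("structure does not cover both domains")
    pivot = 0.5 * (coords[mobile].mean(axis=0) + coords[~mobile].mean(axis=0))
    R = Rotation.from_rotvec(np.radians(angle_deg) * _unit(np.asarray(axis, float))).as_matrix()
    out = coords.copy()
    out[mobile] = (out[mobile] - pivot) @ R.T + pivot
    return s.with_coords(out)


# ---------------------------------------------------------------------------
# triad fragments


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("zero-length direction")
    return v / n


def build_triad_fragment(d_og_ne2: float, d_nd1_od: float, ca_sh: float,
                         ca_dh: float, ca_sd: float, serine_has_og: bool = True,
                         his_id: int = 198, asp_id: int = 228, ser_id: int = 306
                         ) -> Structure:
    """Construct a His/Asp/Ser fragment realizing the five given distances.

    The Cα triangle is embedded in the z=0 plane; the imidazole is an
    idealized planar pentagon oriented so Nε2 faces the serine and Nδ1 the
    aspartate; Oγ and Oδ1 are placed to hit their criterion distances
    exactly. Raises :class:`GeometryError` when the triangle inequality (or
    reach of the side chains) makes the request unrealizable.
    """
    for name, v in (("d_og_ne2", d_og_ne2), ("d_nd1_od", d_nd1_od),
                    ("ca_sh", ca_sh), ("ca_dh", ca_dh), ("ca_sd", ca_sd)):
        if v <= 0:
            raise GeometryError(f"{name} must be positive")
    if not (ca_sh < ca_dh + ca_sd and ca_dh < ca_sh + ca_sd and ca_sd < ca_sh + ca_dh):
        raise GeometryError("Cα distances violate the triangle inequality")

    ca_h = np.zeros(3)
    ca_s = np.array([ca_sh, 0.0, 0.0])
    x_d = (ca_dh**2 + ca_sh**2 - ca_sd**2) / (2 * ca_sh)
    y_sq = ca_dh**2 - x_d**2
    if y_sq <= 1e-9:
        raise GeometryError("degenerate (collinear) Cα triangle")
    ca_d = np.array([x_d, math.sqrt(y_sq), 0.0])

    u_s = _unit(ca_s - ca_h)
    u_d = _unit(ca_d - ca_h)
    e1 = _unit(u_s + u_d)                      # bisector: ring-center direction
    e2 = _unit(u_d - (u_d @ e1) * e1)          # in-plane, toward the aspartate side
    ring_center = ca_h + 3.0 * e1
    ring_r = 1.17                               # idealized imidazole circumradius
    def ring_atom(angle_deg: float) -> np.ndarray:
        a = math.radians(angle_deg)
        return ring_center + ring_r * (math.cos(a) * e1 + math.sin(a) * e2)
    ne2 = ring_atom(-36.0)                      # toward the serine side
    nd1 = ring_atom(108.0)                      # toward the aspartate side
    ce1 = ring_atom(36.0)
    cd2 = ring_atom(-108.0)
    cg = ring_atom(180.0)
    cb_h = ca_h + 1.53 * _unit(cg - ca_h)

    og = ne2 + d_og_ne2 * _unit(ca_s - ne2)
    if np.linalg.norm(og - ca_s) < 0.8:
        raise GeometryError("Oγ placement collides with the serine Cα "
                            "(d_og_ne2 too large for this Cα triangle)")
    cb_s = og + 1.43 * _unit(ca_s - og)

    # Oδ1 sits on the intersection of sphere(Nδ1, d_nd1_od) with a
    # side-chain-reach sphere around the aspartate Cα; this keeps the
    # carboxylate between the two residues instead of on the Cα itself
    reach = 2.5
    u = ca_d - nd1
    d = float(np.linalg.norm(u))
    u = u / d
    a = (d_nd1_od**2 - reach**2 + d**2) / (2 * d)
    h_sq = d_nd1_od**2 - a**2
    if h_sq < 0:
        raise GeometryError("Nδ1–Oδ distance unreachable for this Cα triangle "
                            f"(|Nδ1–Cα(Asp)| = {d:.2f} Å, reach {reach} Å)")
    normal = np.array([0.0, 0.0, 1.0])
    m = _unit(np.cross(normal, u))
    od1 = nd1 + a * u + math.sqrt(h_sq) * m
    cg_d = od1 + 1.25 * _unit(ca_d - od1)
    cb_d = ca_d + 1.53 * _unit(cg_d - ca_d)
    # second carboxylate oxygen: rotate the CG→OD1 direction by 124° about
    # the plane normal, mirrored if that lands it closer to Nδ1 than Oδ1
    normal = np.array([0.0, 0.0, 1.0])
    rot = Rotation.from_rotvec(math.radians(124.0) * normal)
    od2 = cg_d + 1.25 * rot.apply(_unit(od1 - cg_d))
    if np.linalg.norm(od2 - nd1) < np.linalg.norm(od1 - nd1):
        rot = Rotation.from_rotvec(-math.radians(124.0) * normal)
        od2 = cg_d + 1.25 * rot.apply(_unit(od1 - cg_d))

    atoms = []
    serial = iter(range(1, 100))
    def add(name, element, res_name, res_id, coord):
        atoms.append(Atom(serial=next(serial), name=name, element=element,
                          res_name=res_name, res_id=res_id, icode="",
                          chain="A", coord=tuple(map(float, coord))))
    add("CA", "C", "HIS", his_id, ca_h)
    add("CB", "C", "HIS", his_id, cb_h)
    add("CG", "C", "HIS", his_id, cg)
    add("ND1", "N", "HIS", his_id, nd1)
    add("CD2", "C", "HIS", his_id, cd2)
    add("CE1", "C", "HIS", his_id, ce1)
    add("NE2", "N", "HIS", his_id, ne2)
    add("CA", "C", "ASP", asp_id, ca_d)
    add("CB", "C", "ASP", asp_id, cb_d)
    add("CG", "C", "ASP", asp_id, cg_d)
    add("OD1", "O", "ASP", asp_id, od1)
    add("OD2", "O", "ASP", asp_id, od2)
    ser_name = "SER" if serine_has_og else "ALA"
    add("CA", "C", ser_name, ser_id, ca_s)
    add("CB", "C", ser_name, ser_id, cb_s if serine_has_og else ca_s + np.array([0, 0, 1.53]))
    if serine_has_og:
        add("OG", "O", ser_name, ser_id, og)
    return Structure(atoms=atoms, source_id="triad-fragment", missing={"A": []})


_CRITERION_NAMES = ("og_ne2", "nd1_od", "ca_sh", "ca_dh", "ca_sd")


def make_triad_examples(n: int, seed: int = 0, spread: float = 0.5,
                        criteria: TriadCriteria = TriadCriteria()
                        ) -> list[tuple[Structure, str]]:
    """``n`` labelled triad fragments, roughly half competent.

    Competent examples sample each distance uniformly inside its band;
    incompetent ones displace at least one distance outside its band by up
    to ``spread`` beyond the edge (the Cα-triangle criteria keep the
    triangle inequality satisfiable by construction).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if spread <= 0:
        raise ValidationError("spread must be positive")
    rng = np.random.default_rng(seed)
    bands = {"og_ne2": criteria.og_ne2, "nd1_od": criteria.nd1_od,
             "ca_sh": criteria.ca_sh, "ca_dh": criteria.ca_dh,
             "ca_sd": criteria.ca_sd}
    out = []
    for i in range(n):
        label = "competent" if i % 2 == 0 else "incompetent"
        for _attempt in range(50):
            vals = {k: rng.uniform(b.center - b.halfwidth, b.center + b.halfwidth)
                    for k, b in bands.items()}
            if label == "incompetent":
                n_out = int(rng.integers(1, 3))
                broken = rng.choice(_CRITERION_NAMES, size=n_out, replace=False)
                for k in broken:
                    b = bands[k]
                    off = rng.uniform(0.05, spread)
                    side = 1.0 if rng.random() < 0.5 else -1.0
                    vals[k] = b.center + side * (b.halfwidth + off)
            try:
                frag = build_triad_fragment(
                    d_og_ne2=vals["og_ne2"], d_nd1_od=vals["nd1_od"],
                    ca_sh=vals["ca_sh"], ca_dh=vals["ca_dh"], ca_sd=vals["ca_sd"])
            except GeometryError:
                continue
            out.append((frag, label))
            break
        else:
            raise GeometryError(f"spread {spread} incompatible with realizable "
                                "triad geometry after 50 attempts")
    return out


def triad_truth_topology(his_id: int = 198, asp_id: int = 228, ser_id: int = 306
                         ) -> DomainTopology:
    """A minimal topology whose triad points at the fragment residues."""
    return DomainTopology(
        pd_range=(min(his_id, asp_id, ser_id), max(his_id, asp_id, ser_id)),
        linker_range=(400, 401), pdz_range=(402, 460),
        triad=(his_id, asp_id, ser_id), opening_pair=(ser_id, 402),
        axis_reference=(his_id, asp_id),
    )
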