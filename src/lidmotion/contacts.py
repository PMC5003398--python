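"""Residue contacts at a distance criterion, and catalytic-triad competence.

A "contact" is a residue pair whose minimum inter-atomic heavy-atom
distance does not exceed the cutoff (default 3.5 Å). The triad test scores
a His/Asp/Ser constellation against the distance criteria characteristic
of a catalytically ready serine protease of the HtrA type:

* Oγ(Ser)–Nε2(His) = 3.15 ± 0.2 Å
* Nδ1(His)–Oδ(Asp) = 3.3 ± 0.4 Å (min over the two carboxylate oxygens,
  which are chemically equivalent)
* Cα-triangle sides Δ_S-H = 8.6 ± 0.1 Å, Δ_D-H = 6.5 ± 0.1 Å,
  Δ_S-D = 10.2 ± 0.1 Å

A structure whose catalytic serine lacks Oγ (e.g. a Ser→Ala crystallization
mutant) is *non-evaluable* rather than incompetent; the Cα criteria are
still reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ResidueLookupError, SelectionError, TopologyError
from .structure_io import Atom, DomainTopology, Structure

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

ResidueKey = tuple[str, int]  # (chain, author residue number)


@dataclass(frozen=True)
class ContactRecord:
    res_a: tuple[str, int, str]  # chain, res_id, res_name
    res_b: tuple[str, int, str]
    min_distance: float
    atom_pair: tuple[str, str]
    cutoff: float


def _residue_table(s: Structure, selection: list[ResidueKey], atom_scope: str
                   ) -> dict[ResidueKey, list[Atom]]:
    if not selection:
        raise SelectionError("empty residue selection")
    if atom_scope not in ("heavy", "sidechain_heavy"):
        raise SelectionError(f"unknown atom_scope {atom_scope!r}")
    wanted = set(selection)
    table: dict[ResidueKey, list[Atom]] = {k: [] for k in wanted}
    for a in s.atoms:
        key = (a.chain, a.res_id)
        if key not in wanted:
            continue
        if a.element.upper() in ("H", "D"):
            continue
        if atom_scope == "sidechain_heavy" and a.name in _BACKBONE:
            continue
        table[key].append(a)
    table = {k: v for k, v in table.items() if v}
    if not table:
        raise SelectionError("selection matches no atoms in the structure")
    return table


def select_range(s: Structure, chain: str, interval: tuple[int, int]) -> list[ResidueKey]:
    lo, hi = interval
    return [(chain, rid) for rid, _ in s.resolved_residues.get(chain, []) if lo <= rid <= hi]


def select_chain(s: Structure, chain: str) -> list[ResidueKey]:
    return [(chain, rid) for rid, _ in s.resolved_residues.get(chain, [])]


def residue_contacts(s: Structure, set_a: list[ResidueKey], set_b: list[ResidueKey],
                     cutoff: float = 3.5, atom_scope: str = "heavy") -> list[ContactRecord]:
    """All residue pairs (a ∈ set_a, b ∈ set_b) with min atom distance ≤ cutoff.

    The two selections must be disjoint. Sorted by (res_a, res_b); the
    reported atom pair is the closest one, ties broken by atom-name order.
    """
    if set(set_a) & set(set_b):
        raise SelectionError("set_a and set_b must be disjoint")
    ta = _residue_table(s, set_a, atom_scope)
    tb = _residue_table(s, set_b, atom_scope)

    atoms_b = [(k, a) for k, lst in tb.items() for a in lst]
    tree = cKDTree(np.array([a.xyz for _, a in atoms_b]))
    res_names = {(a.chain, a.res_id): a.res_name for a in s.atoms}

    records = []
    for key_a, lst_a in sorted(ta.items()):
        pts_a = np.array([a.xyz for a in lst_a])
        neighbor_lists = tree.query_ball_point(pts_a, r=cutoff)
        best: dict[ResidueKey, tuple[float, str, str]] = {}
        for ia, hits in enumerate(neighbor_lists):
            for ib in hits:
                key_b, atom_b = atoms_b[ib]
                d = float(np.linalg.norm(pts_a[ia] - atom_b.xyz))
                prev = best.get(key_b)
                # keep the strictly closer pair; on ties prefer atom-name order
                if (prev is None or d < prev[0] - 1e-12
                        or (abs(d - prev[0]) <= 1e-12
                            and (lst_a[ia].name, atom_b.name) < (prev[1], prev[2]))):
                    best[key_b] = (d, lst_a[ia].name, atom_b.name)
        for key_b in sorted(best):
            d, na, nb = best[key_b]
            records.append(ContactRecord(
                res_a=(key_a[0], key_a[1], res_names.get(key_a, "UNK")),
                res_b=(key_b[0], key_b[1], res_names.get(key_b, "UNK")),
                min_distance=d, atom_pair=(na, nb), cutoff=cutoff))
    records.sort(key=lambda r: (r.res_a[:2], r.res_b[:2]))
    return records


def hinge_contacts(s: Structure, topo: DomainTopology, cutoff: float = 3.5,
                   chain: str | None = None) -> dict[str, list[ContactRecord]]:
    """Contacts across hinge A and hinge B, computed independently."""
    chain = chain or s.chains[0]
    out = {}
    for name, pd_set, pdz_set in (("A", topo.hinge_a_pd, topo.hinge_a_pdz),
                                  ("B", topo.hinge_b_pd, topo.hinge_b_pdz)):
        if not pd_set or not pdz_set:
            raise TopologyError(f"hinge {name} residue sets undefined in topology")
        resolved = {rid for rid, _ in s.resolved_residues.get(chain, [])}
        sel_pd = [(chain, r) for r in sorted(pd_set) if r in resolved]
        sel_pdz = [(chain, r) for r in sorted(pdz_set) if r in resolved]
        if not sel_pd or not sel_pdz:
            out[name] = []
            continue
        try:
            out[name] = residue_contacts(s, sel_pd, sel_pdz, cutoff=cutoff)
        except SelectionError:
            out[name] = []
    return out


def min_atom_distance(s: Structure, res_a: ResidueKey, res_b: ResidueKey,
                      names_a: set[str], names_b: set[str]) -> tuple[float, tuple[str, str]]:
    """Minimum distance over named atoms of two residues; ties by name order."""
    atoms_a = [a for a in s.residue_atoms(*res_a) if a.name in names_a]
    atoms_b = [a for a in s.residue_atoms(*res_b) if a.name in names_b]
    missing = sorted(names_a - {a.name for a in atoms_a}) + \
        sorted(names_b - {a.name for a in atoms_b})
    if not atoms_a or not atoms_b:
        raise ResidueLookupError(
            f"named atoms absent: {missing} on {res_a}/{res_b}")
    best = None
    for aa in sorted(atoms_a, key=lambda a: a.name):
        for ab in sorted(atoms_b, key=lambda a: a.name):
            d = float(np.linalg.norm(aa.xyz - ab.xyz))
            if best is None or d < best[0] - 1e-12:
                best = (d, (aa.name, ab.name))
    return best


# ---------------------------------------------------------------------------
# catalytic triad


@dataclass(frozen=True)
class Band:
    center: float
    halfwidth: float

    def __post_init__(self):
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")

    def contains(self, value: float) -> bool:
        return abs(value - self.center) <= self.halfwidth


@dataclass(frozen=True)
class TriadCriteria:
    og_ne2: Band = Band(3.15, 0.2)
    nd1_od: Band = Band(3.3, 0.4)
    ca_sh: Band = Band(8.6, 0.1)
    ca_dh: Band = Band(6.5, 0.1)
    ca_sd: Band = Band(10.2, 0.1)


@dataclass
class TriadGeometry:
    d_og_ne2: float | None
    d_nd1_od: float
    ca_sh: float
    ca_dh: float
    ca_sd: float
    verdict: str  # "competent" | "incompetent" | "non_evaluable"
    failures: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "d_og_ne2_angstrom": self.d_og_ne2,
            "d_nd1_od_angstrom": self.d_nd1_od,
            "ca_sh_angstrom": self.ca_sh,
            "ca_dh_angstrom": self.ca_dh,
            "ca_sd_angstrom": self.ca_sd,
            "verdict": self.verdict,
            "failures": list(self.failures),
        }


def triad_geometry(s: Structure, topo: DomainTopology,
                   criteria: TriadCriteria = TriadCriteria(),
                   chain: str | None = None) -> TriadGeometry:
    """Measure the five triad distances and score catalytic competence."""
    chain = chain or s.chains[0]
    his_id, asp_id, ser_id = topo.triad
    his = {a.name: a for a in s.residue_atoms(chain, his_id)}
    asp = {a.name: a for a in s.residue_atoms(chain, asp_id)}
    ser = {a.name: a for a in s.residue_atoms(chain, ser_id)}
    for d, rid, needed in ((his, his_id, ("CA", "NE2", "ND1")),
                           (asp, asp_id, ("CA",)),
                           (ser, ser_id, ("CA",))):
        for nm in needed:
            if nm not in d:
                raise ResidueLookupError(f"triad residue {chain}:{rid} lacks atom {nm}")
    od_atoms = [asp[nm] for nm in ("OD1", "OD2") if nm in asp]
    if not od_atoms:
        raise ResidueLookupError(f"triad Asp {chain}:{asp_id} lacks carboxylate oxygens")

    dist = lambda a, b: float(np.linalg.norm(a.xyz - b.xyz))
    d_nd1_od = min(dist(his["ND1"], o) for o in od_atoms)
    ca_sh = dist(ser["CA"], his["CA"])
    ca_dh = dist(asp["CA"], his["CA"])
    ca_sd = dist(ser["CA"], asp["CA"])
    d_og_ne2 = dist(ser["OG"], his["NE2"]) if "OG" in ser else None

    failures = []
    for name, value, band in (("nd1_od", d_nd1_od, criteria.nd1_od),
                              ("ca_sh", ca_sh, criteria.ca_sh),
                              ("ca_dh", ca_dh, criteria.ca_dh),
                              ("ca_sd", ca_sd, criteria.ca_sd)):
        if not band.contains(value):
            failures.append(name)
    if d_og_ne2 is not None and not criteria.og_ne2.contains(d_og_ne2):
        failures.append("og_ne2")
    if d_og_ne2 is None:
        verdict = "non_evaluable"
    elif failures:
        verdict = "incompetent"
    else:
        verdict = "competent"
    return TriadGeometry(d_og_ne2=d_og_ne2, d_nd1_od=d_nd1_od, ca_sh=ca_sh,
                         ca_dh=ca_dh, ca_sd=ca_sd, verdict=verdict,
                         failures=sorted(failures))
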