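"""PDB-format structures, Cα trajectories and domain topologies.

Author residue numbering (as deposited) is authoritative throughout: the
structures this package targets are cited in the literature by author
numbers (V226, S306, ...), so nothing is ever renumbered.

Parsing and writing of the PDB format go through :mod:`gemmi`; this module
wraps the result in small plain dataclasses that carry exactly what the
geometric analyses need (heavy atoms, author ids, occupancies) plus the
missing-residue bookkeeping that the lid-motion analyses rely on.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

from .errors import (
    FormatError,
    MissingDataUndeterminableError,
    ResidueLookupError,
    ValidationError,
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class Atom:
    """One atom with author identifiers and Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_id: int
    icode: str
    chain: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0

    def __post_init__(self):
        if not all(math.isfinite(c) for c in self.coord):
            raise ValidationError(f"non-finite coordinate for atom {self.serial} {self.name}")
        if not self.res_name:
            raise ValidationError(f"empty residue name for atom {self.serial}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(
                f"occupancy {self.occupancy} outside [0,1] for atom {self.serial} {self.name}"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Structure:
    """A parsed macromolecular model.

    ``missing_residues`` is ``None`` when the source file allowed no
    determination (no unresolved-residue remarks and no usable SEQRES);
    an empty mapping means "determined: nothing missing".
    """

    atoms: list[Atom]
    source_id: str = ""
    missing: dict[str, list[tuple[int, str]]] | None = None

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    @property
    def resolved_residues(self) -> dict[str, list[tuple[int, str]]]:
        out: dict[str, dict[int, str]] = {}
        for a in self.atoms:
            out.setdefault(a.chain, {})[a.res_id] = a.res_name
        return {ch: sorted(d.items()) for ch, d in out.items()}

    def missing_residues(self, chain: str) -> list[tuple[int, str]]:
        if self.missing is None:
            raise MissingDataUndeterminableError(
                f"{self.source_id or 'structure'}: missing residues undeterminable "
                "(no unresolved-residue remarks and no usable SEQRES records)"
            )
        return list(self.missing.get(chain, []))

    # --- convenience lookups used across the analysis modules ---

    def residue_atoms(self, chain: str, res_id: int) -> list[Atom]:
        found = [a for a in self.atoms if a.chain == chain and a.res_id == res_id]
        if not found:
            raise ResidueLookupError(f"residue {chain}:{res_id} not in structure {self.source_id}")
        return found

    def atom(self, chain: str, res_id: int, name: str) -> Atom:
        for a in self.atoms:
            if a.chain == chain and a.res_id == res_id and a.name == name:
                return a
        raise ResidueLookupError(f"atom {name} of {chain}:{res_id} not found")

    def calpha(self, chain: str | None = None) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Cα coordinates and their (chain, res_id) keys, in file order."""
        coords, keys = [], []
        for a in self.atoms:
            if a.name == "CA" and (chain is None or a.chain == chain):
                coords.append(a.coord)
                keys.append((a.chain, a.res_id))
        return np.asarray(coords, dtype=float).reshape(-1, 3), keys

    def n_residues(self, protein_only: bool = True) -> int:
        keys = set()
        for a in self.atoms:
            if protein_only and a.res_name in _WATER_NAMES:
                continue
            keys.add((a.chain, a.res_id, a.icode))
        return len(keys)

    def copy(self) -> "Structure":
        return Structure(
            atoms=list(self.atoms),
            source_id=self.source_id,
            missing=None if self.missing is None else {k: list(v) for k, v in self.missing.items()},
        )

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError(f"coordinate array {coords.shape} != ({len(self.atoms)}, 3)")
        new_atoms = [replace(a, coord=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms=new_atoms, source_id=self.source_id,
                         missing=None if self.missing is None else dict(self.missing))


@dataclass
class Trajectory:
    """An ordered stack of coordinate frames over a fixed atom subset.

    ``topology_ref`` is the frame-0 template structure restricted to the
    selected atoms; frames are (n_atoms, 3) arrays in Å.
    """

    topology_ref: Structure
    frames: list[np.ndarray]
    frame_spacing: float | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValidationError("trajectory must contain at least one frame")
        n = len(self.topology_ref.atoms)
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise FormatError(f"frame {i} has shape {f.shape}, expected ({n}, 3)")
            self.frames[i] = f

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def res_ids(self) -> np.ndarray:
        return np.array([a.res_id for a in self.topology_ref.atoms], dtype=int)

    @property
    def coords(self) -> np.ndarray:
        return np.stack(self.frames)


@dataclass
class DomainTopology:
    """Named residue ranges of a two-domain protease monomer.

    Intervals are closed ``[start, end]`` in author numbering. The defaults
    packaged with the library describe human HtrA2: protease domain (PD)
    150–343, interdomain linker 344–358, PDZ domain 359–458, catalytic triad
    H198/D228/S306, opening pair I179–L398.
    """

    pd_range: tuple[int, int]
    linker_range: tuple[int, int]
    pdz_range: tuple[int, int]
    triad: tuple[int, int, int]
    opening_pair: tuple[int, int] = (179, 398)
    axis_reference: tuple[int, int] = (331, 343)
    n_barrel: tuple[int, int] | None = None
    c_barrel: tuple[int, int] | None = None
    loops: dict[str, tuple[int, int]] = field(default_factory=dict)
    hinge_a_pd: frozenset[int] = frozenset()
    hinge_a_pdz: frozenset[int] = frozenset()
    hinge_b_pd: frozenset[int] = frozenset()
    hinge_b_pdz: frozenset[int] = frozenset()

    def __post_init__(self):
        for name in ("pd_range", "linker_range", "pdz_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} start {lo} > end {hi}")
        order = [("pd_range", self.pd_range), ("linker_range", self.linker_range),
                 ("pdz_range", self.pdz_range)]
        for (na, a), (nb, b) in zip(order, order[1:]):
            if a[1] >= b[0]:
                raise ValidationError(f"{na} {a} overlaps or follows {nb} {b}")
        for rid in self.triad:
            if not (self.pd_range[0] <= rid <= self.pd_range[1]):
                raise ValidationError(f"triad residue {rid} outside pd_range {self.pd_range}")
        a, b = self.opening_pair
        in_pd = lambda r: self.pd_range[0] <= r <= self.pd_range[1]
        in_pdz = lambda r: self.pdz_range[0] <= r <= self.pdz_range[1]
        if not ((in_pd(a) and in_pdz(b)) or (in_pd(b) and in_pdz(a))):
            raise ValidationError(f"opening_pair {self.opening_pair} must span pd_range x pdz_range")

    def in_pd(self, res_id: int) -> bool:
        return self.pd_range[0] <= res_id <= self.pd_range[1]

    def in_pdz(self, res_id: int) -> bool:
        return self.pdz_range[0] <= res_id <= self.pdz_range[1]


# ---------------------------------------------------------------------------
# reading


def _keep_residue(res: gemmi.Residue, include_hetero: bool) -> bool:
    if res.name in _WATER_NAMES:
        return include_hetero
    info = gemmi.find_tabulated_residue(res.name)
    is_aa = info is not None and info.is_amino_acid()
    return is_aa or include_hetero


def _select_altloc(atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Highest-occupancy conformer per atom name; ties by altloc letter order."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in by_name:
        cands = by_name[name]
        cands.sort(key=lambda a: (-a.occ, a.altloc))
        out.append(cands[0])
    return out


def _parse_remark465(lines: Iterable[str]) -> dict[str, list[tuple[int, str]]] | None:
    """Parse unresolved-residue records (REMARK 465). Returns None if absent."""
    found = False
    missing: dict[str, list[tuple[int, str]]] = {}
    for ln in lines:
        if not ln.startswith("REMARK 465"):
            continue
        found = True
        body = ln[10:].rstrip("\n")
        parts = body.split()
        # data rows look like: ['ALA', 'A', '134'] (optionally led by a model no.)
        if len(parts) == 4 and parts[0].isdigit():
            parts = parts[1:]
        if len(parts) != 3:
            continue
        res_name, chain, num = parts
        info = gemmi.find_tabulated_residue(res_name)
        if info is None or not info.is_amino_acid():
            continue
        num = num.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")  # strip insertion codes
        try:
            res_id = int(num)
        except ValueError:
            continue
        missing.setdefault(chain, []).append((res_id, res_name))
    if not found:
        return None
    for ch in missing:
        missing[ch].sort()
    return missing


def _missing_from_seqres(st: gemmi.Structure, resolved: dict[str, list[tuple[int, str]]]
                         ) -> dict[str, list[tuple[int, str]]] | None:
    """SEQRES-vs-ATOM fallback: find the single numbering offset per chain that
    aligns the full sequence with the resolved residues; None when no chain has
    a usable full-sequence record."""
    seqs: dict[str, list[str]] = {}
    for ent in st.entities:
        if not ent.full_sequence:
            continue
        for sub in ent.subchains:
            chain_id = sub[:1] if sub else ""
            seqs.setdefault(chain_id, [gemmi.Entity.first_mon(m) for m in ent.full_sequence])
    # subchain naming is not reliable for PDB input; also map by chain name
    for model in st:
        for chain in model:
            ent = st.get_entity_of(chain.subchains()[0]) if chain.subchains() else None
            if ent is not None and ent.full_sequence:
                seqs.setdefault(chain.name, [gemmi.Entity.first_mon(m) for m in ent.full_sequence])
    if not seqs:
        return None
    out: dict[str, list[tuple[int, str]]] = {}
    usable = False
    for ch, seq in seqs.items():
        res = resolved.get(ch, [])
        if not res:
            continue
        best_offset, best_hits = None, -1
        offsets = {rid - i for rid, _ in res for i in range(len(seq))}
        # restrict to plausible offsets derived from first/last residues
        cand = {res[0][0] - i for i in range(len(seq))}
        for off in sorted(cand):
            hits = sum(1 for rid, rname in res
                       if 0 <= rid - off < len(seq) and seq[rid - off] == rname)
            if hits > best_hits:
                best_hits, best_offset = hits, off
        if best_offset is None or best_hits < 0.95 * len(res):
            continue
        usable = True
        have = {rid for rid, _ in res}
        out[ch] = [(i + best_offset, seq[i]) for i in range(len(seq))
                   if (i + best_offset) not in have]
    return out if usable else None


def _structure_from_gemmi_model(model: gemmi.Model, source_id: str,
                                include_hetero: bool) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if not _keep_residue(res, include_hetero):
                continue
            for ga in _select_altloc([a for a in res if a.element != gemmi.Element("H")]):
                atoms.append(Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name,
                    res_name=res.name,
                    res_id=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    chain=chain.name,
                    coord=(ga.pos.x, ga.pos.y, ga.pos.z),
                    occupancy=min(max(ga.occ, 0.0), 1.0),
                    altloc=ga.altloc or "",
                    b_factor=ga.b_iso,
                ))
    return atoms


def read_structure(path: str | Path, model_index: int = 0,
                   include_hetero: bool = False) -> Structure:
    """Read one model of a PDB-format file.

    Missing residues are taken from unresolved-residue remarks when present,
    else from the SEQRES-vs-ATOM difference; when neither is derivable the
    missing set is left *unknown* and ``Structure.missing_residues`` raises.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    if len(st) == 0 or model_index >= len(st):
        raise FormatError(f"{path}: no model at index {model_index}")
    st.setup_entities()
    atoms = _structure_from_gemmi_model(st[model_index], st.name or path.stem, include_hetero)
    if not atoms:
        raise FormatError(f"{path}: no ATOM records (after filtering)")
    s = Structure(atoms=atoms, source_id=path.stem)
    missing = _parse_remark465(text.splitlines())
    if missing is None:
        missing = _missing_from_seqres(st, s.resolved_residues)
    s.missing = missing
    return s


def missing_residues_in(s: Structure, chain: str,
                        interval: tuple[int, int]) -> list[tuple[int, str]]:
    """Residues of ``interval`` (closed) absent from the resolved set of ``chain``.

    Prefers the structure's own missing-residue record (which carries residue
    names); residues in the interval missing from both records are reported
    with name ``'UNK'``.
    """
    lo, hi = interval
    if lo > hi:
        raise ValidationError(f"interval start {lo} > end {hi}")
    resolved = s.resolved_residues
    if chain not in resolved and (s.missing is None or chain not in (s.missing or {})):
        raise ResidueLookupError(f"chain {chain!r} not in structure {s.source_id}")
    known_missing = {rid: rname for rid, rname in s.missing_residues(chain)}
    have = {rid for rid, _ in resolved.get(chain, [])}
    out = []
    for rid in range(lo, hi + 1):
        if rid in have:
            continue
        out.append((rid, known_missing.get(rid, "UNK")))
    return out


def read_trajectory(path: str | Path, selection: str | None = "CA",
                    include_hetero: bool = False) -> Trajectory:
    """Read a multi-model PDB as a trajectory (one frame per MODEL).

    ``selection`` filters by atom name (default Cα only); ``None`` keeps all
    heavy atoms. All models must yield identical atom counts and ordering.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")

    def sel(atoms: list[Atom]) -> list[Atom]:
        if selection is None:
            return atoms
        return [a for a in atoms if a.name == selection]

    ref_atoms = sel(_structure_from_gemmi_model(st[0], path.stem, include_hetero))
    if not ref_atoms:
        raise FormatError(f"{path}: selection {selection!r} matches no atoms")
    key = [(a.chain, a.res_id, a.name) for a in ref_atoms]
    frames = []
    for i in range(len(st)):
        atoms = sel(_structure_from_gemmi_model(st[i], path.stem, include_hetero))
        if [(a.chain, a.res_id, a.name) for a in atoms] != key:
            raise FormatError(f"{path}: model {i + 1} atom set differs from model 1")
        frames.append(np.array([a.coord for a in atoms], dtype=float))
    topo_ref = Structure(atoms=ref_atoms, source_id=path.stem)
    return Trajectory(topology_ref=topo_ref, frames=frames)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(s: Structure, coords: np.ndarray | None = None, num: int = 1) -> gemmi.Model:
    model = gemmi.Model(num)
    xyz = coords if coords is not None else np.array([a.coord for a in s.atoms])
    chain_obj: gemmi.Chain | None = None
    res_obj: gemmi.Residue | None = None
    last_chain, last_res = None, None
    for a, c in zip(s.atoms, xyz):
        if a.chain != last_chain:
            chain_obj = gemmi.Chain(a.chain)
            model.add_chain(chain_obj)
            last_chain, last_res = a.chain, None
            chain_obj = model[len(model) - 1]
        if (a.res_id, a.icode, a.res_name) != last_res:
            res_obj = gemmi.Residue()
            res_obj.name = a.res_name
            res_obj.seqid = gemmi.SeqId(a.res_id, a.icode or " ")
            chain_obj.add_residue(res_obj)
            res_obj = chain_obj[len(chain_obj) - 1]
            last_res = (a.res_id, a.icode, a.res_name)
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element or a.name[:1])
        ga.pos = gemmi.Position(*map(float, c))
        ga.occ = a.occupancy
        ga.b_iso = a.b_factor
        ga.altloc = a.altloc.strip()[:1] if a.altloc.strip() else "\x00"
        res_obj.add_atom(ga)
    return model


def write_structure(s: Structure, path: str | Path) -> None:
    """Write standard ATOM records; round-trips ids and coordinates (3 dp)."""
    if not s.atoms:
        raise FormatError("refusing to write a structure with no atoms")
    st = gemmi.Structure()
    st.name = s.source_id or "lidmotion"
    st.add_model(_to_gemmi(s))
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (one MODEL per frame)."""
    st = gemmi.Structure()
    st.name = traj.topology_ref.source_id or "trajectory"
    for i, frame in enumerate(traj.frames):
        st.add_model(_to_gemmi(traj.topology_ref, frame, num=i + 1))
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# topology files


def _parse_interval(text: str, key: str) -> tuple[int, int]:
    parts = text.replace("-", " ").split()
    if len(parts) != 2:
        raise ValidationError(f"{key}: expected 'start-end', got {text!r}")
    return int(parts[0]), int(parts[1])


def parse_topology(text: str) -> DomainTopology:
    """Parse the key-value topology format (see the packaged ``htra2_topology``)."""
    kv: dict[str, str] = {}
    for ln in text.splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if ":" not in ln:
            raise ValidationError(f"topology line without ':': {ln!r}")
        key, val = ln.split(":", 1)
        kv[key.strip()] = val.strip()
    required = ("pd_range", "linker_range", "pdz_range", "triad")
    for key in required:
        if key not in kv:
            raise ValidationError(f"topology missing required key {key!r}")
    loops = {}
    hinges = {"hinge_a_pd": frozenset(), "hinge_a_pdz": frozenset(),
              "hinge_b_pd": frozenset(), "hinge_b_pdz": frozenset()}
    extras: dict[str, object] = {}
    for key, val in kv.items():
        if key.startswith("loop."):
            loops[key[5:]] = _parse_interval(val, key)
        elif key in hinges:
            lo, hi = _parse_interval(val, key)
            hinges[key] = frozenset(range(lo, hi + 1))
        elif key in ("n_barrel", "c_barrel"):
            extras[key] = _parse_interval(val, key)
    triad = tuple(int(x) for x in kv["triad"].replace(",", " ").split())
    if len(triad) != 3:
        raise ValidationError(f"triad: expected three residue ids, got {kv['triad']!r}")
    opening = tuple(int(x) for x in kv.get("opening_pair", "179,398").replace(",", " ").split())
    axis_ref = tuple(int(x) for x in kv.get("axis_reference", "331,343").replace(",", " ").split())
    return DomainTopology(
        pd_range=_parse_interval(kv["pd_range"], "pd_range"),
        linker_range=_parse_interval(kv["linker_range"], "linker_range"),
        pdz_range=_parse_interval(kv["pdz_range"], "pdz_range"),
        triad=triad,  # type: ignore[arg-type]
        opening_pair=opening,  # type: ignore[arg-type]
        axis_reference=axis_ref,  # type: ignore[arg-type]
        loops=loops,
        **hinges,
        **extras,  # type: ignore[arg-type]
    )


def format_topology(topo: DomainTopology) -> str:
    """Serialize a topology to the key-value text format read back by
    :func:`parse_topology`."""
    lines = [
        f"pd_range: {topo.pd_range[0]}-{topo.pd_range[1]}",
        f"linker_range: {topo.linker_range[0]}-{topo.linker_range[1]}",
        f"pdz_range: {topo.pdz_range[0]}-{topo.pdz_range[1]}",
        f"triad: {', '.join(map(str, topo.triad))}",
        f"opening_pair: {topo.opening_pair[0]}, {topo.opening_pair[1]}",
        f"axis_reference: {topo.axis_reference[0]}, {topo.axis_reference[1]}",
    ]
    for name in ("n_barrel", "c_barrel"):
        iv = getattr(topo, name)
        if iv is not None:
            lines.append(f"{name}: {iv[0]}-{iv[1]}")
    for name, iv in sorted(topo.loops.items()):
        lines.append(f"loop.{name}: {iv[0]}-{iv[1]}")
    for name in ("hinge_a_pd", "hinge_a_pdz", "hinge_b_pd", "hinge_b_pdz"):
        ids = sorted(getattr(topo, name))
        if ids:
            lines.append(f"{name}: {ids[0]}-{ids[-1]}")
    return "\n".join(lines) + "\n"


def load_topology(path: str | Path | None = None) -> DomainTopology:
    """Load a topology file; with no path, the packaged HtrA2 default."""
    if path is None:
        text = (importlib.resources.files("lidmotion.data") / "htra2_topology").read_text()
    else:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise FormatError(f"cannot read topology {path}: {exc}") from exc
    return parse_topology(text)
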