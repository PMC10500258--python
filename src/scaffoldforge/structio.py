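"""Structure data model and file IO.

Provides the hierarchical atomic model (Structure → chains → Residue →
Atom), readers/writers for PDB/mmCIF coordinate files and MRC/CCP4 density
maps (via gemmi), a small selection-expression language, and rigid-body
superposition (Kabsch) with backbone RMSD.

Coordinates are Å in a right-handed frame; residue numbering is the
author's 1-based numbering as read from the file.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._tables import BACKBONE_ATOMS, FALLBACK_VDW_RADIUS, STANDARD_AA, VDW_RADII

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RigidTransform",
    "DensityMap",
    "StructureError",
    "SelectionError",
    "read_structure",
    "write_structure",
    "select",
    "kabsch_superpose",
    "backbone_rmsd",
    "read_map",
    "write_map",
]


class StructureError(ValueError):
    """Malformed structure file or inconsistent hierarchy."""


class SelectionError(ValueError):
    """Malformed selection expression; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


def element_radius(element: str) -> tuple[float, bool]:
    """vdW radius for an element symbol; (radius, used_fallback)."""
    r = VDW_RADII.get(element.upper())
    if r is None:
        return FALLBACK_VDW_RADIUS, True
    return r, False


@dataclass
class Atom:
    """A single atom: name, element, position (Å), B-factor (Å²), occupancy."""

    name: str
    element: str
    coord: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    vdw_radius: float | None = None
    radius_is_fallback: bool = False

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if self.vdw_radius is None:
            self.vdw_radius, self.radius_is_fallback = element_radius(self.element)
            if self.radius_is_fallback:
                warnings.warn(
                    f"element {self.element!r} not in radius table; "
                    f"using fallback {FALLBACK_VDW_RADIUS} Å",
                    stacklevel=2,
                )
        if self.vdw_radius <= 0:
            raise StructureError(f"atom {self.name}: vdw_radius must be > 0")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coord.copy(), self.bfactor,
                    self.occupancy, self.vdw_radius, self.radius_is_fallback)


@dataclass
class Residue:
    """One residue with a 3-letter name, author seq_id and optional icode."""

    name: str
    seq_id: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.name} {self.seq_id}: duplicate atom names")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, self.insertion_code,
                       [a.copy() for a in self.atoms], self.hetero)


@dataclass
class Structure:
    """Ordered chains of residues plus free-form provenance metadata."""

    id: str = "model"
    chains: list[tuple[str, list[Residue]]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.chains]
        if len(ids) != len(set(ids)):
            raise StructureError("duplicate chain ids")
        for cid, residues in self.chains:
            keys = [r.key for r in residues]
            if len(keys) != len(set(keys)):
                raise StructureError(f"chain {cid}: duplicate residue numbers")

    # -- convenience accessors -------------------------------------------
    def chain(self, chain_id: str) -> list[Residue]:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"no chain {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [cid for cid, _ in self.chains]

    def iter_atoms(self):
        for cid, residues in self.chains:
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (N, 3) array, hierarchy order."""
        out = [a.coord for _, _, a in self.iter_atoms()]
        return np.array(out) if out else np.empty((0, 3))

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = [a for _, _, a in self.iter_atoms()]
        if coords.shape != (len(atoms), 3):
            raise StructureError("coordinate array shape mismatch")
        for a, xyz in zip(atoms, coords):
            a.coord = xyz.copy()

    def transformed(self, t: "RigidTransform") -> "Structure":
        s = self.copy()
        s.set_coords(t.apply(s.coords()))
        return s

    def copy(self) -> "Structure":
        return Structure(self.id,
                         [(cid, [r.copy() for r in res]) for cid, res in self.chains],
                         _copy.deepcopy(self.metadata))


@dataclass
class RigidTransform:
    """Proper rigid-body transform: x ↦ rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3×3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        if np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, axis: np.ndarray, angle_deg: float,
                   center: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by angle_deg about an axis through `center` (origin default)."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        axis = axis / n
        theta = np.deg2rad(angle_deg)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        Rm = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        if center is None:
            return cls(Rm, np.zeros(3))
        center = np.asarray(center, dtype=float)
        return cls(Rm, center - Rm @ center)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply `other` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class DensityMap:
    """3-D scalar grid with per-axis voxel size (Å) and origin (Å)."""

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with ≥2 voxels per axis")
        vs = np.asarray(self.voxel_size, dtype=float)
        self.voxel_size = np.full(3, float(vs)) if vs.ndim == 0 else vs
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        n = self.grid.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(), self.origin.copy())


# ---------------------------------------------------------------------------
# coordinate file IO (gemmi-backed)
# ---------------------------------------------------------------------------

def _guess_format(path: str | Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a Structure.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties favour altloc 'A'); HETATM records are retained as residues with
    ``hetero=True``. Unknown elements get the fallback radius and a warning.
    """
    fmt = _guess_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path.name}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    model = st[0]
    chains: list[tuple[str, list[Residue]]] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            # resolve altlocs: group by atom name, keep highest occupancy
            by_name: dict[str, gemmi.Atom] = {}
            for a in res:
                prev = by_name.get(a.name)
                if prev is None:
                    by_name[a.name] = a
                    continue
                if (a.occ, -ord(a.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
                    by_name[a.name] = a
            atoms = []
            for a in by_name.values():
                elem = a.element.name if a.element else ""
                atoms.append(Atom(a.name, elem,
                                  np.array([a.pos.x, a.pos.y, a.pos.z]),
                                  bfactor=a.b_iso, occupancy=a.occ))
            residues.append(Residue(res.name, res.seqid.num,
                                    (res.seqid.icode or "").strip(),
                                    atoms,
                                    hetero=res.het_flag == "H" or res.name not in STANDARD_AA))
        chains.append((ch.name, residues))
    return Structure(id=path.stem, chains=chains, metadata={"source": str(path)})


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for cid, residues in s.chains:
        ch = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "H" if res.hetero else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.b_iso = float(a.bfactor)
                ga.occ = float(a.occupancy)
                gres.add_atom(ga)
            ch.add_residue(gres)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, format: str = "auto") -> None:
    """Write a Structure to PDB (fixed column) or mmCIF.

    PDB chain ids are limited to one character; longer ids raise for PDB
    and pass through for mmCIF.
    """
    fmt = _guess_format(path, format)
    coords = s.coords()
    if coords.size and not np.all(np.isfinite(coords)):
        raise StructureError("non-finite coordinates")
    if fmt == "pdb":
        for cid in s.chain_ids:
            if len(cid) > 2:
                raise StructureError(
                    f"chain id {cid!r} too long for PDB format; use mmCIF")
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def _parse_ranges(token: str, pos: int) -> list[tuple[int, int]]:
    out = []
    for part in token.split("+"):
        if "-" in part[1:]:  # allow negative start
            lo, _, hi = part.rpartition("-")
            try:
                out.append((int(lo), int(hi)))
            except ValueError:
                raise SelectionError(f"bad residue range {part!r}", pos) from None
        else:
            try:
                v = int(part)
            except ValueError:
                raise SelectionError(f"bad residue id {part!r}", pos) from None
            out.append((v, v))
    return out


def select(s: Structure, expr: str) -> Structure:
    """Select a deep, independent sub-structure.

    Grammar: clauses joined by ``and``; each clause is one of
    ``backbone``, ``chain A+B``, ``resi 5-7+10``, ``name CA+CB``.
    """
    tokens: list[tuple[str, int]] = []
    pos = 0
    for raw in expr.split():
        tokens.append((raw, expr.index(raw, pos)))
        pos = expr.index(raw, pos) + len(raw)

    chain_filter: set[str] | None = None
    resi_filter: list[tuple[int, int]] | None = None
    name_filter: set[str] | None = None
    backbone_only = False

    i = 0
    if not tokens:
        raise SelectionError("empty selection expression", 0)
    while i < len(tokens):
        tok, tpos = tokens[i]
        low = tok.lower()
        if low == "and":
            if i == 0 or i == len(tokens) - 1:
                raise SelectionError("dangling 'and'", tpos)
            i += 1
            continue
        if low == "backbone":
            backbone_only = True
            i += 1
        elif low in ("chain", "resi", "name"):
            if i + 1 >= len(tokens):
                raise SelectionError(f"'{low}' needs an argument", tpos)
            arg, apos = tokens[i + 1]
            if low == "chain":
                chain_filter = set(arg.split("+"))
            elif low == "resi":
                resi_filter = _parse_ranges(arg, apos)
            else:
                name_filter = set(n.upper() for n in arg.split("+"))
            i += 2
        else:
            raise SelectionError(f"unknown token {tok!r}", tpos)

    def keep_res(res: Residue) -> bool:
        if resi_filter is None:
            return True
        return any(lo <= res.seq_id <= hi for lo, hi in resi_filter)

    def keep_atom(a: Atom) -> bool:
        if backbone_only and not a.is_backbone:
            return False
        if name_filter is not None and a.name.upper() not in name_filter:
            return False
        return True

    chains = []
    for cid, residues in s.chains:
        if chain_filter is not None and cid not in chain_filter:
            continue
        picked = []
        for res in residues:
            if not keep_res(res):
                continue
            atoms = [a.copy() for a in res.atoms if keep_atom(a)]
            if atoms:
                picked.append(Residue(res.name, res.seq_id, res.insertion_code,
                                      atoms, res.hetero))
        if picked:
            chains.append((cid, picked))
    return Structure(id=f"{s.id}|{expr}", chains=chains,
                     metadata={"selection": expr, "parent": s.id})


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, target: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns the proper rigid transform taking `mobile` onto `target` and
    the post-fit RMSD in Å. Raises on fewer than 3 points or on degenerate
    (collinear) point sets, where the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    span = max(np.linalg.norm(P, axis=1).max(), 1.0)
    if (np.linalg.matrix_rank(P, tol=1e-8 * span) < 2
            or np.linalg.matrix_rank(Q, tol=1e-8 * span) < 2):
        raise ValueError("degenerate (collinear) point set")
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    Rm = Vt.T @ D @ U.T
    t = tc - Rm @ mc
    transform = RigidTransform(Rm, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mobile) - target) ** 2, axis=1))))
    return transform, rmsd


def _default_pairing(a: Structure, b: Structure
                     ) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Pair residues by author seq_id intersection per common chain id.

    If the structures share no chain ids but each has exactly one chain,
    those two chains are paired.
    """
    common = [cid for cid in a.chain_ids if cid in b.chain_ids]
    chain_pairs: list[tuple[str, str]]
    if common:
        chain_pairs = [(cid, cid) for cid in common]
    elif len(a.chain_ids) == 1 and len(b.chain_ids) == 1:
        chain_pairs = [(a.chain_ids[0], b.chain_ids[0])]
    else:
        return []
    pairing = []
    for ca, cb in chain_pairs:
        ids_b = {r.seq_id for r in b.chain(cb) if not r.hetero}
        for res in a.chain(ca):
            if not res.hetero and res.seq_id in ids_b:
                pairing.append(((ca, res.seq_id), (cb, res.seq_id)))
    return pairing


def backbone_rmsd(a: Structure, b: Structure,
                  pairing: list[tuple[tuple[str, int], tuple[str, int]]] | None = None
                  ) -> float:
    """Backbone (N, CA, C, O) RMSD after optimal superposition.

    `pairing` is a list of ((chain_a, seq_a), (chain_b, seq_b)) residue
    correspondences; by default residues are paired by seq_id intersection
    within matching chains. Only backbone atoms present in both paired
    residues contribute.
    """
    if pairing is None:
        pairing = _default_pairing(a, b)
    pa, pb = [], []
    res_a = {(cid, r.seq_id): r for cid, residues in a.chains for r in residues}
    res_b = {(cid, r.seq_id): r for cid, residues in b.chains for r in residues}
    for ka, kb in pairing:
        ra, rb = res_a.get(tuple(ka)), res_b.get(tuple(kb))
        if ra is None or rb is None:
            continue
        for name in BACKBONE_ATOMS:
            aa, ab = ra.atom(name), rb.atom(name)
            if aa is not None and ab is not None:
                pa.append(aa.coord)
                pb.append(ab.coord)
    if not pa:
        raise StructureError("no common paired backbone atoms")
    _, rmsd = kabsch_superpose(np.array(pa), np.array(pb))
    return rmsd


# ---------------------------------------------------------------------------
# density map IO (MRC2014 via gemmi)
# ---------------------------------------------------------------------------

def read_map(path: str | Path) -> DensityMap:
    """Read an MRC/CCP4 map. Non-float modes are converted with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"corrupt or unreadable map {path.name}: {exc}") from exc
    mode = m.header_i32(4)
    if mode != 2:
        warnings.warn(f"map mode {mode} converted to 32-bit float", stacklevel=2)
    grid = np.array(m.grid, copy=True).astype(np.float32)
    cell = m.grid.unit_cell
    shape = grid.shape
    voxel = np.array([cell.a / shape[0], cell.b / shape[1], cell.c / shape[2]])
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    # nstart offsets (words 5-7) add to the origin in voxel units
    nstart = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)])
    origin = origin + nstart * voxel
    return DensityMap(grid, voxel, origin)


def write_map(m: DensityMap, path: str | Path) -> None:
    """Write a DensityMap as MRC2014 mode 2 (32-bit float)."""
    grid = gemmi.FloatGrid(*m.grid.shape)
    nx, ny, nz = m.grid.shape
    grid.set_unit_cell(gemmi.UnitCell(nx * m.voxel_size[0], ny * m.voxel_size[1],
                                      nz * m.voxel_size[2], 90.0, 90.0, 90.0))
    np.array(grid, copy=False)[...] = m.grid.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))
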