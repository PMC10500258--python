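"""Rigid helical-fusion pose sampling.

A binder domain (e.g. a DARPin) is fused to a cage subunit through a shared
alpha helix: the binder's terminal helix is superposed onto sliding
five-residue windows of the cage subunit's terminal helix, optionally with
small helix flexing (bend/twist at a hinge), and every resulting rigid pose
is screened for steric collisions and favorable binder–binder contacts in
the fully assembled symmetric cage.

No randomness anywhere: poses are enumerated window-ascending, then in
flex-grid order, so runs are exactly reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .structio import Atom, Residue, RigidTransform, Structure, kabsch_superpose
from .symmetry import AssemblySpec, SymmetryGroup

__all__ = [
    "HelixSegment", "FlexParams", "FusionPose",
    "detect_helices", "build_ideal_helix", "sliding_window_alignments",
    "flex_helix", "generate_fusion_poses", "evaluate_pose", "filter_poses",
    "default_flex_grid", "window_flex_transform", "dihedral", "phi_psi",
]

# α-helix dihedral window used for secondary-structure assignment
PHI_RANGE = (-100.0, -30.0)
PSI_RANGE = (-80.0, -5.0)

# idealized backbone internal coordinates (Å, degrees)
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5,
          "N-CA-CB": 110.5}


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(-y, x)))


def phi_psi(residues: list[Residue]) -> list[tuple[float | None, float | None]]:
    """Backbone (φ, ψ) per residue; None where the flanking residue is absent."""
    out: list[tuple[float | None, float | None]] = []
    for i, res in enumerate(residues):
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = None
        if n and ca and c:
            if i > 0:
                prev_c = residues[i - 1].atom("C")
                if prev_c is not None and residues[i - 1].seq_id == res.seq_id - 1:
                    phi = dihedral(prev_c.coord, n.coord, ca.coord, c.coord)
            if i < len(residues) - 1:
                next_n = residues[i + 1].atom("N")
                if next_n is not None and residues[i + 1].seq_id == res.seq_id + 1:
                    psi = dihedral(n.coord, ca.coord, c.coord, next_n.coord)
        out.append((phi, psi))
    return out


@dataclass
class HelixSegment:
    """A maximal helical run within one chain."""

    chain_id: str
    start_seq: int
    end_seq: int
    axis: np.ndarray
    residues: list[Residue]

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("helix segment needs ≥2 residues")
        seqs = [r.seq_id for r in self.residues]
        if any(b - a != 1 for a, b in zip(seqs, seqs[1:])):
            raise ValueError("helix residues must be consecutive")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coord for r in self.residues])

    def backbone_coords(self, start: int, count: int) -> np.ndarray:
        """(count*4, 3) backbone coords (N, CA, C, O) for a residue window."""
        out = []
        for res in self.residues[start:start + count]:
            for name in ("N", "CA", "C", "O"):
                atom = res.atom(name)
                if atom is None:
                    raise ValueError(f"residue {res.seq_id} missing {name}")
                out.append(atom.coord)
        return np.array(out)


def helix_axis(ca: np.ndarray) -> np.ndarray:
    """Unit helix-axis direction from CA positions.

    Second differences of a perfect helix are exactly perpendicular to its
    axis (the translational part cancels), so crosses of successive second
    differences point exactly along the axis; their sum is normalized and
    oriented from the first toward the last residue. Falls back to crosses
    of first differences for 3-point traces.
    """
    ca = np.asarray(ca, dtype=float)
    if len(ca) < 3:
        raise ValueError("need ≥3 CA atoms for an axis")
    if len(ca) >= 4:
        d2 = ca[:-2] - 2 * ca[1:-1] + ca[2:]
        crosses = np.cross(d2[:-1], d2[1:])
    else:
        d = np.diff(ca, axis=0)
        crosses = np.cross(d[:-1], d[1:])
    v = crosses.sum(axis=0)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate CA trace (no curvature)")
    v = v / n
    # orient from first toward last residue
    if v @ (ca[-1] - ca[0]) < 0:
        v = -v
    return v


def _fit_circle_center(xy: np.ndarray) -> np.ndarray:
    """Least-squares (Kåsa) circle center for 2-D points."""
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2]


def detect_helices(s: Structure, min_len: int = 5) -> list[HelixSegment]:
    """Assign α-helical segments from backbone dihedrals.

    A residue is helical when every *defined* backbone dihedral lies inside
    the α window (φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]); chain-terminal
    residues have only one defined angle. Maximal runs of ≥ min_len
    helical residues become segments.
    """
    segments: list[HelixSegment] = []
    for cid, residues in s.chains:
        poly = [r for r in residues if r.atom("CA") is not None and not r.hetero]
        if len(poly) < min_len:
            continue
        angles = phi_psi(poly)

        def helical(i: int) -> bool:
            phi, psi = angles[i]
            if phi is None and psi is None:
                return False
            if phi is not None and not (PHI_RANGE[0] <= phi <= PHI_RANGE[1]):
                return False
            if psi is not None and not (PSI_RANGE[0] <= psi <= PSI_RANGE[1]):
                return False
            return True

        i = 0
        while i < len(poly):
            if not helical(i):
                i += 1
                continue
            j = i
            while j + 1 < len(poly) and helical(j + 1) and \
                    poly[j + 1].seq_id == poly[j].seq_id + 1:
                j += 1
            if j - i + 1 >= min_len:
                run = [poly[k].copy() for k in range(i, j + 1)]
                axis = helix_axis(np.array([r.atom("CA").coord for r in run]))
                segments.append(HelixSegment(cid, run[0].seq_id, run[-1].seq_id,
                                             axis, run))
            i = j + 1
    return segments


def terminal_helix(s: Structure, chain_id: str | None = None,
                   terminus: str = "C", min_len: int = 5) -> HelixSegment:
    """The helical segment nearest the named terminus of a chain."""
    segs = [h for h in detect_helices(s, min_len)
            if chain_id is None or h.chain_id == chain_id]
    if not segs:
        raise ValueError(
            "no terminal helix detected; supply the helix segment explicitly")
    if chain_id is None:
        cid = segs[0].chain_id if terminus == "N" else segs[-1].chain_id
        segs = [h for h in segs if h.chain_id == cid]
    return segs[0] if terminus == "N" else segs[-1]


# ---------------------------------------------------------------------------
# ideal helix construction
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom d bonded to c."""
    angle = np.deg2rad(angle_deg)
    tors = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(angle),
                   bond * np.sin(angle) * np.cos(tors),
                   bond * np.sin(angle) * np.sin(tors)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_phi_psi_helix(n: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Poly-ALA backbone (+CB, O) chain at fixed (φ, ψ), ω = 180°."""
    res: list[dict[str, np.ndarray]] = []
    # seed first three backbone atoms
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C0 = CA0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms = {"N": N0, "CA": CA0, "C": C0}
    res.append(atoms)
    for i in range(1, n):
        prev = res[-1]
        N = _place_atom(prev["N"], prev["CA"], prev["C"],
                        _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        CA = _place_atom(prev["CA"], prev["C"], N,
                         _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        C = _place_atom(prev["C"], N, CA, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        res.append({"N": N, "CA": CA, "C": C})
    # carbonyl O and CB from local frames
    for i, r in enumerate(res):
        if i + 1 < len(res):
            next_n = res[i + 1]["N"]
            r["O"] = _place_atom(next_n, r["CA"], r["C"],
                                 _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        else:
            r["O"] = _place_atom(r["N"], r["CA"], r["C"],
                                 _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
        r["CB"] = _place_atom(r["O"] * 0 + r["C"], r["N"], r["CA"],
                              _BOND["CA-CB"], _ANGLE["N-CA-CB"], -122.6)
    return res


def build_ideal_helix(n: int, rise: float = 1.5, twist: float = 100.0,
                      radius: float = 2.3, chain_id: str = "A",
                      start_seq: int = 1) -> Structure:
    """Poly-ALA ideal α-helix along +z with exact CA rise and twist.

    A template residue is taken from a (φ=−57.8°, ψ=−47.0°) helix, aligned
    to the z axis, radially shifted so the CA sits at `radius`, and
    propagated by the exact screw operation (rotate `twist`, translate
    `rise` per residue).
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    ref = _build_phi_psi_helix(12, -57.8, -47.0)
    ca = np.array([r["CA"] for r in ref])
    axis = helix_axis(ca)
    # rotate axis onto z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s_ = np.linalg.norm(v)
    if s_ < 1e-12:
        Rz = np.eye(3)
    else:
        c_ = float(axis @ z)
        K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        Rz = np.eye(3) + K + K @ K * ((1 - c_) / s_**2)
    ca_z = ca @ Rz.T
    cx, cy = _fit_circle_center(ca_z[:, :2])
    center = np.array([cx, cy, 0.0])
    mid = len(ref) // 2
    tmpl = {k: Rz @ v_ - center for k, v_ in ref[mid].items()}
    # radial shift so CA radius matches; azimuth zeroed at the template CA
    ca_t = tmpl["CA"]
    r_ca = np.hypot(ca_t[0], ca_t[1])
    theta0 = np.arctan2(ca_t[1], ca_t[0])
    rot0 = RigidTransform.about_axis(z, -np.degrees(theta0)).rotation
    shift = radius - r_ca
    adj = {}
    for k, v_ in tmpl.items():
        p = rot0 @ v_
        r_p = np.hypot(p[0], p[1])
        scale = (r_p + shift) / r_p if r_p > 1e-9 else 1.0
        adj[k] = np.array([p[0] * scale, p[1] * scale, p[2] - ca_t[2]])
    residues = []
    for i in range(n):
        Ri = RigidTransform.about_axis(z, twist * i).rotation
        dz = np.array([0.0, 0.0, rise * i])
        atoms = [Atom(name, "C" if name in ("CA", "C", "CB") else name[0],
                      Ri @ adj[name] + dz)
                 for name in ("N", "CA", "C", "O", "CB")]
        residues.append(Residue("ALA", start_seq + i, "", atoms))
    return Structure(id=f"ideal_helix_{n}", chains=[(chain_id, residues)],
                     metadata={"rise": rise, "twist": twist, "radius": radius})


# ---------------------------------------------------------------------------
# window alignment and flexing
# ---------------------------------------------------------------------------

def sliding_window_alignments(binder_helix: HelixSegment, cage_helix: HelixSegment,
                              window: int = 5
                              ) -> list[tuple[int, RigidTransform, float]]:
    """Superpose the binder's first `window` helical residues onto every
    `window`-residue window of the cage terminal helix.

    Returns (window_index, transform, fit_rmsd) per window position,
    window_index 0 at the helix start; count = L − window + 1.
    """
    if window < 3:
        raise ValueError("window must be ≥ 3 residues")
    if len(binder_helix) < window or len(cage_helix) < window:
        raise ValueError("both helices must span at least the window length")
    mobile = binder_helix.backbone_coords(0, window)
    out = []
    for idx in range(len(cage_helix) - window + 1):
        target = cage_helix.backbone_coords(idx, window)
        transform, rmsd = kabsch_superpose(mobile, target)
        out.append((idx, transform, rmsd))
    return out


@dataclass(frozen=True)
class FlexParams:
    """Minor helix flexing: bend (deg), bend direction (deg azimuth about
    the helix axis), and extra twist per residue (deg/residue)."""

    bend_angle: float = 0.0
    bend_azimuth: float = 0.0
    twist_delta: float = 0.0

    def check(self, max_bend: float = 10.0, max_twist: float = 3.0) -> None:
        if abs(self.bend_angle) > max_bend:
            raise ValueError(f"bend_angle {self.bend_angle}° exceeds ±{max_bend}°")
        if abs(self.twist_delta) > max_twist:
            raise ValueError(
                f"twist_delta {self.twist_delta}°/res exceeds ±{max_twist}°/res")


def default_flex_grid(bends=(0.0, 2.5, 5.0, 7.5, 10.0), n_azimuth: int = 8,
                      twists=(-2.0, 0.0, 2.0)) -> list[FlexParams]:
    """Deterministic flex grid; bend 0 collapses the azimuth dimension."""
    grid = []
    for bend in bends:
        azimuths = [0.0] if bend == 0.0 else \
            [360.0 * k / n_azimuth for k in range(n_azimuth)]
        for az, tw in itertools.product(azimuths, twists):
            grid.append(FlexParams(bend, az, tw))
    return grid


def flex_helix(coords: np.ndarray, flex: FlexParams, hinge: int,
               ca_index: int = 1, max_bend: float = 10.0,
               max_twist: float = 3.0) -> np.ndarray:
    """Bend/twist a helical segment at a hinge residue.

    `coords` is (n_res, n_atoms, 3) with the CA at `ca_index` in each
    residue. Residues past the hinge are rotated by `bend_angle` about an
    axis perpendicular to the helix axis (direction chosen by
    `bend_azimuth`) through the hinge CA, with cumulative `twist_delta`
    about the helix axis; a small rigid correction keeps the bond across
    the hinge at its original length.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3:
        raise ValueError("coords must be (n_res, n_atoms, 3)")
    n_res = coords.shape[0]
    if not 0 <= hinge < n_res:
        raise ValueError("hinge outside the segment")
    flex.check(max_bend, max_twist)
    if flex.bend_angle == 0.0 and flex.twist_delta == 0.0:
        return coords.copy()
    ca = coords[:, ca_index, :]
    axis = helix_axis(ca)
    pivot = ca[hinge]
    # bend axis: a perpendicular reference rotated by the azimuth
    ref = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(ref) < 1e-6:
        ref = np.cross(axis, [0.0, 1.0, 0.0])
    ref /= np.linalg.norm(ref)
    bend_dir = RigidTransform.about_axis(axis, flex.bend_azimuth).rotation @ ref
    bend = RigidTransform.about_axis(bend_dir, flex.bend_angle, center=pivot)
    out = coords.copy()
    for j in range(hinge + 1, n_res):
        tw = RigidTransform.about_axis(axis, flex.twist_delta * (j - hinge),
                                       center=pivot)
        out[j] = bend.apply(tw.apply(coords[j]))
    # restore the covalent link across the hinge (translate distal block)
    if hinge + 1 < n_res:
        c_h = coords[hinge, 2, :]          # carbonyl C of the hinge residue
        n_next_old = coords[hinge + 1, 0, :]
        n_next_new = out[hinge + 1, 0, :]
        bond = np.linalg.norm(n_next_old - c_h)
        d = n_next_new - c_h
        norm = np.linalg.norm(d)
        if norm > 1e-9:
            correction = c_h + d / norm * bond - n_next_new
            out[hinge + 1:] += correction
    return out


# ---------------------------------------------------------------------------
# pose generation and evaluation
# ---------------------------------------------------------------------------

@dataclass
class FusionPose:
    """One candidate rigid placement of the binder on the cage subunit."""

    window_index: int
    flex: FlexParams
    transform: RigidTransform
    fused_model: Structure
    fit_rmsd: float
    junction_seq: int            # last cage residue in the fused numbering
    binder_first_seq: int        # first binder residue in the fused numbering
    clash_count: int = -1
    contact_count: int = -1
    status: str = "unevaluated"

    def as_record(self) -> dict:
        return {"window": self.window_index,
                "bend": self.flex.bend_angle,
                "azimuth": self.flex.bend_azimuth,
                "twist_delta": self.flex.twist_delta,
                "fit_rmsd": self.fit_rmsd,
                "clashes": self.clash_count,
                "contacts": self.contact_count,
                "status": self.status}


def _fuse_model(cage: Structure, cage_chain: str, cage_helix: HelixSegment,
                window_idx: int, window: int, binder: Structure,
                binder_chain: str, binder_helix: HelixSegment,
                transform: RigidTransform) -> tuple[Structure, int, int]:
    """Single-chain fused model: cage through the window end, then the
    transformed binder past its first `window` helical residues."""
    window_end_seq = cage_helix.residues[window_idx + window - 1].seq_id
    fused_res: list[Residue] = []
    new_seq = 0
    for res in cage.chain(cage_chain):
        if res.seq_id > window_end_seq:
            break
        new_seq += 1
        r = res.copy()
        r.seq_id = new_seq
        r.insertion_code = ""
        fused_res.append(r)
    junction_seq = new_seq
    binder_skip_after = binder_helix.residues[window - 1].seq_id
    for res in binder.chain(binder_chain):
        if res.seq_id <= binder_skip_after:
            continue
        new_seq += 1
        r = res.copy()
        r.seq_id = new_seq
        r.insertion_code = ""
        for a in r.atoms:
            a.coord = transform.apply(a.coord[None, :])[0]
        fused_res.append(r)
    fused = Structure(id=f"fusion_w{window_idx}",
                      chains=[("A", fused_res)],
                      metadata={"window_index": window_idx})
    return fused, junction_seq, junction_seq + 1


def window_flex_transform(cage_helix: HelixSegment, binder_helix: HelixSegment,
                          idx: int, window: int, flex: FlexParams
                          ) -> tuple[RigidTransform, float]:
    """Rigid transform placing the binder for one (window, flex) choice.

    Composes the Kabsch alignment of the binder's first `window` helical
    residues onto cage window `idx` with the hinge bend/twist applied at
    the window midpoint. Returns (transform, alignment rmsd).
    """
    mobile = binder_helix.backbone_coords(0, window)
    target = cage_helix.backbone_coords(idx, window)
    base, fit_rmsd = kabsch_superpose(mobile, target)
    if flex.bend_angle == 0.0 and flex.twist_delta == 0.0:
        return base, fit_rmsd
    hinge_offset = window // 2
    pivot = cage_helix.residues[idx + hinge_offset].atom("CA").coord
    axis = cage_helix.axis
    ref = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(ref) < 1e-6:
        ref = np.cross(axis, [0.0, 1.0, 0.0])
    ref /= np.linalg.norm(ref)
    bend_dir = RigidTransform.about_axis(axis, flex.bend_azimuth).rotation @ ref
    hinge_rot = RigidTransform.about_axis(bend_dir, flex.bend_angle, center=pivot)
    tw_total = flex.twist_delta * (window - 1 - hinge_offset)
    twist_rot = RigidTransform.about_axis(axis, tw_total, center=pivot)
    return hinge_rot.compose(twist_rot).compose(base), fit_rmsd


def evaluate_pose(pose: FusionPose, spec: AssemblySpec,
                  clash_overlap: float = 0.6, contact_cutoff: float = 8.0
                  ) -> tuple[int, int]:
    """Count clashes and binder–binder contacts in the symmetric assembly.

    Clash: an unordered heavy-atom pair closer than
    ``clash_overlap × (r_i + r_j)``, taken between different operator
    copies, or between binder and cage parts within one copy (pairs with
    either atom within ±2 residues of the junction are exempt). Contact: a
    CB–CB pair (CA for GLY) between binder residues of *different* copies
    within `contact_cutoff` Å. Neighbor search uses a KD-tree with a radius
    covering the largest possible threshold, so counts are exact.
    """
    model = pose.fused_model
    placed = model.transformed(spec.frame)
    coords0, radii, seqs, is_binder, is_contact_atom = [], [], [], [], []
    for cid, res, a in placed.iter_atoms():
        if not a.is_heavy:
            continue
        coords0.append(a.coord)
        radii.append(a.vdw_radius)
        seqs.append(res.seq_id)
        binder_side = res.seq_id >= pose.binder_first_seq
        is_binder.append(binder_side)
        is_contact_atom.append(binder_side and (
            (a.name == "CB") or (res.name == "GLY" and a.name == "CA")))
    coords0 = np.array(coords0)
    radii = np.array(radii)
    seqs = np.array(seqs)
    is_binder = np.array(is_binder)
    is_contact_atom = np.array(is_contact_atom)
    near_junction = np.abs(seqs - pose.junction_seq) <= 2

    all_coords, all_copy = [], []
    for i, op in enumerate(spec.group.operators):
        all_coords.append(op.apply(coords0))
        all_copy.append(np.full(len(coords0), i))
    X = np.vstack(all_coords)
    copy_idx = np.concatenate(all_copy)
    n0 = len(coords0)
    atom_idx = np.tile(np.arange(n0), spec.group.order)

    max_clash_r = clash_overlap * 2 * radii.max()
    search_r = max(max_clash_r, contact_cutoff)
    tree = cKDTree(X)
    pairs = tree.query_pairs(r=search_r, output_type="ndarray")
    if len(pairs) == 0:
        return 0, 0
    ii, jj = pairs[:, 0], pairs[:, 1]
    ai, aj = atom_idx[ii], atom_idx[jj]
    same_copy = copy_idx[ii] == copy_idx[jj]
    d = np.linalg.norm(X[ii] - X[jj], axis=1)

    clash_thresh = clash_overlap * (radii[ai] + radii[aj])
    cross_copy_clash = (~same_copy) & (d < clash_thresh)
    intra_bc = same_copy & (is_binder[ai] != is_binder[aj]) & \
        ~near_junction[ai] & ~near_junction[aj] & (d < clash_thresh)
    clash_count = int(np.count_nonzero(cross_copy_clash | intra_bc))

    contacts = (~same_copy) & is_contact_atom[ai] & is_contact_atom[aj] & \
        (d <= contact_cutoff)
    contact_count = int(np.count_nonzero(contacts))
    return clash_count, contact_count


def generate_fusion_poses(cage: Structure, binder: Structure,
                          group: SymmetryGroup, window: int = 5,
                          flex_grid: list[FlexParams] | None = None,
                          cage_chain: str | None = None,
                          binder_chain: str | None = None,
                          cage_helix: HelixSegment | None = None,
                          binder_helix: HelixSegment | None = None,
                          frame: RigidTransform | None = None,
                          clash_overlap: float = 0.6,
                          contact_cutoff: float = 8.0,
                          max_clashes: int = 0,
                          min_contacts: int = 1) -> list[FusionPose]:
    """Enumerate and evaluate all window × flex fusion poses.

    The binder's N-terminal helix is aligned to sliding windows of the
    cage subunit's C-terminal helix; each aligned pose (optionally hinged
    by FlexParams at the window midpoint) yields a single-chain fused
    model that is evaluated in the full symmetric assembly.
    """
    cage_chain = cage_chain or cage.chain_ids[0]
    binder_chain = binder_chain or binder.chain_ids[0]
    if cage_helix is None:
        cage_helix = terminal_helix(cage, cage_chain, "C", min_len=window)
    if binder_helix is None:
        binder_helix = terminal_helix(binder, binder_chain, "N", min_len=window)
    if flex_grid is None:
        flex_grid = [FlexParams()]
    frame = frame or RigidTransform.identity()
    n_windows = len(cage_helix) - window + 1
    poses: list[FusionPose] = []
    for idx in range(n_windows):
        for flex in flex_grid:
            flex.check()
            transform, fit_rmsd = window_flex_transform(
                cage_helix, binder_helix, idx, window, flex)
            fused, junction_seq, binder_first = _fuse_model(
                cage, cage_chain, cage_helix, idx, window,
                binder, binder_chain, binder_helix, transform)
            pose = FusionPose(idx, flex, transform, fused, fit_rmsd,
                              junction_seq, binder_first)
            spec = AssemblySpec(fused, group, frame)
            clashes, contacts = evaluate_pose(pose, spec, clash_overlap,
                                              contact_cutoff)
            pose.clash_count = clashes
            pose.contact_count = contacts
            if clashes > max_clashes:
                pose.status = "rejected_clash"
            elif contacts >= min_contacts:
                pose.status = "promising"
            else:
                pose.status = "explored"
            poses.append(pose)
    return poses


def filter_poses(poses: list[FusionPose], max_clashes: int = 0,
                 min_contacts: int = 1) -> list[FusionPose]:
    """Promising poses, best first (most contacts, then lowest fit RMSD)."""
    keep = [p for p in poses
            if p.clash_count <= max_clashes and p.contact_count >= min_contacts]
    return sorted(keep, key=lambda p: (-p.contact_count, p.fit_rmsd,
                                       p.window_index))
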