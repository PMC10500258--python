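"""Interface metrics and design ranking.

Computes the quantities protruding-arm fusion designs are triaged by:
buried solvent-accessible surface area, Lawrence–Colman shape
complementarity (Sc), buried unsatisfied polar atoms, and simple physical
proxies for interface energy (Lennard-Jones + hydrogen-bond well) and
solvation (atomic solvation parameters × buried area). On top of the raw
metrics sit the pose-level Sc ≥ 0.6 filter, equal-weight normalized
ranking, and mutation-pattern deduplication used to pick a final design
set.

The energy/solvation numbers are intentionally simple surrogates for a
full molecular-mechanics score: their absolute values carry no meaning
outside this package, but the normalization/weighting/filtering machinery
on top of them is exact and is what the tests pin down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._tables import (ASP, ASP_DEFAULT, LJ_EPSILON, LJ_EPSILON_DEFAULT,
                      polar_atom_names)
from .structio import Structure

__all__ = [
    "DotSurface", "InterfaceDefinition", "DesignShells", "MetricVector",
    "DesignCandidate", "ScResult",
    "sasa", "sphere_dots", "define_interface", "design_shells",
    "shape_complementarity", "buried_unsatisfied_polars",
    "interface_energy_proxy", "solvation_proxy",
    "pose_filter_sc", "normalize_and_rank", "dedupe_mutation_patterns",
]

ResidueKey = tuple[str, int]  # (chain_id, seq_id)


def sphere_dots(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere directions (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _atom_table(s: Structure, heavy_only: bool = True):
    keys, names, resnames, coords, radii = [], [], [], [], []
    for cid, res, a in s.iter_atoms():
        if heavy_only and not a.is_heavy:
            continue
        keys.append((cid, res.seq_id))
        names.append(a.name)
        resnames.append(res.name)
        coords.append(a.coord)
        radii.append(a.vdw_radius)
    return keys, names, resnames, np.array(coords), np.array(radii)


def _accessible_dot_mask(coords: np.ndarray, radii: np.ndarray, probe: float,
                         n_dots: int) -> np.ndarray:
    """(n_atoms, n_dots) boolean: dot on the expanded sphere is solvent
    accessible within this atom set."""
    dirs = sphere_dots(n_dots)
    expanded = radii + probe
    n = len(coords)
    mask = np.ones((n, n_dots), dtype=bool)
    if n == 0:
        return mask
    tree = cKDTree(coords)
    max_reach = expanded.max() * 2
    for i in range(n):
        pts = coords[i] + expanded[i] * dirs
        neighbors = tree.query_ball_point(coords[i], r=expanded[i] + max_reach)
        neighbors = [j for j in neighbors if j != i]
        if not neighbors:
            continue
        nc = coords[neighbors]
        nr = expanded[neighbors]
        d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
        mask[i] = ~(d2 < (nr ** 2)[None, :]).any(axis=1)
    return mask


def sasa(s: Structure, probe: float = 1.4, n_dots: int = 960) -> np.ndarray:
    """Shrake–Rupley solvent-accessible surface area per heavy atom (Å²).

    Dots are a fixed golden-spiral set, so results are deterministic.
    Returns areas in hierarchy order over heavy atoms; total SASA is the
    sum.
    """
    _, _, _, coords, radii = _atom_table(s)
    if len(coords) == 0:
        raise ValueError("structure has no heavy atoms")
    mask = _accessible_dot_mask(coords, radii, probe, n_dots)
    expanded = radii + probe
    per_dot_area = 4 * np.pi * expanded ** 2 / n_dots
    return mask.sum(axis=1) * per_dot_area


@dataclass
class DotSurface:
    """Surface dots with outward normals (one entry per accessible dot)."""

    points: np.ndarray
    normals: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        if self.points.shape != self.normals.shape:
            raise ValueError("points/normals shape mismatch")

    def __len__(self):
        return 0 if self.points.size == 0 else len(self.points)


@dataclass
class InterfaceDefinition:
    """Two residue sets forming an interface, with buried-dot surfaces.

    ``dots_a``/``dots_b`` are the dots buried by the partner side;
    ``rim_a``/``rim_b`` are the dots that stay accessible in the complex
    (used to trim the buried-surface periphery before the Sc statistic).
    """

    side_a: set[ResidueKey]
    side_b: set[ResidueKey]
    buried_sasa: float
    dots_a: DotSurface
    dots_b: DotSurface
    rim_a: DotSurface | None = None
    rim_b: DotSurface | None = None

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise ValueError("interface sides must be disjoint")
        if self.buried_sasa < 0:
            raise ValueError("buried_sasa must be ≥ 0")


def _side_dots(coords, radii, side_idx, other_idx, probe, n_dots):
    """Buried and rim dots for one side of a two-body interface."""
    sc = coords[side_idx]
    sr = radii[side_idx]
    mask_alone = _accessible_dot_mask(sc, sr, probe, n_dots)
    dirs = sphere_dots(n_dots)
    oc = coords[other_idx]
    oexp = radii[other_idx] + probe
    tree = cKDTree(oc) if len(oc) else None
    buried_pts, buried_nrm, rim_pts, rim_nrm = [], [], [], []
    for i in range(len(sc)):
        acc = np.nonzero(mask_alone[i])[0]
        if len(acc) == 0:
            continue
        pts = sc[i] + (sr[i] + probe) * dirs[acc]
        if tree is not None:
            dist, j = tree.query(pts, k=1)
            occluded = dist < oexp[j]
        else:
            occluded = np.zeros(len(pts), dtype=bool)
        nrm = dirs[acc]
        buried_pts.append(pts[occluded])
        buried_nrm.append(nrm[occluded])
        rim_pts.append(pts[~occluded])
        rim_nrm.append(nrm[~occluded])
    cat = lambda xs: np.concatenate(xs) if xs else np.empty((0, 3))
    return (DotSurface(cat(buried_pts), cat(buried_nrm)),
            DotSurface(cat(rim_pts), cat(rim_nrm)))


def define_interface(s: Structure, side_a: set[ResidueKey],
                     side_b: set[ResidueKey], probe: float = 1.4,
                     n_dots: int = 400) -> InterfaceDefinition:
    """Build an InterfaceDefinition between two residue sets of `s`.

    The buried dot surfaces are the solvent-accessible dots of each side in
    isolation that the partner side occludes; buried SASA is the
    separated-minus-complex area difference over both sides.
    """
    keys, _, _, coords, radii = _atom_table(s)
    side_a = set(side_a)
    side_b = set(side_b)
    ia = np.array([i for i, k in enumerate(keys) if k in side_a], dtype=int)
    ib = np.array([i for i, k in enumerate(keys) if k in side_b], dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both interface sides must contain atoms")
    both = np.concatenate([ia, ib])
    sub_coords = coords[both]
    sub_radii = radii[both]
    n_a = len(ia)
    expanded = sub_radii + probe
    per_dot = 4 * np.pi * expanded ** 2 / n_dots
    mask_complex = _accessible_dot_mask(sub_coords, sub_radii, probe, n_dots)
    mask_a = _accessible_dot_mask(sub_coords[:n_a], sub_radii[:n_a], probe, n_dots)
    mask_b = _accessible_dot_mask(sub_coords[n_a:], sub_radii[n_a:], probe, n_dots)
    sasa_sep = (mask_a.sum(axis=1) * per_dot[:n_a]).sum() + \
               (mask_b.sum(axis=1) * per_dot[n_a:]).sum()
    sasa_cpx = (mask_complex.sum(axis=1) * per_dot).sum()
    buried = max(float(sasa_sep - sasa_cpx), 0.0)
    dots_a, rim_a = _side_dots(sub_coords, sub_radii, np.arange(n_a),
                               np.arange(n_a, len(both)), probe, n_dots)
    dots_b, rim_b = _side_dots(sub_coords, sub_radii, np.arange(n_a, len(both)),
                               np.arange(n_a), probe, n_dots)
    return InterfaceDefinition(side_a, side_b, buried, dots_a, dots_b,
                               rim_a, rim_b)


# ---------------------------------------------------------------------------
# design/packable shells
# ---------------------------------------------------------------------------

@dataclass
class DesignShells:
    designable: set[ResidueKey]
    packable: set[ResidueKey]


def design_shells(model: Structure, aligned_binder: set[ResidueKey],
                  cutoff: float = 8.0,
                  variable_loop_mask: set[ResidueKey] | None = None,
                  fusion_helix: set[ResidueKey] | None = None) -> DesignShells:
    """Designable and packable residue shells around the fused binder.

    Designable: residues outside the binder with any heavy atom within
    `cutoff` of any binder heavy atom, minus the variable-loop mask, plus
    the fusion-helix residues. Packable: residues within `cutoff` of any
    designable residue (excluding the designable set itself).
    """
    if not aligned_binder:
        raise ValueError("aligned_binder residue set is empty")
    mask = variable_loop_mask or set()
    fusion = fusion_helix or set()
    keys, _, _, coords, _ = _atom_table(model)
    binder_idx = np.array([i for i, k in enumerate(keys) if k in aligned_binder],
                          dtype=int)
    if len(binder_idx) == 0:
        raise ValueError("aligned_binder matches no atoms in the model")
    tree = cKDTree(coords[binder_idx])
    d, _ = tree.query(coords, k=1)
    near = d <= cutoff
    designable = {keys[i] for i in np.nonzero(near)[0]
                  if keys[i] not in aligned_binder}
    designable -= mask
    designable |= set(fusion)
    des_idx = np.array([i for i, k in enumerate(keys) if k in designable],
                       dtype=int)
    packable: set[ResidueKey] = set()
    if len(des_idx):
        dtree = cKDTree(coords[des_idx])
        dd, _ = dtree.query(coords, k=1)
        packable = {keys[i] for i in np.nonzero(dd <= cutoff)[0]}
        packable -= designable
    return DesignShells(designable, packable)


# ---------------------------------------------------------------------------
# shape complementarity
# ---------------------------------------------------------------------------

@dataclass
class ScResult:
    sc: float | None
    undefined: bool = False
    median_a: float | None = None
    median_b: float | None = None


def _directional_s(from_dots: DotSurface, to_dots: DotSurface, w: float
                   ) -> np.ndarray:
    tree = cKDTree(to_dots.points)
    d, j = tree.query(from_dots.points, k=1)
    # opposed-normal convention: perfect fit (antiparallel normals) → +1
    dot = -(from_dots.normals * to_dots.normals[j]).sum(axis=1)
    return dot * np.exp(-w * d ** 2)


def _trim_periphery(dots: DotSurface, rim: DotSurface | None, trim: float
                    ) -> DotSurface:
    if rim is None or len(rim) == 0 or len(dots) == 0 or trim <= 0:
        return dots
    tree = cKDTree(rim.points)
    d, _ = tree.query(dots.points, k=1)
    keep = d > trim
    return DotSurface(dots.points[keep], dots.normals[keep])


def shape_complementarity(iface: InterfaceDefinition, w: float = 0.5,
                          trim: float = 1.5) -> ScResult:
    """Lawrence–Colman shape complementarity of the buried dot surfaces.

    For each buried dot on one side, the nearest buried dot on the other
    contributes s = (n̂·n̂′, opposed sign) · exp(−w·d²); Sc is the mean of
    the two per-side medians after trimming dots within `trim` Å of the
    buried-surface periphery. Returns an undefined flag (not 0) when a
    buried surface is empty.
    """
    da = _trim_periphery(iface.dots_a, iface.rim_a, trim)
    db = _trim_periphery(iface.dots_b, iface.rim_b, trim)
    if len(da) == 0 or len(db) == 0:
        return ScResult(None, undefined=True)
    sa = _directional_s(da, db, w)
    sb = _directional_s(db, da, w)
    ma, mb = float(np.median(sa)), float(np.median(sb))
    return ScResult((ma + mb) / 2, False, ma, mb)


# ---------------------------------------------------------------------------
# buried unsatisfied polars
# ---------------------------------------------------------------------------

def buried_unsatisfied_polars(s: Structure, iface: InterfaceDefinition,
                              sasa_thresh: float = 0.1,
                              hbond_dist: float = 3.5,
                              probe: float = 1.4, n_dots: int = 400) -> int:
    """Count interface donor/acceptor heavy atoms that are buried in the
    complex (SASA < `sasa_thresh` Å²) with no polar partner within
    `hbond_dist` Å (covalent and geminal same-residue neighbors excluded).
    """
    keys, names, resnames, coords, radii = _atom_table(s)
    areas = None
    polar_idx = [i for i in range(len(keys))
                 if names[i] in polar_atom_names(resnames[i])]
    iface_res = iface.side_a | iface.side_b
    candidates = [i for i in polar_idx if keys[i] in iface_res]
    if not candidates:
        return 0
    mask = _accessible_dot_mask(coords, radii, probe, n_dots)
    expanded = radii + probe
    areas = mask.sum(axis=1) * 4 * np.pi * expanded ** 2 / n_dots
    polar_coords = coords[polar_idx]
    tree = cKDTree(polar_coords)
    count = 0
    for i in candidates:
        if areas[i] >= sasa_thresh:
            continue
        partners = tree.query_ball_point(coords[i], r=hbond_dist)
        satisfied = False
        for pj in partners:
            j = polar_idx[pj]
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d < 1.8:           # covalently bonded
                continue
            if keys[j] == keys[i] and d < 2.9:   # geminal within a residue
                continue
            satisfied = True
            break
        if not satisfied:
            count += 1
    return count


# ---------------------------------------------------------------------------
# energy proxies
# ---------------------------------------------------------------------------

def _lj_pair(d: np.ndarray, rmin: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """12-6 Lennard-Jones with minimum −eps at d = rmin; repulsion capped
    below 0.6·rmin to stay finite for overlapping inputs."""
    d_eff = np.maximum(d, 0.6 * rmin)
    x = (rmin / d_eff) ** 6
    return eps * (x ** 2 - 2 * x)


def interface_energy_proxy(model: Structure, iface: InterfaceDefinition,
                           hbond_strength: float = 1.0,
                           cutoff: float = 12.0) -> float:
    """ΔE between complex and rigidly separated sides (≥500 Å ⇒ zero
    cross terms), i.e. the sum over cross-interface heavy-atom pairs of a
    12-6 Lennard-Jones term plus a hydrogen-bond well for donor/acceptor
    pairs at 2.6–3.5 Å. Within-side energies cancel exactly in the
    difference, so only cross pairs are summed.
    """
    keys, names, resnames, coords, radii = _atom_table(model)
    ia = np.array([i for i, k in enumerate(keys) if k in iface.side_a], dtype=int)
    ib = np.array([i for i, k in enumerate(keys) if k in iface.side_b], dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    eps = np.array([LJ_EPSILON.get(n[0].upper(), LJ_EPSILON_DEFAULT)
                    for n in names])
    polar = np.array([names[i] in polar_atom_names(resnames[i])
                      for i in range(len(keys))])
    tree_b = cKDTree(coords[ib])
    pairs = tree_b.query_ball_point(coords[ia], r=cutoff)
    energy = 0.0
    overlap_warned = False
    for ii, neigh in zip(ia, pairs):
        if not neigh:
            continue
        jj = ib[np.array(neigh)]
        d = np.linalg.norm(coords[jj] - coords[ii], axis=1)
        if np.any(d < 1e-6) and not overlap_warned:
            warnings.warn("exact atom overlap at interface; repulsion capped",
                          stacklevel=2)
            overlap_warned = True
        rmin = radii[ii] + radii[jj]
        eij = np.sqrt(eps[ii] * eps[jj])
        energy += float(_lj_pair(d, rmin, eij).sum())
        if polar[ii]:
            hb = polar[jj] & (d >= 2.6) & (d <= 3.5)
            # smooth well centred at 2.9 Å
            energy += float((-hbond_strength *
                             np.exp(-((d[hb] - 2.9) / 0.3) ** 2)).sum())
    return energy


def solvation_proxy(model: Structure, iface: InterfaceDefinition,
                    probe: float = 1.4, n_dots: int = 400) -> float:
    """Σ ASP(element) × (SASA_complex − SASA_separated) over both sides.

    Atomic solvation parameters favor burying apolar area (negative
    contribution) and penalize burying polar area.
    """
    keys, names, _, coords, radii = _atom_table(model)
    ia = [i for i, k in enumerate(keys) if k in iface.side_a]
    ib = [i for i, k in enumerate(keys) if k in iface.side_b]
    both = np.array(ia + ib, dtype=int)
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    sub_c = coords[both]
    sub_r = radii[both]
    n_a = len(ia)
    expanded = sub_r + probe
    per_dot = 4 * np.pi * expanded ** 2 / n_dots
    cpx = _accessible_dot_mask(sub_c, sub_r, probe, n_dots).sum(axis=1) * per_dot
    sep_a = _accessible_dot_mask(sub_c[:n_a], sub_r[:n_a], probe, n_dots
                                 ).sum(axis=1) * per_dot[:n_a]
    sep_b = _accessible_dot_mask(sub_c[n_a:], sub_r[n_a:], probe, n_dots
                                 ).sum(axis=1) * per_dot[n_a:]
    sep = np.concatenate([sep_a, sep_b])
    asp = np.array([ASP.get(names[i][0].upper(), ASP_DEFAULT) for i in both])
    return float((asp * (cpx - sep)).sum())


# ---------------------------------------------------------------------------
# ranking machinery
# ---------------------------------------------------------------------------

@dataclass
class MetricVector:
    """The four ranked interface metrics plus their normalized values."""

    sc: float
    buried_unsats: float
    interface_energy: float
    solvation: float
    normalized: dict[str, float] = field(default_factory=dict)
    combined_score: float | None = None


@dataclass
class DesignCandidate:
    pose_id: str
    design_id: str
    mutations: frozenset[tuple[int, str, str]]
    metrics: MetricVector

    @property
    def mutation_pattern(self) -> tuple[tuple[int, str], ...]:
        return tuple(sorted((pos, to) for pos, _frm, to in self.mutations))


def pose_filter_sc(candidates: list[DesignCandidate], threshold: float = 0.6
                   ) -> list[DesignCandidate]:
    """Drop whole poses whose design-averaged Sc falls below `threshold`."""
    by_pose: dict[str, list[float]] = {}
    for c in candidates:
        by_pose.setdefault(c.pose_id, []).append(c.metrics.sc)
    viable = {pid for pid, scs in by_pose.items()
              if float(np.mean(scs)) >= threshold}
    return [c for c in candidates if c.pose_id in viable]


_METRIC_ORIENT = {  # True → higher raw value is better
    "sc": True, "buried_unsats": False, "interface_energy": False,
    "solvation": False,
}


def normalize_and_rank(candidates: list[DesignCandidate],
                       scheme: str = "minmax",
                       weights: dict[str, float] | None = None
                       ) -> list[DesignCandidate]:
    """Normalize each metric over the pool, orient so 0 = best, sum with
    equal weights (overridable), and rank ascending by the combined score.

    Min-max (default) maps each metric to [0, 1]; a constant column
    contributes 0 for every candidate. Ties break by (sc desc, pose_id,
    design_id).
    """
    if not candidates:
        raise ValueError("empty candidate pool")
    weights = weights or {m: 1.0 for m in _METRIC_ORIENT}
    cols = {m: np.array([getattr(c.metrics, m) for c in candidates], dtype=float)
            for m in _METRIC_ORIENT}
    for m, raw in cols.items():
        if scheme == "minmax":
            span = raw.max() - raw.min()
            norm = np.zeros_like(raw) if span == 0 else (raw - raw.min()) / span
            if _METRIC_ORIENT[m]:
                norm = 1.0 - norm if span != 0 else norm
        elif scheme == "zscore":
            sd = raw.std()
            norm = np.zeros_like(raw) if sd == 0 else (raw - raw.mean()) / sd
            if _METRIC_ORIENT[m]:
                norm = -norm
        else:
            raise ValueError(f"unknown normalization scheme {scheme!r}")
        for c, v in zip(candidates, norm):
            c.metrics.normalized[m] = float(v)
    for c in candidates:
        c.metrics.combined_score = float(
            sum(weights[m] * c.metrics.normalized[m] for m in _METRIC_ORIENT))
    return sorted(candidates,
                  key=lambda c: (c.metrics.combined_score, -c.metrics.sc,
                                 c.pose_id, c.design_id))


def dedupe_mutation_patterns(ranked: list[DesignCandidate], k: int
                             ) -> list[DesignCandidate]:
    """Greedy pass in rank order keeping only novel mutation patterns,
    stopping at k; warns when fewer than k unique patterns exist."""
    seen: set[tuple] = set()
    out: list[DesignCandidate] = []
    for c in ranked:
        pat = c.mutation_pattern
        if pat in seen:
            continue
        seen.add(pat)
        out.append(c)
        if len(out) == k:
            return out
    if len(out) < k:
        warnings.warn(f"only {len(out)} unique mutation patterns (requested {k})",
                      stacklevel=2)
    return out
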