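"""Synthetic fixtures: every module is testable without downloading data.

The generators build toy-but-geometrically-honest inputs: ideal and
composite helices, a C3 toy cage, a small binder with a terminal helix,
fully specified planted-fusion scenarios with a recorded ground truth,
noisy B-factor profile pairs, and Gaussian-atom synthetic maps. Identical
(kind, parameters, seed) always produce identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._tables import VDW_RADII
from .fusion_sampler import (FlexParams, HelixSegment, _build_phi_psi_helix,
                             build_ideal_helix, default_flex_grid,
                             detect_helices, window_flex_transform)
from .structio import Atom, DensityMap, Residue, RigidTransform, Structure
from .symmetry import point_group

__all__ = ["FixtureSpec", "make_fixture", "PlantedFusionScenario",
           "planted_fusion", "toy_cage_c3", "toy_binder", "ideal_helix",
           "helix_loop_helix", "noisy_bprofile", "gaussian_map",
           "DEFAULT_SEED"]

DEFAULT_SEED = 20230905


@dataclass
class FixtureSpec:
    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = DEFAULT_SEED


def make_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    makers = {
        "ideal_helix": ideal_helix,
        "helix_loop_helix": helix_loop_helix,
        "toy_cage_c3": toy_cage_c3,
        "toy_binder": toy_binder,
        "planted_fusion": planted_fusion,
        "noisy_bprofile": noisy_bprofile,
        "gaussian_map": gaussian_map,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    fn = makers[spec.kind]
    if spec.kind in ("planted_fusion", "noisy_bprofile", "gaussian_map"):
        return fn(seed=spec.seed, **spec.parameters)
    return fn(**spec.parameters)


def ideal_helix(n: int = 12, rise: float = 1.5, twist: float = 100.0,
                radius: float = 2.3) -> Structure:
    return build_ideal_helix(n, rise, twist, radius)


def helix_loop_helix(helix1: int = 8, loop: int = 4, helix2: int = 8
                     ) -> Structure:
    """Two helices joined by an extended loop; planted per-residue (φ, ψ)
    are recorded in metadata for oracle use."""
    phis, psis = [], []
    for _ in range(helix1):
        phis.append(-57.8)
        psis.append(-47.0)
    for _ in range(loop):
        phis.append(-120.0)
        psis.append(120.0)
    for _ in range(helix2):
        phis.append(-57.8)
        psis.append(-47.0)
    n = helix1 + loop + helix2
    chain = _build_varying_chain(phis, psis)
    residues = []
    for i, atoms in enumerate(chain):
        alist = [Atom(name, "C" if name.startswith("C") and name != "N" else name[0],
                      atoms[name]) for name in ("N", "CA", "C", "O", "CB")]
        residues.append(Residue("ALA", i + 1, "", alist))
    return Structure(id="helix_loop_helix", chains=[("A", residues)],
                     metadata={"planted_phi": phis, "planted_psi": psis,
                               "helix1": helix1, "loop": loop, "helix2": helix2})


def _build_varying_chain(phis, psis):
    """NeRF chain with per-residue (φ, ψ); mirrors the ideal-helix builder
    geometry but lets torsions vary along the chain."""
    from .fusion_sampler import _ANGLE, _BOND, _place_atom
    n = len(phis)
    res = []
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.deg2rad(_ANGLE["N-CA-C"])
    C0 = CA0 + _BOND["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = res[-1]
        N = _place_atom(prev["N"], prev["CA"], prev["C"],
                        _BOND["C-N"], _ANGLE["CA-C-N"], psis[i - 1])
        CA = _place_atom(prev["CA"], prev["C"], N,
                         _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        C = _place_atom(prev["C"], N, CA, _BOND["CA-C"], _ANGLE["N-CA-C"],
                        phis[i])
        res.append({"N": N, "CA": CA, "C": C})
    for i, r in enumerate(res):
        if i + 1 < n:
            r["O"] = _place_atom(res[i + 1]["N"], r["CA"], r["C"],
                                 _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        else:
            r["O"] = _place_atom(r["N"], r["CA"], r["C"],
                                 _BOND["C-O"], _ANGLE["CA-C-O"], psis[-1] + 180.0)
        r["CB"] = _place_atom(r["C"], r["N"], r["CA"],
                              _BOND["CA-CB"], _ANGLE["N-CA-CB"], -122.6)
    return res


# ---------------------------------------------------------------------------
# toy C3 cage / binder / planted fusion
# ---------------------------------------------------------------------------

def _tilted_helix(n: int, base_radius: float, tilt_deg: float,
                  base_azimuth_deg: float, start_seq: int = 1) -> Structure:
    """Ideal helix whose axis is tilted outward from the z (symmetry) axis."""
    h = build_ideal_helix(n, start_seq=start_seq)
    tilt = RigidTransform.about_axis([0.0, 1.0, 0.0], tilt_deg)
    spin = RigidTransform.about_axis([0.0, 0.0, 1.0], base_azimuth_deg)
    shift = RigidTransform(np.eye(3), np.array([base_radius, 0.0, 0.0]))
    return h.transformed(spin.compose(shift).compose(tilt))


def _hub_residues(start_seq: int, radius: float = 2.4,
                  azimuths=(0.0, 60.0), z_range=(14.0, 26.0),
                  z_step: float = 1.5) -> list[Residue]:
    """Axial hub: a stack of single-carbon residues near the symmetry axis
    that blocks binder bodies from collapsing onto the axis."""
    residues = []
    seq = start_seq
    for z in np.arange(z_range[0], z_range[1] + 1e-9, z_step):
        for az in azimuths:
            th = np.deg2rad(az)
            coord = np.array([radius * np.cos(th), radius * np.sin(th), z])
            residues.append(Residue("GLY", seq, "", [Atom("CA", "C", coord)]))
            seq += 1
    return residues


def toy_cage_c3(helix_len: int = 12, base_radius: float = 16.0,
                tilt_deg: float = 35.0, with_hub: bool = True) -> Structure:
    """A minimal C3 'cage' subunit: an axial hub plus a C-terminal helix
    tilted outward, constructed so the C3 assembly is clash-free."""
    residues: list[Residue] = []
    if with_hub:
        residues.extend(_hub_residues(1))
    helix = _tilted_helix(helix_len, base_radius, tilt_deg, 0.0,
                          start_seq=len(residues) + 1)
    residues.extend(r.copy() for r in helix.chain("A"))
    return Structure(id="toy_cage_c3", chains=[("A", residues)],
                     metadata={"helix_start": len(residues) - helix_len + 1,
                               "helix_len": helix_len, "group": "C3"})


def toy_binder(helix_len: int = 8, n_body: int = 6,
               body_offset=(8.0, 4.0, 6.0)) -> Structure:
    """A binder with an N-terminal helix and a compact CB-only body."""
    h = build_ideal_helix(helix_len)
    residues = [r.copy() for r in h.chain("A")]
    off = np.asarray(body_offset, dtype=float)
    for i in range(n_body):
        coord = off + np.array([0.0, 0.0, 2.2 * i])
        residues.append(Residue("ALA", helix_len + 1 + i, "",
                                [Atom("CB", "C", coord)]))
    return Structure(id="toy_binder", chains=[("A", residues)],
                     metadata={"helix_len": helix_len, "n_body": n_body})


@dataclass
class PlantedFusionScenario:
    """A fusion-sampling problem with known ground truth.

    The binder body is constructed so that exactly one (window, flex)
    choice parks it at a symmetry-axis-proximal target where the three C3
    copies make CB–CB contacts without clashing; every alternative in the
    stated flex grid either loses its contacts or collides with the axial
    hub. Ground truth and the recovery grid travel in ``truth``.
    """

    cage: Structure
    binder: Structure
    group_name: str
    flex_grid: list[FlexParams]
    truth: dict[str, Any]


def _clash_contact_bruteforce(cage_atoms, binder_atoms, n_ops: int = 3,
                              clash_overlap: float = 0.6,
                              contact_cutoff: float = 8.0):
    """O(N²) clash/contact counts for a C_n scenario.

    `cage_atoms`/`binder_atoms` are (coords, radii, is_contact, exempt)
    tuples for one asymmetric unit; `exempt` marks junction-adjacent atoms
    excluded from the within-copy binder-vs-cage clash check (cross-copy
    clashes and contacts still count them, mirroring the pose evaluator).
    """
    cc, cr, _, cex = cage_atoms
    bc, br, bcb, bex = binder_atoms
    coords = np.vstack([cc, bc])
    radii = np.concatenate([cr, br])
    is_binder = np.concatenate([np.zeros(len(cc), bool), np.ones(len(bc), bool)])
    contact_atom = np.concatenate([np.zeros(len(cc), bool), bcb])
    exempt = np.concatenate([cex, bex])
    ops = [RigidTransform.about_axis([0, 0, 1], 360.0 * k / n_ops).rotation
           for k in range(n_ops)]
    all_c = np.concatenate([coords @ R.T for R in ops])
    n = len(coords)
    copy_of = np.repeat(np.arange(n_ops), n)
    aidx = np.tile(np.arange(n), n_ops)
    d = np.linalg.norm(all_c[:, None, :] - all_c[None, :, :], axis=2)
    iu, ju = np.triu_indices(len(all_c), k=1)
    dd = d[iu, ju]
    thr = clash_overlap * (radii[aidx[iu]] + radii[aidx[ju]])
    cross = copy_of[iu] != copy_of[ju]
    intra_bc = (~cross) & (is_binder[aidx[iu]] != is_binder[aidx[ju]]) & \
        ~exempt[aidx[iu]] & ~exempt[aidx[ju]]
    clashes = int(np.count_nonzero((cross | intra_bc) & (dd < thr)))
    contacts = int(np.count_nonzero(
        cross & contact_atom[aidx[iu]] & contact_atom[aidx[ju]]
        & (dd <= contact_cutoff)))
    return clashes, contacts


def planted_fusion(seed: int = DEFAULT_SEED) -> PlantedFusionScenario:
    """Construct a planted C3 fusion scenario with verified unique optimum.

    Deterministic in `seed`. The cage is a hub + tilted C-terminal helix;
    the binder is an 8-residue ideal helix plus a 6-atom CB body line. The
    body's canonical coordinates are chosen so the planted (window, bend,
    azimuth) lands it on a contact-making target near the symmetry axis;
    candidate ground truths are screened by brute-force geometry until one
    is strictly optimal within the recovery grid.
    """
    rng = np.random.default_rng(seed)
    helix_len = int(rng.integers(10, 13))
    window = 5
    n_windows = helix_len - window + 1
    grid = default_flex_grid(bends=(0.0, 2.5, 5.0), n_azimuth=4, twists=(0.0,))
    body_r = 4.5
    body_n = 6
    body_spacing = 2.2
    base_az = float(rng.uniform(0.0, 360.0))
    # candidate ground truths in deterministic, seed-shuffled order
    combos = [(k, f) for k in range(n_windows) for f in grid]
    rng.shuffle(combos)
    cage = toy_cage_c3(helix_len=helix_len, base_radius=16.0, tilt_deg=35.0)
    spin = RigidTransform.about_axis([0, 0, 1], base_az)
    cage = cage.transformed(spin)
    cage_helix = detect_helices(cage, min_len=window)[-1]
    binder_helix_len = 8

    def cage_part(k):
        """Cage atoms surviving truncation at window k's end; the last
        three helix residues (junction ±2 in fused numbering) are flagged
        exempt from the within-copy clash check."""
        end_seq = cage_helix.residues[k + window - 1].seq_id
        coords, radii, exempt = [], [], []
        for _, res, a in _iter(cage):
            if res.seq_id > end_seq:
                continue
            coords.append(a.coord)
            radii.append(a.vdw_radius)
            exempt.append(end_seq - res.seq_id <= 2 and res.name == "ALA")
        return (np.array(coords), np.array(radii), None,
                np.array(exempt, dtype=bool))

    def _iter(s):
        for cid, res_list in s.chains:
            for res in res_list:
                for a in res.atoms:
                    yield cid, res, a

    binder_canonical = build_ideal_helix(binder_helix_len)
    binder_seg = detect_helices(binder_canonical, min_len=window)[0]
    # binder residues kept in the fused model (seq > window); the first two
    # kept residues sit in the junction-exempt zone
    tail_atoms = [(res.seq_id, a) for _, res, a in _iter(binder_canonical)
                  if res.seq_id > window]
    helix_tail = np.array([a.coord for _, a in tail_atoms])
    helix_tail_r = np.array([a.vdw_radius for _, a in tail_atoms])
    helix_tail_cb = np.array([a.name == "CB" for _, a in tail_atoms])
    helix_tail_ex = np.array([seq <= window + 2 for seq, _ in tail_atoms])

    z_top = max(a.coord[2] for _, _, a in _iter(cage))
    body_z0 = min(max(16.0, z_top * 0.8), 22.0)
    body_target = np.array([[body_r, 0.0, body_z0 + body_spacing * i]
                            for i in range(body_n)])

    cage_cache = {k: cage_part(k) for k in range(n_windows)}
    chosen = None
    for k_star, flex_star in combos:
        T_star, _ = window_flex_transform(cage_helix, binder_seg, k_star,
                                          window, flex_star)
        inv = T_star.inverse()
        body_canonical = inv.apply(body_target)
        # screen all grid combos by brute force; planted must be the strict
        # contact-count optimum among clash-free candidates
        best_alt = -1
        planted_ok = False
        planted_contacts = 0
        ok = True
        for k, f in [(k, f) for k in range(n_windows) for f in grid]:
            T, _ = window_flex_transform(cage_helix, binder_seg, k, window, f)
            tail = T.apply(helix_tail)
            body = T.apply(body_canonical)
            b_coords = np.vstack([tail, body])
            b_radii = np.concatenate([helix_tail_r,
                                      np.full(body_n, VDW_RADII["C"])])
            b_cb = np.concatenate([helix_tail_cb, np.ones(body_n, bool)])
            b_ex = np.concatenate([helix_tail_ex, np.zeros(body_n, bool)])
            clashes, contacts = _clash_contact_bruteforce(
                cage_cache[k], (b_coords, b_radii, b_cb, b_ex))
            if (k, f) == (k_star, flex_star):
                planted_ok = clashes == 0 and contacts >= 1
                planted_contacts = contacts
            elif clashes == 0:
                best_alt = max(best_alt, contacts)
        ok = planted_ok and planted_contacts > best_alt
        if ok:
            chosen = (k_star, flex_star, body_canonical, planted_contacts)
            break
    if chosen is None:
        raise RuntimeError(f"no well-posed planted scenario for seed {seed}")
    k_star, flex_star, body_canonical, planted_contacts = chosen
    residues = [r.copy() for r in binder_canonical.chain("A")]
    for i in range(body_n):
        residues.append(Residue("ALA", binder_helix_len + 1 + i, "",
                                [Atom("CB", "C", body_canonical[i])]))
    binder = Structure(id="planted_binder", chains=[("A", residues)],
                       metadata={"helix_len": binder_helix_len,
                                 "n_body": body_n})
    truth = {"window": k_star, "bend": flex_star.bend_angle,
             "azimuth": flex_star.bend_azimuth,
             "twist_delta": flex_star.twist_delta,
             "expected_contacts": planted_contacts,
             "helix_len": helix_len, "seed": seed}
    return PlantedFusionScenario(cage, binder, "C3", grid, truth)


# ---------------------------------------------------------------------------
# profiles and maps
# ---------------------------------------------------------------------------

def noisy_bprofile(n_res: int = 60, noise: float = 3.0, period: int = 12,
                   amplitude: float = 25.0, baseline: float = 20.0,
                   seed: int = DEFAULT_SEED) -> tuple[Structure, Structure]:
    """Two CA-only structures carrying noisy copies of a sawtooth
    per-residue B-factor track (planted tracks in metadata)."""
    rng = np.random.default_rng(seed)
    base = baseline + amplitude * _sawtooth(np.arange(n_res), period)
    tracks = [base + rng.normal(0.0, noise, n_res) for _ in range(2)]
    out = []
    for t_i, track in enumerate(tracks):
        residues = [Residue("GLY", i + 1, "",
                            [Atom("CA", "C", np.array([3.8 * i, 0.0, 0.0]),
                                  bfactor=float(track[i]))])
                    for i in range(n_res)]
        out.append(Structure(id=f"bprofile_{t_i}", chains=[("A", residues)],
                             metadata={"planted_track": track.tolist(),
                                       "noise": noise, "seed": seed}))
    return out[0], out[1]


def _sawtooth(i: np.ndarray, period: int) -> np.ndarray:
    x = (i % period) / period
    return 2 * np.abs(x - 0.5)


def gaussian_map(n_atoms: int = 20, sigma: float = 1.0, voxel: float = 0.5,
                 box: float = 12.0, pad: float = 5.0,
                 seed: int = DEFAULT_SEED) -> DensityMap:
    """Synthetic map: Gaussian atoms at uniform-random positions."""
    from .rigidity import simulate_map
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n_atoms, 3))
    residues = [Residue("GLY", i + 1, "", [Atom("CA", "C", c)])
                for i, c in enumerate(coords)]
    model = Structure(id="gaussian_map_model", chains=[("A", residues)])
    return simulate_map(model, sigma=sigma, voxel=voxel, pad=pad)


def c3_group():
    return point_group("C", 3)
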