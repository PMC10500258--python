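"""Point-group operators and symmetric assembly expansion.

The fusion sampler evaluates every candidate pose in the fully assembled
symmetric environment, so this module provides the rotation groups of the
platonic solids (T, O, I) and the cyclic/dihedral families (Cn, Dn), plus
expansion of an asymmetric unit into the full assembly.

Axis conventions: Cn/Dn principal axis along z (Dn 2-fold along x); T with
its three 2-fold axes along x, y, z and 3-fold axes along the body
diagonals; O as the rotation group of the cube in the same frame; I in the
icosahedral frame with vertices at cyclic permutations of (0, ±1, ±φ).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structio import Residue, RigidTransform, Structure

__all__ = ["SymmetryGroup", "AssemblySpec", "point_group", "expand_assembly",
           "neighbor_copies", "GROUP_ORDERS"]

GROUP_ORDERS = {"T": 12, "O": 24, "I": 60}

_PHI = (1 + np.sqrt(5)) / 2
_MATCH_TOL = 1e-6  # Frobenius-norm tolerance for operator identity


@dataclass
class SymmetryGroup:
    """A finite rotation group: name plus explicit operator list.

    Operators are proper rotations about the origin; the first operator is
    always the identity.
    """

    name: str
    operators: list[RigidTransform] = field(default_factory=list)

    @property
    def order(self) -> int:
        return len(self.operators)

    def _find(self, matrix: np.ndarray) -> int | None:
        for i, op in enumerate(self.operators):
            if np.linalg.norm(op.rotation - matrix) < _MATCH_TOL:
                return i
        return None

    def validate(self) -> None:
        """Numerically verify the group axioms (closure, identity, inverses)."""
        if self._find(np.eye(3)) is None:
            raise ValueError(f"group {self.name}: identity missing")
        for g in self.operators:
            if self._find(g.rotation.T) is None:
                raise ValueError(f"group {self.name}: inverse missing")
            for h in self.operators:
                if self._find(g.rotation @ h.rotation) is None:
                    raise ValueError(f"group {self.name}: not closed under composition")

    def to_json(self) -> str:
        return json.dumps({"name": self.name,
                           "operators": [op.rotation.tolist() for op in self.operators]})

    @classmethod
    def from_json(cls, text: str) -> "SymmetryGroup":
        data = json.loads(text)
        ops = [RigidTransform(np.array(m), np.zeros(3)) for m in data["operators"]]
        return cls(data["name"], ops)


@dataclass
class AssemblySpec:
    """Asymmetric unit + group + frame placing the unit relative to the axes."""

    asym_unit: Structure
    group: SymmetryGroup
    frame: RigidTransform = field(default_factory=RigidTransform.identity)


def _rot(axis, angle_deg) -> np.ndarray:
    return RigidTransform.about_axis(np.asarray(axis, float), angle_deg).rotation


def _closure(generators: list[np.ndarray], expected: int) -> list[np.ndarray]:
    ops = [np.eye(3)]

    def find(m):
        return any(np.linalg.norm(o - m) < _MATCH_TOL for o in ops)

    for g in generators:
        if not find(g):
            ops.append(g)
    changed = True
    while changed:
        changed = False
        for a in list(ops):
            for b in list(ops):
                c = a @ b
                if not find(c):
                    ops.append(c)
                    changed = True
        if len(ops) > expected:
            raise RuntimeError("group generation exceeded expected order")
    return ops


def point_group(name: str, n: int | None = None) -> SymmetryGroup:
    """Build a point group by name: T, O, I, Cn or Dn (n required for C/D)."""
    name = name.upper()
    if name in ("C", "CN", "D", "DN") or (len(name) > 1 and name[0] in "CD" and name[1:].isdigit()):
        if len(name) > 1 and name[1:].isdigit():
            n = int(name[1:])
            name = name[0]
        else:
            name = name[0]
        if n is None or n < 1:
            raise ValueError("cyclic/dihedral groups need order n ≥ 1")
        ops = [_rot([0, 0, 1], 360.0 * k / n) for k in range(n)]
        if name == "D":
            flip = _rot([1, 0, 0], 180.0)
            ops = ops + [op @ flip for op in ops]
            gname = f"D{n}"
        else:
            gname = f"C{n}"
        mats = ops
    elif name == "T":
        mats = _closure([_rot([0, 0, 1], 180), _rot([1, 1, 1], 120)], 12)
        gname = "T"
    elif name == "O":
        mats = _closure([_rot([0, 0, 1], 90), _rot([1, 1, 1], 120)], 24)
        gname = "O"
    elif name == "I":
        mats = _closure([_rot([0, 1, _PHI], 72), _rot([1, 1, 1], 120)], 60)
        gname = "I"
    else:
        raise ValueError(f"unknown point group {name!r}")
    group = SymmetryGroup(gname, [RigidTransform(m, np.zeros(3)) for m in mats])
    expected = GROUP_ORDERS.get(gname[0]) if gname[0] in "TOI" else (
        n if gname[0] == "C" else 2 * n)
    if group.order != expected:
        raise RuntimeError(f"group {gname}: generated {group.order} operators, "
                           f"expected {expected}")
    return group


# PDB-friendly pool for renaming expanded chains
_CHAIN_POOL = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def expand_assembly(spec: AssemblySpec) -> Structure:
    """Replicate the (frame-placed) asymmetric unit under every operator.

    Chains are renamed `<orig><op index>`; where that exceeds PDB limits a
    fresh single-character id is drawn from a pool and the mapping recorded
    in ``metadata['chain_map']``.
    """
    if spec.asym_unit.n_atoms == 0:
        raise ValueError("empty asymmetric unit")
    placed = spec.asym_unit.transformed(spec.frame)
    chains: list[tuple[str, list[Residue]]] = []
    chain_map: dict[str, tuple[str, int]] = {}
    for i, op in enumerate(spec.group.operators):
        copy_i = placed.transformed(op)
        for cid, residues in copy_i.chains:
            new_id = f"{cid}{i}"
            chains.append((new_id, residues))
            chain_map[new_id] = (cid, i)
    st = Structure(id=f"{spec.asym_unit.id}_{spec.group.name}", chains=chains,
                   metadata={"chain_map": chain_map, "group": spec.group.name,
                             "n_operators": spec.group.order})
    return st


def neighbor_copies(spec: AssemblySpec, probe_chain: str, cutoff: float
                    ) -> list[int]:
    """Operator indices whose copy approaches the probe chain of copy 0.

    An operator i (identity excluded) is a neighbor when any heavy atom of
    its copy of the asymmetric unit lies within `cutoff` Å of any heavy
    atom of `probe_chain` in the identity copy.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    placed = spec.asym_unit.transformed(spec.frame)
    if probe_chain not in placed.chain_ids:
        raise KeyError(f"no chain {probe_chain!r} in asymmetric unit")
    probe = np.array([a.coord for cid, _, a in placed.iter_atoms()
                      if cid == probe_chain and a.is_heavy])
    unit = np.array([a.coord for _, _, a in placed.iter_atoms() if a.is_heavy])
    tree = cKDTree(probe)
    out = []
    for i, op in enumerate(spec.group.operators):
        if np.linalg.norm(op.rotation - np.eye(3)) < _MATCH_TOL and \
                np.linalg.norm(op.translation) < _MATCH_TOL:
            continue
        moved = op.apply(unit)
        if tree.query(moved, k=1, distance_upper_bound=cutoff)[0].min() <= cutoff:
            out.append(i)
    return out
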