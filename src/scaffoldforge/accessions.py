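"""Helpers for the optional real-data exercises on deposited structures.

The design and analytics pipeline is fully testable on synthetic
fixtures; these helpers only support the optional cross-checks against
deposited coordinates (scaffold-displayed KRAS models vs. prior X-ray
structures). They fetch files from RCSB at call time and therefore need
network access.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .structio import Structure, backbone_rmsd, read_structure, select

RCSB_URL = "https://files.rcsb.org/download/{code}.pdb"

# Deposited cryo-EM models of scaffold-displayed KRAS mutants and the
# comparison X-ray structures.
KRAS_G13C_CRYOEM = "8G4E"
KRAS_G12V_CRYOEM = "8G4F"
KRAS_G12C_CRYOEM = "8G4H"
KRAS_XRAY_GDP = "5O2S"


def fetch_pdb(code: str, cache_dir: str | Path = "scratch/pdb",
              timeout: float = 30.0) -> Path:
    """Download (or reuse a cached copy of) a PDB entry."""
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{code.upper()}.pdb"
    if not dest.exists():
        with urllib.request.urlopen(RCSB_URL.format(code=code.upper()),
                                    timeout=timeout) as resp:
            dest.write_bytes(resp.read())
    return dest


def _kras_chain(s: Structure) -> Structure:
    """The KRAS chain: the protein chain whose residue numbering spans the
    GTPase domain (~residues 1–170), largest such chain by residue count."""
    best, best_n = None, 0
    for cid, residues in s.chains:
        poly = [r for r in residues if not r.hetero]
        in_range = [r for r in poly if 1 <= r.seq_id <= 170]
        if len(in_range) > best_n and len(in_range) >= 100:
            best, best_n = cid, len(in_range)
    if best is None:
        raise ValueError("no KRAS-sized chain found")
    return select(s, f"chain {best} and resi 1-170")


def kras_backbone_rmsd(code_a: str, code_b: str,
                       cache_dir: str | Path = "scratch/pdb") -> float:
    """Backbone RMSD (Å) between the KRAS chains of two deposited entries,
    paired by author residue number."""
    a = read_structure(fetch_pdb(code_a, cache_dir))
    b = read_structure(fetch_pdb(code_b, cache_dir))
    ka, kb = _kras_chain(a), _kras_chain(b)
    ca, cb = ka.chain_ids[0], kb.chain_ids[0]
    common = sorted({r.seq_id for r in ka.chain(ca) if not r.hetero} &
                    {r.seq_id for r in kb.chain(cb) if not r.hetero})
    pairing = [((ca, s), (cb, s)) for s in common]
    return backbone_rmsd(ka, kb, pairing)
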