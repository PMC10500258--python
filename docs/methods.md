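# Methods

This note documents the models, conventions and numerical choices behind
scaffoldforge, and what the synthetic fixtures do and do not demonstrate.

## Structure model and IO

Structures are an ordered chain → residue → atom hierarchy with
coordinates in Å (right-handed frame), author 1-based residue numbering,
isotropic B-factors (Å²) and occupancies. Parsing and serialization of
PDB/mmCIF and MRC/CCP4 (mode 2, MRC2014) go through gemmi; the hierarchy,
selection language and all analytics are implemented here. Alternate
locations are resolved to the highest-occupancy conformer, ties going to
altloc "A". Van der Waals radii come from a bundled Bondi-style element
table; unknown elements fall back to 1.7 Å and the atom is flagged, with a
warning. Multi-model ensembles, anisotropic B-factors and map symmetry
beyond P1 are out of scope.

Superposition is closed-form Kabsch (SVD with determinant correction, so
reflections are never returned). Collinear point sets are rejected because
the optimal rotation is then not unique. Backbone RMSD pairs residues by
author seq-id intersection within matching chains (single chains are
paired directly); an explicit pairing list can override this.

## Symmetry

Point groups are generated numerically: Cn/Dn analytically about z (Dn
2-fold along x), and T/O/I by closure from two generators (T and O in the
frame with 2-folds on the coordinate axes; I in the icosahedral frame with
vertices at cyclic permutations of (0, ±1, ±φ)). Every generated group is
verified against the group axioms with a Frobenius-norm operator-matching
tolerance of 1e-6. Assembly expansion applies each operator to the
frame-placed asymmetric unit and renames chains `<id><operator index>`,
recording the mapping in metadata. A user-supplied frame transform absorbs
any difference between these axis conventions and the frame of a real
deposited cage.

## Fusion sampling

Helix assignment uses backbone dihedrals: a residue is helical when its
defined angles fall in φ ∈ [−100°, −30°], ψ ∈ [−80°, −5°]; chain-terminal
residues have only one defined angle and are included when it is in range.
Maximal runs of ≥ 5 residues become segments; the terminal helix is the
run nearest the relevant terminus. Helix axes are fit from CA second
differences, which are exactly perpendicular to the axis of an ideal helix
(the translational component of the screw cancels), making the axis
estimate exact on ideal geometry and robust on real helices.

Ideal helices are built from a template residue extracted from a
NeRF-constructed (φ = −57.8°, ψ = −47.0°) poly-ALA helix, aligned to z and
propagated by the exact screw operation, so the requested rise
(1.5 Å/residue), twist (100°/residue) and CA radius (2.3 Å) hold to
machine precision while backbone dihedrals stay in the helical window.

Window alignment superposes the binder's first five helical residues
(backbone N, CA, C, O; 20 atoms) onto each five-residue cage window.
Flexing is parameterized as a bend (≤ 10° by default) about an axis
perpendicular to the helix axis, with the direction set by an azimuth, plus
an extra twist per residue (≤ 3°/res), hinged at the fusion-window
midpoint. For rigid pose generation the twist contribution is applied as
the cumulative twist accrued between the hinge and the window end. After
the hinge rotation a small rigid translation restores the covalent bond
across the hinge to its original length (rotating strictly about the hinge
CA stretches the peptide bond by up to ~0.4 Å at a 10° bend; the
correction keeps it within 0.05 Å as required).

The fused model keeps the cage chain through the window end, then the
transformed binder past its aligned window, renumbered as one chain. Pose
evaluation expands the model under the point group and counts, via a
KD-tree with a search radius covering the largest threshold (exactness
against brute force is property-tested): clashes as heavy-atom pairs
closer than 0.6 × (r_i + r_j) between copies, or between binder and cage
within a copy with the junction ± 2 residues exempt; contacts as CB–CB
pairs (CA for GLY) between binder residues of different copies within 8 Å
— the contact radius deliberately mirrors the 8 Å designable shell.
Enumeration order (window ascending, flex grid lexicographic) is fixed and
nothing is random, so pose tables are byte-reproducible.

The clash overlap factor, contact definition and flex bounds are design
choices of this package: the source methodology for this family of
scaffolds describes collision and proximity screening qualitatively
(partly by visual inspection) without publishing thresholds.

## Interface metrics and ranking

SASA is Shrake–Rupley on a deterministic golden-spiral dot set (default
960 dots/atom, probe 1.4 Å); it agrees with an independent implementation
(biotite) to ~0.01 % on total area. The same dot machinery yields the
interface dot surfaces: dots accessible on a side in isolation but
occluded by the partner are "buried", the rest form the rim used for
periphery trimming. Sc follows the Lawrence–Colman form (w = 0.5 Å⁻²,
median statistic, 1.5 Å periphery trim, opposed-normal sign convention so
perfect fit → +1), evaluated on accessible-surface dots rather than
molecular-surface dots — adequate for ranking and for the analytic
plate/gap limiting cases, but not numerically identical to implementations
built on the Connolly surface. An empty buried surface is reported as
undefined, never as 0.

Buried unsatisfied polars count donor/acceptor heavy atoms (bundled
per-residue table) in interface residues with complex SASA < 0.1 Å² and no
polar partner within 3.5 Å; covalent (< 1.8 Å) and geminal same-residue
(< 2.9 Å) neighbors do not satisfy.

The interface-energy proxy is ΔE = E(complex) − E(separated) where only
cross-interface heavy-atom pairs contribute (within-side terms cancel
exactly under rigid separation): a 12-6 Lennard-Jones with minimum
−√(ε_i ε_j) at r_i + r_j (repulsion capped below 0.6 r_min so clashy
inputs stay finite, with a warning on exact overlap) plus a Gaussian
hydrogen-bond well (depth 1.0, centered 2.9 Å, active 2.6–3.5 Å) for
donor/acceptor pairs. Solvation is kept as its own metric —
Σ ASP(element) × ΔSASA with Eisenberg–McLachlan-style parameters — rather
than folded into ΔE, so the four ranked metrics stay independent and a
two-atom pair at the LJ minimum scores exactly −ε. These proxies are
deliberately simple stand-ins for a full molecular-mechanics score
function: their absolute values are not comparable to any published
energy, and the faithful part of this module is the machinery around them
(shells, Sc filter, normalization, weighting, deduplication), which is
oracle-tested exactly.

Ranking min-max normalizes each metric over the candidate pool, oriented
so 0 is best (Sc inverted; a constant column contributes 0), sums with
equal weights (1.0 each, overridable), sorts ascending, and breaks ties by
(Sc descending, pose id, design id). A z-score scheme is available behind
a flag; min-max is the default for its scale invariance. Pose filtering
averages Sc over each pose's designs and drops poses below 0.6.
Deduplication is a greedy pass in rank order keeping novel mutation sets
(sorted (position, target-residue) tuples — exact identity, with the
near-duplicate question resolved in favor of exactness) up to k = 12.

## Rigidity analytics

Synthetic maps rasterize atoms as unit-amplitude Gaussians (per-atom
integral occ·(2π)^{3/2}σ³), accumulated within 4σ. FSC bins Fourier
voxels into integer radial shells of width 1/(N·voxel); the masked variant
multiplies both maps by a soft model mask (1 within 3 Å of any atom,
cosine taper over 5 Å) before transforming. Resolution is reported at the
first downward crossing of the threshold (default 0.143 per the half-map
convention; half-bit is a flag away), linearly interpolated between
shells; curves that never cross return the Nyquist limit with an explicit
flag rather than a fabricated number.

Q-scores sample the map on radial shells 0–2.0 Å in 0.1 Å steps with at
least 8 fixed directions per shell, preferring directions whose sample
point is closer to the probed atom than to any other atom (without this,
neighbor density systematically depresses the matched-reference limiting
case from ~0.97 to ~0.85). Samples are trilinearly interpolated and
Pearson-correlated with a reference Gaussian of σ = 0.6 Å; residues
average their atoms. Atoms sampling outside the map are excluded with a
warning; near-constant sample sets are scored 0 and flagged. The hinge
profile pairs each residue's Q with its CA distance from a named hinge
residue and reports the least-squares slope in Q/Å — the summary statistic
for "does map quality decay with distance from the fusion junction".

B-factor comparison averages B over each residue's atoms, smooths with a
centered 3-residue moving average (truncated at the edges), min-max
normalizes each profile to [0, 1], and reports the Pearson correlation
over residues shared by seq-id. The normalization makes the comparison
invariant to any positive affine transform of either structure's raw
B-factors — the property that matters when comparing refinements with
different overall B conventions. Constant profiles raise an error because
the correlation is undefined.

## Synthetic fixtures: what they show

The planted-fusion generator builds a C3 scenario from explicit geometry:
a cage subunit (an axial "hub" stack near the symmetry axis plus a
C-terminal ideal helix tilted 35° outward at 16 Å base radius, spun by a
seed-random azimuth), and a binder whose first residues are the same ideal
helix plus a six-atom CB "body" line. The body's canonical coordinates are
back-computed so one chosen (window, bend, azimuth) parks it at a target
4.5 Å from the symmetry axis, where the three copies make CB–CB contacts
(√3 × 4.5 ≈ 7.8 Å ≤ 8) without clashing; the hub blocks inward-collapsing
alternatives. Candidate ground truths are screened with an O(N²)
brute-force clash/contact computation that mirrors the pose evaluator's
rules exactly, and a candidate is accepted only when it is the strict
contact-count optimum among clash-free grid alternatives — so the recorded
truth is verified, not assumed. The recovery grid (bends {0, 2.5, 5}°,
4 azimuths, no twist; 3–4k poses over 20+ scenarios in well under two
minutes on one CPU) is the generator's stated study condition; the full
default grid (5 bends × 8 azimuths × 3 twists) is available and only
multiplies enumeration cost.

What passing these tests shows: the window enumeration, hinge
parameterization, symmetric expansion and exact neighbor counting
recover a known optimum reliably, and every grid/tree computation agrees
with brute force. What they do not show: performance on real cage/binder
coordinates with imperfect helices, loop flexibility, or sequence-design
energetics — the proxies here rank toy geometry, not chemistry. The
fixtures likewise emulate map formation as sums of isotropic Gaussians,
which exercises the FSC/Q-score arithmetic but not CTF effects, solvent,
or radiation damage present in real reconstructions.

## Degenerate inputs and tie-breaks

- All windows of an ideal helix align with fit RMSD ≈ 0; promising-pose
  ordering therefore sorts by (contacts desc, fit RMSD asc, window asc) so
  ties resolve deterministically.
- Kabsch on < 3 or collinear points, empty selections producing empty
  structures, empty candidate pools, constant B-profiles and empty buried
  surfaces all raise (or flag) explicitly rather than returning silent
  zeros.
- Configuration (`RunConfig`) validates every tunable's bounds and rejects
  unknown keys; YAML and TOML are both accepted, with CLI flags taking
  precedence.

## Known limitations

- Sc on accessible-surface dots (see above); values are comparable within
  this package only.
- The interface energy/solvation proxies are ranking surrogates, not
  physical energies.
- The B-factor comparison assumes both structures use meaningful isotropic
  B columns; TLS-dominated or flattened B-factors will correlate poorly
  for reasons unrelated to flexibility.
- Deposited-coordinate comparisons (`scaffoldforge.accessions`) require
  network access to RCSB at run time; nothing is cached in the repository.
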