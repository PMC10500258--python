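"""SASA, shape complementarity, polar burial, proxies and ranking."""

import numpy as np
import pytest

from scaffoldforge import structio as sio
from scaffoldforge.fusion_sampler import build_ideal_helix
from scaffoldforge.interface_metrics import (DesignCandidate, DotSurface,
                                             InterfaceDefinition, MetricVector,
                                             buried_unsatisfied_polars,
                                             dedupe_mutation_patterns,
                                             define_interface, design_shells,
                                             interface_energy_proxy,
                                             normalize_and_rank,
                                             pose_filter_sc, sasa,
                                             shape_complementarity,
                                             solvation_proxy)

from conftest import single_atom_structure


def _structure_from_atoms(groups):
    """groups: {chain: [(resname, seq, [(name, element, coord), ...])]}"""
    chains = []
    for cid, residues in groups.items():
        rs = []
        for resname, seq, atoms in residues:
            rs.append(sio.Residue(resname, seq, "", [
                sio.Atom(n, e, np.asarray(c, float)) for n, e, c in atoms]))
        chains.append((cid, rs))
    return sio.Structure("t", chains)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        s = single_atom_structure()
        area = sasa(s, probe=1.4, n_dots=960)[0]
        analytic = 4 * np.pi * (1.7 + 1.4) ** 2
        assert abs(area - analytic) / analytic <= 0.01

    def test_two_distant_atoms_are_each_isolated(self):
        s = _structure_from_atoms({"A": [
            ("GLY", 1, [("C1", "C", (0, 0, 0))]),
            ("GLY", 2, [("C2", "C", (20, 0, 0))])]})
        areas = sasa(s, 1.4, 960)
        iso = 4 * np.pi * 3.1 ** 2
        assert np.allclose(areas, iso, rtol=0.01)

    def test_two_overlapping_spheres_match_spherical_cap_formula(self):
        d = 3.0  # center separation < 2(r+probe)
        s = _structure_from_atoms({"A": [
            ("GLY", 1, [("C1", "C", (0, 0, 0))]),
            ("GLY", 2, [("C2", "C", (d, 0, 0))])]})
        areas = sasa(s, 1.4, 960)
        R = 1.7 + 1.4
        # equal spheres: each loses a cap of height h = R - d/2
        cap = 2 * np.pi * R * (R - d / 2)
        expected = 4 * np.pi * R ** 2 - cap
        assert np.allclose(areas, expected, rtol=0.02)

    def test_matches_biotite_on_a_helix(self):
        import biotite.structure as struc
        h = build_ideal_helix(8)
        ours = sasa(h, 1.4, 960).sum()
        arr = struc.AtomArray(h.n_atoms)
        coords, radii = [], []
        for i, (cid, res, a) in enumerate(h.iter_atoms()):
            coords.append(a.coord)
            radii.append(a.vdw_radius)
            arr.chain_id[i] = cid
            arr.res_id[i] = res.seq_id
            arr.atom_name[i] = a.name
            arr.res_name[i] = res.name
            arr.element[i] = a.element
        arr.coord = np.array(coords, dtype=np.float32)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii=np.array(radii)).sum()
        assert ours == pytest.approx(ref, rel=0.01)

    def test_contact_never_increases_total_sasa(self):
        for d in (20.0, 8.0, 5.0, 3.5):
            s = _structure_from_atoms({"A": [("GLY", 1, [("C1", "C", (0, 0, 0))])],
                                       "B": [("GLY", 1, [("C2", "C", (d, 0, 0))])]})
            total = sasa(s, 1.4, 400).sum()
            if d == 20.0:
                free = total
            assert total <= free + 1e-9

    def test_empty_structure_raises(self):
        with pytest.raises(ValueError):
            sasa(sio.Structure("e", []))


def _plates(n_side=20, gap=1.0, extent=10.0):
    x = np.linspace(-extent / 2, extent / 2, n_side)
    gx, gy = np.meshgrid(x, x)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(n_side ** 2)])
    up = np.tile([0.0, 0.0, 1.0], (n_side ** 2, 1))
    return InterfaceDefinition(
        {("A", 1)}, {("B", 1)}, 1.0,
        DotSurface(pts, up), DotSurface(pts + [0, 0, gap], -up))


class TestShapeComplementarity:
    def test_touching_plates_score_one(self):
        assert shape_complementarity(_plates(gap=0.0), trim=0).sc == \
            pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("gap", [0.5, 1.0, 1.5])
    def test_plate_gap_closed_form(self, gap):
        r = shape_complementarity(_plates(gap=gap), trim=0)
        assert r.sc == pytest.approx(np.exp(-0.5 * gap ** 2), abs=0.02)

    def test_monotone_in_gap_and_bounded(self):
        scores = [shape_complementarity(_plates(gap=g), trim=0).sc
                  for g in (0.0, 0.4, 0.8, 1.2, 1.6)]
        assert all(-1 <= s <= 1 for s in scores)
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_empty_surface_flagged_undefined_not_zero(self):
        empty = InterfaceDefinition({("A", 1)}, {("B", 1)}, 0.0,
                                    DotSurface(np.empty((0, 3)),
                                               np.empty((0, 3))),
                                    _plates().dots_b)
        r = shape_complementarity(empty)
        assert r.undefined and r.sc is None

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(13)
        pts_a = rng.uniform(-4, 4, (120, 3))
        nrm_a = rng.normal(size=(120, 3))
        nrm_a /= np.linalg.norm(nrm_a, axis=1, keepdims=True)
        pts_b = rng.uniform(-4, 4, (90, 3))
        nrm_b = rng.normal(size=(90, 3))
        nrm_b /= np.linalg.norm(nrm_b, axis=1, keepdims=True)
        iface = InterfaceDefinition({("A", 1)}, {("B", 1)}, 1.0,
                                    DotSurface(pts_a, nrm_a),
                                    DotSurface(pts_b, nrm_b))
        got = shape_complementarity(iface, w=0.5, trim=0).sc

        def direction(p, n, q, m):
            out = []
            for i in range(len(p)):
                d2 = ((q - p[i]) ** 2).sum(axis=1)
                j = int(np.argmin(d2))
                out.append(-(n[i] @ m[j]) * np.exp(-0.5 * d2[j]))
            return np.median(out)

        expected = 0.5 * (direction(pts_a, nrm_a, pts_b, nrm_b) +
                          direction(pts_b, nrm_b, pts_a, nrm_a))
        assert got == pytest.approx(expected, abs=1e-12)


class TestDesignShells:
    def test_isolated_binder_leaves_only_fusion_helix(self):
        model = _structure_from_atoms({"A": [
            ("ALA", 1, [("CA", "C", (0, 0, 0))]),
            ("ALA", 2, [("CA", "C", (100, 0, 0))]),
            ("ALA", 3, [("CA", "C", (100, 4, 0))])]})
        shells = design_shells(model, {("A", 2), ("A", 3)},
                               fusion_helix={("A", 1)})
        assert shells.designable == {("A", 1)}

    def test_masked_loop_residue_excluded(self):
        model = _structure_from_atoms({"A": [
            ("ALA", 1, [("CA", "C", (0, 0, 0))]),
            ("ALA", 2, [("CA", "C", (5, 0, 0))]),
            ("ALA", 3, [("CA", "C", (6, 3, 0))])]})
        no_mask = design_shells(model, {("A", 1)})
        masked = design_shells(model, {("A", 1)},
                               variable_loop_mask={("A", 2)})
        assert ("A", 2) in no_mask.designable
        assert ("A", 2) not in masked.designable

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            n = 25
            model = _structure_from_atoms({"A": [
                ("ALA", i + 1, [("CA", "C", rng.uniform(-15, 15, 3)),
                                ("CB", "C", rng.uniform(-15, 15, 3))])
                for i in range(n)]})
            binder = {("A", i) for i in rng.choice(np.arange(1, n + 1), 5,
                                                   replace=False)}
            got = design_shells(model, binder, cutoff=8.0)
            coords = {}
            for cid, res, a in model.iter_atoms():
                coords.setdefault((cid, res.seq_id), []).append(a.coord)

            def near(key, targets, cutoff=8.0):
                return any(np.linalg.norm(np.array(c) - np.array(t)) <= cutoff
                           for c in coords[key]
                           for tk in targets for t in coords[tk])

            designable = {k for k in coords
                          if k not in binder and near(k, binder)}
            packable = {k for k in coords if near(k, designable)} - designable
            assert got.designable == designable
            assert got.packable == packable


class TestBuriedUnsats:
    def _cage_of_carbons(self, center, radius=4.0, n=40):
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        th = np.pi * (1 + 5 ** 0.5) * i
        pts = center + radius * np.column_stack(
            [np.sin(phi) * np.cos(th), np.sin(phi) * np.sin(th), np.cos(phi)])
        return [(f"C{k}", "C", p) for k, p in enumerate(pts)]

    def test_exposed_polar_never_counted(self):
        s = _structure_from_atoms({
            "A": [("GLY", 1, [("N", "N", (0, 0, 0))])],
            "B": [("GLY", 2, [("C1", "C", (6, 0, 0))])]})
        iface = define_interface(s, {("A", 1)}, {("B", 2)})
        assert buried_unsatisfied_polars(s, iface) == 0

    def test_buried_without_partner_counts_and_partner_satisfies(self):
        cage = self._cage_of_carbons(np.zeros(3))
        s_unsat = _structure_from_atoms({
            "A": [("GLY", 1, [("N", "N", (0, 0, 0))])],
            "B": [("XLG", 2, cage)]})
        iface = define_interface(s_unsat, {("A", 1)}, {("B", 2)})
        assert buried_unsatisfied_polars(s_unsat, iface) == 1
        # an O at hydrogen-bonding distance satisfies the same nitrogen
        s_sat = _structure_from_atoms({
            "A": [("GLY", 1, [("N", "N", (0, 0, 0))])],
            "B": [("XLG", 2, cage + [("O", "O", (2.8, 0, 0))])]})
        iface2 = define_interface(s_sat, {("A", 1)}, {("B", 2)})
        assert buried_unsatisfied_polars(s_sat, iface2) == 0

    def test_adding_partner_never_increases_count(self):
        cage = self._cage_of_carbons(np.zeros(3))
        without = _structure_from_atoms({
            "A": [("GLY", 1, [("N", "N", (0, 0, 0)), ("O", "O", (0, 2.0, 0))])],
            "B": [("XLG", 2, cage)]})
        with_p = _structure_from_atoms({
            "A": [("GLY", 1, [("N", "N", (0, 0, 0)), ("O", "O", (0, 2.0, 0))])],
            "B": [("XLG", 2, cage + [("O", "O", (2.9, 0, 0))])]})
        ia = define_interface(without, {("A", 1)}, {("B", 2)})
        ib = define_interface(with_p, {("A", 1)}, {("B", 2)})
        assert buried_unsatisfied_polars(with_p, ib) <= \
            buried_unsatisfied_polars(without, ia)


class TestEnergyProxies:
    def test_separated_sides_have_zero_energy(self):
        s = _structure_from_atoms({
            "A": [("GLY", 1, [("C1", "C", (0, 0, 0))])],
            "B": [("GLY", 1, [("C2", "C", (600, 0, 0))])]})
        iface = InterfaceDefinition({("A", 1)}, {("B", 1)}, 0.0,
                                    DotSurface(np.zeros((1, 3)), np.ones((1, 3))),
                                    DotSurface(np.zeros((1, 3)), np.ones((1, 3))))
        assert interface_energy_proxy(s, iface) == 0.0
        assert solvation_proxy(s, iface) == pytest.approx(0.0, abs=1e-9)

    def test_pair_at_lj_minimum_scores_minus_epsilon(self):
        s = _structure_from_atoms({
            "A": [("GLY", 1, [("C1", "C", (0, 0, 0))])],
            "B": [("GLY", 1, [("C2", "C", (3.4, 0, 0))])]})
        iface = define_interface(s, {("A", 1)}, {("B", 1)})
        assert interface_energy_proxy(s, iface) == pytest.approx(-0.10,
                                                                 abs=1e-9)

    def test_matches_brute_force_pairwise_sum(self):
        rng = np.random.default_rng(17)
        a_atoms = [("C%d" % i, "C", rng.uniform(0, 6, 3)) for i in range(6)]
        b_atoms = [("C%d" % i, "C", rng.uniform(4, 10, 3)) for i in range(6)]
        s = _structure_from_atoms({"A": [("XLG", 1, a_atoms)],
                                   "B": [("XLG", 1, b_atoms)]})
        iface = define_interface(s, {("A", 1)}, {("B", 1)})
        got = interface_energy_proxy(s, iface)
        eps, rmin = 0.10, 3.4
        total = 0.0
        for _, _, ca in a_atoms:
            for _, _, cb in b_atoms:
                d = max(np.linalg.norm(np.array(ca) - np.array(cb)), 0.6 * rmin)
                if np.linalg.norm(np.array(ca) - np.array(cb)) > 12.0:
                    continue
                x = (rmin / d) ** 6
                total += eps * (x * x - 2 * x)
        assert got == pytest.approx(total, abs=1e-9)

    def test_solvation_equals_asp_times_buried_area(self):
        s = _structure_from_atoms({
            "A": [("GLY", 1, [("C1", "C", (0, 0, 0))])],
            "B": [("GLY", 1, [("C2", "C", (3.4, 0, 0))])]})
        iface = define_interface(s, {("A", 1)}, {("B", 1)})
        got = solvation_proxy(s, iface, n_dots=400)
        alone = sasa(single_atom_structure(), 1.4, 400)[0]
        cpx = sasa(s, 1.4, 400)
        dsasa = cpx.sum() - 2 * alone
        assert got == pytest.approx(0.016 * dsasa, abs=1e-9)


def _candidate(pose, design, sc, unsats, energy, solv, muts=()):
    return DesignCandidate(pose, design, frozenset(muts),
                           MetricVector(sc, unsats, energy, solv))


class TestRanking:
    def test_pose_filter_averages_over_designs(self):
        pool = [_candidate("p1", "d1", 0.55, 1, -1, -1),
                _candidate("p1", "d2", 0.55, 1, -1, -1),
                _candidate("p2", "d1", 0.55, 1, -1, -1),
                _candidate("p2", "d2", 0.70, 1, -1, -1)]
        kept = pose_filter_sc(pool, threshold=0.6)
        assert {c.pose_id for c in kept} == {"p2"}  # mean 0.625 ≥ 0.6

    def test_single_candidate_scores_zero(self):
        ranked = normalize_and_rank([_candidate("p", "d", 0.7, 2, -5, -1)])
        assert ranked[0].metrics.combined_score == pytest.approx(0.0)

    def test_dominating_candidate_ranks_first(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            pool = [_candidate(f"p{i}", "d",
                               rng.uniform(0.3, 0.8), rng.integers(1, 10),
                               rng.uniform(-10, 0), rng.uniform(-5, 0))
                    for i in range(10)]
            dom = _candidate("dom", "d", 0.95, 0, -50.0, -20.0)
            ranked = normalize_and_rank(pool + [dom])
            assert ranked[0].pose_id == "dom"

    def test_ordering_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(29)
        pool = [_candidate(f"p{i:02d}", f"d{i:02d}",
                           rng.uniform(0, 1), rng.integers(0, 12),
                           rng.uniform(-20, 5), rng.uniform(-8, 2))
                for i in range(20)]
        ranked = normalize_and_rank([c for c in pool])
        cols = {
            "sc": np.array([c.metrics.sc for c in pool]),
            "buried_unsats": np.array([c.metrics.buried_unsats for c in pool]),
            "interface_energy": np.array([c.metrics.interface_energy
                                          for c in pool]),
            "solvation": np.array([c.metrics.solvation for c in pool]),
        }
        score = np.zeros(len(pool))
        for m, v in cols.items():
            n = (v - v.min()) / (v.max() - v.min())
            score += (1 - n) if m == "sc" else n
        expected = [pool[i].pose_id for i in np.argsort(score, kind="stable")]
        assert [c.pose_id for c in ranked] == expected

    def test_normalized_values_bounded_and_sum_consistent(self):
        rng = np.random.default_rng(37)
        pool = [_candidate(f"p{i}", "d", rng.uniform(0, 1),
                           rng.integers(0, 9), rng.uniform(-9, 0),
                           rng.uniform(-4, 0)) for i in range(15)]
        for c in normalize_and_rank(pool):
            for v in c.metrics.normalized.values():
                assert 0.0 <= v <= 1.0
            assert c.metrics.combined_score == pytest.approx(
                sum(c.metrics.normalized.values()), abs=1e-9)

    def test_invariant_under_positive_affine_rescaling(self):
        rng = np.random.default_rng(41)
        pool = [_candidate(f"p{i}", "d", rng.uniform(0, 1),
                           rng.integers(0, 9), rng.uniform(-9, 0),
                           rng.uniform(-4, 0)) for i in range(12)]
        order1 = [c.pose_id for c in normalize_and_rank(
            [_candidate(c.pose_id, c.design_id, c.metrics.sc,
                        c.metrics.buried_unsats, c.metrics.interface_energy,
                        c.metrics.solvation) for c in pool])]
        order2 = [c.pose_id for c in normalize_and_rank(
            [_candidate(c.pose_id, c.design_id, c.metrics.sc,
                        3.0 * c.metrics.buried_unsats + 7.0,
                        0.5 * c.metrics.interface_energy - 2.0,
                        c.metrics.solvation) for c in pool])]
        assert order1 == order2

    def test_constant_metric_contributes_zero(self):
        pool = [_candidate(f"p{i}", "d", 0.7, i, -i, -1.0) for i in range(5)]
        for c in normalize_and_rank(pool):
            assert c.metrics.normalized["sc"] == 0.0

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            normalize_and_rank([])


class TestDedupe:
    def test_duplicate_pattern_dropped(self):
        a = _candidate("p1", "d1", 0.8, 0, -5, -2, [(10, "A", "W")])
        b = _candidate("p2", "d2", 0.7, 1, -4, -1, [(10, "A", "W")])
        assert dedupe_mutation_patterns([a, b], k=5) == [a]

    def test_all_distinct_takes_top_k(self):
        pool = [_candidate(f"p{i}", "d", 0.8 - i * 0.01, i, -5, -2,
                           [(i, "A", "W")]) for i in range(20)]
        assert len(dedupe_mutation_patterns(pool, k=12)) == 12

    def test_matches_brute_force_unique_filter(self):
        rng = np.random.default_rng(43)
        pool = []
        for i in range(30):
            pos = int(rng.integers(1, 5))
            pool.append(_candidate(f"p{i:02d}", "d", 0.9 - i * 0.01, i, -5, -2,
                                   [(pos, "A", "W")]))
        got = dedupe_mutation_patterns(pool, k=10)
        seen, expected = set(), []
        for c in pool:
            if c.mutation_pattern not in seen:
                seen.add(c.mutation_pattern)
                expected.append(c)
        assert got == expected[:10]

    def test_warns_when_fewer_unique_than_requested(self):
        pool = [_candidate("p1", "d1", 0.8, 0, -5, -2, [(1, "A", "W")]),
                _candidate("p2", "d2", 0.7, 1, -4, -1, [(1, "A", "W")])]
        with pytest.warns(UserWarning, match="unique"):
            out = dedupe_mutation_patterns(pool, k=5)
        assert len(out) == 1
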