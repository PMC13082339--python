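"""Developmental rules: zonation, rates, midrib, division, stepping."""

import math

import numpy as np
import pytest

from phyllidsim import mechanics
from phyllidsim import morphogenesis as M
from phyllidsim.params import ScenarioParams
from phyllidsim.fixtures import TemplateSpec, make_template
from phyllidsim.tissue import Tissue, retriangulate

from test_tissue import make_column


def column_tissue(n=7):
    t = make_column(n)
    t.cells[0].tissue_type = "attachment"
    t.cells[0].zone = "attachment"
    t.apical_cell_id = n - 1
    retriangulate(t, sorted(t.cells))
    return t


@pytest.fixture()
def params():
    return ScenarioParams.for_scenario("wt_upper")


class TestZones:
    def test_threshold_rule(self, params):
        t = column_tissue(7)
        dist = t.distance_field([0], "cell-count")
        params.d_prolif = 4
        M.update_zones(t, 2.0, params, dist)
        for cid, c in t.cells.items():
            if cid == 0:
                assert c.zone == "attachment"
            elif dist.values[cid] <= 4 or cid == t.apical_cell_id:
                assert c.zone == "proliferative"
            else:
                assert c.zone == "differentiation"
                assert c.t_diff == 2.0

    def test_phase3_all_differentiate(self, params):
        t = column_tissue(5)
        dist = t.distance_field([0], "cell-count")
        M.update_zones(t, params.t_phase23 + 0.1, params, dist)
        for cid, c in t.cells.items():
            if c.tissue_type != "attachment":
                assert c.zone == "differentiation"

    def test_differentiation_absorbing_in_simulation(self, wt_trajectory):
        """No cell ever reverts from differentiation to proliferative."""
        seen = {}
        for snap in wt_trajectory.snapshots:
            for cid, c in snap.tissue.cells.items():
                if seen.get(cid) == "differentiation":
                    assert c.zone == "differentiation"
                seen[cid] = c.zone


class TestGrowthRates:
    def test_phase1_blade_nearly_isotropic(self, params):
        t = column_tissue(5)
        dist = t.distance_field([0], "cell-count")
        M.update_zones(t, 1.1, params, dist)
        M.assign_growth_rates(t, 1.1, params)
        c = t.cells[2]
        assert c.k_par / c.k_per < 1.5

    def test_midrib_reduction_factor(self, params):
        import dataclasses

        flat = dataclasses.replace(params, k_grad_slope=0.0)
        t = column_tissue(5)
        dist = t.distance_field([0], "cell-count")
        M.update_zones(t, 2.5, flat, dist)
        t.cells[2].tissue_type = "midrib"
        M.assign_growth_rates(t, 2.5, flat)
        blade_k_per = t.cells[1].k_per
        assert t.cells[2].k_per == pytest.approx(
            blade_k_per * flat.midrib_k_per_factor)

    def test_differentiated_rates_decay(self, params):
        import dataclasses

        flat = dataclasses.replace(params, k_grad_slope=0.0)
        t = column_tissue(5)
        c = t.cells[3]
        c.zone = "differentiation"
        c.t_diff = 2.0
        tq = 2.0 + flat.diff_tau_e_days + 3 * flat.diff_tau_d_days
        M.assign_growth_rates(t, tq, flat)
        boosted = (flat.blade_k_par_phase2 * flat.diff_elongation_boost)
        assert c.k_par == pytest.approx(boosted * math.exp(-3.0))
        assert c.k_par < math.exp(-3) * boosted * 1.001

    def test_attachment_slow_isotropic(self, params):
        t = column_tissue(5)
        M.assign_growth_rates(t, 3.0, params)
        c = t.cells[0]
        assert c.k_par == c.k_per == params.attach_k


class TestMidrib:
    def test_symmetric_selection(self, params):
        # symmetric grid: 5 columns x 4 rows centered on x = 0, bottom row
        # attachment, others blade
        t = Tissue()
        grid = {}
        for r in range(5):
            for c in range(6):
                grid[(r, c)] = t.new_vertex([c * 16.0 - 40.0, r * 12.0],
                                            is_base=(r == 0))
        for r in range(4):
            for c in range(5):
                t.new_cell([grid[(r, c)], grid[(r, c + 1)],
                            grid[(r + 1, c + 1)], grid[(r + 1, c)]],
                           tissue_type="attachment" if r == 0 else "blade",
                           zone="attachment" if r == 0 else "proliferative")
        dist = t.distance_field(M.base_cells(t), "cell-count")
        selected = M.assign_midrib(t, 2.0, params, dist)
        assert t.midrib_assigned and selected
        xs = sorted(round(t.cell_centroid(c)[0], 6) for c in selected)
        for x in xs:
            assert any(abs(x + y) < 1e-3 for y in xs)  # mirror partner

    def test_heritable(self, wt_trajectory):
        """Every descendant of a midrib cell is midrib."""
        parent_of = dict(wt_trajectory.final.lineage)
        types = {}
        for snap in wt_trajectory.snapshots:
            for cid, c in snap.tissue.cells.items():
                types.setdefault(cid, c.tissue_type)
        n_checked = 0
        for child, parent in parent_of.items():
            if types.get(parent) == "midrib" and child in types:
                assert types[child] == "midrib"
                n_checked += 1
        assert n_checked > 0

    def test_connected_band(self, wt_trajectory):
        """Midrib forms a single connected band in the final snapshot."""
        import networkx as nx

        f = wt_trajectory.final
        mid = [c for c in f.cells if f.cells[c].tissue_type == "midrib"]
        assert mid
        sub = f.build_adjacency().subgraph(mid)
        assert nx.number_connected_components(sub) == 1


class TestDivideCell:
    def divide_rect(self, w, h, polarity):
        t = Tissue()
        vs = [t.new_vertex(p) for p in
              [[0, 0], [w, 0], [w, h], [0, h]]]
        t.new_cell(vs)
        t.cells[0].polarity = np.array(polarity, float)
        retriangulate(t, [0])
        params = ScenarioParams.for_scenario("wt_upper")
        return t, M.divide_cell(t, 0, params)

    def test_long_axis_split_perpendicular(self):
        """2x1 rectangle, polarity along long axis: wall is the short chord
        perpendicular to polarity; daughters are unit squares."""
        t, (daughters, wall, dirty, dirv) = self.divide_rect(1.0, 2.0, [0, 1])
        a1, a2 = (t.cell_area(d) for d in daughters)
        assert a1 + a2 == pytest.approx(2.0, rel=1e-12)
        assert a1 == pytest.approx(1.0, rel=1e-9)
        # wall direction is perpendicular to polarity
        assert abs(np.dot(dirv, [0, 1])) < 1e-12

    def test_square_tie_breaks_perpendicular(self):
        t, (daughters, wall, dirty, dirv) = self.divide_rect(1.0, 1.0, [0, 1])
        assert abs(np.dot(dirv, [0, 1])) < 1e-12  # perpendicular chosen
        a1, a2 = (t.cell_area(d) for d in daughters)
        assert a1 == pytest.approx(a2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_convex_polygons_choose_shorter_chord(self, seed):
        """On random convex polygons the chosen chord is never longer than
        the rejected orientation's chord."""
        rng = np.random.default_rng(seed)
        npts = rng.integers(5, 10)
        ang = np.sort(rng.uniform(0, 2 * np.pi, npts))
        r = rng.uniform(1, 3, npts)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
        t = Tissue()
        vs = [t.new_vertex(p) for p in pts]
        t.new_cell(vs)
        th = rng.uniform(0, np.pi)
        pol = np.array([math.cos(th), math.sin(th)])
        t.cells[0].polarity = pol
        c = t.cell_centroid(0)
        ring = t.ring_coords(0)

        def chord_len(d):
            ch = M.chord_through(ring, c, d)
            return ch[1][3] - ch[0][3]

        l_par = chord_len(pol)
        l_perp = chord_len(M._perp(pol))
        retriangulate(t, [0])
        params = ScenarioParams.for_scenario("wt_upper")
        daughters, wall, dirty, dirv = M.divide_cell(t, 0, params)
        chosen = l_perp if abs(np.dot(dirv, pol)) < 1e-9 else l_par
        assert chosen <= min(l_par, l_perp) + 1e-9
        # area conservation
        assert sum(t.cell_area(d) for d in daughters) == pytest.approx(
            abs(M.polygon_area(pts)), rel=1e-9)

    def test_daughters_adjacent_and_neighbors_partition(self):
        """After division daughters are adjacent; their neighbor sets cover
        the parent's neighbors."""
        t = make_column(3)
        t.cells[1].polarity = np.array([0.0, 1.0])
        retriangulate(t, sorted(t.cells))
        params = ScenarioParams.for_scenario("wt_upper")
        neighbors_before = set(t.build_adjacency().neighbors(1))
        (d1, d2), wall, dirty, dirv = M.divide_cell(t, 1, params)
        g = t.build_adjacency()
        assert g.has_edge(d1, d2)
        after = (set(g.neighbors(d1)) | set(g.neighbors(d2))) - {d1, d2}
        assert after == neighbors_before


class TestApicalDivision:
    def test_alternating_60_degrees(self, params):
        t = make_template(TemplateSpec())
        t.time = 1.35
        M.apical_divide(t, params)
        retriangulate(t, sorted(t.cells))
        assert t.apical_division_side == "right"
        M.apical_divide(t, params)
        assert t.apical_division_side == "left"

    def test_merophyte_ids_sequential(self, wt_trajectory):
        """Merophyte ids 1..N ordered by formation time; N = 2 + number of
        apical divisions."""
        apical_events = [e for e in wt_trajectory.events if e.is_apical]
        meros = [e.merophyte for e in apical_events]
        assert meros == sorted(meros)
        assert meros == list(range(3, 3 + len(apical_events)))
        assert wt_trajectory.merophyte_count() == 2 + len(apical_events)

    def test_wall_angle_is_60_degrees(self, wt_trajectory):
        for e in wt_trajectory.events:
            if e.is_apical:
                assert e.angle_to_polarity_deg == pytest.approx(60.0, abs=0.5)


class TestStep:
    def test_dt_zero_is_geometric_noop(self, params):
        t = make_template(TemplateSpec())
        t.time = 1.0
        M.step(t, params, params.dt_days)
        pos = {v: t.vertices[v].pos.copy() for v in t.vertices}
        n_cells = len(t.cells)
        M.step(t, params, 0.0)
        assert len(t.cells) == n_cells
        for v, p in pos.items():
            assert np.array_equal(t.vertices[v].pos, p)

    def test_zero_rates_identity(self, params):
        t = make_template(TemplateSpec())
        t.time = 1.0
        # forcing all rates to zero: no geometry change
        p0 = {v: t.vertices[v].pos.copy() for v in t.vertices}
        import dataclasses

        frozen = dataclasses.replace(
            params, apical_k_par=0.0, apical_k_per=0.0,
            blade_k_par_phase1=0.0, blade_k_per_phase1=0.0,
            blade_k_par_phase2=0.0, blade_k_per_phase2=0.0, attach_k=0.0,
            apical_period_days=100.0)
        M.step(t, frozen, frozen.dt_days)
        for v, p in p0.items():
            assert np.allclose(t.vertices[v].pos, p, atol=1e-12)

    def test_half_steps_close_to_full_step(self, params):
        """Two half steps vs one full step agree on areas within 1%."""
        import dataclasses

        quiet = dataclasses.replace(params, apical_period_days=100.0,
                                    area_threshold_um2=1e9)
        t1 = make_template(TemplateSpec())
        t1.time = 1.0
        t2 = t1.copy()
        M.step(t1, quiet, 0.05)
        M.step(t2, quiet, 0.025)
        M.step(t2, quiet, 0.025)
        for cid in t1.cells:
            a1, a2 = t1.cell_area(cid), t2.cell_area(cid)
            assert a1 == pytest.approx(a2, rel=0.01)


class TestBookkeeping:
    def test_cell_count_equals_template_plus_divisions(self, wt_trajectory):
        assert (len(wt_trajectory.final.cells)
                == len(wt_trajectory.snapshots[0].tissue.cells)
                + len(wt_trajectory.events))

    def test_merophyte_heritability(self, wt_trajectory):
        """Merophyte id of every non-apical child matches its parent's."""
        meros = {}
        apical_ids = set()
        for snap in wt_trajectory.snapshots:
            for cid, c in snap.tissue.cells.items():
                meros.setdefault(cid, c.merophyte_id)
        apical_children = {e.daughter_a for e in wt_trajectory.events
                           if e.is_apical}
        apical_children |= {e.daughter_b for e in wt_trajectory.events
                            if e.is_apical}
        for child, parent in wt_trajectory.final.lineage:
            if child in apical_children or child not in meros or \
                    parent not in meros:
                continue
            assert meros[child] == meros[parent]

    def test_division_zone_stays_near_base(self, wt_trajectory):
        """During phase 2 divisions occur below a fixed normalized distance
        from the organ base."""
        p = wt_trajectory.params
        snaps = {round(s.time, 3): s.tissue for s in wt_trajectory.snapshots}
        times = sorted(snaps)
        for e in wt_trajectory.events:
            if e.is_apical or not (p.t_phase12 <= e.time <= p.t_phase23):
                continue
            # nearest snapshot at/after the event (organ extent at division)
            t_next = min(tt for tt in times if tt >= e.time - 1e-9)
            tis = snaps[t_next]
            # wall midpoint height relative to organ extent
            lo, hi = tis.bounds()
            y = 0.5 * (e.wall_a[1] + e.wall_b[1])
            norm = (y - lo[1]) / (hi[1] - lo[1])
            assert norm <= 0.8
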