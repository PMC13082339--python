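"""Developmental rules and the simulation loop.

Positional information drives everything: a cell-count distance field from
the attachment base defines the proliferative zone, the gradient of a
distance field from the apical cell defines per-cell polarity, and three
developmental phases (initiation, expansion, maturation) schedule growth
rates, the midrib, cell division and differentiation.  The apical cell is
special: it divides obliquely at a fixed angle in an alternating left-right
pattern, cutting off one merophyte (clonal sector) per division.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import split as shapely_split

from . import mechanics
from .params import ScenarioParams
from .quantify import classify_wall_orientation
from .tissue import (DistanceField, Tissue, polygon_area, retriangulate)


@dataclass
class DivisionEvent:
    time: float
    parent: int
    daughter_a: int
    daughter_b: int
    wall_a: tuple  # (x, y) of one wall endpoint
    wall_b: tuple
    orientation: str  # longitudinal | mediolateral
    is_apical: bool
    angle_to_polarity_deg: float
    merophyte: int


@dataclass
class Snapshot:
    time: float
    tissue: Tissue


@dataclass
class Trajectory:
    """Ordered tissue snapshots plus the full division/lineage log."""

    params: ScenarioParams
    snapshots: list = field(default_factory=list)
    events: list = field(default_factory=list)

    @property
    def final(self) -> Tissue:
        return self.snapshots[-1].tissue

    def times(self):
        return [s.time for s in self.snapshots]

    def merophyte_count(self) -> int:
        """Distinct merophyte identities in the final snapshot (apical excluded)."""
        return len({c.merophyte_id for c in self.final.cells.values()
                    if c.merophyte_id > 0})

    def aspect_ratio(self) -> float:
        """Final organ length/width from the principal axes of the
        area-weighted cell-centroid distribution (robust to the slight lean
        the alternating apical divisions impart)."""
        tis = self.final
        w = np.array([tis.cell_area(c) for c in sorted(tis.cells)])
        pts = np.array([tis.cell_centroid(c) for c in sorted(tis.cells)])
        mean = (w[:, None] * pts).sum(axis=0) / w.sum()
        d = pts - mean
        cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0)
        cov /= w.sum()
        evals = np.linalg.eigvalsh(cov)
        return float(np.sqrt(evals[1] / max(evals[0], 1e-12)))

    def division_counts(self, orientation=None, include_apical=False):
        n = 0
        for e in self.events:
            if e.is_apical and not include_apical:
                continue
            if orientation is None or e.orientation == orientation:
                n += 1
        return n


# ----------------------------------------------------------------- zonation

def phase_of(t: float, params: ScenarioParams) -> int:
    if t < params.t_phase12 - 1e-9:
        return 1
    if t < params.t_phase23 - 1e-9:
        return 2
    return 3


def base_cells(tissue: Tissue):
    return sorted(c.id for c in tissue.cells.values()
                  if c.tissue_type == "attachment")


def update_zones(tissue: Tissue, t: float, params: ScenarioParams,
                 dist_base: DistanceField):
    """Assign zones from the cell-count distance to the attachment base.

    Attachment is heritable; differentiation is absorbing (records t_diff on
    first entry).  In phase 3 — and, for the auxin-treated mutant scenario,
    from phase 2 on — every non-attachment cell differentiates.
    """
    phase = phase_of(t, params)
    all_diff = phase == 3 or (params.divisions_off_after_phase1 and phase >= 2)
    for cell in tissue.cells.values():
        if cell.tissue_type == "attachment":
            cell.zone = "attachment"
            continue
        if cell.zone == "differentiation":
            continue
        if cell.id == tissue.apical_cell_id and not all_diff:
            cell.zone = "proliferative"
            continue
        d = dist_base.values[cell.id]
        if (not all_diff) and d <= params.d_prolif + 1e-9:
            cell.zone = "proliferative"
        else:
            cell.zone = "differentiation"
            cell.t_diff = t


def assign_midrib(tissue: Tissue, t: float, params: ScenarioParams,
                  dist_base: DistanceField):
    """One-shot midrib specification near the base and the midline (heritable)."""
    if tissue.midrib_assigned or t < params.midrib_t_onset - 1e-9:
        return
    lo, hi = tissue.bounds()
    midline = 0.5 * (lo[0] + hi[0])
    selected = []
    for cell in tissue.cells.values():
        if cell.tissue_type != "blade":
            continue
        cx = tissue.cell_centroid(cell.id)[0]
        if (abs(cx - midline) <= params.midrib_max_offset_um and
                dist_base.values[cell.id] <= params.midrib_max_base_distance):
            selected.append(cell.id)
    for cid in selected:
        tissue.cells[cid].tissue_type = "midrib"
    tissue.midrib_assigned = True
    if not selected:
        warnings.warn("midrib specification selected zero cells; "
                      "parameters inconsistent with template")
    return selected


def assign_growth_rates(tissue: Tissue, t: float, params: ScenarioParams,
                        dist_base: DistanceField | None = None):
    """Set per-cell (k_par, k_per) from zone, tissue type and position.

    Attachment grows very slowly and isotropically.  Blade cells use the
    phase-1 (slow, near-isotropic) or phase-2 (anisotropic) rates,
    attenuated basipetally: rates fall linearly with cell-count distance
    from the base (slope k_grad_slope per cell, floor fraction
    k_grad_floor), producing the proximally-biased growth gradient.  The
    midrib multiplies k_per by a strong reduction factor.  Differentiated
    cells elongate transiently (k_par boosted for tau_e after t_diff) and
    then both rates decay exponentially with timescale tau_d.
    """
    phase = phase_of(t, params)
    if dist_base is None:
        dist_base = tissue.distance_field(base_cells(tissue), "cell-count")
    for cell in tissue.cells.values():
        cell.area_threshold = params.area_threshold_um2
        if cell.tissue_type == "attachment":
            cell.k_par = cell.k_per = params.attach_k
            continue
        if cell.id == tissue.apical_cell_id and cell.t_diff is None:
            cell.k_par = params.apical_k_par
            cell.k_per = params.apical_k_per
            continue
        if cell.zone == "differentiation" or phase >= 2:
            k_par, k_per = params.blade_k_par_phase2, params.blade_k_per_phase2
        else:
            k_par, k_per = params.blade_k_par_phase1, params.blade_k_per_phase1
        d = dist_base.values.get(cell.id, 1.0)
        if params.k_grad_slope > 0 and math.isfinite(d):
            atten = max(params.k_grad_floor,
                        1.0 - params.k_grad_slope * max(0.0, d - 1.0))
            k_par *= atten
            k_per *= atten
        if cell.tissue_type == "midrib":
            k_per *= params.midrib_k_per_factor
        if cell.zone == "differentiation" and cell.t_diff is not None:
            dt_diff = t - cell.t_diff
            if dt_diff < params.diff_tau_e_days:
                k_par *= params.diff_elongation_boost
            else:
                f = math.exp(-(dt_diff - params.diff_tau_e_days)
                             / params.diff_tau_d_days)
                k_par *= params.diff_elongation_boost * f
                k_per *= f
        cell.k_par, cell.k_per = k_par, k_per


# ------------------------------------------------------------ cell division

def _perp(v):
    return np.array([-v[1], v[0]])


def _line_crossings(pts: np.ndarray, point: np.ndarray, dirv: np.ndarray):
    """Boundary crossings of an infinite line with a polygon ring.

    Returns a list of (kind, index, frac, u): kind 'vertex' (ring vertex on
    the line) or 'edge' (interior of edge index..index+1 at fraction frac);
    u is the signed position of the crossing along the line from `point`.
    """
    n = len(pts)
    normal = _perp(dirv)
    s = (pts - point) @ normal
    scale = float(np.abs(pts - point).max()) or 1.0
    eps = 1e-9 * scale
    out = []
    for i in range(n):
        if abs(s[i]) <= eps:
            u = float((pts[i] - point) @ dirv)
            out.append(("vertex", i, 0.0, u))
    for i in range(n):
        j = (i + 1) % n
        si, sj = s[i], s[j]
        if abs(si) <= eps or abs(sj) <= eps:
            continue
        if si * sj < 0:
            frac = si / (si - sj)
            p = pts[i] + frac * (pts[j] - pts[i])
            u = float((p - point) @ dirv)
            out.append(("edge", i, float(frac), u))
    return out


def chord_through(pts: np.ndarray, point: np.ndarray, dirv: np.ndarray):
    """The chord of the polygon along direction dirv containing `point`.

    Returns (neg, pos) crossings bracketing the point, or None if the line
    does not properly cross.
    """
    crossings = _line_crossings(pts, point, dirv)
    neg = [c for c in crossings if c[3] < 0]
    pos = [c for c in crossings if c[3] >= 0]
    if not neg or not pos:
        return None
    a = max(neg, key=lambda c: c[3])
    b = min(pos, key=lambda c: c[3])
    return a, b


def _insert_vertex_on_edge(tissue: Tissue, va: int, vb: int, new_vid: int):
    """Insert new_vid between va and vb in every ring containing that edge."""
    touched = []
    for cid, cell in tissue.cells.items():
        ring = cell.boundary
        n = len(ring)
        for i in range(n):
            a, b = ring[i], ring[(i + 1) % n]
            if (a, b) == (va, vb) or (a, b) == (vb, va):
                ring.insert(i + 1, new_vid)
                touched.append(cid)
                break
    return touched


SNAP_FRAC = 0.02  # snap chord endpoints this close to a ring vertex onto it


def _plan_endpoint(ring, pts, crossing, snap):
    """Resolve one chord crossing to ('vertex', vid) or ('edge', va, vb, p)."""
    kind, idx, frac, _u = crossing
    n = len(ring)
    if kind == "vertex":
        return ("vertex", ring[idx])
    if snap and frac <= SNAP_FRAC:
        return ("vertex", ring[idx])
    if snap and frac >= 1.0 - SNAP_FRAC:
        return ("vertex", ring[(idx + 1) % n])
    p = pts[idx] + frac * (pts[(idx + 1) % n] - pts[idx])
    return ("edge", ring[idx], ring[(idx + 1) % n], p)


def _plan_split(ring, pts, pos_of, endpoints):
    """Daughter rings for a planned split, or None if the plan is degenerate.

    Works on symbolic ids: planned new vertices are ('new', k) placeholders.
    """
    work = list(ring)
    wall = []
    for k, ep in enumerate(endpoints):
        if ep[0] == "vertex":
            wall.append(ep[1])
        else:
            _tag, va, vb, p = ep
            marker = ("new", k)
            # insert between va and vb in the working ring
            for i in range(len(work)):
                a, b = work[i], work[(i + 1) % len(work)]
                if (a, b) == (va, vb) or (a, b) == (vb, va):
                    work.insert(i + 1, marker)
                    break
            else:
                return None
            pos_of = dict(pos_of)
            pos_of[marker] = p
            wall.append(marker)
    if wall[0] == wall[1] or wall[0] not in work or wall[1] not in work:
        return None
    i0, i1 = work.index(wall[0]), work.index(wall[1])
    if i0 > i1:
        i0, i1 = i1, i0
        wall = [wall[1], wall[0]]
    ring_a = work[i0:i1 + 1]
    ring_b = work[i1:] + work[:i0 + 1]
    for r in (ring_a, ring_b):
        if len(r) < 3:
            return None
        coords = np.array([pos_of[v] for v in r])
        if polygon_area(coords) <= 0:
            return None
    return ring_a, ring_b, wall, pos_of


def split_cell(tissue: Tissue, cid: int, point, dirv):
    """Split a cell along the line (point, dirv); returns daughters and wall.

    Creates shared wall vertices, snapping endpoints that land very close to
    an existing ring vertex onto it (avoiding sliver walls); new vertices
    are inserted into neighbouring rings to keep the tiling conforming.
    Removes the parent and creates two daughter cells inheriting its
    identity fields.  Returns (daughter_ids, wall_vids, dirty_cells) where
    dirty_cells are neighbours whose rings changed and need retriangulation.
    """
    cell = tissue.cells[cid]
    pts = tissue.ring_coords(cid)
    point = np.asarray(point, float)
    dirv = np.asarray(dirv, float)
    dirv = dirv / np.linalg.norm(dirv)
    chord = chord_through(pts, point, dirv)
    if chord is None:
        raise ValueError(f"division line misses cell {cid}: point={point}, "
                         f"dir={dirv}, ring={pts.tolist()}")
    ring = cell.boundary
    pos_of = {v: tissue.vertices[v].pos for v in ring}
    plan = None
    for snap in (True, False):
        endpoints = [_plan_endpoint(ring, pts, chord[i], snap) for i in (0, 1)]
        plan = _plan_split(ring, pts, pos_of, endpoints)
        if plan is not None:
            break
    if plan is None:
        raise ValueError(
            f"division chord fails to split cell {cid} into two simple "
            f"parts: point={point.tolist()}, dir={dirv.tolist()}, "
            f"ring={pts.tolist()}")
    ring_a_sym, ring_b_sym, wall_sym, pos_sym = plan

    dirty = set()
    sym_to_vid = {}
    for k, ep in enumerate(endpoints):
        if ep[0] == "edge":
            _tag, va, vb, p = ep
            vid = tissue.new_vertex(p)
            sym_to_vid[("new", k)] = vid
            dirty.update(_insert_vertex_on_edge(tissue, va, vb, vid))

    def realize(sym_ring):
        return [sym_to_vid.get(v, v) for v in sym_ring]

    ring_a = realize(ring_a_sym)
    ring_b = realize(ring_b_sym)
    wall_vids = realize(wall_sym)
    dirty.discard(cid)

    def make_daughter(new_ring):
        did = tissue.new_cell(
            new_ring, merophyte_id=cell.merophyte_id,
            tissue_type=cell.tissue_type, zone=cell.zone,
            polarity=None if cell.polarity is None else cell.polarity.copy(),
            k_par=cell.k_par, k_per=cell.k_per,
            area_threshold=cell.area_threshold, t_diff=cell.t_diff,
            parent_id=cid)
        tissue.lineage.append((did, cid))
        return did

    area_parent = polygon_area(pts)
    # remove parent (and its elements / interior nodes)
    tissue.elements = [e for e in tissue.elements if e.cell_id != cid]
    for vid in cell.interior_vertices:
        tissue.vertices.pop(vid, None)
    del tissue.cells[cid]
    d1 = make_daughter(ring_a)
    d2 = make_daughter(ring_b)
    for did in (d1, d2):
        a = tissue.cell_area(did)
        if a <= 0 or len(tissue.cells[did].boundary) < 3:
            raise ValueError(
                f"division of cell {cid} produced invalid daughter {did}; "
                f"ring={tissue.cells[did].boundary}")
    a1, a2 = tissue.cell_area(d1), tissue.cell_area(d2)
    if abs(a1 + a2 - area_parent) > 1e-9 * max(1.0, abs(area_parent)):
        raise ValueError(f"area not conserved splitting cell {cid}")
    tissue.invalidate()
    return (d1, d2), tuple(wall_vids), dirty


def divide_cell(tissue: Tissue, cid: int, params: ScenarioParams):
    """Divide a cell along the shorter of the polarity-parallel and
    polarity-perpendicular chords through its centroid (tie: perpendicular).

    Returns ((d1, d2), wall_vids, dirty, orientation_dir).
    """
    cell = tissue.cells[cid]
    if cell.polarity is None:
        raise ValueError(f"cell {cid} has no polarity")
    pts = tissue.ring_coords(cid)
    c = tissue.cell_centroid(cid)
    pol = cell.polarity

    def chord_len(dirv):
        ch = chord_through(pts, c, dirv)
        if ch is None:
            return math.inf, None
        (k0, i0, f0, u0), (k1, i1, f1, u1) = ch
        return u1 - u0, ch

    len_par, _ = chord_len(pol)
    len_perp, _ = chord_len(_perp(pol))
    # tie breaks to the perpendicular wall
    dirv = _perp(pol) if len_perp <= len_par else pol
    daughters, wall, dirty = split_cell(tissue, cid, c, dirv)
    return daughters, wall, dirty, dirv


def apical_divide(tissue: Tissue, params: ScenarioParams):
    """Oblique apical-cell division cutting off the next merophyte.

    The wall lies at +/- apical_angle to the cell's polarity axis, the sign
    alternating left/right across successive divisions.  Its position along
    the polarity axis is chosen (by bisection) so the proximal daughter
    takes apical_daughter_frac of the parent area.  The distal daughter
    keeps the apical identity; the proximal one becomes the next merophyte.
    """
    cid = tissue.apical_cell_id
    cell = tissue.cells[cid]
    pol = cell.polarity if cell.polarity is not None else np.array([0.0, 1.0])
    theta = math.radians(params.apical_angle_deg)
    sign = 1.0 if tissue.apical_division_side == "left" else -1.0
    ca, sa = math.cos(sign * theta), math.sin(sign * theta)
    wall_dir = np.array([ca * pol[0] - sa * pol[1], sa * pol[0] + ca * pol[1]])

    pts = tissue.ring_coords(cid)
    c = tissue.cell_centroid(cid)
    poly = Polygon(pts)
    proj = (pts - c) @ pol
    lo, hi = float(proj.min()), float(proj.max())
    span = hi - lo
    diam = float(np.abs(pts - c).max()) * 4 + span

    def proximal_frac(offset):
        p0 = c + offset * pol
        line = LineString([p0 - diam * wall_dir, p0 + diam * wall_dir])
        parts = shapely_split(poly, line)
        if len(parts.geoms) < 2:
            return None
        prox = sum(g.area for g in parts.geoms
                   if (np.array(g.centroid.coords[0]) - p0) @ pol < 0)
        return prox / poly.area

    a, b = lo + 1e-3 * span, hi - 1e-3 * span
    target = params.apical_daughter_frac
    fa = proximal_frac(a)
    fb = proximal_frac(b)
    offset = None
    if fa is not None and fb is not None:
        xa, xb = a, b
        for _ in range(60):
            xm = 0.5 * (xa + xb)
            fm = proximal_frac(xm)
            if fm is None:
                break
            if fm < target:
                xa = xm
            else:
                xb = xm
        offset = 0.5 * (xa + xb)
    if offset is None:
        offset = 0.0
    daughters, wall, dirty = split_cell(tissue, cid, c + offset * pol, wall_dir)
    d1, d2 = daughters
    proj1 = (tissue.cell_centroid(d1) - c) @ pol
    proj2 = (tissue.cell_centroid(d2) - c) @ pol
    distal, proximal = (d1, d2) if proj1 >= proj2 else (d2, d1)
    # sanity: the apex must sit in the distal daughter
    apex_old = pts[np.argmax(proj)]
    distal_pts = tissue.ring_coords(distal)
    if not Polygon(distal_pts).buffer(1e-6).contains(Point(apex_old)):
        raise ValueError("apical division left the apex outside the distal "
                         "daughter")
    tissue.apical_cell_id = distal
    tissue.cells[distal].tissue_type = "apical"
    tissue.cells[distal].merophyte_id = 0
    mero = tissue.next_merophyte_id
    tissue.next_merophyte_id += 1
    tissue.cells[proximal].tissue_type = "blade"
    tissue.cells[proximal].merophyte_id = mero
    tissue.apical_division_side = (
        "right" if tissue.apical_division_side == "left" else "left")
    return daughters, wall, dirty, wall_dir, mero, pol


# ------------------------------------------------------------------- step

def step(tissue: Tissue, params: ScenarioParams, dt: float | None = None,
         material: mechanics.Material | None = None, events: list | None = None):
    """Advance the tissue by one growth/mechanics/division step.

    Sub-steps in order: phase update; distance and polarity fields; zone
    update; midrib (once, when due); growth-rate assignment; specified
    growth of rest shapes; elastic equilibrium; residual-stress release;
    apical division when scheduled; threshold divisions (ascending cell id,
    at most one per cell per step); retriangulation of all cells whose rings
    changed.  With dt = 0 only the label updates run and the state is left
    geometrically unchanged.
    """
    if dt is None:
        dt = params.dt_days
    if material is None:
        material = mechanics.Material(params.material_E_MPa, params.material_nu)
    if events is None:
        events = []
    t = tissue.time
    tissue.phase = phase_of(t, params)
    dist_base = tissue.distance_field(base_cells(tissue), "cell-count")
    pol = tissue.polarity_field()
    for cid, p in pol.items():
        tissue.cells[cid].polarity = p
    update_zones(tissue, t, params, dist_base)
    assign_midrib(tissue, t, params, dist_base)
    assign_growth_rates(tissue, t, params, dist_base)
    if dt == 0:
        return events
    mechanics.apply_growth(tissue, dt)
    mechanics.solve_equilibrium(tissue, material, tol=params.solver_tol,
                                max_iter=params.solver_max_iter)
    mechanics.release_residual_stress(tissue)
    tissue.time = t + dt
    now = tissue.time

    dirty = set()
    # --- apical division schedule
    n_apical_done = tissue.next_merophyte_id - 3
    while True:
        due = params.t0_days + params.apical_period_days * (n_apical_done + 1)
        if due > now + 1e-9 or due > params.t_phase23 - 1e-9:
            break
        daughters, wall, d, wall_dir, mero, pol_ax = apical_divide(tissue, params)
        dirty.update(d)
        dirty.update(daughters)
        wa = tissue.vertices[wall[0]].pos
        wb = tissue.vertices[wall[1]].pos
        events.append(DivisionEvent(
            now, -1, daughters[0], daughters[1], tuple(wa), tuple(wb),
            classify_wall_orientation(wb - wa, pol_ax), True,
            _angle_deg(wb - wa, pol_ax), mero))
        n_apical_done += 1

    # --- threshold divisions
    for cid in sorted(tissue.cells):
        cell = tissue.cells.get(cid)
        if cell is None or cell.zone != "proliferative":
            continue
        if cell.tissue_type == "attachment" or cid == tissue.apical_cell_id:
            continue
        if tissue.cell_area(cid) < cell.area_threshold:
            continue
        daughters, wall, d, dirv = divide_cell(tissue, cid, params)
        dirty.update(d)
        dirty.update(daughters)
        wa = tissue.vertices[wall[0]].pos
        wb = tissue.vertices[wall[1]].pos
        axis = tissue.cells[daughters[0]].polarity
        events.append(DivisionEvent(
            now, cid, daughters[0], daughters[1], tuple(wa), tuple(wb),
            classify_wall_orientation(wb - wa, axis), False,
            _angle_deg(wb - wa, axis), tissue.cells[daughters[0]].merophyte_id))

    retriangulate(tissue, [c for c in dirty if c in tissue.cells])
    return events


def _angle_deg(wall_vec, axis_vec) -> float:
    na = np.linalg.norm(wall_vec)
    nb = np.linalg.norm(axis_vec)
    cosang = abs(float(np.dot(wall_vec, axis_vec))) / (na * nb)
    return math.degrees(math.acos(min(1.0, cosang)))


# --------------------------------------------------------------- simulate

def simulate(scenario: str | None = None, params: ScenarioParams | None = None,
             template: Tissue | None = None, t_end: float | None = None,
             progress: bool = False) -> Trajectory:
    """Run a full scenario simulation and return its Trajectory.

    Snapshots are taken every params.output_cadence_days (matching the
    imaging cadence).  Deterministic: identical inputs give bit-identical
    trajectories.
    """
    if params is None:
        params = ScenarioParams.for_scenario(scenario or "wt_upper")
    if template is None:
        from .fixtures import TemplateSpec, make_template
        template = make_template(TemplateSpec())
    if t_end is None:
        t_end = params.t_end_days
    material = mechanics.Material(params.material_E_MPa, params.material_nu)
    tissue = template.copy()
    tissue.time = params.t0_days
    if not tissue.elements:
        retriangulate(tissue, sorted(tissue.cells))
    traj = Trajectory(params=params)
    traj.snapshots.append(Snapshot(tissue.time, tissue.copy()))
    n_steps = int(round((t_end - params.t0_days) / params.dt_days))
    cadence_steps = max(1, int(round(params.output_cadence_days
                                     / params.dt_days)))
    events: list = []
    for k in range(1, n_steps + 1):
        step(tissue, params, params.dt_days, material, events)
        if k % cadence_steps == 0 or k == n_steps:
            traj.snapshots.append(Snapshot(tissue.time, tissue.copy()))
        if progress:
            print(f"t={tissue.time:.2f} cells={len(tissue.cells)}")
    traj.events = events
    return traj
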