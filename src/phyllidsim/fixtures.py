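"""Synthetic input generators: day-1 primordium templates and
time-lapse-like lineage fixtures with known ground truth.

The template emulates a young primordium flattened into 2D: a basal
attachment region (two rows of cells, the first two clonal sectors), topped
by the apical cell whose polygon tapers to the apex.  The lineage fixtures
emulate segmented time-lapse data: a conforming tissue deformed by a known
global growth map (so per-cell growth rates are known exactly), with
optional scheduled divisions and junction-position noise, for parameter
recovery tests of the quantification pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tissue import (CONSTRAINT_FIXED, CONSTRAINT_LONGITUDINAL, Tissue,
                     retriangulate)


@dataclass
class TemplateSpec:
    """Geometry of the synthetic day-1 template (lengths in µm)."""

    basal_width: float = 80.0
    n_cols: int = 5
    attach_row_height: float = 6.0
    n_attach_rows: int = 2
    apex_height: float = 60.0         # y of the apex point
    shoulder_frac: float = 0.4        # half-width fraction at the shoulder
    shoulder_height: float = 44.0     # y of the shoulder points
    jitter_sigma: float = 0.0
    seed: int = 0


@dataclass
class FixtureSpec:
    """Ground-truth growth fixture: grid tissue + known growth field."""

    n_cols: int = 4
    n_rows: int = 5
    cell_w: float = 10.0
    cell_h: float = 10.0
    # growth field: k_par(y) = k_par_base + k_par_slope * y_norm, k_per const
    k_par_base: float = 0.1
    k_par_slope: float = 0.0
    k_per: float = 0.05
    dt: float = 0.5
    n_intervals: int = 1
    junction_noise_sigma: float = 0.0
    divisions: tuple = ()   # (interval_index, cell_id) pairs
    seed: int = 0


def make_template(spec: TemplateSpec | None = None, seed: int | None = None) -> Tissue:
    """Build the initial primordium tissue from a template spec.

    Deterministic per seed.  Bottom-row vertices are base vertices with the
    longitudinal Dirichlet constraint; the lowest-id base vertex is the
    fully fixed rigid-mode anchor.  The two attachment rows carry merophyte
    ids 1 and 2; the apical cell sits on top with merophyte id 0.
    """
    spec = spec or TemplateSpec()
    if seed is not None:
        spec = TemplateSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    for attempt in range(8):
        sigma = spec.jitter_sigma / (2 ** attempt)
        t = _build_template(spec, rng, sigma)
        try:
            t.validate()
            return t
        except Exception:
            continue
    raise RuntimeError("could not build a valid template; jitter too large")


def _build_template(spec: TemplateSpec, rng, sigma) -> Tissue:
    t = Tissue()
    nx = spec.n_cols
    w = spec.basal_width
    xs = np.linspace(-w / 2, w / 2, nx + 1)
    n_rows = spec.n_attach_rows
    ys = [i * spec.attach_row_height for i in range(n_rows + 1)]

    grid = {}
    for r, y in enumerate(ys):
        for c, x in enumerate(xs):
            pos = np.array([x, y], float)
            if sigma > 0 and 0 < c < nx and r > 0:
                pos = pos + rng.normal(0.0, sigma, 2)
            is_base = r == 0
            constraint = CONSTRAINT_LONGITUDINAL if is_base else 0
            grid[(r, c)] = t.new_vertex(pos, is_base=is_base,
                                        constraint=constraint)
    # rigid-mode anchor: lowest-id base vertex
    t.vertices[grid[(0, 0)]].constraint = CONSTRAINT_FIXED

    for r in range(n_rows):
        for c in range(nx):
            ring = [grid[(r, c)], grid[(r, c + 1)],
                    grid[(r + 1, c + 1)], grid[(r + 1, c)]]
            t.new_cell(ring, merophyte_id=r + 1, tissue_type="attachment",
                       zone="attachment")
    # apical cell: full top row of the attachment, shoulders, apex
    top = ys[-1]
    sh_y = max(spec.shoulder_height, top + 1.0)
    shoulder_r = t.new_vertex([w / 2 * spec.shoulder_frac, sh_y])
    apex = t.new_vertex([0.0, spec.apex_height])
    shoulder_l = t.new_vertex([-w / 2 * spec.shoulder_frac, sh_y])
    ring = [grid[(n_rows, c)] for c in range(nx + 1)]  # left -> right on top
    ring += [shoulder_r, apex, shoulder_l]
    apical = t.new_cell(ring, merophyte_id=0, tissue_type="apical",
                        zone="proliferative")
    t.apical_cell_id = apical
    t.next_merophyte_id = 3
    t.time = 1.0
    retriangulate(t, sorted(t.cells))
    return t


# --------------------------------------------------------------- fixtures

def _grid_tissue(spec: FixtureSpec) -> Tissue:
    """Conforming rectangular grid tissue; bottom row labeled attachment."""
    t = Tissue()
    grid = {}
    for r in range(spec.n_rows + 1):
        for c in range(spec.n_cols + 1):
            pos = np.array([c * spec.cell_w, r * spec.cell_h])
            is_base = r == 0
            grid[(r, c)] = t.new_vertex(
                pos, is_base=is_base,
                constraint=CONSTRAINT_LONGITUDINAL if is_base else 0)
    t.vertices[grid[(0, 0)]].constraint = CONSTRAINT_FIXED
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            ring = [grid[(r, c)], grid[(r, c + 1)],
                    grid[(r + 1, c + 1)], grid[(r + 1, c)]]
            t.new_cell(ring, merophyte_id=1,
                       tissue_type="attachment" if r == 0 else "blade",
                       zone="attachment" if r == 0 else "proliferative")
    return t


@dataclass
class LineageFixture:
    """Snapshots + lineage + stored ground truth for recovery tests."""

    snapshots: list            # (time, Tissue) pairs
    lineage: list              # (child, parent)
    truth: list                # per-interval dict cell -> (k_par, k_per)
    spec: FixtureSpec


def make_lineage_fixture(spec: FixtureSpec | None = None,
                         seed: int | None = None) -> LineageFixture:
    """Generate consecutive time-point tissues with known growth.

    The whole tissue is deformed by the map
        x' = x * exp(k_per * dt),  y' = psi(y)
    with psi'(y) = exp(k_par(y) * dt) and k_par linear in the normalized
    initial height, so the per-cell ground-truth rates are the field values
    at the cell centroid.  Scheduled divisions split the named cells along
    a mediolateral wall.  Junction noise perturbs vertex positions of the
    later snapshots only.
    """
    from .morphogenesis import split_cell

    spec = spec or FixtureSpec()
    if seed is not None:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    t = _grid_tissue(spec)
    height0 = spec.n_rows * spec.cell_h
    # material (initial) coordinates of every vertex
    mat = {v: t.vertices[v].pos.copy() for v in t.vertices}

    def k_par_at(y0):
        return spec.k_par_base + spec.k_par_slope * (y0 / height0)

    def psi(y0, n):
        # integral of exp(k_par(u) * dt * n) du from 0 to y0
        a = spec.k_par_base * spec.dt * n
        b = spec.k_par_slope * spec.dt * n / height0
        if abs(b) < 1e-15:
            return y0 * math.exp(a)
        return (math.exp(a + b * y0) - math.exp(a)) / b

    snapshots = [(0.0, t.copy())]
    truth = []
    current = t
    for k in range(1, spec.n_intervals + 1):
        time = k * spec.dt
        tissue = current.copy()
        # ground truth at interval start: field value at the cell centroid's
        # material height
        interval_truth = {}
        for cid in tissue.cells:
            cy = tissue.cell_centroid(cid)[1]
            y0 = _invert_psi(cy, lambda y: psi(y, k - 1), height0 * 4)
            interval_truth[cid] = (k_par_at(y0), spec.k_per)
        sx = math.exp(spec.k_per * spec.dt * k)
        for vid, v in tissue.vertices.items():
            m = mat[vid]
            v.pos = np.array([m[0] * sx, psi(m[1], k)])
        for (interval, cid) in spec.divisions:
            if interval == k and cid in tissue.cells:
                c = tissue.cell_centroid(cid)
                split_cell(tissue, cid, c, np.array([1.0, 0.0]))
        # register material coordinates of any vertices the splits created
        sx_now = sx
        for vid, v in tissue.vertices.items():
            if vid not in mat:
                y0 = _invert_psi(v.pos[1], lambda y: psi(y, k), height0 * 4)
                mat[vid] = np.array([v.pos[0] / sx_now, y0])
        if spec.junction_noise_sigma > 0:
            for v in tissue.vertices.values():
                v.pos = v.pos + rng.normal(0, spec.junction_noise_sigma, 2)
        snapshots.append((time, tissue))
        truth.append(interval_truth)
        current = tissue
    lineage = list(snapshots[-1][1].lineage)
    return LineageFixture(snapshots, lineage, truth, spec)


def _invert_psi(target, fn, hi):
    lo = 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if fn(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
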