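"""Cellular quantification of time-lapse lineage data.

Applies the same derived quantities to simulator output and to synthetic
time-lapse fixtures: per-interval area expansion and division counts, new
wall orientation classes, growth tensors from matched cell junctions
(principal directions of growth via a polar decomposition of a
least-squares affine fit), distances from the organ base and ten-bin
median/interquartile profiles along the normalized base-to-tip axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import polar

from .tissue import Tissue


# ------------------------------------------------------------ scalar rules

def area_expansion(parent_area: float, daughter_areas) -> float:
    """Relative area increase (%) from a parent cell to its daughters:
    ((sum of daughter areas / parent area) - 1) * 100."""
    daughters = list(daughter_areas)
    if not daughters:
        raise ValueError("empty daughter set")
    if parent_area <= 0:
        raise ValueError("parent area must be positive")
    return (sum(daughters) / parent_area - 1.0) * 100.0


def division_count(children) -> int:
    """Number of divisions in an interval: number of daughters minus one."""
    n = len(list(children))
    if n < 1:
        raise ValueError("a parent must have at least one child")
    return n - 1


def classify_wall_orientation(wall_vec, axis_vec) -> str:
    """Classify a new wall as longitudinal (< 45 deg to the local
    longitudinal axis) or mediolateral (>= 45 deg; the boundary case is
    mediolateral)."""
    wall_vec = np.asarray(wall_vec, float)
    axis_vec = np.asarray(axis_vec, float)
    nw, na = np.linalg.norm(wall_vec), np.linalg.norm(axis_vec)
    if nw == 0:
        raise ValueError("zero-length wall")
    if na == 0:
        raise ValueError("zero-length axis")
    cosang = abs(float(np.dot(wall_vec, axis_vec))) / (nw * na)
    angle = math.degrees(math.acos(min(1.0, cosang)))
    return "longitudinal" if angle < 45.0 else "mediolateral"


# --------------------------------------------------------------- distances

def distance_profiles(tissue: Tissue, base_cell_ids=None) -> pd.DataFrame:
    """Per-cell absolute and normalized distance from the organ base.

    Euclidean-wall-weight shortest-path distances from the labeled base
    cells, normalized by the maximum distance at this time point; bin is
    ceil(10 * normalized) clamped to [1, 10].
    """
    if base_cell_ids is None:
        base_cell_ids = [c.id for c in tissue.cells.values()
                         if c.tissue_type == "attachment"]
    field = tissue.distance_field(base_cell_ids, "euclidean-wall-weight")
    d = pd.Series(field.values, name="distance").sort_index()
    dmax = d[np.isfinite(d)].max()
    if not dmax > 0:
        raise ValueError("maximum distance from base is zero")
    norm = d / dmax
    bins = np.clip(np.ceil(norm * 10).astype(int), 1, 10)
    return pd.DataFrame({"cell": d.index, "distance": d.values,
                         "normalized_distance": norm.values,
                         "bin": bins.values}).set_index("cell")


# ------------------------------------------------------------ growth tensor

@dataclass
class GrowthTensor:
    k_max: float
    k_min: float
    k_par: float
    k_per: float
    anisotropy: float
    dir_max: np.ndarray


def growth_tensor(points_t0: np.ndarray, points_t1: np.ndarray, dt: float,
                  axis=(0.0, 1.0)) -> GrowthTensor:
    """Principal growth rates from matched junction points of one cell.

    Fits the least-squares affine map F x + b taking the junctions at the
    earlier time to the later one, extracts the symmetric stretch U from the
    polar decomposition F = R U, and reports log-stretch rates per day:
    k = ln(lambda)/dt for the principal stretches and for the projections of
    U onto the supplied axis (k_par) and its normal (k_per).  Anisotropy is
    (l1 - l2)/(l1 + l2), bounded in [0, 1).
    """
    P = np.asarray(points_t0, float)
    Q = np.asarray(points_t1, float)
    if P.shape != Q.shape or len(P) < 3:
        raise ValueError("need >= 3 matched junctions")
    A = np.column_stack([P, np.ones(len(P))])
    sol, _, rank, _ = np.linalg.lstsq(A, Q, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient junction set (collinear junctions)")
    F = sol[:2].T  # so that Q ~ (F @ P.T).T + b
    _R, U = polar(F, side="right")
    lams, vecs = np.linalg.eigh(U)
    l1, l2 = float(lams[1]), float(lams[0])
    if l2 <= 0:
        raise ValueError("degenerate (non-positive) stretch")
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    n = np.array([-a[1], a[0]])
    lam_par = float(a @ U @ a)
    lam_per = float(n @ U @ n)
    return GrowthTensor(
        k_max=math.log(l1) / dt, k_min=math.log(l2) / dt,
        k_par=math.log(lam_par) / dt, k_per=math.log(lam_per) / dt,
        anisotropy=(l1 - l2) / (l1 + l2), dir_max=vecs[:, 1])


# ------------------------------------------------------- merophyte fractions

def merophyte_contribution(tissue: Tissue) -> pd.Series:
    """Area fraction of each merophyte (clonal sector) in a snapshot.

    The apical lineage (merophyte id 0) is included so fractions sum to 1.
    """
    areas: dict[int, float] = {}
    for cell in tissue.cells.values():
        areas[cell.merophyte_id] = (areas.get(cell.merophyte_id, 0.0)
                                    + tissue.cell_area(cell.id))
    s = pd.Series(areas).sort_index()
    return s / s.sum()


# ------------------------------------------------------------ binned stats

def binned_profile(records: pd.DataFrame, value_field: str,
                   bin_field: str = "bin") -> pd.DataFrame:
    """Median and interquartile range of a value in the ten distance bins.

    Returns a frame indexed by bin 1..10 with columns median/q1/q3/n;
    empty bins are reported as missing (NaN).
    """
    out = pd.DataFrame(index=pd.RangeIndex(1, 11, name="bin"),
                       columns=["median", "q1", "q3", "n"], dtype=float)
    grouped = records.dropna(subset=[value_field]).groupby(bin_field)[value_field]
    for b, vals in grouped:
        out.loc[b, "median"] = vals.median()
        out.loc[b, "q1"] = vals.quantile(0.25)
        out.loc[b, "q3"] = vals.quantile(0.75)
        out.loc[b, "n"] = len(vals)
    return out


# ------------------------------------------------------- trajectory records

def _ancestor_map(parent_map: dict, ids_now, ids_prev: set) -> dict:
    """Map each current cell id to its ancestor present at the previous
    snapshot (walking parent links through intermediate divisions)."""
    out = {}
    for cid in ids_now:
        a = cid
        while a not in ids_prev:
            if a not in parent_map:
                a = None
                break
            a = parent_map[a]
        if a is not None:
            out[cid] = a
    return out


def growth_records(snapshots, lineage, axis_from_polarity=True) -> pd.DataFrame:
    """Per-parent-cell, per-interval derived quantities for a trajectory.

    snapshots: iterable of (time, Tissue); lineage: (child, parent) pairs.
    For each consecutive snapshot pair and each cell of the earlier one:
    area expansion %, number of divisions, growth-tensor rates from the
    ring vertices that persist across the interval (identified by vertex
    id), distance from base (Euclidean wall weights), normalized distance
    and ten-bin index at the earlier time point.
    """
    snaps = list(snapshots)
    parent_map = dict((c, p) for c, p in lineage)
    rows = []
    for (t0, tis0), (t1, tis1) in zip(snaps[:-1], snaps[1:]):
        dt = t1 - t0
        prev_ids = set(tis0.cells)
        anc = _ancestor_map(parent_map, tis1.cells, prev_ids)
        children: dict[int, list[int]] = {}
        for cid in tis1.cells:
            a = anc.get(cid)
            if a is not None:
                children.setdefault(a, []).append(cid)
        prof = distance_profiles(tis0)
        # local longitudinal axis: polarity where defined, else organ axis
        pol = (tis0.polarity_field()
               if axis_from_polarity and tis0.apical_cell_id is not None
               else None)
        for pid, kids in sorted(children.items()):
            pa = tis0.cell_area(pid)
            da = [tis1.cell_area(k) for k in kids]
            # junction correspondences: ring vertices of the parent that
            # still exist (same id) at the later time point
            ring0 = tis0.cells[pid].boundary
            shared = [v for v in ring0 if v in tis1.vertices]
            k_par = k_per = aniso = np.nan
            if len(shared) >= 3:
                P = np.array([tis0.vertices[v].pos for v in shared])
                Q = np.array([tis1.vertices[v].pos for v in shared])
                axis = pol[pid] if pol is not None else np.array([0.0, 1.0])
                try:
                    gt = growth_tensor(P, Q, dt, axis)
                    k_par, k_per, aniso = gt.k_par, gt.k_per, gt.anisotropy
                except ValueError:
                    pass
            rows.append({
                "t0": t0, "t1": t1, "cell": pid,
                "merophyte": tis0.cells[pid].merophyte_id,
                "area_expansion_pct": area_expansion(pa, da),
                "n_divisions": division_count(kids),
                "k_par": k_par, "k_per": k_per, "anisotropy": aniso,
                "distance": prof.loc[pid, "distance"],
                "normalized_distance": prof.loc[pid, "normalized_distance"],
                "bin": int(prof.loc[pid, "bin"]),
            })
    return pd.DataFrame(rows)


def merophyte_contribution_curve(snapshots) -> pd.DataFrame:
    """Merophyte area fractions at every snapshot (long format)."""
    rows = []
    for t, tis in snapshots:
        frac = merophyte_contribution(tis)
        for mero, f in frac.items():
            rows.append({"time": t, "merophyte": int(mero), "fraction": f})
    return pd.DataFrame(rows)
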